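"""Downstream validation: gene-set over-representation, FPKM→TPM conversion,
bulk-cohort Pearson confirmation of predicted edges, and median-split
Kaplan–Meier / log-rank survival analysis.

These are the computations used to check a ranked candidate list against an
independent bulk cohort: are the candidate's related genes enriched in known
gene sets (hypergeometric ORA over a GMT collection), do the predicted
co-expression edges replicate in the cohort (Pearson with the same r/p
thresholds), and does expression of the candidate stratify survival
(median split, two-group log-rank test)?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .coexpression import ZeroVarianceError, pearson_with_p
from .sc_deg import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "ora",
    "fpkm_to_tpm",
    "EdgeConfirmation",
    "confirm_edges",
    "SurvivalData",
    "read_survival",
    "km_logrank",
]


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, members per tab-separated
    line. Descriptions are discarded and duplicate members uniquified."""
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT lines need >= 3 fields")
            name = parts[0]
            members = {m for m in parts[2:] if m}
            if name in collection:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            collection[name] = members
    if not collection:
        logger.warning("read_gmt(%s): empty collection", path)
    return collection


def ora(query, collection: dict[str, set[str]], universe) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    For a set S: overlap k = |query ∩ S ∩ universe|; upper-tail
    p = P(X >= k) with population |universe|, |S ∩ universe| successes and
    |query| draws; BH adjustment across sets. Query genes outside the
    universe are dropped with a warning.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty universe")
    outside = query - universe
    if outside:
        logger.warning("ora: %d query genes outside the universe dropped: %s",
                       len(outside), sorted(outside)[:5])
        query &= universe
    if not query:
        raise ValueError("empty query (after restriction to the universe)")

    M, N = len(universe), len(query)
    rows = []
    for name in sorted(collection):
        s_in = collection[name] & universe
        k = len(query & s_in)
        n = len(s_in)
        # P(X >= k) = hypergeom.sf(k-1)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if k > 0 else 1.0
        expected = N * n / M
        rows.append({"set": name, "overlap": k, "set_size": n, "expected": expected, "p": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["p", "set"]).reset_index(drop=True)


def fpkm_to_tpm(fpkm: pd.DataFrame) -> pd.DataFrame:
    """TPM = FPKM / FPKMsum * 1e6, per sample column (genes x samples).

    Every output column sums to 1e6; an all-zero sample is an error.
    """
    if (fpkm.values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    sums = fpkm.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise ValueError(f"all-zero samples cannot be converted: {zero[:5]}")
    return fpkm.div(sums, axis=1) * 1e6


@dataclass(frozen=True)
class EdgeConfirmation:
    """Bulk-cohort Pearson check of one predicted anchor-partner edge."""

    anchor: str
    partner: str
    r: float | None
    p: float | None
    confirmed: bool
    testable: bool = True


def confirm_edges(
    anchor: str,
    partners,
    bulk_expr: pd.DataFrame,
    r_min: float = 0.5,
    p_max: float = 0.05,
    *,
    untestable: str = "unconfirmed",
) -> tuple[list[EdgeConfirmation], str]:
    """Pearson-confirm predicted anchor-partner edges in a bulk cohort
    (genes x samples). Returns the per-edge records and a summary line
    "k of n ... confirmed (r > r_min, p < p_max)".

    Partners absent from the cohort (or with zero variance) are untestable;
    by default they count in n as unconfirmed (``untestable="exclude"``
    drops them from n instead).
    """
    if untestable not in ("unconfirmed", "exclude"):
        raise ValueError("untestable must be 'unconfirmed' or 'exclude'")
    if anchor not in bulk_expr.index:
        raise KeyError(f"anchor gene {anchor!r} not in bulk matrix")
    if bulk_expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    xa = bulk_expr.loc[anchor].to_numpy(dtype=float)
    out: list[EdgeConfirmation] = []
    for g in partners:
        if g == anchor:
            out.append(EdgeConfirmation(anchor, g, 1.0, 0.0, True))
            continue
        if g not in bulk_expr.index:
            out.append(EdgeConfirmation(anchor, g, None, None, False, testable=False))
            continue
        try:
            r, p, _n = pearson_with_p(xa, bulk_expr.loc[g].to_numpy(dtype=float))
        except ZeroVarianceError:
            out.append(EdgeConfirmation(anchor, g, None, None, False, testable=False))
            continue
        out.append(EdgeConfirmation(anchor, g, r, p, bool(r > r_min and p < p_max)))
    if untestable == "exclude":
        counted = [e for e in out if e.testable]
    else:
        counted = out
    k = sum(e.confirmed for e in counted)
    n = len(counted)
    summary = f"{k} of {n} edges confirmed (r > {r_min:g}, p < {p_max:g})"
    return out, summary


@dataclass
class SurvivalData:
    """Per-sample follow-up: non-negative time, binary event (1 = event)."""

    time: pd.Series
    event: pd.Series

    def __post_init__(self):
        if (self.time < 0).any():
            raise ValueError("survival times must be non-negative")
        if not self.event.isin([0, 1]).all():
            raise ValueError("event indicators must be 0 or 1")

    @property
    def samples(self) -> list[str]:
        return list(self.time.index)


def read_survival(path) -> SurvivalData:
    """Three-column TSV (sample, time, event), with or without a header."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.columns[0].lower() not in ("sample", "id", "sample_id"):
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["sample", "time", "event"] + list(df.columns[3:])
    time = pd.to_numeric(df["time"]).set_axis(df["sample"].astype(str))
    event = pd.to_numeric(df["event"]).astype(int).set_axis(df["sample"].astype(str))
    return SurvivalData(time, event)


def km_logrank(
    values: pd.Series,
    survival: SurvivalData,
    split: float = 0.5,
) -> dict:
    """Median-split Kaplan–Meier curves and two-group log-rank test.

    Samples with expression strictly above the split quantile (default the
    median) form the "high" group; at-or-below goes "low". Returns the
    chi-square statistic, its chi2(1) p-value, group sizes and the KM step
    functions per group. Requires >= 2 samples per group and >= 1 event.
    """
    common = values.index.intersection(survival.time.index)
    v = values.loc[common].astype(float)
    t = survival.time.loc[common].astype(float)
    e = survival.event.loc[common].astype(int)
    if e.sum() == 0:
        raise ValueError("no events in the survival data")
    cut = float(v.quantile(split))
    high = v > cut
    n_high, n_low = int(high.sum()), int((~high).sum())
    if min(n_high, n_low) < 2:
        raise ValueError(
            f"split leaves a group with < 2 samples (high={n_high}, low={n_low}); "
            "is the expression constant?"
        )
    res = logrank_test(t[high], t[~high], event_observed_A=e[high], event_observed_B=e[~high])
    curves = {}
    for label, mask in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=label)
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf[label].to_numpy()}
        )
    return {
        "chi_square": float(res.test_statistic),
        "p": float(res.p_value),
        "n_high": n_high,
        "n_low": n_low,
        "threshold": cut,
        "curves": curves,
    }
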