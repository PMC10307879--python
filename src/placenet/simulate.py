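"""Seeded synthetic fixtures with known ground truth.

The generators emulate the statistical structure the combinatory analysis
assumes: a sparse undirected interactome; a two-group (tumor T / normal N)
single-cell count matrix in which a planted key gene and its level-1/2/3
partners are differentially expressed and mutually co-expressed through one
shared latent factor; background genes with no such structure; mitochondrial
genes and a fraction of high-mitochondria cells so QC is exercisable; and a
matched bulk cohort with survival times whose hazard depends on key-gene
expression.

The planted component is wired as a tree rooted at the key gene — level-1
partners attach directly, level-2 partners through one intermediate, level-3
partners through a chain of two — and is kept disconnected from the random
background graph, so every planted shortest-path distance is exact by
construction and the manifest can predict the expected score of every gene
without re-simulation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .ppi import PPINetwork, level_profile
from .validation import SurvivalData, fpkm_to_tpm

__all__ = [
    "FixtureManifest",
    "simulate_ppi",
    "simulate_sc_expression",
    "simulate_bulk_and_survival",
    "make_fixture",
    "write_fixture",
]

# default study conditions: 200 genes, 500 cells, 100 bulk samples
DEFAULT_N_GENES = 200
DEFAULT_N_CELLS_PER_GROUP = 250
DEFAULT_N_BULK_SAMPLES = 100
DEFAULT_RHO = 0.9
DEFAULT_DE_MULTIPLIER = 3.0
DEFAULT_DROPOUT = 0.1
DEFAULT_HAZARD_BETA = 1.5
N_LEVEL_PARTNERS = (6, 5, 4)
N_MT_GENES = 5
HIGH_MT_FRACTION = 0.05


@dataclass
class FixtureManifest:
    """Ground truth of one simulated fixture.

    Sufficient to state the expected output of every pipeline stage:
    the planted key gene, its per-level partner lists, the pass-through
    intermediates, the planted DE genes, the planned high-mitochondria cells,
    and the expected retained-count score of every planted gene (computed
    from the planted graph under the construction guarantee that every
    planted pair is co-expressed and no background pair is).
    """

    seed: int
    key_gene: str
    level_partners: dict[int, list[str]]
    intermediates: list[str]
    de_genes: list[str]
    mt_genes: list[str]
    background_genes: list[str]
    high_mt_cells: list[str]
    rho: float
    de_multiplier: float
    dropout: float
    expected_scores: dict[str, tuple[int, int, int]]

    @property
    def planted_family(self) -> list[str]:
        return [self.key_gene] + [g for k in sorted(self.level_partners) for g in self.level_partners[k]]

    def to_json(self, path) -> None:
        d = asdict(self)
        d["level_partners"] = {str(k): v for k, v in self.level_partners.items()}
        d["expected_scores"] = {g: list(s) for g, s in self.expected_scores.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "FixtureManifest":
        with open(path) as fh:
            d = json.load(fh)
        d["level_partners"] = {int(k): v for k, v in d["level_partners"].items()}
        d["expected_scores"] = {g: tuple(s) for g, s in d["expected_scores"].items()}
        return cls(**d)


def simulate_ppi(n_genes: int, model: str = "erdos_renyi", params: dict | None = None,
                 seed: int = 0) -> PPINetwork:
    """Random background interactome with gene labels BG0001..BG{n}.

    Models: erdos_renyi (param p) or barabasi_albert (param m). The same seed
    always yields the identical edge set.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    params = dict(params or {})
    if model == "erdos_renyi":
        p = params.get("p", 0.05)
        if not 0 <= p <= 1:
            raise ValueError(f"edge probability {p} outside [0, 1]")
        g = nx.gnp_random_graph(n_genes, p, seed=seed)
    elif model == "barabasi_albert":
        m = params.get("m", 2)
        if m >= n_genes:
            raise ValueError(f"barabasi_albert m={m} requires m < n_genes={n_genes}")
        g = nx.barabasi_albert_graph(n_genes, m, seed=seed)
    else:
        raise ValueError(f"unknown model {model!r}")
    mapping = {i: f"BG{i + 1:04d}" for i in g.nodes}
    return PPINetwork(nx.relabel_nodes(g, mapping))


def _plant_key_component(net: PPINetwork, key_gene: str,
                         n_partners: tuple[int, int, int]) -> tuple[dict[int, list[str]], list[str]]:
    """Attach the planted tree: key—L1 partners directly; key—INTA—L2
    partners; key—INTB—INTC—L3 partners. Returns partner lists and the
    intermediate names."""
    k1, k2, k3 = n_partners
    g = net.graph
    l1 = [f"L1G{i + 1}" for i in range(k1)]
    l2 = [f"L2G{i + 1}" for i in range(k2)]
    l3 = [f"L3G{i + 1}" for i in range(k3)]
    for p in l1:
        g.add_edge(key_gene, p)
    g.add_edge(key_gene, "INTA")
    for p in l2:
        g.add_edge("INTA", p)
    g.add_edge(key_gene, "INTB")
    g.add_edge("INTB", "INTC")
    for p in l3:
        g.add_edge("INTC", p)
    return {1: l1, 2: l2, 3: l3}, ["INTA", "INTB", "INTC"]


def _expected_scores(net: PPINetwork, family: list[str], max_level: int = 3) -> dict[str, tuple[int, int, int]]:
    """Expected retained counts under the construction guarantee: the DEG
    universe is exactly the planted family and every family pair passes the
    co-expression filter."""
    fam = set(family)
    out = {}
    for g in family:
        prof = level_profile(net, g, max_level)
        out[g] = tuple(len(prof.level_sets[k] & fam - {g}) for k in range(1, max_level + 1))
    return out


def simulate_sc_expression(
    net: PPINetwork,
    key_gene: str,
    *,
    level_partners: dict[int, list[str]],
    intermediates: list[str] | None = None,
    n_cells_per_group: int = DEFAULT_N_CELLS_PER_GROUP,
    rho: float = DEFAULT_RHO,
    de_multiplier: float = DEFAULT_DE_MULTIPLIER,
    dropout: float = DEFAULT_DROPOUT,
    n_mt_genes: int = N_MT_GENES,
    high_mt_fraction: float = HIGH_MT_FRACTION,
    seed: int = 0,
) -> tuple[ExpressionMatrix, FixtureManifest]:
    """Raw single-cell counts with the planted co-expression / DE structure.

    Counts follow a negative-binomial-like scheme: Poisson draws around a
    log-normal rate. Planted-family genes share one per-cell latent Gaussian
    factor whose loading is set so the expected Pearson correlation of a
    planted pair on log-normalized values is about ``rho``; they also carry a
    ``de_multiplier``-fold mean shift in the tumor group, which puts their
    fold change far above the 0.25 log2FC calling threshold. Background genes
    are independent with no group effect; their base expression is set high
    relative to the planted family so the library-composition shift induced
    by the planted up-regulation stays well below the fold-change calling
    threshold. ``n_mt_genes`` MT-prefixed genes are added, and
    ``high_mt_fraction`` of cells get a strongly inflated mitochondrial load
    so the 20% QC cutoff removes them. Bernoulli dropout thins background
    counts (the planted family is exempt — its pairwise correlation is the
    controlled condition), and two all-zero genes exercise zero-variance
    handling. The same seed reproduces the identical matrix.
    """
    if key_gene not in net:
        raise ValueError(f"key gene {key_gene!r} must be in the PPI network")
    if not 0 < rho < 1:
        raise ValueError(f"rho={rho} outside (0, 1)")
    if not 0 <= dropout < 1:
        raise ValueError(f"dropout={dropout} outside [0, 1)")
    rng = np.random.default_rng(seed)

    family = [key_gene] + [g for k in sorted(level_partners) for g in level_partners[k]]
    inter = list(intermediates or [])
    background = sorted(net.nodes - set(family) - set(inter))
    mt_genes = [f"MT-SIM{i + 1}" for i in range(n_mt_genes)]
    silent = ["SILENT1", "SILENT2"]  # all-zero: stress zero-variance paths
    genes = family + inter + background + mt_genes + silent
    n_cells = 2 * n_cells_per_group
    cells = [f"C{i + 1:04d}" for i in range(n_cells)]
    groups = pd.Series(["T"] * n_cells_per_group + ["N"] * n_cells_per_group, index=cells)

    # shared latent factor across the planted family; loading sized against
    # the per-gene log-scale noise so corr ~ loading^2/(loading^2+sigma^2) = rho
    # (Poisson counting noise at the chosen base expression lowers realized r
    # slightly; it is checked, not assumed)
    sigma_g = 0.3
    loading = sigma_g * np.sqrt(rho / (1.0 - rho))
    z = rng.normal(size=n_cells)
    lib = rng.uniform(0.8, 1.2, size=n_cells)
    is_t = (groups == "T").to_numpy()

    log_rate = np.full((len(genes), n_cells), -np.inf)
    bg_mask = np.zeros(len(genes), dtype=bool)
    for i, g in enumerate(genes):
        if g in silent:
            continue
        if g in family:
            base = np.log(10.0) + rng.normal(0, 0.2)
            row = base + loading * z + rng.normal(0, sigma_g, size=n_cells)
            row = row + np.log(de_multiplier) * is_t
        elif g in inter:
            base = np.log(8.0) + rng.normal(0, 0.2)
            row = base + rng.normal(0, sigma_g, size=n_cells)
        elif g in mt_genes:
            base = np.log(100.0)
            row = base + rng.normal(0, sigma_g, size=n_cells)
        else:
            bg_mask[i] = True
            base = rng.normal(np.log(50.0), 0.8)
            row = base + rng.normal(0, sigma_g, size=n_cells)
        log_rate[i] = row + np.log(lib)

    n_high = max(1, int(round(high_mt_fraction * n_cells)))
    high_idx = rng.choice(n_cells, size=n_high, replace=False)
    mt_rows = [genes.index(g) for g in mt_genes]
    for r in mt_rows:
        log_rate[r, high_idx] += np.log(10.0)

    with np.errstate(over="ignore"):
        counts = rng.poisson(np.exp(log_rate)).astype(float)
    if dropout > 0:
        keep = rng.random((int(bg_mask.sum()), n_cells)) >= dropout
        counts[bg_mask] = counts[bg_mask] * keep

    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=cells), cell_groups=groups
    )
    manifest = FixtureManifest(
        seed=seed,
        key_gene=key_gene,
        level_partners={k: list(v) for k, v in level_partners.items()},
        intermediates=inter,
        de_genes=list(family) if de_multiplier > 1 else [],
        mt_genes=mt_genes,
        background_genes=background,
        high_mt_cells=[cells[i] for i in sorted(high_idx)],
        rho=rho,
        de_multiplier=de_multiplier,
        dropout=dropout,
        expected_scores=_expected_scores(net, family),
    )
    return expr, manifest


def make_fixture(
    seed: int = 0,
    *,
    n_genes: int = DEFAULT_N_GENES,
    n_cells_per_group: int = DEFAULT_N_CELLS_PER_GROUP,
    rho: float = DEFAULT_RHO,
    de_multiplier: float = DEFAULT_DE_MULTIPLIER,
    dropout: float = DEFAULT_DROPOUT,
    background_p: float = 0.05,
) -> tuple[PPINetwork, ExpressionMatrix, FixtureManifest]:
    """Full planted fixture: background interactome + planted key-gene tree +
    single-cell counts. ``n_genes`` counts the background genes; the planted
    family, intermediates and MT genes come on top."""
    key = "KEY1"
    n_background = n_genes - sum(N_LEVEL_PARTNERS) - 1 - 3 - N_MT_GENES
    if n_background < 10:
        raise ValueError(f"n_genes={n_genes} too small for the planted structure")
    net = simulate_ppi(n_background, "erdos_renyi", {"p": background_p}, seed=seed)
    partners, inter = _plant_key_component(net, key, N_LEVEL_PARTNERS)
    expr, manifest = simulate_sc_expression(
        net, key, level_partners=partners, intermediates=inter,
        n_cells_per_group=n_cells_per_group, rho=rho,
        de_multiplier=de_multiplier, dropout=dropout, seed=seed,
    )
    return net, expr, manifest


def simulate_bulk_and_survival(
    manifest: FixtureManifest,
    n_samples: int = DEFAULT_N_BULK_SAMPLES,
    hazard_beta: float = DEFAULT_HAZARD_BETA,
    seed: int = 0,
    *,
    censor_rate: float = 0.05,
) -> tuple[pd.DataFrame, SurvivalData]:
    """Matched bulk cohort (TPM, genes x samples) and survival table.

    The planted-family correlation structure carries over through a shared
    per-sample latent factor. Survival times are exponential with the hazard
    multiplied by exp(hazard_beta * standardized key-gene log-expression);
    censoring is independent exponential.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    rng = np.random.default_rng(seed)
    family = set(manifest.planted_family)
    genes = manifest.planted_family + manifest.intermediates + manifest.background_genes
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]

    sigma_g = 0.3
    loading = sigma_g * np.sqrt(manifest.rho / (1.0 - manifest.rho))
    z = rng.normal(size=n_samples)
    log_fpkm = np.empty((len(genes), n_samples))
    for i, g in enumerate(genes):
        if g in family:
            base = rng.normal(np.log(20.0), 0.2)
            log_fpkm[i] = base + loading * z + rng.normal(0, sigma_g, size=n_samples)
        else:
            base = rng.normal(np.log(5.0), 0.8)
            log_fpkm[i] = base + rng.normal(0, 0.5, size=n_samples)
    fpkm = pd.DataFrame(np.exp(log_fpkm), index=genes, columns=samples)
    tpm = fpkm_to_tpm(fpkm)

    x = np.log1p(tpm.loc[manifest.key_gene].to_numpy())
    x = (x - x.mean()) / x.std()
    base_hazard = 0.1
    rate = base_hazard * np.exp(hazard_beta * x)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.exponential(1.0 / censor_rate, size=n_samples)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    surv = SurvivalData(
        time=pd.Series(time, index=samples, name="time"),
        event=pd.Series(event, index=samples, name="event"),
    )
    return tpm, surv


def write_fixture(out_dir, seed: int = 0, **kwargs) -> FixtureManifest:
    """Write a complete fixture to disk: PPI edge TSV, MatrixMarket counts
    with gene/cell label TSVs, a group TSV, bulk TPM TSV, survival TSV, a
    small GMT collection and the manifest JSON."""
    import os

    import scipy.io
    import scipy.sparse

    from .ppi import write_ppi

    os.makedirs(out_dir, exist_ok=True)
    net, expr, manifest = make_fixture(seed, **kwargs)
    write_ppi(net, os.path.join(out_dir, "ppi.tsv"))
    m = scipy.sparse.coo_matrix(expr.values.to_numpy())
    scipy.io.mmwrite(os.path.join(out_dir, "counts.mtx"), m)
    with open(os.path.join(out_dir, "genes.tsv"), "w") as fh:
        fh.write("\n".join(expr.genes) + "\n")
    with open(os.path.join(out_dir, "cells.tsv"), "w") as fh:
        fh.write("\n".join(expr.cells) + "\n")
    expr.cell_groups.to_csv(os.path.join(out_dir, "groups.tsv"), sep="\t", header=False)
    tpm, surv = simulate_bulk_and_survival(manifest, seed=seed)
    tpm.to_csv(os.path.join(out_dir, "bulk_tpm.tsv"), sep="\t", index_label="gene")
    pd.DataFrame({"sample": surv.samples, "time": surv.time.values,
                  "event": surv.event.values}).to_csv(
        os.path.join(out_dir, "survival.tsv"), sep="\t", index=False)
    rng = np.random.default_rng(seed + 1)
    partners = [g for k in sorted(manifest.level_partners) for g in manifest.level_partners[k]]
    with open(os.path.join(out_dir, "sets.gmt"), "w") as fh:
        fh.write("PLANTED_FAMILY\tsynthetic\t" + "\t".join(partners) + "\n")
        for i in range(3):
            members = rng.choice(manifest.background_genes, size=20, replace=False)
            fh.write(f"RANDOM_SET_{i + 1}\tsynthetic\t" + "\t".join(members) + "\n")
    manifest.to_json(os.path.join(out_dir, "manifest.json"))
    return manifest
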