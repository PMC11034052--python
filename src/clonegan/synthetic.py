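"""Coupled synthetic scDNA-seq / scRNA-seq benchmark generator.

Generates a clone-structured integer copy-number matrix together with a
clone-linked gamma-Poisson UMI count matrix, so the whole pipeline can be
exercised without external data.  Clones form a linear phylogeny: each
child inherits its parent's copy-number segments and adds its own, giving
the shared-alteration structure real tumors show.  Expression follows the
standard gamma-Poisson simulation scheme: gamma-distributed baseline gene
means, per-clone differential expression with probability ``de_prob``,
log-normal library sizes, and an optional dosage term (CN/2)^gamma linking
genes inside a clone's altered segments to its copy number.

The default configuration is the package's reference benchmark: 3 clones
with fractions (0.82, 0.11, 0.07) over 260 DNA cells (echoing the
214/28/18 subclone split reported for a triple-negative breast-cancer
xenograft line), 2000 RNA cells, and bin/gene counts scaled so that
preprocessing yields ~1024 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import CNMatrix, ExprMatrix, write_expr_mtx, write_matrix_tsv


@dataclass
class SimConfig:
    n_clones: int = 3
    clone_fractions: tuple[float, ...] = (0.82, 0.11, 0.07)
    n_dna_cells: int = 260
    n_rna_cells: int = 2000
    n_bins: int = 1200
    n_genes: int = 1500
    n_cna_segments_per_clone: int = 8
    cn_states: tuple[int, ...] = (0, 1, 3, 4, 5)  # non-baseline states
    cn_noise_rate: float = 0.08
    de_prob: float = 0.3
    de_factor_sd: float = 0.4
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_size_mu: float = 9.7
    lib_size_sd: float = 0.25
    dosage_coupling: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("need at least one clone")
        if len(self.clone_fractions) != self.n_clones:
            raise ValueError("clone_fractions length must equal n_clones")
        if abs(sum(self.clone_fractions) - 1.0) > 1e-8:
            raise ValueError("clone_fractions must sum to 1")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValueError("de_prob must be in [0, 1]")
        if self.n_bins < self.n_cna_segments_per_clone:
            raise ValueError("n_bins must be >= n_cna_segments_per_clone")


@dataclass
class SimTruth:
    dna_labels: np.ndarray
    rna_labels: np.ndarray
    clone_cn_profiles: np.ndarray
    de_mask: np.ndarray          # n_clones x n_genes boolean
    de_factors: np.ndarray       # n_clones x n_genes multiplicative factors
    gene_bins: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def _rng_for(cfg: SimConfig, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(stream,))
    return np.random.Generator(np.random.PCG64(ss))


def _round_fractions(fractions: tuple[float, ...], n: int) -> np.ndarray:
    """Largest-remainder rounding of fractions * n to integers summing to n."""
    raw = np.asarray(fractions) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def simulate_clone_profiles(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Clone x bin integer copy-number profiles on a linear phylogeny.

    Every clone starts from the diploid baseline (2); each clone adds
    ``n_cna_segments_per_clone`` contiguous non-overlapping segments
    (1-5% of the bins long) with a non-baseline state, on top of the
    segments inherited from its parent.
    """
    profiles = np.full((cfg.n_clones, cfg.n_bins), 2, dtype=int)
    occupied = np.zeros(cfg.n_bins, dtype=bool)
    lo = max(1, int(0.01 * cfg.n_bins))
    hi = max(lo, int(0.05 * cfg.n_bins))
    for c in range(cfg.n_clones):
        if c > 0:
            profiles[c] = profiles[c - 1]  # inherit the parent's segments
        placed = 0
        attempts = 0
        length_hi = hi
        while placed < cfg.n_cna_segments_per_clone:
            attempts += 1
            if attempts > 200:
                if length_hi > 1:  # shrink segments until they fit
                    length_hi = max(1, length_hi // 2)
                    attempts = 0
                    continue
                raise RuntimeError(
                    "could not place CNA segments; too few free bins"
                )
            length = int(rng.integers(min(lo, length_hi), length_hi + 1))
            start = int(rng.integers(0, cfg.n_bins - length + 1))
            if occupied[start:start + length].any():
                continue
            state = int(rng.choice(cfg.cn_states))
            profiles[c, start:start + length] = state
            occupied[start:start + length] = True
            placed += 1
    return profiles


def simulate_cn_matrix(
    cfg: SimConfig, truth: SimTruth, rng: np.random.Generator
) -> CNMatrix:
    """Per-cell copy numbers: the clone profile with +/-1 jitter noise."""
    profiles = truth.clone_cn_profiles
    values = profiles[truth.dna_labels].astype(float)
    jitter_mask = rng.random(values.shape) < cfg.cn_noise_rate
    jitter = rng.choice([-1, 1], size=values.shape)
    values = np.where(jitter_mask, np.maximum(values + jitter, 0), values)
    return CNMatrix(
        values=values,
        cell_ids=[f"dna_cell_{i}" for i in range(values.shape[0])],
        bin_ids=[f"bin_{j}" for j in range(values.shape[1])],
    )


def simulate_expression(
    cfg: SimConfig, truth: SimTruth, rng: np.random.Generator
) -> ExprMatrix:
    """Gamma-Poisson UMI counts with clone-specific DE and dosage effects.

    Baseline gene means are Gamma(mean_shape, 1/mean_rate); per clone each
    gene is differentially expressed with probability ``de_prob`` (its mean
    multiplied by exp(N(0, de_factor_sd))); genes inside a clone's altered
    segments are additionally scaled by (CN/2)^dosage_coupling.  Counts are
    Poisson with cell-specific log-normal library sizes.
    """
    base_means = rng.gamma(cfg.mean_shape, 1.0 / cfg.mean_rate, size=cfg.n_genes)
    base_means = np.maximum(base_means, 1e-8)

    # clone-specific expected relative expression
    rates = np.tile(base_means, (cfg.n_clones, 1))
    rates = rates * truth.de_factors
    if cfg.dosage_coupling > 0 and truth.gene_bins.size:
        cn = truth.clone_cn_profiles[:, truth.gene_bins].astype(float)
        dosage = np.where(cn > 0, cn / 2.0, 0.05) ** cfg.dosage_coupling
        rates = rates * dosage
    rates = rates / rates.sum(axis=1, keepdims=True)

    lib_sizes = rng.lognormal(cfg.lib_size_mu, cfg.lib_size_sd, size=cfg.n_rna_cells)
    lam = lib_sizes[:, None] * rates[truth.rna_labels]
    counts = rng.poisson(lam)
    return ExprMatrix(
        counts=counts,
        cell_ids=[f"rna_cell_{i}" for i in range(cfg.n_rna_cells)],
        gene_ids=[f"gene_{g}" for g in range(cfg.n_genes)],
    )


def _make_truth(cfg: SimConfig) -> SimTruth:
    profile_rng = _rng_for(cfg, 0)
    de_rng = _rng_for(cfg, 1)
    profiles = simulate_clone_profiles(cfg, profile_rng)

    dna_counts = _round_fractions(cfg.clone_fractions, cfg.n_dna_cells)
    rna_counts = _round_fractions(cfg.clone_fractions, cfg.n_rna_cells)
    dna_labels = np.repeat(np.arange(cfg.n_clones), dna_counts)
    rna_labels = np.repeat(np.arange(cfg.n_clones), rna_counts)

    de_mask = de_rng.random((cfg.n_clones, cfg.n_genes)) < cfg.de_prob
    factors = np.exp(de_rng.normal(0.0, cfg.de_factor_sd,
                                   size=(cfg.n_clones, cfg.n_genes)))
    de_factors = np.where(de_mask, factors, 1.0)
    # genes placed evenly along the genome so CNA segments cover some genes
    gene_bins = np.linspace(0, cfg.n_bins - 1, cfg.n_genes).astype(int)
    return SimTruth(
        dna_labels=dna_labels,
        rna_labels=rna_labels,
        clone_cn_profiles=profiles,
        de_mask=de_mask,
        de_factors=de_factors,
        gene_bins=gene_bins,
    )


def make_benchmark(cfg: SimConfig | None = None) -> tuple[CNMatrix, ExprMatrix, SimTruth]:
    """Deterministic coupled benchmark bundle for the given config/seed."""
    cfg = cfg or SimConfig()
    truth = _make_truth(cfg)
    cn = simulate_cn_matrix(cfg, truth, _rng_for(cfg, 2))
    expr = simulate_expression(cfg, truth, _rng_for(cfg, 3))
    return cn, expr, truth


def write_benchmark(
    folder: str | Path, cn: CNMatrix, expr: ExprMatrix, truth: SimTruth
) -> None:
    """Write CN as TSV, expression as an MTX triplet, truth labels as CSV."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(folder / "cn_matrix.tsv", cn.values, cn.cell_ids, cn.bin_ids)
    write_expr_mtx(folder / "rna", expr)
    with open(folder / "truth_dna_labels.csv", "w") as fh:
        fh.write("cell_id,clone\n")
        for cid, lab in zip(cn.cell_ids, truth.dna_labels):
            fh.write(f"{cid},{int(lab)}\n")
    with open(folder / "truth_rna_labels.csv", "w") as fh:
        fh.write("cell_id,clone\n")
        for cid, lab in zip(expr.cell_ids, truth.rna_labels):
            fh.write(f"{cid},{int(lab)}\n")
    np.savetxt(
        folder / "clone_cn_profiles.tsv", truth.clone_cn_profiles,
        fmt="%d", delimiter="\t",
    )
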