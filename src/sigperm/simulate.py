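"""Synthetic RNA-seq data with planted structure.

The generators emulate the study design the downstream analyses assume: four
progenitor groups (normal cord blood CB, normal peripheral blood NPB, chronic
phase CP, blast crisis BC; sizes 3/3/8/9), negative-binomial read counts with
log-normal library sizes, an a-priori 41-gene signature over-expressed in the
BC-like group, and a KEGG-like universe of random gene sets.  Every generator
is a pure function of its configuration and seed, and ships the ground truth
needed to score parameter recovery.

Negative-binomial parameterization: mean mu and dispersion phi with
variance = mu + phi * mu**2 (the standard bulk RNA-seq convention).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, ExpressionMatrix, GeneSetCollection, SampleDesign

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_counts",
    "simulate_geneset_universe",
    "simulate_dormancy_assay",
    "simulate_factorial_treatment",
]

#: Name under which the planted signature is included in the gene-set universe.
SIGNATURE_SET_NAME = "PLANTED_SIGNATURE"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study: 13,850 genes passing expression
    filters, groups CB/NPB/CP/BC of sizes 3/3/8/9, a 41-gene signature with a
    one-log2-unit mean shift in BC, and a universe of KEGG-sized random sets.
    """

    n_genes: int = 13_850
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"CB": 3, "NPB": 3, "CP": 8, "BC": 9})
    library_size_mean: float = 2.0e7
    library_size_cv: float = 0.3
    nb_dispersion: float = 0.15
    signature_size: int = 41
    signature_log2fc: float = 1.0
    signature_group: str = "BC"
    n_gene_sets: int = 100
    set_size_range: tuple[int, int] = (15, 100)
    gene_length_range: tuple[int, int] = (500, 5000)
    abundance_sdlog: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 samples")
        if not self.group_sizes:
            raise ValueError("group_sizes is empty")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size exceeds n_genes")
        if self.signature_group not in self.group_sizes:
            raise ValueError(f"signature_group {self.signature_group!r} "
                             "not among group_sizes")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid set_size_range")
        if hi > self.n_genes:
            raise ValueError("set size exceeds n_genes")
        if self.library_size_mean <= 0 or self.library_size_cv < 0:
            raise ValueError("invalid library size parameters")


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated dataset."""

    signature_gene_ids: list[str]
    log2fc_by_group: dict[str, pd.Series]   # per-group per-gene true log2 FC
    gene_set_members: dict[str, list[str]]
    sample_labels: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "signature_gene_ids": self.signature_gene_ids,
            "log2fc_by_group": {g: {k: float(v) for k, v in s.items() if v != 0}
                                for g, s in self.log2fc_by_group.items()},
            "gene_set_members": self.gene_set_members,
            "sample_labels": self.sample_labels,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # Independent, reproducible streams per generator stage.
    return np.random.default_rng([config.seed, stream])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:06d}" for i in range(n)]


def _signature_indices(config: SimulationConfig) -> np.ndarray:
    rng = _rng(config, 1)
    return np.sort(rng.choice(config.n_genes, config.signature_size,
                              replace=False))


def simulate_counts(config: SimulationConfig
                    ) -> tuple[CountMatrix, SampleDesign, SimulationTruth]:
    """Draw a gene x sample count matrix with a planted group signature.

    Counts are negative binomial with per-sample library-size scaling; the
    signature genes' means are multiplied by ``2**signature_log2fc`` in the
    designated group.  Gene lengths are uniform over ``gene_length_range``.
    """
    rng = _rng(config, 0)
    genes = _gene_ids(config.n_genes)
    lengths = pd.Series(
        rng.integers(config.gene_length_range[0],
                     config.gene_length_range[1] + 1, size=config.n_genes),
        index=genes, name="length")

    sample_ids, labels = [], []
    for group, n in config.group_sizes.items():
        for i in range(n):
            sample_ids.append(f"{group}{i + 1}")
            labels.append(group)
    n_samples = len(sample_ids)

    # Per-gene relative abundance (log-normal) and per-sample library sizes.
    rel = rng.lognormal(0.0, config.abundance_sdlog, size=config.n_genes)
    rel /= rel.sum()
    cv = config.library_size_cv
    sigma2 = np.log1p(cv**2)
    lib = rng.lognormal(np.log(config.library_size_mean) - sigma2 / 2,
                        np.sqrt(sigma2), size=n_samples)

    mu = np.outer(rel, lib)
    sig_idx = _signature_indices(config)
    in_group = np.array([g == config.signature_group for g in labels])
    mu[np.ix_(sig_idx, np.where(in_group)[0])] *= 2.0 ** config.signature_log2fc

    phi = config.nb_dispersion
    n_param = 1.0 / phi
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids),
                     lengths)
    design = SampleDesign(pd.Series(labels, index=sample_ids, name="group"),
                          ordered_levels=list(config.group_sizes))

    sig_ids = [genes[i] for i in sig_idx]
    fc = {g: pd.Series(0.0, index=genes) for g in config.group_sizes}
    if config.signature_log2fc != 0.0:
        fc[config.signature_group].iloc[sig_idx] = config.signature_log2fc
    truth = SimulationTruth(
        signature_gene_ids=sig_ids,
        log2fc_by_group=fc,
        gene_set_members={},
        sample_labels=dict(zip(sample_ids, labels)),
    )
    return cm, design, truth


def simulate_geneset_universe(config: SimulationConfig,
                              truth: SimulationTruth | None = None
                              ) -> GeneSetCollection:
    """Random gene sets over the simulated identifiers, plus the signature.

    Set sizes are uniform over ``set_size_range``; members are sampled
    without replacement from the gene universe.  The planted signature is
    included under :data:`SIGNATURE_SET_NAME` and flagged as the a-priori
    signature.  Duplicate random sets are permitted but recorded in the
    set descriptions.
    """
    if config.n_gene_sets < 1:
        raise ValueError("n_gene_sets must be >= 1")
    rng = _rng(config, 2)
    genes = np.array(_gene_ids(config.n_genes))
    lo, hi = config.set_size_range

    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    seen: dict[frozenset, str] = {}
    for k in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(genes, size, replace=False).tolist())
        name = f"SET_{k + 1:04d}"
        key = frozenset(members)
        descriptions[name] = (f"duplicate of {seen[key]}" if key in seen
                              else "random set")
        seen.setdefault(key, name)
        sets[name] = members

    sig = ([genes[i] for i in _signature_indices(config)]
           if truth is None else list(truth.signature_gene_ids))
    sets[SIGNATURE_SET_NAME] = sig
    descriptions[SIGNATURE_SET_NAME] = "planted a-priori signature"
    coll = GeneSetCollection(sets, descriptions,
                             signature_name=SIGNATURE_SET_NAME)
    if truth is not None:
        truth.gene_set_members = {n: list(m) for n, m in sets.items()}
    return coll


def simulate_dormancy_assay(n_samples: int, rho_true: float,
                            seed: int) -> pd.DataFrame:
    """Paired (expression, percent_G0) table with target rank correlation.

    Pairs are drawn from a Gaussian copula whose Pearson parameter is chosen
    so the population Spearman correlation equals ``rho_true``
    (r = 2 sin(pi * rho / 6)); the marginal for percent_G0 is mapped onto
    [0, 100] through the normal CDF, expression onto a log-normal scale.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 paired samples")
    if abs(rho_true) > 1:
        raise ValueError("|rho_true| must be <= 1")
    rng = np.random.default_rng(seed)
    r = 2.0 * np.sin(np.pi * rho_true / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_samples,
                                method="cholesky")
    expression = np.exp(z[:, 0])
    percent_g0 = 100.0 * stats.norm.cdf(z[:, 1])
    return pd.DataFrame({"expression": expression, "percent_G0": percent_g0},
                        index=[f"S{i + 1}" for i in range(n_samples)])


def simulate_factorial_treatment(n_genes: int,
                                 effects: tuple[float, float, float],
                                 n_per_cell: int,
                                 seed: int,
                                 noise_sd: float = 0.5,
                                 n_affected: int | None = None,
                                 ) -> tuple[ExpressionMatrix, SampleDesign]:
    """Gaussian log-expression under a 2x2 drug-treatment design.

    ``effects`` are the (drugA, drugB, interaction) coefficients of the
    per-gene linear model y = baseline + a*A + b*B + ab*A*B + noise, applied
    to the first ``n_affected`` genes (all genes when None).
    """
    if n_per_cell < 2:
        raise ValueError("n_per_cell must be >= 2")
    if n_affected is None:
        n_affected = n_genes
    if not 0 <= n_affected <= n_genes:
        raise ValueError("n_affected out of range")
    a_eff, b_eff, ab_eff = effects
    rng = np.random.default_rng(seed)

    cells = [(0, 0), (1, 0), (0, 1), (1, 1)]
    sample_ids, a_col, b_col, labels = [], [], [], []
    for a, b in cells:
        tag = f"A{a}B{b}"
        for i in range(n_per_cell):
            sample_ids.append(f"{tag}_{i + 1}")
            a_col.append(a)
            b_col.append(b)
            labels.append(tag)
    a_vec = np.array(a_col, dtype=float)
    b_vec = np.array(b_col, dtype=float)

    genes = _gene_ids(n_genes)
    baseline = rng.normal(5.0, 1.0, size=n_genes)
    affected = np.zeros(n_genes)
    affected[:n_affected] = 1.0
    mean = (baseline[:, None]
            + np.outer(affected * a_eff, a_vec)
            + np.outer(affected * b_eff, b_vec)
            + np.outer(affected * ab_eff, a_vec * b_vec))
    values = mean + rng.normal(0.0, noise_sd, size=mean.shape)

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids),
        stage="log2_centered")
    design = SampleDesign(
        pd.Series(labels, index=sample_ids, name="group"),
        ordered_levels=["A0B0", "A1B0", "A0B1", "A1B1"],
        factors=pd.DataFrame({"drugA": a_col, "drugB": b_col},
                             index=sample_ids))
    return expr, design
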