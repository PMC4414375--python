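"""End-to-end workflows chaining the analysis stages.

Two workflows mirror the study design:

* cohort: raw counts -> RPKM -> detectable-expression filter -> per-gene log2
  median-centering -> signature-restricted PCA permutation test + Spearman
  hierarchical clustering + Mann-Whitney/BH differential expression.
* treatment: raw counts -> minimum-read filter -> upper-quartile
  normalization -> SAM ranking -> GSEA with gene-label permutation, FDR and
  family-wise correction -> core-enrichment extraction.

A run is a pure function of (input files, config, seeds); reports embed every
resolved parameter so results are auditable, and contain no timestamps so
reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster, diffstats, gsea, quantify, sigtest
from .containers import CountMatrix, ExpressionMatrix, GeneSetCollection, SampleDesign

__all__ = ["PipelineConfig", "run_cohort_workflow", "run_treatment_workflow"]

log = logging.getLogger("sigperm")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a pipeline run.

    Defaults match the stated analysis parameters: RPKM > 0.2 in over 75% of
    samples, at least 10 mapped reads, 5000 random signature-sized sets, and
    2000 gene-label permutations.
    """

    counts: str = ""
    lengths: str = ""
    design: str = ""
    gene_sets: str = ""
    signature_name: str | None = None
    family_names: list[str] | None = None
    out_dir: str = "results"

    min_rpkm: float = 0.2
    min_fraction: float = 0.75
    min_reads: int = 10
    n_signature_draws: int = 5000
    n_label_permutations: int = 2000
    pvalue_rule: str = "upper"
    weight_exponent: float = 0.0
    sam_s0: float | str = "auto"
    fdr: float = 0.05
    pseudocount: float = 0.01

    group_a: str = "CP"
    group_b: str = "BC"
    treated_group: str = "treated"
    control_group: str = "vehicle"

    signature_seed: int = 17
    gsea_seed: int = 17

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def check_paths(self) -> None:
        for name in ("counts", "lengths", "design", "gene_sets"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: {p!r} does not exist")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_inputs(config: PipelineConfig
                 ) -> tuple[CountMatrix, SampleDesign, GeneSetCollection]:
    config.check_paths()
    counts = CountMatrix.from_tsv(config.counts, config.lengths)
    design = SampleDesign.from_tsv(config.design)
    sets = GeneSetCollection.from_gmt(config.gene_sets,
                                      signature_name=config.signature_name,
                                      family_names=config.family_names)
    return counts, design, sets


def _timed(name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            log.info("stage %-18s %6.2fs", name, time.perf_counter() - self.t0)
            return False
    return _T()


def _write_json(payload: dict, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=default)


def run_cohort_workflow(config: PipelineConfig) -> dict:
    """Patient-cohort signature analysis; returns the report dict.

    Writes to ``config.out_dir``: cohort_report.json, pc_scores.tsv,
    de_genes.tsv, dendrograms (Newick) for samples and signature genes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, design, sets = _load_inputs(config)

    with _timed("quantify"):
        rpkm = quantify.compute_rpkm(counts)
        # permutation-test universe: annotated genes not zero everywhere
        nonzero = quantify.filter_expressed(rpkm, mode="nonzero")
        expressed = quantify.filter_expressed(
            rpkm, min_rpkm=config.min_rpkm, min_fraction=config.min_fraction)
        logc = quantify.log2_median_center(expressed, config.pseudocount)
        logc_nonzero = quantify.log2_median_center(nonzero, config.pseudocount)

    signature = sets.signature
    annotated = set(sets.universe())
    universe = [g for g in logc_nonzero.gene_ids if g in annotated]

    with _timed("signature-test"):
        result = sigtest.run_signature_test(
            logc_nonzero, design, signature, universe,
            n_draws=config.n_signature_draws, seed=config.signature_seed,
            rule=config.pvalue_rule)

    with _timed("clustering"):
        sig_expr = logc_nonzero.subset_genes(
            [g for g in signature if g in logc_nonzero.values.index])
        d_samples = cluster.spearman_distance(sig_expr.values, axis="samples")
        dend_samples = cluster.hierarchical_cluster(d_samples)
        d_genes = cluster.spearman_distance(sig_expr.values, axis="genes")
        dend_genes = cluster.hierarchical_cluster(d_genes, axis="genes")

    with _timed("diff-expression"):
        de_table, de_selected = diffstats.de_genes(
            logc, design, config.group_a, config.group_b, fdr=config.fdr)

    result.pc_scores.to_csv(out / "pc_scores.tsv", sep="\t",
                            index_label="sample_id")
    de_table.to_csv(out / "de_genes.tsv", sep="\t", index_label="gene_id")
    (out / "samples.nwk").write_text(dend_samples.to_newick() + "\n")
    (out / "signature_genes.nwk").write_text(dend_genes.to_newick() + "\n")

    report = {
        "workflow": "cohort",
        "config": config.to_dict(),
        "n_genes_input": len(counts.gene_ids),
        "n_genes_nonzero": len(nonzero.gene_ids),
        "n_genes_expressed": len(expressed.gene_ids),
        "universe_size": result.universe_size,
        "signature_size_declared": len(signature),
        "signature_size_expressed": len(
            [g for g in signature if g in logc_nonzero.values.index]),
        "permutation_test": result.to_dict(include_null=True),
        "n_de_genes": len(de_selected),
        "de_genes": de_selected,
        "sample_leaf_order": dend_samples.leaf_order(),
    }
    _write_json(report, out / "cohort_report.json")
    return report


def run_treatment_workflow(config: PipelineConfig) -> dict:
    """Treated-vs-vehicle enrichment analysis; returns the report dict.

    Writes gsea_table.tsv (pathway name, genes in pathway, expressed genes,
    ES/NES/direction, nominal p, FDR q, family-wise p, core genes) and
    treatment_report.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, design, sets = _load_inputs(config)
    for g in (config.treated_group, config.control_group):
        if not design.samples_in(g):
            raise ValueError(f"group {g!r} has no samples in the design")

    with _timed("normalize"):
        filtered = quantify.filter_min_counts(counts, config.min_reads)
        uq = quantify.upper_quartile_normalize(filtered)
        # SAM operates on log2 normalized counts
        log_expr = ExpressionMatrix(np.log2(uq.values + 1.0),
                                    stage="uq_normalized")

    with _timed("gsea"):
        res = gsea.run_gsea(
            log_expr, design, config.treated_group, config.control_group,
            sets, family=config.family_names,
            n_perm=config.n_label_permutations, seed=config.gsea_seed,
            sam_config=gsea.SamConfig(s0=config.sam_s0),
            weight_exponent=config.weight_exponent)

    res.to_tsv(out / "gsea_table.tsv")
    running = pd.DataFrame(res.running_sums, index=res.ranked_genes)
    running.to_csv(out / "running_sums.tsv", sep="\t", index_label="gene_id")

    table = res.table.copy()
    report = {
        "workflow": "treatment",
        "config": config.to_dict(),
        "n_genes_input": len(counts.gene_ids),
        "n_genes_filtered": len(filtered.gene_ids),
        "n_permutations": res.n_permutations,
        "params": res.params,
        "pathways": table.to_dict(orient="records"),
    }
    _write_json(report, out / "treatment_report.json")
    return report
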