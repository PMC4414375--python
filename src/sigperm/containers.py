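"""Core data containers for the RNA-seq signature analysis pipeline.

All matrices are thin wrappers around :class:`pandas.DataFrame` objects with
genes as rows and samples as columns, carrying just enough metadata (gene
lengths, processing stage, group design) to keep the downstream stages honest
about what representation they operate on.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "SampleDesign",
    "GeneSetCollection",
    "PermutationPcaResult",
    "DendrogramResult",
    "NmfConsensusResult",
    "GseaResult",
    "STAGES",
]

#: Valid processing stages for an :class:`ExpressionMatrix`.
STAGES = ("rpkm", "uq_normalized", "log2_centered")


def _check_unique(ids: Sequence[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class CountMatrix:
    """Raw gene x sample read counts with per-gene exonic lengths.

    Parameters
    ----------
    counts
        Integer DataFrame, genes as rows (index = gene ids), samples as
        columns.
    gene_lengths
        Series of exonic lengths in nucleotides, indexed by gene id.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene ids")
        _check_unique(self.counts.columns, "sample ids")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("counts contain non-finite values")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths.index[self.gene_lengths.isna()].tolist()
            raise ValueError(f"missing gene lengths for {missing[:5]}")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)],
                           self.gene_lengths.loc[list(gene_ids)])

    # --- TSV round-trip -------------------------------------------------
    def to_tsv(self, counts_path: str | Path, lengths_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.gene_lengths.rename("length").to_csv(
            lengths_path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, counts_path: str | Path,
                 lengths_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts.index.name = None
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0)["length"]
        lengths.index.name = None
        return cls(counts, lengths)


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample expression with a processing-stage tag.

    ``stage`` is one of :data:`STAGES`; stage transitions happen only through
    the operations in :mod:`sigperm.quantify`.  ``zero_mask`` (optional) marks
    entries that were exactly zero before a log transform, preserving the
    "not expressed" semantic for display layers.
    """

    values: pd.DataFrame
    stage: str
    zero_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        if self.stage == "rpkm" and (self.values.to_numpy() < 0).any():
            raise ValueError("rpkm values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(gene_ids)
        zm = self.zero_mask.loc[ids] if self.zero_mask is not None else None
        return ExpressionMatrix(self.values.loc[ids], self.stage, zm)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# stage: {self.stage}\n")
            self.values.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# stage:"):
                raise ValueError(f"{path}: missing '# stage:' header comment")
            stage = first.split(":", 1)[1].strip()
            values = pd.read_csv(fh, sep="\t", index_col=0)
            values.index.name = None
        return cls(values, stage)


@dataclass
class SampleDesign:
    """Sample-to-group mapping with optional ordered levels and 2x2 factors.

    ``ordered_levels`` gives the biological ordering of the groups (e.g.
    normal cord blood -> normal peripheral blood -> chronic phase -> blast
    crisis) used by trend tests; it is never inferred from the data.
    ``factors`` is an optional DataFrame of two binary treatment columns
    indexed by sample id, for factorial designs.
    """

    groups: pd.Series
    ordered_levels: list[str] | None = None
    factors: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.groups.index, "sample ids")
        self.groups = self.groups.astype(str)
        if self.ordered_levels is not None:
            present = set(self.groups)
            missing = present - set(self.ordered_levels)
            if missing:
                raise ValueError(f"groups {sorted(missing)} not in ordered_levels")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups.index)

    def levels(self) -> list[str]:
        """Group labels, in ordered_levels order when available."""
        if self.ordered_levels is not None:
            return [g for g in self.ordered_levels if g in set(self.groups)]
        return list(dict.fromkeys(self.groups))

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_indices(self, sample_ids: Sequence[str]) -> list[np.ndarray]:
        """Integer index arrays into ``sample_ids``, one per level."""
        pos = {s: i for i, s in enumerate(sample_ids)}
        return [np.array([pos[s] for s in self.samples_in(g)], dtype=int)
                for g in self.levels()]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"group": self.groups})
        if self.factors is not None:
            df = df.join(self.factors)
        with open(path, "w") as fh:
            if self.ordered_levels is not None:
                fh.write("# levels: " + ",".join(self.ordered_levels) + "\n")
            df.to_csv(fh, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleDesign":
        levels = None
        with open(path) as fh:
            pos = fh.tell()
            first = fh.readline()
            if first.startswith("# levels:"):
                levels = [x.strip() for x in first.split(":", 1)[1].split(",")]
            else:
                fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", index_col=0)
            df.index.name = None
        factors = df.drop(columns="group") if df.shape[1] > 1 else None
        return cls(df["group"], ordered_levels=levels, factors=factors)


@dataclass
class GeneSetCollection:
    """Named gene sets over a gene-identifier universe (GMT-backed).

    One set may be flagged as the a-priori signature (``signature_name``) and
    a subfamily of sets as the a-priori pathway family (``family_names``).
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    signature_name: str | None = None
    family_names: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")
        if self.signature_name is not None and self.signature_name not in self.sets:
            raise KeyError(f"signature set {self.signature_name!r} not in collection")
        if self.family_names is not None:
            missing = set(self.family_names) - set(self.sets)
            if missing:
                raise KeyError(f"family sets not in collection: {sorted(missing)}")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    @property
    def signature(self) -> list[str]:
        if self.signature_name is None:
            raise ValueError("no set is flagged as the a-priori signature")
        return self.sets[self.signature_name]

    def universe(self) -> list[str]:
        """Union of all member genes, in first-seen order."""
        seen: dict[str, None] = {}
        for members in self.sets.values():
            for g in members:
                seen.setdefault(g)
        return list(seen)

    def restrict_to(self, gene_ids: Sequence[str]) -> "GeneSetCollection":
        """Intersect every set with ``gene_ids``, keeping set order."""
        keep = set(gene_ids)
        sets = {n: [g for g in m if g in keep] for n, m in self.sets.items()}
        return GeneSetCollection(sets, dict(self.descriptions),
                                 self.signature_name, self.family_names)

    # --- GMT round-trip (tab-separated: name, description, members) ------
    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.descriptions.get(name, "na")
                fh.write("\t".join([name, desc, *members]) + "\n")

    @classmethod
    def from_gmt(cls, path: str | Path, signature_name: str | None = None,
                 family_names: list[str] | None = None) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        descriptions: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"malformed GMT line: {line[:60]!r}")
                sets[fields[0]] = fields[2:]
                descriptions[fields[0]] = fields[1]
        return cls(sets, descriptions, signature_name, family_names)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="split")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    return obj


@dataclass
class PermutationPcaResult:
    """Outcome of the signature-restricted PCA + MANOVA permutation test."""

    observed_F: float
    pc_scores: pd.DataFrame            # samples x n_components
    variance_explained: np.ndarray
    null_F: np.ndarray
    p_value: float
    n_draws: int
    seed: int | None
    universe_size: int
    signature_size: int
    rule: str = "upper"

    def __post_init__(self) -> None:
        if len(self.null_F) != self.n_draws:
            raise ValueError("len(null_F) must equal n_draws")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")

    def to_dict(self, include_null: bool = True) -> dict:
        d = dataclasses.asdict(self)
        if not include_null:
            d["null_F"] = None
        return {k: _jsonable(v) for k, v in d.items()}

    def to_json(self, path: str | Path, include_null: bool = True) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(include_null), fh, indent=1, sort_keys=True)


@dataclass
class DendrogramResult:
    """Agglomerative merge sequence over one axis of a matrix.

    ``merges`` lists (node_a, node_b, height) triples in merge order; leaves
    are numbered 0..n-1 in input order and merge *i* creates node ``n + i``
    (the scipy linkage convention).
    """

    merges: list[tuple[int, int, float]]
    labels: list[str]
    axis: str                     # "samples" | "genes"
    metric: str = "spearman"
    linkage: str = "complete"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError("need exactly n-1 merges for n leaves")

    def to_linkage(self) -> np.ndarray:
        """Convert to a scipy-style (n-1) x 4 linkage matrix."""
        n = len(self.labels)
        sizes = {i: 1 for i in range(n)}
        rows = []
        for step, (a, b, h) in enumerate(self.merges):
            sizes[n + step] = sizes[a] + sizes[b]
            rows.append([a, b, h, sizes[n + step]])
        return np.asarray(rows, dtype=float)

    def leaf_order(self) -> list[str]:
        """Left-to-right dendrogram leaf order."""
        n = len(self.labels)
        children = {n + i: (a, b) for i, (a, b, _) in enumerate(self.merges)}

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            a, b = children[node]
            return walk(a) + walk(b)

        root = n + len(self.merges) - 1 if self.merges else 0
        return [self.labels[i] for i in walk(root)]

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences
        (leaves sit at height 0, giving an ultrametric tree)."""
        n = len(self.labels)
        children = {n + i: (a, b) for i, (a, b, _) in enumerate(self.merges)}
        heights = {i: 0.0 for i in range(n)}
        for i, (_, _, h) in enumerate(self.merges):
            heights[n + i] = h

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - heights[node]
            if node < n:
                return f"{self.labels[node]}:{bl:g}"
            a, b = children[node]
            h = heights[node]
            return f"({render(a, h)},{render(b, h)}):{bl:g}"

        if not self.merges:
            return f"{self.labels[0]};" if self.labels else ";"
        root = n + len(self.merges) - 1
        a, b = children[root]
        h = heights[root]
        return f"({render(a, h)},{render(b, h)});"


@dataclass
class NmfConsensusResult:
    """Consensus matrix over random-restart NMF runs at one rank."""

    rank: int
    consensus: pd.DataFrame           # samples x samples in [0, 1]
    cophenetic_rho: float
    n_runs: int
    seed: int | None
    assignments: np.ndarray | None = None   # n_runs x n_samples cluster labels

    def __post_init__(self) -> None:
        C = self.consensus.to_numpy()
        if not np.allclose(C, C.T):
            raise ValueError("consensus matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("consensus diagonal must be 1")
        if C.min() < -1e-12 or C.max() > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")


@dataclass
class GseaResult:
    """Per-pathway enrichment results for one two-group comparison.

    ``table`` has one row per pathway with columns: name, n_genes_in_pathway,
    n_expressed, es, nes, direction, nominal_p, fdr_q, fwer_p, core_genes.
    ``null_es`` is the pathways x n_permutations null matrix.
    """

    table: pd.DataFrame
    running_sums: dict[str, np.ndarray]
    ranked_genes: list[str]
    null_es: pd.DataFrame
    n_permutations: int
    seed: int | None
    params: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["core_genes"] = out["core_genes"].map(",".join)
        out.to_csv(path, sep="\t", index=False)
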