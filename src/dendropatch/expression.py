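"""Tissue-enrichment ranking of expression atlases.

The nomination stage that picks out genes enriched in one tissue compartment
over another: median renormalisation of a probe × tissue intensity matrix,
log transform and per-probe centering, hierarchical clustering of probes with
Pearson-correlation distance and average linkage, flat-cut cluster selection
by marker-tissue score, and ranking of genes by a between-tissue expression
ratio validated against reference genes with known laterality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ExpressionMatrix",
    "NormalizedMatrix",
    "ClusterTree",
    "TissueRatioTable",
    "ReferenceGene",
    "preprocess",
    "cluster_genes",
    "select_cluster",
    "tissue_ratio",
    "rank_and_validate",
]


@dataclass
class ExpressionMatrix:
    """Probe × tissue table of positive raw intensities.

    Each probe maps to exactly one gene symbol; a gene may be represented by
    several probes.
    """

    values: np.ndarray  # (n_probes, n_tissues), all > 0
    probe_ids: list[str]
    gene_symbols: list[str]
    tissue_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        n_probes, n_tissues = self.values.shape
        if len(self.probe_ids) != n_probes or len(self.gene_symbols) != n_probes:
            raise ValueError("probe_ids/gene_symbols length must match row count")
        if len(self.tissue_names) != n_tissues:
            raise ValueError("tissue_names length must match column count")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.probe_ids, columns=self.tissue_names)
        df.insert(0, "gene", self.gene_symbols)
        return df

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        """Read the TSV layout: probe id, gene symbol, then one column per tissue."""
        df = pd.read_csv(path, sep="\t")
        probe_col, gene_col = df.columns[0], df.columns[1]
        tissues = list(df.columns[2:])
        return cls(
            values=df[tissues].to_numpy(dtype=float),
            probe_ids=[str(p) for p in df[probe_col]],
            gene_symbols=[str(g) for g in df[gene_col]],
            tissue_names=tissues,
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.tissue_names)
        df.insert(0, "gene", self.gene_symbols)
        df.insert(0, "probe", self.probe_ids)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class NormalizedMatrix:
    """Log2-scale, row-centered relative expression with provenance."""

    values: np.ndarray
    probe_ids: list[str]
    gene_symbols: list[str]
    tissue_names: list[str]
    grand_median: float  # renormalisation target (grand median of the input)

    def tissue_index(self, name: str) -> int:
        try:
            return self.tissue_names.index(name)
        except ValueError:
            raise KeyError(f"tissue {name!r} not in matrix") from None


@dataclass
class ClusterTree:
    """Average-linkage merge tree over probe rows.

    ``merges`` is a scipy-style linkage matrix: each row
    (node_a, node_b, height, size) records one agglomeration; leaves are
    numbered 0..n-1 and internal nodes n..2n-2 in merge order.
    """

    merges: np.ndarray  # (n_leaves-1, 4) linkage records
    leaf_order: np.ndarray  # dendrogram leaf ordering
    probe_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.probe_ids)

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self, labels: list[str] | None = None) -> str:
        """Nested-parenthesis text rendering for inspection."""
        labels = labels if labels is not None else self.probe_ids
        n = self.n_leaves
        nodes: dict[int, str] = {i: labels[i] for i in range(n)}
        for k, (a, b, h, _sz) in enumerate(self.merges):
            nodes[n + k] = f"({nodes[int(a)]},{nodes[int(b)]}):{h:.6g}"
        return nodes[2 * n - 2] + ";"


@dataclass
class TissueRatioTable:
    """Per-gene numerator/denominator tissue values, ratio and rank."""

    frame: pd.DataFrame  # columns: gene, value_a, value_b, ratio, rank
    numerator_tissue: str
    denominator_tissue: str

    @classmethod
    def from_values(
        cls,
        genes: list[str],
        values_a,
        values_b,
        numerator_tissue: str = "numerator",
        denominator_tissue: str = "denominator",
    ) -> "TissueRatioTable":
        ratios = [tissue_ratio(a, b) for a, b in zip(values_a, values_b)]
        df = pd.DataFrame(
            {"gene": genes, "value_a": values_a, "value_b": values_b, "ratio": ratios}
        )
        # rank: descending ratio, ties broken by ascending gene symbol
        order = df.sort_values(["ratio", "gene"], ascending=[False, True]).index
        rank = pd.Series(np.arange(1, len(df) + 1), index=order)
        df["rank"] = rank
        return cls(df, numerator_tissue, denominator_tissue)

    @classmethod
    def from_matrix(
        cls, matrix: ExpressionMatrix, numerator_tissue: str, denominator_tissue: str
    ) -> "TissueRatioTable":
        """Gene-level table from a probe-level matrix.

        A gene's per-tissue value is the mean of its probes' values.
        """
        df = pd.DataFrame(matrix.values, columns=matrix.tissue_names)
        df["gene"] = matrix.gene_symbols
        gene_means = df.groupby("gene", sort=True).mean()
        for t in (numerator_tissue, denominator_tissue):
            if t not in gene_means.columns:
                raise KeyError(f"tissue {t!r} not in matrix")
        return cls.from_values(
            list(gene_means.index),
            gene_means[numerator_tissue].to_numpy(),
            gene_means[denominator_tissue].to_numpy(),
            numerator_tissue,
            denominator_tissue,
        )

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["ratio"] = out["ratio"].round(6)
        out.sort_values("rank").to_csv(path, index=False)


@dataclass
class ReferenceGene:
    """A validation gene with a known expression side.

    ``side`` is "high" (ratio expected ≥ threshold) or "low"
    (ratio expected ≤ threshold).
    """

    gene: str
    side: str
    threshold: float

    def __post_init__(self) -> None:
        if self.side not in ("high", "low"):
            raise ValueError(f"side must be 'high' or 'low', got {self.side!r}")
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")

    @staticmethod
    def from_csv(path) -> list["ReferenceGene"]:
        df = pd.read_csv(path)
        return [
            ReferenceGene(str(r.gene), str(r.side), float(r.threshold))
            for r in df.itertuples()
        ]


def preprocess(matrix: ExpressionMatrix) -> NormalizedMatrix:
    """Median-renormalise, log2-transform and row-center an intensity matrix.

    Pipeline: (1) divide each tissue column by its median and multiply by the
    grand median of the input matrix, so every array shares a common median
    intensity; (2) log2; (3) subtract each probe row's mean, yielding relative
    expression values.
    """
    v = matrix.values
    bad = np.argwhere(~(v > 0))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"nonpositive intensity at probe {matrix.probe_ids[r]!r} "
            f"({matrix.tissue_names[c]!r}): {v[r, c]}"
        )
    col_med = np.median(v, axis=0)
    if np.any(col_med <= 0):
        j = int(np.argmax(col_med <= 0))
        raise ValueError(f"column {matrix.tissue_names[j]!r} has nonpositive median")
    grand = float(np.median(v))
    renorm = v / col_med * grand
    logged = np.log2(renorm)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return NormalizedMatrix(
        values=centered,
        probe_ids=list(matrix.probe_ids),
        gene_symbols=list(matrix.gene_symbols),
        tissue_names=list(matrix.tissue_names),
        grand_median=grand,
    )


def pearson_distance_condensed(values: np.ndarray) -> np.ndarray:
    """Condensed pairwise d = 1 − Pearson r between rows."""
    return pdist(np.asarray(values, dtype=float), metric="correlation")


def cluster_genes(norm: NormalizedMatrix) -> ClusterTree:
    """Agglomerative clustering of probe rows.

    Distance is 1 − Pearson correlation; linkage is the unweighted average of
    pairwise distances between clusters (UPGMA). Heights are non-decreasing
    along the merge sequence.
    """
    v = np.asarray(norm.values, dtype=float)
    if v.shape[0] < 2:
        raise ValueError("need at least 2 probes to cluster")
    variances = v.var(axis=1)
    if np.any(variances == 0):
        i = int(np.argmax(variances == 0))
        raise ValueError(
            f"probe {norm.probe_ids[i]!r} has zero variance; "
            "Pearson correlation is undefined"
        )
    d = pearson_distance_condensed(v)
    z = hierarchy.linkage(d, method="average")
    return ClusterTree(
        merges=z,
        leaf_order=hierarchy.leaves_list(z),
        probe_ids=list(norm.probe_ids),
    )


def select_cluster(
    tree: ClusterTree,
    norm: NormalizedMatrix,
    marker_tissues: list[str],
    k: int,
) -> list[str]:
    """Cut the tree into ``k`` flat clusters and return the genes of the one
    scoring highest on the marker tissues.

    Score = mean normalized expression of the cluster's probes over the marker
    tissue columns. Ties go to the cluster containing the lowest leaf index.
    """
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k must be in [1, {tree.n_leaves}], got {k}")
    cols = [norm.tissue_index(t) for t in marker_tissues]
    assignments = hierarchy.fcluster(tree.merges, t=k, criterion="maxclust")
    marker_vals = norm.values[:, cols].mean(axis=1)
    best_label, best_key = None, None
    for label in np.unique(assignments):
        members = np.flatnonzero(assignments == label)
        key = (marker_vals[members].mean(), -int(members.min()))
        if best_key is None or key > best_key:
            best_label, best_key = label, key
    members = np.flatnonzero(assignments == best_label)
    seen, genes = set(), []
    for i in members:
        g = norm.gene_symbols[i]
        if g not in seen:
            seen.add(g)
            genes.append(g)
    return genes


def tissue_ratio(value_a: float, value_b: float) -> float:
    """Between-tissue expression ratio value_a / value_b.

    Reporting rounds to 6 decimal places (the precision of the printed
    reference tables); the returned value is unrounded.
    """
    if not value_b > 0:
        raise ValueError(f"denominator tissue value must be > 0, got {value_b}")
    return float(value_a) / float(value_b)


@dataclass
class ValidationReport:
    """Outcome of checking a ratio ranking against reference genes."""

    results: list[dict] = field(default_factory=list)
    top: list[dict] = field(default_factory=list)

    @property
    def all_pass(self) -> bool:
        return all(r["passed"] for r in self.results)

    def to_dict(self) -> dict:
        return {"references": self.results, "top": self.top, "all_pass": self.all_pass}

    def to_text(self) -> str:
        lines = []
        for r in self.results:
            status = "PASS" if r["passed"] else "FAIL"
            lines.append(
                f"{status}  {r['gene']:>10s}  ratio={r['ratio']:.6f}  "
                f"{r['side']}@{r['threshold']}  rank={r['rank']}"
            )
        lines.append("top genes by ratio: " + ", ".join(t["gene"] for t in self.top))
        return "\n".join(lines)


def rank_and_validate(
    table: TissueRatioTable, refs: list[ReferenceGene], top_n: int = 5
) -> ValidationReport:
    """Rank genes by descending ratio and test each reference gene's side.

    "high" references pass when ratio ≥ threshold; "low" references pass when
    ratio ≤ threshold. Ranking ties break by ascending gene symbol.
    """
    df = table.frame.sort_values("rank")
    by_gene = df.set_index("gene")
    report = ValidationReport()
    for ref in refs:
        if ref.gene not in by_gene.index:
            raise KeyError(f"reference gene {ref.gene!r} not present in the table")
        row = by_gene.loc[ref.gene]
        ratio = float(row["ratio"])
        passed = ratio >= ref.threshold if ref.side == "high" else ratio <= ref.threshold
        report.results.append(
            {
                "gene": ref.gene,
                "ratio": round(ratio, 6),
                "side": ref.side,
                "threshold": ref.threshold,
                "rank": int(row["rank"]),
                "passed": bool(passed),
            }
        )
    for r in df.head(top_n).itertuples():
        report.top.append({"gene": r.gene, "ratio": round(float(r.ratio), 6), "rank": int(r.rank)})
    return report
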