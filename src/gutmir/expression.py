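"""Spatial expression analysis: per-locus expression sets, Venn overlaps,
common-reference log ratios, two-way hierarchical clustering, and
homologous-versus-heterologous platform correlation.

The comparative design hybridizes every intestinal locus against a pooled
common reference; log ratios (glog2 differences) of the targets detected in
every sample are clustered with 1 - Pearson correlation distance and average
linkage, on genes and samples independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .arrays import DetectionCall, NormalizedMatrix


def expression_sets(calls: list[DetectionCall]) -> dict[str, set[str]]:
    """Per-sample sets of detected target ids."""
    sets: dict[str, set[str]] = {}
    for c in calls:
        sets.setdefault(c.sample, set())
        if c.detected:
            sets[c.sample].add(c.target)
    return sets


def venn_counts(sets: dict[str, set[str]], samples: tuple[str, ...]) -> int:
    """Size of the intersection of the named samples' detected sets."""
    unknown = [s for s in samples if s not in sets]
    if unknown:
        raise KeyError(f"unknown sample id(s): {unknown}")
    it = iter(samples)
    inter = set(sets[next(it)])
    for s in it:
        inter &= sets[s]
    return len(inter)


def venn_report(sets: dict[str, set[str]], samples: tuple[str, ...]) -> dict[str, int]:
    """All region counts of a 2- or 3-set Venn diagram (inclusion-exclusion exact)."""
    if not 2 <= len(samples) <= 3:
        raise ValueError("venn_report supports 2 or 3 sets")
    universe = [sets[s] for s in samples]
    report: dict[str, int] = {}
    n = len(samples)
    for mask in range(1, 2**n):
        inside = [universe[i] for i in range(n) if mask >> i & 1]
        outside = [universe[i] for i in range(n) if not mask >> i & 1]
        region = set(inside[0]).intersection(*inside)
        for o in outside:
            region -= o
        label = "&".join(samples[i] for i in range(n) if mask >> i & 1)
        report[label] = len(region)
    return report


def ubiquitous_targets(calls: list[DetectionCall]) -> set[str]:
    """Targets detected in every sample (including the common reference)."""
    sets = expression_sets(calls)
    it = iter(sets.values())
    inter = set(next(it))
    for s in it:
        inter &= s
    return inter


def log_ratio_matrix(
    matrix: NormalizedMatrix,
    reference: str,
    targets: set[str] | None = None,
    kind: str = "mature",
) -> pd.DataFrame:
    """Per-target log2 ratios versus the common reference, glog2 subtraction.

    Restricted to ``targets`` (conventionally the everywhere-detected set);
    the reference column is identically zero.
    """
    if reference not in matrix.samples:
        raise ValueError(f"reference sample {reference!r} not in matrix")
    rows = []
    index = []
    for target in matrix.targets:
        if targets is not None and target not in targets:
            continue
        if (target, kind) not in matrix.values.index:
            continue
        v = matrix.values.loc[(target, kind)]
        ref = float(v[reference])
        if not np.isfinite(ref):
            continue
        rows.append([float(v[s]) - ref for s in matrix.samples])
        index.append(target)
    return pd.DataFrame(rows, index=index, columns=matrix.samples)


@dataclass
class ClusterResult:
    gene_order: list[str]
    sample_order: list[str]
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray
    distance: str = "1-pearson"
    linkage: str = "average"

    def sample_newick(self) -> str:
        return _linkage_to_newick(self.sample_linkage, self.sample_order_input)

    def gene_newick(self) -> str:
        return _linkage_to_newick(self.gene_linkage, self.gene_order_input)

    # leaf label lists in input order, set by hierarchical_cluster
    gene_order_input: list[str] = field(default_factory=list)
    sample_order_input: list[str] = field(default_factory=list)

    def siblings(self, axis: str, a: str, b: str) -> bool:
        """True if leaves a and b merge with each other first on the given axis."""
        labels = self.gene_order_input if axis == "gene" else self.sample_order_input
        link = self.gene_linkage if axis == "gene" else self.sample_linkage
        ia, ib = labels.index(a), labels.index(b)
        for row in link:
            if {int(row[0]), int(row[1])} == {ia, ib}:
                return True
        return False


def _pearson_distance_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson over rows; zero-variance rows get correlation 0."""
    x = np.asarray(x, dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered**2).sum(axis=1))
    n = x.shape[0]
    corr = np.zeros((n, n))
    ok = sd > 0
    if ok.any():
        xs = np.where(sd[:, None] > 0, centered / np.where(sd[:, None] > 0, sd[:, None], 1), 0.0)
        corr = xs @ xs.T
    corr[~ok, :] = 0.0
    corr[:, ~ok] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def hierarchical_cluster(ratios: pd.DataFrame) -> ClusterResult:
    """Average-linkage clustering of genes (rows) and samples (columns).

    Distance is 1 - Pearson correlation computed over the other axis;
    tie-breaking is scipy's deterministic input-order rule.
    """
    if ratios.shape[0] < 2 or ratios.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    if ratios.isna().any().any():
        raise ValueError("ratio matrix contains missing values")
    gene_d = _pearson_distance_matrix(ratios.to_numpy())
    sample_d = _pearson_distance_matrix(ratios.to_numpy().T)
    gene_link = hierarchy.linkage(_condense(gene_d), method="average")
    sample_link = hierarchy.linkage(_condense(sample_d), method="average")
    gene_order = [ratios.index[i] for i in hierarchy.leaves_list(gene_link)]
    sample_order = [ratios.columns[i] for i in hierarchy.leaves_list(sample_link)]
    return ClusterResult(
        gene_order=list(gene_order),
        sample_order=list(sample_order),
        gene_linkage=gene_link,
        sample_linkage=sample_link,
        gene_order_input=list(ratios.index),
        sample_order_input=list(ratios.columns),
    )


def _condense(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(d, k=1)
    return d[iu]


def _linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(link)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = rec(node.left), rec(node.right)
        return f"({left}:{node.dist / 2:.4f},{right}:{node.dist / 2:.4f})"

    return rec(tree) + ";"


@dataclass
class PlatformCorrelation:
    per_sample: pd.DataFrame  # index sample, columns r, p, r2, n
    global_r: float
    global_p: float


def correlate_platforms(
    homologous: pd.DataFrame,
    heterologous: pd.DataFrame,
    shared_targets: list[str] | None = None,
) -> PlatformCorrelation:
    """Pearson correlation of the two platforms per sample and pooled.

    Both inputs are target x sample matrices; rows are restricted to
    ``shared_targets`` (default: index intersection). Two-tailed p-values
    come from the t-distribution with n - 2 degrees of freedom.
    """
    if shared_targets is None:
        shared_targets = sorted(set(homologous.index) & set(heterologous.index))
    samples = [s for s in homologous.columns if s in heterologous.columns]
    if len(shared_targets) < 3:
        raise ValueError("need at least 3 shared targets per sample")
    rows = []
    pooled_x: list[float] = []
    pooled_y: list[float] = []
    for s in samples:
        x = homologous.loc[shared_targets, s].to_numpy(dtype=float)
        y = heterologous.loc[shared_targets, s].to_numpy(dtype=float)
        r, p = stats.pearsonr(x, y)
        rows.append({"sample": s, "r": r, "p": p, "r2": r * r, "n": len(x)})
        pooled_x.extend(x)
        pooled_y.extend(y)
    gr, gp = stats.pearsonr(pooled_x, pooled_y)
    per_sample = pd.DataFrame(rows).set_index("sample")
    return PlatformCorrelation(per_sample=per_sample, global_r=float(gr), global_p=float(gp))


@dataclass
class LocusCensus:
    totals: dict[str, int]
    novel: dict[str, int]
    novel_percent: dict[str, int]


def locus_census(
    sets: dict[str, set[str]], novel_ids: set[str]
) -> LocusCensus:
    """Per-locus expressed totals, novel counts, and novel percentages."""
    totals = {s: len(v) for s, v in sets.items()}
    novel = {s: len(v & novel_ids) for s, v in sets.items()}
    pct = {
        s: int(np.floor(100 * novel[s] / totals[s] + 0.5)) if totals[s] else 0
        for s in sets
    }
    return LocusCensus(totals=totals, novel=novel, novel_percent=pct)
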