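"""Haplotype analytics for haploid microsatellite panels.

Distances between haplotypes use the Bruvo metric: for one locus with
repeat unit ``k`` and allele lengths ``a1, a2`` (bp), the repeat-unit
difference is ``x = |a1 - a2| / k`` and the locus distance ``1 - 2**-x``,
bounded in [0, 1]; the haplotype distance is the mean over loci
genotyped in both samples (pairwise deletion), NA when none are shared.
Trees are built with UPGMA (average linkage, ultrametric heights =
cluster distance / 2) and node support is estimated by resampling loci
without replacement.  Diversity per locus is Nei's gene diversity
``h = 1 - sum(p_i**2)`` over allele frequencies among non-missing calls,
optionally with the small-sample factor ``n / (n - 1)``, averaged over
loci.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_TOKEN = "."


@dataclass
class HaplotypeMatrix:
    """Samples x loci table of haploid allele lengths (bp), NaN = missing."""

    samples: list[str]
    loci: list[str]
    periods: list[int]
    alleles: np.ndarray  # float array (n_samples, n_loci), NaN = missing
    groups: dict[str, str] = field(default_factory=dict)  # sample -> species/deme

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=float)
        if self.alleles.shape != (len(self.samples), len(self.loci)):
            raise ValueError("allele table shape does not match samples x loci")
        if len(self.periods) != len(self.loci):
            raise ValueError("one period per locus required")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, periods: list[int], groups: dict[str, str] | None = None):
        return cls(list(df.index), list(df.columns), list(periods), df.to_numpy(dtype=float), groups or {})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.alleles, index=self.samples, columns=self.loci)

    def row(self, sample: str) -> np.ndarray:
        return self.alleles[self.samples.index(sample)]

    def subset_loci(self, idx: list[int]) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.samples,
            [self.loci[i] for i in idx],
            [self.periods[i] for i in idx],
            self.alleles[:, idx],
            self.groups,
        )


def bruvo_distance(h1: np.ndarray, h2: np.ndarray, periods) -> float:
    """Mean Bruvo distance over co-genotyped loci; NaN when none overlap."""
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    k = np.asarray(periods, dtype=float)
    both = ~np.isnan(h1) & ~np.isnan(h2)
    if not both.any():
        return float("nan")
    x = np.abs(h1[both] - h2[both]) / k[both]
    return float(np.mean(1.0 - np.power(2.0, -x)))


def bruvo_matrix(matrix: HaplotypeMatrix) -> pd.DataFrame:
    """Symmetric pairwise Bruvo distance matrix (NaN where no shared loci)."""
    n = len(matrix.samples)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = bruvo_distance(matrix.alleles[i], matrix.alleles[j], matrix.periods)
    return pd.DataFrame(d, index=matrix.samples, columns=matrix.samples)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class TreeNode:
    """Rooted tree node; ``height`` is the distance from node to its leaves."""

    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes (including the root)."""
        return [frozenset(n.leaves()) for n in self.walk() if not n.is_leaf]

    def to_newick(self, with_support: bool = False) -> str:
        def fmt(node: TreeNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{bl:.9g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.9g}"
            return f"({inner}){label}:{bl:.9g}"

        if self.is_leaf:
            return f"{self.name};"
        inner = ",".join(fmt(c, self.height) for c in self.children)
        label = f"{self.support:.9g}" if with_support and self.support is not None else ""
        return f"({inner}){label};"

    def cophenetic(self) -> pd.DataFrame:
        names = sorted(self.leaves())
        idx = {n: i for i, n in enumerate(names)}
        d = np.zeros((len(names), len(names)))

        def rec(node: TreeNode):
            if node.is_leaf:
                return [node.name]
            groups = [rec(c) for c in node.children]
            for a, b in itertools.combinations(range(len(groups)), 2):
                for x in groups[a]:
                    for y in groups[b]:
                        d[idx[x], idx[y]] = d[idx[y], idx[x]] = 2.0 * node.height
            return [x for g in groups for x in g]

        rec(self)
        return pd.DataFrame(d, index=names, columns=names)


def upgma(dist: pd.DataFrame) -> TreeNode:
    """Average-linkage agglomeration with lowest-index-pair tie-breaking.

    Rejects matrices containing NaN: restrict to samples with overlapping
    genotyped loci (or impute) before building a tree.
    """
    d = dist.to_numpy(dtype=float).copy()
    names = list(dist.index)
    if np.isnan(d).any():
        raise ValueError(
            "distance matrix contains NA; restrict to samples with co-genotyped loci first"
        )
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    nodes: list[TreeNode] = [TreeNode(name=n) for n in names]
    sizes = [1] * len(names)
    active = list(range(len(names)))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                val = d[i, j]
                if best is None or val < best[0]:
                    best = (val, i, j)
        val, i, j = best
        parent = TreeNode(children=[nodes[i], nodes[j]], height=val / 2.0)
        # Weighted average of distances (UPGMA: average over original pairs).
        for k in active:
            if k in (i, j):
                continue
            new = (d[i, k] * sizes[i] + d[j, k] * sizes[j]) / (sizes[i] + sizes[j])
            d[i, k] = d[k, i] = new
        nodes[i] = parent
        sizes[i] += sizes[j]
        active.remove(j)
    return nodes[active[0]]


def bootstrap_support(
    matrix: HaplotypeMatrix,
    n_resamples: int = 100,
    n_loci_per_resample: int | None = None,
    seed: int = 0,
) -> TreeNode:
    """UPGMA tree on the full data, with locus-resampling clade support.

    Each resample draws ``n_loci_per_resample`` loci *without replacement*,
    rebuilds Bruvo distances and the UPGMA tree, and each internal node of
    the full-data tree is annotated with the fraction of resample trees
    containing the same leaf set.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    n_loci = len(matrix.loci)
    if n_loci_per_resample is None:
        n_loci_per_resample = n_loci
    if n_loci_per_resample > n_loci:
        raise ValueError("n_loci_per_resample exceeds available loci")
    full = upgma(bruvo_matrix(matrix))
    counts: dict[frozenset[str], int] = {c: 0 for c in full.clades()}
    rng = np.random.default_rng(seed)
    for _ in range(n_resamples):
        idx = sorted(rng.choice(n_loci, size=n_loci_per_resample, replace=False))
        sub = matrix.subset_loci(list(idx))
        tree = upgma(bruvo_matrix(sub))
        seen = set(tree.clades())
        for c in counts:
            if c in seen:
                counts[c] += 1
    for node in full.walk():
        if node.is_leaf:
            node.support = 1.0
        else:
            node.support = counts[frozenset(node.leaves())] / n_resamples
    return full


# ---------------------------------------------------------------------------
# Diversity and polymorphism summaries


def gene_diversity(
    matrix: HaplotypeMatrix,
    grouping: dict[str, str] | None = None,
    corrected: bool = False,
    polymorphic_only: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Nei gene diversity per locus per group, and the per-group mean.

    ``h = 1 - sum(p_i**2)`` with allele frequencies over non-missing calls;
    ``corrected=True`` applies the (n/(n-1)) small-sample factor.  Loci with
    no non-missing call in a group are excluded from that group's mean;
    ``polymorphic_only`` additionally drops monomorphic loci from the mean.
    """
    grouping = grouping if grouping is not None else (matrix.groups or {s: "all" for s in matrix.samples})
    groups = sorted(set(grouping.values()))
    rows = {}
    for g in groups:
        keep = [i for i, s in enumerate(matrix.samples) if grouping.get(s) == g]
        if not keep:
            raise ValueError(f"group {g!r} has no samples")
        hvals = []
        for j in range(len(matrix.loci)):
            col = matrix.alleles[keep, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                hvals.append(np.nan)
                continue
            _, counts = np.unique(col, return_counts=True)
            p = counts / counts.sum()
            h = 1.0 - float(np.sum(p**2))
            if corrected and col.size > 1:
                h *= col.size / (col.size - 1)
            hvals.append(h)
        rows[g] = hvals
    per_locus = pd.DataFrame(rows, index=matrix.loci)
    means = {}
    for g in groups:
        vals = per_locus[g].dropna()
        if polymorphic_only:
            vals = vals[vals > 0]
        means[g] = float(vals.mean()) if len(vals) else float("nan")
    return per_locus, pd.Series(means, name="mean_gene_diversity")


def allele_summary(
    matrix: HaplotypeMatrix, grouping: dict[str, str] | None = None
) -> dict[str, object]:
    """Allele counts per locus, invariant-locus counts per group, and
    per-group mean/median alleles per locus (over loci with data)."""
    grouping = grouping if grouping is not None else (matrix.groups or {s: "all" for s in matrix.samples})
    groups = sorted(set(grouping.values()))
    n_loci = len(matrix.loci)

    def counts_for(rows: list[int]) -> list[int]:
        out = []
        for j in range(n_loci):
            col = matrix.alleles[rows, j]
            col = col[~np.isnan(col)]
            out.append(int(np.unique(col).size))
        return out

    overall = counts_for(list(range(len(matrix.samples))))
    per_group = {}
    invariant = {}
    stats = {}
    for g in groups:
        keep = [i for i, s in enumerate(matrix.samples) if grouping.get(s) == g]
        cts = counts_for(keep)
        per_group[g] = cts
        invariant[g] = sum(1 for c in cts if c == 1)
        with_data = [c for c in cts if c > 0]
        stats[g] = {
            "mean_alleles": float(np.mean(with_data)) if with_data else float("nan"),
            "median_alleles": float(np.median(with_data)) if with_data else float("nan"),
            "sd_alleles": float(np.std(with_data, ddof=1)) if len(with_data) > 1 else float("nan"),
        }
    return {
        "allele_counts": pd.DataFrame({**{"all": overall}, **per_group}, index=matrix.loci),
        "invariant_per_group": invariant,
        "monomorphic_all": sum(1 for c in overall if c == 1),
        "polymorphic_all": sum(1 for c in overall if c > 1),
        "group_stats": stats,
    }
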