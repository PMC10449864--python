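"""Similarity-based assignment of haplotypes to reference panels.

The normalized pairwise similarity index between two haplotypes is the
number of loci with identical alleles divided by the number of loci
genotyped in both (NA when no loci are shared) — robust to heavy
missingness in low-coverage samples.  A query is compared against every
member of two reference panels; a two-sided Wilcoxon rank-sum test
between the two similarity distributions, with multiple-testing
adjustment across the query batch, assigns the query to the panel with
the larger median similarity when the adjusted p-value clears ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .popgen import HaplotypeMatrix

UNASSIGNED = "unassigned"


@dataclass
class SimilarityResult:
    sample_a: str
    sample_b: str
    n_shared: int
    n_match: int

    @property
    def s(self) -> float:
        return self.n_match / self.n_shared if self.n_shared else float("nan")


@dataclass
class PanelAssignment:
    sample: str
    label: str
    p_raw: float | None
    p_adj: float | None
    median_a: float | None
    median_b: float | None
    n_a: int
    n_b: int
    note: str = ""


def similarity(h1: np.ndarray, h2: np.ndarray, name_a: str = "a", name_b: str = "b") -> SimilarityResult:
    """Fraction of co-genotyped loci carrying the same allele."""
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    both = ~np.isnan(h1) & ~np.isnan(h2)
    n_shared = int(both.sum())
    n_match = int((h1[both] == h2[both]).sum())
    return SimilarityResult(name_a, name_b, n_shared, n_match)


def benjamini_hochberg(pvals: list[float]) -> list[float]:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return [float(min(a, 1.0)) for a in adj]


def _adjust(pvals: list[float], method: str) -> list[float]:
    p = np.asarray(pvals, dtype=float)
    if method == "BH":
        return benjamini_hochberg(pvals)
    if method == "bonferroni":
        return [float(min(1.0, x * p.size)) for x in p]
    if method == "holm":
        order = np.argsort(p, kind="stable")
        adj = np.empty(p.size)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, p[i] * (p.size - rank))
            adj[i] = min(running, 1.0)
        return [float(x) for x in adj]
    raise ValueError(f"unknown adjustment method {method!r}")


def _similarities(query: np.ndarray, panel: HaplotypeMatrix, members: list[str]) -> list[float]:
    vals = []
    for m in members:
        s = similarity(query, panel.row(m)).s
        if not np.isnan(s):
            vals.append(s)
    return vals


def assign_samples(
    queries: HaplotypeMatrix,
    panel: HaplotypeMatrix,
    panel_a: list[str],
    panel_b: list[str],
    alpha: float = 0.05,
    adjust: str = "BH",
    label_a: str = "panel_A",
    label_b: str = "panel_B",
) -> list[PanelAssignment]:
    """Assign each query haplotype to one of two panels, batch-adjusted.

    Both matrices must share the same locus universe (same columns).
    A query stays unassigned when either similarity distribution has
    fewer than 2 usable (non-NA) values, when the adjusted p-value is
    >= ``alpha``, or when the two medians tie.
    """
    if not panel_a or not panel_b:
        raise ValueError("both panels must be non-empty")
    if set(panel_a) & set(panel_b):
        raise ValueError("panels must be disjoint")
    if queries.loci != panel.loci:
        raise ValueError("query and panel matrices must share the same loci")

    prelim: list[PanelAssignment] = []
    for sample in queries.samples:
        q = queries.row(sample)
        da = _similarities(q, panel, panel_a)
        db = _similarities(q, panel, panel_b)
        if len(da) < 2 or len(db) < 2:
            prelim.append(
                PanelAssignment(sample, UNASSIGNED, None, None,
                                float(np.median(da)) if da else None,
                                float(np.median(db)) if db else None,
                                len(da), len(db), note="too_few_comparisons")
            )
            continue
        if np.ptp(da + db) == 0.0:
            p = 1.0  # all similarities identical; rank test undefined
        else:
            p = float(sps.mannwhitneyu(da, db, alternative="two-sided").pvalue)
        prelim.append(
            PanelAssignment(sample, UNASSIGNED, p, None,
                            float(np.median(da)), float(np.median(db)), len(da), len(db))
        )

    tested = [a for a in prelim if a.p_raw is not None]
    if tested:
        adj = _adjust([a.p_raw for a in tested], adjust)
        for a, pa in zip(tested, adj):
            a.p_adj = pa
            if pa < alpha:
                if a.median_a > a.median_b:
                    a.label = label_a
                elif a.median_b > a.median_a:
                    a.label = label_b
                else:
                    a.note = "median_tie"
    return prelim
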