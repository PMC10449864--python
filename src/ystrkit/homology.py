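"""Cross-reference marker homology and in-silico PCR screening.

Homology between STR loci of two references is assessed on the repeat
region plus 200 bp of flanking sequence on each side, by best local
alignment (match +1, mismatch -2, gap open -5, gap extend -2).  Two loci
are homologous when identity (matches / alignment columns) exceeds 80%
and query coverage (aligned query span / query length) exceeds 65%, both
strictly.  The same criteria applied within one reference reveal
multi-copy markers (single-linkage clusters of the within-set match
graph), which confound single-locus genotyping.

In-silico PCR scans a genome for primer binding sites on both strands
with at most 10% Hamming mismatches (no indels), enumerates convergent
site pairs into amplicons, and classifies the pair's specificity; extra
amplicons longer than 10 kb are tolerated ("acceptable") since they
compete poorly against a short target during amplification.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .catalog import ReferenceSequence, TandemRepeatLocus

LONG_AMPLICON_BP = 10_000

LOCUS_SPECIFIC = "locus_specific"
ACCEPTABLE = "acceptable"
NON_SPECIFIC = "non_specific"
NO_AMPLICON = "no_amplicon"

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class FlankedLocusSeq:
    name: str
    seq: str
    source: str
    start: int  # flank-extended 0-based start on the source reference
    end: int


@dataclass
class HomologyMatch:
    query: str
    subject: str
    identity: float
    query_coverage: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    best: bool = False


@dataclass
class PrimerPair:
    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if set(p.upper()) - set("ACGT"):
                raise ValueError(f"primer {p!r} contains non-ACGT characters")
            if len(p) < 15:
                raise ValueError(f"primer {p!r} shorter than 15 bp")
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()


@dataclass
class Amplicon:
    chrom: str
    start: int
    end: int
    mm_forward: int
    mm_reverse: int
    target_overlap: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_flanked(
    catalog: list[TandemRepeatLocus], ref: ReferenceSequence, flank_bp: int = 200
) -> list[FlankedLocusSeq]:
    """Repeat region +/- ``flank_bp``, clipped at the chromosome ends."""
    out = []
    for locus in sorted(catalog, key=lambda L: L.start):
        if locus.start < 0 or locus.end > ref.length:
            raise ValueError(f"locus {locus.name or locus.start} outside reference {ref.id}")
        s = max(0, locus.start - flank_bp)
        e = min(ref.length, locus.end + flank_bp)
        out.append(FlankedLocusSeq(locus.name or f"{ref.id}:{locus.start}-{locus.end}",
                                   ref.seq[s:e], ref.id, s, e))
    return out


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -5
    al.extend_gap_score = -2
    return al


def _alignment_stats(aln) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """(identity, query span, subject span) of one local alignment."""
    # aligned blocks: pairs of (target block, query block)
    tgt_blocks, qry_blocks = aln.aligned
    matches = 0
    aligned_cols = 0
    t = aln.target
    q = aln.query
    prev_t_end = prev_q_end = None
    for (ts, te), (qs, qe) in zip(tgt_blocks, qry_blocks):
        if prev_t_end is not None:
            aligned_cols += (ts - prev_t_end) + (qs - prev_q_end)  # gap columns
        for a, b in zip(t[ts:te], q[qs:qe]):
            matches += a == b
        aligned_cols += te - ts
        prev_t_end, prev_q_end = te, qe
    if aligned_cols == 0:
        return 0.0, (0, 0), (0, 0)
    q_span = (int(qry_blocks[0][0]), int(qry_blocks[-1][1]))
    t_span = (int(tgt_blocks[0][0]), int(tgt_blocks[-1][1]))
    return matches / aligned_cols, q_span, t_span


def compare_pair(query: str, subject: str) -> tuple[float, float, tuple[int, int], tuple[int, int]]:
    """Best local alignment of query vs subject: (identity, query coverage, spans)."""
    al = _aligner()
    alns = al.align(subject, query)  # target = subject, query = query
    if len(alns) == 0 or alns.score <= 0:
        return 0.0, 0.0, (0, 0), (0, 0)
    best = alns[0]
    identity, q_span, t_span = _alignment_stats(best)
    coverage = (q_span[1] - q_span[0]) / len(query)
    return identity, coverage, q_span, t_span


def find_homologs(
    set_a: list[FlankedLocusSeq],
    set_b: list[FlankedLocusSeq],
    min_id: float = 0.80,
    min_cov: float = 0.65,
) -> list[HomologyMatch]:
    """All-vs-all local alignment; matches pass BOTH thresholds strictly."""
    if not set_a or not set_b:
        raise ValueError("both locus sets must be non-empty")
    matches: list[HomologyMatch] = []
    for qa in set_a:
        best_for_query: HomologyMatch | None = None
        for sb in set_b:
            identity, coverage, q_span, s_span = compare_pair(qa.seq, sb.seq)
            if identity > min_id and coverage > min_cov:
                m = HomologyMatch(qa.name, sb.name, identity, coverage, q_span, s_span)
                matches.append(m)
                if best_for_query is None or identity * coverage > (
                    best_for_query.identity * best_for_query.query_coverage
                ):
                    best_for_query = m
        if best_for_query is not None:
            best_for_query.best = True
    return matches


def find_multicopy(
    loci: list[FlankedLocusSeq], min_id: float = 0.80, min_cov: float = 0.65
) -> list[list[str]]:
    """Single-linkage clusters of within-reference matches (size >= 2).

    Cluster members are listed sorted by position on the reference;
    clusters sorted by their leftmost member.
    """
    order = {L.name: L.start for L in loci}
    parent = {L.name: L.name for L in loci}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(loci, 2):
        identity, coverage, _, _ = compare_pair(a.seq, b.seq)
        rid, rcov, _, _ = compare_pair(b.seq, a.seq)
        if (identity > min_id and coverage > min_cov) or (rid > min_id and rcov > min_cov):
            parent[find(a.name)] = find(b.name)
    groups: dict[str, list[str]] = {}
    for L in loci:
        groups.setdefault(find(L.name), []).append(L.name)
    clusters = [sorted(g, key=lambda n: order[n]) for g in groups.values() if len(g) >= 2]
    return sorted(clusters, key=lambda c: order[c[0]])


# ---------------------------------------------------------------------------
# In-silico PCR


def _binding_sites(genome: np.ndarray, primer: str, max_mm: float) -> list[tuple[int, int]]:
    """(start, n_mismatches) of sites where primer matches with Hamming
    mismatch fraction <= max_mm (no indels)."""
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    L = p.size
    n = genome.size
    if n < L:
        return []
    allowed = int(np.floor(max_mm * L + 1e-9))
    mm = np.zeros(n - L + 1, dtype=np.int32)
    for j in range(L):
        mm += genome[j : n - L + 1 + j] != p[j]
    hits = np.flatnonzero(mm <= allowed)
    return [(int(i), int(mm[i])) for i in hits]


def insilico_pcr(
    genome: ReferenceSequence,
    pair: PrimerPair,
    max_mm: float = 0.10,
    max_product_bp: int | None = None,
    target: tuple[int, int] | None = None,
) -> tuple[list[Amplicon], str]:
    """Enumerate amplicons of a primer pair on a genome and classify.

    A product arises from a sense primer site and a downstream antisense
    site of the other primer (both orientations are considered); the
    amplicon is the inclusive span from the 5' end of the sense site to
    the 5' end of the antisense site.  Classes: ``locus_specific`` -- a
    single amplicon overlapping the target; ``acceptable`` -- a unique
    sub-10 kb amplicon overlapping the target while every other amplicon
    exceeds 10 kb; ``non_specific`` otherwise (``no_amplicon`` when the
    pair yields no product).  Without a target, a single amplicon is
    ``locus_specific``.
    """
    g = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    fwd, rev = pair.forward, pair.reverse
    amplicons: list[Amplicon] = []
    # orientation 1: forward on + strand, reverse on - strand
    # orientation 2: reverse on + strand, forward on - strand
    for plus_primer, minus_primer, swap in ((fwd, rev, False), (rev, fwd, True)):
        plus_sites = _binding_sites(g, plus_primer, max_mm)
        minus_sites = _binding_sites(g, revcomp(minus_primer), max_mm)
        for ps, pmm in plus_sites:
            for ms, mmm in minus_sites:
                end = ms + len(minus_primer)
                if end <= ps + len(plus_primer):
                    continue  # not convergent
                length = end - ps
                if max_product_bp is not None and length > max_product_bp:
                    continue
                amp = Amplicon(
                    chrom=genome.id,
                    start=ps,
                    end=end,
                    mm_forward=mmm if swap else pmm,
                    mm_reverse=pmm if swap else mmm,
                )
                if target is not None:
                    amp.target_overlap = amp.start < target[1] and target[0] < amp.end
                amplicons.append(amp)
    # Deduplicate palindromic double counting.
    uniq: dict[tuple[int, int], Amplicon] = {}
    for a in sorted(amplicons, key=lambda a: (a.start, a.end)):
        uniq.setdefault((a.start, a.end), a)
    amplicons = list(uniq.values())

    if not amplicons:
        return amplicons, NO_AMPLICON
    on_target = [a for a in amplicons if a.target_overlap or target is None]
    short = [a for a in amplicons if a.length <= LONG_AMPLICON_BP]
    if len(amplicons) == 1 and on_target:
        cls = LOCUS_SPECIFIC
    elif len(short) == 1 and (short[0].target_overlap or target is None):
        cls = ACCEPTABLE
    else:
        cls = NON_SPECIFIC
    return amplicons, cls
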