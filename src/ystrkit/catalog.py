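"""Tandem-repeat discovery on a Y (or W) chromosome reference.

The scanner looks for short tandem repeats (STRs) with repeat units of
2-6 bp directly from the k-periodic self-match structure of the sequence:
position ``i`` supports period ``k`` when ``seq[i] == seq[i + k]``.  A
reported region is a maximal interval whose fraction of supporting
positions (its *purity*) stays at or above a threshold, so near-perfect
repeats are reported as single loci while diverged background is not.

Downstream selection mirrors a marker-development workflow for haploid,
PCR-typeable loci: units of 3-6 bp (dinucleotides are scanned but then
excluded because of their pronounced stutter), at least 8 copies, a
variable region no longer than 100 bp, and exclusion of any locus
touching a pseudoautosomal-region mask, where loci would not be
male-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_VALID = set("ACGTN")

#: Pseudoautosomal region of the olive-baboon Y scaffold NC_044997.1
#: (1-based positions 1..1,047,499), as a 0-based half-open interval.
PANUBIS1_Y_PAR = (0, 1_047_499)


@dataclass(frozen=True)
class ReferenceSequence:
    """A named chromosome-scale DNA sequence over the A,C,G,T,N alphabet."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"reference {self.id!r} is empty")
        bad = set(self.seq.upper()) - _VALID
        if bad:
            raise ValueError(f"reference {self.id!r} contains non-ACGTN characters: {sorted(bad)}")
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class RegionMask:
    """Sorted, non-overlapping 0-based half-open intervals to exclude."""

    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        norm: list[tuple[int, int]] = []
        ivals = sorted((int(s), int(e)) for s, e in self.intervals)
        for start, end in ivals:
            if not 0 <= start < end:
                raise ValueError(f"invalid mask interval ({start}, {end})")
            if norm and start <= norm[-1][1]:
                norm[-1] = (norm[-1][0], max(norm[-1][1], end))
            else:
                norm.append((start, end))
        self.intervals = norm

    def overlaps(self, start: int, end: int) -> bool:
        """True if [start, end) shares at least one bp with the mask."""
        for s, e in self.intervals:
            if s < end and start < e:
                return True
            if s >= end:
                break
        return False


@dataclass
class TandemRepeatLocus:
    chrom: str
    start: int
    end: int
    motif: str
    period: int
    copies: float
    purity: float
    name: str | None = None
    exclusion_reason: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ScanParams:
    """Scan and selection thresholds.

    ``min_period`` defaults to 2 so that dinucleotide repeats are detected
    and then *reported as excluded* by :func:`filter_catalog`, keeping the
    exclusion tally complete; the selection itself keeps periods 3-6.
    """

    min_period: int = 2
    max_period: int = 6
    min_copies: float = 8.0
    max_len: int = 100
    min_purity: float = 0.9
    # Detection floor: the scanner also reports shorter runs (so the
    # exclusion tally is complete); selection applies min_copies.
    scan_min_copies: float = 4.0
    # Candidate intervals longer than this are never considered at scan
    # time; selection caps loci at max_len anyway, so this only bounds the
    # merge search on repeat-dense sequence.
    max_scan_len: int = 2000

    def __post_init__(self) -> None:
        if self.min_period > self.max_period:
            raise ValueError("min_period > max_period")
        if self.min_period < 2 or self.max_period > 6:
            raise ValueError("scan periods must lie in [2, 6]")
        if self.min_copies < 2:
            raise ValueError("min_copies must be >= 2")
        if not 0.0 < self.min_purity <= 1.0:
            raise ValueError("min_purity must be in (0, 1]")

    @property
    def detect_floor(self) -> float:
        """Copy-number floor the scanner itself applies."""
        return min(self.scan_min_copies, self.min_copies)


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation of ``motif`` (same strand only)."""
    motif = motif.upper()
    if not 2 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 2-6, got {motif!r}")
    if set(motif) - {"A", "C", "G", "T"}:
        raise ValueError(f"motif must be ACGT only, got {motif!r}")
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _primitive_period(unit: str) -> int:
    """Smallest p such that ``unit`` is a repetition of its first p characters."""
    n = len(unit)
    for p in range(1, n + 1):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return p
    return n


def _passing_intervals(match: np.ndarray, k: int, params: ScanParams) -> list[tuple[int, int]]:
    """Maximal intervals for period k satisfying the purity rule.

    ``match[i]`` is True when seq[i] == seq[i+k] and neither base is N.
    An interval [s, e) (e - s >= k * min_copies) passes when
    match[s] and match[e-k-1] are True and
    sum(match[s:e-k]) / (e - s - k) >= min_purity.
    Returned intervals are maximal by containment, then overlapping ones
    are merged.
    """
    min_len = int(np.ceil(k * params.detect_floor))
    idx = np.flatnonzero(match)
    if idx.size == 0:
        return []
    csum = np.concatenate([[0], np.cumsum(match)])
    p = params.min_purity

    raw: list[tuple[int, int]] = []
    # Only "run head" starts matter: if match[s-1] holds, any passing
    # interval at s is contained in a passing interval at s-1.
    heads = idx[np.concatenate([[True], np.diff(idx) > 1])]
    for s in heads:
        s = int(s)
        j0 = int(np.searchsorted(idx, s + min_len - k - 1))
        j1 = int(np.searchsorted(idx, s + params.max_scan_len - k - 1, side="right"))
        if j0 >= j1:
            continue
        ends = idx[j0:j1] + k + 1
        m = csum[ends - k] - csum[s]
        ok = m >= p * (ends - s - k)
        hits = np.flatnonzero(ok)
        if hits.size:
            raw.append((s, int(ends[hits[-1]])))
    if not raw:
        return []
    # Maximal by containment.
    raw.sort(key=lambda iv: (iv[0], -iv[1]))
    maximal: list[tuple[int, int]] = []
    best_end = -1
    for s, e in raw:
        if e > best_end:
            maximal.append((s, e))
            best_end = e
    # Merge overlap per period.
    merged = [maximal[0]]
    for s, e in maximal[1:]:
        if s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _trim_to_phase(seq: str, s: int, e: int, period: int, unit: str, anchor: int) -> tuple[int, int]:
    """Trim [s, e) so each end starts/ends with a full unit in phase.

    ``unit`` is the repeat unit read at position ``anchor`` (so
    ``seq[i]`` is expected to equal ``unit[(i - anchor) % period]``).
    The start advances to the first position opening a clean in-phase
    unit; the end recedes to the last position closing one.  Interior
    mismatches (impure repeats) are untouched.
    """

    def ok(i: int) -> bool:
        return seq[i] == unit[(i - anchor) % period]

    s2, e2 = s, e
    while True:
        while s2 + period <= e2 and not all(ok(i) for i in range(s2, s2 + period)):
            s2 += 1
        while e2 - period >= s2 and not all(ok(i) for i in range(e2 - period, e2)):
            e2 -= 1
        if e2 - s2 < period:
            return s, s  # nothing phase-consistent survives
        # Drop terminal units separated from the interior by a full unit
        # of mismatches (coincidental in-phase background hits).
        changed = False
        if e2 - 2 * period >= s2 and not any(ok(i) for i in range(e2 - 2 * period, e2 - period)):
            e2 -= period
            changed = True
        if s2 + 2 * period <= e2 and not any(ok(i) for i in range(s2 + period, s2 + 2 * period)):
            s2 += period
            changed = True
        if not changed:
            return s2, e2


def scan_tandem_repeats(ref: ReferenceSequence, params: ScanParams | None = None) -> list[TandemRepeatLocus]:
    """Scan a reference for tandem repeats of period min_period..max_period.

    Regions are reduced to the smallest period explaining them (an
    (ACTACT)n run is reported with period 3, not 6); homopolymer runs
    (primitive period 1) are outside the scan range and not reported.
    Deterministic; loci are sorted by start, then period.
    """
    params = params or ScanParams()
    seq = ref.seq
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_n = arr == ord("N")

    found: dict[tuple[int, int], TandemRepeatLocus] = {}
    for k in range(params.min_period, params.max_period + 1):
        if n <= k:
            continue
        match = (arr[:-k] == arr[k:]) & ~is_n[:-k] & ~is_n[k:]
        for s, e in _passing_intervals(match, k, params):
            m = int(np.count_nonzero(match[s : e - k]))
            purity = m / (e - s - k)
            # Read the unit from the interval's center: the boundaries may
            # have absorbed impure flanking matches under the purity rule.
            mid = s + (((e - s) // k) // 2) * k
            mid = min(mid, e - k)
            unit = seq[mid : mid + k]
            prim = _primitive_period(unit)
            if prim == 1:
                continue  # homopolymer; period-1 repeats are out of scan range
            period = prim if prim < k else k
            # Boundary refinement: the purity rule can absorb flanking
            # positions that match at lag k without belonging to the
            # repeat; trim to edges phase-consistent with the central unit.
            punit = unit[:period]
            s2, e2 = _trim_to_phase(seq, s, e, period, punit, mid)
            if e2 - s2 < period:
                continue
            copies = (e2 - s2) / period
            if copies < params.detect_floor:
                continue
            key = (s2, e2)
            locus = TandemRepeatLocus(
                chrom=ref.id,
                start=s2,
                end=e2,
                motif=canonical_motif(punit),
                period=period,
                copies=round(copies, 6),
                purity=round(purity, 6),
            )
            prev = found.get(key)
            if prev is None or locus.period < prev.period:
                found[key] = locus

    # A region can surface at several scan periods (e.g. a dinucleotide
    # run at k = 2, 4 and 6 with slightly different boundaries); merge
    # overlapping same-period same-motif regions and recompute stats.
    match_arrays = {}
    for k in range(params.min_period, params.max_period + 1):
        if n > k:
            match_arrays[k] = (arr[:-k] == arr[k:]) & ~is_n[:-k] & ~is_n[k:]
    by_key: dict[tuple[int, str], list[TandemRepeatLocus]] = {}
    for L in found.values():
        by_key.setdefault((L.period, L.motif), []).append(L)
    merged: list[TandemRepeatLocus] = []
    for (period, motif), group in by_key.items():
        group.sort(key=lambda L: L.start)
        spans = [[group[0].start, group[0].end]]
        for L in group[1:]:
            if L.start < spans[-1][1]:
                spans[-1][1] = max(spans[-1][1], L.end)
            else:
                spans.append([L.start, L.end])
        for s, e in spans:
            m = int(np.count_nonzero(match_arrays[period][s : e - period]))
            merged.append(
                TandemRepeatLocus(
                    chrom=ref.id, start=s, end=e, motif=motif, period=period,
                    copies=round((e - s) / period, 6),
                    purity=round(m / (e - s - period), 6),
                )
            )

    loci = sorted(merged, key=lambda L: (L.start, L.period))
    # Smallest-period reduction across nested/overlapping spans: drop a
    # locus when a smaller-period locus whose period divides it covers it.
    kept: list[TandemRepeatLocus] = []
    for L in loci:
        shadowed = False
        for M in loci:
            if M is L or M.period >= L.period or L.period % M.period != 0:
                continue
            if M.start <= L.start and M.end >= L.end:
                shadowed = True
                break
        if not shadowed:
            kept.append(L)
    return kept


# Exclusion reasons, in priority order (first matching wins).
REASON_MASK = "mask"
REASON_PERIOD = "period"
REASON_COPIES = "copies"
REASON_LENGTH = "length"


def filter_catalog(
    loci: list[TandemRepeatLocus],
    mask: RegionMask | None = None,
    params: ScanParams | None = None,
) -> tuple[list[TandemRepeatLocus], list[TandemRepeatLocus]]:
    """Apply the marker-selection filters; returns (kept, excluded).

    A locus is excluded when it overlaps the mask by any single bp, has
    period < 3 (dinucleotide), fewer than ``min_copies`` copies, or is
    longer than ``max_len``; exactly one reason is recorded, in the
    priority order mask > period > copies > length.
    """
    params = params or ScanParams()
    mask = mask or RegionMask()
    kept: list[TandemRepeatLocus] = []
    excluded: list[TandemRepeatLocus] = []
    for locus in sorted(loci, key=lambda L: (L.start, L.period)):
        reason = None
        if mask.overlaps(locus.start, locus.end):
            reason = REASON_MASK
        elif locus.period < 3:
            reason = REASON_PERIOD
        elif locus.copies < params.min_copies:
            reason = REASON_COPIES
        elif locus.length > params.max_len:
            reason = REASON_LENGTH
        if reason is None:
            kept.append(replace(locus, exclusion_reason=None))
        else:
            excluded.append(replace(locus, exclusion_reason=reason))
    return kept, excluded


def assign_names(
    loci: list[TandemRepeatLocus],
    prefix: str,
    human_homologs: dict[tuple[int, int], str] | None = None,
) -> list[TandemRepeatLocus]:
    """Name loci ``<prefix>1..N`` progressively along the chromosome.

    ``human_homologs`` maps (start, end) of a locus to a human Y-STR label
    (e.g. DYS565); homologous loci take the human label while still
    consuming their positional number, keeping downstream numbering stable.
    """
    if not prefix:
        raise ValueError("prefix must be non-empty")
    human_homologs = human_homologs or {}
    labels = list(human_homologs.values())
    dupes = {v for v in labels if labels.count(v) > 1}
    if dupes:
        raise ValueError(f"duplicate human labels for distinct loci: {sorted(dupes)}")
    out: list[TandemRepeatLocus] = []
    names: set[str] = set()
    for i, locus in enumerate(sorted(loci, key=lambda L: L.start), start=1):
        name = human_homologs.get((locus.start, locus.end), f"{prefix}{i}")
        if name in names:
            raise ValueError(f"duplicate locus name {name!r}")
        names.add(name)
        out.append(replace(locus, name=name))
    return out
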