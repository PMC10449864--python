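"""Synthetic study generator: reference, haplotypes, and aligned reads.

Everything the toolkit consumes can be produced here with known truth:
a Y-like reference with perfect tandem repeats planted in non-repetitive
background, male genealogies whose alleles evolve under a single-step
stepwise mutation model (+/-1 repeat unit per transmission), female
samples carrying no Y-derived reads (unless a leak is requested), and
uniformly placed error-free-alignment reads in which PCR stutter
(whole-unit slips of the repeat tract), 1-bp flanking indels and uniform
base errors are injected at configurable rates and recorded per read.

Reads are emitted pre-aligned with exact CIGARs against the reference:
mapping is outside the toolkit's scope, so alignment noise enters only
through the explicit indel and base-error channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import (
    ReferenceSequence,
    ScanParams,
    TandemRepeatLocus,
    assign_names,
    canonical_motif,
    scan_tandem_repeats,
    _primitive_period,
)
from .genotyper import AlignedRead

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    seed: int = 0
    chrom: str = "Ysim"
    chrom_len: int = 80_000
    n_loci: int = 40
    # Tetranucleotides dominate real Y-STR catalogs; weights reflect that.
    period_weights: dict[int, float] = field(
        default_factory=lambda: {3: 0.2, 4: 0.4, 5: 0.2, 6: 0.2}
    )
    copies_range: tuple[int, int] = (8, 15)
    min_spacing: int = 200
    n_males: int = 12
    n_females: int = 4
    founder_allele_spread: int = 3  # founders start at ref +/- U{-spread..spread} units
    mutation_rate: float = 0.002  # per locus per father->son transmission
    coverage: float = 10.0
    read_len: int = 150
    p_stutter: float = 0.05
    p_flank_indel: float = 0.02
    base_error: float = 0.001
    female_leak_reads: int = 0  # reads leaked to each female at leak_locus
    leak_locus: int | None = None
    prefix: str = "SimY"

    def __post_init__(self) -> None:
        for p in (self.p_stutter, self.p_flank_indel, self.base_error, self.mutation_rate):
            if not 0.0 <= p < 1.0:
                raise ValueError("probabilities must lie in [0, 1)")
        max_locus = 6 * self.copies_range[1]
        if self.read_len <= max_locus + 20:
            raise ValueError("read_len must exceed max locus length + 2 x anchor (20 bp)")
        if self.min_spacing < self.read_len:
            # a read may then span two loci; the read builder assumes at most one
            self.min_spacing = self.read_len
        need = self.n_loci * max_locus + (self.n_loci + 1) * self.min_spacing
        if need > self.chrom_len:
            raise ValueError(
                f"cannot pack {self.n_loci} loci with spacing {self.min_spacing} "
                f"into {self.chrom_len} bp (need >= {need})"
            )


@dataclass
class TruthTable:
    alleles: dict[str, dict[str, int]]  # sample -> locus name -> allele bp
    pedigree: dict[str, str | None]  # sample -> father (None for founders)
    females: list[str]
    mutation_events: list[tuple[str, str, int]]  # (son, locus, +/- units)
    read_provenance: dict[str, list[dict]] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode()


_STRICT_BG = ScanParams(min_period=2, min_copies=6.0, min_purity=0.85, max_scan_len=500)


def _clean_background(rng: np.random.Generator, n: int) -> str:
    """Random sequence free of accidental period 2-6 tandem runs."""
    for _ in range(50):
        seq = _random_seq(rng, n)
        if n < 12 or not scan_tandem_repeats(ReferenceSequence("bg", seq), _STRICT_BG):
            return seq
    raise RuntimeError("could not generate repeat-free background")


def _random_unit(rng: np.random.Generator, period: int) -> str:
    while True:
        unit = _random_seq(rng, period)
        if _primitive_period(unit) == period:
            return unit


def simulate_reference(cfg: SimConfig) -> tuple[ReferenceSequence, list[TandemRepeatLocus]]:
    """Reference with ``n_loci`` planted perfect repeats plus truth catalog.

    All planted loci pass the selection filters by construction (period
    3-6, >= 8 copies, <= 100 bp, primitive motif) and are separated by at
    least ``min_spacing`` bp of repeat-free background.
    """
    rng = np.random.default_rng(cfg.seed)
    periods = sorted(cfg.period_weights)
    weights = np.array([cfg.period_weights[p] for p in periods], dtype=float)
    weights /= weights.sum()

    tracts: list[tuple[str, int, int]] = []  # (unit, period, copies)
    for _ in range(cfg.n_loci):
        period = int(rng.choice(periods, p=weights))
        max_copies = min(cfg.copies_range[1], 100 // period)
        copies = int(rng.integers(cfg.copies_range[0], max_copies + 1))
        tracts.append((_random_unit(rng, period), period, copies))

    total_tract = sum(p * c for _, p, c in tracts)
    slack = cfg.chrom_len - total_tract - (cfg.n_loci + 1) * cfg.min_spacing
    extra = rng.multinomial(slack, np.ones(cfg.n_loci + 1) / (cfg.n_loci + 1)) if slack > 0 else np.zeros(cfg.n_loci + 1, dtype=int)

    pieces: list[str] = []
    loci: list[TandemRepeatLocus] = []
    pos = 0
    for i, (unit, period, copies) in enumerate(tracts):
        gap = cfg.min_spacing + int(extra[i])
        pieces.append(_clean_background(rng, gap))
        pos += gap
        tract = unit * copies
        loci.append(
            TandemRepeatLocus(
                chrom=cfg.chrom,
                start=pos,
                end=pos + len(tract),
                motif=canonical_motif(unit),
                period=period,
                copies=float(copies),
                purity=1.0,
            )
        )
        pieces.append(tract)
        pos += len(tract)
    pieces.append(_clean_background(rng, cfg.min_spacing + int(extra[-1])))
    seq = "".join(pieces)
    ref = ReferenceSequence(cfg.chrom, seq)
    return ref, assign_names(loci, cfg.prefix)


def make_pedigree(
    n_males: int, n_founders: int = 1, generations: int = 3, seed: int = 0
) -> dict[str, str | None]:
    """Random male genealogy: sample -> father (None for founders).

    Founders come first; each subsequent male's father is drawn among
    males of any earlier index, with generation depth capped.
    """
    rng = np.random.default_rng(seed)
    names = [f"M{i + 1}" for i in range(n_males)]
    depth = {}
    ped: dict[str, str | None] = {}
    for i, name in enumerate(names):
        if i < n_founders:
            ped[name] = None
            depth[name] = 0
            continue
        candidates = [m for m in names[:i] if depth[m] < generations - 1]
        father = str(rng.choice(candidates)) if candidates else None
        ped[name] = father
        depth[name] = depth[father] + 1 if father else 0
    return ped


def star_pedigree(n_males: int) -> dict[str, str | None]:
    """Independent founders (no shared paternal history)."""
    return {f"M{i + 1}": None for i in range(n_males)}


def simulate_haplotypes(
    catalog: list[TandemRepeatLocus],
    cfg: SimConfig,
    pedigree: dict[str, str | None] | None = None,
) -> TruthTable:
    """Planted alleles per male under single-step stepwise mutation."""
    rng = np.random.default_rng(cfg.seed + 1)
    if pedigree is None:
        pedigree = star_pedigree(cfg.n_males)
    alleles: dict[str, dict[str, int]] = {}
    events: list[tuple[str, str, int]] = []
    # process fathers before sons
    done: set[str] = set()
    order: list[str] = []

    def visit(s: str) -> None:
        if s in done:
            return
        f = pedigree[s]
        if f is not None:
            visit(f)
        done.add(s)
        order.append(s)

    for s in pedigree:
        visit(s)
    for sample in order:
        father = pedigree[sample]
        hap: dict[str, int] = {}
        if father is None:
            for locus in catalog:
                shift = int(rng.integers(-cfg.founder_allele_spread, cfg.founder_allele_spread + 1))
                hap[locus.name] = locus.length + shift * locus.period
        else:
            for locus in catalog:
                allele = alleles[father][locus.name]
                if rng.random() < cfg.mutation_rate:
                    step = int(rng.choice([-1, 1]))
                    allele += step * locus.period
                    events.append((sample, locus.name, step))
                hap[locus.name] = allele
        alleles[sample] = hap
    females = [f"F{i + 1}" for i in range(cfg.n_females)]
    return TruthTable(alleles=alleles, pedigree=dict(pedigree), females=females, mutation_events=events)


# ---------------------------------------------------------------------------
# Read generation


class _Donor:
    """Per-sample chromosome with each repeat tract resized to its allele."""

    def __init__(self, ref: ReferenceSequence, catalog: list[TandemRepeatLocus], hap: dict[str, int]):
        pieces = []
        self.tracts = []  # (donor_start, donor_end, ref_start, ref_end, period, name)
        pos_ref = 0
        pos_donor = 0
        for locus in catalog:
            bg = ref.seq[pos_ref : locus.start]
            pieces.append(bg)
            pos_donor += len(bg)
            allele = hap[locus.name]
            unit = ref.seq[locus.start : locus.start + locus.period]
            tract = (unit * (allele // locus.period + 2))[:allele]
            self.tracts.append((pos_donor, pos_donor + allele, locus.start, locus.end, locus.period, locus.name))
            pieces.append(tract)
            pos_donor += allele
            pos_ref = locus.end
        pieces.append(ref.seq[pos_ref:])
        self.seq = "".join(pieces)
        self.ref = ref

    def tract_at(self, d0: int, d1: int):
        """The single tract intersecting donor interval [d0, d1), or None."""
        for t in self.tracts:
            if t[0] < d1 and d0 < t[1]:
                return t
        return None

    def ref_pos(self, d: int) -> int:
        """Reference coordinate of donor position ``d`` (background only)."""
        shift = 0
        for ds, de, rs, re, _, _ in self.tracts:
            if d >= de:
                shift += (re - rs) - (de - ds)
            elif d >= ds:
                raise ValueError("position inside a tract")
        return d + shift


def _build_read(
    donor: _Donor,
    d0: int,
    read_len: int,
    slip_units: int,
    rng: np.random.Generator,
) -> tuple[int, list[tuple[str, int]], str] | None:
    """Sequence + CIGAR of a read starting at donor position d0.

    ``slip_units`` != 0 resizes the (fully spanned) repeat tract by that
    many units, emulating PCR stutter.  Returns (ref_pos, cigar, seq) or
    None when the read would run off the chromosome.
    """
    d1 = d0 + read_len
    tract = donor.tract_at(d0, d1)
    if tract is None:
        if d1 > len(donor.seq):
            return None
        return donor.ref_pos(d0), [("M", read_len)], donor.seq[d0:d1]

    ds, de, rs, re, period, _ = tract
    la = de - ds  # sample allele length
    lr = re - rs  # reference tract length
    unit = donor.seq[ds : ds + period]
    spans = d0 <= ds and d1 >= de
    if slip_units and not spans:
        slip_units = 0
    la_eff = la + slip_units * period
    if la_eff < period:
        slip_units = 0
        la_eff = la
    tract_seq = (unit * (la_eff // period + 2))[:la_eff]

    pre = donor.seq[d0:ds] if d0 < ds else ""
    # donor offset into the tract where the read starts
    off = max(0, d0 - ds)
    tail_needed = read_len - len(pre) - max(0, la_eff - off)
    seq_parts = [pre, tract_seq[off:]]
    suffix = ""
    if tail_needed > 0:
        nxt = donor.tract_at(de, de + tail_needed)
        if nxt is not None or de + tail_needed > len(donor.seq):
            return None  # would hit a second tract or chromosome end
        suffix = donor.seq[de : de + tail_needed]
    seq = ("".join(seq_parts) + suffix)[:read_len]
    if len(seq) < read_len:
        return None

    cigar: list[tuple[str, int]] = []

    def add(op: str, ln: int) -> None:
        if ln <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))

    m = min(la_eff, lr)  # matched prefix of the tract alignment
    if pre:
        pos = donor.ref_pos(d0)
        add("M", len(pre))
    elif off < m:
        pos = rs + off
    else:  # read starts inside inserted (allele-extra) bases: soft-clip them
        pos = re
    covered = min(la_eff, d1 - ds) - off if off < la_eff else 0
    if covered > 0:
        lo, hi = off, off + covered
        if pre == "" and off >= m:
            add("S", covered if hi <= la_eff else la_eff - off)
        else:
            add("M", max(0, min(hi, m) - lo))
            add("I", max(0, hi - max(lo, m)))
    if (pre or off < m) and (d1 >= de or covered + off >= la_eff):
        # read reaches the tract's 3' boundary on the reference side
        if la_eff < lr and off < m:
            add("D", lr - la_eff)
    add("M", len(suffix))
    # trailing insertion at the very end of a read is representable; keep it
    q = sum(ln for op, ln in cigar if op in "MIS=X")
    if q != read_len:  # defensive: never emit an inconsistent record
        return None
    return pos, cigar, seq


def _inject_flank_indel(
    pos: int,
    cigar: list[tuple[str, int]],
    seq: str,
    donor: _Donor,
    tract,
    rng: np.random.Generator,
) -> tuple[int, list[tuple[str, int]], str] | None:
    """1-bp insertion or deletion in the 10-bp flank upstream of the tract.

    Only applied when the read has a plain M prefix covering the flank;
    the read length is preserved (insertion drops the last base, deletion
    appends the next donor base).
    """
    if not cigar or cigar[0][0] != "M":
        return None
    ds, de, rs, re, period, _ = tract
    pre_len = rs - pos  # M bases before the tract start on the reference
    if pre_len > cigar[0][1]:
        return None
    window = min(10, pre_len - 1)
    if window < 1:
        return None
    # read offset at which the indel is placed (within [start-10, start))
    offset = pre_len - 1 - int(rng.integers(0, window))
    insert = bool(rng.integers(0, 2))
    rest = cigar[1:]
    first_m = cigar[0][1]
    if insert:
        base = "ACGT"[int(rng.integers(0, 4))]
        new_seq = seq[:offset] + base + seq[offset:-1]
        new_cigar = [("M", offset), ("I", 1), ("M", first_m - offset)] + list(rest)
        # dropping the last base shortens the final query-consuming op
        for i in range(len(new_cigar) - 1, -1, -1):
            op, ln = new_cigar[i]
            if op in "MIS":
                if ln == 1:
                    del new_cigar[i]
                else:
                    new_cigar[i] = (op, ln - 1)
                break
    else:
        # delete the reference base at the offset; extend the read by one donor base
        tail_ref_end = pos
        for op, ln in cigar:
            if op in ("M", "D", "N", "=", "X"):
                tail_ref_end += ln
        nxt = donor.ref.seq[tail_ref_end : tail_ref_end + 1]
        if not nxt:
            return None
        new_seq = seq[:offset] + seq[offset + 1 :] + nxt
        new_cigar = [("M", offset), ("D", 1), ("M", first_m - offset - 1)] + list(rest)
        op, ln = new_cigar[-1]
        if op == "M":
            new_cigar[-1] = (op, ln + 1)
        else:
            new_cigar.append(("M", 1))
    merged: list[tuple[str, int]] = []
    for op, ln in new_cigar:
        if ln <= 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return pos, merged, new_seq


def simulate_reads(
    ref: ReferenceSequence,
    catalog: list[TandemRepeatLocus],
    truth: TruthTable,
    sample: str,
    cfg: SimConfig,
    seed_offset: int = 0,
) -> list[AlignedRead]:
    """Uniform-coverage reads for one sample, with recorded noise events.

    Female samples receive no Y-derived reads, except an optional leak of
    ``female_leak_reads`` reads at ``leak_locus`` used to exercise the
    female-read site filter.
    """
    rng = np.random.default_rng((cfg.seed, 2, seed_offset))
    provenance: list[dict] = []
    reads: list[AlignedRead] = []

    if sample in truth.females:
        if cfg.female_leak_reads and cfg.leak_locus is not None:
            locus = catalog[cfg.leak_locus]
            for i in range(cfg.female_leak_reads):
                margin = cfg.read_len - locus.length - 20
                d0 = locus.start - 10 - int(rng.integers(0, max(1, margin)))
                d0 = max(0, d0)
                seq = ref.seq[d0 : d0 + cfg.read_len]
                reads.append(
                    AlignedRead(
                        name=f"{sample}.leak{i}",
                        chrom=ref.id,
                        pos=d0,
                        cigar=(("M", cfg.read_len),),
                        mapq=60,
                        seq=seq,
                    )
                )
                provenance.append({"name": f"{sample}.leak{i}", "locus": locus.name, "slip": 0, "flank_indel": False})
        truth.read_provenance[sample] = provenance
        return reads

    donor = _Donor(ref, catalog, truth.alleles[sample])
    n_reads = int(round(cfg.coverage * len(donor.seq) / cfg.read_len))
    starts = rng.integers(0, len(donor.seq) - cfg.read_len - 10, size=n_reads)
    for i, d0 in enumerate(sorted(int(x) for x in starts)):
        tract = donor.tract_at(d0, d0 + cfg.read_len)
        spans = tract is not None and d0 <= tract[0] and d0 + cfg.read_len >= tract[1]
        slip = 0
        if spans and rng.random() < cfg.p_stutter:
            slip = int(rng.choice([-1, 1]))
        built = _build_read(donor, d0, cfg.read_len, slip, rng)
        if built is None:
            continue
        pos, cigar, seq = built
        flank = False
        if spans and rng.random() < cfg.p_flank_indel:
            injected = _inject_flank_indel(pos, cigar, seq, donor, tract, rng)
            if injected is not None:
                pos, cigar, seq = injected
                flank = True
        n_err = 0
        if cfg.base_error > 0:
            arr = bytearray(seq.encode())
            hits = np.flatnonzero(rng.random(len(arr)) < cfg.base_error)
            for h in hits:
                cur = chr(arr[h])
                arr[h] = ord(rng.choice([b for b in "ACGT" if b != cur]))
                n_err += 1
            seq = arr.decode()
        name = f"{sample}.r{i}"
        reads.append(
            AlignedRead(name=name, chrom=ref.id, pos=pos, cigar=tuple(cigar), mapq=60, seq=seq)
        )
        provenance.append(
            {
                "name": name,
                "locus": tract[5] if tract is not None else None,
                "spans": spans,
                "slip": slip,
                "flank_indel": flank,
                "base_errors": n_err,
            }
        )
    truth.read_provenance[sample] = provenance
    return reads


def simulate_study(
    cfg: SimConfig, pedigree: dict[str, str | None] | None = None
) -> tuple[ReferenceSequence, list[TandemRepeatLocus], TruthTable, dict[str, list[AlignedRead]]]:
    """Reference + catalog + truth + per-sample reads, fully seeded."""
    ref, catalog = simulate_reference(cfg)
    truth = simulate_haplotypes(catalog, cfg, pedigree)
    samples = list(truth.alleles) + truth.females
    reads = {
        s: simulate_reads(ref, catalog, truth, s, cfg, seed_offset=i)
        for i, s in enumerate(samples)
    }
    return ref, catalog, truth, reads
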