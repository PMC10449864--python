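"""Haploid STR genotyping from aligned short reads.

Per locus, every *spanning* read (one whose alignment covers the repeat
tract plus ``anchor_bp`` on each side without clipping) yields an
observed repeat-region length from its CIGAR: the reference tract length
plus insertions minus deletions inside the tract.  A geometric stutter
model then scores candidate alleles: a read supports allele ``a``
exactly with probability ``1 - p_s``, slips by ``u`` whole repeat units
with probability ``p_s * 0.5 * (1 - rho) * rho**(|u| - 1)``, and any
non-unit-multiple length falls to an emission floor ``eps``.  The called
allele maximizes the product over reads under a uniform prior; the
posterior is the normalized likelihood over the candidate set.

The QC cascade mirrors marker-validation practice for male-specific
loci: a genotype is missing when there are no spanning reads, the
posterior falls below ``q_min`` (0.90, or 0.75 in low-coverage mode), or
more than 35% of reads show a stutter artifact or a flanking-region
indel; a site is dropped when more than 50% (75% low-coverage) of male
samples are missing, or when any female sample has more than two reads
mapped to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .catalog import TandemRepeatLocus

MISSING = None

REASON_NONE = "none"
REASON_NO_READS = "no_reads"
REASON_LOW_POSTERIOR = "low_posterior"
REASON_STUTTER = "stutter_frac"
REASON_FLANK = "flank_indel_frac"

SITE_REASON_MISSINGNESS = "missingness"
SITE_REASON_FEMALE = "female_reads"

_REF_CONSUMING = set("MDN=X")
_QUERY_CONSUMING = set("MIS=X")


@dataclass(frozen=True)
class AlignedRead:
    """Minimal alignment record (a thin mirror of a SAM line)."""

    name: str
    chrom: str
    pos: int  # 0-based leftmost reference position
    cigar: tuple[tuple[str, int], ...]
    mapq: int
    properly_paired: bool = True
    primary: bool = True
    seq: str = ""

    @classmethod
    def from_pysam(cls, rec) -> "AlignedRead":
        ops = "MIDNSHP=X"
        cig = tuple((ops[op], ln) for op, ln in (rec.cigartuples or ()))
        return cls(
            name=rec.query_name,
            chrom=rec.reference_name,
            pos=rec.reference_start,
            cigar=cig,
            mapq=rec.mapping_quality,
            properly_paired=rec.is_proper_pair,
            primary=not (rec.is_secondary or rec.is_supplementary),
            seq=rec.query_sequence or "",
        )

    def reference_span(self) -> tuple[int, int]:
        end = self.pos
        for op, ln in self.cigar:
            if op in _REF_CONSUMING:
                end += ln
        return self.pos, end


@dataclass
class ReadObservation:
    locus: str
    obs_len: int
    flank_indel_flag: bool = False
    stutter_flag: bool = False  # assigned relative to the called allele


@dataclass
class StutterModel:
    p_s: float = 0.05
    rho: float = 0.8
    eps: float = 1e-4

    def __post_init__(self) -> None:
        if not 0 <= self.p_s < 1:
            raise ValueError("p_s must be in [0, 1)")
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")
        if not 0 < self.eps < 1:
            raise ValueError("eps must be in (0, 1)")

    def log_emission(self, obs: int, allele: int, period: int) -> float:
        if obs == allele:
            return math.log(1.0 - self.p_s)
        diff = obs - allele
        if diff % period == 0:
            u = abs(diff) // period
            return math.log(self.p_s * 0.5 * (1.0 - self.rho)) + (u - 1) * math.log(self.rho)
        return math.log(self.eps)


@dataclass
class FilterConfig:
    mapq_min: int = 10
    anchor_bp: int = 10
    flank_window_bp: int = 10
    q_min: float = 0.90
    max_artifact_frac: float = 0.35
    max_missing_frac: float = 0.50
    female_max_reads: int = 2
    female_aggregate: bool = False  # sum counts across females instead of per-female

    @classmethod
    def lowcov(cls, **kw) -> "FilterConfig":
        """Low-coverage mode: posterior floor 0.75, missingness cap 0.75."""
        kw.setdefault("q_min", 0.75)
        kw.setdefault("max_missing_frac", 0.75)
        return cls(**kw)


@dataclass
class GenotypeCall:
    sample: str
    locus: str
    allele_len: int | None
    posterior: float | None
    depth: int
    frac_stutter: float
    frac_flank_indel: float
    missing_reason: str = REASON_NONE

    @property
    def is_missing(self) -> bool:
        return self.allele_len is None


def _spans(read: AlignedRead, start: int, end: int) -> bool:
    rs, re = read.reference_span()
    return rs <= start and re >= end


def read_is_eligible(read: AlignedRead, cfg: FilterConfig) -> bool:
    return read.primary and read.properly_paired and read.mapq >= cfg.mapq_min


def extract_observations(
    reads: list[AlignedRead],
    locus: TandemRepeatLocus,
    cfg: FilterConfig | None = None,
) -> tuple[list[ReadObservation], int]:
    """Infer per-read repeat-tract lengths at ``locus``.

    Returns (observations, n_malformed).  A read contributes only when it
    is primary, properly paired, mapq >= mapq_min, on the locus chromosome
    and its alignment spans ``[start - anchor_bp, end + anchor_bp)``
    entirely (soft/hard clips never reach inside the span because they
    only occur at alignment ends).
    """
    cfg = cfg or FilterConfig()
    start, end = locus.start, locus.end
    span_lo, span_hi = start - cfg.anchor_bp, end + cfg.anchor_bp
    fl_lo, fl_hi = start - cfg.flank_window_bp, end + cfg.flank_window_bp
    out: list[ReadObservation] = []
    malformed = 0
    for read in reads:
        if read.chrom != locus.chrom or not read_is_eligible(read, cfg):
            continue
        if any(op not in "MIDNSHP=X" for op, _ in read.cigar):
            malformed += 1
            continue
        if not _spans(read, span_lo, span_hi):
            continue
        try:
            ins = dels = 0
            flank = False
            ref = read.pos
            for op, ln in read.cigar:
                if op == "I":
                    # insertion sits between ref-1 and ref; one at the 3'
                    # boundary (ref == end) extends the tract, not the flank
                    if start <= ref <= end:
                        ins += ln
                    elif fl_lo <= ref < start or end < ref < fl_hi:
                        flank = True
                elif op in ("D", "N"):
                    d_lo, d_hi = ref, ref + ln
                    ov = min(d_hi, end) - max(d_lo, start)
                    if ov > 0:
                        dels += ov
                    if min(d_hi, start) > max(d_lo, fl_lo) or min(d_hi, fl_hi) > max(d_lo, end):
                        flank = True
                    ref += ln
                elif op in ("M", "=", "X"):
                    ref += ln
                elif op in ("S", "H", "P"):
                    pass
                else:
                    raise ValueError(f"unknown CIGAR op {op!r}")
            obs = (end - start) + ins - dels
            if obs < 0:
                raise ValueError("negative repeat-tract length")
        except ValueError:
            malformed += 1
            continue
        out.append(ReadObservation(locus=locus.name or "", obs_len=obs, flank_indel_flag=flank))
    return out, malformed


def genotype_locus(
    obs: list[ReadObservation],
    locus: TandemRepeatLocus,
    model: StutterModel | None = None,
    cfg: FilterConfig | None = None,
    sample: str = "",
) -> GenotypeCall:
    """Call the haploid allele at one locus for one sample."""
    model = model or StutterModel()
    cfg = cfg or FilterConfig()
    name = locus.name or f"{locus.chrom}:{locus.start}-{locus.end}"
    depth = len(obs)
    if depth == 0:
        return GenotypeCall(sample, name, MISSING, None, 0, 0.0, 0.0, REASON_NO_READS)

    period = locus.period
    ref_len = locus.end - locus.start
    lengths = [o.obs_len for o in obs]
    candidates = sorted(set(lengths))
    loglik = {
        a: sum(model.log_emission(x, a, period) for x in lengths) for a in candidates
    }
    best = max(loglik.values())
    # Ties broken toward the allele closest to the reference length, then smaller.
    tied = [a for a in candidates if loglik[a] == best]
    allele = min(tied, key=lambda a: (abs(a - ref_len), a))
    # Posterior: normalized likelihood over candidates (uniform prior).
    total = sum(math.exp(v - best) for v in loglik.values())
    posterior = math.exp(loglik[allele] - best) / total

    n_stutter = 0
    for o in obs:
        o.stutter_flag = o.obs_len != allele and (o.obs_len - allele) % period == 0
        n_stutter += o.stutter_flag
    frac_stutter = n_stutter / depth
    frac_flank = sum(o.flank_indel_flag for o in obs) / depth

    reason = REASON_NONE
    if posterior < cfg.q_min:
        reason = REASON_LOW_POSTERIOR
    elif frac_stutter > cfg.max_artifact_frac:
        reason = REASON_STUTTER
    elif frac_flank > cfg.max_artifact_frac:
        reason = REASON_FLANK
    if reason != REASON_NONE:
        return GenotypeCall(sample, name, MISSING, posterior, depth, frac_stutter, frac_flank, reason)
    return GenotypeCall(sample, name, allele, posterior, depth, frac_stutter, frac_flank)


def genotype_sample(
    reads: list[AlignedRead],
    catalog: list[TandemRepeatLocus],
    model: StutterModel | None = None,
    cfg: FilterConfig | None = None,
    sample: str = "",
) -> list[GenotypeCall]:
    """Genotype one sample at every catalog locus."""
    cfg = cfg or FilterConfig()
    binned = _bin_reads(reads, catalog, cfg.anchor_bp)
    calls = []
    for locus, locus_reads in zip(catalog, binned):
        obs, _ = extract_observations(locus_reads, locus, cfg)
        calls.append(genotype_locus(obs, locus, model, cfg, sample=sample))
    return calls


def _bin_reads(
    reads: list[AlignedRead], catalog: list[TandemRepeatLocus], pad: int
) -> list[list[AlignedRead]]:
    """Assign reads to loci they might span/overlap (interval walk, no index)."""
    spans = [(r, *r.reference_span()) for r in reads]
    spans.sort(key=lambda t: t[1])
    starts = np.array([t[1] for t in spans])
    out: list[list[AlignedRead]] = []
    max_read = max((t[2] - t[1] for t in spans), default=0)
    for locus in catalog:
        lo = locus.start - pad - max_read
        hi = locus.end + pad
        i0 = int(np.searchsorted(starts, lo, side="left"))
        i1 = int(np.searchsorted(starts, hi, side="right"))
        out.append([r for r, rs, re in spans[i0:i1] if re > locus.start - pad and rs < hi])
    return out


def female_read_counts(
    female_reads: dict[str, list[AlignedRead]],
    catalog: list[TandemRepeatLocus],
    cfg: FilterConfig | None = None,
) -> dict[str, dict[str, int]]:
    """Per locus x female sample: count of eligible reads overlapping the repeat.

    Eligibility matches genotyping (primary, properly paired, mapq) but the
    spanning requirement is relaxed to any overlap with [start, end).
    """
    cfg = cfg or FilterConfig()
    counts: dict[str, dict[str, int]] = {}
    for locus in catalog:
        name = locus.name or f"{locus.chrom}:{locus.start}-{locus.end}"
        row: dict[str, int] = {}
        for sample, reads in female_reads.items():
            n = 0
            for read in reads:
                if read.chrom != locus.chrom or not read_is_eligible(read, cfg):
                    continue
                rs, re = read.reference_span()
                if rs < locus.end and re > locus.start:
                    n += 1
            row[sample] = n
        counts[name] = row
    return counts


@dataclass
class SiteStats:
    locus: str
    missing_frac: float
    mean_posterior: float | None
    mean_frac_stutter: float
    mean_frac_flank_indel: float
    n_alleles: int
    max_female_reads: int = 0
    drop_reason: str | None = None


def site_filters(
    calls: dict[str, dict[str, GenotypeCall]],
    female_counts: dict[str, dict[str, int]] | None = None,
    cfg: FilterConfig | None = None,
) -> tuple[list[str], list[str], dict[str, SiteStats]]:
    """Site-level QC over male samples: (kept loci, dropped loci, stats).

    ``calls`` maps locus name -> sample -> GenotypeCall.  A locus is
    dropped when its missing fraction exceeds ``max_missing_frac`` or when
    any female sample (or the female total, in aggregate mode) exceeds
    ``female_max_reads`` (strict inequality on both).
    """
    cfg = cfg or FilterConfig()
    female_counts = female_counts or {}
    kept, dropped, stats = [], [], {}
    for locus_name, per_sample in calls.items():
        cs = list(per_sample.values())
        n = len(cs)
        miss = sum(c.is_missing for c in cs) / n if n else 1.0
        posts = [c.posterior for c in cs if c.posterior is not None]
        fem = female_counts.get(locus_name, {})
        if cfg.female_aggregate:
            fem_max = sum(fem.values())
        else:
            fem_max = max(fem.values(), default=0)
        st = SiteStats(
            locus=locus_name,
            missing_frac=miss,
            mean_posterior=float(np.mean(posts)) if posts else None,
            mean_frac_stutter=float(np.mean([c.frac_stutter for c in cs])) if cs else 0.0,
            mean_frac_flank_indel=float(np.mean([c.frac_flank_indel for c in cs])) if cs else 0.0,
            n_alleles=len({c.allele_len for c in cs if not c.is_missing}),
            max_female_reads=fem_max,
        )
        if miss > cfg.max_missing_frac:
            st.drop_reason = SITE_REASON_MISSINGNESS
            dropped.append(locus_name)
        elif fem_max > cfg.female_max_reads:
            st.drop_reason = SITE_REASON_FEMALE
            dropped.append(locus_name)
        else:
            kept.append(locus_name)
        stats[locus_name] = st
    return kept, dropped, stats


def depth_profile(
    reads: list[AlignedRead],
    chrom: str,
    chrom_len: int,
    window_bp: int = 1000,
    cfg: FilterConfig | None = None,
    min_zero_windows: int = 3,
) -> tuple[list[tuple[int, float]], list[tuple[int, int]]]:
    """Mean per-base depth in non-overlapping windows, plus candidate deletions.

    Runs of >= ``min_zero_windows`` consecutive zero-depth windows are
    flagged as candidate deletions (returned as 0-based half-open bp
    intervals), the signature used to spot lineage-specific structural
    loss of markers.
    """
    if window_bp < 100:
        raise ValueError("window_bp must be >= 100")
    cfg = cfg or FilterConfig()
    cov = np.zeros(chrom_len, dtype=np.int64)
    for read in reads:
        if read.chrom != chrom or not read_is_eligible(read, cfg):
            continue
        rs, re = read.reference_span()
        cov[max(rs, 0) : min(re, chrom_len)] += 1
    profile = []
    for w0 in range(0, chrom_len, window_bp):
        w1 = min(w0 + window_bp, chrom_len)
        profile.append((w0, float(cov[w0:w1].mean())))
    flags = []
    run_start = None
    for i, (w0, depth) in enumerate(profile):
        if depth == 0.0:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= min_zero_windows:
                flags.append((profile[run_start][0], w0))
            run_start = None
    if run_start is not None and len(profile) - run_start >= min_zero_windows:
        flags.append((profile[run_start][0], chrom_len))
    return profile, flags
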