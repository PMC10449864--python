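"""Readers and writers for the standard formats the toolkit exchanges.

Coordinates are 0-based half-open internally; BED stays 0-based
half-open on disk, VCF is 1-based as the format requires, and the
catalog TSV report is 1-based inclusive for human readers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import RegionMask, ReferenceSequence, TandemRepeatLocus
from .genotyper import AlignedRead, GenotypeCall, SiteStats
from .popgen import HaplotypeMatrix


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str, chrom: str | None = None) -> ReferenceSequence:
    """Load one record (by id, or the only/first record) from a FASTA file."""
    records = {r.id: r for r in SeqIO.parse(path, "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if chrom is None:
        if len(records) > 1:
            raise ValueError(f"{path}: multiple records; specify the chromosome id")
        chrom = next(iter(records))
    if chrom not in records:
        raise ValueError(f"{path}: no record named {chrom!r}")
    return ReferenceSequence(chrom, str(records[chrom].seq))


def write_fasta(ref: ReferenceSequence, path: str) -> None:
    SeqIO.write([SeqRecord(Seq(ref.seq), id=ref.id, description="")], path, "fasta")


# ---------------------------------------------------------------------------
# BED


def read_bed_mask(path: str) -> RegionMask:
    ivals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            ivals.append((int(parts[1]), int(parts[2])))
    return RegionMask(ivals)


def write_catalog_bed(loci: list[TandemRepeatLocus], path: str) -> None:
    """Catalog as BED6: name, score = copies, strand '+'."""
    with open(path, "w") as fh:
        for L in sorted(loci, key=lambda x: x.start):
            fh.write(f"{L.chrom}\t{L.start}\t{L.end}\t{L.name or '.'}\t{L.copies:g}\t+\n")


def write_catalog_tsv(
    loci: list[TandemRepeatLocus], path: str, excluded: list[TandemRepeatLocus] | None = None
) -> None:
    rows = []
    for L in list(loci) + list(excluded or []):
        rows.append(
            {
                "chrom": L.chrom,
                "start_1based": L.start + 1,
                "end_1based": L.end,
                "name": L.name or ".",
                "motif": L.motif,
                "period": L.period,
                "copies": L.copies,
                "purity": L.purity,
                "length_bp": L.length,
                "excluded_reason": L.exclusion_reason or ".",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalog_bed(path: str, periods_from_tsv: str | None = None) -> list[TandemRepeatLocus]:
    """Read a catalog written by :func:`write_catalog_bed`.

    Motif/period detail comes from the companion TSV when given;
    otherwise the period is inferred from copies and length.
    """
    detail = {}
    if periods_from_tsv:
        df = pd.read_csv(periods_from_tsv, sep="\t")
        for _, r in df.iterrows():
            detail[(r["start_1based"] - 1, r["end_1based"])] = (r["motif"], int(r["period"]), float(r["purity"]))
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, start, end, name, score, _strand = line.split("\t")[:6]
            start, end = int(start), int(end)
            copies = float(score)
            motif, period, purity = detail.get(
                (start, end), ("." * max(1, round((end - start) / copies)), max(1, round((end - start) / copies)), 1.0)
            )
            out.append(
                TandemRepeatLocus(
                    chrom=chrom, start=start, end=end, motif=motif, period=period,
                    copies=copies, purity=purity, name=None if name == "." else name,
                )
            )
    return out


# ---------------------------------------------------------------------------
# SAM


def write_sam(reads: list[AlignedRead], ref: ReferenceSequence, path: str) -> None:
    """Coordinate-sorted SAM with proper-pair flags set (single-end records)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref.id, "LN": ref.length}],
    }
    ops = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for read in sorted(reads, key=lambda r: r.pos):
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.name
            rec.reference_id = 0
            rec.reference_start = read.pos
            rec.mapping_quality = read.mapq
            rec.cigartuples = [(ops[o], ln) for o, ln in read.cigar]
            rec.query_sequence = read.seq or None
            rec.flag = 0x1 | 0x2 | 0x40  # paired, proper pair, first in pair
            rec.next_reference_id = 0
            rec.next_reference_start = read.pos
            out.write(rec)


def read_alignments(path: str) -> list[AlignedRead]:
    """Load all records of a SAM/BAM file (mapped reads only)."""
    mode = "rb" if path.endswith(".bam") else "r"
    out = []
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            out.append(AlignedRead.from_pysam(rec))
    return out


# ---------------------------------------------------------------------------
# VCF


def _alt_sequence(ref_seq: str, motif: str, delta: int) -> str:
    """Observed allele sequence: reference tract with the net length change
    applied at the repeat's 3' end."""
    if delta == 0:
        return ref_seq
    if delta > 0:
        ext = (motif * (delta // len(motif) + 2))[:delta]
        return ref_seq + ext
    if len(ref_seq) + delta < 1:
        raise ValueError("allele shorter than 1 bp")
    return ref_seq[: len(ref_seq) + delta]


def write_vcf(
    path: str,
    ref: ReferenceSequence,
    catalog: list[TandemRepeatLocus],
    calls: dict[str, dict[str, GenotypeCall]],
    samples: list[str],
    site_stats: dict[str, SiteStats] | None = None,
) -> None:
    """One VCF 4.2 record per locus; haploid GT with Q/DP/FS/FI per sample."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={ref.id},length={ref.length}>")
    header.add_line('##INFO=<ID=MOTIF,Number=1,Type=String,Description="Canonical repeat motif">')
    header.add_line('##INFO=<ID=PERIOD,Number=1,Type=Integer,Description="Repeat unit length (bp)">')
    header.add_line('##INFO=<ID=MISSFRAC,Number=1,Type=Float,Description="Fraction of male samples missing">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">')
    header.add_line('##FORMAT=<ID=Q,Number=1,Type=Float,Description="Posterior probability of the called allele">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Spanning read depth">')
    header.add_line('##FORMAT=<ID=FS,Number=1,Type=Float,Description="Fraction of reads with a stutter artifact">')
    header.add_line('##FORMAT=<ID=FI,Number=1,Type=Float,Description="Fraction of reads with a flanking indel">')
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for locus in sorted(catalog, key=lambda L: L.start):
            per_sample = calls.get(locus.name, {})
            ref_seq = ref.seq[locus.start : locus.end]
            ref_len = locus.end - locus.start
            alts: list[int] = sorted(
                {
                    c.allele_len
                    for c in per_sample.values()
                    if not c.is_missing and c.allele_len != ref_len
                }
            )
            rec = out.new_record()
            rec.chrom = ref.id
            rec.start = locus.start
            rec.id = locus.name or "."
            alleles = [ref_seq] + [_alt_sequence(ref_seq, locus.motif, a - ref_len) for a in alts]
            rec.alleles = tuple(alleles)
            rec.stop = locus.end
            rec.info["MOTIF"] = locus.motif
            rec.info["PERIOD"] = locus.period
            if site_stats and locus.name in site_stats:
                rec.info["MISSFRAC"] = round(site_stats[locus.name].missing_frac, 6)
            index = {ref_len: 0, **{a: i + 1 for i, a in enumerate(alts)}}
            for s in samples:
                call = per_sample.get(s)
                fmt = rec.samples[s]
                if call is None or call.is_missing:
                    fmt["GT"] = (None,)
                else:
                    fmt["GT"] = (index[call.allele_len],)
                if call is not None:
                    if call.posterior is not None:
                        fmt["Q"] = round(call.posterior, 6)
                    fmt["DP"] = call.depth
                    fmt["FS"] = round(call.frac_stutter, 6)
                    fmt["FI"] = round(call.frac_flank_indel, 6)
            out.write(rec)


def read_vcf(path: str) -> tuple[HaplotypeMatrix, pd.DataFrame]:
    """Rebuild the sample x locus allele-length matrix from a toolkit VCF."""
    rows = []
    loci: list[str] = []
    periods: list[int] = []
    with pysam.VariantFile(path) as fh:
        samples = list(fh.header.samples)
        data: dict[str, list[float]] = {s: [] for s in samples}
        meta = []
        for rec in fh:
            loci.append(rec.id)
            periods.append(int(rec.info["PERIOD"]))
            meta.append(
                {
                    "locus": rec.id,
                    "chrom": rec.chrom,
                    "start": rec.start,
                    "end": rec.stop,
                    "motif": rec.info["MOTIF"],
                    "period": int(rec.info["PERIOD"]),
                }
            )
            for s in samples:
                gt = rec.samples[s].get("GT", (None,))
                if gt is None or gt[0] is None:
                    data[s].append(float("nan"))
                else:
                    data[s].append(float(len(rec.alleles[gt[0]])))
    alleles = np.array([data[s] for s in samples], dtype=float)
    matrix = HaplotypeMatrix(samples, loci, periods, alleles)
    return matrix, pd.DataFrame(meta)


# ---------------------------------------------------------------------------
# Genotype tables / sample sheets


def read_tsv_genotypes(
    path: str, periods: dict[str, int] | list[int] | int = 4
) -> HaplotypeMatrix:
    """Wide genotype TSV: rows = samples, columns = loci, '.' = missing.

    ``periods`` gives each locus's repeat-unit size (a mapping, a list in
    column order, or one value for all loci).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["."])
    df = df.astype(float)
    if isinstance(periods, int):
        plist = [periods] * df.shape[1]
    elif isinstance(periods, dict):
        missing = [c for c in df.columns if c not in periods]
        if missing:
            raise ValueError(f"no period given for loci: {missing}")
        plist = [int(periods[c]) for c in df.columns]
    else:
        plist = [int(p) for p in periods]
    return HaplotypeMatrix(list(df.index.astype(str)), list(df.columns), plist, df.to_numpy())


def write_tsv_genotypes(matrix: HaplotypeMatrix, path: str) -> None:
    df = matrix.to_frame()
    df.index.name = "sample"
    out = df.map(lambda v: "." if pd.isna(v) else f"{int(v)}")
    out.to_csv(path, sep="\t")


@dataclass
class SampleSheetRow:
    sample: str
    sex: str  # 'M' or 'F'
    path: str
    mode: str = "default"  # default | lowcov


def read_sample_sheet(path: str) -> list[SampleSheetRow]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "sex", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    rows = []
    for _, r in df.iterrows():
        sex = str(r["sex"]).upper()[:1]
        if sex not in ("M", "F"):
            raise ValueError(f"sample {r['sample']}: sex must be M or F")
        rows.append(
            SampleSheetRow(str(r["sample"]), sex, str(r["path"]), str(r.get("mode", "default")))
        )
    return rows


def write_newick(tree, path: str, with_support: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(with_support=with_support) + "\n")


def write_distance_tsv(dist: pd.DataFrame, path: str) -> None:
    dist.to_csv(path, sep="\t", float_format="%.9g")


def read_distance_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
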