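"""File formats and in-memory records shared across the toolkit.

Coordinates are 0-based half-open everywhere in memory.  The 1-based VCF
anchor convention (indels left-anchored with one shared base) appears only
at the serialization boundary.

Alignment convention: CIGAR strings are stored in target-forward
orientation.  For '-' strand records ``query_start``/``query_end`` are in
original read coordinates (PAF convention); the aligned query sequence is
the reverse complement of the read, see :meth:`AlignmentRecord.oriented_query`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SV_SIZE_THRESHOLD_DEFAULT = 50

_VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised on malformed input files or inconsistent records."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("sequence name must be nonempty")
        self.seq = self.seq.upper()
        if set(self.seq) - _VALID_BASES:
            bad = sorted(set(self.seq) - _VALID_BASES)
            raise FormatError(f"sequence {self.name}: invalid characters {bad}")

    def __len__(self) -> int:
        return len(self.seq)


# CIGAR ops: query-consuming and target-consuming sets
_Q_OPS = set("=XMIS")
_T_OPS = set("=XMD")
_CIGAR_RE = re.compile(r"(\d+)([=XMIDSH])")


def parse_cigar(text: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string into a list of (op, length) tuples."""
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(text)]
    if not ops or sum(len(m.group(0)) for m in _CIGAR_RE.finditer(text)) != len(text):
        raise FormatError(f"malformed CIGAR: {text!r}")
    return ops


def cigar_to_str(cigar: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def cigar_query_span(cigar: Sequence[tuple[str, int]]) -> int:
    """Query bases consumed between query_start and query_end (clips excluded)."""
    return sum(n for op, n in cigar if op in "=XMI")


def cigar_target_span(cigar: Sequence[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in _T_OPS)


def divergence_from_cigar(cigar: Sequence[tuple[str, int]]) -> float:
    """Gap-compressed divergence: (mismatches + gap opens) / (aligned
    columns + gap opens), matching the aligner 'de' tag convention.

    Each indel counts once regardless of length, so reads legitimately
    spanning long structural variants are not scored as divergent.  When
    the CIGAR uses 'M' (match-or-mismatch) instead of '='/'X' the mismatch
    count is unavailable and only gap opens are counted, giving a
    documented lower bound on the true divergence.
    """
    match_cols = sum(n for op, n in cigar if op in "=XM")
    gap_opens = sum(1 for op, _ in cigar if op in "ID")
    denom = match_cols + gap_opens
    if denom == 0:
        return 0.0
    has_m = any(op == "M" for op, _ in cigar)
    mismatches = 0 if has_m else sum(n for op, n in cigar if op == "X")
    return (mismatches + gap_opens) / denom


@dataclass
class AlignmentRecord:
    query_name: str
    query_len: int
    query_start: int
    query_end: int
    target_name: str
    target_start: int
    target_end: int
    strand: str  # '+' or '-'
    cigar: list[tuple[str, int]] = field(default_factory=list)
    divergence: float = 0.0

    def validate(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise FormatError(
                f"{self.query_name}: query interval "
                f"[{self.query_start},{self.query_end}) vs length {self.query_len}")
        if not (0 <= self.target_start < self.target_end):
            raise FormatError(f"{self.query_name}: bad target interval")
        if self.cigar:
            qs = cigar_query_span(self.cigar)
            ts = cigar_target_span(self.cigar)
            if qs != self.query_end - self.query_start:
                raise FormatError(
                    f"{self.query_name}: CIGAR query span {qs} != "
                    f"{self.query_end - self.query_start}")
            if ts != self.target_end - self.target_start:
                raise FormatError(
                    f"{self.query_name}: CIGAR target span {ts} != "
                    f"{self.target_end - self.target_start}")

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    def oriented_query(self, read_seq: str) -> tuple[str, int, int]:
        """Return (sequence, start, end) in target-forward orientation.

        For '+' records this is the read itself with the stored coordinates;
        for '-' records the reverse complement, with coordinates flipped so
        that walking the CIGAR from ``start`` follows the target left to right.
        """
        if self.strand == "+":
            return read_seq, self.query_start, self.query_end
        rc = revcomp(read_seq)
        return rc, self.query_len - self.query_end, self.query_len - self.query_start


@dataclass
class Variant:
    chrom: str
    pos: int                      # 1-based VCF position of the anchor base
    ref: str
    alts: list[str]
    genotype: tuple[int, int] = (0, 1)
    phased: bool = False
    phase_set: Optional[int] = None
    var_class: str = "SNP"        # SNP | INDEL | SV
    sv_len: int = 0               # signed; insertions > 0, deletions < 0, 0 for SNP
    sv_type: Optional[str] = None  # INS | DEL | INV for SVs
    grouped_from: int = 1

    def __post_init__(self) -> None:
        if not self.ref:
            raise FormatError("ref allele must be nonempty")
        if not (1 <= len(self.alts) <= 2):
            raise FormatError("one or two alternate alleles required")
        n_alleles = 1 + len(self.alts)
        if any(g < 0 or g >= n_alleles for g in self.genotype):
            raise FormatError(
                f"genotype {self.genotype} out of range for {n_alleles} alleles")

    # -- 0-based helpers -------------------------------------------------
    @property
    def start0(self) -> int:
        return self.pos - 1

    @property
    def end0(self) -> int:
        return self.pos - 1 + len(self.ref)

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    def allele(self, index: int) -> str:
        return self.ref if index == 0 else self.alts[index - 1]

    def sort_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def classify_variant(ref: str, alts: Sequence[str],
                     sv_threshold: int = SV_SIZE_THRESHOLD_DEFAULT) -> tuple[str, int]:
    """Return (var_class, sv_len) for the given alleles.

    sv_len is taken from the allele with the largest absolute length
    difference to the reference; a variant is an SV iff that difference is
    at least ``sv_threshold``.
    """
    best = 0
    for alt in alts:
        d = len(alt) - len(ref)
        if abs(d) > abs(best):
            best = d
    if best == 0:
        cls = "SNP" if len(ref) == 1 and all(len(a) == 1 for a in alts) else "INDEL"
    elif abs(best) >= sv_threshold:
        cls = "SV"
    else:
        cls = "INDEL"
    return cls, best


@dataclass
class MethSite:
    chrom: str
    pos: int          # 0-based CpG cytosine position
    strand: str       # '+' or '-'
    coverage: int
    meth_frac: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.meth_frac <= 1.0):
            raise FormatError(f"meth_frac {self.meth_frac} outside [0,1]")
        if self.coverage < 0:
            raise FormatError("coverage must be >= 0")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        records.append(GenomeSequence(rec.id, str(rec.seq)))
    if not records:
        raise FormatError(f"{path}: empty or malformed FASTA")
    return records


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s.seq), id=s.name, description="") for s in seqs]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# PAF / SAM alignments
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path, dialect: str = "PAF") -> list[AlignmentRecord]:
    """Read alignments from a PAF (with cg: tag) or text SAM file.

    Records without a CIGAR are skipped with a warning; internally
    inconsistent records raise :class:`FormatError`.
    """
    dialect = dialect.upper()
    if dialect == "PAF":
        return _read_paf(path)
    if dialect == "SAM":
        return _read_sam(path)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def _read_paf(path: str | Path) -> list[AlignmentRecord]:
    out: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: PAF line with <12 columns")
            cg = None
            de = None
            for tag in fields[12:]:
                if tag.startswith("cg:Z:"):
                    cg = tag[5:]
                elif tag.startswith("de:f:"):
                    de = float(tag[5:])
            if cg is None:
                warnings.warn(f"{path}:{lineno}: missing cg: tag, record skipped")
                continue
            cigar = parse_cigar(cg)
            rec = AlignmentRecord(
                query_name=fields[0], query_len=int(fields[1]),
                query_start=int(fields[2]), query_end=int(fields[3]),
                strand=fields[4],
                target_name=fields[5],
                target_start=int(fields[7]), target_end=int(fields[8]),
                cigar=cigar,
                divergence=de if de is not None else divergence_from_cigar(cigar),
            )
            rec.validate()
            out.append(rec)
    return out


def _read_sam(path: str | Path) -> list[AlignmentRecord]:
    out: list[AlignmentRecord] = []
    _PYSAM_OPS = "MIDNSHP=X"
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            if aln.cigartuples is None:
                warnings.warn(f"{path}: {aln.query_name}: missing CIGAR, skipped")
                continue
            cigar = [(_PYSAM_OPS[op], n) for op, n in aln.cigartuples]
            qlen = sum(n for op, n in cigar if op in "=XMIS")  # soft clips included
            if any(op == "H" for op, _ in cigar):
                qlen += sum(n for op, n in cigar if op == "H")
            # clip lengths at either end determine the aligned query interval
            lead = 0
            for op, n in cigar:
                if op in "SH":
                    lead += n
                else:
                    break
            trail = 0
            for op, n in reversed(cigar):
                if op in "SH":
                    trail += n
                else:
                    break
            core = [(op, n) for op, n in cigar if op not in "SH"]
            qspan = cigar_query_span(core)
            strand = "-" if aln.is_reverse else "+"
            if strand == "+":
                qs, qe = lead, lead + qspan
            else:
                # stored coordinates are on the original read
                qs, qe = trail, trail + qspan
            rec = AlignmentRecord(
                query_name=aln.query_name, query_len=qlen,
                query_start=qs, query_end=qe,
                target_name=aln.reference_name,
                target_start=aln.reference_start,
                target_end=aln.reference_start + cigar_target_span(core),
                strand=strand,
                cigar=core,
                divergence=divergence_from_cigar(core),
            )
            rec.validate()
            out.append(rec)
    return out


def write_paf(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            matches = sum(n for op, n in r.cigar if op == "=")
            cols = sum(n for op, n in r.cigar if op in "=XMID")
            fh.write("\t".join(map(str, [
                r.query_name, r.query_len, r.query_start, r.query_end,
                r.strand, r.target_name,
                r.target_end,  # placeholder target length column
                r.target_start, r.target_end,
                matches, cols, 60,
                f"de:f:{r.divergence:.6g}",
                f"cg:Z:{cigar_to_str(r.cigar)}",
            ])) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SAMPLE = "SAMPLE"


def _vcf_header(contigs: Sequence[str]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for c in contigs:
        h.contigs.add(c)
    h.info.add("SVTYPE", 1, "String", "Structural variant type")
    h.info.add("SVLEN", 1, "Integer", "Signed structural variant length")
    h.info.add("GROUPED", 1, "Integer", "Number of raw indels merged into this record")
    h.formats.add("GT", 1, "String", "Genotype")
    h.formats.add("PS", 1, "Integer", "Phase set")
    h.add_sample(_SAMPLE)
    return h


def write_vcf(variants: Sequence[Variant], path: str | Path) -> None:
    """Write VCF 4.2 text.  Input must be sorted by (chrom, pos)."""
    keys = [v.sort_key() for v in variants]
    if keys != sorted(keys):
        raise FormatError("variants must be sorted by (chrom, pos) before writing")
    contigs = list(dict.fromkeys(v.chrom for v in variants))
    header = _vcf_header(contigs or ["chr1"])
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in variants:
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1,
                alleles=(v.ref, *v.alts))
            if v.var_class == "SV":
                rec.info["SVTYPE"] = v.sv_type or ("INS" if v.sv_len > 0 else "DEL")
                rec.info["SVLEN"] = v.sv_len
            if v.grouped_from != 1:
                rec.info["GROUPED"] = v.grouped_from
            rec.samples[_SAMPLE]["GT"] = v.genotype
            rec.samples[_SAMPLE].phased = v.phased
            if v.phased and v.phase_set is not None:
                rec.samples[_SAMPLE]["PS"] = v.phase_set
            vcf.write(rec)


def read_vcf(path: str | Path,
             sv_threshold: int = SV_SIZE_THRESHOLD_DEFAULT) -> list[Variant]:
    out: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = list(rec.alts or [])
            sample = rec.samples[0] if rec.samples else None
            gt = tuple(sample["GT"]) if sample else (0, 1)
            if sample and any(g is None for g in gt):
                raise FormatError(f"{path}: missing genotype at {rec.chrom}:{rec.pos}")
            phased = bool(sample.phased) if sample else False
            ps = None
            if sample and "PS" in sample and sample["PS"] is not None:
                ps = int(sample["PS"])
            cls, svlen = classify_variant(rec.ref, alts, sv_threshold)
            sv_type = rec.info.get("SVTYPE")
            if "SVLEN" in rec.info:
                raw = rec.info["SVLEN"]
                svlen = int(raw[0] if isinstance(raw, tuple) else raw)
                cls = "SV"
            grouped = int(rec.info.get("GROUPED", 1))
            out.append(Variant(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alts=alts,
                genotype=gt, phased=phased, phase_set=ps,
                var_class=cls, sv_len=svlen, sv_type=sv_type,
                grouped_from=grouped))
    return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

Interval = tuple[str, int, int, str]


def read_bed(path: str | Path) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line with <3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            label = fields[3] if len(fields) > 3 else ""
            out.append((chrom, start, end, label))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in intervals:
            if label:
                fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of overlapping/adjacent intervals sharing chrom and label."""
    merged: list[Interval] = []
    for iv in sorted(intervals, key=lambda t: (t[0], t[3], t[1], t[2])):
        if merged and merged[-1][0] == iv[0] and merged[-1][3] == iv[3] \
                and iv[1] <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (prev[0], prev[1], max(prev[2], iv[2]), prev[3])
        else:
            merged.append(iv)
    return merged


# ---------------------------------------------------------------------------
# bedMethyl (modbam2bed 9+2 layout)
# ---------------------------------------------------------------------------

def read_bedmethyl(path: str | Path) -> list[MethSite]:
    out: list[MethSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise FormatError(
                    f"{path}:{lineno}: expected the 9+2 bedMethyl layout "
                    f"(11 columns), got {len(fields)}")
            chrom, start = fields[0], int(fields[1])
            strand = fields[5]
            coverage = int(fields[9])
            percent = float(fields[10])
            if not (0.0 <= percent <= 100.0):
                raise FormatError(
                    f"{path}:{lineno}: percent methylation {percent} outside [0,100]")
            out.append(MethSite(chrom, start, strand, coverage, percent / 100.0))
    return out


def write_bedmethyl(sites: Iterable[MethSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write("\t".join(map(str, [
                s.chrom, s.pos, s.pos + 1, "m",
                min(int(round(s.meth_frac * 1000)), 1000), s.strand,
                s.pos, s.pos + 1, "0,0,0",
                s.coverage, repr(s.meth_frac * 100.0),
            ])) + "\n")
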