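"""Synthetic diploid genomes with full ground truth.

The generator emulates the statistical structure the pipeline assumes: a
heterozygous SNP/indel background, structural variants of at least 50 bp
(including VNTR copy-number changes that decompose into multiple sub-50 bp
indels under naive alignment), noisy long reads with homopolymer-biased
indel errors, and haplotype-specific CpG methylation.

Everything is generated on a single chromosome at desk scale (1 Mb, 30x by
default) so that the full pipeline runs end to end in minutes.
"""

from __future__ import annotations

import bisect
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import edlib
import numpy as np

from .formats import (
    AlignmentRecord, GenomeSequence, Interval, MethSite, Variant,
    classify_variant, divergence_from_cigar, parse_cigar, revcomp,
    write_bed, write_bedmethyl, write_fasta, write_paf, write_vcf,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CHROM = "chr1"

# fixed sub-stream labels: adding a feature must not shift unrelated draws
_STREAMS = {"genome": 1, "variants": 2, "reads": 3, "meth": 4}


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[label]])


def random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    seed: int = 0
    genome_len: int = 1_000_000
    # small-variant background (all heterozygous)
    snp_rate: float = 0.001
    indel_rate: float = 0.0002
    indel_mean_len: float = 3.0
    # structural variants
    n_svs: int = 200
    sv_len_range: tuple[int, int] = (50, 2000)
    sv_types: tuple[str, ...] = ("INS", "DEL")
    hom_sv_fraction: float = 0.2
    # VNTR loci; the first min(n_vntrs, n_svs) SVs are realized as unit
    # copy-number changes inside these repeats
    n_vntrs: int = 50
    vntr_unit_len: int = 25
    vntr_unit_copies: tuple[int, int] = (8, 16)
    vntr_cn_delta_range: tuple[int, int] = (2, 4)   # |delta| in repeat units
    # reads
    read_len_mean: int = 20_000
    read_len_sigma: float = 0.4
    read_min_len: int = 1_000
    coverage: float = 30.0
    read_error: float = 0.01
    error_indel_frac: float = 0.5
    homopolymer_factor: float = 3.0
    homopolymer_min: int = 4
    # methylation
    meth_regions: int = 200
    meth_region_len: int = 2_000
    meth_diff_fraction: float = 0.05
    meth_delta: float = 0.5
    meth_noise_sd: float = 0.05
    meth_coverage: float = 15.0
    min_variant_gap: int = 50

    def validate(self) -> None:
        if self.genome_len <= 0:
            raise ValueError("genome_len must be positive")
        for name in ("snp_rate", "indel_rate", "read_error", "meth_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_svs and self.sv_len_range[0] < 50:
            raise ValueError("sv_len_range minimum must be >= 50")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not (0 <= self.meth_diff_fraction <= 1):
            raise ValueError("meth_diff_fraction must be in [0,1]")


@dataclass
class SimRead:
    name: str
    seq: str
    haplotype: int          # 1 or 2
    hap_start: int
    hap_end: int
    strand: str


@dataclass
class MethRegion:
    chrom: str
    start: int
    end: int
    label: str
    differential: bool
    mean_h1: float
    mean_h2: float


@dataclass
class DiploidTruth:
    reference: GenomeSequence
    hap1: GenomeSequence
    hap2: GenomeSequence
    truth_variants: list[Variant]
    vntr_bed: list[Interval]
    truth_reads: list[SimRead] = field(default_factory=list)
    truth_alignments: list[AlignmentRecord] = field(default_factory=list)
    truth_meth: tuple[list[MethSite], list[MethSite]] = field(
        default_factory=lambda: ([], []))
    meth_regions: list[MethRegion] = field(default_factory=list)
    # identity-segment maps (hap_start, ref_start, length) per haplotype
    hap_maps: tuple[list[tuple[int, int, int]], ...] = ((), ())


# ---------------------------------------------------------------------------
# Variant application and coordinate maps
# ---------------------------------------------------------------------------

def apply_variants(reference: str, variants: list[Variant], hap: int,
                   ) -> tuple[str, list[tuple[int, int, int]]]:
    """Apply one haplotype's alleles to the reference.

    ``hap`` is 0 or 1 (index into the genotype pair).  Returns the haplotype
    sequence and a list of identity segments (hap_start, ref_start, length)
    for coordinate projection.  Variants must be sorted and non-overlapping.
    """
    pieces: list[str] = []
    segments: list[tuple[int, int, int]] = []
    rcur = 0
    hcur = 0
    for v in sorted(variants, key=Variant.sort_key):
        ai = v.genotype[hap]
        if ai == 0:
            continue
        if v.start0 < rcur:
            raise ValueError(f"overlapping variants at {v.chrom}:{v.pos}")
        seglen = v.start0 - rcur
        if seglen:
            pieces.append(reference[rcur:v.start0])
            segments.append((hcur, rcur, seglen))
            hcur += seglen
        allele = v.allele(ai)
        pieces.append(allele)
        hcur += len(allele)
        rcur = v.end0
    if rcur < len(reference):
        pieces.append(reference[rcur:])
        segments.append((hcur, rcur, len(reference) - rcur))
    return "".join(pieces), segments


def hap_to_ref(segments: list[tuple[int, int, int]], hpos: int) -> int:
    """Project a haplotype coordinate onto the reference (clamped inside
    variant alleles to the nearest identity segment)."""
    starts = [s[0] for s in segments]
    i = bisect.bisect_right(starts, hpos) - 1
    if i < 0:
        return segments[0][1]
    hs, rs, ln = segments[i]
    if hpos < hs + ln:
        return rs + (hpos - hs)
    if i + 1 < len(segments):
        return segments[i + 1][1]
    return rs + ln


# ---------------------------------------------------------------------------
# simulate_diploid
# ---------------------------------------------------------------------------

class Occupancy:
    """Sorted non-overlapping reserved intervals with a minimum gap."""

    def __init__(self, gap: int) -> None:
        self.gap = gap
        self.starts: list[int] = []
        self.ends: list[int] = []

    def free(self, start: int, end: int) -> bool:
        i = bisect.bisect_left(self.starts, end + self.gap)
        if i > 0 and self.ends[i - 1] + self.gap > start:
            return False
        return True

    def add(self, start: int, end: int) -> None:
        i = bisect.bisect_left(self.starts, start)
        self.starts.insert(i, start)
        self.ends.insert(i, end)


def _draw_position(rng, occ: Occupancy, span: int, genome_len: int,
                   margin: int, what: str, tries: int = 2000) -> int:
    for _ in range(tries):
        p = int(rng.integers(margin, genome_len - margin - span))
        if occ.free(p, p + span):
            occ.add(p, p + span)
            return p
    raise RuntimeError(
        f"requested variant density infeasible: could not place {what} "
        f"(span {span} bp) after {tries} attempts; reduce rates or counts")


def _genotype(rng, hom_frac: float) -> tuple[int, int]:
    if rng.random() < hom_frac:
        return (1, 1)
    return (1, 0) if rng.random() < 0.5 else (0, 1)


def simulate_diploid(cfg: SimConfig) -> DiploidTruth:
    """Generate a reference, two haplotypes, and the sorted truth VCF.

    Deterministic given ``cfg.seed``.  Variants are non-overlapping on the
    reference with at least ``cfg.min_variant_gap`` bp of separation, and
    VNTR copy-number changes are realized as whole-unit insertions or
    deletions anchored at the repeat start.
    """
    cfg.validate()
    grng = _rng(cfg.seed, "genome")
    ref_arr = grng.choice(_BASES, size=cfg.genome_len)

    # keep variants clear of the chromosome ends, where read coverage
    # necessarily thins out (mirrors confident-region benchmarking)
    margin = min(max(500, cfg.read_len_mean // 4), cfg.genome_len // 8)
    occ = Occupancy(cfg.min_variant_gap)
    pad = cfg.vntr_unit_len
    vntr_bed: list[Interval] = []
    vntr_loci: list[tuple[int, str, int]] = []   # (start, unit, copies)
    for i in range(cfg.n_vntrs):
        copies = int(grng.integers(cfg.vntr_unit_copies[0],
                                   cfg.vntr_unit_copies[1] + 1))
        unit = random_dna(grng, cfg.vntr_unit_len)
        span = copies * cfg.vntr_unit_len
        start = _draw_position(grng, occ, span + 2 * pad, cfg.genome_len,
                               margin, f"VNTR locus {i}") + pad
        tandem = np.frombuffer((unit * copies).encode(), dtype=np.uint8)
        ref_arr[start:start + span] = tandem
        vntr_loci.append((start, unit, copies))
        vntr_bed.append((_CHROM, start - pad, start + span + pad, f"vntr_{i:04d}"))
    reference = ref_arr.tobytes().decode()

    # --- variants ---------------------------------------------------------
    vrng = _rng(cfg.seed, "variants")
    variants: list[Variant] = []

    n_vntr_svs = min(cfg.n_vntrs, cfg.n_svs)
    for i in range(n_vntr_svs):
        start, unit, copies = vntr_loci[i]
        lo, hi = cfg.vntr_cn_delta_range
        delta = int(vrng.integers(lo, hi + 1))
        max_del = max(1, copies - 2)
        sign = -1 if (vrng.random() < 0.5 and delta <= max_del) else 1
        anchor = reference[start - 1]
        if sign > 0:
            ref_al, alt = anchor, anchor + unit * delta
        else:
            ref_al = reference[start - 1:start + cfg.vntr_unit_len * delta]
            alt = anchor
        cls, svlen = classify_variant(ref_al, [alt])
        variants.append(Variant(
            _CHROM, start, ref_al, [alt], _genotype(vrng, cfg.hom_sv_fraction),
            phased=True, phase_set=1, var_class=cls, sv_len=svlen,
            sv_type="INS" if svlen > 0 else "DEL"))

    for i in range(cfg.n_svs - n_vntr_svs):
        svtype = cfg.sv_types[int(vrng.integers(len(cfg.sv_types)))]
        length = int(vrng.integers(cfg.sv_len_range[0], cfg.sv_len_range[1] + 1))
        if svtype == "INS":
            p = _draw_position(vrng, occ, 1, cfg.genome_len, margin, "insertion")
            anchor = reference[p - 1]
            ref_al, alt = anchor, anchor + random_dna(vrng, length)
        elif svtype == "DEL":
            p = _draw_position(vrng, occ, length + 1, cfg.genome_len, margin,
                               "deletion")
            ref_al = reference[p - 1:p + length]
            alt = reference[p - 1]
        else:  # INV
            p = _draw_position(vrng, occ, length, cfg.genome_len, margin,
                               "inversion")
            ref_al = reference[p:p + length]
            alt = revcomp(ref_al)
        cls, svlen = classify_variant(ref_al, [alt])
        pos = p + 1 if svtype == "INV" else p
        if svtype == "INV":
            cls, svlen = "SV", 0
        variants.append(Variant(
            _CHROM, pos, ref_al, [alt], _genotype(vrng, cfg.hom_sv_fraction),
            phased=True, phase_set=1, var_class=cls, sv_len=svlen,
            sv_type=svtype))

    n_snps = int(vrng.binomial(cfg.genome_len, cfg.snp_rate))
    for i in range(n_snps):
        p = _draw_position(vrng, occ, 1, cfg.genome_len, margin, "SNP")
        ref_b = reference[p]
        alt_b = "ACGT".replace(ref_b, "")[int(vrng.integers(3))]
        gt = (1, 0) if vrng.random() < 0.5 else (0, 1)
        variants.append(Variant(_CHROM, p + 1, ref_b, [alt_b], gt,
                                phased=True, phase_set=1, var_class="SNP"))

    n_indels = int(vrng.binomial(cfg.genome_len, cfg.indel_rate))
    for i in range(n_indels):
        length = min(int(vrng.geometric(1.0 / cfg.indel_mean_len)), 49)
        if vrng.random() < 0.5:  # insertion
            p = _draw_position(vrng, occ, 1, cfg.genome_len, margin, "small ins")
            anchor = reference[p - 1]
            ref_al, alt = anchor, anchor + random_dna(vrng, length)
        else:
            p = _draw_position(vrng, occ, length + 1, cfg.genome_len, margin,
                               "small del")
            ref_al = reference[p - 1:p + length]
            alt = reference[p - 1]
        gt = (1, 0) if vrng.random() < 0.5 else (0, 1)
        cls, svlen = classify_variant(ref_al, [alt])
        variants.append(Variant(_CHROM, p, ref_al, [alt], gt,
                                phased=True, phase_set=1,
                                var_class=cls, sv_len=svlen))

    variants.sort(key=Variant.sort_key)
    hap1_seq, map1 = apply_variants(reference, variants, 0)
    hap2_seq, map2 = apply_variants(reference, variants, 1)
    return DiploidTruth(
        reference=GenomeSequence(_CHROM, reference),
        hap1=GenomeSequence("hap1", hap1_seq),
        hap2=GenomeSequence("hap2", hap2_seq),
        truth_variants=variants,
        vntr_bed=vntr_bed,
        hap_maps=(map1, map2),
    )


# ---------------------------------------------------------------------------
# simulate_reads
# ---------------------------------------------------------------------------

def _homopolymer_mask(seq_arr: np.ndarray, min_run: int) -> np.ndarray:
    """Boolean mask of positions inside homopolymer runs >= min_run."""
    n = len(seq_arr)
    if n == 0:
        return np.zeros(0, bool)
    change = np.empty(n, bool)
    change[0] = True
    change[1:] = seq_arr[1:] != seq_arr[:-1]
    run_id = np.cumsum(change) - 1
    run_len = np.bincount(run_id)
    return run_len[run_id] >= min_run


def _merge_push(ops: list[list], op: str, n: int) -> None:
    if n <= 0:
        return
    if ops and ops[-1][0] == op:
        ops[-1][1] += n
    else:
        ops.append([op, n])


def _perturb_read(frag: str, rng: np.random.Generator, cfg: SimConfig,
                  hp_mask_frag: np.ndarray) -> tuple[str, list[list]]:
    """Inject substitution and indel errors at cfg.read_error per base, with
    the error probability multiplied inside homopolymers.

    Returns (read sequence, read-to-fragment CIGAR ops as [op, n] lists).
    """
    n = len(frag)
    if cfg.read_error <= 0:
        return frag, [["=", n]]
    p = np.full(n, cfg.read_error)
    p[hp_mask_frag] *= cfg.homopolymer_factor
    np.clip(p, 0, 0.5, out=p)
    err_pos = np.nonzero(rng.random(n) < p)[0]
    if len(err_pos) == 0:
        return frag, [["=", n]]
    kinds = rng.random(len(err_pos))
    pieces: list[str] = []
    ops: list[list] = []
    cur = 0
    for pos, k in zip(err_pos, kinds):
        pieces.append(frag[cur:pos])
        _merge_push(ops, "=", pos - cur)
        base = frag[pos]
        if k >= cfg.error_indel_frac:          # mismatch
            pieces.append("ACGT".replace(base, "")[int(rng.integers(3))])
            _merge_push(ops, "X", 1)
        elif k >= cfg.error_indel_frac / 2:    # insertion before the base
            pieces.append("ACGT"[int(rng.integers(4))])
            pieces.append(base)
            _merge_push(ops, "I", 1)
            _merge_push(ops, "=", 1)
        else:                                  # deletion of the base
            _merge_push(ops, "D", 1)
        cur = pos + 1
    pieces.append(frag[cur:])
    _merge_push(ops, "=", n - cur)
    return "".join(pieces), ops


# haplotype-vs-reference difference ops.  Query = haplotype, target =
# reference; 'V' marks an inverted block (equal length, reverse complement).
_QCONS = {"=": True, "X": True, "I": True, "V": True, "D": False}
_TCONS = {"=": True, "X": True, "I": False, "V": True, "D": True}


def _hap_diff_ops(reference: str, variants: list[Variant], hap: int,
                  ) -> list[tuple[str, int]]:
    ops: list[list] = []
    rcur = 0
    for v in sorted(variants, key=Variant.sort_key):
        ai = v.genotype[hap]
        if ai == 0:
            continue
        _merge_push(ops, "=", v.start0 - rcur)
        allele = v.allele(ai)
        la, lr = len(allele), len(v.ref)
        if v.sv_type == "INV":
            _merge_push(ops, "V", lr)
        elif la == lr:
            _merge_push(ops, "X", la)
        elif la > lr:
            _merge_push(ops, "=", lr)          # shared anchor prefix
            _merge_push(ops, "I", la - lr)
        else:
            _merge_push(ops, "=", la)
            _merge_push(ops, "D", lr - la)
        rcur = v.end0
    _merge_push(ops, "=", len(reference) - rcur)
    return [(op, n) for op, n in ops]


def simulate_reads(truth: DiploidTruth, cfg: SimConfig,
                   ) -> tuple[list[SimRead], list[AlignmentRecord]]:
    """Sample reads uniformly from both haplotypes at coverage/2 each.

    Lengths are lognormal with the configured mean; errors are injected per
    base with homopolymer-biased indels.  The exact true alignment of each
    read to the reference is produced by composing the read-to-haplotype
    error CIGAR with the haplotype-to-reference variant CIGAR; reads that
    cross an inversion are emitted as strand-split alignment records.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "reads")
    sigma = cfg.read_len_sigma
    mu = np.log(cfg.read_len_mean) - sigma ** 2 / 2
    reads: list[SimRead] = []
    alignments: list[AlignmentRecord] = []
    idx = 0
    for hap_no, hap in ((1, truth.hap1), (2, truth.hap2)):
        hap_arr = np.frombuffer(hap.seq.encode(), dtype=np.uint8)
        hp_mask = _homopolymer_mask(hap_arr, cfg.homopolymer_min)
        hap_len = len(hap.seq)
        diff = _hap_diff_ops(truth.reference.seq, truth.truth_variants,
                             hap_no - 1)
        q_prefix = np.cumsum([0] + [n if _QCONS[op] else 0 for op, n in diff])
        t_prefix = np.cumsum([0] + [n if _TCONS[op] else 0 for op, n in diff])
        target = cfg.coverage / 2.0 * hap_len
        total = 0
        while total < target:
            length = int(np.clip(rng.lognormal(mu, sigma),
                                 cfg.read_min_len, hap_len))
            # clipped-uniform start keeps coverage flat out to the ends
            start = int(rng.integers(1 - length, hap_len - 1))
            end = min(hap_len, start + length)
            start = max(0, start)
            length = end - start
            if length < 500:
                continue
            frag = hap.seq[start:start + length]
            read_seq, a_ops = _perturb_read(
                frag, rng, cfg, hp_mask[start:start + length])
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"r{idx:06d}"
            idx += 1
            total += len(read_seq)
            recs = _true_alignment(
                name, read_seq, a_ops, start, start + length, strand,
                diff, q_prefix, t_prefix, truth.reference)
            alignments.extend(recs)
            out_seq = read_seq if strand == "+" else revcomp(read_seq)
            reads.append(SimRead(name, out_seq, hap_no, start, start + length,
                                 strand))
    truth.truth_reads = reads
    truth.truth_alignments = alignments
    return reads, alignments


def _clip_diff(diff, q_prefix, t_prefix, qs: int, qe: int):
    """Clip hap->ref ops to hap interval [qs, qe); returns (ops, ref_start)."""
    i = int(np.searchsorted(q_prefix, qs, side="right")) - 1
    i = max(i, 0)
    out: list[tuple[str, int]] = []
    ref0: Optional[int] = None
    q = int(q_prefix[i])
    t = int(t_prefix[i])
    started = False
    for op, n in diff[i:]:
        if q >= qe:
            break
        qc, tc = _QCONS[op], _TCONS[op]
        if qc:
            lo, hi = max(q, qs), min(q + n, qe)
            if hi > lo:
                out.append((op, hi - lo))
                if ref0 is None and tc:
                    ref0 = t + (lo - q)
                started = True
            q += n
            if tc:
                t += n
        else:  # 'D' consumes reference only
            if started and q < qe:
                out.append((op, n))
            t += n
    # drop trailing deletions
    while out and out[-1][0] == "D":
        out.pop()
    return out, ref0


def _compose_cigars(a_ops, b_ops) -> list[tuple[str, int]]:
    """Compose read->fragment ops with fragment->reference ops."""
    a = [[op, n] for op, n in a_ops]
    b = [[op, n] for op, n in b_ops]
    out: list[list] = []
    ai = bi = 0
    while ai < len(a) or bi < len(b):
        if ai < len(a) and a[ai][0] == "I":
            _merge_push(out, "I", a[ai][1])
            ai += 1
            continue
        if bi < len(b) and b[bi][0] == "D":
            _merge_push(out, "D", b[bi][1])
            bi += 1
            continue
        if ai >= len(a) or bi >= len(b):
            break
        aop, an = a[ai]
        bop, bn = b[bi]
        n = min(an, bn)
        if aop in "=X" and bop in "=X":
            _merge_push(out, "=" if (aop == "=" and bop == "=") else "X", n)
        elif aop in "=X" and bop == "I":
            _merge_push(out, "I", n)
        elif aop == "D" and bop in "=X":
            _merge_push(out, "D", n)
        elif aop == "D" and bop == "I":
            pass  # base absent from both read and reference
        else:
            raise AssertionError(f"unexpected op pair {aop}/{bop}")
        a[ai][1] -= n
        b[bi][1] -= n
        if a[ai][1] == 0:
            ai += 1
        if b[bi][1] == 0:
            bi += 1
    return [(op, n) for op, n in out]


def _project_query(a_ops, frag_pos: int) -> int:
    """Read coordinate corresponding to a fragment coordinate."""
    q = t = 0
    for op, n in a_ops:
        if op == "I":
            q += n
        elif op == "D":
            if t + n > frag_pos:
                return q
            t += n
        else:
            if t + n > frag_pos:
                return q + (frag_pos - t)
            q += n
            t += n
    return q


def _finish_record(name, read_len, strand, oriented_qs, oriented_qe,
                   target_name, target_start, cigar) -> AlignmentRecord:
    # strip leading/trailing insertions into query clipping
    cigar = list(cigar)
    ts = target_start
    while cigar and cigar[0][0] in "ID":
        op, n = cigar.pop(0)
        if op == "I":
            oriented_qs += n
        else:
            ts += n
    while cigar and cigar[-1][0] in "ID":
        op, n = cigar.pop()
        if op == "I":
            oriented_qe -= n
    if strand == "+":
        qs, qe = oriented_qs, oriented_qe
    else:
        qs, qe = read_len - oriented_qe, read_len - oriented_qs
    rec = AlignmentRecord(
        query_name=name, query_len=read_len,
        query_start=qs, query_end=qe,
        target_name=target_name,
        target_start=ts,
        target_end=ts + sum(n for op, n in cigar if op in "=XD"),
        strand=strand, cigar=cigar,
        divergence=divergence_from_cigar(cigar))
    rec.validate()
    return rec


def _true_alignment(name, read_seq, a_ops, hs, he, strand,
                    diff, q_prefix, t_prefix,
                    reference: GenomeSequence) -> list[AlignmentRecord]:
    b_ops, ref0 = _clip_diff(diff, q_prefix, t_prefix, hs, he)
    if ref0 is None:
        return []  # read lies entirely inside an inserted sequence
    if not any(op == "V" for op, _ in b_ops):
        cigar = _compose_cigars(a_ops, b_ops)
        return [_finish_record(name, len(read_seq), strand, 0, len(read_seq),
                               reference.name, ref0, cigar)]
    # inversion-crossing read: emit split records, middle piece on the
    # opposite strand, each realigned locally with edlib
    records: list[AlignmentRecord] = []
    # walk b_ops grouping maximal non-V and V stretches
    pieces: list[list] = []  # [inverted, frag_q0, frag_q1, t0, t1]
    fq = 0
    t = ref0
    cur_inv = None
    for op, n in b_ops:
        qc, tc = _QCONS[op], _TCONS[op]
        inv = op == "V"
        if cur_inv is None or inv != cur_inv:
            pieces.append([inv, fq, fq, t, t])
            cur_inv = inv
        if qc:
            fq += n
            pieces[-1][2] = fq
        if tc:
            t += n
            pieces[-1][4] = t
    for inv, fq0, fq1, t0, t1 in pieces:
        if fq1 - fq0 < 30 or t1 - t0 < 30:
            continue  # too short to align independently
        rq0 = _project_query(a_ops, fq0)
        rq1 = _project_query(a_ops, fq1)
        if rq1 - rq0 < 30:
            continue
        sub = read_seq[rq0:rq1]
        window = reference.seq[t0:t1]
        if inv:
            sub = revcomp(sub)
        res = edlib.align(sub, window, mode="NW", task="path")
        cigar = parse_cigar(res["cigar"])
        piece_strand = strand
        o_qs, o_qe = rq0, rq1
        if inv:
            piece_strand = "-" if strand == "+" else "+"
            o_qs, o_qe = len(read_seq) - rq1, len(read_seq) - rq0
        records.append(_finish_record(
            name, len(read_seq), piece_strand, o_qs, o_qe,
            reference.name, t0, cigar))
    return records


# ---------------------------------------------------------------------------
# simulate_methylation
# ---------------------------------------------------------------------------

def simulate_methylation(truth: DiploidTruth, cfg: SimConfig,
                         ) -> tuple[list[MethSite], list[MethSite], list[MethRegion]]:
    """Per-haplotype CpG methylation over randomly placed regions.

    CpG sites are enumerated on both strands of the reference (the + site at
    the C, the - site one base downstream at the G).  Each region draws a
    baseline level from a bimodal prior (hypo ~0.1 / hyper ~0.9); in
    ``meth_diff_fraction`` of regions one haplotype's mean is shifted by
    ``meth_delta``.  Per-site Gaussian noise is truncated to [0, 1].
    """
    cfg.validate()
    rng = _rng(cfg.seed, "meth")
    ref = truth.reference.seq
    occ = Occupancy(gap=100)
    h1_sites: list[MethSite] = []
    h2_sites: list[MethSite] = []
    regions: list[MethRegion] = []
    n_diff = int(round(cfg.meth_diff_fraction * cfg.meth_regions))
    diff_flags = np.zeros(cfg.meth_regions, bool)
    if n_diff:
        diff_flags[rng.choice(cfg.meth_regions, size=n_diff, replace=False)] = True
    for i in range(cfg.meth_regions):
        start = _draw_position(rng, occ, cfg.meth_region_len, len(ref), 200,
                               f"methylation region {i}")
        end = start + cfg.meth_region_len
        cpg = [j for j in range(start, end - 1) if ref[j:j + 2] == "CG"]
        if not cpg:
            warnings.warn(f"no CpG in requested region {start}-{end}; dropped")
            continue
        base = 0.1 if rng.random() < 0.5 else 0.9
        base = float(np.clip(base + rng.normal(0, 0.02), 0.02, 0.98))
        mean1 = base
        mean2 = base
        if diff_flags[i]:
            shift = cfg.meth_delta if base < 0.5 else -cfg.meth_delta
            if rng.random() < 0.5:
                mean1 = float(np.clip(base + shift, 0.0, 1.0))
            else:
                mean2 = float(np.clip(base + shift, 0.0, 1.0))
        fr1: list[float] = []
        fr2: list[float] = []
        for j in cpg:
            for strand, pos in (("+", j), ("-", j + 1)):
                f1 = float(np.clip(mean1 + rng.normal(0, cfg.meth_noise_sd), 0, 1))
                f2 = float(np.clip(mean2 + rng.normal(0, cfg.meth_noise_sd), 0, 1))
                c1 = int(rng.poisson(cfg.meth_coverage))
                c2 = int(rng.poisson(cfg.meth_coverage))
                h1_sites.append(MethSite(_CHROM, pos, strand, c1, f1))
                h2_sites.append(MethSite(_CHROM, pos, strand, c2, f2))
                fr1.append(f1)
                fr2.append(f2)
        regions.append(MethRegion(
            _CHROM, start, end, f"region_{i:04d}", bool(diff_flags[i]),
            float(np.mean(fr1)), float(np.mean(fr2))))
    truth.truth_meth = (h1_sites, h2_sites)
    truth.meth_regions = regions
    return h1_sites, h2_sites, regions


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_truth(truth: DiploidTruth, cfg: SimConfig, outdir: str | Path) -> dict:
    """Write the complete simulated dataset as plain-text files.

    Returns a dict of the written paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.fasta",
        "hap1": out / "hap1.fasta",
        "hap2": out / "hap2.fasta",
        "truth_vcf": out / "truth.vcf",
        "vntr_bed": out / "vntr.bed",
        "reads": out / "reads.fasta",
        "alignments": out / "reads.paf",
        "meth_h1": out / "meth_h1.bedmethyl",
        "meth_h2": out / "meth_h2.bedmethyl",
        "regions_bed": out / "regions.bed",
        "config": out / "sim_config.json",
    }
    write_fasta([truth.reference], paths["reference"])
    write_fasta([truth.hap1], paths["hap1"])
    write_fasta([truth.hap2], paths["hap2"])
    write_vcf(truth.truth_variants, paths["truth_vcf"])
    write_bed(truth.vntr_bed, paths["vntr_bed"])
    write_fasta([GenomeSequence(r.name, r.seq) for r in truth.truth_reads],
                paths["reads"])
    write_paf(truth.truth_alignments, paths["alignments"])
    write_bedmethyl(truth.truth_meth[0], paths["meth_h1"])
    write_bedmethyl(truth.truth_meth[1], paths["meth_h2"])
    write_bed([(r.chrom, r.start, r.end,
                f"{r.label}|{'diff' if r.differential else 'same'}")
               for r in truth.meth_regions], paths["regions_bed"])
    with open(paths["config"], "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, default=list)
    return {k: str(v) for k, v in paths.items()}
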