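"""Structural variant calling from diploid contig-to-reference alignments.

Raw variants are read off the alignment CIGARs of each haplotype's contigs.
Inside annotated VNTR intervals, all indels of one haplotype are merged
into a single replacement record spanning from the first to the last
affected reference base — alignment ambiguity inside tandem repeats
otherwise fragments one copy-number allele into several sub-threshold
indels, and grouping restores the single >= 50 bp call.  Per-haplotype
calls are then merged into diploid genotypes.

The contig aligner is external; its exact parameter preset is recorded in
:class:`SvCallConfig` for reproducibility (see :mod:`dualvar.align`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import edlib
from Bio import Align
from intervaltree import IntervalTree

from .formats import (AlignmentRecord, GenomeSequence, Interval, Variant,
                      classify_variant, revcomp)

ALIGNER_PRESET = "-ax asm20 -B 2 -E 3,1 -O 6,100"


@dataclass
class SvCallConfig:
    min_sv_len: int = 50
    vntr_bed: Optional[list[Interval]] = None
    merge_tolerance_pos: int = 500
    merge_tolerance_sizeratio: float = 0.7
    aligner_preset: str = ALIGNER_PRESET

    def __post_init__(self) -> None:
        if self.min_sv_len < 1:
            raise ValueError("min_sv_len must be >= 1")


@dataclass
class HaplotypeVariant(Variant):
    haplotype: int = 1


def _affine_realign(query: str, target: str) -> list[tuple[str, int]]:
    """Globally realign two junction gap sequences with affine gap scoring.

    Unit-cost edit distance smears a long insertion+deletion junction into
    mismatches (random DNA aligns to random DNA at ~52% identity); cheap
    gap extension restores the contiguous indel structure.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -30.0
    aligner.extend_gap_score = -0.1
    aln = aligner.align(target, query)[0]
    t_blocks, q_blocks = aln.aligned
    ops: list[tuple[str, int]] = []
    pt = pq = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if ts > pt:
            ops.append(("D", ts - pt))
        if qs > pq:
            ops.append(("I", qs - pq))
        run_op, run_len = None, 0
        for a, b in zip(target[ts:te], query[qs:qe]):
            op = "=" if a == b else "X"
            if op == run_op:
                run_len += 1
            else:
                if run_op:
                    ops.append((run_op, run_len))
                run_op, run_len = op, 1
        if run_op:
            ops.append((run_op, run_len))
        pt, pq = te, qe
    if len(target) > pt:
        ops.append(("D", len(target) - pt))
    if len(query) > pq:
        ops.append(("I", len(query) - pq))
    return ops


def _hap_variant(chrom, pos, ref, alts, haplotype, sv_type=None,
                 grouped_from=1, sv_threshold=50) -> HaplotypeVariant:
    cls, svlen = classify_variant(ref, alts, sv_threshold)
    if sv_type == "INV":
        cls, svlen = "SV", 0
    return HaplotypeVariant(
        chrom=chrom, pos=pos, ref=ref, alts=alts, genotype=(0, 1),
        var_class=cls, sv_len=svlen,
        sv_type=sv_type or (None if cls != "SV" else
                            ("INS" if svlen > 0 else "DEL")),
        grouped_from=grouped_from, haplotype=haplotype)


# ---------------------------------------------------------------------------
# raw variant extraction
# ---------------------------------------------------------------------------

def extract_raw_variants(alignments: Sequence[AlignmentRecord],
                         contig_seqs: dict[str, str],
                         reference: GenomeSequence,
                         haplotype: int) -> list[HaplotypeVariant]:
    """Every I/D CIGAR op and X run becomes a raw variant (no size filter).

    Indels are left-anchored with one shared reference base.  Inversions
    are derived from strand-flipped split alignments of one contig.  When
    contig alignments overlap on the reference, the lower-identity one is
    ignored with a warning.
    """
    ref = reference.seq
    recs = [a for a in alignments if a.target_name == reference.name]
    recs.sort(key=lambda a: a.divergence)   # best (lowest divergence) first
    accepted: list[AlignmentRecord] = []
    tree = IntervalTree()
    for a in recs:
        hits = tree.overlap(a.target_start, a.target_end)
        overlap = sum(min(h.end, a.target_end) - max(h.begin, a.target_start)
                      for h in hits)
        if overlap > 0.5 * a.target_span:
            warnings.warn(f"overlapping contig alignment for {a.query_name} "
                          f"at {a.target_start}-{a.target_end} ignored")
            continue
        tree.addi(a.target_start, a.target_end)
        accepted.append(a)

    out: list[HaplotypeVariant] = []

    def walk_ops(ops, q_seq, q, t):
        for op, n in ops:
            if op in "=M":
                q += n
                t += n
            elif op == "X":
                if n == 1:
                    out.append(_hap_variant(reference.name, t + 1, ref[t],
                                            [q_seq[q]], haplotype))
                else:
                    out.append(_hap_variant(reference.name, t + 1,
                                            ref[t:t + n], [q_seq[q:q + n]],
                                            haplotype))
                q += n
                t += n
            elif op == "I":
                if t >= 1:
                    out.append(_hap_variant(
                        reference.name, t, ref[t - 1],
                        [ref[t - 1] + q_seq[q:q + n]], haplotype))
                q += n
            elif op == "D":
                if t >= 1:
                    out.append(_hap_variant(
                        reference.name, t, ref[t - 1:t + n], [ref[t - 1]],
                        haplotype))
                t += n
            elif op == "S":
                q += n

    for a in accepted:
        q_seq, q, _ = a.oriented_query(contig_seqs[a.query_name])
        walk_ops(a.cigar, q_seq, q, a.target_start)

    # split-alignment junctions: an aligner may break the contig alignment
    # at a long indel instead of spanning it in the CIGAR; the variant then
    # lives in the gap between consecutive collinear segments
    by_contig: dict[str, list[AlignmentRecord]] = {}
    for a in accepted:
        by_contig.setdefault(a.query_name, []).append(a)
    for contig, parts in by_contig.items():
        if len(parts) < 2:
            continue
        oriented = []
        for p in parts:
            _, oq0, oq1 = p.oriented_query(contig_seqs[contig])
            oriented.append((oq0, oq1, p))
        oriented.sort()
        q_seq = None
        for (a_oq0, a_oq1, a), (b_oq0, b_oq1, b) in zip(oriented, oriented[1:]):
            if a.strand != b.strand or b.target_start < a.target_start:
                continue
            qg = b_oq0 - a_oq1
            tg = b.target_start - a.target_end
            if max(qg, tg) > 100_000:
                continue
            # back the junction off any small segment overlap
            k = max(0, -qg, -tg)
            a_oq1 -= k
            a_t1 = a.target_end - k
            qg += k
            tg += k
            if (qg == 0 and tg == 0) or a_t1 < 1:
                continue
            if q_seq is None:
                q_seq = a.oriented_query(contig_seqs[contig])[0]
            if qg == 0 or tg == 0:
                anchor = ref[a_t1 - 1]
                ref_al = ref[a_t1 - 1:a_t1 + tg]
                alt = anchor + q_seq[a_oq1:a_oq1 + qg]
                out.append(_hap_variant(reference.name, a_t1, ref_al, [alt],
                                        haplotype))
            elif qg * tg <= 64_000_000:
                # the junction replaces one reference stretch by another:
                # realign the two gap sequences so that distinct nearby
                # variants fused into one junction come apart again
                ops = _affine_realign(q_seq[a_oq1:a_oq1 + qg],
                                      ref[a_t1:a_t1 + tg])
                walk_ops(ops, q_seq, a_oq1, a_t1)
            else:
                # too large to realign: emit one replacement record
                out.append(_hap_variant(
                    reference.name, a_t1, ref[a_t1 - 1:a_t1 + tg],
                    [ref[a_t1 - 1] + q_seq[a_oq1:a_oq1 + qg]], haplotype))

    # inversions: one contig aligned +,-,+ (or any strand mix); the
    # minority-strand segment spans the inverted reference interval
    for contig, parts in by_contig.items():
        strands = {p.strand for p in parts}
        if len(strands) < 2:
            continue
        span = {s: sum(p.query_span for p in parts if p.strand == s)
                for s in strands}
        minority = min(span, key=span.get)
        for p in parts:
            if p.strand != minority:
                continue
            s, e = p.target_start, p.target_end
            out.append(_hap_variant(reference.name, s + 1, ref[s:e],
                                    [revcomp(ref[s:e])], haplotype,
                                    sv_type="INV"))
    out.sort(key=Variant.sort_key)
    return out


# ---------------------------------------------------------------------------
# VNTR grouping
# ---------------------------------------------------------------------------

def group_vntr_indels(raw_variants: Sequence[HaplotypeVariant],
                      vntr_bed: Sequence[Interval],
                      reference: GenomeSequence) -> list[HaplotypeVariant]:
    """Merge all indels of one haplotype inside one VNTR interval into a
    single replacement record.

    The record spans from the first to the last affected reference base;
    its alt allele is the reference window with the constituent indels
    applied, so the net length change is the sum of the members'.  SNPs
    are never grouped; variants outside VNTRs pass through unchanged.
    """
    tree = IntervalTree()
    for k, (chrom, start, end, label) in enumerate(vntr_bed):
        if start < end:
            tree.addi(start, end, k)
    groups: dict[int, list[HaplotypeVariant]] = {}
    out: list[HaplotypeVariant] = []
    for v in sorted(raw_variants, key=Variant.sort_key):
        is_indel = len(v.ref) != len(v.alts[0]) and v.sv_type != "INV"
        hit = tree.overlap(v.start0, v.start0 + 1) if is_indel else None
        if hit:
            groups.setdefault(next(iter(hit)).data, []).append(v)
        else:
            out.append(v)
    ref = reference.seq
    for k, members in groups.items():
        members.sort(key=Variant.sort_key)
        start0 = members[0].start0
        end0 = max(m.end0 for m in members)
        pieces: list[str] = []
        cur = start0
        for m in members:
            if m.start0 < cur:
                # members overlap (should not happen for one alignment);
                # keep them ungrouped rather than build an inconsistent alt
                warnings.warn("overlapping indels inside one VNTR; "
                              "left ungrouped")
                out.extend(members)
                pieces = None
                break
            pieces.append(ref[cur:m.start0])
            pieces.append(m.alts[0])
            cur = m.end0
        if pieces is None:
            continue
        pieces.append(ref[cur:end0])
        alt = "".join(pieces)
        ref_al = ref[start0:end0]
        cls, svlen = classify_variant(ref_al, [alt])
        out.append(HaplotypeVariant(
            chrom=members[0].chrom, pos=start0 + 1, ref=ref_al, alts=[alt],
            genotype=(0, 1), var_class=cls, sv_len=svlen,
            sv_type=None if cls != "SV" else ("INS" if svlen > 0 else "DEL"),
            grouped_from=len(members), haplotype=members[0].haplotype))
    out.sort(key=Variant.sort_key)
    return out


def filter_svs(variants: Sequence[HaplotypeVariant],
               cfg: SvCallConfig = SvCallConfig()) -> list[HaplotypeVariant]:
    """Keep records with |net length change| >= min_sv_len, plus inversions
    whose span reaches min_sv_len."""
    out = []
    for v in variants:
        if v.sv_type == "INV":
            if v.end0 - v.start0 >= cfg.min_sv_len:
                out.append(v)
        elif abs(v.sv_len) >= cfg.min_sv_len:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# diploid merge
# ---------------------------------------------------------------------------

def _type_class(v: Variant) -> str:
    if v.sv_type == "INV":
        return "INV"
    return "INS" if v.sv_len > 0 else "DEL"


def _harmonized_similarity(v1: Variant, v2: Variant, reference: str,
                           flank: int = 100) -> float:
    """Similarity of two variants as local haplotype sequences: both alt
    alleles are substituted into a shared reference window and compared."""
    ws = max(0, min(v1.start0, v2.start0) - flank)
    we = min(len(reference), max(v1.end0, v2.end0) + flank)
    s1 = reference[ws:v1.start0] + v1.alts[0] + reference[v1.end0:we]
    s2 = reference[ws:v2.start0] + v2.alts[0] + reference[v2.end0:we]
    d = edlib.align(s1, s2, mode="NW", task="distance")["editDistance"]
    m = max(len(s1), len(s2))
    return 1.0 - d / m if m else 1.0


def merge_diploid(h1_svs: Sequence[HaplotypeVariant],
                  h2_svs: Sequence[HaplotypeVariant],
                  cfg: SvCallConfig = SvCallConfig(),
                  reference: Optional[GenomeSequence] = None) -> list[Variant]:
    """Merge per-haplotype SV calls into genotyped diploid records.

    Same-type records merge into 1|1 when their anchors are within
    ``merge_tolerance_pos``, their sizes agree to ``merge_tolerance_sizeratio``
    and (for insertions) their sequences are at least that similar.
    Single-haplotype records become 1|0 / 0|1; different alts colliding at
    one anchor become a multiallelic 1|2 record.
    """
    h1 = sorted(h1_svs, key=Variant.sort_key)
    h2 = sorted(h2_svs, key=Variant.sort_key)
    used2: set[int] = set()
    out: list[Variant] = []
    unmatched1: list[HaplotypeVariant] = []
    for v1 in h1:
        best_j, best_score = -1, float("inf")
        for j, v2 in enumerate(h2):
            if j in used2 or v2.chrom != v1.chrom:
                continue
            d = abs(v2.pos - v1.pos)
            if d > cfg.merge_tolerance_pos:
                continue
            if _type_class(v1) != _type_class(v2):
                continue
            l1 = abs(v1.sv_len) if v1.sv_type != "INV" else v1.end0 - v1.start0
            l2 = abs(v2.sv_len) if v2.sv_type != "INV" else v2.end0 - v2.start0
            ratio = min(l1, l2) / max(l1, l2) if max(l1, l2) else 1.0
            if ratio < cfg.merge_tolerance_sizeratio:
                continue
            if v1.sv_len > 0 and reference is not None:
                sim = _harmonized_similarity(v1, v2, reference.seq)
                if sim < cfg.merge_tolerance_sizeratio:
                    continue
            score = d / max(cfg.merge_tolerance_pos, 1) + (1.0 - ratio)
            if score < best_score:
                best_score, best_j = score, j
        if best_j >= 0:
            used2.add(best_j)
            out.append(replace(v1, genotype=(1, 1), phased=True, phase_set=1))
        else:
            unmatched1.append(v1)
    unmatched2 = [v for j, v in enumerate(h2) if j not in used2]
    # collision check: different alts anchored at (nearly) the same base
    used_u2: set[int] = set()
    for v1 in unmatched1:
        hit = -1
        for j, v2 in enumerate(unmatched2):
            if j in used_u2 or v2.chrom != v1.chrom:
                continue
            if abs(v2.pos - v1.pos) <= 10 or \
                    (v1.start0 < v2.end0 and v2.start0 < v1.end0):
                hit = j
                break
        if hit >= 0:
            used_u2.add(hit)
            out.append(_multiallelic(v1, unmatched2[hit],
                                     reference.seq if reference else None))
        else:
            out.append(replace(v1, genotype=(1, 0), phased=True, phase_set=1))
    for j, v2 in enumerate(unmatched2):
        if j not in used_u2:
            out.append(replace(v2, genotype=(0, 1), phased=True, phase_set=1))
    out.sort(key=Variant.sort_key)
    return out


def _multiallelic(v1: HaplotypeVariant, v2: HaplotypeVariant,
                  reference: Optional[str]) -> Variant:
    """Re-anchor two colliding single-haplotype records on a shared ref span."""
    if (v1.start0, v1.end0) == (v2.start0, v2.end0) or reference is None:
        alts = [v1.alts[0], v2.alts[0]]
        base = v1
    else:
        start0 = min(v1.start0, v2.start0)
        end0 = max(v1.end0, v2.end0)
        alt1 = reference[start0:v1.start0] + v1.alts[0] + reference[v1.end0:end0]
        alt2 = reference[start0:v2.start0] + v2.alts[0] + reference[v2.end0:end0]
        base = replace(v1, pos=start0 + 1, ref=reference[start0:end0])
        alts = [alt1, alt2]
    return replace(base, alts=alts, genotype=(1, 2), phased=True, phase_set=1)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def call_svs(h1_alignments: Sequence[AlignmentRecord],
             h2_alignments: Sequence[AlignmentRecord],
             contig_seqs: dict[str, str],
             reference: GenomeSequence,
             cfg: SvCallConfig = SvCallConfig()) -> list[Variant]:
    """extract -> group (if VNTR annotation given) -> filter -> merge."""
    per_hap = []
    for hap, alns in ((1, h1_alignments), (2, h2_alignments)):
        raw = extract_raw_variants(alns, contig_seqs, reference, hap)
        if cfg.vntr_bed:
            raw = group_vntr_indels(raw, cfg.vntr_bed, reference)
        per_hap.append(filter_svs(raw, cfg))
    return merge_diploid(per_hap[0], per_hap[1], cfg, reference)
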