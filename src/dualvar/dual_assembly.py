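"""Locally phased diploid (dual) assembly from a haploid draft.

Given a haploid draft assembly and long-read alignments against it, the
procedure (i) filters out reads with large unaligned parts or high
alignment error, (ii) calls heterozygous SNPs from the pileup, (iii)
phases them and haplotags the reads by majority vote, (iv) polishes each
haplotype independently with a chunked plurality consensus — chunk
boundaries are shifted so that regions where reads carry indels at
inconsistent coordinates stay inside a single chunk — and (v) detects
inversion signatures from strand-split read alignments and applies them
to the assigned haplotype.

The output is a dual assembly (one sequence per input contig per
haplotype) or a split assembly cut at phase-set boundaries.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from .formats import AlignmentRecord, GenomeSequence, Variant, parse_cigar
from .phase_harmonize import AlleleSupport, PhasingConfig, phase_variants

_BASE_TO_IDX = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
_IDX_TO_BASE = "ACGT"
_DEL = 4


@dataclass
class ReadFilterConfig:
    min_read_len: int = 5000
    min_aln_len: int = 5000
    max_divergence: float = 0.09
    max_unaligned_frac: float = 0.20

    def __post_init__(self) -> None:
        if self.min_read_len < 0 or self.min_aln_len < 0:
            raise ValueError("length thresholds must be nonnegative")
        if not (0 <= self.max_divergence <= 1):
            raise ValueError("max_divergence must be in [0,1]")
        if not (0 <= self.max_unaligned_frac <= 1):
            raise ValueError("max_unaligned_frac must be in [0,1]")


@dataclass
class HapdupConfig:
    read_filter: ReadFilterConfig = field(default_factory=ReadFilterConfig)
    min_coverage: int = 8
    min_alt_frac: float = 0.25
    chunk_size: int = 10_000
    min_indel_len: int = 5
    indel_pad: int = 10
    min_inversion_support: int = 3
    cluster_eps: int = 500
    phasing: PhasingConfig = field(default_factory=PhasingConfig)


@dataclass
class Haplotag:
    read_name: str
    tag: str                 # 'H1' | 'H2' | 'untagged'
    votes_h1: int = 0
    votes_h2: int = 0


@dataclass
class InversionSignature:
    contig: str
    start: int
    end: int
    support: int
    haplotype: str           # 'H1' | 'H2' | 'both'


# ---------------------------------------------------------------------------
# read filtering
# ---------------------------------------------------------------------------

def filter_read_alignments(alignments: Sequence[AlignmentRecord],
                           cfg: ReadFilterConfig = ReadFilterConfig(),
                           ) -> tuple[list[AlignmentRecord], list[tuple[str, str]]]:
    """Remove reads with large unaligned parts or high alignment error.

    Rules are applied per read (pooled over its alignment records) in a
    fixed order; each removed read is tagged with the first failing rule.
    Returns (kept alignment records, [(read_name, reason), ...]).
    """
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        by_read[a.query_name].append(a)
    kept: list[AlignmentRecord] = []
    removed: list[tuple[str, str]] = []
    for name, recs in by_read.items():
        qlen = recs[0].query_len
        aligned = sum(r.query_span for r in recs)
        div = (sum(r.divergence * r.query_span for r in recs) / aligned
               if aligned else 1.0)
        if qlen < cfg.min_read_len:
            removed.append((name, "read_length"))
        elif aligned < cfg.min_aln_len:
            removed.append((name, "alignment_length"))
        elif div > cfg.max_divergence:
            removed.append((name, "divergence"))
        elif (qlen - min(aligned, qlen)) / qlen > cfg.max_unaligned_frac:
            removed.append((name, "unaligned_fraction"))
        else:
            kept.extend(recs)
    return kept, removed


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

class Pileup:
    """Column counts plus per-alignment mismatch/indel layout over one contig.

    ``counts[:, 0:4]`` are A/C/G/T observations, ``counts[:, 4]`` deletion
    observations.  Insertions are recorded per junction position with the
    full inserted sequence.
    """

    def __init__(self, draft: GenomeSequence,
                 alignments: Sequence[AlignmentRecord],
                 reads: dict[str, str]) -> None:
        self.draft = draft
        self.L = len(draft.seq)
        self.draft_arr = np.frombuffer(draft.seq.encode(), dtype=np.uint8)
        self.draft_idx = np.full(self.L, -1, dtype=np.int8)
        for b, i in _BASE_TO_IDX.items():
            self.draft_idx[self.draft_arr == b] = i
        self.counts = np.zeros((self.L, 5), dtype=np.int32)
        self.insertions: dict[int, Counter] = defaultdict(Counter)
        # per alignment: (record, {tpos: base}, [del intervals], (t0, t1))
        self.infos: list[tuple[AlignmentRecord, dict[int, str],
                               list[tuple[int, int]]]] = []
        for aln in alignments:
            if aln.target_name != draft.name:
                continue
            self._add(aln, reads[aln.query_name])

    def _add(self, aln: AlignmentRecord, read_seq: str) -> None:
        q_seq, q, _ = aln.oriented_query(read_seq)
        t = aln.target_start
        counts = self.counts
        mism: dict[int, str] = {}
        dels: list[tuple[int, int]] = []
        for op, n in aln.cigar:
            if op == "=":
                idx = np.arange(t, t + n)
                counts[idx, self.draft_idx[idx]] += 1
                q += n
                t += n
            elif op == "X":
                for i in range(n):
                    b = q_seq[q + i]
                    bi = _BASE_TO_IDX.get(ord(b))
                    if bi is not None:
                        counts[t + i, bi] += 1
                        mism[t + i] = b
                q += n
                t += n
            elif op == "M":
                sub = np.frombuffer(q_seq[q:q + n].encode(), dtype=np.uint8)
                idx = np.arange(t, t + n)
                eq = sub == self.draft_arr[idx]
                counts[idx[eq], self.draft_idx[idx[eq]]] += 1
                for off in np.nonzero(~eq)[0]:
                    b = q_seq[q + off]
                    bi = _BASE_TO_IDX.get(ord(b))
                    if bi is not None:
                        counts[t + off, bi] += 1
                        mism[t + off] = b
                q += n
                t += n
            elif op == "I":
                self.insertions[t][q_seq[q:q + n]] += 1
                q += n
            elif op == "D":
                counts[t:t + n, _DEL] += 1
                dels.append((t, t + n))
                t += n
            elif op in "SH":
                q += n if op == "S" else 0
        self.infos.append((aln, mism, dels))

    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def allele_at(self, info, pos: int) -> Optional[str]:
        """Base carried by one alignment at a draft position (None if the
        position is outside the aligned span, '-' if deleted)."""
        aln, mism, dels = info
        if not (aln.target_start <= pos < aln.target_end):
            return None
        for ds, de in dels:
            if ds <= pos < de:
                return "-"
        return mism.get(pos, self.draft.seq[pos])


# ---------------------------------------------------------------------------
# het SNP calling
# ---------------------------------------------------------------------------

def call_het_snps(pileup: Pileup, min_coverage: int = 8,
                  min_alt_frac: float = 0.25,
                  ) -> tuple[list[Variant], list[Variant]]:
    """Heterozygous SNP candidates from the pileup.

    A column is a het SNP when its two most frequent base alleles each have
    frequency >= min_alt_frac and coverage >= min_coverage.  Columns where a
    single non-draft base dominates are returned separately as homozygous
    draft differences (used for polishing, not informative for phasing).
    """
    counts = pileup.counts[:, :4]
    cov = pileup.counts.sum(axis=1)
    order = np.argsort(counts, axis=1)
    top1 = order[:, 3]
    top2 = order[:, 2]
    n1 = counts[np.arange(pileup.L), top1]
    n2 = counts[np.arange(pileup.L), top2]
    ok = cov >= min_coverage
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(cov > 0, n1 / cov, 0.0)
        f2 = np.where(cov > 0, n2 / cov, 0.0)
    het_mask = ok & (f1 >= min_alt_frac) & (f2 >= min_alt_frac) & (n2 > 0)
    hets: list[Variant] = []
    for p in np.nonzero(het_mask)[0]:
        ref_b = pileup.draft.seq[p]
        b1, b2 = _IDX_TO_BASE[top1[p]], _IDX_TO_BASE[top2[p]]
        alleles = sorted([b1, b2])
        if ref_b in alleles:
            alt = alleles[0] if alleles[1] == ref_b else alleles[1]
            gt = (0, 1)
            alts = [alt]
        else:
            alts = alleles
            gt = (1, 2)
        hets.append(Variant(pileup.draft.name, int(p) + 1, ref_b, alts,
                            genotype=gt, var_class="SNP"))
    hom_mask = ok & (f1 >= 1.0 - min_alt_frac) & ~het_mask \
        & (top1 != pileup.draft_idx)
    homs: list[Variant] = []
    for p in np.nonzero(hom_mask)[0]:
        ref_b = pileup.draft.seq[p]
        if pileup.draft_idx[p] < 0:
            continue
        homs.append(Variant(pileup.draft.name, int(p) + 1, ref_b,
                            [_IDX_TO_BASE[top1[p]]], genotype=(1, 1),
                            var_class="SNP"))
    return hets, homs


# ---------------------------------------------------------------------------
# phasing + haplotagging
# ---------------------------------------------------------------------------

def snp_allele_supports(het_snps: Sequence[Variant], pileup: Pileup,
                        epsilon: float) -> list[AlleleSupport]:
    """Per-read allele support at het SNP columns, straight from the pileup
    (no window extraction needed for isolated substitution columns)."""
    supports: list[AlleleSupport] = []
    pos_index = {v.pos - 1: i for i, v in enumerate(het_snps)}
    positions = np.array(sorted(pos_index), dtype=int)
    for info in pileup.infos:
        aln = info[0]
        lo = np.searchsorted(positions, aln.target_start)
        hi = np.searchsorted(positions, aln.target_end)
        for p in positions[lo:hi]:
            i = pos_index[int(p)]
            v = het_snps[i]
            base = pileup.allele_at(info, int(p))
            if base is None or base == "-":
                continue
            alleles = [v.ref] + v.alts
            if base not in alleles:
                continue
            k = alleles.index(base)
            n = len(alleles)
            probs = [(1.0 - epsilon) if j == k else epsilon / (n - 1)
                     for j in range(n)]
            supports.append(AlleleSupport(aln.query_name, i, tuple(probs)))
    return supports


def phase_and_haplotag(het_snps: Sequence[Variant], pileup: Pileup,
                       cfg: HapdupConfig = HapdupConfig(),
                       ) -> tuple[list[Variant], list[Haplotag]]:
    """Phase het SNPs and tag each read by majority vote over the phased
    alleles it covers; ties and zero-vote reads stay untagged."""
    if not het_snps:
        names = {info[0].query_name for info in pileup.infos}
        return [], [Haplotag(n, "untagged") for n in sorted(names)]
    supports = snp_allele_supports(het_snps, pileup, cfg.phasing.base_error)
    phased = phase_variants(het_snps, supports, cfg.phasing)
    by_pos = {v.pos - 1: v for v in phased}
    positions = np.array(sorted(by_pos), dtype=int)
    votes: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for info in pileup.infos:
        aln = info[0]
        lo = np.searchsorted(positions, aln.target_start)
        hi = np.searchsorted(positions, aln.target_end)
        for p in positions[lo:hi]:
            v = by_pos[int(p)]
            base = pileup.allele_at(info, int(p))
            if base is None or base == "-":
                continue
            if base == v.allele(v.genotype[0]):
                votes[aln.query_name][0] += 1
            elif base == v.allele(v.genotype[1]):
                votes[aln.query_name][1] += 1
    tags: list[Haplotag] = []
    seen: set[str] = set()
    for info in pileup.infos:
        name = info[0].query_name
        if name in seen:
            continue
        seen.add(name)
        v1, v2 = votes.get(name, (0, 0))
        if v1 > v2:
            tag = "H1"
        elif v2 > v1:
            tag = "H2"
        else:
            tag = "untagged"
        tags.append(Haplotag(name, tag, v1, v2))
    return phased, tags


# ---------------------------------------------------------------------------
# chunk selection
# ---------------------------------------------------------------------------

def inconsistent_indel_regions(alignments: Sequence[AlignmentRecord],
                               min_indel_len: int = 5, pad: int = 10,
                               ) -> list[tuple[int, int]]:
    """Maximal intervals where >=2 reads carry indels (>= min_indel_len)
    whose contig coordinates differ by more than ``pad`` yet whose
    pad-expanded intervals chain together."""
    events: list[tuple[int, int, str, int]] = []  # (padded start, padded end, read, pos)
    for aln in alignments:
        t = aln.target_start
        for op, n in aln.cigar:
            if op in "=XM":
                t += n
            elif op == "I":
                if n >= min_indel_len:
                    events.append((t - pad, t + pad, aln.query_name, t))
            elif op == "D":
                if n >= min_indel_len:
                    events.append((t - pad, t + n + pad, aln.query_name, t))
                t += n
    events.sort()
    regions: list[tuple[int, int]] = []
    cluster: list[tuple[int, int, str, int]] = []

    def flush():
        if not cluster:
            return
        reads = {e[2] for e in cluster}
        span = max(e[3] for e in cluster) - min(e[3] for e in cluster)
        if len(reads) >= 2 and span >= pad:
            regions.append((max(min(e[0] for e in cluster), 0),
                            max(e[1] for e in cluster)))

    cur_end = None
    for ev in events:
        if cur_end is None or ev[0] <= cur_end:
            cluster.append(ev)
            cur_end = max(cur_end or ev[1], ev[1])
        else:
            flush()
            cluster = [ev]
            cur_end = ev[1]
    flush()
    return regions


def select_chunk_boundaries(alignments: Sequence[AlignmentRecord],
                            contig_len: int, chunk_size: int = 10_000,
                            min_indel_len: int = 5, pad: int = 10,
                            ) -> list[int]:
    """Boundaries partitioning [0, contig_len), nominally every chunk_size
    bp, shifted off inconsistent-indel regions; a region longer than
    chunk_size becomes its own chunk."""
    regions = inconsistent_indel_regions(alignments, min_indel_len, pad)
    bounds = {0, contig_len}
    for b in range(chunk_size, contig_len, chunk_size):
        shifted = b
        for rs, re_ in regions:
            if rs < b < re_:
                shifted = rs if b - rs <= re_ - b else re_
                break
        if 0 < shifted < contig_len:
            bounds.add(shifted)
    for rs, re_ in regions:
        if re_ - rs > chunk_size:
            if 0 < rs < contig_len:
                bounds.add(rs)
            if 0 < re_ < contig_len:
                bounds.add(min(re_, contig_len))
    return sorted(bounds)


# ---------------------------------------------------------------------------
# polishing
# ---------------------------------------------------------------------------

def _insertion_consensus(seqs: list[str]) -> str:
    """Consensus of similar inserted sequences: medoid by edit distance,
    refined by a column plurality vote of all members aligned to it."""
    if len(seqs) == 1:
        return seqs[0]
    uniq = Counter(seqs)
    if len(uniq) == 1:
        return seqs[0]
    top, cnt = uniq.most_common(1)[0]
    if cnt * 2 > len(seqs):
        return top
    cand = list(uniq)[:12]
    dists = np.zeros(len(cand))
    for i, a in enumerate(cand):
        for b, c in uniq.items():
            dists[i] += c * edlib.align(b, a, mode="NW",
                                        task="distance")["editDistance"]
    medoid = cand[int(np.argmin(dists))]
    return _column_vote_consensus(medoid, seqs)


def _column_vote_consensus(backbone: str, seqs: list[str]) -> str:
    """Plurality consensus of sequences aligned against a backbone."""
    L = len(backbone)
    counts = np.zeros((L, 5), dtype=np.int32)
    ins: dict[int, Counter] = defaultdict(Counter)
    bb_idx = np.array([_BASE_TO_IDX.get(ord(c), 0) for c in backbone])
    for s in seqs:
        res = edlib.align(s, backbone, mode="NW", task="path")
        q = t = 0
        for op, n in parse_cigar(res["cigar"]):
            if op == "=":
                idx = np.arange(t, t + n)
                counts[idx, bb_idx[idx]] += 1
                q += n
                t += n
            elif op == "X":
                for i in range(n):
                    bi = _BASE_TO_IDX.get(ord(s[q + i]))
                    if bi is not None:
                        counts[t + i, bi] += 1
                q += n
                t += n
            elif op == "I":
                ins[t][s[q:q + n]] += 1
                q += n
            elif op == "D":
                counts[t:t + n, _DEL] += 1
                t += n
    n_seqs = len(seqs)
    out: list[str] = []
    for p in range(L):
        if p in ins and sum(ins[p].values()) * 2 > n_seqs:
            out.append(_insertion_consensus(
                [s for s, c in ins[p].items() for _ in range(c)]))
        win = int(np.argmax(counts[p]))
        if counts[p].sum() == 0:
            out.append(backbone[p])
        elif win != _DEL:
            out.append(_IDX_TO_BASE[win])
    if L in ins and sum(ins[L].values()) * 2 > n_seqs:
        out.append(_insertion_consensus(
            [s for s, c in ins[L].items() for _ in range(c)]))
    return "".join(out)


@dataclass
class PolishResult:
    sequence: str
    covered: np.ndarray            # bool per draft position
    zero_cov_chunks: list[tuple[int, int]]
    pos_map: np.ndarray            # draft position -> polished position


def _segment_for_chunk(pileup: Pileup, info, cs: int, ce: int,
                       reads: dict[str, str]) -> Optional[str]:
    aln = info[0]
    if aln.target_start > cs or aln.target_end < ce:
        return None
    from .phase_harmonize import project_interval
    span = project_interval(aln, cs, ce)
    if span is None:
        return None
    q_seq, _, _ = aln.oriented_query(reads[aln.query_name])
    return q_seq[span[0]:span[1]]


def polish_haplotype(pileup: Pileup, chunks: Sequence[tuple[int, int]],
                     reads: dict[str, str],
                     complex_regions: Sequence[tuple[int, int]] = (),
                     ) -> PolishResult:
    """Plurality-consensus polish of the draft from one haplotype's reads.

    Simple chunks use a per-column vote over the pileup (insertions accepted
    when carried by more than half of the covering reads).  Chunks that
    contain an inconsistent-indel region are rebuilt reference-free from
    read segments spanning the chunk (medoid backbone + column vote), which
    keeps indels with unstable alignment coordinates coherent.  Chunks with
    no coverage are returned unchanged and flagged.
    """
    cov = pileup.coverage()
    out_parts: list[str] = []
    covered = cov > 0
    zero_chunks: list[tuple[int, int]] = []
    pos_map = np.zeros(pileup.L + 1, dtype=np.int64)
    polished_len = 0
    for cs, ce in chunks:
        chunk_cov = cov[cs:ce]
        if chunk_cov.max(initial=0) == 0:
            part = pileup.draft.seq[cs:ce]
            zero_chunks.append((cs, ce))
            pos_map[cs:ce] = polished_len + np.arange(ce - cs)
            out_parts.append(part)
            polished_len += len(part)
            continue
        is_complex = any(rs < ce and re_ > cs for rs, re_ in complex_regions)
        part = None
        if is_complex:
            segments = []
            for info in pileup.infos:
                seg = _segment_for_chunk(pileup, info, cs, ce, reads)
                if seg is not None:
                    segments.append(seg)
            if len(segments) >= 2:
                part = _insertion_consensus(segments)
                pos_map[cs:ce] = polished_len + np.round(
                    np.linspace(0, len(part), ce - cs, endpoint=False)).astype(int)
        if part is None:
            part = _polish_columns(pileup, cs, ce, pos_map, polished_len)
        out_parts.append(part)
        polished_len += len(part)
    pos_map[pileup.L] = polished_len
    return PolishResult("".join(out_parts), covered, zero_chunks, pos_map)


def _polish_columns(pileup: Pileup, cs: int, ce: int,
                    pos_map: np.ndarray, offset: int) -> str:
    counts = pileup.counts
    cov = pileup.coverage()
    out: list[str] = []
    pos = 0
    for p in range(cs, ce):
        if p in pileup.insertions:
            ctr = pileup.insertions[p]
            total = sum(ctr.values())
            junction_cov = max(int(cov[p]), int(cov[p - 1]), 1)
            if total * 2 > junction_cov:
                ins_seq = _insertion_consensus(
                    [s for s, c in ctr.items() for _ in range(c)])
                out.append(ins_seq)
                pos += len(ins_seq)
        pos_map[p] = offset + pos
        if cov[p] == 0:
            out.append(pileup.draft.seq[p])
            pos += 1
            continue
        win = int(np.argmax(counts[p]))
        if win == _DEL:
            continue
        out.append(_IDX_TO_BASE[win])
        pos += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# inversion signatures
# ---------------------------------------------------------------------------

def detect_inversions(alignments: Sequence[AlignmentRecord],
                      min_support: int = 3, cluster_eps: int = 500,
                      haplotags: Optional[Sequence[Haplotag]] = None,
                      ) -> list[InversionSignature]:
    """Inversion candidates from strand-split read alignments.

    A read whose split alignments mix strands contributes its
    minority-strand target interval(s) as candidates; candidates whose
    breakpoints cluster within ``cluster_eps`` bp on the same contig are
    merged, and clusters with at least ``min_support`` reads are emitted.
    The haplotype is taken from the tags of the supporting reads ("both"
    when mixed or untagged).
    """
    tag_of = {t.read_name: t.tag for t in haplotags} if haplotags else {}
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        by_read[a.query_name].append(a)
    candidates: list[tuple[str, int, int, str]] = []
    for name, recs in by_read.items():
        strands = {r.strand for r in recs}
        if len(strands) < 2:
            continue
        span = {s: sum(r.query_span for r in recs if r.strand == s)
                for s in strands}
        minority = min(span, key=span.get)
        for r in recs:
            if r.strand == minority:
                candidates.append((r.target_name, r.target_start, r.target_end,
                                   name))
    candidates.sort()
    signatures: list[InversionSignature] = []
    cluster: list[tuple[str, int, int, str]] = []

    def flush():
        if not cluster:
            return
        reads = {c[3] for c in cluster}
        if len(reads) < min_support:
            return
        start = int(np.median([c[1] for c in cluster]))
        end = int(np.median([c[2] for c in cluster]))
        tags = {tag_of.get(r, "untagged") for r in reads}
        if tags == {"H1"}:
            hap = "H1"
        elif tags == {"H2"}:
            hap = "H2"
        else:
            hap = "both"
        signatures.append(InversionSignature(cluster[0][0], start, end,
                                             len(reads), hap))

    for c in candidates:
        if cluster and c[0] == cluster[0][0] \
                and abs(c[1] - cluster[-1][1]) <= cluster_eps \
                and abs(c[2] - cluster[-1][2]) <= cluster_eps:
            cluster.append(c)
        else:
            flush()
            cluster = [c]
    flush()
    return signatures


def apply_rearrangements(contigs: dict[str, str],
                         signatures: Sequence[InversionSignature],
                         ) -> dict[str, str]:
    """Reverse-complement each signature interval in its contig.

    Intervals are in the coordinates of the given contigs.  Overlapping
    signatures on one contig, or intervals outside the contig, are errors.
    """
    from .formats import revcomp
    by_contig: dict[str, list[InversionSignature]] = defaultdict(list)
    for sig in signatures:
        by_contig[sig.contig].append(sig)
    out = dict(contigs)
    for name, sigs in by_contig.items():
        if name not in out:
            raise ValueError(f"signature on unknown contig {name}")
        seq = out[name]
        sigs.sort(key=lambda s: s.start)
        prev_end = -1
        for s in sigs:
            if s.start < 0 or s.end > len(seq) or s.start >= s.end:
                raise ValueError(f"signature interval outside contig {name}")
            if s.start < prev_end:
                raise ValueError(f"overlapping inversion signatures on {name}")
            prev_end = s.end
        pieces = []
        cur = 0
        for s in sigs:
            pieces.append(seq[cur:s.start])
            pieces.append(revcomp(seq[s.start:s.end]))
            cur = s.end
        pieces.append(seq[cur:])
        out[name] = "".join(pieces)
    return out


# ---------------------------------------------------------------------------
# assembly emission
# ---------------------------------------------------------------------------

def emit_assembly(haplotype_seqs: dict[str, tuple[str, str]],
                  phase_breaks: dict[str, Sequence[int]],
                  mode: str = "dual") -> list[GenomeSequence]:
    """Emit the diploid assembly.

    ``haplotype_seqs`` maps contig -> (hap1 seq, hap2 seq);
    ``phase_breaks`` maps contig -> cut positions (in the emitted
    coordinates) used in split mode.  Dual mode keeps one sequence per
    contig per haplotype; split mode cuts at phase-set boundaries and
    suffixes part indices.
    """
    if mode not in ("dual", "split"):
        raise ValueError("mode must be 'dual' or 'split'")
    out: list[GenomeSequence] = []
    for contig, (h1, h2) in sorted(haplotype_seqs.items()):
        for hap_no, seq in ((1, h1), (2, h2)):
            if mode == "dual":
                out.append(GenomeSequence(f"{contig}_hap{hap_no}", seq))
            else:
                cuts = sorted(c for c in phase_breaks.get(contig, ())
                              if 0 < c < len(seq))
                bounds = [0] + cuts + [len(seq)]
                for i in range(len(bounds) - 1):
                    out.append(GenomeSequence(
                        f"{contig}_hap{hap_no}_part{i + 1}",
                        seq[bounds[i]:bounds[i + 1]]))
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class HapdupResult:
    assembly: list[GenomeSequence]
    haplotype_seqs: dict[str, tuple[str, str]]
    phased_snps: list[Variant]
    haplotags: list[Haplotag]
    inversions: list[InversionSignature]
    covered: dict[str, tuple[np.ndarray, np.ndarray]]  # per-hap draft masks
    pos_maps: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict)  # draft -> polished coordinate maps


def run_hapdup(draft_seqs: Sequence[GenomeSequence],
               alignments: Sequence[AlignmentRecord],
               reads: dict[str, str],
               cfg: HapdupConfig = HapdupConfig(),
               mode: str = "dual") -> HapdupResult:
    """Full dual-assembly procedure over all draft contigs."""
    kept, _removed = filter_read_alignments(alignments, cfg.read_filter)
    all_phased: list[Variant] = []
    all_tags: list[Haplotag] = []
    all_invs: list[InversionSignature] = []
    hap_seqs: dict[str, tuple[str, str]] = {}
    covered: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    pos_maps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    phase_breaks: dict[str, list[int]] = {}
    for draft in draft_seqs:
        contig_alns = [a for a in kept if a.target_name == draft.name]
        pileup = Pileup(draft, contig_alns, reads)
        hets, _homs = call_het_snps(pileup, cfg.min_coverage, cfg.min_alt_frac)
        phased, tags = phase_and_haplotag(hets, pileup, cfg)
        all_phased.extend(phased)
        all_tags.extend(tags)
        tag_of = {t.read_name: t.tag for t in tags}
        regions = inconsistent_indel_regions(contig_alns, cfg.min_indel_len,
                                             cfg.indel_pad)
        bounds = select_chunk_boundaries(contig_alns, len(draft.seq),
                                         cfg.chunk_size, cfg.min_indel_len,
                                         cfg.indel_pad)
        chunks = list(zip(bounds[:-1], bounds[1:]))
        invs = detect_inversions(contig_alns, cfg.min_inversion_support,
                                 cfg.cluster_eps, tags)
        all_invs.extend(invs)
        seqs: list[str] = []
        masks: list[np.ndarray] = []
        maps: list[np.ndarray] = []
        for hap_tag in ("H1", "H2"):
            hap_alns = [a for a in contig_alns
                        if tag_of.get(a.query_name) == hap_tag]
            hp = Pileup(draft, hap_alns, reads)
            res = polish_haplotype(hp, chunks, reads, regions)
            seq = res.sequence
            my_invs = [s for s in invs if s.haplotype in (hap_tag, "both")]
            if my_invs:
                mapped = [InversionSignature(
                    draft.name, int(res.pos_map[s.start]),
                    int(res.pos_map[s.end]), s.support, s.haplotype)
                    for s in my_invs]
                seq = apply_rearrangements({draft.name: seq}, mapped)[draft.name]
            seqs.append(seq)
            masks.append(res.covered)
            maps.append(res.pos_map)
        hap_seqs[draft.name] = (seqs[0], seqs[1])
        covered[draft.name] = (masks[0], masks[1])
        pos_maps[draft.name] = (maps[0], maps[1])
        # split positions: midpoints between adjacent hets of different PS
        hets_sorted = sorted((v for v in phased if v.is_het),
                             key=Variant.sort_key)
        cuts = []
        for a, b in zip(hets_sorted, hets_sorted[1:]):
            if a.phase_set != b.phase_set:
                cuts.append(int(maps[0][(a.pos + b.pos) // 2]))
        phase_breaks[draft.name] = cuts
    assembly = emit_assembly(hap_seqs, phase_breaks, mode)
    return HapdupResult(assembly, hap_seqs, all_phased, all_tags, all_invs,
                        covered, pos_maps)
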