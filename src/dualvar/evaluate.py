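"""Benchmarking metrics.

Covers phasing accuracy (switch and Hamming error), distance-bounded
structural variant set comparison, exact-match small-variant
precision/recall/F1, assembly contiguity (NGx), and SV catalog frequency
annotation with a rarity flag.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from .formats import Interval, Variant


@dataclass
class SvMatchConfig:
    max_dist: int = 2000           # maximum linear distance between anchors
    size_ratio: float = 0.7
    seq_similarity: float = 0.7
    require_genotype: bool = False

    def __post_init__(self) -> None:
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")
        for name in ("size_ratio", "seq_similarity"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class PRF:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p > 0 and r > 0) else 0.0


# ---------------------------------------------------------------------------
# switch / Hamming error
# ---------------------------------------------------------------------------

def switch_hamming(truth_phased: Sequence[Variant],
                   test_phased: Sequence[Variant],
                   ) -> tuple[float, float, list[dict]]:
    """Phasing error against a truth set.

    Comparison is restricted to sites heterozygous and phased in both call
    sets, within blocks where both the truth and the test phase set are
    constant.  Switch error is the fraction of adjacent site pairs whose
    relative phase disagrees; Hamming error is, per block, the fraction of
    sites on the wrong haplotype under the better of the two global block
    orientations.  Pooled rates are count-weighted over blocks; per-block
    figures are returned alongside.
    """
    truth_at = {(v.chrom, v.pos): v for v in truth_phased
                if v.is_het and v.phased}
    shared: list[tuple[Variant, Variant]] = []
    for v in sorted(test_phased, key=Variant.sort_key):
        if not (v.is_het and v.phased):
            continue
        t = truth_at.get((v.chrom, v.pos))
        if t is None:
            continue
        if sorted(t.genotype) != sorted(v.genotype):
            continue
        shared.append((t, v))
    if not shared:
        raise ValueError("no shared phased heterozygous sites to compare")
    blocks: dict[tuple, list[int]] = defaultdict(list)  # orientation bits
    order: list[tuple] = []
    for t, v in shared:
        key = (v.chrom, t.phase_set, v.phase_set)
        if key not in blocks:
            order.append(key)
        # orientation: does the test hap1 allele equal the truth hap1 allele?
        blocks[key].append(1 if v.genotype[0] == t.genotype[0] else 0)
    switches = pairs = 0
    mismatches = sites = 0
    per_block: list[dict] = []
    for key in order:
        bits = blocks[key]
        n = len(bits)
        sw = sum(1 for a, b in zip(bits, bits[1:]) if a != b)
        hm = min(sum(bits), n - sum(bits))
        switches += sw
        pairs += n - 1
        mismatches += hm
        sites += n
        per_block.append({
            "chrom": key[0], "truth_ps": key[1], "test_ps": key[2],
            "n_sites": n,
            "switch_rate": sw / (n - 1) if n > 1 else 0.0,
            "hamming_rate": hm / n,
        })
    switch_rate = switches / pairs if pairs else 0.0
    hamming_rate = mismatches / sites if sites else 0.0
    return switch_rate, hamming_rate, per_block


# ---------------------------------------------------------------------------
# SV set comparison
# ---------------------------------------------------------------------------

def _sv_class(v: Variant) -> str:
    if v.sv_type:
        return v.sv_type
    return "INS" if v.sv_len > 0 else "DEL"


def _sv_size(v: Variant) -> int:
    if v.sv_type == "INV":
        return v.end0 - v.start0
    return abs(v.sv_len)


def _expand_alleles(records: Sequence[Variant]) -> list[Variant]:
    """Split multiallelic records into one entry per alternate allele."""
    from dataclasses import replace
    out = []
    for v in records:
        if len(v.alts) == 1:
            out.append(v)
        else:
            for alt in v.alts:
                from .formats import classify_variant
                cls, svlen = classify_variant(v.ref, [alt])
                out.append(replace(v, alts=[alt], sv_len=svlen,
                                   var_class=cls, genotype=(0, 1),
                                   sv_type=v.sv_type if v.sv_type == "INV"
                                   else ("INS" if svlen > 0 else "DEL")))
    return out


def _seq_similarity(v1: Variant, v2: Variant,
                    reference: Optional[str]) -> float:
    if reference is not None:
        flank = 100
        ws = max(0, min(v1.start0, v2.start0) - flank)
        we = min(len(reference), max(v1.end0, v2.end0) + flank)
        s1 = reference[ws:v1.start0] + v1.alts[0] + reference[v1.end0:we]
        s2 = reference[ws:v2.start0] + v2.alts[0] + reference[v2.end0:we]
    else:
        s1, s2 = v1.alts[0], v2.alts[0]
    d = edlib.align(s1, s2, mode="NW", task="distance")["editDistance"]
    m = max(len(s1), len(s2))
    return 1.0 - d / m if m else 1.0


def compare_sv_sets(truth_svs: Sequence[Variant], test_svs: Sequence[Variant],
                    cfg: SvMatchConfig = SvMatchConfig(),
                    reference: Optional[str] = None,
                    ) -> tuple[PRF, list[dict]]:
    """Distance-bounded one-to-one SV matching.

    Candidate pairs must share chromosome and type class, lie within
    ``max_dist`` bp, agree in size to ``size_ratio`` and (for insertions)
    in sequence to ``seq_similarity``.  When a reference sequence is given,
    insertion similarity is computed between locally reconstructed
    haplotype windows, which makes the comparison robust to equivalent
    representations inside tandem repeats.  Matching is greedy best-score
    with deterministic tie-breaks; returns pooled PRF and a match table.
    """
    truth = _expand_alleles(truth_svs)
    test = _expand_alleles(test_svs)
    cands: list[tuple[float, int, int]] = []
    for i, t in enumerate(truth):
        for j, c in enumerate(test):
            if t.chrom != c.chrom or _sv_class(t) != _sv_class(c):
                continue
            d = abs(t.pos - c.pos)
            if d > cfg.max_dist:
                continue
            st, sc = _sv_size(t), _sv_size(c)
            ratio = min(st, sc) / max(st, sc) if max(st, sc) else 1.0
            if ratio < cfg.size_ratio:
                continue
            if _sv_class(t) == "INS" and cfg.seq_similarity > 0:
                if _seq_similarity(t, c, reference) < cfg.seq_similarity:
                    continue
            if cfg.require_genotype and \
                    sorted(t.genotype) != sorted(c.genotype):
                continue
            score = d / max(cfg.max_dist, 1) + (1.0 - ratio)
            cands.append((score, i, j))
    cands.sort(key=lambda x: (x[0], truth[x[1]].pos, x[1], x[2]))
    used_t: set[int] = set()
    used_c: set[int] = set()
    table: list[dict] = []
    for score, i, j in cands:
        if i in used_t or j in used_c:
            continue
        used_t.add(i)
        used_c.add(j)
        table.append({"truth": truth[i], "test": test[j], "status": "TP",
                      "score": score})
    for i, t in enumerate(truth):
        if i not in used_t:
            table.append({"truth": t, "test": None, "status": "FN",
                          "score": None})
    for j, c in enumerate(test):
        if j not in used_c:
            table.append({"truth": None, "test": c, "status": "FP",
                          "score": None})
    prf = PRF(tp=len(used_t), fp=len(test) - len(used_c),
              fn=len(truth) - len(used_t))
    return prf, table


# ---------------------------------------------------------------------------
# small variant comparison
# ---------------------------------------------------------------------------

def small_variant_prf(truth: Sequence[Variant], test: Sequence[Variant],
                      confident_bed: Optional[Sequence[Interval]] = None,
                      ) -> dict[str, PRF]:
    """Exact normalized-allele + genotype matching, split by SNP / indel.

    A match requires identical (chrom, pos, ref, alt set) and the same
    unordered genotype.  With a confident-region BED, variants outside the
    regions are excluded from all counts.
    """
    def in_conf(v: Variant) -> bool:
        if confident_bed is None:
            return True
        return any(c == v.chrom and s <= v.start0 < e
                   for c, s, e, _ in confident_bed)

    def key(v: Variant):
        return (v.chrom, v.pos, v.ref, tuple(sorted(v.alts)),
                tuple(sorted(v.genotype)))

    def cls(v: Variant) -> str:
        return "SNP" if v.var_class == "SNP" else "INDEL"

    truth_keys = {key(v): cls(v) for v in truth if in_conf(v)}
    test_keys = {key(v): cls(v) for v in test if in_conf(v)}
    out: dict[str, PRF] = {}
    for c in ("SNP", "INDEL"):
        t = {k for k, kc in truth_keys.items() if kc == c}
        s = {k for k, kc in test_keys.items() if kc == c}
        out[c] = PRF(tp=len(t & s), fp=len(s - t), fn=len(t - s))
    return out


# ---------------------------------------------------------------------------
# NGx
# ---------------------------------------------------------------------------

def ngx(lengths: Sequence[int], genome_size: int, x: float) -> int:
    """Length of the sequence at which the descending cumulative sum first
    reaches x% of genome_size; 0 when the total never reaches it."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if not (0 < x <= 100):
        raise ValueError("x must be in (0, 100]")
    need = genome_size * x / 100.0
    total = 0
    for length in sorted(lengths, reverse=True):
        if length <= 0:
            raise ValueError("sequence lengths must be positive")
        total += length
        if total >= need:
            return length
    return 0


# ---------------------------------------------------------------------------
# catalog frequency annotation
# ---------------------------------------------------------------------------

@dataclass
class CatalogSV:
    chrom: str
    start: int          # 0-based
    end: int
    sv_type: str        # INS | DEL | INV
    allele_frequency: float
    sv_len: int = 0


def annotate_sv_frequency(svs: Sequence[Variant],
                          catalog: Sequence[CatalogSV],
                          min_overlap: float = 0.10,
                          max_dist: int = 2000,
                          rare_threshold: float = 0.01,
                          ) -> list[dict]:
    """Annotate each SV with the maximum matched catalog allele frequency.

    Deletions and inversions match by reciprocal overlap >= min_overlap;
    insertions (spanless on the reference) match by anchor distance
    <= max_dist and size ratio >= min_overlap.  An SV is flagged rare when
    its best matched frequency is below ``rare_threshold`` or no catalog
    record matches.
    """
    out: list[dict] = []
    for v in _expand_alleles(svs):
        vclass = _sv_class(v)
        best: Optional[float] = None
        for c in catalog:
            if c.chrom != v.chrom or c.sv_type != vclass:
                continue
            if vclass == "INS":
                if abs(c.start - v.start0) > max_dist:
                    continue
                sz_v = _sv_size(v)
                sz_c = abs(c.sv_len) or max(c.end - c.start, 1)
                ratio = min(sz_v, sz_c) / max(sz_v, sz_c) if max(sz_v, sz_c) \
                    else 1.0
                if ratio < min_overlap:
                    continue
            else:
                ov = min(v.end0, c.end) - max(v.start0, c.start)
                if ov <= 0:
                    continue
                if ov / (v.end0 - v.start0) < min_overlap or \
                        ov / (c.end - c.start) < min_overlap:
                    continue
            if best is None or c.allele_frequency > best:
                best = c.allele_frequency
        out.append({
            "variant": v,
            "max_frequency": best,
            "rare": best is None or best < rare_threshold,
        })
    return out
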