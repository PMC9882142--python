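"""Joint phasing of small and structural variants.

Small variants and SVs are merged into one call set and phased together.
Read support at each locus is computed by reference expansion: a window of
flanking reference bases is extracted around the variant (12 bp for small
variants, 64 bp for SVs, with 50 bp as the size boundary between the two
classes), each candidate allele is substituted into the window, and the
read subsequence projected into the window is aligned to every allele
sequence.  Edit distances become emission probabilities under a uniform
per-base error model with rate ``base_error``.

Phasing itself is a maximum-likelihood two-haplotype partition: variants
are nodes in a graph weighted by per-read cis/trans log-odds, oriented
greedily along a maximum spanning forest and refined by single-site and
suffix flip hill climbing on the exact read log-likelihood.  For small
instances the optimum can be checked against :func:`brute_force_phase`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import edlib
import numpy as np

from .formats import AlignmentRecord, Variant

_LOG_HALF = math.log(0.5)


@dataclass
class PhasingConfig:
    ref_expansion_small: int = 12
    ref_expansion_sv: int = 64
    sv_size_threshold: int = 50
    base_error: float = 0.10
    min_link_reads: int = 2

    def __post_init__(self) -> None:
        if self.ref_expansion_small <= 0 or self.ref_expansion_sv <= 0:
            raise ValueError("reference expansions must be positive")
        if self.sv_size_threshold < 1:
            raise ValueError("sv_size_threshold must be >= 1")
        if not (0.0 < self.base_error < 0.5):
            raise ValueError("base_error must be in (0, 0.5)")


@dataclass
class AlleleSupport:
    read_name: str
    variant_index: int
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.probs):
            raise ValueError("allele probabilities must be nonnegative")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("allele probabilities must sum to 1")


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_vcfs(small: Sequence[Variant], sv: Sequence[Variant]) -> list[Variant]:
    """Sort-merge two individually sorted call sets.

    Exact duplicates (same chrom/pos/ref/alts) are deduplicated keeping the
    SV caller's record; a genotype conflict between duplicates warns.
    """
    for name, records in (("small", small), ("sv", sv)):
        keys = [v.sort_key() for v in records]
        if keys != sorted(keys):
            raise ValueError(f"{name} input is not sorted")
    sv_keys = {(v.chrom, v.pos, v.ref, tuple(v.alts)): v for v in sv}
    out: list[Variant] = []
    for v in small:
        key = (v.chrom, v.pos, v.ref, tuple(v.alts))
        if key in sv_keys:
            dup = sv_keys[key]
            if tuple(sorted(v.genotype)) != tuple(sorted(dup.genotype)):
                warnings.warn(
                    f"conflicting genotypes for duplicate record at "
                    f"{v.chrom}:{v.pos}; keeping the SV record")
            continue
        out.append(v)
    out.extend(sv)
    out.sort(key=Variant.sort_key)
    return out


# ---------------------------------------------------------------------------
# allele extraction and read scoring
# ---------------------------------------------------------------------------

def extract_allele_sequences(reference: str, variant: Variant,
                             cfg: PhasingConfig) -> tuple[list[str], tuple[int, int]]:
    """One sequence per allele plus the 0-based reference window used.

    The expansion is ``ref_expansion_sv`` when the largest allele length
    difference reaches ``sv_size_threshold``, else ``ref_expansion_small``.
    """
    max_diff = max(abs(len(a) - len(variant.ref)) for a in variant.alts)
    e = cfg.ref_expansion_sv if max_diff >= cfg.sv_size_threshold \
        else cfg.ref_expansion_small
    ws = max(0, variant.start0 - e)
    we = min(len(reference), variant.end0 + e)
    if ws >= we:
        raise ValueError(f"empty window for variant at {variant.chrom}:{variant.pos}")
    left = reference[ws:variant.start0]
    right = reference[variant.end0:we]
    seqs = [left + variant.allele(i) + right
            for i in range(1 + len(variant.alts))]
    return seqs, (ws, we)


def project_interval(aln: AlignmentRecord, ws: int, we: int,
                     ) -> Optional[tuple[int, int]]:
    """Oriented-query interval whose alignment columns project into the
    target window [ws, we); None unless the alignment spans it fully."""
    if aln.target_start > ws or aln.target_end < we:
        return None
    if aln.strand == "+":
        q = aln.query_start
    else:
        q = aln.query_len - aln.query_end
    t = aln.target_start
    q0 = q1 = None
    for op, n in aln.cigar:
        qc = op in "=XMI"
        tc = op in "=XMD"
        tn = t + n if tc else t
        if q0 is None and tc and tn > ws:
            q0 = q + (max(ws - t, 0) if qc else 0)
        if tc and tn >= we:
            q1 = q + (max(we - t, 0) if qc else 0)
            break
        if qc:
            q += n
        if tc:
            t += n
    if q0 is None or q1 is None:
        return None
    return q0, q1


def score_read_allele(read_seq: str, aln: AlignmentRecord,
                      allele_seqs: Sequence[str], window: tuple[int, int],
                      cfg: PhasingConfig, variant_index: int = 0,
                      ) -> Optional[AlleleSupport]:
    """Emission probabilities for one read at one locus.

    The read subsequence is the span of read bases whose alignment columns
    project into the window.  For each allele sequence of length L at edit
    distance d the likelihood is eps^d * (1-eps)^(L-d); probabilities are
    the normalized likelihoods.  Returns None when the read does not span
    the window (the read is uninformative at this locus).
    """
    span = project_interval(aln, *window)
    if span is None:
        return None
    oriented, _, _ = aln.oriented_query(read_seq)
    sub = oriented[span[0]:span[1]]
    eps = cfg.base_error
    logliks = []
    for allele in allele_seqs:
        d = edlib.align(sub, allele, mode="NW", task="distance")["editDistance"]
        L = len(allele)
        d = min(d, L)
        logliks.append(d * math.log(eps) + (L - d) * math.log(1.0 - eps))
    arr = np.array(logliks)
    arr -= arr.max()
    probs = np.exp(arr)
    probs /= probs.sum()
    return AlleleSupport(aln.query_name, variant_index, tuple(probs.tolist()))


# ---------------------------------------------------------------------------
# phasing
# ---------------------------------------------------------------------------

class _Component:
    """One linkage component: site indices, per-read log-prob tables."""

    def __init__(self, sites: list[int]) -> None:
        self.sites = sites                       # indices into the het list
        self.site_pos: dict[int, int] = {s: k for k, s in enumerate(sites)}
        # per read: list of (local site index, log p(a), log p(b))
        self.read_terms: dict[str, list[tuple[int, float, float]]] = {}


def _read_site_tables(het_idx: list[int], variants: Sequence[Variant],
                      supports: Sequence[AlleleSupport],
                      ) -> dict[str, dict[int, tuple[float, float]]]:
    """Map read -> {het list position: (log p(a), log p(b))} with (a, b) the
    sorted genotype alleles of each het variant."""
    pos_of = {v: k for k, v in enumerate(het_idx)}
    out: dict[str, dict[int, tuple[float, float]]] = {}
    floor = 1e-6
    for s in supports:
        k = pos_of.get(s.variant_index)
        if k is None:
            continue
        v = variants[s.variant_index]
        a, b = sorted(set(v.genotype))
        pa = max(s.probs[a], floor)
        pb = max(s.probs[b], floor)
        z = pa + pb
        out.setdefault(s.read_name, {})[k] = (math.log(pa / z), math.log(pb / z))
    return out


def _components(n_sites: int, read_tables, min_link_reads: int) -> list[list[int]]:
    link_count: dict[tuple[int, int], int] = {}
    for table in read_tables.values():
        ks = sorted(table)
        for i in range(len(ks)):
            for j in range(i + 1, len(ks)):
                e = (ks[i], ks[j])
                link_count[e] = link_count.get(e, 0) + 1
    parent = list(range(n_sites))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (i, j), c in link_count.items():
        if c >= min_link_reads:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(n_sites):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def _edge_weights(sites: list[int], read_tables) -> dict[tuple[int, int], float]:
    """Pairwise cis-vs-trans log-odds restricted to the given sites."""
    site_set = set(sites)
    w: dict[tuple[int, int], float] = {}
    for table in read_tables.values():
        ks = sorted(k for k in table if k in site_set)
        for i in range(len(ks)):
            la_i, lb_i = table[ks[i]]
            for j in range(i + 1, len(ks)):
                la_j, lb_j = table[ks[j]]
                cis = np.logaddexp(la_i + la_j, lb_i + lb_j)
                trans = np.logaddexp(la_i + lb_j, lb_i + la_j)
                e = (ks[i], ks[j])
                w[e] = w.get(e, 0.0) + float(cis - trans)
    return w


def _spanning_tree_orientation(sites: list[int],
                               weights: dict[tuple[int, int], float]) -> np.ndarray:
    """Kruskal maximum spanning forest on |w|, oriented by edge sign."""
    index = {s: k for k, s in enumerate(sites)}
    n = len(sites)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    adj: dict[int, list[tuple[int, float]]] = {k: [] for k in range(n)}
    for (i, j), w in sorted(weights.items(), key=lambda kv: -abs(kv[1])):
        ii, jj = index[i], index[j]
        ri, rj = find(ii), find(jj)
        if ri != rj:
            parent[ri] = rj
            adj[ii].append((jj, w))
            adj[jj].append((ii, w))
    sigma = np.zeros(n, dtype=np.int8)
    seen = [False] * n
    for root in range(n):
        if seen[root]:
            continue
        stack = [root]
        seen[root] = True
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if not seen[v]:
                    sigma[v] = sigma[u] if w >= 0 else 1 - sigma[u]
                    seen[v] = True
                    stack.append(v)
    return sigma


class _Objective:
    """Exact read log-likelihood of a phasing assignment, with incremental
    single-site and suffix flip evaluation."""

    def __init__(self, sites: list[int], read_tables) -> None:
        self.n = len(sites)
        site_set = {s: k for k, s in enumerate(sites)}
        self.reads: list[list[tuple[int, float, float]]] = []
        for table in read_tables.values():
            terms = [(site_set[k], la, lb) for k, (la, lb) in table.items()
                     if k in site_set]
            if terms:
                self.reads.append(terms)
        self.by_site: dict[int, list[tuple[int, float, float]]] = {}
        for ri, terms in enumerate(self.reads):
            for k, la, lb in terms:
                self.by_site.setdefault(k, []).append((ri, la, lb))

    def full(self, sigma: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        logA = np.zeros(len(self.reads))
        logB = np.zeros(len(self.reads))
        for ri, terms in enumerate(self.reads):
            for k, la, lb in terms:
                if sigma[k] == 0:
                    logA[ri] += la
                    logB[ri] += lb
                else:
                    logA[ri] += lb
                    logB[ri] += la
        F = float(np.logaddexp(logA, logB).sum()) + _LOG_HALF * len(self.reads)
        return F, logA, logB

    def optimize(self, sigma: np.ndarray, max_rounds: int = 200) -> np.ndarray:
        sigma = sigma.copy()
        F, logA, logB = self.full(sigma)
        for _ in range(max_rounds):
            improved = False
            # best single-site flip
            best_gain, best_site = 0.0, -1
            for k in range(self.n):
                gain = self._flip_gain(k, sigma, logA, logB)
                if gain > best_gain + 1e-12:
                    best_gain, best_site = gain, k
            if best_site >= 0:
                self._apply_flip([best_site], sigma, logA, logB)
                F += best_gain
                improved = True
            # best suffix flip (site order = position order)
            gain, start = self._best_suffix(sigma, logA, logB)
            if gain > 1e-9:
                self._apply_flip(list(range(start, self.n)), sigma, logA, logB)
                F += gain
                improved = True
            # paired flips escape two-site frustration (small components only)
            if not improved and self.n <= 30:
                gain, pair = self._best_double(sigma, logA, logB)
                if gain > 1e-9:
                    self._apply_flip(list(pair), sigma, logA, logB)
                    F += gain
                    improved = True
            if not improved:
                break
        return sigma

    def _flip_gain(self, k, sigma, logA, logB) -> float:
        gain = 0.0
        for ri, la, lb in self.by_site.get(k, ()):
            ca, cb = (la, lb) if sigma[k] == 0 else (lb, la)
            newA = logA[ri] - ca + cb
            newB = logB[ri] - cb + ca
            gain += np.logaddexp(newA, newB) - np.logaddexp(logA[ri], logB[ri])
        return float(gain)

    def _apply_flip(self, ks, sigma, logA, logB) -> None:
        for k in ks:
            for ri, la, lb in self.by_site.get(k, ()):
                ca, cb = (la, lb) if sigma[k] == 0 else (lb, la)
                logA[ri] += cb - ca
                logB[ri] += ca - cb
            sigma[k] = 1 - sigma[k]

    def _best_double(self, sigma, logA, logB) -> tuple[float, tuple[int, int]]:
        best_gain, best_pair = 0.0, (-1, -1)
        for i in range(self.n):
            sig = sigma.copy()
            A = logA.copy()
            B = logB.copy()
            self._apply_flip([i], sig, A, B)
            base = np.logaddexp(logA, logB).sum()
            for j in range(i + 1, self.n):
                gain = self._flip_gain(j, sig, A, B) + \
                    float(np.logaddexp(A, B).sum() - base)
                if gain > best_gain + 1e-12:
                    best_gain, best_pair = gain, (i, j)
        return best_gain, best_pair

    def _best_suffix(self, sigma, logA, logB) -> tuple[float, int]:
        sig = sigma.copy()
        A = logA.copy()
        B = logB.copy()
        base = np.logaddexp(A, B).sum()
        best_gain, best_start = 0.0, -1
        # walk suffix start from the end; each step flips one more site
        for start in range(self.n - 1, 0, -1):
            self._apply_flip([start], sig, A, B)
            gain = float(np.logaddexp(A, B).sum() - base)
            if gain > best_gain + 1e-12:
                best_gain, best_start = gain, start
        return best_gain, best_start


def compute_allele_supports(variants: Sequence[Variant],
                            alignments: Sequence[AlignmentRecord],
                            reads: dict[str, str],
                            reference: dict[str, str],
                            cfg: PhasingConfig = PhasingConfig(),
                            ) -> list[AlleleSupport]:
    """Score every read against every heterozygous variant it spans.

    Reads that do not span a variant's full expansion window contribute no
    support there.  ``reference`` maps chromosome name to sequence.
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    windows: dict[int, tuple[list[str], tuple[int, int]]] = {}
    for i, v in enumerate(variants):
        if not v.is_het:
            continue
        seqs, win = extract_allele_sequences(reference[v.chrom], v, cfg)
        windows[i] = (seqs, win)
        by_chrom.setdefault(v.chrom, []).append((win[0], win[1], i))
    for lst in by_chrom.values():
        lst.sort()
    supports: list[AlleleSupport] = []
    for aln in alignments:
        lst = by_chrom.get(aln.target_name)
        if not lst:
            continue
        read_seq = reads.get(aln.query_name)
        if read_seq is None:
            continue
        for ws, we, i in lst:
            if ws < aln.target_start:
                continue
            if we > aln.target_end:
                if ws >= aln.target_end:
                    break
                continue
            sup = score_read_allele(read_seq, aln, windows[i][0],
                                    (ws, we), cfg, variant_index=i)
            if sup is not None:
                supports.append(sup)
    return supports


def phase_variants(variants: Sequence[Variant],
                   supports: Sequence[AlleleSupport],
                   cfg: PhasingConfig = PhasingConfig()) -> list[Variant]:
    """Phase heterozygous variants into phase sets.

    Returns a copy of the input with phased genotypes: heterozygous sites
    carry the allele order (hap1, hap2) and a PS equal to the position of
    the first site in their linkage component; homozygous variants are
    copied through phased.  Each component is canonicalized so its first
    site lists the smaller allele first.
    """
    order = sorted(range(len(variants)), key=lambda i: variants[i].sort_key())
    het_idx = [i for i in order if variants[i].is_het]
    read_tables = _read_site_tables(het_idx, variants, supports)
    comps = _components(len(het_idx), read_tables, cfg.min_link_reads)

    hap1_allele: dict[int, int] = {}   # het list position -> allele index
    hap2_allele: dict[int, int] = {}
    phase_set: dict[int, int] = {}
    for comp in comps:
        weights = _edge_weights(comp, read_tables)
        sigma0 = _spanning_tree_orientation(comp, weights)
        obj = _Objective(comp, read_tables)
        if len(comp) > 1:
            sigma = obj.optimize(sigma0)
            best_F = obj.full(sigma)[0]
            # small components: a few seeded restarts escape the rare
            # frustrated local optimum the greedy init falls into
            if len(comp) <= 30:
                rrng = np.random.default_rng(len(comp) * 7919 + 13)
                for _ in range(8):
                    cand = obj.optimize(
                        rrng.integers(0, 2, len(comp)).astype(np.int8))
                    F = obj.full(cand)[0]
                    if F > best_F + 1e-9:
                        best_F, sigma = F, cand
        else:
            sigma = sigma0
        if sigma[0] == 1:   # canonicalize: first site smaller-allele-first
            sigma = 1 - sigma
        ps = min(variants[het_idx[k]].pos for k in comp)
        for local, k in enumerate(comp):
            v = variants[het_idx[k]]
            a, b = sorted(set(v.genotype))
            if sigma[local] == 0:
                hap1_allele[k], hap2_allele[k] = a, b
            else:
                hap1_allele[k], hap2_allele[k] = b, a
            phase_set[k] = ps

    out: list[Variant] = []
    het_pos = {i: k for k, i in enumerate(het_idx)}
    for i in order:
        v = variants[i]
        if v.is_het:
            k = het_pos[i]
            out.append(replace(v, genotype=(hap1_allele[k], hap2_allele[k]),
                               phased=True, phase_set=phase_set[k]))
        else:
            out.append(replace(v, phased=True,
                               phase_set=v.phase_set if v.phase_set is not None
                               else v.pos))
    return out


def phasing_loglikelihood(variants: Sequence[Variant],
                          supports: Sequence[AlleleSupport],
                          phased: Sequence[Variant]) -> float:
    """Total read log-likelihood of a phased call set (het sites only)."""
    order = sorted(range(len(variants)), key=lambda i: variants[i].sort_key())
    het_idx = [i for i in order if variants[i].is_het]
    read_tables = _read_site_tables(het_idx, variants, supports)
    phased_sorted = sorted((v for v in phased if v.is_het), key=Variant.sort_key)
    sigma = np.zeros(len(het_idx), dtype=np.int8)
    for k, i in enumerate(het_idx):
        a, b = sorted(set(variants[i].genotype))
        sigma[k] = 0 if phased_sorted[k].genotype[0] == a else 1
    obj = _Objective(list(range(len(het_idx))), read_tables)
    return obj.full(sigma)[0]


def brute_force_phase(variants: Sequence[Variant],
                      supports: Sequence[AlleleSupport],
                      ) -> tuple[np.ndarray, float]:
    """Exhaustive maximum-likelihood phasing over all 2^(n-1) assignments.

    Intended as an oracle for small instances; the global objective is the
    same read log-likelihood that :func:`phase_variants` climbs.
    """
    order = sorted(range(len(variants)), key=lambda i: variants[i].sort_key())
    het_idx = [i for i in order if variants[i].is_het]
    n = len(het_idx)
    if n > 20:
        raise ValueError("brute force limited to 20 het sites")
    read_tables = _read_site_tables(het_idx, variants, supports)
    obj = _Objective(list(range(n)), read_tables)
    best_F = -np.inf
    best_sigma = np.zeros(n, dtype=np.int8)
    for mask in range(1 << max(n - 1, 0)):
        sigma = np.zeros(n, dtype=np.int8)
        for k in range(1, n):
            sigma[k] = (mask >> (k - 1)) & 1
        F, _, _ = obj.full(sigma)
        if F > best_F:
            best_F = F
            best_sigma = sigma
    return best_sigma, float(best_F)
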