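"""Joint phasing: VCF merging, reference expansion, emission model,
maximum-likelihood partitioning."""

import math

import numpy as np
import pytest

import dualvar.phase_harmonize as P
from dualvar.formats import AlignmentRecord, Variant, parse_cigar


# ---------------------------------------------------------------------------
# merge_vcfs
# ---------------------------------------------------------------------------

class TestMerge:
    def test_disjoint_concatenation_sorted(self):
        small = [Variant("chr1", 10, "A", ["T"]), Variant("chr1", 30, "C", ["G"])]
        sv = [Variant("chr1", 20, "A", ["A" + "C" * 60], var_class="SV",
                      sv_len=60, sv_type="INS")]
        out = P.merge_vcfs(small, sv)
        assert [v.pos for v in out] == [10, 20, 30]

    def test_duplicate_keeps_sv_record(self):
        a = Variant("chr1", 10, "A", ["T"], genotype=(0, 1))
        b = Variant("chr1", 10, "A", ["T"], genotype=(0, 1), phase_set=9)
        out = P.merge_vcfs([a], [b])
        assert len(out) == 1 and out[0].phase_set == 9

    def test_conflicting_genotype_warns(self):
        a = Variant("chr1", 10, "A", ["T"], genotype=(0, 1))
        b = Variant("chr1", 10, "A", ["T"], genotype=(1, 1))
        with pytest.warns(UserWarning):
            out = P.merge_vcfs([a], [b])
        assert out[0].genotype == (1, 1)

    def test_set_arithmetic(self, rng):
        pos_a = sorted(set(map(int, rng.integers(10, 10_000, 80))))
        pos_b = sorted(set(map(int, rng.integers(10, 10_000, 80))))
        a = [Variant("chr1", p, "A", ["T"]) for p in pos_a]
        b = [Variant("chr1", p, "A", ["T"]) for p in pos_b]
        out = P.merge_vcfs(a, b)
        dups = len(set(pos_a) & set(pos_b))
        assert len(out) == len(a) + len(b) - dups

    def test_unsorted_rejected(self):
        a = [Variant("chr1", 30, "A", ["T"]), Variant("chr1", 10, "A", ["T"])]
        with pytest.raises(ValueError):
            P.merge_vcfs(a, [])


# ---------------------------------------------------------------------------
# allele sequence extraction
# ---------------------------------------------------------------------------

REF = ("ACGTACGTAA" * 30)  # 300 bp


class TestExtract:
    def test_snp_window_size(self):
        v = Variant("chr1", 150, REF[149], ["T" if REF[149] != "T" else "G"])
        seqs, (ws, we) = P.extract_allele_sequences(REF, v, P.PhasingConfig())
        assert we - ws == 25          # 12 + 1 + 12
        assert all(len(s) == 25 for s in seqs)
        assert seqs[0] == REF[ws:we]

    def test_sv_expansion_for_large_deletion(self):
        ref_al = REF[99:160]          # 60 bp deleted + anchor
        v = Variant("chr1", 100, ref_al, [ref_al[0]], var_class="SV",
                    sv_len=-60, sv_type="DEL")
        seqs, (ws, we) = P.extract_allele_sequences(REF, v, P.PhasingConfig())
        assert ws == 99 - 64 and we == 160 + 64
        assert len(seqs[1]) == len(seqs[0]) - 60

    def test_window_clipped_at_chromosome_start(self):
        v = Variant("chr1", 3, REF[2], ["T" if REF[2] != "T" else "G"])
        seqs, (ws, we) = P.extract_allele_sequences(REF, v, P.PhasingConfig())
        assert ws == 0
        assert len(seqs[0]) == we - ws < 25


# ---------------------------------------------------------------------------
# read-allele scoring
# ---------------------------------------------------------------------------

def _perfect_aln(n, name="r"):
    return AlignmentRecord(name, n, 0, n, "chr1", 0, n, "+", [("=", n)])


class TestScoring:
    def test_likelihood_ratio_three_mismatches(self):
        """d_A=0, d_B=3, eps=0.1 -> P(A)/P(B) = 9^3, P(A) ~ 0.99863."""
        window = (100, 125)
        allele_a = REF[100:125]
        allele_b = ("T" if allele_a[0] != "T" else "G") + allele_a[1:]
        allele_b = allele_b[:10] + ("T" if allele_b[10] != "T" else "G") + allele_b[11:]
        allele_b = allele_b[:20] + ("T" if allele_b[20] != "T" else "G") + allele_b[21:]
        sup = P.score_read_allele(REF, _perfect_aln(len(REF)),
                                  [allele_a, allele_b], window,
                                  P.PhasingConfig())
        assert sup.probs[0] == pytest.approx(729 / 730, abs=1e-6)

    def test_tied_distances_symmetric(self):
        window = (100, 125)
        true = REF[100:125]
        alt1 = ("T" if true[0] != "T" else "G") + true[1:]
        alt2 = true[:24] + ("T" if true[24] != "T" else "G")
        sup = P.score_read_allele(REF, _perfect_aln(len(REF)),
                                  [alt1, alt2], window, P.PhasingConfig())
        assert sup.probs[0] == pytest.approx(0.5, abs=1e-9)

    def test_eps_limit_concentrates(self):
        window = (100, 125)
        true = REF[100:125]
        alt = ("T" if true[0] != "T" else "G") + true[1:]
        cfg = P.PhasingConfig(base_error=1e-6)
        sup = P.score_read_allele(REF, _perfect_aln(len(REF)),
                                  [true, alt], window, cfg)
        assert sup.probs[0] > 1 - 1e-5

    def test_partial_overlap_uninformative(self):
        aln = AlignmentRecord("r", 50, 0, 50, "chr1", 90, 140, "+", [("=", 50)])
        sup = P.score_read_allele(REF[90:140], aln, [REF[130:160]],
                                  (130, 160), P.PhasingConfig())
        assert sup is None


# ---------------------------------------------------------------------------
# phasing
# ---------------------------------------------------------------------------

def random_instance(rng, n_sites, n_reads=None, err=0.15, spacing=100):
    """A synthetic phasing instance with known truth orientation.

    Every adjacent site pair is covered by at least two reads, so the
    instance forms a single linkage component and the global exhaustive
    optimum is directly comparable to the component-wise search.
    """
    variants = [Variant("chr1", spacing * (i + 1), "A", ["T"], (0, 1))
                for i in range(n_sites)]
    truth = rng.integers(0, 2, n_sites)
    truth[0] = 0
    supports = []
    windows = []
    n_reads = n_reads or 4 * n_sites
    for _ in range(n_reads):
        span = int(rng.integers(2, min(6, n_sites) + 1)) if n_sites > 1 else 1
        start = int(rng.integers(0, n_sites - span + 1))
        windows.append((start, start + span))
    # linkage backbone: two reads per adjacent pair
    for k in range(n_sites - 1):
        windows += [(k, k + 2), (k, k + 2)]
    for r, (start, end) in enumerate(windows):
        hap = int(rng.integers(0, 2))
        for k in range(start, end):
            allele = truth[k] if hap == 0 else 1 - truth[k]
            if rng.random() < err:
                allele = 1 - allele
            p = (0.9, 0.1) if allele == 0 else (0.1, 0.9)
            supports.append(P.AlleleSupport(f"r{r}", k, p))
    return variants, supports, truth


class TestPhasing:
    def test_cis_dominance(self):
        variants = [Variant("chr1", 100, "A", ["T"], (0, 1)),
                    Variant("chr1", 200, "A", ["T"], (0, 1))]
        supports = []
        for r in range(10):
            supports.append(P.AlleleSupport(f"r{r}", 0, (0.9, 0.1)))
            supports.append(P.AlleleSupport(f"r{r}", 1, (0.9, 0.1)))
        phased = P.phase_variants(variants, supports)
        assert phased[0].phase_set == phased[1].phase_set
        assert phased[0].genotype == phased[1].genotype == (0, 1)

    def test_unlinked_sites_separate_phase_sets(self):
        variants = [Variant("chr1", 100, "A", ["T"], (0, 1)),
                    Variant("chr1", 200, "A", ["T"], (0, 1))]
        supports = [P.AlleleSupport("r1", 0, (0.9, 0.1)),
                    P.AlleleSupport("r2", 1, (0.1, 0.9))]
        phased = P.phase_variants(variants, supports)
        assert phased[0].phase_set != phased[1].phase_set

    def test_canonical_first_site_ref_first(self, rng):
        for trial in range(10):
            variants, supports, _ = random_instance(rng, 6)
            phased = P.phase_variants(variants, supports)
            by_ps = {}
            for v in phased:
                by_ps.setdefault(v.phase_set, []).append(v)
            for vs in by_ps.values():
                first = min(vs, key=lambda v: v.pos)
                assert first.genotype[0] == min(first.genotype)

    def test_homozygous_copied_through_phased(self):
        variants = [Variant("chr1", 100, "A", ["T"], (1, 1))]
        phased = P.phase_variants(variants, [])
        assert phased[0].phased and phased[0].genotype == (1, 1)
        assert phased[0].phase_set is not None

    def test_hill_climb_matches_brute_force(self, rng):
        for trial in range(40):
            n = int(rng.integers(2, 13))
            variants, supports, _ = random_instance(rng, n)
            phased = P.phase_variants(variants, supports)
            F_impl = P.phasing_loglikelihood(variants, supports, phased)
            _, F_best = P.brute_force_phase(variants, supports)
            assert F_impl >= F_best - 1e-6

    def test_sv_links_blocks_across_snp_desert(self):
        """An SV that is the only linking variant across a desert connects
        the flanking blocks; without it, they stay split."""
        variants = [Variant("chr1", 100, "A", ["T"], (0, 1)),
                    Variant("chr1", 200, "A", ["T"], (0, 1)),
                    Variant("chr1", 5_000, "A", ["A" + "C" * 80], (0, 1),
                            var_class="SV", sv_len=80, sv_type="INS"),
                    Variant("chr1", 9_800, "A", ["T"], (0, 1)),
                    Variant("chr1", 9_900, "A", ["T"], (0, 1))]
        supports = []
        r = 0
        # short-range reads inside each flank
        for _ in range(6):
            supports += [P.AlleleSupport(f"s{r}", 0, (0.9, 0.1)),
                         P.AlleleSupport(f"s{r}", 1, (0.9, 0.1))]
            r += 1
            supports += [P.AlleleSupport(f"s{r}", 3, (0.9, 0.1)),
                         P.AlleleSupport(f"s{r}", 4, (0.9, 0.1))]
            r += 1
        # long reads linking each flank only through the SV
        for _ in range(4):
            supports += [P.AlleleSupport(f"L{r}", 1, (0.9, 0.1)),
                         P.AlleleSupport(f"L{r}", 2, (0.9, 0.1))]
            r += 1
            supports += [P.AlleleSupport(f"L{r}", 2, (0.9, 0.1)),
                         P.AlleleSupport(f"L{r}", 3, (0.9, 0.1))]
            r += 1
        with_sv = P.phase_variants(variants, supports)
        assert len({v.phase_set for v in with_sv}) == 1
        small_only = [v for i, v in enumerate(variants) if i != 2]
        small_sup = [P.AlleleSupport(s.read_name,
                                     s.variant_index if s.variant_index < 2
                                     else s.variant_index - 1, s.probs)
                     for s in supports if s.variant_index != 2]
        without_sv = P.phase_variants(small_only, small_sup)
        assert len({v.phase_set for v in without_sv}) == 2
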