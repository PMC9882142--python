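"""Dual assembly: read filtering, het calling, haplotagging, chunking,
consensus polishing, inversion handling."""

import numpy as np
import pytest

import dualvar.dual_assembly as D
from dualvar.formats import AlignmentRecord, GenomeSequence, parse_cigar, revcomp
from dualvar.simulate import SimConfig, simulate_diploid, simulate_reads


def _aln(name, qlen, qspan, div, target="t", tstart=0, strand="+"):
    cigar = [("=", qspan)]
    return AlignmentRecord(name, qlen, 0, qspan, target, tstart,
                           tstart + qspan, strand, cigar, div)


class TestReadFilter:
    def test_passing_read_kept(self):
        kept, removed = D.filter_read_alignments(
            [_aln("a", 10_000, 9_500, 0.05)])
        assert len(kept) == 1 and not removed

    def test_unaligned_fraction_removed(self):
        kept, removed = D.filter_read_alignments(
            [_aln("a", 10_000, 5_000, 0.01)])
        assert not kept
        assert removed == [("a", "unaligned_fraction")]

    def test_divergence_default_threshold(self):
        kept, removed = D.filter_read_alignments(
            [_aln("a", 10_000, 9_900, 0.12)])
        assert removed == [("a", "divergence")]

    def test_short_read_removed_first(self):
        kept, removed = D.filter_read_alignments(
            [_aln("a", 4_000, 1_000, 0.5)])
        assert removed == [("a", "read_length")]

    def test_empty_input(self):
        assert D.filter_read_alignments([]) == ([], [])


def _pileup_from_columns(draft_seq, read_bases):
    """Build a pileup where read i carries read_bases[i] along the draft."""
    draft = GenomeSequence("t", draft_seq)
    alns, reads = [], {}
    for i, bases in enumerate(read_bases):
        name = f"r{i}"
        reads[name] = bases
        cigar = []
        for p, b in enumerate(bases):
            cigar.append(("=" if b == draft_seq[p] else "X", 1))
        merged = []
        for op, n in cigar:
            if merged and merged[-1][0] == op:
                merged[-1][1] += n
            else:
                merged.append([op, n])
        alns.append(AlignmentRecord(name, len(bases), 0, len(bases), "t",
                                    0, len(bases), "+",
                                    [(o, n) for o, n in merged]))
    return D.Pileup(draft, alns, reads)


class TestHetCalling:
    def test_balanced_het_called(self):
        pile = _pileup_from_columns("A" * 10,
                                    ["A" * 10] * 5 + ["T" + "A" * 9] * 5)
        hets, _ = D.call_het_snps(pile)
        assert len(hets) == 1
        assert hets[0].pos == 1
        assert set([hets[0].ref] + hets[0].alts) == {"A", "T"}

    def test_low_alt_fraction_not_het(self):
        pile = _pileup_from_columns("A" * 10,
                                    ["A" * 10] * 9 + ["T" + "A" * 9])
        hets, _ = D.call_het_snps(pile)
        assert not hets

    def test_hom_difference_reported_separately(self):
        pile = _pileup_from_columns("A" * 10, ["G" + "A" * 9] * 10)
        hets, homs = D.call_het_snps(pile)
        assert not hets
        assert len(homs) == 1 and homs[0].alts == ["G"]

    def test_error_free_truth_projection(self, clean_truth):
        cfg, truth = clean_truth
        reads = {r.name: r.seq for r in truth.truth_reads}
        kept, _ = D.filter_read_alignments(truth.truth_alignments)
        pile = D.Pileup(truth.reference, kept, reads)
        hets, _ = D.call_het_snps(pile)
        truth_het = {v.pos for v in truth.truth_variants
                     if v.var_class == "SNP" and v.is_het}
        called = {v.pos for v in hets}
        assert not called - truth_het            # no false positives
        assert len(called & truth_het) >= 0.95 * len(truth_het)


class TestHaplotag:
    def test_majority_and_tie_rules(self, small_truth):
        cfg, truth = small_truth
        reads = {r.name: r.seq for r in truth.truth_reads}
        hap_of = {r.name: r.haplotype for r in truth.truth_reads}
        kept, _ = D.filter_read_alignments(truth.truth_alignments)
        pile = D.Pileup(truth.reference, kept, reads)
        hets, _ = D.call_het_snps(pile)
        phased, tags = D.phase_and_haplotag(hets, pile)
        for t in tags:
            if t.tag == "H1":
                assert t.votes_h1 > t.votes_h2
            elif t.tag == "H2":
                assert t.votes_h2 > t.votes_h1
            else:
                assert t.votes_h1 == t.votes_h2
        # tags are internally consistent with the true read haplotypes up to
        # a global H1/H2 relabeling
        agree = disagree = 0
        for t in tags:
            if t.tag == "untagged" or t.votes_h1 + t.votes_h2 < 3:
                continue
            if (t.tag == "H1") == (hap_of[t.read_name] == 1):
                agree += 1
            else:
                disagree += 1
        frac = max(agree, disagree) / max(agree + disagree, 1)
        assert frac >= 0.99

    def test_no_het_sites_all_untagged(self):
        pile = _pileup_from_columns("ACGT" * 5, ["ACGT" * 5] * 4)
        phased, tags = D.phase_and_haplotag([], pile)
        assert phased == []
        assert all(t.tag == "untagged" for t in tags)


class TestChunking:
    def test_no_indels_regular_boundaries(self):
        alns = [_aln("a", 30_000, 30_000, 0.0)]
        bounds = D.select_chunk_boundaries(alns, 30_000, chunk_size=10_000)
        assert bounds == [0, 10_000, 20_000, 30_000]

    def test_inconsistent_indels_protected(self):
        # two reads with 10 bp insertions at contig positions 95 and 105:
        # the padded region [85, 115] must contain no boundary
        def ins_aln(name, pos):
            cigar = [("=", pos), ("I", 10), ("=", 200 - pos)]
            return AlignmentRecord(name, 210, 0, 210, "t", 0, 200, "+", cigar)
        alns = [ins_aln("a", 95), ins_aln("b", 105)]
        bounds = D.select_chunk_boundaries(alns, 200, chunk_size=100)
        assert all(not (85 < b < 115) for b in bounds)

    def test_boundaries_partition_contig(self):
        rng = np.random.default_rng(5)
        alns = []
        for i in range(20):
            pos = int(rng.integers(100, 49_000))
            cigar = [("=", pos), ("I", int(rng.integers(5, 30))),
                     ("=", 50_000 - pos)]
            alns.append(AlignmentRecord(f"r{i}", 50_100, 0,
                                        sum(n for o, n in cigar if o in "=XI"),
                                        "t", 0, 50_000, "+", cigar))
        bounds = D.select_chunk_boundaries(alns, 50_000)
        assert bounds[0] == 0 and bounds[-1] == 50_000
        assert bounds == sorted(set(bounds))


class TestPolish:
    def test_consensus_fixes_draft_substitution(self):
        draft = GenomeSequence("t", "AAAAGAAAAA")
        reads = {f"r{i}": "AAAATAAAAA" for i in range(5)}
        alns = [AlignmentRecord(f"r{i}", 10, 0, 10, "t", 0, 10, "+",
                                [("=", 4), ("X", 1), ("=", 5)])
                for i in range(5)]
        pile = D.Pileup(draft, alns, reads)
        res = D.polish_haplotype(pile, [(0, 10)], reads)
        assert res.sequence == "AAAATAAAAA"

    def test_zero_coverage_chunk_unchanged_and_flagged(self):
        draft = GenomeSequence("t", "ACGT" * 25)
        pile = D.Pileup(draft, [], {})
        res = D.polish_haplotype(pile, [(0, 100)], {})
        assert res.sequence == draft.seq
        assert res.zero_cov_chunks == [(0, 100)]
        assert not res.covered.any()

    def test_exactness_on_error_free_simulation(self, clean_truth):
        cfg, truth = clean_truth
        reads = {r.name: r.seq for r in truth.truth_reads}
        result = D.run_hapdup([truth.reference], truth.truth_alignments, reads)
        import edlib
        h1, h2 = result.haplotype_seqs[truth.reference.name]
        d1 = min(edlib.align(h1, truth.hap1.seq, mode="NW",
                             task="distance")["editDistance"],
                 edlib.align(h1, truth.hap2.seq, mode="NW",
                             task="distance")["editDistance"])
        d2 = min(edlib.align(h2, truth.hap1.seq, mode="NW",
                             task="distance")["editDistance"],
                 edlib.align(h2, truth.hap2.seq, mode="NW",
                             task="distance")["editDistance"])
        assert d1 == 0 and d2 == 0


class TestInversions:
    def _split_read(self, name, flip_start, flip_end, total=30_000):
        a = AlignmentRecord(name, total, 0, flip_start, "t", 0, flip_start,
                            "+", [("=", flip_start)])
        b = AlignmentRecord(name, total, flip_start, flip_end, "t",
                            flip_start, flip_end, "-",
                            [("=", flip_end - flip_start)])
        c = AlignmentRecord(name, total, flip_end, total, "t", flip_end,
                            total, "+", [("=", total - flip_end)])
        return [a, b, c]

    def test_clustered_signature_called(self):
        alns = []
        for i in range(6):
            alns += self._split_read(f"r{i}", 10_000 + i * 40, 20_000 + i * 40)
        sigs = D.detect_inversions(alns, min_support=3)
        assert len(sigs) == 1
        s = sigs[0]
        assert s.support == 6
        assert abs(s.start - 10_000) < 500 and abs(s.end - 20_000) < 500

    def test_below_support_no_call(self):
        alns = self._split_read("r0", 10_000, 20_000) + \
            self._split_read("r1", 10_000, 20_000)
        assert D.detect_inversions(alns, min_support=3) == []

    def test_apply_is_involution(self):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        sig = D.InversionSignature("c", 1000, 3000, 5, "H1")
        once = D.apply_rearrangements({"c": seq}, [sig])
        twice = D.apply_rearrangements(once, [sig])
        assert once["c"] != seq
        assert twice["c"] == seq

    def test_empty_signatures_noop(self):
        assert D.apply_rearrangements({"c": "ACGT"}, []) == {"c": "ACGT"}

    def test_overlapping_signatures_rejected(self):
        sigs = [D.InversionSignature("c", 100, 300, 5, "H1"),
                D.InversionSignature("c", 200, 400, 5, "H1")]
        with pytest.raises(ValueError):
            D.apply_rearrangements({"c": "A" * 1000}, sigs)

    def test_simulated_inversion_recovered(self):
        cfg = SimConfig(seed=9, genome_len=60_000, n_svs=2, n_vntrs=0,
                        sv_types=("INV",), sv_len_range=(3000, 5000),
                        read_error=0.0, coverage=30)
        truth = simulate_diploid(cfg)
        reads, alns = simulate_reads(truth, cfg)
        rd = {r.name: r.seq for r in reads}
        kept, _ = D.filter_read_alignments(alns)
        sigs = D.detect_inversions(kept, min_support=3)
        truth_inv = [v for v in truth.truth_variants if v.sv_type == "INV"]
        assert len(sigs) >= len([v for v in truth_inv])
        for v in truth_inv:
            hit = [s for s in sigs if abs(s.start - v.start0) <= 500
                   and abs(s.end - v.end0) <= 500]
            assert hit, f"inversion at {v.pos} not detected"


class TestEmit:
    def test_dual_mode_counts(self):
        seqs = {"c1": ("AAAA", "TTTT"), "c2": ("CC", "GG")}
        out = D.emit_assembly(seqs, {}, "dual")
        assert len(out) == 4
        assert sorted(s.name for s in out) == \
            ["c1_hap1", "c1_hap2", "c2_hap1", "c2_hap2"]

    def test_split_mode_counts(self):
        seqs = {"c1": ("A" * 100, "T" * 100)}
        out = D.emit_assembly(seqs, {"c1": [30, 60]}, "split")
        assert len(out) == 6
        assert out[0].name == "c1_hap1_part1"

    def test_single_phase_set_split_equals_dual(self):
        seqs = {"c1": ("A" * 50, "T" * 50)}
        dual = D.emit_assembly(seqs, {"c1": []}, "dual")
        split = D.emit_assembly(seqs, {"c1": []}, "split")
        assert [s.seq for s in dual] == [s.seq for s in split]
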