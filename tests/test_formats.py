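"""Readers and writers: parsing conventions and round-trip inversion."""

import math

import numpy as np
import pytest

from dualvar import formats as F


# ---------------------------------------------------------------------------
# CIGAR and alignment records
# ---------------------------------------------------------------------------

def test_cigar_parse_roundtrip():
    text = "10=1X4=2I3D5="
    ops = F.parse_cigar(text)
    assert ops == [("=", 10), ("X", 1), ("=", 4), ("I", 2), ("D", 3), ("=", 5)]
    assert F.cigar_to_str(ops) == text


def test_cigar_malformed_rejected():
    with pytest.raises(F.FormatError):
        F.parse_cigar("10=xx")


def test_divergence_gap_compressed():
    # 5=1X4=: 1 mismatch over 10 aligned columns
    assert F.divergence_from_cigar(F.parse_cigar("5=1X4=")) == pytest.approx(0.1)
    # a long deletion counts once, not per column
    d = F.divergence_from_cigar(F.parse_cigar("100=2000D100="))
    assert d == pytest.approx(1 / 201)
    # M ops hide mismatches: only gap opens counted (lower bound)
    assert F.divergence_from_cigar(F.parse_cigar("10M1I10M")) == pytest.approx(1 / 21)


def test_alignment_record_validation():
    rec = F.AlignmentRecord("r", 10, 0, 10, "t", 5, 15, "+",
                            F.parse_cigar("10="))
    rec.validate()
    bad = F.AlignmentRecord("r", 10, 0, 10, "t", 5, 16, "+",
                            F.parse_cigar("10="))
    with pytest.raises(F.FormatError):
        bad.validate()


def test_oriented_query_reverse_strand():
    rec = F.AlignmentRecord("r", 8, 2, 8, "t", 0, 6, "-", F.parse_cigar("6="))
    seq, qs, qe = rec.oriented_query("AACCGGTT")
    assert seq == F.revcomp("AACCGGTT")
    assert (qs, qe) == (0, 6)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def test_fasta_case_normalized_and_order(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">a\nacgt\n>b desc\nNNAC\n")
    seqs = F.read_fasta(p)
    assert [s.name for s in seqs] == ["a", "b"]
    assert seqs[0].seq == "ACGT"
    assert seqs[1].seq == "NNAC"


def test_fasta_empty_rejected(tmp_path):
    p = tmp_path / "e.fa"
    p.write_text("")
    with pytest.raises(F.FormatError):
        F.read_fasta(p)


def test_fasta_bad_alphabet_rejected(tmp_path):
    p = tmp_path / "x.fa"
    p.write_text(">a\nACGU\n")
    with pytest.raises(F.FormatError):
        F.read_fasta(p)


# ---------------------------------------------------------------------------
# PAF / SAM
# ---------------------------------------------------------------------------

def test_paf_basic(tmp_path):
    p = tmp_path / "a.paf"
    p.write_text("r1\t10\t0\t10\t+\tt\t100\t20\t30\t10\t10\t60\tcg:Z:10=\n")
    recs = F.read_alignments(p, "PAF")
    assert len(recs) == 1
    a = recs[0]
    assert (a.target_start, a.target_end) == (20, 30)
    assert a.cigar == [("=", 10)]
    assert a.divergence == 0.0


def test_paf_missing_cigar_skipped(tmp_path):
    p = tmp_path / "a.paf"
    p.write_text("r1\t10\t0\t10\t+\tt\t100\t20\t30\t10\t10\t60\n")
    with pytest.warns(UserWarning):
        recs = F.read_alignments(p, "PAF")
    assert recs == []


def test_paf_divergence_from_cigar(tmp_path):
    p = tmp_path / "a.paf"
    p.write_text("r1\t10\t0\t10\t+\tt\t100\t0\t10\t9\t10\t60\tcg:Z:5=1X4=\n")
    recs = F.read_alignments(p, "PAF")
    assert recs[0].divergence == pytest.approx(0.1)


def test_paf_inconsistent_lengths_rejected(tmp_path):
    p = tmp_path / "a.paf"
    p.write_text("r1\t10\t0\t10\t+\tt\t100\t0\t10\t9\t10\t60\tcg:Z:9=\n")
    with pytest.raises(F.FormatError):
        F.read_alignments(p, "PAF")


def test_sam_pos_convention(tmp_path):
    p = tmp_path / "a.sam"
    p.write_text("@HD\tVN:1.6\n@SQ\tSN:t\tLN:1000\n"
                 "r1\t0\tt\t101\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n")
    recs = F.read_alignments(p, "SAM")
    assert recs[0].target_start == 100  # SAM POS is 1-based


def test_paf_roundtrip_random(rng):
    recs = []
    for i in range(200):
        n = int(rng.integers(5, 50))
        ops = []
        q = t = 0
        for _ in range(int(rng.integers(1, 6))):
            op = rng.choice(["=", "X", "I", "D"])
            ln = int(rng.integers(1, 20))
            ops.append((str(op), ln))
        qspan = sum(ln for op, ln in ops if op in "=XI")
        tspan = sum(ln for op, ln in ops if op in "=XD")
        if qspan == 0 or tspan == 0:
            continue
        rec = F.AlignmentRecord(f"r{i}", qspan + 4, 2, 2 + qspan, "t",
                                100, 100 + tspan,
                                str(rng.choice(["+", "-"])), ops,
                                F.divergence_from_cigar(ops))
        rec.validate()
        recs.append(rec)
    import tempfile, os
    with tempfile.TemporaryDirectory() as d:
        path = os.path.join(d, "x.paf")
        F.write_paf(recs, path)
        back = F.read_alignments(path, "PAF")
    assert len(back) == len(recs)
    for a, b in zip(recs, back):
        assert (a.query_name, a.query_len, a.query_start, a.query_end,
                a.strand, a.target_start, a.target_end, a.cigar) == \
               (b.query_name, b.query_len, b.query_start, b.query_end,
                b.strand, b.target_start, b.target_end, b.cigar)
        assert a.divergence == pytest.approx(b.divergence, abs=1e-6)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def test_vcf_phased_record(tmp_path):
    v = F.Variant("chr1", 100, "A", ["T"], (0, 1), phased=True, phase_set=55)
    path = tmp_path / "a.vcf"
    F.write_vcf([v], path)
    text = path.read_text()
    assert "0|1" in text and "PS" in text and ":55" in text


def test_vcf_sv_annotations(tmp_path):
    ref = "A" + "C" * 60
    v = F.Variant("chr1", 10, ref, ["A"], (1, 1), var_class="SV",
                  sv_len=-60, sv_type="DEL")
    path = tmp_path / "sv.vcf"
    F.write_vcf([v], path)
    text = path.read_text()
    assert "SVTYPE=DEL" in text and "SVLEN=-60" in text


def test_vcf_unsorted_rejected(tmp_path):
    vs = [F.Variant("chr1", 200, "A", ["T"]), F.Variant("chr1", 100, "A", ["T"])]
    with pytest.raises(F.FormatError):
        F.write_vcf(vs, tmp_path / "x.vcf")


def test_vcf_roundtrip_random(tmp_path, rng):
    bases = "ACGT"
    variants = []
    pos = 10
    for i in range(1000):
        pos += int(rng.integers(2, 50))
        kind = rng.random()
        if kind < 0.5:
            ref = bases[int(rng.integers(4))]
            alt = bases.replace(ref, "")[int(rng.integers(3))]
            v = F.Variant("chr1", pos, ref, [alt],
                          (0, 1) if rng.random() < 0.5 else (1, 0),
                          phased=bool(rng.random() < 0.7),
                          var_class="SNP")
        elif kind < 0.8:
            ln = int(rng.integers(1, 20))
            anchor = bases[int(rng.integers(4))]
            ins = "".join(bases[int(b)] for b in rng.integers(0, 4, ln))
            v = F.Variant("chr1", pos, anchor, [anchor + ins], (0, 1),
                          phased=True, var_class="INDEL", sv_len=ln)
        else:
            ln = int(rng.integers(50, 200))
            anchor = bases[int(rng.integers(4))]
            ins = "".join(bases[int(b)] for b in rng.integers(0, 4, ln))
            v = F.Variant("chr1", pos, anchor, [anchor + ins], (1, 1),
                          phased=True, var_class="SV", sv_len=ln,
                          sv_type="INS")
        if v.phased:
            v.phase_set = 7
        variants.append(v)
    path = tmp_path / "r.vcf"
    F.write_vcf(variants, path)
    back = F.read_vcf(path)
    assert len(back) == len(variants)
    for a, b in zip(variants, back):
        assert (a.chrom, a.pos, a.ref, a.alts, a.genotype, a.phased,
                a.phase_set, a.sv_len if a.var_class == "SV" else 0) == \
               (b.chrom, b.pos, b.ref, b.alts, b.genotype, b.phased,
                b.phase_set, b.sv_len if b.var_class == "SV" else 0)
        assert a.var_class == b.var_class


def test_snp_offset_serializes_one_based(tmp_path, rng):
    """A SNP at internal 0-based offset k must appear at POS k+1."""
    for k in rng.integers(0, 10_000, size=20):
        v = F.Variant("chr1", int(k) + 1, "A", ["G"])
        assert v.start0 == int(k)
    path = tmp_path / "p.vcf"
    F.write_vcf([F.Variant("chr1", 43, "A", ["G"])], path)
    line = [l for l in path.read_text().splitlines()
            if not l.startswith("#")][0]
    assert line.split("\t")[1] == "43"


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def test_bed_basic(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("track name=x\n# comment\nchr1\t1000\t1100\nchr1\t5\t10\tlabel\n")
    ivs = F.read_bed(p)
    assert ivs[0] == ("chr1", 1000, 1100, "")
    assert ivs[1] == ("chr1", 5, 10, "label")


def test_bed_invalid_interval(tmp_path):
    p = tmp_path / "b.bed"
    p.write_text("chr1\t10\t10\n")
    with pytest.raises(F.FormatError):
        F.read_bed(p)


def test_merge_intervals_union():
    merged = F.merge_intervals([("c", 0, 10, ""), ("c", 5, 20, "")])
    assert merged == [("c", 0, 20, "")]
    # different labels are not merged
    merged = F.merge_intervals([("c", 0, 10, "a"), ("c", 5, 20, "b")])
    assert len(merged) == 2


def test_bed_roundtrip_random(tmp_path, rng):
    ivs = []
    for i in range(1000):
        s = int(rng.integers(0, 10_000_000))
        ivs.append(("chr%d" % rng.integers(1, 4), s,
                    s + int(rng.integers(1, 5000)), f"label{i}"))
    path = tmp_path / "r.bed"
    F.write_bed(ivs, path)
    assert F.read_bed(path) == ivs


# ---------------------------------------------------------------------------
# bedMethyl
# ---------------------------------------------------------------------------

def test_bedmethyl_basic(tmp_path):
    p = tmp_path / "a.bedmethyl"
    p.write_text("chr1\t100\t101\tm\t750\t+\t100\t101\t0,0,0\t12\t75\n")
    sites = F.read_bedmethyl(p)
    assert sites[0].coverage == 12
    assert sites[0].meth_frac == pytest.approx(0.75)


def test_bedmethyl_empty(tmp_path):
    p = tmp_path / "e.bedmethyl"
    p.write_text("")
    assert F.read_bedmethyl(p) == []


def test_bedmethyl_bad_percent(tmp_path):
    p = tmp_path / "b.bedmethyl"
    p.write_text("chr1\t100\t101\tm\t0\t+\t100\t101\t0,0,0\t5\t120\n")
    with pytest.raises(F.FormatError):
        F.read_bedmethyl(p)


def test_bedmethyl_roundtrip_random(tmp_path, rng):
    sites = [F.MethSite("chr1", int(p), "+" if rng.random() < 0.5 else "-",
                        int(rng.integers(0, 60)), float(rng.integers(0, 1001)) / 1000)
             for p in sorted(rng.integers(0, 1_000_000, size=1000))]
    path = tmp_path / "r.bedmethyl"
    F.write_bedmethyl(sites, path)
    back = F.read_bedmethyl(path)
    assert len(back) == len(sites)
    for a, b in zip(sites, back):
        assert (a.chrom, a.pos, a.strand, a.coverage) == \
               (b.chrom, b.pos, b.strand, b.coverage)
        assert math.isclose(a.meth_frac, b.meth_frac, rel_tol=1e-12,
                            abs_tol=1e-12)
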