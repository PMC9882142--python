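"""Single-process pipeline wiring the stages in order, with a run manifest.

Stage order mirrors the analysis flow: diploid assembly from a haploid
draft, assembly-based SV calling, joint phasing of small and structural
variants, and haplotype-differential methylation.  Intermediate files are
retained in the output directory and every run writes exactly one
manifest (tool version, config snapshot, input checksums, per-stage wall
time, seed).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .formats import (GenomeSequence, Variant, read_alignments, read_bed,
                      read_bedmethyl, read_fasta, read_vcf, write_bed,
                      write_fasta, write_vcf)

STAGES = ["simulate", "hapdup", "svcall", "phase", "methdiff"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


class Manifest:
    def __init__(self, outdir: Path, config: dict, seed: Optional[int]):
        self.data = {
            "tool_version": __version__,
            "config": config,
            "seed": seed,
            "inputs": {},
            "stage_seconds": {},
        }
        self.path = Path(outdir) / "manifest.json"

    def add_input(self, label: str, path: str | Path) -> None:
        self.data["inputs"][label] = {"path": str(path),
                                      "sha256": _sha256(Path(path))}

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                manifest.data["stage_seconds"][name] = round(
                    time.perf_counter() - self.t0, 3)

        return _Timer()

    def write(self) -> None:
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: dict, outdir: Path, seed: Optional[int]) -> dict:
    from .simulate import (SimConfig, simulate_diploid, simulate_methylation,
                           simulate_reads, write_truth)
    fields = {k: v for k, v in config.items() if k in SimConfig.__dataclass_fields__}
    for key in ("sv_len_range", "sv_types", "vntr_unit_copies",
                "vntr_cn_delta_range"):
        if key in fields and isinstance(fields[key], list):
            fields[key] = tuple(fields[key])
    cfg = SimConfig(**fields)
    if seed is not None:
        cfg.seed = seed
    truth = simulate_diploid(cfg)
    simulate_reads(truth, cfg)
    simulate_methylation(truth, cfg)
    return write_truth(truth, cfg, outdir)


def stage_hapdup(draft_fa, alignments_path, reads_fa, outdir: Path,
                 mode: str = "dual", dialect: str = "PAF") -> dict:
    from .dual_assembly import HapdupConfig, run_hapdup
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    draft = read_fasta(draft_fa)
    alignments = read_alignments(alignments_path, dialect)
    reads = {s.name: s.seq for s in read_fasta(reads_fa)}
    result = run_hapdup(draft, alignments, reads, HapdupConfig(), mode)
    paths = {
        "assembly": outdir / "assembly.fasta",
        "hap1": outdir / "hapdup_hap1.fasta",
        "hap2": outdir / "hapdup_hap2.fasta",
        "haplotags": outdir / "haplotags.tsv",
        "phased_snps": outdir / "phased_snps.vcf",
        "inversions": outdir / "inversions.bed",
    }
    write_fasta(result.assembly, paths["assembly"])
    write_fasta([GenomeSequence(f"{c}_hap1", s[0])
                 for c, s in sorted(result.haplotype_seqs.items())],
                paths["hap1"])
    write_fasta([GenomeSequence(f"{c}_hap2", s[1])
                 for c, s in sorted(result.haplotype_seqs.items())],
                paths["hap2"])
    with open(paths["haplotags"], "w") as fh:
        fh.write("read\ttag\tvotes_h1\tvotes_h2\n")
        for t in result.haplotags:
            fh.write(f"{t.read_name}\t{t.tag}\t{t.votes_h1}\t{t.votes_h2}\n")
    write_vcf(sorted(result.phased_snps, key=Variant.sort_key),
              paths["phased_snps"])
    write_bed([(s.contig, s.start, s.end, f"{s.haplotype}|support={s.support}")
               for s in result.inversions], paths["inversions"])
    return {k: str(v) for k, v in paths.items()}


def stage_svcall(hap1_fa, hap2_fa, ref_fa, vntr_bed_path, outdir: Path,
                 threads: int = 1) -> dict:
    from .align import align_contigs
    from .sv_from_assembly import SvCallConfig, call_svs
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = read_fasta(ref_fa)[0]
    h1 = read_fasta(hap1_fa)
    h2 = read_fasta(hap2_fa)
    vntr = read_bed(vntr_bed_path) if vntr_bed_path else None
    a1 = align_contigs(reference, h1, threads)
    a2 = align_contigs(reference, h2, threads)
    seqs = {s.name: s.seq for s in [*h1, *h2]}
    cfg = SvCallConfig(vntr_bed=vntr)
    called = call_svs(a1, a2, seqs, reference, cfg)
    out_vcf = outdir / "sv.vcf"
    write_vcf(called, out_vcf)
    return {"sv_vcf": str(out_vcf)}


def stage_phase(small_vcf, sv_vcf, reads_fa, aln_path, ref_fa, outdir: Path,
                dialect: str = "PAF") -> dict:
    from .phase_harmonize import (PhasingConfig, compute_allele_supports,
                                  merge_vcfs, phase_variants)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    small = [v for v in read_vcf(small_vcf) if v.is_het]
    sv = read_vcf(sv_vcf)
    reference = {s.name: s.seq for s in read_fasta(ref_fa)}
    reads = {s.name: s.seq for s in read_fasta(reads_fa)}
    alignments = read_alignments(aln_path, dialect)
    merged = merge_vcfs(sorted(small, key=Variant.sort_key),
                        sorted(sv, key=Variant.sort_key))
    cfg = PhasingConfig()
    supports = compute_allele_supports(merged, alignments, reads, reference,
                                       cfg)
    phased = phase_variants(merged, supports, cfg)
    out_vcf = outdir / "phased.vcf"
    write_vcf(phased, out_vcf)
    return {"phased_vcf": str(out_vcf)}


def stage_methdiff(h1_bedmethyl, h2_bedmethyl, regions_bed, sv_vcf,
                   flank: int, outdir: Path) -> dict:
    from .methylation import (call_differential, collapse_cpg_strands,
                              regions_from_svs, summarize_regions)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h1 = collapse_cpg_strands(read_bedmethyl(h1_bedmethyl))
    h2 = collapse_cpg_strands(read_bedmethyl(h2_bedmethyl))
    regions = []
    if regions_bed:
        regions.extend(read_bed(regions_bed))
    if sv_vcf:
        svs = [v for v in read_vcf(sv_vcf) if v.var_class == "SV"]
        regions.extend(regions_from_svs(svs, flank))
    summaries, dropped = summarize_regions(h1, h2, regions)
    calls = call_differential(summaries)
    summary_tsv = outdir / "methdiff_summary.tsv"
    flagged_bed = outdir / "methdiff_flagged.bed"
    with open(summary_tsv, "w") as fh:
        fh.write("chrom\tstart\tend\tlabel\tn_sites\tmean_h1\tmean_h2\t"
                 "delta\trobust_z\tflagged\n")
        for c in calls:
            s = c.summary
            chrom, start, end, label = s.region
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\t{s.n_sites}\t"
                     f"{s.mean_h1:.4f}\t{s.mean_h2:.4f}\t{s.delta:.4f}\t"
                     f"{c.robust_z:.3f}\t{int(c.flagged)}\n")
    write_bed([(c.summary.region[0], c.summary.region[1],
                c.summary.region[2], c.summary.region[3])
               for c in calls if c.flagged], flagged_bed)
    return {"summary": str(summary_tsv), "flagged": str(flagged_bed)}


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, outdir: str | Path,
                 seed: Optional[int] = None,
                 from_stage: str = "simulate",
                 until_stage: str = "methdiff",
                 threads: int = 1) -> Manifest:
    """Execute the pipeline stages in order with checkpoint files.

    ``config`` mirrors the simulator configuration; stages before
    ``from_stage`` must have left their outputs in ``outdir`` from a
    previous run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in (from_stage, until_stage):
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}; stages: {STAGES}")
    lo, hi = STAGES.index(from_stage), STAGES.index(until_stage)
    if lo > hi:
        raise ValueError("--from stage comes after --until stage")
    manifest = Manifest(outdir, config, seed)
    sim_dir = outdir / "simulate"
    active = STAGES[lo:hi + 1]

    # pre-flight: every input needed by the active stages must exist
    missing = []
    if "simulate" not in active:
        for f in ("reference.fasta", "reads.fasta", "reads.paf"):
            if not (sim_dir / f).exists():
                missing.append(str(sim_dir / f))
    if missing:
        raise FileNotFoundError("missing pipeline inputs: " + ", ".join(missing))

    if "simulate" in active:
        with manifest.time_stage("simulate"):
            stage_simulate(config, sim_dir, seed)
    for label in ("reference", "reads", "alignments"):
        fname = {"reference": "reference.fasta", "reads": "reads.fasta",
                 "alignments": "reads.paf"}[label]
        if (sim_dir / fname).exists():
            manifest.add_input(label, sim_dir / fname)
    if "hapdup" in active:
        with manifest.time_stage("hapdup"):
            stage_hapdup(sim_dir / "reference.fasta", sim_dir / "reads.paf",
                         sim_dir / "reads.fasta", outdir / "hapdup")
    if "svcall" in active:
        with manifest.time_stage("svcall"):
            vntr = sim_dir / "vntr.bed"
            stage_svcall(outdir / "hapdup" / "hapdup_hap1.fasta",
                         outdir / "hapdup" / "hapdup_hap2.fasta",
                         sim_dir / "reference.fasta",
                         vntr if vntr.exists() else None,
                         outdir / "svcall", threads)
    if "phase" in active:
        with manifest.time_stage("phase"):
            stage_phase(outdir / "hapdup" / "phased_snps.vcf",
                        outdir / "svcall" / "sv.vcf",
                        sim_dir / "reads.fasta", sim_dir / "reads.paf",
                        sim_dir / "reference.fasta", outdir / "phase")
    if "methdiff" in active:
        with manifest.time_stage("methdiff"):
            stage_methdiff(sim_dir / "meth_h1.bedmethyl",
                           sim_dir / "meth_h2.bedmethyl",
                           sim_dir / "regions.bed", None, 1000,
                           outdir / "methdiff")
    manifest.write()
    return manifest
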