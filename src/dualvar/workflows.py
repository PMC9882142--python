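"""In-memory end-to-end workflows used by tests, benchmarks and the CLI.

These wire the library stages together without touching the filesystem:
simulate a diploid genome, rebuild it from reads via the dual-assembly
procedure, call SVs from the polished haplotypes, jointly phase small and
structural variants, and score everything against the simulator's truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .align import align_contigs
from .dual_assembly import HapdupConfig, HapdupResult, run_hapdup
from .evaluate import PRF, SvMatchConfig, compare_sv_sets, switch_hamming
from .formats import GenomeSequence, Variant
from .phase_harmonize import (PhasingConfig, compute_allele_supports,
                              merge_vcfs, phase_variants)
from .simulate import DiploidTruth, SimConfig, simulate_diploid, simulate_reads
from .sv_from_assembly import SvCallConfig, call_svs


@dataclass
class EndToEndResult:
    truth: DiploidTruth
    hapdup: HapdupResult
    called_svs: list[Variant]
    phased: list[Variant]
    sv_prf: PRF
    switch_rate: float
    hamming_rate: float


def run_end_to_end(cfg: SimConfig, threads: int = 1) -> EndToEndResult:
    """simulate -> dual assembly -> SV calling -> joint phasing -> scoring.

    The haploid draft is the simulated reference itself (assembly of the
    draft is outside this toolkit's scope), and reads are presented with
    their true placements, as an aligner would provide them.
    """
    truth = simulate_diploid(cfg)
    reads_list, alignments = simulate_reads(truth, cfg)
    reads = {r.name: r.seq for r in reads_list}

    hap = run_hapdup([truth.reference], alignments, reads, HapdupConfig())
    h1, h2 = hap.haplotype_seqs[truth.reference.name]
    contigs1 = [GenomeSequence("asm_hap1", h1)]
    contigs2 = [GenomeSequence("asm_hap2", h2)]
    a1 = align_contigs(truth.reference, contigs1, threads)
    a2 = align_contigs(truth.reference, contigs2, threads)
    contig_seqs = {"asm_hap1": h1, "asm_hap2": h2}
    called = call_svs(a1, a2, contig_seqs, truth.reference,
                      SvCallConfig(vntr_bed=truth.vntr_bed))

    truth_svs = [v for v in truth.truth_variants if v.var_class == "SV"]
    sv_prf, _ = compare_sv_sets(truth_svs, called, SvMatchConfig(),
                                reference=truth.reference.seq)

    small = sorted((v for v in hap.phased_snps if v.is_het),
                   key=Variant.sort_key)
    merged = merge_vcfs(small, called)
    supports = compute_allele_supports(
        merged, alignments, reads, {truth.reference.name: truth.reference.seq},
        PhasingConfig())
    phased = phase_variants(merged, supports, PhasingConfig())
    switch, hamming, _ = switch_hamming(truth.truth_variants, phased)
    return EndToEndResult(truth, hap, called, phased, sv_prf, switch, hamming)
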