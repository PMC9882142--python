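"""Thin wrappers around the external minimap2 aligner.

Contig-to-reference alignment uses a fixed parameter preset optimized for
alignment across long structural variants; keeping the preset fixed (and
recording it in :class:`dualvar.sv_from_assembly.SvCallConfig`) matters
for reproducibility.  Output is requested as PAF with an extended (=/X)
cg: CIGAR tag so downstream variant extraction sees mismatches directly.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Sequence

from .formats import AlignmentRecord, GenomeSequence, read_alignments, write_fasta

# the SV-tuned contig preset (recorded, and passed to minimap2 as split flags)
CONTIG_PRESET_FLAGS = ["-x", "asm20", "-B", "2", "-E", "3,1", "-O", "6,100"]
READ_PRESET_FLAGS = ["-x", "map-ont"]


def minimap2_available() -> bool:
    return shutil.which("minimap2") is not None


def _run_minimap2(reference: GenomeSequence | Sequence[GenomeSequence],
                  queries: Sequence[GenomeSequence],
                  preset_flags: Sequence[str],
                  threads: int = 1) -> list[AlignmentRecord]:
    if not minimap2_available():
        raise RuntimeError("minimap2 not found on PATH")
    refs = [reference] if isinstance(reference, GenomeSequence) else list(reference)
    with tempfile.TemporaryDirectory(prefix="dualvar_mm2_") as tmp:
        ref_fa = Path(tmp) / "ref.fa"
        qry_fa = Path(tmp) / "qry.fa"
        out_paf = Path(tmp) / "out.paf"
        write_fasta(refs, ref_fa)
        write_fasta(queries, qry_fa)
        cmd = ["minimap2", "-c", "--eqx", "-t", str(threads),
               *preset_flags, str(ref_fa), str(qry_fa)]
        with open(out_paf, "w") as fh:
            subprocess.run(cmd, stdout=fh, stderr=subprocess.DEVNULL,
                           check=True)
        return read_alignments(out_paf, "PAF")


def align_contigs(reference, contigs: Sequence[GenomeSequence],
                  threads: int = 1) -> list[AlignmentRecord]:
    """Align assembly contigs to the reference with the fixed SV preset."""
    return _run_minimap2(reference, contigs, CONTIG_PRESET_FLAGS, threads)


def align_reads(reference, reads: Sequence[GenomeSequence],
                threads: int = 1) -> list[AlignmentRecord]:
    """Align long reads with the standard long-read preset."""
    return _run_minimap2(reference, reads, READ_PRESET_FLAGS, threads)
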