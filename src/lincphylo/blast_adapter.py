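"""Optional adapter to an external blastn executable.

The internal engine is the default and the tested code path; this
adapter exists so results can be cross-checked against (or produced
by) NCBI BLASTN with the protocol's exact parameters: reward 1,
penalty -2, gapopen 5, gapextend 2, word size 8. Output is parsed from
tabular format 6.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

from .genome import Genome, write_genome
from .homology import LocusHit
from .intervals import GenomeInterval

BLAST6_COLS = ("qseqid sseqid pident length mismatch gapopen qstart qend "
               "sstart send evalue bitscore score").split()


def blastn_available() -> bool:
    return shutil.which("blastn") is not None


def parse_blast6(text: str, species_id: str) -> list[LocusHit]:
    """Tabular (outfmt 6 with raw score) lines -> LocusHits.

    BLAST coordinates are 1-based inclusive with sstart > send on the
    minus strand; they are converted to 0-based half-open plus-strand
    intervals.
    """
    hits = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = dict(zip(BLAST6_COLS, line.rstrip("\n").split("\t")))
        sstart, send = int(f["sstart"]), int(f["send"])
        if sstart <= send:
            start, end, strand = sstart - 1, send, "+"
        else:
            start, end, strand = send - 1, sstart, "-"
        hits.append(LocusHit(
            query_id=f["qseqid"],
            interval=GenomeInterval(species_id, f["sseqid"], start, end,
                                    strand),
            score=int(float(f["score"])),
            evalue=float(f["evalue"]),
            q_span=(int(f["qstart"]) - 1, int(f["qend"]))))
    return sorted(hits, key=LocusHit.sort_key)


def blastn_search(query: str, genome: Genome, e_cutoff: float,
                  query_id: str = "query") -> list[LocusHit]:
    """Run external blastn (subject mode, protocol flags) and parse hits."""
    if not blastn_available():
        raise RuntimeError("blastn not found on PATH")
    with tempfile.TemporaryDirectory() as td:
        qf = Path(td) / "q.fasta"
        sf = Path(td) / "s.fasta"
        qf.write_text(f">{query_id}\n{query}\n")
        write_genome(genome, sf)
        cmd = ["blastn", "-query", str(qf), "-subject", str(sf),
               "-reward", "1", "-penalty", "-2",
               "-gapopen", "5", "-gapextend", "2",
               "-word_size", "8", "-evalue", f"{e_cutoff:g}",
               "-dust", "no",
               "-outfmt", "6 " + " ".join(BLAST6_COLS)]
        out = subprocess.run(cmd, capture_output=True, text=True, check=True)
    return parse_blast6(out.stdout, genome.species_id)
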