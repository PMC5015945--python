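"""Readers/writers for BED, GFF3 and the pipeline's TSV report tables.

Internal coordinates are 0-based half-open everywhere; BED is emitted
as-is and GFF3 converts to 1-based inclusive only here, at the
serialization boundary.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .intervals import GenomeInterval

BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]
GFF3_COLS = ["seqid", "source", "type", "start", "end", "score",
             "strand", "phase", "attributes"]


def write_bed(items: list[tuple[str, GenomeInterval]], path: str | Path) -> None:
    """Write (name, interval) pairs as BED6 (0-based half-open)."""
    rows = [(iv.chrom, iv.start, iv.end, name, 0, iv.strand)
            for name, iv in items]
    pd.DataFrame(rows, columns=BED_COLS).to_csv(path, sep="\t", index=False,
                                                header=False)


def read_bed(path: str | Path, species_id: str) -> list[tuple[str, GenomeInterval]]:
    p = Path(path)
    if p.stat().st_size == 0:
        return []
    df = pd.read_csv(p, sep="\t", header=None, comment="#")
    df.columns = BED_COLS[: df.shape[1]]
    out = []
    for i, r in enumerate(df.itertuples(index=False)):
        name = getattr(r, "name", None) or f"feature{i}"
        strand = getattr(r, "strand", ".") if "strand" in df.columns else "."
        out.append((str(name), GenomeInterval(species_id, str(r.chrom),
                                              int(r.start), int(r.end), strand)))
    return out


def write_gff3(genes: list[tuple[str, GenomeInterval]], path: str | Path) -> None:
    """Write gene intervals as GFF3 gene/mRNA/CDS triplets (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, iv in genes:
            s1, e1 = iv.start + 1, iv.end  # 0-based half-open -> 1-based incl.
            strand = iv.strand if iv.strand != "." else "+"
            fh.write(f"{iv.chrom}\tlincphylo\tgene\t{s1}\t{e1}\t.\t{strand}\t.\t"
                     f"ID={gene_id}\n")
            fh.write(f"{iv.chrom}\tlincphylo\tmRNA\t{s1}\t{e1}\t.\t{strand}\t.\t"
                     f"ID={gene_id}.1;Parent={gene_id}\n")
            fh.write(f"{iv.chrom}\tlincphylo\tCDS\t{s1}\t{e1}\t.\t{strand}\t0\t"
                     f"ID={gene_id}.1.cds;Parent={gene_id}.1\n")


def read_gff3_genes(path: str | Path, species_id: str) -> list[tuple[str, GenomeInterval]]:
    """Gene-type features from a GFF3 file, back in 0-based half-open coords."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gene_id = attrs.get("ID", f"{f[0]}:{f[3]}")
            genes.append((gene_id, GenomeInterval(
                species_id, f[0], int(f[3]) - 1, int(f[4]),
                f[6] if f[6] in "+-" else ".")))
    return genes


def write_report(tables: dict[str, pd.DataFrame], outdir: str | Path) -> dict[str, Path]:
    """Write each report table as <name>.tsv with a deterministic column order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
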