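"""Indexed genomes: FASTA reading, random access, k-mer indexing.

Sequences are held in memory as uint8 code arrays (A=0, C=1, G=2, T=3,
anything else = 4). Ns never match anything in alignment scoring and
never seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i  # lowercase
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 codes (A0 C1 G2 T3, other 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


class KmerIndex:
    """Sorted exact k-mer index of one chromosome.

    Windows containing a non-ACGT base are excluded. Lookup returns the
    (possibly empty) array of 0-based start positions of a k-mer code.
    """

    def __init__(self, codes: np.ndarray, k: int):
        self.k = k
        n = len(codes)
        if n < k:
            self._codes = np.empty(0, dtype=np.int64)
            self._pos = np.empty(0, dtype=np.int64)
            return
        kmers = np.zeros(n - k + 1, dtype=np.int64)
        ok = np.ones(n - k + 1, dtype=bool)
        for i in range(k):
            seg = codes[i : n - k + 1 + i]
            kmers = kmers * 4 + np.where(seg < 4, seg, 0)
            ok &= seg < 4
        pos = np.nonzero(ok)[0]
        kmers = kmers[pos]
        order = np.argsort(kmers, kind="stable")
        self._codes = kmers[order]
        self._pos = pos[order].astype(np.int64)

    def lookup(self, kmer_code: int) -> np.ndarray:
        lo = np.searchsorted(self._codes, kmer_code, side="left")
        hi = np.searchsorted(self._codes, kmer_code, side="right")
        return self._pos[lo:hi]

    def lookup_many(self, kmer_codes: np.ndarray,
                    query_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Positions of many k-mers at once.

        Returns (qpos, gpos) arrays: one entry per seed, where seed i is
        an occurrence of the query k-mer starting at qpos[i] found at
        genome position gpos[i].
        """
        lo = np.searchsorted(self._codes, kmer_codes, side="left")
        hi = np.searchsorted(self._codes, kmer_codes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return (np.empty(0, dtype=np.int64),) * 2
        starts_rep = np.repeat(lo, counts)
        offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        gpos = self._pos[starts_rep + offsets]
        qpos = np.repeat(query_pos, counts)
        return qpos, gpos


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, codes) of all valid k-mers of a query sequence."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    kmers = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for i in range(k):
        seg = codes[i : n - k + 1 + i]
        kmers = kmers * 4 + np.where(seg < 4, seg, 0)
        ok &= seg < 4
    pos = np.nonzero(ok)[0]
    return pos.astype(np.int64), kmers[pos]


class GenomeIndex:
    """Genome-wide sorted k-mer index over all chromosomes at once.

    Chromosomes are laid out on a virtual global coordinate axis with
    gaps between them; seed positions are global and
    :meth:`locate` maps them back to (chromosome, local position).
    """

    GAP = 4096  # virtual gap between chromosomes; larger than any query

    def __init__(self, chroms: dict[str, np.ndarray], k: int):
        self.k = k
        self.names = list(chroms)
        offs, cur = [], 0
        all_codes, all_pos = [], []
        for name in self.names:
            arr = chroms[name]
            offs.append(cur)
            n = len(arr)
            if n >= k:
                kmers = np.zeros(n - k + 1, dtype=np.int64)
                ok = np.ones(n - k + 1, dtype=bool)
                for i in range(k):
                    seg = arr[i : n - k + 1 + i]
                    kmers = kmers * 4 + np.where(seg < 4, seg, 0)
                    ok &= seg < 4
                pos = np.nonzero(ok)[0] + cur
                all_codes.append(kmers[ok])
                all_pos.append(pos)
            cur += n + self.GAP
        self.offsets = np.array(offs, dtype=np.int64)
        self.lengths = np.array([len(chroms[n]) for n in self.names],
                                dtype=np.int64)
        codes = np.concatenate(all_codes) if all_codes else np.empty(0, np.int64)
        pos = np.concatenate(all_pos) if all_pos else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order]

    def lookup_many(self, kmer_codes: np.ndarray,
                    query_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self._codes, kmer_codes, side="left")
        hi = np.searchsorted(self._codes, kmer_codes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return (np.empty(0, dtype=np.int64),) * 2
        starts_rep = np.repeat(lo, counts)
        offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        gpos = self._pos[starts_rep + offsets]
        qpos = np.repeat(query_pos, counts)
        return qpos, gpos

    def locate(self, global_pos: int) -> tuple[int, str, int]:
        """(chrom index, chrom name, local position) of a global position."""
        ci = int(np.searchsorted(self.offsets, global_pos, side="right")) - 1
        return ci, self.names[ci], int(global_pos - self.offsets[ci])


class Genome:
    """One species' chromosomes with random access and cached k-mer indexes."""

    def __init__(self, species_id: str, chroms: dict[str, str]):
        if not chroms:
            raise ValueError(f"empty genome for {species_id}")
        self.species_id = species_id
        self.chroms: dict[str, np.ndarray] = {}
        for name, seq in chroms.items():
            if name in self.chroms:
                raise ValueError(f"duplicate chromosome {name!r}")
            self.chroms[name] = encode(seq)
        self._indexes: dict[tuple[str, int], KmerIndex] = {}
        self._global_indexes: dict[int, GenomeIndex] = {}

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.chroms.values())

    def chrom_length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    def fetch_codes(self, interval) -> np.ndarray:
        try:
            codes = self.chroms[interval.chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {interval.chrom!r} in {self.species_id}")
        if interval.end > len(codes):
            raise IndexError(
                f"interval end {interval.end} beyond chromosome "
                f"{interval.chrom} length {len(codes)}"
            )
        sub = codes[interval.start : interval.end]
        if interval.strand == "-":
            sub = revcomp_codes(sub)
        return sub

    def fetch(self, interval) -> str:
        """Uppercased subsequence; reverse-complemented on the minus strand."""
        return decode(self.fetch_codes(interval))

    def index(self, chrom: str, k: int) -> KmerIndex:
        key = (chrom, k)
        if key not in self._indexes:
            self._indexes[key] = KmerIndex(self.chroms[chrom], k)
        return self._indexes[key]

    def global_index(self, k: int) -> GenomeIndex:
        if k not in self._global_indexes:
            self._global_indexes[k] = GenomeIndex(self.chroms, k)
        return self._global_indexes[k]


def read_genome(path: str | Path, species_id: str | None = None) -> Genome:
    """Load a FASTA file into an indexed :class:`Genome`.

    Duplicate record names and empty files are errors. The species id
    defaults to the file stem.
    """
    path = Path(path)
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
        chroms[rec.id] = str(rec.seq)
    if not chroms:
        raise ValueError(f"no sequences in {path}")
    return Genome(species_id or path.stem, chroms)


def write_genome(genome: Genome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, codes in genome.chroms.items():
            fh.write(f">{name}\n")
            seq = decode(codes)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
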