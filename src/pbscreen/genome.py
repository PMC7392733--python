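"""Genome-side inputs of a piggyBac screen: TTAA motif index and gene models.

piggyBac integrates exclusively at TTAA tetranucleotides, so the set of TTAA
start positions defines the discrete space of possible insertion sites and
therefore the Monte-Carlo null of the CIS caller.  TTAA is its own reverse
complement, so the index carries no strand.
"""
from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError

_MOTIF = b"TTAA"
_VALID_BYTES = frozenset(b"ACGTN")

GENE_COLUMNS = ["gene_id", "name", "chrom", "start", "end", "strand"]


class TTAAIndex:
    """Sorted 1-based TTAA start positions per chromosome.

    Parameters
    ----------
    positions : mapping of chromosome name to array of 1-based motif starts
    lengths : mapping of chromosome name to chromosome length (bp)
    """

    def __init__(self, positions: Mapping[str, Iterable[int]], lengths: Mapping[str, int]):
        self.positions: dict[str, np.ndarray] = {}
        self.lengths: dict[str, int] = {str(c): int(n) for c, n in lengths.items()}
        for chrom, pos in positions.items():
            arr = np.asarray(list(pos) if not isinstance(pos, np.ndarray) else pos,
                             dtype=np.int64)
            if arr.size and np.any(np.diff(arr) <= 0):
                raise InputError(f"TTAA positions for {chrom} must be strictly increasing")
            if arr.size and arr[0] < 1:
                raise InputError(f"TTAA positions for {chrom} must be >= 1")
            length = self.lengths.get(str(chrom))
            if length is not None and arr.size and arr[-1] + 3 > length:
                raise InputError(
                    f"TTAA position {int(arr[-1])} + 3 exceeds length of {chrom} ({length})"
                )
            self.positions[str(chrom)] = arr

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.positions

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.positions[chrom]

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.positions[chrom].size)
        return int(sum(p.size for p in self.positions.values()))

    def to_tsv(self, path: str | os.PathLike) -> None:
        """Cache the index as a two-column TSV (chrom, pos) with a length header."""
        with open(path, "w") as fh:
            for chrom in self.positions:
                fh.write(f"#length\t{chrom}\t{self.lengths.get(chrom, 0)}\n")
            fh.write("chrom\tpos\n")
            for chrom, arr in self.positions.items():
                for p in arr:
                    fh.write(f"{chrom}\t{p}\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "TTAAIndex":
        lengths: dict[str, int] = {}
        with open(path) as fh:
            data_start = 0
            for line in fh:
                if line.startswith("#length\t"):
                    _, chrom, n = line.rstrip("\n").split("\t")
                    lengths[chrom] = int(n)
                    data_start += len(line)
                else:
                    break
        df = pd.read_csv(path, sep="\t", comment="#")
        positions = {str(c): np.sort(g["pos"].to_numpy(np.int64))
                     for c, g in df.groupby("chrom", sort=True)}
        for chrom in positions:
            lengths.setdefault(chrom, int(positions[chrom][-1]) + 3)
        return cls(positions, lengths)


def scan_ttaa(genome_sequences: Mapping[str, str]) -> TTAAIndex:
    """Locate every exact TTAA occurrence in each chromosome sequence.

    Scanning is case-insensitive; ``N`` never matches; overlap-adjacent motifs
    (e.g. ``TTAATTAA``) are both reported.  Returns 1-based start positions.

    Raises
    ------
    InputError
        If a sequence contains a character outside ``{A,C,G,T,N}``; the error
        names the chromosome and 0-based offset of the first offending byte.
    """
    positions: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for chrom, seq in genome_sequences.items():
        raw = str(seq).upper().encode("ascii", errors="replace")
        arr = np.frombuffer(raw, dtype=np.uint8)
        lengths[str(chrom)] = arr.size
        bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
        if bad.any():
            off = int(np.flatnonzero(bad)[0])
            raise InputError(
                f"non-DNA character {chr(arr[off])!r} in {chrom} at offset {off}"
            )
        if arr.size < 4:
            positions[str(chrom)] = np.empty(0, dtype=np.int64)
            continue
        t, a = ord("T"), ord("A")
        hit = (arr[:-3] == t) & (arr[1:-2] == t) & (arr[2:-1] == a) & (arr[3:] == a)
        positions[str(chrom)] = np.flatnonzero(hit).astype(np.int64) + 1
    return TTAAIndex(positions, lengths)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into a chrom -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gff3_genes(path: str | os.PathLike) -> pd.DataFrame:
    """Read gene models from a GFF3 file.

    Only ``type == gene`` features are used, with seqid, start, end, strand
    and the ``ID`` and ``Name`` attributes.  Returns a DataFrame with columns
    ``gene_id, name, chrom, start, end, strand`` (1-based inclusive).
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        name = feat.attributes.get("Name", [gene_id])[0]
        rows.append((gene_id, name, feat.seqid, int(feat.start), int(feat.end),
                     feat.strand))
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    if ((df["start"] > df["end"]).any()):
        raise InputError("gene with start > end in GFF3")
    return df.sort_values(["chrom", "start"], ignore_index=True)


def write_gff3_genes(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a gene table (columns as in :data:`GENE_COLUMNS`) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = f"ID={row.gene_id};Name={row.name}"
            fh.write(f"{row.chrom}\tpbscreen\tgene\t{row.start}\t{row.end}\t."
                     f"\t{row.strand}\t.\t{attrs}\n")
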