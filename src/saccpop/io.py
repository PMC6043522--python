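"""Shared readers and writers: FASTA, BED, newick, pileup tables.

Conventions: BED and internal intervals are 0-based half-open; pileup
positions are 1-based.  FASTA goes through Bio.SeqIO, newick through
dendropy.
"""

from __future__ import annotations

import os
from typing import Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from saccpop.synthgen import GeneInterval

PILEUP_COLUMNS = ["chrom", "pos", "ref", "depth",
                  "countA", "countC", "countG", "countT"]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | os.PathLike) -> list[GeneInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED record")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer interval") from exc
            name = parts[3] if len(parts) > 3 else f"feature{lineno}"
            intervals.append(GeneInterval(name, parts[0], start, end))
    return intervals


def write_bed(path: str | os.PathLike,
              intervals: list[GeneInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(path: str | os.PathLike, tree: dendropy.Tree) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_pileup_table(path: str | os.PathLike) -> pd.DataFrame:
    """Tab-separated pileup (chrom, 1-based pos, ref, depth, per-base
    counts); validates column names and basic invariants."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pileup columns {missing}")
    if (df["pos"] < 1).any():
        raise ValueError(f"{path}: pileup positions must be 1-based")
    counts = df[["countA", "countC", "countG", "countT"]].sum(axis=1)
    if (counts > df["depth"]).any():
        raise ValueError(f"{path}: allele counts exceed depth")
    return df


def write_pileup_table(path: str | os.PathLike, pileup: pd.DataFrame) -> None:
    pileup[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)
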