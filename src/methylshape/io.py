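"""File-format plumbing: FASTA (six-letter alphabet) and BED methylation.

FASTA is read and written with Biopython, preserving case — lowercase
``m``/``g`` carry the methylation marks.  Methylation positions arrive as
BED intervals (0-based, half-open); an interval ``[i, i+2)`` on sequence
``chrom`` must cover a CpG dinucleotide of that sequence.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AlphabetError, MethylationError, validate

__all__ = ["read_fasta", "write_fasta", "read_bed", "methylation_positions"]


def read_fasta(path, mode: str = "fragment") -> List[Tuple[str, str]]:
    """(id, sequence) pairs; each sequence is validated against the CpG
    grammar in ``mode`` (uppercase ACGT with lowercase m/g)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        bad = validate(seq, mode)
        if bad:
            raise AlphabetError(
                f"{path}: record {rec.id!r}: "
                + "; ".join(f"pos {v.position}: {v.message}" for v in bad)
            )
        out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable[Tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_bed(path) -> pd.DataFrame:
    """BED3+ as a frame with columns chrom, start, end (0-based half-open).

    Empty files (no intervals) are valid and yield an empty frame.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def methylation_positions(bed: pd.DataFrame, seq_id: str, seq: str) -> List[int]:
    """0-based CpG start positions for one sequence from a BED frame.

    Each interval for ``seq_id`` must be exactly 2 bp wide and cover a CG
    dinucleotide of ``seq``.
    """
    positions = []
    for _, row in bed[bed["chrom"] == seq_id].iterrows():
        i, j = int(row["start"]), int(row["end"])
        if j - i != 2:
            raise MethylationError(
                f"{seq_id}: interval [{i}, {j}) must be 2 bp wide"
            )
        if i < 0 or j > len(seq) or seq[i : i + 2] != "CG":
            raise MethylationError(
                f"{seq_id}: interval [{i}, {j}) does not cover a CpG"
            )
        positions.append(i)
    return sorted(set(positions))
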