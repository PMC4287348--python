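"""Length statistics of an assembled transcriptome FASTA.

N50 follows the convention used for de novo transcriptomes: the largest
contig length L such that contigs of length >= L together contain at least
half the assembly's bases.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import SeqIO

from .io_formats import FormatError

__all__ = ["read_lengths", "n50", "length_summary"]


def read_lengths(fasta_path: str | Path) -> dict[str, int]:
    """Per-contig lengths (bp) from a FASTA file.

    Raises on duplicate IDs or empty sequences.
    """
    lengths: dict[str, int] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in lengths:
            raise FormatError(f"{fasta_path}: duplicate contig ID {rec.id!r}")
        if len(rec.seq) == 0:
            raise FormatError(f"{fasta_path}: empty sequence for {rec.id!r}")
        lengths[rec.id] = len(rec.seq)
    return lengths


def _as_array(lengths: Mapping[str, int] | np.ndarray | list) -> np.ndarray:
    if isinstance(lengths, Mapping):
        arr = np.asarray(list(lengths.values()))
    else:
        arr = np.asarray(lengths)
    if arr.size == 0:
        raise ValueError("empty length set")
    if (arr < 1).any():
        raise ValueError("contig lengths must be >= 1 bp")
    return arr.astype(np.int64)


def n50(lengths: Mapping[str, int] | np.ndarray | list) -> int:
    """Largest length L with sum(lengths >= L) >= half the total bases."""
    arr = np.sort(_as_array(lengths))[::-1]
    half = arr.sum() / 2.0
    cum = np.cumsum(arr)
    # first position (largest lengths first) where cumulative bases reach half
    i = int(np.searchsorted(cum, half, side="left"))
    return int(arr[i])


def length_summary(lengths: Mapping[str, int] | np.ndarray | list) -> dict:
    """Count, total bp, N50, mean and median length of a contig set."""
    arr = _as_array(lengths)
    return {
        "count": int(arr.size),
        "total_bp": int(arr.sum()),
        "n50": n50(arr),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
    }
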