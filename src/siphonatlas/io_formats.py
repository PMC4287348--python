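"""Readers and writers for every external table the pipeline touches.

All tables are tab-separated UTF-8; lines starting with ``#`` are ignored.
The central container is :class:`CountMatrix`, a transcript × sample integer
count table plus a sample sheet mapping each sample to the pseudo-organ it
was dissected from (apex, pinnule, rachis, frond base, stolon, holdfast by
default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "DEFAULT_ORGANS",
    "CountMatrix",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_best_hits",
    "write_best_hits",
    "read_go_annotation",
    "write_go_annotation",
    "read_node_table",
    "write_node_table",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


#: Pseudo-organ labels of the default sampling design.
DEFAULT_ORGANS = ("apex", "pinnule", "rachis", "frond_base", "stolon", "holdfast")

_GO_RE = re.compile(r"^GO:\d{7}$")

#: Canonical 12 columns of BLAST tabular output (-outfmt 6).
BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass
class CountMatrix:
    """Integer transcript × sample counts with a sample → pseudo-organ sheet.

    Parameters
    ----------
    counts
        DataFrame indexed by transcript ID with one column per sample.
    sample_sheet
        Series mapping sample ID to pseudo-organ label.
    organ_labels
        The admissible label set; defaults to the six-pseudo-organ design.
    """

    counts: pd.DataFrame
    sample_sheet: pd.Series
    organ_labels: tuple[str, ...] = field(default=DEFAULT_ORGANS)

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate transcript ID: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample ID: {dup!r}")
        missing = [s for s in cols if s not in self.sample_sheet.index]
        if missing:
            raise FormatError(f"samples missing from sample sheet: {missing}")
        bad = [
            s for s in cols if self.sample_sheet[s] not in self.organ_labels
        ]
        if bad:
            raise FormatError(
                f"samples with pseudo-organ label outside {self.organ_labels}: {bad}"
            )
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError("counts must be integers (see round_counts)")
        if (arr < 0).any():
            t, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at transcript {idx[t]!r}, sample {cols[s]!r}"
            )
        self.sample_sheet = self.sample_sheet.loc[cols]

    @property
    def transcript_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def organs(self) -> list[str]:
        """Organ labels present, in configured order."""
        present = set(self.sample_sheet)
        return [o for o in self.organ_labels if o in present]

    def organ_samples(self) -> dict[str, list[str]]:
        """Mapping organ → list of its sample IDs (column order)."""
        out: dict[str, list[str]] = {o: [] for o in self.organs}
        for s in self.sample_ids:
            out[self.sample_sheet[s]].append(s)
        return out

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_transcripts(self, ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(ids)], self.sample_sheet,
                           self.organ_labels)


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_sample_sheet(path: str | Path) -> pd.Series:
    """Read a two-column TSV (sample_id, pseudo_organ) into a Series."""
    df = _read_tsv(path, header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: sample sheet needs 2 columns, got {df.shape[1]}")
    sheet = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="organ")
    if sheet.index.has_duplicates:
        dup = sheet.index[sheet.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample ID {dup!r}")
    return sheet


def write_sample_sheet(sheet: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": sheet.index, "pseudo_organ": sheet.to_numpy()}).to_csv(
        path, sep="\t", index=False)


def read_count_matrix(
    path: str | Path,
    sheet_path: str | Path,
    organ_labels: tuple[str, ...] = DEFAULT_ORGANS,
    round_counts: bool = True,
) -> CountMatrix:
    """Read a transcript × sample count TSV plus its sample sheet.

    The count file has a header row of sample IDs and transcript IDs in the
    first column.  RSEM-style estimators emit fractional expected counts;
    with ``round_counts`` (default) cells are rounded half-to-even before
    integer validation, otherwise any non-integral cell is an error.
    """
    df = _read_tsv(path, header=0, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate transcript ID {dup!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = np.argwhere(~np.vectorize(np.isreal)(arr))
        t, s = bad[0]
        raise FormatError(
            f"{path}: non-numeric count at transcript {df.index[t]!r}, "
            f"sample {df.columns[s]!r}")
    arr = arr.astype(float)
    if not np.isfinite(arr).all():
        t, s = np.argwhere(~np.isfinite(arr))[0]
        raise FormatError(
            f"{path}: non-finite count at transcript {df.index[t]!r}, "
            f"sample {df.columns[s]!r}")
    if round_counts:
        arr = np.rint(arr)
    elif not np.array_equal(arr, np.rint(arr)):
        t, s = np.argwhere(arr != np.rint(arr))[0]
        raise FormatError(
            f"{path}: non-integer count at transcript {df.index[t]!r}, "
            f"sample {df.columns[s]!r} (pass round_counts=True to round)")
    counts = pd.DataFrame(arr.astype(np.int64), index=df.index, columns=df.columns)
    sheet = read_sample_sheet(sheet_path)
    return CountMatrix(counts, sheet, organ_labels)


def write_count_matrix(cm: CountMatrix, path: str | Path,
                       sheet_path: str | Path | None = None) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="transcript_id")
    if sheet_path is not None:
        write_sample_sheet(cm.sample_sheet, sheet_path)


# ---------------------------------------------------------------------------
# BLAST tabular best hits
# ---------------------------------------------------------------------------

def read_best_hits(path: str | Path, evalue_ceiling: float = 1e-5) -> pd.DataFrame:
    """Read 12-column BLAST tabular output and reduce to one best hit per query.

    Rows with e-value above ``evalue_ceiling`` are dropped first.  Best-hit
    selection is a total order so the result is independent of input row
    order: highest bit score, then lowest e-value, then highest percent
    identity, then lexicographically smallest subject ID.

    Returns a DataFrame with columns ``query_id, subject_id,
    percent_identity, e_value, bit_score``, one row per surviving query.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(BLAST6_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(BLAST6_COLUMNS)} "
                    f"tab-separated columns, got {len(parts)}")
            try:
                rec = (parts[0], parts[1], float(parts[2]),
                       float(parts[10]), float(parts[11]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            rows.append(rec)
    df = pd.DataFrame(rows, columns=[
        "query_id", "subject_id", "percent_identity", "e_value", "bit_score"])
    df = df[df["e_value"] <= evalue_ceiling]
    if df.empty:
        return df.reset_index(drop=True)
    df = df.sort_values(
        by=["query_id", "bit_score", "e_value", "percent_identity", "subject_id"],
        ascending=[True, False, True, False, True],
        kind="mergesort",
    )
    df = df.drop_duplicates(subset="query_id", keep="first")
    return df.reset_index(drop=True)


def write_best_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GO annotation
# ---------------------------------------------------------------------------

def read_go_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column TSV (transcript_id, GO ID), aggregating per transcript."""
    ann: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            tid, go = parts[0], parts[1]
            if not _GO_RE.match(go):
                raise FormatError(
                    f"{path}:{lineno}: malformed GO ID {go!r} "
                    "(expected 'GO:' + 7 digits)")
            ann.setdefault(tid, set()).add(go)
    return ann


def write_go_annotation(ann: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid in sorted(ann):
            for go in sorted(ann[tid]):
                fh.write(f"{tid}\t{go}\n")


# ---------------------------------------------------------------------------
# Node membership tables (transcript -> cluster label)
# ---------------------------------------------------------------------------

def read_node_table(path: str | Path) -> pd.Series:
    """Read a 2-column TSV (transcript_id, node) into a Series."""
    df = _read_tsv(path, header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: node table needs 2 columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str),
                  name="node")
    if s.index.has_duplicates:
        dup = s.index[s.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate transcript ID {dup!r}")
    return s


def write_node_table(nodes: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"transcript_id": nodes.index, "node": nodes.to_numpy()}).to_csv(
        path, sep="\t", index=False)
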