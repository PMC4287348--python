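"""Cross-species atlas intersection via best-hit homologs and a χ² test.

Each source-atlas transcript inherits the expression-atlas node of its best
BLAST-hit homolog in a foreign species.  For every source node, the
distribution of its transcripts over foreign nodes is compared with the
foreign atlas's own node distribution (the null) by a Pearson χ²
goodness-of-fit test: a significant statistic means the source node's genes
concentrate in particular foreign accumulation patterns.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "assign_foreign_nodes",
    "null_distribution",
    "intersection_chisq",
]

log = logging.getLogger(__name__)


def assign_foreign_nodes(
    hits: pd.DataFrame,
    foreign_membership: Mapping[str, object] | pd.Series,
    source_nodes: Mapping[str, object] | pd.Series | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Gene-level table mapping source transcripts to foreign atlas nodes.

    ``hits`` must be best-hit reduced (one row per query).  Queries whose
    subject lacks a foreign node, or (when ``source_nodes`` is given) which
    themselves lack a source node, are excluded; exclusion counts are
    returned by reason.
    """
    membership = pd.Series(foreign_membership) \
        if not isinstance(foreign_membership, pd.Series) else foreign_membership
    if hits["query_id"].duplicated().any():
        raise ValueError("hits table is not best-hit reduced")
    excluded = {"subject_without_foreign_node": 0, "query_without_source_node": 0}

    rows = []
    for rec in hits.itertuples(index=False):
        if rec.subject_id not in membership.index:
            excluded["subject_without_foreign_node"] += 1
            continue
        source_node = None
        if source_nodes is not None:
            if rec.query_id not in source_nodes:
                excluded["query_without_source_node"] += 1
                continue
            source_node = source_nodes[rec.query_id]
        rows.append({
            "transcript_id": rec.query_id,
            "homolog_id": rec.subject_id,
            "source_node": source_node,
            "foreign_node": membership[rec.subject_id],
            "percent_identity": rec.percent_identity,
            "e_value": rec.e_value,
            "bit_score": rec.bit_score,
        })
    table = pd.DataFrame(rows, columns=[
        "transcript_id", "homolog_id", "source_node", "foreign_node",
        "percent_identity", "e_value", "bit_score"])
    log.info("foreign-node assignment: %d kept, %s excluded", len(table),
             excluded)
    return table, excluded


def null_distribution(foreign_membership: Mapping[str, object] | pd.Series
                      ) -> pd.Series:
    """Proportion of all foreign transcripts in each foreign node."""
    membership = pd.Series(foreign_membership) \
        if not isinstance(foreign_membership, pd.Series) else foreign_membership
    if membership.empty:
        raise ValueError("empty foreign membership")
    props = membership.value_counts(normalize=True).sort_index()
    return props.rename("proportion")


def intersection_chisq(
    gene_table: pd.DataFrame,
    null_proportions: pd.Series,
    warn_expected_below: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-source-node χ² goodness of fit against the foreign null.

    Returns ``(summary, long)``: one χ²/df/p row per source node, and a
    long observed/expected/fold table per (source node, foreign node).
    Expected counts are the node total times the null proportions; a zero
    expected count with a positive observed count is an error (merge the
    offending foreign categories first), as is a single foreign category
    (df = 0).
    """
    if len(null_proportions) < 2:
        raise ValueError("χ² needs >= 2 foreign node categories (df >= 1)")
    cats = null_proportions.index
    summaries, longs = [], []
    for node, sub in gene_table.groupby("source_node", sort=True):
        observed = sub["foreign_node"].value_counts().reindex(cats, fill_value=0)
        unknown = set(sub["foreign_node"]) - set(cats)
        if unknown:
            raise ValueError(
                f"foreign nodes {sorted(unknown)} absent from null distribution")
        total = int(observed.sum())
        expected = null_proportions * total
        bad = (expected == 0) & (observed > 0)
        if bad.any():
            raise ValueError(
                f"source node {node!r}: zero expected count with positive "
                f"observed in foreign node(s) {list(cats[bad])}; merge categories")
        if (expected < warn_expected_below).any():
            log.warning("source node %r: expected count below %g in %d "
                        "foreign node(s)", node, warn_expected_below,
                        int((expected < warn_expected_below).sum()))
        df_free = len(cats) - 1
        chi2 = float((((observed - expected) ** 2) / expected).sum())
        p = float(stats.chi2.sf(chi2, df_free))
        summaries.append({"source_node": node, "n_genes": total,
                          "chi2": chi2, "df": df_free, "p_value": max(p, 0.0)})
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = observed / expected
        for cat in cats:
            longs.append({"source_node": node, "foreign_node": cat,
                          "observed": int(observed[cat]),
                          "expected": float(expected[cat]),
                          "fold": float(fold[cat])})
    return pd.DataFrame(summaries), pd.DataFrame(longs)
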