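"""Per-node GO term over-representation with optional length-bias correction.

The core test is the upper-tail hypergeometric: with N transcripts in the
universe, n of them carrying a term, and a node of K members containing k
carriers, p = P(X >= k).  Long transcripts are more likely to be called
differentially abundant in count-based pipelines, which inflates
hypergeometric enrichment of categories of long genes; the length-aware
variant estimates a probability-weighting function by isotonic regression of
node-membership rate on transcript length over quantile bins, converts it to
a per-category odds (mean weight inside / outside the category), and takes
the upper tail of the Wallenius noncentral hypergeometric distribution with
that odds.  The Wallenius tail is computed by an exact dynamic program over
the sequential biased-urn process that defines the distribution.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .differential_expression import bh_fdr

__all__ = [
    "hypergeom_enrich",
    "wallenius_enrich",
    "wallenius_sf",
    "pwf_weights",
]

log = logging.getLogger(__name__)


def _terms_over(universe: list[str], annotation: Mapping[str, set[str]]
                ) -> dict[str, set[str]]:
    by_term: dict[str, set[str]] = {}
    for t in universe:
        for go in annotation.get(t, ()):
            by_term.setdefault(go, set()).add(t)
    return by_term


def _check_node(node_members: Iterable[str], universe: Iterable[str]
                ) -> tuple[list[str], list[str]]:
    node = list(dict.fromkeys(node_members))
    uni = list(dict.fromkeys(universe))
    extra = set(node) - set(uni)
    if extra:
        raise ValueError(f"node members outside universe: {sorted(extra)[:10]}")
    return node, uni


def hypergeom_enrich(
    node_members: Iterable[str],
    universe: Iterable[str],
    annotation: Mapping[str, set[str]],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each GO term.

    Returns one row per term present in the universe, with counts
    (k, n, K, N), the p-value, BH FDR across terms, and a ``significant``
    flag at ``fdr_threshold``.
    """
    node, uni = _check_node(node_members, universe)
    by_term = _terms_over(uni, annotation)
    if not by_term:
        raise ValueError("annotation covers no universe member")
    n_total, k_node = len(uni), len(node)
    node_set = set(node)
    rows = []
    for term in sorted(by_term):
        carriers = by_term[term]
        k = len(carriers & node_set)
        n = len(carriers)
        p = float(stats.hypergeom.sf(k - 1, n_total, n, k_node))
        rows.append({"term": term, "k": k, "n": n, "K": k_node, "N": n_total,
                     "p_value": min(p, 1.0), "method": "hypergeometric"})
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    df["significant"] = df["fdr"] < fdr_threshold
    return df


def wallenius_sf(k: int, total: int, n_cat: int, n_draw: int,
                 odds: float) -> float:
    """P(X >= k) for Wallenius' noncentral hypergeometric distribution.

    ``n_draw`` items are drawn one at a time without replacement from
    ``total`` items of which ``n_cat`` belong to the category; at each draw
    a category item is picked with probability
    odds*(remaining in) / (odds*(remaining in) + (remaining out)).
    Computed by exact forward recursion on the number of category items
    drawn, O(n_draw * min(n_draw, n_cat)).
    """
    if odds <= 0:
        raise ValueError("odds must be positive")
    if n_draw > total or n_cat > total:
        raise ValueError("category or draw larger than population")
    gmax = min(n_draw, n_cat)
    if k <= 0:
        return 1.0
    if k > gmax:
        return 0.0
    g = np.arange(gmax + 1)
    prob = np.zeros(gmax + 1)
    prob[0] = 1.0
    for j in range(n_draw):
        rem_in = np.maximum(n_cat - g, 0).astype(float)
        rem_out = np.maximum((total - n_cat) - (j - g), 0).astype(float)
        denom = odds * rem_in + rem_out
        with np.errstate(invalid="ignore", divide="ignore"):
            p_in = np.where(denom > 0, odds * rem_in / np.maximum(denom, 1e-300),
                            0.0)
        new = prob * (1.0 - p_in)
        new[1:] += prob[:-1] * p_in[:-1]
        prob = new
    return float(prob[k:].sum())


def pwf_weights(is_member: np.ndarray, lengths: np.ndarray,
                n_bins: int = 20) -> np.ndarray:
    """Probability-weighting function: membership rate vs length, isotonic.

    Transcripts are binned into length quantiles; the per-bin membership
    rate is smoothed by isotonic (monotone non-decreasing) regression on
    bin median length and each transcript receives its bin's fitted rate.
    A small floor keeps weights positive.
    """
    lengths = np.asarray(lengths, dtype=float)
    is_member = np.asarray(is_member, dtype=bool)
    n_bins = min(n_bins, max(2, len(np.unique(lengths))))
    edges = np.quantile(lengths, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        # (near-)constant lengths: no length gradient to regress on
        return np.full(len(lengths), max(is_member.mean(), 1e-9))
    bins = np.clip(np.searchsorted(edges, lengths, side="right") - 1,
                   0, len(edges) - 2)
    bin_len = np.array([np.median(lengths[bins == b])
                        for b in range(len(edges) - 1)])
    bin_rate = np.array([is_member[bins == b].mean() if (bins == b).any() else 0.0
                         for b in range(len(edges) - 1)])
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(bin_len, bin_rate)
    weights = fitted[bins]
    floor = max(is_member.mean() * 1e-3, 1e-9)
    return np.maximum(weights, floor)


def wallenius_enrich(
    node_members: Iterable[str],
    universe: Iterable[str],
    annotation: Mapping[str, set[str]],
    lengths: Mapping[str, int],
    fdr_threshold: float = 0.05,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Length-bias-corrected GO over-representation (Wallenius test).

    Falls back to the plain hypergeometric test (with a warning) when
    lengths cover fewer than 90% of the universe.  Per-term odds is the
    mean probability weight of transcripts inside the category divided by
    the mean outside; odds of exactly 1 reduces to the hypergeometric.
    """
    node, uni = _check_node(node_members, universe)
    covered = [t for t in uni if t in lengths]
    if len(covered) < 0.9 * len(uni):
        log.warning("lengths cover %d/%d universe members (<90%%); "
                    "falling back to hypergeometric", len(covered), len(uni))
        return hypergeom_enrich(node, uni, annotation, fdr_threshold)
    len_arr = np.array([lengths[t] for t in covered], dtype=float)
    if (len_arr <= 0).any():
        raise ValueError("non-positive transcript length")
    uni = covered
    node_set = set(node) & set(uni)
    by_term = _terms_over(uni, annotation)
    if not by_term:
        raise ValueError("annotation covers no universe member")

    is_member = np.array([t in node_set for t in uni])
    weights = pwf_weights(is_member, len_arr, n_bins=n_bins)
    w = pd.Series(weights, index=uni)

    n_total, k_node = len(uni), len(node_set)
    rows = []
    for term in sorted(by_term):
        carriers = by_term[term]
        k = len(carriers & node_set)
        n = len(carriers)
        inside = w.loc[list(carriers)].mean()
        out_ids = [t for t in uni if t not in carriers]
        outside = w.loc[out_ids].mean() if out_ids else inside
        odds = float(inside / outside) if outside > 0 else 1.0
        p = wallenius_sf(k, n_total, n, k_node, odds)
        rows.append({"term": term, "k": k, "n": n, "K": k_node, "N": n_total,
                     "odds": odds, "p_value": min(p, 1.0),
                     "method": "wallenius"})
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    df["significant"] = df["fdr"] < fdr_threshold
    return df
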