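"""Pairwise negative-binomial differential-abundance tests between pseudo-organs.

The model is a negative binomial with variance mu + phi * mu**2 and a single
common dispersion phi shared by all transcripts, estimated by maximizing the
conditional likelihood given per-group totals on library-size-equalized
counts.  The per-transcript test conditions on the pooled count of an organ
pair: given the total z and equal per-sample effective depths, the count sum
of group A follows a beta-binomial(z, nA/phi, nB/phi) distribution under the
null of equal means (binomial(z, nA/(nA+nB)) in the Poisson limit phi -> 0).
Two-sided p-values double the smaller tail, capped at 1.  This is a
deliberately self-contained simplification of the edgeR-style exact test: no
quantile adjustment and no tagwise shrinkage.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix

__all__ = [
    "DispersionModel",
    "equalize_library_sizes",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_fdr",
    "pairwise_de",
    "de_union",
]

log = logging.getLogger(__name__)


@dataclass
class DispersionModel:
    """Common NB dispersion phi (0 = Poisson limit)."""

    common_dispersion: float

    def __post_init__(self) -> None:
        if self.common_dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def equalize_library_sizes(cm: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Rescale counts to the geometric mean of TMM-effective library sizes.

    Returns an integer pseudo-count matrix on which the conditional exact
    test is valid (it assumes equal depths).
    """
    lib = cm.library_sizes.to_numpy(dtype=float)
    eff = lib * factors.loc[cm.sample_ids].to_numpy(dtype=float)
    target = np.exp(np.mean(np.log(eff)))
    scaled = cm.counts.to_numpy(dtype=float) * (target / eff)[None, :]
    return pd.DataFrame(np.rint(scaled).astype(np.int64),
                        index=cm.transcript_ids, columns=cm.sample_ids)


def _conditional_loglik(phi: float, group_counts: list[np.ndarray]) -> float:
    """Conditional NB log-likelihood given per-group totals, common phi."""
    r = 1.0 / phi
    ll = 0.0
    for y in group_counts:           # y: transcripts × replicates
        n = y.shape[1]
        z = y.sum(axis=1)
        ll += float(
            np.sum(special.gammaln(y + r))
            - y.size * special.gammaln(r)
            + len(z) * special.gammaln(n * r)
            - np.sum(special.gammaln(z + n * r))
        )
    return ll


def estimate_common_dispersion(
    cm_or_counts: CountMatrix | pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    grid: tuple[float, float, int] = (1e-4, 4.0, 25),
) -> DispersionModel:
    """Maximum conditional-likelihood common dispersion.

    ``groups`` maps group label to its sample IDs; only groups with >= 2
    replicates inform the estimate.  The likelihood is scanned on a log
    grid then refined by bounded scalar minimization; a maximum at the
    lower grid edge is reported as dispersion 0 (sub-Poisson data).
    """
    counts = cm_or_counts.counts if isinstance(cm_or_counts, CountMatrix) \
        else cm_or_counts
    group_counts = []
    for g, samples in groups.items():
        if len(samples) >= 2:
            group_counts.append(counts[list(samples)].to_numpy(dtype=float))
    if not group_counts:
        raise ValueError(
            "no group has >= 2 replicates; supply a fixed dispersion instead")

    lo, hi, n_grid = grid
    phis = np.geomspace(lo, hi, n_grid)
    lls = np.array([_conditional_loglik(p, group_counts) for p in phis])
    best = int(np.argmax(lls))
    if best == 0:
        return DispersionModel(0.0)
    left = phis[max(best - 1, 0)]
    right = phis[min(best + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda p: -_conditional_loglik(p, group_counts),
        bounds=(left, right), method="bounded",
        options={"xatol": 1e-6})
    phi = float(res.x)
    if phi <= lo * 1.01:
        return DispersionModel(0.0)
    return DispersionModel(phi)


def nb_exact_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    dispersion: float,
) -> np.ndarray:
    """Two-sided conditional exact p-values per transcript.

    ``group_a`` and ``group_b`` are transcripts × replicates matrices of
    depth-equalized counts.  For each transcript the pooled total z is
    split between the groups; under equal means the group-A sum is
    beta-binomial(z, nA/phi, nB/phi) (binomial for phi = 0).  The smaller
    tail is doubled and capped at 1; transcripts with z = 0 get p = 1.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    group_a = np.atleast_2d(np.asarray(group_a))
    group_b = np.atleast_2d(np.asarray(group_b))
    na, nb = group_a.shape[1], group_b.shape[1]
    sa = group_a.sum(axis=1)
    z = sa + group_b.sum(axis=1)

    p = np.ones(len(z))
    pos = z > 0
    if pos.any():
        if dispersion == 0:
            dist = stats.binom(z[pos], na / (na + nb))
        else:
            r = 1.0 / dispersion
            dist = stats.betabinom(z[pos], na * r, nb * r)
        lower = dist.cdf(sa[pos])
        upper = dist.sf(sa[pos] - 1)
        p[pos] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return p


def bh_fdr(pvalues: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_de(
    cm: CountMatrix,
    factors: pd.Series,
    dispersion: float | None = None,
    fdr_threshold: float = 0.05,
    prior_count: float = 0.5,
) -> dict[frozenset, pd.DataFrame]:
    """NB exact tests for every unordered pseudo-organ pair.

    Returns a mapping ``frozenset({organA, organB})`` → DataFrame with
    columns ``log2_fold_change`` (B over A in organ-label order), ``p_value``,
    ``fdr`` and ``significant``.  The common dispersion is estimated from
    the equalized counts unless supplied.
    """
    eq = equalize_library_sizes(cm, factors)
    organ_samples = cm.organ_samples()
    if dispersion is None:
        dispersion = estimate_common_dispersion(eq, organ_samples) \
            .common_dispersion
        log.info("common dispersion estimate: %.4g", dispersion)

    results: dict[frozenset, pd.DataFrame] = {}
    for org_a, org_b in itertools.combinations(cm.organs, 2):
        ya = eq[organ_samples[org_a]].to_numpy()
        yb = eq[organ_samples[org_b]].to_numpy()
        p = nb_exact_test(ya, yb, dispersion)
        adj = bh_fdr(p)
        lfc = np.log2((yb.mean(axis=1) + prior_count)
                      / (ya.mean(axis=1) + prior_count))
        results[frozenset((org_a, org_b))] = pd.DataFrame(
            {
                "log2_fold_change": lfc,
                "p_value": p,
                "fdr": adj,
                "significant": adj < fdr_threshold,
            },
            index=cm.transcript_ids,
        )
    return results


def de_union(
    results: Mapping[frozenset, pd.DataFrame],
    organs: Sequence[str],
    threshold: float = 0.05,
) -> list[str]:
    """Transcripts significant (FDR < threshold) in at least one organ pair.

    Requires all k*(k-1)/2 pairwise results; order follows the first
    result's transcript index.
    """
    expected = {frozenset(p) for p in itertools.combinations(organs, 2)}
    missing = expected - set(results)
    if missing:
        names = sorted("-".join(sorted(m)) for m in missing)
        raise ValueError(f"missing pairwise comparisons: {names}")

    union: set[str] = set()
    order: list[str] = []
    for pair in results:
        df = results[pair]
        if not order:
            order = list(df.index)
        union |= set(df.index[df["fdr"] < threshold])
    if not union:
        log.warning("no transcript significant in any organ pair")
    return [t for t in order if t in union]
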