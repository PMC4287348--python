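"""Low-count filtering, TMM scaling factors, and counts-per-million.

The trimmed-mean-of-M-values (TMM) factor of a sample is computed against a
reference sample: per-transcript log2 ratios of library-normalized
proportions (M) and mean log2 abundances (A) are formed over transcripts
nonzero in both samples, the most extreme 30% of M values and 5% of A
values are trimmed, and the factor is two to the precision-weighted mean of
the surviving M values (weights are inverse asymptotic binomial variances).
Factors are rescaled to geometric mean one so normalized values are
comparable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

__all__ = ["filter_low_counts", "tmm_factors", "cpm", "NormalizedMatrix"]

log = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Normalized counts-per-million with the factors that produced them."""

    values: pd.DataFrame          # transcripts × samples, CPM
    factors: pd.Series            # per-sample TMM factor, geometric mean 1
    library_sizes: pd.Series      # raw per-sample totals


def filter_low_counts(cm: CountMatrix, min_total: int = 30) -> CountMatrix:
    """Keep transcripts whose count summed over ALL samples is >= ``min_total``.

    Row order is preserved.  An empty result is allowed (warning logged).
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = cm.counts.sum(axis=1) >= min_total
    if not keep.any():
        log.warning("low-count filter (min_total=%d) removed every transcript",
                    min_total)
    return CountMatrix(cm.counts.loc[keep], cm.sample_sheet, cm.organ_labels)


def _trimmed_mask(x: np.ndarray, frac: float) -> np.ndarray:
    """Boolean mask keeping values whose rank lies inside the two-sided trim."""
    n = x.size
    k = int(np.floor(n * frac))
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks >= k) & (ranks < n - k)


def tmm_factors(
    cm: CountMatrix,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference defaults to the sample whose 75th-percentile count
    fraction is closest to the mean of those quantiles.
    """
    counts = cm.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = cm.sample_ids[np.argwhere(lib <= 0)[0][0]]
        raise ValueError(f"sample {bad!r} has zero library size")

    if ref_sample is None:
        q75 = np.quantile(counts, 0.75, axis=0) / lib
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = int(cm.sample_ids.get_loc(ref_sample))

    yr = counts[:, ref_idx]
    nr = lib[ref_idx]
    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        ys, ns = counts[:, j], lib[j]
        ok = (ys > 0) & (yr > 0)
        if not ok.any():
            continue
        ps, pr = ys[ok] / ns, yr[ok] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        # inverse of the asymptotic variance of M (delta method, binomial)
        w = 1.0 / ((ns - ys[ok]) / (ns * ys[ok]) + (nr - yr[ok]) / (nr * yr[ok]))
        keep = _trimmed_mask(m, trim_m) & _trimmed_mask(a, trim_a)
        if not keep.any():
            continue
        factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.sample_ids, name="tmm_factor")


def cpm(cm: CountMatrix, factors: pd.Series) -> NormalizedMatrix:
    """Counts per million over TMM-effective library sizes.

    value[t, s] = counts[t, s] / (library_size[s] * factor[s]) * 1e6
    """
    f = factors.loc[cm.sample_ids].to_numpy(dtype=float)
    if (f <= 0).any():
        raise ValueError("factors must be positive")
    lib = cm.library_sizes.to_numpy(dtype=float)
    vals = cm.counts.to_numpy(dtype=float) / (lib * f)[None, :] * 1e6
    values = pd.DataFrame(vals, index=cm.transcript_ids, columns=cm.sample_ids)
    return NormalizedMatrix(values, factors.loc[cm.sample_ids],
                            cm.library_sizes)
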