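"""Replicate averaging, row scaling, PCA, and the hexagonal self-organizing map.

The SOM is the classical online algorithm: codebook vectors initialized from
a seeded random sample of the data, inputs presented in seeded random order
each iteration, winner chosen by Euclidean distance (ties to the lowest unit
index), and a bubble neighborhood whose radius shrinks linearly from 2/3 of
the maximum inter-unit grid distance to 0 while the learning rate decays
linearly (default 0.05 -> 0.01 over 100 iterations).  Hexagonal grids use
odd-row offset coordinates converted to cube coordinates for inter-unit
distances; rectangular grids use Euclidean distance on (row, col).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .io_formats import DEFAULT_ORGANS

__all__ = [
    "ScaledProfileMatrix",
    "PcaResult",
    "SomModel",
    "average_replicates",
    "scale_rows",
    "pca",
    "train_som",
    "node_summary",
]

log = logging.getLogger(__name__)


def average_replicates(values: pd.DataFrame, sheet: pd.Series,
                       organ_order: tuple[str, ...] = DEFAULT_ORGANS
                       ) -> pd.DataFrame:
    """Arithmetic mean of normalized values per pseudo-organ.

    ``values`` is transcripts × samples (e.g. CPM); columns are grouped by
    the sample sheet.  Every organ present keeps the configured order.
    """
    organs = [o for o in organ_order if o in set(sheet.loc[values.columns])]
    if not organs:
        raise ValueError("no sample maps to a known pseudo-organ")
    out = {}
    for organ in organs:
        cols = [s for s in values.columns if sheet[s] == organ]
        if not cols:
            raise ValueError(f"pseudo-organ {organ!r} has no samples")
        out[organ] = values[cols].mean(axis=1)
    return pd.DataFrame(out, index=values.index)


@dataclass
class ScaledProfileMatrix:
    """Per-transcript accumulation profiles scaled to mean 0, variance 1."""

    values: pd.DataFrame                      # transcripts × organs
    dropped: list[str] = field(default_factory=list)   # constant rows removed

    @property
    def organ_labels(self) -> list[str]:
        return list(self.values.columns)


def scale_rows(matrix: pd.DataFrame) -> ScaledProfileMatrix:
    """Center and scale each row to mean 0 and unit (n-1) variance.

    Constant rows carry no profile shape and are dropped with a warning.
    """
    arr = matrix.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    const = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    if const.all():
        raise ValueError("every row is constant; nothing to scale")
    dropped = list(matrix.index[const])
    if dropped:
        log.warning("dropping %d constant row(s): %s%s", len(dropped),
                    dropped[:5], "..." if len(dropped) > 5 else "")
    scaled = (arr[~const] - mean[~const]) / sd[~const]
    return ScaledProfileMatrix(
        pd.DataFrame(scaled, index=matrix.index[~const],
                     columns=matrix.columns),
        dropped,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    """Column-centered SVD principal components."""

    scores: pd.DataFrame                 # observations × PCs
    loadings: pd.DataFrame               # variables × PCs
    explained_variance_ratio: np.ndarray
    means: pd.Series                     # column means removed before SVD


def pca(matrix: pd.DataFrame) -> PcaResult:
    """PCA of ``matrix`` treating rows as observations.

    Columns are centered (not scaled) and decomposed by SVD, matching the
    default behavior of standard PCA implementations.  Component signs are
    fixed so each loading's largest-magnitude entry is positive.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 observations and 2 variables")
    x = matrix.to_numpy(dtype=float)
    means = x.mean(axis=0)
    xc = x - means
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign convention
    signs = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    signs[signs == 0] = 1.0
    vt = vt * signs[:, None]
    u = u * signs[None, :]
    scores = u * s
    var = s**2 / max(matrix.shape[0] - 1, 1)
    ratio = var / var.sum() if var.sum() > 0 else var
    pcs = [f"PC{i+1}" for i in range(len(s))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=pcs),
        loadings=pd.DataFrame(vt.T, index=matrix.columns, columns=pcs),
        explained_variance_ratio=ratio,
        means=pd.Series(means, index=matrix.columns),
    )


# ---------------------------------------------------------------------------
# Self-organizing map
# ---------------------------------------------------------------------------

def _unit_distances(rows: int, cols: int, topology: str) -> np.ndarray:
    """Pairwise inter-unit grid distances, units indexed row-major."""
    coords = [(r, c) for r in range(rows) for c in range(cols)]
    n = len(coords)
    d = np.zeros((n, n))
    for i, (r1, c1) in enumerate(coords):
        for j, (r2, c2) in enumerate(coords):
            if topology == "hexagonal":
                # odd-r offset -> cube coordinates
                x1 = c1 - (r1 - (r1 & 1)) // 2
                x2 = c2 - (r2 - (r2 & 1)) // 2
                z1, z2 = r1, r2
                y1, y2 = -x1 - z1, -x2 - z2
                d[i, j] = (abs(x1 - x2) + abs(y1 - y2) + abs(z1 - z2)) / 2
            elif topology == "rectangular":
                d[i, j] = np.hypot(r1 - r2, c1 - c2)
            else:
                raise ValueError(f"unknown topology {topology!r}")
    return d


@njit(cache=False)
def _som_train(data, codebook, orders, alphas, radii, unit_dist):  # pragma: no cover
    n_iter = orders.shape[0]
    n, dim = data.shape
    n_units = codebook.shape[0]
    mean_dist = np.empty(n_iter)
    for it in range(n_iter):
        total = 0.0
        for k in range(n):
            i = orders[it, k]
            best = 0
            best_d = 1e300
            for u in range(n_units):
                s = 0.0
                for j in range(dim):
                    diff = data[i, j] - codebook[u, j]
                    s += diff * diff
                if s < best_d:      # strict: ties keep the lowest index
                    best_d = s
                    best = u
            total += np.sqrt(best_d)
            a = alphas[it]
            r = radii[it]
            for u in range(n_units):
                if unit_dist[best, u] <= r:
                    for j in range(dim):
                        codebook[u, j] += a * (data[i, j] - codebook[u, j])
        mean_dist[it] = total / n
    return mean_dist


def _quantization(data: np.ndarray, codebook: np.ndarray, full: bool = False):
    """Squared distances, nearest-unit assignment and mean quantization error."""
    diff = data[:, None, :] - codebook[None, :, :]
    d2 = np.einsum("iuj,iuj->iu", diff, diff)
    assignment = d2.argmin(axis=1)
    qe = float(np.sqrt(d2[np.arange(len(assignment)), assignment]).mean())
    return (d2, assignment, qe) if full else (None, assignment, qe)


@dataclass
class SomModel:
    """A trained self-organizing map over pseudo-organ profiles."""

    grid: tuple[int, int]
    topology: str
    codebook: pd.DataFrame            # units × organ labels
    assignment: pd.Series             # transcript -> unit index (row-major)
    distance: pd.Series               # transcript -> Euclidean distance
    mean_distance_per_iteration: np.ndarray
    alpha: tuple[float, float]
    n_iterations: int
    seed: int

    @property
    def n_units(self) -> int:
        return self.grid[0] * self.grid[1]


def train_som(
    spm: ScaledProfileMatrix | pd.DataFrame,
    grid: tuple[int, int] = (3, 2),
    topology: str = "hexagonal",
    n_iter: int = 100,
    alpha: tuple[float, float] = (0.05, 0.01),
    seed: int = 0,
    initial_radius: float | None = None,
    n_restarts: int = 20,
) -> SomModel:
    """Train an online SOM on scaled accumulation profiles.

    Defaults reproduce the atlas configuration: a 3×2 hexagonal grid,
    100 iterations, learning rate decaying 0.05 -> 0.01.  Online SOMs on
    small grids inherit the dead-unit local optima of competitive learning,
    so — as k-means implementations do — training is repeated
    ``n_restarts`` times from different seeded initializations and the
    codebook with the lowest mean quantization error is kept.  All restart
    seeds derive from ``seed``; the result is deterministic.
    """
    values = spm.values if isinstance(spm, ScaledProfileMatrix) else spm
    data = np.ascontiguousarray(values.to_numpy(dtype=float))
    rows, cols = grid
    n_units = rows * cols
    if data.shape[0] < n_units:
        raise ValueError(
            f"grid of {n_units} units larger than data ({data.shape[0]} rows)")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    unit_dist = _unit_distances(rows, cols, topology)
    if initial_radius is None:
        initial_radius = unit_dist.max() * 2.0 / 3.0

    t_frac = np.arange(n_iter) / max(n_iter - 1, 1)
    alphas = alpha[0] + (alpha[1] - alpha[0]) * t_frac
    radii = initial_radius * (1.0 - t_frac)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        init_idx = rng.choice(data.shape[0], size=n_units, replace=False)
        codebook = np.ascontiguousarray(data[init_idx].copy())
        orders = np.empty((n_iter, data.shape[0]), dtype=np.int64)
        for t in range(n_iter):
            orders[t] = rng.permutation(data.shape[0])
        mean_dist = _som_train(data, codebook, orders, alphas, radii,
                               unit_dist)
        qe = _quantization(data, codebook)[2]
        if best is None or qe < best[0]:
            best = (qe, codebook, mean_dist)

    _, codebook, mean_dist = best
    d2, assignment, _ = _quantization(data, codebook, full=True)
    distance = np.sqrt(d2[np.arange(len(assignment)), assignment])

    return SomModel(
        grid=grid,
        topology=topology,
        codebook=pd.DataFrame(codebook, columns=values.columns),
        assignment=pd.Series(assignment, index=values.index, name="node"),
        distance=pd.Series(distance, index=values.index, name="distance"),
        mean_distance_per_iteration=mean_dist,
        alpha=alpha,
        n_iterations=n_iter,
        seed=seed,
    )


def node_summary(model: SomModel, spm: ScaledProfileMatrix | pd.DataFrame
                 ) -> pd.DataFrame:
    """Per-node member count, median scaled profile, and organs above zero.

    The ``organs_above_zero`` column lists organs whose median scaled
    abundance among the node's members exceeds 0 (the textual labels of the
    atlas node profiles).  Empty nodes get count 0 and NA profiles.
    """
    values = spm.values if isinstance(spm, ScaledProfileMatrix) else spm
    records = []
    for unit in range(model.n_units):
        members = model.assignment.index[model.assignment == unit]
        rec: dict = {"node": unit, "n_members": len(members)}
        if len(members):
            med = values.loc[members].median(axis=0)
            above = [o for o in values.columns if med[o] > 0]
        else:
            med = pd.Series(np.nan, index=values.columns)
            above = []
        for o in values.columns:
            rec[f"median_{o}"] = med[o]
        rec["organs_above_zero"] = ",".join(above)
        records.append(rec)
    return pd.DataFrame(records).set_index("node")
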