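"""Cluster-number validation by repeated SOM partitioning and LDA reassignment.

For each candidate grid, the scaled profile matrix is partitioned by a SOM
many times under different random seeds.  After each run a linear
discriminant model is fit on the transcripts' scores for the first five
principal components against that run's cluster labels, and each cluster's
reassignment fraction is the share of its members the discriminants place
back into it.  Redundant clusterings (more clusters than distinct profile
densities) confuse the discriminants and drive the fractions down, so the
recommended cluster number is the largest one whose median fraction stays
high — a codified, overridable reading of the "drops before a plateau"
shape; the raw per-run fractions are always returned so other rules can be
applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .profiles_clustering import ScaledProfileMatrix, train_som

__all__ = [
    "LdaModel",
    "lda_fit",
    "lda_predict",
    "reassignment_fractions",
    "ValidationResult",
    "validate_cluster_numbers",
]

log = logging.getLogger(__name__)


@dataclass
class LdaModel:
    """Gaussian linear discriminant model with pooled covariance."""

    classes: np.ndarray
    means: np.ndarray          # classes × features
    cov_inv: np.ndarray        # pooled within-class covariance inverse
    log_priors: np.ndarray


def lda_fit(scores: np.ndarray | pd.DataFrame, labels,
            ridge: float = 1e-8, equal_priors: bool = False) -> LdaModel:
    """Fit Gaussian LDA (class means, pooled covariance, class priors).

    Classes with a single member cannot contribute to the within-class
    covariance and are excluded with a warning.  Priors are proportional to
    class size unless ``equal_priors``.  A ridge of ``ridge * trace/d`` is
    added to the pooled covariance to guard against collinear features.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    uniq, counts = np.unique(y, return_counts=True)
    keep = uniq[counts >= 2]
    if len(keep) < len(uniq):
        log.warning("excluding %d singleton class(es) from LDA",
                    len(uniq) - len(keep))
    if len(keep) < 2:
        raise ValueError("LDA needs at least 2 classes with >= 2 members")
    mask = np.isin(y, keep)
    x, y = x[mask], y[mask]

    d = x.shape[1]
    means = np.vstack([x[y == c].mean(axis=0) for c in keep])
    pooled = np.zeros((d, d))
    for c, mu in zip(keep, means):
        xc = x[y == c] - mu
        pooled += xc.T @ xc
    pooled /= (len(x) - len(keep))
    pooled += np.eye(d) * ridge * np.trace(pooled) / d
    cov_inv = linalg.inv(pooled)

    sizes = np.array([(y == c).sum() for c in keep], dtype=float)
    priors = np.full(len(keep), 1.0 / len(keep)) if equal_priors \
        else sizes / sizes.sum()
    return LdaModel(classes=keep, means=means, cov_inv=cov_inv,
                    log_priors=np.log(priors))


def lda_predict(model: LdaModel, scores: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Class with maximal linear discriminant score for each row."""
    x = np.asarray(scores, dtype=float)
    # linear discriminant: x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 + log prior
    w = model.cov_inv @ model.means.T                       # d × classes
    const = -0.5 * np.einsum("cd,dc->c", model.means, w) + model.log_priors
    return model.classes[np.argmax(x @ w + const, axis=1)]


def reassignment_fractions(scores, labels, model: LdaModel) -> pd.Series:
    """Per-class fraction of members re-predicted into their own class."""
    y = np.asarray(labels)
    pred = lda_predict(model, scores)
    fracs = {}
    for c in model.classes:
        members = y == c
        fracs[c] = float((pred[members] == c).mean())
    return pd.Series(fracs, name="reassignment_fraction")


@dataclass
class ValidationResult:
    """Long-format reassignment fractions plus the heuristic recommendation."""

    records: pd.DataFrame      # columns: grid, n_clusters, run, seed, cluster, fraction
    n_runs: int
    recommended_k: int
    medians: pd.Series         # per candidate cluster count


def validate_cluster_numbers(
    spm: ScaledProfileMatrix | pd.DataFrame,
    pc_scores: pd.DataFrame,
    grids: list[tuple[int, int]],
    n_runs: int = 100,
    master_seed: int = 0,
    n_pcs: int = 5,
    threshold: float = 0.8,
    tolerance: float = 0.05,
    topology: str = "hexagonal",
    n_iter: int = 100,
    alpha: tuple[float, float] = (0.05, 0.01),
    n_restarts: int = 1,
) -> ValidationResult:
    """Repeated SOM partitioning + LDA reassignment over candidate grids.

    ``pc_scores`` are the transcripts' PCA scores; the first ``n_pcs``
    columns are used (five by default — the last organ-profile PC carries
    negligible variance once rows are scaled and would make the pooled
    covariance singular).  Seeds for each run derive deterministically from
    ``master_seed`` via a counter, so results are bit-reproducible.  Each
    run is a single SOM training (``n_restarts=1``): the run-to-run
    variability of the partitions under random seeds is part of what the
    procedure measures.

    ``recommended_k`` is the largest cluster count whose median fraction is
    >= ``threshold`` and within ``tolerance`` of the median at the smallest
    grid.  This rule is a heuristic; use ``records`` to apply another.
    """
    if not grids:
        raise ValueError("empty grid list")
    values = spm.values if isinstance(spm, ScaledProfileMatrix) else spm
    x = pc_scores.loc[values.index].iloc[:, :n_pcs]

    rows_out = []
    counter = 0
    for grid in grids:
        k = grid[0] * grid[1]
        for run in range(n_runs):
            seed = (master_seed * 1_000_003 + counter) % (2**31 - 1)
            counter += 1
            model = train_som(values, grid=grid, topology=topology,
                              n_iter=n_iter, alpha=alpha, seed=seed,
                              n_restarts=n_restarts)
            labels = model.assignment.to_numpy()
            if len(np.unique(labels)) < 2:
                log.warning("grid %s run %d collapsed to one cluster; skipped",
                            grid, run)
                continue
            lda = lda_fit(x.to_numpy(), labels)
            fracs = reassignment_fractions(x.to_numpy(), labels, lda)
            for cluster, frac in fracs.items():
                rows_out.append({
                    "grid": f"{grid[0]}x{grid[1]}", "n_clusters": k,
                    "run": run, "seed": seed,
                    "cluster": int(cluster), "fraction": frac,
                })
    records = pd.DataFrame(rows_out)
    medians = records.groupby("n_clusters")["fraction"].median()
    baseline = medians.loc[medians.index.min()]
    ok = medians[(medians >= threshold) & (medians >= baseline - tolerance)]
    recommended = int(ok.index.max()) if len(ok) else int(medians.index.min())
    return ValidationResult(records=records, n_runs=n_runs,
                            recommended_k=recommended, medians=medians)
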