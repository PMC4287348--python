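"""Shared fixtures: a small synthetic atlas run through the core pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from siphonatlas import (
    average_replicates,
    cpm,
    de_union,
    filter_low_counts,
    pairwise_de,
    scale_rows,
    tmm_factors,
    train_som,
)
from siphonatlas.profiles_clustering import pca
from siphonatlas.synthetic_data import generate_atlas


@pytest.fixture(scope="session")
def atlas():
    """Default synthetic atlas (counts + planted truth), fixed seed."""
    cm, truth = generate_atlas(seed=1)
    return cm, truth


@pytest.fixture(scope="session")
def pipeline_products(atlas):
    """Filter → TMM → DE → average → scale → PCA → SOM on the default atlas."""
    cm, truth = atlas
    cm_f = filter_low_counts(cm)
    factors = tmm_factors(cm_f)
    nm = cpm(cm_f, factors)
    de = pairwise_de(cm_f, factors)
    union = de_union(de, cm_f.organs)
    avg = average_replicates(nm.values.loc[union], cm_f.sample_sheet)
    spm = scale_rows(avg)
    model = train_som(spm, seed=1)
    return {
        "cm": cm_f, "truth": truth, "factors": factors, "nm": nm,
        "de": de, "union": union, "avg": avg, "spm": spm,
        "pca": pca(spm.values), "som": model,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def matched_agreement(assignment: pd.Series, truth_labels: pd.Series) -> float:
    """Best label-matched agreement (Hungarian) between a clustering and truth.

    Only transcripts with a planted node (label >= 0) count.
    """
    from scipy.optimize import linear_sum_assignment

    common = assignment.index.intersection(truth_labels.index)
    pred = assignment.loc[common].to_numpy()
    true = truth_labels.loc[common].to_numpy()
    mask = true >= 0
    pred, true = pred[mask], true[mask]
    n_pred = int(pred.max()) + 1
    n_true = int(true.max()) + 1
    c = np.zeros((n_pred, n_true))
    for p, t in zip(pred, true):
        c[p, t] += 1
    r, ccol = linear_sum_assignment(-c)
    return float(c[r, ccol].sum() / mask.sum())
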