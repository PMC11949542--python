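"""Interpreting compressed features against network metrics.

Every (feature, metric) pair is scored by mutual information estimated
with a k-nearest-neighbour (Kraskov-style) estimator for continuous data
(k = 3).  Significance comes from a permutation test (default 100
iterations, add-one p-value so 100 permutations can never report p = 0),
corrected across the pooled feature x metric family with the
Benjamini-Hochberg step-up.

Raw MI mostly reflects what all features share (a few metrics dominate
every feature).  To expose *variation among features*, MI values are
min-max normalised per metric across the features, and each feature is
assigned the metric with the highest normalised MI.  The headline summary
is the proportion of (feature, network) assignments falling in each
metric category (centrality / noncentrality / new).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_regression

from .exceptions import ConfigurationError
from .metrics import METRIC_CATEGORIES, MetricTable
from .nne import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "InterpretationResult",
    "mutual_information",
    "permutation_test",
    "bh_fdr",
    "normalize_mi",
    "assign_best_metric",
    "interpret_features",
    "aggregate_proportions",
]

CATEGORY_ORDER = ("centrality", "noncentrality", "new")


@dataclass
class InterpretationResult:
    """Feature-by-metric MI analysis for one network."""

    mi: pd.DataFrame                      # features x metrics, raw (nats)
    mi_normalized: pd.DataFrame           # min-max scaled per metric column
    p_values: pd.DataFrame | None
    q_values: pd.DataFrame | None
    best_metric: pd.Series                # per feature
    category_proportions: dict[str, float]
    constant_metrics: list[str] = field(default_factory=list)


def mutual_information(
    x: np.ndarray, y: np.ndarray, k: int = 3, seed: int = 0
) -> float:
    """kNN mutual-information estimate between two continuous vectors (nats).

    Negative estimates are clipped to 0; a constant input yields 0 with a
    warning.  Symmetric in its arguments up to estimator noise.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ConfigurationError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 10:
        raise ConfigurationError("need at least 10 samples for the kNN estimator")
    if k >= len(x):
        raise ConfigurationError("k must be smaller than the sample size")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input vector; mutual information set to 0")
        return 0.0
    mi = mutual_info_regression(
        x.reshape(-1, 1), y, n_neighbors=k, random_state=seed
    )[0]
    return float(max(mi, 0.0))


def permutation_test(
    x: np.ndarray, y: np.ndarray, n_perm: int = 100, seed: int = 0, k: int = 3
) -> tuple[float, float]:
    """Permutation p-value for MI(x, y).

    ``p = (1 + #{MI(x, shuffle(y)) >= MI(x, y)}) / (1 + n_perm)`` — the
    add-one form keeps p positive at finite permutation counts.  Returns
    ``(observed_mi, p)``.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    obs = mutual_information(x, y, k=k, seed=seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        if mutual_information(x, perm, k=k, seed=seed) >= obs:
            exceed += 1
    return obs, (1 + exceed) / (1 + n_perm)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over all entries pooled."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    q = multipletests(p.ravel(), method="fdr_bh")[1]
    return q.reshape(p.shape)


def normalize_mi(mi: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Min-max scale each metric column across features.

    A constant column carries no between-feature variation; it is set to
    all zeros and reported in the returned flag list.
    """
    if len(mi) < 2:
        raise ConfigurationError("need at least 2 features to normalise across")
    out = mi.copy().astype(float)
    constant = []
    for col in out.columns:
        v = out[col].to_numpy()
        rng_ = v.max() - v.min()
        if rng_ == 0:
            out[col] = 0.0
            constant.append(col)
        else:
            out[col] = (v - v.min()) / rng_
    if constant:
        logger.warning("constant MI column(s) flagged: %s", constant)
    return out, constant


def assign_best_metric(
    mi_normalized: pd.DataFrame,
    categories: dict[str, str] | None = None,
) -> tuple[pd.Series, dict[str, float]]:
    """Argmax metric per feature and category proportions.

    Ties break toward the earlier column (catalogue order) with a logged
    warning.  Proportions are over all features and sum to 1.
    """
    categories = categories or METRIC_CATEGORIES
    vals = mi_normalized.to_numpy()
    best_idx = vals.argmax(axis=1)
    for r, b in enumerate(best_idx):
        if (vals[r] == vals[r, b]).sum() > 1:
            logger.warning(
                "feature %s: tie for best metric, earlier column kept",
                mi_normalized.index[r],
            )
    best = pd.Series(
        [mi_normalized.columns[b] for b in best_idx],
        index=mi_normalized.index,
        name="best_metric",
    )
    counts = {c: 0 for c in CATEGORY_ORDER}
    for m in best:
        counts[categories[m]] += 1
    total = len(best)
    proportions = {c: counts[c] / total for c in CATEGORY_ORDER}
    return best, proportions


def interpret_features(
    features: FeatureMatrix,
    metric_table: MetricTable,
    k: int = 3,
    n_perm: int | None = 100,
    seed: int = 0,
) -> InterpretationResult:
    """Full MI pipeline for one network's features against its metric table.

    Set ``n_perm=None`` to skip significance testing (p/q left as None).
    """
    feats = features.to_frame()
    mets = metric_table.values
    mi = pd.DataFrame(
        np.zeros((feats.shape[1], mets.shape[1])),
        index=feats.columns,
        columns=mets.columns,
    )
    p = mi.copy() if n_perm else None
    for fi, fname in enumerate(feats.columns):
        for mi_i, mname in enumerate(mets.columns):
            x = feats[fname].to_numpy()
            y = mets[mname].to_numpy()
            pair_seed = seed + 1000 * fi + mi_i
            if n_perm:
                obs, pval = permutation_test(x, y, n_perm=n_perm, seed=pair_seed, k=k)
                p.loc[fname, mname] = pval
            else:
                obs = mutual_information(x, y, k=k, seed=pair_seed)
            mi.loc[fname, mname] = obs
    q = None
    if p is not None:
        q = pd.DataFrame(bh_fdr(p.to_numpy()), index=p.index, columns=p.columns)
    mi_norm, constant = normalize_mi(mi)
    best, proportions = assign_best_metric(mi_norm, metric_table.categories)
    return InterpretationResult(mi, mi_norm, p, q, best, proportions, constant)


def aggregate_proportions(
    results: Sequence[InterpretationResult],
) -> dict[str, float]:
    """Pool best-metric assignments over (feature, network) pairs.

    Each network contributes one assignment per feature; the proportions
    are counts over all pairs, normalised to sum to 1.
    """
    if not results:
        raise ConfigurationError("no interpretation results to aggregate")
    counts = {c: 0.0 for c in CATEGORY_ORDER}
    total = 0
    for r in results:
        for m in r.best_metric:
            counts[METRIC_CATEGORIES[m]] += 1
            total += 1
    return {c: counts[c] / total for c in CATEGORY_ORDER}
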