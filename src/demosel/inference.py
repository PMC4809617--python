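"""Applying a trained model: demography estimates, selection calls,
uncertainty summaries, and misspecification flags.

Three ways of combining the regions that share a demography into one
size estimate:

* ``average_stat``: average the feature vectors, one forward pass;
* ``final``: forward pass per region, then average the per-region size
  predictions (with across-region std and 2.5/97.5 percentiles);
* ``neutral_regions``: as ``final`` but restricted to regions whose
  selection call is neutral.

A region whose *normalized* size prediction falls outside [0, 1] for any
of the three sizes indicates that the data lie outside the range of the
training simulations; such regions are flagged and excluded from the
demography averaging (with a logged fallback to all regions if every
region is flagged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import Model, denormalize_targets, feed_forward
from .simdata import CLASS_NAMES

logger = logging.getLogger(__name__)

MODES = ("average_stat", "final", "neutral_regions")


@dataclass
class RegionCall:
    probs: np.ndarray          # (4,), sums to 1
    called: int                # argmax; ties -> lowest class index
    confidence: float
    tie: bool = False

    @property
    def name(self) -> str:
        return CLASS_NAMES[self.called]


@dataclass
class DemographyEstimate:
    sizes: np.ndarray               # (3,), individuals
    q_low: np.ndarray               # 2.5th percentile, or NaN
    q_high: np.ndarray              # 97.5th percentile, or NaN
    std: np.ndarray                 # across-region std, or NaN
    mode: str
    n_used: int
    n_flagged: int = 0


def _check_features(features: np.ndarray, model: Model) -> np.ndarray:
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.arch.n_inputs:
        raise ValueError(f"feature length {X.shape[1]} does not match the "
                         f"model contract ({model.arch.n_inputs})")
    return X


def raw_normalized_predictions(features: np.ndarray, model: Model) -> np.ndarray:
    """Per-region normalized size predictions (m, 3), unclamped."""
    X = _check_features(features, model)
    return feed_forward(X, model.weights).linear


def flag_misspecification(raw_normalized: np.ndarray) -> np.ndarray:
    """Boolean (m, 3): prediction outside [0, 1] per size."""
    raw = np.atleast_2d(raw_normalized)
    return (raw < 0.0) | (raw > 1.0)


def classify_region(features: np.ndarray, model: Model) -> RegionCall:
    X = _check_features(features, model)
    probs = feed_forward(X, model.weights).probs[0]
    top = float(probs.max())
    winners = np.flatnonzero(probs == top)
    tie = winners.size > 1
    if tie:
        logger.info("classification tie between classes %s; calling the "
                    "lowest index", winners.tolist())
    return RegionCall(probs, int(winners[0]), top, tie)


def classify_many(features: np.ndarray, model: Model) -> np.ndarray:
    """Called class per region (ties -> lowest index)."""
    X = _check_features(features, model)
    probs = feed_forward(X, model.weights).probs
    return probs.argmax(axis=1)


def _unflagged(features: np.ndarray, model: Model,
               exclude_flagged: bool) -> tuple[np.ndarray, int]:
    X = _check_features(features, model)
    if not exclude_flagged:
        return X, 0
    flags = flag_misspecification(raw_normalized_predictions(X, model))
    bad = flags.any(axis=1)
    if bad.all():
        logger.warning("all %d regions flagged as out of the simulated "
                       "range; using all of them", X.shape[0])
        return X, 0
    return X[~bad], int(bad.sum())


def predict_average_stat(regions_features: np.ndarray, model: Model,
                         *, exclude_flagged: bool = True) -> DemographyEstimate:
    """Average the feature vectors, then one forward pass."""
    X, n_flagged = _unflagged(regions_features, model, exclude_flagged)
    if X.shape[0] == 0:
        raise ValueError("no regions to predict from")
    raw = raw_normalized_predictions(X.mean(axis=0, keepdims=True), model)
    sizes = denormalize_targets(raw, model.config.prior_bounds)[0] * model.N_ref
    nan3 = np.full(3, np.nan)
    return DemographyEstimate(sizes, nan3, nan3, nan3, "average_stat",
                              X.shape[0], n_flagged)


def predict_final(regions_features: np.ndarray, model: Model,
                  *, exclude_flagged: bool = True) -> DemographyEstimate:
    """Per-region forward passes; mean, std and empirical 2.5/97.5
    percentiles (linear interpolation) of the per-region sizes."""
    X, n_flagged = _unflagged(regions_features, model, exclude_flagged)
    if X.shape[0] == 0:
        raise ValueError("no regions to predict from")
    raw = raw_normalized_predictions(X, model)
    sizes = denormalize_targets(raw, model.config.prior_bounds) * model.N_ref
    return DemographyEstimate(
        sizes.mean(axis=0),
        np.percentile(sizes, 2.5, axis=0),
        np.percentile(sizes, 97.5, axis=0),
        sizes.std(axis=0, ddof=0),
        "final", X.shape[0], n_flagged)


def predict_neutral_only(regions_features: np.ndarray, model: Model,
                         *, exclude_flagged: bool = True) -> DemographyEstimate:
    """As predict_final, restricted to regions called neutral; falls back
    to all regions (with a warning) when none are called neutral."""
    X = _check_features(regions_features, model)
    calls = classify_many(X, model)
    neutral = calls == 0
    if not neutral.any():
        logger.warning("no regions called neutral; falling back to all "
                       "%d regions", X.shape[0])
        est = predict_final(X, model, exclude_flagged=exclude_flagged)
    else:
        logger.info("using %d/%d regions called neutral",
                    int(neutral.sum()), X.shape[0])
        est = predict_final(X[neutral], model,
                            exclude_flagged=exclude_flagged)
    est.mode = "neutral_regions"
    return est


def predict(regions_features: np.ndarray, model: Model, mode: str,
            **kw) -> DemographyEstimate:
    if mode == "average_stat":
        return predict_average_stat(regions_features, model, **kw)
    if mode == "final":
        return predict_final(regions_features, model, **kw)
    if mode in ("neutral_regions", "neutral"):
        return predict_neutral_only(regions_features, model, **kw)
    raise ValueError(f"unknown prediction mode {mode!r}")
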