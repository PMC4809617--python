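"""End-to-end orchestration: simulate -> featurize -> split -> pretrain ->
fine-tune -> evaluate -> statistic importance.

Evaluation mirrors the standard report layout for this method: a
relative-error table per prediction mode (|N_est - N_true| / N_true,
averaged over test demographies), a 4x4 row-normalized confusion matrix
for the selection classes, and a hard-sweep breakdown by the realized
present-day frequency of the selected allele (low [0, 0.3), moderate
[0.3, 0.7), high [0.7, 1]).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import simdata
from .features import feature_names, featurize_many
from .importance import permutation_importance, perturbation_importance
from .inference import classify_many, predict
from .network import Architecture, Model, TrainConfig, normalize_targets, train_model
from .simdata import CLASS_NAMES, Corpus, CorpusConfig, DemographyParams, HARD, SimOptions

logger = logging.getLogger(__name__)

SIZE_COLUMNS = ("N_1 error", "N_2 error", "N_3 error")
MODE_ROWS = {"average_stat": "Average stat prediction",
             "final": "Final prediction",
             "neutral_regions": "Neutral regions prediction"}
FREQ_BINS = ((0.0, 0.3), (0.3, 0.7), (0.7, 1.0 + 1e-12))
FREQ_ROWS = ("Low", "Moderate", "High")


def split_corpus(corpus: Corpus, train_frac: float = 0.75,
                 seed: int = 0) -> tuple[Corpus, Corpus]:
    """Split by demography group; no group ever straddles the split."""
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must lie in (0, 1)")
    ids = np.unique(corpus.demography_ids)
    if ids.size < 2:
        raise ValueError("need at least 2 demography groups to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    n_train = int(round(train_frac * ids.size))
    n_train = min(max(n_train, 1), ids.size - 1)
    train_ids = set(perm[:n_train].tolist())
    train = [r for r in corpus.records if r.demography_id in train_ids]
    test = [r for r in corpus.records if r.demography_id not in train_ids]
    return (Corpus(train, corpus.master_seed, "train"),
            Corpus(test, corpus.master_seed, "test"))


def corpus_features(corpus: Corpus, expected_n: int = 100) -> np.ndarray:
    return featurize_many([r.region for r in corpus.records],
                          expected_n=expected_n)


def corpus_responses(corpus: Corpus, prior_bounds) -> np.ndarray:
    """(m, 7): normalized size factors + one-hot selection class."""
    lams = np.array([[r.demography.lambda1, r.demography.lambda2,
                      r.demography.lambda3] for r in corpus.records])
    z = normalize_targets(lams, prior_bounds)
    onehot = np.zeros((len(corpus.records), 4))
    for i, r in enumerate(corpus.records):
        onehot[i, r.selection.sel_class] = 1.0
    return np.hstack([z, onehot])


def demography_error_table(test: Corpus, X_test: np.ndarray,
                           model: Model) -> pd.DataFrame:
    """Mean relative error |N_est - N_true| / N_true per size and mode,
    averaged over the test demographies."""
    ids = test.demography_ids
    errors = {mode: [] for mode in MODE_ROWS}
    for dem_id in np.unique(ids):
        mask = ids == dem_id
        rec = test.records[int(np.flatnonzero(mask)[0])]
        truth = rec.demography.sizes
        for mode in MODE_ROWS:
            est = predict(X_test[mask], model, mode)
            errors[mode].append(np.abs(est.sizes - truth) / truth)
    table = pd.DataFrame(
        [np.mean(errors[mode], axis=0) for mode in MODE_ROWS],
        index=[MODE_ROWS[m] for m in MODE_ROWS], columns=list(SIZE_COLUMNS))
    return table


def confusion_table(test: Corpus, X_test: np.ndarray,
                    model: Model) -> tuple[pd.DataFrame, float]:
    """Row-normalized 4x4 confusion matrix and the overall
    misclassification fraction."""
    truth = np.array([r.selection.sel_class for r in test.records])
    called = classify_many(X_test, model)
    mat = np.zeros((4, 4))
    for t, c in zip(truth, called):
        mat[t, c] += 1
    rows = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(rows > 0, mat / rows, 0.0)
    table = pd.DataFrame(norm, index=list(CLASS_NAMES),
                         columns=list(CLASS_NAMES))
    overall = float(np.mean(called != truth))
    return table, overall


def sweep_frequency_table(test: Corpus, X_test: np.ndarray,
                          model: Model) -> pd.DataFrame:
    """Hard-sweep calls broken down by realized selected-allele frequency."""
    truth = np.array([r.selection.sel_class for r in test.records])
    called = classify_many(X_test, model)
    freqs = np.array([r.selection.end_freq for r in test.records])
    hard = truth == HARD
    rows = []
    for (lo, hi), label in zip(FREQ_BINS, FREQ_ROWS):
        mask = hard & (freqs >= lo) & (freqs < hi)
        row = {"fraction of datasets": (mask.sum() / hard.sum()
                                        if hard.any() else 0.0)}
        for k, name in enumerate(CLASS_NAMES):
            row[name] = float(np.mean(called[mask] == k)) if mask.any() else 0.0
        rows.append(row)
    return pd.DataFrame(rows, index=list(FREQ_ROWS))


def default_config() -> dict:
    """The reference study conditions (full scale; needs cluster-level
    compute to run end to end)."""
    return {
        "n_demographies": 2500, "regions_per_class": 40,
        "region_len": 100_000, "n": 100,
        "N_ref": 100_000.0, "mu": 8.4e-9, "r": 8.4e-9,
        "t1": 0.5, "t2": 5.0,
        "rescaled_N_ref": 1000.0, "burn_in_mult": 8.0,
        "prior_bounds": [[3.0, 14.0], [0.5, 6.0], [2.0, 10.0]],
        "hidden": [25, 25, 10],
        "lambda_decay": 1e-4, "rho": 0.25, "beta": 3.0,
        "max_iter": 400, "pretrain_max_iter": 200,
        "train_frac": 0.75, "seed": 0,
        "importance": True, "importance_k": 25,
        "pretrain": True,
    }


def small_reference_config() -> dict:
    """Scaled-down study conditions that run on a single workstation:
    100 demographies x 16 regions, a stronger rescaling (baseline
    rescaled size 100) and a proportionally reduced mutation/recombination
    rate (mu = r = 5e-11, i.e. theta about 1/170 of full scale) so that a
    region carries on the order of 10^2 segregating sites.  Priors,
    epoch times, sample size, region length, selection classes and s
    values are unchanged."""
    cfg = default_config()
    cfg.update({
        "n_demographies": 100, "regions_per_class": 4,
        "mu": 5e-11, "r": 5e-11,
        "rescaled_N_ref": 75.0, "burn_in_mult": 5.0,
        "max_iter": 800, "pretrain_max_iter": 200,
    })
    return cfg


def corpus_config_from(cfg: dict) -> CorpusConfig:
    return CorpusConfig(
        prior_bounds=tuple(tuple(b) for b in cfg["prior_bounds"]),
        region_len=int(cfg["region_len"]), n=int(cfg["n"]),
        demography_defaults=DemographyParams(
            1.0, 1.0, 1.0, N_ref=cfg["N_ref"], t1=cfg["t1"], t2=cfg["t2"],
            mu=cfg["mu"], r=cfg["r"]),
        options=SimOptions(rescaled_N_ref=cfg["rescaled_N_ref"],
                           burn_in_mult=cfg["burn_in_mult"]))


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None
                 ) -> dict:
    """Run every stage; returns an artifact dictionary and optionally
    writes tables, the model and the manifest under out_dir."""
    cfg = default_config()
    cfg.update(config or {})
    seed = int(cfg["seed"])
    artifacts: dict = {"config": dict(cfg)}
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s (seed %d)", name, seed)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    stage("simulate")
    corpus = simdata.generate_corpus(
        int(cfg["n_demographies"]), int(cfg["regions_per_class"]),
        corpus_config_from(cfg), seed=seed)
    done("simulate")

    stage("featurize")
    X = corpus_features(corpus, expected_n=int(cfg["n"]))
    done("featurize")

    stage("split")
    train, test = split_corpus(corpus, float(cfg["train_frac"]), seed=seed)
    train_mask = np.isin(corpus.demography_ids,
                         np.unique(train.demography_ids))
    X_train, X_test = X[train_mask], X[~train_mask]
    bounds = tuple(tuple(b) for b in cfg["prior_bounds"])
    Y_train = corpus_responses(train, bounds)
    done("split")

    stage("train")
    arch = Architecture(X.shape[1], tuple(int(h) for h in cfg["hidden"]))
    tc = TrainConfig(lambda_decay=float(cfg["lambda_decay"]),
                     rho=float(cfg["rho"]), beta=float(cfg["beta"]),
                     max_iter=int(cfg["max_iter"]),
                     pretrain_max_iter=int(cfg["pretrain_max_iter"]),
                     seed=seed, prior_bounds=bounds)
    model, info = train_model(X_train, Y_train, arch, tc,
                              pretrain=bool(cfg["pretrain"]),
                              N_ref=float(cfg["N_ref"]),
                              feature_names=feature_names(int(cfg["n"])))
    done("train")

    stage("evaluate")
    size_errors = demography_error_table(test, X_test, model)
    confusion, overall_mis = confusion_table(test, X_test, model)
    sweep_freq = sweep_frequency_table(test, X_test, model)
    done("evaluate")

    artifacts.update({
        "corpus": corpus, "features": X, "train": train, "test": test,
        "X_train": X_train, "X_test": X_test, "model": model,
        "train_info": info, "size_errors": size_errors,
        "confusion": confusion, "overall_misclassification": overall_mis,
        "sweep_frequency": sweep_freq,
    })

    if cfg.get("importance", True):
        stage("importance")
        lam_test = np.array([[r.demography.lambda1, r.demography.lambda2,
                              r.demography.lambda3] for r in test.records])
        cls_test = np.array([r.selection.sel_class for r in test.records])
        artifacts["importance_permutation"] = permutation_importance(
            model, X_test, lam_test, cls_test, k=int(cfg["importance_k"]),
            seed=seed)
        artifacts["importance_perturbation"] = perturbation_importance(
            model, X_test, k=int(cfg["importance_k"]))
        done("importance")

    artifacts["timings"] = timings
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        simdata.save_corpus(corpus, out_dir / "corpus")
        model.save(out_dir / "model.npz")
        size_errors.to_csv(out_dir / "size_errors.tsv", sep="\t")
        confusion.to_csv(out_dir / "confusion.tsv", sep="\t")
        sweep_freq.to_csv(out_dir / "sweep_frequency.tsv", sep="\t")
        if "importance_permutation" in artifacts:
            artifacts["importance_permutation"].scores.to_csv(
                out_dir / "importance_permutation.tsv", sep="\t")
            artifacts["importance_perturbation"].scores.to_csv(
                out_dir / "importance_perturbation.tsv", sep="\t")
        with open(out_dir / "run.json", "w") as fh:
            json.dump({"config": cfg,
                       "overall_misclassification": overall_mis,
                       "timings": timings}, fh, indent=2)
    return artifacts
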