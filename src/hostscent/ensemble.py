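"""Ensembles of random olfactory models and the trade-off analysis.

Each model of an ensemble is scored for fruit detectability (sum of antennal
responses over all fruit volatile samples), fruit-species discriminability
(out-of-bag proportion of samples correctly assigned to species by a random
forest on OR response patterns) and joint functionality (the product of the
two indices after rescaling each into [0, 1] around 0.5).  Two chemical-
tuning descriptors are computed per model: the point-biserial correlation of
the detection indicator with compound sharedness (r_prob), and the Pearson
correlation of the single-compound response amplitude at each probing dose
with sharedness over detected compounds (r_amp).  All indices are z-scored
within their configuration cell (OR count x compounds-per-OR level x input
dataset) before cross-cell comparison and the trade-off fits.

The out-of-bag scoring has two interchangeable random-forest engines:
``ranger`` (R, run once per ensemble as a batch; the default, and much the
fastest on these small response matrices) and ``sklearn`` (in-process).  Both
compute the same statistic; a test asserts their agreement.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .olfactory import (OlfactoryModel, sample_model, or_response_matrix,
                        single_compound_responses)

__all__ = [
    "LEVEL_MAP",
    "DEFAULT_PROBING_DOSES",
    "EnsembleConfig",
    "grid_configs",
    "detectability_index",
    "discriminability_index",
    "oob_scores_batch",
    "joint_functionality",
    "detection_sharedness_corr",
    "amplitude_sharedness_corr",
    "run_ensemble",
    "zscore_cell",
    "tradeoff_fit",
    "manifest",
]

# Compounds detected per OR for each (OR count, level) cell of the grid.
LEVEL_MAP: dict[int, dict[str, int]] = {
    10: {"low": 10, "medium": 20, "high": 60},
    20: {"low": 5, "medium": 10, "high": 30},
}

# Probing doses for the amplitude-sharedness correlations: even coverage of
# the 0-5 log-unit stimulus range.
DEFAULT_PROBING_DOSES: tuple[float, ...] = (1.25, 2.5, 3.75, 5.0)

_RANGER_SCRIPT = """\
args <- commandArgs(trailingOnly = TRUE)
dir <- args[1]
suppressMessages(library(ranger))
meta <- scan(file.path(dir, "meta.txt"), what = integer(), quiet = TRUE)
nm <- meta[1]; n <- meta[2]; p <- meta[3]; ntree <- meta[4]
y <- factor(readLines(file.path(dir, "y.txt")))
seeds <- scan(file.path(dir, "seeds.txt"), what = integer(), quiet = TRUE)
con <- file(file.path(dir, "X.bin"), "rb")
X <- matrix(readBin(con, "double", nm * n * p), nrow = nm * n, ncol = p)
close(con)
colnames(X) <- paste0("or", seq_len(p))
scores <- numeric(nm)
for (m in seq_len(nm)) {
  Xi <- X[((m - 1) * n + 1):(m * n), , drop = FALSE]
  fit <- ranger(x = Xi, y = y, num.trees = ntree, num.threads = 1,
                seed = seeds[m])
  scores[m] <- 1 - fit$prediction.error
}
writeLines(sprintf("%.10f", scores), file.path(dir, "scores.txt"))
"""


@dataclass(frozen=True)
class EnsembleConfig:
    """One configuration cell of the model grid."""

    n_ors: int = 10
    level: str = "medium"
    dataset_id: str = "intact"
    n_models: int = 10_000
    master_seed: int = 0
    probing_doses: tuple[float, ...] = DEFAULT_PROBING_DOSES
    rf_trees: int = 1000
    compute_discriminability: bool = True
    rf_backend: str = "ranger"

    def __post_init__(self) -> None:
        if self.n_ors not in LEVEL_MAP:
            raise ValueError(f"n_ors must be one of {sorted(LEVEL_MAP)}")
        if self.level not in LEVEL_MAP[self.n_ors]:
            raise ValueError("level must be 'low', 'medium' or 'high'")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.rf_backend not in ("ranger", "sklearn"):
            raise ValueError("rf_backend must be 'ranger' or 'sklearn'")

    @property
    def compounds_per_or(self) -> int:
        return LEVEL_MAP[self.n_ors][self.level]


def grid_configs(n_models: int = 10_000, master_seed: int = 0,
                 datasets: tuple[str, ...] = ("intact", "sliced"),
                 **kwargs) -> list[EnsembleConfig]:
    """The full 2 x 3 x 2 grid of configuration cells (12 cells)."""
    configs = []
    cell = 0
    for n_ors in sorted(LEVEL_MAP):
        for level in ("low", "medium", "high"):
            for ds in datasets:
                configs.append(EnsembleConfig(
                    n_ors=n_ors, level=level, dataset_id=ds,
                    n_models=n_models, master_seed=master_seed + cell,
                    **kwargs))
                cell += 1
    return configs


def detectability_index(model: OlfactoryModel,
                        dose_matrix: pd.DataFrame) -> float:
    """Sum of total antennal responses over all volatile samples."""
    if len(dose_matrix) < 1:
        raise ValueError("detectability needs at least one sample")
    return float(or_response_matrix(model, dose_matrix).sum())


def _check_labels(species: np.ndarray) -> int:
    classes, counts = np.unique(species, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 species with >= 2 samples each")
    return len(classes)


def discriminability_index(or_responses: np.ndarray,
                           species: np.ndarray,
                           rf_trees: int = 1000,
                           seed: int = 0) -> tuple[float, bool]:
    """Out-of-bag proportion of samples correctly classified to species.

    A random forest (``rf_trees`` trees) classifies the per-sample OR-activity
    vectors into fruit species; the index is 1 minus the out-of-bag error.  A
    constant feature matrix carries no information: the index falls back to
    the chance level (1 / number of species) and is flagged degenerate.
    """
    species = np.asarray(species)
    n_classes = _check_labels(species)
    if np.allclose(np.asarray(or_responses).std(axis=0), 0.0):
        return 1.0 / n_classes, True
    rf = RandomForestClassifier(n_estimators=rf_trees, oob_score=True,
                                n_jobs=1, random_state=seed)
    rf.fit(or_responses, species)
    return float(rf.oob_score_), False


def oob_scores_batch(response_stack: np.ndarray, species: np.ndarray,
                     rf_trees: int, seeds: np.ndarray,
                     backend: str = "ranger") -> tuple[np.ndarray, np.ndarray]:
    """OOB proportion-correct for a stack of (n, n_ors) response matrices.

    Returns (scores, degenerate flags).  Models with a constant response
    matrix get the chance level and a flag without touching the forest.
    """
    species = np.asarray(species)
    n_classes = _check_labels(species)
    n_models = response_stack.shape[0]
    degenerate = np.array([np.allclose(m.std(axis=0), 0.0)
                           for m in response_stack])
    scores = np.full(n_models, 1.0 / n_classes)
    todo = np.flatnonzero(~degenerate)
    if todo.size == 0:
        return scores, degenerate
    if backend == "sklearn":
        for m in todo:
            scores[m], _ = discriminability_index(
                response_stack[m], species, rf_trees=rf_trees,
                seed=int(seeds[m]))
        return scores, degenerate
    if backend != "ranger":
        raise ValueError("backend must be 'ranger' or 'sklearn'")
    with tempfile.TemporaryDirectory() as tmp:
        tmpdir = Path(tmp)
        sub = response_stack[todo]
        n, p = sub.shape[1], sub.shape[2]
        np.asarray(sub, dtype=np.float64).reshape(-1, p).flatten(
            order="F").tofile(tmpdir / "X.bin")
        (tmpdir / "meta.txt").write_text(
            f"{len(todo)} {n} {p} {rf_trees}\n")
        (tmpdir / "y.txt").write_text(
            "\n".join(map(str, species)) + "\n")
        (tmpdir / "seeds.txt").write_text(
            "\n".join(str(int(seeds[m])) for m in todo) + "\n")
        script = tmpdir / "oob.R"
        script.write_text(_RANGER_SCRIPT)
        proc = subprocess.run(["Rscript", "--vanilla", str(script),
                               str(tmpdir)], capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                "ranger OOB scoring failed (is R with the ranger package "
                f"available?):\n{proc.stderr}")
        got = np.loadtxt(tmpdir / "scores.txt")
    scores[todo] = np.atleast_1d(got)
    return scores, degenerate


def joint_functionality(detectability: np.ndarray,
                        discriminability: np.ndarray,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Product of the two indices after rescaling each into [0, 1].

    Each index is standardized over the ensemble, then mapped to
    0.5 + z * s with s = 0.5 / max|z|, which guarantees mean 0.5 and range
    within [0, 1].  Returns (J, rescaled detectability, rescaled
    discriminability).
    """
    out = []
    for name, v in (("detectability", detectability),
                    ("discriminability", discriminability)):
        v = np.asarray(v, float)
        sd = v.std(ddof=0)
        if np.isclose(sd, 0.0):
            raise ValueError(f"{name} is constant over the ensemble")
        z = (v - v.mean()) / sd
        out.append(0.5 + z * (0.5 / np.abs(z).max()))
    return out[0] * out[1], out[0], out[1]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def detection_sharedness_corr(model: OlfactoryModel,
                              sharedness: pd.Series) -> float:
    """Point-biserial correlation of the detection indicator with sharedness.

    Computed over every compound of the universe; NaN when the indicator is
    constant (the model detects all compounds or none).
    """
    s = sharedness.reindex(model.universe).to_numpy(float)
    if len(s) < 3 or np.isnan(s).any():
        raise ValueError("sharedness must cover the compound universe")
    indicator = np.zeros(len(model.universe))
    indicator[np.unique(model.idx)] = 1.0
    return _pearson(indicator, s)


def amplitude_sharedness_corr(model: OlfactoryModel, sharedness: pd.Series,
                              dose: float) -> float:
    """Pearson correlation of single-compound response amplitude at ``dose``
    with sharedness, over detected compounds only; NaN when fewer than three
    compounds are detected or the responses have zero variance."""
    resp = single_compound_responses(model, dose)
    det = np.zeros(len(model.universe), dtype=bool)
    det[np.unique(model.idx)] = True
    if det.sum() < 3:
        return np.nan
    s = sharedness.reindex(model.universe).to_numpy(float)
    return _pearson(resp.to_numpy()[det], s[det])


def run_ensemble(config: EnsembleConfig, dose_matrix: pd.DataFrame,
                 species: pd.Series, sharedness: pd.Series) -> pd.DataFrame:
    """Sample, score and correlate ``config.n_models`` random models.

    ``dose_matrix`` is the processed stimulus matrix (samples x compounds,
    NaN = absent); ``species`` labels its rows; ``sharedness`` is indexed by
    compound.  Per-model RNG substreams derive from the master seed and model
    index, so any single model can be replayed in isolation.  Returns one row
    per model with within-cell z-scores appended.
    """
    universe = dose_matrix.columns
    species_arr = species.to_numpy()
    records = []
    stack = (np.empty((config.n_models, len(dose_matrix), config.n_ors),
                      dtype=np.float64)
             if config.compute_discriminability else None)
    rf_seeds = np.empty(config.n_models, dtype=np.int64)
    for m in range(config.n_models):
        rng = np.random.default_rng([config.master_seed, m])
        model = sample_model(config.n_ors, config.compounds_per_or, universe,
                             rng, model_id=m)
        responses = or_response_matrix(model, dose_matrix)
        rf_seeds[m] = int(rng.integers(1, 2**31))
        if stack is not None:
            stack[m] = responses
        rec = {
            "model_id": m,
            "n_ors": config.n_ors,
            "level": config.level,
            "dataset_id": config.dataset_id,
            "detectability": float(responses.sum()),
            "r_prob": detection_sharedness_corr(model, sharedness),
        }
        for dose in config.probing_doses:
            rec[f"r_amp_{dose:g}"] = amplitude_sharedness_corr(
                model, sharedness, dose)
        records.append(rec)
    metrics = pd.DataFrame(records)
    if stack is not None:
        scores, degen = oob_scores_batch(stack, species_arr,
                                         config.rf_trees, rf_seeds,
                                         backend=config.rf_backend)
        metrics["discriminability"] = scores
        metrics["degenerate"] = degen
        j, _, _ = joint_functionality(metrics["detectability"].to_numpy(),
                                      metrics["discriminability"].to_numpy())
        metrics["joint"] = j
    return zscore_cell(metrics)


def zscore_cell(metrics: pd.DataFrame) -> pd.DataFrame:
    """Append within-cell z-scores for every index and correlation column."""
    metrics = metrics.copy()
    cols = ["detectability", "discriminability", "joint", "r_prob"]
    cols += [c for c in metrics.columns if c.startswith("r_amp_")]
    for c in cols:
        if c not in metrics.columns:
            continue
        v = metrics[c].to_numpy(float)
        sd = np.nanstd(v, ddof=0)
        metrics[f"z_{c}"] = (v - np.nanmean(v)) / sd if sd > 0 else np.nan
    return metrics


def _ols_report(y: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> dict:
    import statsmodels.api as sm

    X = sm.add_constant(np.column_stack([x1, x2, x1 * x2]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient trade-off design")
    fit = sm.OLS(y, X).fit()
    names = ["intercept", "r_prob", "r_amp", "interaction"]
    return {
        "coef": dict(zip(names, fit.params.tolist())),
        "p": dict(zip(names, fit.pvalues.tolist())),
        "F": float(fit.fvalue),
        "F_p": float(fit.f_pvalue),
        "n": int(fit.nobs),
    }


def tradeoff_fit(metrics: pd.DataFrame,
                 amp_col: str = "r_amp_2.5",
                 indices: tuple[str, ...] = ("detectability",
                                             "discriminability", "joint"),
                 top_fraction: float = 0.1,
                 min_models: int = 100) -> dict:
    """Linear fits of the z-scored indices on the two tuning correlations.

    For each index, fits z(index) ~ z(r_prob) * z(r_amp) (main effects plus
    interaction) over models with defined correlations (models with undefined
    correlations are excluded listwise and counted), and summarizes the mean
    r_prob and r_amp among the top-``top_fraction`` models for that index —
    the chemical tuning of the most efficient systems.
    """
    cols = ["z_r_prob", f"z_{amp_col}", "r_prob", amp_col]
    sub = metrics.dropna(subset=[c for c in cols if c in metrics.columns])
    if len(sub) < min_models:
        raise ValueError(
            f"need >= {min_models} models with defined correlations")
    report: dict = {"n_models": len(sub), "amp_col": amp_col,
                    "excluded": int(len(metrics) - len(sub)), "fits": {}}
    x1 = sub["z_r_prob"].to_numpy(float)
    x2 = sub[f"z_{amp_col}"].to_numpy(float)
    for index in indices:
        col = f"z_{index}"
        if col not in sub.columns:
            continue
        fit = _ols_report(sub[col].to_numpy(float), x1, x2)
        top = sub.nlargest(max(1, int(round(top_fraction * len(sub)))), col)
        fit["top_decile"] = {
            "mean_r_prob": float(top["r_prob"].mean()),
            "mean_r_amp": float(top[amp_col].mean()),
            "ensemble_mean_r_prob": float(sub["r_prob"].mean()),
            "ensemble_mean_r_amp": float(sub[amp_col].mean()),
        }
        report["fits"][index] = fit
    return report


def manifest(configs: list[EnsembleConfig]) -> dict:
    """Run manifest: grid arithmetic and per-cell configuration."""
    return {
        "n_cells": len(configs),
        "n_models_total": int(sum(c.n_models for c in configs)),
        "cells": [asdict(c) for c in configs],
    }
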