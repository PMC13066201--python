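"""Volatilome preprocessing: control filter, normalization, dose mapping.

The chain is order-fixed: control-based compound exclusion (one-sided
rank-sum test, control > fruit), per-sample geometric-mean normalization,
Box-Cox transform (lambda = 0.014) with per-compound Pareto scaling, and an
affine mapping of the detected transformed values onto a 0-5 log-dose scale.
Undetected entries are carried as NaN ("absent"), never as dose 0 — dose 0 is
a valid weak stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .synthetic import VolatilomeDataset

__all__ = [
    "ProcessedVolatilome",
    "control_filter",
    "geometric_mean_normalize",
    "boxcox_pareto",
    "detection_matrix",
    "to_dose_scale",
    "preprocess",
]

DOSE_RANGE = (0.0, 5.0)  # log units spanned by the model's stimulus space


@dataclass
class ProcessedVolatilome:
    """Model-ready stimuli and the provenance of excluded compounds."""

    transformed: pd.DataFrame  # samples x retained compounds; NaN = absent
    detection: pd.DataFrame  # binary, same shape
    dose: pd.DataFrame  # [0, 5] where detected, NaN = absent
    exclusions: pd.DataFrame  # compound_id, reason, p_value
    flags: dict = field(default_factory=dict)


def control_filter(data: VolatilomeDataset, alpha: float = 0.05,
                   ) -> tuple[set[str], pd.DataFrame]:
    """Exclude compounds whose control abundance exceeds fruit abundance.

    A compound is excluded when a one-sided rank-sum test supports
    control > fruit at level ``alpha`` (exact null distribution when both
    groups have <= 10 observations and no ties, normal approximation with tie
    correction otherwise).  Compounds absent from every sample of both groups
    cannot be control-dominated and are retained, flagged untestable.

    Returns the exclusion set and a per-compound report with p-values.
    """
    if len(data.control) < 1:
        raise ValueError("control filter needs at least one control sample")
    records = []
    excluded: set[str] = set()
    for cid in data.abundance.columns:
        ctrl = data.control[cid].to_numpy(float)
        fruit = data.abundance[cid].to_numpy(float)
        if not (ctrl > 0).any() and not (fruit > 0).any():
            records.append((cid, "untestable", np.nan))
            continue
        pooled = np.concatenate([ctrl, fruit])
        exact = (len(ctrl) <= 10 and len(fruit) <= 10
                 and len(np.unique(pooled)) == len(pooled))
        res = stats.mannwhitneyu(ctrl, fruit, alternative="greater",
                                 method="exact" if exact else "asymptotic")
        p = float(res.pvalue)
        if p < alpha:
            excluded.add(cid)
            records.append((cid, "control_dominated", p))
        else:
            records.append((cid, "retained", p))
    report = pd.DataFrame(records,
                          columns=["compound_id", "reason", "p_value"])
    return excluded, report


def geometric_mean_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample's positive entries by their geometric mean.

    Zeros (not detected) stay zero.  A sample with no positive entry has no
    geometric mean; that is an error naming the sample.
    """
    values = matrix.to_numpy(float).copy()
    for i, sample in enumerate(matrix.index):
        pos = values[i] > 0
        if not pos.any():
            raise ValueError(f"sample {sample!r} has no positive abundance")
        gm = np.exp(np.mean(np.log(values[i, pos])))
        values[i, pos] = values[i, pos] / gm
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


def boxcox_pareto(matrix: pd.DataFrame, lmbda: float = 0.014,
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Box-Cox transform positive entries, then Pareto scale per compound.

    The transform is (x**lmbda - 1)/lmbda (ln x at lmbda = 0); zeros are
    undefined under Box-Cox and become NaN (absent).  Pareto scaling centres
    each compound on its mean over detected entries and divides by the square
    root of its standard deviation; compounds with zero variance are centred
    only and reported in the returned flag list.
    """
    values = matrix.to_numpy(float)
    out = np.full_like(values, np.nan)
    pos = values > 0
    out[pos] = special.boxcox(values[pos], lmbda)
    flagged: list[str] = []
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # columns with a single detected entry have no ddof=1 variance; they
        # are centred-only below
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(pos, out, np.nan), axis=0)
        sd = np.nanstd(np.where(pos, out, np.nan), axis=0, ddof=1)
    for j, cid in enumerate(matrix.columns):
        col = out[:, j]
        det = ~np.isnan(col)
        if not det.any():
            continue
        if det.sum() < 2 or not np.isfinite(sd[j]) or np.isclose(sd[j], 0.0):
            out[det, j] = col[det] - mean[j]
            flagged.append(cid)
        else:
            out[det, j] = (col[det] - mean[j]) / np.sqrt(sd[j])
    return (pd.DataFrame(out, index=matrix.index, columns=matrix.columns),
            flagged)


def detection_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """1 where the raw abundance is positive, else 0."""
    return (matrix > 0).astype(int)


def to_dose_scale(transformed: pd.DataFrame, detection: pd.DataFrame,
                  minmax: tuple[float, float] | None = None,
                  ) -> tuple[pd.DataFrame, dict]:
    """Affine map of detected transformed values onto [0, 5] log units.

    The map sends the global minimum of the detected values to 0 and the
    global maximum to 5; ``minmax`` overrides those anchors so paired runs
    (intact / sliced) can share one stimulus scale.  Undetected entries stay
    NaN (absent).
    """
    det = detection.to_numpy() > 0
    vals = transformed.to_numpy(float)
    detected_vals = vals[det]
    if detected_vals.size == 0:
        raise ValueError("no detected entries to map onto the dose scale")
    lo, hi = minmax if minmax is not None else (
        float(np.min(detected_vals)), float(np.max(detected_vals)))
    flags = {"minmax": (lo, hi), "degenerate": False}
    lo_d, hi_d = DOSE_RANGE
    out = np.full_like(vals, np.nan)
    if np.isclose(hi, lo):
        out[det] = (lo_d + hi_d) / 2  # all equal: midpoint, flagged
        flags["degenerate"] = True
    else:
        out[det] = lo_d + (vals[det] - lo) * (hi_d - lo_d) / (hi - lo)
        out[det] = np.clip(out[det], lo_d, hi_d)
    return (pd.DataFrame(out, index=transformed.index,
                         columns=transformed.columns), flags)


def preprocess(data: VolatilomeDataset, alpha: float = 0.05,
               lmbda: float = 0.014,
               minmax: tuple[float, float] | None = None,
               ) -> ProcessedVolatilome:
    """Run the full fixed-order chain on one dataset."""
    excluded, report = control_filter(data, alpha=alpha)
    kept = [c for c in data.abundance.columns if c not in excluded]
    raw = data.abundance[kept]
    # Compounds never detected in any fruit sample cannot enter the stimulus
    # space (their sharedness is undefined); drop them with provenance.
    never = [c for c in kept if not (raw[c] > 0).any()]
    if never:
        raw = raw.drop(columns=never)
        extra = pd.DataFrame({"compound_id": never, "reason": "never_detected",
                              "p_value": np.nan})
        report = pd.concat([report[~report["compound_id"].isin(never)],
                            extra], ignore_index=True)
    det = detection_matrix(raw)
    norm = geometric_mean_normalize(raw)
    transformed, pareto_flags = boxcox_pareto(norm, lmbda=lmbda)
    dose, dose_flags = to_dose_scale(transformed, det, minmax=minmax)
    exclusions = report[report["reason"] != "retained"].reset_index(drop=True)
    return ProcessedVolatilome(
        transformed=transformed, detection=det, dose=dose,
        exclusions=exclusions,
        flags={"pareto_zero_variance": pareto_flags, **dose_flags,
               "alpha": alpha, "lambda": lmbda},
    )
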