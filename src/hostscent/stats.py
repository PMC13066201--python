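"""Partial-correlation statistics for antennal-response tables.

The chain mirrors a standard electrophysiology analysis: responses are made
log-equivalent by a shift-selected Box-Cox normalization, qualitative
covariates (individual, chemical class, ...) are removed from every
quantitative variable by linear-model residualization, a partial Pearson
correlation is computed controlling for the remaining quantitative
covariates, and case-resampling bootstrap (1000 samples) provides percentile
95% confidence intervals and a two-tailed test against zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PartialCorrResult",
    "shift_boxcox_normalize",
    "residualize",
    "partial_corr",
    "bootstrap_test",
    "recover_sharedness_correlation",
]

LAMBDA_TOL = 0.05  # |lambda| below which Box-Cox counts as log-equivalent


@dataclass
class PartialCorrResult:
    rho: float
    ci_low: float
    ci_high: float
    p_two_tailed: float
    n: int
    qualitative: tuple[str, ...] = ()
    quantitative: tuple[str, ...] = ()
    n_boot: int = 0
    flags: dict = field(default_factory=dict)


def shift_boxcox_normalize(responses: np.ndarray | pd.Series,
                           tol: float = LAMBDA_TOL,
                           ) -> tuple[np.ndarray, float, float, float, bool]:
    """Shift responses so that Box-Cox is log-equivalent, then log them.

    Searches a constant c > -min(x) such that the maximum-likelihood Box-Cox
    exponent of x + c lies within ``tol`` of 0, and returns
    (ln(x + c), c, lambda_at_c, shapiro_W, flagged).  When no shift in the
    bracket reaches |lambda| <= tol the best c found is used and the result
    is flagged.  Normality of the transformed values is summarized by the
    Shapiro-Wilk W statistic.
    """
    x = np.asarray(responses, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("responses must be finite")
    if np.isclose(x.std(ddof=0), 0.0):
        raise ValueError("responses are constant: no transform is defined")

    # c may be negative (down-shifting responses that sit above zero), as
    # long as every shifted value stays positive
    span = x.max() - x.min()
    lo = -x.min() + 1e-6 * max(span, 1.0)
    hi = 10.0 * span + 1.0

    def abs_lambda(c: float) -> float:
        return abs(float(sps.boxcox_normmax(x + c, method="mle")))

    from scipy.optimize import minimize_scalar
    res = minimize_scalar(abs_lambda, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-5 * (hi - lo)})
    c = float(res.x)
    # Already log-normal data qualifies with essentially no shift; prefer
    # that (keeps ln(x + c) close to ln x).
    near_zero = 1e-6 * max(span, 1.0)
    if x.min() > 0 and abs_lambda(near_zero) <= tol and abs(c) > near_zero:
        c = near_zero
    lam = float(sps.boxcox_normmax(x + c, method="mle"))
    flagged = abs(lam) > tol
    transformed = np.log(x + c)
    w = float(sps.shapiro(transformed).statistic) if len(x) >= 3 else np.nan
    return transformed, c, lam, w, flagged


def _dummy_design(qualitative: pd.DataFrame) -> np.ndarray:
    """Intercept plus drop-first dummy columns for each qualitative factor."""
    parts = [np.ones((len(qualitative), 1))]
    for col in qualitative.columns:
        d = pd.get_dummies(qualitative[col].astype("category"),
                           drop_first=True, dtype=float)
        if d.shape[1]:
            parts.append(d.to_numpy())
    return np.column_stack(parts)


def _residuals(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def residualize(y: np.ndarray | pd.Series,
                qualitative: pd.DataFrame) -> np.ndarray:
    """Least-squares residuals of y on qualitative factor dummies.

    A factor level observed once fits its own dummy exactly, so its residual
    is 0 by construction.
    """
    y = np.asarray(y, dtype=float)
    Z = _dummy_design(qualitative)
    return _residuals(y[:, None], Z)[:, 0]


def partial_corr(y, x, qualitative: pd.DataFrame | None = None,
                 quantitative: pd.DataFrame | None = None) -> float:
    """Partial Pearson correlation of y and x.

    Qualitative factors are removed from every quantitative variable by
    residualization first; the partial coefficient then controls for the
    (residualized) quantitative covariates.  With no covariates this reduces
    to the plain Pearson correlation.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    q = 0 if quantitative is None else quantitative.shape[1]
    if n <= q + 2:
        raise ValueError("too few observations for the requested controls")
    M = np.column_stack([y, x] + (
        [np.asarray(quantitative, dtype=float)] if q else []))
    if qualitative is not None and len(qualitative.columns):
        M = _residuals(M, _dummy_design(qualitative))
    if q:
        M[:, :2] = _residuals(M[:, :2],
                              np.column_stack([np.ones(n), M[:, 2:]]))
    sy, sx = M[:, 0].std(ddof=0), M[:, 1].std(ddof=0)
    if np.isclose(sy, 0.0) or np.isclose(sx, 0.0):
        raise ValueError("zero residual variance: partial correlation "
                         "undefined")
    return float(np.corrcoef(M[:, 0], M[:, 1])[0, 1])


def bootstrap_test(estimator, data: pd.DataFrame | np.ndarray, B: int = 1000,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[float, float, float, np.ndarray]:
    """Case-resampling bootstrap of ``estimator`` over the rows of ``data``.

    ``data`` may be a DataFrame or a plain array; the resampling unit is the
    observation row either way.  Returns (ci_low, ci_high, p_two_tailed,
    bootstrap estimates): percentile 95% interval and two-tailed p-value for
    a null of zero, floored at 1/B.  Raises if the estimator is undefined on
    more than 20% of resamples.
    """
    rng = rng or np.random.default_rng()
    n = len(data)
    take = (lambda idx: data.iloc[idx]) if isinstance(data, pd.DataFrame) \
        else (lambda idx: data[idx])
    estimates = np.full(B, np.nan)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            estimates[b] = estimator(take(idx))
        except (ValueError, np.linalg.LinAlgError):
            pass
    ok = np.isfinite(estimates)
    if ok.mean() < 0.8:
        raise ValueError("estimator undefined on more than 20% of resamples")
    est = estimates[ok]
    ci_low, ci_high = np.percentile(est, [2.5, 97.5])
    p = 2.0 * min((est <= 0).mean(), (est >= 0).mean())
    p = float(min(1.0, max(p, 1.0 / B)))
    return float(ci_low), float(ci_high), p, est


def recover_sharedness_correlation(eag: pd.DataFrame,
                                   sharedness: pd.Series,
                                   covariates: pd.DataFrame,
                                   B: int = 1000,
                                   rng: np.random.Generator | None = None,
                                   qualitative: tuple[str, ...] = (
                                       "individual_id", "chemical_class"),
                                   quantitative: tuple[str, ...] = (
                                       "atmospheric_lifetime",
                                       "depletion_rate"),
                                   ) -> PartialCorrResult:
    """Partial correlation of antennal response with compound sharedness.

    ``eag`` is a long table (individual_id, compound_id, response, ...);
    ``sharedness`` and ``covariates`` are indexed by compound.  Responses are
    shift-Box-Cox normalized once, merged with the compound-level variables,
    and the partial correlation (controlling for the qualitative and
    quantitative covariates) is bootstrapped over rows.
    """
    df = eag.copy()
    df["sharedness"] = df["compound_id"].map(sharedness)
    for col in set(qualitative) | set(quantitative):
        if col not in df.columns:
            df[col] = df["compound_id"].map(covariates[col])
    df = df.dropna(subset=["sharedness", "response"])
    transformed, shift, lam, w, flagged = shift_boxcox_normalize(
        df["response"].to_numpy())
    df["log_response"] = transformed

    qual_cols = [c for c in qualitative if df[c].nunique() > 1]

    rho = partial_corr(df["log_response"], df["sharedness"],
                       qualitative=df[qual_cols],
                       quantitative=df[list(quantitative)])

    # Bootstrap on a pre-assembled numeric design: identical estimator, but
    # the dummy expansion is done once instead of per resample.
    M = np.column_stack([df["log_response"].to_numpy(float),
                         df["sharedness"].to_numpy(float)]
                        + [df[c].to_numpy(float) for c in quantitative])
    Z = _dummy_design(df[qual_cols])
    A = np.column_stack([M, Z])
    k = M.shape[1]

    def estimator(rows: np.ndarray) -> float:
        Mb, Zb = rows[:, :k], rows[:, k:]
        R = _residuals(Mb, Zb)
        Q = np.column_stack([np.ones(len(R)), R[:, 2:]])
        R2 = _residuals(R[:, :2], Q)
        if np.isclose(R2[:, 0].std(), 0) or np.isclose(R2[:, 1].std(), 0):
            raise ValueError("zero residual variance")
        return float(np.corrcoef(R2[:, 0], R2[:, 1])[0, 1])

    ci_low, ci_high, p, _ = bootstrap_test(estimator, A, B=B, rng=rng)
    return PartialCorrResult(
        rho=rho, ci_low=ci_low, ci_high=ci_high, p_two_tailed=p, n=len(df),
        qualitative=tuple(qual_cols), quantitative=tuple(quantitative),
        n_boot=B,
        flags={"boxcox_shift": shift, "boxcox_lambda": lam,
               "shapiro_w": w, "boxcox_flagged": flagged},
    )
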