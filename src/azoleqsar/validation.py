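"""Model validation statistics for MLR QSAR: cross-validation (leave-one-out
and leave-many-out), Y-scrambling, the QUIK collinearity rule, and the Williams
plot applicability domain.

All routines take a plain descriptor matrix ``X`` (n × p, no intercept column)
and response ``y``; an intercept is always included in the fits.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import json
import numpy as np
import pandas as pd

from .errors import CollinearityError


def _design(X):
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.column_stack([np.ones(X.shape[0]), X])


def _hat_and_residuals(X, y):
    d = _design(X)
    y = np.asarray(y, dtype=float)
    n, pp = d.shape
    gram = d.T @ d
    if np.linalg.matrix_rank(gram) < pp:
        raise CollinearityError("singular design matrix in cross-validation")
    ginv = np.linalg.inv(gram)
    coef = ginv @ d.T @ y
    h = np.einsum("ij,jk,ik->i", d, ginv, d)
    resid = y - d @ coef
    return h, resid, coef, d


def q2_loo(X, y) -> float:
    """Leave-one-out cross-validated Q² = 1 − PRESS/TSS.

    Uses the leverage shortcut e_i/(1 − h_i) for the deleted residuals, which
    is algebraically identical to refitting n times.
    """
    y = np.asarray(y, dtype=float)
    h, resid, _, d = _hat_and_residuals(X, y)
    n, pp = d.shape
    if n <= pp + 1:
        raise ValueError(f"need n > p + 2 for LOO, got n={n}, p'={pp}")
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("constant response; Q2 undefined")
    return 1.0 - press / tss


def r2_score(X, y) -> float:
    """Training R² of the OLS fit (1 − RSS/TSS)."""
    y = np.asarray(y, dtype=float)
    _, resid, _, _ = _hat_and_residuals(X, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(resid @ resid) / tss


def q2_lmo(X, y, fraction: float = 0.30, iterations: int = 2000,
           seed: int = 0, aggregate: str = "mean") -> float:
    """Leave-many-out Q² over random iterations.

    Each iteration holds out ``round(n · fraction)`` compounds (at least one),
    refits on the remainder and scores 1 − PRESS_out/TSS_out with TSS_out taken
    about the training mean.  ``aggregate="mean"`` averages the per-iteration
    statistic (the convention of QSAR validation software); ``"pooled"`` forms
    1 − ΣPRESS/ΣTSS across iterations, which converges to Q²_LOO as the
    held-out fraction shrinks to one compound.  Degenerate splits (singular
    refit or zero TSS_out) are skipped.
    """
    if aggregate not in ("mean", "pooled"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    m = max(1, int(round(n * fraction)))
    if n - m < X.shape[1] + 2:
        raise ValueError(f"leave-out fraction {fraction} leaves too few compounds")
    rng = np.random.default_rng(seed)
    vals = []
    press_sum = tss_sum = 0.0
    for _ in range(iterations):
        out = rng.choice(n, size=m, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[out] = False
        try:
            d_in = _design(X[mask])
            coef, *_ = np.linalg.lstsq(d_in, y[mask], rcond=None)
        except np.linalg.LinAlgError:
            continue
        d_out = _design(X[~mask])
        press = float(np.sum((y[~mask] - d_out @ coef) ** 2))
        tss = float(np.sum((y[~mask] - y[mask].mean()) ** 2))
        if tss == 0:
            continue
        vals.append(1.0 - press / tss)
        press_sum += press
        tss_sum += tss
    if not vals:
        raise ValueError("no valid leave-many-out split")
    if aggregate == "pooled":
        return 1.0 - press_sum / tss_sum
    return float(np.mean(vals))


@dataclass
class YScrambleSummary:
    """Distribution of Q²_LOO after permuting the response."""

    iterations: int
    mean_q2: float | None
    max_q2: float | None
    q2_real: float | None
    empty: bool = False
    values: list[float] = field(default_factory=list, repr=False)

    @property
    def passes(self) -> bool | None:
        """Chance-correlation check: the best scrambled Q² stays well below
        (≥ 0.2 under) the real Q²_LOO."""
        if self.empty or self.q2_real is None:
            return None
        return self.max_q2 < self.q2_real - 0.2


def y_scramble(X, y, iterations: int = 2000, seed: int = 0) -> YScrambleSummary:
    """Y-scrambling: refit the same descriptors against permuted activities.

    Returns the scrambled-Q² distribution summary; an informative model shows a
    scrambled mean well below zero while the real Q²_LOO stays high.
    """
    if iterations == 0:
        return YScrambleSummary(iterations=0, mean_q2=None, max_q2=None,
                                q2_real=None, empty=True)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(iterations):
        vals.append(q2_loo(X, rng.permutation(y)))
    vals = np.array(vals)
    return YScrambleSummary(
        iterations=iterations,
        mean_q2=float(vals.mean()),
        max_q2=float(vals.max()),
        q2_real=float(q2_loo(X, y)),
        values=vals.tolist(),
    )


def k_correlation(M) -> float:
    """Multivariate K correlation of the columns of ``M``.

    From the eigenvalues λ_j of the column correlation matrix (m columns):
    K = Σ_j |λ_j/Σλ − 1/m| / (2(m−1)/m); 0 for mutually uncorrelated columns,
    1 for perfectly correlated ones.
    """
    if isinstance(M, pd.DataFrame):
        M = M.to_numpy(dtype=float)
    M = np.asarray(M, dtype=float)
    m = M.shape[1]
    if m < 2:
        raise ValueError("K correlation needs at least 2 columns")
    sd = M.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant column; correlation undefined")
    corr = np.corrcoef(M, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    frac = lam / lam.sum()
    return float(np.sum(np.abs(frac - 1.0 / m)) / (2.0 * (m - 1) / m))


def quik_delta(X, y) -> float:
    """QUIK rule ΔK = K_xy − K_xx.

    K_xy is the K correlation of the descriptors augmented with the response,
    K_xx that of the descriptors alone; models need ΔK ≥ 0.05 to be considered
    free of masked collinearity.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    k_xx = k_correlation(X)
    k_xy = k_correlation(np.hstack([X, y]))
    return k_xy - k_xx


#: QUIK acceptability threshold for ΔK
QUIK_THRESHOLD = 0.05


@dataclass
class WilliamsResult:
    """Leverages and standardized residuals with the two outlier rules:
    |standardized residual| > 3 (response) and h > h* = 3p′/n (structural)."""

    leverages: np.ndarray
    std_residuals: np.ndarray
    h_star: float
    response_outliers: np.ndarray
    structural_outliers: np.ndarray


def williams(X, y) -> WilliamsResult:
    """Williams-plot quantities for an OLS fit of y on X (with intercept)."""
    y = np.asarray(y, dtype=float)
    h, resid, _, d = _hat_and_residuals(X, y)
    n, pp = d.shape
    dof = n - pp
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    s = np.sqrt(float(resid @ resid) / dof)
    std_resid = resid / s if s > 0 else np.zeros_like(resid)
    h_star = 3.0 * pp / n
    return WilliamsResult(
        leverages=h,
        std_residuals=std_resid,
        h_star=h_star,
        response_outliers=np.abs(std_resid) > 3.0,
        structural_outliers=h > h_star,
    )


def error_metrics(y, y_hat) -> tuple[float, float]:
    """Mean absolute error and root mean square error."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size == 0 or y.size != y_hat.size:
        raise ValueError("need equal-length, non-empty vectors")
    e = y - y_hat
    return float(np.mean(np.abs(e))), float(np.sqrt(np.mean(e * e)))


@dataclass
class ValidationReport:
    """Full validation summary of one fitted MLR model."""

    r2: float
    q2_loo: float
    q2_lmo: float
    delta_k: float
    mae_train: float
    rmse_train: float
    mae_cv: float
    rmse_cv: float
    h_star: float
    leverages: list[float]
    std_residuals: list[float]
    response_outliers: list[bool]
    structural_outliers: list[bool]
    y_scrambling: YScrambleSummary | None = None
    flags: dict[str, bool] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        if self.y_scrambling is not None:
            payload["y_scrambling"].pop("values", None)
        text = json.dumps(payload, indent=2)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


def validate_model(X, y, lmo_fraction: float = 0.30, lmo_iterations: int = 2000,
                   scramble_iterations: int = 2000, seed: int = 0) -> ValidationReport:
    """Run the full validation battery on one descriptor matrix / response."""
    y = np.asarray(y, dtype=float)
    h, resid, coef, d = _hat_and_residuals(X, y)
    fitted = d @ coef
    mae_t, rmse_t = error_metrics(y, fitted)
    press_resid = resid / (1.0 - h)
    mae_cv, rmse_cv = error_metrics(y, y - press_resid)
    r2 = r2_score(X, y)
    q2 = q2_loo(X, y)
    lmo = q2_lmo(X, y, fraction=lmo_fraction, iterations=lmo_iterations, seed=seed)
    dk = quik_delta(X, y)
    wil = williams(X, y)
    scr = y_scramble(X, y, iterations=scramble_iterations, seed=seed)
    flags = {
        "quik_ok": dk >= QUIK_THRESHOLD,
        "scramble_ok": bool(scr.passes) if scr.passes is not None else False,
        "q2_ok": q2 > 0.55,
        "r2_ok": r2 > 0.7,
    }
    return ValidationReport(
        r2=r2, q2_loo=q2, q2_lmo=lmo, delta_k=dk,
        mae_train=mae_t, rmse_train=rmse_t, mae_cv=mae_cv, rmse_cv=rmse_cv,
        h_star=wil.h_star,
        leverages=wil.leverages.tolist(),
        std_residuals=wil.std_residuals.tolist(),
        response_outliers=wil.response_outliers.tolist(),
        structural_outliers=wil.structural_outliers.tolist(),
        y_scrambling=scr,
        flags=flags,
    )
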