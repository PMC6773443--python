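"""Nutritional-geometry fitness landscapes and selection gradients.

Fitness is Z-standardized within each sex, then regressed on protein (P) and
carbohydrate (C) intake following the response-surface approach of selection
analysis: linear gradients beta come from a linear-terms-only OLS model;
quadratic/correlational gradients gamma from the full second-order model
w = alpha + beta'z + 1/2 z' gamma z, so the reported gamma diagonal equals
twice the fitted squared-term coefficients and the off-diagonal equals the
fitted cross-term coefficient.

Sex differences in the landscape are tested with a parametric bootstrap of
the likelihood ratio between a shared (single-surface) and a sex-specific
(separate surfaces and residual variances) Gaussian model: the null
distribution is built by simulating response vectors from the fitted shared
model and refitting both models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_QUAD_COLS = ("P", "C", "P2", "C2", "PC")


class LandscapeDataError(ValueError):
    """Degenerate fitness/intake data (constant fitness, rank deficiency)."""


def standardize_fitness(table: pd.DataFrame, by: str = "sex") -> pd.DataFrame:
    """Within-group Z-transformation of raw fitness.

    Returns a copy with a ``fitness_z`` column of per-group mean 0, SD 1;
    ``fitness_raw`` retained. SD uses the n-1 denominator.
    """
    out = table.copy()
    if "fitness_raw" not in out.columns:
        if "fitness" in out.columns:
            out = out.rename(columns={"fitness": "fitness_raw"})
        else:
            raise LandscapeDataError("table lacks a fitness/fitness_raw column")
    z = np.empty(len(out))
    for _, idx in out.groupby(by, sort=False).groups.items():
        vals = out.loc[idx, "fitness_raw"].to_numpy(dtype=float)
        if vals.size < 2 or np.std(vals, ddof=1) == 0:
            raise LandscapeDataError(
                "need >=2 distinct fitness values per group for Z-transformation"
            )
        z[out.index.get_indexer(idx)] = (vals - vals.mean()) / np.std(vals, ddof=1)
    out["fitness_z"] = z
    return out


def _design_quadratic(P: np.ndarray, C: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(P), P, C, P * P, C * C, P * C])


def _design_linear(P: np.ndarray, C: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(P), P, C])


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS coefficients and residual sum of squares; raises on rank deficiency."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise LandscapeDataError("rank-deficient design (observations on one rail?)")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _gauss_ll(rss: float, n: int) -> float:
    """Gaussian profile log-likelihood at the MLE variance rss/n."""
    if rss <= 0:
        rss = 1e-300
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


@dataclass
class SurfaceFit:
    sex: str
    intercept: float
    beta: np.ndarray  # (2,) linear gradients (P, C), linear-only model
    gamma: np.ndarray  # (2, 2) symmetric quadratic/correlational gradients
    full_coef: np.ndarray  # (6,) full quadratic-model coefficients
    residual_sd: float
    loglik: float
    n: int
    beta_se: np.ndarray | None = None  # (2,) classical OLS SEs of beta
    gamma_se: np.ndarray | None = None  # (2, 2) SEs on the gamma scale

    def predict(self, P, C) -> np.ndarray:
        """Predicted z-fitness from the full quadratic model."""
        P = np.asarray(P, dtype=float)
        C = np.asarray(C, dtype=float)
        return _design_quadratic(P.ravel(), C.ravel()) @ self.full_coef

    def stationary_point(self) -> np.ndarray:
        """Analytic stationary point -gamma^{-1} beta_full of the quadratic
        surface (using the full model's linear coefficients)."""
        b = self.full_coef[1:3]
        return -np.linalg.solve(self.gamma, b)


def fit_gradients(table: pd.DataFrame, sex: str) -> SurfaceFit:
    """Linear and nonlinear selection gradients for one sex.

    beta comes from the linear-terms-only model; the quadratic model adds
    P^2, C^2 and P*C, with gamma_PP = 2 * coef(P^2), gamma_CC = 2 * coef(C^2)
    and gamma_PC = coef(P*C).
    """
    sub = table[table["sex"] == sex]
    if len(sub) < 7:
        raise LandscapeDataError(f"need >=7 observations for sex {sex!r}")
    P = sub["protein_intake"].to_numpy(dtype=float)
    C = sub["carbohydrate_intake"].to_numpy(dtype=float)
    z = sub["fitness_z"].to_numpy(dtype=float)
    Xl, Xq = _design_linear(P, C), _design_quadratic(P, C)
    lin_coef, rss_lin = _ols(Xl, z)
    full_coef, rss = _ols(Xq, z)
    gamma = np.array([
        [2.0 * full_coef[3], full_coef[5]],
        [full_coef[5], 2.0 * full_coef[4]],
    ])
    n = len(sub)

    def _se(X, rss_):
        s2 = rss_ / max(X.shape[0] - X.shape[1], 1)
        return np.sqrt(s2 * np.diag(np.linalg.inv(X.T @ X)))

    se_lin = _se(Xl, rss_lin)
    se_full = _se(Xq, rss)
    gamma_se = np.array([
        [2.0 * se_full[3], se_full[5]],
        [se_full[5], 2.0 * se_full[4]],
    ])
    return SurfaceFit(
        sex=sex, intercept=float(lin_coef[0]), beta=lin_coef[1:3].copy(),
        gamma=gamma, full_coef=full_coef,
        residual_sd=float(np.sqrt(rss / max(n - 6, 1))),
        loglik=_gauss_ll(rss, n), n=n,
        beta_se=se_lin[1:3].copy(), gamma_se=gamma_se,
    )


def gradient_table(fits: list[SurfaceFit]) -> pd.DataFrame:
    """Coefficient table (gamma reported under the 1/2 z'gamma z convention)."""
    rows = []
    for f in fits:
        rows.append({
            "sex": f.sex, "n": f.n,
            "beta_P": f.beta[0], "beta_C": f.beta[1],
            "gamma_PP": f.gamma[0, 0], "gamma_CC": f.gamma[1, 1],
            "gamma_PC": f.gamma[0, 1],
            "residual_sd": f.residual_sd,
        })
    return pd.DataFrame(rows)


def predict_surface(fit: SurfaceFit, grid: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Predicted z-fitness over a (P, C) grid, long format."""
    if isinstance(grid, pd.DataFrame):
        P = grid["protein_intake"].to_numpy(dtype=float)
        C = grid["carbohydrate_intake"].to_numpy(dtype=float)
    else:
        arr = np.asarray(grid, dtype=float)
        P, C = arr[:, 0], arr[:, 1]
    return pd.DataFrame({
        "sex": fit.sex,
        "protein_intake": P,
        "carbohydrate_intake": C,
        "fitness_z_pred": fit.predict(P, C),
    })


def make_grid(p_max: float, c_max: float, n: int = 50) -> pd.DataFrame:
    p = np.linspace(0, p_max, n)
    c = np.linspace(0, c_max, n)
    PP, CC = np.meshgrid(p, c)
    return pd.DataFrame({"protein_intake": PP.ravel(),
                         "carbohydrate_intake": CC.ravel()})


# ---------------------------------------------------------------------------
# parametric bootstrap sex-difference test


@dataclass
class PBResult:
    pb_stat: float
    B: int
    seed: int
    null_draws: np.ndarray
    p: float
    n_redrawn: int = 0


def _pb_stat_vectorized(Y: np.ndarray, Xq: np.ndarray, female: np.ndarray,
                        pinv_all: np.ndarray, pinv_f: np.ndarray,
                        pinv_m: np.ndarray) -> np.ndarray:
    """PB statistics for response matrix Y (n, B): shared vs sex-specific
    Gaussian quadratic-surface models, per column."""
    n = Y.shape[0]
    n_f, n_m = int(female.sum()), int(n - female.sum())
    resid_all = Y - Xq @ (pinv_all @ Y)
    rss_all = np.sum(resid_all ** 2, axis=0)
    Yf, Ym = Y[female], Y[~female]
    rss_f = np.sum((Yf - Xq[female] @ (pinv_f @ Yf)) ** 2, axis=0)
    rss_m = np.sum((Ym - Xq[~female] @ (pinv_m @ Ym)) ** 2, axis=0)
    ll_shared = -0.5 * n * (np.log(2 * np.pi * rss_all / n) + 1.0)
    ll_sex = (-0.5 * n_f * (np.log(2 * np.pi * rss_f / n_f) + 1.0)
              - 0.5 * n_m * (np.log(2 * np.pi * rss_m / n_m) + 1.0))
    return np.maximum(2.0 * (ll_sex - ll_shared), 0.0)


def _restandardize_columns(Y: np.ndarray, female: np.ndarray) -> np.ndarray:
    """Apply the per-sex Z-transformation to every simulated response column,
    mirroring the preprocessing of the observed data."""
    out = Y.copy()
    for mask in (female, ~female):
        block = out[mask]
        mean = block.mean(axis=0, keepdims=True)
        sd = block.std(axis=0, ddof=1, keepdims=True)
        out[mask] = (block - mean) / sd
    return out


def parametric_bootstrap_sex_difference(table: pd.DataFrame, B: int = 999,
                                        seed: int = 0,
                                        restandardize: bool = True) -> PBResult:
    """Parametric-bootstrap test for sex differences in the fitness landscape.

    Shared model: one quadratic surface (and one residual variance) for both
    sexes' z-fitness. Sex-specific model: separate surfaces and variances.
    PB statistic = 2*(ll_sexspecific - ll_shared) with Gaussian likelihoods
    at MLE variances. The null distribution simulates B response vectors
    from the fitted shared model (Gaussian residuals at its MLE variance),
    re-applies the per-sex Z-transformation to each replicate (the same
    preprocessing the observed fitness received — omitting it makes the test
    sharply anticonservative, because the sampling error of the per-sex SD
    masquerades as a real amplitude difference between the sex surfaces),
    and refits both models; p = (1 + #{PB* >= PB_obs}) / (B + 1).
    """
    if B < 99:
        raise ValueError("B must be at least 99")
    sexes = set(table["sex"])
    if len(sexes) != 2:
        raise LandscapeDataError("exactly two sexes required")
    P = table["protein_intake"].to_numpy(dtype=float)
    C = table["carbohydrate_intake"].to_numpy(dtype=float)
    z = table["fitness_z"].to_numpy(dtype=float)
    sex_labels = sorted(sexes)
    female = (table["sex"] == sex_labels[0]).to_numpy()
    Xq = _design_quadratic(P, C)
    for X in (Xq, Xq[female], Xq[~female]):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise LandscapeDataError("rank-deficient design within a sex")
    pinv_all = np.linalg.pinv(Xq)
    pinv_f = np.linalg.pinv(Xq[female])
    pinv_m = np.linalg.pinv(Xq[~female])
    n = len(z)

    obs = float(_pb_stat_vectorized(z[:, None], Xq, female, pinv_all, pinv_f,
                                    pinv_m)[0])
    # shared-model MLE fit for null simulation
    coef_shared = pinv_all @ z
    fitted = Xq @ coef_shared
    sigma_mle = float(np.sqrt(np.sum((z - fitted) ** 2) / n))
    rng = np.random.default_rng(seed)

    def draw(k: int) -> np.ndarray:
        Y = fitted[:, None] + rng.normal(0.0, sigma_mle, size=(n, k))
        if restandardize:
            Y = _restandardize_columns(Y, female)
        return _pb_stat_vectorized(Y, Xq, female, pinv_all, pinv_f, pinv_m)

    null = draw(B)
    bad = ~np.isfinite(null)
    n_redrawn = 0
    while bad.any():
        if n_redrawn > 0.1 * B:
            raise LandscapeDataError("too many degenerate bootstrap replicates")
        n_redrawn += int(bad.sum())
        null[bad] = draw(int(bad.sum()))
        bad = ~np.isfinite(null)
    if n_redrawn:
        logger.info("parametric bootstrap: redrew %d replicates", n_redrawn)
    p = (1.0 + float(np.sum(null >= obs))) / (B + 1.0)
    return PBResult(pb_stat=obs, B=B, seed=seed, null_draws=null, p=p,
                    n_redrawn=n_redrawn)
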