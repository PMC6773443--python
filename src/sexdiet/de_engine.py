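"""Negative-binomial differential-expression engine, from first principles.

Pipeline: TMM between-sample normalization -> low-expression filtering ->
common and tagwise (shrunken) dispersion estimation by adjusted profile
likelihood -> per-gene NB log-link GLM via IRLS with step-halving ->
nested-model likelihood-ratio tests per design term -> Benjamini-Hochberg
FDR -> per-sex diet-only fold-change models.

The NB parameterization is variance = mu + phi * mu^2 (phi the dispersion);
phi = 0 degenerates to Poisson. All GLM coefficients live on the natural-log
scale internally; reported fold changes are log2, oriented from the
carbohydrate-rich (C) to the protein-rich (P) diet.

Design matrices are built with deviation (sum-to-zero, +/-1/2) factor coding
by default, so that the drop-column test for diet measures the across-sex
average diet effect and the interaction column measures the male-minus-female
difference in diet response. Treatment coding (reference female/carbohydrate)
is available via ``coding="treatment"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .tables_io import CountMatrix

logger = logging.getLogger(__name__)

LOG2E = float(np.log2(np.e))
_PHI_POISSON = 1e-8  # below this the Poisson likelihood branch is used
_ETA_CAP = 50.0  # linear-predictor cap; |eta| past this marks a boundary fit


class DataError(ValueError):
    """Input data violate a precondition (zero library, bad p-values...)."""


class UsageError(ValueError):
    """Operation called with incompatible arguments (non-nested designs...)."""


# ---------------------------------------------------------------------------
# design matrices


def build_design(samples: pd.DataFrame, terms=("sex", "diet", "sex:diet"),
                 coding: str = "sum") -> tuple[np.ndarray, list[str]]:
    """Design matrix for the 2x2 sex-by-diet layout.

    Deviation coding: F/C -> -1/2, M/P -> +1/2; interaction is the product.
    Treatment coding: F/C -> 0, M/P -> 1.
    """
    if coding not in ("sum", "treatment"):
        raise UsageError(f"unknown coding {coding!r}")
    n = len(samples)
    cols = [np.ones(n)]
    names = ["intercept"]
    if coding == "sum":
        s = np.where(samples["sex"].to_numpy() == "M", 0.5, -0.5)
        d = np.where(samples["diet"].to_numpy() == "P", 0.5, -0.5)
    else:
        s = (samples["sex"].to_numpy() == "M").astype(float)
        d = (samples["diet"].to_numpy() == "P").astype(float)
    for term in terms:
        if term == "sex":
            cols.append(s)
        elif term == "diet":
            cols.append(d)
        elif term == "sex:diet":
            cols.append(s * d)
        else:
            raise UsageError(f"unknown design term {term!r}")
        names.append(term)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise UsageError("design matrix is rank deficient")
    return X, names


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormFactors:
    lib_sizes: np.ndarray  # column sums N_i
    factors: np.ndarray  # TMM factors f_i, geometric mean 1
    samples: list[str]

    @property
    def effective_lib_sizes(self) -> np.ndarray:
        return self.lib_sizes * self.factors

    def offsets(self) -> np.ndarray:
        """Natural-log GLM offsets ln(N_i f_i)."""
        return np.log(self.effective_lib_sizes)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float = 0.30, trim_a: float = 0.05) -> float:
    """log2 TMM factor of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 0.0
    o = obs[keep] / n_obs
    r = ref[keep] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # precision weights: delta-method variance of M
    w = (n_obs - obs[keep]) / (n_obs * obs[keep]) + (n_ref - ref[keep]) / (
        n_ref * ref[keep]
    )
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 0.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f):
        return 0.0
    return float(f)


def tmm_normalize(counts: CountMatrix | np.ndarray,
                  trim_m: float = 0.30, trim_a: float = 0.05) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    Reference sample: the one whose 75th-percentile count fraction is closest
    to the mean of those fractions. M (log-ratio) and A (log-abundance) values
    use genes nonzero in both sample and reference; M is trimmed 30% each
    side, A 5% each side; the factor is the precision-weighted mean of the
    retained M values, and factors are rescaled to geometric mean 1.
    """
    if isinstance(counts, CountMatrix):
        arr = counts.counts.to_numpy(dtype=float)
        sample_names = list(counts.counts.columns)
    else:
        arr = np.asarray(counts, dtype=float)
        sample_names = [f"s{i}" for i in range(arr.shape[1])]
    if arr.shape[1] < 2:
        raise DataError("need at least two samples to normalize")
    lib = arr.sum(axis=0)
    if (lib == 0).any():
        raise DataError("sample with zero total count")
    q75 = np.quantile(arr / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    log_f = np.array(
        [
            _tmm_pair(arr[:, i], arr[:, ref_idx], lib[i], lib[ref_idx],
                      trim_m, trim_a)
            for i in range(arr.shape[1])
        ]
    )
    factors = 2.0 ** log_f
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(lib_sizes=lib, factors=factors, samples=sample_names)


def cpm(counts: CountMatrix | np.ndarray, norm: NormFactors | None = None) -> np.ndarray:
    arr = counts.counts.to_numpy(dtype=float) if isinstance(counts, CountMatrix) else np.asarray(counts, float)
    lib = norm.effective_lib_sizes if norm is not None else arr.sum(axis=0)
    return arr / lib * 1e6


def ave_log_cpm(counts: CountMatrix | np.ndarray, norm: NormFactors | None = None) -> np.ndarray:
    """Average log2 CPM per gene with a 0.5-count prior against log(0)."""
    arr = counts.counts.to_numpy(dtype=float) if isinstance(counts, CountMatrix) else np.asarray(counts, float)
    lib = norm.effective_lib_sizes if norm is not None else arr.sum(axis=0)
    return np.log2(((arr + 0.5) / (lib + 1.0) * 1e6).mean(axis=1))


def filter_low_expression(counts: CountMatrix, cpm_threshold: float = 1.0,
                          min_samples: int = 3) -> CountMatrix:
    """Keep genes with CPM > cpm_threshold in at least min_samples samples."""
    if cpm_threshold < 0 or min_samples < 0:
        raise UsageError("thresholds must be non-negative")
    c = cpm(counts)
    keep = (c > cpm_threshold).sum(axis=1) >= min_samples
    n_removed = int((~keep).sum())
    logger.info(
        "filter_low_expression: removed %d of %d genes (CPM>%g in >=%d samples)",
        n_removed, counts.n_genes, cpm_threshold, min_samples,
    )
    return CountMatrix(counts.counts.loc[keep], counts.samples.copy())


# ---------------------------------------------------------------------------
# NB likelihood and IRLS


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; phi below ~1e-8 uses the Poisson limit."""
    y = np.asarray(y, float)
    mu = np.maximum(mu, 1e-12)
    phi = np.asarray(phi, float)
    out = np.empty(y.shape[0])
    pois = phi <= _PHI_POISSON
    if pois.any():
        yp, mp = y[pois], mu[pois]
        out[pois] = np.sum(yp * np.log(mp) - mp - special.gammaln(yp + 1), axis=1)
    nb = ~pois
    if nb.any():
        yn, mn = y[nb], mu[nb]
        r = (1.0 / phi[nb])[:, None]
        out[nb] = np.sum(
            special.gammaln(yn + r)
            - special.gammaln(r)
            - special.gammaln(yn + 1)
            + r * np.log(r / (r + mn))
            + yn * np.log(mn / (r + mn)),
            axis=1,
        )
    return out


@dataclass
class GLMFit:
    beta: np.ndarray  # (G, p), natural-log scale
    mu: np.ndarray  # (G, S) fitted means
    loglik: np.ndarray  # (G,)
    converged: np.ndarray  # (G,) bool
    boundary: np.ndarray  # (G,) bool: a coefficient pinned at the eta cap
    design: np.ndarray
    term_names: list[str]
    phi: np.ndarray
    offset: np.ndarray

    def cr_adjustment(self) -> np.ndarray:
        """Cox-Reid adjustment 0.5*logdet(X' W X) per gene."""
        w = self.mu / (1.0 + self.phi[:, None] * self.mu)
        A = np.einsum("sp,gs,sq->gpq", self.design, w, self.design)
        sign, logdet = np.linalg.slogdet(A + 1e-10 * np.eye(A.shape[-1]))
        return 0.5 * logdet


def fit_nb_glm(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
               phi: np.ndarray | float, tol: float = 1e-8,
               max_iter: int = 50, term_names: list[str] | None = None) -> GLMFit:
    """Vectorized per-gene NB GLM (log link) by IRLS with step-halving.

    y: (G, S) counts; X: (S, p) shared design; offset: (S,) natural-log
    offsets; phi: scalar or (G,) dispersions. Convergence: relative deviance
    change below ``tol``.
    """
    y = np.asarray(y, float)
    G, S = y.shape
    p = X.shape[1]
    phi = np.broadcast_to(np.asarray(phi, float), (G,)).copy()
    offset = np.asarray(offset, float)
    if np.linalg.matrix_rank(X) < p:
        raise UsageError("design matrix is rank deficient")

    # init from a log-linear least-squares fit
    z0 = np.log(np.maximum(y, 0.5)) - offset[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (G, p)

    def eval_state(b):
        eta = np.clip(offset[None, :] + b @ X.T, -_ETA_CAP, _ETA_CAP)
        mu = np.exp(eta)
        ll = nb_loglik(y, mu, phi)
        return eta, mu, ll

    eta, mu, ll = eval_state(beta)
    converged = np.zeros(G, dtype=bool)
    eye = 1e-8 * np.eye(p)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        w = mu / (1.0 + phi[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / np.maximum(mu, 1e-12)
        A = np.einsum("sp,gs,sq->gpq", X, w, X) + eye
        b_rhs = np.einsum("sp,gs,gs->gp", X, w, z)
        beta_new = np.linalg.solve(A, b_rhs[:, :, None])[:, :, 0]
        delta = beta_new - beta
        # step-halving where the likelihood would decrease
        step = np.ones((G, 1))
        for _half in range(12):
            cand = beta + step * delta
            _, _, ll_new = eval_state(cand)
            worse = ll_new < ll - 1e-10
            if not worse.any():
                break
            step[worse] *= 0.5
        cand = beta + step * delta
        eta_new, mu_new, ll_new = eval_state(cand)
        # don't move genes that still got worse after halving
        accept = ll_new >= ll - 1e-10
        beta = np.where(accept[:, None], cand, beta)
        eta = np.where(accept[:, None], eta_new, eta)
        mu = np.where(accept[:, None], mu_new, mu)
        rel = np.abs(ll_new - ll) / (np.abs(ll) + 1.0)
        ll = np.where(accept, ll_new, ll)
        converged |= (rel < tol) & accept
    boundary = np.abs(beta @ X.T + offset[None, :]).max(axis=1) >= _ETA_CAP - 1e-6
    n_fail = int((~converged).sum())
    if n_fail:
        logger.info("fit_nb_glm: %d/%d genes not converged", n_fail, G)
    return GLMFit(
        beta=beta, mu=mu, loglik=ll, converged=converged, boundary=boundary,
        design=X, term_names=term_names or [f"b{i}" for i in range(p)],
        phi=phi, offset=offset,
    )


# ---------------------------------------------------------------------------
# dispersion estimation


@dataclass
class DispersionEstimates:
    common: float
    tagwise: np.ndarray
    prior_df: float
    raw: np.ndarray | None = None


def _apl(y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: float) -> np.ndarray:
    """Per-gene Cox-Reid adjusted profile log-likelihood at dispersion phi."""
    fit = fit_nb_glm(y, X, offset, phi, max_iter=30)
    return fit.loglik - fit.cr_adjustment()


def estimate_dispersions(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                         prior_df: float = 10.0,
                         grid_span: float = 6.0, grid_points: int = 21,
                         ) -> DispersionEstimates:
    """Common + tagwise NB dispersions by adjusted profile likelihood.

    The common dispersion maximizes the summed Cox-Reid adjusted profile
    likelihood over all genes. Tagwise estimates maximize the per-gene APL
    plus ``prior_df / residual_df`` times the gene-averaged APL (weighted-
    likelihood shrinkage toward the common value), on a log-spaced grid of
    2^(+/- grid_span) around the common value; they are clipped to lie
    between the raw per-gene maximizer and the common value.
    """
    y = np.asarray(y, float)
    G, S = y.shape
    resid_df = S - X.shape[1]
    if resid_df < 1:
        raise UsageError("need at least 1 residual degree of freedom")

    def neg_sum_apl(log10_phi: float) -> float:
        return -float(np.sum(_apl(y, X, offset, 10.0 ** log10_phi)))

    res = optimize.minimize_scalar(
        neg_sum_apl, bounds=(-8.0, 1.0), method="bounded",
        options={"xatol": 1e-3},
    )
    common = float(10.0 ** res.x)
    if common < 2e-8:
        common = 0.0

    base = max(common, 1e-4)
    grid = base * 2.0 ** np.linspace(-grid_span, grid_span, grid_points)
    grid = np.unique(np.concatenate([[1e-8], grid]))
    apl_mat = np.column_stack([_apl(y, X, offset, g) for g in grid])  # (G, K)
    mean_apl = apl_mat.mean(axis=0)  # (K,)
    raw = grid[np.argmax(apl_mat, axis=1)]
    if np.isinf(prior_df):
        tagwise = np.full(G, common)
    else:
        prior_n = prior_df / resid_df
        score = apl_mat + prior_n * mean_apl[None, :]
        tagwise = grid[np.argmax(score, axis=1)]
        lo = np.minimum(raw, common)
        hi = np.maximum(raw, common)
        tagwise = np.clip(tagwise, lo, hi)
    logger.info("estimate_dispersions: common phi=%.4g (prior df %g)", common, prior_df)
    return DispersionEstimates(common=common, tagwise=tagwise,
                               prior_df=prior_df, raw=raw)


# ---------------------------------------------------------------------------
# testing


def lrt_term(fit_full: GLMFit, fit_reduced: GLMFit) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood-ratio test of nested NB GLMs (dispersions held fixed).

    Returns (LR, p): LR = 2*(ll_full - ll_reduced) clipped at zero; p from
    the chi-squared distribution with df = rank difference.
    """
    Xf, Xr = fit_full.design, fit_reduced.design
    if Xf.shape[0] != Xr.shape[0]:
        raise UsageError("designs fitted on different samples")
    rank_f = np.linalg.matrix_rank(Xf)
    rank_r = np.linalg.matrix_rank(Xr)
    if rank_r >= rank_f:
        if rank_r == rank_f and np.linalg.matrix_rank(np.hstack([Xf, Xr])) == rank_f:
            # identical column span: LR identically 0, p = 1
            lr = np.zeros(fit_full.loglik.shape)
            return lr, np.ones_like(lr)
        raise UsageError("reduced design is not nested in the full design")
    if np.linalg.matrix_rank(np.hstack([Xf, Xr])) != rank_f:
        raise UsageError("reduced design is not nested in the full design")
    if not np.allclose(fit_full.phi, fit_reduced.phi):
        raise UsageError("dispersions differ between full and reduced fits")
    df = rank_f - rank_r
    lr = np.maximum(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    p = stats.chi2.sf(lr, df)
    return lr, p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# the full-model analysis


def de_analysis(counts: CountMatrix, coding: str = "sum",
                prior_df: float = 10.0,
                dispersions: DispersionEstimates | None = None) -> pd.DataFrame:
    """Sex + diet + sex:diet NB GLM analysis of a filtered count matrix.

    Returns a per-gene table with columns gene, logCPM and, for each term in
    (S, D, DxS): logFC_*, LR_*, p_*, q_*. The diet logFC is on the log2 scale
    and oriented carbohydrate -> protein.
    """
    y = counts.counts.to_numpy(dtype=float)
    norm = tmm_normalize(counts)
    offset = norm.offsets()
    X_full, names = build_design(counts.samples, ("sex", "diet", "sex:diet"), coding)
    if dispersions is None:
        dispersions = estimate_dispersions(y, X_full, offset, prior_df=prior_df)
    phi = dispersions.tagwise
    fit_full = fit_nb_glm(y, X_full, offset, phi, term_names=names)
    out = pd.DataFrame({"gene": counts.genes})
    out["logCPM"] = ave_log_cpm(counts, norm)
    term_map = {"S": "sex", "D": "diet", "DxS": "sex:diet"}
    for label, term in term_map.items():
        reduced_terms = tuple(t for t in ("sex", "diet", "sex:diet") if t != term)
        X_red, _ = build_design(counts.samples, reduced_terms, coding)
        fit_red = fit_nb_glm(y, X_red, offset, phi)
        lr, p = lrt_term(fit_full, fit_red)
        coef_idx = names.index(term)
        logfc = fit_full.beta[:, coef_idx] * LOG2E
        out[f"logFC_{label}"] = logfc
        out[f"LR_{label}"] = lr
        out[f"p_{label}"] = p
        out[f"q_{label}"] = bh_adjust(p)
    out.attrs["phi_common"] = dispersions.common
    out.attrs["converged"] = fit_full.converged
    out.attrs["boundary"] = fit_full.boundary
    return out


def diet_only_de(counts: CountMatrix, prior_df: float = 10.0) -> pd.DataFrame:
    """Diet-only NB GLM (one sex's samples): per-gene carb->protein log2FC,
    LR, p and BH q. Normalization and dispersions are computed within the
    given subset."""
    samples = counts.samples
    if set(samples["diet"]) != {"C", "P"}:
        raise UsageError("both diets must be present")
    y = counts.counts.to_numpy(dtype=float)
    norm = tmm_normalize(counts)
    offset = norm.offsets()
    d = np.where(samples["diet"].to_numpy() == "P", 1.0, 0.0)
    X_full = np.column_stack([np.ones(len(samples)), d])
    X_red = np.ones((len(samples), 1))
    disp = estimate_dispersions(y, X_full, offset, prior_df=prior_df)
    fit_full = fit_nb_glm(y, X_full, offset, disp.tagwise, term_names=["intercept", "diet"])
    fit_red = fit_nb_glm(y, X_red, offset, disp.tagwise)
    lr, p = lrt_term(fit_full, fit_red)
    return pd.DataFrame({
        "gene": counts.genes,
        "logCPM": ave_log_cpm(counts, norm),
        "logFC": fit_full.beta[:, 1] * LOG2E,
        "LR": lr,
        "p": p,
        "q": bh_adjust(p),
    })


def per_sex_fold_changes(counts: CountMatrix, alpha: float = 0.05,
                         prior_df: float = 10.0) -> pd.DataFrame:
    """Per-sex diet-only fold changes with the four-way significance flag.

    Fits a diet-only NB GLM separately to the female and male samples
    (normalization factors and dispersions recomputed within each subset);
    log2FC oriented carbohydrate -> protein; flags at the per-sex BH q <
    alpha: female_only / male_only / both / neither.
    """
    for sex in ("F", "M"):
        sub = counts.samples[counts.samples["sex"] == sex]
        if len(set(sub["diet"])) < 2:
            raise UsageError(f"sex {sex} lacks both diet levels")
    female = diet_only_de(counts.subset_sex("F"), prior_df=prior_df)
    male = diet_only_de(counts.subset_sex("M"), prior_df=prior_df)
    out = pd.DataFrame({
        "gene": counts.genes,
        "logFC_female": female["logFC"].to_numpy(),
        "q_female": female["q"].to_numpy(),
        "logFC_male": male["logFC"].to_numpy(),
        "q_male": male["q"].to_numpy(),
    })
    sig_f = out["q_female"] < alpha
    sig_m = out["q_male"] < alpha
    flag = np.select(
        [sig_f & sig_m, sig_f & ~sig_m, ~sig_f & sig_m],
        ["both", "female_only", "male_only"],
        default="neither",
    )
    out["flag"] = flag
    return out
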