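"""Cross-sex fold-change concordance and bootstrapped correlation contrasts.

For a gene set, the concordance statistic is the correlation between male
and female carb->protein log2 fold changes over the set's genes. A target
set (e.g. a metabolic annotation term) is contrasted against a baseline set
(e.g. all biological-process genes minus the metabolic branch) by an
independent within-set gene bootstrap of both correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import GeneSetCollection, TermHierarchy

logger = logging.getLogger(__name__)


class UndefinedResultError(ValueError):
    """Fewer than 3 usable genes: correlation undefined."""


@dataclass
class CorrelationResult:
    set_name: str
    n: int
    r: float
    p: float
    method: str = "pearson"


def _paired_fold_changes(fc: pd.DataFrame, gene_set) -> tuple[np.ndarray, np.ndarray]:
    sub = fc[fc["gene"].isin(set(gene_set))]
    x = sub["logFC_male"].to_numpy(dtype=float)
    y = sub["logFC_female"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def cross_sex_correlation(fc: pd.DataFrame, gene_set, set_name: str = "",
                          method: str = "pearson") -> CorrelationResult:
    """Correlation of (male, female) carb->protein log2FC over a gene set.

    ``fc`` is a per_sex_fold_changes table (columns gene, logFC_female,
    logFC_male). Pearson by default; Spearman via ``method``.
    """
    x, y = _paired_fold_changes(fc, gene_set)
    if x.size < 3:
        raise UndefinedResultError(
            f"gene set {set_name!r}: only {x.size} usable genes (need >=3)"
        )
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(set_name=set_name, n=int(x.size), r=float(r),
                             p=float(p), method=method)


def build_baseline_set(collection: GeneSetCollection, hierarchy: TermHierarchy,
                       parent_term: str, exclude_term: str) -> set[str]:
    """Genes of ``parent_term`` minus ``exclude_term``'s whole branch.

    The excluded genes are the union of the exclude term's own annotation and
    the annotations of all its hierarchy descendants; terms of the branch
    that carry no annotation in the collection contribute nothing. The
    exclude term must be a descendant of the parent term in the hierarchy.
    """
    if parent_term not in collection:
        raise ValueError(f"parent term {parent_term!r} not in collection")
    if exclude_term not in hierarchy.descendants(parent_term):
        raise ValueError(
            f"{exclude_term!r} is not a hierarchy descendant of {parent_term!r}"
        )
    excluded = set(collection[exclude_term]) if exclude_term in collection else set()
    for term in hierarchy.descendants(exclude_term):
        if term in collection:
            excluded |= collection[term]
    return set(collection[parent_term]) - excluded


def _bootstrap_r(x: np.ndarray, y: np.ndarray, B: int, rng: np.random.Generator,
                 ) -> tuple[np.ndarray, int]:
    """B bootstrap correlations by resampling gene pairs; degenerate
    (zero-variance) resamples are redrawn."""
    n = x.size
    draws = np.empty(B)
    n_redraws = 0
    filled = 0
    while filled < B:
        todo = B - filled
        idx = rng.integers(0, n, size=(todo, n))
        xs, ys = x[idx], y[idx]
        xs_c = xs - xs.mean(axis=1, keepdims=True)
        ys_c = ys - ys.mean(axis=1, keepdims=True)
        sx = np.sqrt((xs_c ** 2).sum(axis=1))
        sy = np.sqrt((ys_c ** 2).sum(axis=1))
        ok = (sx > 0) & (sy > 0)
        r = np.full(todo, np.nan)
        r[ok] = (xs_c * ys_c).sum(axis=1)[ok] / (sx[ok] * sy[ok])
        good = r[ok]
        take = min(good.size, todo)
        draws[filled:filled + take] = good[:take]
        filled += take
        n_redraws += int((~ok).sum())
    return draws, n_redraws


@dataclass
class BootstrapContrast:
    target_name: str
    baseline_name: str
    B: int
    seed: int
    r_target_obs: float
    r_baseline_obs: float
    r_target: np.ndarray  # (B,)
    r_baseline: np.ndarray  # (B,)
    ci_target: tuple[float, float]
    ci_baseline: tuple[float, float]
    ci_difference: tuple[float, float]
    p_difference: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate": np.arange(self.B),
            "r_target": self.r_target,
            "r_baseline": self.r_baseline,
        })


def bootstrap_correlation_contrast(fc: pd.DataFrame, target_set, baseline_set,
                                   B: int = 1000, seed: int = 0,
                                   target_name: str = "target",
                                   baseline_name: str = "baseline",
                                   ) -> BootstrapContrast:
    """Bootstrap contrast of two within-set cross-sex correlations.

    Each replicate resamples genes with replacement independently within the
    target and baseline sets and recomputes both Pearson correlations.
    Reports 95% percentile CIs and the two-sided empirical p-value for a
    nonzero difference, floored at 1/B.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    xt, yt = _paired_fold_changes(fc, target_set)
    xb, yb = _paired_fold_changes(fc, baseline_set)
    for name, x in (("target", xt), ("baseline", xb)):
        if x.size < 3:
            raise UndefinedResultError(f"{name} set has fewer than 3 usable genes")
    rng = np.random.default_rng(seed)
    rt_obs = float(stats.pearsonr(xt, yt)[0])
    rb_obs = float(stats.pearsonr(xb, yb)[0])
    rt, redraw_t = _bootstrap_r(xt, yt, B, rng)
    rb, redraw_b = _bootstrap_r(xb, yb, B, rng)
    if redraw_t or redraw_b:
        logger.info("bootstrap: redrew %d degenerate replicates", redraw_t + redraw_b)
    diff = rt - rb
    frac_le = np.mean(diff <= 0.0)
    frac_ge = np.mean(diff >= 0.0)
    p = max(2.0 * min(frac_le, frac_ge), 1.0 / B)
    p = min(p, 1.0)

    def ci(a):
        lo, hi = np.percentile(a, [2.5, 97.5])
        return (float(lo), float(hi))

    return BootstrapContrast(
        target_name=target_name, baseline_name=baseline_name, B=B, seed=seed,
        r_target_obs=rt_obs, r_baseline_obs=rb_obs,
        r_target=rt, r_baseline=rb,
        ci_target=ci(rt), ci_baseline=ci(rb), ci_difference=ci(diff),
        p_difference=float(p),
    )
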