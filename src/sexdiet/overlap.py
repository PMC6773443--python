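"""Gene-list overlap statistics against an explicit universe.

Overlap of two gene lists drawn from a common universe is assessed with the
hypergeometric (Fisher's exact, one-sided over-enrichment) test; expected
overlap n_a*n_b/N and percent excess are reported alongside the sample odds
ratio. Cross-classification correspondence between two categorical gene
labelings uses the Pearson chi-squared test on the R x C contingency table.
A generic hypergeometric gene-set enrichment runs the overlap test against
every member of a collection with BH adjustment.

The universe must always be supplied explicitly; sets not contained in it
are an error, never silently intersected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de_engine import bh_adjust
from .tables_io import GeneSetCollection

logger = logging.getLogger(__name__)


class UniverseError(ValueError):
    """A gene set is not contained in the stated universe."""


@dataclass
class OverlapResult:
    name_a: str
    name_b: str
    universe_size: int
    n_a: int
    n_b: int
    observed: int
    expected: float
    percent_excess: float
    odds_ratio: float
    p: float
    alternative: str = "greater"

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def fisher_overlap(set_a, set_b, universe, name_a: str = "A", name_b: str = "B",
                   alternative: str = "greater") -> OverlapResult:
    """Hypergeometric overlap test of two gene sets in an explicit universe.

    One-sided over-enrichment p = P(X >= k), X ~ Hypergeom(N, n_a, n_b).
    Expected overlap is n_a*n_b/N; percent excess 100*(k/expected - 1).
    The odds ratio is the unconditional 2x2 sample estimate, with a Haldane
    0.5 correction only when a zero cell occurs (logged).
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe:
        raise UniverseError(f"set {name_a!r} is not contained in the universe")
    if not set_b <= universe:
        raise UniverseError(f"set {name_b!r} is not contained in the universe")
    N = len(universe)
    n_a, n_b = len(set_a), len(set_b)
    k = len(set_a & set_b)
    expected = n_a * n_b / N if N else float("nan")
    pct_excess = 100.0 * (k / expected - 1.0) if expected > 0 else float("nan")
    if alternative == "greater":
        p = float(stats.hypergeom.sf(k - 1, N, n_a, n_b))
    elif alternative == "two-sided":
        table = [[k, n_a - k], [n_b - k, N - n_a - n_b + k]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    a, b = k, n_a - k
    c, d = n_b - k, N - n_a - n_b + k
    if 0 in (a, b, c, d):
        logger.info("fisher_overlap: zero cell, Haldane 0.5 correction applied")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return OverlapResult(
        name_a=name_a, name_b=name_b, universe_size=N, n_a=n_a, n_b=n_b,
        observed=k, expected=expected, percent_excess=pct_excess,
        odds_ratio=float(odds), p=min(p, 1.0), alternative=alternative,
    )


@dataclass
class CorrespondenceResult:
    table: pd.DataFrame  # contingency table, labels_a rows x labels_b cols
    chi2: float
    df: int
    p: float
    obs_exp_ratio: pd.DataFrame


def classification_correspondence(labels_a: pd.Series | dict,
                                  labels_b: pd.Series | dict,
                                  ) -> CorrespondenceResult:
    """Pearson chi-squared correspondence of two gene labelings.

    Both labelings must cover the identical gene universe. No continuity
    correction; a warning is logged when any expected cell is below 5.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if set(a.index) != set(b.index):
        raise UniverseError("labelings are defined on different gene universes")
    b = b.loc[a.index]
    table = pd.crosstab(a, b)
    chi2, p, df, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    if (expected < 5).any():
        logger.warning("classification_correspondence: %d expected cells < 5",
                       int((expected < 5).sum()))
    ratio = pd.DataFrame(table.to_numpy() / expected, index=table.index,
                         columns=table.columns)
    return CorrespondenceResult(table=table, chi2=float(chi2), df=int(df),
                                p=float(p), obs_exp_ratio=ratio)


def contingency_chi2(table: np.ndarray | pd.DataFrame) -> CorrespondenceResult:
    """Pearson chi-squared on an already-built contingency table."""
    arr = np.asarray(table, dtype=float)
    chi2, p, df, expected = stats.chi2_contingency(arr, correction=False)
    if (expected < 5).any():
        logger.warning("contingency_chi2: %d expected cells < 5",
                       int((expected < 5).sum()))
    tab = table if isinstance(table, pd.DataFrame) else pd.DataFrame(arr)
    ratio = pd.DataFrame(arr / expected, index=tab.index, columns=tab.columns)
    return CorrespondenceResult(table=tab, chi2=float(chi2), df=int(df),
                                p=float(p), obs_exp_ratio=ratio)


def expressed_universe(genes_a, genes_b) -> set[str]:
    """Cross-study comparison universe: genes expressed in both datasets."""
    return set(genes_a) & set(genes_b)


def enrich_gene_sets(query_set, collection: GeneSetCollection, universe,
                     alternative: str = "greater") -> pd.DataFrame:
    """Hypergeometric enrichment of a query against a gene-set collection.

    Each collection member is tested with fisher_overlap; p-values are BH
    adjusted across the collection; rows sorted by q then p.
    """
    query_set, universe = set(query_set), set(universe)
    if not query_set <= universe:
        raise UniverseError("query set is not contained in the universe")
    rows = []
    for name in collection.names():
        members = collection[name] & universe
        if not members:
            continue
        res = fisher_overlap(query_set, members, universe, name_a="query",
                             name_b=name, alternative=alternative)
        rows.append({
            "set": name, "n_set": res.n_b, "observed": res.observed,
            "expected": res.expected, "percent_excess": res.percent_excess,
            "odds_ratio": res.odds_ratio, "p": res.p,
        })
    if not rows:
        return pd.DataFrame(
            columns=["set", "n_set", "observed", "expected", "percent_excess",
                     "odds_ratio", "p", "q"]
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["q", "p"], kind="mergesort").reset_index(drop=True)
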