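"""Detection partition, significance-cell classification, and sex-limited DE.

Shared genes (detected in both sexes) are classified by the significance of
the sex (S), diet (D) and interaction (DxS) terms at a working FDR into the
eight S/D/DxS significance cells and three headline diet-response categories:

* ``D``        — diet significant, interaction not: concordant response.
* ``DxS``      — interaction significant, diet not: opposing response.
* ``DplusDxS`` — both significant: sex-biased (shared direction, different
  magnitude) response.

Sex-limited genes (detected in only one sex) get a per-sex diet-only DE
summary of UP / Ns / DOWN counts for the carbohydrate -> protein contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import de_engine
from .tables_io import CountMatrix

logger = logging.getLogger(__name__)

CATEGORIES = ("D", "DxS", "DplusDxS")


@dataclass
class DetectionPartition:
    shared: list[str]
    male_limited: list[str]
    female_limited: list[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            "male_limited": len(self.male_limited),
            "female_limited": len(self.female_limited),
        }


def partition_by_detection(counts: CountMatrix, min_count: int = 1,
                           use_cpm: bool = False, cpm_threshold: float = 1.0,
                           ) -> DetectionPartition:
    """Split genes by where they are detected.

    A gene is detected in a library when its raw count >= ``min_count``
    (or CPM > ``cpm_threshold`` with ``use_cpm=True``). Shared genes are
    detected in at least one library of each sex; sex-limited genes in at
    least one library of one sex and none of the other. Genes detected
    nowhere belong to no list (their number is logged).
    """
    if "sex" not in counts.samples.columns:
        raise de_engine.UsageError("sample metadata lacks sex labels")
    if use_cpm:
        mat = de_engine.cpm(counts) > cpm_threshold
    else:
        mat = counts.counts.to_numpy() >= min_count
    is_male = (counts.samples["sex"] == "M").to_numpy()
    det_m = mat[:, is_male].any(axis=1)
    det_f = mat[:, ~is_male].any(axis=1)
    genes = np.asarray(counts.genes)
    shared = genes[det_m & det_f].tolist()
    male_limited = genes[det_m & ~det_f].tolist()
    female_limited = genes[det_f & ~det_m].tolist()
    n_silent = int((~det_m & ~det_f).sum())
    if n_silent:
        logger.info("partition_by_detection: %d all-zero genes dropped", n_silent)
    return DetectionPartition(shared, male_limited, female_limited)


@dataclass
class GeneClassification:
    table: pd.DataFrame  # gene, q_S, q_D, q_DxS, cell, category
    alpha: float

    def category_counts(self) -> dict[str, int]:
        vc = self.table.loc[self.table["category"] != "none", "category"].value_counts()
        return {cat: int(vc.get(cat, 0)) for cat in CATEGORIES}

    def cell_table(self) -> pd.DataFrame:
        """Eight-row S/D/DxS significance-cell summary."""
        rows = []
        tab = self.table[self.table["cell"] != "untestable"]
        for s in ("-", "Y"):
            for d in ("-", "Y"):
                for i in ("-", "Y"):
                    cell = f"{s}{d}{i}"
                    rows.append({
                        "S": s, "D": d, "DxS": i,
                        "n_genes": int((tab["cell"] == cell).sum()),
                    })
        return pd.DataFrame(rows)


def classify_patterns(de: pd.DataFrame, alpha: float = 0.05) -> GeneClassification:
    """Assign each shared gene a significance cell and headline category.

    ``de`` is a de_engine.de_analysis table with q_S, q_D, q_DxS columns.
    Genes whose full-model fit failed to converge are assigned the cell
    "untestable" and excluded from category totals.
    """
    for col in ("q_S", "q_D", "q_DxS"):
        if col not in de.columns:
            raise de_engine.UsageError(f"DE table lacks column {col}")
    sig = {t: (de[f"q_{t}"] < alpha).to_numpy() for t in ("S", "D", "DxS")}
    cell = np.array([
        "".join("Y" if sig[t][i] else "-" for t in ("S", "D", "DxS"))
        for i in range(len(de))
    ], dtype=object)
    category = np.select(
        [sig["D"] & sig["DxS"], sig["D"], sig["DxS"]],
        ["DplusDxS", "D", "DxS"],
        default="none",
    ).astype(object)
    converged = de.attrs.get("converged")
    if converged is not None and not np.all(converged):
        bad = ~np.asarray(converged)
        cell[bad] = "untestable"
        category[bad] = "none"
        logger.info("classify_patterns: %d unconverged genes marked untestable",
                    int(bad.sum()))
    table = pd.DataFrame({
        "gene": de["gene"],
        "q_S": de["q_S"], "q_D": de["q_D"], "q_DxS": de["q_DxS"],
        "cell": cell, "category": category,
    })
    return GeneClassification(table=table, alpha=alpha)


@dataclass
class SexLimitedDESummary:
    summary: pd.DataFrame  # sex, UP, Ns, DOWN, total
    tables: dict[str, pd.DataFrame]  # per-sex per-gene DE tables


def sex_limited_de(counts: CountMatrix, partition: DetectionPartition,
                   alpha: float = 0.05, prior_df: float = 10.0,
                   ) -> SexLimitedDESummary:
    """Diet-only DE of sex-limited genes within each sex's own libraries.

    Normalization offsets come from the full gene complement of the sex's
    libraries; the diet-only model and the BH adjustment are applied to the
    sex-limited gene set only. UP = significant positive carb->protein
    log2FC, DOWN = significant negative, Ns = the rest.
    """
    rows = []
    tables: dict[str, pd.DataFrame] = {}
    for sex, genes in (("F", partition.female_limited), ("M", partition.male_limited)):
        if not genes:
            rows.append({"sex": sex, "UP": 0, "Ns": 0, "DOWN": 0, "total": 0})
            continue
        sub_all = counts.subset_sex(sex)
        if len(set(sub_all.samples["diet"])) < 2:
            raise de_engine.UsageError(f"sex {sex} lacks both diet levels")
        norm = de_engine.tmm_normalize(sub_all)
        offset = norm.offsets()
        sub = sub_all.subset_genes(genes)
        y = sub.counts.to_numpy(dtype=float)
        d = np.where(sub.samples["diet"].to_numpy() == "P", 1.0, 0.0)
        X_full = np.column_stack([np.ones(len(d)), d])
        X_red = np.ones((len(d), 1))
        disp = de_engine.estimate_dispersions(y, X_full, offset, prior_df=prior_df)
        fit_full = de_engine.fit_nb_glm(y, X_full, offset, disp.tagwise)
        fit_red = de_engine.fit_nb_glm(y, X_red, offset, disp.tagwise)
        lr, p = de_engine.lrt_term(fit_full, fit_red)
        q = de_engine.bh_adjust(p)
        logfc = fit_full.beta[:, 1] * de_engine.LOG2E
        tab = pd.DataFrame({"gene": genes, "logFC": logfc, "LR": lr, "p": p, "q": q})
        tables[sex] = tab
        sig = q < alpha
        up = int((sig & (logfc > 0)).sum())
        down = int((sig & (logfc < 0)).sum())
        rows.append({"sex": sex, "UP": up, "Ns": len(genes) - up - down,
                     "DOWN": down, "total": len(genes)})
    return SexLimitedDESummary(summary=pd.DataFrame(rows), tables=tables)


def summarize_classification(classification: GeneClassification,
                             partition: DetectionPartition | None = None,
                             ) -> pd.DataFrame:
    """Category counts and proportions of the diet-responsive total."""
    counts = classification.category_counts()
    total = sum(counts.values())
    rows = []
    for cat in CATEGORIES:
        n = counts[cat]
        rows.append({
            "category": cat,
            "n_genes": n,
            "pct_of_diet_responsive": 100.0 * n / total if total else 0.0,
        })
    out = pd.DataFrame(rows)
    out.attrs["diet_responsive_total"] = total
    if partition is not None:
        out.attrs["shared_total"] = len(partition.shared)
    return out
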