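"""Seeded synthetic data with known ground truth.

Emulates the study design this package analyses: a 2 sexes x 2 diets x
n-replicate bulk RNA-seq layout of pooled whole flies with negative-binomial
counts and planted gene categories, a small GO-like annotation hierarchy for
baseline construction, overlap fixtures with exact intersections, and
fitness landscapes over protein:carbohydrate rails with quadratic structure.

Planted gene categories (diet log2 fold changes oriented carb -> protein):

* ``D``             concordant: same effect in both sexes;
* ``DxS``           opposing: equal and opposite effects;
* ``DplusDxS``      sex-biased: a large effect in one (dominant) sex, a small
  same-direction effect in the other;
* ``male_limited`` / ``female_limited``  expressed in one sex only (true zero
  mean in the silent sex), a fraction of them diet-responsive in the
  directions the biology predicts (female-limited up on protein,
  male-limited up on carbohydrate);
* ``null``          everything else.

Counts are drawn NB via a gamma-Poisson mixture; library sizes are
log-normal. Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import CountMatrix, GeneSetCollection, TermHierarchy


class ParameterError(ValueError):
    """Infeasible simulation parameters."""


DEFAULT_RAILS = (4.0, 2.0, 1.0, 1 / 2, 1 / 4, 1 / 8, 1 / 16, 1 / 32)


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


# ---------------------------------------------------------------------------
# counts


@dataclass
class SimCountParams:
    """Parameters of the planted-truth count simulation.

    Defaults echo the study's magnitudes: ~9000 genes, 3 replicate libraries
    per sex x diet cell, deep libraries, 600 concordant / 50 opposing /
    120 sex-biased planted genes, log2 effect size 1.5.
    """

    n_genes: int = 9000
    n_reps: int = 3
    lib_size_mean: float = 1.8e7
    lib_size_cv: float = 0.1
    baseline_logcpm_range: tuple[float, float] = (0.5, 10.0)
    dispersion_shape: float | tuple[float, float] = 0.1
    n_D: int = 600
    n_DxS: int = 50
    n_DplusDxS: int = 120
    n_sexlim_male: int = 300
    n_sexlim_female: int = 60
    effect_logfc: float = 1.5
    sex_logfc: float = 1.0
    frac_sex_affected: float = 0.8
    frac_dominant_female: float = 0.8
    frac_sexlim_de: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        planted = (self.n_D + self.n_DxS + self.n_DplusDxS
                   + self.n_sexlim_male + self.n_sexlim_female)
        if planted > self.n_genes:
            raise ParameterError(
                f"planted category sizes sum to {planted} > n_genes={self.n_genes}"
            )
        if self.n_reps < 2:
            raise ParameterError("need n_reps >= 2")
        for v in (self.effect_logfc, self.sex_logfc, self.lib_size_mean):
            if not np.isfinite(v):
                raise ParameterError("magnitudes must be finite")


@dataclass
class TruthLabels:
    """Per-gene planted category and true per-sex diet log2 fold changes."""

    table: pd.DataFrame  # gene, category, logfc_female, logfc_male

    def genes_in(self, category: str) -> list[str]:
        return self.table.loc[self.table["category"] == category, "gene"].tolist()

    @property
    def categories(self) -> pd.Series:
        return self.table.set_index("gene")["category"]


def _draw_phi(rng: np.random.Generator, shape, n: int) -> np.ndarray:
    if np.isscalar(shape):
        return np.full(n, float(shape))
    a, scale = shape
    return rng.gamma(a, scale, size=n)


def simulate_counts(params: SimCountParams) -> tuple[CountMatrix, TruthLabels]:
    """Simulate a 2x2 sex-by-diet NB count matrix with planted truth.

    Returns the CountMatrix (n_genes x 4*n_reps; metadata sex F/M, diet C/P,
    replicate) and the TruthLabels. Identical params (including seed) give
    identical output.
    """
    rng = np.random.default_rng(params.seed)
    G = params.n_genes
    genes = _gene_ids(G)

    # planted category assignment on a seeded permutation
    perm = rng.permutation(G)
    category = np.full(G, "null", dtype=object)
    cursor = 0
    for name, size in (("D", params.n_D), ("DxS", params.n_DxS),
                       ("DplusDxS", params.n_DplusDxS),
                       ("male_limited", params.n_sexlim_male),
                       ("female_limited", params.n_sexlim_female)):
        category[perm[cursor:cursor + size]] = name
        cursor += size

    e = params.effect_logfc
    logfc_f = np.zeros(G)
    logfc_m = np.zeros(G)
    sign = rng.choice([-1.0, 1.0], size=G)
    is_d = category == "D"
    logfc_f[is_d] = sign[is_d] * e
    logfc_m[is_d] = sign[is_d] * e
    is_i = category == "DxS"
    logfc_f[is_i] = sign[is_i] * e
    logfc_m[is_i] = -sign[is_i] * e
    # sex-biased genes: a large (2e) response in the dominant sex, a small
    # same-direction (e/2) response in the other, so both the average-diet
    # and the interaction contrasts are of magnitude >= e
    is_b = category == "DplusDxS"
    dominant_female = rng.random(G) < params.frac_dominant_female
    fem_dom = is_b & dominant_female
    male_dom = is_b & ~dominant_female
    logfc_f[fem_dom] = sign[fem_dom] * 2.0 * e
    logfc_m[fem_dom] = sign[fem_dom] * 0.5 * e
    logfc_m[male_dom] = sign[male_dom] * 2.0 * e
    logfc_f[male_dom] = sign[male_dom] * 0.5 * e
    sexlim_de = rng.random(G) < params.frac_sexlim_de
    is_fl = category == "female_limited"
    is_ml = category == "male_limited"
    logfc_f[is_fl & sexlim_de] = e  # up on the protein diet females prefer
    logfc_m[is_ml & sexlim_de] = -e  # up on the carbohydrate diet males prefer

    # sex effect (baseline dimorphism), independent of diet categories
    sex_shift = np.where(
        rng.random(G) < params.frac_sex_affected,
        rng.choice([-1.0, 1.0], size=G) * params.sex_logfc,
        0.0,
    )

    lo, hi = params.baseline_logcpm_range
    base_logcpm = rng.uniform(lo, hi, size=G)
    phi = _draw_phi(rng, params.dispersion_shape, G)

    sexes = ["F"] * (2 * params.n_reps) + ["M"] * (2 * params.n_reps)
    diets = (["C"] * params.n_reps + ["P"] * params.n_reps) * 2
    reps = list(range(1, params.n_reps + 1)) * 4
    sample_ids = [f"{s}{d}{r}" for s, d, r in zip(sexes, diets, reps)]
    S = len(sample_ids)

    sigma2 = np.log(1.0 + params.lib_size_cv ** 2)
    lib = rng.lognormal(np.log(params.lib_size_mean) - sigma2 / 2.0,
                        np.sqrt(sigma2), size=S)

    is_male_s = np.array([s == "M" for s in sexes])
    is_protein_s = np.array([d == "P" for d in diets])
    d_centered = np.where(is_protein_s, 0.5, -0.5)

    log2_level = (
        base_logcpm[:, None]
        + sex_shift[:, None] * is_male_s[None, :]
        + d_centered[None, :]
        * np.where(is_male_s[None, :], logfc_m[:, None], logfc_f[:, None])
    )
    q = 2.0 ** log2_level / 1e6
    q[is_fl, :] = np.where(is_male_s[None, :], 0.0, q[is_fl, :])
    q[is_ml, :] = np.where(is_male_s[None, :], q[is_ml, :], 0.0)
    mu = lib[None, :] * q

    counts = np.zeros((G, S), dtype=np.int64)
    pois_rows = phi <= 0
    if pois_rows.any():
        counts[pois_rows] = rng.poisson(mu[pois_rows])
    nb_rows = ~pois_rows
    if nb_rows.any():
        r = 1.0 / phi[nb_rows]
        lam = np.zeros_like(mu[nb_rows])
        pos = mu[nb_rows] > 0
        lam[pos] = rng.gamma(np.broadcast_to(r[:, None], lam.shape)[pos],
                             (mu[nb_rows] * phi[nb_rows, None])[pos])
        counts[nb_rows] = rng.poisson(lam)

    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=sample_ids),
        pd.DataFrame({"sex": sexes, "diet": diets, "replicate": reps},
                     index=pd.Index(sample_ids, name="sample")),
    )
    truth = TruthLabels(pd.DataFrame({
        "gene": genes, "category": category,
        "logfc_female": logfc_f, "logfc_male": logfc_m,
        "phi": phi,
    }))
    return cm, truth


# ---------------------------------------------------------------------------
# fitness landscapes


def _optimum_beta(gamma: np.ndarray, optimum: tuple[float, float]) -> np.ndarray:
    """beta that places the quadratic surface's stationary point at optimum."""
    return -np.asarray(gamma) @ np.asarray(optimum, dtype=float)


# Curvature scaled so the quadratic surface explains roughly half the
# fitness variance at the default noise (R^2 ~ 0.45, between the moderate
# male and strong female signal of real landscape assays); stronger
# curvature makes high-intake observations implausibly catastrophic.
_GAMMA_DEFAULT = np.array([[-2.0, 0.0], [0.0, -2.0]])
# female optimum on the 2:1 P:C rail, male on 1:4, at total intake ~0.9
_OPT_F = (0.6, 0.3)
_OPT_M = (0.18, 0.72)


@dataclass
class LandscapeParams:
    """Parameters of the fitness-landscape simulation.

    ``n_per_sex`` is the total number of observations per sex, spread as
    evenly as possible over the rails. Default gradients place the female
    fitness optimum on the 2:1 protein:carbohydrate rail and the male
    optimum on 1:4, with strong negative-definite curvature.
    """

    n_per_sex: int = 120
    rails: tuple[float, ...] = DEFAULT_RAILS
    intake_scale: float = 1.0
    beta_f: np.ndarray = field(default_factory=lambda: _optimum_beta(_GAMMA_DEFAULT, _OPT_F))
    beta_m: np.ndarray = field(default_factory=lambda: _optimum_beta(_GAMMA_DEFAULT, _OPT_M))
    gamma_f: np.ndarray = field(default_factory=lambda: _GAMMA_DEFAULT.copy())
    gamma_m: np.ndarray = field(default_factory=lambda: _GAMMA_DEFAULT.copy())
    alpha_f: float = 0.0
    alpha_m: float = 0.0
    noise_sd: float = 0.5
    intake_cv: float = 0.35
    binomial_n: int | None = None  # optional binomial male fitness, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.rails) == 0:
            raise ParameterError("rails must be non-empty")
        if any(r <= 0 for r in self.rails):
            raise ParameterError("rails must be strictly positive ratios")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        for g in (self.gamma_f, self.gamma_m):
            if not np.allclose(g, np.asarray(g).T):
                raise ParameterError("gamma matrices must be symmetric")


def simulate_landscape(params: LandscapeParams) -> pd.DataFrame:
    """Simulate per-fly fitness over protein:carbohydrate rails.

    Each observation sits on one rail (fixed P:C ratio) with log-normal
    variation in total intake; fitness = alpha + beta'z + 1/2 z'gamma z + eps
    with z = (P, C) and eps ~ Normal(0, noise_sd). Returns a table with
    columns sex, rail, protein_intake, carbohydrate_intake, fitness_raw.
    """
    rng = np.random.default_rng(params.seed)
    rails = np.asarray(params.rails, dtype=float)
    n_rails = rails.size
    rows = []
    for sex, beta, gamma, alpha in (
        ("F", params.beta_f, params.gamma_f, params.alpha_f),
        ("M", params.beta_m, params.gamma_m, params.alpha_m),
    ):
        beta = np.asarray(beta, dtype=float)
        gamma = np.asarray(gamma, dtype=float)
        rail_of = np.repeat(np.arange(n_rails),
                            np.diff(np.linspace(0, params.n_per_sex, n_rails + 1)
                                    .round().astype(int)))
        ratio = rails[rail_of]
        sigma2 = np.log(1.0 + params.intake_cv ** 2)
        total = params.intake_scale * rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2),
                                                    size=rail_of.size)
        P = total * ratio / (1.0 + ratio)
        C = total / (1.0 + ratio)
        z = np.column_stack([P, C])
        w = (alpha + z @ beta
             + 0.5 * np.einsum("ij,jk,ik->i", z, gamma, z))
        if params.noise_sd > 0:
            w = w + rng.normal(0.0, params.noise_sd, size=w.size)
        if sex == "M" and params.binomial_n is not None:
            prob = 1.0 / (1.0 + np.exp(-w))
            w = rng.binomial(params.binomial_n, prob) / params.binomial_n
        rows.append(pd.DataFrame({
            "sex": sex, "rail": ratio,
            "protein_intake": P, "carbohydrate_intake": C,
            "fitness_raw": w,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# annotation hierarchy


def simulate_annotation(n_genes: int, seed: int = 0,
                        root_size: int | None = None,
                        metabolic_size: int | None = None,
                        glycolysis_size: int | None = None,
                        tca_size: int | None = None,
                        ) -> tuple[GeneSetCollection, TermHierarchy]:
    """A GO-like toy annotation over the synthetic gene universe.

    ``biological_process`` (root) covers most genes; ``metabolic_process``
    is a child of the root with its own children ``glycolysis`` and
    ``tca_cycle``; ``neuronal_process`` and ``development`` are unrelated
    siblings under the root. Genes in any child term are also annotated to
    the root; grandchild genes are also in ``metabolic_process``.
    """
    if n_genes <= 0:
        raise ParameterError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    genes = np.asarray(_gene_ids(n_genes))
    root_size = root_size if root_size is not None else int(0.8 * n_genes)
    metabolic_size = (metabolic_size if metabolic_size is not None
                      else max(root_size // 4, 1))
    glycolysis_size = (glycolysis_size if glycolysis_size is not None
                       else max(metabolic_size // 8, 1))
    tca_size = tca_size if tca_size is not None else max(metabolic_size // 10, 1)
    if metabolic_size > root_size or glycolysis_size + tca_size > metabolic_size:
        raise ParameterError("term sizes are not nested")

    root = rng.choice(genes, size=root_size, replace=False)
    metabolic = rng.choice(root, size=metabolic_size, replace=False)
    grandkids = rng.choice(metabolic, size=glycolysis_size + tca_size,
                           replace=False)
    glycolysis = grandkids[:glycolysis_size]
    tca = grandkids[glycolysis_size:]
    non_metabolic = np.setdiff1d(root, metabolic)
    sib_size = max(min(len(non_metabolic), root_size // 5), 1)
    neuronal = rng.choice(non_metabolic, size=sib_size, replace=False)
    development = rng.choice(non_metabolic, size=sib_size, replace=False)

    collection = GeneSetCollection(
        sets={
            "biological_process": set(root),
            "metabolic_process": set(metabolic),
            "glycolysis": set(glycolysis),
            "tca_cycle": set(tca),
            "neuronal_process": set(neuronal),
            "development": set(development),
        },
        descriptions={
            "biological_process": "root term",
            "metabolic_process": "metabolic branch",
            "glycolysis": "carbohydrate catabolism",
            "tca_cycle": "citric acid cycle",
            "neuronal_process": "non-metabolic sibling",
            "development": "non-metabolic sibling",
        },
    )
    hierarchy = TermHierarchy([
        ("biological_process", "metabolic_process"),
        ("biological_process", "neuronal_process"),
        ("biological_process", "development"),
        ("metabolic_process", "glycolysis"),
        ("metabolic_process", "tca_cycle"),
    ])
    return collection, hierarchy


# ---------------------------------------------------------------------------
# overlap fixture


def make_overlap_fixture(universe_size: int, size_a: int, size_b: int,
                         overlap: int, seed: int = 0,
                         ) -> tuple[set[str], set[str], set[str]]:
    """Two gene sets with an exact intersection inside an explicit universe."""
    if overlap > min(size_a, size_b):
        raise ParameterError("overlap exceeds a set size")
    if max(size_a, size_b) > universe_size:
        raise ParameterError("set size exceeds universe size")
    if size_a + size_b - overlap > universe_size:
        raise ParameterError("sets cannot fit in the universe")
    rng = np.random.default_rng(seed)
    universe = np.asarray(_gene_ids(universe_size))
    picked = rng.choice(universe, size=size_a + size_b - overlap, replace=False)
    shared = picked[:overlap]
    a_only = picked[overlap:size_a]
    b_only = picked[size_a:]
    set_a = set(shared) | set(a_only)
    set_b = set(shared) | set(b_only)
    return set_a, set_b, set(universe)
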