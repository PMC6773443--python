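# sexdiet

Analysis pipeline for **sex-specific responses to dietary composition** in
*Drosophila*-style experiments that pair bulk RNA-seq with nutritional-geometry
fitness assays. The package answers two linked questions:

1. **Transcriptome** — when males and females are reared on a protein-rich
   (female-optimal, P:C 2:1) versus a carbohydrate-rich (male-optimal, 1:4)
   diet, which genes respond to diet concordantly in both sexes, which respond
   in opposite directions, and which respond in a sex-biased way?
2. **Fitness** — do the sexes differ in the nutrient intake that maximises
   fitness, judged from quadratic response surfaces over protein and
   carbohydrate intake?

## The statistics at the core

**Differential expression.** Counts for gene *g* in library *i* are modelled
as NB(μ_gi, φ_g) with variance μ + φμ², log μ_gi = offset_i + x_iᵀβ_g, and
offsets ln(N_i f_i) from TMM normalization. The design is
`~ sex + diet + sex:diet` (deviation coding by default, so the diet column is
the across-sex average diet effect). Common and gene-wise dispersions are
estimated by Cox–Reid adjusted profile likelihood with weighted-likelihood
shrinkage toward the common value (prior df 10). Each term is tested by a
nested-model likelihood-ratio χ²₁ test, with Benjamini–Hochberg FDR control.
Shared genes (detected in both sexes) are classified by their (S, D, D×S)
significance triple into three headline categories: **D** (concordant),
**D×S** (opposing), **D+D×S** (sex-biased). Per-sex diet-only refits give the
carb→protein log₂ fold changes whose cross-sex Pearson correlation measures
concordance; a gene bootstrap contrasts a target annotation term against a
"non-metabolic" baseline (parent term minus the metabolic branch).

**Fitness landscapes.** Fitness is Z-standardized within sex; linear
selection gradients β come from an OLS fit of z on (P, C), quadratic and
correlational gradients γ from the full second-order fit under the
w = α + βᵀz + ½ zᵀγz convention (γ diagonal = 2 × squared-term coefficients).
Sex differences in the whole surface are tested by a parametric bootstrap of
the likelihood ratio between a shared-surface and a sex-specific model; each
null replicate is simulated from the fitted shared model and passed through
the same per-sex Z-transformation before refitting.

Gene-list overlap uses the hypergeometric (Fisher) test against an explicit
universe with expected overlap and percent excess; correspondence between two
gene classifications uses the Pearson χ² contingency test.

All generators (counts with planted truth, GO-like annotation hierarchies,
fitness landscapes on the eight P:C rails 4:1 … 1:32) are seeded and live in
`sexdiet.synthdata`.

## Worked example

```python
from sexdiet import synthdata, de_engine, classify, concordance

params = synthdata.SimCountParams(n_genes=2000, n_D=200, n_DxS=30,
                                  n_DplusDxS=60, n_sexlim_male=50,
                                  n_sexlim_female=20, seed=1)
cm, truth = synthdata.simulate_counts(params)
part = classify.partition_by_detection(cm)
de = de_engine.de_analysis(cm.subset_genes(part.shared))
cls = classify.classify_patterns(de, alpha=0.05)
print(cls.category_counts())

fc = de_engine.per_sex_fold_changes(cm.subset_genes(part.shared))
for cat in ("D", "DxS"):
    genes = cls.table.loc[cls.table["category"] == cat, "gene"]
    print(cat, round(concordance.cross_sex_correlation(fc, genes, cat).r, 3))
```

prints

```
{'D': 233, 'DxS': 34, 'DplusDxS': 47}
D 0.911
DxS -0.938
```

i.e. of 200/30/60 planted concordant/opposing/sex-biased genes the pipeline
recovers 233/34/47 calls in the right categories (the small excesses are
boundary effects between categories), male and female fold changes correlate
at +0.91 within the concordant class and −0.94 within the opposing class —
the qualitative signature of a shared transcriptional diet response with a
small antagonistic component.

The same pipeline is scriptable end to end:

```bash
sexdiet all --seed 1 --out-dir results/
```

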