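# allohet

Allometry-based quantification and prediction of heterosis in plant
crosses.

## The problem

Heterosis — the deviation of an F1 hybrid's phenotype from its parents —
is usually approached genetically, yet parental genetic distance rarely
explains more than a few percent of its amplitude.  An alternative,
going back to Sewall Wright's model of physiological dominance, is
geometric: if two traits are linked by a *nonlinear* function, a hybrid
that is perfectly additive for the lower-level trait is automatically
non-additive for the higher-level one.  At the whole-plant scale the
relevant nonlinearities are allometric: across *Arabidopsis thaliana*
accessions, growth rate G (mg/d) follows a power law of vegetative dry
mass M (mg) with a mass-dependent exponent,

    g(M) = a · M^(b + c·log10 M),        (c < 0 → concave on log-log axes)

and fruit number F follows a right-skewed hump (inverse-quadratic)

    f(M) = M / (a + b·M + c·M²),         (interior maximum at M = √(a/c)).

`allohet` fits these curves by nonlinear least squares (plus SMA
regression for the log–log allometric exponent), quantifies per-hybrid
heterosis,

    MPH = (Y₁ₓ₂ − mean(Y₁, Y₂)) / mean(Y₁, Y₂)
    BPH = (Y₁ₓ₂ − max(Y₁, Y₂)) / max(Y₁, Y₂),

and predicts it from curvature alone: with parental masses M₁, M₂ and
hybrid mass M₁ₓ₂,

    MP_pred = (g(M₁) + g(M₂))/2,   BP_pred = max(g(M₁), g(M₂))
    NLDev_MP = (g(M₁ₓ₂) − MP_pred) / MP_pred
    NLDev_BP = (g(M₁ₓ₂) − BP_pred) / BP_pred.

Jensen's inequality makes NLDev_MP positive wherever g is concave
between the parents — mid-parent heterosis with no genetics at all.
Genetic (allele-count), geographic (great-circle) and phenotypic
(Euclidean / |ΔM|) distance baselines are included for comparison, along
with bootstrap classification of hybrids (below-worst … above-best),
broad-sense heritability H² = var(G)/(var(G)+var(residual)), and a
synthetic-data generator that emulates the reference panel design (451
accessions × 2 replicates, 450 hybrids × 4 replicates) so the entire
pipeline is testable without any external download.

It is aimed at quantitative geneticists and plant breeders who want to
ask, for their own panel: *how much of the heterosis I observe is just
the curvature of trait–trait relationships?*

## Worked example

```python
from allohet import PipelineConfig, SyntheticConfig, run_pipeline

cfg = PipelineConfig(
    synthetic=True,
    synthetic_config=SyntheticConfig(seed=1),  # panel-scale defaults
    seed=1,
    outdir="demo",
)
report = run_pipeline(cfg)
print(report["fits"]["accessions"]["growth"]["coefficients"])
print(report["nldev"]["growth_mg_per_d"]["r2_nldev_mp_vs_mph"])
```

With the default (panel-scale) synthetic configuration and seed 1 this
prints, in ~3 s:

```
{'a': 0.0185327982, 'b': 1.5478865469, 'c': -0.1775965145}
0.7700122823
```

The fitted accession growth curve recovers the generative coefficients
(a, b, c) = (0.022, 1.483, −0.164) up to sampling noise, and the
curvature-only NLDev_MP explains 77% of the variance in observed
mid-parent heterosis of growth rate — against 97% for predicting the
hybrid trait value itself (`r2_pred_vs_obs` = 0.972) and only ~10% for
the far noisier fruit-number allometry (`r2_nldev_mp_vs_mph` = 0.105).
The heterosis stage of the same report classifies 64% of hybrids as
significantly heterotic for vegetative dry mass, most of them negative,
and estimates H² between 0.91 (age) and 0.99 (mass).  Heterosis of the
*derived* traits emerges here purely from curvature: the generator gives
hybrids near-additive masses and the very same trait~mass curves as the
accessions.

The same analysis runs from the shell:

```
allohet simulate --seed 1 --out data/
allohet run-all --seed 1 --out results/            # synthetic mode
allohet nldev my_phenotypes.csv --out results/     # your own panel
```

External tables use the column schema
`genotype_id,type,parent1,parent2,experiment,replicate,mass_mg,age_d,growth_mg_per_d,fruit_n`
(CSV or TSV), SNPs as a genotype × marker 0/1 TSV, coordinates as
`genotype_id,longitude,latitude`.

## Layout

| module | contents |
| --- | --- |
| `allohet.synthetic_data` | cohort, SNP, coordinate and growth-trajectory generators |
| `allohet.phenotype_io` | table reading/validation, cross-experiment correction, genotype summaries |
| `allohet.allometry` | NLS allometric fits, AIC comparison, SMA regression, sigmoid growth fits |
| `allohet.heterosis` | MPH/BPH, bootstrap classification, heritability |
| `allohet.nldev` | curvature-based prediction and comparison with observed heterosis |
| `allohet.distances` | SNP filtering, genetic/geographic/phenotypic distances, heterosis~distance regressions |
| `allohet.pipeline`, `allohet.cli` | orchestration and the `allohet` command |

See `docs/methods.md` for the statistical details and design choices.
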