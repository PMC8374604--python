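# cuegene

Transcriptomic markers of fungal growth, respiration and carbon-use
efficiency (CUE).

## The problem

When fungi metabolize carbon they partition it between new biomass and
respired CO₂; the fraction retained in biomass is the carbon-use
efficiency,

    CUE = μ / (μ + qCO₂),

where μ (day⁻¹) is the relative growth rate, estimated from inoculum and
harvest dry masses under exponential growth as μ = ln(B_t/B₀)/t, and
qCO₂ (day⁻¹) is the metabolic quotient — respiration per unit biomass
carbon, with respiration derived from a CO₂ rise in a closed sampling
loop via the ideal gas law and biomass carbon from dry mass at an
assumed 0.43 g C per g dry mass. Direct measurement of these fluxes is
intrusive and hard outside the lab, but gene expression is not: the
transcription of 1,3-β-glucan synthase (GT48, EC 2.4.1.34; cell-wall
glucan polymerase) tracks growth, and 2-oxoglutarate dehydrogenase (KGD,
EC 1.2.4.2; the CO₂-releasing TCA-cycle step) tracks respiration. This
package implements the full analysis that turns a culture experiment
(four isolates × two nitrogen media × nine replicates) into calibrated
transcriptomic markers and a CUE index, for ecophysiologists who want to
assess fungal metabolic priorities from (meta)transcriptomes.

## The method

1. **Fluxes** (`cuegene.physiology`): μ, respiration, qCO₂ and CUE from
   raw culture measurements, with QC flags (negative growth, zero
   biomass) instead of hard failures.
2. **Expression** (`cuegene.expression`): RPKM normalization
   (count / (gene-length-kb · library-millions)), aggregation of gene
   RPKM into Enzyme Commission (EC) classes so expression is comparable
   across species, and a filter retaining classes with ≥ 10 RPKM in
   every sample.
3. **Markers** (`cuegene.markers`): log-log OLS marker models
   ln μ = α₁ + β₁ ln GT48 + ε and ln qCO₂ = α₂ + β₂ ln KGD + ε, giving
   the power laws μ̂ = e^{α₁}·GT48^{β₁} and q̂ = e^{α₂}·KGD^{β₂}; plus a
   genome-wide screen ranking every EC class by the Pearson correlation
   of its ln expression with each ln flux.
4. **Index** (`cuegene.cue_index`): the transcript index of CUE,

       CUE_gene = μ̂ / (μ̂ + q̂) = (1 + C·KGD^{β₂}/GT48^{β₁})⁻¹,
       C = e^{α₂−α₁},

   evaluated against measured CUE by untransformed linear regression.
5. **Group statistics** (`cuegene.group_stats`): two-way ANOVA
   (isolate × medium, sequential Type I SS), Tukey HSD between isolates,
   and per-isolate Welch t-tests for the medium effect.
6. **Synthetic studies** (`cuegene.synthetic`): a generator that plants
   known marker–flux power laws in a realistic count matrix and inverts
   the flux equations into raw phenotype measurements, so the entire
   pipeline is testable against ground truth without external data.

## Worked example

```python
from cuegene import StudyConfig, PipelineConfig, run_pipeline
from cuegene.pipeline import simulate_to_dir

simulate_to_dir(StudyConfig(seed=42), "demo/study")
report = run_pipeline(PipelineConfig(
    phenotypes="demo/study/phenotypes.tsv",
    counts="demo/study/counts.tsv",
    annotation="demo/study/annotation.tsv",
    metadata="demo/study/metadata.tsv",
    outdir="demo/results",
))
```

which prints (via the report dictionary):

```text
usable samples        : 62
EC classes retained   : 391 of 450
growth model (GT48)   : alpha=-9.58 beta=1.40 R2=0.57
respiration model(KGD): alpha=-6.19 beta=0.95 R2=0.37
screen rank of GT48   : 1
screen rank of KGD    : 1
compact constant      : 29.6
index vs measured CUE : slope=1.07 R2=0.57
```

The generator planted the power laws (α₁, β₁) = (−9.64, 1.4) and
(α₂, β₂) = (−6.37, 0.98) with realistic residual noise; the fitted
coefficients recover them within sampling error, both planted markers
top their genome-wide screens of ~390 retained enzyme classes, and the
derived CUE_gene index predicts measured CUE with a positive slope. The
same stages are available from the shell:

```sh
cuegene simulate --seed 42 --outdir demo/study
cuegene run --phenotypes demo/study/phenotypes.tsv \
            --counts demo/study/counts.tsv \
            --annotation demo/study/annotation.tsv \
            --metadata demo/study/metadata.tsv \
            --outdir demo/results
```

Individual stages (`fluxes`, `normalize`, `screen`, `fit`, `index`,
`stats`, `fixtures`) run standalone on the same TSV/JSON artifacts, so
externally produced tables can enter at any boundary.

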