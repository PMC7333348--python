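# phosphokin

Analysis pipeline for label-free phosphoproteomic **time courses** of
T-cell receptor (TCR) signaling: from MaxQuant-dialect quantification
tables to TCR-regulated phosphosite calls, kinetic clusters, and
enrichment statistics. A first-class synthetic-data generator produces
realistic MaxQuant-like inputs with ground truth, so every stage is
testable without any download.

## The problem

TCR engagement triggers a phosphorylation cascade that unfolds within
seconds. Label-free LC-MS quantification of phosphopeptides across a
stimulation time course (0, 15, 30, 120, 300, 600 s; TiO₂ enrichment
for pS/pT and anti-phosphotyrosine IP for the rare pY) yields a
site × run intensity matrix with intensity-dependent (MNAR) dropout.
The statistical challenge is to call sites whose phosphorylation is
regulated over the time course without letting left-censored
imputation drive the calls.

## The method

For each phosphosite (mono- and multi-phosphorylated peptide forms are
kept as independent series), after iRT-spike-in normalization of runs,
PEP ≤ 0.01 and localization ≥ 75% filters, technical-replicate
averaging and a missingness filter (≥ 3 time points with ≥ 2
biological replicates each):

1. **Stochastic left-censored imputation.** Conditions with ≤ 1
   observed replicate are filled with draws from N(q₀.₀₅, c·σ), where
   q₀.₀₅ and σ are the 5% quantile and s.d. of the observed log₂
   intensities (c = 0.3 by default).
2. **Replicate normalization**, then a one-way ANOVA over conditions
   with **Tukey HSD** post hoc (studentized-range distribution, pooled
   within-condition variance).
3. **Stability selection.** Steps 1–2 are repeated 200 times with
   fresh imputation draws. A site is *regulated* iff in ≥ 90% of
   iterations: ANOVA p ≤ 0.05 **and** some pair of time points has
   > 2 observed (non-imputed) values per side, Tukey p ≤ 0.05 and
   |fold change| ≥ 1.75.

Regulated-site kinetics (condition means of linear intensities scaled
by their maximum over the time course) are embedded with t-SNE and
clustered by local density maxima (Rodriguez–Laio): centers are points
with outlying γ = ρ·δ, where ρ is a Gaussian-kernel local density and
δ the distance to the nearest denser point. Annotation terms and
kinase-substrate sets are scored per cluster and per embedding
neighborhood (radius 4) with one-sided hypergeometric tests.
Protein-level LFQ regulation uses the same machinery with
|log₂ FC| ≥ 1 and a ≥ 2-unique-peptides filter.

## Worked example

```python
from phosphokin.benchmark import run_synthetic_pipeline
from phosphokin.simulate import GeneratorConfig

metrics, extras = run_synthetic_pipeline(
    GeneratorConfig(n_sites=1000, seed=42),  # 10% regulated, FC 2-8
    n_iter=50, base_seed=43, tsne_seed=44,
)
print(metrics["n_tested"], metrics["n_called"],
      metrics["sensitivity"], round(metrics["fdr"], 3))
```

prints `918 90 0.88 0.022`: of 1000 simulated sites (100 truly
regulated), 918 survive the quality/missingness filters, 90 are called
regulated — 88% of the true effects at an observed false-discovery
rate of 2.2%. `extras["cluster_map"]` holds the t-SNE/density-peak
clustering of the 90 called kinetics (4 clusters of sizes 33/29/22/6
here), and `extras["dataset"].truth` the generating ground truth.

The same analysis runs from files via the CLI:

```sh
phosphokin simulate --out data/ --seed 1 --n-sites 1000
phosphokin run --config cfg.yaml      # points at data/*.tsv
phosphokin eval --truth data/truth.tsv \
    --calls results/regulation_TiO2.tsv --clusters results/clusters.tsv
```

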