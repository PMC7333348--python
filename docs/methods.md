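# Methods

## Input model and parsing

The pipeline starts from MaxQuant-style output: a phosphosite table
(`Phospho (STY)Sites.txt` dialect) and optionally a protein-group
table, plus a run-design table mapping each MS run to (dataset,
enrichment channel, biological replicate, time point, technical
replicate). Intensity columns `Intensity <run>___k` carry the
multiplicity k (number of phosphates on the quantified peptide form);
each multiplicity becomes an independent quantification series,
because the mono- and multi-phosphorylated forms of a residue can have
different kinetics. Zeros are treated as absence of quantification
(missing), never as measured zeros. Column-name→run resolution can be
overridden through an `intensity_column` column in the design, since
MaxQuant headers vary between versions. Positions are 1-based protein
residue coordinates.

## Preprocessing

Stages run in a fixed order; every stage either removes rows, fills
cells, or shifts values — a present cell never becomes missing.

1. **iRT normalization.** Each run's offset is the median over spiked
   iRT standard peptides of the deviation of log₂ intensity from that
   peptide's cross-run mean; the median makes one aberrant standard
   harmless. Runs without iRT observations get offset 0 with a
   warning.
2. **Identification quality.** Contaminant/reverse entries and PSMs
   with PEP > 0.01 are removed.
3. **Localization.** Sites need localization probability ≥ 0.75 in at
   least one replicate (the boundary is inclusive and configurable;
   class bands 1–4 at >75%, >50%, >25%, ≤25% are annotated for
   diagnostics).
4. **Channel cross-filter.** pS/pT are removed from the pY-IP channel;
   pY sites are removed from TiO₂ only if they were actually
   quantified in the (filtered) pY-IP data — a pY seen only in TiO₂
   stays there.
5. **Technical averaging.** Log₂ intensities of technical MS
   replicates are averaged; a cell is missing only when all technical
   replicates are.
6. **Missingness filter.** Sites are kept when ≥ 3 conditions each
   have ≥ 2 observed biological-replicate values.

## Imputation

Missing values in a condition with ≤ 1 observed replicate are drawn
i.i.d. from N(q₀.₀₅, c·σ), with q₀.₀₅ the 5% quantile and σ the
standard deviation of all observed log₂ intensities of the channel's
matrix (each enrichment channel is fit separately, since their
intensity distributions differ). A literal draw with the full data-set
σ (≈ 2.5 log₂ units) produces implausibly wide left-censored values,
so the spread is shrunk by c = 0.3 by default; c is exposed in the
configuration and c = 1 restores the literal reading. Conditions with
≥ 2 observed values are never touched, and imputed cells are flagged
so they can be excluded from observed-point counts.

## Regulation calls

Per site and iteration: biological-replicate kinetics are mean-centered
(grand mean restored) and passed to a one-way fixed-effects ANOVA over
conditions, with all-pairs Tukey HSD (Tukey–Kramer for unequal group
sizes, pooled within-condition variance, studentized-range reference
distribution). An iteration passes when the ANOVA p ≤ 0.05 and at
least one pair of time points satisfies: > 2 observed (non-imputed)
values on each side, Tukey-adjusted p ≤ 0.05 and |log₂ FC| ≥
log₂ 1.75. The impute→normalize→test process is repeated 200 times
with iteration seeds `base_seed + i`; a site is regulated when ≥ 90%
of iterations pass. With no missing cells the procedure is fully
deterministic and seed-invariant. Imputed values participate in the
ANOVA but never in the observed-point requirement, which is what keeps
imputation from generating calls on its own: a condition poor enough
to be imputed can never anchor the qualifying pair.

Per-condition up/down labels compare each time point against the
unstimulated point: up when the median-iteration log₂ FC ≥ log₂ 1.75
and the Tukey contrast is significant in ≥ 90% of iterations; down
symmetrically. Protein LFQ regulation reuses the machinery with
|log₂ FC| ≥ 1 and a ≥ 2-unique-peptides pre-filter. No across-site
multiple-testing correction is applied (the Tukey correction is
within-site); this matches the procedure the thresholds were defined
for.

### Numerical notes

Significance decisions use studentized-range critical values per
residual df; exact tail probabilities (reported per pair as the median
over iterations) come from a Gauss–Legendre quadrature of the
studentized-range distribution, accurate to ~1e-9 against
`scipy.stats.studentized_range` but vectorized, which makes the
200 × sites × pairs workload tractable. Degenerate sites (zero
within-condition variance and equal means, F = 0/0) get p = 1 by
convention; zero variance with unequal means gives p = 0. Median
Tukey p equals the sf of the median q because the sf is monotone.

## Kinetic clustering

Regulated-site kinetics are summarized as condition means of linear
intensities (2^log₂, from one reference imputation at the base seed)
divided by the maximum across the time course, giving 6-vectors in
(0, 1] with max exactly 1. These are embedded with t-SNE (seeded;
perplexity defaults to 12 at pipeline level, capped at (n−1)/3) and
clustered on the 2D coordinates by density peaks: ρᵢ = Σ_{j≠i}
exp(−(d_ij/d_c)²) with d_c the 0.02 quantile of pairwise distances;
δᵢ the distance to the nearest denser point (global maximum: largest
pairwise distance); centers are points with γ = ρ·δ above
mean + 1.5 sd of γ; remaining points join their nearest denser
neighbor's cluster in decreasing-density order. The mean + 1.5 sd
center rule was chosen because a 3 sd rule collapses maps of a few
hundred points into 2–4 clusters; both the multiplier and d_c quantile
are configuration options, and a flag allows clustering the 6-D
kinetics directly as a robustness check. Cluster labels C1, C2, … are
ordered by time of peak and persistence, dephosphorylation clusters
(peak at t = 0) last.

## Enrichment

Over-representation uses the upper-tail hypergeometric test
P(X ≥ k) with fold change (k/n)/(K/N) against a fixed universe (all
regulated sites, or all identified units for global analyses). Gates:
keyword terms per cluster {p ≤ 0.01, FC ≥ 2, k ≥ 2}; kinase-substrate
sets per cluster {p ≤ 0.05, FC ≥ 2, k ≥ 2}, with kinases restricted
to a supplied expressed-protein list; protein-level keywords
{p ≤ 0.05, FC ≥ 1.5, k ≥ 2}. Neighborhood enrichment scores, for each
annotated site, the sites within Euclidean radius 4 of it in the
embedding (anchor included); the per-anchor p is the transparency
weight for map overlays. Annotations are supplied as plain
(term, unit) tables — no databases are downloaded, since term counts
are version-dependent; protein-level annotations are inherited by each
of the protein's sites when a site-level universe is used. No
across-term correction is applied, matching the gate definitions; a
Benjamini–Hochberg column can be added downstream if desired.

## Cross-dataset comparison

Two independently processed datasets are joined on a canonical site
key: leading accession + residue letters/positions + multiplicity
(protein-group ambiguity is deliberately collapsed to the leading
accession). Overlap counts are reported per stratum (identified /
regulated). Per-site kinetic correlation uses replicate-centered,
condition-averaged log₂ kinetics (imputed values included) and Pearson
r over conditions present in both datasets, requiring ≥ 4 shared
conditions; zero-variance kinetics are omitted with a logged reason.

## Synthetic data generator

The generator emulates the study design: 6 stimulation conditions
(0–600 s), 4 biological replicates (3 with a pY-IP channel), 3
technical runs each, and a pre-enrichment proteome channel for LFQ.
Per site: log₂ baseline ~ N(21, 2.5); regulated sites (10% by
default) add log₂(effect)·a(t) with effect uniform in [2, 8] (linear
fold change at peak) and a(t) one of 13 fixed kinetic archetypes —
transient-early (peak 15/30 s), early-sustained, early-stable,
mid-peak with decay or maintenance, gradual rising, late-rising, and
five dephosphorylation variants differing in onset and depth
(dephosphorylation templates peak at t = 0 and decay, so the site
starts elevated and loses signal). Noise: per-(site, replicate)
offsets (sd 0.25), biological variation per (site, replicate,
condition) (sd 0.25), technical noise per run (sd 0.15), and per-run
instrument offsets (sd 0.30) that are recoverable from 11 simulated
iRT standards. Dropout is MNAR: P(missing) =
logistic(−0.7·(log₂ I − 18.0)), a midpoint solved so the default
intensity distribution loses 20% of cells overall (the
`expected_missing_rate` helper integrates the model numerically).
PEP values are small with a 2% heavy tail above 0.01; 5% of sites are
poorly localized (< 75% in every replicate); 2% contaminant rows are
appended. Residues are 81/15.5/3.5% S/T/Y, matching a TiO₂-dominated
data set; pY sites live in the pY-IP channel (30% also visible in
TiO₂, exercising the cross-filter). Written tables round-trip exactly
(`%.17g` formatting, round-trip float parsing).

What the generator does *not* emulate: peptide-level identity
(shared/razor peptides), retention-time structure, correlated noise
between co-regulated sites, batch effects beyond per-run offsets, and
protein-abundance changes. Passing tests therefore demonstrate that
the statistics behave as designed under the stated noise model, not
that every real-data pathology is handled.

## Validation results and limitations

The built-in benchmarks (`phosphokin.benchmark`, run by
`scripts/acceptance.py` and the test suite) show, at the default
study scale (2,000 sites, 10% regulated):

- **Type-I calibration:** on all-null data the regulated fraction is
  well below the nominal 5% (the observed-point requirement on the
  qualifying pair makes the procedure conservative).
- **Recovery:** sensitivity ≥ 0.85 with empirical FDR ≤ 0.05 across
  seeds.
- **Cluster–archetype agreement is limited at this scale:** with only
  ~200 regulated sites spread over 13 archetypes, max-scaling maps a
  site with effect e to value 2^(−e·…) at the non-peak points, so one
  archetype spreads along an effect-size curve; together with
  biological noise this caps the adjusted Rand index against the
  generating archetypes near ~0.65 even for an oracle k-means with the
  true number of clusters, and the density-peak/t-SNE procedure
  reaches ~0.4–0.6 with 6–11 clusters. Recovering 13 distinct kinetic
  classes reliably needs several-fold more regulated sites. Cluster
  *means* remain faithful: recovered cluster mean curves correlate
  > 0.9 with their dominant archetype.

Problem sizes in the shipped benchmarks (2,000 sites / 200 iterations
for recovery; 500 sites / 50 iterations for the null calibration) are
the package's default desk-scale working points; all sizes are
parameters.
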