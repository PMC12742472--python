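# Methods

This note documents the models, conventions, and numerical choices behind
karstclpp, and what the synthetic generators do and do not emulate.

## EcoPlate geometry and the substrate registry

A 96-well EcoPlate is three replicate blocks of 32 wells (physical columns
1–4, 5–8, 9–12). Logical positions A1..H4 index wells within a block; A1 is
the water control. The default registry
(`karstclpp/data/ecoplate_substrates.tsv`) carries the standard 31-substrate
EcoPlate layout and is user-editable; any registry covering exactly the 32
logical positions is accepted. One to three inoculated blocks per plate are
supported; the model records which blocks are present and requires each
present block to be complete (all 31 substrate wells plus its own control).

## CLPP responses, AMR, and CMD

Responses are computed in two floored subtraction steps: turbidity
correction `max(OD590 − OD750, 0)` per well, then blank subtraction of the
same block's corrected control, floored again. Flooring at zero is the
standard average-well-color-development convention; it prevents inactive
wells from reducing the community mean. Blocks are averaged after per-block
blanking so block-level offsets (inoculum or reader drift per block) cancel
exactly.

AMR is the mean response over the 31 substrates. AMR is identified with the
AWCD time course; no separate AWCD statistic exists. CMD counts responses
strictly above the positivity threshold (default 0.400 OD). The threshold
is applied to the same corrected response used in AMR; internal consistency
is the reason (a plate with no activity then yields CMD = 0, matching the
zero endpoints observed under anaerobic regimes). `threshold_on="raw590"`
exposes thresholding of raw 590 nm reads instead for sensitivity analyses.
CMD percentages are `100·c/31` rounded half-up to one decimal; all printed
endpoint percentages are insensitive to the half-up vs half-even choice.

Time courses report AMR/CMD at every recorded timepoint and expose
per-phase endpoints (the last reading at or before each oxygen-phase
boundary), which covers both endpoint and time-averaged readings of
summary statistics. The built-in cultivation schedule registry pairs
aerobic and anaerobic-then-aerobic regimes at 10/20/30 °C with reading
intervals of 48 h (10 °C) and 12 h (20/30 °C).

Substrate prevalence flags carbon sources metabolized (response above
threshold) by strictly fewer than half of the samples; both the cutoff and
threshold are parameters.

## CFU per gram dry mass

Each replicate plate at dilution 10^−d with volume v mL plated estimates a
suspension concentration `count·10^d / v` CFU/mL. Multiplying by the
suspension volume gives total CFU, and dividing by dry mass (wet mass ×
dry-mass fraction) gives CFU/g DM. Dimensional analysis forces this formula
up to the averaging point; the mean and sample SD (n−1) are taken over
replicate-level estimates, and SD is reported as absent for a single
replicate. The reported SD is across plating replicates of one record, not
across dilution levels. Countable-range filtering (e.g. 30–300 colonies) is
available but off by default. Inoculum planning inverts
`stock/f × volume = target`; an understrength stock returns factor 1 with a
warning.

## Rarefaction and alpha diversity

Rarefaction subsamples each library without replacement to a common depth
(default: minimum library size) using numpy's multivariate hypergeometric
generator — an exact draw from the read multiset, bit-reproducible given
the seed. Analytic rarefaction curves use the hypergeometric expectation
`E[S_n] = Σ_i (1 − C(N−c_i, n)/C(N, n))` evaluated in log space (gammaln)
for numerical stability; Monte-Carlo mode averages observed richness over
seeded subsamples and converges to the analytic value.

Shannon uses the natural log by default (values in nats, consistent with
genus-level indices around 2–2.5 for libraries of 55–228 OTUs); `log_base`
is exposed. Simpson is the Gini–Simpson complement `1 − Σ p²` (values near
0.8–0.9 for such communities), with dominance and inverse forms available.
Indices are computed on the rarefied table by default since normalization
precedes analysis; `rarefy_first=False` computes on raw counts. Both orders
are provided because either may be encountered in published tables.

## Geochemical clustering

Samples are clustered by z-scoring each parameter (sample SD, n−1),
Euclidean distance, and complete linkage. The agglomeration is implemented
in-package so that the merge history is explicit and ties break
deterministically on the lexicographically smallest pair of member-label
tuples; it agrees with scipy's complete linkage on tie-free data (asserted
in the test suite). Complete linkage is monotone, so merge heights never
decrease; this is validated on every constructed dendrogram. Dendrograms
export to Newick with branch lengths equal to the drop between merge
heights.

Censored values ("<x") enter numeric analyses as x/2 by default (a common
convention for below-detection-limit data); zero and full-limit
substitution are provided, and the packaged-fixture cluster structure is
stable under all three.

The default variable set for sample clustering is the bulk mineral matrix
(ash, dry-mass content) plus the eleven trace metals. pH and the
nutrient-status elements (C, N, P, S, Ca, K, Mg, Na) track recent organic
input and soil acidity rather than the sediment's mineral load; including
them makes an acidic organic-rich soil sample dominate the geometry and
mask the metal-driven grouping of the sediments. The set is configurable
(`parameters=None` clusters on everything).

Regulatory exceedance is strict (`value > limit`); a censored cell can
never exceed a limit since only its upper bound is known. The report is
invariant under unit rescaling applied jointly to values and limits.

## Spearman screens

Rho is Pearson correlation of average ranks (ties averaged). Two-sided
p-values come from the t approximation `t = ρ√((n−2)/(1−ρ²))` on n−2 df
(the default, matching common statistical software), or from permutation:
full enumeration of all n! rank permutations for n ≤ 8, seeded Monte-Carlo
beyond. Zero-variance vectors make rho undefined; such pairs are flagged
and excluded from significance. No multiple-testing correction is applied;
the screen annotates raw p < α (default 0.05), as is conventional for these
exploratory taxon–environment heatmaps. Taxa can additionally be grouped by
complete-linkage clustering of their correlation profiles.

## Synthetic generators

The generators define the conditions under which the pipeline is validated;
they are fixtures with known ground truth, not mechanistic models.

* **Plates** — logistic color development
  `OD590 = turbidity + control_level + A_eff/(1 + e^{−r_eff (t − t_m)}) (+ noise)`,
  `OD750 = turbidity (+ noise)`. Control wells have A = 0. Anaerobic phases
  scale the asymptote by `anaerobic_effect` (default 0.3); temperature
  scales the rate by a peaked multiplier (0.25 / 1.0 / 0.7 at 10/20/30 °C)
  so simulated sweeps show the mesophilic ordering 20 > 30 > 10 °C.
  Noise is additive Gaussian truncated at zero (defaults: baseline 0.04 OD,
  control level 0.05 OD, rate 0.06 /h, midpoint 120 h, noise SD 0.01 OD —
  magnitudes typical of plate-reader kinetics over two-week incubations).
  At zero noise the CLPP pipeline recovers the planted positive-substrate
  count exactly and AMR converges to the planted asymptote.
* **Communities** — Dirichlet(α)-multinomial counts; defaults (50 taxa,
  concentration 0.5, libraries of a few thousand reads over 8 samples)
  produce the uneven genus-level compositions and unequal library sizes
  typical of amplicon surveys. Library sizes are hit exactly.
* **Dilution counts** — Poisson replicate counts with mean implied by a
  planted CFU/g DM under the record's dilution, volumes, and masses; the
  estimator inverts this exactly in expectation.
* **Geochemistry** — groups separated by a chosen effect size (in SD units)
  on every parameter with unit-variance noise, plus an optional outlier
  displaced 3× further, planted as ground truth for cluster recovery.

What the generators do not emulate: substrate-specific kinetic families
(diauxie, lags), reader saturation and pipetting artifacts, taxon-taxon
covariance or phylogenetic structure in communities, spatial heterogeneity
of sediments, and correlated measurement error across geochemical
parameters. Passing tests therefore demonstrate correctness of the
statistics and their implementations under controlled conditions, not
robustness to every failure mode of real plate or sequence data.

## Problem sizes and determinism

Validation suites run at desk scale by choice: Monte-Carlo rarefaction
uses 500–1000 replicates on 30–50-taxon tables; permutation agreement uses
100 seeded n = 8 cases (8! enumeration each); CFU calibration uses 200
Poisson replicates. All randomness flows through numpy `default_rng`
seeds recorded in outputs and manifests; pipeline runs are byte-identical
given a config, and a run's manifest carries the seeds, versions, and
parameter values needed to reproduce it.

## Known limitations

* Published per-sample diversity indices cannot be recomputed from counts
  here because raw sequence data live in an external archive; the packaged
  survey table carries the printed summaries only (used for read
  accounting), and no numerical match to them is asserted.
* Environmental tables assume one value per (parameter, sample); replicate
  chemistry measurements must be aggregated upstream.
* The exact-permutation p-value is O(n!) and capped at n = 8 before
  switching to Monte-Carlo.
* Kinetic parameters of observed plates are not fitted; the logistic family
  exists only on the simulation side.
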