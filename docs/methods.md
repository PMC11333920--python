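# Methods

This note documents the statistical models, numerical choices and known
limitations of `phyllonet`. It is written for users deciding whether the
defaults match their data, and for maintainers wondering why a particular
convention was chosen.

## Data model and filtering cascade

Counts live in an OTU × sample integer table with per-OTU taxonomy and
marker-group ("kingdom") labels and per-sample metadata (compartment, site,
season, year, time point). All filters are pure functions and idempotent;
they are applied in a fixed order: low-depth samples first, rare OTUs
second. The boundary conventions are deliberate and tested:

- samples with **< 50** total reads are removed (strictly below; a 50-read
  sample stays);
- OTUs with **> 50** total reads are retained (a 50-read OTU is dropped);
- for networks, an OTU is kept within a (time point, compartment) stratum
  iff it has **≥ 10** reads in **≥ 5** samples (both inclusive);
- genera totalling fewer than 50 reads are excluded before the
  environmental models.

Environmental factors are the 14 monthly TerraClimate variables (aet, def,
pdsi, pet, ppt, q, soil, srad, swe, tmax, tmin, vap, vpd, ws), keyed by
(site, year, month) and z-scored with the sample standard deviation (n−1
denominator, the default of mainstream statistics environments). Samples are
matched to factor values by the collection month of their season (spring →
March, fall → November by default).

## SparCC correlation inference

For fractions `f` estimated from counts (posterior mean `(c+1)/(N+D)` under
a uniform Dirichlet prior, or one Dirichlet draw per sample), the variation
matrix is `t_ij = Var(ln f_i − ln f_j)`, computed from the covariance of log
fractions. Under the sparsity approximation the basis variances ω solve
`[(D−2)I + J] ω = t·1`; correlations follow as
`ρ_ij = (ω_i + ω_j − t_ij)/(2√(ω_i ω_j))`, clipped to [−1, 1].

Numerical conventions:

- **Exclusion iterations.** The strongest off-diagonal pair with |ρ| above
  0.1 is removed from the linear system (its `t` entry leaves both row sums;
  the matching diagonal/off-diagonal coefficients are decremented), up to 10
  times. A pair is not excluded if either member would fall below three
  usable partners; an OTU losing all partners raises an error rather than
  producing NaNs.
- **Variance floor.** Estimated basis variances below 1e-12 are clamped with
  a warning; they arise only in degenerate toys.
- **Outer rounds.** 50 Dirichlet-resampling rounds, elementwise median.
  These defaults (0.1 / 10 / 50 / 1000 bootstraps) mirror the published
  SparCC/FastSpar defaults.
- **Bootstrap null.** Each OTU row is resampled with replacement across
  samples independently of other rows, preserving marginals while destroying
  association (`--null permute` permutes within rows instead; both are
  exposed). Bootstrap SparCC runs use 5 outer rounds for tractability; the
  count is a parameter. Two-sided p-values use the add-one rule
  `p = (k+1)/(B+1)`, so the minimum attainable p with 1000 bootstraps is
  1/1001 ≈ 9.99·10⁻⁴ and a `p ≤ .001` edge filter is attainable exactly at
  the floor — the reason the add-one convention was chosen.

D < 4 is rejected (the basis system is underdetermined), as are all-zero OTU
rows (the prevalence filter should run first).

## Networks and cohesion

Edges require `p ≤ p_max` (default .001) and non-zero correlation; isolated
OTUs are dropped, so "nodes" counts connected OTUs (edge-list semantics, as
in a network-visualisation export). Complexity is (nodes, edges, positive
edge fraction); inherited nodes are OTUs shared by consecutive time points.

Per-OTU connectivity is the mean of significant positive (respectively
negative) correlations, zero when there is no such partner. Cohesion per
sample is the RA-weighted sum of connectivities. Relative abundances are
renormalised over the network-filtered OTU set, which makes the bounds
exact: positive cohesion ∈ [0, 1], negative ∈ [−1, 0], total ∈ [0, 2]
(asserted on every output). The alternative basis (RA over the unfiltered
table, giving sums ≤ 1) is available via the `full` RA basis flag in the
cohesion call sites. Cohesion uses all significant correlations, with no
extra magnitude cutoff.

Network-level environment correlations are Pearson r of per-time-point node
counts against the cross-site mean of each factor for the matching month
(the aggregation over sites is this package's choice); per-sample total
cohesion uses Spearman ρ against the factor values matched to each sample's
site and month.

## Diversity and PERMANOVA

Shannon H uses the natural log over non-zero proportions. Bray–Curtis runs
on log10(x+1)-transformed relative abundances by default (raw mode
available). The PERMANOVA partitions the Gower-centred inner-product matrix
by sequential (Type-I) sums of squares in the user's term order; categorical
terms enter as full dummy blocks orthogonalised against earlier terms (rank
increments give the df), continuous variables as single regression columns,
and interactions as products of parent encodings. A term adding no rank
(confounded design) raises an error naming the term. Permutations are free
row permutations (no strata), with add-one p-values that can never be zero;
an exact mode enumerates all n! relabelings for n ≤ 8. The single-factor
environmental screen fits each factor alone as a one-df regression term —
the factors are continuous and are used as such, not binned into classes.
R² is scale-invariant, so whether the environment is z-scored before the
screen is immaterial.

## Per-genus environmental models

The response is the genus relative abundance on the raw fraction scale
(a logit-response variant is deliberately not the default, matching the
ordinary linear-model convention for this analysis). Before fitting,
highly collinear factors (|r| > 0.95) are removed greedily, dropping the
member of the worst pair with the higher mean absolute correlation to all
others — with TerraClimate-like factors this removes actual
evapotranspiration, which tracks potential evapotranspiration.

Subset selection is exhaustive over all non-empty subsets (8191 models for
13 factors; an optional size cap reduces this for small designs). The
selection criterion is MSEP = PRESS/n, the leave-one-out prediction error
computed in closed form from leverages (`e_loo = e/(1−h)`); subsets
containing a leverage-one point or a rank-deficient design are disqualified
(infinite MSEP). Ties break toward the smaller subset, then lexicographic
factor order, implemented by size-ascending enumeration with a
strictly-better replacement rule. PRESS is a standard, testable
prediction-error estimate; other software computes its "msep" from an
unstated formula, so exact selection matches with such tools are not
guaranteed.

The drop-one test for each selected factor uses the Gaussian
likelihood-ratio statistic `n·ln(SSE_reduced/SSE_full)` against χ²₁. (R's
`drop1(test="Chisq")` on a Gaussian GLM uses a scaled-deviance variant;
the LR form is asymptotically equivalent and is what this package
implements and calibrates.) P-values are pooled across genus × factor pairs
and BH-adjusted; significance is called at FDR < .05. The "most responsive
shared genera" ranking averages each genus's mean |coefficient| across the
two compartments over genera present in both; per-compartment scores are
also exposed.

## Synthetic data generator

The generator defines the study conditions under which the estimators are
validated:

- **Design.** 6 sites × 11 time points alternating spring/fall from spring
  2014 (spring → March, fall → November), several plants per site per time
  point, each plant yielding an epiphyte and an endophyte sample. Sequencing
  depths are uniform on 10⁴–10⁵ reads (surveys of this kind do not publish
  per-sample depths; this range is a realistic MiSeq per-sample budget and
  is fixed once here).
- **Counts.** Log basis abundances are multivariate normal with a known
  (planted) correlation matrix (log-normal basis), fractions are the closed
  basis, and counts are multinomial at the drawn depth — the standard
  benchmark regime for compositional correlation estimators. A non-PSD
  planted matrix is rejected with the offending eigenvalue.
- **Compartment gap.** Endophyte samples draw from a basis with a fixed
  random OTU subset zeroed (default keeps D/2, targeting a richness ratio
  of 2, inside the 1.6–2.6 band reported for leaf communities). Masking
  rather than depth reduction keeps the diversity gap a niche effect, not a
  sequencing artifact.
- **Environment.** factor = site offset + one-year sinusoid (factor-specific
  phase) + Gaussian noise; with positive amplitude the March/November means
  differ for most factors, mimicking the seasonal contrasts of monthly
  climate data.
- **Genus–environment links.** RA = logistic(intercept + Σβx + noise) on the
  z-scored factors, rescaled to per-sample sums ≤ 1. With zero noise the
  planted β is exactly recoverable on the logit scale.

What the generator does **not** emulate: taxonomic misassignment, chimeras
and read-level error; overdispersion beyond the log-normal–multinomial
hierarchy; temporal autocorrelation of communities between time points;
spatially correlated environments. Passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to every artifact of real amplicon data.

## Problem sizes and determinism

The validation suite runs at desk scale: SparCC recovery uses D=50 OTUs,
n=100 samples, depth 5·10⁴ with one planted ρ=0.8 (200 bootstraps in the
test suite, 1000 in the acceptance script); PERMANOVA type-I calibration
uses 500 null simulations of 12 samples at 999 permutations; the pipeline
demo uses a 16-OTU, 48-sample design. Every stochastic stage takes an
explicit seed; pipeline stages derive their seeds from one master seed by
fixed offsets, and a repeated run is bit-identical.

## Known limitations

- Field studies' headline statistics (multi-year PERMANOVA R², r≈0.7
  node–precipitation correlations) depend on their full datasets and are not
  reproducible from synthetic desk-scale data; the package validates the
  machinery, including directional contrasts between compartments.
- Kingdom-merged tables keep each marker's sequencing depth unnormalised
  (as merged OTU tables imply); cross-marker correlations therefore mix
  compositions with different denominators. Interpret cross-kingdom edges
  with this caveat.
- The bootstrap with few outer rounds (5) perturbs p-values slightly
  relative to full-strength SparCC per bootstrap; on toy suites fewer than
  10% of pairs change significance, and the round count is exposed.
- Best-subset search is exponential in the factor count; beyond ~15 factors
  use the subset-size cap.
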