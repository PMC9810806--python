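# Methods

## Data model

Counts are integral everywhere (`OtuTable`: samples × OTUs); relative
abundances exist only as a derived `RelAbundanceTable` whose rows sum to
one or are flagged empty. Taxonomy is a six-rank lineage
(kingdom…genus) per OTU, canonicalised so that no named rank sits below
an UNASSIGNED one; aggregation at a rank pools unassigned OTUs into
`unclassified <deepest assigned ancestor>` buckets (e.g. `unclassified
Chlorophyta`, `unclassified Eukaryota`). Sample metadata carries site,
season (Dec/Mar/Jun/Sep), compartment (gut | water) and, for water
samples, eleven environmental variables (Temp, DO, pH, salinity, depth,
Secchi transparency, Chl-a, COD_Mn, TP, NH4-N, TN); environmental rows
must be complete for water samples because constrained ordination
cannot use partial rows. Gut samples borrow the environment of the
paired water sample (same site and season) when ordinated.

## Consumer-read removal

Gut libraries are dominated by the consumer's own 18S reads. Removal
matches the consumer name at a configurable rank (default genus,
`Polyarthra`) and drops every matching OTU before proportions are
computed. A sample left with zero reads is retained but flagged empty
and excluded from proportion-based statistics — a real outcome when a
gut library is ~90% consumer. Counts are never rarefied or subsampled
before statistics; proportions are computed directly from reads.

## Electivity, dominance, enrichment

Electivity per taxon and season is `E = (r−p)/(r+p)` with `r` the diet
share and `p` the ambient share. Reads are pooled across sites within a
season per compartment before computing shares (one E per taxon per
season); a per-site-then-average variant is available
(`pooling="site-mean"`). `E` at `r = p = 0` is defined as 0 (a flag
returns NaN instead), matching the convention of printing 0 for taxa
absent from both pools. Classification uses strict inequalities at
±0.25: values exactly at the threshold are non-selective. The rank is a
parameter (default class).

The dominance index uses the McNaughton abundance–occupancy form
`Y_i = (n_i/N)·f_i`; under full occupancy `Y` equals the overall read
share. Other conventions exist; this one is the standard in the
regional limnological literature and is what the per-class magnitudes
in published tables of this kind correspond to.

Differential enrichment runs a two-sided Wilcoxon rank-sum test per
taxon on per-sample proportions, gut vs water. The null is the exact
rank-assignment distribution when `n1+n2 ≤ 12` with no ties, otherwise
the normal approximation with tie and continuity corrections (both
routes verified in tests against full enumeration). Benjamini–Hochberg
q-values control FDR at 0.05; per-taxon raw-p significance is reported
alongside because figure-level conventions sometimes use it. A taxon
absent from every sample gets `p = 1` by convention.

## Community comparison

Bray–Curtis `d(x,y) = Σ|x−y|/Σ(x+y)` on class-level proportions
(OTU-level available). ANOSIM ranks all pairwise distances once (ties →
mean ranks) and computes `R = (mean between-group rank − mean
within-group rank)/(n(n−1)/4)`; being rank-based it is invariant to
monotone transforms of the distances. The permutation p-value carries
the +1 correction, `p = (1+#{R* ≥ R})/(1+n_perm)`, so it is never zero.
Interpretation bands: `R > 0.75` large, `> 0.5` medium, `> 0.25` small,
else negligible (the sub-0.25 zone is unnamed in the convention; we
label it "negligible"). Heatmap ordering comes from average-linkage
agglomerative clustering; rendering is out of scope — the tested
artifacts are the distance matrix and the leaf order.

## Rarefaction and Venn

Expected richness at depth `n` uses the exact hypergeometric closed
form `E[S_n] = Σ_i [1 − C(N−N_i,n)/C(N,n)]` in log-gamma arithmetic
(stable at 60,000-read depths). Venn presence is ≥ 1 read summed per
group by default (`detection_min` configurable); no abundance filter is
applied by default.

## Ordination

Correspondence analysis is the SVD of the chi-square standardised
residual matrix `Q_ij = (p_ij − r_i c_j)/√(r_i c_j)`; total inertia is
`ΣQ²`. CCA projects `Q` onto the row-mass-weighted span of the
standardised environmental variables before the SVD; RDA projects the
centred species matrix onto the (z-scored) variables and
eigen-decomposes the fitted values on the variance scale. Collinear
environment columns are dropped with a warning. Both reproduce the
`vegan` constrained eigenvalues to numerical precision on test
fixtures, and CCA with `n−1` free dummy constraints reproduces plain CA.
Per-axis explained fractions are reported against the constrained
(community–environment) inertia; fractions against total inertia are
also available.

The DCA axis-1 gradient length starts from CA (reciprocal-averaging)
site scores and applies nonlinear rescaling by segments (defaults: 26
segments, 4 iterations): within each segment the abundance-weighted
dispersion of site scores about species optima is estimated, segment
widths are divided by the local SD, and the axis is rebuilt; the final
length is the score range divided by the global weighted SD, i.e. the
number of species-turnover SD units spanned. Exact numerical agreement
with legacy DECORANA is not claimed (its deshrinking and detrending
details differ); the tested contract is the decision rule and
monotonicity in simulated coenocline turnover. One consequence worth
knowing: on structureless data the range/SD ratio has a floor around
√12 ≈ 3.5 (uniform scores), so short true gradients read as ~3 rather
than ~1. This makes the mid-zone default matter: gradient length > 4 →
CCA, < 3 → RDA, and the [3, 4] gap defaults to CCA (the unimodal model
is safe on linear data; the reverse is not), overridable.

Forward selection is greedy on added constrained inertia. The chosen
candidate is tested by permuting the residuals of the current reduced
model (ter Braak-style): the pseudo-F is
`(added/1)/((resid − added)/df)` with `df = n − 1 − q_new`, permutation
p with the +1 correction, stop when the best candidate's `p > α`
(default 0.05). For CCA the permutation acts on the weighted residual
matrix with row weights held fixed — an approximation that calibrates
correctly in the null simulations. Step-1 false-selection rate on pure
noise is verified to sit in [0.03, 0.07] at α = 0.05.

## Synthetic study generator

The generator emulates the survey design, not the sequencer: 3 sites ×
4 seasons, one water and one gut library per site-season. Ambient
composition is Dirichlet around season-specific baselines (total
concentration 150) over 40 OTUs in 13 class groups with seasonal
succession (cryptophytes peak in December, trebouxiophytes in March,
chlorophytes in June, diatoms rising in September) and a geometric
rank-abundance split within classes. The diet is "ingestion ∝
availability × preference": `q ∝ w·p` with per-taxon weights `w`
(default 1, i.e. non-selective); no digestion-rate term is modelled
because it is unidentifiable from composition alone. Gut libraries draw
`Binomial(5500, 0.9)` consumer reads (a single OTU with genus
`Polyarthra`, so host removal is exercised by name matching) and the
remainder multinomially from `q` (~550 diet reads/sample); water
libraries are `Multinomial(60000, p)`. Eleven environmental variables
follow seasonal means for a subtropical lake plus Gaussian noise; TN,
TP and Chl-a load positively, and transparency negatively, on one
latent trophic factor with a summer-eutrophic seasonal trend. Ground
truth (per-season `p`, `q`, and `E_true = (q−p)/(q+p)`) is returned
with the tables; season-level truth uses the site-averaged `p`.

What the generator does *not* emulate: PCR/primer bias, chimeras,
sequencing error, OTU-clustering artifacts, copy-number variation, or
taxa present in gut but absent from water (detritus, terrestrial
input). Passing tests therefore demonstrate estimator correctness under
the stated generative model, not robustness to those upstream effects.
One visible consequence: because the simulated diet is a mild
reweighting of the ambient community, gut and water class profiles
separate weakly (ANOSIM R near 0), unlike surveys where digestion and
sequencing biases amplify the contrast.

## Problem sizes and numerical choices

Tests and the acceptance script use the default study size (24
samples, 40 OTUs), 199–999 permutations, 500-replicate null
calibrations, 10,000-resample Monte-Carlo rarefaction oracles, and
50-replicate parameter-recovery runs; these sizes give stable
calibration estimates (binomial SE < 0.01 on rejection rates) at
desk-scale runtimes. Eigen tolerances are 1e-10 against dense oracles;
permutation engines are `numpy.random.default_rng`-seeded and
reproducible; BH q-values are clipped to never fall below raw p; all
thresholds (E ±0.25, FDR 0.05, selection α 0.05, gradient-length 3/4)
are surfaced in the run report.

## Known limitations

- Electivity from pooled reads is a plug-in estimator; no uncertainty
  interval is attached to `E` (rare taxa at ~550 diet reads/sample are
  noisy — the recovery tests quantify this at the default depths).
- The dominance-index formula is a convention choice (see above);
  published per-class values of `Y` depend on it.
- DCA lengths are comparable within this implementation but not
  numerically interchangeable with DECORANA/vegan output (noise floor
  noted above).
- CCA forward-selection permutes weighted residuals with fixed weights;
  exactness holds only asymptotically, though calibration is verified
  at the study's n.
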