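# Methods

`dietmix` implements a dual workflow for describing the diet of a marine
top predator — here parameterised for bottlenose dolphins (*Tursiops
truncatus*) in the Gulf of Cadiz — from two independent lines of
evidence: stomach contents (ingested diet) and stable isotopes
(assimilated diet).

## Stomach-content reconstruction

Hard parts are converted to individuals with the standard counting
rules: every otolith represents 0.5 fish, diagnostic bones (premaxilla,
maxilla, cleitrum, dentary, opercula) are counted per element, and the
highest estimate across structures is kept. Half-individuals round up,
per (stomach, taxon): a detected hard part always proves at least one
individual, and published diet tables report integer counts. The paired
elements are configurable because pairing arithmetic differs between
laboratories. Cephalopods are counted as max(upper beaks, lower beaks);
when both beak sides carry measurements the lower beak is used (the
common convention in the cephalopod literature), also configurable.

Sizes are back-calculated through allometric regressions: structure
measurement (mm) → prey length (mm) via a linear or power model, length
→ wet weight (g) via a power law `w = c L^d`. Lookups are
species-first with a fallback to group-level (family) entries; a taxon
with no applicable entry keeps its count but carries no weight, and is
excluded from every weight-based statistic rather than entered at zero.
When fewer structures were measurable than individuals counted, the
total weight is the mean reconstructed individual weight times the
individual count; with one measured pair per fish this reduces to the
exact sum.

## Diet indices

For taxon *i*: `%N = 100 N_i / ΣN`, `%O = 100 O_i / n_stomachs`,
`%W = 100 W_i / ΣW` with ΣW taken over weight-bearing taxa only, and
`IRI = (%N + %W) × %O` (range 0–20,000). Two arithmetic modes exist
because published tables round percentages to two decimals *before*
forming the IRI product, which shifts the IRI in its second decimal
(e.g. (21.48 + 35.18) × 61.54 = 3486.86 versus 3486.66 unrounded).
`reporting` mode reproduces that convention with half-away-from-zero
rounding; `analysis` mode keeps full precision and is the default
everywhere else.

Prey-specific abundance follows the Amundsen–Costello definition:
`%P_i = 100 Σ W_i / Σ W_ti`, the taxon's weight share over only those
stomachs that contain it. Plotted against %O it separates specialist
(high %P) from generalist feeding and dominant from rare prey.

Bootstrap confidence limits resample whole stomachs — the sampling
unit — with replacement, recompute every index per replicate, and
report the 2.5/50/97.5 percentiles (plain percentile method; the
simplest estimator consistent with a "median and 95% confidence
limits over 1000 runs" design; BCa would require jackknife influence
values the small stomach counts cannot support). A taxon absent from a
replicate contributes zero; within a replicate, %O counts selected
stomachs with multiplicity. Correctness is established against
exhaustive enumeration of all `S^S` ordered resamples on small
instances, compared on inverted-CDF quantiles of the enumerated
population — the quantity a large percentile bootstrap converges to
when the resampling distribution is atomic.

## Source grouping

Prey species are summarised per isotope (mean, n−1 sd, min, max) and
clustered on their (δ13C, δ15N) means with Ward's minimum-variance
criterion, Euclidean distance, unstandardised ‰ axes (the two isotopes'
spreads are comparable here; a `standardize` flag exists). Both Ward
dialects are supported: `ward2` (scipy's `ward`, the Lance–Williams
recursion on squared distances) and `ward1` (the legacy recursion,
realised by feeding the recursion the square roots of the distances).
The cut level k is user-chosen; on the 12 Gulf of Cadiz species means
both dialects recover the published four groups. Group summaries pool
the species statistics exactly:

    m = Σ n_i m_i / Σ n_i
    s² = [Σ (n_i−1) s_i² + Σ n_i (m_i − m)²] / (Σ n_i − 1)

which equals recomputation from the concatenated raw values.

## Mixing model

The consumer value on isotope j is a mass-balance mixture of K
TDF-corrected sources with diet proportions p on the simplex:

    x_ij ~ Normal(m_j, √(v_j + ξ_j²))
    m_j = Σ_k p_k (μ_kj + λ_kj),   v_j = Σ_k p_k² (σ_kj² + τ_kj²)

Priors are Dirichlet(α = 1) on p and Uniform(0, upper) on the residual
scales ξ_j, with upper defaulting to twice the consumer sd on that
isotope. The residual ("process + residual") error structure is the
default and can be disabled. The discrimination factor (λ ± τ, per
isotope or per source × isotope) is a required input: no defensible
default exists for this predator's skin, so none is shipped.

Sampling is random-walk Metropolis on the additive-log-ratio transform
of p (last source as reference, log-Jacobian Σ log p_k included), which
keeps every retained draw exactly on the simplex; ξ is updated on the
log scale (Jacobian Σ log ξ_j). Proposal scales adapt in 50-draw
batches (×1.1 / ÷1.1 outside a 20–40% acceptance band) during the
first half of burn-in, then freeze, preserving detailed balance for
all retained draws. Likelihood evaluation uses per-isotope sufficient
statistics (n, Σx, Σx²), making each iteration O(K·J). The default
profile is 3 chains × (5,000 burn-in + 5,000 draws), which reaches
split-chain R̂ < 1.1 on the four-group problem in seconds; a
`--paper-scale` profile (200,000 + 300,000) is available when a
long-run posterior is wanted. Split-chain R̂ is floored at 1 (values
below 1 are estimator noise). Posterior summaries are central quantile
intervals (50/75/95%), which are nested by construction.

Correctness rests on two independent oracles: a 10,000-point quadrature
of the two-source posterior (mean and sd of p₁ matched within 3
Monte-Carlo standard errors, effective sample size from `arviz`), and
parameter recovery on synthetic four-group data (true proportions
inside their 95% credible intervals, posterior means within ±0.10).
With zero consumers the sampler reproduces its Dirichlet prior.

## Mixing-polygon validation

A mixing model can only explain consumers inside the polygon of
TDF-corrected sources, and the polygon is itself uncertain. Each of
n_iter (default 1,500) iterations draws every source position from
Normal(μ + λ, √(σ² + τ²)), builds the convex hull (Andrew's monotone
chain; degenerate one- and two-point hulls handled explicitly), and
tests every consumer with an orientation test, boundary counting as
inside (tolerance 1e-12, conservative toward acceptance). A consumer's
inside-probability is the covered fraction; the design passes when all
consumers reach the 0.05 threshold — the operational reading of "all
consumers inside the 95% mixing region". Combined source + TDF sds are
used for the vertex scatter by default; a `use_sem` option divides by
√n_k for the standard-error convention, which some applications of the
method prefer. The probability surface on a 200×200 grid (data extent
±1‰) supports 10%-step contour plots.

## Synthetic data

The stomach generator draws a per-stomach composition from
Dirichlet(concentration × base proportions), counts from a multinomial,
and lengths from per-taxon normals (magnitude-folded to keep them
positive); measurements are the inverse regression of the lengths, so
reconstruction is exact by construction and any discrepancy is a bug in
the counting or back-calculation rules, not noise. Defaults mirror the
study scale: 13 stomachs and 77 individuals per stomach (≈ 1001/13);
per-stomach diversity then resembles the reported handful of species
per stomach at moderate concentrations. Every simulated fish leaves
exactly two otoliths and every cephalopod one lower beak — digestion
loss, otolith erosion and secondary ingestion are deliberately not
simulated, so round-trip tests validate the arithmetic, not taphonomy.

The isotope generator samples consumers directly from the mixing
likelihood at a known p (default p = (0.52, 0.22, 0.13, 0.13), the
study's reported contribution pattern), with the published four-group
source summaries and n = 51 consumers as the default configuration;
residual sd defaults to 0. Isotopes are drawn independently, matching
the model's likelihood; real δ13C–δ15N correlation within sources is a
known unmodelled feature, so recovery tests say nothing about
misspecified-correlation behaviour. The global default seed is
20170912.

## Numerical conventions and limitations

- Rounding in reporting mode is half-away-from-zero at two decimals,
  applied to `repr`-level decimals to avoid binary-float artefacts.
- Percentile computations use linear interpolation between order
  statistics (numpy default); enumeration oracles use inverted-CDF
  quantiles as explained above.
- Taxon labels match case-insensitively after whitespace normalisation.
- The ALR walker is adequate for K ≲ 8 sources; larger source sets
  would want a better-mixing sampler.
- Published per-stomach raw data and the TDF values used in the
  original Gulf of Cadiz analysis were never released, so the printed
  bootstrap intervals and posterior means (52.4% / 22.3%) are not
  reproducible from public numbers; the enumeration, quadrature and
  recovery oracles above stand in for them, and the printed values that
  *are* arithmetically self-contained (Table-level indices, pooled
  group summaries, the four-group partition) are reproduced exactly.
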