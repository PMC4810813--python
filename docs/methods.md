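# Methods

## Sampling model and estimator

Fossil sampling of a clade within a geological interval of duration `d`
Myr is modelled as a homogeneous Poisson process per lineage with rate `λ`
(observations per lineage per Myr), shared by all lineages of the clade in
that interval. Two assumptions are explicit: (i) every lineage observed in
an interval is treated as extant through the whole interval, and (ii) all
lineages share the interval's sampling rate. A taxon contributes data only
if sampled at least once, so the likelihood is conditioned on `O > 0`,
giving the zero-truncated Poisson for the observed counts.

The rate MLE is found by solving the moment identity
`x/(1 − e^(−x)) = mean(O)` for `x = λd` with bracketed root-finding
(Brent, tolerance 1e−12 in `x`); this is equivalent to maximising the
truncated-Poisson likelihood and more robust than generic optimisation.
The left-hand side is increasing from 1 and strictly greater than `x`, so
`(0, mean(O)]` always brackets the root. All-singleton data (every count
1) puts the maximum at the `λ = 0` boundary: the estimate is exactly 0 and
the interval is flagged non-estimable. The profile-likelihood upper bound
is still well defined there and is reported.

The 95% confidence interval for `λ` is the set of rates whose profile
log-likelihood lies within half the χ²₁ 0.95 quantile (1.9207) of the
maximum; the two crossings are found by bisection on each flank (the lower
crossing exists strictly above 0 whenever any count exceeds 1, because the
truncated likelihood vanishes as `λ → 0`). The quantile is hard-coded for
the default 95% level and computed from `scipy.stats.chi2` for any other
level.

The detection probability is `p = 1 − e^(−λd)`; its point estimate and
bounds are the monotone transforms of the `λ` point estimate and bounds.
True richness given `n` observed taxa is the integer `N` maximising
`Binomial(n; N, p)`. The maximiser is `⌊n/p⌋` (likelihood-ratio argument;
exact ties at integral `n/p` go to the larger `N`), computed in exact
rational arithmetic on the binary value of `p` so the result is correct at
any magnitude. Richness confidence bounds are the χ²₁ profile-likelihood
bounds of the binomial likelihood *in N*: the lower richness bound is the
profile lower bound evaluated at the upper confidence limit of `p`, the
upper richness bound the profile upper bound at the lower limit of `p`.
This construction reproduces the published whole-era extrapolation for
dinosaurs (1124 observed species at p = 0.580 (0.474–0.706) → 1937
(1543–2473) against the printed 1936 (1543–2468), the differences being
rounding of the printed probabilities). When the lower `p` bound
underflows to 0, or is so small that the bound would exceed 10^15, the
upper richness bound is reported as unbounded (`inf`).

## Occurrence pipeline

Occurrence CSVs are read with a configurable column mapping whose defaults
follow PaleoDB download field names (`accepted_name`, `accepted_rank`,
`max_ma`, `min_ma`, ...). Records are filtered to the requested rank and
against exclusion lists (invalid names, ichnotaxa, ootaxa, ichno-genera);
taxon identity is the whitespace/case-normalised name with no synonymy
resolution. Each record is assigned to one stage with probability
proportional to the *overlap* (Myr) of its reported age range with each
stage — the measure-consistent reading of duration-proportional
assignment, to which it reduces when the range spans whole stages. A
zero-length range exactly on a shared boundary goes to the older stage; a
record entirely outside the timescale is dropped with a logged warning.
Because assignment is stochastic, analyses run on replicated count
matrices (default 100); a master seed spawns one child stream per
replicate so replicate `r` is reproducible independently of the number of
replicates. Replicates are aggregated per stage by medians — of the rate,
of its CI bounds, and of the observed richness (rounded half up) — with
richness re-estimated from those medians; only the median *rate* rule is
externally prescribed, and medianing the remaining quantities keeps the
chain self-consistent.

The packaged Mesozoic stage table (Induan–Maastrichtian, 30 stages) uses
GTS2012 boundaries rounded to 0.1 Ma with two documented adjustments
(Norian 228–208.5 so its duration is 19.5 Myr; Carnian late bound 228 for
contiguity). Contiguity of adjacent stages is checked to 1e−6 Ma.

## Birth–death–fossilize simulator

Each lineage independently speciates (rate `b`), goes extinct (rate `d`)
and leaves fossils (rate `λᵢ`) as competing exponential events;
fossilization does not alter demography. Lineages being independent in a
linear birth–death process, the realisation is generated breadth-first
with vectorised draws: exponential lifespans, Poisson daughter counts
placed uniformly over the parent's span inside the window (budding
convention — the parent persists), and Poisson fossil counts at
`λᵢ = mean_sampling × U(1−v, 1+v)` over the same span. Per-lineage rates
are drawn fresh for each lineage (no inheritance). A cap of 10⁵ lineages
guards against parameter combinations that explode; exceeding it raises
rather than truncating silently.

True richness of a realisation is the number of distinct lineages alive
at any point inside the window — with the budding convention that is
simply every lineage ever created before the window closes, observed or
not. The observed count is always a subset, so `N_true ≥ N_obs` holds by
construction.

Default parameter ranges are the validation study's conditions:
speciation and extinction log-uniform on 0.001–0.15 per lineage per Myr
(the upper end comparable to the fastest Cenozoic bird speciation
estimates), initial richness uniform-integer 10–250, window duration
uniform 2–20 Myr (the span of Mesozoic stage durations, Hettangian to
Norian), clade-mean sampling rate uniform 0.001–1.5 fossils per lineage
per Myr, and sampling variability `v` uniform 0–0.3 (at `v = 0.3`
per-lineage rates span 0.7–1.3 × the clade mean, i.e. twice the
coefficient of variation).

## Evaluation metrics and conventions

For each simulated clade the estimator sees only the positive fossil
counts and the window duration. Metrics:

* **success rate** — fraction of simulations whose 95% CI contains the
  truth; for the sampling rate the truth is the clade-*mean* rate (with
  heterogeneous lineages a per-lineage truth is ill-defined and the
  estimator targets the group mean);
* **mean scaled error** — signed mean of `(estimate − truth)/truth`
  (its magnitude is reported alongside);
* **Pearson ρ** between true and estimated richness.

Simulations with no estimate (nothing sampled, or all singletons) count
as coverage failures in the headline rates; rates over the estimable
subset, the number of zero-observation runs, and a correlation variant
where non-estimable runs fall back to their observed richness are all
reported so either denominator convention can be read off. The mean
scaled error and ρ are computed over estimable runs.

The study is reproducible from one seed (one spawned child stream per
simulation, parameter draw and realisation sharing the stream). The
validation study runs 10,000 simulations — large enough that the binomial
standard error on a ~36% success rate is about half a percentage point —
and completes in under a minute on one CPU. At that size the headline
metrics land at ~36% richness coverage, ~39% rate coverage, ρ ≈ 0.98–0.99
and a mean scaled error of −0.06 to −0.07 (the estimator's known slight
underestimate when within-interval turnover violates the
full-interval-extancy assumption). Coverage declines with window duration
(more turnover) and with the sampling rate (tighter, bias-dominated
intervals), which the binned success surface makes visible.

## Era aggregation and the collections diagnostic

Era-level mean rate and detection probability are means over estimable
stages weighted by estimated stage richness; CI bounds of the means are
the same weighted means of the per-stage bounds (the published tables do
not state their construction; this choice keeps bounds ordered and
interpretable). Era total richness reuses the binomial machinery at the
mean probability with the number of unique taxa observed across the era.

The collections diagnostic regresses `log₁₀` of per-stage collection
counts on stage rank order (oldest = 0) by ordinary least squares,
removing the secular trend, and correlates the residuals with the
estimated detection probabilities (point estimates only). Rank is the
default covariate because a linear detrend is not anchored to any
particular time axis; stage midpoint ages can be passed instead. Residuals
that vanish (counts exactly exponential in the covariate) make the
correlation undefined and raise.

## Synthetic fixtures

The fixture generator plants a known number of species per stage, each
sampled by a homogeneous Poisson process at a chosen rate, and emits only
species with at least one occurrence — exactly the censoring the
estimator is built for, so planted richness is a usable truth for
end-to-end tests. Age ranges equal the stage bounds, optionally widened to
force multi-stage assignment. What the fixtures (and the simulator) do
*not* emulate: heterogeneous collection effort within a stage, spatial
structure, taxonomic error, and synonymy — so green tests certify the
statistical machinery under the model's own assumptions, not robustness
to every field reality.

## Numerical choices, in one place

* χ²₁ 0.95 quantile fixed at 3.841459; confidence level configurable.
* Rate root-finding: Brent on `(0, mean]`, `xtol` 1e−12; profile
  crossings: Brent with `xtol` 1e−10 to 1e−12, upper bracket grown
  geometrically.
* Richness MLE: exact rational floor of `n/p`, ties to larger `N`;
  profile bounds in `N` by integer bisection on each flank of the
  unimodal log-likelihood (log-gamma evaluation).
* Contiguity tolerance of stage tables: 1e−6 Ma.
* Stage assignment ties (zero-overlap boundary ranges): older stage.
* Observed-richness median across replicates: rounded half up.

## Known limitations

* Within-interval turnover biases the rate downward and the detection
  probability upward; the net richness bias is small and negative, but
  the CIs are then too narrow — coverage degrades with long intervals and
  high rates. Estimates for long stages are best read as minimum richness.
* One rate per clade per interval: no species-specific or time-varying
  rates, and no hierarchical pooling across subclades.
* No taxonomic synonymy handling; database validity flags are trusted.
* The era-mean CI construction and the replicate-median conventions are
  package choices where the published account is silent (documented
  above).
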