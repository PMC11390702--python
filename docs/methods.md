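# Methods

## Scope and data model

`mdephen` analyses community flowering phenology recorded at month
resolution: for each species in each region, a first and a last flowering
month and a growth form (woody or herbaceous). The package treats the month
axis as linear within an analysis; windows that wrap the December/January
seam (legal input, encoded as first > last) are linearized by continuing the
axis past 12, and a wrapped window analysed against a non-wrapping domain is
re-cut at the seam when months are matched. Phenology is of course cyclic
rather than intrinsically bounded; the linearization is an explicit modelling
choice, shared with spatial mid-domain analyses, and the boundary rule below
is the knob that controls its consequences.

Each window is reduced to two parameters: its **duration** (count of calendar
months covered, 1–12) and its **midpoint** (real-valued; even durations give
half-month values, wrapped windows reduce modulo 12, so November–February has
midpoint 0.5). Only integer durations enter the null model; the midpoint is
descriptive.

## Domain boundaries

A region's flowering season (the *domain*, n consecutive months) is set from
the cumulative distribution of flowering records over the calendar year. A
"record" is one (species, month-in-flower) pair by default — the only reading
under which the distribution responds smoothly to flowering duration — with a
one-record-per-species (midpoint) alternative behind
`BoundaryRule(record_definition="species_midpoint")`. The domain start is the
earliest month whose cumulative fraction strictly exceeds `q_low`; the end is
the earliest month reaching `1 − q_low`. Strict-exceedance below and
reach-or-exceed above make month-resolution ties deterministic and guarantee
that at least `1 − 2·q_low` of the records fall inside the domain. The
default is `q_low = 0.05` (the stricter boundary); 0.025 is the conventional
sensitivity alternative, and `run_sensitivity` runs both and reports the
qualitative agreement (latitude-slope signs, contribution rankings) side by
side without asserting it. A legacy whole-season rule (`rule="minmax"`: min
first month to max last month) is included for comparison.

Species whose windows do not overlap the domain are dropped from that
region's analysis (and counted); overlapping windows are clipped, and the
clipped durations are what the null model resamples. This is forced by the
null model's geometry: every placed range must fit inside the bounded domain.

## The random-placement null model

The null model is the "random placement" scheme (RangeModel model 4): each
replicate draws S durations with replacement from the empirical (clipped)
duration multiset and places each at a uniformly random feasible start in the
n-month domain. Placement is parameterized by start position; for a fixed
duration on a discrete domain the feasible starts and feasible midpoints are
in bijection, so uniform-start equals the uniform-midpoint description. A
no-resampling variant (permute the exact observed multiset each replicate,
`resample=False`) is available for comparison.

Defaults are 5000 replicates and a 95% per-month envelope. The envelope is
the empirical percentile interval across replicates by default; a
normal-approximation (mean ± z·SD) option exists because simulation
envelopes are reported both ways in the literature. Replicates are generated
in fixed blocks of 256, block b of a run with seed s using generator seed
[s, b], so results are bit-reproducible and independent of how many blocks
execute.

Because ranges are i.i.d. draws, the expectation is exact and cheap:
a range of duration d covers month k with probability
`cover(d,n,k) / (n−d+1)` where `cover(d,n,k) = min(k, n−d+1) − max(1, k−d+1)
+ 1`, and E[richness_k] is S times the mixture over the empirical duration
frequencies. This analytic curve is carried alongside every simulation and
serves as the simulator's oracle in the tests (agreement within Monte Carlo
error, per-replicate month conservation, symmetry about the domain centre,
central maximum, monotone tails). It can also replace the simulated mean as
the regression predictor (`RunConfig(use_analytic=True)`); the default is
the simulated mean, matching standard RangeModel practice.

## Fit statistics

Observed monthly richness is regressed on the null prediction by ordinary
least squares with intercept; the fit is summarized by R², F = R²/(1−R²)·
(n−2) on (1, n−2) df, and the two-sided F-test P. (The analysis is sometimes
described as a generalized linear model; with F and R² as the reported
outputs it is the Gaussian-identity case, i.e. OLS.) Significance labels
follow the convention significant (p ≤ 0.05), marginally significant
(0.05 < p < 0.10, upper bound exclusive), else not significant. Fits require
at least 3 domain months and a non-constant predictor; regions or groups
failing these contracts are skipped with a logged reason rather than fitted
badly.

The latitudinal trend is OLS of per-region R² on latitude. `LatitudeFit`
carries both the plain coefficient of determination and its adjusted form;
`r2_reported` exposes the adjusted value, which is the convention used for
the published per-group trend summaries this package replays (the adjusted
values, not the plain ones, match the printed numbers, while the printed
p-values match either way).

## Climate partitioning

Monthly richness is modelled as
`log(N + c) ~ log(MDE + c) + T_min + MMP + Sunshine + (1 | region)`,
REML-fitted with statsmodels' MixedLM. The offset c defaults to 1 month⁻¹
count so that zero-richness months near domain edges stay defined; climate
covariates enter untransformed. Fixed-effect p-values use a residual-df
approximation (df = n_obs − n_fixed_effects, recorded on the result); |t| is
capped at 10⁶ when the residual variance degenerates. Fits that land on the
zero random-intercept-variance boundary are flagged `singular`, not raised.
Two numerical safeguards matter in practice: optimizers occasionally report
convergence at a spurious point, so the first two optimizers are both run
and the better restricted log-likelihood kept; and a response the fixed
effects reproduce exactly leaves REML nothing to estimate, in which case the
fit falls back to the least-squares projection with zero variance
components.

Multicollinearity is screened with VIF_j = 1/(1 − R²_j) from OLS of each
predictor on the others; perfect collinearity is an error in the full-model
fit but not in the partition (see below).

Individual contributions follow hierarchical partitioning on **marginal R²**
(fixed-effects variance over fixed + random-intercept + residual variance,
the Nakagawa decomposition, as in glmm.hp's default for lmer models;
conditional-R² mode is available). All 2^k − 1 non-empty fixed-effect subsets
are fitted with the random intercept retained, and predictor j's contribution
is the Shapley-style average of its R² increment over all orderings of
entry. The weights telescope, so the contributions sum exactly to the full
model's marginal R² (asserted to 1e-8); I.perc scales them to percentages.
Collinear subsets are reduced to a full-rank column basis before fitting —
fitted values, and hence R², are unchanged — which is what makes the
duplicated-predictor limit well-defined (two copies of one predictor split
its contribution 50/50 by symmetry). k ≤ 6 predictors are allowed (64
submodels); the study model has k = 4.

## Synthetic data

The generator emulates the statistical shape of a province-level flora
compilation so every stage is testable without external downloads. Defaults
are the emulated study's conditions: 27 regions evenly spanning 19.2–46.8° N,
600 species per region, woody fraction 0.35, and a domain length falling
linearly from 12 months at the southern end to 7 at the northern end with
the season start shifting from January to April accordingly (the
tropical-to-boreal span of the real provinces; the demo preset shrinks this
to 5 regions × 300 species for sub-minute end-to-end runs). Durations are
truncated-geometric (p = 0.35, mean ≈ 3 months) — many short, few long
flowering periods — with an empirical multiset injectable instead.

Window placement encodes the competing hypotheses:

- `mde_null` — uniform feasible starts: data that conform to the geometric
  null.
- `mid_peaked` — Gaussian weighting of window midpoints toward the domain
  centre (scale `concentration`·n), overlap stronger than the null's.
- `edge_peaked` — exponential weighting toward either season edge,
  producing detectable anti-mid-domain signal (central observed richness
  falls below the null envelope at realistic S).
- `climate_coupled` — placement weight exp(effect · T_min) using the
  *realized* monthly minimum temperature at the window midpoint, so richness
  carries a genuinely temperature-driven component, including the
  month-to-month anomalies that none of the other covariates share.

Climate series are seasonal but deliberately non-collinear: T_min is a
July-peaked cosine with latitude-dependent mean and amplitude; precipitation
a sharply summer-concentrated (von Mises-shaped) cycle, wetter in the south;
sunshine a June-peaked cosine plus a semi-annual harmonic. Three distinct
waveforms keep pooled VIFs moderate, as in real monsoon-climate normals —
with three same-frequency sinusoids any one would be an exact linear
combination of the other two. Gaussian noise (0.5 °C, 10 mm, 8 h SDs, scaled
by `noise_scale`) is added per region-month.

What the generator does *not* emulate: taxonomic structure, spatial
autocorrelation among regions, right-skewed within-window flowering
intensity, masting, species interactions, and year-to-year variation.
Passing tests therefore demonstrate correctness of the machinery and
detectability of the encoded signals, not that real floras behave this way.

## Published-table replay

A 27-province table of per-group F/R²/P and domain periods, as published for
the national-scale analysis, ships with the package (checksum-pinned;
27 rows exactly). The replay path recomputes cross-province summaries from
it — the latitude regressions of variance explained (all species adjusted
R² ≈ 0.37, herbaceous ≈ 0.30, woody not significant), the census of woody
fits with p < 0.10 (14 of 27), and the per-group R² ranges — without any
simulation. The per-province F/R²/P values themselves derive from a
16,267-species compilation that is not bundled; supplying that data (or any
flora in the same shape) through `read_flora_table` runs the full pipeline
on it.

## Problem sizes and numerical choices

Simulation defaults (5000 replicates) are used throughout the acceptance
checks; the self-consistency harness uses single regions of S = 2000 species
on a 7-month domain over 20 generator seeds, and the oracle comparison 50
randomized duration multisets on domains of 2–8 months. Percentile envelopes
use numpy's default quantile interpolation. Boundary quantile comparisons
carry a 1e-12 tolerance so that exact-fraction ties (e.g. cumulative 0.95)
resolve as reach-or-exceed regardless of float rounding. Seeds are mandatory
at every stochastic entry point; per-(region, group) simulation seeds are
derived from the study seed by CRC32 mixing, stable across processes.
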