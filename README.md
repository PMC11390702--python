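# mdephen

Mid-domain-effect null models for flowering phenology.

When species' flowering periods are placed at random within a bounded
flowering season, their overlap — and hence the number of species in flower —
peaks in mid-season purely because of geometry. `mdephen` implements this
*mid-domain effect* (MDE) as a temporal null model for community phenology:
it sets a bounded flowering domain per region from the data, simulates random
placement of the empirically sized flowering ranges inside it, measures how
much of the observed monthly richness pattern the null explains, and
partitions richness variance between the null prediction and climate. It is
aimed at macroecologists and phenologists working with floras or phenology
compilations recorded at month resolution.

## The model

Each species' flowering window (first month *f*, last month *l*; windows may
wrap the year) is reduced to a duration *d* = number of months covered and a
midpoint. A region's flowering season — the *domain* of *n* consecutive
months — is set by a quantile rule: the start (end) is the earliest month at
which the cumulative distribution of species-month flowering records exceeds
*q* (reaches 1 − *q*), with *q* = 0.05 by default and 0.025 as a sensitivity
alternative.

The null model (the "random placement" scheme of Colwell's RangeModel,
model 4) draws *S* durations with replacement from the empirical duration
distribution and gives each a uniformly random feasible position in the
domain. A range of duration *d* has *n* − *d* + 1 feasible placements, of
which min(*k*, *n* − *d* + 1) − max(1, *k* − *d* + 1) + 1 cover month *k*, so
the exact expectation is

    E[richness_k] = S · Σ_d f(d) · cover(d, n, k) / (n − d + 1),

which the package uses as an oracle for the Monte Carlo simulator (5000
replicates, per-month mean and 95% percentile envelope, by default).

Fit of observation to prediction is OLS of observed on predicted monthly
richness (R², F on (1, *n* − 2) df, two-sided P); the trend of R² with
latitude is a second OLS across regions. Finally a linear mixed model

    log(N) ~ log(MDE) + T_min + MMP + Sunshine + (1 | region)

is fitted by REML, screened with variance inflation factors, and each
predictor's individual contribution (I.perc) is obtained by hierarchical
partitioning of the marginal R² over all 2⁴ fixed-effect subsets.

## Worked example

A synthetic five-region study (300 species per region, null-conforming
placement, seed 42) analysed end to end:

```python
import mdephen as m

bundle = m.demo_study(seed=42)                       # flora + climate + latitudes
res = m.run_study(bundle, m.RunConfig(seed=42, n_reps=5000))
print(res.fits_frame()[["region_id", "latitude", "all_f", "all_r2", "all_p", "all_period"]])
```

```
region_id  latitude   all_f  all_r2  all_p all_period
      R01      19.2  34.265   0.811  0.000       2-11
      R02      26.1  25.727   0.786  0.001       3-11
      R03      33.0 273.709   0.975  0.000       3-11
      R04      39.9 129.976   0.956  0.000       3-10
      R05      46.8 231.794   0.979  0.000       4-10
```

Each row is one region: the F statistic, variance explained and P value of
observed monthly richness regressed on the null-model prediction, plus the
domain the boundary rule chose (e.g. `4-10` = April through October). Because
these data were *generated* by random placement, the null explains 79–98% of
the variance everywhere; note R² rising as the domain shortens with latitude.
The latitude trend and climate partition follow the same pattern:

```python
lat = res.latitude_fits["all"]       # slope 0.0073, adjusted R2 0.618, p 0.072
part = res.partitions["all"]         # i_perc: log_mde 59.8, t_min 13.5, mmp 12.7, sunshine 13.9
```

so the MDE term carries the largest individual contribution (59.8%) to
richness variance, as it should for null-generated data.

The same pipeline is scriptable from the shell:

```bash
mdephen synth --preset demo --seed 42 --out demo/
mdephen run-all --flora demo/flora.csv --climate demo/climate.csv \
    --latitudes demo/latitudes.csv --seed 42 --out demo/results/
mdephen replay-table1        # cross-province summaries from the packaged fit table
```

Real compilations in the same five-column shape (species, region, growth
form, first and last flowering month) can be supplied directly; column names
and delimiter are configurable via `TableDialect`.

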