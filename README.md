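# fledgeline

Breeding phenology of Alpine woodland songbirds along an elevational
gradient, estimated from citizen-science breeding-bird records.

Nationwide monitoring schemes record bird observations with standardized
integer **Atlas codes** describing breeding behaviour (13 = recently
fledged young, 16 = adult with food for nestlings, ...). These codes never
give nest-level laying or fledging dates, but they do say whether a brood
is *certainly fledged* or *certainly/likely not fledged*. `fledgeline`
turns that into a phenology estimate: the day of year on which 50% of
observed broods are certainly fledged (**t50**), how much later that date
falls at high versus low elevation, and how that delay compares with two
physical baselines — the date a daily mean temperature threshold is first
exceeded, and larch budburst.

The package is aimed at quantitative ecologists working with opportunistic
or semi-structured monitoring extracts (e.g. ornitho-style databases),
gridded daily temperature products, and phenology-network station data. A
synthetic-data module generates all three input streams with known truth,
so the entire pipeline is testable without restricted data.

## The model

Each observation *i* (species filtered beforehand; one model per species)
carries a binary response *y<sub>i</sub>* (1 = certainly fledged, from
Atlas code 13; 0 = codes 9, 15, 16, 18, 19; all other codes excluded and
counted). With z-transformed day of year *t<sub>i</sub>* and elevation
*e<sub>i</sub>*:

```
y_i ~ Bernoulli(p_i)
logit(p_i) = β0 + β1·e_i + β2·(t_i + d_year[i]) + β3·(t_i + d_year[i])·e_i
d_year     ~ Normal(0, σ)
```

The random year displacement `d_year` slides the whole seasonal curve
earlier or later per year; the slope and its elevational change are shared
across years. The 50%-fledged date follows in closed form as the root of
the linear predictor,

```
t50(e) = −(β0 + β1·e) / (β2 + β3·e) − d        (z-date scale),
```

back-transformed to day of year. Posteriors are sampled with Hamiltonian
Monte Carlo (4 chains × 2000 transitions, second halves retained → 4000
draws; non-centered year displacements; R-hat/ESS diagnostics via ArviZ).
All derived quantities — t50 per elevation, delays between elevations,
per-year deviations, fitted proportion curves — are computed per draw and
summarized with 2.5/97.5% quantiles (95% compatibility intervals).

The two baselines:

* **Exceedance days** — per grid cell and year, the first day of year (in
  a spring/early-summer window) whose daily mean temperature strictly
  exceeds a threshold; band medians at 1500 ± 100 m and 2200 ± 100 m, the
  yearly high−low difference, its median across years per threshold
  (−5…+15 °C), and an OLS trend per decade.
* **Larch budburst** — OLS of budburst day of year on elevation and year
  (both continuous), with the 1500→2200 m delay obtained by extrapolating
  the fitted line beyond the 1933 m station ceiling.

## Worked example

```python
from fledgeline import (coal_tit_preset, simulate_observations, encode_responses,
                        fit_posterior, t50_summary, elevational_delay)

truth, cond = coal_tit_preset()          # n=764 obs, 10 years, t50(1650)=165.0
obs, sidecar = simulate_observations(truth, cond["n"], cond["years"], seed=1)
encoded, excluded = encode_responses(obs)
draws = fit_posterior(encoded.dropna(subset=["response"]), seed=1)

print(t50_summary(draws).round(1).to_string(index=False))
delay = elevational_delay(draws, 1650, 2050)
print(f"delay 1650->2050 m: {delay['delay_days']:.1f} days "
      f"[{delay['ci_low']:.1f}; {delay['ci_high']:.1f}], "
      f"{delay['delay_days_per_100m']:.2f} days/100 m")
```

prints

```
 elevation_m    mode  t50_doy  ci_low  ci_high  n_nonfinite
      1650.0 average    160.1   156.9    163.5            0
      1850.0 average    166.7   164.0    169.3            0
      2050.0 average    172.5   169.6    175.3            0
delay 1650->2050 m: 12.4 days [8.6; 16.1], 3.09 days/100 m
```

Rows are posterior means and 95% intervals of the 50%-fledged day of year
at three presentation elevations for an *average* year (`d_year = 0`); the
delay line converts the 1650→2050 m difference into days per 100 m. At
n = 764 a single simulated dataset carries real sampling noise — the truth
here is t50(1650) = 165.0 and 1.5 days/100 m, and this particular
realization happens to sit low and steep (a maximum-likelihood refit of
the same dataset agrees with the posterior); across replicate datasets the
estimator is unbiased with an SD of about 1.6 days (see
`docs/methods.md`).

The same steps run from the shell:

```bash
fledgeline all --seed 1 --out demo/    # simulate + fit + exceedance + budburst
fledgeline fit --input obs.csv --species coal_tit --chains 4 --iters 2000 \
               --seed 1 --out fit/
fledgeline exceedance --input grid.csv --years 1991-2022 --out exc/
fledgeline budburst --input stations.csv --out bud/
```

Every output directory contains a `config_echo.yaml` (including the seed)
and a `run.log`; reruns with the same config and seed reproduce the
summary CSVs exactly.

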