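# chillforce

Parallel chilling–forcing dormancy modelling for temperate woody plants:
accumulate temperature-effectiveness-weighted chilling and forcing units
from hourly weather records, fit species *possibility lines* (the forcing
required for budburst as a declining exponential in chilling received),
predict budburst dates as the first line crossing, and project how
budburst shifts when monthly warming deltas are added to contemporary
climate records.

It is written for phenologists, silviculturists and nursery managers who
work with chilling-requirement species (Douglas-fir, hemlock, larch,
pines, redcedar, madrone, …) and want a testable, scriptable
implementation of the parallel dormancy model, including a synthetic-data
generator that emulates greenhouse/ambient trial regimes and multi-year
station records so the whole pipeline runs with no external data.

## The model

Hourly air temperature `T` is weighted by unitless effectiveness curves
`e_c(T)` (chilling, peaking near 2–4 °C) and `e_f(T)` (forcing, a sigmoid
saturating near 25 °C), and summed from the season start (default Nov 1):

    C(t) = Σ e_c(T_i)·Δt_i        F(t) = Σ e_f(T_i)·Δt_i     [hours]

Both accumulate in parallel until budburst — there is no spring cutoff on
chilling. The possibility line for a species is

    F_req(C) = a0 + exp(a1 + a2·C),   a0 ≥ 0, a2 ≤ 0,

and budburst is possible once `F(t) ≥ F_req(C(t))`; well-chilled plants
need less forcing. Species with an obligate chilling requirement carry a
threshold `c_min` below which budburst is impossible regardless of
forcing. Lines are fit to per-treatment (C, F) points at the date of 50%
budburst by constrained nonlinear least squares.

## Worked example

Simulate a five-regime dormancy trial (all-greenhouse "warm" through
all-outdoor "ambient", 24 seedlings each, weekly checks) from a known
obligate line, then refit the line from the simulated observations:

```sh
python analysis/01_simulate_trials.py --seed 1
python analysis/02_fit_possibility_line.py
```

prints the 50%-budburst points

```
             treatment  chill_units  force_units  reached_50
                  warm   269.627038  5496.545360           0
warm_cool_interruption   558.488647  2792.132440           1
         ambient_warm2  1652.041760   994.689685           1
         ambient_warm1  2106.413730   700.963030           1
               ambient  2681.091230   500.994550           1
```

— the warm regime accumulates too little chilling to ever reach 50%
budburst (obligate requirement unmet), while chillier regimes need
progressively less forcing — and recovers the generating line from the
four usable points:

```
  a0     fitted=       283.4  true=      300  rel.err=5.5%
  a1     fitted=      8.4723  true=      8.5  rel.err=0.3%
  a2     fitted=  -0.0011545  true=  -0.0012  rel.err=3.8%
  c_min  fitted=      279.24  true=      300  rel.err=6.9%
```

Project that line along a 20-station mild-maritime-to-cold-montane
gradient under a uniform +4 °C warming:

```sh
python analysis/03_project_warming.py --seed 1
# range: -55.5 to +28.5 days; 5 of 20 stations later, 15 earlier
```

Cold stations burst up to ~8 weeks earlier (sub-freezing hours shift into
the effective chilling range, so warming adds both chilling and forcing),
while the mildest stations burst up to ~4 weeks *later* (warming strips
their already-marginal chilling). `analysis/04_warming_sensitivity.py`
measures ~12 days earlier budburst per °C on a well-chilled site.

The same operations are available as a CLI
(`chillforce accumulate|fit|predict|project|simulate`) and as library
functions (`accumulate_units`, `fit_possibility_line`,
`predict_budburst_date`, `batch_project`, …).

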