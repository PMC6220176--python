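# pulse-coupler

Single-cell ERK activity is pulsatile: discrete bursts of kinase activity
whose frequency encodes growth-factor dose and controls proliferation.
`pulse-coupler` implements a mechanistic model in which those pulses are
triggered by localized membrane protrusions, together with the image- and
trace-analysis pipeline needed to quantify the coupling in time-lapse
microscopy — and a ground-truthed synthetic-data generator so the whole
stack runs and is tested without any external data.

It is aimed at systems-biology modellers and quantitative cell biologists
working on excitable signaling networks (Ras/PI3K), kinase translocation
reporters (KTRs), and protrusion dynamics.

## The model

Protrusive signaling on the cell perimeter is an excitable
activator–inhibitor reaction–diffusion system on a periodic 1-D ring
(300 grid points, central differences, fixed-step Euler–Maruyama at
dt = 0.01):

    ∂X/∂t = D_X ∇²X − a₁X − a₂(Y − R)X + a₃X²/(a₄² + X²) + a₅ + U_N
    ∂Y/∂t = D_Y ∇²Y + ε(−Y + b₁X)

The activator X is autocatalytic; the slower inhibitor Y (gain b₁,
time-scale ε) terminates each firing and imposes a refractory period.
R is an external (EGF-like) stimulus; U_N is zero-mean white noise on X.
Two presets, differing only in b₁ and the noise level, produce the two
observed regimes: `high_threshold` (rare localized firings → discrete ERK
pulses) and `low_threshold` (frequent firings → sustained ERK activation).

Whole-cell ERK is a zero-order ultrasensitive (Goldbeter–Koshland-type)
switch driven by the spatial mean of the inhibitor, U_E = ⟨Y⟩:

    dZ/dt = c₁( U_E(c₂ − Z)/(c₃ + (c₂ − Z)) − c₄Z/(c₃ + Z) − c₅Z )

With c₃ ≪ c₂ the converting reactions saturate and Z(U_E) is switch-like,
so protrusions covering a small arc of the perimeter still flip ERK fully
on.

## The analysis pipeline

* **FDM (frame difference method)** — per-pixel percent change between
  temporally averaged frames separated by a set interval (+100 = a
  twofold increase). Protrusions: ≥ 100% over 6 min in a band around the
  cell outline, tracked by overlap with ≥ 5 min duration and minimum-area
  filters. Interior Ras/PI3K "flashes": ≥ 10% after boundary removal.
* **Perimeter kymographs** — percent change sampled along the segmented
  cell outline, resampled by arclength, position × time.
* **Trace metrics** — C/N ratio of a translocation reporter (optionally
  volume-normalized), YFP/CFP FRET ratio, membrane-marker normalization,
  pulse calling at a 20% fractional-rise threshold, lagged Pearson
  cross-correlation, and half-maximum rise-time lags between paired
  protrusion/ERK events.

## Worked example

Render the standard synthetic movie (a circular cell with 4 planted
boundary protrusions and 2 interior flashes over 6 h at 1 frame/min),
then analyze it:

```bash
$ pulse-coupler synth --seed 4 --out out/synth
wrote 4 channels + ground truth to out/synth

$ pulse-coupler fdm --input out/synth/protrusion.tif --out out/fdm --png
4 protrusions, 2 flashes -> out/fdm
```

All four planted protrusions and both flashes are recovered; the summary
table (`out/fdm/summary.csv`) reads

```
n_protrusions,n_flashes,frequency_per_h
4,2,0.6666666666666666
```

i.e. 4 events in 360 min = 0.67 protrusions per hour. The end-to-end
pipeline (movie → FDM → reporter quantification → lag analysis) via
`pulse-coupler run` prints, for the same movie,

```
n_protrusions  n_flashes  n_pulses  frequency_per_h  best_lag_min  half_max_lag_min
            4          2         4         0.666667           6.0          6.208333
```

The 4 reporter pulses each follow a protrusion; the cross-correlogram
peaks at +6 min (reporter lags protrusion), and the mean half-maximum
rise-time lag is ≈ 6.2 min — the generator plants a 5-min signaling delay
plus a 3-min reporter rise, and the differencing interval centers the
measured lag there.

Simulate the model itself (2-h-equivalent stochastic run, high-threshold
preset, coupled ERK switch):

```bash
pulse-coupler simulate --preset high_threshold --duration 1200 --seed 3 \
    --out out/sim
```

which writes the space–time fields (`trajectory.csv`), the ERK drive
(`mean_Y.csv`) and the switch trace (`erk.csv`).

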