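# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the tests demonstrate.

## Problem setting

Daily airborne pollen concentrations (grains/m³ per 24 h) for birch
(*Betula*) and grasses (Poaceae) are forecast 1, 4 and 7 days ahead, both as
raw concentrations (regression; MAE/RMSE) and as clinical classes
(classification; overall accuracy). A pollen season runs from the first to
the last day of a calendar year with non-zero pollen; interior zero days
belong to the season. Class bounds: low ≤ 10 grains/m³ for both taxa
(zero-concentration days are assigned to "low" — the printed class ranges
start at 1 yet the class frequencies cover every season day, so zeros must
be absorbed somewhere, and "low" is the clinically conservative choice; a
separate "none" class is available via `CategoryScheme(zero_as_none=True)`);
medium ≤ 75 (birch) / ≤ 50 (grasses); high above.

MAE is implemented in its mean form `(1/N) Σ|y−ŷ|`: reported error
magnitudes in this problem (tens of grains/m³) are only consistent with a
mean, not a bare sum.

## Feature construction

**EMA features.** For window size t, `EMA_t` is the finite geometrically
weighted mean with weights (1−α)^k, k = 0 on the newest observation. The
smoothing factor defaults to α = 2/(t+1), the standard EMA convention; it is
configurable per call. Six features per base series: ema3, ema7, ema20 and
the ratios ema1/3 = x_i/ema3, ema3/7, ema7/20 ("the EMAs and their
derivatives" — no additional difference features). A zero denominator yields
the neutral ratio 1 with a logged warning: season data contain long zero
runs and dropping those rows would discard most of the low season. Rows
without a full 20-day history are dropped, not padded — padding would
fabricate pre-season values. Ratio features are computed uniformly for
pollen and all ten meteorological variables.

**Window geometry.** To predict `n` days ahead with window `w`, pollen
inputs are restricted to lags n+w … n (the `lag_indices` helper returns
these w+1 lags). The tabular table carries, per base feature, the raw lag-n
value plus the six EMA features evaluated at the last usable day (lag n for
pollen) or at the target day (meteorology). Meteorological inputs on the
target day and n days before simulate a perfect weather forecast from
recorded values, isolating the pollen-model skill from forecast error.
Sequence samples carry a pollen lag vector of length w (lags n+w−1 … n) and
a (w+n+1) × 10 meteorological matrix ending on the target day; the two
shape contracts are intentionally exact and tested.

Features are computed on the full daily panel (pollen zero outside
seasons), but rows are emitted only for within-season target dates: early
season days then have usable 20-day histories instead of being dropped
wholesale. Missing meteorological values are carried forward at most 3 days
at feature time (never by the readers); rows still missing are dropped.

## Model families

One fit/predict contract covers eight families. knn (k=5, standardized
inputs), linear (OLS for regression, multinomial logistic for direct
classification), decision tree, random forest (300 trees) and gradient
boosted trees (200 rounds, depth 6, learning rate 0.1) are the standard
library estimators, single-threaded and seeded. Every family is trained in
both tracks: native classification on the labels, and regression whose
clipped predictions are post-categorized — the two tracks are reported
separately because a regression-then-categorize pipeline and a direct
classifier answer different questions.

**Sequence nets.** The conv-LSTM and conv-GRU families are small numpy
networks written here: one valid-padding 1-D convolution over time (16
channels, kernel 3, ReLU), one recurrent layer (32 units) whose final
hidden state feeds a dense head (linear for regression on z-scored targets,
softmax for classification), trained 30 epochs with Adam (lr 3e-3, batch
64, gradient-norm clipping at 5). Gradients are exact (verified against
finite differences in the test suite's development); training is
deterministic given the seed. These are deliberately desk-scale: the point
is the architectural contract (conv → recurrent → dense over the lagged
sequences), not the capacity of a GPU-trained model. Pollen lags enter the
sequence tensor as an eleventh channel aligned with the meteorological
days, zero-filled over the embargoed last n days.

**MAGN.** The associative graph stores one sensory field per feature — its
sorted unique training values, each with a duplicate counter and a
similarity link to its value-order neighbours weighted 1 − |v_i − v_j|/range
— and one object neuron per distinct (feature row, target), with its own
duplicate counter. Prediction is lazy similarity voting: the query value
activates each field with an activation that decays linearly with
normalized distance, activation propagates to objects over their defining
links, and the k = 5 most activated objects vote with weight
activation × counter (classification: weight-majority; regression:
weighted mean; ties go to the more activated label).

Two design choices here were genuinely open and are this package's own:

* *Distance normalization.* Activation defaults to **rank distance** — the
  fraction of the field's ordered neuron chain separating query and value —
  rather than |v−q|/range. Daily pollen is heavy-tailed (season maxima three
  orders of magnitude above the median), so range-normalized distances are
  nearly flat over the bulk of the data and discriminate poorly; rank
  distance is the natural metric along the field's neighbor chain and
  handles the tails gracefully. The range form remains available
  (`activation="range"`).
* *Field relevance weighting.* Object activation is the weighted mean of
  field activations, with weights the normalized mutual information of each
  field with the training target — computed by the graph's own MI machinery
  from its value/target co-occurrences. Uninformative fields (of which the
  77-column EMA table has many) would otherwise dilute the vote. With a
  constant target the weights are uniform. The original network's
  incremental neuron-prioritization ("tuning") algorithm is out of scope;
  counters and activations are all that prediction uses.

On the calibrated 12-year benchmark these two choices lift the graph
learner from roughly the majority-class baseline to parity with the boosted
trees, which is also where a well-functioning lazy associative learner is
expected to sit relative to boosting on this problem.

**Mutual information and mining.** MI is computed in bits (log base 2) from
discrete joints; zero cells contribute nothing. Numeric variables are
discretized by equal-frequency terciles (duplicate quantile edges collapse;
ties fall to the lower bin). Normalized MI is MI(X,Y)/H(Y). Frequent
patterns are mined level-wise (apriori) over (feature, value) items with at
most one item per feature; supports, confidences and lifts are exact
`Fraction`s of counts, converted to floats only for export. Correctness is
defined against an exhaustive enumerator, which the tests run on random
fixtures. Season rules use tercile-binned 3-day trailing means of mean
temperature, cloud cover, humidity, wind speed and sunshine as antecedent
items and the day's pollen class as consequent, ranked by lift.

## Benchmark protocol

Years are split 70/30 (round-half-up on the train side, at least one year
per side) with a seeded permutation; every model in a (taxon, horizon) cell
sees the identical split, since cross-model comparability demands it. The
split is drawn per cell from the master seed; repeated seeded splits are
supported and the benchmark can be averaged over seeds. Results sort by
descending accuracy, ties by ascending MAE. Fit wall-time and peak traced
memory are recorded per model but never asserted — they are
hardware-dependent diagnostics.

## Synthetic data

Meteorology is generated first and pollen conditioned on it (weather drives
pollen, matching the causal direction the forecasting models assume). Per
year and variable the generator draws from an independent stream keyed
(seed, year, stream), so adding years never perturbs earlier ones and
identical (model, seed) gives byte-identical exports.

*Meteorology.* Mean temperature is a seasonal sinusoid (annual mean 9 °C,
amplitude 10.5 °C, peak in late July) plus stationary AR(1) anomalies
(φ = 0.72, sd 3.2 °C). Min/max temperature, humidity, cloud cover,
sunshine, wind, pressure, radiation and snow depth derive from it with
their own noise, reproducing the sign structure of real covariances (cloudy
days: cooler, more humid, less sunshine and radiation; snow only near
freezing). Values are stored as ECA&D-style tenths-unit integers.

*Pollen.* Each year draws a season window (birch: start ~ N(doy 95, 7),
length ~ N(42, 7); grasses: N(132, 6), N(115, 10)) and a log peak scale
(birch logpeak ~ N(5.8, 0.25); grasses N(4.1, 0.14)). Within the season,

    log c = logpeak · G(u) + 0.12 · T_anom − 0.5 · 1[humidity > 70 %] + AR(1) noise

with G a Gaussian bump over the relative season position (birch width 0.10
at position 0.38; grasses 0.18 at 0.32), noise sd 0.85/0.8 with AR
coefficient 0.55, exponentiated, rounded to integer grains, and zeroed with
probability 0.06 (zero inflation). The multiplicative log-normal structure
gives the heavy right tail; the bump keeps seasons unimodal.

The amplitude and width defaults were calibrated once so that simulated
within-season class frequencies over ≥ 30 years sit within ±5 percentage
points of the clinical anchor frequencies (birch 76.0/12.8/11.2 %, grasses
68.3/22.6/9.1 %), the medians stay at a few grains/m³, and birch maxima
exceed grass maxima by an order of magnitude; they are frozen in
`synthetic.py`. The within-season AR coefficient of the noise (0.55) is a
free parameter — no empirical autocorrelation figure was available to
anchor it — chosen so that day-to-day persistence is strong enough for
lag-based forecasting to be meaningfully better than the majority class,
as it is in real records.

What the generator does **not** emulate: real phenology (heat-sum season
onset, diurnal release patterns), multi-modal grass seasons, rain-washout
events, long-term climate trends, inter-annual teleconnections, or
measurement artefacts (sampler downtime, recounts). Passing tests therefore
demonstrate that the pipeline's mechanics are correct under the assumed
statistical structure — not that any model would achieve these accuracies
on a particular real monitoring series.

## Numerical and degenerate-input choices

* Dates are ISO-8601 in native files; the ECA&D reader also accepts
  YYYYMMDD. Readers never impute; quality flag 9 becomes NA, flag 1
  (suspect) is kept.
* Tenths-unit integers are preserved exactly (nullable Int64) with explicit
  SI accessors, so source files round-trip bit-exactly.
* Station distance uses the haversine formula with the IUGG mean Earth
  radius 6371.0088 km.
* Zero-denominator EMA ratios → 1 (neutral) with a warning; empty inputs,
  out-of-range α, negative concentrations, duplicate dates, unknown quality
  flags and schema mismatches raise validation errors.
* An all-zero year yields no season slice (not an error); a one-day season
  is valid.
* Pattern/rule arithmetic is exact rational until export.
* Equal-frequency binning collapses duplicate quantile edges, so
  few-distinct-value variables degrade to fewer bins rather than erroring.
* In similarity voting, a query value outside a field's training range
  clamps to the chain end; unseen categorical values contribute zero
  activation; if every activation is zero the vote falls back to duplicate
  counters.

## Interfaces

The package is a library first: the importable API plus `examples/` scripts
are the intended surface, with a thin `pollencast` CLI
(simulate / features / bench / characterize / report) over the same calls
for shell use. Reports are CSVs (results, rules, shares) plus two plots
(support-vs-confidence rule scatter, per-model accuracy overview).

## Known limitations

* The sequence nets are single-configuration and small; no early stopping,
  no hyperparameter search (deliberately out of scope for all families).
* MAGN prediction is O(objects × fields) per query — fine at desk scale,
  not tuned for millions of rows; insertion is append-and-rebuild, not the
  original incremental algorithm.
* Rule mining is exact and therefore exponential in the worst case; it is
  intended for the handful of tercile-binned antecedent variables used
  here, not for wide tables at low support.
* The 1/4/7-day horizons share one feature table geometry; sub-daily data
  and multi-station fusion are out of scope.
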