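# Methods

## Degradation model and synthetic monitoring data

Residue decay is modelled as first-order kinetics with a
condition-dependent rate constant,

    C(t) = C0 · exp(−k(T, H) · t) · (1 + ε_t),
    k(T, H) = k0 · exp(a · (T − T0)) · (1 + b · (H − H0)),

with `C0` the initial concentration (mg/kg), `k0` the base rate per day
at the reference condition (T0 = 25 °C, H0 = 65 %), `a` the exponential
temperature sensitivity (per °C), `b` the linear humidity sensitivity
(per %), and `ε_t ~ N(0, σ²)` i.i.d. multiplicative assay noise
(σ < 0.5; concentrations are clipped at 0). This is the simplest law
consistent with the qualitative behaviour of stored-grain residue
monitoring: monotone decay that accelerates with temperature (strongly)
and humidity (weakly). The exponential temperature modifier is an
Arrhenius-style simplification; the humidity modifier is linear because
the observed humidity effect is mild and monotone. A rate driven
negative by a large humidity sensitivity far below reference is clamped
to zero with a warning.

Per-pesticide defaults (chosen once, to sit near each compound's
typical residue scale in wheat and to reproduce the qualitative
ordering that dimethoate and chlorpyrifos-methyl degrade fast and
temperature-sensitively while chlorpyrifos is slow and weakly
condition-dependent):

| pesticide           | C0 (mg/kg) | k0 (/day) | a (/°C) | b (/%) | σ    |
|---------------------|-----------:|----------:|--------:|-------:|-----:|
| dimethoate          | 0.055      | 0.020     | 0.060   | 0.010  | 0.05 |
| chlorpyrifos        | 0.35       | 0.006     | 0.015   | 0.004  | 0.05 |
| chlorpyrifos-methyl | 3.5        | 0.025     | 0.055   | 0.010  | 0.05 |

The default study design is 3 pesticides × 9 conditions
({10, 25, 35} °C × {54, 65, 75} %) × 90 days = 2430 records. The
monitoring campaign the design emulates reported 2655 records without
stating the composition, so the generator exposes the grid and series
length rather than forcing a total. Regulatory maximum residue limits
default to 0.05 (dimethoate), 0.5 (chlorpyrifos) and 5 mg/kg
(chlorpyrifos-methyl); the source list for these limits names
chlorpyrifos twice and we attribute the 0.05 entry to dimethoate, which
is the standard value. A record exactly at the limit is compliant
(strict `>` flags).

**Splitting.** With N records and ratios (0.7, 0.2, 0.1), global sizes
are `train = floor(0.7·N)`, `test = round(0.2·N)`,
`validation = N − train − test` (2655 → 1858/531/266). Within each
(pesticide, condition) series the split is a chronological prefix
(train, then test, then validation), because the task is temporal and a
random split would leak future values; per-series quotas are set by
largest-remainder apportionment so the global sizes hold exactly. A
small epsilon (1e-9) is added before flooring so that float
representation error cannot flip an exact product (0.7 × 90 is 63, not
62).

**What the generator does not emulate.** Constant temperature and
humidity within a series (no weather, no diurnal cycles); no spatial
silo structure (sampling layers/points); no pest, CO₂ or moisture
dynamics; noise is i.i.d. multiplicative Gaussian with no assay drift
or detection limit censoring. Tests passing on these data therefore
demonstrate the correctness of the pipeline's arithmetic and the
forecasters' ability to learn smooth condition-dependent decay — not
performance on real monitoring data.

## Series decomposition

`trend = AvgPool(Padding(x))` with a centred odd-length window and
edge-replication padding (keeps length L and avoids injecting zeros
that would bend the trend at the boundaries); `seasonal = x − trend`.
The decomposition is additive by construction; reconstruction
`seasonal + trend` equals the input up to one float64 rounding of the
defining subtraction (≤ 1 ulp; tests bound the error at 1e-12 for
order-1 data). Multichannel sequences are decomposed
channel-independently. The standalone default window is 25 samples; the
window used inside the forecaster defaults to 9 because its decoder
sequences are only `label_length + horizon` (14 by default) samples
long. The window must satisfy `kernel ≤ 2L − 1` and be odd.

## Auto-correlation mechanism

For queries and keys of length L, lag scores are

    R(τ) = (1/L) Σ_t q_t · k_{(t+τ) mod L},   τ = 0..L−1,

averaged over channels and computed in O(L log L) as
`ifft(conj(fft(q)) · fft(k))` (Wiener–Khinchin). The conjugate is
placed on the query transform so the time-domain identity above holds
exactly as written; tests verify equality with a brute-force O(L²) loop
for every length 2–64. The top `k = ⌊factor · ln L⌋` lags are kept
(default factor 1; ties broken toward the smaller lag; lag 0 is
eligible), their scores pass through a softmax, and the output is the
weighted sum of circularly rolled value copies — position t of the copy
for lag τ holds the value from position (t+τ) mod L. The roll is
circular (not shift-and-truncate) so every copy preserves the
per-channel mean, and hence so does the convex combination.

Inside the multi-head layer, lag *selection* uses scores averaged over
batch and channels per head (one shared lag set per head per forward
pass), while the softmax *weights* are per sample, recomputed
differentiably at the selected lags. Cross-correlation against an
encoder output of different length truncates or zero-pads the key/value
source at the end to the query length.

## Forecaster architecture

Inputs are windows of `context_length` days × 3 channels
(concentration, temperature, humidity). The target channel is z-scored
per series using train-split statistics only (no leakage of test-range
levels); the covariates use pooled train statistics across series so
that between-condition contrasts survive. Predictions are
de-standardized back to mg/kg before metric computation and clipped at
zero when entering the quality index.

Encoder (N layers): auto-correlation with residual connection →
decomposition keeping the seasonal part → feed-forward (two-layer ReLU
MLP) with residual → second decomposition, again keeping the seasonal
part. Decoder input: the trailing `label_length` steps of the context
are decomposed; the seasonal part is extended by `horizon` zeros and
embedded, the trend part extended by the context mean. Decoder (M
layers), seasonal branch: self auto-correlation → cross
auto-correlation against the encoder output → feed-forward, each
followed by a decomposition whose trend components T¹, T², T³ are
accumulated into the trend branch through learned per-layer linear
projections. The forecast is `projection(seasonal) + trend` on the last
`horizon` steps. Embeddings are value projections plus a sinusoidal
day-index encoding.

Default configuration: width 32, 2 heads, 1 encoder + 1 decoder layer,
feed-forward width 64, context 14 days, label 7, horizon 7, dropout
0.05 — sized so that the full pipeline runs in minutes on one CPU. The
horizon default of 7 days also sets n in the quality index below.

**Baselines.** RNN (Elman) and LSTM encoders with a linear head mapping
the final hidden state to the horizon; the head predicts the deviation
from the last observed value (a skip connection), so an untrained
baseline starts at the repeat-last forecast and learns the decay
correction on top — without this the recurrent nets extrapolate poorly
once the test range falls below everything seen in training. The
Transformer baseline is a standard one-layer encoder–decoder with
scaled dot-product attention sharing the main model's embedding, width
and horizon. A `NaiveLastForecaster` (repeat the last observation) is
the no-skill reference.

**Training.** Adam on window MSE, batch size 64, per-epoch exponential
learning-rate decay (0.97) and global gradient-norm clipping (5.0).
Unless explicit validation windows are passed, every seventh window is
held out and the parameters from the epoch with the lowest holdout loss
are restored — small-series training otherwise shows late-run
divergence whose severity depends on the seed. Everything is
deterministic given `random_state` (initialisation, batching, dropout,
holdout). All networks run on the package's own reverse-mode autodiff
engine (`residuecast._tensor`), a deliberately small dense-float64
implementation verified against central finite differences.

## Error metrics

MAE, MSE, RMSE per their defining formulas; MAPE excludes zero-truth
points with a warning (error if all truths are zero); SMAPE uses the
symmetric denominator `(|d̂| + |d|)/2`. MAPE and SMAPE are reported as
decimals (0.04681, not 4.681 %) to match the convention of published
error tables; `as_percent=True` multiplies by 100. A literal audit mode
computes the SMAPE denominator with a minus sign; it diverges as
predictions approach the truth and is never the default. Comparison
tables store one metric report per model and expose exact pairwise
differences; CSVs round-trip at 5 decimals.

## Quality index and clustering

Row i of the quality table is `(d_i, d̄_i)`: the observed concentration
and the mean of the forecasts for days i+1..i+n (n = 7 by default,
matching the forecast horizon). Days without a full n-day forecast
window are dropped with a logged count.

K-means++ seeding: first center uniform, subsequent centers drawn with
probability `D(x)² / Σ D(x)²` where D is the distance to the nearest
chosen center; Lloyd iterations then assign to the nearest center
(Euclidean) and recompute means until the maximum center shift falls
below 1e-8 or 300 iterations. An emptied cluster is re-seeded with the
point farthest from its former center (logged). Clustering runs in the
raw mg/kg plane by default — centers are then directly interpretable as
concentrations — with a `standardize` flag for z-scored clustering.

Silhouette: `s(i) = (b(i) − a(i)) / max(a(i), b(i))` with a(i) the mean
intra-cluster distance (defined as 0 for singletons) and b(i) the
smallest mean distance to another cluster; Davies–Bouldin: mean over
clusters of `max_{j≠i} (s_i + s_j)/d_ij` with s the mean
point-to-center distance and d the center separation (coincident
centers are an error). Cluster-count selection fits each k in 2..7
(best of 10 seeded restarts by within-cluster sum of squares), chooses
the silhouette argmax, reports the Davies–Bouldin argmin alongside, and
logs — rather than silently resolving — any disagreement. The range
starts at 2 so that a three-level structure is a discovery, not an
assumption. Levels are assigned by sorting centers on the observed
component (ties on the forecast component): the lowest-residue cluster
is Level 1.

On the default synthetic data both criteria typically choose k = 2: a
smooth exponential decay cloud has no planted three-cluster structure,
so the three-level grading of real monitoring data is not an artefact
the generator reproduces. The planted-structure tests instead verify
that when three well-separated clusters exist, both criteria find them
and the level ordering follows the planted means.

## Problem sizes and runtime

The test suite trains desk-scale models only: the forecaster-skill
checks use one pesticide × three temperatures × 90 noiseless days
(129 train windows), width 64, and 60–150 epochs per model, about a
minute in total; the full pipeline smoke test uses a 2-condition,
45-day study with a width-8 model. The acceptance script adds the
noisy 2430-record default study with the width-32 default model. These
sizes are the package's demonstration defaults; all of them are
configurable upward.

## Known limitations

- The autodiff engine is dense float64 without operator fusion; it is
  sized for these models, not for large-scale training.
- Forecasts are point forecasts; no predictive intervals.
- Each pesticide is forecast independently from its own channel plus
  the shared covariates; no joint multivariate head.
- The quality grading inherits forecast error: a biased forecaster
  shifts d̄ and can move points across cluster boundaries.
- Chronological splitting means test windows extrapolate below the
  training range by construction; per-series standardization makes this
  a genuine extrapolation test but also means very short series (< ~3
  windows) cannot be used.
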