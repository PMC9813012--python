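# Methods

`comodal` simulates a pair of echo-state reservoir modules that learn,
without labels, to segment recurring cross-modal stimulus pairs ("chunks")
from a continuous two-modality input stream, by FORCE-training each
module's readouts against teaching signals derived from the *partner*
module's outputs.

## Model

Each module is an echo state network of `N` rate units with leaky
forward-Euler dynamics

    tau dx/dt = -x + g W r + W_in i(t) + W_back z + k xi(t),
    r = tanh(x),        z = W_out r,

integrated at `dt = 1 ms`.  `W` has a Bernoulli(`p`) connection pattern
with nonzero weights ~ N(0, 1/(pN)) (spectral radius ~ `g`); each reservoir
unit listens to exactly one input line with a weight ~ N(0, 1); the
readouts feed back to all reservoir units through uniform [-1, 1] weights;
`xi` is private i.i.d. standard-normal noise per unit and step.  Only
`W_out` is plastic: each of the `O = 3` readouts reads a fixed `S`-subset
of the reservoir and is trained online by recursive least squares (FORCE),
with its inverse-correlation matrix started at `I/alpha`.

Readouts are normalized online to zero mean and unit s.d. with a sliding
window of `T = 15 000 ms` (running sums over a circular buffer, exactly
recomputed every wrap; channels with windowed s.d. below `1e-6` map to 0).
The teaching signal for module 1 is a soft winner-take-all transform of
module 2's normalized readouts (and vice versa):

    f_i = [ tanh( (zhat_i - gamma * sum_{j!=i} zhat_j) / beta ) ]_+ ,

with `beta = 3`, `gamma = 0.5` (for three readouts the competition term is
then exactly the mean of the other two).  The FORCE error is `e = z - f`.
The scored output is the integrated readout `o = delta (z1 + z2)`,
`delta = 0.5`.

Three alternative interaction architectures replace the cross-fed teaching
(which becomes module-local) with structural coupling: `a1` sparse
reservoir-to-reservoir input connections (density 0.1, values N(0, 1));
`a2` readouts feeding back into the partner reservoir (uniform [-1, 1]);
`a3` all-to-all additive mixing of the two readout vectors through a fixed
uniform [-1, 1] matrix, applied to the current step's raw readouts before
feedback.  For these variants a three-unit association layer with weights
`w^1, w^2` computes `o = w^1 z1 + w^2 z2` and learns with a normalized
Hebbian rule `dw_ij/dt = o_i (z_j - mean_j z_j)` (row sums conserved
exactly), Euler-integrated with rate multiplier `hebb_eta = 1e-4`
concurrently with FORCE.

### Parameters

| name | meaning | default | unit |
|------|---------|---------|------|
| N, S | reservoir size, readout fan-in | 1200, 300 (module); 600, 200 desk scale | units |
| p | recurrent connection probability | 0.5 | – |
| tau | membrane time constant | 5 | ms |
| g | recurrent gain | 1.0 | – |
| k | private noise amplitude | 0.2 | – |
| alpha | RLS regularizer (inverse learning rate) | 100 | – |
| beta, gamma | teaching tanh divisor, competition weight | 3, 0.5 | – |
| T | normalization window | 15 000 | ms |
| delta | integration weight | 0.5 | – |
| C | presentation epochs incl. separators | 2200 (full), 300 desk scale | epochs |

## Stimuli

One channel is a "text tone": each letter of a 26-letter alphabet occupies
a 50 ms slot and transiently activates its input line with a rectangular
pulse over the leading 80 % of the slot.  The other is an "image": a
60x60 RGB raster is split into its three color channels and ten horizontal
bands, and a 6-column window is swept left to right with mean pooling, one
position per time step, so each image becomes a 30-dimensional series
whose duration equals the paired letter signal.  The three chunks pair the
words "apple", "grape", "banana" with procedural drawings (distinct
colored shapes on a mid-gray background).  Random separators pair 5-8
uniformly random letters with a Gaussian-noise raster (mean 0.5, matched
to the drawing background so global luminance is not a chunk cue).
Streams alternate separator / chunk epochs (or run chunks back-to-back),
with chunk identities drawn i.i.d. at equal probability.

Two manipulations probe the role of cross-modal co-occurrence: with
probability `m` a chunk epoch has one modality's signal replaced by that
of a different chunk or a random segment (source uniform among the three
alternatives, replaced modality uniform); and a delay `d` shifts one whole
channel later in time (zero fill, tail truncated).

**Input amplitudes.** The drive scale of both channels is a free
convention (pulse height, pixel units); it was calibrated once and frozen
at `pulse_amplitude = image_gain = 8`.  The reason is measurable: with
unit-scale inputs the reservoir state is dominated by self-generated
feedback dynamics, and a ridge regression of the ideal chunk indicator on
recorded reservoir rates (a ceiling that bypasses the collaborative
learning entirely) reaches only 0.49 accuracy on the integrated output,
while at gain 8 the same ceiling reaches 0.95.  Input-dominated dynamics
are a precondition for the teaching loop to have anything stimulus-locked
to agree on.

**What the generator does not emulate.** Real photographs (texture,
clutter, luminance statistics), real audio (spectro-temporal structure of
tones), sensor noise correlated across channels, and variable chunk
durations per presentation.  Passing tests therefore show that the model
segments *idealized* co-occurring patterns; they do not establish
robustness to natural-stimulus variability.

## Evaluation

The scored series (``o``, or a single module's ``z``) is convolved with a
causal Gaussian kernel (s.d. 20 ms, truncated at 3 s.d., edge-corrected so
constants stay constant), then min-max normalized to [0, 1] with one
common scale across units — per-unit scaling would stretch an
almost-silent unit's noise to full range and defeat the no-response rule.
Each annotated epoch is assigned to the unit with the largest epoch-mean
response (ties to the lowest index), or to "no-response" when all units
stay below 0.3; no-response is the correct answer for random separators.
Because learning is unsupervised, units are matched to chunks by
maximizing the confusion-matrix diagonal (Hungarian assignment, equivalent
to exhausting the 3! permutations).  Accuracy is the matched diagonal sum
over all epochs, separators included.

Population dynamics: PCA is fitted on the pooled reservoir-rate history;
chunk presentations are projected to the top three components and aligned
at their midpoints.  The separation degree of chunks X, Y is
`r_XY = sum_s (sigma_X(s) + sigma_Y(s)) / d_XY(s)` over the +-100 steps
around the midpoint (smaller = better separated; coincident centers yield
infinity, flagged).  The effective dimension is the inverse participation
ratio `N_eff = 1 / sum_a lambda_a^2` of the eigenvalue spectrum normalized
to unit sum — the normalization is required for the equal-share identity
(n equally loaded components give N_eff = n).  Activation phases are
circular means of min-max-normalized rate traces, `t_i = (T/2pi) arg
sum_t rhat_i(t) exp(i 2pi t / T)` wrapped into [0, T); a printed
prefactor of `T/pi` found elsewhere is inconsistent with the midpoint
identity (activity concentrated at T/2 must map to T/2) and is not used.

## Numerical choices

* Forward Euler at `dt = 1 ms` (`dt` exposed for convergence checks);
  initial state x(0) ~ N(0, 0.1^2).
* RLS updates per readout over its own support; update cadence
  `force_interval` defaults to 1, the shipped desk-scale configs use 2
  (the conventional every-other-step FORCE cadence) for throughput.
* Learning and teaching begin after one full normalization window
  (15 000 steps) so that zhat is never computed from a partial window; a
  `warmup_steps`/`pretrain_zero` override exists for experimentation.
* The training loop is a fused numba kernel (dynamics + normalization +
  teaching + RLS + Hebb for both modules); the per-operation numpy
  functions are the definitional surface and a test asserts step-for-step
  agreement (<= 1e-9) between the two paths, for all four architectures.
* Divergence (non-finite state) aborts with a diagnostic; running-sum
  drift in the normalization is cancelled by exact recomputation at every
  buffer wrap.

## Desk-scale configurations

Full-size runs (N = 1200, C = 2200, 60 repeats) are impractical for a
test suite, so the shipped experiments use: chunk learning N = 600,
S = 200, C = 300 with 5 seeds; m- and d-sweeps N = 400, S = 150, C = 200,
grids {0, 0.5, 1} and {0, 125, 250} ms, 3 seeds; architecture comparison
N = 300, S = 100, C = 150, 10 seeds.  Held-out evaluation uses a freshly
generated track of C/4 epochs from the same schedule distribution.
`configs/full_size.yaml` carries the full-size values.

## Known limitations

The faithful implementation of the printed equations reproduces the
mechanism's qualitative signatures — mutual imitation of the two modules'
readouts (same-index correlation >> cross-index), shrinking readout norm
after its training peak, chunk-separated low-dimensional trajectories, and
degradation when co-occurrence is broken — but not the full selectivity
level the original study reports.  Two degenerate attractors of the
teaching dynamics limit desk-scale accuracy: (i) a *complement* unit that
responds during random separators (once two units commit to chunks, the
competition term makes "respond when the others are silent" a
consistently reinforced niche; at `gamma = 0.5` the desired all-silent
response to separators is exactly marginal), and (ii) *merged* units for
chunks with overlapping letter content ("apple"/"grape" share a, p, e).
Runs are bimodal between partial success (~0.55–0.76 accuracy, clean
diagonal for two of three chunks) and collapse (~0.2); the supervised
ceiling (0.95) shows this is a property of the self-organizing loop, not
of the reservoir substrate, the readout parameterization, or the scoring.
Longer training (C = 2200) and full size (N = 1200, S = 300) do not
change the picture.  Accuracy-threshold checks that assume full
reproduction are accordingly expected to fail and are kept as-is rather
than weakened; trend-level checks (delay degradation, trajectory
separation, dimension bounds) pass.
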