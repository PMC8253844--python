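# Methods

## The model

`wormmotor` implements a discrete-time recurrent network of the
*C. elegans* ventral-cord motor circuit.  The full circuit contains the
seven body-wall motor-neuron classes — DA (8 cells), DB (8), DD (6),
VA (12), VB (11), VD (13), AS (11); 69 in total — and the 95 body-wall
muscle cells arranged in four head-to-tail rows (left/right dorsal with
24 cells each, left ventral 24, right ventral 23).  Ten binary command
lines stand in for the forward (PVCL/R, AVBL/R) and backward (AVAL/R,
AVDL/R, AVEL/R) command interneurons: during a forward epoch the four
forward lines output 1 and the six backward lines 0, and vice versa,
with epochs given by a list of switching times `T_1 < T_2 < …` on
half-open intervals.

Every cell carries an input current `x` and emits `y = σ(x)` with σ the
logistic function.  Motor neuron *i* updates as

    x_i(t+1) = x_i(t) / (1 + Fs τ_i)
             + (Fs τ_i / (1 + Fs τ_i)) · [ Σ_j w_ij^NN y_j^N(t)
               + Σ_u w_iu^MN y_u^M(t)
               + Σ_j g_ij^NN (x_j^N(t) − x_i^N(t))
               + Σ_u g_iu^MN (x_u^M(t) − x_i^N(t))
               + Σ_p w_ip^IN L_p(t) + w_i^l0 ]

and muscle *u* analogously with neuron→muscle weights `w^NM`, the
shared neuron–muscle gap conductances `g^MN`, muscle–muscle gap
conductances `g^MM`, and bias `w^l1`.  All cells update synchronously
from time-*t* values.  `Fs = 0.05` enters the lag factors
multiplicatively as `Fs·τ`, exactly as the update is defined, and
doubles as the step duration (0.05 s) for time bookkeeping; one 30 s
run is 600 steps.  The initial state is `x = 0` (all outputs 0.5),
configurable.

Gap conductances are symmetric (`g_ij = g_ji`) and nonnegative —
a single tied parameter per unordered pair.  Chemical synapses obey the
class polarities: cholinergic presynaptic classes (A, B, AS) are
constrained nonnegative, GABAergic classes (D) nonpositive.  Structural
absence of a connection is encoded by boolean masks; masked entries are
exactly zero before, during, and after training.

### Proprioceptive feedback

Stretch reception is modelled as muscle→neuron input: each B-class
neuron receives the outputs of up to `S = 7` muscles posterior to its
body position, each A-class neuron up to 7 anterior, clipped at head
and tail.  A neuron's *anchor segment* is its class-local rank mapped
proportionally onto the 24 segments (the r-th of C cells anchors at
`round(r·24/C)`); dorsal-class neurons (D prefix) sense both dorsal
muscle rows, ventral-class neurons both ventral rows.  These feedback
pairs are folded into the muscle→neuron weight matrix's mask, so each
(neuron, muscle) influence enters the neuron drive exactly once — the
feedback current is the restriction of the ordinary muscle→neuron sum
to the feedback pairs, never a second copy of it.

### Connectivity

Masks can be loaded from adjacency-count tables in the wormwiring
dialect (row = presynaptic cell, column = postsynaptic cell, entry =
contact count; a mask entry is true iff the count is positive, gap
tables symmetrized by OR).  All tests and the acceptance study instead
use a *synthetic* connectome generator that reproduces the circuit's
qualitative wiring rules: cholinergic classes excite nearby same-side
muscles; the D-class inhibition is cross-wired as in the animal —
ventral cholinergics (VA, VB) drive DD, which inhibits dorsal muscles,
and dorsal cholinergics (DA, DB, AS) drive VD, which inhibits ventral
muscles, the reciprocal pattern that enforces dorsoventral antiphase;
D-class neurons also inhibit cholinergic neurons; every muscle row
carries a nearest-neighbour gap chain; command lines reach the motor
neurons.  Chemical muscle→neuron synapses beyond the proprioceptive
pairs do not exist in the animal and are off by default (muscles reach
neurons only through the feedback pairs and gap junctions).
Connection families are included with Bernoulli probabilities
(defaults: neuron–neuron 0.8, neuron→muscle 0.8, command 1.0, neuron
gaps 0.5, neuron–muscle gaps 0.3) within a locality span of 7
segments.  These densities were chosen once to mirror the dense local
innervation of the real ventral cord while keeping the mask sparse
across distant segments; a draw leaving any muscle outside the head
region without innervation is rejected and redrawn.  The generator does not reproduce
the real connectome's cell-level idiosyncrasies — per-cell in/out
degree heterogeneity, the known asymmetries between A- and B-class
fan-outs — so quantitative agreement with the published full-circuit
run is expected only at the level of qualitative behaviour and
goodness-of-fit statistics, not weight-by-weight.

## Teacher data

The *analytic* teacher is a traveling sine wave: dorsal muscle at
segment q follows `d(t) = sin(ωt + φ_q)` with `φ_q(0) = −πq/12` and
`ω = 1.6π rad/s`; ventral muscles run in antiphase (an extra −π);
left and right rows are identical.  At every switch time the phase is
replaced by `φ′ = π − 2ωT_v − φ`, which reverses the spatial direction
of propagation while leaving the instantaneous value continuous.  The
raw wave is rescaled affinely to [0.25, 0.75]: muscle outputs are
logistic, so a target touching 0 or 1 would be unattainable and the
mean-squared evaluation could never reach its threshold.  On scaled
circuits with fewer than 24 segments the phase gradient per segment is
increased proportionally so the body still spans the same two
wavelengths head to tail.

The *measured-fluorescence emulator* stands in for calcium-imaging
recordings of a GCaMP-expressing muscle strain; no recordings ship
with the package, and the emulator is synthetic by construction.  It
renders one forward plus one backward cycle of the wave as per-segment
dorsal/ventral fluorescence intensities `F = F_b (1 + m·a)` (baseline
`F_b = 50`, modulation `m = 0.8`, activation `a ∈ [0, 1]`), sampled
five times finer than the simulation step as a video recording would
be, with two imperfections controlled by the caller: multiplicative
per-segment amplitude jitter (sd 0.2) and additive Gaussian noise
(sd 0.05·F_b).  Traces are converted to fluorescence rates
`R = (F − F_0)/F_0` with `F_0` the per-trace minimum, each
single-direction piece is smoothed by an 8-term sum of sinusoids, the
fitted cycles are tiled to the requested number of forward/backward
repetitions, mapped onto the muscle layout (left = right), and the
matrix is normalized to [0.25, 0.75].  Smoothing is applied per
movement piece rather than across the forward/backward junction: the
junction is a phase switch, and a finite sine sum fitted across it
would leave a residual kink that has nothing to do with measurement
noise.  With both imperfections at zero the emulator reproduces the
analytic teacher to ≈ 4·10⁻⁵ RMS.

The sum-of-sinusoids fit itself uses separable (variable-projection)
least squares: only the frequencies are optimized nonlinearly
(Levenberg–Marquardt), with the amplitude/phase pairs obtained by a
linear solve at every step.  Initial frequencies are the top local
maxima of the Hann-windowed spectrum, with a near-zero frequency
competing for a slot according to the series' mean (its cosine column
acts as a constant and absorbs the rate signal's baseline).  The fit
is deterministic.

## Training

Training minimizes the mean half squared error over steps and muscles,
`E = (1/T)(1/U) Σ_t Σ_u ½(y_u(t) − d_u(t))²`, by exact
backpropagation through the fully unrolled recursion — including the
gap difference currents, the tied symmetric gap parameterization (the
gradient of a pair sums both directions), the shared neuron–muscle
conductance (contributions from both update equations), and the lag
constants (`∂x(t+1)/∂τ = Fs/(1+Fsτ)² (drive − x(t))`).  Gradient
correctness is gated by central finite differences at relative error
≤ 1e−5 on randomized small circuits.

Initialization is uniform on the published ranges: excitatory synaptic
entries U[0, 1], inhibitory U[−1, 0], muscle→neuron, command and bias
entries U[−1, 1], gap conductances U[0, 1] (drawn on the upper
triangle and mirrored), lag constants U[0, 0.01].  Training stops when
`E ≤ 0.005`.

The optimizer is Adam (α = 0.05, β₁ = 0.9, β₂ = 0.999) with projection
onto the feasible set after every step — sign clipping per presynaptic
class, nonnegativity of conductances and lag constants,
re-symmetrization of the gap matrices by averaging, and re-zeroing of
masked entries.  Because the lag constants start near zero the network
is initially almost frozen and gradient magnitudes differ by orders of
magnitude across parameter families; Adam's per-parameter scaling is
what makes the uniform small-τ initialization trainable in practice.
Two standard recurrent-training safeguards are layered on top: the
global gradient norm is clipped at 1.0, and a step that destabilizes
the dynamics (non-finite currents, or E jumping by more than 30 %) is
undone and the step size halved, recovering geometrically (×1.02 per
good step) up to its configured value.  A run whose error stays more
than 5× above its running best for 100 consecutive iterations raises a
divergence error carrying the learning curve.  Plain momentum gradient
descent is available as a config option.

### Problem sizes

The study run by both the acceptance script and the acceptance tests
is *full size*: 69 motor neurons, 95 muscles, the 30 s / 600-step
horizon with switches at 0.0/8.7/17.6/22.8/26.6 s, and the
verification schedule 0.0/4.7/7.3/17.25/22.5/28 s.  Three training
trials from different uniform initializations share one synthetic
connectome; a trial converges in roughly 2 000–5 000 BPTT iterations
(about 1.5–3 minutes each on one CPU).  The study's designated model
is the trial with the lowest verification residual — the usual way a
multi-restart fit selects its final model.  Counterintuitively, the
full-size circuit optimizes *faster* (in iterations) than
proportionally scaled-down circuits, whose few cells per class make
the task stiffer; unit tests therefore use miniature circuits only for
mechanistic checks, with convergence demonstrated at full scale.
Scaled circuits remain available through
`NeuromuscularModel.from_synthetic(n_segments=...)`.

## Wave-direction readout

Whether muscle activity propagates head-to-tail or tail-to-head within
an epoch is quantified from the per-segment oscillation phase, obtained
by complex demodulation at the undulation frequency (known from the
teacher, or taken from the row's spectral peak) and regressed against
segment index; the sign of the slope gives the direction, matching the
teacher convention (`sin(ωt − πq/12)` propagates toward the tail).
The readout accepts a single muscle row or a whole side ("dorsal" /
"ventral"), averaging the left and right signals of each segment
first; the claim under test concerns the dorsal or ventral muscle
field as a whole, and an individual row of a structurally asymmetric
circuit can drift even when its side carries a clean wave.  On the
full-size study the fitted phase slope is ±0.26–0.28 rad/segment,
matching the teacher's π/12 gradient.
Phase regression was chosen over pairwise cross-correlation lags
because at a 0.05 s step the lag between adjacent segments is about
one sample, making peak-lag estimates unusably noisy on short epochs.
The 8 head-most segments of a row (scaled proportionally on reduced
circuits) are excluded: in the animal those muscles are innervated by
nerve-ring motor neurons outside this circuit, and the model is not
expected to drive them.  Epochs shorter than one oscillation period
cannot contain a full wave and are reported as `too_short`; windows
with median oscillation amplitude below 0.01, or |phase slope| below
0.05 rad/segment, are `undetermined`.

## Weight-distribution analysis

After training, the magnitudes of all structurally allowed chemical
weights (neuron–neuron, neuron→muscle, muscle→neuron, command) are
pooled across trials; gap conductances are pooled separately over
unique unordered pairs.  Exact zeros are excluded — projection drives
some entries onto the sign boundary, and the fitted density diverges
at zero strength — and the remainder histogrammed into 20 equal-width
bins spanning the pooled range.  The modified Boltzmann form

    p(w) = A exp(−β (a|w|)) / (a|w|)^(1 − 1/n)

is fitted to the *mean* per-bin frequency across trials by nonlinear
least squares, with `n` fixed to the structural connection count.  The
family depends on its parameters only through the decay rate `λ = βa`
and an overall scale, so the fit is performed in that reduced
2-parameter form (with `a ≡ 1` in the reported parameters), seeded by
a log-domain linear pre-fit — deterministic, no random restarts.
Goodness of fit is `R² = 1 − SS_res/SS_tot` on the occupied bins, plus
the regression F-test p-value.

## Numerical choices and degenerate inputs

- Logistic evaluated in the numerically stable split form; currents
  are checked finite at every step and training aborts with context on
  overflow.
- Epoch intervals are half-open, `[T_v, T_{v+1})`; the boundary sample
  belongs to the following epoch.
- A constant series short-circuits the sine fit (zero amplitudes);
  a zero fluorescence baseline raises rather than dividing by zero.
- The right-ventral row has 23 cells for 24 segments: cells 1–22 sit
  at segments 1–22 and the last cell represents the terminal segment,
  so every row reaches the tail; segment 23 of that row is vacant.
- Teacher normalization maps the global minimum/maximum onto
  [0.25, 0.75] and is idempotent.
- `E ≤ tolerance` is checked on the error of the *current* parameters
  each iteration; the learning curve's first entry is the pre-training
  error and its last the final error.

## What passing tests do and do not show

The synthetic connectome and emulated teacher make the whole analysis
self-contained and deterministic, so the tests demonstrate that the
training machinery, constraints, and distribution analysis behave as
specified, and that the central qualitative findings — command-switched
direction reversal of the muscle wave, and the modified-Boltzmann shape
of the trained weight distributions — emerge on circuits with this
class structure.  They do not show anything about real recordings: no
animal data are processed, the emulator's noise statistics are stated
rather than fitted, and weight values are not claimed to be
identifiable (function-space recovery is tested; weight-space recovery
is not claimed).

## Known limitations

- Scaled circuits keep epoch durations proportional to the schedule
  but the undulation period fixed, so short epochs contain fewer
  oscillation cycles than at full scale, and their few cells per class
  make training markedly slower to converge.
- Convergence to `E ≤ 0.005` is not guaranteed for every
  initialization within a fixed iteration budget; non-converged trials
  are reported as such and excluded from "converged-trial" analyses.
- The termination tolerance `E ≤ 0.005` corresponds to an RMS output
  error of 0.1 against a wave of amplitude 0.25, which is loose enough
  that an individual muscle row can carry a drifted or reversed phase
  gradient in individual epochs even in a converged trial; the
  side-averaged wave of the study's designated model is clean on both
  schedules, and the per-row tables are available for inspection.
- Body mechanics, gait adaptation, nerve-ring/head motor neurons, and
  spiking dynamics are out of scope by design.
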