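# Methods

## Model and training procedure

A trained network is an ordered list of Gaussian activation functions
(AFs) — each a center c (input units), an isotropic width σ > 0 (input
units) and an amplitude A — combined linearly through a binary blocking
layer. Kernels use the standard convention A·exp(−‖x−c‖²/(2σ²)); "width"
always means σ.

Training is greedy, one node per iteration up to `K_max`:

1. Every remaining candidate AF is tentatively appended. Its design
   column is the kernel response gated by the blocks already active
   (points blocked by earlier nodes contribute zero). All output weights
   are re-solved by least squares and two statistics are read off: the
   global error GE over all points and the local error LE over the
   points inside the candidate's receptive field (‖x−c‖ ≤ ρσ, default
   ρ = 3, covering ≈99.7% of the kernel mass). For classification the
   statistic is the misclassification ratio of the signed output (an
   exactly-zero output counts as an error — conservative and
   deterministic); for regression it is the mean absolute error.
2. Candidates are ranked by S = w·LE + (1−w)·GE + R with w the
   iteration's local weight and R a penalty on near-empty well-fitted
   neighborhoods (below). The lowest S wins; ties break on lower GE then
   lower candidate index so runs are order-independent. A candidate
   whose GE already beats the global target is taken immediately and
   ends training.
3. If the winner's LE beats the local target over at least
   `min_support` points — and this is not the final node — its blocking
   node is activated: the winner's receptive field is frozen as a
   blocked region, removed from all *later* columns (never its own).
   Blocks compose multiplicatively and are irreversible within a run.
4. After the loop, one joint least-squares solve fine-tunes all weights
   (and the bias where fitted).

Candidates with an empty receptive field get a deterministic worst-case
LE (1 for classification; the largest observed candidate MAE for
regression) so they can never win on local error.

### Local-weight schedules

The exact decay law is a design choice and is pluggable. Two families
are provided, both emitting w ∈ [0,1] with the global weight 1−w:

* `power_decay` (classification default): w(k) = w0·(1−(k−1)/K_max)^m.
  w0 ∈ [0,1] is the initial local weight, m > 0 the decay rate.
  Sanctioned node budgets are 20–40 for classification.
* `regression_ramp` (regression default): w(k) = min(1, w0·(K_max−k+1)/K_max),
  largest at the first node, where a strong local pull is needed to keep
  a high-variability waveform from being absorbed by one wide kernel.
  Budgets of 4–7 nodes are typical for waveforms.
* `constant`: w(k) = w0, used where a K_max-independent selection
  sequence is required (see nestedness below).

For waveforms, w0 is chosen per signal by an exhaustive grid over
{1.0, 0.9, …, 0.0} (11 runs), keeping the model with the lowest relMAE
(ties: lower relSDE, then the earlier grid entry). The w0 = 0 entry is
run as the multi-kernel baseline: a zero local weight means local
statistics never influence selection, so blocking is not part of that
degenerate run either.

### The small-neighborhood penalty R

When a candidate's LE already beats the local target (i.e. blocking
would trigger), a kernel fitting a single low-magnitude point must not
win on local error alone. R engages only then:
R = scale·max(0, 1 − support/min_support), additive on the error scale,
default scale 1. Whether the condition should enter additively or
multiplicatively is not determined by theory; the additive form keeps
every term on the error scale and is isolated in one function
(`selection.support_condition`). With `min_support = 0` the penalty is
off — the configuration used for the waveform experiments.

### Baselines

* **MKRBF** (multi-kernel): the identical loop with w ≡ 0 and blocking
  off; bit-identical by construction to the multi-scale network run with
  those settings, which pins down exactly what the local statistics add.
* **SKRBF** (single-width): one shared σ (given, or searched over a
  small span-relative grid), centers free on the training points plus an
  even grid over the input bounding box, global-error-only selection,
  no blocking.

### Candidate pools

* Regression: data-anchored — every bin whose amplitude exceeds the
  noise floor contributes (center = bin position, amplitude = bin
  amplitude), crossed with `n_widths` (default 50) widths evenly spaced
  over the half-open interval (0, T/6], T the record span; zero is
  excluded because widths must be positive. The noise floor is the
  maximum amplitude of the leading 150 bins (configurable prefix).
* Classification: random — centers drawn from training points, widths
  uniform over a configured range, amplitude fixed to 1 since the output
  least squares absorbs scale; or evolved by the genetic search.

### Genetic candidate search

One GA run per node iteration (matching the sequential selection loop),
on two-gene genomes (training-point index, width): tournament selection
(size 3), one-point crossover, Gaussian width mutation (sd = 10% of the
width range, clipped), center re-draw mutation, one elite carried over
unchanged — since fitness is deterministic, the best fitness is
non-increasing across generations. Fitness is the selection score S
minus a receptive-field occupancy bonus (support/n, weight 0.1), which
biases the search toward larger widths and better generalization.
Defaults (population 24, 8 generations) are package choices; the search
budget, not the operators, dominates the outcome on the synthetic
benchmarks.

## Numerical choices

* All least-squares solves return the minimum-norm solution under rank
  deficiency (duplicate or fully blocked columns must not crash a run).
  The vectorized per-candidate scorer solves the batched normal
  equations through a pseudo-inverse of the Gram matrix, which yields
  the same minimum-norm solution (A⁺ = (AᵀA)⁺Aᵀ); tests pin the two
  routes together at 1e−8 and against a planted solution.
* The bias b is an appended all-ones column, on by default for
  classification and off for waveform regression, where signals decay to
  the noise floor and a global offset is not physical.
* relMAE/relSDE normalize each return's absolute error by that return's
  reference amplitude, excluding bins at or below the noise floor from
  the sums (per-point normalization with a sub-floor cut avoids division
  blow-up); normalizing by the waveform maximum instead is available
  behind `normalize_by="max"`. The SDE uses the population denominator
  n, so hand-computed expectations in tests are exact. Both metrics are
  invariant under joint positive rescaling of the two signals.
* Winners are removed from a fixed pool after selection so duplicate
  columns cannot accumulate.

## Synthetic study conditions

The generators define the conditions everything is measured under; they
are fixed once, not tuned per test.

* **Two-scale overlap fixture**: wide width σ_L ~ U(3, 5) input units,
  narrow width σ_L/10, equal unit amplitudes, narrow center 1.0–1.8
  wide-widths off the wide center (where the wide pattern is only weakly
  active), 161 even grid points over ±3.2 σ_L so the width grid (0, T/6]
  contains both generating widths. Noiseless by default; recovery is
  declared when both fitted widths are within 25% of the generating ones
  and both centers within one narrow-width.
* **Cluster fixture**: two balanced isotropic Gaussian clusters in 2-D,
  unit spread, centers 10 spreads apart — linearly separable, so the
  end-to-end classification benchmark (100+100 training, 300+300 test
  points) isolates the training machinery rather than class geometry.
* **Waveform fixture**: 500 bins of 0.3 units (150-unit record), a broad
  canopy-like return (σ = 6, amplitude 0.6) and a sharp ground-like
  return (σ = 1.5, amplitude 1.0) placed beyond bin 150, over a flat
  noise floor (|N(0, 0.02)|, absolute value keeps amplitudes
  non-negative) so the leading-bin noise-floor rule is genuinely
  exercised.

What these fixtures do **not** emulate: real spectral mixing and class
overlap in satellite imagery, PCA-compressed band structure,
atmospheric/georeferencing artifacts, multi-layer canopy returns, or
detector ringing. Passing tests demonstrate the training machinery and
its claimed mechanisms on controlled signals, not field accuracy.

## Problem sizes

The shipped test and acceptance runs use 161-point two-scale fixtures
(50-width pools, two-node budget, 20 seeds), a 500-bin waveform with a
25-width pool at a 4-node budget, and 5 classification seeds — sizes at
which every documented property is exercised with comfortable margins
on a single CPU.

## Nestedness and schedules

Appending a column never increases the optimal squared residual, and the
within-run trace asserts this. *Across* runs with growing K_max the
property additionally requires a K_max-independent selection sequence,
which only the `constant` schedule family guarantees (the decaying
families re-scale their weights with K_max and may legitimately choose
different early nodes). The cross-budget monotonicity check therefore
runs under the constant family; this isolates the architecture's
algebra from the schedule.

## Known limitations

* Isotropic kernels only; adequate for 1-D regression and
  low-dimensional classification, not for strongly anisotropic feature
  spaces.
* Exact per-candidate refitting costs one small solve per candidate per
  iteration (a residual-projection shortcut is available behind
  `exact_refit=False` but changes selection slightly).
* The blocked region is frozen at block creation as the node's
  receptive field at the configured radius factor; no later un-blocking
  or soft gating.
* On signals without genuine multi-scale structure the exhaustive w0
  grid frequently selects w0 = 0 — the multi-kernel baseline is then the
  right model, and the framework degrades to it gracefully rather than
  forcing local structure.
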