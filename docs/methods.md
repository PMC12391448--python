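# Methods

## Statevector simulation

An n-qubit register is the dense complex amplitude vector of length 2ⁿ;
gates act by tensor contraction against the relevant axis, so execution
is exact up to float64 rounding. **Qubit 0 is the least-significant bit
of the basis index** (little-endian) everywhere: gate application,
Pauli-Z readout, shot-histogram bitstrings (written most-significant
qubit first) and QASM export all share this convention.

Gate conventions are the OpenQASM 2.0 ones:

- RY(θ) = exp(−iθY/2), RZ(θ) = exp(−iθZ/2) = diag(e^{−iθ/2}, e^{iθ/2}),
- U3(θ, φ, λ) = [[cos θ/2, −e^{iλ} sin θ/2], [e^{iφ} sin θ/2, e^{i(φ+λ)} cos θ/2]],
- CZ = diag(1, 1, 1, −1), H = (X + Z)/√2.

These make QASM export bit-faithful; other toolkits may differ by
global phase, which never affects probabilities or expectations, so
cross-toolkit state comparisons should be made up to global phase.
Registers are capped at 24 qubits (a 256 MiB vector) to fail fast on
accidental sizes. `apply_gate` returns a fresh state; referential
transparency keeps gradient checking simple.

## Embeddings

**Angle encoding** (default). x′ = arctan(x) maps an unbounded real
feature one-to-one into (−π/2, π/2); the qubit, prepared in |+⟩,
receives RY(x′) then RZ((x′)²). The squared Z-angle is a deliberate
extra nonlinearity in the encoded phase; because RZ only rephases
amplitudes, the single-qubit Bloch readout obeys the closed form
⟨Z_i⟩ = −sin(arctan x_i), which the tests pin to 1e−10. Depth is
constant and no entangling gates are needed, so this encoding runs
as-is on hardware.

**Amplitude encoding.** The L2-normalized feature vector becomes the
state amplitudes of ⌈log₂ N⌉ qubits, zero-padded (after normalization;
irrelevant either way since pads are zero) to a power of two. State
preparation circuits for arbitrary amplitudes need O(N) depth, so the
simulator assigns amplitudes directly — a simulator-only shortcut,
which is also why the hardware path uses angle encoding. The inner
product of two encoded states equals the cosine similarity of the
inputs, preserved to 1e−10.

**Basis encoding** is included for completeness (bit vectors only; real
backbone features are continuous, so it is not used by the head).

## The variational ansatz

Each of K layers applies one U3 per qubit (3 angles) and then a CZ
entangler over neighboring pairs. The default topology is a **ring**
(qubit i with i+1, wrap-around; a single CZ at N = 2, none at N = 1);
a `chain` switch drops the wrap-around bond to match strictly
linear hardware connectivity. Layers are applied first-index first;
since all layers are architecturally identical, any other order only
relabels parameters. K = 0 is allowed and reduces the model to the
embedding's Z-profile exactly — a useful degenerate baseline.

Parameter accounting: the circuit trains 3KN angles; the dense N→N
layer it replaces holds N² weights (+ N biases). The headline
comparison counts weights only, giving 1 − 96/256 = 62.5 % at N = 16,
K = 2. The FC head's bias is reported separately in the benchmark
(N² + N) so both conventions are visible.

## Gradients

Two independent routes:

- **Adjoint backpropagation** (training default). One forward pass;
  then gates are undone one by one on the ket while the
  observable-weighted bra is dragged backwards, each parameterized gate
  contributing 2 Re⟨bra| ∂U |ket⟩. Cost is O(gates · 2ⁿ) per batch with
  full batching over samples. The same sweep continues through the
  encoding rotations, yielding exact gradients with respect to the raw
  inputs via d(arctan u)/du = 1/(1+u²) (and the chain factor 2x′ for
  the squared RZ angle); the amplitude route instead projects
  2 Re(bra) through the derivative of L2 normalization.
- **Parameter-shift rule** (hardware-compatible). Each U3 Euler angle
  parameterizes a rotation with generator eigenvalues ±1/2 via the
  RZ(φ)RY(θ)RZ(λ) decomposition (global phase immaterial), so
  df/da = [f(a+π/2) − f(a−π/2)]/2 exactly. Available both as a
  standalone function and as a `gradient_mode` for training.

The test suite pins shift-rule vs central finite differences (h = 1e−5)
to 1e−5 and adjoint vs shift rule to 1e−10.

## The hybrid head and training protocol

Both heads are Linear(in_dim → N) → middle → Linear(N → 2); only the
middle differs (circuit vs dense N×N + bias). Training parameters,
with defaults:

| parameter | default | role |
|---|---|---|
| epochs | 80 | cosine annealing horizon |
| lr (classical / quantum) | 0.0004 / 0.004 | two SGD groups; the 10× quantum rate compensates the bounded ⟨Z⟩ output scale |
| momentum | 0.9 | SGD momentum, both groups |
| weight decay | 1e−4 | classical weights only — rotation angles are periodic, shrinking them toward 0 is meaningless |
| label smoothing | 0.1 | smoothed cross entropy, targets (1−s/2, s/2) |
| schedule | cosine | η_t = η₀·½(1+cos(πt/T)), annealed to 0, no restarts |
| balanced resampling | on | class drawn uniformly, then a member with replacement (minority oversampled) |
| batch size | 32 | ordinary mini-batch choice; not part of the protocol's stated settings |
| shots | 0 (analytic) | training is analytic; positive values Monte-Carlo sample inference, 1000 being the hardware-parity setting |

Initialization: circuit angles uniform on [0, 2π) (the standard choice
for this ansatz), linear maps Glorot-normal, biases zero. All
randomness flows from one seeded generator, so analytic-mode runs are
bit-reproducible. Per-epoch training loss is the mean over the
(resampled) epoch stream; validation loss uses the plain, unresampled
validation set. A non-finite loss aborts with a diagnostic rather than
continuing silently. Prediction thresholds the softmax probability of
class 1 at 0.5; that probability is also the ROC score.

The **overfitting gap** is final-epoch validation loss minus training
loss (the per-epoch series is also available). The benchmark runs both
heads on identical splits across seeds and reports gaps, final losses,
BACC/AUC and middle-block parameter counts with across-seed means and
standard deviations. Whether the quantum head's gap is smaller on a
given synthetic task is an empirical outcome the report states — the
package deliberately does not assert it as an invariant.

## Shots and readout mitigation

Measurement is a seeded multinomial draw from |amplitude|². Readout
error is modeled as independent per-qubit 2×2 column-stochastic
confusion matrices A_i = P(measured | true) — a tensor-product model;
real devices also show correlated readout, which this stand-in does
not emulate. Mitigation solves the confusion system restricted to the
observed bitstrings plus their single-bit-flip neighbors (cost grows
with distinct outcomes, not 4ⁿ, in the matrix-free spirit of M3-style
correction), then normalizes to unit total. Outputs are
quasi-probabilities — small negative entries are reported as-is — with
a clip-at-zero-and-renormalize variant for consumers needing a proper
distribution. Calibration matrices with |det| < 1e−8 (e.g. symmetric
flip p = 0.5) are rejected as uninvertible.

Expected behavior pinned by tests: the empirical ⟨Z⟩ of a 1000-shot
histogram lands within 3/√1000 ≈ 0.095 of the exact value in ≥ 99 % of
trials, and applying p = 0.1 noise then mitigating reduces the
total-variation distance to the true distribution versus the
unmitigated histogram in ≥ 19/20 seeded trials at 10⁵ shots.

## Synthetic data

The generator emulates what a trained vision backbone hands its
classification head: real-valued feature vectors for two classes of
controllable separability (Mahalanobis distance between unit-covariance
Gaussian means, placed along the first feature so a single-feature
threshold is Bayes-optimal), class imbalance, and label noise. A
`ring_vs_disc` variant provides a radially separable task no linear
head can solve. Splits are independent seeded draws, so train/val/test
are disjoint by construction.

What this does **not** emulate: the correlation structure, heavy tails
and domain shift of real backbone features, cohort effects, or any
image-level variability. Passing benchmarks here shows the head and
protocol are implemented correctly and can learn separable structure —
not that a quantum head improves a real screening pipeline.

## Problem sizes used in the reproduction script

`scripts/acceptance.py` uses: 200 random circuits at ≤ 4 qubits for the
oracle check; 50 random (params, state) instances at N = 4, K = 2 for
gradient agreement; 1000 trials × 1000 shots for shot convergence; 20
trials × 10⁵ shots at 3 qubits, p = 0.1, for mitigation; and one full
training run (n = 400 train / 200 validation samples, N = 8 qubits,
K = 2, separation 6, the default 80-epoch protocol). These sizes make
every quantity statistically stable while keeping the whole script
around half a minute on one CPU.

## Known limitations

- Pure-state simulation only: no density matrices, decoherence
  channels or mid-circuit measurement; readout noise is the only
  imperfection modeled.
- Tensor-product readout calibration cannot express correlated
  assignment errors.
- Shot-mode gradients exist only through the parameter-shift route;
  the training loop itself runs analytically.
- The ansatz is fixed (U3 + CZ ring/chain); no architecture search or
  multi-qubit entanglers.
- QASM support covers exactly the gate set used (h, ry, rz, u3, cz) on
  a single register — it is an interchange format for this circuit
  family, not a general parser.
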