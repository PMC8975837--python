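# Methods

## Model

The package models per-subject brain dynamics as a linear control
system `ẋ(t) = A(t) x(t) + B u(t)` whose interaction matrix A(t) is
derived from functional connectivity.  Three connectivity objects feed
the analysis:

- **static correlation** — Pearson correlation over the full series;
- **autoregression** — the coefficient matrix of the first-order vector
  autoregression `x(t) = A_β x(t−1) + ε(t)`, fit jointly over all
  regions by multi-output ordinary least squares (a rank-deficient
  lagged design falls back to the minimum-norm solution and is
  flagged);
- **sliding-window correlation** — Pearson correlations in rectangular
  windows of 60 frames at step 10 (half-open, 0-based, trailing partial
  window dropped; window-local means and variances, i.e. no reuse of
  the global z-scoring).

Connectivity F becomes an interaction matrix through the signed
weighted Laplacian `L_ij = δ_ij Σ_k |F_ik| − F_ij`, normalized as
`A = −L/λ_max(L)` with λ_max the largest absolute eigenvalue.  For a
symmetric F this places the spectrum of A in [−1, 0].  A nonnegative F
always leaves a zero eigenvalue (marginal stability); whenever the
largest real part of an eigenvalue of A exceeds −1e−10, a diagonal
shift of 1e−6 is subtracted and recorded on the returned object, so the
exact normalization and the stabilized matrix are both available.  The
shift magnitude is small enough that energies and controllability
values on horizons up to ~10³ frames change only in the fifth
significant digit, and it can be audited per matrix.

All horizons are expressed in frame (TR) units; the physical TR
(0.72 s for the motivating acquisitions) is metadata only.

## Controllability and energy

Finite-horizon Gramians `W(τ) = ∫₀^τ e^{At} BBᵀ e^{Aᵀt} dt` are
computed by the augmented-matrix exponential construction.  Because the
augmented matrix contains −A, whose exponential grows on long horizons
for stable A, the construction is applied on a sub-interval with
`‖A‖ τ ≤ 1` and extended by the doubling identity
`W(2t) = W(t) + e^{At} W(t) e^{Aᵀt}`; agreement with direct quadrature
of the integral is at machine precision even at τ = 240.
Infinite-horizon Gramians solve the Lyapunov equation
`A W + W Aᵀ + B Bᵀ = 0` and require a strictly stable A.

Minimum transition energy uses the half-quadratic-form convention
`E = ½ dᵀ W⁻¹ d` (the classical least-norm input energy ∫|u|² dt is
twice this; tests against the discretized least-norm oracle account for
the factor).  For the snapshot-switching system the drift is the
ordered product of snapshot exponentials (later snapshots act on the
left) and the temporal Gramian is `Σ_m S_m W_m S_mᵀ` with `S_m` the
product of the exponentials of all later snapshots.  Gramian inverses
are symmetric solves with condition monitoring; above condition 1e12 a
pseudo-inverse (relative cutoff 1e−12) is used, and a target component
outside the range of a singular Gramian (relative residual > 1e−6)
raises an unreachable-target error.

Per-region measures: average controllability `ψ_i = Tr(W_i)` with the
single-region input `B_i`; modal controllability
`φ_i = Σ_j (1 − λ_j²) v_ij²` with unit-norm right eigenvectors (for
asymmetric, autoregression-derived A the extension uses |λ_j|² and
|v_ij|², with a warning — the real-spectrum formula does not apply
verbatim); regional activation energy
`ε_i = ½ (W(τ)⁻¹)_{ii}` for the 0 → e_i transition with full control.
The activation-energy horizon is not fixed by the transition
experiments and defaults to τ = 1 frame (configurable).  Sliding-window
controllability averages per-window profiles unweighted over windows.

## The transition-energy experiment

For each sampled frame pair the segment between the two frames is cut
into consecutive **non-overlapping** 60-frame windows (overlapping
step-10 windows would double-count time against the paired static
horizon; overlap remains configurable for sensitivity checks).  End
snapshots last 30 frames and middle snapshots 60 — states are defined
at window centers, so half a window lies outside the horizon at each
end — and the static system runs on the summed horizon with the
segment's own correlation matrix.  Endpoint states are the mean of the
central 10 frames of the first and last window (frames 25–34 of a
60-frame window, 0-based); an endpoint-value mode (first/last frame) is
available.  Twelve transitions are sampled per subject with a default
minimum separation of 180 frames (three windows).

Shuffle nulls permute the snapshot matrices over 20 uniformly drawn
permutations (distinctness not forced), keeping durations attached to
positions so the total horizon is preserved and only the
reconfiguration order changes.  The summary statistic is
`log-inflation = mean(log E_r) − log E_d` — the mean of logs is robust
to the heavy right tail of shuffled energies.  The horizon sweep
divides each total horizon τ evenly across snapshots (τ/M each) and
reports (τ, E_s, E_d) rows.

## Synthetic data

`generate_switching_lds` emulates the statistical structure the
analysis assumes: per subject, `x(t) = C_e x(t−1) + η(t)` within epoch
e, with `η ~ N(0, noise_sd² I)` the innovation noise of the recurrence.
Epoch matrices are block-modular (positive within-module coupling,
weaker mixed-sign between-module coupling — the signed case exercises
the Laplacian normalization) and drift in a fixed order: each next
epoch is a convex interpolation, with weight `drift_rate`, toward a
fresh random modular target, rescaled to the common spectral radius so
every segment is stationary.  Subject heterogeneity adds a per-subject
perturbation (sd `subject_sd`) to every epoch matrix, again rescaled.
Defaults: 20 subjects, 30 regions, 1200 frames, 4 modules, 6 epochs of
200 frames (a regime dwell of ~2.4 min at TR 0.72 s), drift 0.3,
spectral radius 0.9, unit innovation noise, subject sd 0.1.

With `noise_sd = 0` the recurrence is exact and the trajectory decays
deterministically from a random initial state; ordinary least squares
then recovers `C_e` to machine precision, which anchors the generator
recovery tests.  Behavioral scores are planted as
`score = features·w + N(0, σ²)` with σ calibrated so the population
correlation `sqrt(Var(signal)/(Var(signal)+σ²))` hits a target (0.5 by
default).  In the pipeline the planted weights point along the leading
principal component of the standardized control features, so the
planted variance lies in the dominant mode of between-subject variation
rather than in per-column estimation noise — dense random weights on
~6N weakly correlated columns would put most planted variance in
directions no regression can estimate from ~10² subjects.

What the generator does **not** emulate: hemodynamic convolution,
physiological noise and motion artifacts, spatial autocorrelation,
continuous (rather than piecewise) connectivity drift, and realistic
network topography.  Passing tests therefore certify the estimators and
the energy machinery, not effect sizes on real fMRI.  Two consequences
are worth stating plainly.  First, the per-transition advantage of the
observed snapshot order over shuffles is real but modest on this
generator: across cohorts about 75–79% of transitions have
`E_d ≤ mean(E_r)`, robustly above chance but below sharper thresholds
one might hope for; segments confined to a single epoch contain no
reconfiguration and dilute the effect.  Second, the static-vs-temporal
comparison `E_s` vs `E_d` does not systematically favour the temporal
paradigm on this generator, unlike reports on real resting-state data —
the windowed correlation estimates at 60 frames are noisy relative to
the full-segment estimate.  Note also that the endpoint states are
extracted from the same frames as the last window's correlation matrix,
so the observed order beats shuffles even at zero drift; this coupling
is inherent to defining states and snapshots from the same series.

## Graph metrics

All metrics use absolute weights with the diagonal excluded (signed FC
has no canonical distance; the absolute-value convention is recorded in
output metadata and alternatives can be layered on the same
primitives).  Weighted degree is the absolute strength.  Local
efficiency follows the cube-root weighted convention with
inverse-weight shortest-path distances on each node's neighborhood
subgraph; nodes with fewer than two neighbors score 0; asymmetric input
is symmetrized with a warning.  Participation coefficient is
`1 − Σ_s (k_is/k_i)²` over the given community partition, 0 for
isolated nodes.

## Prediction

Feature vectors are 6N per subject: three control measures × two matrix
kinds (static correlation, autoregression), or three graph measures ×
two kinds, or a 3N control block plus a 3N graph block (default
pairing: control on static, graph on autoregression; configurable).
The sliding-window kind is excluded from prediction features.  Ordering
is measurement-major, then matrix kind, then region, recorded in an
index frame.

Kernel ridge regression uses the cosine kernel; 10-fold outer
cross-validation pools held-out predictions; the penalty is chosen per
outer fold by inner 5-fold grid search over a log grid 1e−3…1e3.
Features and scores are standardized with training-fold statistics
only.  Each held-out fold's predictions are recentred to zero mean
before pooling: a fold's prediction mean tracks its training-fold score
mean, which carries no subject-level signal under exchangeability but
is anti-correlated with the held-out scores and biases the pooled
correlation negative (about −0.1 with 10 folds on null data).

Models are compared by
`z_d = (z₁ − z₂)/sqrt(1/(N₁−3) + 1/(N₂−3))` on Fisher-z-transformed
correlations (r clamped at ±(1−1e−12)).  The formula assumes
independent samples; it is applied to same-cohort models as commonly
printed, which is conservative in the typical positively-dependent
case.  Region (or community) importance refits the full pipeline with
the unit's columns removed and reports the z_d drop; the subject-level
null shuffles the score–subject correspondence and reruns the whole
prediction.

## Numerical choices and scale

Problem sizes were chosen so the full test suite and the acceptance
script each run in minutes on one CPU: cohorts of 15–30 regions and
20–100 subjects, 1200-frame series, 12 transitions and 20 shuffles per
subject, 2000-replicate calibration of the correlation test, 20–50
replicate prediction experiments at 300 subjects.  Random streams
derive from a single master seed via named substreams, so every stage
is reproducible and the pipeline summary is byte-identical across runs
with the same config and seed.
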