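# funcontrol

Control-theoretic analysis of functional brain connectivity.

Resting-state fMRI gives, per subject, a region × time matrix of BOLD
activity whose correlation structure (functional connectivity, FC)
reconfigures over time. `funcontrol` treats those connectivity estimates
as the interaction matrix of a linear control system and asks two
questions that matter to systems and network neuroscientists:

1. **Is the observed order of FC reconfiguration energetically
   efficient?**  Minimum control energy for state transitions is
   compared between a time-invariant system (static FC), a
   snapshot-switching system (sliding-window FC in observed order), and
   order-shuffled nulls.
2. **Do control-theoretic regional features predict behaviour
   differently from graph-theoretic ones?**  Per-region controllability
   and activation-energy features are pitted against weighted degree,
   local efficiency and participation coefficient in a cosine-kernel
   ridge regression, compared on the Fisher-z scale.

A synthetic-data module generates multi-subject piecewise-stationary
vector-autoregressive series with modular, slowly drifting coupling and
behavioral scores with planted effects, so the full analysis runs at
desk scale with known ground truth.

## Model

States follow the linear system `ẋ(t) = A(t) x(t) + B u(t)`.  A
connectivity matrix F is normalized into a stable interaction matrix via
the signed weighted Laplacian

```
L_ij = δ_ij Σ_k |F_ik| − F_ij,        A = −L / λ_max(L),
```

with λ_max the largest absolute eigenvalue of L (a 1e−6 diagonal shift
is subtracted when A is only marginally stable).  From the
controllability Gramian `W(τ) = ∫₀^τ e^{At} B Bᵀ e^{Aᵀt} dt` the package
computes:

- minimum transition energy `E_s = ½ dᵀ W(τ)⁻¹ d`,
  `d = x_f − e^{Aτ} x₀`;
- for M snapshots `(A_m, τ_m)` the temporal Gramian
  `W_dyn = S W S ᵀ` with `S` the row of partial exponential products and
  `W = diag(W_1 … W_M)`, giving the switching-system energy `E_d`;
- average controllability `ψ_i = Tr(W_i)` (infinite-horizon Gramian,
  single-region input), modal controllability
  `φ_i = Σ_j (1 − λ_j²) v_ij²`, and regional activation energy
  `ε_i = ½ (W(τ)⁻¹)_{ii}`.

## Worked example

```python
import numpy as np, warnings
import funcontrol as fc

warnings.simplefilter("ignore", RuntimeWarning)
cfg = fc.SyntheticConfig(n_subjects=1, n_regions=15, n_timepoints=1200,
                         n_modules=3, n_epochs=6, drift_rate=0.3, seed=0)
(ts,), truth = fc.generate_switching_lds(cfg)
pre = fc.preprocess_series(ts, n_discard=50)

windows = fc.sliding_window_fc(pre, window=60, step=10)
print(len(windows))                       # 110

system, spec, static_A = fc.transition_experiment(pre, (100, 700), np.eye(15))
E_s = fc.static_min_energy(static_A, np.eye(15), spec).energy
E_d = fc.temporal_min_energy(system, spec).energy
null = fc.shuffle_null(system, spec, n_perm=20, seed=0)
print(round(E_s, 3), round(E_d, 3), round(null.log_inflation, 3))
# 0.498 0.456 0.242
```

The 1150 retained frames yield 110 sliding windows.  For the sampled
transition, the snapshot-switching system in observed order costs
`E_d = 0.456` against `E_s = 0.498` for the static system on the same
horizon, and randomly reordering the snapshots inflates the log energy
by 0.242 on average — the observed reconfiguration order is cheaper
than its shuffles.

The whole pipeline (simulate → connectivity → controllability → energy
experiments → graph metrics → prediction → summary) runs from one
config:

```bash
funcontrol run-all --config config.yaml --seed 1 --out results/
```

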