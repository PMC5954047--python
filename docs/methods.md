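# Methods

## Model and assumptions

`colbci` implements a channel-selecting classifier for two-class
epoched EEG. The model assumes (i) class information is carried by the
band power of a narrow oscillatory band that may differ per channel;
(ii) channels contribute independently (no spatial filtering or
leadfield modeling — the combiner weights channels, it does not unmix
them); (iii) classes are approximately balanced. The pipeline stages
and their equations are summarized in the README; this note records the
choices behind them.

### Preprocessing

Per trial and channel, the temporal mean (DC) is removed. The
common-average-reference variant (subtracting the spatial mean per
sample) is available via `remove_channel_means(..., spatial=True)` but
is not part of the default chain, which treats channels independently.
The band-pass is a zero-phase (forward–backward) 4th-order Butterworth:
the filter family is a free choice here; a zero-phase IIR is standard
in band-power pipelines because it preserves envelope timing and has a
monotone passband. Filtering is applied per trial with no cross-trial
padding. Envelope edge effects are *not* trimmed — the feature uses all
M samples — which is why the pure-tone tests in the suite measure only
the central 80% of samples.

### Band search

Candidate band edges come from the geometric grid `f0·θ^k`
(defaults `f0 = 7` Hz, `θ = 1.22`, `k = 0..9`, top edge 41.9 Hz < the
50 Hz Nyquist limit at the 100 Hz sampling rate the package targets).
Two enumeration modes:

- `fidelity` (default): the literal published loop order — the initial
  pair `(0, 1)`, then `kmin = 1..Nf−1`, `kmax = kmin..Nf`. For `Nf = 9`
  this enumerates 45 candidates of which 8 are zero-width
  (`kmax = kmin`); a zero-width band cannot be filtered, so those score
  `−∞` (enumerated but never selected). Note this loop never widens the
  lower edge `f0` beyond the pair `(0, 1)`.
- `full`: all 45 pairs `kmin < kmax` over the whole grid.

Ties break by loop order (a later candidate must *strictly* improve the
Fisher score). The Fisher-score denominator uses population variances
(mean squared deviation from the class mean) and is floored at 1e-12 so
degenerate inputs yield a large finite score instead of NaN. The
envelope and feature are recomputed for every candidate band; band
features do not depend on trial labels, so `cross_validate` and
`training_ratio_sweep` compute the feature table once per dataset and
each training fold re-scores its own subset — numerically identical to
recomputing per fold, since filtering is per-trial.

### Decision values

`Δγ` — "the variance of γ" — is not pinned down to a trial set by the
method's source; the package pools the population variance over all
training trials (both classes), which uses all data and is symmetric
under class swap. The divisor is the variance, not the standard
deviation, exactly as the rule is stated, so decision values are not
scale-free; constant feature shifts cancel (midpoint centering), which
the suite asserts. A channel with equal class means emits the
uninformative constant 0.5. Logistic outputs are clamped to the open
interval at one ulp to keep the decision matrix strictly inside (0, 1)
when the logistic saturates in float64.

### Sparse combiner

The objective is `½‖Pw + 1b − ỹ‖² + α‖w‖₁` with `w ≥ 0`.

**Bias update.** The alternating scheme fixes `w`, sets the bias in
closed form, then takes one line-searched gradient step on `w`. Two
conventions exist because the printed bias update in the method's
source, `b ← +mean(Pw − ỹ)`, is the sign-flipped stationary point of
the bias objective (the derivative condition `1(Pw−ỹ) + Nb = 0` gives
`b = −mean(Pw − ỹ)`). The package's default, `bias_mode="corrected"`,
uses the true minimizer; its substituted objective is the trial-
centered convex problem `½‖(I − J/N)(Pw − ỹ)‖² + α‖w‖₁`.
`bias_mode="paper"` reproduces the printed equations verbatim,
including the gradient whose quadratic form carries a `3J/N` term
(consistent with `(I + J/N)ᵀ(I + J/N) = I + 3J/N`). The verbatim
variant is kept for faithfulness studies but is not a useful
classifier-trainer: the `+` sign makes every substituted design column
share a large all-ones component, and its exact optimum degenerates to
one- or two-channel supports at any penalty strength — measured on the
synthetic study data, it cannot contain a planted five-channel support.

**Penalty scaling.** `alpha_scaling="per_trial"` (default) uses
`α·N` as the effective penalty, reading the documented `α = 0.01` as
the constant of a penalty proportional to the trial count. A fixed
penalty would be washed out as N grows (the data term is a sum over
trials); with the N-scaled reading the method reproduces its described
behavior — compact, informative supports — across training-set sizes,
which the recovery tests exercise from 40 to 200 effective trials.
`alpha_scaling="literal"` uses `α` as-is.

**Line search** (per gradient step): linear estimate
`η_l = H(w)/‖∇‖²`; nonnegativity cap `η_m = min(η_l, min⁺ w_c/∇_c)`;
halving while the objective does not decrease (a guard raises after 200
halvings — unreachable for a descent direction in practice); parabolic
fit through the objective at `{0, η_m/2, η_m}` with the vertex capped
at `η_m`, falling back to `η_m` when the fit is concave; a final guard
returns the best evaluated point. Objective evaluations clip the
candidate point at zero, which is a no-op in exact arithmetic (the cap
prevents sign changes) and only absorbs last-ulp overshoot.

**Freezing.** A weight that reaches zero is frozen: removed from the
gradient, the step-ratio set and all further updates. Freezing is
structurally required — an unfrozen zero coordinate with positive
gradient has ratio 0 (excluded from the positive-ratio cap) and the
next step would drive it negative. Weights below 1e-12 in magnitude
snap to zero before freezing; solution weights are otherwise O(0.01–1),
so the snap only absorbs rounding at the cap boundary. Initialization
is uniform `w = 1/C` (positive, deterministic — training involves no
randomness), `b = 0`. Termination: relative objective decrease below
`rel_tol = 1e-4` (the `H_new > 0.9999·H_old` rule), all channels
frozen, or `max_iter = 1000`.

**Known limitation — greedy active set.** Because freezing is
permanent, the solver is an active-set heuristic, not a globally
convergent lasso solver: the line search sometimes accepts the full
capped step and locks a coordinate at zero that the global optimum
keeps slightly positive. Measured on 100 random (N=60, C=12) instances
at α=0.05, the endpoint is always the exact minimizer *restricted to
its own face* (Karush–Kuhn–Tucker residual ≤ 4e-6 against an
independent projected-coordinate-descent reference) and the face is the
globally optimal one in 83/100 instances; when it is not, the objective
excess stays below 0.25%. A second practical consequence of the capped
step is that the relative-decrease rule can fire while a few channels
still hold tiny positive weights (the step is throttled by the smallest
dying channel), so trained models may report the true support plus a
few near-zero leftovers.

## Parameters

| name | default | meaning |
|---|---|---|
| `alpha` | 0.01 | l1 penalty per trial (effective penalty `α·N` by default) |
| `f0`, `theta`, `n_f` | 7 Hz, 1.22, 9 | geometric band grid `f0·θ^k`, `k = 0..n_f` |
| `beta` | 4 | output-normalizer slope constant (unit derivative at p = 0.5) |
| `max_iter`, `rel_tol` | 1000, 1e-4 | solver stopping rules |
| `band_search_mode` | fidelity | literal loop order vs. all ordered pairs |
| `bias_mode` | corrected | true bias minimizer vs. printed sign |
| `alpha_scaling` | per_trial | `α·N` vs. literal `α` |
| `filter_order` | 4 | Butterworth order (even) |

## Synthetic data

The generator emulates the statistical structure of public
motor-imagery benchmarks at desk scale: 200 trials, 32 channels, 3 s
epochs at 100 Hz, balanced classes. All channels carry pink (1/f)
background noise — EEG-like spectra make band selection nontrivial —
and 5 informative channels each add a random-phase oscillation at a
frequency drawn inside a designated μ/β band, with amplitude
`a·(1 + effect)` for class 1 and `a·(1 − effect)` for class 0
(amplitude, not frequency, carries the effect, mimicking ERD/ERS power
modulation). The base amplitude `a = 0.4` is calibrated so the
strong-class oscillation rms (≈0.5) is comparable to the pink-noise rms
inside a ~4 Hz μ band (≈0.28): single channels are then informative but
noisy, as in real MI data, rather than trivially separable. Channels
are independent by default (`mixing > 0` adds a random mixing matrix
for robustness studies). The generator is bit-deterministic from its
seed.

What passing tests on this data do **not** show: robustness to volume
conduction, artifacts (EOG/EMG), non-stationarity across a session, or
electrode-montage effects — none of which the generator models.

## Degenerate inputs and tie-breaks

- Prediction ties at `p_normal = 0.5` go to class 1 (documented,
  measure-zero).
- F1 uses label 1 as the positive class; folds are stratified
  (the benchmarks the conditions emulate are balanced by design).
- A zero envelope (identically zero channel) is an error: the
  log-power feature is undefined.
- Zero feature variance with distinct class means raises a
  degenerate-channel error rather than emitting ±∞ logits.
- All-frozen solutions predict through the bias alone.

## Limitations

Binary classification only; no artifact handling; no continuous-data
epoching (inputs are already epoched); the greedy active-set property
above; and accuracy on real recordings will depend on the unstated
filter family/order of the original experiments.
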