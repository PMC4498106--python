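# Methods

## Model

`nfdbs` simulates the reciprocally connected subthalamic nucleus (STN) and
external globus pallidus (GPe) as a pair of delayed neural fields on a 1-D
domain.  In parkinsonian conditions this excitatory–inhibitory loop is a
candidate pacemaker for the sustained β-band (13–30 Hz) oscillations that
correlate with bradykinesia and rigidity.  The activity z_i(r, t) (spk/s) of
population i ∈ {1 = STN, 2 = GPe} at position r obeys

    τ_i ∂z_i/∂t = −z_i + S_i( Σ_j ∫_Ω w_ij(r, r′) z_j(r′, t − d_j(r, r′)) dr′ + I_i^ext(r, t) )

* **Domain.** Ω = [0, 15] mm, normalized to [0, 1] for simulation and
  discretized with m = 60 cell-centered nodes (positions (i + ½)/m).  The
  STN occupies the left m/6 nodes ([0, 2.5] mm), the GPe the right m/6
  ([12.5, 15] mm); the 2m/3 nodes in between are silent spacers that carry no
  state and only generate conduction distance.
* **Activations.** S_i(x) = m_i b_i / (b_i + (m_i − b_i) e^(−4x/m_i)) with
  (m₁, b₁) = (300, 17) and (m₂, b₂) = (400, 75) spk/s.  The 4/m_i exponent
  normalizes the maximum slope to exactly 1 for any parameter pair, which is
  what the stability condition below is calibrated against.
* **Kernels.** w₁₁ ≡ 0 (no STN self-excitation).  Cross-population kernels
  are Gaussians of the *topographic offset* (r − μ_post) − (r′ − μ_pre), with
  population centers μ taken as the mean node positions (1/12 and 11/12
  normalized; configurable): homologous positions in the two mapped
  populations are maximally coupled.  w₁₂ ≤ 0 (pallidal GABA), w₂₁ ≥ 0
  (subthalamic glutamate), amplitudes K₁₂ = 30, K₂₁ = 38, variances 0.03
  (normalized length²).  The GPe lateral kernel is w₂₂(r, r′) =
  −|r − r′| K₂₂ exp(−(r − r′)²/(2·0.015)) with K₂₂ = 2.55: it vanishes at
  r = r′ (neighboring GPe neurons are essentially uncorrelated) and decays at
  long range.
* **Quadrature.** The synaptic integrals are discretized by the midpoint
  rule: each weight matrix entry carries the node measure Δr = 1/m.  A
  "plain" (measure-free) convention is available in the configuration.  We
  verified that the plain convention at the nominal amplitudes produces
  cross-coupling row gains of ~250–300, which lock the STN in a silent,
  stable fixed point — no oscillation at all — whereas the measure
  convention (row gains ≈ 4–5) produces the sustained relaxation oscillation
  with STN mean-rate swings of ~0–130 spk/s that the protocols analyze.
* **Delays.** d_j(r, r′) = |r − r′| / c_j, with the conduction velocity of
  the *presynaptic* population: c₁ = 0.166, c₂ = 0.09 normalized/ms
  (2.5 and 1.4 m/s on the 15 mm domain).  Delays are rounded to integer
  Euler steps (half up); the longest nominal delay is 11 steps.
* **Inputs.** Cortical drive to STN I₁ = 12.5·(27 + η) and striatal drive to
  GPe I₂ = −110·(2 + η′), with η, η′ Gaussian white noise of variance 0.05
  drawn independently per node and per step (per-population sharing is a
  configuration option).  The noise is applied per step with the stated
  variance and no 1/√dt scaling — it models the discrete-time input at
  dt = 1 ms, so dt-refinement studies change the effective noise bandwidth.

## Closed-loop stimulation

The STN is assumed photosensitized: a position-dependent gain α(r) (Gaussian,
amplitude 1 at the 1.25 mm STN center, variance 1.25 mm², zero outside the
STN) scales the effect of light at each node.  A degeneracy fraction p zeroes
round(p · n_STN) randomly chosen entries (seeded, without replacement),
modeling failed gene transfer.  Three controllers produce a stimulation
*rate* u from the measured STN activity:

* proportional: u(r, t) = −k_c (z₁(r, t) − z_ref(r));
* averaged single source: u(t) = −k_c ∫_STN (z₁ − z_ref) dr, one scalar for
  the whole population (a single optical fiber);
* delayed proportional: u(r, t) = −k_c (z₁(r, t − T) − z_ref(r)), modeling an
  acquisition/processing latency T.

The term α(r)·u enters the STN activation argument multiplied by the uniform
afferent synaptic weight (12.5, the same weight that carries the cortical
rate).  This "fictitious afferent population" reading of the actuator is a
deliberate design choice: with the raw (unweighted) insertion, a gain of
k_c = 2 only halves the oscillation amplitude, no finite acquisition delay in
the 1–20 ms range destabilizes the loop, and the single-source controller has
no workable gain — whereas with the afferent weighting the package reproduces
the full phenomenology (near-complete disruption at k_c = 2, delay tolerance
up to ≈9 ms that shrinks with gain, single-source disruption at k_c = 6.5
with a *smaller* peak stimulation rate than the distributed controller).  The
weight is exposed as `stimulation_weight` (set 1.0 for the raw reading).

The averaged controller's default aggregation is the spatial integral
(= node mean / 6 on this geometry).  The "mean" and "sum" readings are
switchable; only the integral reading yields both disruption at k_c = 6.5 and
a smaller peak |u| than the distributed controller, which is the point of the
single-source protocol.

## Integration

Forward Euler, dt = 1 ms (dt < min(τ₁, τ₂) enforced), horizon 1 s,
stimulation switched on at 0.5 s.  A ring buffer stores the last
max-delay + 1 state vectors per population; each connection reads its own
lag, and lags that reach before t = 0 return the initial history (constant
0 spk/s by default; baseline or seeded-random options exist — oscillation
onset is robust to this choice because the stochastic inputs immediately
perturb the system off the unstable equilibrium).  Because dt/τ_i < 1 and
S_i ∈ (0, m_i), every update is a convex combination of the current state
and a value inside (0, m_i), so trajectories started in [0, m_i] remain
there; the integrator additionally aborts with a diagnostic on non-finite
states.  The ring-buffer implementation is validated to machine precision
against a full-trajectory direct-indexing reference on a small instance.
Halving dt moves the nominal main harmonic by < 1 Hz.

## Analysis conventions

* **Main harmonic**: discard a transient (300 ms for unstimulated runs),
  subtract the window mean, take the FFT magnitude, and report the peak over
  f > 2 Hz.  The default window gives 1.43 Hz bins; 4× zero-padding is used
  where finer localization matters.  Runs whose half peak-to-peak amplitude
  is below 5 spk/s are classified non-oscillatory (frequency 0): input noise
  produces mean-rate jitter well under that gate while the pathological
  oscillation is tens of spk/s, so the classes are cleanly separated.
* **Amplitude**: half peak-to-peak of the spatially averaged STN rate.
  Stimulated runs are scored on the final 300 ms (onset 500 ms + 200 ms of
  settling); the pre-onset reference window is 200–500 ms.
* **Disruption**: post/pre amplitude ratio < 0.2.  This package-level
  criterion is used for pass/fail flags only; raw amplitudes are always
  emitted.
* **Stability margin**: the provable-disruption condition bounds the gain of
  the GPe lateral-inhibition operator by 1/ℓ₂ (ℓ₂ = 1).  On the discrete
  grid we report, by default, ℓ₂ × the absolute row sum at the *central* GPe
  node — the bulk gain of the translation-invariant operator away from the
  population edges — which is 0.944 at nominal parameters (< 1: no endogenous
  GPe instability, oscillations are a network effect).  The maximum-row-sum
  bound (1.297, edge-dominated because of the |r − r′| prefactor) and the
  continuum L2 quadrature (0.021) are available as modes.

## Protocols and problem sizes

Default sizes are chosen to keep a full run on one CPU within minutes; the
full-scale sweep is opt-in.

* **A — sensitivity.** K₁₂, K₂₁, K₂₂, c₁, c₂ scaled over ±35%; default 4
  values per parameter (1024 runs, ~2 min), `--full` uses 10 (10⁵ runs).
  Per-combination seeds mix the combination index into the base seed so any
  single cell is reproducible in isolation.
* **B — disruption.** Proportional, k_c = 2, z_ref = 0.
* **C — degeneracy.** Degeneracies {0, 25, 50, 75, 100}%, gains {2, 6, 12},
  10 mask seeds each (averaged; dispersion emitted).
* **D — single source.** Averaged controller, k_c = 6.5.
* **E — delays.** T ∈ {1, 3, 5, 7, 8, 9, 10, 13, 15, 20} ms, gains
  {2, 6, 12}, 5 seeds.

## What the model does and does not reproduce

At the nominal parameters the simulator produces a robust, seed-stable
sustained oscillation of the STN/GPe mean rates.  Proportional feedback at
k_c = 2 suppresses it to the noise floor (post/pre ≈ 0.003); at 50%
degeneracy the residual amplitude is ≈ 36 spk/s with a small but consistent
benefit from raising the gain; the single-source controller disrupts at
k_c = 6.5 with peak |u| about half the distributed controller's; delay
tolerance extends to T ≈ 9 ms at k_c = 2 and shrinks to ≈ 7 ms at k_c = 12.

Two quantitative discrepancies against the reference in-silico results this
simulator targets remain, and we left them visible rather than retuning:

1. **Nominal frequency.** The printed geometry and velocities give a
   round-trip STN↔GPe conduction delay of ≈ 14.3 ms; together with the
   membrane lags this places the main harmonic at 15.0 Hz (low β), not the
   reported ≈ 19 Hz.  A 19 Hz rhythm would require a loop delay of
   ≈ 9–10 ms (e.g. velocities normalized by the 10 mm inter-structure gap
   rather than the 15 mm domain).  We verified that variant: it does yield
   19.3 Hz, but it contradicts the printed normalized velocities and pushes
   the delay-tolerance threshold down to ~7 ms, so we kept the printed
   values.
2. **Sweep outcome classes.** Within ±35% of nominal the oscillation never
   dies (nonzero harmonics span ≈ 11–19 Hz); the no-oscillation outcomes
   reported for that range would require the nominal loop gain to sit near
   the Hopf margin, which the printed amplitudes (under either quadrature
   convention) do not produce.  Much wider excursions do show the expected
   behavior: at 0.2× coupling the rhythm disappears, and at 5× conduction
   velocity it leaves the β band.

The synthetic drive is the model's own stochastic input, not recorded data:
passing tests demonstrate the internal consistency of the model and
controllers, not agreement with electrophysiological recordings.  Other known
limitations: 1-D geometry with stylized topographic connectivity; no opsin
photocurrent dynamics (stimulation is an instantaneous rate); no synaptic
plasticity; the controller reads the true state with no measurement noise
beyond the model's input noise.
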