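# Methods

`crtsim` simulates a cortico-reticulo-thalamic (CRT) spiking circuit that
tracks or fixates a visual stimulus through a closed perception–action loop,
and quantifies how degrading each of the circuit's inhibitory mechanisms
disrupts that behavior. This note records the model as implemented, the
parameter and parsing choices that were genuinely open, the calibration
rationale, and known limitations.

## Circuit and dynamics

Six populations are simulated: thalamic relay neurons T (40), reticular
nucleus neurons R (40), middle- and deep-layer cortical pyramids M and D
(120 each), and parvalbumin (PV) and calbindin (CB) interneurons (40 each).
Every neuron is a two-variable Izhikevich unit,

    dv/dt = 0.04 v² + 5 v + 140 − u + ΣI,      du/dt = a (b v − u),

with reset v←c, u←u+d at v ≥ 30 mV; the regular-spiking set
(a, b, c, d) = (0.02, 0.2, −65, 0) is used everywhere except the PV cells,
which use the fast-spiking set (0.1, 0.2, −65, 2). Note the RS set has
d = 0, not the canonical 8; it is implemented as printed in the source
parameter table. All cell parameters, initial voltages, and synaptic
rise/fall times carry independent ±5 % multiplicative jitter per neuron.

The time-scale constant τ_s of the membrane and synaptic equations is
printed in the source table as 0.001 ms, which is dimensionally inconsistent
with millisecond Izhikevich dynamics (it would put the resting dynamics six
orders of magnitude off the published spike shapes). The dynamics here are
integrated in milliseconds, i.e. an effective τ_s = 1 ms; the constant is
exposed in `IntegratorConfig.tau_s`. The governing contract is
single-neuron behavior: the RS/FS sets produce their canonical firing
patterns, and the resting fixed point (v, u) = (−70, −14) is preserved.

### Synapses

All chemical synapses share the saturating-differential scheme: a spike
raises a rectangular transmitter pulse K (default magnitude 1 for one
integration step; duration is specified in milliseconds so that changing
the step size automatically compensates the injected transmitter), K drives
the cleft variable Q, and Q drives the conductance g:

    dQ/dt = (1 − Q) K − Q/τ_rise
    dg/dt = ((τ_fall + τ_rise)/τ_fall)² (1/τ_rise) (1 − g) Q − g/τ_fall.

The flattened source rendering of the g-equation coefficient is ambiguous;
the form above was adopted because it gives a near-uniform saturation level
(~0.85–0.95) across all five kinetics families of the parameter table —
fast (2/10 ms), NMDA (8/100), PV (0.1/0.5), GABA_B (8/30), and the
extra-slow conductance (200/400) — which is the evident design intent of a
*saturating* synapse. Q and g then stay in [0, 1] for any spike train.

Receptor currents are driving-force terms that move the postsynaptic
voltage toward the receptor reversal: I = A (E_rev − v)(W·g) with E_rev = 0
for AMPA/NMDA, −70 mV for GABA_A, −90 mV for GABA_B. The printed current
equations give magnitudes whose literal signs would invert the physiology
when added to +ΣI; the excitatory/inhibitory column assignment of the
circuit's input table is taken as ground truth, enforced by
reversal-potential tests. The NMDA magnesium gate is implemented as
B(v) = [1 + 0.4202 e^(−0.062 v)]⁻¹ — opening with depolarization, the
standard Jahr–Stevens form; the printed positive exponent would close the
channel with depolarization and is treated as a sign typo. TRN neurons are
additionally coupled by gap junctions, I_i = Σ_j W_ij (v_j − v_i), with a
symmetric zero-diagonal Gaussian coupling matrix.

### T-type calcium channel

T and R neurons carry a low-threshold calcium current in
Goldman–Hodgkin–Katz form, I = −A_Ca s m²h Φ(v, Ca_int), with activation
m∞ half-set at −79 mV, inactivation h∞ at −92 mV, and the
Destexhe/Huguenard–McCormick voltage-dependent time constants; the
removable GHK singularity at 0 mV is evaluated by its closed-form limit
P z F (Ca_int − Ca_ext). The printed flattened τ_h expression parses to
(30.8 + (211.4 + e^((v+119.2)/5))/(1 + e^((v+90)/3.2)))/3.7373, the same
family as the thalamic models the parameterization derives from. The
source gives no unit chain for the current amplitude; the raw SI flux is
~10⁹ in Izhikevich current units, so a fixed unit-folding scale s = 10⁻⁶
is applied (`NetworkConfig.ca_unit_scale`), chosen once so that
subthreshold leak is O(0.01) and a full rebound surge is O(100), comparable
to the synaptic currents. The calibration contract is behavioral:
hyperpolarization deinactivates the channel and release produces a rebound
burst, and a reticular neuron driven by I_hyp = −60 is silenced and bursts
on release. The internal calcium pool relaxes to 0.00024 mM at 0.2/ms and
responds to the rectified channel current as printed; because external
calcium dominates the flux at physiological voltages, this pool has
negligible dynamical effect and the rectifier parse is guarded only by the
fixed-point test.

### Disinhibitory short-term plasticity

Deep-layer firing drives an extra-slow conductance g_xslow (200/400 ms)
which weakens reticulo-thalamic GABA_B inhibition multiplicatively:

    P_T,i = [1 + A_STP Σ_j W_{Dj→Ti} (g_xslow,j)⁶]⁻¹,   A_STP = 3000.

P_T is recomputed every step from the current g_xslow (memoryless given the
slow kinetics), equals 1 without cortical drive, and scales only the R→T
GABA_B current. With the narrow Gaussian D→T topography (σ = 0.05), the
factor carves focal "islands" of thalamic disinhibition; appreciable
disinhibition requires roughly 200 ms of sustained deep-layer firing.

### Connectivity

Topographic projections are Gaussian in normalized position,
W[i→j] = A exp(−((i/N_pre − j/N_post)/σ)²), with indices 1..N and no
centering correction, so the 120-neuron cortical groups align
retinotopically with the 40-neuron thalamic groups. The R→T projection is
uniformly all-to-all at weight 0.32 — inhibition is spatially unstructured
and only the plasticity factor creates structure. PV→PV includes
self-inhibition (the printed sum has no self-exclusion); only the
gap-junction diagonal is zeroed. CB interneurons inhibit exclusively the
distal-dendrite branch of the thalamo-cortical drive onto M, inside a
rectified bracket:

    I_T→M = (0 − v)(W^p·g_T) + (0 − v)[W^d·g_T − W_CB→M·g_CB]⁺,

so CB activity can cancel distal excitation but never touches the proximal
branch nor inverts the drive. The thalamo-cortical drive is AMPA-only, as
the circuit's input table lists it. External afferents (one per thalamic
neuron) carry both a fast and an NMDA conductance, driven by the same
Poisson train with amplitude 1 (the table does not list them).

## Task loop

The target is a near-Gaussian bump in the Poisson rate of the 40 afferents:
rate_i = 30 + 220·exp(−u⁴/2) with u = 0.5 N_T − i − (x_c − x_T), clipped at
250 sp/s. The flattened source is ambiguous between a quartic and squared
exponent; the quartic reading (a flat-topped bump ~±1.5 afferents wide) is
the default and the exponent is exposed in `TaskSpec.bump_exponent`. In
pursuit the target center follows 20.5 + 9.5 sin(2πt) (1 Hz, extremes at
indices 11 and 30, phase 0 at t = 0); in fixation it is constant at 10 with
an optional equal-amplitude distractor at 25 appearing at 2 s. Target and
distractor bumps combine by element-wise maximum, which preserves the
printed 250 sp/s ceiling (summation would exceed it).

The middle layer is read out as a motor error map: rectified linear ramps
(slope 0.025, zero at the map center) weight the fast conductances of the
left and right halves into leftward/rightward signals L and R, and the
gaze integrates x_c ← clamp(x_c + R − L, 5, 36) every integration step.
Gaze starts at the map center (20.5). There is no prediction of target
motion; tracking is purely error-driven. Trials run 8 s at h = 0.025 ms
(forward Euler throughout); behavioral and neural traces are sampled at
400 Hz (every 2.5 ms boundary, entry state), and perturbations switch on as
a step function at 6 s.

## Perturbation protocols

Each protocol scales one mechanism from 6 s to trial end, never mutating
the baseline configuration: NMDA amplitude on PV or CB interneurons (or
both jointly) scaled to 50–10 %; direct PV GABA output (A_PV→PV and A_PV→M
jointly) to 90–50 %; direct CB output to 50–10 %; A_STP to 50–10 %; or a
constant hyperpolarizing current I_hyp ∈ {−15 … −75} added to every
reticular neuron. Strength 1 (or I_hyp = 0) reproduces the unperturbed
trajectory bit-exactly.

## Analysis

Summed middle-layer voltage, linearly detrended, feeds a 400 Hz
spectrogram (400 ms Hann window, 360 ms overlap → 191 frames for an 8 s
trial) and per-epoch FFT power spectra; the normal epoch is 4–6 s and the
perturbed epoch 6–8 s. "Alpha power" is the integrated 8–12 Hz FFT power
(the source uses "alpha" qualitatively). Behavioral metrics are the rms
eye-target error (map-index units, deliberately unitless) and the count of
samples whose per-sample gaze displacement strictly exceeds 0.5 index units
per 2.5 ms. Sweeps run 5 strengths × 5 seeded model instances per
perturbation and are summarized as mean ± SD per cell.

## Numerical implementation

The production trial loop is a fused numba kernel; a modular numpy
implementation of the identical step (`crtsim.network.step_network`) is the
readable reference, and a third, scalar pure-Python implementation lives in
the test suite as an independent oracle. Kernel and numpy engines share one
Mersenne-Twister Poisson stream and agree spike-for-spike over short
horizons; over many seconds the chaotic spike dynamics amplify
summation-order rounding differences, so cross-engine agreement is asserted
on a 100 ms window and determinism (bit-identical repeat runs) per engine.
Gaussian weight matrices are applied as banded products in the kernel,
dropping entries below 10⁻¹⁸ of the peak (sub-ulp); conductance tails below
10⁻³⁰ are flushed to exact zero in all engines to avoid denormal-float
slowdowns. An 8 s trial takes ~15–20 s on one CPU core.

## Calibration and its limits

Two constants are not fixed by the source: the spike-pulse K
(magnitude/duration) and the calcium unit scale. They were calibrated
jointly against the published *unperturbed* behavioral contracts —
a single presynaptic spike produces a visible unitary PSP; pursuit
converges after an initial error-reduction epoch; summed middle-layer
activity shows a ~10 Hz (alpha) rhythm before convergence that subsides
once tracking is accurate; the cortically-created disinhibition island is
focal; reticular neurons rebound-burst under hyperpolarization — and the
defaults (K: magnitude 1 for one 0.025 ms step; scale 10⁻⁶) are the only
regime found in which the alpha/intermittent-attention signature is robust
across seeds. This operating point reproduces the perturbation phenotypes
directionally (CB and dSTP perturbations raise alpha power in both tasks,
TRN hyperpolarization raises it in fixation, PV perturbation remains far
below the CB/dSTP alpha signature, high-velocity counts grow with
perturbation strength, perturbed/normal rms ratios span the 1.1–1.9 range
reported for patients versus controls), with three known quantitative
shortfalls, stated here because the tests assert them honestly:

1. **Pursuit lag.** Purely error-driven tracking through three conductance
   stages with ~8 ms kernel centroids plus membrane integration yields a
   ~50 ms closed-loop lag, i.e. steady-state rms error ≈ 2.2 index units
   (~23 % of the 9.5-index target amplitude) rather than the ≤15 %
   calibration target. Raising the global gain shortens the lag but
   destroys the pre-convergence alpha epoch, which is the stronger
   published contract.
2. **Distractor rejection.** With the printed weights the reticular GABA_B
   pool only marginally out-weighs the 250 sp/s afferent peak, so an
   equal-amplitude distractor leaks spikes into the high-leverage eccentric
   part of the error map and can capture gaze in a fraction of seeds.
   Fixation without a distractor is accurate to ~0.3 index units rms.
3. **PV oscillation frequency.** The PV-perturbation eye oscillation
   emerges at 2–7 Hz (its period is set by the motor-loop gain), below the
   published ~10 Hz.

## What the simulations do and do not show

All inputs are synthetic Poisson trains; the model abstracts away retinal
and oculomotor plant dynamics, predictive pursuit, explicit task
instruction, and the multi-area architecture of the real attention network.
Passing tests therefore demonstrate the internal consistency of the circuit
mechanism — topographic gating, selective disinhibition, rhythm switching,
and the mapping from specific inhibitory deficits to distinct oculomotor
signatures — not quantitative agreement with human eye-tracking data.
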