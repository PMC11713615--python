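# Methods

## The model

Binary activity of a culture of N neurons is described by a kinetic Ising
process. With `s_i^t = ±1` marking whether unit i spikes in time bin t, each
unit updates synchronously from the previous bin:

    P(s_i^t | s^{t-1}) = exp[(H_i + Σ_j J_ij s_j^{t-1}) s_i^t]
                         / 2 cosh(H_i + Σ_j J_ij s_j^{t-1}).

`J_ij` is the directed effective coupling from source j to target i and
`H_i` the intrinsic field (how active a unit is absent input). Because the
update conditions only on the previous bin, the joint transition probability
factorises over targets and the log-likelihood of a raster is a sum over
bins and units. Longer synaptic delays are not modelled; their influence is
weak compared with the single-bin delay once the bin width is chosen well
(see below). Self-couplings `J_jj` are allowed and are typically inferred
negative — a refractory effect, not anatomy.

## Structural priors

Biology enters through priors on (J, H) governed by hyperparameters
ρ = {γ, a, μ_H, v_H, μ_J±, v_J±, ε}:

* **Neuron type** `z_j = ±1` (excitatory/inhibitory), prior P(z_j=+1) = γ.
  All outgoing couplings of a neuron share its sign (Dale's principle).
* **Link existence** `φ_ij ∈ {0,1}` with prior
  P(φ_ij=1) = θ_ij·exp(−a·l_ij): connection probability decays with the
  Euclidean distance l_ij (µm) at rate a (1/µm), and θ_ij encodes substrate
  knowledge — for stripe-patterned cultures θ_ij = 0.5^md with md the number
  of stripe boundaries between i and j, θ = 1 otherwise.
* **Coupling magnitude**: an existing link has log-normal |J_ij| with
  per-type location/scale (μ_J±, v_J±); an absent link has J_ij ~ N(0, ε)
  with small ε — a Gaussian stand-in for a delta at zero.
* **Fields**: H_i ~ N(μ_H, v_H).

The evidence objective is the log-likelihood plus the log-priors, with the
coupling prior marginalised over z and φ per source column (the type is
shared along a column).

## Estimators

* **MLE** maximises the likelihood alone.
* **MAP** maximises the evidence objective in (J, H) at fixed ρ, then reads
  off the latent posteriors.
* **GML** (generalised maximum likelihood / evidence approximation)
  alternates a macro E-step (the MAP optimisation at current ρ) with a
  macro M-step that re-estimates ρ by an inner EM over the latents:
  the micro E-step computes P(z_j | J) ∝ p(z_j)·Π_{l≠j} m_z(J_lj) (with
  m_z the per-entry spike/slab mixture) and P(φ_ij=1 | z); the micro M-step
  updates γ, μ_J±, v_J±, μ_H, v_H in closed form from
  responsibility-weighted moments and the decay rate a by projected
  gradient ascent on [0, 1] with backtracking (so its Q terms never
  decrease). MAP is exactly GML with one macro iteration.

Final decisions take the highest-probability states: ẑ_j = sign at
P(z_j=+1) ≥ 0.5 (ties to the majority class) and φ̂_ij = 1 at
P(φ_ij=1) ≥ 0.5.

### Numerical choices

* The (J, H) maximisations use L-BFGS-B on the per-transition-normalised
  objective (gradient tolerance 1e-5, fields bounded at |H| ≤ 20). The
  objective and gradient are exact; the dense (T × N) algebra runs in
  single precision when T·N exceeds 5·10^5, which is three times faster and
  far above the float32 noise floor at these tolerances.
* Hyperparameter seeding ("from MLE"): columns are provisionally typed by
  the sign of their summed off-diagonal couplings; log-normal moments come
  from matching-sign couplings above 10^-3; μ_H, v_H from the field moments.
* All mixture evaluations run in log-space. The link probability
  θ_ij e^{−a l_ij} is clipped to 1 − 10^-9 so the spike component never
  loses support entirely (θ = 1 would otherwise give mixed-sign columns
  zero prior mass under both types).
* In the micro M-step, couplings with |J| < 3√ε are excluded from the
  log-normal moment updates: inside the spike's own support they carry no
  information about the slab and their ln|J| tails would otherwise inflate
  v_J±. A zero-responsibility class keeps its previous value (warned).
* ε defaults to 10^-4; variances are floored at 10^-6.
* Diagonal couplings carry a flat prior, are excluded from the type product
  and the moment updates, and their link posterior uses a sign-agnostic
  slab. Link metrics exclude the diagonal by default.
* Units that always or never spike have a separable likelihood whose field
  optimum is at ±∞; their H is clipped to ±20 with a warning.
* Simulation from a fitted network starts from the all-silent state and
  discards a 1,000-step burn-in before covariances are computed.

## Bin-width selection

Spike events are binned into half-open, left-aligned bins of width τ. τ is
chosen to maximise (T_rec/τ − 1)·Σ_{i≠j} I_τ(s_i, s_j), the number of
transitions times the total plug-in delayed mutual information (bits,
0·log 0 = 0, no bias correction) between each unit's activity and every
other unit's previous-bin activity; the maximiser approximates the
culture's effective reaction time. T_rec and τ are both in seconds. The
default grid is geometric from one camera frame (1/33 s) to 2 s in 20
steps; ties and the all-silent degenerate case resolve to the smallest τ.
Fluorescence traces are first converted to events with a Schmitt trigger
(on at mean + 3 SD, off at mean + 1 SD, per trace; optional
sliding-percentile detrending).

## The in silico emulator

The emulator supplies ground truth the method can be scored against. It is
generative in three stages, each consuming an independent stream spawned
from one seed:

1. **Placement.** N somata (r_soma = 7.5 µm) are rejection-sampled without
   overlap on the substrate. The patterned substrate is four 300 µm stripes
   separated by 200 µm gaps, 150 µm deep — about 870 cells/mm², a typical
   plating density; neurons sit only on stripes.
2. **Axon growth.** Each axon is a chain of 400 segments of 10 µm whose
   heading jitters by σφ = 0.15 rad per segment. Culture edges reflect the
   growth cone; a stripe-edge wall is climbed with probability 0.5 and
   otherwise deflects it — the topographic guidance that makes stripes act
   as modules. Every segment passing within r_soma of another soma gives an
   independent Bernoulli(α·penalty^md) chance of a synapse (α = 0.33,
   penalty 0.1 per stripe boundary); a connected pair is never duplicated.
   Weights are Normal(Ω_type, 0.05) truncated positive, negated for
   inhibitory sources; 20% of neurons are inhibitory. The strong-coupling
   regime is (Ω_E, Ω_I) = (6, 12), the weak one (4, 8). Mean out-degree at
   the defaults is ≈10, with ~95% of links within a stripe.
3. **Dynamics.** Izhikevich neurons (regular-spiking excitatory, a=0.02,
   b=0.2, c=−65, d=8; fast-spiking inhibitory, a=0.1, b=0.2, c=−65, d=2;
   threshold 30 mV) are Euler-integrated at dt = 0.5 ms with synaptic
   resources: a spike of j increments its postsynaptic variable P_j by
   β·R_j and depletes the reserve R_j by the fraction γ_R; P decays with
   τ_P, R recovers with τ_R, and target i receives Σ_j W_ij P_j. Defaults
   τ_P = 30 ms, τ_R = 3 s, β = 1, γ_R = 0.5, with white-noise drive
   3.0 (exc) / 1.2 (inh) mV·ms^-1/2. These produce sparse spontaneous
   firing (~1–2 Hz), single-synapse transmission probability ≈0.4 at the
   strong weights, and depression-terminated network-wide bursts. Default
   recording length is 600 s (a typical 10-minute imaging session).

None of the dynamical constants are dictated by the inference method; they
are this package's documented choices, and every quantitative conclusion
drawn from emulated data inherits their uncertainty. What the emulator does
*not* reproduce: calcium-indicator dynamics and imaging noise (events are
exact spike times), glia, synaptic plasticity over days, conduction delays,
and multi-neuron ROIs. Tests passing on emulated data therefore demonstrate
correct inference under a plausible spiking model of a patterned culture,
not performance on any particular recording rig.

## Problem sizes and observed behaviour

The bundled validation uses a 156-neuron patterned culture (the scale of
the motivating experiments) for the headline link-identification rates and
a 50-neuron, two-stripe variant for desk-scale checks; parameter-recovery
tests draw T = 10^5 bins from the generative model at N = 20. On the
156-neuron culture the full pipeline (emulate → binarize → MLE → MAP) runs
in ≈2 minutes on one CPU core.

## Known limitations

* The MAP/GML posterior over J is multimodal (spike vs slab basin per
  coupling); gradient ascent from the MLE keeps each coupling in the basin
  the data favour, so results depend mildly on the initialisation — the
  same property the decimation behaviour of the method relies on.
* GML's macro loop is the computational bottleneck at N ≳ 100; MAP (one
  macro iteration) is the pragmatic choice at scale, as in the sensitivity
  analyses.
* With θ ≡ 1 the link prior carries no information and link detection rests
  entirely on the coupling-magnitude contrast.
* The excitatory fraction γ enters both the prior and the random baselines;
  cultures far from the assumed 80/20 split weaken the type prior's help.
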