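# Methods

`banetsim` models the basal nucleus of the amygdala (BA) at two levels of
description and simulates the behavioural protocols of cued fear
conditioning, extinction and context-dependent renewal. This note documents
the models, the parameterisation and its rationale, the numerical choices,
and the limits of what the simulations show.

## Scientific background

Extinction of conditioned fear is not unlearning: presenting an extinguished
conditioned stimulus (CS) outside the extinction context renews the fear
response. In vivo recordings in the BA show two intermingled populations of
principal neurons — "fear neurons" that respond to the CS after
conditioning, and "extinction neurons" that respond after extinction
training — whose balance tracks the behavioural state. The models here test
the hypothesis that this differential recruitment needs nothing more than
(i) convergence of CS afferents and context-specific (hippocampal/prefrontal)
afferents onto the same BA principal cells, (ii) a coincidence-based
plasticity rule on those afferents, and (iii) competition between the two
populations through shared feedback inhibition.

## Mean-field model

Two identical Wilson–Cowan populations A and B with activities X ∈ {A, B}:

    τ_X dX/dt = −X + (k_X − r_X · X) · S(I_X + η(t))
    I_X = w_X,CS · CS(t) + w_X,CTX · CTX_X(t) − w_inh · X_other + bkg

S is a logistic transfer with steepness p and midpoint θ; k_X is the maximum
rate, r_X the refractoriness coefficient (activities stay in [0, k_X];
with r = 1 the attainable maximum is k/2, so rates remain far from
saturation); η is zero-mean Gaussian noise applied inside the transfer
function and scaled by √dt at the integration step (Euler–Maruyama,
dt = 0.1 ms). Activities are normalised (k = 1).

CS input arrives as 50 ms pulses to both populations; context input is tonic
and population-specific. At the offset of each CS pulse, the CS and context
weights of the population whose context was active grow by the additive
learning rate (a = 0.05 in normalised units, initial weights 0.05,
calibrated so that five conditioning trials produce clear dominance). There
is no depotentiation in this model: weights never decrease. Five CS
presentations in context A (conditioning) followed by six in context B
(extinction) reproduce the canonical pattern: population A's CS response
grows during conditioning; during extinction population B's response grows
until, once its CS weight exceeds A's, mutual inhibition suppresses A.
Trial curves are averaged over 30 repeats by default.

## Spiking network model

### Composition and dynamics

A random recurrent network of 3400 excitatory (EXC) and 600 inhibitory (INH)
leaky integrate-and-fire neurons (≈10% of the rat BA). Subthreshold dynamics

    C dV/dt = −g_L (V − E_L) − g_E (V − E_E) − g_I (V − E_I)

with conductance-based synapses decaying mono-exponentially (τ_E = 3 ms,
τ_I = 6 ms; E_E = 0 mV, E_I = −80 mV). A spike fires on an upward threshold
crossing; V is reset to E_L = −70 mV and clamped for the refractory period.
EXC thresholds are Gaussian around −57 mV (σ = 1 mV). The EXC refractory
period is 25 ms — a deliberately long value standing in for the strong
spike-frequency adaptation/AHP of BA principal cells; it guarantees the
observed response regime in which a responsive principal cell fires at most
two spikes per 50 ms CS. INH neurons are faster (τ_m = 10 ms, t_ref = 1 ms).
An option draws INH thresholds from an equal bimodal mixture peaked at
−35/−28 mV (fast-spiking vs delayed-firing interneuron classes) for
heterogeneity experiments.

Connections are independent Bernoulli draws per directed pair (autapses
allowed) with per-edge delays uniform on [1, 2] ms. The sparse default uses
p(E→E) = 0.01, p(E→I) = 0.15, p(I→E) = 0.15, p(I→I) = 0.10 with weights
0.5/0.85/2/2 nS; the *dense preset* raises p(E→I) = p(I→I) = 0.5 with 3 nS
inhibitory synapses, the regime in which gamma oscillations emerge.

### Inputs

Every neuron owns independent Poisson generators per stream (correlations
between neurons arise only through recurrence): tonic background to all
neurons (1300 Hz through 1.2 nS lumped synapses), 50 ms CS pulses at 500 Hz
to all neurons (plastic synapse on EXC, fixed 0.8 nS on INH), and tonic
context input at 500 Hz to a fixed, randomly chosen 20% subset of EXC
neurons per context (configurable overlap between the context-A and
context-B sets; a third context C is always disjoint). A single stream plays
both US and CS roles — the model makes no explicit US/CS distinction.

### Plasticity

Only the CS and context afferents onto EXC neurons are plastic. Each EXC
neuron keeps a CS tag c and one context tag h per context afferent;
presynaptic spikes increment the tag by 0.1 and tags decay with τ = 60 ms,
giving a coincidence window of roughly 100 ms. At each CS offset the tags
are probed (calcium-control logic with fixed thresholds):

* c + h > θ_high (2.9): LTP of both synapses, Δw = a1 · m · (w_max − w)
* θ_low (0.8) < c + h ≤ θ_high: LTD of both, Δw = −a2 · (w − w_min)
* otherwise: no change

with a1 = 0.35, a2 = 0.03, bounds [0.1, 1.7] nS, initial weights 0.3 nS (CS)
and 0.15 nS (context — close to the lower bound, which is why context
synapses are not depressed during conditioning). The soft-bound factors make
increments vanish exactly at the bounds. LTD is not scaled by the
neuromodulator (its gating is specific to potentiation).

The neuromodulatory gain m multiplies the potentiation step and is
phase-schedulable: 1.0 during conditioning (US present, neuromodulator
released) and 0.4 during extinction (CS alone). This asymmetry is what
leaves fear neurons' CS weights above extinction neurons' at the end of
extinction, and is required for renewal in a *novel* context (ABC renewal):
with a symmetric gain the six extinction-trial potentiations always end
above the five conditioning ones and the extinction population would win in
any context. Eligibility tags are reset at phase boundaries (the inter-phase
gap is long against τ = 60 ms); weights persist throughout.

Pre-conditioning CS probes and renewal-test CS presentations run with the
plasticity probe disabled: they are readouts. In particular, weights are
exactly constant during renewal blocks, so the activity switch on a context
change is demonstrably a network effect, not a learning effect.

### Protocols

The standard experiment is 2 pre-conditioning probes in context A, 5 CS
presentations in context A (conditioning), 6 in context B (extinction), with
2 s inter-trial intervals, 1 s warm-up per phase, and 30-repeat averaging
supported through derived seeds. Variants: renewal (post-extinction CS in
context A or C, 3 readout trials), extinction over-training (default 12
extra extinction trials, both renewal variants branched from a common
checkpoint), inhibition blockade (50%/90% of INH silenced during
extinction), context removal (context rates zeroed after conditioning or
after extinction), and sweeps over context overlap, inhibitory connectivity,
delay range and synaptic strength.

### Analysis

Evoked responses are per-neuron spike counts in a 60 ms window from CS onset
(50 ms when the quantity of interest is the rate during the CS itself).
A neuron is *responsive* in a phase if it fires ≥1 spike in ≥2 of the last
3 trials; fear/extinction/persistent/nonresponsive labels follow from
responsiveness after conditioning vs after extinction. Distinct populations
exist when extinction-labelled neurons out-respond fear-labelled neurons by
a factor 2 at the end of extinction (configurable). Recruitment profiles
report the trial at which each neuron switches (persistently) from
non-responding to responding; the graded population curve is the cumulative
recruitment of all-or-none units. Synchrony uses the Golomb–Rinzel index
(χ² = variance of the population-averaged binned signal over the mean
single-train variance, 2 ms bins; 1 for perfect coincidence, → 0 for
independence). Spectra are Welch periodograms of the 1 ms-binned population
rate (1 s Hann segments, 50% overlap), with the peak excluding DC.

## Calibration

The defaults are a calibrated set: they were fixed once against the target
observables of the modelled circuit and then frozen:

1. background rates/weights for EXC baseline < 1 Hz and INH baseline ≈ 10 Hz
   (measured: 0.7 Hz and 10.8 Hz over 10 s);
2. CS rate and INH CS weight for CS-evoked INH rates near 20 Hz after
   conditioning (measured ≈ 22 Hz over the final two trials);
3. plasticity magnitudes for a monotone 5-trial acquisition staircase, return
   of fear responses to pre-conditioning levels by the end of extinction,
   instantaneous ABA renewal with fear > extinction, weaker-but-present ABC
   renewal, and its abolition by over-training;
4. the dense preset for a 30–80 Hz spectral peak (measured 32 Hz) that is
   quenched by 0.2–1 ms delays at connectivity ≤ 0.4.

## Numerical choices

* Clock-driven integration at dt = 0.1 ms; conductances decay exactly and
  the membrane uses an exponential update with the total conductance frozen
  over the step (exact for constant input, O(dt) at threshold crossings).
* Delays round to the nearest grid step with a minimum of one step; the
  0.2–1 ms delay sweeps therefore require dt ≤ 0.1 ms.
* Spike delivery through a ring buffer of per-neuron conductance increments;
  external Poisson counts are drawn per neuron per step inside the kernel
  (numba-compiled) from the phase seed, making every phase bit-reproducible.
* Every stochastic component (wiring, thresholds, context assignment, each
  phase of each repeat) derives its seed from the master seed by a named
  CRC-32 path, so checkpoint-resumed runs equal continuous runs exactly.
* Scaled-down networks divide the connection probabilities by the scale
  factor (capped at 1) to preserve in-degrees; the quarter-scale network
  (850 EXC + 150 INH) reproduces the full model's operating point and is
  used for protocol-heavy tests and the overlap sweep.

## What the synthetic protocols do and do not show

All inputs are generated: Poisson surrogates for LA (CS/US), hippocampal/
prefrontal (context) and nonspecific background afferents. The simulations
therefore demonstrate the *mechanistic sufficiency* of convergence +
coincidence plasticity + inhibitory competition for the observed population
phenomenology. They do not model real afferent spike statistics
(correlations, theta modulation), the central amygdala readout or behaviour
(freezing is assumed proportional to fear-neuron activity), neuromodulator
dynamics beyond a scalar gain, plasticity of recurrent synapses, or
conditioning and extinction in the same context (the model cannot
distinguish them by construction).

## Known limitations

* The 25 ms EXC refractory period is a coarse stand-in for adaptation; it
  caps single-neuron CS responses at two spikes by construction rather than
  through an adaptive current.
* The synchrony measure and spectral peak depend on bin/segment choices;
  qualitative contrasts (delay range, connectivity, strength) are robust but
  absolute index values are measure-specific.
* ABC renewal is reproduced with a modest fear/extinction margin (~1.5×);
  it is the most parameter-sensitive of the reproduced phenomena, consistent
  with it being the behaviourally weakest.
* Context-swap symmetry holds exactly for the rate model; in the spiking
  network it holds at the level of roles (which target set becomes the fear
  population), not spike-for-spike, because the two context target sets are
  different random neurons.
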