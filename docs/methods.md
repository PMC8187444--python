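# Methods

This note documents the models implemented in `spikeconn`, the
numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations.

## The inference problem

Given parallel spike trains from N units, decide for every ordered
pair (i, j) whether neuron i makes a monosynaptic connection onto
neuron j, and if so estimate the postsynaptic potential (PSP) it
evokes, in mV. The observable is the cross-correlogram (CCG): the
histogram of lags t_j − t_i over a ±50 ms window at 1 ms resolution. A
connection appears as a short-latency, transmission-delayed peak
(excitatory) or trough (inhibitory) on the causal side of the CCG,
superimposed on background structure produced by co-modulation,
oscillations and higher-order network paths. The package provides two
estimators that read this image in different ways — a convolutional
network trained on simulated ground truth, and a generalized linear
model with a likelihood-ratio test — plus the simulator that supplies
the ground truth.

## Network simulator (`netsim`)

### Neuron model

Units are multi-timescale adaptive threshold (MAT) neurons: a leaky
membrane integrated passively, with spikes emitted when the voltage
crosses an adaptive threshold; the voltage is *not* reset at a spike.
Membrane dynamics (voltages mV, time ms, conductances mS cm⁻²):

    tau_m dv/dt = −(v − V_L) − tau_m [g_e (v − V_E) + g_i (v − V_I)] − R·I_bg

with tau_m = 20 ms (excitatory) / 10 ms (inhibitory), V_L = −70,
V_E = 0, V_I = −80 mV. Synaptic conductances decay exponentially
(tau_s = 1 ms excitatory, 2 ms inhibitory) and jump by the synaptic
weight G one transmission delay after each presynaptic spike. The
threshold is

    theta(t) = omega + Σ_spikes [alpha_1 e^{−Δt/tau_1} + alpha_2 e^{−Δt/tau_2}]

with tau_1 = 10 ms, tau_2 = 200 ms; omega = −55 mV (E) / −57 mV (I);
alpha_1 drawn once per excitatory neuron from N(1.5, 0.25²) mV,
alpha_2 = 0.5 mV; inhibitory neurons use alpha_1 = 3, alpha_2 = 0. An
absolute refractory period of 2 ms is imposed (the MAT-literature
default; configurable). Because there is no voltage reset, a neuron
held above its (adapting) threshold can fire at the refractory limit.

### Background drive and the leak-conductance convention

Each neuron receives fluctuating background conductances modelling the
bombardment from unrecorded neurons, as in point-conductance models:
independent Ornstein–Uhlenbeck (OU) processes with stationary means
0.123 / 0.322 mS cm⁻², SDs 0.0163 / 0.0265 mS cm⁻², time constants
2.7 / 10.5 ms (excitatory/inhibitory channels), reversal potentials
0 / −80 mV. The background current enters the voltage equation as
R·I_bg; writing R as the inverse leak conductance,

    R·I_bg = [g_e_bg (v − E_e) + g_i_bg (v − E_i)] / g_L,  g_L = 0.0452 mS cm⁻²,

the Destexhe-type leak value from which the background parameters
descend. This convention matters: treating the background
conductances as dimensionless multipliers instead leaves the network
~30 noise-SDs below threshold and silent, whereas with the g_L
division the resting point sits ~2 noise-SDs below threshold and the
population fires irregularly at a few Hz (excitatory) to tens of Hz
(inhibitory), inhibitory above excitatory, with interval irregularity
Lv ≈ 1 — the in-vivo-like regime the generator is meant to produce.
g_L is a configuration field.

To mimic slow in-vivo rhythms, three disjoint subgroups (100 neurons
each at full scale, 80 E + 20 I) receive an extra noise term
A sin(ωt + δ) ξ(t) on the excitatory background channel at 7, 10 and
20 Hz, with per-neuron phase δ ~ U[0, 2π) and amplitude
A ~ U[Ã/2, 3Ã/2], Ã = 0.015. Because this term multiplies white
noise, it modulates the *instantaneous variance* of the background —
the mean trace of g carries no spectral line at f; the envelope
oscillates at 2f (sin² = (1 − cos 2ωt)/2). Tests therefore check the
periodogram of the squared, mean-removed trace at 2f. Inhibitory group
members receive the term on their excitatory background channel as
well (the groups explicitly contain inhibitory neurons).

OU updates use the exact stationary discretization
g′ = μ + (g − μ)e^{−Δ/τ} + σ√(1 − e^{−2Δ/τ}) ξ, which preserves the
stationary mean and SD at any step size. Background conductances may
transiently go negative (point-conductance convention); an optional
clipping flag is provided, off by default.

### Wiring and weights

800 excitatory and 200 inhibitory neurons (80/20 at any scale); every
neuron receives exactly 100 excitatory and 50 inhibitory inputs chosen
uniformly without replacement, excluding self-connections — per-pair
connection probabilities 12.5% and 25%. Excitatory conductances are
log-normal (ln-mean −5.543, ln-SD 1.30); inhibitory conductances are
normal (mean 0.0217, SD 0.00171 mS cm⁻²) with negative draws
resampled. Delays are uniform: 3–5 ms (excitatory), 2–4 ms
(inhibitory). Scaled configurations (`SimConfig.scaled(N)`) keep the
80/20 split and the per-pair probabilities by setting in-degrees to
round(N_E/8) and round(N_I/4), and scale the oscillation groups to
N/10 neurons each.

### Ground-truth PSP

The teaching signal per synapse is the signed peak deflection of the
postsynaptic membrane from V_L when the single synapse alone fires
once into an otherwise passive membrane (no background, no other
inputs), obtained by integrating the voltage equation at dt = 0.01 ms.
This definition is reproducible, strictly monotone in G, and matches
the linearized closed form (difference of exponentials) to <1% at
small G; at large G the conductance nonlinearity (driving-force
shunting) caps the deflection, as it should. Network construction
evaluates it via a 200-point log-G interpolation table per
(synapse sign × postsynaptic class), accurate to ~1e-4 relative.
Median EPSP at the default weights is ≈0.23 mV with a long log-normal
tail to several mV; IPSPs are ≈ −0.32 ± 0.03 mV.

### Integration

Forward Euler at dt = 0.1 ms for the membrane; synaptic and threshold
decays are applied as exact exponential factors; delayed deliveries
are queued in a ring buffer with delays rounded to the nearest step.
The OU background sample paths are advanced on a coarser 1 ms grid
(configurable via `bg_update_dt`) using the exact discretization above
and held constant between updates; since the OU time constants are
2.7 and 10.5 ms and the membrane filters at ≥2 ms, this changes the
voltage statistics negligibly while cutting the dominant cost (Gaussian
variate generation) tenfold. A fine-step oracle test verifies that a
deterministically driven neuron's firing rate at dt = 0.1 ms matches a
dt = 0.001 ms reference within 2% (observed: <0.1%). A single compiled
noise stream, seeded from the run seed, makes simulations
bit-reproducible; results are independent of the chunking used to
bound memory.

## Correlograms (`ccg`)

Bins are half-open with inclusive lower edge, so an exact coincidence
falls in the first positive bin [0, 1) ms; 100 bins cover [−50, 50) ms.
Positive lags mean "target after reference", so the causal impact of
the reference unit occupies the right half. Shadow trimming removes
the four bins covering [−2, 2) ms — the interval corrupted by the
spike-sorting shadowing artifact, in which near-synchronous spikes on
one electrode are lost — and concatenates the remainder (96 bins).
Trimming is also applied to synthetic data so that models see the same
geometry they will meet on recordings.

Time-rescaling augmentation multiplies all spike times (and the
duration) by a factor; rates scale inversely, labels are unchanged.
The default factor set {1, 2, 4} teaches the estimator the same
connectivity at 1×, 1/2× and 1/4× the original count level. The local
variation statistic uses the standard definition
Lv = 3/(n−1) Σ [(I_k − I_{k+1})/(I_k + I_{k+1})]², undefined below
three spikes.

## CNN estimator (`cnn_estimator`)

Architecture: 1-D convolution (kernel 10, 5 output channels, stride 1,
tanh) → average pooling (window 2, stride 1) → fully connected hidden
layer of 100 ReLU units → 2 outputs: connection probability z (logistic)
and PSP in mV (linear). With 96-bin input this is 43,357 trainable
parameters (45,357 at 100 bins) — within the intended "about fifty
thousand" budget, which is what fixed the pooling geometry and the
absence of convolution padding. Training: Adam (lr 0.001, β₁ 0.9,
β₂ 0.999), 20 epochs, no dropout, loss 0.5·BCE(z) + 0.5·MSE(PSP),
batch size 64. The batch size was chosen by a validation sweep over
{256, 128, 64, 32} at the scaled study conditions; 64 gave the best
held-out detection and amplitude recovery. The implementation is plain
numpy with hand-derived backpropagation (verified against finite
differences to 1e-4), which keeps training deterministic under a seed.

Inputs are the integer CCG counts divided by one scalar: the mean
count of the training set, calibrated once at the start of training and
stored in the checkpoint. Without it the tanh convolution operates in
deep saturation on raw counts (measured 96–100% of units beyond
|pre-activation| = 2 even after training), which erases the amplitude
information the PSP head needs; the scalar preserves every
correlogram's absolute and relative structure, unlike per-correlogram
normalization. Raw-count behaviour is recoverable by setting
`input_scale = 1`.

Each unordered pair contributes one correlogram per augmentation
factor, used twice: as computed (candidate direction = positive-lag
half) and lag-reversed, labelled z ∈ {0, 1} and PSP (0 when
unconnected) per direction. Inference evaluates both orientations of
each pair and thresholds z at θ = 0.5 — validated by a threshold sweep
whose macro-MCC shows a broad maximum near 0.5. Detected sign is the
sign of the estimated PSP; undetected pairs report PSP = 0 by
convention. Class imbalance (~15% connected) is left unweighted.

## GLM with likelihood-ratio test (`glmcc`)

The CCG of a pair is modelled as an inhomogeneous Poisson intensity
λ(t) = exp[a(t) + J₁₂ f(t) + J₂₁ f(−t)] over [−50, 50] ms, where the
baseline a(t) (one value per 1 ms bin, in log expected counts per bin)
absorbs slow fluctuations under a smoothness prior
−Σ (1/γΔ)(a_{k+1} − a_k)², γ = 2×10⁻⁴ ms⁻¹, and
f(t) = e^{−(t−d)/τ} for t > d (else 0) with τ = 4 ms and delay d
selected per direction from {1, 2, 3, 4} ms by maximal posterior.
Fitting maximizes the penalized likelihood (binned counts; trimmed-out
bins are masked from the likelihood but kept in the prior so the
baseline interpolates the gap and f keeps its true lag alignment) over
the 102 parameters with L-BFGS-B and analytic gradients, warm-started
from a baseline-only fit; the objective is concave given the delays,
and multi-start tests confirm a unique optimum.

Significance per direction uses the likelihood ratio: D is the gap
between the optimized objective and the objective re-optimized with
that coupling pinned to 0 (everything else free, delays fixed at their
selected values). Twice D is asymptotically χ²₁ (Wilks), and the null
is rejected when 2D > 15.14, the upper 10⁻⁴ quantile.

Monte-Carlo calibration on independent Poisson pairs (5 Hz, 30 min)
with the delay held fixed shows 2D tracking χ²₁ closely but with a
mild, systematic ~20% deflation (e.g. median 0.35 vs 0.455; 2.6–2.8%
rejection at the nominal 5% threshold). The mechanism is leakage
between the baseline and the coupling: the smoothness prior is strong
(penalty weight 1/γΔ = 5000) but still lets a(t) mimic the
low-frequency part of the one-sided exponential kernel, so the
constrained (J = 0) refit recovers part of the objective gap. The
deflation is therefore intrinsic to the model's hyperparameters, is
independent of the optimizer and of whether D is measured on the
penalized objective or the raw likelihood, and acts in the safe
direction: the test is slightly conservative. Delay *selection*, by
contrast, makes the deployed statistic the maximum of four correlated
statistics, inflating the moderate-α tail (~12% at nominal 5%); at the
operating α = 10⁻⁴ the two effects combined leave measured
false-positive rates on null data at ≤1%.
No mapping from J to mV is part of the model; a least-squares J→PSP
slope against simulator truth is available as a clearly-labelled
convenience only.

## Evaluation (`evalmetrics`)

Detection is scored one-vs-rest per sign category with the Matthews
correlation coefficient, macro-averaged: MCC = (MCC_E + MCC_I)/2,
guarded to 0 when a marginal is empty. True excitatory connections
below a visibility threshold (default 0.1 mV) are excluded from the
excitatory tally entirely — they are undetectable at realistic
recording lengths, and detecting one is not an error (the connection
exists). The rates reported are FPR = FP/(FP+TP) (false discovery) and
FNR = FN/(FN+TP) (miss); both denominators are conventions, chosen
here as the discovery/omission readings, with the raw counts always
available. The E–I dominance index d_ei = (n_e − n_i)/(n_e + n_i)
over a unit's detected outgoing connections classifies units as
putative excitatory (>0), inhibitory (<0) or undetermined (0 or no
detections). Duration curves re-run an estimator on truncated
recordings; split-half stability compares detected signs between the
two halves of a recording.

## Problem sizes used in the tests

The test suite and worked examples run a scaled configuration chosen
once: 100 neurons (80 E / 20 I, in-degrees 10/5), 60 min of biological
time for both the training network and an independently wired held-out
network, 4,950 pairs → 29,700 training examples after orientation and
augmentation. At this scale the full pipeline (two simulations,
training, evaluation) completes in a few minutes on one CPU. Under
these conditions the held-out results are: macro-MCC ≈ 0.75–0.80 with
a broad θ-optimum at 0.5–0.7; sign agreement ≈ 99% among detected true
connections; excitatory false negatives non-increasing over 10 → 30 →
60 min; and estimated-vs-true PSP correlation r ≈ 0.72–0.75 for
|PSP| ≥ 0.5 mV. The correlation is limited at this scale by two
effects quantified during development: synapses above 4 mV are too
rare (≈7 in a 100-unit network) for the regression tail to generalize,
and 0.5–1 mV synapses sit near the information floor of a 60-min
correlogram, so the conditional-mean estimate shrinks toward the bulk.
Both effects recede with the full-scale configuration (1000 neurons,
400 recorded units, ~80k pairs, 120 min), which is hours of compute
and is exposed through the same API and CLI defaults.

## What the generator does and does not emulate

The simulator produces irregular, fluctuation-driven spiking with
oscillatory co-modulation, realistic rate heterogeneity and exact
ground truth — the features that make CCG inference hard and
trainable. It does not emulate: spike-sorting errors other than the
shadowing notch (no contamination/splitting), electrode drift,
non-stationary rates beyond the imposed rhythms, plasticity, spatial
structure in connectivity, or conduction-delay distributions beyond
the uniform ranges. Passing tests therefore demonstrate recovery of
connectivity under this generative family, not under every failure
mode of real recordings; the shadow-trimming step and rate filtering
are the only preprocessing defenses carried over to real data.

## Degenerate inputs and edge conventions

Empty spike trains yield zero correlograms (with a warning on file
ingestion); Lv is NaN below 3 spikes; MCC is 0 when undefined;
d_ei is undetermined without detections; double trimming, length
mismatches, in-degrees exceeding the pool, durations beyond the
recording, and units missing from a truth table all raise immediately.
Simulation aborts with a diagnostic if the membrane leaves physical
bounds. All randomness flows from explicit `numpy.random.Generator`
objects or integer seeds; identical seeds give bit-identical spike
trains, weights and estimate tables.
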