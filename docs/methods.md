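# Model and methods

## Scope

`betacol` implements a two-column model of sensory cortex in which a
synchronous 20 Hz ("beta") EPSC train delivered to the layer-5 pyramidal
cells of one column (the *attended* column) biases the competition between
the columns. Each column contains nine populations of 20 conductance-based
cells: L2/3 regular-spiking pyramids (RS), fast-spiking (FS) and
slow-inhibitory (SI, LTS/Martinotti-like) interneurons; L4 excitatory (E)
and FS cells; and L5 intrinsically-bursting (IB) and regular-spiking
pyramids, FS and SI interneurons. The columns interact only through
ascending excitation from L5 pyramids to the other column's L2/3 FS and SI
cells, the projection onto SI cells being 50% stronger than its
intracolumnar counterpart; inside a column, L5 SI cells send slow
"ascending inhibition" to L4 FS cells.

## Cell models

All cells obey current-balance dynamics

    C dV/dt = -I_NaF - I_KDR - I_leak - I_M - I_CaH - I_syn - I_tonic + I_epsc + I_couple

with Hodgkin–Huxley gates `dx/dt = (x_inf(V) - x)/tau_x(V)`. The transient
sodium current is `g_NaF m^3 h (V - E_Na)`, the delayed rectifier
`g_KDR n^4 (V - E_K)`, the muscarinic-sensitive M-current `g_M w (V - E_K)`
(first power; this current carries spike-frequency adaptation and is the
knob through which cholinergic modulation is represented), and the
high-threshold calcium current `g_CaH q^2 (V - E_Ca)` (L5 pyramidal
dendrites only; IB dendrites carry 4 mS/cm² against 1.6 for L5 RS, which is
what makes IB cells burst). Kinetic forms are collected in the named table
`kramer-reduced-v1` (`betacol.kinetics`): reduced-Traub steady-state/tau
forms for excitatory cells, a shifted variant with instantaneous sodium
activation for SI cells, Wang–Buzsáki rates (temperature factor 5,
instantaneous activation) for FS cells, forward/backward rates of the
McCarthy type for the M-current and of the Traub high-threshold type for
CaH. The table can be swapped through the model config.

L5 pyramids have three compartments (axon, soma, apical dendrite) joined by
electrical coupling (axon–soma 3.0, soma–dendrite 1.0 mS/cm²); spikes are
detected on the axon, which is also the presynaptic terminal. All other
classes are single compartments. Every compartment receives a *frozen*
tonic drive: one Gaussian sample per compartment per run, generated with
the Box–Muller transform, with the per-class mean and standard deviation of
the bundled tables. The sign convention is that *negative* tonic drive
depolarizes. Freezing the draw (rather than refreshing it every step)
makes the tonic term a per-cell heterogeneity, which is its stated purpose;
a per-step refresh at dt = 0.01 ms would integrate to essentially nothing.

### Free biophysical parameters

The per-class M-current and CaH conductances, tonic-drive statistics,
external-EPSC conductances, synaptic time constants and conductances, and
the connectivity counts are fixed by the bundled tables. The remaining
"background" biophysics (spike-current densities, leak, reversals,
capacitance, compartment coupling) is not pinned down by those tables and
was fixed once, by single-cell and circuit-level phenotype under the chosen
kinetics, before any of the acceptance quantities was evaluated at network
level:

| parameter | value | phenotype criterion |
|---|---|---|
| g_NaF / g_KDR (exc) | 200 / 20 mS/cm² | regular spiking, stable rest |
| g_NaF (SI) | 100 | stable rest with low rheobase; strong adaptation under g_M = 8 |
| FS cells | Wang–Buzsáki g_Na 35, g_K 9, E_Na 55, E_K −90, C 0.5 µF/cm² | non-adapting fast spiking; transient (EPSP) responsiveness with a modest steady-state shift under the hyperpolarizing tonic bias |
| g_leak | 2.5 (default); 1.25 L2/3 RS (halved); 4.5 L4 E; 1.5 L5 dendrites; 1.0 L2/3+L4 FS, 0.5 L5 FS | L2/3 RS fire sporadically on coincident background EPSCs; L4 E respond to bottom-up volleys but not to single EPSCs; L5 dendrites integrate descending excitation into bursts; FS quiescent at rest |
| E_Na, E_K, E_leak, E_Ca, C | 50, −100, −67 (exc) / −65 (inh), 125 mV, 0.9 µF/cm² | convention of the cited reduced models |

The sentence fixing a "50% reduction" for L2/3 RS cells is applied to the
leak conductance by default; the affected parameter is a config switch
(`defaults.l23_rs_halved_param`), with `g_naf` and `g_kdr` as alternatives.

## Synapses

Each chemical synapse is a kinetic gate driven by the presynaptic voltage
through `drive(V) = 1/(1 + exp(-V/2 mV))`:

    ds/dt = drive(V_pre) (1 - s)/tau_rise - s/tau_decay,
    I = g_max s (V_post - E_rev).

Receptors: AMPA 0.25/1 ms, FS-type GABA 0.5/8 ms, NMDA 5/100 ms, SI-type
GABA 0.5/20 ms, and the slow L5-pyramid→L2/3-SI excitation 2.5/50 ms.
Reversals are 0 mV (excitatory) and −80 mV (GABA). NMDA is a slow linear
conductance by default (no magnesium block; a Mg-block switch exists in the
config but is off). Gates are shared between all contacts of one
presynaptic cell with the same receptor (the gate depends only on the
presynaptic voltage), while each contact keeps its own conductance and
reversal; this is exact, not an approximation.

External inputs are EPSC trains: each arrival adds a conductance transient
of amplitude g_max decaying with tau = 2 ms (superposition of per-arrival
exponentials, matching the Heaviside-sum drive term of the membrane
equation). A saturating "reset" mode — the conductance jumps to g_max and
cannot exceed it — is available per train or globally
(`external_inputs.epsc_mode`); with reset, a single-EPSC-subthreshold cell
can never be recruited by its train, which silences the background-driven
periods, so superposition is the bundled default. Bottom-up (100 Hz, L4 E
and FS) and background (50 Hz, L2/3 RS) trains are independent Poisson
processes per target cell; the top-down train (20 Hz) is one shared
periodic arrival array delivered to every attended-column L5 pyramidal
dendrite. The asynchronous-top-down control replaces it with independent
20 Hz Poisson trains (equal mean drive, no shared timing).

## Network realization

Connectivity is a fixed in-degree per (presynaptic, postsynaptic) class
pair: each postsynaptic cell draws exactly the tabulated number of distinct
presynaptic partners uniformly, excluding itself; a within-class rule
demanding as many partners as the class holds (the L5 SI→SI and FS→FS
entries) connects all-to-all including the cell itself — the only
consistent reading of count = population size. A quarter of the L2/3 FS
and SI cells (5 of 20, chosen per seed) additionally receive NMDA contacts
from 10 L2/3 RS cells (g = 0.04 and 0.03 mS/cm²). The connectivity table
is stored with rows = presynaptic class; the bundled file resolves two
defects of its source: the row listing four L2/3 FS targets carries only
three conductances (the missing L2/3 FS→L4 E value is set to 0.4, the same
as its other pyramidal target), and a typographic "(0,3)" is read as 0.3.

On L5 pyramids, excitatory contacts and SI-type inhibition target the
dendrite, FS-type (perisomatic) inhibition the soma. Realizations are
deterministic per seed; manipulations (removing L2/3 SI cells, deleting
the L5 SI→L4 FS projection, scaling intercolumnar conductances, overriding
FS tonic means, switching to asynchronous top-down) return modified copies
and leave the base network untouched.

## Integration

The full system (compartment voltages and gates, synaptic gates) is
advanced jointly by classical fixed-step RK4 at dt = 0.01 ms. Gate
steady-states and inverse time constants are evaluated by linear
interpolation in tables on a 0.02 mV grid over [−130, 70] mV; the
interpolation error (≲1e-6 in the gate functions) is far below the O(dt⁴)
integration error and removes most transcendental cost. EPSC arrivals are
snapped to the nearest step boundary; within a step the train conductance
decays exactly (stage-wise exponential factors). Gates and synaptic open
fractions are clamped to [0, 1] after each step. Spikes are upward 0 mV
crossings with a 2 ms dead time, linearly interpolated. A voltage outside
±200 mV or a non-finite state aborts the run with the cell, time and
config hash. Populations and compartments are laid out in a fixed
documented order (cell id, then axon/soma/dendrite), so seeded runs are
bit-reproducible.

LFP sources — the summed synaptic currents (including external EPSC
currents) onto each L2/3 RS cell — are computed from the full-resolution
state and stored at 1 ms; voltage traces are optional at 0.1 ms.

## Analysis

* **Firing rate**: spikes / (cells × seconds), per population and column.
* **LFP**: pointwise sum of all synaptic currents onto the 20 L2/3 RS
  cells of a column (for the deep-layer variant, onto the 40 L5 pyramids).
* **STA**: mean of 600 ms LFP segments centred on L2/3 RS spikes (300 ms
  on either side; edge spikes excluded), pooled over realizations.
* **Spectra**: multitaper estimates with time-bandwidth product 3 and 5
  DPSS tapers on the 600 ms windows (config-exposed).
* **SFC**: power spectrum of the STA divided by the mean spike-triggered
  power spectrum (same 600 ms window for numerator and denominator);
  invariant to LFP rescaling; masked where the denominator vanishes.
  Band summaries: gamma 25–70 Hz, low 8–25 Hz, alpha 8–15 Hz, beta
  15–25 Hz (band mean over frequency bins; an optional harmonic-excluded
  variant exists, the raw mean is the default since the ~40 Hz component
  is a 20 Hz harmonic only in the delay condition).
* **Attentional indices**: AI = (att − unatt)/(att + unatt) per
  realization for band-averaged SFC (gamma, low) and the L2/3 RS rate;
  positive when the attended column is stronger; one-sample two-sided
  t-test against 0 across realizations.
* **Pairwise synchrony**: binary 1 ms bins,
  κ(i,j) = Σ X_i X_j / sqrt(Σ X_i · Σ X_j); silent cells excluded from the
  population mean and counted.
* **Population burst events** (deep-layer alpha): 10 ms bins in which at
  least 25% of L5 IB cells spike; runs of consecutive qualifying bins are
  merged into one event; the recurrence frequency is the inverse mean
  inter-event interval over intervals < 300 ms.

## Experiment protocols and problem sizes

Protocols pair the attended (column 0) and unattended (column 1) columns
within each seeded realization; paired conditions reuse the same
realization seeds so all contrasts are within-realization. The reference
protocol set runs 10 realizations of 1 s each (delay: top-down +
background; stimulus: + bottom-up; controls without top-down; the
manipulation battery on top of the stimulus protocol). The test suite
scales this down — 5 realizations for conditions whose assertions require
significance, 3 where non-significance is asserted — as the package's own
choice of problem size; the acceptance script keeps 10 realizations for
the control-alpha quantity.

## What the generator does and does not emulate

All inputs are synthetic by construction (the model is the study object):
stochastic EPSC trains, seeded connectivity and frozen tonic heterogeneity
define the study conditions. The model has no thalamus and no L6, no
synaptic plasticity, two columns only, 20 cells per population, and a
point LFP (summed currents, no volume conduction); passing tests therefore
demonstrate properties of this circuit model, not of cortical recordings.

## Known limitations

* The attentional gamma-band SFC contrast is the model's weakest effect
  and, under the bundled parameters, comes out *negative*: the attended
  column fires more but its extra spikes are less tightly locked to the
  25–70 Hz LFP content, so the rate-normalized coherence favours the
  unattended column even though the attended column's absolute gamma-band
  LFP power is larger. The contrast depends delicately on the unprinted
  FS-cell biophysics (how readily L4 FS cells fire without an L4 E
  volley); parameter variants exist (higher L4 FS leak) in which the
  gamma index is positive but small, at the cost of much weaker low-band
  and rate effects, and the bundled model keeps the variant with robust
  low-band and rate modulation. The delay-period low-band index is
  negative on average but not reliably significant across seeds at the
  tested sample sizes.
* Absolute firing rates are higher than in vivo cortical rates; the model
  reproduces contrasts between conditions, not absolute levels.
* With fixed-step RK4 and grid-snapped arrivals, results are exactly
  reproducible per seed but not invariant to re-ordering of populations.
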