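# Methods

## Overview

`mcbead` implements a two-step Torsades-de-Pointes (TdP) risk classifier
for drug panels characterized by multi-channel patch-clamp assays, together
with the biophysical layer that motivates it: O'Hara–Rudy human ventricular
myocyte simulation, pause-induced early-afterdepolarization (EAD) analysis,
and derived action-potential/calcium biomarkers.

The chain runs: Hill-equation pharmacology → conductance-scaled myocyte
simulation → biomarkers and EAD detection → block-space scans → statistical
classification → 2D risk maps.

## Drug-block pharmacology

Fractional block of a channel at free drug concentration `c` follows the
Hill equation, `block = 100 · cʰ/(IC50ʰ + cʰ)`; drug effect on the myocyte
is a pure conductance scaling `g → (1 − block/100) · g` (no state-dependent
or kinetic binding). The anchor concentration of the whole method is
IC60,hERG — the concentration producing 60% hERG (IKr) block — always
derived from IC50 and the Hill coefficient via the closed-form inverse
`IC50 · (f/(1−f))^(1/h)`, never read from input. The step-1 statistic is
the hERG ratio, IC60,hERG / EFTPC (effective free therapeutic plasma
concentration). Missing channel assays are treated as zero block and
flagged `assumed-zero`; missing Hill coefficients default to 1. All
concentrations are normalized to nM internally (readers accept µM/nM
through a schema file).

When duplicate drugs are merged across panels, per-channel IC50s, Hill
coefficients and EFTPCs are averaged arithmetically on the concentration
scale. Averaging IC50s rather than block fractions is a choice; for
same-order IC50s the two differ little, and it keeps the merged record a
valid assay. Categorical label conflicts resolve to the higher-risk
category with a logged provenance note.

## Myocyte models

The cell models are hand-transcribed implementations of the O'Hara–Rudy
(2011) human ventricular myocyte (41 states; endo/mid/epi parameter sets),
in two variants:

* **OHR** — the original published parameterization;
* **OHRmv** — the Dutta et al. conductance-rescaled variant:
  GKr ×1.119, GKs ×1.648, GK1 ×1.414, GNaL ×2.661, PCa ×1.018.

The LQT3 configuration doubles the late-sodium conductance (`gnal_scale=2`)
before any drug scaling. Drug block maps to the maximal conductances of
IKr, ICaL (ICaV), INaL, fast INa, IKs, IK1 and Ito.

### Integration

Two integrators are provided:

* **Fixed-step forward Euler**, `dt = 0.001 ms` — the gold standard, and
  mandatory for every simulation feeding an EAD decision (an adaptive
  scheme demonstrably changes EAD outcomes near threshold). To make 10⁸
  steps per protocol affordable, all voltage-dependent rate expressions are
  tabulated on a 0.01 mV grid over [−120, 80] mV with linear interpolation,
  the standard device of production cardiac simulators; the table
  reproduces the exact expressions to ~5·10⁻⁷ relative (tested), and
  halving `dt` moves APD90 by < 0.5 ms and never changes an EAD call in
  the acceptance scenarios.
* **Hybrid rapid integrator** — Rush–Larsen exponential updates for the
  Hodgkin–Huxley gates plus a three-level adaptive Euler step for the
  remaining states (0.001 ms during stimulus/upstroke, 0.002 ms while
  |dV/dt| > 0.2 mV/ms or subspace Ca exceeds 0.25 µM — SR release is
  explosively sensitive to junctional SR load, and larger steps there
  destabilize heavily loaded cells — 0.02 ms in diastole). It tracks the
  Euler reference to ≲ 0.5 ms in APD90 and a few percent in Ca-transient
  amplitude over 200-beat trains and is used only for plain steady-state
  runs (pre-pacing, the derived-feature pipeline), never for EAD calls.

The stimulus is −80 µA/µF for 0.5 ms (the published model's default),
configurable. Traces are recorded at 0.1 ms; biomarkers are insensitive to
resampling from 0.001 to 0.1 ms within 1%/1 ms (tested).

### Protocols

* `pace_to_steady` — fixed-count pacing (default 1000 beats) at a constant
  cycle length, returning the final beat. Steady state is fixed-count, not
  convergence-detected.
* `pause_protocol` — the short–long EAD protocol: `n_stimuli` beats
  (default 200) at a 500 ms cycle length, then one further stimulus after
  a quiescent pause. Two pause conventions are supported:
  `pause_reference="stimulus"` treats the pause as the S1–S2 interval from
  the last train stimulus (the classic convention; used for all EAD work
  here), while `"cycle"` treats it as extra quiescence beyond the regular
  slot (so `pause=0` degenerates to constant pacing).

EAD studies initialize the train from the **drug-free model's 1 Hz steady
state** (1000 beats at CL 1000 ms, hybrid integrator, memoized per
variant/cell/configuration), then apply the drug for the 200-stimulus
train. This emulates acute drug exposure of a cell in its normal working
rhythm and matters quantitatively: intracellular Na⁺ (hence repolarizing
Na/K-pump current) keeps accumulating for many hundreds of beats, and the
EAD block threshold moves by several percentage points between a cold start
and a steady-state start. The published approximate initial conditions
remain available (`initialize="published"`).

## Biomarkers and EAD detection

Thirteen per-beat metrics: upstroke velocity (max dV/dt of the primary
upstroke), peak voltage, APD50/APD90, duration above −60 mV, resting
(pre-stimulus diastolic) voltage, AP triangulation (APD90 − APD30),
diastolic/peak intracellular Ca, Ca-transient amplitude, CaTD50/CaTD90 and
CaT triangulation (CaTD90 − CaTD30). APDx uses the per-beat peak and
pre-stimulus diastolic value as references (robust to slow drift), linear
interpolation at level crossings, and — for beats with
afterdepolarization re-crossings — the final decay crossing. "Duration
above −60 mV" is implemented literally as time spent above −60 mV; the
metric's name does not pin down a unique rule and this reading is the
simplest. A beat whose peak rises less than 10 mV above the diastolic
value is flagged "no capture" and its metrics are undefined.

The EAD criterion is operational and configurable (`EADConfig`): after the
primary upstroke has ended, a positive dV/dt exceeding 0.01 mV/ms sustained
for ≥ 1 ms, taking off from a membrane potential between −60 mV and
−10 mV. The takeoff ceiling excludes the normal early-plateau rise
(phase-1 notch recovery and slow dome drift driven by late Na⁺ current),
which is not an afterdepolarization; genuine pause-induced EADs in these
models take off during late phase 2/phase 3, between roughly −40 and
−15 mV, with secondary upstrokes of tens of mV, so the calls are
insensitive to the exact numeric values.

## EAD block-space scans

At fixed hERG block (60% by default), the pause protocol is run over the
(ICaV, INaL, IKs) block grid — 0–100% inclusive at 10% steps, 11³ = 1331
points (a 25%-step smoke grid ships for quick runs). The EAD+/EAD−
boundary along the ICaV axis is the midpoint between the last EAD+ and
first EAD− level, per (INaL, IKs) column; non-monotone columns are flagged
and never silently ignored. Drug-level EAD classification first applies
the hERG-ratio gate, then either interpolates the scanned surface or
directly simulates the drug's full block profile at IC60,hERG (the
authoritative mode). Threshold searches over a single axis
(`minimal_herg_block_for_ead`, `max_channel_block_with_ead`) use bisection
followed by a verification walk: the EAD onset is *fringed* — narrow
EAD-free notches from beat-pattern bifurcations sit just above the onset
(e.g. OHR at the 700 ms pause EADs at 56–61% hERG block, not at 62%, and
again from 63%) — so the search descends (or, for the sweeps, ascends)
from the bisection candidate until two consecutive EAD-free levels
confirm the boundary. The end-of-train state is memoized per block
combination (it does not depend on the pause), so probing several pauses
or walking the fringe reuses the expensive 200-beat train; the cached path
is numerically identical to a cold run.

## Classifier

Step 1 gates on the hERG ratio: drugs at/above the selected threshold
(candidates 50, 100, 150, 200) are called TdP−. Step 2 is a logistic
regression on features evaluated at IC60,hERG — so it is independent of
EFTPC — fitted by maximum likelihood with a very weak ridge penalty
(1e−6 relative, i.e. `C = 1e6`) to stabilize separable data. The gate with
the best overall training accuracy wins (gated drugs count as TdP−
predictions; ties go to the smallest gate). Drugs without an EFTPC bypass
the gate into step 2 with a warning; the probability cutoff is 0.5.
Leave-one-out cross validation refits everything per fold, including gate
re-selection (selection outside the loop would leak the held-out drug).
The one-step baseline is the same logistic model on features at EFTPC with
no gate.

The ternary extension for three-tier (CiPA-style) categories scores each
drug by an equal-weight feature sum (% ICaV block + % INaL block + the
drug-trapping scalar, missing entries zero) with two fitted y-thresholds
(−β₀/β_f from "high vs rest" and "high+intermediate vs low" fits) and two
fixed hERG-ratio cuts (25 and 150, configurable).

## Risk maps

The step-2 hyperplane is normalized to the ICaV coefficient, so the y axis
reads `block_ICaV + (β_INaL/β_ICaV)·block_INaL + …` with threshold
−β₀/β_ICaV, and the x axis is the hERG ratio (log scale). Region
classification is algebraically identical to the generating model's
predictions — a tested invariant, which also fixes the sign convention
(the risky side is below the y threshold exactly when the ICaV coefficient
is negative, i.e. ICaV block is protective). The coordinates table is the
canonical artifact; the rendered figure is not unit-tested.

## Derived-feature pipeline

Each drug is simulated in 3 cell types × 3 pacing rates (0.5/1/2 Hz) at one
of the two concentration rules, with a content-addressed cache keyed on the
exact simulation inputs so reruns are incremental. Per (feature, cell,
rate) cell, a single-feature classifier is evaluated by LOO: two-step
gating at the IC60 rule, plain logistic at the EFTPC rule. Steady-state
runs use the hybrid integrator; EAD flags always come from fixed-step Euler
via the block-space machinery.

## Synthetic panels

The fixture generator draws hERG IC50 log-uniformly over 10 nM–100 µM,
the hERG ratio log-uniformly over 1–10⁴ (EFTPC back-derived), and the ICaV
block at IC60,hERG uniformly over (0, 100) (ICaV IC50 back-solved), with a
known generative rule: TdP+ iff ratio < threshold and ICaV block < cutoff.
A small exclusion margin (4% of a decade on the ratio axis, 4 percentage
points on the block axis) keeps noise-free panels separable under
leave-one-out resampling; real panels do not place compounds adversarially
on a cutoff. Labels are encoded as CredibleMeds CM1/CM3 plus a matching
label-warning flag. What passing tests on these panels demonstrate is that
the estimator recovers a rule of exactly the model's functional form;
they say nothing about label noise, assay variability between datasets, or
risk mechanisms outside the (ratio, ICaV) plane, which is where real-data
accuracy is lost.

## Problem sizes and reproduced quantities

The acceptance script (`scripts/acceptance.py`) recomputes the EAD block
thresholds end to end: integer-percent bisection over hERG block for the
pause-EAD thresholds in OHR/OHRmv at 700 and 1000 ms pauses, and 10%-grid
sweeps for the largest ICaV/INaL block still producing EADs at fixed hERG
block, including the LQT3 configuration. Each bisection is 5–8 pause
simulations of ~101 s simulated time at dt = 0.001 ms; the full script is
roughly 45 simulations. With the lookup-table Euler core this runs in
about 15 minutes on one CPU. The test suite runs the same protocols for
the acceptance criteria and shortened trains (5–30 stimuli) for structural
tests.

Under the adopted protocol the reproduced thresholds are: OHR 56%/48% and
OHRmv 55%/42% at 700/1000 ms pauses; ICaV suppression boundaries of 20%
(OHR) and 30% (OHRmv) at 60% hERG block; INaL suppression above 50%
(OHRmv); and, in the LQT3 configuration, EADs from 20% hERG block on the
10% grid with ICaV and INaL suppression above 20%. These are computed, not
quoted; the test suite asserts the corresponding scientific claims at the
tolerances stated there.

## Known limitations

* The conductance-block drug model ignores state-dependent and kinetic
  binding; the only trapping information used is the scalar classifier
  feature.
* The EAD protocol's initialization and pause convention are not uniquely
  determined by the method's usual description in the literature; both are
  configurable, and the defaults documented above are the package's choice.
* Single-cell only: no tissue-level propagation, no transmural-dispersion
  metrics.
* The pause-EAD thresholds are sensitive at the 2–4 percentage-point level
  to initialization provenance and solver details; comparisons across
  implementations should expect differences of that order.
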