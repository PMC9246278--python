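# Methods

## Model scope and assumptions

The package implements a deterministic, single-cell ODE model of the
budding-yeast cell cycle as a free-running relaxation oscillator.  State
variables are particle numbers (molecules per cell); time is minutes.  The
model deliberately simplifies where the surrounding physiology is out of
scope:

* cyclin paralog pairs are lumped (Cln1/2, Clb5/6, Clb3/4, Clb1/2 are one
  species each, standing for their Cdc28 complexes; Cdc28 itself is not a
  state variable);
* DNA replication and the replication checkpoint are absent — the length of
  S phase is produced by a cyclin cascade timer (Clb5 drives Clb3
  accumulation, Clb3 switches on Mcm1 and thereby Clb2);
* *CLB2* expression is driven directly by Mcm1 (no Fkh2/Ndd1 cofactors),
  with Clb2 feeding back on Mcm1 activation;
* APC is a single active/inactive pair (no Cdc20/Cdh1 distinction); Mcm1
  activation of APC stands for Mcm1-driven *CDC20* expression, and a
  Cdc14-driven activation leg stands for Cdh1 dephosphorylation;
* Cdc14 release is triggered by Clb2-phosphorylated Net1 and amplified by a
  self-activation term that abstracts the mitotic exit network;
* the MAPK cascades themselves are not modelled: Fus3 and Hog1 activity are
  binary inputs switched at scheduled clock times, and nutrition is a
  constant scalar multiplying all production rate constants;
* the pheromone interface induces Far1 transcription directly (no Ste12
  intermediate); Hog1 blocks Swe1 phosphorylation directly (no Hsl1/Hsl7);
* Cln3 synthesis is constitutive (nutrition-scaled).

## State space and conservation pools

33 species: five cyclin forms plus Swe1-phosphorylated Clb2; Sic1 in seven
forms (free, CDK-phosphorylated, Hog1-phosphorylated, and four
cyclin-bound complexes, two of which carry the Hog1 mark); the Whi5/SBF
module (Whi5, Whi5_p, SBF, SBF_Whi5, SBF_p); MBF (inactive/active); active
Mcm1, APC and Swi5 (their inactive complements are parameter totals
`Mcm1_tot`, `APC_tot`, `Swi5_tot`); Net1/Net1_p; Cdc14/Cdc14_p; Swe1/Swe1_p;
Far1/Far1_p and the Far1_p–Cln complexes.

Five pools are conserved by construction — SBF, Whi5, MBF, Cdc14, Net1 —
because every rate law moves their members one-for-one.  SBF_Whi5 belongs
to both the SBF and Whi5 pools.  Pool totals are set by the initial state;
changing a pool total (e.g. total SBF) moves the system to a different
attractor, which is itself a tested property.

## Kinetic forms

* synthesis and degradation: mass action, first order in the template
  (transcription factor) or the substrate;
* stoichiometric inhibitor binding (Sic1–Clb, Far1_p–Cln): reversible mass
  action, with complex destruction through degradation of either moiety —
  the CDK-triggered route destroys the Sic1 moiety and frees the cyclin,
  the APC route destroys the cyclin moiety and frees the inhibitor;
* covalent modification cycles (Whi5, SBF, Sic1, Swe1/Clb2, Net1, Cdc14):
  Michaelis–Menten in the substrate, linear in the converting enzyme;
  small Michaelis constants relative to the pools give the zero-order
  ultrasensitivity the transitions need;
* transcription-factor activation (MBF by Cln2; Mcm1 by Clb3/Clb2; APC by
  Mcm1 and Cdc14; Swi5 by Cdc14): Hill functions with exponent 2 and
  threshold constants, so the switches flip sharply at defined activator
  levels.

The Hog1 downregulation of *CLN1/2* and *CLB5/6* acts directly on the
expression rates (divisive factors `1 + kh * HOG1`); the Hog1-stabilised
Sic1 phosphoform (and its Clb5 complex) is exempt from CDK-triggered
destruction but still binds and inhibits Clb5.

## Calibration

The parameter values in `data/parameters.csv` are this package's own
calibration, produced by iterative adjustment until
(1) the system shows stable limit-cycle oscillation, (2) the reference
cycle duration and phase proportions are realistic (117 min, G1-heavy),
(3) time-averaged particle numbers sit at whole-cell measurement scale,
and (4) the pheromone, osmostress and nutrition programs behave as
published.  The bundled abundance table
(`data/synthetic_abundance_reference.csv`) is a synthetic stand-in with
literature-scale round numbers; the validation machinery (time averaging,
relative deviation, 60 % margin) is independent of its specific values and
is additionally tested in self-comparison mode, where deviations are zero.

Two calibration-driven design points deserve record:

* **APC latching.**  With APC activation driven by Mcm1 alone the system
  stalls in mid-mitosis for part of parameter space (APC equilibrates at
  intermediate activity and Clb2 production balances destruction).  The
  Cdc14-driven activation leg (the Cdh1 abstraction) latches APC once
  Cdc14 is released and makes mitotic exit robust, including under
  nutrition scaling up to factor 1.7.
* **Phase-duration anatomy.**  G1 length is dominated by the decay of the
  mitotic-exit machinery plus the Cln3-driven Whi5 phosphorylation clock;
  S/G2 length by the Clb3 accumulation timer and the Swe1 "wall" that
  converts early Clb2 into its inactive phosphoform; M length by APC/Cdc14
  kinetics.  The nutrition response arises almost entirely from the S/G2
  timer (production-limited), which reproduces the near-linear duration
  response across factors 0.7–1.7.

## Phase markers

All thresholds are relative (half of the per-cycle extremum), so runs with
different amplitudes — nutrition-scaled runs in particular — annotate
identically, and multiplying all species by a constant leaves event times
unchanged.  Cycles are anchored on Clb2_total peaks.

* **START**: free SBF above half its per-cycle maximum while nuclear Whi5
  (Whi5 + SBF_Whi5) is below half its per-cycle maximum, with the pair of
  conditions required to hold continuously until S entry.  The persistence
  requirement encodes commitment: a transient partial Whi5 exclusion that
  re-binds SBF (as happens when a pheromone brake engages just before
  commitment) is not a START.
* **G1/S**: upward crossing of Clb5_total through half its per-cycle
  maximum.  Total (not active) Clb5 is used.
* **G2/M**: upward crossing of Clb2_total through half its per-cycle
  maximum.
* **M exit**: downward crossing of *active* Clb2 through half its
  per-cycle maximum after the G2/M peak.  The M→G1 boundary has no
  canonical marker; the activity-based convention captures both
  APC/Cdc14/Sic1-driven destruction and Swe1-driven inactivation — the
  route by which osmotic stress in M produces early mitotic exit.
  Crossing times are linearly interpolated between grid points.

## Numerical choices

* Stiff-capable LSODA with rtol 1e-8 / atol 1e-10 as defaults (exposed in
  the run configuration); analysis-scale runs (experiments, scans) use
  rtol 1e-6 / atol 1e-8, at which the categorical verdicts and durations
  are insensitive (tolerance-halving changes endpoint states by < 1e-4
  relative).
* Signals switch at known clock times, so integration restarts at every
  switch instead of event root-finding; every switch time is an exact grid
  point.  Intervals are half-open `[t_on, t_off)`.
* Output grid 0.5 min by default, well below all transition time scales.
* Negative states are rejected, never clamped; the tight tolerances keep
  trajectories nonnegative to integrator accuracy (> -1e-6 molecules over
  ten cycles in the shipped tests).
* The default steady-state protocol discards the first 3 completed cycles
  and measures at least 10 where the horizon allows; the bundled initial
  state lies on the reference limit cycle (frozen at a START event), so
  adaptation is mild.
* "Stable cycling" is operationalized as ≥3 successive Clb2_total peaks
  with amplitudes within 20 % and inter-peak intervals within 10 %;
  peak detection uses a prominence of 5 % of the signal range.
* Orbit convergence is measured as the symmetric mean nearest-point
  distance between successive loops in a 2-D projection; on the attractor
  this sequence sits at a small sampling-resolution floor.
* Problem sizes: the reference run covers 1800 min (≈15 cycles), the
  nutrition scan 6 factors x ≈15 cycles, the robustness scan 222 runs of
  1200–1500 min each.

## Experiment conventions

Signals are applied from the midpoint of the targeted phase of an embedded
control run (configurable via `onset_offset`).  Synchronization after
pheromone release is the spread (max − min) of the first post-release START
times across the four phase-targeted runs, aligned to the release time;
the default acceptance tolerance is 10 min.  The late-G1 stress delay
equals or exceeds the stress duration when the onset falls late in the
phase (commitment nearly reached); at the midpoint some pre-stress
progress is retained and the delay is correspondingly shorter, though S
entry is always pushed beyond the stress window.

## What the tests do and do not show

The test suite exercises the model's own dynamics and the analysis
machinery on those dynamics.  Passing tests demonstrate internal
consistency (conservation, determinism, convergence), the published
categorical behaviours, and duration quantities within stated bands.  They
do not demonstrate agreement with wet-lab measurements beyond the
order-of-magnitude abundance comparison, and the bundled abundance table
is a synthetic stand-in, not a measurement.  Single-cell stochasticity,
cell growth and volume, population heterogeneity, and the upstream MAPK
cascades are outside the model; conclusions about those layers cannot be
drawn from these simulations.

## Known limitations

* The reference duration (117.2 min) sits ~4 % below the 122-minute
  nominal duration; the nutrition endpoints (141.6 / 99.6 min) sit within
  5 % of the 138 / 96-minute targets.  The three constraints trade off
  against each other through the S/G2 timer and were balanced inside the
  ±5 % bands rather than individually centred.
* Early-M osmostress (first ~20 % of M) delays rather than advances exit;
  the early-exit behaviour appears from mid-M onward and its magnitude is
  modest (≈0.4 min at the midpoint), limited by the constitutive Swe1
  synthesis rate.
* Swe1 accumulates during G1 osmostress without consequence (Clb2 is
  absent in G1); this mirrors the model's unregulated Swe1 expression, not
  known biology.
* The SBML layer covers the L3V2 core subset the model uses; documents
  with rules, events, or function definitions are rejected explicitly.
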