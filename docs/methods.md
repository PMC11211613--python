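# Methods

This note documents the model the package implements, the parameter choices
behind it, what the assessment does and does not establish, and the known
limitations. It states no number that the test suite or
`scripts/acceptance.py` does not itself compute.

## The neural mass unit

Every population pathway is a second-order critically damped synaptic
kernel, `h(t) = G·ω·t·e^{−ωt}`, integrated as a pair of first-order state
equations with a fixed-step Euler scheme (position update first, velocity
update on the new position — slightly more stable for the fast kernels).
The default step is `dt = 1e-4 s`; halving it changes a unit's dominant
frequency by well under 2% (tested). Population firing is
`z = 5 / (1 + exp(0.56·(6 − v)))` spikes/s, clamped to [0, 5].

Each Unit has four populations — pyramidal (p), excitatory interneurons
(e), slow GABA (s), fast GABA (f) — and six kernels: one glutamatergic per
p and e output, slow GABA for s, fast GABA for f, and two input kernels
carrying the external/long-range drives onto p and f. Internal couplings
`C_ij` (post, pre) select the regime:

| preset | key couplings | behavior |
|---|---|---|
| gamma | `C_pe=120, C_ep=140, C_pf=350, C_fp=140`, bias −5 mV | silent at rest; graded ~38–40 Hz limit cycle above ~450 spikes/s of drive, full-amplitude above ~600 |
| theta | `C_ps=150, C_sp=15`, slowed glu/slow kernels (ω=89.6, 22.4 s⁻¹), drive 550 | autonomous 4.00 Hz relaxation oscillation, on-phase fraction ≈ 0.44 |
| wm | gamma couplings with `C_pe=C_ep=0, C_pf=100, C_pp=200`, bias 0 | bistable: 50 ms strong cue latches persistent firing; reset = zeroing the self-loop kernel state |

L1 units additionally carry a slow-GABA adaptation loop
(`C_ps=30, C_sp=60`) that fatigues an episode after its burst, and L2 units
read L1 through a fast input kernel (ω = 300 s⁻¹) so the brief gamma bursts
pass without attenuation.

**Provenance of the constants.** The model's architecture, rate ceiling
(5 spikes/s), training schedule, detection threshold (3.5) and assessment
protocol are fixed by its reference formulation; the numerical tables of
unit and learning constants are not part of that formulation's openly
available text. All constants above were therefore calibrated once,
against the model's canonical operating points: a
~40 Hz isolated gamma unit, a 4 Hz pacemaker whose on-phase holds a
five-episode replay, ~35 Hz effective replay rhythm, a silent untrained
network (nothing crosses the 3.5 spikes/s detection threshold without
training), and the reference weight structure. They are the package's own
parameterization of the model, not a transcription.

## Wiring and gating

Fixed wiring: diagonal WM→L1 (gain 100) and L1→L2 (gain 185) feedforward,
and a uniform theta→L1 disinhibition (gain 88). Two gating choices matter:

* **Theta enters L1 through a fast pathway** — a single 5 ms low-pass onto
  the pyramidal potential rather than the full glutamatergic kernel. The
  kernel's ~20 ms decay tail would let the replay chain keep running well
  into the theta off-phase, erasing the cycle-truncation effect that makes
  the last episodes frequency-sensitive; the 5 ms stage keeps the off-edge
  sharp while avoiding an onset overshoot of the whole layer.
* **The desynchronizing synapses `A_f` transmit the supra-threshold part of
  the pre-synaptic discharge** (`clip(z − 3.5, 0)`, algebraic, no kernel).
  They connect every stored feature to every other stored episode's
  features (~65 pre-synapses per Unit); transmitting the raw rate would
  couple the sub-threshold background of the whole layer into every fast
  interneuron as a static inhibition floor that no cue can overcome. With
  the threshold they convey exactly what they are for: the episode bursts.

## Learning

Glutamatergic kinds (`W_p^{L1L1}`, `W_f^{L1L1}`, `W_p^{L1L2}`) use a
thresholded-correlation Hebb rule,
`ΔW_ij = η·dt·[z_post,i − 3]₊·[z_pre,j − 3]₊`, clipped to a per-synapse
saturation. The desynchronizing kind grows on anti-correlation with the
orientation *silent post, firing pre*:
`ΔA_ij = η·dt·[1 − z_post,i]₊·[z_pre,j − 3]₊`. This orientation is what
the reference weight structure requires: a feature shared by two episodes
is active whenever either of its homes is presented, so it never
accumulates desynchronizing input from either partner set — with the
opposite orientation it would, and the shared feature would be suppressed
by its own episode at retrieval.

Per-Unit normalization caps the summed incoming weight of each kind
(`W_p`: 160, `W_f`: 15, `A_f`: 100, `W_p^{L1L2}`: 105) and is enforced at
the end of every 250 ms presentation. Enforcing it every integration step
instead lets the most recently presented episode pump its synapses while
the standing rescale bleeds the earlier ones to zero — on shared rows the
last-trained home then owns the entire cap. Per-presentation enforcement
rescales, never erases: after training, a feature shared by two episodes
holds incoming weights at roughly half the strength of an unshared feature
(asserted in the tests), and richer episodes hold weaker per-synapse
weights than poorer ones. Each presentation starts from the resting network
state so the ~25 ms decay tail of one episode pair cannot write spurious
skip-links into the succession matrix.

Training drives the presented features' pyramidal and fast-inhibitory
populations at 1800 and 50 spikes/s — strong enough to hold the driven
units at the rate ceiling so the correlations are clean and the final
weights are set by saturation and normalization alone.

## Assessment

Cycles are delimited on the pacemaker's own noise-free trace (upward
crossings of 50% of its range); cycles not fully inside the simulated
window are dropped. An episode is recovered in a cycle if all of its L2
features simultaneously exceed 3.5 spikes/s for at least one integration
step; episode *k* additionally requires its first crossing to come after
that of every *detected* earlier episode (ties fail). Episodes are scored
individually — a missed first episode does not forfeit the later ones,
which is why the first position scores below the middle ones (the cued
feature leads its partners, and their overlap sometimes misses the strict
simultaneity requirement). The standard protocol is 10 runs × 1.0 s per
sequence with distinct noise streams, cue at t = 0.05 s.

Noise: zero-mean Gaussian terms (per-step SD 120 at the default dt, scaled
as `1/√(dt/dt₀)`) on every cortical Unit's two input pathways; the
isolation modes add uniform positive drive to L1 (imagination U(0, 260),
dreaming-class modes U(0, 390)), calibrated once so that imagination
spontaneously replays stored sequences while retrieval mode never ignites
spontaneously.

Frequency manipulations rescale kernel time constants with gains scaled
alongside (`G/ω` invariant), which for the autonomous pacemaker is an exact
time rescaling: factor 1.5 → 2.67 Hz, 0.8 → 5 Hz, 2/3 → 6 Hz. The
fast-gamma condition multiplies the L1/L2 fast-GABA time constants by 0.72,
raising the isolated unit's rhythm to ≈ 45 Hz.

## What the synthetic material does and does not show

The canonical sequence sets are the study conditions: three sequences of
five episodes (sizes 4–6), either fully orthogonal (tiling all 75 features)
or with five shared feature-slots in the canonical pattern (episodes 2/14
sharing two features, 3/7, 3/12 and 9/13 one each; a variant with the 9/14
reading is provided because the two source descriptions disagree). Passing
tests on this material show that the *mechanism* — pattern completion,
gamma-cycle succession, theta gating, recombination at shared features —
works as described; they do not show capacity scaling, robustness to
biologically realistic feature statistics, or anything about episodes far
richer or more numerous than the study conditions.

## Numerical and degenerate-input choices

Initial state is zero everywhere; assessments ignore the partial cycle
before the cue. A constant pacemaker trace (no-theta mode) yields zero
cycles and a flag rather than an error. The no-theta mode replaces the
oscillating drive with the on-phase plateau held constant — sustained
disinhibition — because replacing it with the temporal mean leaves the
whole layer sub-threshold and nothing is ever recalled; with the plateau
the isolated network produces the continuous, boundary-free recombinations
that the non-theta sleep state is described to show. Mode transforms always
operate on a copy of the pristine trained weights and are never composed.

## Known limitations

* The non-orthogonal basal table is reproduced at the episode-4 position
  (the headline of that condition) but undershoots the reference row at
  episodes 2 and 5: episodes containing two shared features fail the strict
  simultaneity criterion more often here than the reference values imply, and a
  missed episode weakens the succession pulse for its follower.
* The fast-gamma condition reproduces the reference episode-4 rescue at
  theta 5 Hz, but not the episode-5 lift at basal theta: with the shorter
  bursts the sequence restarts earlier within the on-phase and interferes
  with the fifth episode's slot instead of profiting from the extra gamma
  cycles. This is the one headline quantity this reconstruction does not
  reach (see `scripts/acceptance.py` output).
* Working-memory reset is modeled as zeroing the self-excitation kernel
  state at cue onset; the trigger is the arrival of a new cue event, not a
  comparison of maintained versus incoming content.
* Replay timing (first-episode latency ≈ 20 ms, inter-episode spacing
  ≈ 17 ms) sits at the fast end of the nominal ~35 Hz replay; the
  theta-frequency collapse pattern is reproduced through the on-phase
  geometry rather than through an exact match of the replay period.
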