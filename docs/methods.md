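# Methods

## Scope and model structure

`mouseap` simulates single mouse ventricular myocytes in which the four
voltage-gated K⁺ currents that shape murine repolarization — the fast and
slow transient outward currents I_Ktof (Kv4.x) and I_Ktos (Kv1.4), the
ultra-rapid delayed rectifier I_Kur (Kv1.5), and the slow delayed rectifier
I_Ks (KCNQ1/KCNE1) — are continuous-time Markov chains, and in which two
idealized I_Ktof-specific blockers act by state-dependent binding. The rest
of the cell (fast Na⁺ current, L-type Ca²⁺ current, rapid delayed rectifier,
inward rectifier, background and pump/exchanger currents, and the
Ca²⁺-handling subsystem with subspace, SR compartments, RyR gating and
troponin/calmodulin/calsequestrin buffering) is the Bondarenko et al. (2004)
mouse model, which serves as substrate, not contribution. Tissue-level
propagation, temperature scaling, and refits of rate constants to raw
experimental traces are out of scope.

The membrane equation is dV/dt = −(ΣI_ion + I_stim) with every current a
density in pA/pF, so capacitance never appears explicitly. The stimulus
(default 0.5 ms, 60 pA/pF, depolarizing) is carried as a K⁺ flux in the
intracellular K⁺ balance so that long pacing runs conserve charge.

## Markov schemes

Each channel is a generator matrix Q(V, [D]) acting on a column occupancy
vector, dp/dt = Q p, columns summing to zero. All occupancies are
integrated (no state is eliminated by the conservation identity for the
four K⁺ schemes); conservation is asserted, never silently repaired. This
keeps the schemes extensible — the drug-bound states are appended without
touching the base states.

* **I_Ktof** — C1⇌C2⇌C3⇌O (the Hodgkin–Huxley a³ activation gate of the
  substrate model expanded into a three-closed-state ladder with 3α/2α/α
  forward and β/2β/3β backward rates), plus open-state inactivation
  O⇌I1⇌I2 and a closed-state inactivation path C3⇌I1. The closed-state
  path is deliberately faster inward than its reverse (no microscopic
  reversibility on that loop): that is what produces the negatively
  shifted steady-state availability midpoint (≈ −45 mV) characteristic of
  Kv4 channels, while recovery at −80 mV keeps a ~40 ms fast component
  plus a slower component carried by I2 that drives short-coupling-interval
  restitution.
* **I_Ktos** — four closed states, one open state, an N-type inactivated
  state IN, a coupled state INC reached from IN, and a C-type chain
  IC1⇌IC2 from O. All inactivation rates are voltage-insensitive, so the
  decay rate saturates at positive potentials; recovery is seconds-scale
  (Kv1.4 phenotype). Its conductance is zero except in the septal variant.
* **I_Kur** — four closed states, one open, one inactivated. The O⇌I rates
  are the algebraic decomposition of the substrate's inactivation steady
  state and time constant (k_OI = (1−i_∞)/τ, k_IO = i_∞/τ) plus a residual
  recovery rate (1.7×10⁻⁴ ms⁻¹) that leaves inactivation incomplete at
  depolarized potentials, as observed for cloned Kv1.5.
* **I_Ks** — the Silva–Rudy two-step voltage-sensor zipper: 15 closed
  states indexed by how many of four subunits have completed each sensor
  transition, then C→O1⇌O2 with two conducting states. Open probability is
  the sum over O1 and O2.

Activation-ladder rates come from the published substrate gate rates; where
a single gate feeds a four-step ladder the per-subunit midpoint is shifted
so the ladder's open-probability midpoint matches (documented per constant
in `src/mouseap/params/*.yaml`; every constant carries a provenance tag,
see `params/PROVENANCE.md`). Inactivation and drug constants were fixed
once against channel-level phenotype targets and never revisited.

## Drug binding

Both blockers are strictly non-conducting when bound, bind competitively,
and associate at kon·[D] with dose-independent dissociation.

* **Closed-state blocker ("drug C", 4-AP-like).** Binds C1–C3, adding
  B1–B3; the bound ladder interconverts with the same activation rates as
  the closed ladder. Resting affinity Kd = koff/kon = 2.5 mM; unbinding
  from the resting bound states is slow (koff = 2×10⁻⁴ ms⁻¹, multi-second
  equilibration) but fast from the activated bound state B3
  (10⁻² ms⁻¹) — block is relieved on depolarization. The slow resting leg
  makes block accumulate only when diastole is long (reverse use
  dependence); the fast B3 leg releases blocked channels during a long
  depolarizing step, so the late current is spared and the current area is
  reduced far less than the peak.
* **Open-state blocker ("drug O", quinidine-like).** Binds O, adding BO,
  with kon = 4 mM⁻¹ms⁻¹ and koff = 2×10⁻³ ms⁻¹. Because dissociation is
  slow on the 500 ms pulse scale, the area-reduction half-max dose is
  kinetic — the dose at which kon·[D] matches the open-state inactivation
  rate — and sits at ~10 µM, far above the equilibrium Kd. Block builds
  during each action potential and dissipates over ~0.5 s of rest, so at
  short cycle lengths block accumulates (use dependence).

At zero concentration both augmented schemes reduce exactly to the
unblocked scheme; the bound states are integrated regardless, which makes
drug-free and zero-dose builds bit-comparable.

## Cell variants

The epicardial variant uses the substrate model's apex conductances
(G_Ktof = 0.4067 mS/µF, G_Kur = 0.160, G_Kss = 0.050). The endocardial
variant differs only in I_Ktof, I_Kur and I_Kss (G = 0.200, 0.120,
0.045 mS/µF); no printed table for these was available, so they were fixed
once so the endocardial control action potential at 1 Hz lands on
APD75 ≈ 18–19 ms and APD90 ≈ 29–30 ms and are tagged `calibrated-apd-anchor`
in the parameter files. The septal variant (the only one with I_Ktos > 0)
is provided for clamp work, not AP simulation. One substrate adjustment
was required: the Na⁺ channel's open↔fast-inactivated reverse rate is
scaled by 0.1 to bound the Na⁺ window current in the −40…−10 mV range,
where the mouse late repolarization sits; without it the plateau fails to
repolarize.

## Numerics

The whole-cell system (75 states) is integrated with an adaptive embedded
Dormand–Prince 4(5) pair, mixed error control (atol 10⁻⁸, rtol 10⁻⁶,
per-state scaling), FSAL reuse, and a 1 ms cap on the step size. Fixed-step
convergence order is asserted ≈ 4–5 by test, and APD90 moves by <0.1% under
a 10× tolerance refinement. Clamp protocols disable the membrane equation
and propagate the channel generator exactly by matrix exponentials between
output samples (piecewise-constant command voltage; ideal clamp, no series
resistance). Stationary occupancies come from an augmented least-squares
nullspace solve and are cross-checked against long-time forward integration
by an independent ODE solver.

Output traces are sampled on a dense 0.05 ms grid through the upstroke
window and 0.5 ms elsewhere. APDx is measured from the time of (dV/dt)max
(searched within 10 ms of the stimulus to avoid artifacts) to x%
repolarization of the excursion from the per-beat pre-stimulus diastolic
potential to the peak, with linear interpolation at the crossing and
first-crossing-after-peak tie-breaking. The per-beat diastolic baseline
matters at fast rates, where diastolic potential is elevated.

Steady pacing runs up to 1000 beats by default but stops early when no
state changes by more than 0.01% between beat onsets (the bulk Na⁺/K⁺
drift, which is orders of magnitude slower than electrical accommodation,
is excluded from the criterion, and near-zero occupancies are floored at
10⁻² scale). Tests and the acceptance script use 30–120 pre-pacing beats
(more at fast rates, where rate-dependent accumulation has a long memory)
and carry the convergence flag; dose–response half-max doses are located by
monotone log-dose interpolation with optional bisection refinement to ±1%,
cross-checked against Boltzmann (log-logistic) fits.

## What the checks do and do not show

The channel-level anchors (80%/\<20% peak/area dissociation of the
closed-state blocker at 10 mM, the 10 µM kinetic area-IC50 and near-total
flow block of the open-state blocker) are calibration targets realized by
construction, so the tests on them verify the mechanism wiring, not an
independent prediction. The emergent results — the V-shaped APD–BCL
relation turning near 200 ms, the transmural APD gradient, reverse use
dependence of closed-state block vs use dependence of open-state block,
the negative initial restitution slope and S2-amplitude recovery — are
genuine predictions of the assembled model and are asserted as such. Two
reconstruction limits are known: the closed-state blocker's AP-level
half-max dose (~2.5 mM at 1 Hz) is higher than the clamp anchors imply
when combined, and the use-dependence rank trends are unambiguous in one
variant each (drug C endocardially, drug O epicardially) while the
complementary variant shows the same direction with a non-monotone trend.
Both trace to the substrate transcription and the phenomenological
inactivation rates, and both are documented in the parameter provenance
file.
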