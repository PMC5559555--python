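# Methods

`sqt2sim` is a multi-scale model of the short-QT-syndrome type 2 (SQT2)
V307L KCNQ1 mutation: a Markov-chain model of the slow
delayed-rectifier potassium current (IKs) embedded in a human
ventricular action-potential model, scaled up to 1D transmural tissue
with a pseudo-ECG and to an idealised 2D sheet. This note documents the
model, its assumptions, the parameters that matter, the synthetic
fitting targets, the numerical choices and the known limitations.

## Channel model

IKs (KCNQ1 + KCNE1) is a 17-state continuous-time Markov chain with 15
closed states and two open states. Each of four voltage sensors makes
two sequential transitions (resting → intermediate at rates α/β,
intermediate → activated at γ/δ); closed states are indexed by the
sensor occupation numbers `(n1, n2, n3)` with `n1+n2+n3 = 4`, giving
C(6,2) = 15 closed states with combinatorial rate multiplicities. With
all sensors activated the channel opens (θ/η) and can enter a second
open state (ψ/ω). Macroscopic current is

    I_Ks = g_Ks · scale · (O1 + O2) · (V − E_Ks)   [pA/pF]

with `E_Ks` given by the host model's reversal-potential convention
(K⁺ with a 0.03 Na⁺ permeability ratio).

Every transition class carries a single-exponential voltage dependence
`rate(V) = a·exp(b·V)` (`a` in 1/ms, `b` in 1/mV). The voltage
sensitivities are sign-constrained — forward sensor steps and opening
(`α, γ, θ`) have `b ≥ 0`, backward steps and closure (`β, δ, η`) have
`b ≤ 0`, and `ψ, ω` are voltage-independent — which guarantees a
monotone equilibrium activation curve and reflects conventional
gating-charge directionality. A soft cap of 20 ms⁻¹ on any rate over
−90…+60 mV keeps the generator non-stiff in the tissue solver. With
these constraints the model has 14 free coefficients per genotype.

Genotypes: `WT`, homozygous `V307L`, and the heterozygote `WT-V307L`
modelled as two *independent* half-populations (50 % WT, 50 % mutant
channels) sharing the membrane potential; heterozygote current is the
exact 50:50 average of the population currents. Combinatorial
WT/mutant subunit stoichiometries are out of scope.

## Synthetic fitting targets

The voltage-clamp characterisation the channel models are fitted to is
not available as tabulated data, so `sqt2sim.fixtures` generates it
synthetically. Channel activation is a Boltzmann curve
`B(V) = 1/(1+exp((V½−V)/k))` per genotype; the end-of-step I-V target
is `B(V)·(V−E)` normalised at +60 mV — activation times ohmic driving
force, the shape an end-of-pulse current measurement actually produces
(an early version used a pure-Boltzmann *current* target, which implies
a non-monotone open probability above the activation midpoint and is
unfittable by a monotone scheme). Defaults, chosen once as the study
conditions:

| quantity | WT | V307L | note |
|---|---|---|---|
| activation V½ | +20 mV | −16 mV | mutant shift exactly −36 mV |
| activation slope k | 12 mV | 12 mV | |
| tail deactivation τ at −40 mV | 150 ms | 300 ms | 2× slow-down |
| time to half activation at +20 mV | 350 ms | 175 ms | 2× speed-up |
| equilibrium open probability at +60 mV | 0.6 | 0.6 | amplitude anchor |

The −36 mV shift is the defining property of the mutation; the two-fold
kinetic factors express "slower deactivation / accelerated activation"
as round factors typical of the reported phenotype. The absolute WT
kinetics are typical of IKs at physiological temperature. The
amplitude anchor is needed because normalised I-V data leave the open
probability scale free (without it, vanishing-amplitude generators fit
the normalised data perfectly).

## Fitting

`fit_params` minimises, by Nelder–Mead simplex (standard
reflection/expansion/contraction coefficients with the adaptive
dimensional scaling, prefactors log-transformed, 1e-8 tolerances,
iteration cap):

* squared residuals of the simulated end-of-step I-V (protocol: hold
  −80 mV, 50 ms pre-pulse to −40 mV, 3 s steps −70…+60 mV in 10 mV
  increments, 5 s tail at −40 mV) against the target I-V;
* an equilibrium-activation term (same target, equilibrium occupancies)
  — the 3-s transient alone admits generators whose true equilibrium is
  non-monotone, e.g. channels that effectively never deactivate;
* the amplitude anchor `(Po_eq(+60) − 0.6)²`;
* squared relative errors of the tail deactivation time constant
  (−40 mV) and time-to-half activation (+20 mV);
* the rate-cap and sensitivity-sign regularisers.

Kinetic measures that are undefined away from the physical region (no
tail current) contribute a fixed graded penalty instead of a hard
failure, so the I-V terms keep guiding the simplex back. Because the
kinetics are linear at fixed voltage, clamp segments are propagated
exactly through the eigendecomposition of the generator, making an
objective evaluation ~3 ms.

Packaged preset generation (`fit_default_presets`) seeds the simplex
with a bounded trust-region least-squares pass over the same residual
vector; the mutant fit starts from the fitted WT coefficients with the
voltage axis translated by the shift target. The frozen presets in
`_presets.py` are the result and are regenerable with
`sqt2sim refit-presets`.

Half-activation voltages are measured from *tail-current* (G-V) curves
— peak tail at the fixed −40 mV tail potential, where the driving force
cancels — so the Boltzmann fit reports pure activation. The fitted
shift is −34.8 mV against the −36 mV construction (the residual bias
comes from the 3-s steps not being fully at equilibrium).

## Host cell model

The host is the 2006 ten Tusscher–Panfilov human ventricular AP model
(EPI / MIDDLE / ENDO variants), transcribed in full, with its native
Hodgkin–Huxley IKs gate replaced by the Markov open probability; the
host's `E_Ks` formula and the 1:4 MIDDLE:EPI IKs-conductance ratio are
retained. Two constants are anchored once:

* `g_Ks` (WT, EPI/ENDO) is bisected so the WT EPI steady-state APD90 at
  1 Hz equals 325.6 ms → 0.120 nS/pF. Every other number in the
  package (mutant APDs, QT intervals, refractoriness, titration
  fractions) is then a prediction.
* The mutant scale factor is 1: both genotypes share the conductance
  and the mutant gain is purely kinetic. The AP-clamp peak-current
  ratio between the fitted models (≈3, under the packaged EPI AP
  command) is reported as a validation metric, not applied as a
  multiplier — applying a measured peak ratio on top of kinetics that
  already produce it would double-count the gain.

Integration: Rush–Larsen for Hodgkin–Huxley gates with the
voltage-dependent factors linearly interpolated from 0.02 mV lookup
tables; classical RK4 with stiffness-bounded sub-stepping and
renormalisation for the Markov occupancies; forward Euler with the
analytic quadratic buffering update for the calcium subsystem;
Δt = 0.02 ms for cells and strands. Halving Δt changes APD90 by less
than 0.5 ms. The stimulus is −52 pA/pF for 1 ms (2 ms in tissue),
carried as a K⁺ flux as in the host model.

Predicted APD90 at 1 Hz (ms), with the wild-type EPI value anchored:

| | WT | WT-V307L | V307L |
|---|---|---|---|
| EPI | 325.6 | 233.9 | 192.0 |
| MIDDLE | 435.4 | 362.0 | 312.8 |
| ENDO | 326.0 | 231.8 | 187.9 |

## Protocols

* **APD90** — maximal upstroke-velocity time to 90 % recovery of the
  beat amplitude (resting V to peak), linearly interpolated.
* **ERP** — after ≥50 conditioning beats, the shortest S1–S2 interval
  whose S2 elicits a regenerative AP (overshoot > 0 mV and amplitude
  ≥ 80 % of the S1 amplitude from the pre-S2 diastolic potential),
  bisected to 1 ms.
* **APD restitution** — S1 train (default 10 beats at the conditioning
  BCL) then one S2 per diastolic interval; maximal slope by finite
  differences on adjacent points. **ERP restitution** — dynamic steady
  pacing per BCL.
* **Block titration** — conductance scaling by (1−f) on all
  populations; the smallest f whose steady APD90 (cell, ±1 ms) or QT
  (strand, ±2 ms) matches the WT reference, bisected and reported on a
  1 % grid.

## Strand and pseudo-ECG

15 mm monodomain cable at dx = 0.2 mm (75 nodes), no-flux ends,
explicit diffusion. Composition, ordered from the stimulated (ENDO)
end: 25 % ENDO, 35 % MIDDLE, 40 % EPI. These are the three published
regional percentages; their transmural ordering is chosen so the
wild-type strand produces an upright T wave — the selection criterion
the tissue construction is stated to satisfy. (With the literal 40 %
ENDO / 25 % EPI ordering, repolarisation runs monotonically toward the
electrode and the T wave inverts at any physiological coupling we
tested.) D is bisected so the WT planar conduction velocity is
70 cm/s → 0.145 mm²/ms. Nodes are initialised from their cell type's
1 Hz single-cell steady state and coupled for 3 conditioning beats
before the measured beat.

The pseudo-ECG is the standard unipolar far-field integral
`Φ(t) ∝ Σ −∂V/∂x · ∂(1/r)/∂x · dx` at an axial electrode 2 cm beyond
the EPI end. Metrics: baseline is the median of the final 50 ms; QRS
onset is the first deflection beyond 2 % of the maximal early
deflection; T-peak is the largest absolute deflection after 60 ms;
T-end is the first return to within 2 % of the T amplitude above
baseline (declared rule; no standard exists and the printed source
gives none, so sensitivity to this rule is absorbed into the QT
comparison rather than assumed away).

Computed single-beat metrics: QT 382 / 294 / 250 ms and Tpeak–Tend
32 / 35 / 33 ms for WT / WT-V307L / V307L, all with upright T waves.
The QT shortening with mutant dose and the genotype ordering reproduce
the SQT2 phenotype; the absolute WT QT runs ~30 ms long and the T wave
~ 17 ms narrow against the reference values (351/292/262 and 49/60/64).
The discrepancy is traceable to the MIDDLE-cell island: the reference
QT together with the single-cell APDs implies near-total electrotonic
suppression of the island (coupled M APD ≈ 330 ms against a
single-cell 453.6 ms), whereas our contiguous 5.25 mm island retains
~25 ms of late repolarisation, delaying T-end and compressing the
apparent T width. The exact strand construction that produced the
reference values is not published; we deliberately do not tune hidden
geometry against printed outputs beyond the declared polarity
criterion.

* **Vulnerable window** — a conditioning wave from the ENDO end; a
  1 mm premature S2 at 5 mm from the EPI end, scanned at 1 ms
  resolution (coarse bracket first); each S2 classified by probing for
  new upstrokes near both strand ends as bidirectional block /
  unidirectional / bidirectional conduction. All three genotypes show
  a positive window (8 ms). The mutant-vs-WT widening reported in the
  source (×1.37 / ×1.82) does not reproduce: in our construction the
  local repolarisation-time dispersion at the prescribed site is
  essentially genotype-independent, again reflecting the compressed
  MIDDLE island.

## 2D sheet

Isotropic monodomain rectangle (uniform cell type by default, or
transmurally layered rows), no-flux boundaries; planar S1 from the left
edge, premature cross-field S2 over the lower-left quadrant timed in
the tissue's vulnerable phase (measured from the recovery of the
quadrant's leading edge, or estimated as transit time plus APD90).
Re-entry is quantified by lifespan (last −20 mV upstroke anywhere after
S2) and the dominant frequency of the whole-field mean potential
(Hann-windowed periodogram, ≥ 2 s signal, ≤ 0.2 Hz resolution, search
band 0.5–20 Hz).

The geometry is an idealised stand-in: quantitative lifespans and
frequencies from anatomically realistic tissue are explicitly not
reproducible here, and only the direction of effect (longer-lived,
faster re-entry under the mutation) is asserted. The packaged
comparison runs a 40 × 40 mm sheet coarsened to dx = 0.4 mm and
Δt = 0.1 ms for 2 s — sizes chosen to keep a paired comparison
tractable on one CPU; at this resolution the planar CV is ~20 % slow,
which is immaterial for a paired direction-only comparison.

## What the synthetic targets do and do not show

The fixture generator emulates the *constraints* the channel model was
built to satisfy (activation shift, kinetic factor orderings, I-V
shape), not the underlying recordings: passing the fit and downstream
tests shows the pipeline reproduces the mutation's mechanism —
left-shifted, accelerated IKs activation producing dose-ordered APD/QT
abbreviation, reduced ERP and normalisable by partial block — under
these idealised targets. It does not validate the model against raw
experimental traces, cell-to-cell variability, or temperature effects;
all behaviour is folded into 37 °C coefficients.

## Numerical and degenerate-input choices

* Markov occupancies are renormalised after every step; drift beyond
  1e-8 raises.
* `advance` agrees with the matrix-exponential propagator to < 1e-6
  per state over 100 ms; the equilibrium solver (SVD null space) agrees
  with long fixed-V relaxation to < 1e-8.
* Ties in the titration bisection resolve to the smaller block
  fraction; a reference unreachable at 100 % block raises with the
  achieved value.
* Degenerate inputs (all-zero clamp currents, flat I-V, flat ECG,
  constant spectra, single-point restitution curves) raise or report
  absent values rather than fabricating numbers.
* Explicit-diffusion stability (4DΔt/dx² ≤ 0.5) is validated at
  construction; sheet instability (|V| > 200 mV) aborts.

## Known limitations

* The MIDDLE-island electrotonics dominate every remaining
  quantitative gap (T-wave width/amplitude ordering, WT QT, vulnerable
  window widening, "MIDDLE ΔAPD largest"); resolving it would require
  the unpublished tissue construction.
* Single-exponential rate laws cannot represent saturating rate
  voltage dependences; all mutant effects are expressed through the 14
  fitted coefficients.
* No stochastic channel gating, no anisotropy, no realistic anatomy,
  no Purkinje system, no mechanics, and drug block is pure conductance
  scaling.
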