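# Methods

This note documents the model, the calibration procedure, the study
pipeline and the numerical choices behind `aprvdp`, in enough detail to
judge what the package's results do and do not show.

## The question

Airway pressure release ventilation (APRV) holds a high airway pressure
`P_high` for a long `T_high` and releases briefly to `P_low` for `T_low`.
Because the release is much shorter than the expiratory time constant of an
ARDS lung, exhalation is deliberately incomplete: the lung pressure at end
of release (total PEEP, `PEEP_tot`) stays well above `P_low`, and the
ventilator cannot display the driving pressure

    dP = P_plat - PEEP_tot,

the recognised mediator of ventilator-induced lung injury.  Clinicians
therefore use surrogate formulas.  The package rebuilds, in silico, a
validation of three such bedside estimators against the true `dP` read
directly from simulated lung-pressure waveforms of a virtual ARDS cohort.

## The lung model

The lung is 100 alveolar compartments in parallel behind a common proximal
node, fed through a central airway resistance `R_c` and a series dead-space
gas column of volume `VD`.

**Pressure-volume relation.** Compartment `i` with gas volume `V` exerts

    P_el(V) = P_ext_i + exp(k_i) * sinh(beta * (V - V0)) / (beta * C0),

a sigmoid PV curve that is softest at the resting volume `V0` = 25 mL
(compliance `C0 exp(-k_i)`, `C0` = 0.5 mL/cmH2O) and stiffens symmetrically
away from it.  `P_ext_i` (cmH2O) is an extrinsic compressive pressure
(positive values displace the unit toward collapse), `k_i` a dimensionless
stiffness.  The two anchors are the constraints the healthy 70-kg reference
lung must satisfy: FRC = 100 x V0 = 2.5 L at zero airway pressure and total
compliance 100 x C0 = 50 mL/cmH2O there.  The curvature `beta` = 320 /L
was fixed, once, so that a mid-severity ARDS lung ventilated at `P_high` =
30 cmH2O operates on the stiffened upper limb with an effective release
compliance near 15 mL/cmH2O — the clinically reported scale for APRV
release volumes — while its baseline chord compliance at VT = 6 mL/kg
remains near 20-25 mL/cmH2O.  The sigmoid (rather than purely exponential)
form also makes compressed low-volume units stiff, which is both the
physiological shape and what keeps the calibration from inventing soft,
unphysically slow lungs.

**Recruitment.** A collapsed unit opens when the proximal (bronchiolar
inlet) pressure reaches its threshold opening pressure `TOP_i`; an open
unit closes when its volume falls to 1% of `V0` (the simplest rule
consistent with TOP being the only recruitment parameter).  Closed units
neither ventilate nor exchange gas; their trapped volume is frozen.

**Flows.** Each open unit communicates with the node through a bronchiolar
resistance `R_b_i`; flows and the node pressure are solved algebraically
each step from the applied boundary condition (pressure at the airway
opening, or mouth flow for volume control).  Expiratory flow meets a
resistance `exp_factor` = 2.4 times the inspiratory value (dynamic airway
compression plus the expiratory circuit), applied per branch according to
the branch's own flow direction.  `R_b_i` is not part of the calibration
data vector; it is drawn from a fixed lognormal pattern (median 880
cmH2O/(L/s), sigma 0.85 in the log) scaled by one calibratable factor.
The wide spread is deliberate: heterogeneous expiratory time constants are
what make a multi-compartment lung release non-mono-exponentially, which
is the phenomenon the bedside estimators are being tested against.

**Gas transport and exchange.** Alveolar O2 and CO2 are tracked as species
volumes per compartment; the dead space is a chain of 10 well-mixed slices
(a CSTR approximation of plug flow), so expired alveolar gas is re-inspired
before fresh gas arrives and the end-tidal CO2 (`Pe'CO2`) is read from the
mouth-side slice at end expiration.  Perfusion is uniform across all 100
compartments at a fixed cardiac output of 5 L/min; blood reaching closed
units is shunted unchanged, as is the anatomical shunt fraction.
End-capillary blood equilibrates with alveolar gas through a Severinghaus
O2 saturation curve (1.34 mL/g Hb binding + 0.03 mL/L/mmHg dissolved) and
a CO2 content curve linearised about 40 mmHg (480 + 5.5 (P-40) mL/L).
The mixed-venous composition is updated between breaths from the Fick
steady state (`VO2`, `VCO2 = RQ x VO2`) with relaxation factor 0.6, which
converges in ~10 breaths; arterial tensions are recovered by inverting the
content curves.  Gas-exchange fluxes do not change compartment volume (the
implicit N2/water balance absorbs the respiratory-quotient deficit), so
total gas volume is conserved exactly against the integral of mouth flow.
Metabolic volumes are treated as BTPS throughout.  Tensions are kept in
mmHg (P/F ratios and Berlin bands are defined in mmHg); a kPa converter is
provided.

**Integration.** Fixed 1-ms explicit stepping; the per-compartment volume
update is semi-implicit (the local compliance contributes a `dt/C` term to
the branch impedance), which keeps stiff compartments stable without
sub-stepping.  Gas exchange is sub-stepped every 10 mechanics steps.  A
configuration with `beta = 0` gives an exactly linear lung, used by the
analytic (RC) test fixtures; with 100 identical compartments the model
collapses to a single RC element with closed-form trajectories, and the
simulated release matches them to <1%.

## Calibration

A virtual patient is fitted to a record Y = [PaO2, PaCO2, Pe'CO2, PIP,
P_plat, TOP_mean, V_frc] by minimising

    J = sqrt( sum ((Yhat_i - Y_i)/Y_i)^2 )

(the squared-relative-error reading; the printed form of this cost omits
the square, which can go negative under the root, so it is implemented as
least squares).  Model outputs are read from a simulated baseline
constant-flow VCV run at the record's fixed VT, FiO2, PEEP, RR and DC
(RR/DC join the genome, bounded [10, 35] /min and [0.25, 0.5], when a
record lacks them).  `TOP_mean` is targeted at 30 cmH2O for every patient.

The optimiser is a real-coded GA — tournament of 3, BLX(0.3) crossover,
per-gene Gaussian mutation (sigma 10% of range) clipped to bounds, elitism
of 1 — over either the full 305-gene space (P_ext, k_stiff, TOP per
compartment plus RQ, VO2, Hb, Shunt_anat, VD, each within its allowed
range) or a 14-gene reduced space in which the compartment features are
generated from distribution parameters: mean/spread for P_ext and k_stiff,
a lognormal low-TOP group mixed with a high-TOP mode (four genes: log
median, log spread, high fraction, high value), and the bronchiolar
resistance scale.  Compartment realisations use fixed normal-quantile
patterns (one fixed permutation per feature), so a genome maps to exactly
one patient and the cost is invariant under permutation of compartment
indices.  The reduced mode is what the cohort pipeline uses: the
compartment-level parameters are not identifiable from seven data points,
so the acceptance surface is J itself, and 14 genes converge orders of
magnitude faster.  Three archetype genomes spanning the severity spectrum
are injected into the initial population as starting points; a Nelder-Mead
polish refines the best individual, and a second GA round (incumbent
injected) runs when J remains above 0.2.  The search is deterministic
given the seed.  Cohort runs use population 16, 10 generations, polish cap
60 iterations and stop early at J <= 0.05; parameter-recovery experiments
on targets generated by the model itself reach J <= 0.05 reliably within
this budget.  Patients whose fit stays above J = 0.5 are excluded from the
study with a logged reason.

## Synthetic cohort

The original cohort (90 ARDS patients from the ARMA low-VT arm; 26%
severe, 61% moderate, 13% mild) is not public, so the generator emulates
its *structure*, not its values.  Severity counts follow largest-remainder
rounding of the published mixture (23/55/12 at n = 90).  Per patient:

* P/F uniform within the Berlin band (severe 65-100, moderate 105-195,
  mild 205-290 mmHg) and FiO2 increasing with severity; PaO2 = P/F x FiO2.
* PaCO2 ~ N(42, 4) truncated [35, 52] mmHg; Pe'CO2 = PaCO2 - U(3, 7).
* VT = 6 mL/kg x 70 kg = 0.42 L; PEEP stepped with FiO2 (ARMA-style
  ladder, 5-16 cmH2O); RR ~ N(14, 2) in [10, 20] /min; DC ~ U(0.30, 0.42).
* PIP, P_plat and V_frc are produced by simulating a provisional mechanics
  patient of the matching severity (stiffer, more compressed, less
  recruitable with increasing severity) and perturbing the outputs by
  up to +/-5% — this guarantees every record is reachable by the model
  family while keeping the blood-gas targets independent draws.
* Each patient's bronchiolar-resistance scale is an independent lognormal
  draw (sigma 0.15 in the log) around the population median.

The RR range sits below typical ARMA practice: with uniform perfusion the
model's physiological dead-space fraction cannot reach the values implied
by high-RR low-VT ventilation, and records must remain matchable at the
printed PaCO2 range.  All sampling distributions are package choices made
once; they emulate a plausible ARDS cohort and are explicitly not the ARMA
data, so agreement of cohort summaries with the original study's values
is a consistency check of the whole pipeline under emulated conditions,
not a reproduction of patient data.

## Study pipeline and estimators

Each calibrated patient is ventilated with APRV (T_high = 5 s, T_low =
0.5 s; mandatory rate 60/5.5 ~ 11 /min) at P_high/P_low = 30/5, 30/0 and
25/0 cmH2O, nominally for 30 min; runs stop early at cyclic steady state
(consecutive-cycle PEEP_tot within 0.1 cmH2O and PaCO2 within 0.25 mmHg)
and the final complete cycle is analysed.  True dP uses P_plat = maximum of
the volume-weighted mean alveolar pressure of the communicating lung and
PEEP_tot = the same waveform at end expiration.  The estimators:

* **Time-constant method** (n = 4 or 3):
  `PEEP_i = [ (n/2) tau PEFR - V_released ] x E`, then
  `dP = P_high - (PEEP_i + P_low)`; negative `PEEP_i` clamps to zero with
  a warning.  `tau = R_aw x C` and `E = 1/C` are taken from the baseline
  constant-flow VCV measurement set — under APRV's square pressure wave,
  lung pressure approaches `P_high` at end-inspiration, so an APRV-derived
  `(P_peak - P_plat)/PeakFlow` degenerates to ~0 and with it `tau`; a
  constant-flow breath is also how the measurement is made clinically.
  As printed, the formula implies a full-exhalation volume of
  `2 tau PEFR`, double the mono-exponential value `tau PEFR`; it is
  implemented as printed, and the heterogeneous lung (measured `tau` well
  below the slow tail of the release) is what keeps the n = 3 variant
  nearly unbiased.
* **Mono-exponential method**: `PEEP_i = (EEFR/PEFR) P_high`,
  `dP = P_high - (PEEP_i + P_low)`.  Fast compartments dominate the flow
  signal while slow compartments hold the pressure, so EEFR/PEFR
  undershoots the pressure ratio and the method overestimates dP — the
  systematic sign this model family predicts.
* **VCV switch**: ventilate 5 min with VT = V_released and set PEEP =
  PEEP_tot (recruitment state carried over from the APRV run), read
  P_plat(VCV) and take `dP = P_plat - PEEP`, assuming the monitoring PEEP
  equals the true total expiratory pressure.  A small positive bias
  (~1-2 cmH2O) remains because P_plat is read as the maximum of the lung
  pressure waveform, which under constant flow is the end-of-flow value
  before pendelluft redistribution.

Method comparison uses Bland-Altman bias and 95% limits of agreement
(sample n-1 SD; LOA = bias +/- 1.96 SD) per estimator and setting, Pearson
correlations (with two-sided p from the t transform) of true dP against
baseline compliance and P/F, and — reported, not asserted — the slope of
estimation error against P/F and compliance.

## Problem sizes and determinism

The packaged study runs 20 patients (the original used 90) with the
reduced GA budget; cost evaluations cap simulated time at 50 s (about
8-14 breaths, enough for the venous relaxation to settle), APRV runs stop
at steady state (typically 30-60 cycles), and the acceptance script
finishes on a single core in well under half an hour.  Every random draw —
cohort sampling, GA, per-patient seeds — derives from one user seed via
`numpy` `SeedSequence` spawning, so identical configurations reproduce
byte-identical outputs.

## Known limitations

* No spontaneous breathing effort: all virtual patients are passive, so
  every dP here is a lower bound on what an actively breathing patient
  would experience.
* The cardiovascular side is a fixed cardiac output with uniform
  perfusion; there is no hypoxic vasoconstriction, so closed units shunt
  fully and the alveolar dead-space fraction is modest.
* The cohort is synthetic.  Passing the cohort-level checks shows the
  model family plus calibration plus estimators reproduce the study's
  behaviour under emulated conditions; it says nothing about any real
  patient record.
* True dP is strongly and negatively correlated with baseline compliance
  across this synthetic cohort, whereas the original cohort showed no
  correlation with compliance.  The coupling is structural here: the
  bronchiolar-resistance distribution is fixed up to one scale, so the
  expiratory time constant is proportional to compliance, and because
  T_high far exceeds every inspiratory time constant the plateau is nearly
  identical across patients — all dP variance sits in the release
  fraction.  Real patients add independent resistance variability and
  plateau variability that dilute this coupling.  P/F correlations, by
  contrast, are weak here as in the original cohort.  The pipeline reports
  the full correlation table (with p-values) rather than hiding the
  discrepancy.
* Compliance/elastance naming follows the universal convention
  (C = VT/dP in L/cmH2O, E = 1/C); the source measurement list prints the
  two with formula and units swapped.
* Blood-gas curves are deliberately simple (no Bohr/Haldane coupling, no
  temperature or base-excess corrections); they are accurate to a few
  percent in the physiologic range, which is sufficient for calibration
  targets specified to ~5%.
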