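# Methods

`enzyres` implements, end to end, the computational pipeline of an
enzymatic reservoir sensor: a recursive protease competition network in
a continuous stirred tank reactor (CSTR) acts as a fixed nonlinear
dynamical system, and only a linear readout layer is trained on its
measured output. Because the package cannot run the wet reactor, it
ships a kinetic surrogate whose role is to reproduce the *statistical
structure* of the reservoir's outputs — a multi-feature response that is
nonlinear in substrate composition, temperature, pH and pulsed light —
so that the readout, cross-validation and scoring machinery can be
exercised and validated on data with known ground truth.

## Network model

Species are peptide fragments (one-letter codes; phosphoserine is the
extra token `pS`, written `(pS)`). Six proteases cleave after/before
configured residues; cut positions are 1-based, "cut after residue i",
so a length-n peptide has candidate sites 1..n-1. The network is the
breadth-first closure of the seven input peptides under all cleavage
rules up to `max_depth` successive cuts (default 6, which is a fixed
point for this peptide set: regenerating at depth 7 adds nothing).
Alkaline phosphatase adds dephosphorylation reactions (`pS` -> `S`)
without consuming fragmentation depth. Residue composition treats `pS`
as serine, making composition exactly conserved by every reaction — the
invariant the simulator's mass-balance checks rest on.

Specificity rules are data, not code (`enzyres.library`, overridable
via YAML): trypsin after K/R not before P, chymotrypsin after F/W/Y not
before P, elastase after A/V/G/S, thermolysin before I/L/V/F/M/A,
thrombin after R only in the R|G context, prolyl endopeptidase after P.
Disulfide chemistry of the cysteine-rich peptides is ignored (linear
sequences only); no kinetic information exists to support it.

Four of the seven input peptides are the published sequences
(CCFSWRCRC, CCF(pS)WRCRC, IYPFVEPI, TKIFKI). Peptides 1, 2 and 6 are
synthetic stand-ins (so labelled in `enzyres.library`) designed to the
same brief: 8-9 residues, multiple cleavage sites for at least two
proteases each, peptide 6 carrying the canonical thrombin motif
LVPR/GS. With this set the full network holds 141 species and 432
reactions, of which 134 fragment species form the default feature set —
the same order as the 103 ion traces tracked experimentally.

## CSTR surrogate

For species i with inflow concentration S_i,in:

    dS_i/dt = (phi/V) (S_i,in - S_i) + sum(production) - sum(consumption)

with V = 100 ul and phi = 400 ul/h (800 ul/h for light runs), i.e. a
residence time V/phi of 15 min. Enzymes are immobilized and appear only
as parameters. Each cleavage channel r of enzyme e contributes the
shared-denominator competitive Michaelis-Menten rate

    v_r = a_e kcat_r E_e (S_parent/KM_r) / (1 + sum_m S_m/KM_m),

the exact quasi-steady-state form for substrates competing for one
active-site pool; it reduces to single-substrate MM with one channel.

**Kinetic parameters.** Individual kcat/KM values are not identifiable
from the published experiments, so they are sampled log-uniformly from
a seeded generator: kcat in [1e-3, 10] s^-1 and KM in [1, 100] uM, with
enzyme loadings of 1 uM. The KM range is deliberately *below or at* the
working substrate concentrations (15-160 uM): the enzymes then operate
near saturation and the competitive denominators are far from 1, which
is what makes the steady-state map strongly nonlinear in the inputs.
(The experimental design makes the same point: input concentration
ranges were chosen for their nonlinear effects.) With KM mostly above
the working range the surrogate's response is nearly linear and the
reservoir loses its advantage over raw-input classification, so that
regime is not a faithful stand-in. Slow substrates (CCFSWRCRC ->
chymotrypsin, IYPFVEPI -> prolyl endopeptidase, TKIFKI -> trypsin) get
tight-binding, low-turnover overrides (KM in [1, 10] uM, kcat in
[1e-3, 1e-2] s^-1, both below the population medians): they occupy the
active site while being degraded slowly — effective reversible
inhibitors. The phosphorylated proinhibitor acquires this behaviour
only after dephosphorylation, because overrides attach to the
dephosphorylated sequence.

**Environment response.** Each enzyme's activity multiplier is a
normalized product of (i) an Arrhenius factor (reference 37 C) times a
denaturation sigmoid in temperature and (ii) a double-protonation bell
in pH, scaled so the optimum maps to 1. Per-enzyme defaults give the
network diversity over the tested windows: thermolysin is thermostable
(midpoint 85 C), thrombin and prolyl endopeptidase denature inside the
25-55 C range (50 and 48 C), alkaline phosphatase prefers alkaline pH.
These defaults are qualitative, not fitted constants; they exist so
that temperature and pH genuinely reweight the network's connections.

**Light forcing.** The merocyanine photoacid is modelled as two-rate
first-order pH relaxation: toward (baseline - 3.5) with tau = 10 s
while illuminated, back toward baseline with tau = 60 s in the dark —
fast acidification, slower thermal reversion. The trace is piecewise
exponential, continuous at switching times, and enters the kinetics
through the pH bells.

**Integration and steady state.** The stiff system (rates span >= 4
decades) is integrated with BDF at rtol 1e-6 / atol 1e-9 uM, with a
finite-difference Jacobian restricted to the analytically known
sparsity pattern (dilution diagonal plus, per enzyme, the coupling of
every product/parent to every parent through the shared denominator).
Steady state is declared when max |dS/dt| normalized by the largest
inflow concentration falls below 1e-6 s^-1; the 1-h equilibration
horizon is doubled (up to 4 h) until the criterion holds, so steadiness
is verified, never assumed. Dynamic runs integrate segment-wise between
forcing discontinuities (light switches).

**Measurement model.** The reported output of a steady-state run is the
per-feature time average over the final 10 min, multiplied by fixed
per-feature log-normal response factors (sigma = 0.3, seeded once per
dataset; unequal ionization efficiencies) and by per-measurement
log-normal noise with 5% coefficient of variation. Replicate scatter in
the synthetic datasets comes from this model. What it does *not*
emulate: ionization suppression and feature-feature crosstalk, drift
across days/reactors, dropout of whole runs (the experimental
temperature dataset lost 2 of 84), or raw-spectrum artefacts. Passing
tests therefore validate the pipeline's logic and calibration on clean
multiplicative noise, not robustness to instrument systematics.

## Study conditions (scenario generators)

- classification: 60 random (S1, S2) inputs, S1 ~ U(40, 100) uM,
  S2 ~ U(15, 75) uM, at 37 C / pH 7.4; peptides 6 and 7 fixed at 160 uM.
- pH x temperature: 10 random temperatures in 25-55 C crossed with the
  six buffer pH levels 6.0-8.5 (60 inputs), fixed peptide inputs.
- temperature battery: np.linspace(25.5, 55, 21) — the printed "1.5 C
  intervals, 21 inputs" are mutually inconsistent, so the endpoint count
  is kept and the step becomes 1.475 C — in quadruplicate (84 rows).
- light: 17 periodicities, log-spaced over [30, 600] s (spacing not
  published; the periods span an order of magnitude), duty 0.5, 15-min
  trains at 30 C and 800 ul/h, duplicate measurements; the feature is
  the time average over the whole train (cumulative dynamic response).
- forecasting: S1 inflow 70 + 30 sin(2 pi t / 60 min) uM, sampled every
  4.5 min over 7 h; targets are the inflow value 9 or 13.5 min ahead
  (2 or 3 samples on the grid).

## Readout and evaluation

Features are standardized to zero mean, unit variance (population s.d.;
the SNR filter uses the sample n-1 convention — both choices are
explicit to prevent silent drift), zero-variance features dropped. The
SNR filter retains a feature iff its total s.d. is at least the pooled
within-replicate-group s.d. (the square root of the mean within-group
variance), skipping single-replicate groups. Pooling variances rather
than averaging s.d.s matters: with four replicates per group the sample
s.d. is biased low by the c4 factor (~0.92), which would let nearly
every pure-noise feature pass the threshold of 1; under the pooled
convention a noise feature sits at SNR ~ 1 and is removed about half
the time, which is what a threshold of exactly 1 presumes. All statistics, including the SNR filter, are
computed on each training fold only.

Ridge regression is closed-form with an unpenalized intercept. The
classifier minimizes 0.5(||w||^2 + b^2) + C sum max(0, 1 - y f)^2 by
L-BFGS — a smooth convex primal whose regularized intercept matches the
liblinear convention, so `sklearn.svm.LinearSVC` serves as an
independent cross-check in the tests rather than as the implementation.
Defaults alpha = 1, C = 1 (the common library defaults the published
tooling implies).

Cross-validation is repeated leave-5-out: each repeat partitions the
dataset into batches of five (last batch smaller if n mod 5 != 0);
stratification deals each class round-robin into capacity-limited
batches after shuffling, so 30/30 labels give every batch both classes.
Classification scores are per-batch transformed Phi, (MCC+1)/2, with a
zero denominator factor defining Phi = 0 (the standard MCC convention);
continuous tasks report R^2 pooled over all repeated test predictions.
The sensor error is the average per-test-set s.d. of predicted - true;
because a pure s.d. ignores constant bias, the RMSE variant is reported
alongside. Per-input accuracy maps average the correctness indicator
over the splits in which the input was held out.

Task boundaries: the tuning target is the factor-4-scaled logistic
bell (maximum exactly 1); the decision and light-switch boundaries are
inclusive (y = 1 at T = T0 and P = P0). The T0 grid is
arange(30.75, 51, 1.5) = 14 boundaries ending at 50.25 C (start,
spacing and count cannot all be honoured together with an endpoint of
51). The sharpness default k = 1 /C spans several grid steps, keeping
the tuning task learnable at ~1.5 C resolution. The classification
geometries in normalized coordinates: XOR by quadrant, a centred circle
of radius sqrt(1/(2 pi)) (exact 50/50 area split), and the vertical
wedge pair |u2 - 1/2| > |u1 - 1/2|; all parameters are configurable
since only the qualitative geometry is published.

## Validation design

Exact constants (split bookkeeping 10 x 12 = 120, the 21-level grid,
tuning maximum 1, Phi = 1 for a perfect confusion matrix, the T0 grid)
are asserted directly. Simulator fidelity is checked against
independent oracles: residue conservation over every generated
reaction, closed-reactor mass balance under integration, and a
single-reaction CSTR steady state against a scalar root-find (< 0.1%).
Pipeline calibration uses a label-permutation null (held-out
transformed Phi = 0.5 within 3 s.e.). The headline property — the
simulated seven-enzyme reservoir beats raw-input linear classification
on XOR and hourglass by >= 0.2 transformed Phi, while a three-enzyme
subnetwork falls back toward baseline — is checked on pinned-seed
datasets. The ablation subset (trypsin/elastase/thermolysin) keeps
broad cleavage activity but removes chymotrypsin, prolyl endopeptidase
and alkaline phosphatase and with them the slow-substrate/proinhibitor
feedback, which is what collapses the nonlinear capacity. Temperature
recovery requires pooled R^2 > 0.9 for sensing, and the
tuning-trails-activation ordering is asserted as a tendency over five
replicate datasets, not as a constant.

Problem sizes in the test suite (60-sample classification tables, 84-row
temperature tables, 10-25 CV repeats) are the package's own fixture
scale: large enough for the statistical assertions' standard errors,
small enough to keep the suite fast.

## Known limitations

- Kinetics are sampled, not measured; conclusions transfer to the wet
  system only at the level of qualitative structure.
- Peptides 1, 2, 6 are synthetic stand-ins; fragment identities (and
  hence feature names) differ from the deposited ion-trace tables.
- The measurement model omits instrument systematics (see above), so
  the surrogate's sensor error (~0.2 C) is better than the reported
  1.33 C; the package's claim is R^2-level recovery, not the absolute
  error.
- Thrombin/thermolysin secondary-site preferences beyond the encoded
  rules, and the exact published specificity table, are unknown; the
  YAML config is the extension point.
- No multi-class tasks, no nonlinear readouts, and none of the
  GP/MLP/ELM comparator models.
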