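# Methods

`etqsp` couples a kinetic model of endothelin-1 (ET-1) disposition to a
reduced model of cardiorenal physiology, links receptor occupancy to
physiological parameters through simple effect functions, and identifies
which candidate mechanisms time-series data can support. This note records
the model equations and assumptions, the reference parameterization and why
each value was chosen, what the synthetic data emulate (and what they do
not), the numerical choices, and known limitations.

## 1. ET-1 kinetics

Big ET-1 is produced at a constant rate in a lumped tissue compartment
(volume `V_tissue`) and converted to ET-1 by endothelin-converting enzyme at
rate `k_ECE`. ET-1 exchanges with a plasma compartment (`V_plasma`) through
first-order transfer (`k_tp`, `k_pt`). In each compartment ET-1 binds ET_A
and ET_B receptors by mass action (`kon`, `koff` per receptor), and the
receptor–ligand complexes are cleared by internalization (`k_int_A`,
`k_int_B`). An optional first-order non-receptor plasma clearance
(`k_cl_plasma`, default 0 in the dataclass) represents proteolytic and
pulmonary extraction.

Competitive antagonists (BQ123, BQ788, VML588) follow one-compartment PK
with first-order elimination, distribute with the same transfer constants as
ET-1, and occupy free receptor without being internalized. Free receptor
available to either ligand is `R_total − bound(ET-1) − bound(antagonist)`,
which is the entire mechanism of competition. Antagonist dissociation is
fixed at 2 min⁻¹ and the association rate derived from the dissociation
constant, which keeps the binding equations non-stiff across six orders of
magnitude in affinity.

### Reference kinetics

The reference rate constants (`data/reference_kinetics.yaml`) are the
package's own calibration, chosen once by forward simulation against these
constraints and then frozen:

* baseline plasma ET-1 ≈ 2 pM (the production rate is solved exactly for
  this, given the other constants);
* a stepped 0.2/0.4/0.8 pmol/kg/min infusion raises plasma ET-1 ≈ 3.8-fold
  (peak ≈ 7.6 pM) — within the "doubles to quadruples" physiological range
  for this design;
* ET_B carries ~87% of total clearance at baseline, so ET_B blockade raises
  circulating ET-1 several-fold while ET_A blockade raises it only a few
  percent;
* renal (tissue) ET_B density (200 pM) far exceeds ET_A density (6.5 pM),
  while the systemic (plasma) compartment is relatively ET_A-rich;
* ET_A affinity (Kd ≈ 21 pM; effective Kd with internalization ≈ 25 pM) puts
  baseline tissue ET_A occupancy at ≈ 0.5 pM. This matters in two opposite
  directions: occupancy excursions under dosing must be large enough (≈ 1 pM
  on the infusion ramp, ≈ 3–4 pM under the strongest challenge) for tubular
  effects to be identifiable, yet the *baseline* occupancy must be small
  enough that complete ET_A blockade — which moves every linear effect to
  `E = 1 − m·occ0` — does not drive the afferent resistance to its zero
  clamp. With the afferent slope of 1.66 pM⁻¹ this caps tolerable baseline
  occupancy near 0.5 pM.
* the saturating ET_A isotherm also caps occupancy at high ET-1 so the
  combined ET_B-antagonist + ET-1 challenge constricts strongly without
  collapsing glomerular filtration.

## 2. Reduced cardiorenal model

The kidney is one preafferent resistance feeding N identical nephrons
(afferent, efferent, peritubular in series; all resistances stored as
whole-kidney lumped values). Glomerular filtration uses the Starling balance
`GFR = K_f (P_glom − P_bowman − π_avg)` with the capillary-average oncotic
pressure approximated as `π_in (1 + FF)` — a linear filtration-fraction
correction rather than an integrated oncotic profile; the approximation
error is absorbed into the calibrated `K_f`. Negative net filtration
pressure clamps GFR at zero and sets a flag on the outputs.

Filtered sodium passes four segments with fractional reabsorptions
η_PT → η_LoH → η_DCT → η_CD. Fractional lithium excretion is `1 − η_PT,eff`
(lithium as a pure proximal marker). Macula-densa sodium delivery (end of
the loop) drives tubuloglomerular feedback (TGF), a first-order state
multiplying the afferent resistance (gain 2, time constant 3 min, clamped to
[0.3, 2.2]); a myogenic state responding to arterial pressure multiplies the
preafferent resistance (gain 1, 2 min). These two autoregulatory loops are
what make the preafferent and afferent ET-1 effects separately identifiable:
both effects add preglomerular resistance, but the TGF state selectively
relaxes the afferent term as filtration falls while the myogenic state
responds to systemic pressure.

Systemically, cardiac output is linear in stressed blood volume
(`blood_volume − venous_capacitance`, with the venous compliance parameter
scaling the gain), `MAP = CO × SVR`. Volume, sodium and water balance close
the loop: sodium distributes in an exchangeable osmotic pool (plasma +
~39 L of non-plasma water, so oral water loads dilute "plasma Na" the way
they dilute osmolality in vivo); vasopressin activity tracks that
concentration and sets the excreted fraction of post-proximal water on a log
scale (`fw = fw0 · exp(s_adh (1 − a_ADH))`, capped at 0.6) — suppression by
a 25 mL/kg water load raises urine flow from 1 to ≈ 20 mL/min. A lumped
RAAS activity (driven down by pressure and macula-densa delivery) acts
weakly on systemic resistance, distal reabsorption and proximal
reabsorption; ANP (volume-driven) and a direct pressure-natriuresis term act
on the collecting duct. All hormone states are first-order with 15–30 min
time constants. The full chronic machinery of large cardiorenal models
(glucose handling, non-osmotic Na storage, staged RAAS biochemistry,
interstitial Starling exchange) is deliberately absent: the fitted protocols
are ≤ 4 h, where only fast feedback shapes the response.

The reference operating point (MAP 93 mmHg, GFR 120 mL/min, RBF 1.1 L/min,
CO 5 L/min, plasma Na 140 mmol/L, urine 1 mL/min at 150 mmol/day sodium and
1.44 L/day water) is made an *exact* steady state by construction: `K_f`,
`η_CD` and `fw0` are derived from the targets at load time instead of being
quoted. Baseline fractional sodium excretion is then 0.69%. Resistance
fractions (preafferent 0.33, afferent 0.15, efferent 0.40, peritubular
0.12) put glomerular pressure at 50 mmHg; the relatively small afferent
share keeps the large afferent effect slope (1.66 pM⁻¹) from collapsing
filtration under the strongest antagonist + infusion challenge.

## 3. Occupancy → effect link

Each candidate mechanism maps bound-receptor concentration to a
dimensionless multiplier on one target parameter:

* linear: `E = max(1 + m (ET1R − ET1R₀), 0)`;
* sigmoidal: `E = 1 + m / (1 + exp((ET1R − ET1R₀)/b)) − m/2`.

Both return exactly 1 at the baseline occupancy, so a model with all
mechanisms at baseline is identical to a model with none. The sigmoid as
written *decreases* with occupancy for positive `m`; the sign of `m` carries
the direction (negative slopes are legitimate and reported as such, e.g. the
efferent ET_B arm). Targets hit by several mechanisms compose
multiplicatively (order-independent, positivity-preserving). Renal vascular
and tubular targets read tissue-compartment occupancy; systemic vascular and
venous targets read plasma occupancy.

The seven-arm reference set (preset "refined", with an "initial" variant)
carries the calibrated slopes used as ground truth throughout the test
suite: ET_A on preafferent resistance 0.288, afferent resistance 1.66,
efferent resistance 0.0635, systemic resistance 0.060, proximal sodium
reabsorption 0.0311; ET_B on efferent resistance −0.0059 and systemic
resistance 0.0135 (all per pM of occupancy).

## 4. Study protocols

Three acute clinical designs are encoded (`protocols.py`):

* **rabelink** — 5 days at 200 mmol/day sodium (represented by initializing
  at that intake's steady state), 25 mL/kg oral water load absorbed over the
  20 min before baseline, drink-to-match-output, then ET-1 at 0.2/0.4/0.8
  pmol/kg/min in three 60-min blocks. Plasma ET-1 sampled at 0/75/125/225
  min; hemodynamics every 30 min; urine variables (flow, UNaV, FENa, FELi)
  as 30-min collection-bin averages.
* **bohm** — saline, BQ123 (5 nmol/kg/min × 50 min; the published range was
  2.5–5 and the upper end is the default, configurable) or BQ788 (4
  nmol/kg/min × 15 min), with ET-1 4 pmol/kg/min from minute 30 for 20 min.
  MAP, RBF, RVR and plasma ET-1 at 0/15/30/40/50 min (a PAH-clearance study:
  no inulin GFR).
* **vml588** — the ET_A antagonist VML588 at 0, 0.05, 0.2 or 0.4 mg/kg/hr
  for 4 h with ET-1 1 pmol/kg/min at minute 90 for 20 min, maintained
  diuresis, hemodynamics every 30 min and urine (UNaV, FELi) in 30-min bins.
  VML588's affinity and PK are not published with the protocol; the shipped
  values (Kd_A 3 µM, 60-min half-life, 500 g/mol) are chosen so the three
  doses span a graded ~50–90% ET_A blockade.

Dose conversions use an ET-1 molar mass of 2491.9 g/mol, reproducing the
printed equivalences (0.5 ng/kg/min = 0.2 pmol/kg/min; 4 pmol/kg/min =
10 ng/kg/min).

## 5. Synthetic observations

The clinical datasets this pipeline emulates were published as group
mean ± SE time courses over n subjects (n = 6, 6 and 9). The generator
therefore simulates each protocol under a known mechanism set, samples at
the protocols' measurement times/bins, and perturbs each value with
multiplicative Gaussian noise whose standard deviation is the standard error
of an n-subject mean with per-subject CV `noise_cv` (default 0.03):
`sd = value × noise_cv / √n`. The emitted `se` column equals that sd, so
the reported uncertainty is the true sampling noise and weighted residuals
are unit-scaled (the weighted SSR at truth ≈ the number of observations).
Multiplicative noise corrupts mmHg- and percent-scale variables comparably.

What the synthetic tables do **not** emulate: between-subject random
effects, within-subject crossover correlation, assay-specific error
structure (e.g. PAH extraction drift), model misspecification. Passing
recovery tests therefore demonstrates that the estimation machinery is
correct and the design is informative *under the model*, not that the model
is identifiable from any particular real dataset.

## 6. Estimation and mechanism selection

The objective is the weighted sum of squared residuals over every
observation of every study arm, with weights equal to the reported SE where
available and 5% of the variable's baseline value otherwise. Simulations run
once per study arm per evaluation; because hemodynamics do not feed back on
ET-1 disposition, the kinetic stage is solved once per protocol and cached,
and only the cardiorenal stage is re-integrated during fitting.

Slopes are estimated by bounded trust-region least squares
(`scipy.optimize.least_squares`, TRF) with seeded multi-start (Gaussian
jitter around the supplied start). Two numerical details matter:
finite-difference steps must sit well above the ODE solver's noise floor
(relative `diff_step` 10⁻³; the default ~10⁻⁸ collapses the trust region),
and parameter scaling is explicit (`max(|x₀|, 0.1)`) because Jacobian-based
autoscaling fails for candidates whose parameter is numerically inert (a
venous-compliance arm when blood volume never leaves baseline). Standard
errors come from the Gauss–Newton covariance at the optimum and are reported
as percent of each estimate; because the weights equal the observation SEs,
no residual-variance rescaling is applied.

Forward selection starts from a NULL model (no ET-1 effects). Each round
jointly refits every retained slope together with each remaining candidate
(receptor × target × form) and keeps the arm with the greatest objective
reduction; rounds stop when the best reduction is below 1% (relative) or
within the multi-start spread. Candidate refits start cold (all slopes
zero): warm-starting from the previous round's optimum was observed to lock
the greedy search into local minima, whereas this landscape converges
reliably from the origin. Objective values within the same 1% resolution are
treated as ties and resolved toward fewer parameters, so a sigmoidal form is
selected over a linear one only when it improves the objective meaningfully
— with linear ground truth it never is. Backward elimination then refits the
set with each arm removed and flags arms whose removal does not worsen the
objective beyond the 1% tolerance; the final set is the selection minus the
flagged arms. A `refit_all=False` variant (freeze previously accepted
slopes) exists for comparison. The refined calibration is the same machinery
with the third study's observations appended to the objective.

## 7. Numerical choices

* Integration: `scipy.integrate.odeint` (LSODA) with numba-compiled
  right-hand sides; kinetics at rtol 10⁻⁷/atol 10⁻⁹ (antagonist states,
  which run at ~10⁶ pM, get a proportionally looser absolute tolerance),
  cardiorenal at rtol 10⁻⁶/atol 10⁻⁹. Dose on/off times are passed as
  critical points. An independent BDF solve (`solve_ivp`) at rtol 10⁻¹⁰
  serves as the stiff reference; the production path agrees with it to
  better than 10⁻⁴ relative on antagonist + infusion protocols.
* Occupancy trajectories are sampled on a 0.25-min grid and linearly
  interpolated inside the cardiorenal right-hand side; the cardiorenal
  output grid is 1 min plus all measurement times and bin edges.
* Steady states are found with `scipy.optimize.root` (hybr) on scaled
  variables, polishing an integrate-to-rest initial guess for the kinetic
  subsystem and the nominal operating point for the cardiorenal one;
  residuals above 10⁻¹⁰ (state-relative) raise an error naming the worst
  equation.
* Degenerate situations are clamped and flagged rather than allowed to
  produce NaNs: GFR at 0 (flag; FENa reported missing), linear effects at 0,
  TGF/myogenic states at their physiological ranges, urine at a 0.05 mL/min
  floor.
* Problem sizes: the acceptance-scale experiments use the three-study
  design as specified (≈ 320 observations), one cold multi-start for each
  selection fit and two to three for the joint seven-slope fit; the
  estimator-calibration test runs 20 noise replicates of the two-study
  joint fit. These sizes keep a full selection run in the minutes range on
  one core while leaving the statistical conclusions unchanged.

## 8. Known limitations

* The cardiorenal reduction has no explicit interstitial Starling exchange,
  glucose handling, or staged RAAS biochemistry; hormone activities are
  lumped first-order states. Chronic (> days) behavior is out of scope.
* Renal resistance changes do not feed back on systemic pressure (the
  renal circuit is a parallel observer of MAP); the systemic effect arm
  carries all pressor response.
* Venous capacitance/compliance arms are present and testable but weakly
  informed by arterial-style measurements, mirroring the physiological
  reality that arterial data carry little venous information.
* The ET_B-blockade ET-1 rise is strong (several-fold at full blockade);
  real antagonist exposures produce smaller rises. Only the direction and
  ordering of these responses, not their magnitudes, are asserted.
* Lithium is treated as a pure proximal marker; any distal lithium
  transport is ignored.
* All parameters represent healthy adult male physiology (the source
  studies enrolled men); no female parameterization is provided.
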