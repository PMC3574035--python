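# Methods

## The model

`cholsim` implements a deterministic whole-body model of human cholesterol
metabolism as 19 coupled ODEs over six physiological blocks: dietary intake,
the intestinal pool, faecal excretion, the hepatic compartment, plasma
lipoproteins, and peripheral tissue. The subject it describes is a generic
normolipidaemic 20-year-old male (70 kg, 304 mg/day dietary cholesterol,
plasma LDL-C 100 / HDL-C 45 / VLDL-C 20 / IDL-C 20 mg/dL).

State variables and units follow the source parameterisation exactly: tissue
pools in mg (intestinal cholesterol IC, hepatic free cholesterol HFC and
esters HCE, hepatic/intestinal bile salts HBS/IBS, peripheral free
cholesterol PFC and esters PCE), plasma lipoprotein cholesterol in mg/dL
(VLDLC, IDLC, LDLC, HDLC), and dimensionless indices with nominal value 100
for receptor counts (HLDLR, PLDLR), nascent HDL particles (NHDL) and the
seven enzyme/transporter activities (ACAT, CEH, LPL, HSL, LCAT, CETP, SR-BI),
which are fixed boundary species together with dietary cholesterol DC.
No plasma-volume factor converts between mg and mg/dL; the model is therefore
not globally mass-conserving across compartments. This is reproduced, not
repaired, because the rate constants were fitted in these mixed units.

Five species are pure sinks (faecal cholesterol EC, faecal bile salts EBS,
steroidogenesis PSS, degraded receptors HLDLRD/PLDLRD); they accumulate
monotonically and are excluded from all steady-state definitions.

### Rate laws

Most fluxes are first- or second-order mass action (e.g. absorption
`k6*IBS*IC`, receptor-mediated LDL uptake `k18*LDLC*HLDLR`). Four processes
carry saturating feedback:

* intestinal, hepatic and peripheral cholesterol synthesis are Hill-type
  negative feedbacks of the local free pool,
  `Vmax / (1 + (pool/threshold)^n)` with n = 5 throughout
  (`ICSmax`=100, `HCSmax`=`PCSmax`=500 mg/day);
* biliary cholesterol release is the feed-forward mirror image,
  `BCRmax / (1 + (BCRt/HFC)^5)`, half-maximal at 55.5 g of hepatic free
  cholesterol and saturating at 2 g/day;
* bile-salt synthesis is reciprocal, `k5*HFC/HBS` (production rises when the
  bile pool is depleted), giving ~400 mg/day at the documented pools;
* LDL-receptor synthesis is reciprocally inhibited by the local free
  cholesterol, `khrs*HRS/HFC` hepatically and `kprs*PRS/PFC` peripherally,
  with HRS/PRS constant source terms. At steady state the receptor count is
  `khrs*HRS/(k13*HFC)`: receptor expression is down-regulated as the cell's
  cholesterol rises, which is the transmission mechanism from absorption to
  plasma LDL-C.

The receptor law deserves a note. The source material is ambiguous here and
also prints companion "source species" values (600 hepatic, 575.16
peripheral). The peripheral value satisfies
`kprs*575.16/PFC0 = k22*PLDLR0` exactly, identifying it as the constant
source of a turnover law balanced at the documented state; the hepatic
default `HRS = 60` applies the identical construction (the printed 600 is off
by exactly one order of magnitude against the printed degradation constant
and is kept as `printed_values` metadata). An alternative reading — synthesis
proportional to the receptor count itself — was implemented and rejected: it
pins HFC to `khrs/k13` at any live equilibrium, which (after summing the
remaining balances) leaves steady states existing only on a measure-zero
parameter surface where they form a line of equilibria. Under that reading
the model's own steady-state parameter scans would be ill-posed.

### Printed-equation ambiguities (mode flags)

Two resolutions of garbled printed equations are exposed as flags on
`ModelOptions`, both serialised through config and SBML:

* `strict_paper_cetp` (default off): as printed, the CETP fluxes
  `k27*CETP*HDLC` and `k28*CETP*HDLC` drain HDL-C without crediting
  VLDL-C/LDL-C. The default adds the matching gain terms so CETP transfer
  conserves plasma cholesterol, as the process description requires.
* `bilinear_bile_return` (default off): the printed bile-return strings read
  `k3*IBS*IC`, but only `k3*IBS` balances the documented enterohepatic fluxes
  (release ~2400, return ~2000, excretion ~400 mg/day); the bilinear form
  would move ~6e6 mg/day.

Two further constant choices: `ICt = 3120` mg (the printed 312 makes
intestinal synthesis ~1e-3 mg/day, contradicting the same source's 49 mg/day
budget), and `k21`, `k25` enter as zeroth-order fluxes exactly as printed.

## Numerics

Integration uses `scipy.solve_ivp` with Radau (rtol 1e-8, atol 1e-10 by
default); the system is stiff, with rates spanning 1e-6..6e2 /day and a
receptor loop relaxing over ~1/k13 = 1000 days. Time-varying protocols are
piecewise-linear `Schedule`s; integration restarts at every schedule
breakpoint so the solver never steps across a slope discontinuity. The
singular pools (HBS, HFC, PFC) carry terminal events at zero; crossing one,
or any non-sink species falling below a small multiple of the absolute
tolerance, raises an error naming the species and time — there is no silent
clamping, since the baseline regime never goes negative.

A steady state is a state where every *included* species satisfies
`|d/dt| < tol * max(1, |value|)` (default tol 1e-6; 1e-9 for baselines).
Included = dynamic species minus NHDL. The nascent-HDL pool has constant
production `k8 + k11` = 0.0505/day and no removal — as printed it grows
without bound — so it is frozen at its instantaneous value during
steady-state computation, and scenario integrations hold it at the baseline
value by default (`clamp_nhdl=False` restores the drift, which over 45
simulated years would multiply the HDL production term ~9-fold). The
`steady_state` solver relaxes by integration, then polishes with a damped
Newton (hybr) solve in log-space, which enforces positivity across the five
orders of magnitude separating species. `parameter_scan` warm-starts each
value from the previous solution and records failures per row.

## Calibration

The baseline calibration mirrors the model's staged construction: parameters
are adjusted sequentially, one per target (a damped log-space secant step per
pair per sweep), then jointly polished with bounded least squares on
log-parameters (finite-difference step 0.01 decades, well above solver
noise). Targets are the four plasma fractions *plus* the documented
peripheral free-cholesterol pool (57,516 mg), free parameters
`k12, khrs, k26, k29`. The PFC target matters: without it the calibrated
equilibrium drifts to PFC ~29 g with a doubled peripheral receptor count,
which reallocates LDL clearance away from the liver and flattens the
receptor-ageing responses. The five-target system is slightly
over-determined (the printed LDL balance and the printed PFC/receptor pair
disagree by ~9% of one flux), so the optimum leaves sub-percent residuals:
LDL-C 100.08, VLDL-C 20.11, IDL-C 19.88, HDL-C 45.00, PFC 57,513. Calibrated
values (printed in parentheses): k12 0.0134 (0.016), khrs 105.0 (100),
k26 8.49e-7 (1.5e-5), k29 0.0975 (0.05). With the printed set unchanged the
steady state sits at LDL-C 89.1, VLDL-C/IDL-C 27.8 and HDL-C 166: the printed
constants were never a self-consistent steady state, particularly on the HDL
branch.

## Scenario protocols

All scenarios start from the calibrated baseline steady state. Ageing runs
span days 0..16,425 (ages 20..65 at one model day per real day) with linear
ramps ("gradually" is not further specified in the source).

**Absorption.** A labelled absorption efficiency of X% is imposed by scaling
the absorption rate constant with the label, `k6 -> k6 * X/50` (the
`proportional` protocol, default). The strict alternative — forcing the
absorbed *fraction* `k6/(k6+k7)` itself to X% — is available as
`protocol="fraction"` and produces several-fold larger responses, because at
high absorbed fractions biliary cholesterol is recycled back to the liver
almost quantitatively. The proportional protocol is the default because it
reproduces the published response family of this model (ageing deltas
~10/21/32 mg/dL for labels 60/70/80 and a scan slope ~10.5 mg/dL per 10%
label) and makes the dietary and absorption sensitivities mutually consistent
(both transmit ~0.13-0.14 mg/dL of LDL-C per mg/day of extra hepatic influx);
the fraction protocol yields 27/76/163 mg/dL and would invert the model's
central conclusion.

**Receptor decline.** The terminal value of a linear khrs ramp is found by
shooting (Brent bisection) so that the hepatic receptor count at day 16,425
equals the prescribed endpoint to 0.1%; shots run at relaxed tolerance
(rtol 1e-7) and the accepted protocol is re-integrated at full tolerance.

**Readout.** Headline deltas are trajectory values at day 16,425 minus the
baseline steady-state LDL-C; the post-ramp relaxed steady state is computed
and reported alongside. With the default receptor timescale (1/k13 = 1000
days) the trajectory lags the quasi-static response by a few mg/dL in the
receptor protocol (e.g. +100.1 at the endpoint vs +112.9 relaxed for the
halved-receptor run); both numbers are in every `ScenarioResult`.

## Known limitations

* Mixed units (mg vs mg/dL) are reproduced verbatim; absolute inter-compartment
  mass balance is not defined.
* NHDL, as printed, has no removal; all steady-state semantics freeze it.
* The dietary slope of steady-state LDL-C is convex in intake: ~5 mg/dL per
  100 mg/day at low intake rising to ~9.6 at 1 g/day, with a full-range
  linear fit of ~6.9. Reported single-number slopes therefore depend strongly
  on the fitting range.
* The model describes one hypothetical subject; no inter-individual
  variability, no intracellular (SREBP-level) regulation, no stochasticity.
* SBML documents carry the mixed units in species/parameter annotations; unit
  consistency checks in downstream tools will warn, by construction.
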