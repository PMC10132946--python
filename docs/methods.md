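# Methods

`gravipulse` couples a one-dimensional pulse-wave solver to gestational
growth-and-remodeling rules and a target-driven calibration loop, producing
converged maternal arterial hemodynamics for a normal pregnancy and two
preeclampsia phenotypes at any gestational age from conception (s = 0 weeks)
to term (s = 40 weeks).

## 1. Governing equations

Each vessel segment carries the standard 1D equations for cross-sectional
area A(z,t), pressure P(z,t) and volumetric flow Q(z,t):

- continuity (wall storage form): `C_A ∂P/∂t + ∂Q/∂z = 0`, with
  `C_A = A·D_P` the area compliance per unit length;
- momentum: `∂Q/∂t + ∂(Q²/A)/∂z + (A/ρ) ∂P/∂z = f/ρ`, with the
  friction term `f = −2(ζ+2) π μ Q / A` for a power-law velocity profile
  (ζ = 9 by default; ζ = 2 recovers Poiseuille flow).

Blood: ρ = 1050 kg/m³, μ = 4 mPa·s. Internal solver units are CGS; the
constitutive API is in kPa and I/O is in mmHg.

## 2. Wall constitutive law

Pressure-area coupling uses a strain-stiffening tube law defined through a
pressure-dependent distensibility

```
D_P(P) = [a1 + b1 / (1 + ((P − PmaxC)/Pwidth)²)] · Dref
```

with a1 = 0.4, b1 = 5, PmaxC = 2.67 kPa, Pwidth = 4 kPa. Integrating
`d(lnA)/dP = D_P` exactly gives

```
A(P) = Aref · exp[ a1·Dref·(P − Pref)
                 + b1·Dref·Pwidth·(atan((P−PmaxC)/Pwidth) − atan((Pref−PmaxC)/Pwidth)) ]
```

anchored at the reference pressure Pref = 100 mmHg. The reference
distensibility of a vessel of diameter d̄ follows the Bramwell–Hill form of
the empirical wave-speed law `c = a2 / d̄^b2` (a2 = 7.03, b2 = 0.3565, c in
m/s, d̄ in cm): `Dref = 1/(ρc²)`. Distensibility is maximal near typical
operating pressures and falls off at both extremes — the strain-stiffening
behavior of collagen recruitment.

## 3. Network and boundary conditions

The reduced synthetic tree (default 29 segments) represents the maternal
systemic circulation: ascending/descending/abdominal aorta, one
carotid/cerebral branch, one arm branch, renal and mesenteric branches, and
bilateral iliac→femoral plus iliac→uterine→arcuate→radial uterine circuits.
Side branches stand for whole parallel beds (both carotids, both arms, …),
so their diameters are merged-bed equivalents `d_eq = (Σ dᵢ^(2+b2))^(1/(2+b2))`,
which conserves the summed characteristic admittance (Zc ∝ d^−(2+b2)).
Conduit lengths are physiological so the tree carries a realistic conduit
compliance volume (~150 mL).

Numerics: staggered grid (P, A at nodes; Q at faces, including the boundary
faces of every segment end), dz = 0.5 cm (half-length for segments shorter
than 0.75 cm), implicit backward-Euler in time with nt = 500 steps per
cardiac cycle, per-step Newton iteration on the full nonlinear residual with
a reused LU-factorized Jacobian (refreshed when Newton progress stalls).
Junctions impose exact mass balance ΣQ = 0 and total-pressure equality.

The inlet prescribes a half-sine systolic ejection waveform whose time mean
equals the target cardiac output. Every leaf ends in a three-element
Windkessel (WK3): proximal resistance R1 set to the leaf's characteristic
impedance clamped to 5–40% of the total terminal resistance RT, distal
resistance R2 = RT − R1, and compliance C. The capacitor pressure is
cold-started at its DC-divider value P·R2/RT (its natural time constant R2C
far exceeds a run, so a wrong start never re-equilibrates). Runs are
reported from the 10th cycle; a cycle-to-cycle periodicity metric below 1e-3
defines convergence to the periodic state.

## 4. Gestational scenarios

Scenario targets are smooth monotone (PCHIP) anchor curves over gestational
age for cardiac output, heart rate, MAP, uterine flow fraction, uterine
artery pulsatility index (UA-PI), axial growth stretch, and a global
distensibility multiplier (maternal arterial compliance rises ~30% by
mid-pregnancy and partly reverses at term). Systolic pressure targets are
brachial (cuff) values, SBP = 1.35·MAP. The `early_pe` and `late_pe`
scenarios are expressed as multiples-of-the-mean (MoM) curves on the normal
scenario — TPR MoM reaching 1.7 at 32 weeks with CO ~80% of normal for
early PE; mildly elevated CO (+5–7%) and TPR rising to 1.14 by 36 weeks for
late PE — plus a 0.88 wall-distensibility multiplier for both phenotypes.
MAP MoM is constructed as TPR MoM × CO MoM so the published TPR ratios hold
exactly by construction.

## 5. Growth and remodeling

Uterine-circuit vessels (uterine, arcuate, radial) grow to restore their
nongravid mean wall shear `τ̄w = 32 μ Q̄ / (π d³)` at the target flow:
`d = d0 (Q̄/Q̄0)^(1/3)`. The resulting circumferential stretch λθ = d/d0 and
the prescribed axial stretch λz feed a sigmoidal remodeling law for the
reference distensibility,

```
Dref(s) = (Dref0 / Ro) · [1 + kr3 / (1 + exp(−kr1 (λθ λz − kr2)))]
```

with kr1 = 2.2, kr2 = 1.7, kr3 = −0.85 and Ro chosen so the map is the
identity at λθλz = 1. Placental engagement is distributed over both uterine
sides; engaged radial leaves absorb the flow increase beyond the nongravid
baseline.

## 6. Calibration

Each (scenario, age) point is calibrated independently from the nongravid
tree in three steps:

1. **Resistances.** A DC resistive solve sets each terminal RT so MAP and
   the regional flow fractions hold exactly at mean flow, accounting for the
   Poiseuille resistance of the conduit path.
2. **Diameters.** The shear-homeostatic growth and remodeling of §5.
3. **Compliances.** An outer loop of short, warm-started pulsatile
   simulations tunes (a) all RT for MAP/flow errors (damped multiplicative
   updates), (b) a global terminal time constant aRTC = RT·C against the
   brachial SBP error, and (c) the uterine-bed time constant against the
   UA-PI error, to a 2% tolerance. SBP as a function of aRTC is U-shaped
   (peripheral reflection boosts SBP at small aRTC; windkessel recoil at
   large), so the loop first scans a coarse log grid to choose the branch
   (tie-broken toward the branch with better UA-PI) and then tracks SBP with
   a clipped, noise-guarded secant in log-log space. UA-PI increases
   monotonically with downstream terminal compliance (compliance-charging
   flow raises velocity pulsatility in the feeding artery), but its log-log
   slope flattens well below one at small time constants, so the uterine
   knob also uses a clipped secant with the slope bounded to [0.1, 2].

The calibrated tree is re-run cold for 10 cycles and the 10th cycle is
reported.

## 7. Derived metrics

TPR = MAP/CO; UA-PI = (vmax − vmin)/vmean of the uterine-artery centerline
velocity; carotid-femoral PWV by foot-to-foot transit (intersecting-tangent
foot detection) over the clinical subtraction distance; AIx from P1/P2
shoulder detection with AIx75 = 0.39·(HR − 75) + AIx; MoM values as
scenario/normal ratios at matched age.

## 8. Known limitations

- The tree is a reduced, merged-bed representation: regional waveforms are
  indicative, not patient-specific, and absolute PWV/AIx magnitudes depend
  on stiffness inputs that published sources constrain only loosely.
- Wall viscoelasticity is neglected (purely elastic tube law), which
  sharpens reflected waves slightly.
- Scenario curves are population anchors, not an individual-level model;
  each age is calibrated independently (no path dependence of remodeling).
- The venous side and autoregulation are outside scope; terminals are
  stationary WK3 elements per cardiac cycle.
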