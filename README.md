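# gravipulse

A one-dimensional fluid–solid–growth–remodeling (FSGR) simulator of the
maternal arterial tree across gestation. It couples a nonlinear 1D
pulse-wave solver (strain-stiffening tube law, three-element Windkessel
terminals) to shear-driven vascular growth and sigmoidal wall remodeling,
and calibrates the tree against gestational hemodynamic targets for a
normal pregnancy and for early- and late-onset preeclampsia phenotypes.

## The science in brief

Pregnancy remodels the maternal circulation profoundly: cardiac output
rises 20–30%, systemic compliance increases, and the uterine circulation
transforms from a trickle (~0.5 mL/s) into a major low-resistance bed
(>10 mL/s, an 8-fold-plus increase) as the uterine arteries more than
double in diameter. Doppler pulsatility of the uterine artery (UA-PI) falls from
~3 to ~0.75 by term. In preeclampsia this adaptation fails: total
peripheral resistance (TPR) runs high (up to 1.7× normal in early-onset
disease), cardiac output diverges between phenotypes (low in early PE,
mildly elevated in late PE), and UA-PI stays elevated (~2× normal in the
third trimester of early PE).

`gravipulse` reproduces these trajectories mechanistically on a reduced
synthetic arterial tree:

- **Pulse waves.** 1D continuity + momentum equations per vessel, implicit
  backward-Euler in time on a staggered grid, exact junction mass balance
  and total-pressure continuity, WK3 terminals at every leaf.
- **Wall law.** Area–pressure relation from a pressure-dependent
  distensibility `D_P = [a1 + b1/(1+((P−PmaxC)/Pwidth)²)]·Dref`, integrated
  in closed form; `Dref = 1/(ρc²)` from the empirical wave-speed law
  `c = a2/d^b2`.
- **Growth and remodeling.** Uterine-circuit vessels dilate to restore
  their nongravid wall shear `τ̄w = 32μQ̄/(πd³)` at the gestational target
  flow; the resulting stretches drive a sigmoidal remodeling of reference
  distensibility.
- **Calibration.** Per (scenario, age): a DC solve pins terminal
  resistances to MAP and regional flow fractions, growth sets the uterine
  geometry, then an outer loop of warm-started simulations tunes terminal
  compliances to brachial SBP and uterine-artery PI within 2%.

See [docs/methods.md](docs/methods.md) for the full model account and its
limitations.

## Worked example

Calibrate the tree for a normal pregnancy at 32 weeks and report the
achieved hemodynamics (about a minute on one CPU):

```console
$ gravipulse calibrate normal 32
scan aRTC 0.05: SBP 110.8 PI 1.594
scan aRTC 0.15: SBP 109.4 PI 1.218
scan aRTC 0.5: SBP 108.9 PI 1.057
scan aRTC 1.5: SBP 110.5 PI 1.031
scan aRTC 4.0: SBP 112.5 PI 1.056
iter 1: worst UA_PI +30.380%
iter 2: worst UA_PI +11.543%
iter 3: worst UA_PI +3.500%
iter 4: worst UA_PI +1.101%
normal @ 32 wk: converged in 4 iterations
  MAP 84.8 (target 84.0)  SBP 113.0 (target 113.4) mmHg
  UA-PI 0.81 (target 0.80)  uterine flow 9.81 mL/s  d_ut ratio 2.69
  cf-PWV 4.30 m/s  AIx75 21.1%
```

The uterine artery diameter has grown ~2.7×, the bed carries ~9.8 mL/s
(vs ~0.5 mL/s nongravid), and its velocity pulsatility index has fallen to
the expected third-trimester value.

Other entry points:

```bash
gravipulse make-network --out network.json     # nongravid tree fixture
gravipulse scenario early_pe                   # target table for a scenario
gravipulse simulate network.json --co 5 --hr 70
gravipulse run-study --out-dir results         # full gestational sweep
```

`run-study` writes `summary.csv` (all metrics per scenario/age point),
`mom.csv` (multiples-of-the-mean vs the matched normal pregnancy), a JSON
run manifest, and a JSON-lines calibration log.

## Package layout

| Module | Contents |
| --- | --- |
| `gravipulse.network` | vessel/junction/terminal data model, reduced-tree generator, JSON serialization |
| `gravipulse.constitutive` | tube law, distensibility, remodeling law |
| `gravipulse.solver` | implicit 1D pulse-wave solver, inlet waveforms, probes |
| `gravipulse.scenarios` | gestational anchor curves and scenario target tables |
| `gravipulse.calibration` | three-step per-age calibration loop |
| `gravipulse.metrics` | PI, TPR, PWV, AIx/AIx75, MoM, waveform summaries |
| `gravipulse.study` | full-sweep driver, CSV/JSON reporting |
| `gravipulse.cli` | `gravipulse` command-line interface |
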