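# Methods

## The HFPNe formalism as implemented

A network is a bipartite graph of places and transitions. Continuous places
carry nonnegative real marks ("unit"); generic places carry booleans or
numbers and serve as on/off switches and parameter modulators. Continuous
transitions carry a speed expression over place marks and named parameters
(unit/pt); generic transitions carry a guarded assignment evaluated on the
post-step state. Arcs come in three kinds: normal arcs transfer
`weight · speed · dt` units per step; test arcs gate on `mark ≥ threshold`
without consuming (used for enzymes); inhibitory arcs disable their
transition while the inhibitor mark is **at or above** the threshold
(enabling is the strict inequality `mark < threshold`). Thresholds are
expressions, so a modulator place can retune an arc at run time. Discrete
places and transitions are rejected at validation: the terpenoid model uses
only continuous and generic kinds.

Arcs additionally accept an optional boolean guard expression; a guarded arc
is inert (neither gates nor consumes) while its guard is false. This is how
the crosstalk substrate arcs into the GPP/FPP synthases are "consumed only
when the crosstalk switch is on" without changing the arc census: the
MEV-side substrate arcs of reactions 8–9 are guarded by `MEV_switch`, the
plastidial IPP_2/DMAPP_2 arcs by `crossSwitch`.

### Integration scheme

Explicit fixed-step Euler. Per step, all continuous transition speeds are
evaluated simultaneously on the pre-step marking; a one-pass starvation
guard then zeroes, for that step, every transition whose demanded
consumption would overdraw some source place (the demand test is the *sum*
over all consumers of a place, and all consumers of an overdrawn place
idle together — deterministic and order-independent). The marking update is
applied in one shot; generic updates run afterwards in declaration order at
the new time. Continuous marks therefore stay nonnegative by construction.

Defaults: `dt = 0.02` pt, `sample_every = 1` pt, horizon 300 pt, overflow
abort at 1e9 units. The step size is deliberately below the coarsest stable
choice: under the zero-speed starvation rule a bimolecular consumer
`k·S·P` idles whenever `k·P·dt > 1` *independently of its own substrate
level*, so the step must satisfy `k·P·dt ≪ 1` for the largest co-substrate
pool P (ATP reaches ~500 units under scenario 3; with `k ≤ 0.05` this gives
`dt ≈ 0.02`). The guard is meant to be a safety net at sharp transients,
not the integrator.

### Expression grammar

Speeds, thresholds, guards and update rules are strings in a whitelisted
subset of Python expression syntax: numeric/boolean literals, names,
`+ - * /`, unary minus, `min/max/abs`, comparisons, `and/or/not`, and
`x if cond else y`. `time` and `dt` are reserved. The AST is validated and
compiled once; evaluation is pure. Booleans coerce to 0/1 in arithmetic,
which is how switches gate reaction speeds multiplicatively without adding
arcs or transitions.

## The terpenoid model

Census: 19 reaction transitions + 41 metabolites × (production +
degradation) = **101 continuous transitions**; 42 metabolites (incl. the
injected inhibitor fosmidomycin, which has no production/degradation pair)
+ 19 enzymes = **61 continuous places**, plus 3 switches and 2 modulators =
**66 places**. Fosmidomycin enters through a generic transition
(`fosmidomycin += k_fos·dt` once `time ≥ t_fos` and `crossSwitch`), so the
continuous census is scenario-invariant; scenario 5 adds one more generic
transition that flips `crossSwitch` at `t_fos`.

Rate laws are irreversible mass action, first order in each *distinct*
substrate and in the enzyme: `v = k·E·∏ S_i`. Two standard conventions
apply: a weight-2 substrate is consumed at `2v` but does not enter the rate
squared, and water never appears in a rate law (solvent activity is
constant and absorbed into `k`) though it is consumed stoichiometrically.
Protons are omitted entirely, as are the water by-products on the MEP side,
which is what reconciles the 101/66 entity census exactly. The IPP ⇄ DMAPP
isomerase is modeled forward-only; net forward flux is all the five
scenarios require, and a reverse transition would break the 101 census.

Regulatory wiring (all four inhibitory arcs exist in every scenario; a
scenario "disables" one by parking its threshold at the overflow bound):

| arc | threshold | default | scenario value |
|---|---|---|---|
| MEVP ⊣ ATP production | `theta_mevp_atp` | disabled | 80 (scenario 3) |
| ATP ⊣ PMK (r5) | `theta_atp_pmk` | 50, sampled [50, 80] | active (scenario 3) |
| FPP ⊣ MK (r4) | `fpp_mk_threshold_mod` | 100 | 10 (scenario 4) |
| fosmidomycin ⊣ DXR (rB) | `theta_fos_dxr` | 20, sampled [5, 50] | active (scenario 5) |

The two modulator places hold the ATP production rate (10 unit/pt baseline,
30 in scenario 3) and the FPP ⊣ MK threshold; they are the only numeric
generic places read by speed/threshold expressions.

## Synthetic parameters: what is emulated and what is not

Most rate constants in a dimensionless pathway model have no literature
reference values; they are normally hand-tuned until the known qualitative
behaviors emerge. `terpnet.synthetic` stands in for that tuning with
uniform draws from documented ranges through a counter-based stream keyed
by `(seed, draw_index, name)` — no global random state, bit-reproducible.
The fixed reference values are pinned. The ranges are a *calibration*,
chosen so the documented feedback mechanisms are operative across the whole
ensemble, which is exactly what hand-tuning a single parameter set would
achieve for one point:

* `k` ∈ [0.01, 0.05] /pt for reactions; the two terminal terpene synthases
  use [0.01, 0.02] (terpene synthases are slow enzymes; a fast terminal
  drain would hold FPP below its 10-unit regulatory threshold).
* Degradation: cofactors/byproducts [0.1, 0.2] /pt (turnover 5–10 pt),
  carbon intermediates [0.005, 0.02] /pt (turnover 50–200 pt), end products
  pinned 0 (terminal pools accumulate). The split matters: the ATP/MEVP
  relay oscillates only if ATP relaxes quickly — the MEVP overshoot above
  its 80-unit threshold is roughly `f·ln(ATP_ss/θ)/d_ATP` (f = chain flux)
  and must stay below the ATP stock `θ`, otherwise the system slides into a
  chattering equilibrium pinned at the threshold; and MEVP/FPP can only
  *reach* 80/10 units if their own decay is slow (`f/d > threshold`).
* Source production [8, 15] unit/pt; `theta_atp_pmk` ∈ [50, 80],
  `theta_fos_dxr` ∈ [5, 50]; fosmidomycin injection 1 unit/pt.

What the generator does **not** emulate: saturating (Michaelis–Menten)
kinetics, enzyme expression dynamics, reversible isomerisation, cellular
transport, or real units — pt and unit are dimensionless by
construction. Passing behavior tests therefore shows that the *network
structure plus threshold logic* produces the expected qualitative dynamics
robustly over a realistic kinetic ensemble; it says nothing about
quantitative agreement with any organism's measured fluxes.

Random small mass-action nets (`random_hfpn`) provide engine fixtures whose
rate equations are integrated independently (scipy `solve_ivp` at
rtol 1e-10) as an accuracy oracle; at `dt = 1e-3` the Euler trajectories
agree to well under 0.5% relative sup-norm at t = 10.

## Numerical choices and degenerate inputs

* Enabling uses `≥` for normal/test arcs and strict `<` for inhibitory
  arcs; either convention is defensible, and the choice only moves
  switching events by one step at most.
* The starvation test allows exact full consumption
  (`demand ≤ marking·(1+1e-12)+1e-12`); post-step negative dust below
  1e-9 is clipped to zero, anything larger is an internal error.
* Threshold "disabled" = 1e9, the overflow abort bound, so a disabled arc
  can never fire before the run aborts anyway.
* `simulate(t_end=0)` returns the initial marking only; sampling always
  includes t = 0 and t_end; times are reconstructed as `i·dt` to avoid
  accumulation drift.
* Trace CSV and model JSON use shortest round-trip float representation:
  re-reading reproduces values exactly and rewrites are byte-identical.
* Peak counting: strict local maxima, prominence measured against the
  lower of the two flanking minima (flanks delimited by neighboring strict
  maxima or the series ends); default prominence 1 unit. Deceleration:
  centered moving-average growth rate over a 10 pt window, first sampled
  time below 0.5× the running maximum; exactly linear series never
  decelerate.

## Known limitations

* Euler + hard thresholds makes switching times accurate only to O(dt);
  halving dt can shift a peak by a sample. Peak *counts* and threshold
  crossings are robust; exact peak times are not.
* The engine is interpreted (compiled expressions over dict namespaces): a
  300 pt scenario takes on the order of a second. Fine for this model's
  scale, not for thousand-node networks.
* With both `MEV_switch` and `crossSwitch` on, reactions 8–9 draw on the
  cytosolic and plastidial precursor pools at one common speed; no scenario
  exercises that combination.
* Ensemble robustness is a pass-fraction screen, not a sensitivity
  analysis; no Sobol/Morris indices.
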