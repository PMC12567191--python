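# tgmo — therapeutically guided multidrug optimization

`tgmo` implements the design-of-experiments workflow used to distil a large
panel of candidate drugs into small, low-dose, tumour-selective drug
combinations — the strategy behind optimized drug combination (ODC) screens
in renal cell carcinoma and related models. It is aimed at computational
scientists who analyse (or simulate) combination viability screens run on
one or more cancer cell lines alongside a non-malignant control line.

## The method

The search space of k drugs at 3 dose levels (absent / half dose / screen
dose) is far too large to measure exhaustively. Instead, each search round:

1. **Dose selection.** Per-drug inhibition curves
   `v(c) = 100 / (1 + (c/IC50)^h)` (variable-slope logistic, asymptotes
   fixed at 100 and 0) are fitted to monotherapy data and inverted in closed
   form, `IC_f = IC50 · (f/(100−f))^{1/h}`. The screen dose is the IC20
   capped at the clinically used dose (CUD, derived from plasma exposure):
   flat curves or IC20 > CUD fall back to the CUD, so no screened dose ever
   exceeds clinical exposure.
2. **Design.** An orthogonal array composite design (OACD) — a regular
   resolution-IV two-level fraction at levels {0, 2}, k columns of a
   standard three-level orthogonal array (full 3^k, OA(18, 3⁷) or
   OA(27, 3¹³)), and a vehicle-control center run — defines which coded
   combinations `x ∈ {0,1,2}^k` are measured, with the fraction escalated
   automatically until the full quadratic model is estimable.
3. **Modelling.** Two endpoints are fitted per cancer line by second-order
   stepwise regression (entry p = 0.05, removal p = 0.10) with
   Cook's-distance outlier elimination, RMSE/R²/ANOVA diagnostics:

   `y = β₀ + Σᵢ βᵢ xᵢ + Σᵢ βᵢᵢ xᵢ² + Σ_{i<j} βᵢⱼ xᵢxⱼ + ε`

   on the cancer viability `y` (% of vehicle control) and on the
   therapeutic window `TW = viability(normal) − viability(cancer)`
   (percentage points; positive = tumour-selective).
4. **Elimination.** Significant coefficients become per-drug evidence:
   on the cancer endpoint negative is beneficial (more kill), on the TW
   endpoint positive is beneficial (more selectivity); a significant
   interaction that is detrimental on either endpoint is antagonism, and a
   drug pushing the normal line below 80% viability on its own is toxic.
   The most detrimental drugs (at most three per round) are dropped and
   the screen repeats.
5. **ODC selection.** Once ≤ 4 compatible drugs remain, a final round runs
   at current and at twofold-escalated (CUD-capped) doses, and emits a
   synergistic combination (drugs joined by beneficial interactions) and,
   when present, a purely additive one (beneficial single agents with
   mutually neutral interactions).

A Bliss-independence simulator with planted pairwise interactions
(`ψ < 0` synergy, `ψ > 0` antagonism) and Gaussian plate noise provides
ground truth for every stage; see `docs/methods.md` for the model and its
limits.

## Worked example

Run the scripted 10-drug scenario (three antagonism-laden drugs, a
normal-line-toxic drug, a mutually antagonistic trio, and a planted
crizotinib–telaglenastat synergy) end to end:

```python
from tgmo import (TgmoConfig, make_screen_scenario, run_tgmo,
                  select_screen_doses, render_report)

truth = make_screen_scenario(seed=0)          # 10-drug renal screen stand-in
config = TgmoConfig(seed=1)
specs = select_screen_doses(truth, seed=config.seed)   # IC20 capped at CUD
states = run_tgmo(truth, specs, config, cancer_lines=["786O_like"])

state = states["786O_like"]
print(f"status: {state.status}")
for rnd in state.rounds:
    print(f"round {rnd.round} ({rnd.label}): "
          f"{len(rnd.active_drugs)} drugs, {rnd.n_runs} runs, "
          f"removed: {', '.join(rnd.removed) or 'none'}")
for odc in state.odcs:
    doses = ", ".join(f"{d} {v:.3f} µM" for d, v in odc.doses_uM.items())
    print(f"{odc.kind} ODC: {doses}")
```

prints

```
status: converged
round 1 (elimination): 10 drugs, 164 runs, removed: aspirin, palbociclib, axitinib
round 2 (elimination): 7 drugs, 56 runs, removed: osimertinib, selumetinib, simvastatin
round 3 (elimination): 4 drugs, 30 runs, removed: none
round 4 (final_current): 4 drugs, 30 runs, removed: none
round 5 (final_escalated): 4 drugs, 30 runs, removed: none
synergistic ODC: crizotinib 0.664 µM, telaglenastat 2.113 µM
```

Rounds 1–2 eliminate all six planted detrimental drugs; the final
combination is the planted synergy pair at clinically capped doses.
`render_report(state.rounds[-1].models)` then lists the fitted
coefficients in the conventional three-part layout (first-order terms,
drug–drug interactions, second-order terms) with significance stars — in
this run the crizotinib:telaglenastat interaction is `-3.72 (****)` on the
cancer endpoint and `+2.60 (***)` on the therapeutic window, i.e. synergy
that widens the window.

The same pipeline is scriptable from a shell: `tgmo design`,
`tgmo simulate`, `tgmo fit`, `tgmo eliminate` and `tgmo run --config
config.yaml` read/write plain CSV/JSON/YAML (run `tgmo --help`).

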