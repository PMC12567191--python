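# Methods

This note documents the models, numerical choices and open design decisions
behind `tgmo`, and what the synthetic validation does and does not
demonstrate.

## Endpoints and normalization

All viability values are percentages of the vehicle (DMSO) control: each
(cell line, replicate) plate is normalized by the arithmetic mean of its
vehicle wells, so vehicle wells average to exactly 100 by construction. The
mean (not the median) matches the %-of-control convention of luminescent
ATP assays; values above 100 are retained because the raw readout can
exceed the control. Replicate-level rows are carried into the regression
unaveraged — pre-averaging would discard the error degrees of freedom that
stepwise p-values and the ANOVA test rely on. Whether pooling of
independent experiments should be per plate or per experiment is not
determinable from typical screen layouts; the implementation normalizes per
(line, replicate) plate.

Two endpoints are analysed per cancer line: cancer-cell viability, and the
therapeutic window TW = viability(normal) − viability(cancer) in percentage
points. TW pairs replicate r of the normal line with replicate r of the
cancer line; the pairing is a bookkeeping convention (replicates are
exchangeable), but it propagates both lines' noise, so TW values carry
roughly √2 times the single-line noise.

A condition is called toxic when it pushes normal-line viability below 80%
of control. The boundary itself (exactly 80.0) is non-toxic under the
default strict-< convention; `flag_toxicity(..., strict=False)` switches
to ≤.

## Dose–response and dose selection

Monotherapy curves use the variable-slope logistic with fixed asymptotes,
v(c) = 100/(1 + (c/IC50)^h), fitted by least squares in log10-dose space
with bounds h ∈ [0.1, 10] and IC50 ∈ [10⁻⁶, 10⁶] µM and uniform weights.
At least 4 distinct positive doses are required. A fit is declared *flat*
(parameters unusable) when R² < 0.5 or the estimated IC50 exceeds the
largest tested dose more than 10-fold — thresholds chosen to catch both
no-signal wells and extrapolated pseudo-fits; both are configurable.
Inversion to any inhibition level is closed-form,
IC_f = IC50·(f/(100−f))^(1/h).

The screen dose (coded level 2) is the IC20 capped at the clinically used
dose (CUD); flat curves fall back to the CUD directly. Level 1 is half the
screen dose — a second non-zero level is required for the quadratic terms,
and halving is the simplest convention when no other information exists.
Dose refinement between the last two rounds doubles the screen dose, again
capped at the CUD, so no emitted dose can exceed clinical plasma exposure.

## Design construction

The OACD concatenates (a) a regular two-level fraction at {0, 2} with
resolution ≥ IV, (b) k columns of a standard three-level orthogonal array
(full 3^k for k ≤ 3, OA(18, 3⁷) for k ≤ 7, OA(27, 3¹³) for k ≤ 13,
the latter built from the 13 GF(3) linear forms in three index digits),
and (c) one all-zero center run; duplicate rows keep their first
occurrence with recorded multiplicity, and run order is a seeded
permutation (the run *set* is a pure function of k).

Minimal resolution-IV fractions are not sufficient: their two-factor
interactions are aliased in chains that 18–27 three-level runs cannot fully
disambiguate (e.g. 2^(10−4) + OA(27) + center has rank 63 of the 66
required columns). The constructor therefore chooses added-factor
generators as odd-size subsets of the basic factors — every defining word
then has even length ≥ 4, i.e. a fold-over/resolution-IV structure —
greedily maximising pairwise symmetric differences (longer words, pushing
toward resolution V/VI), and escalates the number of basic factors until
the full second-order model matrix of the composite reaches full column
rank. The resulting sizes range from 9 runs (k = 2) to 282 (k = 13);
estimability for every supported k is verified by test. `validate_design`
reports rank, three-level balance, the maximum pairwise column correlation
and D-efficiency det(XᵀX)^(1/p)/n on the standardized model matrix.

For pipeline runs the design is augmented with any missing single-drug runs
at level 2. These monotherapy wells anchor the per-drug ledger (measured
single-agent effect, single-agent toxicity on the normal line); they are
rows of the full two-level factorial and keep that block label. When a
singleton run is absent the ledger falls back to the model prediction at
that corner.

## Regression

The model is the full quadratic response surface over coded levels,
with predictors centered (not standardized) before squares and products
are formed — this decorrelates the intercept from the quadratics while
keeping coefficients in interpretable level units. Selection is
bidirectional p-value stepwise starting from the intercept-only model:
the candidate with the smallest partial-F p-value enters while p < 0.05,
then any included term with coefficient p > 0.10 is dropped (worst first);
no term hierarchy is enforced (an interaction may stay without its main
effects, as interaction-driven activity is exactly what the screen looks
for). The scan maintains a QR basis of the current model, so each candidate
costs one projection; a repeated selection state terminates the loop.
Perfectly collinear candidates (residual norm ≤ 10⁻¹⁰ of the column norm)
are skipped, and once the residual sum of squares is numerically zero no
further term can enter — noiseless truths are recovered exactly. The final
fit is ordinary least squares; standard errors come from σ̂²(XᵀX)⁻¹.

Cook's distances D_i = r_i² h_ii / (p s² (1−h_ii)²) are computed for the
selected model; rows with D > 3·mean(D) (configurable to the classic 4/n)
are removed in a single pass and the same term set is refitted once.
Removal aborts (with the original fit kept) if fewer rows than
coefficients + 1 would remain. Because Cook's distances are strongly
right-skewed, the 3×mean rule normally flags a *few* rows even on clean
data; the refit is what matters, and gross outliers (tens of viability
points) are reliably caught — both properties are under test. Diagnostics
report R², adjusted R², RMSE on residual degrees of freedom, the
overall-model ANOVA F-test p-value and the fitted–observed Pearson
correlation (whose square equals R² for OLS with intercept, checked
numerically); zero residual degrees of freedom flags them unavailable.

## Interpretation, elimination and ODC selection

Sign conventions: on the cancer endpoint a negative coefficient is
beneficial (less viability), on the TW endpoint a positive one is
(more selectivity). Terms with p ≥ 0.05 are neutral.

One additional relevance floor applies to *interaction* terms in the
pipeline (default 2 viability points, `TgmoConfig.interaction_floor`).
The reason is structural: the data-generating surface is multiplicative
(Bliss-like), and fitting a product of single-agent survivals with an
additive polynomial on the % scale produces small positive cross-terms
(≈ 100·a_i·a_j /4 per coded unit², about +1 point for two agents at 80%
single-agent viability) that are statistically significant at realistic
replication even when the drugs do not interact at all. Without the floor
every Bliss-independent pair reads as weakly antagonistic.
`classify_terms` defaults to floor = 0 for standalone use.

Each round, per-drug evidence is assembled: counts of significant
detrimental/beneficial interactions on either endpoint, counter-productive
main effects, measured monotherapy effect, and single-agent toxicity.
The detriment score is a weighted sum (defaults 1 per detrimental
interaction, 2 for toxicity, 1 per detrimental main effect — toxicity
weighs double because safety is a hard requirement, not a trade-off);
up to three drugs with positive score are removed per round, ties broken
by weaker single-agent effect, then name. Elimination stops shrinking the
panel once ≤ 4 drugs remain: at that size, residual detrimental pairs are
resolved during ODC composition instead of dropping whole drugs, because
the product-surface artifact above makes score-based removal at k = 4
eliminate genuinely good drugs. If the panel stalls above 4 drugs with no
detriment left, the 4 most beneficial drugs are enrolled in the final
round.

The final round screens the survivors at current and at twofold-escalated
(CUD-capped) doses, and picks the variant with the larger predicted TW of
the full combination. The synergistic ODC is the union of significant
beneficial interaction pairs among non-toxic drugs, pruned until no
detrimental interaction remains within the set (least-beneficial member
dropped first); the additive ODC — optional, since such combinations may
equally be chosen by inspection — collects non-toxic drugs with beneficial
main effects whose within-set interactions are all neutral. Searches on
multiple cancer lines run independently and may disagree, as parallel
screens on different lines do.

## The synthetic screen

The simulator draws each measurement as
100·[∏ᵢ vᵢ(cᵢ)]·exp(Σ_{i<j} ψᵢⱼ aᵢaⱼ) + N(0, σ), truncated at 0 (not at
100), where vᵢ is the drug's Hill survival, aᵢ = 1 − vᵢ its activity, and
ψᵢⱼ a symmetric log-scale interaction (ψ < 0 synergy, ψ > 0 antagonism).
Scaling by the activity product keeps interactions bounded, smooth, and
vanishing when either drug is absent, and makes the fitted interaction
coefficient inherit the sign of ψ. σ defaults to 5 viability points with
N = 3 replicates — a realistic scatter for ATP-luminescence screens run as
independent experiments. With σ = 0 the output is a pure function of the
truth (bit-reproducible); seeded runs are bit-reproducible too.

The scripted 10-drug scenario plants, in both cancer lines: two drugs with
three strong antagonisms each (ψ = +8) and one drug toxic to the normal
line as a single agent (65% viability at its dose) — removed first; a
mutually antagonistic trio (ψ = +8 within the trio) — removed second; one
synergy pair (ψ = −8, absent in the normal line); and two clean beneficial
single agents. Cancer-line IC50s sit at twice the clinical dose with Hill
slope 2, so the selected IC20 dose equals the clinical cap and single-agent
viability is ~80% there; interaction magnitudes were chosen by power
analysis so planted effects are detectable at σ = 5, N = 3 without
saturating combination responses near zero.

What passing these experiments shows: the pipeline recovers *this* class of
structure — monotonic single-agent curves, pairwise log-scale interactions,
homoscedastic Gaussian plate noise — at realistic screen sizes. What it
does not show: robustness to biphasic dose–response, higher-order (3-way)
interactions, heteroscedastic or batch-structured noise, plate-position
effects, or model misspecification beyond the Bliss product form. Real
screens also involve judgment calls (e.g. which borderline drug to drop)
that the deterministic detriment score only approximates.

## Problem sizes and determinism

The bundled experiments use the sizes a desk-scale validation needs:
200-seed Monte-Carlo runs for detection power and ANOVA type-I calibration
on k = 3–4 designs, and 50 seeded end-to-end searches (each two to three
elimination rounds plus two final variants) for the recovery experiment.
Every stochastic component takes an explicit seed; `run_tgmo` derives
per-round seeds from the config seed via a seed sequence, and reruns with
the same seed and config produce byte-identical traces.
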