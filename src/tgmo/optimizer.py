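"""Iterative drug elimination and optimized-drug-combination (ODC) selection.

Each search round screens the active drugs with an OACD, fits the two
second-order endpoint models (cancer viability; therapeutic window), and
turns significant coefficients into per-drug evidence:

* sign convention — on the cancer-viability endpoint a *negative*
  coefficient is beneficial (more cell kill); on the therapeutic-window
  endpoint a *positive* coefficient is beneficial (more selectivity);
* antagonism — a significant interaction term that is detrimental on either
  endpoint;
* single-agent toxicity — normal-line viability below the 80% threshold at
  the drug's screen dose alone.

Drugs accumulating detriment (antagonistic interactions, toxicity,
counter-productive main effects) are eliminated, at most three per round.
Once at most four mutually compatible drugs remain, a final round re-screens
at (i) the current doses and (ii) doses escalated twofold but never beyond
the clinically used dose, and the ODCs are read off the better variant:
a synergistic combination built from beneficial interaction partners and,
optionally, a purely additive combination of beneficial single agents with
mutually neutral interactions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .doe_design import (
    DesignMatrix,
    augment_monotherapies,
    generate_oacd,
    map_to_concentrations,
)
from .dose_response import DrugSpec
from .plate_io import TOXICITY_THRESHOLD_PCT, ScreenDataset, flag_toxicity
from .response_model import (
    ModelTerm,
    RegressionModel,
    build_model_matrix,
    compute_tw,
    cooks_filter,
    stepwise_fit,
)

__all__ = [
    "PUBLISHED_ODC_DOSES_UM",
    "TgmoConfig",
    "TermClassification",
    "DrugEvidence",
    "DrugLedger",
    "ODC",
    "SearchRound",
    "SearchState",
    "classify_terms",
    "build_drug_ledger",
    "eliminate_drugs",
    "refine_doses",
    "run_tgmo",
]

logger = logging.getLogger(__name__)

ENDPOINT_CANCER = "cancer_viability"
ENDPOINT_TW = "therapeutic_window"

#: Published optimized combinations of the renal screen (µM), kept as
#: reference fixtures for worked examples: combination A was selected in the
#: sarcomatoid-chromophobe line screen, B (purely additive) and C
#: (synergistic) in the clear-cell line screen.
PUBLISHED_ODC_DOSES_UM: dict[str, dict[str, float]] = {
    "ODC_A": {
        "crizotinib": 0.664,
        "telaglenastat": 0.013,
        "u104": 9.524,
        "vismodegib": 12.754,
    },
    "ODC_B": {"telaglenastat": 0.013, "u104": 9.524, "vismodegib": 12.754},
    "ODC_C": {"crizotinib": 0.664, "telaglenastat": 0.013},
}

#: Called for each round: (design, concentrations µM, replicates, seed) ->
#: ScreenDataset covering the cancer line(s) and the normal line.
MeasureFn = Callable[[DesignMatrix, pd.DataFrame, int, int], ScreenDataset]


@dataclass
class TgmoConfig:
    """Tunable knobs of a search; defaults follow the screen conventions."""

    replicates: int = 3
    p_enter: float = 0.05
    p_remove: float = 0.10
    alpha_sig: float = 0.05
    max_removals: int = 3
    max_rounds: int = 5
    toxicity_threshold: float = TOXICITY_THRESHOLD_PCT
    detriment_weights: tuple[float, float, float] = (1.0, 2.0, 1.0)
    escalation: float = 2.0
    cooks_rule: str = "3xmean"
    emit_additive: bool = True
    final_size: int = 4
    #: Minimum |beta| (viability points per coded-unit²) for an interaction
    #: term to be called beneficial/detrimental.  A multiplicative
    #: (Bliss-independent) null surface fitted with an additive polynomial
    #: on the % scale produces small but statistically significant positive
    #: cross-terms (~1 point for two agents at ~80% single-agent viability);
    #: the floor keeps such null pairs neutral.
    interaction_floor: float = 2.0
    seed: int = 0


@dataclass
class TermClassification:
    """A model term called beneficial, detrimental or neutral.

    Neutral iff p >= alpha; otherwise the call follows the endpoint's sign
    convention (cancer endpoint: beneficial iff beta < 0; TW endpoint:
    beneficial iff beta > 0).
    """

    term: ModelTerm
    endpoint: str
    call: str


@dataclass
class DrugEvidence:
    """Per-drug evidence accumulated from one round's fitted models."""

    drug: str
    monotherapy_effect: float = float("nan")
    monotherapy_source: str = "unmeasured"
    detrimental_interactions: dict[str, int] = field(default_factory=dict)
    beneficial_interactions: dict[str, int] = field(default_factory=dict)
    detrimental_mains: int = 0
    beneficial_mains: int = 0
    toxic_alone: bool = False
    decision: str = "keep"
    reasons: list[str] = field(default_factory=list)

    @property
    def total_detrimental_interactions(self) -> int:
        return sum(self.detrimental_interactions.values())

    @property
    def total_beneficial_interactions(self) -> int:
        return sum(self.beneficial_interactions.values())


@dataclass
class DrugLedger:
    """Evidence table driving elimination for one search round."""

    entries: dict[str, DrugEvidence]
    weights: tuple[float, float, float] = (1.0, 2.0, 1.0)

    def detriment_score(self, drug: str) -> float:
        ev = self.entries[drug]
        w_int, w_tox, w_main = self.weights
        return (
            w_int * ev.total_detrimental_interactions
            + w_tox * float(ev.toxic_alone)
            + w_main * ev.detrimental_mains
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for drug, ev in sorted(self.entries.items()):
            rows.append(
                {
                    "drug": drug,
                    "monotherapy_effect": ev.monotherapy_effect,
                    "detrimental_interactions": ev.total_detrimental_interactions,
                    "beneficial_interactions": ev.total_beneficial_interactions,
                    "detrimental_mains": ev.detrimental_mains,
                    "beneficial_mains": ev.beneficial_mains,
                    "toxic_alone": ev.toxic_alone,
                    "detriment_score": self.detriment_score(drug),
                    "decision": ev.decision,
                    "reasons": ";".join(ev.reasons),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ODC:
    """A final optimized drug combination: drug -> dose (µM)."""

    doses_uM: dict[str, float]
    kind: str  # "synergistic" | "additive"
    cell_line: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.doses_uM) < 2:
            raise ValueError("an ODC requires at least 2 drugs")
        if any(d <= 0 for d in self.doses_uM.values()):
            raise ValueError("ODC doses must be positive")


@dataclass
class SearchRound:
    round: int
    active_drugs: list[str]
    doses_uM: dict[str, float]
    n_runs: int
    models: dict[str, RegressionModel]
    ledger: DrugLedger
    removed: list[str]
    label: str = "elimination"


@dataclass
class SearchState:
    """Trace of one per-cancer-line TGMO search."""

    cell_line: str
    rounds: list[SearchRound] = field(default_factory=list)
    odcs: list[ODC] = field(default_factory=list)
    status: str = "running"
    failure_reason: str = ""

    @property
    def active_drugs(self) -> list[str]:
        return self.rounds[-1].active_drugs if self.rounds else []

    def to_jsonable(self) -> dict:
        def model_summary(m: RegressionModel) -> dict:
            d = m.diagnostics
            return {
                "endpoint": m.endpoint,
                "terms": [
                    {
                        "label": m.space.label(t.key),
                        "beta": round(t.beta, 6),
                        "se": round(t.se, 6),
                        "p": round(t.p_value, 6),
                    }
                    for t in m.terms
                ],
                "removed_points": m.removed_points,
                "diagnostics": None
                if d is None
                else {k: (None if isinstance(v, float) and np.isnan(v) else v)
                      for k, v in asdict(d).items()},
            }

        return {
            "cell_line": self.cell_line,
            "status": self.status,
            "failure_reason": self.failure_reason,
            "rounds": [
                {
                    "round": r.round,
                    "label": r.label,
                    "active_drugs": r.active_drugs,
                    "doses_uM": r.doses_uM,
                    "n_runs": r.n_runs,
                    "removed": r.removed,
                    "ledger": r.ledger.to_frame().to_dict(orient="records"),
                    "models": {e: model_summary(m) for e, m in r.models.items()},
                }
                for r in self.rounds
            ],
            "odcs": [
                {
                    "kind": o.kind,
                    "cell_line": o.cell_line,
                    "doses_uM": o.doses_uM,
                    "provenance": o.provenance,
                }
                for o in self.odcs
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_jsonable(), indent=2, sort_keys=True, **kwargs)


def classify_terms(
    model: RegressionModel,
    alpha_sig: float = 0.05,
    interaction_floor: float = 0.0,
) -> list[TermClassification]:
    """Classify every non-intercept term of a fitted model.

    ``interaction_floor`` additionally requires |beta| of an *interaction*
    term to reach that many viability points before a non-neutral call
    (guards against the small positive cross-terms a Bliss-null surface
    induces in an additive polynomial fit; 0 disables it).
    """
    if model.endpoint not in (ENDPOINT_CANCER, ENDPOINT_TW):
        raise ValueError(f"unknown endpoint {model.endpoint!r}")
    out = []
    for term in model.terms:
        if term.kind == "intercept":
            continue
        below_floor = (
            term.kind == "interaction" and abs(term.beta) < interaction_floor
        )
        if not term.p_value < alpha_sig or below_floor:
            call = "neutral"
        elif model.endpoint == ENDPOINT_CANCER:
            call = "beneficial" if term.beta < 0 else "detrimental"
        else:
            call = "beneficial" if term.beta > 0 else "detrimental"
        out.append(TermClassification(term=term, endpoint=model.endpoint, call=call))
    return out


def _monotherapy_lookup(
    dataset: ScreenDataset, line: str, drug_index: int
) -> float | None:
    """Measured mean viability of the level-2 single-drug run, if present."""
    design = dataset.design
    target = np.zeros(design.k, dtype=int)
    target[drug_index] = 2
    matches = np.flatnonzero((design.runs == target).all(axis=1))
    if matches.size == 0:
        return None
    rid = design.run_ids[int(matches[0])]
    sub = dataset.records
    vals = sub.loc[
        (sub["run_id"] == rid) & (sub["cell_line"] == line), "viability_pct"
    ]
    return float(vals.mean()) if len(vals) else None


def build_drug_ledger(
    models: dict[str, RegressionModel],
    dataset: ScreenDataset,
    cancer_line: str,
    alpha_sig: float = 0.05,
    toxicity_threshold: float = TOXICITY_THRESHOLD_PCT,
    weights: tuple[float, float, float] = (1.0, 2.0, 1.0),
    interaction_floor: float = 0.0,
) -> DrugLedger:
    """Fold the round's models and monotherapy runs into per-drug evidence.

    Monotherapy effect and single-agent toxicity use the measured level-2
    single-drug run when the design contains one, falling back to the
    model prediction at that corner otherwise.
    """
    drugs = list(dataset.design.drug_order)
    entries = {d: DrugEvidence(drug=d) for d in drugs}
    for ev in entries.values():
        ev.detrimental_interactions = {e: 0 for e in models}
        ev.beneficial_interactions = {e: 0 for e in models}

    for endpoint, model in models.items():
        for cls in classify_terms(model, alpha_sig, interaction_floor):
            if cls.call == "neutral":
                continue
            kind, idx = cls.term.kind, cls.term.index
            if kind == "interaction":
                for i in idx:
                    tgt = (
                        entries[drugs[i]].detrimental_interactions
                        if cls.call == "detrimental"
                        else entries[drugs[i]].beneficial_interactions
                    )
                    tgt[endpoint] += 1
            elif kind == "linear":
                if cls.call == "detrimental":
                    entries[drugs[idx[0]]].detrimental_mains += 1
                else:
                    entries[drugs[idx[0]]].beneficial_mains += 1

    cancer_model = models.get(ENDPOINT_CANCER)
    tw_model = models.get(ENDPOINT_TW)
    for i, drug in enumerate(drugs):
        ev = entries[drug]
        measured = _monotherapy_lookup(dataset, cancer_line, i)
        if measured is not None:
            ev.monotherapy_effect = measured
            ev.monotherapy_source = "measured"
        elif cancer_model is not None:
            corner = np.zeros(len(drugs))
            corner[i] = 2
            ev.monotherapy_effect = float(cancer_model.predict(corner)[0])
            ev.monotherapy_source = "predicted"

        normal_v = _monotherapy_lookup(dataset, dataset.normal_line, i)
        if normal_v is None and cancer_model is not None and tw_model is not None:
            corner = np.zeros(len(drugs))
            corner[i] = 2
            normal_v = float(cancer_model.predict(corner)[0] + tw_model.predict(corner)[0])
        if normal_v is not None:
            ev.toxic_alone = flag_toxicity(max(normal_v, 0.0), toxicity_threshold)

    return DrugLedger(entries=entries, weights=weights)


def eliminate_drugs(
    ledger: DrugLedger, max_removals: int = 3
) -> tuple[list[str], DrugLedger]:
    """Remove up to ``max_removals`` drugs with positive detriment score.

    Ranking: higher detriment score first; ties broken by weaker
    single-agent effect (higher monotherapy viability removed first), then
    lexicographic drug name.  An empty removal set signals convergence.
    """
    if len(ledger.entries) < 3:
        raise ValueError("elimination requires at least 3 active drugs")
    scored = []
    for drug, ev in ledger.entries.items():
        score = ledger.detriment_score(drug)
        if score > 0:
            mono = ev.monotherapy_effect
            weak = mono if np.isfinite(mono) else 100.0
            scored.append((-score, -weak, drug))
    scored.sort()
    removed = [drug for _, _, drug in scored[:max_removals]]
    for drug in removed:
        ev = ledger.entries[drug]
        ev.decision = "eliminate"
        if ev.total_detrimental_interactions:
            ev.reasons.append(
                f"{ev.total_detrimental_interactions} detrimental interaction(s)"
            )
        if ev.toxic_alone:
            ev.reasons.append("toxic to the normal line as single agent")
        if ev.detrimental_mains:
            ev.reasons.append("counter-productive main effect")
    return removed, ledger


def refine_doses(
    specs: dict[str, DrugSpec], escalation: float = 2.0
) -> dict[str, DrugSpec]:
    """Escalate screen doses by ``escalation``, capped at the CUD."""
    out = {}
    for drug, spec in specs.items():
        out[drug] = DrugSpec(
            drug=drug,
            cud_uM=spec.cud_uM,
            screen_dose_uM=min(escalation * spec.screen_dose_uM, spec.cud_uM),
        )
    return out


def _fit_round_models(
    dataset: ScreenDataset,
    cancer_line: str,
    config: TgmoConfig,
) -> dict[str, RegressionModel]:
    """Stepwise + Cook's-filtered models for both endpoints of one line."""
    design = dataset.design
    X, space = build_model_matrix(design, config.replicates)
    cancer = dataset.line_matrix(cancer_line)
    normal = dataset.line_matrix(dataset.normal_line)
    y_cancer = cancer["viability_pct"].to_numpy()
    merged = cancer.merge(
        normal, on=["run_id", "replicate"], suffixes=("_cancer", "_normal")
    )
    if len(merged) != len(cancer):
        raise ValueError("cancer and normal lines have mismatched replicates")
    y_tw = compute_tw(
        merged["viability_pct_normal"].to_numpy(),
        merged["viability_pct_cancer"].to_numpy(),
    )
    models = {}
    for endpoint, y in ((ENDPOINT_CANCER, y_cancer), (ENDPOINT_TW, y_tw)):
        model = stepwise_fit(
            X,
            y,
            space,
            endpoint=endpoint,
            p_enter=config.p_enter,
            p_remove=config.p_remove,
            cell_line=cancer_line,
        )
        models[endpoint] = cooks_filter(model, X, y, config.cooks_rule)
    return models


def _beneficial_rank(ledger: DrugLedger) -> list[str]:
    """Drugs ordered by beneficial evidence (best first)."""
    def key(item):
        drug, ev = item
        mono = ev.monotherapy_effect if np.isfinite(ev.monotherapy_effect) else 100.0
        return (
            -ev.total_beneficial_interactions,
            -ev.beneficial_mains,
            mono,  # stronger single-agent kill (lower viability) first
            drug,
        )
    return [drug for drug, _ in sorted(ledger.entries.items(), key=key)]


def _select_odcs(
    models: dict[str, RegressionModel],
    ledger: DrugLedger,
    specs: dict[str, DrugSpec],
    cell_line: str,
    config: TgmoConfig,
    provenance: dict,
) -> list[ODC]:
    """Read the final combinations off the last round's evidence.

    Synergistic ODC: the union of significant beneficial interaction pairs
    between non-toxic drugs, pruned until no detrimental interaction
    remains *within* the emitted set.  Additive ODC (optional): non-toxic
    drugs with significant beneficial main effects whose pairwise
    interactions within the set are all neutral.  Drugs conflicting inside
    a set are dropped least-beneficial-first (fewer beneficial
    interactions, then weaker single-agent effect, then name).
    """
    odcs: list[ODC] = []
    nontoxic = {d for d, ev in ledger.entries.items() if not ev.toxic_alone}

    ben_pairs: set[tuple[str, str]] = set()
    det_pairs: set[tuple[str, str]] = set()
    for model in models.values():
        for cls in classify_terms(model, config.alpha_sig, config.interaction_floor):
            if cls.term.kind != "interaction" or cls.call == "neutral":
                continue
            i, j = cls.term.index
            pair = (drugs_at(model, i), drugs_at(model, j))
            (ben_pairs if cls.call == "beneficial" else det_pairs).add(pair)
    # A pair called both ways across endpoints is treated as detrimental.
    ben_pairs -= det_pairs

    def drop_order(drug: str) -> tuple:
        ev = ledger.entries[drug]
        mono = ev.monotherapy_effect if np.isfinite(ev.monotherapy_effect) else 100.0
        return (ev.total_beneficial_interactions, -mono, [drug])

    def prune_conflicts(members: set[str], conflicts: set[tuple[str, str]]) -> set[str]:
        members = set(members)
        while True:
            inside = [p for p in conflicts if p[0] in members and p[1] in members]
            if not inside:
                return members
            involved = {d for p in inside for d in p}
            members.discard(min(involved, key=drop_order))

    syn: set[str] = set()
    for a, b in ben_pairs:
        if a in nontoxic and b in nontoxic:
            syn.update((a, b))
    syn = prune_conflicts(syn, det_pairs)
    if len(syn) >= 2:
        odcs.append(
            ODC(
                doses_uM={d: specs[d].screen_dose_uM for d in sorted(syn)},
                kind="synergistic",
                cell_line=cell_line,
                provenance=provenance,
            )
        )

    if config.emit_additive:
        additive = {
            d for d in nontoxic if ledger.entries[d].beneficial_mains > 0
        }
        additive = prune_conflicts(additive, ben_pairs | det_pairs)
        if len(additive) >= 2 and additive != syn:
            odcs.append(
                ODC(
                    doses_uM={d: specs[d].screen_dose_uM for d in sorted(additive)},
                    kind="additive",
                    cell_line=cell_line,
                    provenance=provenance,
                )
            )
    return odcs


def drugs_at(model: RegressionModel, index: int) -> str:
    return model.space.drug_order[index]


def run_tgmo(
    truth_or_measure,
    specs: dict[str, DrugSpec],
    config: TgmoConfig | None = None,
    cancer_lines: list[str] | None = None,
) -> dict[str, SearchState]:
    """Run independent per-cancer-line searches to final ODCs.

    ``truth_or_measure`` is either a ``TruthParams`` (screens are simulated)
    or a ``MeasureFn`` callable producing a ScreenDataset per round.
    Returns a mapping cell line -> SearchState trace; reruns with the same
    seed and config are byte-identical (``SearchState.to_json``).
    """
    from .synthetic_screen import TruthParams, simulate_bliss  # cycle-free

    config = config or TgmoConfig()
    if isinstance(truth_or_measure, TruthParams):
        truth = truth_or_measure
        lines = cancer_lines or truth.cancer_lines

        def measure(design, conc, replicates, seed):
            return simulate_bliss(truth, design, conc, replicates, seed)

    else:
        measure = truth_or_measure
        if cancer_lines is None:
            raise ValueError("cancer_lines required with a measurement callable")
        lines = cancer_lines

    return {
        line: _run_single_search(measure, specs, line, i, config)
        for i, line in enumerate(lines)
    }


def _screen_round(
    measure: MeasureFn,
    active: list[str],
    specs: dict[str, DrugSpec],
    cancer_line: str,
    config: TgmoConfig,
    seed: int,
):
    design = augment_monotherapies(generate_oacd(active, seed=seed))
    conc = map_to_concentrations(design, specs)
    dataset = measure(design, conc, config.replicates, seed)
    models = _fit_round_models(dataset, cancer_line, config)
    ledger = build_drug_ledger(
        models,
        dataset,
        cancer_line,
        alpha_sig=config.alpha_sig,
        toxicity_threshold=config.toxicity_threshold,
        weights=config.detriment_weights,
        interaction_floor=config.interaction_floor,
    )
    return design, models, ledger


def _run_single_search(
    measure: MeasureFn,
    specs: dict[str, DrugSpec],
    cancer_line: str,
    line_index: int,
    config: TgmoConfig,
) -> SearchState:
    state = SearchState(cell_line=cancer_line)
    active = sorted(specs)
    round_no = 0

    while round_no < config.max_rounds:
        round_no += 1
        seed = int(
            np.random.SeedSequence([config.seed, line_index, round_no]).generate_state(1)[0]
            % 2**31
        )
        cur_specs = {d: specs[d] for d in active}
        design, models, ledger = _screen_round(
            measure, active, cur_specs, cancer_line, config, seed
        )
        if len(active) > config.final_size:
            removed, ledger = eliminate_drugs(ledger, config.max_removals)
        else:
            # At the final-round size, residual detrimental pairs are
            # resolved during ODC composition rather than by further
            # whole-drug elimination.
            removed = []
        state.rounds.append(
            SearchRound(
                round=round_no,
                active_drugs=list(active),
                doses_uM={d: cur_specs[d].screen_dose_uM for d in active},
                n_runs=design.n_runs,
                models=models,
                ledger=ledger,
                removed=removed,
            )
        )
        if removed:
            active = [d for d in active if d not in removed]
            if len(active) < 2:
                state.status = "failed"
                state.failure_reason = "fewer than 2 drugs survived elimination"
                return state
            continue

        # Converged: no drug carries positive detriment.
        any_beneficial = any(
            ev.total_beneficial_interactions + ev.beneficial_mains > 0
            for ev in ledger.entries.values()
        )
        if not any_beneficial:
            state.status = "failed"
            state.failure_reason = "no beneficial terms"
            return state
        if len(active) > config.final_size:
            keep = _beneficial_rank(ledger)[: config.final_size]
            dropped = sorted(set(active) - set(keep))
            for d in dropped:
                ledger.entries[d].decision = "eliminate"
                ledger.entries[d].reasons.append(
                    "not among the top beneficial drugs enrolled in the final round"
                )
            state.rounds[-1].removed = dropped
            active = sorted(keep)
            continue
        break
    else:
        state.status = "failed"
        state.failure_reason = f"no convergence within {config.max_rounds} rounds"
        return state

    # Final dose-refinement round at current and escalated doses.
    variants = {
        "current": {d: specs[d] for d in active},
        "escalated": refine_doses({d: specs[d] for d in active}, config.escalation),
    }
    results = {}
    for vi, (label, vspecs) in enumerate(variants.items()):
        seed = int(
            np.random.SeedSequence([config.seed, line_index, 1000 + vi]).generate_state(1)[0]
            % 2**31
        )
        design, models, ledger = _screen_round(
            measure, active, vspecs, cancer_line, config, seed
        )
        full_combo = np.full(len(active), 2)
        tw_pred = float(models[ENDPOINT_TW].predict(full_combo)[0])
        results[label] = (design, models, ledger, vspecs, tw_pred)
        state.rounds.append(
            SearchRound(
                round=round_no + 1 + vi,
                active_drugs=list(active),
                doses_uM={d: vspecs[d].screen_dose_uM for d in active},
                n_runs=design.n_runs,
                models=models,
                ledger=ledger,
                removed=[],
                label=f"final_{label}",
            )
        )

    best = max(results, key=lambda lab: results[lab][4])
    design, models, ledger, vspecs, _ = results[best]
    odcs = _select_odcs(
        models,
        ledger,
        vspecs,
        cancer_line,
        config,
        provenance={"variant": best, "round": len(state.rounds)},
    )
    state.odcs = odcs
    if odcs:
        state.status = "converged"
    else:
        state.status = "failed"
        state.failure_reason = "no beneficial terms"
    return state
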