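"""Synthetic combination-screen generator with planted ground truth.

Stands in for wet-lab plates: every downstream stage (normalization,
regression, drug elimination) is exercised against data whose true
single-agent curves, pairwise interactions and noise level are known.

The viability model is Bliss independence with a pairwise interaction
modifier on the log scale: for a run dosing drug i at concentration c_i,

    v_run = [ prod_i v_i(c_i) ] * exp( sum_{i<j} psi_ij * a_i * a_j )

where v_i(c) = 1 / (1 + (c / IC50_i)^h_i) is the fractional monotherapy
viability and a_i = 1 - v_i its activity.  psi_ij < 0 plants synergy
(viability below the Bliss product), psi_ij > 0 antagonism.  Scaling by the
activity product keeps the interaction bounded and smooth and vanishes when
either drug is absent; the second-order regression detects it with
sign(beta_ij) = sign(psi_ij) on the cancer-viability endpoint.

Measured values are 100 * v_run + Gaussian plate noise (sd in viability
points), truncated at 0 but not at 100 — ATP-luminescence readouts can
exceed the vehicle control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doe_design import DesignMatrix
from .dose_response import CLINICAL_DOSES_UM
from .plate_io import ScreenDataset
from .response_model import TermKey, TermSpace

__all__ = [
    "TruthParams",
    "simulate_bliss",
    "simulate_linear",
    "simulate_dose_response",
    "select_screen_doses",
    "make_screen_scenario",
    "DEFAULT_NOISE_SD",
]

#: Default plate-noise standard deviation, in viability points.  Chosen as a
#: realistic replicate scatter for ATP-luminescence screens run as N = 3
#: independent experiments.
DEFAULT_NOISE_SD: float = 5.0


@dataclass
class TruthParams:
    """Ground truth of a synthetic two-arm screen.

    ``hill[line][drug] = (ic50_uM, h)`` defines per-line monotherapy curves;
    ``psi[line]`` is the symmetric, zero-diagonal pairwise interaction matrix
    over ``drugs`` order (log-scale modifiers).  ``linear_truth_beta`` is an
    optional explicit coefficient set for the regression-family generator
    (`simulate_linear`).  ``roles`` records planted drug roles for scripted
    scenarios (documentation and tests, not used by the simulator itself).
    """

    drugs: list[str]
    cancer_lines: list[str]
    normal_line: str
    hill: dict[str, dict[str, tuple[float, float]]]
    psi: dict[str, np.ndarray]
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    linear_truth_beta: dict[TermKey, float] | None = None
    roles: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        k = len(self.drugs)
        for line, mat in self.psi.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (k, k):
                raise ValueError(f"psi[{line!r}] must be {k}x{k}")
            if not np.allclose(mat, mat.T):
                raise ValueError(f"psi[{line!r}] must be symmetric")
            if not np.allclose(np.diag(mat), 0.0):
                raise ValueError(f"psi[{line!r}] must have zero diagonal")
            self.psi[line] = mat
        for line in self.lines:
            for drug in self.drugs:
                ic50, h = self.hill[line][drug]
                if ic50 <= 0 or h <= 0:
                    raise ValueError(f"bad Hill parameters for {drug}/{line}")

    @property
    def lines(self) -> list[str]:
        return self.cancer_lines + [self.normal_line]

    def monotherapy_viability(self, line: str, drug: str, conc_uM) -> np.ndarray:
        ic50, h = self.hill[line][drug]
        c = np.asarray(conc_uM, dtype=float)
        with np.errstate(divide="ignore"):
            return 1.0 / (1.0 + (c / ic50) ** h)

    def expected_viability(self, line: str, conc_row: dict[str, float]) -> float:
        """Noise-free viability fraction of one combination on one line."""
        unknown = set(conc_row) - set(self.drugs)
        if unknown:
            raise KeyError(f"unknown drugs in concentration row: {sorted(unknown)}")
        v = np.array(
            [
                float(self.monotherapy_viability(line, d, conc_row.get(d, 0.0)))
                for d in self.drugs
            ]
        )
        a = 1.0 - v
        psi = self.psi[line]
        inter = 0.0
        k = len(self.drugs)
        for i in range(k):
            for j in range(i + 1, k):
                inter += psi[i, j] * a[i] * a[j]
        return float(np.prod(v) * np.exp(inter))


def simulate_bliss(
    truth: TruthParams,
    design: DesignMatrix,
    concentrations: pd.DataFrame,
    replicates: int = 3,
    seed: int = 0,
) -> ScreenDataset:
    """Simulate a full screen: every design run on every line, n replicates.

    ``concentrations`` is the run x drug µM table (index run_id, e.g. from
    ``map_to_concentrations``).  With ``noise_sd = 0`` the output is a pure
    function of truth and concentrations (bit-reproducible anywhere).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    unknown = set(concentrations.columns) - set(truth.drugs)
    if unknown:
        raise KeyError(f"concentrations for unknown drugs: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for line in truth.lines:
        for rid in design.run_ids:
            conc = concentrations.loc[rid].to_dict()
            mu = 100.0 * truth.expected_viability(line, conc)
            noise = (
                rng.normal(0.0, truth.noise_sd, size=replicates)
                if truth.noise_sd > 0
                else np.zeros(replicates)
            )
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "run_id": rid,
                        "cell_line": line,
                        "replicate": rep,
                        "viability_pct": max(0.0, mu + noise[rep - 1]),
                    }
                )
    return ScreenDataset(
        design=design,
        records=pd.DataFrame(rows),
        normal_line=truth.normal_line,
    )


def simulate_linear(
    truth: TruthParams,
    design: DesignMatrix,
    replicates: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Endpoint vector drawn exactly from the regression model family.

    y = X beta + Normal(0, noise_sd) on the centered second-order model
    matrix of the design — the oracle generator for selection/recovery
    tests, since the fitted family contains the truth.
    """
    if truth.linear_truth_beta is None:
        raise ValueError("truth has no linear_truth_beta coefficient set")
    space = TermSpace(
        drug_order=tuple(design.drug_order),
        means=tuple(design.runs.mean(axis=0)),
    )
    all_terms = space.terms
    k = design.k
    for kind, idx in truth.linear_truth_beta:
        if any(i >= k for i in idx):
            raise ValueError(f"beta term {(kind, idx)} references an absent drug")
        if (kind, idx) not in all_terms:
            raise ValueError(f"unknown term {(kind, idx)}")
    beta = np.zeros(len(all_terms))
    for key, value in truth.linear_truth_beta.items():
        beta[all_terms.index(key)] = value
    levels = np.repeat(design.runs, replicates, axis=0)
    y = space.expand(levels) @ beta
    if truth.noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, truth.noise_sd, size=len(y))
    return y


def simulate_dose_response(
    truth: TruthParams,
    drug: str,
    line: str,
    doses_uM: np.ndarray,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Monotherapy dose-response table (dose_uM, viability_pct) with noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for dose in np.asarray(doses_uM, dtype=float):
        mu = 100.0 * float(truth.monotherapy_viability(line, drug, dose))
        for _ in range(replicates):
            noise = rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
            rows.append({"dose_uM": dose, "viability_pct": max(0.0, mu + noise)})
    return pd.DataFrame(rows)


def select_screen_doses(
    truth: TruthParams,
    replicates: int = 3,
    seed: int = 0,
    f: float = 20.0,
    cud_uM: dict[str, float] | None = None,
):
    """Stage-one dose selection on simulated monotherapy data.

    For every drug, simulates a dose-response experiment on the first
    cancer line (8 log-spaced doses spanning well past the clinical dose —
    the clinical cap applies to dose *selection*, not to the in-vitro
    assay), fits the variable-slope curve, inverts it to the ICf (IC20 by
    default) and caps at the clinically used dose.  Returns a drug ->
    DrugSpec mapping ready for ``map_to_concentrations``/``run_tgmo``.
    """
    from .dose_response import build_drug_specs, fit_4pl

    line = truth.cancer_lines[0]
    if cud_uM is None:
        cud_uM = {
            d: CLINICAL_DOSES_UM.get(d, truth.hill[line][d][0])
            for d in truth.drugs
        }
    curves = {}
    for i, drug in enumerate(truth.drugs):
        cud = cud_uM[drug]
        doses = np.geomspace(cud / 50.0, 8.0 * cud, 8)
        df = simulate_dose_response(
            truth, drug, line, doses, replicates=replicates,
            seed=(seed * 1000 + i) % 2**31,
        )
        curves[drug] = fit_4pl(
            df["dose_uM"].to_numpy(),
            df["viability_pct"].to_numpy(),
            drug=drug,
            cell_line=line,
        )
    return build_drug_specs(curves, cud_uM, f=f)


def _ic50_for_target(dose_uM: float, viability_frac: float, h: float) -> float:
    """IC50 such that the curve passes through (dose, viability_frac)."""
    return dose_uM * (1.0 / viability_frac - 1.0) ** (-1.0 / h)


def make_screen_scenario(seed: int = 0, noise_sd: float = DEFAULT_NOISE_SD) -> TruthParams:
    """Scripted 10-drug truth for end-to-end recovery experiments.

    Two cancer lines and one non-malignant line, with planted roles:

    * ``aspirin``, ``axitinib`` — multiple strong antagonistic interactions
      (psi = +8) with other drugs in both cancer lines;
    * ``osimertinib`` — toxic to the normal line as a single agent
      (normal-line viability ~65% at its screen dose) plus one antagonism;
      these three carry the highest detriment and fall in round 1;
    * ``palbociclib``, ``selumetinib``, ``simvastatin`` — mutually
      antagonistic (psi = +8 within the trio), eliminated in round 2;
    * ``crizotinib`` + ``telaglenastat`` — the planted synergy pair
      (psi = -8 in both cancer lines, 0 in the normal line);
    * ``u104``, ``vismodegib`` — beneficial single agents with neutral
      interactions, completing the additive combination.

    Every drug's cancer-line IC50 equals twice its clinically used dose
    (Hill slope 2), so the computed IC20 equals the CUD and the selected
    screen dose sits at the clinical cap with ~80% monotherapy viability —
    single-agent activities of ~0.2 keep the planted interactions within
    the regression's detection range without saturating combination
    responses.  The normal line is insensitive (IC50 = 50x CUD) except for
    osimertinib.
    """
    drugs = sorted(CLINICAL_DOSES_UM)
    k = len(drugs)
    cancer_lines = ["786O_like", "UOK276_like"]
    normal = "RPTEC_like"
    h = 2.0

    hill: dict[str, dict[str, tuple[float, float]]] = {}
    for line in cancer_lines:
        hill[line] = {d: (2.0 * CLINICAL_DOSES_UM[d], h) for d in drugs}
    hill[normal] = {d: (50.0 * CLINICAL_DOSES_UM[d], h) for d in drugs}
    # Osimertinib singly toxic on the normal line: ~65% viability at its
    # screen dose (the CUD).
    osi_dose = CLINICAL_DOSES_UM["osimertinib"]
    hill[normal]["osimertinib"] = (_ic50_for_target(osi_dose, 0.65, h), h)

    def idx(d: str) -> int:
        return drugs.index(d)

    psi_cancer = np.zeros((k, k))
    antagonism, synergy = 8.0, -8.0
    round1_pairs = [
        ("aspirin", "crizotinib"),
        ("aspirin", "u104"),
        ("aspirin", "axitinib"),
        ("axitinib", "telaglenastat"),
        ("axitinib", "vismodegib"),
        ("osimertinib", "palbociclib"),
    ]
    round2_pairs = [
        ("palbociclib", "selumetinib"),
        ("palbociclib", "simvastatin"),
        ("selumetinib", "simvastatin"),
    ]
    for a, b in round1_pairs + round2_pairs:
        psi_cancer[idx(a), idx(b)] = psi_cancer[idx(b), idx(a)] = antagonism
    psi_cancer[idx("crizotinib"), idx("telaglenastat")] = synergy
    psi_cancer[idx("telaglenastat"), idx("crizotinib")] = synergy

    psi = {line: psi_cancer.copy() for line in cancer_lines}
    psi[normal] = np.zeros((k, k))

    return TruthParams(
        drugs=drugs,
        cancer_lines=cancer_lines,
        normal_line=normal,
        hill=hill,
        psi=psi,
        noise_sd=noise_sd,
        seed=seed,
        roles={
            "round1_detrimental": ["aspirin", "axitinib", "osimertinib"],
            "round2_detrimental": ["palbociclib", "selumetinib", "simvastatin"],
            "synergy_pair": ["crizotinib", "telaglenastat"],
            "additive": ["telaglenastat", "u104", "vismodegib"],
        },
    )


def truth_from_dict(spec: dict) -> TruthParams:
    """Build TruthParams from a plain (YAML-loadable) mapping.

    Schema: drugs (list), cancer_lines (list), normal_line (str),
    hill: {line: {drug: [ic50_uM, h]}}, psi: list of [drug_a, drug_b, value]
    (symmetry implied; per-line via {line: [...]} is also accepted),
    noise_sd (float), seed (int).
    """
    drugs = list(spec["drugs"])
    k = len(drugs)
    lines = list(spec["cancer_lines"]) + [spec["normal_line"]]
    hill = {
        line: {d: tuple(map(float, spec["hill"][line][d])) for d in drugs}
        for line in lines
    }
    raw_psi = spec.get("psi", {})
    if isinstance(raw_psi, list):
        raw_psi = {line: raw_psi for line in lines}
    psi = {}
    for line in lines:
        mat = np.zeros((k, k))
        for a, b, value in raw_psi.get(line, []):
            i, j = drugs.index(a), drugs.index(b)
            mat[i, j] = mat[j, i] = float(value)
        psi[line] = mat
    return TruthParams(
        drugs=drugs,
        cancer_lines=list(spec["cancer_lines"]),
        normal_line=spec["normal_line"],
        hill=hill,
        psi=psi,
        noise_sd=float(spec.get("noise_sd", DEFAULT_NOISE_SD)),
        seed=int(spec.get("seed", 0)),
    )
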