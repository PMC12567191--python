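"""Single-agent dose-response fitting, ICf inversion and screen-dose choice.

The inhibition model is the variable-slope logistic (four-parameter logistic
with asymptotes fixed at 100 and 0):

    v(c) = 100 / (1 + (c / IC50)^h)

fitted in log10-dose space.  Inversion to an arbitrary inhibition level f is
closed-form, IC_f = IC50 * (f / (100 - f))^(1/h).  Screen doses are the IC20
capped at the clinically used dose (CUD): when the curve is flat or the IC20
exceeds the CUD, the CUD is used instead, so no screened dose ever exceeds
clinical plasma exposure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseCurve",
    "DrugSpec",
    "CLINICAL_DOSES_UM",
    "hill_viability",
    "fit_4pl",
    "invert_to_icf",
    "select_screen_dose",
    "build_drug_specs",
]

logger = logging.getLogger(__name__)

#: Clinically used doses (µM) of the renal-screen drug panel, derived from
#: plasma AUC values (vismodegib from the median steady-state plasma
#: concentration).  These cap every screened dose.
CLINICAL_DOSES_UM: dict[str, float] = {
    "aspirin": 80.000,
    "axitinib": 0.029,
    "crizotinib": 0.664,
    "osimertinib": 0.469,
    "palbociclib": 0.264,
    "selumetinib": 0.296,
    "simvastatin": 0.005,
    "telaglenastat": 2.113,
    "u104": 9.524,
    "vismodegib": 17.000,
}


@dataclass
class DoseResponseCurve:
    """Fitted variable-slope inhibition curve for one drug on one line."""

    drug: str
    cell_line: str
    ic50_uM: float
    hill_slope: float
    r2: float
    flat_flag: bool = False

    def viability(self, conc_uM: float | np.ndarray) -> float | np.ndarray:
        if self.flat_flag:
            raise ValueError(
                f"curve for {self.drug}/{self.cell_line} is flat; "
                "its parameters must not be evaluated"
            )
        return hill_viability(conc_uM, self.ic50_uM, self.hill_slope)


@dataclass
class DrugSpec:
    """Doses chosen for one drug in a screen round.

    Level 2 of the coded design maps to ``screen_dose_uM``, level 1 to half
    of it.  The screen dose never exceeds the clinically used dose.
    """

    drug: str
    cud_uM: float
    screen_dose_uM: float

    def __post_init__(self) -> None:
        if self.cud_uM <= 0:
            raise ValueError(f"{self.drug}: CUD must be positive")
        if self.screen_dose_uM <= 0:
            raise ValueError(f"{self.drug}: screen dose must be positive")
        if self.screen_dose_uM > self.cud_uM * (1 + 1e-12):
            raise ValueError(
                f"{self.drug}: screen dose {self.screen_dose_uM} exceeds "
                f"CUD {self.cud_uM}"
            )

    @property
    def half_dose_uM(self) -> float:
        return self.screen_dose_uM / 2.0


def hill_viability(
    conc_uM: float | np.ndarray, ic50_uM: float, hill_slope: float
) -> float | np.ndarray:
    """Viability (% of control) of the variable-slope inhibition model."""
    c = np.asarray(conc_uM, dtype=float)
    with np.errstate(divide="ignore"):
        v = 100.0 / (1.0 + (c / ic50_uM) ** hill_slope)
    return float(v) if np.ndim(conc_uM) == 0 else v


def _logistic_log10(logc: np.ndarray, log_ic50: float, h: float) -> np.ndarray:
    return 100.0 / (1.0 + 10.0 ** (h * (logc - log_ic50)))


def fit_4pl(
    doses_uM,
    responses_pct,
    drug: str = "",
    cell_line: str = "",
    flat_r2: float = 0.5,
    flat_ic50_factor: float = 10.0,
) -> DoseResponseCurve:
    """Least-squares fit of the variable-slope curve in log10-dose space.

    Requires >= 4 distinct positive doses.  The fit is flagged flat —
    parameters unusable, screening falls back to the CUD — when R² of the
    fit drops below ``flat_r2`` or the estimated IC50 exceeds the largest
    tested dose by more than ``flat_ic50_factor``.  Non-convergence flags
    flat with a warning rather than returning a silent number.
    """
    doses = np.asarray(doses_uM, dtype=float)
    resp = np.asarray(responses_pct, dtype=float)
    if doses.shape != resp.shape:
        raise ValueError("doses and responses must have equal length")
    pos = doses > 0
    if len(np.unique(doses[pos])) < 4:
        raise ValueError("need at least 4 distinct positive doses to fit")
    logc = np.log10(doses[pos])
    y = resp[pos]

    flat = DoseResponseCurve(drug, cell_line, np.nan, np.nan, 0.0, flat_flag=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _logistic_log10,
                logc,
                y,
                p0=[float(np.median(logc)), 1.0],
                bounds=([-6.0, 0.1], [6.0, 10.0]),
                maxfev=10000,
            )
    except RuntimeError:
        logger.warning("dose-response fit for %s/%s did not converge", drug, cell_line)
        return flat

    log_ic50, h = popt
    fitted = _logistic_log10(logc, log_ic50, h)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    ic50 = 10.0 ** log_ic50

    if r2 < flat_r2 or ic50 > flat_ic50_factor * doses[pos].max():
        logger.info(
            "flat dose-response for %s/%s (r2=%.3f, ic50=%.3g µM)",
            drug, cell_line, r2, ic50,
        )
        flat.r2 = r2
        return flat
    return DoseResponseCurve(drug, cell_line, float(ic50), float(h), r2)


def invert_to_icf(curve: DoseResponseCurve, f: float) -> float:
    """Concentration producing f% inhibition (viability = 100 - f).

    Closed form: IC_f = IC50 * (f / (100 - f))^(1 / h).
    """
    if not 0 < f < 100:
        raise ValueError("inhibition level f must lie in (0, 100)")
    if curve.flat_flag:
        raise ValueError(
            f"curve for {curve.drug}/{curve.cell_line} is flat: no ICf exists; "
            "use the clinically used dose instead"
        )
    return float(curve.ic50_uM * (f / (100.0 - f)) ** (1.0 / curve.hill_slope))


def select_screen_dose(
    ic20_uM: float | None, cud_uM: float, flat_flag: bool = False
) -> float:
    """Screen dose: the IC20 capped at the clinically used dose.

    The CUD is used when the curve was flat or the IC20 exceeds it.
    """
    if cud_uM <= 0:
        raise ValueError("CUD must be positive")
    if flat_flag:
        return cud_uM
    if ic20_uM is None:
        raise ValueError("IC20 missing for a non-flat curve")
    return cud_uM if ic20_uM > cud_uM else float(ic20_uM)


def build_drug_specs(
    curves: dict[str, DoseResponseCurve],
    cud_uM: dict[str, float],
    f: float = 20.0,
) -> dict[str, DrugSpec]:
    """Apply ICf inversion and CUD capping across a drug panel.

    When a drug appears on several lines upstream, pass the curve whose line
    drives dosing (conventionally the most sensitive cancer line).
    """
    specs = {}
    for drug, cud in cud_uM.items():
        curve = curves.get(drug)
        if curve is None or curve.flat_flag:
            dose = select_screen_dose(None, cud, flat_flag=True)
        else:
            dose = select_screen_dose(invert_to_icf(curve, f), cud)
        specs[drug] = DrugSpec(drug=drug, cud_uM=cud, screen_dose_uM=dose)
    return specs
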