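"""Screen-plate I/O: vehicle normalization, replicate aggregation, toxicity.

Viability is expressed throughout as a percentage of the vehicle (DMSO)
control on the same plate: 100 means no measurable effect, 0 means complete
loss of the ATP-proxy signal.  Values above 100 are possible (luminescence
can exceed the control) and are kept.  Replicate-level rows are preserved
all the way to the regression stage — pre-averaging would discard the error
degrees of freedom that the stepwise p-values rely on.

CSV conventions: comma-separated, UTF-8, header row, decimal point; all
concentrations in µM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .doe_design import DesignMatrix

__all__ = [
    "NormalizationError",
    "ViabilityRecord",
    "ScreenDataset",
    "TOXICITY_THRESHOLD_PCT",
    "normalize_to_vehicle",
    "aggregate_replicates",
    "flag_toxicity",
    "read_viability_csv",
    "read_drug_table",
    "write_normalized_csv",
]

logger = logging.getLogger(__name__)

#: Single-agent / combination safety threshold on the non-malignant line:
#: a condition is called toxic when it pushes normal-cell viability below
#: 80% of the vehicle control.
TOXICITY_THRESHOLD_PCT: float = 80.0


class NormalizationError(ValueError):
    """Raised when a plate's vehicle wells cannot anchor the 100% level."""


@dataclass(frozen=True)
class ViabilityRecord:
    """One well-level measurement, already normalized to the vehicle."""

    run_id: str
    cell_line: str
    replicate: int
    viability_pct: float

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        if self.viability_pct < 0:
            raise ValueError("viability_pct must be non-negative")


@dataclass
class ScreenDataset:
    """A combination screen: a design plus its normalized measurements.

    ``records`` holds one row per (run, cell line, replicate).  The dataset
    spans at least one cancer line and exactly one non-malignant line
    (``normal_line``); the design's all-zero run is the vehicle anchor.
    """

    design: DesignMatrix
    records: pd.DataFrame
    normal_line: str
    vehicle_label: str = "vehicle"

    _REQUIRED = ("run_id", "cell_line", "replicate", "viability_pct")

    def __post_init__(self) -> None:
        missing = [c for c in self._REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")
        if (self.records["viability_pct"] < 0).any():
            raise ValueError("negative viability values in records")
        known = set(self.design.run_ids)
        unknown = set(self.records["run_id"]) - known
        if unknown:
            raise ValueError(f"records reference unknown runs: {sorted(unknown)}")
        lines = set(self.records["cell_line"])
        if self.normal_line not in lines:
            raise ValueError(f"normal line {self.normal_line!r} absent from records")

    @property
    def cancer_lines(self) -> list[str]:
        return sorted(set(self.records["cell_line"]) - {self.normal_line})

    def line_matrix(self, cell_line: str) -> pd.DataFrame:
        """Replicate-level viability for one line, rows ordered by design run.

        Returns a DataFrame with columns run_id, replicate, viability_pct in
        design-run order (replicates nested within run).
        """
        sub = self.records[self.records["cell_line"] == cell_line]
        order = {rid: i for i, rid in enumerate(self.design.run_ids)}
        sub = sub.sort_values(
            ["run_id", "replicate"],
            key=lambda s: s.map(order) if s.name == "run_id" else s,
            kind="stable",
        )
        return sub.reset_index(drop=True)

    def aggregate(self) -> pd.DataFrame:
        """Per (run, line) mean, sample sd and replicate count."""
        rows = []
        for (rid, line), grp in self.records.groupby(["run_id", "cell_line"]):
            mean, sd, n = aggregate_replicates(grp["viability_pct"].to_numpy())
            rows.append(
                {"run_id": rid, "cell_line": line, "mean": mean, "sd": sd, "n": n}
            )
        out = pd.DataFrame(rows)
        order = {rid: i for i, rid in enumerate(self.design.run_ids)}
        return (
            out.sort_values(["run_id", "cell_line"], key=lambda s: s.map(order) if s.name == "run_id" else s)
            .reset_index(drop=True)
        )


def normalize_to_vehicle(
    raw_signal: float | np.ndarray,
    vehicle_signals: Sequence[float] | np.ndarray,
    plate: str = "",
) -> float | np.ndarray:
    """Express a raw luminescence signal as % of the mean vehicle signal.

    The arithmetic mean of the vehicle wells anchors 100%, so the vehicle
    wells themselves average to exactly 100 after normalization.
    """
    vehicle = np.asarray(vehicle_signals, dtype=float)
    label = f" on plate {plate!r}" if plate else ""
    if vehicle.size == 0:
        raise NormalizationError(f"no vehicle wells{label}")
    vmean = float(vehicle.mean())
    if vmean <= 0:
        raise NormalizationError(f"vehicle mean signal is {vmean}{label}")
    result = 100.0 * np.asarray(raw_signal, dtype=float) / vmean
    if np.ndim(raw_signal) == 0:
        return float(result)
    return result


def aggregate_replicates(
    values: Iterable[float],
) -> tuple[float, float, int]:
    """Mean, sample standard deviation (n-1) and count of replicate values.

    A single replicate yields ``sd = nan`` (reported missing) with a logged
    warning; an empty collection is an error.
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    n = int(arr.size)
    if n == 0:
        raise ValueError("cannot aggregate zero replicates")
    mean = float(arr.mean())
    if n == 1:
        logger.warning("single replicate: standard deviation unavailable")
        return mean, math.nan, 1
    return mean, float(arr.std(ddof=1)), n


def flag_toxicity(
    viability_pct_normal: float,
    threshold: float = TOXICITY_THRESHOLD_PCT,
    strict: bool = True,
) -> bool:
    """True when normal-line viability falls below the toxicity threshold.

    The boundary itself is non-toxic under the default strict-< convention
    (set ``strict=False`` for <=).
    """
    if viability_pct_normal < 0:
        raise ValueError("viability must be non-negative")
    if strict:
        return viability_pct_normal < threshold
    return viability_pct_normal <= threshold


def read_viability_csv(
    path,
    design: DesignMatrix,
    normal_line: str,
    vehicle_label: str = "vehicle",
) -> ScreenDataset:
    """Load a tidy viability table.

    Accepts either a ``viability_pct`` column (already normalized) or a raw
    ``signal`` column, in which case each (cell_line, replicate) plate is
    normalized to its own vehicle run (the design's all-zero run).
    """
    df = pd.read_csv(path)
    if "viability_pct" not in df.columns:
        if "signal" not in df.columns:
            raise ValueError("need a 'viability_pct' or 'signal' column")
        vehicle_run = design.vehicle_run_id
        parts = []
        for (line, rep), grp in df.groupby(["cell_line", "replicate"]):
            vehicle = grp.loc[grp["run_id"] == vehicle_run, "signal"].to_numpy()
            out = grp.copy()
            out["viability_pct"] = normalize_to_vehicle(
                grp["signal"].to_numpy(), vehicle, plate=f"{line}/rep{rep}"
            )
            parts.append(out)
        df = pd.concat(parts, ignore_index=True)
    return ScreenDataset(
        design=design,
        records=df[["run_id", "cell_line", "replicate", "viability_pct"]],
        normal_line=normal_line,
        vehicle_label=vehicle_label,
    )


def read_drug_table(path) -> pd.DataFrame:
    """Load the drug table: columns drug, cud_uM and optionally screen_dose_uM."""
    df = pd.read_csv(path)
    required = {"drug", "cud_uM"}
    if not required <= set(df.columns):
        raise ValueError(f"drug table must contain columns {sorted(required)}")
    if (df["cud_uM"] <= 0).any():
        raise ValueError("clinically used doses must be positive")
    return df


def write_normalized_csv(dataset: ScreenDataset, path) -> None:
    """Write per-run per-line mean/sd/n to ``screen_normalized.csv`` format."""
    dataset.aggregate().to_csv(path, index=False)
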