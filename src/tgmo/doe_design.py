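"""Orthogonal array composite designs (OACD) for multidrug screens.

An OACD concatenates three blocks:

1. a regular two-level fraction at coded levels {0, 2} with resolution >= IV
   (full factorial when k <= 4),
2. k columns of a standard three-level orthogonal array at levels {0, 1, 2}
   (full 3^k for k <= 3, OA(18, 3^7) for k <= 7, OA(27, 3^13) for k <= 13),
3. a single all-zero center (vehicle control) run.

Coded levels map to concentrations as 0 = drug absent, 1 = half the screen
dose, 2 = the screen dose.  The composite supports a full second-order
(quadratic + pairwise interaction) response-surface model in far fewer runs
than a full factorial: the two-level block carries the interaction
information, the three-level block the curvature.

Minimal resolution-IV fractions leave two-factor interactions aliased in
pairs that a 27-run three-level block cannot always disambiguate, so the
constructor escalates the fraction deterministically — generators are
odd-size subsets of the basic factors chosen to maximise aliasing word
length, and the basic-factor count grows until the full quadratic model
matrix reaches full column rank.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignMatrix",
    "DesignDiagnostics",
    "generate_oacd",
    "validate_design",
    "map_to_concentrations",
    "augment_monotherapies",
]

# Taguchi L18 array, three-level columns only (column 1 of the canonical
# L18(2^1 3^7) is dropped).  Each level appears 6 times per column and all
# column pairs are orthogonal.
_L18 = np.array(
    [
        [0, 0, 0, 0, 0, 0, 0],
        [0, 1, 1, 1, 1, 1, 1],
        [0, 2, 2, 2, 2, 2, 2],
        [1, 0, 0, 1, 1, 2, 2],
        [1, 1, 1, 2, 2, 0, 0],
        [1, 2, 2, 0, 0, 1, 1],
        [2, 0, 1, 0, 2, 1, 2],
        [2, 1, 2, 1, 0, 2, 0],
        [2, 2, 0, 2, 1, 0, 1],
        [0, 0, 2, 2, 1, 1, 0],
        [0, 1, 0, 0, 2, 2, 1],
        [0, 2, 1, 1, 0, 0, 2],
        [1, 0, 1, 2, 0, 2, 1],
        [1, 1, 2, 0, 1, 0, 2],
        [1, 2, 0, 1, 2, 1, 0],
        [2, 0, 2, 1, 2, 0, 1],
        [2, 1, 0, 2, 0, 1, 2],
        [2, 2, 1, 0, 1, 2, 0],
    ],
    dtype=int,
)


def _l27_13() -> np.ndarray:
    """OA(27, 3^13): all 13 GF(3) linear forms in three index digits."""
    rows = []
    for a, b, c in itertools.product(range(3), repeat=3):
        rows.append(
            [
                a,
                b,
                (a + b) % 3,
                (a + 2 * b) % 3,
                c,
                (a + c) % 3,
                (a + 2 * c) % 3,
                (b + c) % 3,
                (b + 2 * c) % 3,
                (a + b + c) % 3,
                (a + b + 2 * c) % 3,
                (a + 2 * b + c) % 3,
                (a + 2 * b + 2 * c) % 3,
            ]
        )
    return np.array(rows, dtype=int)


def _three_level_block(k: int) -> np.ndarray:
    if k <= 3:
        return np.array(list(itertools.product(range(3), repeat=k)), dtype=int)
    if k <= 7:
        return _L18[:, :k].copy()
    if k <= 13:
        return _l27_13()[:, :k]
    raise ValueError(f"no standard three-level orthogonal array for k={k}")


def _pick_generators(q: int, n_add: int) -> list[tuple[int, ...]] | None:
    """Choose added-factor generators among odd-size subsets of the q basic
    factors, greedily maximising the minimum symmetric difference to those
    already chosen.

    Odd subset sizes keep every word of the defining contrast subgroup of
    even length (a fold-over design, hence resolution >= IV); large symmetric
    differences lengthen the words further.
    """
    candidates: list[tuple[int, ...]] = []
    top = q if q % 2 else q - 1
    for size in range(top, 2, -2):
        candidates.extend(itertools.combinations(range(q), size))
    if n_add > len(candidates):
        return None
    chosen: list[tuple[int, ...]] = []
    for _ in range(n_add):
        best, best_score = None, -1
        for cand in candidates:
            if cand in chosen:
                continue
            score = min(
                (len(set(cand) ^ set(other)) for other in chosen),
                default=q + 1,
            )
            if score > best_score:
                best, best_score = cand, score
        chosen.append(best)  # type: ignore[arg-type]
    return chosen


def _two_level_fraction(k: int, q: int) -> np.ndarray | None:
    """Regular 2^(k-(k-q)) fraction at +-1 coding, resolution >= IV."""
    base = np.array(list(itertools.product([-1, 1], repeat=q)), dtype=int)
    if k == q:
        return base
    gens = _pick_generators(q, k - q)
    if gens is None:
        return None
    cols = [base[:, i] for i in range(q)]
    for subset in gens:
        cols.append(np.prod(base[:, list(subset)], axis=1))
    return np.column_stack(cols)


def _second_order_matrix(levels: np.ndarray) -> np.ndarray:
    """Full quadratic model matrix on centered coded levels.

    Columns: intercept, x_i (centered), x_i^2, x_i * x_j (i < j), with the
    squares and products formed from the centered predictors.
    """
    n, k = levels.shape
    xc = levels - levels.mean(axis=0)
    cols = [np.ones(n)]
    cols.extend(xc[:, i] for i in range(k))
    cols.extend(xc[:, i] ** 2 for i in range(k))
    for i in range(k):
        for j in range(i + 1, k):
            cols.append(xc[:, i] * xc[:, j])
    return np.column_stack(cols)


@dataclass
class DesignMatrix:
    """Coded-level run table of an OACD screen.

    Attributes
    ----------
    runs : (n, k) int array with entries in {0, 1, 2}
    block : per-run label in {"two_level", "three_level", "center"}
    drug_order : the k drug labels, fixing column order everywhere downstream
    multiplicity : how many times each kept run occurred across blocks before
        duplicate collapse (first occurrence kept)
    """

    runs: np.ndarray
    block: list[str]
    drug_order: list[str]
    multiplicity: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.runs = np.asarray(self.runs, dtype=int)
        if self.runs.ndim != 2:
            raise ValueError("runs must be a 2-D array")
        if not np.isin(self.runs, [0, 1, 2]).all():
            raise ValueError("coded levels must be in {0, 1, 2}")
        if len(self.block) != self.n_runs:
            raise ValueError("block labels must match the number of runs")
        if not (self.runs == 0).all(axis=1).any():
            raise ValueError("design must contain an all-zero (vehicle) run")
        if not self.multiplicity:
            self.multiplicity = [1] * self.n_runs

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def k(self) -> int:
        return self.runs.shape[1]

    @property
    def run_ids(self) -> list[str]:
        return [f"R{i + 1:03d}" for i in range(self.n_runs)]

    @property
    def vehicle_run_id(self) -> str:
        idx = int(np.flatnonzero((self.runs == 0).all(axis=1))[0])
        return self.run_ids[idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.runs, columns=self.drug_order)
        df.insert(0, "run_id", self.run_ids)
        df.insert(1, "block", self.block)
        return df

    def subset(self, drugs: list[str]) -> "DesignMatrix":
        """Restrict to the given drugs (columns); rows are kept as-is."""
        idx = [self.drug_order.index(d) for d in drugs]
        return DesignMatrix(
            runs=self.runs[:, idx],
            block=list(self.block),
            drug_order=list(drugs),
            multiplicity=list(self.multiplicity),
        )


@dataclass
class DesignDiagnostics:
    rank_ok: bool
    rank: int
    n_params: int
    balance: pd.DataFrame
    max_pairwise_corr: float
    d_efficiency: float


def generate_oacd(drugs: list[str] | int, seed: int = 0) -> DesignMatrix:
    """Construct the orthogonal array composite design for 2..13 drugs.

    Parameters
    ----------
    drugs : drug labels (or a count k, which yields labels ``drug_01`` ...)
    seed : permutes the run order reproducibly; the run *set* is a pure
        function of k.

    The two-level fraction starts at the smallest regular resolution-IV
    fraction and is escalated (more basic factors, up to the full factorial)
    until the full second-order model matrix of the composite reaches full
    column rank — the estimability guarantee the regression stage relies on.
    """
    if isinstance(drugs, int):
        drugs = [f"drug_{i + 1:02d}" for i in range(drugs)]
    k = len(drugs)
    if not 2 <= k <= 13:
        raise ValueError(f"OACD supports 2 to 13 drugs, got k={k}")

    three = _three_level_block(k)
    n_params = 1 + 2 * k + k * (k - 1) // 2

    chosen = None
    for q in range(min(k, 4), k + 1):
        frac = _two_level_fraction(k, q)
        if frac is None:
            continue
        two = np.where(frac > 0, 2, 0)
        stacked = np.vstack([two, three, np.zeros((1, k), dtype=int)])
        uniq = np.unique(stacked, axis=0)
        if np.linalg.matrix_rank(_second_order_matrix(uniq)) == n_params:
            chosen = two
            break
    if chosen is None:  # pragma: no cover - escalation ends at full factorial
        raise RuntimeError(
            f"no resolution-IV fraction up to the full 2^{k} factorial yields "
            "an estimable second-order model"
        )

    rows: list[np.ndarray] = []
    blocks: list[str] = []
    mult: dict[tuple[int, ...], int] = {}
    for block_rows, label in (
        (chosen, "two_level"),
        (three, "three_level"),
        (np.zeros((1, k), dtype=int), "center"),
    ):
        for row in block_rows:
            key = tuple(int(v) for v in row)
            if key in mult:
                mult[key] += 1
            else:
                mult[key] = 1
                rows.append(np.asarray(row))
                blocks.append(label)

    runs = np.array(rows, dtype=int)
    multiplicity = [mult[tuple(r)] for r in runs]

    order = np.random.default_rng(seed).permutation(len(runs))
    return DesignMatrix(
        runs=runs[order],
        block=[blocks[i] for i in order],
        drug_order=list(drugs),
        multiplicity=[multiplicity[i] for i in order],
    )


def augment_monotherapies(design: DesignMatrix) -> DesignMatrix:
    """Append any missing single-drug runs at level 2.

    Monotherapy runs anchor the per-drug evidence ledger (measured
    single-agent effect and single-agent toxicity).  They are rows of the
    full two-level factorial, so they keep the ``two_level`` block label.
    """
    existing = {tuple(r) for r in design.runs}
    new_rows, new_blocks = [], []
    for i in range(design.k):
        row = np.zeros(design.k, dtype=int)
        row[i] = 2
        if tuple(row) not in existing:
            new_rows.append(row)
            new_blocks.append("two_level")
    if not new_rows:
        return design
    return DesignMatrix(
        runs=np.vstack([design.runs, np.array(new_rows)]),
        block=list(design.block) + new_blocks,
        drug_order=list(design.drug_order),
        multiplicity=list(design.multiplicity) + [1] * len(new_rows),
    )


def validate_design(
    design: DesignMatrix, model_order: str = "full_quadratic"
) -> DesignDiagnostics:
    """Rank, balance, collinearity and D-efficiency diagnostics.

    ``rank_ok`` is True iff the model matrix for ``model_order`` (``linear``
    or ``full_quadratic``) has full column rank.  Balance counts levels per
    drug within the three-level block.  D-efficiency is
    ``det(X'X)^(1/p) / n`` on the column-standardized model matrix.
    """
    if design.n_runs == 0:
        raise ValueError("design is empty")
    if model_order == "full_quadratic":
        X = _second_order_matrix(design.runs)
    elif model_order == "linear":
        xc = design.runs - design.runs.mean(axis=0)
        X = np.column_stack([np.ones(design.n_runs), xc])
    else:
        raise ValueError(f"unknown model order: {model_order!r}")

    p = X.shape[1]
    rank = int(np.linalg.matrix_rank(X))

    three_mask = np.array([b == "three_level" for b in design.block])
    counts = {}
    for j, drug in enumerate(design.drug_order):
        col = design.runs[three_mask, j]
        counts[drug] = [int((col == lev).sum()) for lev in (0, 1, 2)]
    balance = pd.DataFrame(counts, index=["level_0", "level_1", "level_2"]).T

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X[:, 1:], rowvar=False)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    off = off[np.isfinite(off)]  # constant columns yield undefined correlations
    max_corr = float(np.max(np.abs(off))) if off.size else 0.0

    norms = np.linalg.norm(X, axis=0)
    Xs = X / np.where(norms == 0, 1.0, norms) * np.sqrt(X.shape[0])
    sign, logdet = np.linalg.slogdet(Xs.T @ Xs)
    d_eff = float(np.exp(logdet / p) / X.shape[0]) if sign > 0 else 0.0

    return DesignDiagnostics(
        rank_ok=rank == p,
        rank=rank,
        n_params=p,
        balance=balance,
        max_pairwise_corr=max_corr,
        d_efficiency=d_eff,
    )


def map_to_concentrations(design: DesignMatrix, specs: dict) -> pd.DataFrame:
    """Translate coded levels to concentrations (µM) per run and drug.

    ``specs`` maps drug label -> DrugSpec (level 1 = half dose, level 2 =
    screen dose).  Returns a DataFrame indexed by run_id.
    """
    missing = [d for d in design.drug_order if d not in specs]
    if missing:
        raise KeyError(f"no dose specification for drugs: {', '.join(missing)}")
    cols = {}
    for j, drug in enumerate(design.drug_order):
        spec = specs[drug]
        lookup = np.array([0.0, spec.half_dose_uM, spec.screen_dose_uM])
        cols[drug] = lookup[design.runs[:, j]]
    return pd.DataFrame(cols, index=pd.Index(design.run_ids, name="run_id"))
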