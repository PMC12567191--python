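"""Second-order stepwise response-surface regression on screen endpoints.

Two endpoints are modelled per cancer line:

* cancer-cell viability (% of vehicle control) — lower is better;
* the therapeutic window TW = viability(normal) - viability(cancer), in
  percentage points — higher is better (selectivity toward the tumour).

The model over the coded drug levels x in {0, 1, 2}^k is the full quadratic
response surface

    y = b0 + sum_i bi x_i + sum_i bii x_i^2 + sum_{i<j} bij x_i x_j + e,

with predictors centered (not standardized) before squares and products are
formed.  Terms are chosen by bidirectional p-value stepwise selection
(partial-F entry at 0.05, removal at 0.10, no hierarchy enforcement), the
convention of the numerical environments this class of screen analysis is
usually scripted in.  Model reliability is assessed by Cook's-distance
outlier elimination followed by a single refit, R²/adjusted R², RMSE, the
overall-model ANOVA F-test and the fitted-observed correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .doe_design import DesignMatrix

__all__ = [
    "TermKey",
    "TermSpace",
    "ModelTerm",
    "ModelDiagnostics",
    "RegressionModel",
    "compute_tw",
    "build_model_matrix",
    "stepwise_fit",
    "cooks_filter",
    "cooks_distances",
    "model_diagnostics",
]

logger = logging.getLogger(__name__)

# A term is identified by its kind and drug index/indices:
#   ("intercept", ()), ("linear", (i,)), ("quadratic", (i,)),
#   ("interaction", (i, j)) with i < j.
TermKey = tuple[str, tuple[int, ...]]


@dataclass(frozen=True)
class TermSpace:
    """The full second-order term basis over a fixed drug ordering.

    Stores the per-drug centering constants so any coded-level vector can be
    expanded into a model-matrix row consistent with the fit.
    """

    drug_order: tuple[str, ...]
    means: tuple[float, ...]

    @property
    def k(self) -> int:
        return len(self.drug_order)

    @property
    def terms(self) -> list[TermKey]:
        k = self.k
        out: list[TermKey] = [("intercept", ())]
        out += [("linear", (i,)) for i in range(k)]
        out += [("quadratic", (i,)) for i in range(k)]
        out += [("interaction", (i, j)) for i in range(k) for j in range(i + 1, k)]
        return out

    def expand(self, levels: np.ndarray) -> np.ndarray:
        """Model matrix rows for coded levels (n, k): intercept, centered
        x_i, centered-x_i squares, centered cross-products."""
        levels = np.atleast_2d(np.asarray(levels, dtype=float))
        if levels.shape[1] != self.k:
            raise ValueError("levels have wrong number of drugs")
        xc = levels - np.asarray(self.means)
        n = levels.shape[0]
        cols = [np.ones(n)]
        cols.extend(xc[:, i] for i in range(self.k))
        cols.extend(xc[:, i] ** 2 for i in range(self.k))
        for i in range(self.k):
            for j in range(i + 1, self.k):
                cols.append(xc[:, i] * xc[:, j])
        return np.column_stack(cols)

    def label(self, term: TermKey) -> str:
        kind, idx = term
        if kind == "intercept":
            return "(intercept)"
        if kind == "linear":
            return self.drug_order[idx[0]]
        if kind == "quadratic":
            return f"{self.drug_order[idx[0]]}^2"
        return f"{self.drug_order[idx[0]]}:{self.drug_order[idx[1]]}"


@dataclass
class ModelTerm:
    """One selected regression term with its inference."""

    kind: str
    index: tuple[int, ...]
    beta: float
    se: float
    p_value: float

    def __post_init__(self) -> None:
        if self.kind == "interaction" and not self.index[0] < self.index[1]:
            raise ValueError("interaction indices must satisfy i < j")

    @property
    def key(self) -> TermKey:
        return (self.kind, self.index)


@dataclass
class ModelDiagnostics:
    r2: float
    adj_r2: float
    rmse: float
    anova_p: float
    fitted_observed_r: float
    df_resid: int
    available: bool = True


@dataclass
class RegressionModel:
    """A fitted second-order model for one endpoint on one cell line."""

    endpoint: str
    terms: list[ModelTerm]
    space: TermSpace
    diagnostics: ModelDiagnostics | None = None
    removed_points: list[tuple[int, float]] = field(default_factory=list)
    cell_line: str = ""

    def __post_init__(self) -> None:
        keys = [t.key for t in self.terms]
        if ("intercept", ()) not in keys:
            raise ValueError("model must contain an intercept")
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate model terms")

    @property
    def term_keys(self) -> list[TermKey]:
        return [t.key for t in self.terms]

    def get(self, kind: str, index: tuple[int, ...]) -> ModelTerm | None:
        for t in self.terms:
            if t.kind == kind and t.index == index:
                return t
        return None

    def predict(self, levels: np.ndarray) -> np.ndarray:
        """Predicted endpoint at coded-level vectors (n, k)."""
        full = self.space.expand(levels)
        all_terms = self.space.terms
        cols = [all_terms.index(t.key) for t in self.terms]
        beta = np.array([t.beta for t in self.terms])
        return full[:, cols] @ beta


def compute_tw(
    viability_normal: float | np.ndarray, viability_cancer: float | np.ndarray
) -> float | np.ndarray:
    """Therapeutic window: normal-line minus cancer-line viability.

    Positive values mean the condition spares the non-malignant cells more
    than the cancer cells (selectivity).  Antisymmetric in its arguments.
    """
    result = np.asarray(viability_normal, dtype=float) - np.asarray(
        viability_cancer, dtype=float
    )
    if np.ndim(viability_normal) == 0 and np.ndim(viability_cancer) == 0:
        return float(result)
    return result


def build_model_matrix(
    design: DesignMatrix, replicates: int = 1
) -> tuple[np.ndarray, TermSpace]:
    """Full second-order model matrix with rows repeated per replicate.

    Row order matches ``ScreenDataset.line_matrix``: design-run order with
    replicates nested within run.  Column count is 1 + 2k + k(k-1)/2.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    space = TermSpace(
        drug_order=tuple(design.drug_order),
        means=tuple(design.runs.mean(axis=0)),
    )
    levels = np.repeat(design.runs, replicates, axis=0)
    X = space.expand(levels)
    p = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        logger.warning(
            "model matrix is rank deficient (rank %d < %d columns); "
            "stepwise selection will skip collinear terms", rank, p,
        )
    return X, space


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS fit: returns (beta, se, p, rss, df_resid)."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    if df > 0:
        sigma2 = rss / df
        cov = sigma2 * np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, np.inf)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    else:
        se = np.full(p, np.nan)
        pvals = np.full(p, np.nan)
    return beta, se, pvals, rss, df


def stepwise_fit(
    X: np.ndarray,
    y: np.ndarray,
    space: TermSpace,
    endpoint: str = "cancer_viability",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    forced: list[TermKey] | None = None,
    cell_line: str = "",
    max_steps: int = 200,
) -> RegressionModel:
    """Bidirectional p-value stepwise selection with OLS refits.

    Starts from the intercept-only model; at each step the candidate term
    with the smallest partial-F p-value below ``p_enter`` enters, then any
    included term whose coefficient p-value exceeds ``p_remove`` is dropped
    (worst first).  Forced terms are never dropped.  Perfectly collinear
    candidates are skipped with a log message.  Returns the final term set
    with standard errors and p-values from the last OLS refit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p_all = X.shape
    if len(y) != n:
        raise ValueError("X and y have incompatible shapes")
    all_terms = space.terms
    if p_all != len(all_terms):
        raise ValueError("X does not match the term space")

    included = [0]
    for key in forced or []:
        j = all_terms.index(key)
        if j not in included:
            included.append(j)
    protected = set(included)
    candidates = [j for j in range(p_all) if j not in included]

    col_norm2 = np.einsum("ij,ij->j", X, X)
    visited: set[frozenset] = set()
    entered_any = False

    for _ in range(max_steps):
        state = frozenset(included)
        if state in visited:
            break  # selection cycle: accept current model
        visited.add(state)
        changed = False

        # Forward scan via partial F on the residualized candidate.
        Q, _ = np.linalg.qr(X[:, included])
        r = y - Q @ (Q.T @ y)
        rss_old = float(r @ r)
        df_new = n - len(included) - 1
        perfect_fit = rss_old <= 1e-16 * (float(y @ y) + 1e-30)
        if df_new > 0 and candidates and not perfect_fit:
            best_j, best_p = None, np.inf
            for j in candidates:
                xj = X[:, j]
                z = xj - Q @ (Q.T @ xj)
                z2 = float(z @ z)
                if z2 <= 1e-10 * max(col_norm2[j], 1.0):
                    continue  # collinear with current model
                delta = float(z @ r) ** 2 / z2
                rss_new = max(rss_old - delta, 0.0)
                if rss_new <= 0:
                    pval = 0.0
                else:
                    F = delta / (rss_new / df_new)
                    pval = float(stats.f.sf(F, 1, df_new))
                if pval < best_p:
                    best_j, best_p = j, pval
            if best_j is not None and best_p < p_enter:
                included.append(best_j)
                candidates.remove(best_j)
                changed = True
                entered_any = True

        # Backward scan on the refit p-values.
        _, _, pvals, _, df = _ols(X[:, included], y)
        if df > 0:
            removable = [
                (pv, j)
                for pv, j in zip(pvals, included)
                if j not in protected and pv > p_remove
            ]
            if removable:
                _, worst = max(removable)
                included.remove(worst)
                candidates.append(worst)
                changed = True

        if not changed:
            break

    if not entered_any and len(included) == len(protected):
        logger.warning("stepwise selection: no term entered (%s)", endpoint)

    beta, se, pvals, _, _ = _ols(X[:, included], y)
    order = sorted(range(len(included)), key=lambda i: included[i])
    terms = [
        ModelTerm(
            kind=all_terms[included[i]][0],
            index=all_terms[included[i]][1],
            beta=float(beta[i]),
            se=float(se[i]),
            p_value=float(pvals[i]) if not math.isnan(pvals[i]) else 1.0,
        )
        for i in order
    ]
    model = RegressionModel(
        endpoint=endpoint, terms=terms, space=space, cell_line=cell_line
    )
    model.diagnostics = model_diagnostics(model, X, y)
    return model


def _selected_columns(model: RegressionModel, X: np.ndarray) -> np.ndarray:
    all_terms = model.space.terms
    cols = [all_terms.index(t.key) for t in model.terms]
    return X[:, cols]


def cooks_distances(Xs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cook's distance per observation for an OLS fit of y on Xs."""
    n, p = Xs.shape
    beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
    resid = y - Xs @ beta
    df = n - p
    if df <= 0:
        return np.zeros(n)
    s2 = float(resid @ resid) / df
    H = Xs @ np.linalg.pinv(Xs.T @ Xs) @ Xs.T
    h = np.clip(np.diag(H), 0.0, 1.0 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        D = resid**2 * h / (p * s2 * (1.0 - h) ** 2)
    return np.where(np.isfinite(D), D, 0.0)


def cooks_filter(
    model: RegressionModel,
    X: np.ndarray,
    y: np.ndarray,
    threshold_rule: str = "3xmean",
) -> RegressionModel:
    """Single-pass Cook's-distance outlier removal and one refit.

    Rows with D above the rule — ``"3xmean"`` (default): D > 3 * mean(D);
    ``"4/n"``: the classic D > 4/n — are dropped and the *same* term set is
    refitted once.  If removal would leave fewer rows than coefficients the
    original fit is kept with a warning.  Removed row indices and their
    Cook's distances are recorded on the returned model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Xs = _selected_columns(model, X)
    n, p = Xs.shape
    if n < p + 2:
        logger.warning("too few rows for influence analysis; model kept as-is")
        return model
    D = cooks_distances(Xs, y)
    if threshold_rule == "3xmean":
        cut = 3.0 * float(D.mean()) if D.mean() > 0 else np.inf
    elif threshold_rule == "4/n":
        cut = 4.0 / n
    else:
        raise ValueError(f"unknown threshold rule: {threshold_rule!r}")
    drop = np.flatnonzero(D > cut)
    if drop.size == 0:
        return model
    keep = np.setdiff1d(np.arange(n), drop)
    if keep.size < p + 1:
        logger.warning(
            "Cook's filtering would leave %d rows for %d coefficients; "
            "removal aborted", keep.size, p,
        )
        return model

    beta, se, pvals, _, _ = _ols(Xs[keep], y[keep])
    terms = [
        ModelTerm(
            kind=t.kind,
            index=t.index,
            beta=float(beta[i]),
            se=float(se[i]),
            p_value=float(pvals[i]) if not math.isnan(pvals[i]) else 1.0,
        )
        for i, t in enumerate(model.terms)
    ]
    refit = RegressionModel(
        endpoint=model.endpoint,
        terms=terms,
        space=model.space,
        removed_points=[(int(i), float(D[i])) for i in drop],
        cell_line=model.cell_line,
    )
    refit.diagnostics = model_diagnostics(refit, X[keep], y[keep])
    return refit


def model_diagnostics(
    model: RegressionModel, X: np.ndarray, y: np.ndarray
) -> ModelDiagnostics:
    """R², adjusted R², RMSE, overall-model ANOVA p and fitted-observed r.

    Computed for the model's selected terms on the given rows (post-removal
    rows when called after Cook's filtering).  With zero residual degrees of
    freedom the diagnostics are flagged unavailable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Xs = _selected_columns(model, X)
    n, p = Xs.shape
    beta = np.array([t.beta for t in model.terms])
    fitted = Xs @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    df = n - p
    if df <= 0:
        return ModelDiagnostics(
            r2=np.nan, adj_r2=np.nan, rmse=np.nan, anova_p=np.nan,
            fitted_observed_r=np.nan, df_resid=0, available=False,
        )
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df
    rmse = math.sqrt(rss / df)
    if p > 1 and tss > rss > 0:
        F = ((tss - rss) / (p - 1)) / (rss / df)
        anova_p = float(stats.f.sf(F, p - 1, df))
    elif p > 1 and rss == 0:
        anova_p = 0.0
    else:
        anova_p = np.nan
    if np.std(fitted) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(fitted, y)[0, 1])
    else:
        r = np.nan
    return ModelDiagnostics(
        r2=float(np.clip(r2, 0.0, 1.0)),
        adj_r2=float(adj_r2),
        rmse=rmse,
        anova_p=anova_p,
        fitted_observed_r=r,
        df_resid=df,
    )
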