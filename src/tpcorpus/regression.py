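"""Stepwise trend regression with collinearity screening.

The time-course question — do certain transitional probabilities drift
over a composer's career? — is asked by regressing the piece serial
number (publication order, 1..N) on the universal-pattern probabilities.
Predictors enter by forward stepwise selection (smallest partial p-value
below ``p_enter``), are removed backward when their p-value exceeds
``p_remove``, and the adopted model is the one on the path with the most
predictors among those passing the multicollinearity screens
VIF < ``vif_limit`` and condition index < ``ci_limit``.

Conventions
-----------
* Standardized coefficients: ``beta_j = B_j * sd(x_j) / sd(y)`` with
  sample standard deviations.
* VIF_j = 1 / (1 - R^2_j) from regressing column j on the remaining
  columns plus an intercept; exactly 1 for a single predictor.
* Condition indices follow the SPSS collinearity-diagnostics convention:
  append the intercept column, scale every column to unit Euclidean norm
  (uncentered), and divide the largest singular value by each singular
  value.

:class:`ProbabilityTrendModel` wraps the procedure in a model object
whose :meth:`~ProbabilityTrendModel.fit` returns
:class:`TrendResults` carrying the stepwise path, the adopted model and
a printable summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .corpus import CorpusMatrix
from .markov import IntervalPattern

__all__ = [
    "FittedModel",
    "StepwiseResult",
    "StepwiseSettings",
    "SingularDesignError",
    "ScreenedOutError",
    "fit_ols",
    "vif",
    "condition_indices",
    "stepwise",
    "select_final",
    "ProbabilityTrendModel",
    "TrendResults",
]


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is exactly collinear."""


class ScreenedOutError(ValueError):
    """No model on the stepwise path passes the collinearity screens."""


@dataclass
class StepwiseSettings:
    p_enter: float = 0.05
    p_remove: float = 0.10
    vif_limit: float = 2.0
    ci_limit: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.p_enter <= self.p_remove < 1:
            raise ValueError("require 0 < p_enter <= p_remove < 1")


@dataclass
class FittedModel:
    """One ordinary-least-squares fit with its collinearity diagnostics.

    ``B``, ``SE``, ``beta``, ``p_values`` and ``VIF`` are aligned with
    ``predictors``; ``CI`` holds the condition indices of the scaled
    design (intercept included), ascending.
    """

    predictors: list[str]
    intercept: float
    B: list[float]
    SE: list[float]
    beta: list[float]
    p_values: list[float]
    VIF: list[float]
    CI: list[float]
    R2: float
    adj_R2: float
    F: float
    F_df: tuple[int, int]
    F_p: float
    n_obs: int

    @property
    def k(self) -> int:
        return len(self.predictors)

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table in the conventional report layout."""
        return pd.DataFrame(
            {
                "Variable": self.predictors,
                "B": self.B,
                "SE B": self.SE,
                "beta": self.beta,
                "p": self.p_values,
                "VIF": self.VIF,
                "CI": [max(self.CI)] * self.k if self.k else [],
            }
        )


def adj_r2_from_f(F: float, k: int, df_resid: int) -> float:
    """Adjusted R^2 implied by an F statistic with (k, df_resid) degrees of
    freedom, via R^2 = kF / (kF + df_resid)."""
    r2 = k * F / (k * F + df_resid)
    n = k + df_resid + 1
    return 1 - (1 - r2) * (n - 1) / (n - k - 1)


def vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factors, one per column of ``X``.

    Exact collinearity yields ``inf`` for the affected columns rather
    than an exception.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with at least one column")
    k = X.shape[1]
    if k == 1:
        return np.array([1.0])
    out = np.empty(k)
    for j in range(k):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def condition_indices(X: np.ndarray) -> np.ndarray:
    """Condition indices of the unit-scaled design including the intercept.

    Returns k+1 values sorted ascending; the smallest is 1 by definition.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with at least one column")
    A = np.column_stack([np.ones(X.shape[0]), X])
    norms = np.linalg.norm(A, axis=0)
    if np.any(norms == 0):
        raise ValueError("degenerate design: zero column")
    s = np.linalg.svd(A / norms, compute_uv=False)
    s = np.where(s <= 0, np.finfo(float).tiny, s)
    return np.sort(s.max() / s)


def fit_ols(
    X: np.ndarray, y: np.ndarray, names: Sequence[str] | None = None
) -> FittedModel:
    """OLS with intercept, standardized coefficients and collinearity
    diagnostics."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and len(y) > 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 observations (n={n}, k={k})")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < k + 1:
        raise SingularDesignError("design matrix is exactly collinear")
    res = sm.OLS(y, design).fit()
    sd_x = X.std(axis=0, ddof=1)
    sd_y = y.std(ddof=1)
    betas = res.params[1:] * sd_x / sd_y
    return FittedModel(
        predictors=list(names) if names is not None else [f"x{j}" for j in range(k)],
        intercept=float(res.params[0]),
        B=[float(b) for b in res.params[1:]],
        SE=[float(s) for s in res.bse[1:]],
        beta=[float(b) for b in betas],
        p_values=[float(p) for p in res.pvalues[1:]],
        VIF=[float(v) for v in vif(X)],
        CI=[float(c) for c in condition_indices(X)],
        R2=float(res.rsquared),
        adj_R2=float(res.rsquared_adj),
        F=float(res.fvalue),
        F_df=(k, n - k - 1),
        F_p=float(res.f_pvalue),
        n_obs=n,
    )


def _null_model(y: np.ndarray) -> FittedModel:
    """Intercept-only model, used when no candidate enters."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    return FittedModel(
        predictors=[],
        intercept=float(y.mean()),
        B=[],
        SE=[],
        beta=[],
        p_values=[],
        VIF=[],
        CI=[1.0],
        R2=0.0,
        adj_R2=0.0,
        F=0.0,
        F_df=(0, n - 1),
        F_p=1.0,
        n_obs=n,
    )


@dataclass
class StepwiseResult:
    """The stepwise path: one fitted model per accepted add/remove step."""

    path: list[FittedModel]
    final: FittedModel
    settings: StepwiseSettings = field(default_factory=StepwiseSettings)


def _sort_key(name: str):
    try:
        return IntervalPattern.from_string(name).offsets
    except (ValueError, TypeError):
        return name


def stepwise(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    settings: StepwiseSettings | None = None,
    names: Sequence[str] | None = None,
) -> StepwiseResult:
    """Forward stepwise selection with backward removal.

    At each step the candidate with the smallest partial p-value enters
    if that p-value is below ``p_enter`` (ties broken toward the
    lexicographically smaller pattern); then any included predictor whose
    p-value exceeds ``p_remove`` is removed, worst first.  Every accepted
    model is recorded on the path.  When no candidate ever enters, the
    path is empty and the final model is intercept-only.
    """
    settings = settings or StepwiseSettings()
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, ncand = X.shape
    if n < 4:
        raise ValueError("stepwise selection needs at least 4 observations")
    if ncand < 1:
        raise ValueError("at least one candidate column is required")
    if names is None:
        names = [f"x{j}" for j in range(ncand)]
    cols = {name: X[:, j] for j, name in enumerate(names)}

    included: list[str] = []
    path: list[FittedModel] = []
    while True:
        changed = False
        candidates = [c for c in names if c not in included]
        if n < len(included) + 3:  # adding one more would leave n <= k + 1
            candidates = []
        best_name, best_p = None, np.inf
        for c in sorted(candidates, key=_sort_key):
            trial = np.column_stack([cols[v] for v in included + [c]])
            try:
                model = fit_ols(trial, y, names=included + [c])
            except SingularDesignError:
                continue
            p = model.p_values[-1]
            if p < best_p:  # strict: ties keep the earlier (lex-smaller) name
                best_name, best_p = c, p
        if best_name is not None and best_p < settings.p_enter:
            included.append(best_name)
            path.append(
                fit_ols(
                    np.column_stack([cols[v] for v in included]), y, names=included
                )
            )
            changed = True
        while included:
            model = fit_ols(
                np.column_stack([cols[v] for v in included]), y, names=included
            )
            worst = int(np.argmax(model.p_values))
            if model.p_values[worst] > settings.p_remove:
                included.pop(worst)
                if included:
                    path.append(
                        fit_ols(
                            np.column_stack([cols[v] for v in included]),
                            y,
                            names=included,
                        )
                    )
                else:
                    path.append(_null_model(y))
                changed = True
            else:
                break
        if not changed:
            break
    final = path[-1] if path else _null_model(y)
    return StepwiseResult(path=path, final=final, settings=settings)


def select_final(
    result: StepwiseResult,
    vif_limit: float = 2.0,
    ci_limit: float = 20.0,
) -> FittedModel:
    """Adopt the path model with the most predictors among those passing
    the collinearity screens (ties broken by higher R^2).

    Raises :class:`ScreenedOutError`, naming the violated criterion, when
    no path model passes.
    """
    if not result.path:
        raise ValueError("stepwise path is empty; nothing to select")
    passing = [
        m
        for m in result.path
        if all(v < vif_limit for v in m.VIF) and all(c < ci_limit for c in m.CI)
    ]
    if not passing:
        worst = result.path[-1]
        if any(v >= vif_limit for v in worst.VIF):
            raise ScreenedOutError(f"every path model violates VIF < {vif_limit}")
        raise ScreenedOutError(f"every path model violates CI < {ci_limit}")
    return max(passing, key=lambda m: (m.k, m.R2))


class ProbabilityTrendModel:
    """Trend model: piece serial number regressed on universal-pattern
    transitional probabilities.

    Parameters
    ----------
    matrix:
        A :class:`~tpcorpus.corpus.CorpusMatrix` (or an equivalent
        DataFrame via :meth:`from_dataframe`) of pieces x patterns.
    y:
        Regressand; defaults to the matrix's piece serial numbers.
    """

    def __init__(self, matrix: CorpusMatrix, y: Sequence[float] | None = None):
        self.matrix = matrix
        self.endog = np.asarray(
            matrix.piece_index if y is None else y, dtype=float
        )
        self.exog = matrix.to_frame()

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, y: Sequence[float] | None = None
    ) -> "ProbabilityTrendModel":
        """Build from a DataFrame indexed by piece serial number with
        pattern-string columns."""
        return cls(CorpusMatrix.from_frame(df), y=y)

    def fit(self, settings: StepwiseSettings | None = None) -> "TrendResults":
        settings = settings or StepwiseSettings()
        result = stepwise(self.exog, self.endog, settings=settings)
        if result.path:
            try:
                final = select_final(
                    result, vif_limit=settings.vif_limit, ci_limit=settings.ci_limit
                )
            except ScreenedOutError:
                final = _null_model(self.endog)
        else:
            final = result.final
        return TrendResults(model=self, stepwise_result=result, final=final)


@dataclass
class TrendResults:
    """Results of a fitted :class:`ProbabilityTrendModel`."""

    model: ProbabilityTrendModel
    stepwise_result: StepwiseResult
    final: FittedModel

    @property
    def path(self) -> list[FittedModel]:
        return self.stepwise_result.path

    @property
    def selected(self) -> list[str]:
        return list(self.final.predictors)

    def summary(self) -> str:
        """Plain-text summary of the adopted model and its path."""
        m = self.final
        lines = [
            f"Markov order {self.model.matrix.order}: "
            f"{self.model.matrix.values.shape[1]} universal patterns, "
            f"n = {m.n_obs} pieces",
            f"Stepwise path: {len(self.path)} accepted step(s)",
        ]
        if m.k == 0:
            lines.append("No significant regression model (intercept-only).")
            return "\n".join(lines)
        lines.append(
            f"Adopted model: {m.k} predictor(s), "
            f"R2 = {m.R2:.3f}, adj R2 = {m.adj_R2:.3f}, "
            f"F({m.F_df[0]},{m.F_df[1]}) = {m.F:.2f}, p = {m.F_p:.4g}"
        )
        lines.append(f"Intercept: {m.intercept:.3f}")
        table = m.to_frame()
        lines.append(
            table.to_string(
                index=False,
                formatters={
                    "B": "{:.3f}".format,
                    "SE B": "{:.3f}".format,
                    "beta": "{:.3f}".format,
                    "p": "{:.4f}".format,
                    "VIF": "{:.2f}".format,
                    "CI": "{:.2f}".format,
                },
            )
        )
        return "\n".join(lines)

    def to_report_csv(self, path: str | Path) -> None:
        """Coefficient table plus model-level rows, mirroring the
        conventional stepwise report layout."""
        table = self.final.to_frame()
        with open(path, "w", newline="") as fh:
            table.to_csv(fh, index=False)
            fh.write(f"R2,{self.final.R2:.6g}\n")
            fh.write(f"adj_R2,{self.final.adj_R2:.6g}\n")
            fh.write(
                f"F,{self.final.F:.6g},df,{self.final.F_df[0]},{self.final.F_df[1]}\n"
            )
            fh.write(f"F_p,{self.final.F_p:.6g}\n")

    def to_json(self, path: str | Path | None = None) -> str:
        """Machine-readable report of the full stepwise path."""
        def model_dict(m: FittedModel) -> dict:
            return {
                "predictors": m.predictors,
                "intercept": m.intercept,
                "B": m.B,
                "SE": m.SE,
                "beta": m.beta,
                "p_values": m.p_values,
                "VIF": m.VIF,
                "condition_indices": m.CI,
                "R2": m.R2,
                "adj_R2": m.adj_R2,
                "F": m.F,
                "F_df": list(m.F_df),
                "F_p": m.F_p,
                "n_obs": m.n_obs,
            }

        payload = json.dumps(
            {
                "order": self.model.matrix.order,
                "settings": vars(self.stepwise_result.settings),
                "path": [model_dict(m) for m in self.path],
                "final": model_dict(self.final),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload
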