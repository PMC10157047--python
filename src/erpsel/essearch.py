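"""Exhaustive best-subset regression with leave-one-out cross-validation.

Every nonempty subset of the candidate predictors is fitted by OLS and
scored by the mean absolute error of its leave-one-out predictions (CVE).
Models are ranked by ascending CVE, and the top-K are summarized as a weight
diagram: a models x variables grid of standardized partial regression
coefficients with per-variable selection counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

MAX_VARIABLES = 20


class SingularFitError(RuntimeError):
    """Raised when the design matrix of a requested fit is rank deficient."""


def enumerate_subsets(n_vars: int) -> list[int]:
    """All 2**n - 1 nonempty predictor subsets as bitmasks, ascending."""
    if not 1 <= n_vars <= MAX_VARIABLES:
        raise ValueError(f"n_vars must be in [1, {MAX_VARIABLES}], got {n_vars}")
    return list(range(1, 2**n_vars))


def subset_indices(mask: int) -> np.ndarray:
    """Column indices included in a bitmask subset."""
    if mask <= 0:
        raise ValueError("subset mask must be a positive integer")
    return np.flatnonzero([(mask >> j) & 1 for j in range(mask.bit_length())])


def subset_size(mask: int) -> int:
    return int(mask).bit_count()


@dataclass
class PredictorMatrix:
    """Response vector and candidate predictor columns for one electrode."""

    y: np.ndarray
    X: np.ndarray
    names: list[str]
    electrode: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if len(self.y) != n:
            raise ValueError("y and X row counts differ")
        if len(self.names) != p:
            raise ValueError("names do not match X columns")
        if np.isnan(self.y).any() or np.isnan(self.X).any():
            raise ValueError("missing values in predictor matrix")
        constant = [self.names[j] for j in range(p) if np.ptp(self.X[:, j]) == 0]
        if constant:
            raise ValueError(f"constant predictor column(s): {constant}")
        if n <= p + 1:
            raise ValueError(
                f"need n > {p + 1} rows to fit the largest subset, got n={n}"
            )

    @classmethod
    def from_features(
        cls,
        features: pd.DataFrame,
        electrode: str,
        trait_col: str = "satq",
        columns: Sequence[str] | None = None,
    ) -> "PredictorMatrix":
        if columns is None:
            columns = [
                c for c in features.columns if c.startswith(f"{electrode}_")
            ]
        return cls(
            y=features[trait_col].to_numpy(float),
            X=features[list(columns)].to_numpy(float),
            names=list(columns),
            electrode=electrode,
        )

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_vars(self) -> int:
        return self.X.shape[1]


@dataclass
class OLSFit:
    """Full-sample OLS summary for one subset."""

    mask: int
    names: list[str]
    coef: np.ndarray  # unstandardized B per included variable
    stderr: np.ndarray
    pvalues: np.ndarray
    betas: np.ndarray  # standardized coefficients
    intercept: float
    r_squared: float
    adj_r_squared: float
    f_stat: float
    f_pvalue: float
    df_model: int
    df_resid: int


def fit_ols(data: PredictorMatrix, mask: int) -> OLSFit:
    """OLS with intercept on the included columns (statsmodels backend)."""
    idx = subset_indices(mask)
    Xs = data.X[:, idx]
    design = sm.add_constant(Xs, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = [data.names[j] for j in idx]
        raise SingularFitError(f"rank-deficient design for columns {bad}")
    res = sm.OLS(data.y, design).fit()
    coef = res.params[1:]
    betas = standardized_betas(coef, data, idx)
    return OLSFit(
        mask=mask,
        names=[data.names[j] for j in idx],
        coef=coef,
        stderr=res.bse[1:],
        pvalues=res.pvalues[1:],
        betas=betas,
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
    )


def standardized_betas(
    coef: np.ndarray, data: PredictorMatrix, idx: np.ndarray
) -> np.ndarray:
    """beta_j = B_j * sd(x_j) / sd(y), with sample (ddof=1) SDs."""
    sy = data.y.std(ddof=1)
    if sy == 0:
        raise ValueError("response has zero variance")
    sx = data.X[:, idx].std(axis=0, ddof=1)
    if np.any(sx == 0):
        raise ValueError("zero-variance predictor column")
    return np.asarray(coef) * sx / sy


def loocv_mae(data: PredictorMatrix, mask: int) -> tuple[float, np.ndarray]:
    """CVE of one subset: mean |leave-one-out prediction error| over n folds.

    Uses the exact hat-matrix identity e_i / (1 - h_ii) for the held-out
    residual of an OLS refit without row i; algebraically identical to
    refitting each of the n folds (the test suite checks this against a
    naive per-fold refit).  Returns (CVE, per-fold absolute errors).
    Rank-deficient designs or leverage-one rows make the model invalid:
    (nan, empty array) is returned and the event logged.
    """
    idx = subset_indices(mask)
    n = data.n
    k = len(idx)
    if n - 1 < k + 1:
        raise ValueError(f"LOOCV needs n - 1 >= k + 1 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), data.X[:, idx]])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        logger.warning("subset %d: singular design, CVE invalid", mask)
        return float("nan"), np.empty(0)
    coef, *_ = np.linalg.lstsq(design, data.y, rcond=None)
    resid = data.y - design @ coef
    q, _ = np.linalg.qr(design)
    leverage = np.einsum("ij,ij->i", q, q)
    if np.any(1.0 - leverage < 1e-10):
        logger.warning("subset %d: leverage-one row, CVE invalid", mask)
        return float("nan"), np.empty(0)
    fold_errors = np.abs(resid / (1.0 - leverage))
    return float(fold_errors.mean()), fold_errors


def evaluate_all_subsets(data: PredictorMatrix) -> pd.DataFrame:
    """Fit and cross-validate every nonempty subset.

    Returns one row per model: bitmask, included variables, size, CVE and the
    full-sample fit statistics.  Invalid (singular) models carry NaN CVE and
    valid=False.
    """
    rows = []
    for mask in enumerate_subsets(data.n_vars):
        cve, _ = loocv_mae(data, mask)
        try:
            fit = fit_ols(data, mask)
        except SingularFitError:
            rows.append(
                {
                    "mask": mask,
                    "variables": "+".join(data.names[j] for j in subset_indices(mask)),
                    "k": subset_size(mask),
                    "cve": float("nan"),
                    "r_squared": float("nan"),
                    "adj_r_squared": float("nan"),
                    "f_stat": float("nan"),
                    "f_pvalue": float("nan"),
                    "valid": False,
                }
            )
            continue
        rows.append(
            {
                "mask": mask,
                "variables": "+".join(fit.names),
                "k": subset_size(mask),
                "cve": cve,
                "r_squared": fit.r_squared,
                "adj_r_squared": fit.adj_r_squared,
                "f_stat": fit.f_stat,
                "f_pvalue": fit.f_pvalue,
                "valid": bool(np.isfinite(cve)),
            }
        )
    return pd.DataFrame(rows)


def rank_models(table: pd.DataFrame, top_k: int = 50) -> pd.DataFrame:
    """Valid models sorted by ascending CVE; ties favour smaller subsets.

    Tie-break: fewer predictors first, then ascending bitmask.  Requests for
    more models than are valid are truncated with a warning.
    """
    valid = table[table["valid"]].copy()
    if top_k > len(valid):
        logger.warning("top_k=%d exceeds %d valid models; truncating", top_k, len(valid))
        top_k = len(valid)
    ordered = valid.sort_values(
        ["cve", "k", "mask"], kind="mergesort"
    ).reset_index(drop=True)
    return ordered.head(top_k)


def selection_frequency(masks: Sequence[int], n_vars: int) -> np.ndarray:
    """Per-variable count of top-K models that include it."""
    if len(masks) == 0:
        raise ValueError("no models supplied")
    counts = np.zeros(n_vars, dtype=int)
    for mask in masks:
        for j in subset_indices(mask):
            counts[j] += 1
    return counts


@dataclass
class WeightDiagram:
    """Top-K models x variables grid of standardized coefficients.

    ``betas[i, j]`` is NaN exactly where model i excludes variable j (the
    "absent" marker, rendered white when plotted).
    """

    names: list[str]
    masks: list[int]
    cves: np.ndarray
    betas: np.ndarray  # K x N, NaN = absent
    selection_counts: np.ndarray

    @property
    def k(self) -> int:
        return len(self.masks)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.betas, columns=self.names)
        frame.insert(0, "mask", self.masks)
        frame.insert(1, "cve", self.cves)
        return frame

    def to_json(self) -> str:
        return json.dumps(
            {
                "names": self.names,
                "masks": [int(m) for m in self.masks],
                "cves": self.cves.tolist(),
                "betas": [
                    [None if np.isnan(b) else b for b in row] for row in self.betas
                ],
                "selection_counts": self.selection_counts.tolist(),
            }
        )


def build_weight_diagram(
    top_models: pd.DataFrame,
    fits: Mapping[int, OLSFit],
    names: Sequence[str],
) -> WeightDiagram:
    """Assemble the weight diagram from ranked models and their fits."""
    masks = [int(m) for m in top_models["mask"]]
    n_vars = len(names)
    betas = np.full((len(masks), n_vars), np.nan)
    for i, mask in enumerate(masks):
        fit = fits.get(mask)
        if fit is None:
            raise RuntimeError(f"no fit available for model mask {mask}")
        betas[i, subset_indices(mask)] = fit.betas
    return WeightDiagram(
        names=list(names),
        masks=masks,
        cves=top_models["cve"].to_numpy(float),
        betas=betas,
        selection_counts=selection_frequency(masks, n_vars),
    )


def single_variable_regression(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized coefficient of y on one predictor (= Pearson correlation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input")
    slope = np.cov(x, y, ddof=1)[0, 1] / sx**2
    return float(slope * sx / sy)


@dataclass
class ElectrodeReport:
    """All subset-search outputs for one electrode."""

    electrode: str
    data: PredictorMatrix
    table: pd.DataFrame
    top_models: pd.DataFrame
    diagram: WeightDiagram
    best_fit: OLSFit
    single_variable_betas: dict[str, float] = field(default_factory=dict)


def run_electrode(
    features: pd.DataFrame,
    electrode: str,
    trait_col: str = "satq",
    top_k: int = 50,
) -> ElectrodeReport:
    """Full subset search for one electrode's feature table."""
    data = PredictorMatrix.from_features(features, electrode, trait_col)
    table = evaluate_all_subsets(data)
    top = rank_models(table, top_k)
    fits = {int(mask): fit_ols(data, int(mask)) for mask in top["mask"]}
    diagram = build_weight_diagram(top, fits, data.names)
    best_fit = fits[int(top["mask"].iloc[0])]
    singles = {
        name: single_variable_regression(data.X[:, j], data.y)
        for j, name in enumerate(data.names)
    }
    return ElectrodeReport(
        electrode=electrode,
        data=data,
        table=table,
        top_models=top,
        diagram=diagram,
        best_fit=best_fit,
        single_variable_betas=singles,
    )
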