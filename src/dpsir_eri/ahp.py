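"""Analytic-hierarchy-process weighting with consistency control.

Expert judgments on the 1–9 Saaty scale are averaged per element, turned
into a positive reciprocal pairwise-comparison matrix of score ratios
C_ij = s_i / s_j, and reduced to a priority weight vector by the
row-geometric-mean method:

    M_i = prod_j C_ij            (row products)
    V_i = M_i^(1/n) / sum_j M_j^(1/n)

Judgment quality is screened by Saaty's consistency machinery: the
principal eigenvalue lambda_max of the matrix satisfies lambda_max >= n,
with equality exactly when the matrix is consistent; the consistency index
CI = (lambda_max - n)/(n - 1) is compared against the expected CI of random
reciprocal matrices of the same size (the random index RI), and the
judgment set is accepted when the consistency ratio CR = CI/RI does not
exceed a tolerance of 0.1.

Ratio-constructed matrices are consistent by construction, so they always
pass the gate with CR = 0; the gate matters for matrices entered directly
from pairwise judgments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpertPanel",
    "ScoreVector",
    "ComparisonMatrix",
    "AhpDerivation",
    "WeightVector",
    "ConsistencyReport",
    "mean_scores",
    "ratio_matrix",
    "row_products",
    "weights_from_products",
    "lambda_max",
    "lambda_max_saaty",
    "consistency_index",
    "random_index",
    "consistency_ratio",
    "overall_consistency_ratio",
    "check_consistency",
    "derive_weights",
    "ahp_weights",
    "RI_LARGE_SAMPLE",
    "RI_SAATY_1980",
    "SAATY_SCALE",
]

#: Admissible judgment values: integers 1..9 and their reciprocals.
SAATY_SCALE = tuple(
    sorted(set([1.0 / k for k in range(1, 10)] + [float(k) for k in range(1, 10)]))
)

#: Random-index table from large-sample Monte-Carlo estimates of the mean CI
#: of uniform random Saaty-scale reciprocal matrices (Saaty's later
#: published values; reproduced by the simulation oracle in the test suite).
RI_LARGE_SAMPLE = {
    1: 0.0, 2: 0.0, 3: 0.52, 4: 0.89, 5: 1.11, 6: 1.25, 7: 1.35,
    8: 1.40, 9: 1.45, 10: 1.49, 11: 1.51, 12: 1.54, 13: 1.56,
    14: 1.57, 15: 1.58,
}

#: Saaty's original 1980 table, kept for comparability with older studies.
RI_SAATY_1980 = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32,
    8: 1.41, 9: 1.45, 10: 1.49, 11: 1.51, 12: 1.54, 13: 1.56,
    14: 1.57, 15: 1.58,
}

_RI_TABLES = {"large-sample": RI_LARGE_SAMPLE, "saaty1980": RI_SAATY_1980}

DEFAULT_CR_TOLERANCE = 0.1


class AhpError(ValueError):
    pass


class ConsistencyGateError(AhpError):
    """A comparison matrix failed the CR <= tolerance gate."""

    def __init__(self, element: str, cr: float, tolerance: float):
        self.element, self.cr, self.tolerance = element, cr, tolerance
        super().__init__(
            f"comparison matrix for {element!r} fails the consistency gate: "
            f"CR = {cr:.4f} > {tolerance}"
        )


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpertPanel:
    """Long-format expert questionnaire scores (one row per expert x element).

    ``responses`` must have columns ``expert_id``, ``element_id``, ``score``;
    scores live on the 1–9 importance scale.
    """

    responses: pd.DataFrame
    n_distributed: int | None = None

    def __post_init__(self) -> None:
        required = {"expert_id", "element_id", "score"}
        missing = required - set(self.responses.columns)
        if missing:
            raise AhpError(f"expert panel missing columns: {sorted(missing)}")
        scores = self.responses["score"].to_numpy(dtype=float)
        if len(scores) == 0:
            raise AhpError("expert panel is empty")
        if np.any(scores < 1.0) or np.any(scores > 9.0):
            bad = self.responses.loc[(scores < 1) | (scores > 9)]
            raise AhpError(
                f"scores outside the 1–9 scale for elements "
                f"{sorted(bad['element_id'].unique().tolist())}"
            )
        if self.n_distributed is not None and self.n_returned > self.n_distributed:
            raise AhpError(
                f"{self.n_returned} questionnaires returned but only "
                f"{self.n_distributed} distributed"
            )

    @property
    def element_ids(self) -> list[str]:
        return list(pd.unique(self.responses["element_id"]))

    @property
    def n_returned(self) -> int:
        return self.responses["expert_id"].nunique()

    @classmethod
    def from_csv(cls, path: str | Path, n_distributed: int | None = None) -> "ExpertPanel":
        return cls(pd.read_csv(path), n_distributed=n_distributed)

    def to_csv(self, path: str | Path) -> None:
        self.responses.to_csv(path, index=False)


@dataclass
class ScoreVector:
    """Mean expert score per element (all strictly positive)."""

    element_ids: tuple[str, ...] | None
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.element_ids is None:
            self.element_ids = tuple(f"e{i + 1}" for i in range(len(self.scores)))
        self.element_ids = tuple(self.element_ids)
        if len(self.element_ids) != len(self.scores):
            raise AhpError("element_ids and scores length mismatch")
        if np.any(self.scores <= 0):
            raise AhpError("scores must be strictly positive")

    def subset(self, ids: Sequence[str]) -> "ScoreVector":
        index = {e: i for i, e in enumerate(self.element_ids)}
        missing = [e for e in ids if e not in index]
        if missing:
            raise AhpError(f"no score for elements {missing}")
        return ScoreVector(tuple(ids), self.scores[[index[e] for e in ids]])

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreVector":
        df = pd.read_csv(path)
        return cls(tuple(df.iloc[:, 0].astype(str)), df.iloc[:, 1].to_numpy(float))


@dataclass
class ComparisonMatrix:
    """Square positive reciprocal pairwise-comparison matrix."""

    entries: np.ndarray
    element_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise AhpError(f"comparison matrix must be square, got shape {m.shape}")
        if np.any(m <= 0):
            raise AhpError("comparison matrix entries must be positive")
        if not np.allclose(np.diag(m), 1.0, atol=1e-9):
            raise AhpError("comparison matrix diagonal must be 1")
        if not np.allclose(m * m.T, 1.0, atol=1e-9):
            raise AhpError("comparison matrix is not reciprocal (C_ij * C_ji != 1)")
        self.entries = m
        if self.element_ids is not None:
            self.element_ids = tuple(self.element_ids)
            if len(self.element_ids) != m.shape[0]:
                raise AhpError("element_ids length does not match matrix dimension")

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ComparisonMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), tuple(df.columns.astype(str)))


@dataclass
class WeightVector:
    """Normalized importance weights (nonnegative, summing to one)."""

    weights: np.ndarray
    element_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise AhpError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise AhpError(f"weights must sum to 1 (got {w.sum():.12f})")
        self.weights = w
        if self.element_ids is not None:
            self.element_ids = tuple(self.element_ids)
            if len(self.element_ids) != len(w):
                raise AhpError("element_ids length does not match weights")

    def __len__(self) -> int:
        return len(self.weights)

    def as_series(self) -> pd.Series:
        ids = self.element_ids or tuple(f"e{i+1}" for i in range(len(self)))
        return pd.Series(self.weights, index=list(ids), name="weight")


@dataclass
class ConsistencyReport:
    n: int
    lambda_max: float
    ci: float
    ri: float
    cr: float
    tolerance: float = DEFAULT_CR_TOLERANCE
    accepted: bool = field(init=False)

    def __post_init__(self) -> None:
        self.accepted = self.cr <= self.tolerance

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "lambda_max": self.lambda_max,
            "ci": self.ci,
            "ri": self.ri,
            "cr": self.cr,
            "tolerance": self.tolerance,
            "accepted": self.accepted,
        }


@dataclass
class AhpDerivation:
    """Full weight extraction from one comparison matrix."""

    matrix: ComparisonMatrix
    row_products: np.ndarray
    weights: WeightVector
    lambda_max: float


# ---------------------------------------------------------------------------
# operations


def mean_scores(panel: ExpertPanel, element_ids: Sequence[str] | None = None) -> ScoreVector:
    """Arithmetic mean of the available responses per element.

    Elements with no response at all raise; partially missing responses are
    averaged over whoever answered.
    """
    grouped = panel.responses.groupby("element_id")["score"]
    means = grouped.mean()
    counts = grouped.size()
    ids = list(element_ids) if element_ids is not None else panel.element_ids
    missing = [e for e in ids if e not in means.index or counts[e] == 0]
    if missing:
        raise AhpError(f"no expert responses for elements {missing}")
    return ScoreVector(tuple(ids), means[ids].to_numpy(float))


def ratio_matrix(s: ScoreVector, clip: bool = False) -> ComparisonMatrix:
    """Pairwise-comparison matrix of mean-score ratios, C_ij = s_i / s_j.

    Consistent (hence CR = 0) by construction.  Entries outside the nominal
    [1/9, 9] judgment range trigger a warning; with ``clip=True`` they are
    clipped, which breaks exact consistency and is off by default.
    """
    scores = s.scores
    m = np.outer(scores, 1.0 / scores)
    if np.any(m > 9.0) or np.any(m < 1.0 / 9.0):
        warnings.warn(
            "score ratios exceed the nominal [1/9, 9] judgment range",
            stacklevel=2,
        )
        if clip:
            m = np.clip(m, 1.0 / 9.0, 9.0)
            iu = np.triu_indices_from(m, 1)
            m[(iu[1], iu[0])] = 1.0 / m[iu]  # restore exact reciprocity
            np.fill_diagonal(m, 1.0)
    return ComparisonMatrix(m, s.element_ids)


def row_products(m: ComparisonMatrix) -> np.ndarray:
    """M_i = product over the row of the comparison entries."""
    return m.entries.prod(axis=1)


def weights_from_products(
    products: np.ndarray, n: int, element_ids: Sequence[str] | None = None
) -> WeightVector:
    """Row-geometric-mean priority vector V_i = M_i^(1/n) / sum_j M_j^(1/n)."""
    products = np.asarray(products, dtype=float)
    if np.any(products <= 0):
        raise AhpError("row products must be strictly positive")
    roots = products ** (1.0 / n)
    return WeightVector(roots / roots.sum(), tuple(element_ids) if element_ids else None)


def lambda_max(
    m: ComparisonMatrix,
    w: WeightVector | None = None,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> float:
    """Principal eigenvalue of the comparison matrix, by power iteration.

    A positive reciprocal matrix has a simple dominant eigenvalue with a
    positive eigenvector (Perron–Frobenius), so power iteration from any
    positive start converges; the geometric-mean weight vector, exact for
    consistent matrices, is the default start.  For any ratio-constructed
    matrix the result equals the dimension n.
    """
    a = m.entries
    if w is not None:
        v = np.asarray(w.weights, dtype=float)
        if len(v) != m.n:
            raise AhpError("weight vector dimension does not match matrix")
        if np.any(v <= 0):
            raise AhpError("starting weights must be strictly positive")
    else:
        v = a.prod(axis=1) ** (1.0 / m.n)
    v = v / v.sum()
    lam = np.inf
    for _ in range(max_iter):
        av = a.dot(v)
        lam_new = float(av.sum())  # sum(Av) with sum(v) = 1 estimates lambda
        v = av / av.sum()
        if abs(lam_new - lam) < tol:
            break
        lam = lam_new
    return lam_new


def lambda_max_saaty(m: ComparisonMatrix, w: WeightVector) -> float:
    """Saaty's textbook estimate: mean over rows of (A w)_i / w_i.

    Exact on consistent matrices and for n <= 3; on inconsistent larger
    matrices it deviates from the true principal eigenvalue, so
    :func:`lambda_max` is used for consistency screening.
    """
    v = np.asarray(w.weights, dtype=float)
    if np.any(v <= 0):
        raise AhpError("weights must be strictly positive")
    return float(np.mean(m.entries.dot(v) / v))


def consistency_index(lam: float, n: int) -> float:
    """CI = (lambda_max - n) / (n - 1); zero for n = 1 by convention."""
    if n < 1:
        raise AhpError("matrix dimension must be >= 1")
    if n == 1:
        return 0.0
    return (lam - n) / (n - 1)


def random_index(n: int, table: str = "large-sample") -> float:
    """Expected CI of random Saaty-scale reciprocal matrices of size n."""
    try:
        ri_table = _RI_TABLES[table]
    except KeyError:
        raise AhpError(f"unknown RI table {table!r}; choose from {sorted(_RI_TABLES)}")
    if n not in ri_table:
        raise AhpError(f"random index undefined for n = {n} (supported: 1–15)")
    return ri_table[n]


def consistency_ratio(ci: float, ri: float) -> float:
    """CR = CI / RI; 0/0 resolves to 0 (1x1 and 2x2 matrices are consistent)."""
    if ri < 0:
        raise AhpError("random index must be nonnegative")
    if ri == 0:
        if abs(ci) < 1e-12:
            return 0.0
        raise AhpError("CR undefined for n <= 2 with nonzero CI")
    return ci / ri


def overall_consistency_ratio(
    cis: Sequence[float], ris: Sequence[float], a: WeightVector | Sequence[float]
) -> float:
    """Hierarchy-wide ratio CR = sum(a_i CI_i) / sum(a_i RI_i).

    ``a`` holds the parent-level weights of the sub-matrices being combined.
    """
    weights = a.weights if isinstance(a, WeightVector) else np.asarray(a, float)
    cis, ris = np.asarray(cis, float), np.asarray(ris, float)
    if not (len(cis) == len(ris) == len(weights)):
        raise AhpError("cis, ris and weights must have equal length")
    num = float(weights @ cis)
    den = float(weights @ ris)
    if den == 0:
        if abs(num) < 1e-12:
            return 0.0
        raise AhpError("overall CR undefined: zero weighted RI with nonzero CI")
    return num / den


def derive_weights(m: ComparisonMatrix) -> AhpDerivation:
    """Row products -> geometric-mean weights -> principal eigenvalue."""
    products = row_products(m)
    weights = weights_from_products(products, m.n, m.element_ids)
    return AhpDerivation(m, products, weights, lambda_max(m, weights))


def check_consistency(
    m: ComparisonMatrix,
    tolerance: float = DEFAULT_CR_TOLERANCE,
    ri_table: str = "large-sample",
) -> ConsistencyReport:
    """Assemble lambda_max, CI, RI and CR; accepted iff CR <= tolerance."""
    derivation = derive_weights(m)
    ci = consistency_index(derivation.lambda_max, m.n)
    # tiny negative CI from floating point on consistent matrices
    ci = 0.0 if abs(ci) < 1e-12 else ci
    ri = random_index(m.n, ri_table)
    cr = consistency_ratio(ci, ri)
    return ConsistencyReport(m.n, derivation.lambda_max, ci, ri, cr, tolerance)


def ahp_weights(
    scores: ScoreVector,
    tolerance: float = DEFAULT_CR_TOLERANCE,
    ri_table: str = "large-sample",
) -> tuple[WeightVector, ConsistencyReport]:
    """Score vector -> ratio matrix -> weights plus consistency report."""
    m = ratio_matrix(scores)
    derivation = derive_weights(m)
    report = check_consistency(m, tolerance=tolerance, ri_table=ri_table)
    return derivation.weights, report
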