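"""Standardization, hierarchical aggregation and risk classification.

Raw indicator series are rescaled to [0, 1] by min-max standardization,
with the direction reversed for negative-polarity indicators (those whose
growth reduces risk):

    positive:  Z = (x - xmin) / (xmax - xmin)
    negative:  Z = 1 - (x - xmin) / (xmax - xmin)

Standardized leaf values are combined child-to-parent with weighted sums
S = sum_j X_j W_j at every internal node until each of the five DPSIR
indices has one score per year; the composite environmental risk index is
the weighted sum ERI = sum_{i=1..5} S_i W_i over the index scores.  Because
every weight vector is convex and every Z lies in [0, 1], all scores and
the ERI stay in [0, 1].

The ERI scale is partitioned into five labelled risk bands (I extremely low
… V extremely high); the top band opens at the 0.8 critical point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ahp import AhpError, WeightVector
from .hierarchy import Hierarchy

__all__ = [
    "IndicatorSeries",
    "StandardizedSeries",
    "RiskBand",
    "RiskLevelTable",
    "RiskTrajectory",
    "standardize",
    "indicator_score",
    "rollup",
    "composite_eri",
    "subindex_composite",
    "classify",
    "annual_rate",
    "compute_trajectory",
    "default_risk_table",
    "DEFAULT_NEUTRAL",
]

logger = logging.getLogger(__name__)

#: Z assigned to a constant series (xmax == xmin), where min-max rescaling
#: is undefined; the midpoint is the neutral choice.
DEFAULT_NEUTRAL = 0.5


class ScoringError(ValueError):
    pass


@dataclass
class IndicatorSeries:
    """Yearly raw values for one leaf factor, with its risk polarity."""

    factor_id: str
    years: np.ndarray
    values: np.ndarray
    polarity: str = "positive"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.years) != len(self.values):
            raise ScoringError(f"{self.factor_id}: years/values length mismatch")
        if len(self.years) == 0:
            raise ScoringError(f"{self.factor_id}: empty series")
        if np.any(np.diff(self.years) <= 0):
            raise ScoringError(f"{self.factor_id}: years must be strictly increasing")
        if self.polarity not in ("positive", "negative"):
            raise ScoringError(f"{self.factor_id}: unknown polarity {self.polarity!r}")


@dataclass
class StandardizedSeries:
    """Min-max standardized twin of an :class:`IndicatorSeries`."""

    factor_id: str
    years: np.ndarray
    z_values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.z_values = np.asarray(self.z_values, dtype=float)
        if np.any(self.z_values < -1e-12) or np.any(self.z_values > 1 + 1e-12):
            raise ScoringError(f"{self.factor_id}: standardized values outside [0, 1]")


def standardize(
    series: IndicatorSeries,
    bounds: tuple[float, float] | None = None,
    neutral: float = DEFAULT_NEUTRAL,
) -> StandardizedSeries:
    """Rescale a series to [0, 1], reversing direction for negative polarity.

    ``bounds`` fixes (xmin, xmax) externally — needed when runs over
    different windows must be comparable, or for monotonicity analyses;
    by default the series' own range is used.  A zero range (constant
    series) maps every year to ``neutral`` with a logged warning.
    """
    x = series.values
    xmin, xmax = bounds if bounds is not None else (x.min(), x.max())
    if xmax < xmin:
        raise ScoringError(f"{series.factor_id}: bounds must satisfy xmin <= xmax")
    if xmax == xmin:
        logger.warning(
            "%s: constant series (range 0); standardizing to neutral %.3f",
            series.factor_id, neutral,
        )
        z = np.full_like(x, float(neutral))
    else:
        z = (x - xmin) / (xmax - xmin)
        if bounds is not None:
            if np.any(z < -1e-12) or np.any(z > 1 + 1e-12):
                raise ScoringError(
                    f"{series.factor_id}: values fall outside the fixed bounds"
                )
            z = np.clip(z, 0.0, 1.0)
        if series.polarity == "negative":
            z = 1.0 - z
    return StandardizedSeries(series.factor_id, series.years, z)


def indicator_score(z_values: Sequence[float], w: WeightVector | Sequence[float]) -> float:
    """Weighted sum S = sum_j X_j W_j of child scores under one node."""
    weights = w.weights if isinstance(w, WeightVector) else np.asarray(w, float)
    z = np.asarray(z_values, dtype=float)
    if len(z) != len(weights):
        raise ScoringError(
            f"got {len(z)} scores for {len(weights)} weights"
        )
    return float(z @ weights)


def rollup(
    h: Hierarchy,
    standardized: Mapping[str, StandardizedSeries],
    weights: Mapping[str, WeightVector] | None = None,
) -> pd.DataFrame:
    """Aggregate standardized series up the tree; one score column per index.

    ``standardized`` maps node ids to series.  Series are normally attached
    at the leaves, but a series supplied for an internal node (e.g. a
    B-level composite) is used directly and its subtree is not descended.
    ``weights`` maps a parent id to the weight vector over its children;
    parents without an entry use equal sibling weights.  A leaf in the tree
    with no series (and no scored ancestor) is an error, named.

    Returns a DataFrame indexed by year with one column per A-index.
    """
    weights = dict(weights or {})
    years = _common_years(standardized)

    def node_scores(node_id: str) -> np.ndarray:
        if node_id in standardized:
            s = standardized[node_id]
            if not np.array_equal(s.years, years):
                raise ScoringError(f"{node_id}: series years differ from the panel's")
            return s.z_values
        children = h.children(node_id)
        if not children:
            raise ScoringError(f"no series attached for leaf {node_id!r}")
        child_matrix = np.vstack([node_scores(c) for c in children])
        if node_id in weights:
            wv = weights[node_id]
            if wv.element_ids is not None and tuple(wv.element_ids) != tuple(children):
                raise ScoringError(
                    f"weights for {node_id!r} cover {wv.element_ids}, "
                    f"but its children are {tuple(children)}"
                )
            if len(wv) != len(children):
                raise ScoringError(
                    f"weights for {node_id!r} have length {len(wv)}, "
                    f"expected {len(children)}"
                )
            wvec = wv.weights
        else:
            wvec = np.full(len(children), 1.0 / len(children))
        return wvec @ child_matrix

    roots = sorted(h.roots, key=lambda r: (r[0], int(r[1:])))
    data = {root: node_scores(root) for root in roots}
    return pd.DataFrame(data, index=pd.Index(years, name="year"))


def _common_years(standardized: Mapping[str, StandardizedSeries]) -> np.ndarray:
    if not standardized:
        raise ScoringError("no standardized series supplied")
    series = list(standardized.values())
    years = series[0].years
    for s in series[1:]:
        if not np.array_equal(s.years, years):
            raise ScoringError(
                f"{s.factor_id}: series years differ from {series[0].factor_id}'s"
            )
    return years


def composite_eri(s: Sequence[float], w: WeightVector | Sequence[float]) -> float:
    """ERI = sum over the five index scores of S_i W_i."""
    weights = w.weights if isinstance(w, WeightVector) else np.asarray(w, float)
    s = np.asarray(s, dtype=float)
    if len(s) != len(weights):
        raise ScoringError(f"{len(s)} index scores for {len(weights)} weights")
    return float(s @ weights)


def subindex_composite(
    s: Sequence[float], w: WeightVector | Sequence[float]
) -> float:
    """Weighted mean over a subset of indices, weights renormalized to 1.

    Used e.g. to track the driving-force/pressure/state/impact composite
    against the response index alone.
    """
    weights = w.weights if isinstance(w, WeightVector) else np.asarray(w, float)
    s = np.asarray(s, dtype=float)
    if len(s) == 0:
        raise ScoringError("sub-index composite of an empty subset")
    if len(s) != len(weights):
        raise ScoringError(f"{len(s)} scores for {len(weights)} weights")
    total = weights.sum()
    if total <= 0:
        raise ScoringError("subset weights sum to zero")
    return float(s @ (weights / total))


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class RiskBand:
    label: str
    lower: float
    upper: float
    degree: str = ""
    state: str = ""
    action: str = ""


@dataclass
class RiskLevelTable:
    """Ordered, contiguous bands covering [0, 1].

    Bands are half-open [lower, upper), except the top band which closes
    at 1.0.
    """

    bands: tuple[RiskBand, ...]

    def __post_init__(self) -> None:
        self.bands = tuple(self.bands)
        if not self.bands:
            raise ScoringError("risk table needs at least one band")
        if self.bands[0].lower != 0.0 or self.bands[-1].upper != 1.0:
            raise ScoringError("risk bands must cover [0, 1]")
        for a, b in zip(self.bands, self.bands[1:]):
            if b.lower != a.upper:
                raise ScoringError(
                    f"bands {a.label} and {b.label} are not contiguous"
                )


def default_risk_table() -> RiskLevelTable:
    """The five-level interpretation guide.

    The published guide starts band I at 0.1; values in [0, 0.1) are folded
    into band I so that classification is total on [0, 1] (a note is logged
    when that happens).  Band V opens at the 0.8 critical point.
    """
    return RiskLevelTable((
        RiskBand("I", 0.0, 0.2, "Extremely low", "Low external pressure",
                 "Good condition, needs to be maintained"),
        RiskBand("II", 0.2, 0.4, "Relatively low", "Less external pressure",
                 "Good condition, vigilance required to avoid further disturbances"),
        RiskBand("III", 0.4, 0.6, "Medium",
                 "Environmental state is changing with external pressure",
                 "Need to work on the changing state"),
        RiskBand("IV", 0.6, 0.8, "Relatively high",
                 "Poor state with large external pressure",
                 "Immediate action and management programs required at all levels"),
        RiskBand("V", 0.8, 1.0, "Extremely high",
                 "Serious damage due to great pressure",
                 "Dangerous environment; rehabilitation programs urgently required"),
    ))


def classify(value: float, table: RiskLevelTable | None = None) -> str:
    """Risk-level label (I–V) for a composite index value in [0, 1]."""
    if not (0.0 <= value <= 1.0) or not np.isfinite(value):
        raise ScoringError(f"risk value {value!r} outside [0, 1]")
    table = table or default_risk_table()
    if value < 0.1:
        logger.info("value %.4f below the published 0.1 floor; folded into band I", value)
    for band in table.bands[:-1]:
        if band.lower <= value < band.upper:
            return band.label
    return table.bands[-1].label


def annual_rate(first_value: float, last_value: float, n_years: int) -> float:
    """Average change per year, (last - first) / n_years."""
    if n_years < 1:
        raise ScoringError("n_years must be at least 1")
    return (last_value - first_value) / n_years


# ---------------------------------------------------------------------------
# trajectory


@dataclass
class RiskTrajectory:
    """Per-year index scores, composite ERI and risk levels."""

    years: np.ndarray
    index_scores: pd.DataFrame  # year x A-index
    eri: np.ndarray
    levels: tuple[str, ...]
    a_weights: WeightVector | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        df = self.index_scores.copy()
        df.columns = [f"S_{c}" for c in df.columns]
        df["ERI"] = self.eri
        df["level"] = list(self.levels)
        return df


def compute_trajectory(
    index_scores: pd.DataFrame,
    a_weights: WeightVector,
    table: RiskLevelTable | None = None,
) -> RiskTrajectory:
    """Composite ERI and risk level per year from the per-index score frame."""
    if a_weights.element_ids is not None:
        missing = [e for e in a_weights.element_ids if e not in index_scores.columns]
        if missing:
            raise ScoringError(f"no index scores for {missing}")
        ordered = index_scores[list(a_weights.element_ids)]
    else:
        ordered = index_scores
    eri = ordered.to_numpy() @ a_weights.weights
    levels = tuple(classify(float(v), table) for v in eri)
    return RiskTrajectory(
        years=index_scores.index.to_numpy(),
        index_scores=index_scores,
        eri=eri,
        levels=levels,
        a_weights=a_weights,
    )
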