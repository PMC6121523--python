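"""End-to-end assessment runs: load -> weights -> consistency gate ->
standardize -> rollup -> composite index -> classification -> reports.

A run reads three inputs (hierarchy document, expert panel CSV, indicator
panel CSV), derives AHP weights for every judged sibling group, refuses to
continue if any comparison matrix fails the CR <= 0.1 gate, aggregates the
standardized panel up the tree, and writes the yearly risk trajectory with
its five-band classification plus weight/consistency/summary reports and a
machine-readable manifest.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import ahp
from .ahp import (
    ConsistencyGateError,
    ConsistencyReport,
    ExpertPanel,
    ScoreVector,
    WeightVector,
)
from .hierarchy import Hierarchy, default_hierarchy, load_hierarchy
from .scoring import (
    IndicatorSeries,
    RiskTrajectory,
    annual_rate,
    compute_trajectory,
    rollup,
    standardize,
    subindex_composite,
)

__all__ = [
    "RunConfig",
    "RunResult",
    "run",
    "report_summary",
    "paper_table_a_weights",
    "MissingSeriesError",
]

logger = logging.getLogger(__name__)

#: Published per-index weight column of the study's weight table.  It sums
#: to 1.557, so it is not a normalized weight vector; the optional
#: "paper-table" mode renormalizes it by that sum.
_PAPER_TABLE_A_COLUMN = {
    "A1": 0.157, "A2": 0.447, "A3": 0.354, "A4": 0.285, "A5": 0.314,
}


class MissingSeriesError(ValueError):
    pass


def paper_table_a_weights() -> WeightVector:
    """The published A-layer weight column, renormalized to sum to one."""
    ids = tuple(_PAPER_TABLE_A_COLUMN)
    col = np.array([_PAPER_TABLE_A_COLUMN[i] for i in ids])
    return WeightVector(col / col.sum(), ids)


@dataclass
class RunConfig:
    """Everything one assessment run needs.

    ``hierarchy_path`` of ``None`` selects the packaged default system.
    ``a_weight_mode`` is ``"derived"`` (AHP weights from the expert panel's
    A-layer scores) or ``"paper-table"`` (the published column,
    renormalized).  ``bounds_mode`` is ``"window"`` (each series' own
    min/max) or ``"fixed:<csv>"`` with columns factor_id, xmin, xmax.
    """

    experts_path: str | Path
    panel_path: str | Path
    out_dir: str | Path
    hierarchy_path: str | Path | None = None
    a_weight_mode: str = "derived"
    bounds_mode: str = "window"
    tolerance: float = 0.1
    seed: int | None = None
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("consistency tolerance must be positive")
        if self.a_weight_mode not in ("derived", "paper-table"):
            raise ValueError(f"unknown a_weight_mode {self.a_weight_mode!r}")
        if self.bounds_mode != "window" and not str(self.bounds_mode).startswith("fixed:"):
            raise ValueError(f"unknown bounds_mode {self.bounds_mode!r}")


@dataclass
class RunResult:
    trajectory: RiskTrajectory
    weights: dict[str, WeightVector]          # parent id -> child weights
    a_weights: WeightVector
    consistency: dict[str, ConsistencyReport]  # group id -> report
    subindex: pd.DataFrame                     # pressure-side composite vs response
    summary: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _read_panel(path: str | Path, h: Hierarchy) -> dict[str, IndicatorSeries]:
    df = pd.read_csv(path)
    required = {"factor_id", "year", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"indicator panel must have columns {sorted(required)}")
    series = {}
    for factor_id, grp in df.groupby("factor_id"):
        grp = grp.sort_values("year")
        if factor_id not in h:
            raise ValueError(f"panel factor {factor_id!r} not in the hierarchy")
        polarity = h[str(factor_id)].polarity or "positive"
        series[str(factor_id)] = IndicatorSeries(
            str(factor_id), grp["year"].to_numpy(), grp["value"].to_numpy(), polarity
        )
    return series


def _read_bounds(spec: str) -> dict[str, tuple[float, float]]:
    path = spec.split("fixed:", 1)[1]
    df = pd.read_csv(path)
    return {
        str(r.factor_id): (float(r.xmin), float(r.xmax)) for r in df.itertuples()
    }


def derive_group_weights(
    h: Hierarchy,
    scores: ScoreVector,
    tolerance: float = 0.1,
) -> tuple[dict[str, WeightVector], dict[str, ConsistencyReport]]:
    """AHP weights for every sibling group whose members all have scores.

    Groups without full score coverage (typically C-level and below, where
    no questionnaire data exists) are left out and fall back to equal
    weights during rollup.  Raises :class:`ConsistencyGateError` on the
    first group whose matrix fails the gate.
    """
    scored = set(scores.element_ids)
    weights: dict[str, WeightVector] = {}
    reports: dict[str, ConsistencyReport] = {}
    for node in h.nodes:
        children = h.children(node.id)
        if not children or not set(children) <= scored:
            continue
        if len(children) == 1:
            weights[node.id] = WeightVector(np.array([1.0]), tuple(children))
            continue
        wv, report = ahp.ahp_weights(scores.subset(children), tolerance=tolerance)
        if not report.accepted:
            raise ConsistencyGateError(node.id, report.cr, tolerance)
        weights[node.id] = wv
        reports[node.id] = report
    return weights, reports


def run(cfg: RunConfig) -> RunResult:
    """Execute a full assessment and write all reports under ``out_dir``."""
    logging.basicConfig(
        stream=sys.stderr,
        level={0: logging.WARNING, 1: logging.INFO}.get(cfg.verbosity, logging.DEBUG),
    )
    h = (
        default_hierarchy()
        if cfg.hierarchy_path is None
        else load_hierarchy(cfg.hierarchy_path)
    )
    panel = ExpertPanel.from_csv(cfg.experts_path)
    scores = ahp.mean_scores(panel)
    weights, reports = derive_group_weights(h, scores, cfg.tolerance)

    root_ids = tuple(sorted(h.roots, key=lambda r: int(r[1:])))
    if cfg.a_weight_mode == "paper-table":
        a_weights = paper_table_a_weights()
    else:
        a_weights, a_report = ahp.ahp_weights(
            scores.subset(root_ids), tolerance=cfg.tolerance
        )
        if not a_report.accepted:
            raise ConsistencyGateError("A-layer", a_report.cr, cfg.tolerance)
        reports["A-layer"] = a_report
    logger.info("A-layer weights: %s", dict(zip(root_ids, np.round(a_weights.weights, 4))))

    series = _read_panel(cfg.panel_path, h)
    # a series attached at an internal node (e.g. a B-level composite)
    # covers its whole subtree
    covered: set[str] = set()
    for node_id in series:
        covered.update(h.subtree_leaves(node_id))
    missing = [leaf for leaf in h.leaves if leaf not in covered]
    if missing:
        raise MissingSeriesError(
            f"no indicator series for leaves: {', '.join(missing[:10])}"
            + (" …" if len(missing) > 10 else "")
        )

    fixed = _read_bounds(cfg.bounds_mode) if str(cfg.bounds_mode).startswith("fixed:") else {}
    standardized = {
        fid: standardize(s, bounds=fixed.get(fid)) for fid, s in series.items()
    }
    index_scores = rollup(h, standardized, weights)
    trajectory = compute_trajectory(index_scores[list(root_ids)], a_weights)

    # pressure-side composite (all indices but the response index) vs response
    response_root = root_ids[-1]
    other_roots = [r for r in root_ids if r != response_root]
    idx = {r: i for i, r in enumerate(root_ids)}
    other_w = a_weights.weights[[idx[r] for r in other_roots]]
    sub = pd.DataFrame(
        {
            "others_composite": [
                subindex_composite(row[other_roots].to_numpy(), other_w)
                for _, row in index_scores.iterrows()
            ],
            response_root: index_scores[response_root].to_numpy(),
        },
        index=index_scores.index,
    )

    summary = report_summary(trajectory)
    result = RunResult(trajectory, weights, a_weights, reports, sub, summary)
    result.paths = _write_outputs(cfg, h, result)
    return result


def _write_outputs(cfg: RunConfig, h: Hierarchy, result: RunResult) -> dict[str, Path]:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    traj = result.trajectory.to_frame()
    paths["trajectory"] = out / "trajectory.csv"
    traj.round(4).to_csv(paths["trajectory"], float_format="%.4f")
    paths["trajectory_full"] = out / "trajectory.json"
    paths["trajectory_full"].write_text(
        json.dumps(
            {
                "years": result.trajectory.years.tolist(),
                "index_scores": {
                    c: result.trajectory.index_scores[c].tolist()
                    for c in result.trajectory.index_scores.columns
                },
                "eri": result.trajectory.eri.tolist(),
                "levels": list(result.trajectory.levels),
            },
            indent=2,
        )
    )

    rows = []
    for parent, wv in sorted(result.weights.items()):
        ids = wv.element_ids or tuple(f"e{i+1}" for i in range(len(wv)))
        rows.extend(
            {"parent": parent, "element": e, "weight": round(float(w), 4)}
            for e, w in zip(ids, wv.weights)
        )
    a_ids = result.a_weights.element_ids or ()
    rows.extend(
        {"parent": "(composite)", "element": e, "weight": round(float(w), 4)}
        for e, w in zip(a_ids, result.a_weights.weights)
    )
    paths["weights"] = out / "weights.csv"
    pd.DataFrame(rows).to_csv(paths["weights"], index=False)

    paths["consistency"] = out / "consistency.json"
    paths["consistency"].write_text(
        json.dumps({k: r.to_dict() for k, r in result.consistency.items()}, indent=2)
    )

    paths["subindex"] = out / "subindex.csv"
    result.subindex.round(4).to_csv(paths["subindex"], float_format="%.4f")

    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(result.summary, indent=2))

    try:
        version = metadata.version("dpsir-eri")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = {
        "package": "dpsir-eri",
        "version": version,
        "hierarchy": str(cfg.hierarchy_path) if cfg.hierarchy_path else "packaged default",
        "hierarchy_name": h.name,
        "experts": str(cfg.experts_path),
        "panel": str(cfg.panel_path),
        "a_weight_mode": cfg.a_weight_mode,
        "bounds_mode": str(cfg.bounds_mode),
        "tolerance": cfg.tolerance,
        "seed": cfg.seed,
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


def report_summary(trajectory: RiskTrajectory) -> dict:
    """Minimum/maximum composite values, average yearly drift, level counts."""
    years = trajectory.years
    eri = trajectory.eri
    i_min, i_max = int(np.argmin(eri)), int(np.argmax(eri))
    n_years = int(years[-1] - years[0])
    overall = annual_rate(float(eri[0]), float(eri[-1]), n_years) if n_years else 0.0
    span = int(abs(years[i_max] - years[i_min]))
    min_to_max = (
        annual_rate(float(eri[i_min]), float(eri[i_max]), span) if span else 0.0
    )
    levels = pd.Series(trajectory.levels)
    return {
        "min_eri": {"year": int(years[i_min]), "value": round(float(eri[i_min]), 4)},
        "max_eri": {"year": int(years[i_max]), "value": round(float(eri[i_max]), 4)},
        "annual_rate_overall": round(overall, 4),
        "annual_rate_min_to_max": round(min_to_max, 4),
        "years_per_level": levels.value_counts().sort_index().to_dict(),
        "final": {
            "year": int(years[-1]),
            "value": round(float(eri[-1]), 4),
            "level": trajectory.levels[-1],
        },
    }
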