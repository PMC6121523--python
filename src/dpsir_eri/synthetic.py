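"""Seeded generators for expert panels and multi-year indicator panels.

The study design being emulated: 38 questionnaires sent to solid-waste
experts with roughly 92% returned, each scoring every hierarchy element on
the 1–9 importance scale; and a 12-year (2006–2017) yearly panel in which
raw series for driving-force, pressure, state and impact leaves trend
upward while response-side leaves trend downward (improving responses show
up as falling raw risk contributions under the negative-polarity
convention).

Every generator is a pure function of its :class:`SyntheticConfig`; equal
seeds give identical output.  A :class:`GroundTruth` record accompanies
each dataset so recovery tests can check what the pipeline should find —
in particular the expected sign of each index's standardized score trend,
which is the raw slope sign flipped for negative-polarity leaves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ahp import ExpertPanel, ScoreVector
from .hierarchy import Hierarchy, default_hierarchy
from .scoring import IndicatorSeries

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "simulate_expert_panel",
    "simulate_indicator_panel",
    "write_dataset",
    "DEFAULT_A_SCORES",
    "DEFAULT_B_SCORES",
]

#: Latent consensus scores of the expert panel for the five DPSIR indices
#: (the study's published A-layer means).
DEFAULT_A_SCORES = {"A1": 3.0, "A2": 8.5, "A3": 7.5, "A4": 5.0, "A5": 5.5}

#: Latent consensus scores for the B-layer indicators (published means).
DEFAULT_B_SCORES = {
    "B1": 6.5, "B2": 5.0, "B3": 3.5,
    "B4": 9.0, "B5": 8.5, "B6": 7.5, "B7": 7.7, "B8": 7.0,
    "B9": 9.0, "B10": 8.5, "B11": 6.5,
    "B12": 9.0, "B13": 7.5, "B14": 5.5,
    "B15": 8.7, "B16": 7.5, "B17": 7.0, "B18": 8.5,
}


@dataclass
class SyntheticConfig:
    """Study conditions for the generators.

    ``slopes`` gives the expected raw trend per year for leaves under each
    index; the defaults rise for the four pressure-side indices and fall
    for the response index.  ``noise_sd`` is the yearly Gaussian noise on
    raw series (unitless, against a default 12-year trend range of about
    0.55); ``expert_noise_sd`` is the spread of expert judgments in Saaty
    scale points, rounded to whole points before clamping to [1, 9].
    """

    seed: int = 0
    n_experts: int = 38
    response_rate: float = 0.92
    years: tuple[int, int] = (2006, 2017)
    slopes: dict[str, float] = field(
        default_factory=lambda: {"A1": 0.05, "A2": 0.05, "A3": 0.05, "A4": 0.05, "A5": -0.05}
    )
    noise_sd: float = 0.05
    expert_noise_sd: float = 1.0
    true_scores: dict[str, float] = field(
        default_factory=lambda: {**DEFAULT_A_SCORES, **DEFAULT_B_SCORES}
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.response_rate <= 1.0):
            raise ValueError("response_rate must lie in (0, 1]")
        if self.noise_sd < 0 or self.expert_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if self.years[1] < self.years[0]:
            raise ValueError("years range is empty")
        if self.n_experts < 1:
            raise ValueError("need at least one expert")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def n_respondents(self) -> int:
        return int(round(self.n_experts * self.response_rate))


@dataclass
class GroundTruth:
    """What the generators actually planted, for recovery tests."""

    latent_scores: dict[str, float] = field(default_factory=dict)
    slopes: dict[str, float] = field(default_factory=dict)          # per leaf
    polarities: dict[str, str] = field(default_factory=dict)        # per leaf
    expected_score_trend: dict[str, int] = field(default_factory=dict)  # per index

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def _rngs(cfg: SyntheticConfig) -> tuple[np.random.Generator, np.random.Generator]:
    seq = np.random.SeedSequence(cfg.seed)
    experts_ss, panel_ss = seq.spawn(2)
    return np.random.default_rng(experts_ss), np.random.default_rng(panel_ss)


def simulate_expert_panel(cfg: SyntheticConfig) -> tuple[ExpertPanel, GroundTruth]:
    """Draw a returned-questionnaire panel around the latent consensus.

    ``round(n_experts * response_rate)`` respondents are kept (drop-outs are
    uniform at random); each respondent reports, per element, the latent
    score plus integer-rounded Gaussian noise, clamped to the 1–9 scale.
    """
    rng, _ = _rngs(cfg)
    elements = list(cfg.true_scores)
    latent = np.array([cfg.true_scores[e] for e in elements])
    respondents = np.sort(
        rng.choice(np.arange(1, cfg.n_experts + 1), size=cfg.n_respondents, replace=False)
    )
    rows = []
    for expert in respondents:
        noise = np.round(rng.normal(0.0, cfg.expert_noise_sd, size=len(elements)))
        scores = np.clip(latent + noise, 1.0, 9.0)
        rows.extend(
            {"expert_id": f"E{expert:02d}", "element_id": e, "score": s}
            for e, s in zip(elements, scores)
        )
    panel = ExpertPanel(pd.DataFrame(rows), n_distributed=cfg.n_experts)
    truth = GroundTruth(latent_scores=dict(cfg.true_scores))
    return panel, truth


def simulate_indicator_panel(
    cfg: SyntheticConfig, h: Hierarchy | None = None
) -> tuple[dict[str, IndicatorSeries], GroundTruth]:
    """One raw yearly series per hierarchy leaf.

    A leaf's series is a line with the slope configured for its index plus
    Gaussian noise: base + slope * (year - first_year) + N(0, noise_sd).
    Base levels are drawn once per leaf.  The ground truth records each
    leaf's slope and polarity and each index's expected standardized-score
    trend sign (slope sign, flipped where polarity is negative).
    """
    h = h or default_hierarchy()
    _, rng = _rngs(cfg)
    years = np.array(cfg.year_list)
    t = years - years[0]
    series: dict[str, IndicatorSeries] = {}
    truth = GroundTruth(latent_scores=dict(cfg.true_scores))
    for leaf in h.leaves:
        root = h.root_of(leaf)
        slope = cfg.slopes.get(root, 0.0)
        polarity = h[leaf].polarity or "positive"
        base = rng.uniform(0.2, 0.6)
        values = base + slope * t + rng.normal(0.0, cfg.noise_sd, size=len(t))
        series[leaf] = IndicatorSeries(leaf, years, values, polarity)
        truth.slopes[leaf] = slope
        truth.polarities[leaf] = polarity
    for root in h.roots:
        slope = cfg.slopes.get(root, 0.0)
        polarities = {truth.polarities[leaf] for leaf in h.subtree_leaves(root)}
        flip = -1 if polarities == {"negative"} else 1
        truth.expected_score_trend[root] = int(np.sign(slope)) * flip
    return series, truth


def write_dataset(cfg: SyntheticConfig, out_dir: str | Path,
                  h: Hierarchy | None = None) -> dict[str, Path]:
    """Write experts.csv, panel.csv and ground_truth.json for a config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, expert_truth = simulate_expert_panel(cfg)
    series, series_truth = simulate_indicator_panel(cfg, h)
    truth = GroundTruth(
        latent_scores=expert_truth.latent_scores,
        slopes=series_truth.slopes,
        polarities=series_truth.polarities,
        expected_score_trend=series_truth.expected_score_trend,
    )
    paths = {
        "experts": out / "experts.csv",
        "panel": out / "panel.csv",
        "ground_truth": out / "ground_truth.json",
    }
    panel.to_csv(paths["experts"])
    long = pd.concat(
        pd.DataFrame({"factor_id": s.factor_id, "year": s.years, "value": s.values})
        for s in series.values()
    )
    long.to_csv(paths["panel"], index=False)
    truth.to_json(paths["ground_truth"])
    return paths
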