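"""Peak and main-peak classification of fitted expression mixtures.

Each fitted normal component is a *peak* of the expression distribution.
A *main peak* is a component whose mixing proportion is at least the main
threshold (default 15% of the clustered, i.e. nonzero-coverage, genes).
The per-dataset summary row (sample, condition, peaks, main peaks) is the
headline modality statistic of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from fungiflow.mixture import MixtureModel

DEFAULT_MAIN_THRESHOLD = 0.15

TABLE_COLUMNS = ("sample", "condition", "n_peaks", "n_main_peaks")


@dataclass(frozen=True)
class ComponentSummary:
    weight: float
    mean: float
    variance: float
    is_main: bool


@dataclass(frozen=True)
class PeakSummary:
    """Modality summary of one fitted mixture."""

    n_peaks: int
    n_main_peaks: int
    main_threshold: float
    per_component: tuple[ComponentSummary, ...]
    label: str

    def to_dict(self) -> dict:
        return {
            "n_peaks": self.n_peaks,
            "n_main_peaks": self.n_main_peaks,
            "main_threshold": self.main_threshold,
            "label": self.label,
            "components": [
                {
                    "weight": c.weight,
                    "mean": c.mean,
                    "variance": c.variance,
                    "is_main": c.is_main,
                }
                for c in self.per_component
            ],
        }


def _label(n_main: int) -> str:
    if n_main >= 3:
        return "multimodal"
    if n_main == 2:
        return "bimodal"
    return "unimodal"


def summarize_peaks(
    model: MixtureModel, main_threshold: float = DEFAULT_MAIN_THRESHOLD
) -> PeakSummary:
    """Count peaks and main peaks of a fitted mixture.

    The main-peak rule is inclusive: a component carrying exactly the
    threshold proportion ("at least 15%") is a main peak. Components are
    reported sorted by mean, ascending.
    """
    if model.collapsed:
        raise ValueError("cannot summarize a collapsed mixture fit")
    if not 0.0 < main_threshold <= 1.0:
        raise ValueError("main_threshold must be in (0, 1]")
    order = np.argsort(model.means, kind="stable")
    comps = tuple(
        ComponentSummary(
            weight=float(model.weights[k]),
            mean=float(model.means[k]),
            variance=float(model.variances[k]),
            is_main=bool(model.weights[k] >= main_threshold),
        )
        for k in order
    )
    n_main = sum(c.is_main for c in comps)
    return PeakSummary(
        n_peaks=model.K,
        n_main_peaks=n_main,
        main_threshold=main_threshold,
        per_component=comps,
        label=_label(n_main),
    )


def dominant_peak_fraction(model: MixtureModel) -> float:
    """Mixing proportion of the largest component."""
    if model.collapsed:
        raise ValueError("cannot summarize a collapsed mixture fit")
    return float(np.max(model.weights))


def modality_table(
    summaries: Sequence[PeakSummary],
    samples: Sequence[str],
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-dataset modality rows: (sample, condition, n_peaks, n_main_peaks)."""
    if not summaries:
        raise ValueError("no summaries given")
    if len(samples) != len(summaries):
        raise ValueError("one sample label per summary required")
    if conditions is None:
        conditions = [""] * len(summaries)
    if len(conditions) != len(summaries):
        raise ValueError("one condition label per summary required")
    frame = pd.DataFrame(
        {
            "sample": list(samples),
            "condition": list(conditions),
            "n_peaks": [s.n_peaks for s in summaries],
            "n_main_peaks": [s.n_main_peaks for s in summaries],
        },
        columns=list(TABLE_COLUMNS),
    )
    return frame


def write_modality_table(path: str | Path, table: pd.DataFrame) -> None:
    if list(table.columns) != list(TABLE_COLUMNS):
        raise ValueError(f"modality table must have columns {TABLE_COLUMNS}")
    table.to_csv(path, sep="\t", index=False)


def read_modality_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"condition": str})
    if list(frame.columns) != list(TABLE_COLUMNS):
        raise ValueError(f"modality table must have columns {TABLE_COLUMNS}")
    frame["n_peaks"] = frame["n_peaks"].astype(int)
    frame["n_main_peaks"] = frame["n_main_peaks"].astype(int)
    return frame


def count_density_modes(
    model: MixtureModel, grid_points: int = 2001, span_sd: float = 4.0
) -> int:
    """Diagnostic: count true local maxima of the mixture density on a grid.

    Overlapping components need not produce distinct density modes, so this
    can be smaller than the component count. Not used by the headline
    classification, which equates peaks with components.
    """
    from fungiflow.mixture import mixture_density

    sd = np.sqrt(model.variances)
    lo = float(np.min(model.means - span_sd * sd))
    hi = float(np.max(model.means + span_sd * sd))
    grid = np.linspace(lo, hi, grid_points)
    total, _ = mixture_density(model, grid)
    interior = (total[1:-1] > total[:-2]) & (total[1:-1] >= total[2:])
    return int(interior.sum())
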