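"""Compression-series statistics: distributions and threshold exceedance.

Turns converged piston states into the quantities a crowd-safety analyst
reads off: the distribution of the local density each agent experiences,
the fraction of the crowd above an injury-risk threshold (10 people/m^2 is
the customary guide value), and how both evolve as the occupied area
shrinks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .density import DensityField, RasterSettings, local_density_field
from .physics import (PhysicsParams, WorldState, compress_to, initial_state,
                      settle_packing)
from .scenario import AgentSpec, ScenarioSpec

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (10.0, 15.0, 20.0)


class AnalysisError(ValueError):
    pass


def fraction_above(densities: Sequence[float], threshold: float) -> float:
    """Fraction of entries strictly greater than ``threshold``."""
    arr = np.asarray(densities, dtype=float)
    if arr.size == 0:
        raise AnalysisError("fraction_above requires a non-empty density list")
    return float(np.count_nonzero(arr > threshold) / arr.size)


def density_histogram(densities: Sequence[float], bin_width: float = 1.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Counts per half-open bin [k*w, (k+1)*w); returns (edges, counts).

    Counts always sum to the number of input values.
    """
    if bin_width <= 0.0:
        raise AnalysisError(f"bin_width must be > 0, got {bin_width}")
    arr = np.asarray(densities, dtype=float)
    if arr.size == 0:
        return np.array([0.0, bin_width]), np.array([0], dtype=np.int64)
    k_max = int(math.floor(arr.max() / bin_width)) + 1
    edges = np.arange(k_max + 1) * bin_width
    idx = np.clip((arr / bin_width).astype(int), 0, k_max - 1)
    counts = np.bincount(idx, minlength=k_max).astype(np.int64)
    return edges, counts


def area_reduction(displacement: float, width_W: float) -> float:
    """Occupied-area shrinkage fraction: displacement / initial width."""
    if not (0.0 <= displacement < width_W):
        raise AnalysisError(
            f"displacement {displacement} outside [0, width_W={width_W})"
        )
    return displacement / width_W


@dataclass(frozen=True)
class CompressionRecord:
    """Converged snapshot at one piston displacement."""

    displacement: float
    area_reduction: float
    per_agent_density: np.ndarray
    fraction_above: Mapping[float, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.area_reduction < 1.0):
            raise AnalysisError(
                f"area_reduction must lie in [0, 1), got {self.area_reduction}"
            )
        for t, f in self.fraction_above.items():
            if not (0.0 <= f <= 1.0):
                raise AnalysisError(f"fraction above {t} out of [0, 1]: {f}")

    @property
    def mean_density(self) -> float:
        return float(np.mean(self.per_agent_density))


@dataclass
class CompressionSeries:
    """Ordered records of one scenario's compression protocol."""

    label: str
    records: list[CompressionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        disps = [r.displacement for r in self.records]
        if any(b <= a for a, b in zip(disps, disps[1:])):
            raise AnalysisError(f"displacements must be strictly increasing: {disps}")

    @property
    def final(self) -> CompressionRecord:
        if not self.records:
            raise AnalysisError(f"series {self.label!r} is empty")
        return self.records[-1]

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy table: scenario, displacement_m, area_reduction, threshold, fraction."""
        rows = [
            {
                "scenario": self.label,
                "displacement_m": r.displacement,
                "area_reduction": r.area_reduction,
                "threshold": t,
                "fraction": f,
            }
            for r in self.records
            for t, f in sorted(r.fraction_above.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["scenario", "displacement_m", "area_reduction",
                     "threshold", "fraction"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run_compression_series(
    spec: ScenarioSpec,
    agent: AgentSpec | None = None,
    params: PhysicsParams | None = None,
    settings: RasterSettings | None = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    label: str | None = None,
    on_record: Callable[[CompressionRecord, WorldState, DensityField], None] | None = None,
) -> CompressionSeries:
    """Run the scenario's full piston protocol and collect statistics.

    The crowd is hex-packed, relaxed (resolving any initial overlaps from
    the random orientations), then for each scheduled displacement in
    order: the piston advances and the crowd re-converges, the density
    field is measured, and a record is appended.  ``on_record`` (if given)
    receives each record with the converged state and field, e.g. to write
    per-displacement files.
    """
    agent = agent or AgentSpec()
    params = params or PhysicsParams()
    settings = settings or RasterSettings()
    label = label or f"crowd{spec.n_agents}"

    state = settle_packing(initial_state(spec, agent), agent, params)
    records: list[CompressionRecord] = []
    for d in spec.piston_schedule:
        logger.info("%s: compressing to %.2f m", label, d)
        state = compress_to(state, d, agent, params)
        density_field = local_density_field(state.agents, agent, settings)
        record = CompressionRecord(
            displacement=d,
            area_reduction=area_reduction(d, spec.width_W),
            per_agent_density=density_field.per_agent_density.copy(),
            fraction_above={
                float(t): fraction_above(density_field.per_agent_density, t)
                for t in thresholds
            },
        )
        records.append(record)
        if on_record is not None:
            on_record(record, state, density_field)
    return CompressionSeries(label=label, records=records)


def plot_threshold_curves(series_list: Sequence[CompressionSeries],
                          threshold: float = 10.0,
                          path: str | Path | None = None):
    """Percentage of the crowd above ``threshold`` vs area reduction."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for series in series_list:
        x = [r.area_reduction * 100.0 for r in series.records]
        y = [r.fraction_above[threshold] * 100.0 for r in series.records]
        ax.plot(x, y, marker="o", label=series.label)
    ax.set_xlabel("area reduction (%)")
    ax.set_ylabel(f"crowd above {threshold:g} people/m$^2$ (%)")
    ax.set_ylim(-2, 102)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
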