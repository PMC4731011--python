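"""Core in-memory containers shared by every pipeline stage.

The pipeline operates on gene x time expression matrices, one per molecular
level (RNA or protein) and biological replicate, sampled on a common ordered
time grid (hours).  Matrices are carried as :class:`pandas.DataFrame` objects
wrapped in a thin :class:`ExpressionMatrix` that tracks the molecular level
and whether values are on the natural (intensity) or natural-log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RNA = "rna"
PROTEIN = "protein"
NATURAL = "natural"
LOG = "log"

#: default sampling grid of the experimental design, in hours
DEFAULT_TIME_GRID = (0.0, 0.5, 1.0, 2.0, 8.0, 16.0, 24.0, 30.0)


class ConfigurationError(ValueError):
    """Raised when a configuration or matrix violates a structural contract."""


@dataclass
class ExpressionMatrix:
    """Gene x time expression values for one level and one replicate.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per time point.
        Columns must be convertible to float hours, strictly increasing.
    level
        ``"rna"`` or ``"protein"``.
    scale
        ``"natural"`` (non-negative intensities) or ``"log"`` (natural log).
    replicate
        1-based replicate label.
    """

    values: pd.DataFrame
    level: str
    scale: str = NATURAL
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.level not in (RNA, PROTEIN):
            raise ConfigurationError(f"unknown level {self.level!r}")
        if self.scale not in (NATURAL, LOG):
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        grid = np.asarray([float(c) for c in self.values.columns])
        if grid.size >= 2 and not np.all(np.diff(grid) > 0):
            raise ConfigurationError("time grid must be strictly increasing")
        if self.values.index.has_duplicates:
            raise ConfigurationError("duplicate gene ids")
        # normalise column labels to floats so joins across files line up
        self.values = self.values.copy()
        self.values.columns = grid

    @property
    def time_grid(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def copy_with(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            level=self.level,
            scale=self.scale if scale is None else scale,
            replicate=self.replicate,
        )


def interior_points(time_grid: np.ndarray) -> np.ndarray:
    """Interior time points — candidate change points (all but first and last)."""
    grid = np.asarray(time_grid, dtype=float)
    return grid[1:-1]


def interval_labels(time_grid: np.ndarray) -> list[str]:
    """Labels for the inter-timepoint intervals, e.g. ``"2-8"``."""
    grid = np.asarray(time_grid, dtype=float)
    return [f"{a:g}-{b:g}" for a, b in zip(grid[:-1], grid[1:])]


@dataclass
class KineticGroundTruth:
    """Simulation truth: per-interval log rate ratios and change indicators.

    ``theta`` maps level -> genes x intervals DataFrame of true log
    synthesis:degradation rate ratios; ``z`` maps level -> genes x interior
    time points {0,1} change indicators; ``pattern`` maps level -> Series of
    {"pulse", "switch", "null"} labels.  ``rates`` (ODE mode only) maps level
    -> dict of piecewise-constant synthesis/degradation rate DataFrames.
    """

    theta: dict[str, pd.DataFrame]
    z: dict[str, pd.DataFrame]
    pattern: dict[str, pd.Series]
    noise_sd: dict[str, float]
    rates: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)


@dataclass
class PecaFit:
    """Posterior summaries of the rate-ratio segmentation for one level/replicate.

    ``theta_mean``/``theta_sd`` are genes x intervals posterior summaries of
    the log rate ratio; ``cps`` is genes x interior points change-point
    scores in [0, 1]; ``direction`` holds the sign (+1/-1/0) of the
    posterior-mean rate-ratio difference across each interior point.
    ``cps_se`` carries Monte-Carlo standard errors in sampling mode.
    """

    theta_mean: pd.DataFrame
    theta_sd: pd.DataFrame
    cps: pd.DataFrame
    direction: pd.DataFrame
    cps_se: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> pd.Index:
        return self.cps.index
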