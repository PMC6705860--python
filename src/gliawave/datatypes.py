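"""Core containers shared across the analysis stages.

All physical quantities use the units of the imaging literature this package
targets: positions and lengths in micrometres (um), time in seconds, speeds
in um/min.  Image stacks are T x H x W arrays (time, rows, columns) with
pixel size in um/px and frame interval in seconds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "ImageStack",
    "Trajectory",
    "TurnEvent",
    "Kymograph",
    "EdgeTrace",
    "WaveMeasurement",
    "CorrelationResult",
]


@dataclass
class ImageStack:
    """Time-lapse image stack: intensity (0-255) or height map (um).

    Parameters
    ----------
    data
        T x H x W array.  A single 2-D frame is promoted to T=1.
    pixel_size
        Lateral sampling, um per pixel.
    frame_interval
        Time between frames, seconds.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ParameterError("stack data must be T x H x W with T >= 1")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ParameterError("pixel_size and frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) * float(self.frame_interval)

    def extent_um(self) -> tuple:
        """(width_um, height_um) of one frame."""
        _, h, w = self.data.shape
        return w * self.pixel_size, h * self.pixel_size


@dataclass
class Trajectory:
    """Centroid trajectory with optional smoothed path and curvature series.

    ``times`` are seconds, positions um.  ``curvature`` and
    ``filtered_curvature`` are signed planar curvature in 1/um, aligned
    sample-for-sample with ``times``.
    """

    times: np.ndarray
    raw_xy: np.ndarray
    smooth_xy: np.ndarray | None = None
    curvature: np.ndarray | None = None
    filtered_curvature: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.raw_xy = np.asarray(self.raw_xy, dtype=float)
        if self.raw_xy.ndim != 2 or self.raw_xy.shape[1] != 2:
            raise ParameterError("raw_xy must be an (N, 2) array")
        if len(self.times) != len(self.raw_xy):
            raise ParameterError("times and raw_xy must have equal length")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ParameterError("times must be strictly increasing")
            if np.ptp(dt) > 1e-6 * max(1.0, dt[0]):
                raise ParameterError("times must be uniformly spaced")
        for name in ("smooth_xy", "curvature", "filtered_curvature"):
            val = getattr(self, name)
            if val is not None and len(val) != len(self.times):
                raise ParameterError(f"{name} must align with times")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        if len(self.times) < 2:
            raise ParameterError("trajectory too short to define dt")
        return float(self.times[1] - self.times[0])

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_s": self.times, "x_um": self.raw_xy[:, 0], "y_um": self.raw_xy[:, 1]}
        if self.smooth_xy is not None:
            cols["x_smooth_um"] = self.smooth_xy[:, 0]
            cols["y_smooth_um"] = self.smooth_xy[:, 1]
        if self.curvature is not None:
            cols["k_per_um"] = self.curvature
        if self.filtered_curvature is not None:
            cols["k_filtered"] = self.filtered_curvature
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class TurnEvent:
    """A detected turning point of a crawling trajectory.

    ``alpha`` is the absolute heading change (degrees, 0-180) between the mean
    heading of the run preceding the event and the run following it;
    ``k_extremum`` is the filtered-curvature value at the extremum (1/um).
    """

    time: float
    position: tuple
    alpha: float
    k_extremum: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 180.0):
            raise ParameterError("alpha must lie in [0, 180] degrees")


@dataclass
class Kymograph:
    """Space x time matrix sampled along a line.

    Rows are positions along the line (step ``space_step`` um), columns are
    frames (step ``time_step`` s).  ``line`` stores the ((x0, y0), (x1, y1))
    endpoints in um defining the 1-D space; position 0 is the first endpoint.
    """

    data: np.ndarray
    line: tuple
    space_step: float
    time_step: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or min(self.data.shape) < 2:
            raise ParameterError("kymograph must be S x T with S, T >= 2")
        if self.space_step <= 0 or self.time_step <= 0:
            raise ParameterError("space_step and time_step must be > 0")

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.space_step

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) * self.time_step


@dataclass
class EdgeTrace:
    """Leading-edge position (um along a kymograph line) over time (s)."""

    times: np.ndarray
    edge_position: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.edge_position = np.asarray(self.edge_position, dtype=float)
        if len(self.times) != len(self.edge_position):
            raise ParameterError("times and edge_position must align")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class WaveMeasurement:
    """Summary geometry/kinetics of one wave class (ruffle or dorsal).

    Mirrors the standard reporting columns: period (with sd), propagation
    speed (um/min; None for non-propagating ruffles), height, width and
    length in um.  ``n`` is the number of components/events aggregated.
    """

    period: float | None = None
    period_sd: float | None = None
    speed: float | None = None
    speed_sd: float | None = None
    height: float | None = None
    height_sd: float | None = None
    width: float | None = None
    width_sd: float | None = None
    length: float | None = None
    length_sd: float | None = None
    n: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


@dataclass
class CorrelationResult:
    """Normalised lagged cross-correlation C_tau on a symmetric lag grid.

    ``lags`` are in the time units of the input sampling step; ``values`` are
    dimensionless and bounded by 1 in magnitude (up to numerical tolerance);
    ``n_samples[i]`` is the overlap count used at ``lags[i]``.
    """

    lags: np.ndarray
    values: np.ndarray
    n_samples: np.ndarray
    primary_peak_lag: float | None = None
    primary_peak_value: float | None = None
    global_peak_lag: float | None = None
    global_peak_value: float | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_samples = np.asarray(self.n_samples, dtype=int)
        if not (len(self.lags) == len(self.values) == len(self.n_samples)):
            raise ParameterError("lags, values, n_samples must align")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"lag": self.lags, "C": self.values, "N": self.n_samples})
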