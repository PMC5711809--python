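"""Reduction of raw MST fluorescence time traces to binding responses.

An MST trace records capillary fluorescence before and during IR-laser
heating (time zero = laser on).  The normalized response combines the fast
temperature-jump change of the fluorophore with the slower thermophoretic
depletion, and is computed as the ratio of the mean fluorescence in a "hot"
window (laser on, default 27–29 s) to a "cold" window (before the laser,
default -3 – -1 s), conventionally scaled per-mil:

    Fnorm = 1000 * mean(F_hot) / mean(F_cold)

An optional cold-anchored linear detrend removes photobleaching drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthgen import TitrationDataset

__all__ = [
    "MstTrace",
    "WindowConfig",
    "fnorm",
    "traces_to_dataset",
    "merge_replicates",
    "load_traces",
    "save_traces",
]

#: Per-mil scaling of the hot/cold ratio (instrument-vendor convention).
FNORM_SCALE = 1000.0


@dataclass(frozen=True)
class MstTrace:
    """One capillary's fluorescence time course at a known ligand concentration."""

    capillary_id: int
    ligand_concentration_nM: float
    times_s: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "fluorescence", f)
        if t.ndim != 1 or t.shape != f.shape:
            raise ValueError("times and fluorescence must be 1-D arrays of equal length")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(f < 0):
            raise ValueError("fluorescence must be non-negative")
        if not self.ligand_concentration_nM > 0:
            raise ValueError("ligand concentration must be positive")


@dataclass(frozen=True)
class WindowConfig:
    """Cold (pre-laser) and hot (laser-on) averaging windows in seconds."""

    cold: tuple[float, float] = (-3.0, -1.0)
    hot: tuple[float, float] = (27.0, 29.0)

    def __post_init__(self) -> None:
        for name in ("cold", "hot"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} window start must be before its end")
        if not self.cold[1] <= 0:
            raise ValueError("cold window must lie entirely before time zero")


def _window_values(trace: MstTrace, window: tuple[float, float], name: str) -> np.ndarray:
    mask = (trace.times_s >= window[0]) & (trace.times_s <= window[1])
    if not mask.any():
        raise ValueError(f"{name} window {window} contains no samples")
    return trace.fluorescence[mask], trace.times_s[mask]


def fnorm(
    trace: MstTrace,
    windows: WindowConfig | None = None,
    scale: float = FNORM_SCALE,
    detrend: bool = False,
) -> float:
    """Normalized response: ``scale * mean(F_hot) / mean(F_cold)``.

    With ``detrend=True`` a line is fitted to the cold-window samples and the
    hot-window mean is referenced to that line extrapolated into the hot
    window, removing any linear bleaching drift (for a purely linear drift
    the result is exactly ``scale``, independent of the slope).
    """
    windows = windows or WindowConfig()
    f_cold, t_cold = _window_values(trace, windows.cold, "cold")
    f_hot, t_hot = _window_values(trace, windows.hot, "hot")
    if detrend:
        if t_cold.size >= 2 and np.ptp(t_cold) > 0:
            slope, intercept = np.polyfit(t_cold, f_cold, 1)
        else:
            slope, intercept = 0.0, float(np.mean(f_cold))
        baseline = float(np.mean(intercept + slope * t_hot))
    else:
        baseline = float(np.mean(f_cold))
    if baseline == 0:
        raise ValueError("cold-window mean fluorescence is zero")
    return scale * float(np.mean(f_hot)) / baseline


def traces_to_dataset(
    traces: list[MstTrace],
    windows: WindowConfig | None = None,
    replicate_id: int = 1,
    detrend: bool = False,
) -> TitrationDataset:
    """One dataset point per capillary, ordered by descending concentration.

    Duplicate concentrations trigger a warning but both points are kept.
    """
    if not traces:
        raise ValueError("no traces given")
    rows = [
        {
            "replicate": replicate_id,
            "concentration_nM": tr.ligand_concentration_nM,
            "response": fnorm(tr, windows, detrend=detrend),
            "capillary": tr.capillary_id,
        }
        for tr in traces
    ]
    df = pd.DataFrame(rows).sort_values("concentration_nM", ascending=False, ignore_index=True)
    dupes = df["concentration_nM"].duplicated()
    if dupes.any():
        warnings.warn(
            f"duplicate ligand concentrations in replicate {replicate_id}: "
            f"{sorted(df.loc[dupes, 'concentration_nM'])}; keeping all points",
            stacklevel=2,
        )
    # a standalone dataset must carry contiguous replicate ids starting at 1;
    # use merge_replicates to combine several reduced series
    df["replicate"] = 1
    df.attrs["source_replicate_id"] = replicate_id
    return TitrationDataset(data=df)


def merge_replicates(datasets: list[TitrationDataset]) -> TitrationDataset:
    """Stack single-replicate datasets, renumbering replicates 1..k."""
    if not datasets:
        raise ValueError("no datasets given")
    frames = []
    for i, ds in enumerate(datasets, start=1):
        df = ds.data.copy()
        df["replicate"] = i
        frames.append(df)
    return TitrationDataset(data=pd.concat(frames, ignore_index=True))


def load_traces(path: str | Path) -> list[MstTrace]:
    """Read traces from long-format delimited text.

    Columns: ``capillary, concentration_nM, time_s, fluorescence``; lines
    starting with '#' are metadata and skipped.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = ("capillary", "concentration_nM", "time_s", "fluorescence")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    traces = []
    for cap, grp in df.groupby("capillary", sort=True):
        grp = grp.sort_values("time_s")
        conc = grp["concentration_nM"].unique()
        if conc.size != 1:
            raise ValueError(f"{path}: capillary {cap} has inconsistent concentrations {conc}")
        traces.append(
            MstTrace(
                capillary_id=int(cap),
                ligand_concentration_nM=float(conc[0]),
                times_s=grp["time_s"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
            )
        )
    return traces


def save_traces(traces: list[MstTrace], path: str | Path) -> None:
    """Write traces in the long CSV format read by :func:`load_traces`."""
    frames = [
        pd.DataFrame(
            {
                "capillary": tr.capillary_id,
                "concentration_nM": tr.ligand_concentration_nM,
                "time_s": tr.times_s,
                "fluorescence": tr.fluorescence,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
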