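"""Event-level cytometry primitives.

Implements the study's bespoke measurements: the merged virtual MB channel
(per-event sum of the AF647, AF700 and APC-Cy7 signals, widening detection to
655-810 nm), geometric mean fluorescence intensity (MFI), the
fluorescence-minus-one (FMO) derived MB-high gate, and the red-shift ratio
(APC-Cy7 : AF647 geometric-MFI ratio), plus scatter-box gating and FCS/CSV
event reading.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fcsio

__all__ = [
    "ChannelMap",
    "GateDefinition",
    "DEFAULT_CHANNEL_MAP",
    "read_events",
    "merge_mb_channel",
    "spectral_to_conventional",
    "spectral_bin_columns",
    "geometric_mfi",
    "fmo_threshold",
    "classify_mb",
    "redshift_ratio",
    "scatter_gate",
    "GEOMETRIC_MFI_FLOOR",
]

log = logging.getLogger(__name__)

#: Geometric means are computed on max(value, floor); the floor absorbs zero
#: and (clipped) negative intensities without discarding events.
GEOMETRIC_MFI_FLOOR = 1.0

MIN_FMO_EVENTS = 200


@dataclass(frozen=True)
class ChannelMap:
    """Names of the MB-detecting channels and the derived merged channel."""

    af647: str = "AF647"
    af700: str = "AF700"
    apccy7: str = "APC-Cy7"
    merged: str = "MB_merged"
    markers: tuple[str, ...] = ("CD11b", "CD66b", "CD45", "CD62L", "CD14", "CD16")

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        src = (self.af647, self.af700, self.apccy7)
        if len(set(src)) != 3:
            raise ValueError("the three MB source channels must be distinct")
        if self.merged in src:
            raise ValueError("merged channel must not collide with a source channel")

    @property
    def sources(self) -> tuple[str, str, str]:
        return (self.af647, self.af700, self.apccy7)


DEFAULT_CHANNEL_MAP = ChannelMap()

#: Detection windows backing the conventional channels (nm).
CHANNEL_WINDOWS = {"AF647": (655.0, 685.0), "AF700": (705.0, 750.0),
                   "APC-Cy7": (750.0, 810.0)}


@dataclass(frozen=True)
class GateDefinition:
    """A scatter box or a 1-D lower-threshold gate."""

    kind: str  # "scatter_box" | "threshold_1d"
    channels: tuple[str, ...]
    bounds: tuple[float, ...]  # box: (lo1, hi1, lo2, hi2); threshold: (cutoff,)
    provenance: str = "manual"  # "manual" | "FMO-derived"

    def __post_init__(self) -> None:
        if self.kind not in ("scatter_box", "threshold_1d"):
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if not all(np.isfinite(self.bounds)):
            raise ValueError("gate bounds must be finite")
        if self.kind == "threshold_1d" and (len(self.channels), len(self.bounds)) != (1, 1):
            raise ValueError("threshold_1d takes one channel and one lower cutoff")
        if self.kind == "scatter_box" and (len(self.channels), len(self.bounds)) != (2, 4):
            raise ValueError("scatter_box takes two channels and four bounds")

    @property
    def threshold(self) -> float:
        if self.kind != "threshold_1d":
            raise AttributeError("threshold is defined for threshold_1d gates only")
        return self.bounds[0]


def read_events(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read an FCS 3.1 file (or the CSV/TSV tabular fallback) to an event table."""
    table = fcsio.read_events_table(path)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise KeyError(f"{Path(path).name}: missing required channel(s) {missing}")
    return table


def spectral_bin_columns(t: pd.DataFrame) -> list[tuple[str, float, float]]:
    """(column, lo_nm, hi_nm) for every wavelength-bin channel in the table."""
    out = []
    for col in t.columns:
        if col.startswith("MB_") and col.endswith("nm"):
            try:
                _, lo, hi = col[:-2].split("_")
                out.append((col, float(lo), float(hi)))
            except ValueError:
                continue
    return out


def _bin_window_sum(t: pd.DataFrame, lo: float, hi: float) -> pd.Series:
    """Overlap-weighted sum of wavelength-bin channels over [lo, hi] nm."""
    total = pd.Series(0.0, index=t.index)
    for col, blo, bhi in spectral_bin_columns(t):
        ov = max(0.0, min(hi, bhi) - max(lo, blo))
        if ov > 0:
            total = total + t[col] * (ov / (bhi - blo))
    return total


def spectral_to_conventional(t: pd.DataFrame, m: ChannelMap = DEFAULT_CHANNEL_MAP) -> pd.DataFrame:
    """Derive virtual AF647/AF700/APC-Cy7 columns from wavelength bins."""
    if not spectral_bin_columns(t):
        raise ValueError("table has no MB_<lo>_<hi>nm wavelength-bin channels")
    out = t.copy()
    for name, (lo, hi) in CHANNEL_WINDOWS.items():
        target = {"AF647": m.af647, "AF700": m.af700, "APC-Cy7": m.apccy7}[name]
        out[target] = _bin_window_sum(t, lo, hi)
    return out


def merge_mb_channel(t: pd.DataFrame, m: ChannelMap = DEFAULT_CHANNEL_MAP) -> pd.DataFrame:
    """Add the merged virtual MB channel (per-event sum of the three sources).

    Negative input intensities are clipped to zero first (count logged), so
    the merged value dominates each component per event.
    """
    missing = [c for c in m.sources if c not in t.columns]
    if missing:
        raise KeyError(f"missing MB source channel(s) {missing}")
    src = t[list(m.sources)].to_numpy(dtype=float)
    n_neg = int((src < 0).sum())
    if n_neg:
        log.warning("clipped %d negative MB-channel values to 0 before merging", n_neg)
        src = np.clip(src, 0.0, None)
    out = t.copy()
    out[m.merged] = src.sum(axis=1)
    return out


def geometric_mfi(values, floor: float = GEOMETRIC_MFI_FLOOR) -> float:
    """exp(mean(log(max(v, floor)))): the geometric mean fluorescence intensity."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("geometric MFI of an empty sample is undefined")
    clipped = np.maximum(v, floor)
    if np.all(clipped == floor):
        warnings.warn("all values at or below the floor; MFI returned as the floor",
                      stacklevel=2)
        return float(floor)
    return float(np.exp(np.mean(np.log(clipped))))


def fmo_threshold(control: pd.DataFrame, channel: str, percentile: float = 99.5) -> GateDefinition:
    """MB-high cutoff from a fluorescence-minus-one control.

    The control (cells cocultured with unlabeled bacteria, gated to the target
    population) carries everything except the dye; the stated percentile of
    its channel distribution separates MB-low from MB-high.
    """
    if channel not in control.columns:
        raise KeyError(f"control table has no channel {channel!r}")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    if len(control) < MIN_FMO_EVENTS:
        raise ValueError(
            f"FMO control has {len(control)} events; need >= {MIN_FMO_EVENTS} "
            "for a stable threshold")
    cutoff = float(np.percentile(control[channel].to_numpy(dtype=float), percentile))
    return GateDefinition(kind="threshold_1d", channels=(channel,), bounds=(cutoff,),
                          provenance="FMO-derived")


def classify_mb(t: pd.DataFrame, gate: GateDefinition) -> tuple[pd.Series, dict[str, int]]:
    """Partition events into MB_hi / MB_lo; counts always sum to the table size."""
    if gate.kind != "threshold_1d":
        raise ValueError("classify_mb needs a threshold_1d gate")
    channel = gate.channels[0]
    if channel not in t.columns:
        raise KeyError(f"table has no channel {channel!r}")
    hi = t[channel].to_numpy(dtype=float) > gate.threshold
    labels = pd.Series(np.where(hi, "MB_hi", "MB_lo"), index=t.index, name="mb_class")
    return labels, {"MB_hi": int(hi.sum()), "MB_lo": int((~hi).sum())}


def redshift_ratio(t: pd.DataFrame, m: ChannelMap = DEFAULT_CHANNEL_MAP) -> float:
    """APC-Cy7 : AF647 geometric-MFI ratio of a (pre-gated) population.

    Brightness-invariant: scaling all MB channels by a > 0 leaves it unchanged
    as long as values stay above the geometric-mean floor.
    """
    for c in (m.apccy7, m.af647):
        if c not in t.columns:
            raise KeyError(f"table has no channel {c!r}")
    den = geometric_mfi(t[m.af647])
    if den <= GEOMETRIC_MFI_FLOOR:
        raise ValueError("AF647 MFI at the floor: red-shift ratio undefined")
    return geometric_mfi(t[m.apccy7]) / den


def scatter_gate(t: pd.DataFrame, g: GateDefinition) -> pd.DataFrame:
    """Subset events inside a scatter box (bounds inclusive)."""
    if g.kind != "scatter_box":
        raise ValueError("scatter_gate needs a scatter_box gate")
    c1, c2 = g.channels
    lo1, hi1, lo2, hi2 = g.bounds
    mask = t[c1].between(lo1, hi1) & t[c2].between(lo2, hi2)
    out = t[mask]
    if out.empty:
        warnings.warn("scatter gate excluded all events", stacklevel=2)
    return out


#: Default granulocyte (SSC-high / FSC-high) box for the simulator's scale.
GRANULOCYTE_GATE = GateDefinition(
    kind="scatter_box", channels=("FSC", "SSC"),
    bounds=(480.0, 1e9, 430.0, 1e9), provenance="manual")
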