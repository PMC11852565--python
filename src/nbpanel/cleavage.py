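"""Cleavage-inhibition quantification from gel band densitometry.

A nuclease time course is sampled by quenching aliquots at fixed times and
resolving uncut substrate from cleavage products on a gel.  Band
intensities (already proportional to mass x stain) give

    percent cleavage = 100 * sum(products) / (uncut + sum(products))

per lane.  Triplicate lanes are averaged into a time course, and an
inhibition verdict compares a nanobody-treated course against the
RNP-alone control: the call is non-inhibitory when the absolute percent
difference stays within a threshold (default 15 points) at every shared
time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GelLane",
    "CleavageTimeCourse",
    "percent_cleavage",
    "build_time_course",
    "compare_inhibition",
    "InhibitionVerdict",
    "lanes_from_frame",
    "lanes_to_frame",
]


@dataclass(frozen=True)
class GelLane:
    """One gel lane: uncut band plus product bands, arbitrary units."""

    condition: str
    time_min: float
    uncut: float
    products: tuple[float, ...]
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.uncut < 0 or any(p < 0 for p in self.products):
            raise ValueError("band intensities must be non-negative")


def percent_cleavage(lane: GelLane, product_weights: tuple[float, ...] | None = None) -> float:
    """Fraction of substrate converted to products, as a percentage.

    ``product_weights`` rescales individual product bands before summing
    (default: unweighted — stain intensity already scales with mass).
    """
    products = np.asarray(lane.products, dtype=float)
    if product_weights is not None:
        if len(product_weights) != len(products):
            raise ValueError("one weight per product band required")
        products = products * np.asarray(product_weights, dtype=float)
    total = lane.uncut + products.sum()
    if total <= 0:
        raise ValueError(f"lane {lane.condition!r} @ {lane.time_min} min: all bands zero")
    return 100.0 * products.sum() / total


@dataclass
class CleavageTimeCourse:
    """Replicate-averaged percent-cleavage series for one condition."""

    condition: str
    times: np.ndarray
    mean_percent: np.ndarray
    sd_percent: np.ndarray
    n_replicates: int

    def interpolate(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if times.min() < self.times.min() or times.max() > self.times.max():
            raise ValueError("requested times outside the measured range")
        return np.interp(times, self.times, self.mean_percent)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "time_min": self.times,
                "mean_percent": self.mean_percent,
                "sd_percent": self.sd_percent,
            }
        )


def build_time_course(lanes: list[GelLane]) -> CleavageTimeCourse:
    """Assemble lanes of one condition into an ordered time course.

    Replicates at each time are averaged; the spread is the sample
    standard deviation (ddof=1, zero for a single lane).  Duplicate times
    within one replicate are an input error.
    """
    if not lanes:
        raise ValueError("no lanes")
    conditions = {lane.condition for lane in lanes}
    if len(conditions) != 1:
        raise ValueError(f"mixed conditions in one course: {sorted(conditions)}")
    seen: set[tuple[int, float]] = set()
    for lane in lanes:
        key = (lane.replicate, lane.time_min)
        if key in seen:
            raise ValueError(f"duplicate time {lane.time_min} min in replicate {lane.replicate}")
        seen.add(key)
    by_time: dict[float, list[float]] = {}
    for lane in lanes:
        by_time.setdefault(lane.time_min, []).append(percent_cleavage(lane))
    times = np.array(sorted(by_time))
    if len(times) < 2:
        raise ValueError("a time course needs >= 2 time points")
    means = np.array([np.mean(by_time[t]) for t in times])
    sds = np.array([np.std(by_time[t], ddof=1) if len(by_time[t]) > 1 else 0.0 for t in times])
    return CleavageTimeCourse(
        condition=lanes[0].condition,
        times=times,
        mean_percent=means,
        sd_percent=sds,
        n_replicates=max(len(v) for v in by_time.values()),
    )


def lanes_from_frame(df: pd.DataFrame) -> list[GelLane]:
    """Build lanes from long-format rows.

    Expected columns: ``condition, replicate, time_min, band_role,
    intensity`` with ``band_role`` one of ``uncut``/``product``.
    """
    lanes = []
    keys = ["condition", "replicate", "time_min"]
    for (condition, rep, t), sub in df.groupby(keys, sort=False):
        roles = set(sub["band_role"])
        if not roles <= {"uncut", "product"}:
            raise ValueError(f"unknown band_role values: {sorted(roles - {'uncut', 'product'})}")
        uncut = float(sub.loc[sub["band_role"] == "uncut", "intensity"].sum())
        products = tuple(sub.loc[sub["band_role"] == "product", "intensity"].astype(float))
        lanes.append(GelLane(condition=str(condition), time_min=float(t),
                             uncut=uncut, products=products, replicate=int(rep)))
    return lanes


def lanes_to_frame(lanes: list[GelLane]) -> pd.DataFrame:
    """Inverse of :func:`lanes_from_frame`."""
    rows = []
    for lane in lanes:
        rows.append((lane.condition, lane.replicate, lane.time_min, "uncut", lane.uncut))
        for p in lane.products:
            rows.append((lane.condition, lane.replicate, lane.time_min, "product", p))
    return pd.DataFrame(rows, columns=["condition", "replicate", "time_min", "band_role", "intensity"])


@dataclass(frozen=True)
class InhibitionVerdict:
    inhibitory: bool
    max_abs_difference: float
    worst_time_min: float
    threshold: float


def compare_inhibition(
    control: CleavageTimeCourse,
    treated: CleavageTimeCourse,
    *,
    threshold: float = 15.0,
) -> InhibitionVerdict:
    """Compare a treated course against the no-nanobody control.

    Both courses are evaluated on the shared part of their time grids
    (linear interpolation where grids differ).  The verdict magnitude is
    symmetric in the argument order.
    """
    lo = max(control.times.min(), treated.times.min())
    hi = min(control.times.max(), treated.times.max())
    if lo >= hi:
        raise ValueError("time ranges do not overlap")
    grid = np.union1d(control.times, treated.times)
    grid = grid[(grid >= lo) & (grid <= hi)]
    diff = control.interpolate(grid) - treated.interpolate(grid)
    worst = int(np.argmax(np.abs(diff)))
    max_abs = float(np.abs(diff[worst]))
    return InhibitionVerdict(
        inhibitory=max_abs > threshold,
        max_abs_difference=max_abs,
        worst_time_min=float(grid[worst]),
        threshold=threshold,
    )
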