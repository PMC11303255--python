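"""PNN hole detection and per-hole marker occupancy on WFA line profiles.

A PNN hole is a contiguous drop of the contour WFA intensity below a
threshold set at 40–66 % of the unsaturated peak intensity, at least 0.5 µm
wide.  The threshold fraction is chosen per cell as the one covering the
maximum number of qualifying drops; hole boundaries are sub-sample
interpolated threshold crossings, so the 0.5-µm cutoff does not depend on the
sampling step.  Per-hole occupancy by an astrocytic or synaptic channel is
called from the presence of a clearly distinguishable intra-hole peak,
operationalised as boundary-referenced prominence of at least ``k_sigma``
robust noise standard deviations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SaturationError, ValidationError
from .profiles import LineProfile

__all__ = [
    "ThresholdResult",
    "Hole",
    "HoleSet",
    "OccupancyCall",
    "OccupancyTable",
    "unsaturated_peak",
    "select_threshold",
    "detect_holes",
    "classify_occupancy",
    "occupancy_summary",
    "holes_per_perimeter",
]

W_MIN_DEFAULT = 0.5  # µm; resolution-limit-motivated minimum hole width


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    fraction_of_peak: float
    unsaturated_peak: float
    n_holes_at_threshold: int


@dataclass(frozen=True)
class Hole:
    """A circular half-open arc interval [start_s, end_s) of width ≥ w_min µm."""

    index: int
    start_s: float
    end_s: float
    width: float


@dataclass
class HoleSet:
    holes: list[Hole]
    threshold_used: ThresholdResult | None
    perimeter: float

    def __len__(self) -> int:
        return len(self.holes)

    def widths(self) -> np.ndarray:
        return np.array([h.width for h in self.holes])

    def to_frame(self, cell_id: str | int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "hole_index": [h.index for h in self.holes],
                "start_s": [h.start_s for h in self.holes],
                "end_s": [h.end_s for h in self.holes],
                "width": [h.width for h in self.holes],
            }
        )
        if cell_id is not None:
            df.insert(0, "cell_id", cell_id)
        return df


@dataclass(frozen=True)
class OccupancyCall:
    hole_index: int
    channel: str
    present: bool
    peak_position: float | None = None
    peak_prominence: float | None = None


@dataclass
class OccupancyTable:
    """Per-cell and cohort occupancy percentages over marker combinations."""

    per_cell: pd.DataFrame  # index: cell, columns: combination / marginal / any / none
    cohort_mean: pd.Series
    cohort_sd: pd.Series
    pooled: pd.Series  # pooled-hole percentages, same columns
    channels: tuple[str, ...]
    n_holes_per_cell: pd.Series


def unsaturated_peak(profile: LineProfile, channel: str, saturation_level: float) -> float:
    """Maximum sample strictly below the saturation level.

    The threshold of hole detection is anchored to the brightest *unsaturated*
    WFA sample, so clipped pixels cannot inflate it.
    """
    x = profile.intensities[channel]
    if x.size == 0:
        raise ValidationError("empty profile")
    below = x[x < saturation_level]
    if below.size == 0:
        raise SaturationError("all profile samples are saturated")
    return float(below.max())


def _interp_crossing(s_prev, v_prev, s_next, v_next, threshold, L):
    """Sub-sample position where the profile crosses the threshold."""
    if v_prev == v_next:
        return s_prev % L
    frac = (v_prev - threshold) / (v_prev - v_next)
    step = (s_next - s_prev) % L
    return (s_prev + frac * step) % L


def detect_holes(
    profile: LineProfile,
    channel: str,
    threshold: float,
    w_min: float = W_MIN_DEFAULT,
) -> HoleSet:
    """Detect holes as maximal circular runs strictly below a threshold.

    Runs wrapping the profile origin are merged into one; boundaries are
    linearly interpolated threshold crossings; runs narrower than ``w_min``
    µm are discarded.  Any single supra-threshold sample splits a run.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    x = profile.intensities[channel]
    s = profile.s
    n = x.size
    L = profile.L
    below = x < threshold
    holes: list[Hole] = []
    if below.all():
        holes = [Hole(0, 0.0, 0.0, L)] if L >= w_min else []
        return HoleSet(holes=holes, threshold_used=None, perimeter=L)
    if below.any():
        k = int(np.argmin(below))  # first above-threshold sample
        b = np.roll(below, -k)
        padded = np.concatenate([[False], b, [False]])
        starts = np.nonzero(~padded[:-1] & padded[1:])[0]
        ends = np.nonzero(padded[:-1] & ~padded[1:])[0]
        raw: list[tuple[float, float]] = []
        for i0, i1 in zip(starts, ends):  # run occupies rolled samples [i0, i1)
            pa = (k + i0 - 1) % n  # last above sample before the run
            pb = (k + i0) % n  # first below sample
            qa = (k + i1 - 1) % n  # last below sample
            qb = (k + i1) % n  # first above sample after the run
            start_s = _interp_crossing(s[pa], x[pa], s[pb], x[pb], threshold, L)
            end_s = _interp_crossing(s[qa], x[qa], s[qb], x[qb], threshold, L)
            raw.append((start_s, end_s))
        raw.sort(key=lambda t: t[0])
        idx = 0
        for start_s, end_s in raw:
            width = (end_s - start_s) % L
            if width >= w_min - 1e-12:
                holes.append(Hole(idx, start_s, end_s, width))
                idx += 1
    return HoleSet(holes=holes, threshold_used=None, perimeter=L)


def select_threshold(
    profile: LineProfile,
    channel: str,
    saturation_level: float = 4095.0,
    f_min: float = 0.40,
    f_max: float = 0.66,
    f_step: float = 0.01,
    w_min: float = W_MIN_DEFAULT,
) -> ThresholdResult:
    """Sweep the threshold fraction and keep the one maximising the hole count.

    Fractions run over ``[f_min, f_max]`` in ``f_step`` increments of the
    unsaturated peak; ties break toward the smallest fraction (the most
    conservative hole boundaries).
    """
    if not (0.0 < f_min < f_max < 1.0):
        raise ValidationError("need 0 < f_min < f_max < 1")
    peak = unsaturated_peak(profile, channel, saturation_level)
    fractions = np.round(np.arange(f_min, f_max + f_step / 2, f_step), 9)
    counts = [
        len(detect_holes(profile, channel, float(f) * peak, w_min)) for f in fractions
    ]
    best = int(np.argmax(counts))  # first occurrence == smallest fraction
    f_best = float(fractions[best])
    return ThresholdResult(
        threshold=f_best * peak,
        fraction_of_peak=f_best,
        unsaturated_peak=peak,
        n_holes_at_threshold=int(counts[best]),
    )


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise sd from the median absolute deviation of first differences.

    ``sd = 1.4826 * MAD(diff(x)) / sqrt(2)`` — insensitive to the slow signal
    structure (ring, bumps) that dominates the raw variance.
    """
    d = np.diff(np.asarray(x, dtype=float))
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _interp_at(profile: LineProfile, channel: str, pos: float) -> float:
    """Linear circular interpolation of a channel at arc position ``pos``."""
    x = profile.intensities[channel]
    n = x.size
    u = (pos % profile.L) / profile.ds
    i0 = int(np.floor(u)) % n
    i1 = (i0 + 1) % n
    frac = u - np.floor(u)
    return float((1 - frac) * x[i0] + frac * x[i1])


def classify_occupancy(
    holes: HoleSet,
    profile: LineProfile,
    channel: str,
    k_sigma: float = 5.0,
) -> list[OccupancyCall]:
    """Call per-hole presence of a marker channel.

    A hole is occupied when the channel has a local maximum strictly inside
    the hole whose prominence over the higher of the channel values at the two
    hole boundaries reaches ``k_sigma`` times the channel's robust noise sd.
    """
    if channel not in profile.intensities:
        raise ValidationError(f"channel {channel!r} not in profile")
    x = profile.intensities[channel]
    s = profile.s
    n = x.size
    L = profile.L
    sigma = robust_noise_sd(x)
    calls: list[OccupancyCall] = []
    for hole in holes.holes:
        if hole.width >= L:  # degenerate whole-circle hole
            inside = np.ones(n, dtype=bool)
        else:
            if hole.end_s >= hole.start_s:
                inside = (s > hole.start_s) & (s < hole.end_s)
            else:
                inside = (s > hole.start_s) | (s < hole.end_s)
        idx_in = np.nonzero(inside)[0]
        if idx_in.size == 0:
            calls.append(OccupancyCall(hole.index, channel, False))
            continue
        peak_rel = int(np.argmax(x[idx_in]))
        p = idx_in[peak_rel]
        is_local_max = x[p] >= x[(p - 1) % n] and x[p] >= x[(p + 1) % n]
        b1 = _interp_at(profile, channel, hole.start_s)
        b2 = _interp_at(profile, channel, hole.end_s)
        prominence = float(x[p] - max(b1, b2))
        present = bool(is_local_max and prominence > 0 and prominence >= k_sigma * sigma)
        calls.append(
            OccupancyCall(
                hole.index,
                channel,
                present,
                peak_position=float(s[p]) if present else None,
                peak_prominence=prominence if present else None,
            )
        )
    return calls


def _combo_label(combo: tuple[str, ...]) -> str:
    return "+".join(combo) if combo else "none"


def calls_to_frame(calls_by_channel: dict[str, list[OccupancyCall]]) -> pd.DataFrame:
    """Wide boolean table (one row per hole, one column per channel)."""
    cols = {}
    for ch, calls in calls_by_channel.items():
        cols[ch] = pd.Series(
            {c.hole_index: c.present for c in calls}, dtype=bool
        ).sort_index()
    return pd.DataFrame(cols)


def occupancy_summary(
    calls_by_cell: dict[str | int, pd.DataFrame] | dict[str | int, dict[str, list[OccupancyCall]]],
    channels: list[str],
) -> OccupancyTable:
    """Summarise occupancy over cells: exclusive partition plus derived unions.

    Input is a per-cell wide boolean table (or per-channel call lists) over
    ``channels``.  For each cell the percentages over the exclusive
    combination partition are computed (summing to 100), plus per-channel
    marginals, pairwise intersections, "any" and "none"; cohort mean ± sd
    across cells and pooled-hole percentages are reported alongside.
    """
    if not calls_by_cell:
        raise ValidationError("no cells supplied")
    frames: dict = {}
    for cell, val in calls_by_cell.items():
        df = val if isinstance(val, pd.DataFrame) else calls_to_frame(val)
        if df.empty:
            raise ValidationError(f"cell {cell!r} has no holes")
        missing = [c for c in channels if c not in df.columns]
        if missing:
            raise ValidationError(f"cell {cell!r} lacks channels {missing}")
        frames[cell] = df[channels].astype(bool)

    combos = [
        tuple(c for c in channels if c in subset)
        for r in range(len(channels), -1, -1)
        for subset in itertools.combinations(channels, r)
    ]

    def _percent(df: pd.DataFrame) -> pd.Series:
        n = len(df)
        out = {}
        for combo in combos:
            mask = np.ones(n, dtype=bool)
            for ch in channels:
                mask &= df[ch].to_numpy() == (ch in combo)
            out[_combo_label(combo)] = 100.0 * mask.sum() / n
        for ch in channels:  # marginals
            out[ch] = 100.0 * df[ch].sum() / n
        for a, b in itertools.combinations(channels, 2):
            out[f"{a}&{b}"] = 100.0 * (df[a] & df[b]).sum() / n
        any_mask = df.any(axis=1)
        out["any"] = 100.0 * any_mask.sum() / n
        return pd.Series(out)

    per_cell = pd.DataFrame({cell: _percent(df) for cell, df in frames.items()}).T
    pooled = _percent(pd.concat(frames.values(), ignore_index=True))
    return OccupancyTable(
        per_cell=per_cell,
        cohort_mean=per_cell.mean(axis=0),
        cohort_sd=per_cell.std(axis=0, ddof=1) if len(per_cell) > 1 else per_cell.iloc[0] * 0.0,
        pooled=pooled,
        channels=tuple(channels),
        n_holes_per_cell=pd.Series({cell: len(df) for cell, df in frames.items()}),
    )


def holes_per_perimeter(holes: HoleSet) -> float:
    """Hole count normalised to the cell perimeter (count / µm)."""
    if holes.perimeter <= 0:
        raise ValidationError("perimeter must be positive")
    return len(holes) / holes.perimeter
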