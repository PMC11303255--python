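"""Synthetic fluorescence and electrophysiology data with ground-truth manifests.

Every analysis stage of the package can be validated against data whose truth
is known by construction:

* 1D WFA line profiles and 2D annular "net" images with troughs (holes) of
  prescribed widths, each hole carrying a known combination of marker signals;
* soma-plus-marker images with a pericellular coverage fraction and synaptic
  puncta at recorded coordinates;
* uptake-current sweeps with prescribed peak and exponential decay;
* EEG traces with embedded rhythmic-discharge epochs.

Design notes
------------
Hole troughs have a flat floor across the nominal interval with raised-cosine
edges one PSF width wide placed *outside* it, so that after PSF blurring the
entire nominal interval stays strictly below 40 % of the WFA peak — the lower
bound of the detection threshold range.  Marker bumps are placed uniformly
within the central 60 % of their hole to avoid boundary ambiguity.  Noise is
additive Gaussian (optionally with Poisson shot noise), matching confocal PMT
statistics to first order.  All randomness flows from one explicit seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ValidationError
from .profiles import CalibratedImage, ClosedContour, LineProfile
from .ephys import Sweep, SweepSet, EEGRecord, baseline_amplitude

__all__ = [
    "NetSpec",
    "OccupancyProfile",
    "GroundTruth",
    "sample_occupancy",
    "make_profile",
    "make_net_image",
    "net_contour",
    "make_pericellular_image",
    "make_uptake_sweeps",
    "make_eeg",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class NetSpec:
    """Geometry, optics and noise of a synthetic perineuronal net.

    Defaults emulate the acquisition the analyses assume: 12-bit intensities,
    0.031 µm pixels, a net of ~25 holes of 0.5–1.5 µm width on a soma contour
    of 9 µm radius.  ``noise_sd`` in intensity counts; the marker bump
    amplitude is required to stay at least five noise standard deviations
    after PSF attenuation, the contract occupancy classification relies on.
    """

    contour_radius: float = 9.0  # µm
    pixel_size: float = 0.031  # µm / px
    n_holes: int = 25
    hole_width_dist: tuple[float, float] = (0.5, 1.5)  # µm
    wfa_peak_level: float = 3000.0  # 12-bit counts
    wfa_floor_frac: float = 0.10  # hole floor as a fraction of the peak
    psf_sigma: float = 0.10  # µm
    noise_sd: float = 0.0  # counts, additive Gaussian
    poisson_noise: bool = False
    saturation_level: float = 4095.0
    marker_amp: float = 2500.0  # counts, pre-PSF bump amplitude
    marker_sigma: float = 0.20  # µm, bump width
    min_gap: float = 0.9  # µm, minimal inter-hole peak incl. taper margin
    ring_thickness: float = 0.6  # µm, radial width of the WFA coat

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.contour_radius <= 0:
            raise ValidationError("pixel_size and contour_radius must be positive")
        if not 0 < self.wfa_floor_frac < 0.40:
            raise ValidationError("wfa_floor_frac must lie in (0, 0.40)")
        lo, hi = self.hole_width_dist
        if not 0 < lo <= hi:
            raise ValidationError("hole_width_dist must satisfy 0 < min <= max")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    @property
    def circumference(self) -> float:
        return 2.0 * np.pi * self.contour_radius

    def with_snr(self, snr: float) -> "NetSpec":
        """Copy of the spec with ``noise_sd = wfa_peak_level / snr``."""
        from dataclasses import replace

        return replace(self, noise_sd=self.wfa_peak_level / snr)


@dataclass(frozen=True)
class OccupancyProfile:
    """Mutually exclusive per-hole marker-combination probabilities.

    ``probabilities`` maps sorted channel-name tuples (``()`` for empty holes)
    to probabilities summing to one.
    """

    channel_names: tuple[str, ...]
    probabilities: dict[tuple[str, ...], float]

    def __post_init__(self) -> None:
        total = 0.0
        for combo, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} out of [0, 1] for {combo}")
            if any(ch not in self.channel_names for ch in combo):
                raise ValidationError(f"unknown channel in combination {combo}")
            if tuple(sorted(combo)) != tuple(combo):
                raise ValidationError(f"combination {combo} must be sorted")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"probabilities sum to {total}, not 1")

    @classmethod
    def from_dict(cls, channels, probs: dict) -> "OccupancyProfile":
        return cls(
            channel_names=tuple(channels),
            probabilities={tuple(sorted(k)): float(v) for k, v in probs.items()},
        )

    def marginal(self, channel: str) -> float:
        return sum(p for combo, p in self.probabilities.items() if channel in combo)


@dataclass
class GroundTruth:
    """Generator manifest: what was placed where, for recovery tests."""

    hole_intervals: list[tuple[float, float]] = field(default_factory=list)  # µm on [0, L)
    per_hole_occupancy: list[dict[str, bool]] = field(default_factory=list)
    peak_positions: list[dict[str, float]] = field(default_factory=list)  # µm per occupied channel
    puncta_truth: list[tuple[float, float, float, str]] = field(default_factory=list)  # row, col (px), amp, channel
    seizure_epochs: list[tuple[float, float]] = field(default_factory=list)  # s
    sweep_params: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["hole_intervals"] = [tuple(h) for h in d["hole_intervals"]]
        d["puncta_truth"] = [tuple(p) for p in d["puncta_truth"]]
        d["seizure_epochs"] = [tuple(e) for e in d["seizure_epochs"]]
        return cls(**d)


def sample_occupancy(
    occ: OccupancyProfile, n: int, rng: np.random.Generator
) -> list[tuple[str, ...]]:
    """Draw ``n`` hole combinations from the occupancy partition."""
    combos = list(occ.probabilities)
    probs = np.array([occ.probabilities[c] for c in combos])
    probs = probs / probs.sum()
    idx = rng.choice(len(combos), size=n, p=probs)
    return [combos[i] for i in idx]


def _place_holes(spec: NetSpec, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Pairwise disjoint circular hole intervals with at least ``min_gap`` between."""
    L = spec.circumference
    lo, hi = spec.hole_width_dist
    widths = rng.uniform(lo, hi, spec.n_holes)
    used = widths.sum() + spec.n_holes * spec.min_gap
    free = L - used
    if spec.n_holes > 0 and free < 0:
        raise GeometryError(
            f"holes + inter-hole peaks need {used:.1f} µm but circumference is {L:.1f} µm"
        )
    if spec.n_holes == 0:
        return []
    extra = rng.dirichlet(np.ones(spec.n_holes)) * free
    offset = rng.uniform(0.0, L)
    intervals = []
    s = offset
    for w, e in zip(widths, extra):
        intervals.append((s % L, (s + w) % L))
        s += w + spec.min_gap + e
    return intervals


def _circular_dist(a: np.ndarray, b: float, L: float) -> np.ndarray:
    """Signed-free circular distance |a - b| on a ring of circumference L."""
    d = np.abs(a - b) % L
    return np.minimum(d, L - d)


def _in_interval(s: np.ndarray, start: float, end: float, L: float) -> np.ndarray:
    """Membership of arc positions in the half-open circular interval [start, end)."""
    if end >= start:
        return (s >= start) & (s < end)
    return (s >= start) | (s < end)


def _trough_modulation(
    s: np.ndarray, intervals: list[tuple[float, float]], spec: NetSpec
) -> np.ndarray:
    """WFA multiplier: 1 on the net, ``wfa_floor_frac`` inside holes.

    The floor is flat across the nominal interval; raised-cosine edges one PSF
    width wide sit outside it.
    """
    L = spec.circumference
    edge = max(spec.psf_sigma, 1e-6)
    depth = np.zeros_like(s)
    for start, end in intervals:
        width = (end - start) % L
        inside = _in_interval(s, start, end, L)
        g = np.zeros_like(s)
        g[inside] = 1.0
        # distance outside the interval to the nearest boundary
        d_start = _circular_dist(s, start, L)
        d_end = _circular_dist(s, end, L)
        d_out = np.minimum(d_start, d_end)
        taper = ~inside & (d_out < edge)
        g[taper] = 0.5 * (1.0 + np.cos(np.pi * d_out[taper] / edge))
        depth = np.maximum(depth, g)
    return 1.0 - (1.0 - spec.wfa_floor_frac) * depth


def _check_bump_contract(spec: NetSpec, attenuation: float) -> None:
    if spec.noise_sd > 0 and spec.marker_amp * attenuation < 5.0 * spec.noise_sd:
        raise ValidationError(
            "marker bump amplitude after PSF attenuation falls below 5x noise sd; "
            "raise marker_amp or lower noise_sd"
        )


def make_profile(
    spec: NetSpec, occ: OccupancyProfile, seed
) -> tuple[LineProfile, GroundTruth]:
    """Generate a 1D circular line profile with known holes and occupancy.

    The WFA channel sits at ``wfa_peak_level`` with troughs to
    ``wfa_floor_frac`` x peak over the hole intervals, blurred by the PSF;
    each occupied channel receives a Gaussian bump centred within its hole.
    """
    rng = _rng(seed)
    L = spec.circumference
    ds = spec.pixel_size
    n = int(round(L / ds))
    ds_actual = L / n
    s = np.arange(n) * ds_actual
    sigma_px = spec.psf_sigma / ds_actual

    intervals = _place_holes(spec, rng)
    combos = sample_occupancy(occ, len(intervals), rng)
    _check_bump_contract(spec, _gauss1d_attenuation(spec))

    wfa = spec.wfa_peak_level * _trough_modulation(s, intervals, spec)
    wfa = ndimage.gaussian_filter1d(wfa, sigma_px, mode="wrap")

    channels: dict[str, np.ndarray] = {"WFA": wfa}
    occupancy: list[dict[str, bool]] = []
    centers: list[dict[str, float]] = []
    for name in occ.channel_names:
        channels[name] = np.zeros(n)
    for (start, end), combo in zip(intervals, combos):
        width = (end - start) % L
        occupancy.append({ch: ch in combo for ch in occ.channel_names})
        ctr: dict[str, float] = {}
        for ch in combo:
            c = (start + width * (0.5 + rng.uniform(-0.3, 0.3))) % L
            ctr[ch] = c
            d = _circular_dist(s, c, L)
            channels[ch] += spec.marker_amp * np.exp(-0.5 * (d / spec.marker_sigma) ** 2)
        centers.append(ctr)
    for name in occ.channel_names:
        channels[name] = ndimage.gaussian_filter1d(channels[name], sigma_px, mode="wrap")

    for name in channels:
        x = channels[name]
        if spec.poisson_noise:
            x = rng.poisson(np.clip(x, 0, None)).astype(float)
        if spec.noise_sd > 0:
            x = x + rng.normal(0.0, spec.noise_sd, n)
        channels[name] = np.clip(x, 0.0, spec.saturation_level)

    profile = LineProfile(s=s, intensities=channels, ds=ds_actual, L=L)
    gt = GroundTruth(
        hole_intervals=intervals,
        per_hole_occupancy=occupancy,
        peak_positions=centers,
        extras={"perimeter": L, "n_holes": len(intervals)},
    )
    return profile, gt


def _gauss1d_attenuation(spec: NetSpec) -> float:
    s2 = spec.marker_sigma**2
    return float(np.sqrt(s2 / (s2 + spec.psf_sigma**2)))


def _gauss2d_attenuation(spec: NetSpec) -> float:
    s2 = spec.marker_sigma**2
    return float(s2 / (s2 + spec.psf_sigma**2))


def net_contour(spec: NetSpec, image: CalibratedImage, n_vertices: int = 720) -> ClosedContour:
    """The true soma/net contour of a generated net image: a centred circle."""
    nrow, ncol = image.shape
    center = (ncol * image.pixel_size / 2.0, nrow * image.pixel_size / 2.0)
    return ClosedContour.circle(center, spec.contour_radius, n_vertices)


def make_net_image(
    spec: NetSpec, occ: OccupancyProfile, seed, margin: float = 1.0
) -> tuple[CalibratedImage, GroundTruth]:
    """Generate a 2D multi-channel image of an annular net with broken arcs.

    The WFA ring (radial top-hat of ``ring_thickness``) is interrupted over
    the hole arcs; marker spots are placed on the ring at the occupied-hole
    positions.  Extracting a profile along :func:`net_contour` and running the
    detection pipeline recovers the manifest.
    """
    rng = _rng(seed)
    if margin < 2 * spec.psf_sigma:
        raise GeometryError("margin must be at least two PSF widths")
    ps = spec.pixel_size
    L = spec.circumference
    half = spec.contour_radius + spec.ring_thickness / 2 + margin
    n_px = 2 * int(np.ceil(half / ps)) + 1
    c_um = n_px * ps / 2.0  # image centre, µm

    intervals = _place_holes(spec, rng)
    combos = sample_occupancy(occ, len(intervals), rng)
    _check_bump_contract(spec, _gauss2d_attenuation(spec))

    idx = (np.arange(n_px) + 0.5) * ps
    X, Y = np.meshgrid(idx - c_um, idx - c_um)  # x: columns, y: rows
    R = np.hypot(X, Y)
    theta = np.arctan2(Y, X) % (2 * np.pi)
    s_of_theta = theta * spec.contour_radius

    # angular modulation via a dense 1D lookup table
    n_lut = 8192
    s_lut = np.arange(n_lut) * (L / n_lut)
    lut = _trough_modulation(s_lut, intervals, spec)
    mod = lut[np.minimum((s_of_theta / (L / n_lut)).astype(int), n_lut - 1)]

    radial = (np.abs(R - spec.contour_radius) <= spec.ring_thickness / 2).astype(float)
    wfa = spec.wfa_peak_level * radial * mod

    channels: dict[str, np.ndarray] = {"WFA": wfa}
    for name in occ.channel_names:
        channels[name] = np.zeros((n_px, n_px))

    occupancy: list[dict[str, bool]] = []
    centers: list[dict[str, float]] = []
    for (start, end), combo in zip(intervals, combos):
        width = (end - start) % L
        occupancy.append({ch: ch in combo for ch in occ.channel_names})
        ctr: dict[str, float] = {}
        for ch in combo:
            c_s = (start + width * (0.5 + rng.uniform(-0.3, 0.3))) % L
            ctr[ch] = c_s
            ang = c_s / spec.contour_radius
            x0 = c_um + spec.contour_radius * np.cos(ang)
            y0 = c_um + spec.contour_radius * np.sin(ang)
            _add_spot(channels[ch], x0, y0, spec.marker_amp, spec.marker_sigma, ps)
        centers.append(ctr)

    sigma_px = spec.psf_sigma / ps
    for name in channels:
        x = ndimage.gaussian_filter(channels[name], sigma_px)
        if spec.poisson_noise:
            x = rng.poisson(np.clip(x, 0, None)).astype(float)
        if spec.noise_sd > 0:
            x = x + rng.normal(0.0, spec.noise_sd, x.shape)
        channels[name] = np.clip(x, 0.0, spec.saturation_level)

    image = CalibratedImage(channels=channels, pixel_size=ps, bit_depth=12)
    gt = GroundTruth(
        hole_intervals=intervals,
        per_hole_occupancy=occupancy,
        peak_positions=centers,
        extras={"perimeter": L, "n_holes": len(intervals), "center_um": c_um},
    )
    return image, gt


def _add_spot(chan: np.ndarray, x0: float, y0: float, amp: float, sigma: float, ps: float) -> None:
    """Add a 2D Gaussian spot (µm coordinates) in a local window."""
    n = chan.shape[0]
    r_px = int(np.ceil(4 * sigma / ps)) + 1
    col0 = int(round(x0 / ps - 0.5))
    row0 = int(round(y0 / ps - 0.5))
    r0, r1 = max(0, row0 - r_px), min(n, row0 + r_px + 1)
    c0, c1 = max(0, col0 - r_px), min(n, col0 + r_px + 1)
    if r0 >= r1 or c0 >= c1:
        raise GeometryError("spot outside image bounds")
    cols = (np.arange(c0, c1) + 0.5) * ps
    rows = (np.arange(r0, r1) + 0.5) * ps
    Xl, Yl = np.meshgrid(cols, rows)
    chan[r0:r1, c0:c1] += amp * np.exp(-((Xl - x0) ** 2 + (Yl - y0) ** 2) / (2 * sigma**2))


def make_pericellular_image(
    soma_radius: float,
    marker_band_coverage: float,
    puncta_density: float,
    puncta_amp: float,
    seed,
    pixel_size: float = 0.031,
    band_width: float = 0.8,
    n_sectors: int = 72,
    noise_sd: float = 20.0,
    soma_level: float = 3000.0,
    marker_level: float = 2000.0,
    puncta_sigma: float = 0.15,
    min_puncta_sep: float = 0.6,
    margin: float = 1.5,
) -> tuple[CalibratedImage, GroundTruth]:
    """Soma disk, pericellular marker band and synaptic puncta with truth.

    The marker (astrocyte) channel occupies ``marker_band_coverage`` of the
    0.8-µm pericellular band *by area*, realised as randomly chosen angular
    sectors.  Puncta (density per µm² of band) are Gaussian spots at recorded
    coordinates, separated by at least ``min_puncta_sep`` µm.
    """
    if not 0.0 <= marker_band_coverage <= 1.0:
        raise ValidationError("coverage fraction must lie in [0, 1]")
    if puncta_density < 0 or puncta_amp < 0:
        raise ValidationError("puncta density and amplitude must be non-negative")
    rng = _rng(seed)
    ps = pixel_size
    half = soma_radius + band_width + margin
    n_px = 2 * int(np.ceil(half / ps)) + 1
    c_um = n_px * ps / 2.0
    idx = (np.arange(n_px) + 0.5) * ps
    X, Y = np.meshgrid(idx - c_um, idx - c_um)
    R = np.hypot(X, Y)
    theta = np.arctan2(Y, X) % (2 * np.pi)

    soma = (R <= soma_radius).astype(float) * soma_level
    band = (R > soma_radius) & (R <= soma_radius + band_width)

    k = int(round(marker_band_coverage * n_sectors))
    chosen = rng.choice(n_sectors, size=k, replace=False) if k else np.array([], int)
    sector = np.floor(theta / (2 * np.pi / n_sectors)).astype(int) % n_sectors
    marker_mask = band & np.isin(sector, chosen)
    marker = marker_mask.astype(float) * marker_level

    band_area = band.sum() * ps**2
    n_puncta = int(round(puncta_density * band_area))
    puncta = np.zeros((n_px, n_px))
    placed: list[tuple[float, float]] = []  # (row, col) px
    truth: list[tuple[float, float, float, str]] = []
    attempts = 0
    while len(placed) < n_puncta and attempts < 200 * max(1, n_puncta):
        attempts += 1
        ang = rng.uniform(0, 2 * np.pi)
        rad = np.sqrt(rng.uniform(soma_radius**2, (soma_radius + band_width) ** 2))
        x0 = c_um + rad * np.cos(ang)
        y0 = c_um + rad * np.sin(ang)
        row, col = y0 / ps - 0.5, x0 / ps - 0.5
        if any(np.hypot(row - r, col - c) * ps < min_puncta_sep for r, c in placed):
            continue
        placed.append((row, col))
        truth.append((row, col, puncta_amp, "puncta"))
        _add_spot(puncta, x0, y0, puncta_amp, puncta_sigma, ps)

    channels = {"soma": soma, "astro": marker, "puncta": puncta}
    for name in channels:
        x = ndimage.gaussian_filter(channels[name], 1.0)
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, x.shape)
        channels[name] = np.clip(x, 0.0, 4095.0)

    image = CalibratedImage(channels=channels, pixel_size=ps, bit_depth=12)
    gt = GroundTruth(
        puncta_truth=truth,
        extras={
            "soma_radius": soma_radius,
            "band_width": band_width,
            "band_area_um2": float(band_area),
            "marker_coverage": (k / n_sectors),
            "perimeter": 2 * np.pi * soma_radius,
            "center_um": c_um,
            "n_puncta": len(placed),
            "puncta_on_marker": [
                bool(marker_mask[int(round(r)), int(round(c))]) for r, c in placed
            ],
        },
    )
    return image, gt


def make_uptake_sweeps(
    peak: float,
    tau_decay: float,
    n_sweeps: int,
    noise_sd: float,
    seed,
    fs: float = 10_000.0,
    duration: float = 1.0,
    onset: float = 0.2,
    stimulus: float | None = None,
    kinetics: str = "exp",
) -> tuple[SweepSet, GroundTruth]:
    """Inward uptake-current sweeps: flat baseline, fast rise, exponential decay.

    ``kinetics='exp'`` gives an instantaneous rise with exponential decay of
    time constant ``tau_decay`` (s); ``'alpha'`` gives an alpha-function
    ``(t/tau) * exp(1 - t/tau)`` time course.  Currents are inward (negative)
    with magnitude ``peak`` pA; Gaussian noise of ``noise_sd`` pA is added.
    """
    if n_sweeps < 1:
        raise ValidationError("n_sweeps must be >= 1")
    if tau_decay <= 0 or peak < 0:
        raise ValidationError("peak must be >= 0 and tau_decay > 0")
    rng = _rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    shape = np.zeros(n)
    after = t >= onset
    rel = t[after] - onset
    if kinetics == "exp":
        shape[after] = np.exp(-rel / tau_decay)
    elif kinetics == "alpha":
        shape[after] = (rel / tau_decay) * np.exp(1.0 - rel / tau_decay)
    else:
        raise ValidationError(f"unknown kinetics {kinetics!r}")
    clean = -peak * shape
    sweeps = []
    for _ in range(n_sweeps):
        noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
        sweeps.append(
            Sweep(t=t, i=clean + noise, fs=fs, stimulus=stimulus,
                  baseline_window=(0.0, onset * 0.9))
        )
    gt = GroundTruth(
        sweep_params={
            "peak_pA": peak,
            "tau_decay_s": tau_decay,
            "onset_s": onset,
            "kinetics": kinetics,
            "noise_sd_pA": noise_sd,
        }
    )
    return SweepSet(sweeps=sweeps, protocol=(stimulus,) if stimulus is not None else ()), gt


def make_eeg(
    duration: float,
    fs: float,
    baseline_amp: float,
    seizures: list[tuple[float, float, float, float]],
    seed,
    spike_width: float = 0.04,
) -> tuple[EEGRecord, GroundTruth]:
    """EEG background with embedded rhythmic-discharge epochs.

    ``seizures`` lists ``(t_start, dur_s, spike_hz, amp_ratio)``; within each
    epoch, sharp waves at ``spike_hz`` are added with peak amplitude
    ``amp_ratio`` times the average baseline deflection amplitude (the same
    block-maximum measure the detector uses).  ``baseline_amp`` is the
    Gaussian sd of the background, µV.
    """
    rng = _rng(seed)
    n = int(round(duration * fs))
    if n < 2:
        raise ValidationError("record too short")
    epochs = sorted((t0, t0 + d) for t0, d, _, _ in seizures)
    for (a0, a1), (b0, b1) in zip(epochs, epochs[1:]):
        if b0 < a1:
            raise ValidationError("seizure epochs overlap")
    for t0, d, hz, ratio in seizures:
        if t0 < 0 or t0 + d > duration:
            raise ValidationError("seizure epoch outside the record")
        if hz < 0 or d <= 0:
            raise ValidationError("spike rate must be >= 0 and duration > 0")

    x = rng.normal(0.0, baseline_amp, n)
    first_start = min((t0 for t0, *_ in seizures), default=duration)
    base_end = max(1.0, min(first_start, duration))
    base_ref = baseline_amplitude(x[: int(base_end * fs)], fs)

    half_w = int(round(spike_width / 2 * fs))
    pulse = np.cos(np.linspace(-np.pi / 2, np.pi / 2, 2 * half_w + 1)) ** 2
    for t0, d, hz, ratio in seizures:
        if hz == 0:
            continue
        times = t0 + (np.arange(int(d * hz)) + 0.5) / hz
        amp = ratio * base_ref
        for ts in times:
            c = int(round(ts * fs))
            lo, hi = max(0, c - half_w), min(n, c + half_w + 1)
            x[lo:hi] += amp * pulse[lo - (c - half_w) : hi - (c - half_w)]

    gt = GroundTruth(
        seizure_epochs=[(t0, t0 + d) for t0, d, _, _ in seizures],
        extras={
            "baseline_reference_amp": base_ref,
            "baseline_window": (0.0, base_end),
            "spikes": [
                {"t_start": t0, "dur": d, "hz": hz, "amp_ratio": ratio}
                for t0, d, hz, ratio in seizures
            ],
        },
    )
    return EEGRecord(x=x, fs=fs), gt
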