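"""Synthetic-data generators with attached ground truth.

Every input the quantification pipelines consume can be produced here:

* :func:`simulate_sted_pair` — a two-channel super-resolution field: a
  filamentous microtubule channel plus a punctate enzyme channel with a
  controllable true on-filament fraction, Gaussian PSF blur, Poisson photon
  noise and Gaussian read noise;
* :func:`simulate_puncta_field` — a punctate channel with per-punctum true
  disc diameters straddling the 400 nm size filter;
* :func:`simulate_sarcomere_trace` / :func:`simulate_calcium_trace` — 2 Hz
  field-paced sarcomere-shortening and Fura-2 ratio transients with
  closed-form per-beat kinetics;
* :func:`simulate_gel_table` — control/treatment densitometry tables;
* :func:`simulate_competition` — a lattice random-sequential-adsorption
  model of MAP4/VASH2 competition for microtubule binding sites.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .coloc import CellROI, ChannelImage
from .kinetics import CalciumKinetics, SarcomereKinetics, Trace

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548
# Digitization: a structure of unit intensity (mean photons = photon_scale)
# maps to about 2/3 of the 16-bit range, i.e. a rendered Value near 170 —
# bright but unsaturated, as one would set display gain at acquisition.
_GAIN_FRACTION = 0.66
_U16_MAX = 65535


# ---------------------------------------------------------------------------
# STED two-channel fields
# ---------------------------------------------------------------------------

@dataclass
class StedSimParams:
    """Acquisition-like parameters for a synthetic two-channel STED field.

    ``filament_width`` is the apparent labelled-microtubule width (nm): a
    25 nm microtubule decorated by primary+secondary antibodies images at
    roughly 50-60 nm under STED. ``puncta_sigma`` is the physical Gaussian
    radius of an enzyme punctum before PSF blur; ``puncta_intensity`` its
    peak intensity relative to the unit filament intensity.
    """

    image_size: int = 512
    pixel_size: float = 20.0          # nm
    n_filaments: int = 12
    filament_length_range: tuple[float, float] = (2000.0, 8000.0)  # nm
    filament_intensity: float = 1.0
    filament_width: float = 60.0      # nm
    psf_fwhm: float = 60.0            # nm
    n_puncta: int = 80
    puncta_sigma: float = 20.0        # nm
    puncta_intensity: float = 1.5
    true_frac_on: float = 0.5
    photon_scale: float = 200.0       # mean photons at unit intensity
    read_noise_sd: float = 2.0        # photons
    off_margin: float = 200.0         # nm, min centerline distance for "off"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not 0.0 <= self.true_frac_on <= 1.0:
            raise ValueError("true_frac_on must be in [0, 1]")
        for name in ("pixel_size", "psf_fwhm", "puncta_sigma",
                     "filament_width", "photon_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.filament_length_range[0] <= 0:
            raise ValueError("filament lengths must be positive")
        if self.n_filaments < 0 or self.n_puncta < 0:
            raise ValueError("counts must be non-negative")
        n_on = round(self.n_puncta * self.true_frac_on)
        if n_on > 0 and self.n_filaments == 0:
            raise ValueError("on-filament puncta requested with no filaments")


@dataclass
class StedFixture:
    tubulin_channel: ChannelImage
    vash2_channel: ChannelImage
    truth_tubulin_mask: np.ndarray
    truth_puncta_table: pd.DataFrame
    truth_frac_on: float
    cell_roi: CellROI


def _segment_distance(rows: np.ndarray, cols: np.ndarray,
                      p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Distance (px) from each grid pixel to the segment p0-p1."""
    d = p1 - p0
    len2 = float(d @ d)
    pr = rows - p0[0]
    pc = cols - p0[1]
    if len2 == 0.0:
        return np.hypot(pr, pc)
    tt = np.clip((pr * d[0] + pc * d[1]) / len2, 0.0, 1.0)
    return np.hypot(pr - tt * d[0], pc - tt * d[1])


def _draw_filaments(params: StedSimParams, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
    """Render filament intensity, min centerline-distance map, and segments."""
    n = params.image_size
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    intensity = np.zeros((n, n))
    min_dist = np.full((n, n), np.inf)
    half_w = params.filament_width / params.pixel_size / 2.0
    segments = []
    for _ in range(params.n_filaments):
        length_px = rng.uniform(*params.filament_length_range) / params.pixel_size
        theta = rng.uniform(0.0, np.pi)
        center = rng.uniform(0.0, n, size=2)
        delta = 0.5 * length_px * np.array([np.sin(theta), np.cos(theta)])
        p0, p1 = center - delta, center + delta
        dist = _segment_distance(rows, cols, p0, p1)
        intensity += params.filament_intensity * (dist <= half_w)
        np.minimum(min_dist, dist, out=min_dist)
        segments.append((p0, p1))
    return intensity, min_dist, segments


def _place_puncta(params: StedSimParams, rng: np.random.Generator,
                  segments: list, min_dist: np.ndarray
                  ) -> pd.DataFrame:
    """Deterministic on/off assignment: exactly round(n * frac) on-filament."""
    n = params.image_size
    n_on = round(params.n_puncta * params.true_frac_on)
    n_off = params.n_puncta - n_on
    margin_px = params.off_margin / params.pixel_size
    records = []
    # on-filament: uniform along a length-weighted random segment, clipped
    # to the field interior
    if n_on > 0:
        lengths = np.array([np.linalg.norm(p1 - p0) for p0, p1 in segments])
        probs = lengths / lengths.sum()
        placed = 0
        while placed < n_on:
            idx = rng.choice(len(segments), p=probs)
            p0, p1 = segments[idx]
            pos = p0 + rng.uniform() * (p1 - p0)
            if 2.0 <= pos[0] <= n - 3 and 2.0 <= pos[1] <= n - 3:
                records.append((pos[0], pos[1], True))
                placed += 1
    # off-filament: uniform, rejected within off_margin of any centerline
    placed = 0
    while placed < n_off:
        pos = rng.uniform(2.0, n - 3.0, size=2)
        r, c = int(round(pos[0])), int(round(pos[1]))
        if min_dist[r, c] > margin_px:
            records.append((pos[0], pos[1], False))
            placed += 1
    table = pd.DataFrame(records, columns=["row", "col", "on_filament"])
    # reported punctum diameter = Gaussian FWHM
    table["diameter_nm"] = params.puncta_sigma / FWHM_TO_SIGMA
    return table


def _render_puncta(table: pd.DataFrame, params: StedSimParams) -> np.ndarray:
    n = params.image_size
    img = np.zeros((n, n))
    sigma_px = params.puncta_sigma / params.pixel_size
    half = int(np.ceil(5 * sigma_px)) + 1
    for rec in table.itertuples():
        r0, c0 = rec.row, rec.col
        rlo, rhi = max(0, int(r0) - half), min(n, int(r0) + half + 1)
        clo, chi = max(0, int(c0) - half), min(n, int(c0) + half + 1)
        rr, cc = np.mgrid[rlo:rhi, clo:chi].astype(float)
        img[rlo:rhi, clo:chi] += params.puncta_intensity * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma_px ** 2))
    return img


def _acquire(intensity: np.ndarray, params: StedSimParams,
             rng: np.random.Generator) -> np.ndarray:
    """PSF blur, Poisson photon noise, Gaussian read noise, 16-bit digitization."""
    sigma_psf = params.psf_fwhm * FWHM_TO_SIGMA / params.pixel_size
    blurred = ndimage.gaussian_filter(intensity, sigma_psf, mode="reflect")
    photons = rng.poisson(np.clip(blurred, 0.0, None) * params.photon_scale)
    photons = photons + rng.normal(0.0, params.read_noise_sd, photons.shape)
    gain = _GAIN_FRACTION * _U16_MAX / params.photon_scale
    return np.clip(np.round(photons * gain), 0, _U16_MAX).astype(np.uint16)


def simulate_sted_pair(params: StedSimParams | None = None) -> StedFixture:
    """Simulate a matched filament + puncta channel pair with ground truth.

    On/off assignment is by exact deterministic count: the truth table holds
    exactly ``round(n_puncta * true_frac_on)`` on-filament puncta, so the
    attached ``truth_frac_on`` is noise-free.
    """
    params = params or StedSimParams()
    rng = np.random.default_rng(params.seed)
    filament_img, min_dist, segments = _draw_filaments(params, rng)
    half_w = params.filament_width / params.pixel_size / 2.0
    truth_mask = min_dist <= half_w
    if params.n_puncta > 0:
        table = _place_puncta(params, rng, segments, min_dist)
    else:
        table = pd.DataFrame(columns=["row", "col", "on_filament", "diameter_nm"])
    vash2_img = _render_puncta(table, params)
    tub = _acquire(filament_img, params, rng)
    vash = _acquire(vash2_img, params, rng)
    truth_frac = (float(table["on_filament"].mean()) if len(table) else 0.0)
    roi = CellROI(np.ones((params.image_size,) * 2, dtype=bool),
                  pixel_size=params.pixel_size)
    return StedFixture(
        tubulin_channel=ChannelImage(tub, 16, "TUBULIN", params.pixel_size),
        vash2_channel=ChannelImage(vash, 16, "VASH2", params.pixel_size),
        truth_tubulin_mask=truth_mask,
        truth_puncta_table=table,
        truth_frac_on=truth_frac,
        cell_roi=roi,
    )


# ---------------------------------------------------------------------------
# Puncta fields with per-punctum diameters
# ---------------------------------------------------------------------------

@dataclass
class PunctaFieldParams:
    """Disc-shaped puncta of known diameter, mixing detectable (supra) and
    sub-threshold sizes around the 400 nm filter."""

    image_size: int = 512
    pixel_size: float = 20.0
    n_supra: int = 12
    n_sub: int = 12
    supra_range: tuple[float, float] = (480.0, 800.0)   # nm
    sub_range: tuple[float, float] = (200.0, 300.0)     # nm
    intensity: float = 1.0
    psf_fwhm: float = 60.0
    photon_scale: float = 200.0
    read_noise_sd: float = 2.0
    min_separation: float = 400.0     # nm, edge-to-edge
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.sub_range[1] >= 400.0 or self.supra_range[0] <= 400.0:
            raise ValueError("sub_range must lie below and supra_range above "
                             "the 400 nm filter")


def simulate_puncta_field(params: PunctaFieldParams | None = None
                          ) -> tuple[ChannelImage, pd.DataFrame, CellROI]:
    """Render discs of known diameter; returns channel, truth table, ROI."""
    params = params or PunctaFieldParams()
    rng = np.random.default_rng(params.seed)
    n = params.image_size
    rows, cols = np.mgrid[0:n, 0:n].astype(float)
    diams = np.concatenate([
        rng.uniform(*params.supra_range, size=params.n_supra),
        rng.uniform(*params.sub_range, size=params.n_sub),
    ])
    is_supra = np.arange(diams.size) < params.n_supra
    order = rng.permutation(diams.size)
    diams, is_supra = diams[order], is_supra[order]

    centers: list[tuple[float, float]] = []
    radii_px: list[float] = []
    intensity = np.zeros((n, n))
    sep_px = params.min_separation / params.pixel_size
    truth = []
    for d_nm, supra in zip(diams, is_supra):
        r_px = d_nm / params.pixel_size / 2.0
        for _ in range(10_000):
            pos = rng.uniform(r_px + 5, n - r_px - 6, size=2)
            if all(np.hypot(pos[0] - cr, pos[1] - cc) > r_px + rp + sep_px
                   for (cr, cc), rp in zip(centers, radii_px)):
                break
        else:  # pragma: no cover - field too crowded
            raise RuntimeError("could not place puncta without overlap")
        centers.append(tuple(pos))
        radii_px.append(r_px)
        dist = np.hypot(rows - pos[0], cols - pos[1])
        intensity += params.intensity * (dist <= r_px)
        truth.append((pos[0], pos[1], d_nm, bool(supra)))

    sted = StedSimParams(image_size=n, pixel_size=params.pixel_size,
                         psf_fwhm=params.psf_fwhm,
                         photon_scale=params.photon_scale,
                         read_noise_sd=params.read_noise_sd)
    img = _acquire(intensity, sted, rng)
    table = pd.DataFrame(truth, columns=["row", "col", "diameter_nm", "supra"])
    roi = CellROI(np.ones((n, n), dtype=bool), pixel_size=params.pixel_size)
    return ChannelImage(img, 16, "MAP4", params.pixel_size), table, roi


# ---------------------------------------------------------------------------
# Paced-cell traces
# ---------------------------------------------------------------------------

@dataclass
class TraceSimParams:
    """Shared parameters for 2 Hz-paced trace simulation.

    For sarcomere traces the waveform is
    ``SL(t) = baseline - amplitude * sin^2(pi t / T_c)`` on ``[0, T_c]``
    within each beat and baseline elsewhere; for calcium-ratio traces it is
    ``R(t) = basal + amplitude * (1 - exp(-t/tau_rise)) * exp(-t/tau_decay)``.
    """

    stim_freq: float = 2.0            # Hz
    duration: float = 10.0            # s
    sample_rate: float = 1000.0       # Hz
    baseline: float = 1.80            # um (sarcomere) or ratio units (calcium)
    amplitude: float = 0.18           # same units
    contraction_duration: float = 0.30  # s (sarcomere)
    tau_rise: float = 0.03            # s (calcium)
    tau_decay: float = 0.15           # s (calcium)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate < 100.0:
            raise ValueError("sample_rate must be >= 100 Hz")
        if self.contraction_duration >= 1.0 / self.stim_freq:
            raise ValueError("contraction_duration must fit one period")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be positive")
        if self.duration < 1.0 / self.stim_freq:
            raise ValueError("duration must cover at least one period")


def _sarcomere_model(phase: np.ndarray, params: TraceSimParams) -> np.ndarray:
    tc = params.contraction_duration
    out = np.full_like(phase, params.baseline)
    active = phase <= tc
    out[active] = params.baseline - params.amplitude * np.sin(
        np.pi * phase[active] / tc) ** 2
    return out


def simulate_sarcomere_trace(params: TraceSimParams | None = None
                             ) -> tuple[Trace, SarcomereKinetics]:
    """Paced sarcomere-length trace plus closed-form ground-truth kinetics.

    Truth: peak shortening = amplitude/baseline * 100 %, time to peak =
    T_c / 2, max departure/return speed = amplitude * pi / T_c.
    """
    params = params or TraceSimParams()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sample_rate))
    time = np.arange(n) / params.sample_rate
    phase = np.mod(time, 1.0 / params.stim_freq)
    value = _sarcomere_model(phase, params)
    if params.noise_sd > 0:
        value = value + rng.normal(0.0, params.noise_sd, n)
    truth = SarcomereKinetics(
        resting_sl=params.baseline,
        peak_shortening_pct=params.amplitude / params.baseline * 100.0,
        max_departure_velocity=params.amplitude * np.pi / params.contraction_duration,
        max_return_velocity=params.amplitude * np.pi / params.contraction_duration,
        time_to_peak=params.contraction_duration / 2.0,
    )
    return Trace(time=time, value=value, stim_freq=params.stim_freq,
                 kind="sarcomere"), truth


def _calcium_model(phase: np.ndarray, params: TraceSimParams) -> np.ndarray:
    return params.baseline + params.amplitude * (
        1.0 - np.exp(-phase / params.tau_rise)) * np.exp(-phase / params.tau_decay)


def calcium_ground_truth(params: TraceSimParams,
                         oversample: int = 100) -> CalciumKinetics:
    """Numerical kinetics of the noiseless per-beat calcium model on a dense
    grid (``oversample`` x the sample rate)."""
    period = 1.0 / params.stim_freq
    tt = np.arange(0.0, period, 1.0 / (params.sample_rate * oversample))
    rr = _calcium_model(tt, params)
    i_pk = int(np.argmax(rr))
    basal = params.baseline
    amp = float(rr[i_pk] - basal)
    half = basal + amp / 2.0
    decay50 = float("nan")
    post = rr[i_pk:]
    below = np.nonzero(post <= half)[0]
    if amp > 0 and below.size:
        j = below[0]
        if j == 0:
            decay50 = 0.0
        else:
            t0, t1 = tt[i_pk + j - 1], tt[i_pk + j]
            y0, y1 = post[j - 1], post[j]
            frac = (y0 - half) / (y0 - y1)
            decay50 = float(t0 + frac * (t1 - t0) - tt[i_pk])
    dt = tt[1] - tt[0]
    deriv = np.gradient(rr, dt)
    release = float(deriv[: i_pk + 1].max()) if i_pk > 0 else 0.0
    reuptake = float(-deriv[i_pk:].min()) if i_pk < rr.size - 1 else 0.0
    return CalciumKinetics(
        basal=basal, amplitude=amp, release_speed=release,
        reuptake_speed=reuptake, elevation_time=float(tt[i_pk]),
        reuptake_time=decay50,
    )


def simulate_calcium_trace(params: TraceSimParams | None = None,
                           f380_base: float = 1000.0
                           ) -> tuple[Trace, Trace, CalciumKinetics]:
    """Two excitation-channel Fura-2 traces whose ratio is the transient model.

    The 380 nm channel is constant and the 360 nm channel is ``R(t) * F380``,
    so the recomputed ratio reproduces the (noisy) model exactly; noise of
    ``noise_sd`` (ratio units) is applied to the ratio before factoring.
    Ground truth is computed numerically on the noiseless model.
    """
    params = params or TraceSimParams(baseline=1.0, amplitude=0.5,
                                      noise_sd=0.0)
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sample_rate))
    time = np.arange(n) / params.sample_rate
    phase = np.mod(time, 1.0 / params.stim_freq)
    ratio = _calcium_model(phase, params)
    if params.noise_sd > 0:
        ratio = ratio + rng.normal(0.0, params.noise_sd, n)
    f380 = np.full(n, f380_base)
    f360 = ratio * f380
    truth = calcium_ground_truth(params)
    return (
        Trace(time=time, value=f360, stim_freq=params.stim_freq,
              kind="fluorescence"),
        Trace(time=time, value=f380, stim_freq=params.stim_freq,
              kind="fluorescence"),
        truth,
    )


# ---------------------------------------------------------------------------
# Gel tables
# ---------------------------------------------------------------------------

@dataclass
class GelSimParams:
    n_control: int = 6
    n_treated: int = 6
    control_mean: float = 100.0
    effect_multiplier: float = 2.0
    marker_density: float = 50.0
    noise_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1:
            raise ValueError("need at least one control sample")
        if self.n_treated < 0:
            raise ValueError("n_treated must be non-negative")
        if self.marker_density <= 0:
            raise ValueError("marker_density must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def simulate_gel_table(params: GelSimParams | None = None) -> pd.DataFrame:
    """Control/treatment band-density table with a shared marker column.

    Band densities carry multiplicative noise of the stated CV around
    ``control_mean`` (controls) and ``control_mean * effect_multiplier``
    (treated); the marker density carries the same CV independently.
    """
    params = params or GelSimParams()
    rng = np.random.default_rng(params.seed)
    rows = []
    groups = ["control"] * params.n_control + ["treatment"] * params.n_treated
    for i, grp in enumerate(groups):
        mean = params.control_mean
        if grp == "treatment":
            mean *= params.effect_multiplier
        band = mean * max(1.0 + rng.normal(0.0, params.noise_cv), 1e-6)
        marker = params.marker_density * max(
            1.0 + rng.normal(0.0, params.noise_cv), 1e-6)
        rows.append((f"S{i:02d}", grp, band, marker, 0))
    return pd.DataFrame(rows, columns=["sample_id", "group", "band_density",
                                       "marker_density", "gel_id"])


# ---------------------------------------------------------------------------
# Lattice competition model
# ---------------------------------------------------------------------------

@dataclass
class CompetitionSimParams:
    """Random sequential adsorption of two proteins on a 1-D lattice.

    Competitor (MAP4) molecules bind first at each dose, then a fixed amount
    of enzyme (VASH2) binds the remaining free stretches. Doses are in
    concentration units; ``molecules_per_unit`` converts a dose unit to the
    number of binding attempts (default scales so the top of the 1-4 uM
    range approaches lattice saturation).
    """

    n_sites: int = 2000
    map4_footprint: int = 4
    vash2_footprint: int = 2
    map4_doses: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0)
    vash2_dose: float = 3.0
    molecules_per_unit: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.map4_footprint < 1 or self.vash2_footprint < 1:
            raise ValueError("footprints must be >= 1")
        if max(self.map4_footprint, self.vash2_footprint) > self.n_sites:
            raise ValueError("footprint larger than lattice")
        if any(b <= a for a, b in zip(self.map4_doses, self.map4_doses[1:])):
            raise ValueError("doses must be strictly increasing")

    @property
    def attempts_per_unit(self) -> int:
        if self.molecules_per_unit is not None:
            return self.molecules_per_unit
        return max(1, self.n_sites // (4 * self.map4_footprint))


def _rsa_fill(occupied: np.ndarray, footprint: int, n_attempts: int,
              rng: np.random.Generator) -> int:
    """Place up to n_attempts molecules of the given footprint; returns the
    number bound. One uniform position draw per molecule (unsuccessful
    collisions leave the molecule unbound)."""
    n = occupied.size
    bound = 0
    max_start = n - footprint
    if max_start < 0:
        return 0
    starts = rng.integers(0, max_start + 1, size=n_attempts)
    for s in starts:
        seg = occupied[s:s + footprint]
        if not seg.any():
            seg[:] = True
            bound += 1
    return bound


def simulate_competition(params: CompetitionSimParams | None = None
                         ) -> pd.DataFrame:
    """Bound enzyme count per competitor dose (one stochastic replicate).

    Columns: dose, map4_bound, vash2_bound. Expected vash2_bound is
    non-increasing in dose.
    """
    params = params or CompetitionSimParams()
    rng = np.random.default_rng(params.seed)
    rows = []
    for dose in params.map4_doses:
        occupied = np.zeros(params.n_sites, dtype=bool)
        n_map4 = int(round(dose * params.attempts_per_unit))
        m_bound = _rsa_fill(occupied, params.map4_footprint, n_map4, rng)
        n_vash2 = int(round(params.vash2_dose * params.attempts_per_unit))
        v_bound = _rsa_fill(occupied, params.vash2_footprint, n_vash2, rng)
        rows.append((dose, m_bound, v_bound))
    return pd.DataFrame(rows, columns=["dose", "map4_bound", "vash2_bound"])
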