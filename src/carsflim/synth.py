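"""Synthetic HS-CARS and FLIM scene generators with known ground truth.

No public dataset accompanies the uptake study this package models, so
every downstream stage (spectral unmixing, lipid:protein refinement,
pixel- and cell-level classification) is exercised against simulated
scenes whose generating parameters are known exactly.

The spectral generator draws, for each cell, seven Gaussian component
centers from per-class normal distributions whose means and standard
deviations are the published peak positions of the C-H stretch sub-bands
(2750-3100 cm^-1) for the Control / LNP / SAM-LNP / SAM-GFP-LNP
treatment groups.  LNP-treated classes carry elevated lipid-band
amplitudes (components 1-3), globally and additionally inside bright
lipid droplets, emulating the elevated CH2 signal of LNP uptake.

The FLIM generator produces beta1 (bound NAD(P)H fraction), tau1, tau_m
and intensity channel maps in which the within-cell Pearson correlation
between beta1 and tau_m is controlled exactly, with an optional linear
drift of that correlation over post-treatment hours — the mechanism
behind the rising beta1-tau_m colocalization seen after SAM expression.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so every generator is
bit-reproducible and independent of call order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import InvalidArgumentError

__all__ = [
    "CLASS_PRESETS",
    "ClassSpectralSpec",
    "DecayTrace",
    "FlimChannels",
    "FlimScene",
    "FlimSceneSpec",
    "SceneSpec",
    "SimulatedCube",
    "class_spec",
    "make_axis",
    "noise_sd_for_snr",
    "simulate_class_spectra",
    "simulate_decay",
    "simulate_flim_scene",
    "simulate_hypercube",
]

# Default amplitude/width profile of the seven C-H stretch components.
# These are explicit stand-ins (the study never tabulates amplitudes or
# widths of real data): the CH2 lipid peak near 2860 cm^-1 dominates,
# flanked by the protein/nucleic-acid CH3 bands, all ~20 cm^-1 wide so
# neighbouring components overlap but stay resolvable.
DEFAULT_AMPLITUDES = (0.15, 0.3, 1.0, 0.8, 0.6, 0.2, 0.1)
DEFAULT_SIGMA = 20.0
LIPID_COMPONENTS = (0, 1, 2)  # first three components: CH2 lipid sub-bands


def make_axis(start: float = 2750.0, stop: float = 3100.0, n_points: int = 240) -> np.ndarray:
    """Evenly spaced wavenumber axis (cm^-1), endpoints inclusive.

    The default reproduces the instrument's spectral-focusing sweep:
    240 delay steps covering 2750-3100 cm^-1.
    """
    if n_points < 2:
        raise InvalidArgumentError(f"n_points must be >= 2, got {n_points}")
    if not stop > start:
        raise InvalidArgumentError(f"stop must exceed start, got [{start}, {stop}]")
    return np.linspace(float(start), float(stop), int(n_points))


@dataclass(frozen=True)
class ClassSpectralSpec:
    """Class-conditional parameters of the 7-component spectral mixture.

    ``centers``/``center_sds`` are the per-class population mean and SD
    of each sub-band's peak position; each simulated cell draws its own
    centers from Normal(centers, center_sds).  ``lipid_scale`` is a
    global amplitude multiplier on the lipid components for LNP-treated
    classes; ``droplet_lipid_boost`` multiplies lipid amplitudes further
    inside droplet pixels.
    """

    class_name: str
    centers: tuple[float, ...]
    center_sds: tuple[float, ...]
    amplitudes: tuple[float, ...] = DEFAULT_AMPLITUDES
    sigmas: tuple[float, ...] = tuple([DEFAULT_SIGMA] * 7)
    lipid_scale: float = 1.0
    droplet_lipid_boost: float = 3.0

    def __post_init__(self) -> None:
        for name in ("centers", "center_sds", "amplitudes", "sigmas"):
            vals = getattr(self, name)
            if len(vals) != 7:
                raise InvalidArgumentError(f"{name} must have exactly 7 entries, got {len(vals)}")
        if any(c < 2750.0 or c > 3100.0 for c in self.centers):
            raise InvalidArgumentError("component centers must lie within [2750, 3100] cm^-1")
        if any(s <= 0 for s in self.sigmas):
            raise InvalidArgumentError("component widths must be positive")
        if any(a < 0 for a in self.amplitudes):
            raise InvalidArgumentError("component amplitudes must be nonnegative")

    def effective_amplitudes(self, droplet: bool = False) -> np.ndarray:
        """Amplitudes after lipid scaling, optionally inside a droplet."""
        amp = np.asarray(self.amplitudes, dtype=float).copy()
        boost = self.lipid_scale * (self.droplet_lipid_boost if droplet else 1.0)
        amp[list(LIPID_COMPONENTS)] *= boost
        return amp


# Published per-class peak positions (mean, SD) of the seven sub-bands.
_PEAK_TABLE = {
    "control": (
        (2767.89, 2.11), (2823.98, 2.46), (2856.42, 3.87), (2910.18, 3.08),
        (2949.25, 0.17), (2997.05, 3.31), (3045.66, 1.98),
    ),
    "lnp": (
        (2771.10, 0.55), (2826.95, 3.30), (2861.62, 3.07), (2909.46, 2.53),
        (2949.52, 1.09), (2990.41, 1.43), (3049.78, 2.91),
    ),
    "sam_lnp": (
        (2766.15, 2.02), (2827.11, 1.12), (2860.33, 1.41), (2905.84, 0.42),
        (2946.91, 2.84), (2989.24, 0.28), (3051.87, 2.04),
    ),
    "sam_gfp_lnp": (
        (2768.49, 2.16), (2824.91, 2.34), (2856.34, 1.89), (2907.57, 2.36),
        (2954.51, 0.60), (2991.84, 0.72), (3050.46, 2.53),
    ),
}

CLASS_PRESETS = tuple(_PEAK_TABLE)


def class_spec(name: str, **overrides) -> ClassSpectralSpec:
    """Preset :class:`ClassSpectralSpec` for one treatment group.

    Groups other than ``control`` were exposed to lipid nanoparticles and
    get ``lipid_scale`` = 1.5 by default (elevated lipid intensities).
    """
    key = name.lower().replace("-", "_").replace(" ", "_")
    if key not in _PEAK_TABLE:
        raise InvalidArgumentError(f"unknown class {name!r}; presets: {sorted(_PEAK_TABLE)}")
    mus, sds = zip(*_PEAK_TABLE[key])
    kwargs = dict(
        class_name=key,
        centers=mus,
        center_sds=sds,
        lipid_scale=1.0 if key == "control" else 1.5,
    )
    kwargs.update(overrides)
    return ClassSpectralSpec(**kwargs)


@dataclass(frozen=True)
class SceneSpec:
    """Spatial layout of a simulated field of view."""

    image_shape: tuple[int, int] = (64, 64)
    n_cells: int = 3
    droplet_density: float = 2.0  # expected droplets per cell
    noise_sd: float = 0.0  # additive Gaussian noise, intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        r, c = self.image_shape
        if r < 16 or c < 16:
            raise InvalidArgumentError("image_shape must be at least 16 x 16")
        if self.n_cells < 0 or self.droplet_density < 0 or self.noise_sd < 0:
            raise InvalidArgumentError("n_cells, droplet_density, noise_sd must be >= 0")


@dataclass
class SimulatedCube:
    """A simulated hyperspectral cube plus its generating ground truth."""

    cube: np.ndarray  # (rows, cols, n_wavenumbers)
    axis: np.ndarray
    cell_mask: np.ndarray  # integer labels, 0 = background
    droplet_mask: np.ndarray  # boolean
    true_centers: np.ndarray  # (n_cells, 7), per-cell drawn centers
    true_amplitudes: np.ndarray  # (rows, cols, 7), per-pixel amplitudes
    true_sigmas: np.ndarray  # (7,)
    spec: ClassSpectralSpec
    scene: SceneSpec


def _mean_class_spectrum(spec: ClassSpectralSpec, axis: np.ndarray) -> np.ndarray:
    amp = spec.effective_amplitudes()
    mu = np.asarray(spec.centers)
    sg = np.asarray(spec.sigmas)
    return (amp[:, None] * np.exp(-0.5 * ((axis[None, :] - mu[:, None]) / sg[:, None]) ** 2)).sum(0)


def noise_sd_for_snr(spec: ClassSpectralSpec, axis: np.ndarray, snr_db: float) -> float:
    """Noise SD giving the requested power SNR against the class mean spectrum.

    SNR(dB) = 10 log10(mean signal power / noise variance), so
    ``noise_sd = rms(mean spectrum) * 10**(-snr_db / 20)``.
    """
    rms = float(np.sqrt(np.mean(_mean_class_spectrum(spec, axis) ** 2)))
    return rms * 10.0 ** (-snr_db / 20.0)


def simulate_class_spectra(
    spec: ClassSpectralSpec,
    axis: np.ndarray,
    n_spectra: int,
    snr_db: float | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw standalone spectra of one class (no spatial scene).

    Each spectrum draws its seven centers from Normal(centers,
    center_sds) and uses the class's effective amplitudes and widths;
    additive Gaussian noise is set either directly (``noise_sd``) or
    via :func:`noise_sd_for_snr` (``snr_db``).  Returns ``(spectra,
    true_centers)`` of shapes (n, len(axis)) and (n, 7).
    """
    axis = np.asarray(axis, dtype=float)
    if n_spectra < 1:
        raise InvalidArgumentError("n_spectra must be >= 1")
    if noise_sd is None:
        noise_sd = 0.0 if snr_db is None else noise_sd_for_snr(spec, axis, snr_db)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    centers = rng.normal(np.asarray(spec.centers), np.asarray(spec.center_sds),
                         size=(n_spectra, 7))
    amp = spec.effective_amplitudes()
    sig = np.asarray(spec.sigmas)
    basis = np.exp(
        -0.5 * ((axis[None, None, :] - centers[:, :, None]) / sig[None, :, None]) ** 2
    )  # (n, 7, len(axis))
    spectra = np.einsum("k,nkx->nx", amp, basis)
    if noise_sd > 0:
        spectra = spectra + rng.normal(0.0, noise_sd, size=spectra.shape)
    return spectra, centers


def _place_ellipses(shape, n, rng, r_lo_frac=0.10, r_hi_frac=0.20, margin=1):
    """Label image of n filled ellipses; later labels do not overwrite earlier."""
    rows, cols = shape
    labels = np.zeros(shape, dtype=np.int32)
    rr, cc = np.mgrid[0:rows, 0:cols]
    scale = min(rows, cols)
    for k in range(1, n + 1):
        for _attempt in range(50):
            a = rng.uniform(r_lo_frac, r_hi_frac) * scale
            b = rng.uniform(r_lo_frac, r_hi_frac) * scale
            theta = rng.uniform(0, np.pi)
            cy = rng.uniform(a + margin, rows - a - margin)
            cx = rng.uniform(b + margin, cols - b - margin)
            ct, st = np.cos(theta), np.sin(theta)
            u = (rr - cy) * ct + (cc - cx) * st
            v = -(rr - cy) * st + (cc - cx) * ct
            ell = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            if not (ell & (labels > 0)).any():
                labels[ell] = k
                break
        else:  # crowded scene: accept overlap, keep earlier labels
            labels[ell & (labels == 0)] = k
    return labels


def simulate_hypercube(
    spec: ClassSpectralSpec,
    scene: SceneSpec,
    axis: np.ndarray | None = None,
) -> SimulatedCube:
    """Simulate one field of view of hyperspectral CARS data.

    Background pixels contain noise only.  Every cell draws its seven
    component centers from Normal(spec.centers, spec.center_sds); each
    cell pixel's noiseless spectrum is the sum of the seven Gaussians
    with a smooth multiplicative interior texture on the amplitudes.
    Droplet pixels (small disks inside cells) have their lipid-component
    amplitudes boosted by ``spec.droplet_lipid_boost``.
    """
    if axis is None:
        axis = make_axis()
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 15:
        raise InvalidArgumentError("axis must be a 1-D array of >= 15 wavenumbers")
    if min(spec.centers) < axis[0] or max(spec.centers) > axis[-1]:
        raise InvalidArgumentError("axis does not cover all component centers")

    ss = np.random.SeedSequence(scene.seed)
    s_layout, s_centers, s_texture, s_noise = [np.random.default_rng(s) for s in ss.spawn(4)]

    rows, cols = scene.image_shape
    labels = _place_ellipses((rows, cols), scene.n_cells, s_layout)

    # droplets: small bright disks inside cells
    droplet = np.zeros((rows, cols), dtype=bool)
    rr, cc = np.mgrid[0:rows, 0:cols]
    for k in range(1, scene.n_cells + 1):
        ys, xs = np.nonzero(labels == k)
        if ys.size == 0:
            continue
        n_drop = s_layout.poisson(scene.droplet_density)
        for _ in range(n_drop):
            i = s_layout.integers(ys.size)
            rad = s_layout.uniform(2.0, 4.0)
            disk = (rr - ys[i]) ** 2 + (cc - xs[i]) ** 2 <= rad**2
            droplet |= disk & (labels == k)

    true_centers = s_centers.normal(
        np.asarray(spec.centers), np.asarray(spec.center_sds), size=(max(scene.n_cells, 1), 7)
    )

    # smooth interior texture, mean ~1, strictly positive
    texture = ndimage.gaussian_filter(s_texture.standard_normal((rows, cols)), sigma=3.0)
    sd = texture.std()
    texture = 1.0 + 0.2 * (texture / sd if sd > 0 else texture)
    texture = np.clip(texture, 0.2, None)

    amp_base = spec.effective_amplitudes(droplet=False)
    amp_drop = spec.effective_amplitudes(droplet=True)
    true_amp = np.zeros((rows, cols, 7))
    inside = labels > 0
    true_amp[inside] = amp_base
    true_amp[droplet] = amp_drop
    true_amp *= texture[:, :, None]
    true_amp[~inside] = 0.0

    sig = np.asarray(spec.sigmas, dtype=float)
    cube = np.zeros((rows, cols, axis.size))
    for k in range(1, scene.n_cells + 1):
        sel = labels == k
        if not sel.any():
            continue
        mus = true_centers[k - 1]
        basis = np.exp(-0.5 * ((axis[None, :] - mus[:, None]) / sig[:, None]) ** 2)  # (7, n)
        cube[sel] = true_amp[sel] @ basis

    if scene.noise_sd > 0:
        cube = cube + s_noise.normal(0.0, scene.noise_sd, size=cube.shape)

    return SimulatedCube(
        cube=cube,
        axis=axis,
        cell_mask=labels,
        droplet_mask=droplet,
        true_centers=true_centers,
        true_amplitudes=true_amp,
        true_sigmas=sig,
        spec=spec,
        scene=scene,
    )


# --------------------------------------------------------------------------
# FLIM scenes


@dataclass(frozen=True)
class FlimSceneSpec:
    """Parameters of a simulated NAD(P)H FLIM time course.

    ``coloc_rho`` is the target within-cell Pearson correlation between
    the beta1 and tau_m channels at hour 0; ``rho_drift_per_hour`` moves
    it linearly with post-treatment time (SAM-expressing cells show a
    rising beta1-tau_m correlation; empty-LNP cells do not).
    """

    n_cells: int = 4
    beta1_mean: float = 0.6
    tau1_mean: float = 0.4  # ns, short (free) component
    tau2_mean: float = 2.5  # ns, long (bound) component
    taum_mean: float = 1.2  # ns
    coloc_rho: float = 0.2
    rho_drift_per_hour: float = 0.0
    nucleus_rho: float | None = None  # plant the coupling only outside the nucleus
    hours: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta1_mean <= 1.0:
            raise InvalidArgumentError("beta1_mean must lie in [0, 1]")
        if min(self.tau1_mean, self.tau2_mean, self.taum_mean) <= 0:
            raise InvalidArgumentError("lifetimes must be positive")
        for h in self.hours:
            rho = self.coloc_rho + self.rho_drift_per_hour * h
            if not -1.0 <= rho <= 1.0:
                raise InvalidArgumentError(
                    f"target correlation {rho:.3f} at hour {h} is outside [-1, 1]"
                )
        if self.nucleus_rho is not None and not -1.0 <= self.nucleus_rho <= 1.0:
            raise InvalidArgumentError("nucleus_rho must lie in [-1, 1]")

    def rho_at(self, hour: int) -> float:
        return self.coloc_rho + self.rho_drift_per_hour * hour


@dataclass
class FlimChannels:
    """The four FLIM channel maps of one field of view."""

    beta1: np.ndarray
    tau1: np.ndarray
    taum: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.beta1, self.tau1, self.taum, self.intensity)}
        if len(shapes) != 1:
            raise InvalidArgumentError("all FLIM channel maps must share one shape")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}


@dataclass
class FlimScene:
    """Simulated FLIM time course: channel maps per hour plus label masks."""

    channels: dict[int, FlimChannels]  # keyed by hour
    cell_mask: np.ndarray  # labels 1..n_cells
    nucleus_mask: np.ndarray  # labels matching cell labels
    spec: FlimSceneSpec


def _smooth_field(rng, shape, sigma=2.5):
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)


def _coupled_fields(rng, shape, sel, rho):
    """Two smooth fields whose empirical Pearson correlation over ``sel``
    equals ``rho`` exactly (Gram-Schmidt on the latent fields)."""
    z = _smooth_field(rng, shape)[sel]
    w = _smooth_field(rng, shape)[sel]
    z = (z - z.mean()) / z.std()
    w = w - w.mean()
    w = w - (w @ z) / (z @ z) * z  # orthogonal to z
    w_sd = w.std()
    if w_sd > 0:
        w = w / w_sd
    y = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * w
    return z, y


def simulate_flim_scene(
    spec: FlimSceneSpec, image_shape: tuple[int, int] = (128, 128)
) -> FlimScene:
    """Simulate beta1/tau1/tau_m/intensity maps for each requested hour.

    Within each cell, beta1 and tau_m are smooth random fields whose
    empirical Pearson correlation equals ``spec.rho_at(hour)`` before
    clipping (beta1 to [0,1], lifetimes to a small positive floor); the
    perturbation amplitudes are small enough that clipping is rare, so
    the realized correlation stays within a few hundredths of target.
    """
    rows, cols = image_shape
    if rows < 16 or cols < 16:
        raise InvalidArgumentError("image_shape must be at least 16 x 16")
    ss = np.random.SeedSequence(spec.seed)
    s_layout, s_fields = [np.random.default_rng(s) for s in ss.spawn(2)]

    cells = _place_ellipses((rows, cols), spec.n_cells, s_layout, 0.12, 0.22, margin=2)
    nuclei = np.zeros_like(cells)
    # nucleus: erode each cell to roughly a third of its area
    for k in range(1, spec.n_cells + 1):
        sel = cells == k
        if not sel.any():
            continue
        area = sel.sum()
        er = sel
        while er.sum() > area / 3.0:
            nxt = ndimage.binary_erosion(er)
            if nxt.sum() < 8:
                break
            er = nxt
        nuclei[er] = k

    channels: dict[int, FlimChannels] = {}
    for hour in spec.hours:
        rho = spec.rho_at(hour)
        beta1 = np.zeros((rows, cols))
        taum = np.zeros((rows, cols))
        tau1 = np.zeros((rows, cols))
        inten = np.zeros((rows, cols))
        for k in range(1, spec.n_cells + 1):
            sel = cells == k
            if sel.sum() < 4:
                continue
            if spec.nucleus_rho is None:
                regions = [(sel, rho)]
            else:
                nuc = nuclei == k
                regions = [(sel & ~nuc, rho), (nuc, spec.nucleus_rho)]
            for region, region_rho in regions:
                if region.sum() < 4:
                    continue
                z, y = _coupled_fields(s_fields, (rows, cols), region, region_rho)
                beta1[region] = np.clip(spec.beta1_mean + 0.08 * z, 0.0, 1.0)
                taum[region] = np.clip(spec.taum_mean * (1.0 + 0.12 * y), 0.05, None)
            t1 = _smooth_field(s_fields, (rows, cols))[sel]
            t1 = (t1 - t1.mean()) / (t1.std() or 1.0)
            tau1[sel] = np.clip(spec.tau1_mean * (1.0 + 0.10 * t1), 0.02, None)
            ii = _smooth_field(s_fields, (rows, cols))[sel]
            ii = (ii - ii.mean()) / (ii.std() or 1.0)
            inten[sel] = np.clip(500.0 * (1.0 + 0.25 * ii), 10.0, None)
        channels[hour] = FlimChannels(beta1=beta1, tau1=tau1, taum=taum, intensity=inten)

    return FlimScene(channels=channels, cell_mask=cells, nucleus_mask=nuclei, spec=spec)


# --------------------------------------------------------------------------
# Decay traces


@dataclass
class DecayTrace:
    """A TCSPC-style fluorescence decay histogram."""

    time_bins: np.ndarray  # ns
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.time_bins = np.asarray(self.time_bins, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.time_bins.shape != self.counts.shape:
            raise InvalidArgumentError("time_bins and counts must have equal length")
        if (self.counts < 0).any():
            raise InvalidArgumentError("counts must be nonnegative")


def biexponential(t: np.ndarray, beta1: float, tau1: float, tau2: float,
                  amplitude: float = 1.0, offset: float = 0.0) -> np.ndarray:
    """A(beta1 e^(-t/tau1) + (1-beta1) e^(-t/tau2)) + offset."""
    t = np.asarray(t, dtype=float)
    return amplitude * (beta1 * np.exp(-t / tau1) + (1.0 - beta1) * np.exp(-t / tau2)) + offset


def simulate_decay(
    beta1: float,
    tau1: float,
    tau2: float,
    amplitude: float = 1000.0,
    n_bins: int = 256,
    t_max: float = 12.5,
    noise: str = "none",
    seed: int = 0,
) -> DecayTrace:
    """Simulate a two-component NAD(P)H decay trace.

    ``noise='poisson'`` replaces each bin's expectation with a Poisson
    draw, the shot-noise model of photon counting.
    """
    if not 0.0 <= beta1 <= 1.0:
        raise InvalidArgumentError("beta1 must lie in [0, 1]")
    if tau1 <= 0 or tau2 <= 0:
        raise InvalidArgumentError("lifetimes must be positive")
    if noise not in ("none", "poisson"):
        raise InvalidArgumentError(f"noise must be 'none' or 'poisson', got {noise!r}")
    t = np.linspace(0.0, t_max, n_bins)
    counts = biexponential(t, beta1, tau1, tau2, amplitude)
    if noise == "poisson":
        counts = np.random.default_rng(seed).poisson(counts).astype(float)
    return DecayTrace(time_bins=t, counts=counts)
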