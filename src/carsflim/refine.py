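"""Lipid:protein sub-band refinement of cell masks.

To focus classification on lipid-rich areas (where LNP uptake shows),
the spectrum at each cell pixel is reduced to the energies of the CH2
lipid sub-band (2750-2890 cm^-1) and the CH3 protein / nucleic-acid
sub-band (2890-2990 cm^-1).  The per-pixel lipid:protein energy ratio
is thresholded with Otsu's method over all valid in-cell pixels, and
only the high-ratio ("yellow") pixels are kept for classification.

Band energy is the trapezoidal integral of the spectrum over the band,
with the band edges inserted as interpolated nodes, so that adjacent
bands tile exactly: energy(lipid) + energy(protein) =
energy(2750-2990).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .carsfit import Hypercube
from .exceptions import DegenerateInputError, InvalidArgumentError

__all__ = [
    "BandDefinition",
    "LIPID_BAND",
    "PROTEIN_BAND",
    "RatioMap",
    "RefinedMask",
    "band_energy",
    "band_energy_map",
    "lipid_protein_ratio",
    "otsu_threshold",
    "refine_mask",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandDefinition:
    """A named spectral sub-band [lo, hi] in cm^-1."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise InvalidArgumentError(f"band {self.name}: lo must be < hi")


LIPID_BAND = BandDefinition("lipid", 2750.0, 2890.0)
PROTEIN_BAND = BandDefinition("protein", 2890.0, 2990.0)


def _band_nodes(axis: np.ndarray, band: BandDefinition) -> np.ndarray:
    if band.lo < axis[0] or band.hi > axis[-1]:
        raise InvalidArgumentError(
            f"band {band.name} [{band.lo}, {band.hi}] lies outside axis "
            f"[{axis[0]}, {axis[-1]}]"
        )
    inner = axis[(axis > band.lo) & (axis < band.hi)]
    return np.concatenate(([band.lo], inner, [band.hi]))


def band_energy(spectrum: np.ndarray, axis: np.ndarray, band: BandDefinition) -> float:
    """Trapezoidal integral of the spectrum over ``band`` (intensity * cm^-1)."""
    x = np.asarray(axis, dtype=float)
    y = np.asarray(spectrum, dtype=float)
    if x.shape != y.shape:
        raise InvalidArgumentError("spectrum and axis must have equal length")
    nodes = _band_nodes(x, band)
    vals = np.interp(nodes, x, y)
    return float(np.trapezoid(vals, nodes))


def band_energy_map(cube: Hypercube, band: BandDefinition) -> np.ndarray:
    """Per-pixel band energy over a whole hypercube (vectorized)."""
    nodes = _band_nodes(cube.axis, band)
    # linear interpolation weights of each node on the original axis
    idx = np.searchsorted(cube.axis, nodes, side="right") - 1
    idx = np.clip(idx, 0, cube.axis.size - 2)
    frac = (nodes - cube.axis[idx]) / (cube.axis[idx + 1] - cube.axis[idx])
    vals = cube.data[..., idx] * (1 - frac) + cube.data[..., idx + 1] * frac
    return np.trapezoid(vals, nodes, axis=-1)


@dataclass
class RatioMap:
    """Per-pixel lipid:protein band-energy ratio with a validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray
    n_invalid: int = 0


def lipid_protein_ratio(
    cube: Hypercube,
    mask: np.ndarray,
    lipid_band: BandDefinition = LIPID_BAND,
    protein_band: BandDefinition = PROTEIN_BAND,
    eps: float = 1e-3,
) -> RatioMap:
    """Lipid:protein band-energy ratio over masked pixels.

    Pixels whose protein-band energy is at most ``eps`` times the
    masked maximum are marked invalid rather than producing infinities;
    their count is logged.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != cube.spatial_shape:
        raise InvalidArgumentError("mask shape does not match cube spatial shape")
    if not mask.any():
        raise InvalidArgumentError("mask selects no pixels")
    lipid = band_energy_map(cube, lipid_band)
    protein = band_energy_map(cube, protein_band)
    pmax = protein[mask].max()
    valid = mask & (protein > eps * max(pmax, 0.0))
    values = np.zeros(cube.spatial_shape)
    values[valid] = lipid[valid] / protein[valid]
    n_invalid = int(mask.sum() - valid.sum())
    if n_invalid:
        logger.info("lipid_protein_ratio: %d masked pixels invalid (protein energy ~ 0)",
                    n_invalid)
    return RatioMap(values=values, valid_mask=valid, n_invalid=n_invalid)


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: the histogram cut maximizing between-class variance.

    Returns the upper edge of the best cut bin; samples strictly above
    the returned threshold fall in the high class.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2 or np.unique(v).size < 2:
        raise DegenerateInputError("Otsu threshold undefined for constant input")
    if n_bins < 2:
        raise InvalidArgumentError("n_bins must be >= 2")
    counts, edges = np.histogram(v, bins=n_bins)
    w = counts.astype(float)
    p = w / w.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    omega0 = np.cumsum(p)[:-1]  # cut after bin i -> low class = bins 0..i
    omega1 = 1.0 - omega0
    cum_mean = np.cumsum(p * centers)[:-1]
    total_mean = (p * centers).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / omega0
        mu1 = (total_mean - cum_mean) / omega1
        sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    sigma_b = np.where((omega0 > 0) & (omega1 > 0), sigma_b, -np.inf)
    best = int(np.argmax(sigma_b))
    return float(edges[best + 1])


@dataclass
class RefinedMask:
    """High-ratio pixels retained for classification."""

    mask: np.ndarray
    threshold: float
    retention_fraction: float


def refine_mask(ratio: RatioMap, cell_mask: np.ndarray, n_bins: int = 256) -> RefinedMask:
    """Keep in-cell pixels whose ratio exceeds the Otsu threshold.

    The threshold is computed over valid in-cell pixels of this ratio
    map; to pool statistics across a whole experiment instead, compute
    :func:`otsu_threshold` on the concatenated ratios and apply it
    manually.
    """
    cell = np.asarray(cell_mask).astype(bool)
    pool = ratio.valid_mask & cell
    if not pool.any():
        raise DegenerateInputError("no valid in-cell pixels to refine")
    thr = otsu_threshold(ratio.values[pool], n_bins=n_bins)
    kept = pool & (ratio.values > thr)
    frac = float(kept.sum() / pool.sum())
    logger.info("refine_mask: threshold %.4f retains %.1f%% of %d valid pixels",
                thr, 100 * frac, int(pool.sum()))
    return RefinedMask(mask=kept, threshold=thr, retention_fraction=frac)
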