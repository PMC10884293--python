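"""Single-cell FLIM feature extraction over cell compartments.

Cells arrive as label masks (segmentation itself is an input, not a
step of this package); each cell is split into whole-cell, nucleus and
cytoplasm (= cell minus nucleus) compartments, and per compartment the
four channel maps (beta1, tau1, tau_m, intensity) are reduced to:

* pairwise correlation / colocalization statistics — Pearson r, Costes
  coefficients behind automatically determined dual thresholds, and
  rank-weighted colocalization (RWC);
* per-channel intensity statistics, including edge statistics on the
  4-connected compartment boundary;
* basic morphology of the compartment mask.

The Costes procedure fits an orthogonal regression line between the two
channels on standardized data, then walks 256 candidate thresholds down
the first channel's range (the second channel's threshold following the
regression line) until the pixels *below* both thresholds are
uncorrelated (Pearson <= 0); the fraction of each channel's intensity
above both thresholds is its Costes coefficient.  RWC additionally
weights each colocalized pixel by the agreement of its intensity ranks
across the two channels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.stats import rankdata
from skimage.measure import regionprops

from .exceptions import InvalidArgumentError, UndefinedStatisticError
from .synth import DecayTrace

__all__ = [
    "BiexpFit",
    "CellRecord",
    "COMPARTMENTS",
    "build_feature_table",
    "costes_coefficients",
    "costes_thresholds",
    "derive_compartments",
    "fit_biexponential",
    "intensity_features",
    "morphology_features",
    "pearson_corr",
    "pivot_compartments",
    "rwc_coefficients",
]

logger = logging.getLogger(__name__)

COMPARTMENTS = ("cell", "nucleus", "cytoplasm")
CHANNEL_NAMES = ("beta1", "tau1", "taum", "intensity")


@dataclass
class CellRecord:
    """One cell's compartment masks plus its (noisy) group label and hour."""

    cell_id: int
    cell: np.ndarray  # boolean whole-cell mask
    nucleus: np.ndarray
    cytoplasm: np.ndarray
    group: str = ""
    hour: int = 0

    def compartment(self, name: str) -> np.ndarray:
        if name not in COMPARTMENTS:
            raise InvalidArgumentError(f"unknown compartment {name!r}")
        return getattr(self, name)


def derive_compartments(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    group: str = "",
    hour: int = 0,
) -> list[CellRecord]:
    """Split labelled cells into whole/nucleus/cytoplasm compartments.

    Cells touching the image border are dropped (their morphology and
    edge statistics would be truncated).  A nucleus overlapping zero or
    several cells, or a cell without a nucleus, is skipped with a
    warning.
    """
    cells = np.asarray(cell_mask)
    nuclei = np.asarray(nucleus_mask)
    if cells.shape != nuclei.shape:
        raise InvalidArgumentError("cell and nucleus masks must share a shape")

    # map nucleus label -> owning cell label (must be unique)
    cell_to_nuc: dict[int, np.ndarray] = {}
    for nl in np.unique(nuclei):
        if nl == 0:
            continue
        sel = nuclei == nl
        owners = np.unique(cells[sel])
        owners = owners[owners != 0]
        if owners.size != 1 or (cells[sel] == 0).any():
            warnings.warn(f"nucleus {nl} does not lie inside exactly one cell; skipped")
            continue
        owner = int(owners[0])
        if owner in cell_to_nuc:
            cell_to_nuc[owner] |= sel
        else:
            cell_to_nuc[owner] = sel

    records: list[CellRecord] = []
    n_border = 0
    for cl in np.unique(cells):
        if cl == 0:
            continue
        sel = cells == cl
        if sel[0, :].any() or sel[-1, :].any() or sel[:, 0].any() or sel[:, -1].any():
            n_border += 1
            continue
        nuc = cell_to_nuc.get(int(cl))
        if nuc is None:
            warnings.warn(f"cell {cl} has no nucleus; skipped")
            continue
        cyto = sel & ~nuc
        if not cyto.any() or not nuc.any():
            warnings.warn(f"cell {cl} has an empty compartment; skipped")
            continue
        records.append(
            CellRecord(cell_id=int(cl), cell=sel, nucleus=nuc, cytoplasm=cyto,
                       group=group, hour=hour)
        )
    if n_border:
        logger.info("derive_compartments: dropped %d border-touching cells", n_border)
    return records


# --------------------------------------------------------------------------
# correlation / colocalization


def _masked_pair(ch_a, ch_b, mask):
    mask = np.asarray(mask).astype(bool)
    a = np.asarray(ch_a, dtype=float)[mask]
    b = np.asarray(ch_b, dtype=float)[mask]
    return a, b


def pearson_corr(ch_a: np.ndarray, ch_b: np.ndarray, mask: np.ndarray) -> float:
    """Sample Pearson correlation of two channels over masked pixels."""
    a, b = _masked_pair(ch_a, ch_b, mask)
    if a.size < 3:
        raise InvalidArgumentError("need at least 3 masked pixels")
    if a.std() == 0 or b.std() == 0:
        raise UndefinedStatisticError("correlation undefined for a constant channel")
    return float(np.corrcoef(a, b)[0, 1])


def _orthogonal_line(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Standardized orthogonal (reduced-major-axis) regression b = g a + o.

    Fitting on standardized data makes the thresholds exactly
    equivariant under positive affine rescaling of either channel.
    """
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise UndefinedStatisticError("regression undefined for a constant channel")
    r = np.corrcoef(a, b)[0, 1]
    gain = (1.0 if r >= 0 else -1.0) * sb / sa
    offset = b.mean() - gain * a.mean()
    return float(gain), float(offset)


def costes_thresholds(
    ch_a: np.ndarray, ch_b: np.ndarray, mask: np.ndarray, n_steps: int = 256
) -> tuple[float, float]:
    """Automatic dual thresholds for colocalization (Costes procedure).

    Scans T_a downward from max(ch_a) in ``n_steps`` steps, with
    T_b = gain * T_a + offset along the orthogonal regression line, and
    returns the highest pair for which the pixels below both thresholds
    are uncorrelated (Pearson <= 0).  If that point is never reached the
    scan floor (the channel minimum) is returned — the fully correlated
    limit in which every pixel counts as colocalized.
    """
    a, b = _masked_pair(ch_a, ch_b, mask)
    if a.size < 3:
        raise InvalidArgumentError("need at least 3 masked pixels")
    gain, offset = _orthogonal_line(a, b)
    if np.corrcoef(a, b)[0, 1] <= 0:
        # anti-correlated channels carry no colocalization: place both
        # thresholds a full channel range above the maxima (affine-
        # equivariant), so no pixel passes the gate
        return (
            float(a.max() + (a.max() - a.min())),
            float(b.max() + (b.max() - b.min())),
        )
    grid = np.linspace(a.max(), a.min(), n_steps)
    for t_a in grid:
        t_b = gain * t_a + offset
        below = (a < t_a) & (b < t_b)
        if below.sum() < 3:
            continue
        ab, bb = a[below], b[below]
        if ab.std() == 0 or bb.std() == 0:
            continue
        if np.corrcoef(ab, bb)[0, 1] <= 0:
            return float(t_a), float(t_b)
    t_a = float(grid[-1])
    return t_a, float(gain * t_a + offset)


def _coloc_gate(a, b, thresholds):
    t_a, t_b = thresholds
    return (a >= t_a) & (b >= t_b)


def costes_coefficients(
    ch_a: np.ndarray,
    ch_b: np.ndarray,
    mask: np.ndarray,
    thresholds: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Costes colocalization coefficients (C_a, C_b), each in [0, 1].

    C_a is the fraction of channel a's total masked intensity carried
    by pixels at or above both thresholds (symmetrically for C_b).
    """
    a, b = _masked_pair(ch_a, ch_b, mask)
    if thresholds is None:
        thresholds = costes_thresholds(ch_a, ch_b, mask)
    tot_a, tot_b = a.sum(), b.sum()
    if tot_a <= 0 or tot_b <= 0:
        raise UndefinedStatisticError("zero total intensity; coefficients undefined")
    gate = _coloc_gate(a, b, thresholds)
    return float(a[gate].sum() / tot_a), float(b[gate].sum() / tot_b)


def rwc_coefficients(
    ch_a: np.ndarray,
    ch_b: np.ndarray,
    mask: np.ndarray,
    thresholds: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Rank-weighted colocalization coefficients (RWC_a, RWC_b) in [0, 1].

    Within the mask, each pixel gets weight W = (R_max - |R_a - R_b|) /
    R_max from the disagreement of its average-tie intensity ranks in
    the two channels (R_max = number of masked pixels); RWC_a is the
    W-weighted intensity fraction of channel a over the colocalized
    (above-both-thresholds) pixels.
    """
    a, b = _masked_pair(ch_a, ch_b, mask)
    if a.size < 3:
        raise InvalidArgumentError("need at least 3 masked pixels")
    if thresholds is None:
        thresholds = costes_thresholds(ch_a, ch_b, mask)
    tot_a, tot_b = a.sum(), b.sum()
    if tot_a <= 0 or tot_b <= 0:
        raise UndefinedStatisticError("zero total intensity; coefficients undefined")
    r_a = rankdata(a, method="average")
    r_b = rankdata(b, method="average")
    w = (a.size - np.abs(r_a - r_b)) / a.size
    gate = _coloc_gate(a, b, thresholds)
    return (
        float((a[gate] * w[gate]).sum() / tot_a),
        float((b[gate] * w[gate]).sum() / tot_b),
    )


# --------------------------------------------------------------------------
# intensity / morphology


def _edge_mask(mask: np.ndarray) -> np.ndarray:
    """Masked pixels with at least one 4-connected neighbor outside."""
    cross = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(mask, structure=cross, border_value=0)
    return mask & ~interior


def intensity_features(channel: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """min/max/mean/median/sd over the mask plus edge statistics."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise InvalidArgumentError("mask selects no pixels")
    vals = np.asarray(channel, dtype=float)[mask]
    edge = _edge_mask(mask)
    evals = np.asarray(channel, dtype=float)[edge]
    return {
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "median": float(np.median(vals)),
        "sd": float(vals.std()),
        "min_edge": float(evals.min()) if evals.size else float("nan"),
        "mean_edge": float(evals.mean()) if evals.size else float("nan"),
    }


def morphology_features(mask: np.ndarray) -> dict[str, float]:
    """area, perimeter, eccentricity, solidity of a binary mask."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise InvalidArgumentError("mask selects no pixels")
    props = regionprops(mask.astype(np.uint8))[0]
    return {
        "area": float(props.area),
        "perimeter": float(props.perimeter),
        "eccentricity": float(props.eccentricity),
        "solidity": float(props.solidity),
    }


# --------------------------------------------------------------------------
# feature table


def _cell_features(channels: dict[str, np.ndarray], mask: np.ndarray) -> dict[str, float]:
    feats: dict[str, float] = {}
    names = [n for n in CHANNEL_NAMES if n in channels]
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            a, b = channels[na], channels[nb]
            try:
                thr = costes_thresholds(a, b, mask)
                c_a, c_b = costes_coefficients(a, b, mask, thr)
                rw_a, rw_b = rwc_coefficients(a, b, mask, thr)
                pr = pearson_corr(a, b, mask)
            except (UndefinedStatisticError, InvalidArgumentError):
                c_a = c_b = rw_a = rw_b = pr = float("nan")
            feats[f"costes_{na}_{nb}"] = c_a
            feats[f"costes_{nb}_{na}"] = c_b
            feats[f"rwc_{na}_{nb}"] = rw_a
            feats[f"rwc_{nb}_{na}"] = rw_b
            feats[f"pearson_{na}_{nb}"] = pr
    for na in names:
        try:
            stats = intensity_features(channels[na], mask)
        except InvalidArgumentError:
            stats = {k: float("nan") for k in
                     ("min", "max", "mean", "median", "sd", "min_edge", "mean_edge")}
        feats.update({f"{k}_{na}": v for k, v in stats.items()})
    feats.update(morphology_features(mask))
    return feats


def build_feature_table(
    records: list[CellRecord],
    channels: dict[str, np.ndarray] | "FlimChannels",  # noqa: F821
    clean: bool = True,
) -> pd.DataFrame:
    """Per cell x compartment feature table with NaN/zero-variance cleanup.

    One row per (cell, compartment); metadata columns cell_id,
    compartment, group, hour.  With ``clean=True``, feature columns
    containing any NaN and feature columns with zero variance across
    all rows are dropped; the drop list is logged and stored in
    ``DataFrame.attrs['dropped_columns']``.
    """
    if hasattr(channels, "as_dict"):
        channels = channels.as_dict()
    rows = []
    for rec in records:
        for comp in COMPARTMENTS:
            row = {
                "cell_id": rec.cell_id,
                "compartment": comp,
                "group": rec.group,
                "hour": rec.hour,
            }
            row.update(_cell_features(channels, rec.compartment(comp)))
            rows.append(row)
    table = pd.DataFrame(rows)
    meta = ["cell_id", "compartment", "group", "hour"]
    dropped: list[str] = []
    if clean and len(table):
        for col in [c for c in table.columns if c not in meta]:
            vals = table[col].to_numpy()
            if np.isnan(vals).any() or np.nanstd(vals) == 0:
                dropped.append(col)
        table = table.drop(columns=dropped)
        if dropped:
            logger.info("build_feature_table: dropped %d columns (NaN or zero variance): %s",
                        len(dropped), dropped)
    table.attrs["dropped_columns"] = dropped
    return table


def pivot_compartments(table: pd.DataFrame) -> pd.DataFrame:
    """Wide per-cell table: one row per cell, feature columns prefixed by
    compartment (``cytoplasm:costes_beta1_taum`` etc.), metadata kept."""
    meta = [c for c in ("cell_id", "group", "hour") if c in table.columns]
    pieces = []
    for comp in COMPARTMENTS:
        sub = table[table["compartment"] == comp].drop(columns=["compartment"])
        feats = [c for c in sub.columns if c not in meta]
        sub = sub.rename(columns={f: f"{comp}:{f}" for f in feats})
        pieces.append(sub.set_index(meta))
    wide = pd.concat(pieces, axis=1).reset_index()
    return wide


# --------------------------------------------------------------------------
# biexponential decay fitting


@dataclass
class BiexpFit:
    """A two-component decay fit; components sorted by ascending lifetime.

    ``beta1`` is the fractional amplitude of the tau1 (shorter)
    component; ``taum = beta1 tau1 + (1 - beta1) tau2`` by construction.
    Which component is "bound" NAD(P)H is an instrument convention left
    to the caller.
    """

    beta1: float
    tau1: float
    tau2: float
    taum: float
    amplitude: float
    offset: float
    converged: bool
    degenerate: bool = False  # one component vanishing: other lifetime unidentifiable


def fit_biexponential(trace: DecayTrace, init: dict | None = None) -> BiexpFit:
    """Least-squares fit of A(b e^(-t/tau1) + (1-b) e^(-t/tau2)) + c.

    Tail fit without instrument-response deconvolution.  beta1 is
    constrained to [0, 1] and lifetimes to be positive; if the fitted
    mixture collapses onto one component (beta1 near 0 or 1), the
    unidentifiable lifetime is flagged via ``degenerate``.
    """
    t, y = trace.time_bins, trace.counts
    if t.size < 20:
        raise InvalidArgumentError("need at least 20 bins to fit a biexponential")
    if y.sum() <= 0:
        raise InvalidArgumentError("trace has no counts")

    init = init or {}
    span = max(t[-1] - t[0], 1e-6)
    p0 = np.array([
        init.get("beta1", 0.5),
        init.get("tau1", span / 20),
        init.get("tau2", span / 3),
        init.get("amplitude", float(y.max() - y.min())),
        init.get("offset", float(y.min())),
    ])
    lo = np.array([0.0, 1e-4, 1e-4, 0.0, -np.inf])
    hi = np.array([1.0, np.inf, np.inf, np.inf, np.inf])
    p0 = np.clip(p0, lo, np.where(np.isinf(hi), p0, hi))

    def resid(p):
        b, t1, t2, amp, c = p
        return amp * (b * np.exp(-t / t1) + (1 - b) * np.exp(-t / t2)) + c - y

    res = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                        ftol=1e-10, xtol=1e-10, max_nfev=5000)
    b, t1, t2, amp, c = res.x
    if t1 > t2:  # report ascending lifetimes
        t1, t2 = t2, t1
        b = 1.0 - b
    taum = b * t1 + (1 - b) * t2
    degenerate = bool(b < 1e-3 or b > 1 - 1e-3 or abs(t2 - t1) < 1e-3 * t2)
    return BiexpFit(
        beta1=float(b), tau1=float(t1), tau2=float(t2), taum=float(taum),
        amplitude=float(amp), offset=float(c),
        converged=bool(res.status > 0), degenerate=degenerate,
    )
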