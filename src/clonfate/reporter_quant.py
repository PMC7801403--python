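"""Reporter-based quantification: flow gating and intravital-image geometry.

The mTORC1 reporter is a degron fusion degraded when mTORC1 is active, so
mVenus fluorescence is *inversely* proportional to mTORC1 activity.  Gating
follows the published convention: the mTORC1-low (mVenus-bright) gate is the
set of events with mVenus strictly above the lower 10th percentile of a
rapamycin-treated (fully inhibited) reference sample; events at or below the
threshold are mTORC1-high.

Image quantification classifies detected cells by the mVenus/TdTomato
intensity ratio (>= 0.4 -> mTORC1-low, < 0.4 -> mTORC1-high, boundary
inclusive to low) and measures each cell's shortest 3-D Euclidean distance
to the bone (second-harmonic) surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

__all__ = [
    "GateModel",
    "CellDetection",
    "fit_reference_gate",
    "classify_events",
    "inhibition_rate",
    "burden_activity_correlation",
    "g0_fraction",
    "apoptosis_call",
    "detect_cells",
    "classify_cells_by_ratio",
    "distance_to_bone",
]


@dataclass(frozen=True)
class GateModel:
    """Intensity gate anchored at a percentile of a reference sample."""

    threshold: float
    percentile: float = 10.0
    reference: str = "rapamycin-treated reference"
    degenerate: bool = False


@dataclass
class CellDetection:
    """One detected cell: centroid (um), channel means, class, geometry."""

    centroid_um: tuple[float, float, float]   # (z, y, x)
    mean_mvenus: float
    mean_tdtomato: float
    ratio: float | None = None
    label: str | None = None                  # mTORC1_high / mTORC1_low / unclassifiable
    distance_to_bone_um: float | None = None


def _wilson_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    z = stats.norm.ppf(1 - alpha / 2)
    p = k / n
    denom = 1 + z ** 2 / n
    centre = (p + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


# ---------------------------------------------------------------------------
# Flow gating
# ---------------------------------------------------------------------------


def fit_reference_gate(reference_mvenus, percentile: float = 10.0) -> GateModel:
    """Set the gate threshold at the lower percentile of the reference.

    Uses numpy's linear interpolation between order statistics.  A constant
    reference yields a degenerate (flagged) gate.
    """
    ref = np.asarray(reference_mvenus, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference sample")
    if ref.size < 10:
        raise ValueError("need at least 10 reference values")
    thr = float(np.percentile(ref, percentile))
    return GateModel(thr, percentile, degenerate=bool(ref.min() == ref.max()))


def classify_events(events: pd.DataFrame, gate: GateModel):
    """Label events by the mVenus gate and report the mTORC1-low fraction.

    mVenus strictly above the threshold -> ``mTORC1_low``; at or below ->
    ``mTORC1_high`` ("higher than" in the gating convention is strict).
    Returns (labels, low_fraction, wilson_95_ci).
    """
    if "mVenus" not in events.columns:
        raise ValueError("events table lacks an mVenus column")
    low = events["mVenus"].to_numpy() > gate.threshold
    labels = pd.Series(np.where(low, "mTORC1_low", "mTORC1_high"),
                       index=events.index)
    n = len(events)
    frac = float(low.sum() / n) if n else np.nan
    return labels, frac, _wilson_ci(int(low.sum()), n)


def inhibition_rate(treated_mvenus, vehicle_mvenus, method: str = "geometric"):
    """mTORC1 inhibition responsiveness: treated / vehicle mVenus intensity.

    Ratio of geometric means by default (fluorescence intensities are
    log-distributed); an arithmetic-mean variant is available.  Values > 1
    indicate that the inhibitor stabilised the probe, i.e. mTORC1 was active.
    """
    t = np.asarray(treated_mvenus, dtype=float)
    v = np.asarray(vehicle_mvenus, dtype=float)
    if t.size == 0 or v.size == 0:
        raise ValueError("both samples must be nonempty")
    if method == "geometric":
        if (t <= 0).any() or (v <= 0).any():
            raise ValueError("geometric means require positive intensities")
        return float(np.exp(np.log(t).mean() - np.log(v).mean()))
    if method == "arithmetic":
        return float(t.mean() / v.mean())
    raise ValueError("method must be 'geometric' or 'arithmetic'")


def burden_activity_correlation(burden, mean_mvenus):
    """Spearman correlation between per-animal burden and mVenus intensity.

    Because mVenus is inverse to mTORC1 activity, the activity-burden
    correlation is the negated coefficient; both are returned as
    ``(rho_mvenus, rho_activity, p_value)``.
    """
    b = np.asarray(burden, dtype=float)
    m = np.asarray(mean_mvenus, dtype=float)
    if len(b) != len(m) or len(b) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(b) == 0 or np.ptp(m) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(b, m)
    return float(rho), float(-rho), float(p)


def g0_fraction(p27_mvenus, gate: GateModel) -> float:
    """Fraction of cells in G0 (above the p27 reporter gate)."""
    v = np.asarray(p27_mvenus, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    return float((v > gate.threshold).mean())


def apoptosis_call(
    events: pd.DataFrame,
    control_events: pd.DataFrame,
    threshold_percentile: float = 1.0,
):
    """Call apoptotic cells from the caspase FRET probe.

    The per-event FRET/Amcyan ratio normalises FRET to probe expression;
    probe cleavage in apoptosis collapses the ratio.  The cutoff is the
    ``threshold_percentile`` (default 1st) percentile of the untreated
    control's ratio; events strictly below it are apoptotic.  Events with
    nonpositive Amcyan are dropped and counted.  Returns
    ``(apoptotic_fraction, labels, n_dropped)``.
    """
    for df, name in ((events, "events"), (control_events, "control_events")):
        if not {"Amcyan", "FRET"} <= set(df.columns):
            raise ValueError(f"{name} must have Amcyan and FRET columns")
    if len(control_events) == 0:
        raise ValueError("control sample must be nonempty")

    ok = events["Amcyan"].to_numpy() > 0
    n_dropped = int((~ok).sum())
    ratio = events.loc[ok, "FRET"].to_numpy() / events.loc[ok, "Amcyan"].to_numpy()
    ctrl_ok = control_events["Amcyan"] > 0
    ctrl_ratio = (control_events.loc[ctrl_ok, "FRET"]
                  / control_events.loc[ctrl_ok, "Amcyan"])
    cutoff = float(np.percentile(ctrl_ratio, threshold_percentile))
    apo = ratio < cutoff
    labels = pd.Series(apo, index=events.index[ok], name="apoptotic")
    return float(apo.mean()) if len(apo) else np.nan, labels, n_dropped


# ---------------------------------------------------------------------------
# Imaging
# ---------------------------------------------------------------------------


def detect_cells(
    stack: np.ndarray,
    voxel_size: tuple[float, float, float],
    channel_names: tuple[str, ...] = ("TdTomato", "mVenus", "bone"),
    smooth_sigma: float = 1.0,
    min_distance_voxels: int = 2,
    threshold_rel: float = 0.1,
) -> list[CellDetection]:
    """Detect cells in a multi-channel stack by blurred local maxima.

    The cell channels (all channels except 'bone') are summed, Gaussian
    blurred, and local maxima above ``threshold_rel`` of the global maximum
    become detections.  Per-cell channel means are taken over a 2-voxel
    neighbourhood.  Centroids are reported in micrometres.
    """
    if stack.ndim != 4:
        raise ValueError("stack must be (channels, z, y, x)")
    if len(channel_names) != stack.shape[0]:
        raise ValueError("channel_names must match the channel axis")
    if len(voxel_size) != 3:
        raise ValueError("voxel_size must be (dz, dy, dx)")
    names = list(channel_names)
    cell_idx = [i for i, n in enumerate(names) if n != "bone"]
    tdt_i, mv_i = names.index("TdTomato"), names.index("mVenus")

    signal = stack[cell_idx].sum(axis=0).astype(float)
    if signal.max() <= 0:
        return []
    sm = ndimage.gaussian_filter(signal, smooth_sigma)
    peaks = peak_local_max(sm, min_distance=min_distance_voxels,
                           threshold_abs=threshold_rel * sm.max())

    out = []
    vs = np.asarray(voxel_size)
    r = 2
    for pz, py, px in peaks:
        sl = tuple(slice(max(0, c - r), c + r + 1) for c in (pz, py, px))
        mask = np.ones(stack[tdt_i][sl].shape, dtype=bool)
        # intensity-weighted centroid refinement inside the window
        local = sm[sl]
        com = ndimage.center_of_mass(local)
        cz = (sl[0].start + com[0]) * vs[0]
        cy = (sl[1].start + com[1]) * vs[1]
        cx = (sl[2].start + com[2]) * vs[2]
        out.append(CellDetection(
            centroid_um=(float(cz), float(cy), float(cx)),
            mean_mvenus=float(stack[mv_i][sl][mask].mean()),
            mean_tdtomato=float(stack[tdt_i][sl][mask].mean()),
        ))
    return out


def classify_cells_by_ratio(
    detections: list[CellDetection], threshold: float = 0.4,
) -> list[CellDetection]:
    """Classify detections by the mVenus/TdTomato ratio.

    Ratio >= threshold (default 0.4, boundary inclusive) -> ``mTORC1_low``;
    below -> ``mTORC1_high``.  Cells with zero TdTomato are flagged
    unclassifiable.
    """
    for d in detections:
        if d.mean_tdtomato <= 0:
            d.ratio, d.label = None, "unclassifiable"
            continue
        d.ratio = d.mean_mvenus / d.mean_tdtomato
        d.label = "mTORC1_low" if d.ratio >= threshold else "mTORC1_high"
    return detections


def distance_to_bone(
    centroids_um: np.ndarray,
    bone_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Shortest 3-D Euclidean distance from each centroid to the bone surface.

    Distances are measured to bone voxel centres in micrometres (anisotropic
    voxels supported); equivalent to a brute-force scan over all bone voxels.
    """
    if not bone_mask.any():
        raise ValueError("bone mask is empty")
    pts = np.atleast_2d(np.asarray(centroids_um, dtype=float))
    bone_um = np.argwhere(bone_mask) * np.asarray(voxel_size, dtype=float)
    dist, _ = cKDTree(bone_um).query(pts)
    return dist
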