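"""Synthetic raw-data generators for the downstream pipeline.

Produces, with known ground truth, the four raw data modalities the analysis
consumes:

* FASTQ reads carrying 30-nt semi-random barcodes (alternating weak A/T and
  strong C/G positions, ClonTracer-style) between fixed flanking sequences;
* flow-cytometry event tables with mVenus / TdTomato / iRFP channels, where
  mVenus reports mTORC1 activity inversely (high activity -> probe degraded
  -> dim mVenus) with a configurable 3-4x dynamic range;
* FRET event tables (Amcyan donor + FRET channels) in which apoptotic cells
  carry a cleaved probe and hence a reduced FRET/Amcyan ratio;
* 3-D two-channel image stacks with a bone-surface channel, Gaussian-blob
  cells, and an exact ground-truth table of centroids, intensity ratios and
  distances to bone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "IntensityModel",
    "ReadSpec",
    "GroundTruthImage",
    "barcode_sequences",
    "reads_from_counts",
    "write_fastq",
    "cytometry_from_population",
    "fret_events",
    "image_stack",
    "save_stack",
    "load_stack",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_WEAK = np.frombuffer(b"AT", dtype="S1")
_STRONG = np.frombuffer(b"CG", dtype="S1")


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadSpec:
    """Read architecture for the barcode amplicon library.

    The read is ``flank_5prime + barcode + flank_3prime`` with the barcode at
    a fixed offset.  ``ws_pattern`` marks each barcode position as weak (W:
    A/T) or strong (S: C/G); the default alternates WS over 30 nt.  Base
    qualities follow a flat Q30 model with dips at error-injected positions.
    """

    flank_5prime: str = "TGACCATGTACGATTGACTA"
    flank_3prime: str = "CAGTACTGGATCCAGTTGCA"
    barcode_length: int = 30
    ws_pattern: str = "WS" * 15
    per_base_error_rate: float = 0.001
    base_quality: int = 30
    error_quality: int = 15

    def __post_init__(self) -> None:
        if self.barcode_length % 2 != 0:
            raise ValueError("barcode_length must be even")
        if len(self.ws_pattern) != self.barcode_length:
            raise ValueError("ws_pattern must cover all barcode positions")
        if set(self.ws_pattern) - {"W", "S"}:
            raise ValueError("ws_pattern may contain only W and S")
        if not 0.0 <= self.per_base_error_rate < 1.0:
            raise ValueError("per_base_error_rate must be in [0, 1)")

    @property
    def read_length(self) -> int:
        return len(self.flank_5prime) + self.barcode_length + len(self.flank_3prime)

    @property
    def barcode_start(self) -> int:
        return len(self.flank_5prime)


@dataclass(frozen=True)
class IntensityModel:
    """Log-normal channel intensity model for the reporter populations.

    mVenus geometric means differ between states by ``dynamic_range``
    (fully-inhibited / fully-active, default 3.5, the midpoint of the
    reported 3-4x range).  The rapamycin-treated reference sample is broader
    (``reference_sigma``) than in-vivo populations (``channel_sigma``),
    reflecting independent culture treatment.  ``bimodal_weight`` is the
    default mTORC1-high mixture weight for early-disease bimodal profiles.
    """

    mvenus_gm_high: float = 100.0       # geometric mean, mTORC1-high (active) state
    dynamic_range: float = 3.5
    channel_sigma: float = 0.25          # log-scale SD of in-vivo populations
    reference_sigma: float = 0.5         # log-scale SD of the rapamycin reference
    tdtomato_gm: float = 500.0
    irfp_gm: float = 200.0
    amcyan_gm: float = 150.0
    fret_ratio_intact: float = 2.0       # FRET/Amcyan geometric mean, intact probe
    fret_ratio_cleaved: float = 0.4      # after caspase cleavage (apoptotic)
    bimodal_weight: float = 0.5

    def __post_init__(self) -> None:
        for name in ("mvenus_gm_high", "channel_sigma", "reference_sigma",
                     "tdtomato_gm", "irfp_gm", "amcyan_gm",
                     "fret_ratio_intact", "fret_ratio_cleaved"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dynamic_range <= 1:
            raise ValueError("dynamic_range must be > 1")
        if not 0.0 <= self.bimodal_weight <= 1.0:
            raise ValueError("bimodal_weight must be in [0, 1]")

    @property
    def mvenus_gm_low(self) -> float:
        """Geometric mean of the mTORC1-low (probe-stable, bright) state."""
        return self.mvenus_gm_high * self.dynamic_range


@dataclass
class GroundTruthImage:
    """Exact generating record for a synthetic image stack."""

    shape: tuple[int, int, int]              # (nz, ny, nx) voxels
    voxel_size: tuple[float, float, float]   # (dz, dy, dx) in um
    bone_mask: np.ndarray                    # boolean (nz, ny, nx)
    cells: pd.DataFrame                      # z/y/x um, state, mVenus, TdTomato,
                                             # ratio, distance_um

    def to_json(self) -> str:
        return json.dumps({
            "shape": list(self.shape),
            "voxel_size": list(self.voxel_size),
            "cells": self.cells.to_dict(orient="list"),
        })


# ---------------------------------------------------------------------------
# Barcode reads
# ---------------------------------------------------------------------------


def barcode_sequences(clone_ids: np.ndarray, spec: ReadSpec, seed: int) -> dict[int, str]:
    """Deterministic barcode sequence for each clone id.

    Each clone id maps to a WS-patterned 30-mer drawn from a child RNG keyed
    by (seed, clone_id), so any subset of the table regenerates identical
    sequences.
    """
    weak = np.array([p == "W" for p in spec.ws_pattern])
    out: dict[int, str] = {}
    for cid in np.asarray(clone_ids, dtype=np.int64):
        r = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                         spawn_key=(int(cid),)))
        bits = r.integers(0, 2, size=spec.barcode_length)
        seq = np.where(weak, _WEAK[bits], _STRONG[bits])
        out[int(cid)] = seq.tobytes().decode()
    return out


@dataclass
class FastqRead:
    """One sequencing read (4-line FASTQ record equivalent)."""

    id: str
    sequence: str
    qualities: np.ndarray  # Phred scores

    def to_fastq(self) -> str:
        qual = "".join(chr(q + 33) for q in self.qualities)
        return f"@{self.id}\n{self.sequence}\n+\n{qual}\n"


def reads_from_counts(
    counts: pd.Series,
    depth_per_cell: float,
    read_spec: ReadSpec,
    seed: int,
    depth_mode: str = "poisson",
) -> list[FastqRead]:
    """Emit sequencing reads for a barcode count table.

    ``counts`` is indexed by clone id.  Read numbers per barcode are
    ``Poisson(count * depth_per_cell)`` (or exactly ``round(count * depth)``
    in ``depth_mode='exact'``).  Substitution errors are injected per base at
    ``read_spec.per_base_error_rate``; erroneous bases get a quality dip.
    Barcode sequences come from :func:`barcode_sequences` with the same seed,
    so the generating table is recoverable.
    """
    if depth_per_cell <= 0:
        raise ValueError("depth_per_cell must be > 0")
    if depth_mode not in ("poisson", "exact"):
        raise ValueError("depth_mode must be 'poisson' or 'exact'")
    counts = counts[counts > 0]
    if len(counts) == 0:
        return []
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                       spawn_key=(0x5EAD5,)))

    seqs = barcode_sequences(counts.index.to_numpy(), read_spec, seed)
    if depth_mode == "exact":
        n_reads = np.rint(counts.to_numpy() * depth_per_cell).astype(np.int64)
    else:
        n_reads = rng.poisson(counts.to_numpy() * depth_per_cell)

    total = int(n_reads.sum())
    if total == 0:
        return []

    # full-read template per barcode, then row-repeat by read count
    templates = np.array(
        [read_spec.flank_5prime + seqs[int(cid)] + read_spec.flank_3prime
         for cid in counts.index],
        dtype=f"S{read_spec.read_length}",
    ).view("S1").reshape(len(counts), read_spec.read_length)
    reads = np.repeat(templates, n_reads, axis=0)

    quals = np.full(reads.shape, read_spec.base_quality, dtype=np.int16)
    p = read_spec.per_base_error_rate
    if p > 0:
        err = rng.random(reads.shape) < p
        if err.any():
            idx = _BASES.searchsorted(reads[err])
            shift = rng.integers(1, 4, size=int(err.sum()))
            reads[err] = _BASES[(idx + shift) % 4]
            quals[err] = read_spec.error_quality

    out = []
    for i in range(total):
        out.append(FastqRead(f"read_{i:08d}", reads[i].tobytes().decode(), quals[i]))
    return out


def write_fastq(reads: list[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(r.to_fastq())


# ---------------------------------------------------------------------------
# Flow cytometry
# ---------------------------------------------------------------------------


def _lognormal(rng, gm: float, sigma: float, n: int) -> np.ndarray:
    return rng.lognormal(np.log(gm), sigma, size=n)


def cytometry_from_population(
    n_events: int,
    high_fraction: float | None,
    model: IntensityModel,
    seed: int,
    reference: bool = False,
) -> pd.DataFrame:
    """Draw a flow-cytometry event table from the two-state mixture.

    mVenus is inversely tied to mTORC1 state: high-activity (H) events are
    dim, low-activity (L) events bright, with geometric-mean ratio equal to
    ``model.dynamic_range``.  ``high_fraction=None`` uses the model's
    ``bimodal_weight`` (early-disease bimodal profile).  With
    ``reference=True`` a pure mTORC1-low, rapamycin-style reference sample is
    drawn with the broader ``reference_sigma``.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if high_fraction is None:
        high_fraction = model.bimodal_weight
    if not 0.0 <= high_fraction <= 1.0:
        raise ValueError("high_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    if reference:
        mv = _lognormal(rng, model.mvenus_gm_low, model.reference_sigma, n_events)
        state = np.full(n_events, "L")
    else:
        state = np.where(rng.random(n_events) < high_fraction, "H", "L")
        gm = np.where(state == "H", model.mvenus_gm_high, model.mvenus_gm_low)
        mv = np.exp(rng.normal(np.log(gm), model.channel_sigma))

    df = pd.DataFrame({
        "mVenus": mv,
        "TdTomato": _lognormal(rng, model.tdtomato_gm, model.channel_sigma, n_events),
        "iRFP": _lognormal(rng, model.irfp_gm, model.channel_sigma, n_events),
        "state_truth": state,
    })
    return df


def fret_events(
    n_events: int,
    apoptotic_fraction: float,
    model: IntensityModel,
    seed: int,
) -> pd.DataFrame:
    """Draw FRET-probe events; apoptotic cells have a cleaved (low) ratio.

    Returns columns Amcyan, FRET and the ground-truth label ``apoptotic``.
    The per-event FRET/Amcyan ratio has geometric mean
    ``fret_ratio_intact`` for live cells and ``fret_ratio_cleaved`` for
    apoptotic cells.
    """
    if not 0.0 <= apoptotic_fraction <= 1.0:
        raise ValueError("apoptotic_fraction must be in [0, 1]")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    rng = np.random.default_rng(seed)

    apo = rng.random(n_events) < apoptotic_fraction
    amcyan = _lognormal(rng, model.amcyan_gm, model.channel_sigma, n_events)
    ratio_gm = np.where(apo, model.fret_ratio_cleaved, model.fret_ratio_intact)
    ratio = np.exp(rng.normal(np.log(ratio_gm), model.channel_sigma))
    return pd.DataFrame({"Amcyan": amcyan, "FRET": amcyan * ratio, "apoptotic": apo})


# ---------------------------------------------------------------------------
# 3-D image stacks
# ---------------------------------------------------------------------------


def image_stack(
    n_cells: int,
    grid: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = (2.0, 1.0, 1.0),
    bone_geometry: str = "plane",
    state_mix: float = 0.5,
    model: IntensityModel | None = None,
    seed: int = 0,
    blob_sigma: float = 1.0,
    min_separation: float = 6.0,
) -> tuple[np.ndarray, GroundTruthImage]:
    """Render a synthetic two-photon stack with bone and reporter channels.

    The returned array has shape ``(3, nz, ny, nx)`` with channels
    (TdTomato, mVenus, bone).  Bone is a plane at z=0 (``'plane'``) or a
    curved sheet (``'curved'``).  Cells are isotropic Gaussian blobs (sigma
    ``blob_sigma`` voxels) at random non-overlapping positions; each cell is
    mTORC1-high with probability ``state_mix``.  Per-cell intensities are
    drawn so the truth-table mVenus/TdTomato ratio respects the 0.4
    classification rule (H < 0.4 <= L).  Ground-truth distances are exact
    Euclidean distances from each centroid to the nearest bone voxel centre.
    """
    model = model or IntensityModel()
    nz, ny, nx = grid
    if min(grid) <= 0:
        raise ValueError("grid dimensions must be positive")
    rng = np.random.default_rng(seed)
    dz, dy, dx = voxel_size

    bone = np.zeros(grid, dtype=bool)
    if bone_geometry == "plane":
        bone[0, :, :] = True
    elif bone_geometry == "curved":
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        zsurf = (1.5 + 1.4 * np.sin(2 * np.pi * xx / nx) *
                 np.cos(2 * np.pi * yy / ny)).astype(int)
        zsurf = np.clip(zsurf, 0, nz - 1)
        bone[zsurf, yy, xx] = True
    else:
        raise ValueError("bone_geometry must be 'plane' or 'curved'")

    # place cells with rejection sampling, min pairwise separation in um
    margin = 3.0 * blob_sigma
    lo = np.array([margin * dz + 2 * dz, margin * dy, margin * dx])
    hi = np.array([(nz - 1 - margin) * dz, (ny - 1 - margin) * dy,
                   (nx - 1 - margin) * dx])
    if np.any(hi <= lo):
        raise ValueError("grid too small for any cell")
    centroids: list[np.ndarray] = []
    attempts = 0
    while len(centroids) < n_cells:
        attempts += 1
        if attempts > 200 * max(n_cells, 1):
            raise ValueError("packing error: too many cells for grid")
        cand = lo + rng.random(3) * (hi - lo)
        if all(np.linalg.norm(cand - c) >= min_separation for c in centroids):
            centroids.append(cand)
    cent = np.array(centroids).reshape(n_cells, 3)  # (z, y, x) in um

    states = np.where(rng.random(n_cells) < state_mix, "H", "L")
    tdt = _lognormal(rng, model.tdtomato_gm, model.channel_sigma, n_cells)
    mv = np.empty(n_cells)
    for i, st in enumerate(states):
        gm = model.mvenus_gm_high if st == "H" else model.mvenus_gm_low
        while True:  # enforce truth-table consistency with the 0.4 rule
            v = float(rng.lognormal(np.log(gm), model.channel_sigma))
            r = v / tdt[i]
            if (st == "H" and r < 0.4) or (st == "L" and r >= 0.4):
                mv[i] = v
                break

    img = np.zeros((3, nz, ny, nx), dtype=np.float32)
    img[2][bone] = 1000.0
    zi = np.arange(nz)[:, None, None]
    yi = np.arange(ny)[None, :, None]
    xi = np.arange(nx)[None, None, :]
    for i in range(n_cells):
        cz, cy, cx = cent[i] / np.array([dz, dy, dx])  # voxel coordinates
        w = 4  # local rendering window in voxels, +-4 sigma at sigma=1
        z0, z1 = max(0, int(cz) - w), min(nz, int(cz) + w + 1)
        y0, y1 = max(0, int(cy) - w), min(ny, int(cy) + w + 1)
        x0, x1 = max(0, int(cx) - w), min(nx, int(cx) + w + 1)
        g = np.exp(-(((zi[z0:z1] - cz) ** 2) + ((yi[:, y0:y1] - cy) ** 2)
                     + ((xi[:, :, x0:x1] - cx) ** 2)) / (2 * blob_sigma ** 2))
        img[0, z0:z1, y0:y1, x0:x1] += (tdt[i] * g).astype(np.float32)
        img[1, z0:z1, y0:y1, x0:x1] += (mv[i] * g).astype(np.float32)

    bone_um = np.argwhere(bone) * np.array([dz, dy, dx])
    dist, _ = cKDTree(bone_um).query(cent) if n_cells else (np.empty(0), None)

    cells = pd.DataFrame({
        "z_um": cent[:, 0], "y_um": cent[:, 1], "x_um": cent[:, 2],
        "state": states, "mVenus": mv, "TdTomato": tdt,
        "ratio": mv / tdt, "distance_um": dist,
    })
    truth = GroundTruthImage(grid, voxel_size, bone, cells)
    return img, truth


def save_stack(path, image: np.ndarray,
               voxel_size: tuple[float, float, float],
               channel_names: tuple[str, ...] = ("TdTomato", "mVenus", "bone")) -> None:
    """Write a stack as multi-page TIFF (.tif) or NPZ, with a JSON sidecar.

    The sidecar (``<path>.json``) carries voxel size (um) and channel names.
    """
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile
        tifffile.imwrite(path, image.astype(np.float32))
    elif path.endswith(".npz"):
        np.savez_compressed(path, image=image)
    else:
        raise ValueError("stack path must end in .tif/.tiff/.npz")
    meta = {"voxel_size_um": list(voxel_size), "channel_names": list(channel_names)}
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh)


def load_stack(path) -> tuple[np.ndarray, tuple[float, float, float], tuple[str, ...]]:
    """Read a stack written by :func:`save_stack`; returns (image, voxel, channels)."""
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile
        image = tifffile.imread(path)
    elif path.endswith(".npz"):
        image = np.load(path)["image"]
    else:
        raise ValueError("stack path must end in .tif/.tiff/.npz")
    with open(path + ".json") as fh:
        meta = json.load(fh)
    return image, tuple(meta["voxel_size_um"]), tuple(meta["channel_names"])
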