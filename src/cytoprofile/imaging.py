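"""Segmentation and per-cell feature extraction from multi-channel scenes.

The imaging front end mirrors a standard bacterial cytological profiling
workflow: cells are found on the membrane-stain channel, optionally
expanded under the guidance of a phase image, nucleoids are detected on
the DNA channel and associated to cells, cells without a nucleoid are
discarded, and a configurable registry of cytological parameters (39 by
default: 12 shape + 9 intensity statistics x 3 fluorescence channels) is
measured per cell. Intensity statistics are only taken from channels that
are not flagged as deconvolved, since deconvolution redistributes photon
counts and invalidates intensity comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage import filters, measure, segmentation

from .feature_table import METADATA_COLUMNS

__all__ = [
    "ImageScene",
    "CellObject",
    "NucleoidObject",
    "segment_cells",
    "detect_nucleoids",
    "filter_cells_by_nucleoid",
    "extract_features",
    "default_parameter_registry",
    "SHAPE_PARAMETERS",
    "INTENSITY_STATS",
    "FLUOR_CHANNELS",
]

FLUOR_CHANNELS = ("membrane", "dna", "permeability")

SHAPE_PARAMETERS = [
    "area",
    "perimeter",
    "major_axis",
    "minor_axis",
    "eccentricity",
    "solidity",
    "extent",
    "orientation",
    "form_factor",
    "compactness",
    "feret_max",
    "feret_min",
]

INTENSITY_STATS = [
    "mean",
    "median",
    "sd",
    "min",
    "max",
    "integrated",
    "mass_displacement",
    "q25",
    "q75",
]


def default_parameter_registry() -> list[str]:
    """The default per-cell parameter set: 12 shape parameters plus 9
    intensity statistics on each of the three fluorescence channels
    (membrane, dna, permeability), 39 parameters in total.

    This registry is a documented reconstruction of a typical
    CellProfiler-style measurement set; the parameter count, not the
    exact identity of each measure, is the stable contract.
    """
    names = list(SHAPE_PARAMETERS)
    for ch in FLUOR_CHANNELS:
        names.extend(f"{ch}_{stat}" for stat in INTENSITY_STATS)
    return names


@dataclass
class ImageScene:
    """A single-focal-plane multi-channel field of view.

    channels maps channel name -> 2-D nonnegative float array; all
    channels share one shape. ``deconvolved_flags`` records which
    channels carry deconvolved data (intensity statistics refuse them).
    ``ground_truth`` holds the generating cell list for synthetic scenes.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0
    deconvolved_flags: dict[str, bool] = field(default_factory=dict)
    ground_truth: list | None = None
    has_overlaps: bool = False

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("scene needs at least one channel")
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for ch, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)) or (arr < 0).any():
                raise ValueError(f"channel {ch!r} has negative or non-finite pixels")
            self.channels[ch] = arr
            self.deconvolved_flags.setdefault(ch, False)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class CellObject:
    """A segmented cell: a full-frame boolean mask plus basic geometry."""

    label: int
    mask: np.ndarray
    centroid: tuple[float, float]
    area: int
    major_axis: float
    minor_axis: float
    eccentricity: float
    perimeter: float
    nucleoid_labels: list[int] = field(default_factory=list)


@dataclass
class NucleoidObject:
    label: int
    mask: np.ndarray
    centroid: tuple[float, float]
    parent_cell: int | None = None


def _threshold(image: np.ndarray, method: str) -> float:
    if method == "otsu":
        return filters.threshold_otsu(image)
    if method == "mean":
        return float(image.mean())
    raise ValueError(f"unknown threshold method {method!r}")


def _label_above_threshold(image: np.ndarray, method: str) -> np.ndarray:
    """8-connected labelling of the above-threshold foreground.

    A constant image has no separable foreground and yields no objects.
    """
    if np.ptp(image) == 0:
        return np.zeros(image.shape, dtype=int)
    mask = image > _threshold(image, method)
    return measure.label(mask, connectivity=2)


def segment_cells(
    scene: ImageScene,
    threshold_method: str = "otsu",
    expansion_px: int = 0,
) -> list[CellObject]:
    """Identify cell objects on the membrane channel.

    Connected components above an automatic threshold are optionally
    expanded by up to ``expansion_px`` pixels. When a phase channel is
    present the expansion is guided by it: a candidate pixel joins the
    cell only while its phase intensity stays within the cell interior's
    own range (mean +/- 3 SD). Objects touching the image border are
    discarded, since truncated cells corrupt shape statistics.
    """
    if "membrane" not in scene.channels:
        raise ValueError("scene has no 'membrane' channel; cannot segment")
    membrane = scene.channels["membrane"]
    labels = _label_above_threshold(membrane, threshold_method)

    if expansion_px > 0 and labels.max() > 0:
        expanded = segmentation.expand_labels(labels, distance=expansion_px)
        if "phase" in scene.channels:
            phase = scene.channels["phase"]
            keep = labels > 0
            for lab in range(1, labels.max() + 1):
                interior = phase[labels == lab]
                mu, sd = interior.mean(), interior.std()
                band = 3.0 * sd + 1e-9
                new_px = (expanded == lab) & ~keep
                ok = new_px & (np.abs(phase - mu) <= band)
                keep |= ok
            expanded = np.where(keep, expanded, 0)
        labels = expanded

    labels = segmentation.clear_border(labels)

    cells: list[CellObject] = []
    for rp in measure.regionprops(labels):
        mask = labels == rp.label
        cells.append(
            CellObject(
                label=int(rp.label),
                mask=mask,
                centroid=tuple(rp.centroid),
                area=int(rp.area),
                major_axis=float(rp.axis_major_length),
                minor_axis=float(rp.axis_minor_length),
                eccentricity=float(rp.eccentricity),
                perimeter=float(rp.perimeter),
            )
        )
    return cells


def detect_nucleoids(
    scene: ImageScene, cells: list[CellObject], threshold_method: str = "otsu"
) -> list[NucleoidObject]:
    """Find nucleoids on the DNA channel and assign each to the cell whose
    mask contains its centroid (no containing cell -> orphan nucleoid)."""
    if "dna" not in scene.channels:
        raise ValueError("scene has no 'dna' channel; cannot detect nucleoids")
    labels = _label_above_threshold(scene.channels["dna"], threshold_method)
    nucleoids: list[NucleoidObject] = []
    for rp in measure.regionprops(labels):
        r, c = (int(round(x)) for x in rp.centroid)
        parent = None
        for cell in cells:
            if cell.mask[r, c]:
                parent = cell.label
                break
        nucleoids.append(
            NucleoidObject(
                label=int(rp.label),
                mask=labels == rp.label,
                centroid=tuple(rp.centroid),
                parent_cell=parent,
            )
        )
    return nucleoids


def filter_cells_by_nucleoid(
    cells: list[CellObject], nucleoids: list[NucleoidObject]
) -> list[CellObject]:
    """Keep only cells with at least one associated nucleoid (the
    DNA-stain presence gate); links are recorded on the retained cells."""
    by_parent: dict[int, list[int]] = {}
    for nuc in nucleoids:
        if nuc.parent_cell is not None:
            by_parent.setdefault(nuc.parent_cell, []).append(nuc.label)
    kept = []
    for cell in cells:
        links = by_parent.get(cell.label, [])
        if links:
            cell.nucleoid_labels = sorted(links)
            kept.append(cell)
    return kept


def _min_feret(mask: np.ndarray) -> float:
    """Minimal caliper width of the mask's pixel-center convex hull.

    Rotating-calipers over hull edges: the minimal width is attained
    perpendicular to some edge. Degenerate (collinear) masks fall back
    to one pixel.
    """
    pts = np.argwhere(mask).astype(float)
    if len(pts) < 3:
        return 1.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 1.0
    verts = pts[hull.vertices]
    widths = []
    n = len(verts)
    for i in range(n):
        p, q = verts[i], verts[(i + 1) % n]
        edge = q - p
        norm = np.hypot(*edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        widths.append(np.abs((verts - p) @ normal).max())
    return float(min(widths)) if widths else 1.0


def _max_feret(rp) -> float:
    return float(rp.feret_diameter_max)


def _shape_features(cell: CellObject) -> dict[str, float]:
    rp = measure.regionprops(cell.mask.astype(int))[0]
    area = float(rp.area)
    perim = float(rp.perimeter)
    with np.errstate(divide="ignore", invalid="ignore"):
        form_factor = 4.0 * np.pi * area / perim**2 if perim > 0 else np.nan
        compactness = perim**2 / (4.0 * np.pi * area)
    return {
        "area": area,
        "perimeter": perim,
        "major_axis": float(rp.axis_major_length),
        "minor_axis": float(rp.axis_minor_length),
        "eccentricity": float(rp.eccentricity),
        "solidity": float(rp.solidity),
        "extent": float(rp.extent),
        "orientation": float(rp.orientation),
        "form_factor": form_factor,
        "compactness": compactness,
        "feret_max": _max_feret(rp),
        "feret_min": _min_feret(cell.mask),
    }


def _intensity_features(cell: CellObject, image: np.ndarray) -> dict[str, float]:
    vals = image[cell.mask]
    total = float(vals.sum())
    # mass displacement: distance between the intensity-weighted centroid
    # and the binary centroid, in pixels
    if total > 0:
        rr, cc = np.nonzero(cell.mask)
        wr = float((rr * vals).sum() / total)
        wc = float((cc * vals).sum() / total)
        br, bc = rr.mean(), cc.mean()
        displacement = float(np.hypot(wr - br, wc - bc))
    else:
        displacement = 0.0
    return {
        "mean": float(vals.mean()),
        "median": float(np.median(vals)),
        "sd": float(vals.std(ddof=0)),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "integrated": total,
        "mass_displacement": displacement,
        "q25": float(np.percentile(vals, 25)),
        "q75": float(np.percentile(vals, 75)),
    }


def extract_features(
    scene: ImageScene,
    cells: list[CellObject],
    parameter_set: list[str] | None = None,
    treatment: str = "untreated",
    replicate: int | str = 1,
) -> pd.DataFrame:
    """Measure the configured parameters for each (already filtered) cell.

    Returns a feature table with one row per cell: metadata columns
    (cell_id, treatment, replicate) followed by one column per parameter.
    Intensity parameters are named ``<channel>_<stat>`` and are computed
    only on channels not flagged as deconvolved; requesting one for an
    absent channel raises with the channel named.
    """
    if parameter_set is None:
        parameter_set = default_parameter_registry()

    needed_channels = set()
    for name in parameter_set:
        if name in SHAPE_PARAMETERS:
            continue
        ch, _, stat = name.partition("_")
        if stat not in INTENSITY_STATS:
            raise ValueError(f"unknown parameter {name!r}")
        if ch not in scene.channels:
            raise ValueError(
                f"parameter {name!r} needs channel {ch!r}, absent from scene"
            )
        if scene.deconvolved_flags.get(ch, False):
            raise ValueError(
                f"channel {ch!r} is flagged deconvolved; intensity statistics "
                "must come from non-deconvolved data"
            )
        needed_channels.add(ch)

    rows = []
    for cell in cells:
        shape_vals = _shape_features(cell)
        chan_vals = {
            ch: _intensity_features(cell, scene.channels[ch])
            for ch in needed_channels
        }
        row: dict[str, object] = {
            "cell_id": f"{treatment}_r{replicate}_c{cell.label}",
            "treatment": treatment,
            "replicate": replicate,
        }
        for name in parameter_set:
            if name in SHAPE_PARAMETERS:
                row[name] = shape_vals[name]
            else:
                ch, _, stat = name.partition("_")
                row[name] = chan_vals[ch][stat]
        rows.append(row)

    if not rows:
        warnings.warn("no cells to measure; returning empty feature table")
    return pd.DataFrame(rows, columns=METADATA_COLUMNS + list(parameter_set))
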