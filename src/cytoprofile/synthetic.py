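"""Seeded generators for every input the profiling pipeline consumes.

Four generators cover the pipeline end to end:

* per-cell feature tables with treatment structure — each treatment's
  cells drawn from a multivariate normal with its own mean vector and
  covariance, with entry-wise missingness and single-parameter gross
  outliers layered on top;
* single-plane multi-channel images of rod cells rendered as capsules
  (spherocylinders) with per-channel uniform intensity, retaining the
  generating geometry as ground truth;
* microdilution plates with a step OD profile at a known true MIC;
* 4PL dose-response curves with known IC50/Hill/top/bottom.

The Gaussian mean-shift model of treatment effects is a statistical
stand-in for real cytological profiles, not a claim about their true
distribution; it provides known structure for validating the analysis.
All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import DoseResponse, PlateAssay, four_pl
from .feature_table import METADATA_COLUMNS
from .imaging import ImageScene

__all__ = [
    "TreatmentSpec",
    "CellTruth",
    "gen_feature_table",
    "gen_image_scene",
    "gen_plate",
    "gen_dose_response",
    "rasterize_capsule",
    "default_parameter_names",
    "moa_panel_specs",
]


def default_parameter_names(n: int = 39) -> list[str]:
    """Generic parameter labels p01..pNN for feature-table simulations."""
    return [f"p{i + 1:02d}" for i in range(n)]


@dataclass
class TreatmentSpec:
    """Generating distribution for one treatment's cell population.

    Cells are multivariate normal around ``mean_vector`` with
    ``covariance``; a ``missing_rate`` fraction of entries is blanked
    completely at random, and an ``outlier_rate`` fraction of cells is
    displaced by ``outlier_scale`` within-treatment SDs in one randomly
    chosen parameter (gross, single-parameter contamination — the kind a
    k-SD univariate filter is designed to catch).
    """

    name: str
    n_cells: int
    mean_vector: np.ndarray
    covariance: np.ndarray
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    outlier_scale: float = 10.0

    def __post_init__(self) -> None:
        self.mean_vector = np.asarray(self.mean_vector, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        p = len(self.mean_vector)
        if self.covariance.shape != (p, p):
            raise ValueError(
                f"covariance shape {self.covariance.shape} does not match "
                f"mean vector length {p}"
            )
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        min_eig = np.linalg.eigvalsh(self.covariance).min()
        if min_eig < -1e-8 * max(1.0, np.abs(self.covariance).max()):
            raise ValueError("covariance must be positive semi-definite")
        for rate in (self.missing_rate, self.outlier_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.outlier_scale <= 0:
            raise ValueError("outlier_scale must be positive")

    @property
    def n_parameters(self) -> int:
        return len(self.mean_vector)


def gen_feature_table(
    specs: list[TreatmentSpec],
    parameter_names: list[str],
    n_replicates: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a per-cell feature table from the treatment specs.

    Replicate labels 1..n_replicates are assigned round-robin within each
    treatment (labels only — cells are exchangeable across replicates,
    matching an analysis that pools cells). Outlier displacement is
    applied before missingness.
    """
    p = len(parameter_names)
    for spec in specs:
        if spec.n_parameters != p:
            raise ValueError(
                f"treatment {spec.name!r} has {spec.n_parameters} parameters, "
                f"expected {p}"
            )
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    for spec in specs:
        values = rng.multivariate_normal(
            spec.mean_vector, spec.covariance, size=spec.n_cells, method="cholesky"
        )
        sds = np.sqrt(np.diag(spec.covariance))
        contaminated = rng.random(spec.n_cells) < spec.outlier_rate
        for i in np.nonzero(contaminated)[0]:
            j = rng.integers(p)
            values[i, j] += spec.outlier_scale * sds[j]
        missing = rng.random(values.shape) < spec.missing_rate
        values[missing] = np.nan
        df = pd.DataFrame(values, columns=parameter_names)
        df.insert(0, "cell_id", [f"{spec.name}_c{i}" for i in range(spec.n_cells)])
        df.insert(1, "treatment", spec.name)
        df.insert(2, "replicate", [(i % n_replicates) + 1 for i in range(spec.n_cells)])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass
class CellTruth:
    """Ground-truth geometry and intensity of one synthetic rod cell.

    A capsule of ``length_px`` total length and ``width_px`` diameter,
    centred at ``center`` (row, col; 0-based, origin top-left), rotated
    by ``orientation`` radians (0 = aligned with the column axis).
    """

    center: tuple[float, float]
    length_px: float
    width_px: float
    orientation: float = 0.0
    channel_intensities: dict[str, float] = field(default_factory=dict)
    has_nucleoid: bool = True

    def __post_init__(self) -> None:
        if not (self.length_px >= self.width_px > 0):
            raise ValueError("need length_px >= width_px > 0")
        for ch, v in self.channel_intensities.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"intensity for channel {ch!r} must be finite, >= 0")


def rasterize_capsule(
    shape: tuple[int, int],
    center: tuple[float, float],
    length_px: float,
    width_px: float,
    orientation: float = 0.0,
) -> np.ndarray:
    """Boolean footprint of a capsule on the pixel grid.

    A pixel belongs to the capsule when its centre lies within
    width/2 of the central segment of length (length - width).
    """
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    half = max(length_px - width_px, 0.0) / 2.0
    d = np.array([np.sin(orientation), np.cos(orientation)])
    p0 = np.asarray(center) - half * d
    p1 = np.asarray(center) + half * d
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    vr, vc = rr - p0[0], cc - p0[1]
    if seg_len2 > 0:
        t = np.clip((vr * seg[0] + vc * seg[1]) / seg_len2, 0.0, 1.0)
    else:
        t = 0.0
    dr = vr - t * seg[0]
    dc = vc - t * seg[1]
    return dr**2 + dc**2 <= (width_px / 2.0) ** 2


#: nucleoid footprint relative to the cell capsule (fractional scale)
NUCLEOID_SCALE = 0.6


def gen_image_scene(
    cells: list[CellTruth],
    image_shape: tuple[int, int] = (256, 256),
    background: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pixel_size: float = 1.0,
) -> ImageScene:
    """Render rod cells into a membrane/dna/permeability channel stack.

    Each cell adds uniform intensity over its capsule footprint on every
    channel it names in ``channel_intensities``; the DNA channel is drawn
    only for cells with a nucleoid, on an inner capsule (60% scale) so a
    nucleoid sits strictly inside its cell. Gaussian read noise is added
    per pixel and clipped at zero. Cells whose bounding circle leaves the
    frame are rejected; overlapping cells are allowed but flagged on the
    scene.
    """
    if background < 0 or noise_sd < 0:
        raise ValueError("background and noise_sd must be nonnegative")
    channel_names = set(FLUOR := ("membrane", "dna", "permeability"))
    for cell in cells:
        channel_names |= set(cell.channel_intensities)
    channels = {ch: np.full(image_shape, float(background)) for ch in channel_names}
    coverage = np.zeros(image_shape, dtype=int)

    for i, cell in enumerate(cells):
        r, c = cell.center
        half = cell.length_px / 2.0
        if (
            r - half < -0.5
            or c - half < -0.5
            or r + half > image_shape[0] - 0.5
            or c + half > image_shape[1] - 0.5
        ):
            raise ValueError(f"cell {i} extends beyond the image frame")
        footprint = rasterize_capsule(
            image_shape, cell.center, cell.length_px, cell.width_px, cell.orientation
        )
        coverage += footprint
        for ch, intensity in cell.channel_intensities.items():
            if ch == "dna":
                continue  # handled below, gated on has_nucleoid
            channels[ch][footprint] += intensity
        if cell.has_nucleoid and "dna" in cell.channel_intensities:
            nucleoid = rasterize_capsule(
                image_shape,
                cell.center,
                cell.length_px * NUCLEOID_SCALE,
                cell.width_px * NUCLEOID_SCALE,
                cell.orientation,
            )
            channels["dna"][nucleoid] += cell.channel_intensities["dna"]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for ch in sorted(channels):
            channels[ch] = np.clip(
                channels[ch] + rng.normal(0.0, noise_sd, image_shape), 0.0, None
            )
    return ImageScene(
        channels=channels,
        pixel_size=pixel_size,
        deconvolved_flags={ch: False for ch in channels},
        ground_truth=list(cells),
        has_overlaps=bool((coverage > 1).any()),
    )


def gen_plate(
    concentrations: np.ndarray,
    mic_true: float,
    od_growth: float = 0.6,
    od_blank: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PlateAssay:
    """Step-profile microdilution plate: wells at or above the true MIC
    read blank OD, wells below read growth OD, plus Gaussian read noise."""
    conc = np.asarray(concentrations, dtype=float)
    if od_growth <= 0 or od_blank < 0 or noise_sd < 0:
        raise ValueError("od_growth > 0, od_blank >= 0, noise_sd >= 0 required")
    od = np.where(conc >= mic_true, od_blank, od_growth).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = np.clip(od + rng.normal(0.0, noise_sd, od.shape), 0.0, None)
    return PlateAssay(concentrations=conc, od=od, od_blank=od_blank)


def gen_dose_response(
    ic50_true: float,
    hill: float,
    concentrations: np.ndarray,
    top: float = 100.0,
    bottom: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseResponse:
    """Viability from the 4PL curve plus Gaussian noise (percent units)."""
    conc = np.asarray(concentrations, dtype=float)
    v = four_pl(conc, ic50_true, hill, top, bottom)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, v.shape)
    return DoseResponse(concentrations=conc, viability=v)


def moa_panel_specs(
    n_parameters: int = 39,
    n_cells: int = 300,
    shift: float = 2.0,
    n_shifted: int = 5,
    missing_rate: float = 0.005,
    outlier_rate: float = 0.01,
) -> tuple[TreatmentSpec, dict[str, TreatmentSpec]]:
    """A reference panel for mechanism-of-action recovery studies.

    The query and one reference (``ref_same``) share a generating
    distribution (standard normal profile); ``n_shifted`` further
    references are displaced by ``shift`` SD along distinct parameter
    axes, emulating antibiotics of other mechanism classes. Defaults
    reflect a realistic experiment: a few hundred cells per treatment,
    sparse missingness and ~1% gross outliers.
    """
    ident = np.eye(n_parameters)
    zero = np.zeros(n_parameters)

    def spec(name: str, mean: np.ndarray) -> TreatmentSpec:
        return TreatmentSpec(
            name=name,
            n_cells=n_cells,
            mean_vector=mean,
            covariance=ident,
            missing_rate=missing_rate,
            outlier_rate=outlier_rate,
        )

    query = spec("query", zero)
    refs = {"ref_same": spec("ref_same", zero)}
    for k in range(n_shifted):
        mean = zero.copy()
        mean[(2 * k) % n_parameters] = shift
        mean[(2 * k + 1) % n_parameters] = shift
        refs[f"ref_shift{k + 1}"] = spec(f"ref_shift{k + 1}", mean)
    return query, refs
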