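"""Readers/writers for the pipeline's file formats and the pipeline runner.

Feature tables travel as CSV (cell_id, treatment, replicate, then one
numeric column per parameter; exporter-style two-row headers are
flattened with a dot). Image scenes are multi-page TIFFs, one page per
channel, with a JSON sidecar carrying channel names, pixel size,
deconvolution flags and (for synthetic scenes) the generating ground
truth. Every run writes a provenance record sufficient to reproduce it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .concordance import BCPConcordance
from .feature_table import METADATA_COLUMNS, parameter_columns, validate_feature_table
from .imaging import ImageScene
from .qc import apply_qc
from .synthetic import CellTruth

__all__ = [
    "read_feature_csv",
    "write_feature_csv",
    "read_scene",
    "write_scene",
    "read_plate_csv",
    "read_dose_response_csv",
    "RunConfig",
    "run_pipeline",
]

MISSING_TOKENS = ["NA", "NaN", "nan", ""]


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    """Load a per-cell feature table, validating structure.

    Accepts a plain single header row or an exporter-style two-row header
    (object name over measurement name), which is flattened with a dot.
    "NA" and empty cells become missing values and are counted in a
    warning; parameter columns are coerced to numeric.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split(",")
        second = fh.readline().rstrip("\n").split(",")
    two_row = not any(tok in first for tok in METADATA_COLUMNS) and any(
        tok in second for tok in METADATA_COLUMNS
    )
    if two_row:
        df = pd.read_csv(path, header=[0, 1], na_values=MISSING_TOKENS,
                         keep_default_na=True)
        df.columns = [
            str(b).strip() if str(a).startswith("Unnamed") or not str(a).strip()
            else f"{str(a).strip()}.{str(b).strip()}"
            for a, b in df.columns
        ]
        # metadata columns may arrive prefixed (e.g. "Image.treatment")
        rename = {}
        for col in df.columns:
            tail = col.rsplit(".", 1)[-1]
            if tail in METADATA_COLUMNS:
                rename[col] = tail
        df = df.rename(columns=rename)
    else:
        df = pd.read_csv(path, na_values=MISSING_TOKENS, keep_default_na=True)
    validate_feature_table(df)
    params = parameter_columns(df)
    df[params] = df[params].apply(pd.to_numeric, errors="coerce")
    n_missing = int(df[params].isna().sum().sum())
    if n_missing:
        warnings.warn(f"{path.name}: {n_missing} missing parameter entries")
    return df


def write_feature_csv(table: pd.DataFrame, path: str | Path) -> None:
    validate_feature_table(table)
    table.to_csv(path, index=False)


def write_scene(scene: ImageScene, path: str | Path) -> None:
    """Multi-page TIFF (one page per channel, sorted order) + JSON sidecar."""
    path = Path(path)
    names = sorted(scene.channels)
    stack = np.stack([scene.channels[ch] for ch in names]).astype(np.float32)
    tifffile.imwrite(path, stack, metadata={"channel_names": names})
    sidecar = {
        "channel_names": names,
        "pixel_size": scene.pixel_size,
        "deconvolved_flags": scene.deconvolved_flags,
        "has_overlaps": scene.has_overlaps,
        "ground_truth": [
            {**asdict(cell)} for cell in (scene.ground_truth or [])
        ],
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1, default=float)
    )


def read_scene(path: str | Path) -> ImageScene:
    path = Path(path)
    stack = np.asarray(tifffile.imread(path), dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        names = meta["channel_names"]
        truth = [CellTruth(
            center=tuple(c["center"]),
            length_px=c["length_px"],
            width_px=c["width_px"],
            orientation=c.get("orientation", 0.0),
            channel_intensities=c.get("channel_intensities", {}),
            has_nucleoid=c.get("has_nucleoid", True),
        ) for c in meta.get("ground_truth", [])] or None
        return ImageScene(
            channels=dict(zip(names, stack)),
            pixel_size=meta.get("pixel_size", 1.0),
            deconvolved_flags=meta.get("deconvolved_flags", {}),
            ground_truth=truth,
            has_overlaps=meta.get("has_overlaps", False),
        )
    # no sidecar: fall back to positional channel names
    default = ["membrane", "dna", "permeability", "phase"]
    names = default[: len(stack)]
    return ImageScene(channels=dict(zip(names, stack)))


def read_plate_csv(path: str | Path):
    """Plate CSV with columns concentration, od (descending twofold series)."""
    from .assays import PlateAssay

    df = pd.read_csv(path)
    need = {"concentration", "od"}
    if not need <= set(df.columns):
        raise ValueError(f"plate CSV needs columns {sorted(need)}")
    df = df.sort_values("concentration", ascending=False)
    kw = {}
    for col in ("od_blank", "growth_margin"):
        if col in df.columns:
            kw[col] = float(df[col].iloc[0])
    return PlateAssay(df["concentration"].to_numpy(), df["od"].to_numpy(), **kw)


def read_dose_response_csv(path: str | Path):
    """Dose-response CSV: concentration plus viability, or raw readouts
    (treated, vehicle) which are normalised to percent of vehicle."""
    from .assays import DoseResponse, normalize_viability

    df = pd.read_csv(path)
    if "viability" in df.columns:
        return DoseResponse(df["concentration"].to_numpy(), df["viability"].to_numpy())
    if {"treated", "vehicle"} <= set(df.columns):
        return normalize_viability(
            df["treated"].to_numpy(),
            float(df["vehicle"].iloc[0]),
            df["concentration"].to_numpy(),
        )
    raise ValueError("dose-response CSV needs 'viability' or 'treated'+'vehicle'")


@dataclass
class RunConfig:
    """All knobs of an end-to-end concordance run, loadable from YAML."""

    seed: int = 0
    outlier_sd: float = 5.0
    subsample_n: int | None = None
    level: float = 0.95
    ellipse_method: str = "t"
    query_path: str = ""
    reference_paths: dict[str, str] = field(default_factory=dict)
    out_dir: str = "bcp_results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: RunConfig):
    """Feature tables -> QC -> pairwise concordance -> ranked results bundle.

    Writes results.csv (one row per reference pair, ranked), scores.csv,
    a QC report and a provenance record into ``config.out_dir``; returns
    the fitted results object. Deterministic for a fixed config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

    query_raw = stage("read_query", read_feature_csv, config.query_path)
    query, query_report = stage(
        "qc_query", apply_qc, query_raw,
        outlier_sd=config.outlier_sd, subsample_n=config.subsample_n,
        seed=config.seed,
    )
    refs = {}
    reports = {"query": query_report}
    for name, p in config.reference_paths.items():
        raw = stage(f"read_ref[{name}]", read_feature_csv, p)
        refs[name], reports[name] = stage(
            f"qc_ref[{name}]", apply_qc, raw,
            outlier_sd=config.outlier_sd, subsample_n=config.subsample_n,
            seed=config.seed,
        )

    # each pair is re-balanced to its own minimum inside the fit
    model = BCPConcordance(
        query, refs, level=config.level, method=config.ellipse_method,
    )
    results = stage("concordance", model.fit, seed=config.seed)

    results.to_frame().to_csv(out / "results.csv", index=False)
    results.scores_frame().to_csv(out / "scores.csv", index=False)
    (out / "qc_report.txt").write_text(
        "\n\n".join(f"[{k}]\n{r.to_text()}" for k, r in reports.items())
    )
    (out / "provenance.json").write_text(
        json.dumps(
            {
                "cytoprofile_version": __version__,
                "numpy_version": np.__version__,
                "pandas_version": pd.__version__,
                "config": asdict(config),
            },
            indent=1,
        )
    )
    return results
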