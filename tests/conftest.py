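import numpy as np
import pandas as pd
import pytest

from cytoprofile.synthetic import (
    CellTruth,
    TreatmentSpec,
    default_parameter_names,
    gen_feature_table,
    gen_image_scene,
)


@pytest.fixture
def param_names():
    return default_parameter_names(39)


@pytest.fixture
def two_treatment_table(param_names):
    """Two clean treatments, one shifted, 200 cells each."""
    p = len(param_names)
    shift = np.zeros(p)
    shift[0] = 2.0
    specs = [
        TreatmentSpec("ctrl", 200, np.zeros(p), np.eye(p)),
        TreatmentSpec("drug", 200, shift, np.eye(p)),
    ]
    return gen_feature_table(specs, param_names, seed=11)


@pytest.fixture
def three_cell_scene():
    """Three well-separated capsules; the middle one lacks a nucleoid."""
    cells = [
        CellTruth(
            center=(30.0, 40.0),
            length_px=20,
            width_px=8,
            channel_intensities={"membrane": 100.0, "dna": 80.0, "permeability": 10.0},
        ),
        CellTruth(
            center=(60.0, 40.0),
            length_px=18,
            width_px=7,
            channel_intensities={"membrane": 100.0, "dna": 80.0, "permeability": 10.0},
            has_nucleoid=False,
        ),
        CellTruth(
            center=(90.0, 40.0),
            length_px=22,
            width_px=9,
            orientation=np.pi / 2,
            channel_intensities={"membrane": 100.0, "dna": 80.0, "permeability": 10.0},
        ),
    ]
    return gen_image_scene(cells, (128, 80), background=0.0, noise_sd=0.0, seed=0)


def brute_capsule_mask(shape, center, length, width, orientation=0.0):
    """Independent pixel-by-pixel capsule rasterization (test oracle)."""
    mask = np.zeros(shape, dtype=bool)
    half = max(length - width, 0.0) / 2.0
    d = np.array([np.sin(orientation), np.cos(orientation)])
    p0 = np.asarray(center) - half * d
    p1 = np.asarray(center) + half * d
    for r in range(shape[0]):
        for c in range(shape[1]):
            pt = np.array([r, c], dtype=float)
            seg = p1 - p0
            L2 = seg @ seg
            t = float(np.clip((pt - p0) @ seg / L2, 0, 1)) if L2 > 0 else 0.0
            closest = p0 + t * seg
            if np.sum((pt - closest) ** 2) <= (width / 2.0) ** 2:
                mask[r, c] = True
    return mask


@pytest.fixture
def small_feature_table():
    rng = np.random.default_rng(5)
    n = 12
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "treatment": ["A"] * 6 + ["B"] * 6,
            "replicate": [1, 2] * 6,
            "p1": rng.normal(size=n),
            "p2": rng.normal(size=n),
        }
    )
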