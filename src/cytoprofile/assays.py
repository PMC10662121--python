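"""Microbiological and cytotoxicity assay arithmetic.

Covers the three companion calculations of a natural-product MoA study:
colony-count back-calculation (CFU/mL), broth-microdilution MIC calling
on a twofold dilution series, and IC50 estimation by variable-slope
four-parameter logistic (4PL) regression on vehicle-normalised viability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PlateAssay",
    "MICCall",
    "DoseResponse",
    "FourPL",
    "FourPLResults",
    "cfu_per_ml",
    "read_mic",
    "normalize_viability",
    "fit_4pl",
    "twofold_series",
]


def twofold_series(low: float, high: float) -> np.ndarray:
    """Descending twofold dilution series from ``high`` down to ~``low``.

    Values are exact halvings of ``high``; the series stops at the last
    step within 1% of ``low`` or above. twofold_series(0.06, 128) yields
    128 ... 0.0625 (the 0.06 of a printed plate map is the rounded form).
    """
    if not (0 < low <= high):
        raise ValueError("need 0 < low <= high")
    vals = []
    c = float(high)
    while c >= low * 0.99:
        vals.append(c)
        c /= 2.0
    return np.array(vals)


def cfu_per_ml(
    dilution_factor: float, mean_colonies: float, volume_plated_ml: float
) -> float:
    """Viable count: dilution factor x mean colony count / volume plated (mL)."""
    if volume_plated_ml <= 0:
        raise ValueError("volume plated must be positive")
    if dilution_factor <= 0:
        raise ValueError("dilution factor must be positive")
    if mean_colonies < 0:
        raise ValueError("colony count cannot be negative")
    return dilution_factor * mean_colonies / volume_plated_ml


@dataclass
class PlateAssay:
    """One microdilution row: OD readings over a descending twofold series.

    'No visible growth' is quantified as OD <= od_blank + growth_margin;
    the margin (default 0.05 OD) is the numeric proxy for a visual call.
    """

    concentrations: np.ndarray
    od: np.ndarray
    od_blank: float = 0.05
    growth_margin: float = 0.05

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        c = self.concentrations
        if c.ndim != 1 or len(c) < 2:
            raise ValueError("need a 1-D series of at least two concentrations")
        if (c <= 0).any():
            raise ValueError("concentrations must be positive")
        ratios = c[1:] / c[:-1]
        if np.any(np.abs(ratios / 0.5 - 1.0) > 0.01):
            raise ValueError(
                "concentrations must form a descending twofold series "
                "(each within 1% of half the previous)"
            )
        if self.od.shape != c.shape:
            raise ValueError("od must align with concentrations")
        if self.od_blank < 0:
            raise ValueError("od_blank cannot be negative")

    def growth(self) -> np.ndarray:
        """Boolean growth call per well."""
        return self.od > self.od_blank + self.growth_margin


@dataclass(frozen=True)
class MICCall:
    """MIC on the plate's discrete steps, possibly censored at either end."""

    value: float
    censored: str  # "exact" | "above_max" | "at_or_below_min"
    flagged: bool = False  # growth pattern non-monotone

    def __str__(self) -> str:
        if self.censored == "above_max":
            return f"> {self.value:g} µg/mL"
        if self.censored == "at_or_below_min":
            return f"<= {self.value:g} µg/mL"
        return f"{self.value:g} µg/mL"


def read_mic(plate: PlateAssay) -> MICCall:
    """Lowest concentration with no growth and none at any higher step.

    All wells growing -> censored above the top of the series; no well
    growing -> censored at or below the bottom. A growth well above a
    no-growth well is biologically inconsistent (skipped wells); the call
    is then the lowest step above the highest growing well, flagged.
    """
    conc = plate.concentrations  # descending
    growth = plate.growth()
    if not growth.any():
        return MICCall(float(conc[-1]), "at_or_below_min")
    highest_growth = int(np.argmax(growth))  # first True in descending order
    if highest_growth == 0:
        return MICCall(float(conc[0]), "above_max")
    flagged = not growth[highest_growth:].all()
    if flagged:
        warnings.warn(
            "non-monotone growth pattern: no-growth well below a growth well",
            stacklevel=2,
        )
    return MICCall(float(conc[highest_growth - 1]), "exact", flagged=flagged)


@dataclass
class DoseResponse:
    """Viability (% of vehicle control) over a concentration series (µM)."""

    concentrations: np.ndarray
    viability: np.ndarray
    vehicle_readout: float | None = None
    treated_readouts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.concentrations.shape != self.viability.shape:
            raise ValueError("concentrations and viability must align")
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be positive")
        if not np.all(np.isfinite(self.viability)):
            raise ValueError("viability must be finite")


def normalize_viability(
    treated_readouts: np.ndarray,
    vehicle_readout: float,
    concentrations: np.ndarray,
) -> DoseResponse:
    """Percent viability = 100 x treated / paired vehicle control."""
    if vehicle_readout <= 0:
        raise ValueError("vehicle readout must be positive")
    treated = np.asarray(treated_readouts, dtype=float)
    return DoseResponse(
        concentrations=np.asarray(concentrations, dtype=float),
        viability=100.0 * treated / vehicle_readout,
        vehicle_readout=float(vehicle_readout),
        treated_readouts=treated,
    )


def four_pl(conc: np.ndarray, ic50: float, hill: float, top: float, bottom: float):
    """Variable-slope logistic: bottom + (top-bottom)/(1 + (c/ic50)^hill)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


class FourPL:
    """Four-parameter logistic dose-response model.

    Fitted by least squares on log-concentration with a fixed multi-start
    grid, so the estimate is deterministic for given data. The Hill slope
    is unconstrained in sign; results are canonicalised to top >= bottom.
    """

    #: multi-start Hill slopes; log10(IC50) starts span the data range
    HILL_STARTS = (-4.0, -2.0, -1.0, -0.5, 0.5, 1.0, 2.0, 4.0)
    N_IC50_STARTS = 5

    def __init__(self, dose_response: DoseResponse):
        self.data = dose_response
        if len(np.unique(dose_response.concentrations)) < 5:
            raise ValueError("need at least 5 distinct concentrations")

    @classmethod
    def from_arrays(cls, concentrations, viability) -> "FourPL":
        return cls(DoseResponse(np.asarray(concentrations), np.asarray(viability)))

    def _residuals(self, theta, logc, v):
        log_ic50, hill, top, bottom = theta
        with np.errstate(over="ignore"):
            u = np.clip(hill * (logc - log_ic50), -300, 300)
            pred = bottom + (top - bottom) / (1.0 + 10.0**u)
        return pred - v

    def fit(self) -> "FourPLResults":
        c = self.data.concentrations
        v = self.data.viability
        if np.ptp(v) < 1e-12 * max(1.0, np.abs(v).max()):
            raise ValueError("viability is flat; IC50 is unidentifiable")
        logc = np.log10(c)
        ic50_starts = np.linspace(logc.min(), logc.max(), self.N_IC50_STARTS)
        top0, bot0 = float(v.max()), float(v.min())

        best = None
        for l0 in ic50_starts:
            for h0 in self.HILL_STARTS:
                try:
                    sol = least_squares(
                        self._residuals,
                        x0=[l0, h0, top0, bot0],
                        args=(logc, v),
                        xtol=1e-15,
                        ftol=1e-15,
                        gtol=1e-15,
                        max_nfev=2000,
                    )
                except Exception:
                    continue
                if best is None or sol.cost < best.cost - 1e-12:
                    best = sol
        if best is None or not best.success:
            raise RuntimeError(
                "4PL fit failed to converge from every start "
                f"(n={len(c)}, viability range {v.min():.3g}..{v.max():.3g})"
            )
        log_ic50, hill, top, bottom = best.x
        if top < bottom:  # equivalent curve with mirrored slope
            top, bottom, hill = bottom, top, -hill
        return FourPLResults(
            model=self,
            ic50=float(10.0**log_ic50),
            hill=float(hill),
            top=float(top),
            bottom=float(bottom),
            residual_norm=float(np.sqrt(2.0 * best.cost)),
        )


@dataclass
class FourPLResults:
    """Fitted 4PL parameters; IC50 in the concentration units of the data."""

    model: FourPL
    ic50: float
    hill: float
    top: float
    bottom: float
    residual_norm: float

    def predict(self, conc) -> np.ndarray:
        return four_pl(conc, self.ic50, self.hill, self.top, self.bottom)

    def summary(self) -> str:
        d = self.model.data
        lines = [
            "Four-parameter logistic fit",
            "===========================",
            f"n points          {len(d.concentrations):>10d}",
            f"IC50              {self.ic50:>10.4g}",
            f"Hill slope        {self.hill:>10.4g}",
            f"top (%)           {self.top:>10.4g}",
            f"bottom (%)        {self.bottom:>10.4g}",
            f"residual norm     {self.residual_norm:>10.4g}",
        ]
        return "\n".join(lines)


def fit_4pl(dr: DoseResponse) -> FourPLResults:
    """Convenience wrapper: fit the 4PL model to a dose-response table."""
    return FourPL(dr).fit()
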