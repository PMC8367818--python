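"""Michaelis-Menten kinetics for taxadiene synthase assays.

Nonlinear least-squares fitting of v = Vmax * S / (Km + S) to
substrate-concentration / velocity data (the GGPP assay grid spans
0.2-50 uM), with the turnover number kcat = Vmax / [E] when the enzyme
concentration is known, and simple parameter-ratio comparisons between two
fitted enzymes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KineticAssay",
    "MMFit",
    "fit_michaelis_menten",
    "kinetic_ratios",
    "michaelis_menten",
]

GGPP_GRID_UM = (0.2, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0)


def michaelis_menten(s, vmax: float, km: float):
    return vmax * np.asarray(s, dtype=float) / (km + np.asarray(s, dtype=float))


@dataclass(frozen=True)
class KineticAssay:
    """Substrate concentrations (uM) with matched reaction velocities."""

    substrate_conc: tuple[float, ...]
    velocity: tuple[float, ...]
    enzyme_conc: float | None = None  # molar, enables kcat

    def __post_init__(self):
        if len(self.substrate_conc) != len(self.velocity):
            raise ValueError("substrate and velocity lists differ in length")
        if len(self.substrate_conc) < 4:
            raise ValueError("need at least 4 points to fit")
        if any(s <= 0 for s in self.substrate_conc):
            raise ValueError("substrate concentrations must be positive")


@dataclass(frozen=True)
class MMFit:
    Km: float  # uM
    Vmax: float
    kcat: float | None = None  # s^-1
    rss: float = math.nan
    converged: bool = True


def _initial_km(s: np.ndarray, v: np.ndarray) -> float:
    """Km starting value: substrate level at half-maximal velocity,
    linearly interpolated along the concentration-sorted curve."""
    order = np.argsort(s)
    s_sorted, v_sorted = s[order], v[order]
    half = v_sorted.max() / 2.0
    above = np.flatnonzero(v_sorted >= half)
    if len(above) == 0:
        return float(np.median(s_sorted))
    k = above[0]
    if k == 0 or v_sorted[k] == v_sorted[k - 1]:
        return float(s_sorted[k])
    frac = (half - v_sorted[k - 1]) / (v_sorted[k] - v_sorted[k - 1])
    return float(s_sorted[k - 1] + frac * (s_sorted[k] - s_sorted[k - 1]))


def fit_michaelis_menten(assay: KineticAssay) -> MMFit:
    """Least-squares Michaelis-Menten fit.

    Deterministic initialisation (Vmax0 = max velocity, Km0 = substrate at
    half-max by linear interpolation), relative-parameter tolerance 1e-10,
    at most 500 iterations.  A monotonically decreasing velocity series
    (substrate inhibition or mislabelled data) triggers a warning.
    """
    s = np.asarray(assay.substrate_conc, dtype=float)
    v = np.asarray(assay.velocity, dtype=float)
    order = np.argsort(s)
    if np.all(np.diff(v[order]) < 0):
        warnings.warn(
            "velocity decreases monotonically with substrate; "
            "Michaelis-Menten model is likely inappropriate",
            stacklevel=2,
        )
    x0 = np.array([v.max() if v.max() > 0 else 1.0, _initial_km(s, v)])

    def residuals(params):
        vmax, km = params
        return michaelis_menten(s, vmax, km) - v

    result = least_squares(
        residuals,
        x0,
        xtol=1e-10,
        ftol=1e-12,
        gtol=None,
        max_nfev=500,
        bounds=([0.0, 1e-12], [np.inf, np.inf]),
    )
    vmax, km = result.x
    kcat = None
    if assay.enzyme_conc is not None:
        if assay.enzyme_conc <= 0:
            raise ValueError("enzyme concentration must be positive")
        kcat = float(vmax / assay.enzyme_conc)
    return MMFit(
        Km=float(km),
        Vmax=float(vmax),
        kcat=kcat,
        rss=float(2.0 * result.cost),
        converged=bool(result.success),
    )


def kinetic_ratios(fit_a: MMFit, fit_b: MMFit) -> tuple[float, float | None]:
    """(Km ratio, kcat ratio) of enzyme b over enzyme a.

    kcat ratio is None when either fit lacks a turnover number.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    if fit_a.Km == 0:
        raise ValueError("zero Km denominator")
    km_ratio = fit_b.Km / fit_a.Km
    kcat_ratio = None
    if fit_a.kcat is not None and fit_b.kcat is not None:
        if fit_a.kcat == 0:
            raise ValueError("zero kcat denominator")
        kcat_ratio = fit_b.kcat / fit_a.kcat
    return km_ratio, kcat_ratio
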