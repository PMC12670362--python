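"""Thermal response-pattern mapping: sweep, slopes, classification, windows.

A response surface is built by simulating one individual per cell of a
(mean temperature x context factor) grid.  Local thermal slopes of the three
trait reaction norms (mass-, age-at-maturity and juvenile growth rate)
classify each cell into the canonical life-history response types:

* TSR        - mass and age both decrease with warming (growth rate rises);
* r-TSR      - mass increases while age decreases (reverse pattern);
* non-TSR    - the somatic growth rate decreases with warming;
* flat       - no slope exceeds the tolerance;
* no-maturity - the cell (or a neighbour needed for its slope) failed to
  reach maturity within the horizon.

Slopes are central finite differences on interior cells (one-sided at the
edges) computed on traits normalised by their grid median, so the
classification tolerance is unit-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .deb import DEBError, DEBParameters
from .forcing import EnvironmentSpec, NutritionContext, ThermalRegime
from .simulate import simulate_individual

#: default unit-free slope tolerance (per degC, on median-normalised traits)
SLOPE_EPS = 1e-3

#: default grid: 5-32 degC at 0.5 degC steps
DEFAULT_T_GRID = np.arange(5.0, 32.01, 0.5)

LABELS = ("TSR", "r-TSR", "non-TSR", "flat", "no-maturity")

#: reference (non-stressful) context: high food, high quality, constant T
REFERENCE_CONTEXT = {"X": 3.0, "quality_level": 1.0, "amplitude": 0.0}

FACTORS = ("food", "quality", "amplitude")


def _environment(T: float, factor: str, value: float) -> EnvironmentSpec:
    ctx = dict(REFERENCE_CONTEXT)
    key = {"food": "X", "quality": "quality_level", "amplitude": "amplitude"}[factor]
    ctx[key] = value
    return EnvironmentSpec(
        ThermalRegime(T_mean=T, amplitude=ctx["amplitude"]),
        NutritionContext(X=ctx["X"], quality_level=ctx["quality_level"]),
    )


@dataclass
class ResponseSurface:
    """Trait values over a (factor x temperature) grid.

    Arrays are indexed ``[i_factor, i_T]``; cells that failed to mature hold
    NaN traits and ``matured = False``.
    """

    temperatures: np.ndarray
    factor: str
    factor_values: np.ndarray
    mass: np.ndarray
    age: np.ndarray
    growth: np.ndarray
    matured: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.temperatures) > 0):
            raise DEBError("temperature grid must be strictly increasing")
        if len(self.factor_values) > 1 and not np.all(np.diff(self.factor_values) > 0):
            raise DEBError("factor grid must be strictly increasing")
        shape = (len(self.factor_values), len(self.temperatures))
        for arr in (self.mass, self.age, self.growth, self.matured):
            if arr.shape != shape:
                raise DEBError("surface arrays inconsistent with grids")


@dataclass
class PatternMap:
    """Per-cell response-type labels and normalised slope triples."""

    surface: ResponseSurface
    labels: np.ndarray           # object array of LABELS entries
    dmass_dT: np.ndarray         # raw slopes, trait units per degC
    dage_dT: np.ndarray
    dgrowth_dT: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (one row per grid cell)."""
        s = self.surface
        F, T = np.meshgrid(s.factor_values, s.temperatures, indexing="ij")
        return pd.DataFrame({
            "T": T.ravel(),
            s.factor: F.ravel(),
            "mass_ug": s.mass.ravel(),
            "age_d": s.age.ravel(),
            "growth_d": s.growth.ravel(),
            "matured": s.matured.ravel(),
            "dmass_dT": self.dmass_dT.ravel(),
            "dage_dT": self.dage_dT.ravel(),
            "dg_dT": self.dgrowth_dT.ravel(),
            "label": self.labels.ravel(),
        })


def sweep_surface(
    params: DEBParameters,
    factor: str = "food",
    factor_values=None,
    temperatures=None,
    progress: Callable[[int, int], None] | None = None,
) -> ResponseSurface:
    """Simulate one individual per (factor, temperature) cell.

    Failures to mature are recorded as NaN cells, never raised: a solver or
    horizon failure is itself the 'no-maturity' observation.
    """
    if factor not in FACTORS:
        raise DEBError(f"factor must be one of {FACTORS}")
    temperatures = np.asarray(
        DEFAULT_T_GRID if temperatures is None else temperatures, dtype=float)
    if len(temperatures) < 3:
        raise DEBError("need at least 3 temperature points")
    if factor_values is None:
        factor_values = {
            "food": np.linspace(0.4, 3.0, 20),
            "quality": np.linspace(0.0, 1.0, 20),
            "amplitude": np.linspace(0.0, 5.0, 20),
        }[factor]
    factor_values = np.atleast_1d(np.asarray(factor_values, dtype=float))

    shape = (len(factor_values), len(temperatures))
    mass = np.full(shape, np.nan)
    age = np.full(shape, np.nan)
    growth = np.full(shape, np.nan)
    matured = np.zeros(shape, dtype=bool)
    total = shape[0] * shape[1]
    for i, fv in enumerate(factor_values):
        for j, T in enumerate(temperatures):
            try:
                res = simulate_individual(params, _environment(T, factor, fv))
            except Exception:
                res = None
            if res is not None and res.matured:
                mass[i, j], age[i, j], growth[i, j] = res.traits
                matured[i, j] = True
            if progress is not None:
                progress(i * shape[1] + j + 1, total)
    return ResponseSurface(temperatures, factor, factor_values,
                           mass, age, growth, matured)


def local_slopes(surface: ResponseSurface) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thermal slopes of the three traits, trait units per degC.

    Central differences on interior cells, one-sided at the edges; NaN
    wherever a required neighbour did not mature.  Central differences are
    exact for trait norms linear in T and second-order accurate otherwise.
    """
    T = surface.temperatures
    out = []
    for trait in (surface.mass, surface.age, surface.growth):
        s = np.full_like(trait, np.nan)
        # np.gradient handles interior/edge stencils; NaNs propagate to
        # every slope whose stencil includes a failed neighbour
        for i in range(trait.shape[0]):
            s[i] = np.gradient(trait[i], T)
        s[~surface.matured] = np.nan     # a failed cell has no slope of its own
        out.append(s)
    return tuple(out)


def classify_cell(dmass: float, dage: float, dgrowth: float,
                  eps: float = SLOPE_EPS) -> str:
    """Label one cell from its (normalised) slope triple.

    Priority follows the pattern definitions: any decrease of growth rate is
    non-TSR; otherwise joint mass/age decrease is TSR and mass increase with
    age decrease is r-TSR; sub-tolerance slopes are flat.
    """
    if np.isnan(dmass) or np.isnan(dage) or np.isnan(dgrowth):
        return "no-maturity"
    if dgrowth < -eps:
        return "non-TSR"
    if dmass < -eps and dage < -eps:
        return "TSR"
    if dmass > eps and dage < -eps:
        return "r-TSR"
    return "flat"


def build_pattern_map(surface: ResponseSurface, eps: float = SLOPE_EPS) -> PatternMap:
    """Classify every cell of a response surface.

    Slopes are normalised by each trait's grid median (over matured cells)
    before comparison with ``eps``, making the tolerance unit-free; the
    stored slope arrays keep raw trait units.
    """
    dm, da, dg = local_slopes(surface)
    meds = [np.nanmedian(x) if np.any(surface.matured) else np.nan
            for x in (surface.mass, surface.age, surface.growth)]
    labels = np.empty(surface.mass.shape, dtype=object)
    for i in range(labels.shape[0]):
        for j in range(labels.shape[1]):
            labels[i, j] = classify_cell(
                dm[i, j] / meds[0], da[i, j] / meds[1], dg[i, j] / meds[2], eps)
    return PatternMap(surface, labels, dm, da, dg)


def tsr_window(labels_row: np.ndarray, temperatures: np.ndarray,
               interior_only: bool = True) -> tuple[float, float] | None:
    """Endpoints of the widest contiguous TSR band along one factor row.

    Returns None when no cell is TSR-labelled.  Edge cells carry one-sided
    slope estimates, so by default windows are reported on interior cells.
    """
    lo, hi = (1, len(temperatures) - 1) if interior_only else (0, len(temperatures))
    best = None
    start = None
    for j in range(lo, hi):
        if labels_row[j] == "TSR":
            if start is None:
                start = j
            if best is None or (j - start) > (best[1] - best[0]):
                best = (start, j)
        else:
            start = None
    if best is None:
        return None
    return (float(temperatures[best[0]]), float(temperatures[best[1]]))


def lambda_sensitivity(
    params: DEBParameters,
    lambdas,
    temperatures=None,
    eps: float = SLOPE_EPS,
) -> pd.DataFrame:
    """Sensitivity of the mass reaction norm to the kappa-sigmoid stiffness.

    For each stiffness value, simulates the reference-context reaction norm
    and reports the TSR window, the width of the near-flat mass-slope
    region inside it (cells where |normalised mass slope| < 10 * eps) and
    the steepest normalised mass decline inside the window.  Stiffer
    sigmoids concentrate the allocation shift, producing steeper mass
    declines over a narrower temperature band.
    """
    from dataclasses import replace

    rows = []
    for lam in lambdas:
        p = replace(params, lambda_=float(lam))
        surf = sweep_surface(p, "food", [REFERENCE_CONTEXT["X"]], temperatures)
        pmap = build_pattern_map(surf, eps)
        win = tsr_window(pmap.labels[0], surf.temperatures)
        flat_width, max_decline = 0.0, np.nan
        if win is not None:
            med = np.nanmedian(surf.mass)
            sel = (surf.temperatures >= win[0]) & (surf.temperatures <= win[1])
            norm_slope = pmap.dmass_dT[0] / med
            step = np.median(np.diff(surf.temperatures))
            flat_width = float(np.sum(np.abs(norm_slope[sel]) < 10 * eps) * step)
            max_decline = float(np.nanmax(-norm_slope[sel]))
        rows.append({"lambda": float(lam),
                     "T_low": win[0] if win else np.nan,
                     "T_high": win[1] if win else np.nan,
                     "flat_mass_width": flat_width,
                     "max_mass_decline": max_decline})
    return pd.DataFrame(rows)
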