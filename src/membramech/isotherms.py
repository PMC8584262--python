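"""Langmuir π–A isotherm analytics.

A compression isotherm records the mean molecular area A (Å²) against the
surface pressure π (mN/m) of a lipid film at the air–water interface.  This
module reads such records, reads off the area at a chosen pressure (33 mN/m
is the conventional monolayer–bilayer equivalence point), computes the
compressibility C_s = −(1/A) dA/dπ and its reciprocal modulus −A dπ/dA
("surface elasticity", reported in mN/m), builds the ideal-mixing reference
A_ideal(π) = Σ X_k A_k(π), and integrates the excess free energy of mixing

    ΔG_m^ex(π) = N_A [ ∫ A_mix dπ′ − Σ_k X_k ∫ A_k dπ′ ]   (J/mol),

which vanishes identically for an ideally miscible film.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import savgol_filter

from .units import J_PER_MOL_PER_A2_MNM


@dataclass
class Isotherm:
    """A monotone compression record (area strictly decreasing)."""

    area: np.ndarray  # Å², strictly decreasing along compression
    pressure: np.ndarray  # mN/m
    composition: dict[str, float]
    temperature: float = 295.15  # K
    collapse_pressure: float | None = None
    area_sigma: float = 0.0  # Å², replicate deviation of the APL readout

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.area.shape != self.pressure.shape:
            raise ValueError("area and pressure must have equal length")
        if self.area.size < 10:
            raise ValueError("an isotherm needs at least 10 points")
        if np.any(self.pressure < 0):
            raise ValueError("pressures must be non-negative")
        if abs(sum(self.composition.values()) - 1.0) > 1e-9:
            raise ValueError("mole fractions must sum to 1")
        if np.any(np.diff(self.area) >= 0):
            raise ValueError("area must be strictly decreasing along compression")

    @property
    def pi_range(self) -> tuple[float, float]:
        return float(self.pressure.min()), float(self.pressure.max())

    def lift_off_pressure(self, threshold: float = 0.5) -> float:
        """First recorded pressure exceeding ``threshold`` mN/m."""
        above = self.pressure > threshold
        if not above.any():
            raise ValueError("isotherm never lifts off the baseline")
        return float(self.pressure[above].min())


def read_isotherm(
    path, composition: dict[str, float], temperature: float = 295.15
) -> Isotherm:
    """Read a two-column (area Å², pressure mN/m) CSV/TSV/whitespace table.

    Rows are sorted by decreasing area, duplicate areas are averaged, and a
    non-monotone pressure after sorting triggers a warning (kinks can be
    genuine phase transitions).
    """
    table = pd.read_csv(path, sep=None, engine="python", comment="#", header=None,
                        skip_blank_lines=True)
    if not np.issubdtype(np.asarray(table.iloc[0]).dtype, np.number):
        table = table.iloc[1:].astype(float)
    data = table.to_numpy(dtype=float)[:, :2]
    frame = pd.DataFrame(data, columns=["area", "pressure"])
    frame = frame.groupby("area", as_index=False).mean()
    frame = frame.sort_values("area", ascending=False)
    iso = Isotherm(
        frame["area"].to_numpy(), frame["pressure"].to_numpy(), composition, temperature
    )
    if np.any(np.diff(iso.pressure) < -0.5):
        warnings.warn("pressure is not monotone along compression beyond tolerance")
    return iso


def apl_at_pressure(iso: Isotherm, target_pi: float) -> float:
    """Linearly interpolated molecular area (Å²) at a surface pressure."""
    lo, hi = iso.pi_range
    if not (lo <= target_pi <= hi):
        raise ValueError(
            f"pressure {target_pi} mN/m outside recorded range [{lo}, {hi}]"
        )
    order = np.argsort(iso.pressure)
    return float(np.interp(target_pi, iso.pressure[order], iso.area[order]))


@dataclass
class CompressibilityResult:
    """Compressibility and its reciprocal surface-elasticity modulus."""

    modulus_mN_per_m: float  # −A dπ/dA, the conventionally tabulated value
    cs_raw_per_mN_per_m: float  # −(1/A) dA/dπ, units (mN/m)^-1
    at_pressure: float
    units: str = "mN/m"


def compressibility_modulus(
    iso: Isotherm,
    target_pi: float,
    smoothing: dict | None = None,
) -> CompressibilityResult:
    """Surface elasticity at a target pressure by central differences.

    ``smoothing`` optionally applies a Savitzky–Golay local polynomial
    (keys ``window``, ``order``; defaults 7 and 2) to the area record
    before differentiation; it is off by default so analytic records are
    differentiated exactly.
    """
    lo, hi = iso.pi_range
    if not (lo <= target_pi <= hi):
        raise ValueError(f"pressure {target_pi} outside recorded range [{lo}, {hi}]")
    order = np.argsort(iso.pressure)
    pi = iso.pressure[order]
    area = iso.area[order]
    if smoothing is not None:
        window = int(smoothing.get("window", 7))
        poly = int(smoothing.get("order", 2))
        window = min(window if window % 2 else window + 1, len(area) - (len(area) + 1) % 2)
        area = savgol_filter(area, window, poly)
        # local-polynomial derivative on the (near-uniform) pressure grid
        h = float(np.mean(np.diff(pi)))
        dadp = savgol_filter(area, window, poly, deriv=1, delta=h)
    else:
        dadp = np.gradient(area, pi)
    dadp_t = float(np.interp(target_pi, pi, dadp))
    a_t = float(np.interp(target_pi, pi, area))
    if abs(dadp_t) < 1e-12:
        raise ValueError("phase transition plateau: dA/dπ vanishes at the target pressure")
    return CompressibilityResult(
        modulus_mN_per_m=-a_t / dadp_t,
        cs_raw_per_mN_per_m=-dadp_t / a_t,
        at_pressure=target_pi,
    )


# --------------------------------------------------------------------------
# mixing


@dataclass
class MixingResult:
    """Ideal-mixing reference and excess free energy of mixing vs pressure."""

    pressures: np.ndarray  # mN/m
    ideal_area: np.ndarray  # Å²
    mixed_area: np.ndarray  # Å²
    dg_excess: np.ndarray  # J/mol
    dg_sigma: np.ndarray  # J/mol, propagated replicate deviation
    pi0: float  # lower integration limit, mN/m
    units: str = "J/mol"


def _common_pressure_grid(isotherms, pi_min=None, pi_max=None) -> np.ndarray:
    lo = max(iso.pi_range[0] for iso in isotherms)
    hi = min(iso.pi_range[1] for iso in isotherms)
    if pi_min is not None:
        lo = max(lo, pi_min)
    if pi_max is not None:
        hi = min(hi, pi_max)
    if hi <= lo:
        raise ValueError("empty common pressure range across isotherms")
    merged = np.unique(
        np.concatenate([iso.pressure for iso in isotherms] + [np.array([lo, hi])])
    )
    return merged[(merged >= lo) & (merged <= hi)]


def _area_on(iso: Isotherm, grid: np.ndarray) -> np.ndarray:
    order = np.argsort(iso.pressure)
    return np.interp(grid, iso.pressure[order], iso.area[order])


def ideal_mixed_apl(
    components: list[Isotherm], fractions: list[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Mole-fraction-weighted mean area of non-interacting components.

    Returns ``(pressure_grid, ideal_area)`` on the intersection of the
    component pressure ranges.
    """
    if len(components) not in (2, 3):
        raise ValueError("ideal mixing is defined for 2 or 3 components")
    if len(fractions) != len(components):
        raise ValueError("one mole fraction per component is required")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("mole fractions must sum to 1")
    grid = _common_pressure_grid(components)
    ideal = np.zeros_like(grid)
    for x, iso in zip(fractions, components):
        ideal += x * _area_on(iso, grid)
    return grid, ideal


def excess_free_energy(
    mixed: Isotherm,
    components: list[Isotherm],
    fractions: list[float],
    pi_max: float = 33.0,
    pi0: float | None = None,
) -> MixingResult:
    """Excess free energy of mixing ΔG_m^ex(π) by trapezoidal quadrature.

    Integration runs from the lift-off pressure π₀ (first point above
    0.5 mN/m; override with ``pi0``) up to ``pi_max``.  The replicate
    deviation is propagated linearly as the sum of the area deviations of
    all involved isotherms scaled by N_A·(π − π₀).
    """
    if len(fractions) != len(components):
        raise ValueError("one mole fraction per component is required")
    comp_sum = {sp: 0.0 for iso in components for sp in iso.composition}
    for x, iso in zip(fractions, components):
        for sp, xs in iso.composition.items():
            comp_sum[sp] += x * xs
    for sp, x in mixed.composition.items():
        if abs(comp_sum.get(sp, 0.0) - x) > 1e-6:
            raise ValueError(
                f"mixed-film composition inconsistent with fractions for {sp!r}"
            )
    if pi0 is None:
        pi0 = mixed.lift_off_pressure()
    grid = _common_pressure_grid([mixed] + components, pi_min=pi0, pi_max=pi_max)
    a_mix = _area_on(mixed, grid)
    ideal = np.zeros_like(grid)
    for x, iso in zip(fractions, components):
        ideal += x * _area_on(iso, grid)
    deviation = a_mix - ideal
    dg = (
        cumulative_trapezoid(deviation, grid, initial=0.0) * J_PER_MOL_PER_A2_MNM
    )
    sigma_sum = mixed.area_sigma + sum(iso.area_sigma for iso in components)
    dg_sigma = sigma_sum * (grid - grid[0]) * J_PER_MOL_PER_A2_MNM
    return MixingResult(grid, ideal, a_mix, dg, dg_sigma, float(grid[0]))
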