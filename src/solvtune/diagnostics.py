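"""Delocalization-error and one-particle-picture diagnostics.

Two independent checks of whether a tuned functional is physically
meaningful:

1. **Fractional-charge curve.**  Between the neutral (q = 0) and the anion
   (q = 1) the exact energy is piecewise linear in the fractional electron
   number.  A quadratic-spline interpolant through the computed edge
   quantities,

       E(q) = ΔE·q + [(ε_LUMO(N) − ΔE)(1 − q) + (ΔE − ε_HOMO(N+1))·q]·q(1 − q)
       F(q) = E(q) − ΔE·q,                         ΔE = IP(N+1),

   quantifies the deviation: F ≡ 0 means no delocalization error, negative
   F delocalization, positive F overlocalization.

2. **One-particle picture.**  If ionization removes exactly the HOMO,
   Δρ = ρ_N − ρ_{N−1} equals |φ_HOMO|².  Both fields are condensed to atoms
   by Hirshfeld (stockholder) partitioning with free-atom promolecule
   weights, and the squared Pearson correlation R² between the two per-atom
   population vectors measures agreement; R² > 0.90 counts as compliant.

Densities arrive on rectangular (cube-style) grids and are integrated by
Riemann summation; the quadrature scheme does not move the R² decision at
sensible resolutions.  The classic per-atom multicenter grid arithmetic
(radial × angular points) is provided as a utility for parity with
atom-centered integrators.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.stats import pearsonr

from .engine import DensityGrid

__all__ = [
    "FractionalChargeCurve",
    "HirshfeldReport",
    "FreeAtomProfiles",
    "fractional_charge_curve",
    "hirshfeld_populations",
    "one_particle_r2",
    "per_atom_grid_points",
    "load_default_profiles",
    "PROMOLECULE_FLOOR",
]

#: promolecule density below this value (e·Å⁻³) contributes nothing — avoids
#: 0/0 in the stockholder weights far from every atom
PROMOLECULE_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# fractional-charge curve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FractionalChargeCurve:
    """E(q) and the linearity deviation F(q) on a fractional-charge grid.

    Endpoints are exact by construction: E(0) = 0, E(1) = ΔE,
    F(0) = F(1) = 0.  The midpoint obeys the closed form
    F(1/2) = (ε_LUMO(N) − ε_HOMO(N+1))/8.
    """

    q: np.ndarray
    E: np.ndarray
    F: np.ndarray
    delta_e: float
    eps_lumo_n: float
    eps_homo_n1: float


def fractional_charge_curve(ip_n1: float, eps_lumo_n: float,
                            eps_homo_n1: float,
                            n_points: int = 101) -> FractionalChargeCurve:
    """Build the fractional-charge interpolant between N and N+1 states.

    Parameters are in eV: ``ip_n1`` is ΔE = IP(N+1) = E(N) − E(N+1), and
    ``eps_lumo_n`` / ``eps_homo_n1`` are the neutral LUMO and anion HOMO
    energies.  ``n_points`` ≥ 3 samples are placed uniformly on [0, 1].
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    for name, v in (("ip_n1", ip_n1), ("eps_lumo_n", eps_lumo_n),
                    ("eps_homo_n1", eps_homo_n1)):
        if not math.isfinite(v):
            raise ValueError(f"{name} is not finite")
    de = ip_n1
    q = np.linspace(0.0, 1.0, n_points)
    bracket = (eps_lumo_n - de) * (1.0 - q) + (de - eps_homo_n1) * q
    F = bracket * q * (1.0 - q)
    E = de * q + F
    return FractionalChargeCurve(q=q, E=E, F=F, delta_e=de,
                                 eps_lumo_n=eps_lumo_n,
                                 eps_homo_n1=eps_homo_n1)


# ---------------------------------------------------------------------------
# Hirshfeld populations
# ---------------------------------------------------------------------------


class FreeAtomProfiles:
    """Spherically averaged free-atom densities, log-radially interpolated.

    ``tables`` maps an element symbol to ``(radii Å, density e·Å⁻³)``
    arrays with strictly increasing radii.  Lookups interpolate the density
    linearly in log r; inside the first tabulated radius the first value is
    held, beyond the last the density is zero.
    """

    def __init__(self, tables: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._tables = {}
        for el, (r, rho) in tables.items():
            r = np.asarray(r, dtype=float)
            rho = np.asarray(rho, dtype=float)
            if r.ndim != 1 or r.shape != rho.shape or np.any(np.diff(r) <= 0):
                raise ValueError(f"bad radial table for element {el!r}")
            self._tables[el] = (r, rho)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(sorted(self._tables))

    def density(self, element: str, r) -> np.ndarray:
        """ρ_free(r) for one element at radial distances r (Å)."""
        if element not in self._tables:
            raise KeyError(
                f"no free-atom profile for element {element!r}; "
                f"available: {', '.join(self.elements)}"
            )
        radii, rho = self._tables[element]
        r = np.asarray(r, dtype=float)
        rc = np.clip(r, radii[0], None)
        out = np.interp(np.log(rc), np.log(radii), rho, right=0.0)
        out = np.where(r > radii[-1], 0.0, out)
        return out


def load_default_profiles() -> FreeAtomProfiles:
    """Load the packaged free-atom density table.

    The shipped table (``free_atom_densities_synthetic.json``) is a
    synthetic stand-in: Slater-rule single-zeta exponential densities
    normalized to the element's electron count, tabulated on a log-radial
    grid.  It reproduces the qualitative core/valence decay that the
    stockholder weights need; swap in tabulated reference atomic densities
    for production work via :class:`FreeAtomProfiles`.
    """
    ref = resources.files("solvtune.data") / "free_atom_densities_synthetic.json"
    data = json.loads(ref.read_text())
    tables = {
        el: (np.array(t["r_angstrom"]), np.array(t["rho_e_per_ang3"]))
        for el, t in data["elements"].items()
    }
    return FreeAtomProfiles(tables)


def hirshfeld_populations(density: DensityGrid,
                          atoms,
                          free_atom_profiles: FreeAtomProfiles) -> np.ndarray:
    """Condense a gridded scalar field to per-atom Hirshfeld populations.

    The stockholder weight of atom A at grid point r is
    w_A(r) = ρ_A^free(|r − R_A|) / Σ_B ρ_B^free(|r − R_B|); where the
    promolecule denominator falls below :data:`PROMOLECULE_FLOOR` the point
    contributes nothing.  Populations are Riemann sums Σ w_A·ρ·Δv, so they
    sum to the grid integral of the field wherever the promolecule covers
    the field's support (partition of unity).

    ``atoms`` is a sequence of ``(element, position Å)`` pairs.
    """
    if len(atoms) == 0:
        raise ValueError("need at least one atom")
    pts = density.points()
    values = density.values.ravel()
    free = np.empty((len(atoms), len(pts)))
    for i, (el, pos) in enumerate(atoms):
        d = np.linalg.norm(pts - np.asarray(pos, dtype=float)[None, :], axis=1)
        free[i] = free_atom_profiles.density(el, d)
    promol = free.sum(axis=0)
    ok = promol > PROMOLECULE_FLOOR
    weights = np.zeros_like(free)
    weights[:, ok] = free[:, ok] / promol[ok]
    return (weights * values[None, :]).sum(axis=1) * density.dvol


def per_atom_grid_points(n_radial: int = 75, n_angular: int = 434) -> int:
    """Points per atom of an atom-centered product grid (radial × angular).

    The conventional medium-quality multicenter setting of 75 radial shells
    with 434 angular points per shell gives 32,550 points per atom; the
    total for a molecule scales linearly with its atom count.
    """
    if n_radial < 1 or n_angular < 1:
        raise ValueError("grid factors must be positive")
    return n_radial * n_angular


# ---------------------------------------------------------------------------
# one-particle picture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HirshfeldReport:
    """Per-atom populations of Δρ and |φ_HOMO|² with their agreement R²."""

    pop_delta_rho: np.ndarray
    pop_homo_sq: np.ndarray
    r2: float
    compliant: bool


def one_particle_r2(pop_delta_rho, pop_homo_sq,
                    threshold: float = 0.90) -> HirshfeldReport:
    """Squared Pearson correlation between Δρ and |φ_HOMO|² populations.

    R² > ``threshold`` (default 0.90) marks the tuning as consistent with
    the one-particle picture.  Raises if either population vector is
    constant — the correlation is undefined there.
    """
    a = np.asarray(pop_delta_rho, dtype=float)
    b = np.asarray(pop_homo_sq, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("correlation undefined for constant population vectors")
    r = pearsonr(a, b).statistic
    r2 = float(r * r)
    return HirshfeldReport(pop_delta_rho=a, pop_homo_sq=b, r2=r2,
                           compliant=bool(r2 > threshold))
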