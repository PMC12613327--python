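"""Charge-transfer asymptotics for donor–acceptor dimer scans.

A functional with the correct long-range behavior must reproduce, at large
donor–acceptor separation R, the screened Mulliken limit of the CT
excitation energy

    ΔE_CT(R) = IP_donor + EA_acceptor − k/(ε∞ R),        k = 14.3996 eV·Å,

where only the solvent's fast (optical, ε∞) polarization screens the
electron–hole attraction — a vertical excitation leaves the slow
polarization frozen.  At ε∞ = 1 this is Mulliken's vacuum rule.  A more
accurate finite-R reference replaces the point-charge attraction with the
pairwise Coulomb sum over atomic partial charges of the donor cation and
acceptor anion.

The module also builds the rigid separation scan (acceptor displaced along
+z) and implements the CT-state selection rule: the lowest state whose
unrelaxed excited-state dipole component along the transfer axis exceeds a
threshold (default 12.5 D).

Sign convention: EA = E(N+1) − E(N) (electron-attachment energy), so the
vacuum R → ∞ limit is literally IP + EA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .engine import ExcitationSet, Molecule
from .pcm import COULOMB_EV_ANG

__all__ = [
    "DimerScan",
    "CTReference",
    "build_dimer_scan",
    "ct_energy_point_charge",
    "ct_energy_atomic_charges",
    "select_ct_state",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class DimerScan:
    """Rigid donor–acceptor separation scan along +z.

    Both monomers are recentered (geometric center at the origin) before
    monomer B is translated to each separation; ``geometries`` holds the
    combined dimers in the same order as ``separations`` (Å, strictly
    increasing).
    """

    monomer_a: Molecule
    monomer_b: Molecule
    separations: tuple[float, ...]
    geometries: tuple[Molecule, ...]


@dataclass(frozen=True)
class CTReference:
    """Reference CT energies over a separation scan (all energies eV)."""

    ip_donor: float
    ea_acceptor: float
    eps: float
    eps_inf: float
    separations: tuple[float, ...]
    energies: tuple[float, ...]


def build_dimer_scan(mon_a: Molecule, mon_b: Molecule,
                     r_min: float = 5.0, r_max: float = 9.0,
                     step: float = 0.5) -> DimerScan:
    """Generate dimer geometries with B displaced along +z by each R.

    With the default 5.0–9.0 Å range and 0.5 Å step this yields 9
    conformers.  The centroid of the translated B copy equals (0, 0, R)
    exactly.  If any A–B atom pair at the smallest separation is closer
    than 1.0 Å a warning (not an error) is emitted.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if r_min > r_max:
        raise ValueError("r_min must not exceed r_max")
    a = mon_a.recentered()
    b = mon_b.recentered()
    n = int(np.floor((r_max - r_min) / step + 1e-9)) + 1
    seps = tuple(round(r_min + k * step, 10) for k in range(n))

    geoms = []
    net = a.net_charge + b.net_charge
    for r in seps:
        b_shift = b.translated((0.0, 0.0, r))
        atoms = a.atoms + b_shift.atoms
        n_e = (a.n_electrons + a.net_charge) + (b.n_electrons + b.net_charge) - net
        mult = 1 if n_e % 2 == 0 else 2
        geoms.append(Molecule(atoms, net_charge=net, multiplicity=mult))

    da = a.coordinates
    db = b.coordinates + np.array([0.0, 0.0, seps[0]])
    dmin = float(np.linalg.norm(da[:, None, :] - db[None, :, :], axis=2).min())
    if dmin < 1.0:
        warnings.warn(
            f"overlapping atoms at R={seps[0]} Å (closest A-B pair "
            f"{dmin:.3f} Å)", stacklevel=2)
    return DimerScan(monomer_a=a, monomer_b=b, separations=seps,
                     geometries=tuple(geoms))


def ct_energy_point_charge(ip: float, ea: float, R: float,
                           eps_inf: float = 1.0) -> float:
    """Screened Mulliken CT energy: IP + EA − k/(ε∞·R), in eV.

    Monotonically increasing in ε∞ at fixed R (weaker attraction) and
    tending to IP + EA as R → ∞.  At ε∞ = 1 this is the vacuum Mulliken
    rule.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if eps_inf < 1:
        raise ValueError("eps_inf must be >= 1")
    return ip + ea - COULOMB_EV_ANG / (eps_inf * R)


def ct_energy_atomic_charges(ip: float, ea: float, charges_a, charges_b,
                             eps_inf: float = 1.0) -> float:
    """CT energy with the electron–hole term from atomic partial charges.

    ``charges_a`` / ``charges_b`` are sequences of ``(position Å, charge e)``
    for the donor cation and acceptor anion; the screened pairwise Coulomb
    sum Σ_i Σ_j k·q_i·q_j/(ε∞·r_ij) replaces the point-charge attraction.
    For single ±1 point charges this reduces exactly to
    :func:`ct_energy_point_charge`.  Raises if any cross pair is closer
    than 1e-6 Å.
    """
    if eps_inf < 1:
        raise ValueError("eps_inf must be >= 1")
    pos_a = np.array([p for p, _ in charges_a], dtype=float)
    q_a = np.array([q for _, q in charges_a], dtype=float)
    pos_b = np.array([p for p, _ in charges_b], dtype=float)
    q_b = np.array([q for _, q in charges_b], dtype=float)
    dist = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=2)
    bad = np.argwhere(dist < 1e-6)
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"singular atomic pair: donor atom {i} and acceptor atom {j} "
            f"are {dist[i, j]:.2e} Å apart"
        )
    coulomb = COULOMB_EV_ANG * float((q_a[:, None] * q_b[None, :] / dist).sum())
    return ip + ea + coulomb / eps_inf


def select_ct_state(states: ExcitationSet, dipole_axis: str = "y",
                    threshold: float = 12.5) -> int | None:
    """Pick the CT state: first state with |dipole_axis component| > threshold.

    Returns the 1-based index of the lowest-energy state whose unrelaxed
    excited-state dipole component along ``dipole_axis`` exceeds
    ``threshold`` (in Debye) in magnitude, or ``None`` if no state
    qualifies.
    """
    try:
        axis = _AXES[dipole_axis]
    except KeyError:
        raise ValueError(f"dipole_axis must be one of x, y, z, got {dipole_axis!r}")
    for i, dip in enumerate(states.dipoles):
        if abs(dip[axis]) > threshold:
            return i + 1
    return None
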