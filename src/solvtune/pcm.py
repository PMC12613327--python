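"""Fast/slow partitioning of continuum polarization charges.

In nonequilibrium continuum solvation the solvent's polarization splits into
a fast (electronic) component, which follows the solute instantaneously, and
a slow (orientational/nuclear) component, which stays frozen on the
timescale of electron attachment or removal.  Given the apparent surface
charges of a fully equilibrated run, this module performs the Marcus-type
partition

    q_slow = [(ε − ε∞)/(ε − 1)] · q_eq,       q_fast = q_eq − q_slow,

and packages the slow part as a frozen external point-charge field whose
Coulomb potential can be evaluated anywhere.  The partition is applied
per surface point, positions untouched, so the fast and slow components sum
back to the equilibrium charges exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COULOMB_EV_ANG",
    "FrozenSlowField",
    "partition_charges",
    "slow_field_potential",
    "charges_to_csv",
    "charges_from_csv",
]

#: Coulomb constant e²/(4πε₀) in eV·Å — the potential of a unit charge at
#: 14.3996 Å is exactly 1 eV per unit test charge.
COULOMB_EV_ANG = 14.3996


@dataclass(frozen=True)
class FrozenSlowField:
    """The slow polarization component, frozen as an external field.

    ``positions`` (n, 3) in Å coincide with the cavity surface points of the
    equilibrium run the charges came from; ``charges`` (n,) in e.
    ``provenance`` records which run produced it (free-form string).
    """

    positions: np.ndarray
    charges: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        q = np.atleast_1d(np.asarray(self.charges, dtype=float))
        if pos.shape != (len(q), 3):
            raise ValueError("positions must be (n, 3) matching n charges")
        if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(q)):
            raise ValueError("positions and charges must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", q)

    def __len__(self) -> int:
        return len(self.charges)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


def _split_charge_list(q_eq):
    """Accept either (positions, charges) arrays or a list of (pos, q)."""
    if isinstance(q_eq, tuple) and len(q_eq) == 2 and not np.isscalar(q_eq[0]):
        first = np.asarray(q_eq[0], dtype=float)
        if first.ndim == 2 and first.shape[1] == 3:
            return first, np.asarray(q_eq[1], dtype=float)
    pos = np.array([p for p, _ in q_eq], dtype=float)
    q = np.array([c for _, c in q_eq], dtype=float)
    return pos, q


def slow_fraction(eps: float, eps_inf: float) -> float:
    """Marcus slow fraction f_slow = (ε − ε∞)/(ε − 1); 0 in the gas limit.

    f_slow → 1 as ε → ∞ at fixed ε∞ (everything orientational), and
    f_slow → 0 as ε∞ → ε (no slow response at all).
    """
    if not (1.0 <= eps_inf <= eps):
        raise ValueError(
            f"require 1 <= eps_inf <= eps, got eps_inf={eps_inf}, eps={eps}"
        )
    if eps == 1.0:
        return 0.0
    return (eps - eps_inf) / (eps - 1.0)


def partition_charges(q_eq, eps: float, eps_inf: float):
    """Split equilibrium surface charges into fast and slow components.

    Parameters
    ----------
    q_eq
        Equilibrium polarization charges, either a sequence of
        ``(position, charge)`` pairs or a ``(positions (n,3), charges (n,))``
        tuple.
    eps, eps_inf
        Static and optical dielectric constants, 1 ≤ ε∞ ≤ ε.

    Returns
    -------
    (positions, q_fast, q_slow)
        Positions unchanged; per point ``q_slow = f_slow · q_eq`` and
        ``q_fast = q_eq − q_slow``, so they conserve the total charge
        exactly.
    """
    positions, charges = _split_charge_list(q_eq)
    if len(charges) == 0:
        raise ValueError("q_eq must be nonempty")
    f_slow = slow_fraction(eps, eps_inf)
    q_slow = f_slow * charges
    q_fast = charges - q_slow
    return positions, q_fast, q_slow


def slow_field_potential(field: FrozenSlowField, points) -> np.ndarray:
    """Coulomb potential of the frozen slow charges at each point (eV/e).

    V(r) = Σ_i k·q_i / |r − r_i| with k = 14.3996 eV·Å/e²; linear in the
    charge vector.  Raises if any evaluation point sits within 1e-6 Å of a
    source charge.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("points must be (m, 3)")
    # (m, n) pairwise distances
    diff = pts[:, None, :] - field.positions[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    bad = np.argwhere(dist < 1e-6)
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"evaluation point {i} coincides with charge {j} "
            f"(separation {dist[i, j]:.2e} Å < 1e-6 Å)"
        )
    return COULOMB_EV_ANG * (field.charges[None, :] / dist).sum(axis=1)


def charges_to_csv(positions, charges, path: str | Path) -> None:
    """Serialize a charge list as CSV with columns x, y, z, q (Å, e)."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    df = pd.DataFrame({
        "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        "q": np.asarray(charges, dtype=float),
    })
    df.to_csv(path, index=False)


def charges_from_csv(path: str | Path):
    """Load a charge list written by :func:`charges_to_csv`."""
    df = pd.read_csv(path)
    return df[["x", "y", "z"]].to_numpy(), df["q"].to_numpy()
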