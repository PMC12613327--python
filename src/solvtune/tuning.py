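"""Optimal tuning of the range-separation parameter γ in solution.

The tuning condition enforces Koopmans'/Janak's theorem at both edges of
the gap by minimizing

    J²(γ) = [ε_HOMO(N; γ) + IP(N; γ)]² + [ε_HOMO(N+1; γ) + IP(N+1; γ)]²

where IP(N) = E(N−1) − E(N) and IP(N+1) = E(N) − E(N+1) are ΔSCF
ionization energies of the neutral and the anion.  Three schemes differ in
how the continuum solvent enters the N, N−1, N+1 runs:

* **GP** (gas-phase tuning): all three states in vacuum.
* **PV** (partial-vertical): all three states with the fully equilibrated
  continuum at the static ε — the solvent's nuclear degrees of freedom
  relax along with the ionization, which is unphysical for a vertical
  process.
* **SV** (strict-vertical): the neutral in equilibrium at ε; its
  polarization charges are split into fast and slow parts, and the ions are
  run with the optical ε∞ continuum plus the neutral's slow charges frozen
  as an external field — only the electronic polarization responds to the
  vertical electron attachment/removal.

The optimum is located by the two-round grid search: a coarse scan over
γ ∈ {0.00, 0.15, 0.30, 0.45, 0.60} a₀⁻¹ followed by a fine 0.02-step scan
within ±0.15 of the coarse minimum (clipped at γ = 0, ties broken toward
smaller γ).  The fine grid is anchored on the 0.02 lattice so its points
are comparable across rounds and runs.

Also provided: the screened-RSH rule β = 1/ε − α that emulates dielectric
screening of the long-range exchange.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .engine import (
    HARTREE_TO_EV,
    Engine,
    Molecule,
    RSHParams,
    SolvationMode,
    SolventSpec,
)
from .pcm import FrozenSlowField, partition_charges

__all__ = [
    "TuningScheme",
    "LossVariant",
    "IonizationQuantities",
    "GammaScan",
    "TuningResult",
    "j2_loss",
    "ionization_quantities",
    "two_round_minimize",
    "two_round_search",
    "srsh_beta",
    "ROUND1_GRID",
]


class TuningScheme(enum.Enum):
    """Solvation protocol used for the charge-state runs during tuning."""

    GP = "gp"  # gas phase for all states
    PV = "pv"  # equilibrium continuum (static eps) for all states
    SV = "sv"  # equilibrium neutral; nonequilibrium ions with frozen q_slow


class LossVariant(enum.Enum):
    """Which Koopmans residuals enter the tuning loss."""

    FULL = "full"        # both HOMO/IP terms
    IP_ONLY = "ip_only"  # neutral term only
    EA_FORM = "ea_form"  # second term replaced by (eps_LUMO(N) + EA(N))^2


@dataclass(frozen=True)
class IonizationQuantities:
    """Frontier energies entering J² at one γ, in eV.

    ``homo_n`` / ``homo_n1`` are orbital energies of the neutral and the
    anion (negative for bound orbitals); ``ip_n`` / ``ip_n1`` are the ΔSCF
    ionization energies IP(N) = E(N−1) − E(N), IP(N+1) = E(N) − E(N+1),
    each state evaluated under the scheme's solvation mode.  ``lumo_n`` is
    the neutral LUMO energy (used only by the EA-form loss); ``ea_n`` is the
    electron-attachment energy E(N+1) − E(N) = −IP(N+1).
    """

    homo_n: float
    ip_n: float
    homo_n1: float
    ip_n1: float
    lumo_n: float | None = None
    scheme: TuningScheme | None = None
    gamma: float | None = None
    solvent: str | None = None

    def __post_init__(self):
        for name in ("homo_n", "ip_n", "homo_n1", "ip_n1"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")

    @property
    def ea_n(self) -> float:
        """Electron-attachment energy E(N+1) − E(N) in eV."""
        return -self.ip_n1


@dataclass(frozen=True)
class GammaScan:
    """J²(γ) sampled on a strictly increasing γ grid (a₀⁻¹, eV²)."""

    gammas: tuple[float, ...]
    j2: tuple[float, ...]
    quantities: tuple[IonizationQuantities | None, ...] = ()

    def __post_init__(self):
        g = tuple(float(x) for x in self.gammas)
        j = tuple(float(x) for x in self.j2)
        if len(g) != len(j):
            raise ValueError("gammas and j2 must align")
        if any(g[i] >= g[i + 1] for i in range(len(g) - 1)):
            raise ValueError("gamma grid must be strictly increasing")
        if any(x < -1e-12 for x in j):
            raise ValueError("J² must be nonnegative")
        q = self.quantities or tuple([None] * len(g))
        if len(q) != len(g):
            raise ValueError("quantities must align with the grid")
        object.__setattr__(self, "gammas", g)
        object.__setattr__(self, "j2", j)
        object.__setattr__(self, "quantities", tuple(q))

    @property
    def argmin(self) -> float:
        """Grid γ of smallest J²; exact ties resolve to the smaller γ."""
        return self.gammas[int(np.argmin(self.j2))]


@dataclass(frozen=True)
class TuningResult:
    """Outcome of the two-round search, with both scans for provenance."""

    gamma_opt: float
    j2_at_opt: float
    round1: GammaScan
    round2: GammaScan
    scheme: TuningScheme | None = None
    variant: LossVariant = LossVariant.FULL


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def j2_loss(q: IonizationQuantities,
            variant: LossVariant = LossVariant.FULL) -> float:
    """Koopmans residual J² in eV² for one set of frontier quantities.

    FULL: (ε_HOMO(N) + IP(N))² + (ε_HOMO(N+1) + IP(N+1))².
    IP_ONLY: first term only.
    EA_FORM: second term replaced by (ε_LUMO(N) + EA(N))², with
    EA(N) = E(N+1) − E(N).
    """
    first = (q.homo_n + q.ip_n) ** 2
    if variant is LossVariant.IP_ONLY:
        return first
    if variant is LossVariant.EA_FORM:
        if q.lumo_n is None:
            raise ValueError("EA_FORM loss requires lumo_n")
        return first + (q.lumo_n + q.ea_n) ** 2
    return first + (q.homo_n1 + q.ip_n1) ** 2


# ---------------------------------------------------------------------------
# scheme orchestration
# ---------------------------------------------------------------------------


def _annotate(err: Exception, state: str, mode: SolvationMode) -> Exception:
    err.args = (f"[state {state}, mode {mode.tag}] {err.args[0] if err.args else ''}",)
    return err


def ionization_quantities(engine: Engine, molecule: Molecule,
                          params: RSHParams, scheme: TuningScheme,
                          solvent: SolventSpec | None = None,
                          ) -> IonizationQuantities:
    """Run the N, N−1, N+1 states under a tuning scheme and collect J² inputs.

    GP runs all three states in the gas phase (the solvent argument is
    ignored).  PV runs all three in the equilibrium continuum at the static
    ε.  SV runs the neutral in equilibrium, partitions its polarization
    charges into fast and slow components, and runs both ions in the
    nonequilibrium continuum at ε∞ with the neutral's slow charges frozen
    as a fixed external field.
    """
    if molecule.net_charge != 0:
        raise ValueError("tuning starts from a neutral molecule")
    if scheme is not TuningScheme.GP and solvent is None:
        raise ValueError(f"{scheme.value} tuning requires a solvent")

    cation = molecule.with_charge(+1)
    anion = molecule.with_charge(-1)

    if scheme is TuningScheme.GP:
        mode_n = mode_ion = SolvationMode.gas()
    elif scheme is TuningScheme.PV:
        mode_n = mode_ion = SolvationMode.equilibrium(solvent.eps)
    else:  # SV
        mode_n = SolvationMode.equilibrium(solvent.eps)

    try:
        res_n = engine.run_ground_state(molecule, params, mode_n)
    except Exception as err:  # annotate and re-raise
        raise _annotate(err, "N", mode_n)

    if scheme is TuningScheme.SV:
        positions, _q_fast, q_slow = partition_charges(
            res_n.polarization_charges, solvent.eps, solvent.eps_inf)
        frozen = FrozenSlowField(
            positions, q_slow,
            provenance=f"equilibrium neutral run, eps={solvent.eps}, "
                       f"gamma={params.gamma}")
        mode_ion = SolvationMode.nonequilibrium(solvent.eps_inf, frozen)

    try:
        res_cat = engine.run_ground_state(cation, params, mode_ion)
    except Exception as err:
        raise _annotate(err, "N-1", mode_ion)
    try:
        res_an = engine.run_ground_state(anion, params, mode_ion)
    except Exception as err:
        raise _annotate(err, "N+1", mode_ion)

    h2ev = HARTREE_TO_EV
    return IonizationQuantities(
        homo_n=res_n.eps_homo * h2ev,
        ip_n=(res_cat.E_total - res_n.E_total) * h2ev,
        homo_n1=res_an.eps_homo * h2ev,
        ip_n1=(res_n.E_total - res_an.E_total) * h2ev,
        lumo_n=res_n.eps_lumo * h2ev,
        scheme=scheme,
        gamma=params.gamma,
        solvent=solvent.name if solvent is not None else None,
    )


# ---------------------------------------------------------------------------
# two-round grid search
# ---------------------------------------------------------------------------

ROUND1_GRID: tuple[float, ...] = (0.00, 0.15, 0.30, 0.45, 0.60)
_STEP2 = 0.02
_WINDOW = 0.15


def _round2_grid(gamma1: float, step: float = _STEP2,
                 window: float = _WINDOW) -> tuple[float, ...]:
    """Fine grid on [max(0, γ₁ − window), γ₁ + window], 0.02-lattice aligned."""
    lo = max(0.0, gamma1 - window)
    hi = gamma1 + window
    k0 = math.ceil(lo / step - 1e-9)
    k1 = math.floor(hi / step + 1e-9)
    return tuple(round(k * step, 10) for k in range(k0, k1 + 1))


def two_round_minimize(j2_of_gamma: Callable[[float], float],
                       round1: Sequence[float] = ROUND1_GRID,
                       step2: float = _STEP2,
                       window: float = _WINDOW,
                       quantities_of_gamma=None) -> TuningResult:
    """Two-round grid minimization of an arbitrary J²(γ) landscape.

    Round 1 evaluates the coarse grid and takes its argmin γ₁ (ties toward
    smaller γ); round 2 evaluates the 0.02-lattice grid spanning γ₁ ± 0.15
    (clipped at 0) and returns its argmin.  Evaluations are cached by γ so
    overlapping grid points are computed once.
    """
    if len(round1) == 0:
        raise ValueError("round-1 grid must be nonempty")
    cache: dict[float, float] = {}
    qcache: dict[float, IonizationQuantities | None] = {}

    def evaluate(g: float) -> float:
        key = round(g, 10)
        if key not in cache:
            cache[key] = float(j2_of_gamma(key))
            qcache[key] = (quantities_of_gamma(key)
                           if quantities_of_gamma is not None else None)
        return cache[key]

    g1 = tuple(round(float(g), 10) for g in round1)
    scan1 = GammaScan(g1, tuple(evaluate(g) for g in g1),
                      tuple(qcache[round(g, 10)] for g in g1))
    gamma1 = scan1.argmin

    g2 = _round2_grid(gamma1, step2, window)
    scan2 = GammaScan(g2, tuple(evaluate(g) for g in g2),
                      tuple(qcache[round(g, 10)] for g in g2))
    gamma_opt = scan2.argmin
    return TuningResult(gamma_opt=gamma_opt,
                        j2_at_opt=min(scan2.j2),
                        round1=scan1, round2=scan2)


def two_round_search(engine: Engine, molecule: Molecule,
                     scheme: TuningScheme,
                     solvent: SolventSpec | None = None,
                     variant: LossVariant = LossVariant.FULL,
                     params: RSHParams = RSHParams(),
                     round1: Sequence[float] = ROUND1_GRID) -> TuningResult:
    """Find the optimal γ for a molecule under one tuning scheme.

    α and β are taken from ``params`` and held fixed; only γ varies over
    the grids.  Engine failures propagate annotated with the γ already
    completed so a scan can be resumed.
    """
    done: list[float] = []
    qcache: dict[float, IonizationQuantities] = {}

    def quantities(gamma: float) -> IonizationQuantities:
        key = round(gamma, 10)
        if key not in qcache:
            p = replace(params, gamma=key)
            try:
                qcache[key] = ionization_quantities(engine, molecule, p,
                                                    scheme, solvent)
            except Exception as err:
                raise RuntimeError(
                    f"engine failure at gamma={key} "
                    f"(completed grid points: {sorted(done)})"
                ) from err
            done.append(key)
        return qcache[key]

    def j2(gamma: float) -> float:
        return j2_loss(quantities(gamma), variant)

    result = two_round_minimize(j2, round1=round1,
                                quantities_of_gamma=quantities)
    return replace(result, scheme=scheme, variant=variant)


# ---------------------------------------------------------------------------
# screened-RSH rule
# ---------------------------------------------------------------------------


def srsh_beta(alpha: float, eps_target: float, gamma: float = 0.0) -> RSHParams:
    """Screened-RSH parameters with α + β = 1/ε_target.

    Setting the asymptotic exchange fraction to 1/ε emulates the dielectric
    screening of long-range exchange by the environment (use ε∞ as the
    target for optical response).  γ is left to the caller and defaults
    to 0.
    """
    if eps_target < 1:
        raise ValueError("eps_target must be >= 1")
    beta = 1.0 / eps_target - alpha
    if beta < 0:
        raise ValueError(
            f"alpha={alpha} exceeds 1/eps_target={1.0 / eps_target:.4f}; "
            "negative beta is not permitted"
        )
    return RSHParams(alpha=alpha, beta=beta, gamma=gamma)
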