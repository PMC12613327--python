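"""Electronic-structure engine contract and the analytic mock engine.

This module defines the narrow data model every backend must speak —
molecules, range-separated-hybrid parameters, solvation modes, ground-state
and excited-state results — plus an analytic mock engine whose frontier
energetics are affine in the range-separation parameter γ with
dielectric-scaled solvent shifts.  The mock engine lets every downstream
stage (charge partitioning, γ-tuning, diagnostics, spectra) run and be
tested without a quantum-chemistry code.

Units at the engine boundary follow quantum-chemistry convention: total and
orbital energies in hartree, geometry in Å, excitation energies in eV,
dipoles in Debye.  Consumer modules convert hartree to eV exactly once.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "HARTREE_TO_EV",
    "BOHR_TO_ANGSTROM",
    "Molecule",
    "RSHParams",
    "SolventSpec",
    "SolvationMode",
    "GroundStateResult",
    "ExcitationSet",
    "DensityGrid",
    "MockLinearModel",
    "MockEngineSpec",
    "MockEngine",
    "mock_quantities",
    "EngineError",
    "ConvergenceError",
    "UnsupportedElementError",
    "read_xyz",
    "write_xyz",
    "read_cube",
    "write_cube",
    "get_engine",
    "register_engine",
]

# ---------------------------------------------------------------------------
# constants and element data
# ---------------------------------------------------------------------------

HARTREE_TO_EV = 27.211386
BOHR_TO_ANGSTROM = 0.52917721092

#: atomic numbers for the elements the toolkit knows about (organic set plus
#: halogens and a few common heteroatoms; adapters may extend this)
ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Zn": 30, "Br": 35,
    "I": 53,
}


class EngineError(RuntimeError):
    """Base class for failures raised by an electronic-structure backend."""


class ConvergenceError(EngineError):
    """SCF or response convergence failure, carrying iteration diagnostics."""

    def __init__(self, message: str, iterations: int | None = None,
                 residual: float | None = None):
        super().__init__(message)
        self.iterations = iterations
        self.residual = residual


class UnsupportedElementError(EngineError):
    """The backend has no parameters for an element in the molecule."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Molecule:
    """A molecular geometry with net charge and spin multiplicity.

    ``atoms`` is a sequence of ``(element symbol, (x, y, z))`` tuples with
    coordinates in Å.  ``net_charge`` counts removed electrons (+1 for a
    cation, −1 for an anion).  Electron count and multiplicity must have
    consistent parity (even electron count ⇔ odd multiplicity).
    """

    atoms: tuple[tuple[str, tuple[float, float, float]], ...]
    net_charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        if len(self.atoms) == 0:
            raise ValueError("molecule must contain at least one atom")
        norm: list[tuple[str, tuple[float, float, float]]] = []
        for sym, xyz in self.atoms:
            sym = str(sym).capitalize()
            if sym not in ATOMIC_NUMBERS:
                raise UnsupportedElementError(f"unknown element symbol {sym!r}")
            xyz = tuple(float(c) for c in xyz)
            if len(xyz) != 3 or not all(math.isfinite(c) for c in xyz):
                raise ValueError(f"non-finite or non-3D coordinates for {sym}: {xyz}")
            norm.append((sym, xyz))
        object.__setattr__(self, "atoms", tuple(norm))
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be a positive integer")
        if (self.n_electrons + self.multiplicity) % 2 != 1:
            raise ValueError(
                f"{self.n_electrons} electrons is inconsistent with "
                f"multiplicity {self.multiplicity}"
            )

    @property
    def n_electrons(self) -> int:
        return sum(ATOMIC_NUMBERS[s] for s, _ in self.atoms) - self.net_charge

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of Cartesian coordinates in Å."""
        return np.array([xyz for _, xyz in self.atoms], dtype=float)

    def geometric_center(self) -> np.ndarray:
        return self.coordinates.mean(axis=0)

    def translated(self, shift: Sequence[float]) -> "Molecule":
        shift = np.asarray(shift, dtype=float)
        atoms = tuple(
            (s, tuple(np.asarray(xyz) + shift)) for s, xyz in self.atoms
        )
        return replace(self, atoms=atoms)

    def recentered(self) -> "Molecule":
        """Translate so the geometric center sits at the origin."""
        return self.translated(-self.geometric_center())

    def with_charge(self, net_charge: int) -> "Molecule":
        """Return the same geometry with a different net charge.

        The multiplicity is reset to the lowest spin state of consistent
        parity (singlet for even electron counts, doublet for odd).
        """
        n_e = sum(ATOMIC_NUMBERS[s] for s, _ in self.atoms) - net_charge
        mult = 1 if n_e % 2 == 0 else 2
        return replace(self, net_charge=net_charge, multiplicity=mult)


@dataclass(frozen=True)
class RSHParams:
    """Range-separated hybrid parameters (α, β, γ).

    The Coulomb operator is split with an error function at range 1/γ:
    the short-range Fock fraction is α and the long-range fraction tends to
    α + β, so α + β = 1 restores the full long-range exchange needed for
    correct −1/r asymptotics.  γ is in inverse Bohr (a₀⁻¹).  Defaults are
    the ωPBEh values (0.2, 0.8, 0.2).
    """

    alpha: float = 0.2
    beta: float = 0.8
    gamma: float = 0.2

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 <= self.alpha + self.beta <= 1.0 + 1e-12:
            raise ValueError("alpha + beta must lie in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass(frozen=True)
class SolventSpec:
    """A solvent's static (ε) and optical (ε∞ = n²) dielectric constants."""

    name: str
    eps: float
    eps_inf: float

    def __post_init__(self):
        if not (1.0 <= self.eps_inf <= self.eps):
            raise ValueError(
                f"require 1 <= eps_inf <= eps, got eps_inf={self.eps_inf}, "
                f"eps={self.eps}"
            )


@dataclass(frozen=True)
class SolvationMode:
    """Gas phase, equilibrium continuum, or nonequilibrium continuum.

    In equilibrium mode the continuum with static ε is fully relaxed.  In
    nonequilibrium mode only the fast (electronic, ε∞) polarization responds;
    an optional frozen slow-charge field (from a previous equilibrium run of
    another charge state) is applied as a fixed external potential.
    Nonequilibrium without a frozen field is legal — that is the
    linear-response excited-state solvation used for TDDFT.
    """

    tag: str  # "gas" | "equilibrium" | "nonequilibrium"
    eps: float | None = None
    eps_inf: float | None = None
    frozen_field: "object | None" = None  # pcm.FrozenSlowField

    def __post_init__(self):
        if self.tag not in ("gas", "equilibrium", "nonequilibrium"):
            raise ValueError(f"unknown solvation tag {self.tag!r}")
        if self.tag == "gas":
            if self.eps is not None or self.eps_inf is not None:
                raise ValueError("gas mode carries no dielectric constant")
        elif self.tag == "equilibrium":
            if self.eps is None or self.eps < 1:
                raise ValueError("equilibrium mode requires eps >= 1")
        else:
            if self.eps_inf is None or self.eps_inf < 1:
                raise ValueError("nonequilibrium mode requires eps_inf >= 1")

    # constructors ----------------------------------------------------------
    @staticmethod
    def gas() -> "SolvationMode":
        return SolvationMode("gas")

    @staticmethod
    def equilibrium(eps: float) -> "SolvationMode":
        return SolvationMode("equilibrium", eps=eps)

    @staticmethod
    def nonequilibrium(eps_inf: float, frozen_field=None) -> "SolvationMode":
        return SolvationMode("nonequilibrium", eps_inf=eps_inf,
                             frozen_field=frozen_field)

    @property
    def is_continuum(self) -> bool:
        return self.tag != "gas"

    @property
    def active_eps(self) -> float | None:
        """The dielectric constant the continuum responds with (ε or ε∞)."""
        if self.tag == "equilibrium":
            return self.eps
        if self.tag == "nonequilibrium":
            return self.eps_inf
        return None


@dataclass(frozen=True)
class DensityGrid:
    """Scalar field on an orthogonal rectangular grid.

    ``origin`` (Å), per-axis ``steps`` (Å) and integer ``counts`` define the
    lattice; ``values`` holds the samples in C order (x slowest), either flat
    or shaped ``counts``.  Densities are in e·Å⁻³, orbitals in amplitude
    units (Å⁻³ᐟ²).
    """

    origin: tuple[float, float, float]
    steps: tuple[float, float, float]
    counts: tuple[int, int, int]
    values: np.ndarray

    def __post_init__(self):
        origin = tuple(float(c) for c in self.origin)
        steps = tuple(float(c) for c in self.steps)
        counts = tuple(int(c) for c in self.counts)
        if any(s <= 0 for s in steps):
            raise ValueError("grid steps must be positive")
        if any(c < 1 for c in counts):
            raise ValueError("grid counts must be >= 1")
        values = np.asarray(self.values, dtype=float)
        if values.size != counts[0] * counts[1] * counts[2]:
            raise ValueError(
                f"value count {values.size} does not match grid "
                f"{counts[0]}x{counts[1]}x{counts[2]}"
            )
        values = values.reshape(counts)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "steps", steps)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "values", values)

    @property
    def dvol(self) -> float:
        """Volume element in Å³."""
        return self.steps[0] * self.steps[1] * self.steps[2]

    def points(self) -> np.ndarray:
        """(n_points, 3) array of grid-point coordinates in Å, C order."""
        axes = [
            self.origin[i] + self.steps[i] * np.arange(self.counts[i])
            for i in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    def integral(self) -> float:
        """Riemann-sum integral of the field over the grid."""
        return float(self.values.sum() * self.dvol)


@dataclass(frozen=True)
class GroundStateResult:
    """Converged ground-state energetics from one engine run.

    Energies are in hartree.  ``polarization_charges`` is a list of
    ``(position Å, charge e)`` apparent surface charges, empty if and only
    if the run was gas phase.
    """

    E_total: float
    eps_homo: float
    eps_lumo: float
    polarization_charges: tuple[tuple[tuple[float, float, float], float], ...] = ()
    density_grid: DensityGrid | None = None

    def __post_init__(self):
        for name in ("E_total", "eps_homo", "eps_lumo"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")


@dataclass(frozen=True)
class ExcitationSet:
    """Vertical excitations: energies (eV), oscillator strengths, dipoles (D).

    States are ordered by ascending energy; energies must be strictly
    positive.  ``dipoles`` holds the unrelaxed excited-state dipole vector of
    each state.
    """

    energies: tuple[float, ...]
    oscillator_strengths: tuple[float, ...]
    dipoles: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        e = tuple(float(x) for x in self.energies)
        f = tuple(float(x) for x in self.oscillator_strengths)
        d = tuple(tuple(float(c) for c in v) for v in self.dipoles)
        if not (len(e) == len(f) == len(d)):
            raise ValueError("energies, strengths and dipoles must align")
        if len(e) == 0:
            raise ValueError("excitation set must contain at least one state")
        if any(x <= 0 for x in e):
            raise ValueError("excitation energies must be strictly positive")
        if any(e[i] > e[i + 1] for i in range(len(e) - 1)):
            raise ValueError("excitation energies must be nondecreasing")
        if any(x < 0 for x in f):
            raise ValueError("oscillator strengths must be >= 0")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "oscillator_strengths", f)
        object.__setattr__(self, "dipoles", d)

    def __len__(self) -> int:
        return len(self.energies)

    def truncated(self, n: int) -> "ExcitationSet":
        return ExcitationSet(self.energies[:n], self.oscillator_strengths[:n],
                             self.dipoles[:n])


# ---------------------------------------------------------------------------
# engine protocol
# ---------------------------------------------------------------------------


@runtime_checkable
class Engine(Protocol):
    """The contract every electronic-structure backend satisfies.

    Implementations must be deterministic: repeated identical calls return
    identical results.
    """

    def run_ground_state(self, molecule: Molecule, params: RSHParams,
                         solvation: SolvationMode) -> GroundStateResult: ...

    def run_excited_states(self, molecule: Molecule, params: RSHParams,
                           solvation: SolvationMode,
                           n_states: int = 10) -> ExcitationSet: ...


# ---------------------------------------------------------------------------
# mock engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MockLinearModel:
    """Affine model q(γ) = intercept + slope·γ (eV, eV·a₀)."""

    intercept: float
    slope: float

    def __call__(self, gamma: float) -> float:
        return self.intercept + self.slope * gamma


#: default fixed excitation table for the mock engine: a bright S2 dye-like
#: spectrum with a CT-flavored S3 (large y-dipole).  Fixture values.
_DEFAULT_MOCK_STATES = ExcitationSet(
    energies=(2.60, 3.10, 3.45, 3.90, 4.20, 4.55, 4.80, 5.05, 5.30, 5.60),
    oscillator_strengths=(0.02, 0.85, 0.10, 0.30, 0.00, 0.12, 0.40, 0.05,
                          0.22, 0.08),
    dipoles=(
        (1.0, 2.0, 0.5), (0.5, 4.0, 1.0), (0.2, 15.0, 0.3),
        (1.5, 3.0, 0.8), (0.1, 1.0, 0.1), (2.0, 5.0, 1.2),
        (0.8, 2.5, 0.4), (0.3, 13.5, 0.2), (1.1, 3.2, 0.6),
        (0.4, 1.8, 0.9),
    ),
)


@dataclass(frozen=True)
class MockEngineSpec:
    """Parameters of the analytic mock engine.

    Gas-phase −ε_HOMO and IP for the neutral (N) and anionic (N+1) charge
    states are affine in γ; default slopes are the dataset-average values
    10.16, 8.56, 1.31, −0.49 eV·a₀ for −ε_HOMO(N), −ε_HOMO(N+1), IP(N),
    IP(N+1).  Continuum solvation adds a shift calibrated at a reference
    solvent (defaults: DCM, ε_ref = 8.93; +0.07, +2.66, −1.19, +1.39 eV for
    the same four quantities) and scaled to other dielectrics by the Onsager
    factor ratio [(ε−1)/ε] / [(ε_ref−1)/ε_ref].  Nonequilibrium solvation
    scales with ε∞ in place of ε — equivalent to an equilibrium solvent of
    that smaller dielectric constant.

    Intercepts are fixtures chosen so both gas-phase Koopmans crossings sit
    near γ ≈ 0.15 a₀⁻¹; they are configurable.
    """

    neg_homo_n: MockLinearModel = MockLinearModel(6.00, 10.16)
    ip_n: MockLinearModel = MockLinearModel(7.33, 1.31)
    neg_homo_n1: MockLinearModel = MockLinearModel(-0.50, 8.56)
    ip_n1: MockLinearModel = MockLinearModel(0.85, -0.49)
    shift_neg_homo_n: float = 0.07
    shift_ip_n: float = -1.19
    shift_neg_homo_n1: float = 2.66
    shift_ip_n1: float = 1.39
    eps_ref: float = 8.93
    excitations: ExcitationSet = _DEFAULT_MOCK_STATES
    n_surface_points: int = 64

    def dielectric_scale(self, solvation: SolvationMode) -> float:
        """Shift scale factor: 0 in gas, 1 at the reference solvent."""
        eps = solvation.active_eps
        if eps is None:
            return 0.0
        onsager = (eps - 1.0) / eps
        ref = (self.eps_ref - 1.0) / self.eps_ref
        return onsager / ref


def mock_quantities(spec: MockEngineSpec, state: str, gamma: float,
                    solvation: SolvationMode) -> tuple[float, float]:
    """Mock (−ε_HOMO, IP) in eV for charge state ``state`` ∈ {"N", "N+1"}.

    Each quantity is its gas-phase affine value in γ plus the reference
    solvent shift scaled by the mode's dielectric factor.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    scale = spec.dielectric_scale(solvation)
    if state == "N":
        return (spec.neg_homo_n(gamma) + spec.shift_neg_homo_n * scale,
                spec.ip_n(gamma) + spec.shift_ip_n * scale)
    if state == "N+1":
        return (spec.neg_homo_n1(gamma) + spec.shift_neg_homo_n1 * scale,
                spec.ip_n1(gamma) + spec.shift_ip_n1 * scale)
    raise ValueError(f"unknown charge state {state!r} (want 'N' or 'N+1')")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


class MockEngine:
    """Analytic stand-in for a DFT/TDDFT backend.

    Total energies are built so that the energy differences the tuning
    module forms reproduce :func:`mock_quantities` exactly for every scheme,
    including mixed-mode differences (neutral in equilibrium, ion in
    nonequilibrium): the neutral total energy is the zero of energy in every
    mode, the cation carries +IP(N) and the anion −IP(N+1), each with its
    mode-scaled solvent shift.  Apparent surface charges are generated on a
    deterministic spherical cavity so the fast/slow partitioning machinery
    has realistic input.  All outputs are pure functions of the inputs.
    """

    name = "mock"

    def __init__(self, spec: MockEngineSpec | None = None):
        self.spec = spec if spec is not None else MockEngineSpec()

    # -- ground state -------------------------------------------------------
    def run_ground_state(self, molecule: Molecule, params: RSHParams,
                         solvation: SolvationMode) -> GroundStateResult:
        spec = self.spec
        gamma = params.gamma
        scale = spec.dielectric_scale(solvation)
        q = molecule.net_charge

        if q == 0:
            neg_homo = spec.neg_homo_n(gamma) + spec.shift_neg_homo_n * scale
            # LUMO(N) modelled as the anion-HOMO level of the same system
            neg_lumo = spec.neg_homo_n1(gamma) + spec.shift_neg_homo_n1 * scale
            e_total_ev = 0.0
            eps_homo = -neg_homo / HARTREE_TO_EV
            eps_lumo = -neg_lumo / HARTREE_TO_EV
        elif q == 1:
            # cation: E(N-1) - E(N) = IP(N) by construction
            e_total_ev = spec.ip_n(gamma) + spec.shift_ip_n * scale
            # deep closed-shell-like HOMO; fixture filler, not used by J²
            eps_homo = -(spec.neg_homo_n(gamma) + spec.shift_neg_homo_n * scale
                         + 5.0) / HARTREE_TO_EV
            eps_lumo = eps_homo + 0.15
        elif q == -1:
            # anion: E(N) - E(N+1) = IP(N+1) by construction
            e_total_ev = -(spec.ip_n1(gamma) + spec.shift_ip_n1 * scale)
            eps_homo = -(spec.neg_homo_n1(gamma)
                         + spec.shift_neg_homo_n1 * scale) / HARTREE_TO_EV
            eps_lumo = eps_homo + 0.15
        else:
            raise EngineError(
                f"mock engine models net charges -1, 0, +1; got {q:+d}"
            )

        charges = self._surface_charges(molecule, solvation)
        return GroundStateResult(
            E_total=e_total_ev / HARTREE_TO_EV,
            eps_homo=eps_homo,
            eps_lumo=eps_lumo,
            polarization_charges=charges,
        )

    def _surface_charges(self, molecule: Molecule, solvation: SolvationMode):
        """Deterministic apparent surface charges on a spherical cavity."""
        if not solvation.is_continuum:
            return ()
        eps = solvation.active_eps
        f = (eps - 1.0) / eps
        coords = molecule.coordinates
        center = coords.mean(axis=0)
        radius = float(np.linalg.norm(coords - center, axis=1).max()) + 1.68
        n = self.spec.n_surface_points
        unit = _fibonacci_sphere(n)
        # monopole response to the net charge plus a small dipolar pattern
        zcomp = unit[:, 2] - unit[:, 2].mean()
        q = f * (-molecule.net_charge / n + 0.005 * zcomp)
        positions = center[None, :] + radius * unit
        return tuple(
            ((float(p[0]), float(p[1]), float(p[2])), float(c))
            for p, c in zip(positions, q)
        )

    # -- excited states -----------------------------------------------------
    def run_excited_states(self, molecule: Molecule, params: RSHParams,
                           solvation: SolvationMode,
                           n_states: int = 10) -> ExcitationSet:
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        table = self.spec.excitations
        if n_states > len(table):
            raise EngineError(
                f"mock state table holds {len(table)} states; "
                f"{n_states} requested"
            )
        return table.truncated(n_states)


# ---------------------------------------------------------------------------
# engine registry
# ---------------------------------------------------------------------------

_ENGINES: dict[str, type] = {}


def register_engine(name: str, factory) -> None:
    """Register an engine adapter under a config key."""
    _ENGINES[name.lower()] = factory


def get_engine(name: str, **kwargs) -> Engine:
    """Instantiate an engine by its config key (``engine: mock | <adapter>``)."""
    try:
        factory = _ENGINES[name.lower()]
    except KeyError:
        known = ", ".join(sorted(_ENGINES))
        raise KeyError(f"unknown engine {name!r}; registered engines: {known}")
    return factory(**kwargs)


register_engine("mock", MockEngine)


# ---------------------------------------------------------------------------
# file formats: XYZ and Gaussian cube
# ---------------------------------------------------------------------------


def read_xyz(path: str | Path, net_charge: int = 0,
             multiplicity: int | None = None) -> Molecule:
    """Read a standard two-header-line XYZ file (coordinates in Å)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: not an XYZ file (fewer than 2 lines)")
    n = int(lines[0].split()[0])
    body = lines[2:2 + n]
    if len(body) < n:
        raise ValueError(f"{path}: header promises {n} atoms, found {len(body)}")
    atoms = []
    for ln in body:
        parts = ln.split()
        atoms.append((parts[0], (float(parts[1]), float(parts[2]),
                                 float(parts[3]))))
    if multiplicity is None:
        n_e = sum(ATOMIC_NUMBERS[s.capitalize()] for s, _ in atoms) - net_charge
        multiplicity = 1 if n_e % 2 == 0 else 2
    return Molecule(tuple(atoms), net_charge=net_charge,
                    multiplicity=multiplicity)


def write_xyz(molecule: Molecule, path: str | Path, comment: str = "") -> None:
    """Write a standard XYZ file (Å)."""
    out = [str(len(molecule.atoms)), comment.replace("\n", " ")]
    for sym, (x, y, z) in molecule.atoms:
        out.append(f"{sym:<2s} {x:15.8f} {y:15.8f} {z:15.8f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_cube(path: str | Path) -> tuple[DensityGrid, Molecule]:
    """Read a Gaussian cube file into a grid (Å) and the molecule it carries.

    Cube files store lengths in Bohr and densities per Bohr³; both are
    converted to Å conventions in memory.  Only orthogonal axes are
    supported.
    """
    with open(path) as fh:
        fh.readline()
        fh.readline()
        parts = fh.readline().split()
        natoms = int(parts[0])
        origin = np.array([float(x) for x in parts[1:4]]) * BOHR_TO_ANGSTROM
        counts, steps = [], []
        for axis in range(3):
            parts = fh.readline().split()
            counts.append(int(parts[0]))
            vec = np.array([float(x) for x in parts[1:4]])
            nonzero = np.nonzero(np.abs(vec) > 1e-12)[0]
            if len(nonzero) != 1 or nonzero[0] != axis:
                raise ValueError(f"{path}: non-orthogonal cube axes unsupported")
            steps.append(vec[axis] * BOHR_TO_ANGSTROM)
        atoms = []
        for _ in range(abs(natoms)):
            parts = fh.readline().split()
            z = int(parts[0])
            sym = {v: k for k, v in ATOMIC_NUMBERS.items()}[z]
            pos = tuple(float(x) * BOHR_TO_ANGSTROM for x in parts[2:5])
            atoms.append((sym, pos))
        values = np.array(fh.read().split(), dtype=float)
    values = values / BOHR_TO_ANGSTROM ** 3  # e/Bohr³ -> e/Å³
    grid = DensityGrid(tuple(origin), tuple(steps),
                       tuple(counts), values)
    return grid, Molecule(tuple(atoms))


def write_cube(grid: DensityGrid, molecule: Molecule,
               path: str | Path, comment: str = "solvtune grid") -> None:
    """Write a Gaussian cube file (Bohr units on disk)."""
    b = BOHR_TO_ANGSTROM
    lines = [comment, "scalar field"]
    o = [c / b for c in grid.origin]
    lines.append(f"{len(molecule.atoms):5d} {o[0]:12.6f} {o[1]:12.6f} {o[2]:12.6f}")
    for axis in range(3):
        vec = [0.0, 0.0, 0.0]
        vec[axis] = grid.steps[axis] / b
        lines.append(f"{grid.counts[axis]:5d} {vec[0]:12.6f} {vec[1]:12.6f} "
                     f"{vec[2]:12.6f}")
    for sym, xyz in molecule.atoms:
        z = ATOMIC_NUMBERS[sym]
        x, y, zz = (c / b for c in xyz)
        lines.append(f"{z:5d} {float(z):12.6f} {x:12.6f} {y:12.6f} {zz:12.6f}")
    vals = (grid.values * b ** 3).ravel()  # e/Å³ -> e/Bohr³
    for i in range(0, len(vals), 6):
        lines.append(" ".join(f"{v:13.5E}" for v in vals[i:i + 6]))
    Path(path).write_text("\n".join(lines) + "\n")
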