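"""Shared domain types for generalized-Born (GB) electrostatic analysis.

The GB model describes a solute as a set of charged spheres embedded in a
high-dielectric continuum (water).  Each sphere carries a partial charge ``q``
(units of the elementary charge *e*) and an *intrinsic radius* ``rho`` (Å),
the lower limit of the spatial integral of the electric-field energy density
that defines the dielectric boundary.  This module holds the atom/system
containers, the GB configuration, the per-class radius tables, and the
inter-molecular pair partition used by the interaction-energy sums.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Electrostatic conversion constant, kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.0636

#: Gas constant, kcal/(mol·K).
GAS_CONSTANT = 0.0019872

#: Van der Waals (Bondi) radii in Å, as rounded in common biomolecular GB
#: parameter sets (oxygen 1.5 Å rather than the crystallographic 1.52 Å).
BONDI_RADII: dict[str, float] = {
    "H": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.5,
    "S": 1.8,
    "P": 1.85,
}

#: The mBondi2 variant: Bondi radii with nitrogen-bonded hydrogens at 1.3 Å.
MBONDI2_RADII: dict[str, float] = {**BONDI_RADII, "H-on-N": 1.3}

#: Default class->radius table used by the synthetic builders.  Class labels
#: are free tokens; these entries cover the classes the builders emit.
DEFAULT_RADII: dict[str, float] = {
    **MBONDI2_RADII,
    "O-carboxyl": 1.5,
    "bead": 1.8,
}


@dataclass(frozen=True, eq=False)
class AtomSite:
    """One charged sphere: position, partial charge, intrinsic radius.

    Parameters
    ----------
    atom_id : str
        Opaque unique identifier.
    class_label : str
        Token naming the parameterization class (element plus bonded
        context, e.g. ``"H-on-N"``, ``"O-carboxyl"``).  Radius overrides
        address atoms through this label.
    position : array-like, shape (3,)
        Cartesian coordinates in Å.
    charge : float
        Partial charge in units of the elementary charge *e*.
    intrinsic_radius : float
        The GB atomic radius rho in Å (> 0).
    descreen_scale : float
        Dimensionless factor applied to this atom's radius when it acts as a
        descreening sphere for other atoms (HCT-style scale factor);
        default 1.0.
    lj_rmin_half : float, optional
        Lennard-Jones rmin/2 in Å (caller supplied).
    lj_epsilon : float, optional
        Lennard-Jones well depth in kcal/mol (caller supplied).
    molecule_tag : str
        Token identifying the molecule the atom belongs to; drives the
        intra/inter-molecular partition.
    """

    atom_id: str
    class_label: str
    position: np.ndarray
    charge: float
    intrinsic_radius: float
    descreen_scale: float = 1.0
    lj_rmin_half: Optional[float] = None
    lj_epsilon: Optional[float] = None
    molecule_tag: str = "A"

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_id!r}: non-finite position {pos}")
        pos.setflags(write=False)
        object.__setattr__(self, "position", pos)
        if not (math.isfinite(self.intrinsic_radius) and self.intrinsic_radius > 0):
            raise ValueError(
                f"atom {self.atom_id!r}: intrinsic_radius must be positive and "
                f"finite, got {self.intrinsic_radius}"
            )
        if not self.descreen_scale > 0:
            raise ValueError(
                f"atom {self.atom_id!r}: descreen_scale must be > 0, "
                f"got {self.descreen_scale}"
            )

    def with_radius(self, rho: float) -> "AtomSite":
        """Return a copy with a new intrinsic radius."""
        return replace(self, intrinsic_radius=rho)

    @property
    def has_lj(self) -> bool:
        return self.lj_rmin_half is not None and self.lj_epsilon is not None


@dataclass(frozen=True, eq=False)
class MolecularSystem:
    """An ordered collection of :class:`AtomSite` with an optional reaction
    coordinate.

    ``separation`` is the system's scalar reaction coordinate *d* in Å, with
    ``separation_definition`` declaring what it measures (an atom-atom
    distance or a center-of-mass distance between molecule tags).
    """

    atoms: tuple[AtomSite, ...]
    separation: Optional[float] = None
    separation_definition: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        if len(self.atoms) == 0:
            raise ValueError("MolecularSystem needs at least one atom")
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate atom_ids: {dup}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def intrinsic_radii(self) -> np.ndarray:
        return np.array([a.intrinsic_radius for a in self.atoms], dtype=float)

    @property
    def descreen_scales(self) -> np.ndarray:
        return np.array([a.descreen_scale for a in self.atoms], dtype=float)

    @property
    def molecule_tags(self) -> tuple[str, ...]:
        return tuple(a.molecule_tag for a in self.atoms)

    @property
    def atom_ids(self) -> tuple[str, ...]:
        return tuple(a.atom_id for a in self.atoms)

    @property
    def class_labels(self) -> tuple[str, ...]:
        return tuple(a.class_label for a in self.atoms)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances, Å, shape (N, N)."""
        pos = self.positions
        diff = pos[:, None, :] - pos[None, :, :]
        return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))

    def molecule_count(self) -> int:
        return len(set(self.molecule_tags))


@dataclass(frozen=True)
class GBConfig:
    """Configuration of the GB evaluation.

    Parameters
    ----------
    epsilon_w : float
        Bulk water dielectric constant (default 78.5).
    rmax : float
        Outer cutoff of the descreening integral, Å.  The default 999 Å is
        effectively no cutoff for molecular systems.
    coulomb_constant : float
        Electrostatic conversion constant, kcal·Å/(mol·e²).
    born_mode : {"plain", "obc2"}
        ``plain``: 1/R = 1/rho - I.  ``obc2``: tanh-rescaled Born radius of
        the OBC model (second parameter set), using ``obc_coefficients``.
    obc_coefficients : tuple (alpha, beta, gamma, offset)
        OBC(II) coefficients; offset in Å is subtracted from the intrinsic
        radius before integration.  Defaults (1.0, 0.8, 4.85, 0.09).
    radius_overrides : mapping class_label -> rho (Å)
        Per-class intrinsic-radius overrides applied when Born radii are
        computed; this is the handle the rho parameter scans use.
    rmax_mode : {"clip", "drop"}
        ``clip``: each descreening sphere is geometrically clipped at the
        outer shell |r| = rmax (default).  ``drop``: descreening atoms whose
        center lies beyond rmax are dropped whole; the rest are integrated
        without outer clipping.
    temperature : float
        Temperature in K for thermal quantities (default 300).
    """

    epsilon_w: float = 78.5
    rmax: float = 999.0
    coulomb_constant: float = COULOMB_CONSTANT
    born_mode: str = "plain"
    obc_coefficients: tuple[float, float, float, float] = (1.0, 0.8, 4.85, 0.09)
    radius_overrides: Mapping[str, float] = field(default_factory=dict)
    rmax_mode: str = "clip"
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if not self.epsilon_w > 1:
            raise ValueError(f"epsilon_w must be > 1, got {self.epsilon_w}")
        if not self.rmax > 0:
            raise ValueError(f"rmax must be > 0, got {self.rmax}")
        if not self.coulomb_constant > 0:
            raise ValueError("coulomb_constant must be > 0")
        if self.born_mode not in ("plain", "obc2"):
            raise ValueError(f"born_mode must be 'plain' or 'obc2', got {self.born_mode!r}")
        if self.rmax_mode not in ("clip", "drop"):
            raise ValueError(f"rmax_mode must be 'clip' or 'drop', got {self.rmax_mode!r}")
        if len(self.obc_coefficients) != 4:
            raise ValueError("obc_coefficients must be (alpha, beta, gamma, offset)")
        for label, rho in dict(self.radius_overrides).items():
            if not rho > 0:
                raise ValueError(f"override radius for {label!r} must be > 0, got {rho}")
        object.__setattr__(self, "radius_overrides", dict(self.radius_overrides))
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GBConfig):
            return NotImplemented
        return self.as_dict() == other.as_dict()

    def as_dict(self) -> dict:
        return {
            "epsilon_w": self.epsilon_w,
            "rmax": self.rmax,
            "coulomb_constant": self.coulomb_constant,
            "born_mode": self.born_mode,
            "obc_coefficients": tuple(self.obc_coefficients),
            "radius_overrides": dict(self.radius_overrides),
            "rmax_mode": self.rmax_mode,
            "temperature": self.temperature,
        }

    def effective_rho(self, atom: AtomSite) -> float:
        """Intrinsic radius of ``atom`` after class overrides."""
        return float(self.radius_overrides.get(atom.class_label, atom.intrinsic_radius))


def assign_radii(
    system: MolecularSystem,
    table: Mapping[str, float],
    overrides: Optional[Mapping[str, float]] = None,
) -> MolecularSystem:
    """Assign intrinsic radii from a class table, with per-class overrides.

    Every atom's ``class_label`` must resolve in ``overrides`` (first) or
    ``table``; the resolved radius replaces ``intrinsic_radius`` and all
    other fields are untouched.  Idempotent for fixed table/overrides.

    Raises
    ------
    KeyError
        If a class label resolves in neither mapping.
    ValueError
        If a resolved radius is not positive.
    """
    overrides = dict(overrides or {})
    new_atoms = []
    for atom in system.atoms:
        label = atom.class_label
        if label in overrides:
            rho = overrides[label]
        elif label in table:
            rho = table[label]
        else:
            raise KeyError(f"no radius for class label {label!r} (atom {atom.atom_id!r})")
        if not rho > 0:
            raise ValueError(f"radius for class {label!r} must be > 0, got {rho}")
        new_atoms.append(atom.with_radius(float(rho)))
    return replace(system, atoms=tuple(new_atoms))


def interaction_pairs(system: MolecularSystem) -> list[tuple[int, int]]:
    """Indices (i, j), i < j, of all atom pairs with distinct molecule tags.

    These are the cross-molecule pairs the interaction-energy sums run over;
    intra-molecular pairs are excluded.  For two molecules of N_A and N_B
    atoms the count is N_A * N_B.

    Raises
    ------
    ValueError
        If the system has fewer than two distinct molecule tags (the
        interaction energy is undefined).
    """
    tags = system.molecule_tags
    if len(set(tags)) < 2:
        raise ValueError(
            "interaction_pairs requires >= 2 distinct molecule_tags; "
            f"got {sorted(set(tags))}"
        )
    n = system.n_atoms
    return [(i, j) for i in range(n) for j in range(i + 1, n) if tags[i] != tags[j]]
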