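"""GB energy terms: self (desolvation), interaction, totals, and optional LJ.

Conventions
-----------
Energies in kcal/mol, distances in Å, charges in units of *e*.  The solute
interior dielectric is 1; water enters only through ``epsilon_w``.  The
desolvation energy of atom *i* is its GB self energy at the current geometry
relative to the fully solvated (infinite-separation) atom, whose effective
Born radius equals its intrinsic radius (minus the OBC offset in obc2 mode).
The interaction energy runs over cross-molecule pairs only; intra-molecular
pairs contribute to desolvation (through descreening) but not to G_int.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .descreening import BornRadiusResult, born_radii, isolated_radius
from .model import GBConfig, MolecularSystem, interaction_pairs

__all__ = [
    "f_gb",
    "gb_self_energy",
    "desolvation_energies",
    "interaction_energy",
    "total_gb_energy",
    "lj_energy",
    "energy_breakdown",
    "EnergyBreakdown",
    "InteractionEnergy",
]


def f_gb(d, r_i, r_j):
    """The GB effective interaction distance.

    f_gb = sqrt(d^2 + R_i R_j exp(-d^2 / (4 R_i R_j))).

    Symmetric in (i, j); equals sqrt(R_i R_j) at d = 0 and approaches d from
    above at large separation.  Accepts scalars or broadcastable arrays.
    """
    d = np.asarray(d, dtype=float)
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    if np.any(r_i <= 0) or np.any(r_j <= 0):
        raise ValueError("effective Born radii must be positive")
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    prod = r_i * r_j
    val = np.sqrt(d * d + prod * np.exp(-(d * d) / (4.0 * prod)))
    return float(val) if val.ndim == 0 else val


def gb_self_energy(q, radius, config: GBConfig):
    """GB (Born) self energy (1/eps_w - 1) k q^2 / (2 R), kcal/mol.

    Non-positive for eps_w > 1; its magnitude shrinks as the effective Born
    radius grows (a buried charge loses solvation energy).
    """
    q = np.asarray(q, dtype=float)
    radius = np.asarray(radius, dtype=float)
    if np.any(radius <= 0):
        raise ValueError("radius must be positive")
    val = (1.0 / config.epsilon_w - 1.0) * config.coulomb_constant * q * q / (2.0 * radius)
    return float(val) if val.ndim == 0 else val


def _check_config(born: BornRadiusResult, config: GBConfig) -> None:
    if born.config != config:
        raise ValueError(
            "GBConfig mismatch: Born radii were computed with a different "
            "configuration than the one passed for the energy evaluation"
        )


def desolvation_energies(
    system: MolecularSystem, born: BornRadiusResult, config: GBConfig
) -> tuple[np.ndarray, float]:
    """Per-atom and total desolvation energies, kcal/mol.

    Delta G_self[i] = G_self(q_i, R_i(d)) - G_self(q_i, R_i(inf)).  The
    infinite-separation reference is the intact molecules fully solvated and
    infinitely far apart: the reference Born radii are computed analytically
    at the same geometry with the descreening sum restricted to
    same-molecule pairs (no large-d numerical evaluation).  For single-atom
    molecules, such as the two-atom system, this reduces exactly to
    R_i(inf) = rho_i.  The total is the sum over all atoms of the system,
    both molecules.
    """
    _check_config(born, config)
    q = system.charges
    ref = born_radii(system, config, intra_only=True)
    per_atom = gb_self_energy(q, born.effective_radius, config) - gb_self_energy(
        q, ref.effective_radius, config
    )
    per_atom = np.asarray(per_atom, dtype=float)
    return per_atom, float(np.sum(per_atom))


class InteractionEnergy(NamedTuple):
    e_vac: float   # vacuum Coulomb term, kcal/mol
    g_gb: float    # GB screening term, kcal/mol
    g_int: float   # total interaction, e_vac + g_gb


def interaction_energy(
    system: MolecularSystem, born: BornRadiusResult, config: GBConfig
) -> InteractionEnergy:
    """Cross-molecule Coulomb interaction energy in water.

    G_int = sum over cross-molecule pairs (k, l) of

        k_e q_k q_l / d_kl  +  (1/eps_w - 1) k_e q_k q_l / f_gb(d_kl, R_k, R_l).

    Raises on coincident atoms across molecules (the vacuum term is
    singular) and on single-molecule systems.
    """
    _check_config(born, config)
    pairs = interaction_pairs(system)
    pos = system.positions
    q = system.charges
    R = born.effective_radius
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    d = np.linalg.norm(pos[ii] - pos[jj], axis=1)
    if np.any(d == 0):
        k = int(np.nonzero(d == 0)[0][0])
        raise ValueError(
            f"coincident atoms across molecules: {system.atom_ids[ii[k]]!r} "
            f"and {system.atom_ids[jj[k]]!r} (vacuum Coulomb term singular)"
        )
    qq = q[ii] * q[jj]
    ke = config.coulomb_constant
    e_vac = float(np.sum(ke * qq / d))
    g_gb = float(
        np.sum((1.0 / config.epsilon_w - 1.0) * ke * qq / f_gb(d, R[ii], R[jj]))
    )
    return InteractionEnergy(e_vac=e_vac, g_gb=g_gb, g_int=e_vac + g_gb)


def total_gb_energy(
    system: MolecularSystem, born: BornRadiusResult, config: GBConfig
) -> float:
    """Unified GB energy: (1/2)(1/eps_w - 1) k_e sum_{i,j} q_i q_j / f_gb.

    The double sum runs over all ordered pairs including i = j (for which
    f_gb = R_i, recovering the self term q_i^2 / (2 R_i)).  Numerically
    identical to the sum of all per-atom self energies plus the screening
    terms of all unordered pairs, intra- and inter-molecular.
    """
    _check_config(born, config)
    pos = system.positions
    q = system.charges
    R = born.effective_radius
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    F = f_gb(d, R[:, None], R[None, :])
    qq = q[:, None] * q[None, :]
    pref = 0.5 * (1.0 / config.epsilon_w - 1.0) * config.coulomb_constant
    return float(pref * np.sum(qq / F))


def lj_energy(
    system: MolecularSystem,
    pairs: Optional[Sequence[tuple[int, int]]] = None,
) -> float:
    """12-6 Lennard-Jones energy over cross-molecule pairs, kcal/mol.

    Uses Lorentz-Berthelot combination: rmin = rmin_half_i + rmin_half_j,
    eps = sqrt(eps_i eps_j), E = eps [(rmin/d)^12 - 2 (rmin/d)^6].
    Parameters must be present on every atom appearing in ``pairs``.
    """
    if pairs is None:
        pairs = interaction_pairs(system)
    pos = system.positions
    total = 0.0
    for i, j in pairs:
        ai, aj = system.atoms[i], system.atoms[j]
        for atom in (ai, aj):
            if not atom.has_lj:
                raise ValueError(f"atom {atom.atom_id!r} has no LJ parameters")
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if d == 0:
            raise ValueError(
                f"coincident atoms {ai.atom_id!r} and {aj.atom_id!r} in LJ sum"
            )
        rmin = ai.lj_rmin_half + aj.lj_rmin_half
        eps = math.sqrt(ai.lj_epsilon * aj.lj_epsilon)
        s6 = (rmin / d) ** 6
        total += eps * (s6 * s6 - 2.0 * s6)
    return total


@dataclass(frozen=True, eq=False)
class EnergyBreakdown:
    """All energy terms of one system at one geometry, kcal/mol."""

    atom_ids: tuple[str, ...]
    gb_self: np.ndarray          # per-atom GB self energies at this geometry
    delta_self_atoms: np.ndarray  # per-atom desolvation energies
    delta_self: float            # total desolvation energy
    e_vac_int: float             # vacuum Coulomb interaction
    g_gb_int: float              # GB screening interaction
    g_int: float                 # e_vac_int + g_gb_int
    coulomb_total: float         # delta_self + g_int
    lj: Optional[float] = None
    total: Optional[float] = None  # coulomb_total + lj when LJ present

    def as_dict(self) -> dict:
        d = {
            "delta_self": self.delta_self,
            "e_vac_int": self.e_vac_int,
            "g_gb_int": self.g_gb_int,
            "g_int": self.g_int,
            "coulomb_total": self.coulomb_total,
            "delta_self_atoms": {
                aid: float(v) for aid, v in zip(self.atom_ids, self.delta_self_atoms)
            },
        }
        if self.lj is not None:
            d["lj"] = self.lj
            d["total"] = self.total
        return d

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1)

    def to_frame(self):
        """Flat table: one row per atom for self terms, one summary row."""
        import pandas as pd

        rows = [
            {
                "row": aid,
                "gb_self": float(gs),
                "delta_self": float(ds),
            }
            for aid, gs, ds in zip(self.atom_ids, self.gb_self, self.delta_self_atoms)
        ]
        summary = {
            "row": "TOTAL",
            "delta_self": self.delta_self,
            "e_vac_int": self.e_vac_int,
            "g_gb_int": self.g_gb_int,
            "g_int": self.g_int,
            "coulomb_total": self.coulomb_total,
        }
        if self.lj is not None:
            summary["lj"] = self.lj
            summary["total"] = self.total
        rows.append(summary)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def energy_breakdown(
    system: MolecularSystem,
    config: GBConfig,
    born: Optional[BornRadiusResult] = None,
    include_lj: Optional[bool] = None,
) -> EnergyBreakdown:
    """Compute the full energy decomposition of a system.

    ``include_lj=None`` (the default) computes the LJ term exactly when all
    atoms carry LJ parameters.
    """
    if born is None:
        born = born_radii(system, config)
    else:
        _check_config(born, config)
    per_atom_self = np.asarray(
        gb_self_energy(system.charges, born.effective_radius, config), dtype=float
    )
    delta_atoms, delta_total = desolvation_energies(system, born, config)
    inter = interaction_energy(system, born, config)
    coulomb = delta_total + inter.g_int

    if include_lj is None:
        include_lj = all(a.has_lj for a in system.atoms)
    lj = total = None
    if include_lj:
        lj = lj_energy(system)
        total = coulomb + lj
    return EnergyBreakdown(
        atom_ids=system.atom_ids,
        gb_self=per_atom_self,
        delta_self_atoms=delta_atoms,
        delta_self=delta_total,
        e_vac_int=inter.e_vac,
        g_gb_int=inter.g_gb,
        g_int=inter.g_int,
        coulomb_total=coulomb,
        lj=lj,
        total=total,
    )
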