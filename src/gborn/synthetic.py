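"""Synthetic study systems: the H-O pair, an idealized Arg-Glu salt bridge,
a toy charge-complementary protein pair, and Boltzmann samples for the PMF
estimator.

All builders are deterministic given a seed and regenerate byte-identical
coordinates, so every analysis in the package runs with no external data.
The salt-bridge and toy-pair ensembles are idealized stand-ins for
molecular-dynamics snapshot ensembles: rigid fragments at prescribed
separations with small Gaussian positional jitter emulating thermal spread.
They are not force-field samples; see docs/methods.md for what they do and
do not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import GAS_CONSTANT, AtomSite, MolecularSystem

__all__ = [
    "EnsembleSpec",
    "build_ho_system",
    "build_salt_bridge_ensemble",
    "build_toy_protein_pair",
    "sample_boltzmann_1d",
    "FF99_HO_LJ",
    "GUANIDINIUM_CHARGES",
    "CARBOXYLATE_CHARGES",
    "HCT_SCALES",
]

#: Lennard-Jones parameters (rmin/2 in Å, epsilon in kcal/mol) for the
#: arginine H(eta) hydrogen (amber type H) and the glutamate carboxylate
#: oxygen (amber type O2), transcribed from the parm99 parameter file.
#: Convenience values for the two-atom analyses; builders take
#: caller-supplied parameters.
FF99_HO_LJ: dict[str, tuple[float, float]] = {
    "H-on-N": (0.6000, 0.0157),
    "O-carboxyl": (1.6612, 0.2100),
}

#: Partial charges (units of e) for the idealized guanidinium fragment.
#: CZ/NE/NH follow the arginine side-chain convention of the amber ff99
#: charge set; the N-bonded hydrogens carry the rounded +0.45 e used for
#: the H-O pair analyses.  A documented approximation, not a force field.
GUANIDINIUM_CHARGES: dict[str, float] = {
    "CZ": 0.8076,
    "NE": -0.5295,
    "NH": -0.8627,
    "H-on-N": 0.45,
}

#: Partial charges for the idealized carboxylate fragment (glutamate
#: side-chain convention; carboxyl oxygens at the rounded -0.82 e).
CARBOXYLATE_CHARGES: dict[str, float] = {
    "CD": 0.8054,
    "O-carboxyl": -0.82,
}

#: HCT-style descreening scale factors by element, as used by the pairwise
#: descreening parameterization underlying the OBC model; attached to the
#: salt-bridge and toy-pair builders so their obc2-mode energetics emulate
#: the standard biomolecular GB setup.
HCT_SCALES: dict[str, float] = {"H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85}

# idealized internal geometry (Å, degrees): planar guanidinium with C-N
# 1.33 and N-H 1.01; carboxylate with C-O 1.25 and an O-C-O angle of 126
_CN = 1.33
_NH = 1.01
_CO = 1.25
_OCO_HALF = math.radians(63.0)


def _scale_for(class_label: str) -> float:
    return HCT_SCALES.get(class_label[0].upper(), 1.0)


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of a synthetic conformer ensemble.

    ``d_values`` are target values of the separation coordinate (Å);
    ``snapshots_per_d`` snapshots are drawn at each, jittered by an
    isotropic Gaussian of width ``sigma`` (Å) and re-measured.  A fixed
    ``seed`` regenerates byte-identical ensembles.
    """

    family: str  # "ho" | "saltbridge" | "toyprotein"
    d_values: tuple[float, ...]
    snapshots_per_d: int = 1
    sigma: float = 0.1
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("ho", "saltbridge", "toyprotein"):
            raise ValueError(f"unknown ensemble family {self.family!r}")
        object.__setattr__(self, "d_values", tuple(float(d) for d in self.d_values))
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.snapshots_per_d < 1:
            raise ValueError("snapshots_per_d must be >= 1")


def build_ho_system(
    d: float,
    rho_H: float = 1.2,
    lj_params: Optional[dict[str, tuple[float, float]]] = None,
) -> MolecularSystem:
    """The two-atom H-O system at separation ``d``.

    A carboxylate-type oxygen (q = -0.82 e, rho = 1.5 Å) at the origin and a
    nitrogen-bonded hydrogen (q = +0.45 e, rho = ``rho_H``) on the x axis at
    distance ``d``, in different molecules.  ``lj_params`` optionally maps
    class label -> (rmin/2, epsilon) to attach Lennard-Jones parameters
    (e.g. :data:`FF99_HO_LJ`).
    """
    if not d > 0:
        raise ValueError(f"d must be > 0, got {d}")
    lj = lj_params or {}

    def _lj(label):
        pair = lj.get(label)
        return (None, None) if pair is None else (float(pair[0]), float(pair[1]))

    o_rm, o_eps = _lj("O-carboxyl")
    h_rm, h_eps = _lj("H-on-N")
    atoms = (
        AtomSite(
            atom_id="O",
            class_label="O-carboxyl",
            position=(0.0, 0.0, 0.0),
            charge=-0.82,
            intrinsic_radius=1.5,
            lj_rmin_half=o_rm,
            lj_epsilon=o_eps,
            molecule_tag="glu",
        ),
        AtomSite(
            atom_id="H",
            class_label="H-on-N",
            position=(float(d), 0.0, 0.0),
            charge=0.45,
            intrinsic_radius=float(rho_H),
            lj_rmin_half=h_rm,
            lj_epsilon=h_eps,
            molecule_tag="arg",
        ),
    )
    return MolecularSystem(atoms=atoms, separation=float(d), separation_definition="O-H distance")


def _rot2d(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])


def _salt_bridge_template(d: float) -> list[tuple[str, str, str, np.ndarray, float, float]]:
    """Planar bidentate guanidinium/carboxylate geometry at Czeta-Cdelta
    distance ``d``.  Returns (atom_id, class, tag, xyz, charge, rho)."""
    qg = GUANIDINIUM_CHARGES
    qc = CARBOXYLATE_CHARGES

    def at(aid, label, tag, xy, q, rho):
        return (aid, label, tag, np.array([xy[0], xy[1], 0.0]), q, rho)

    atoms = []
    # guanidinium: CZ at origin, NE pointing away from the interface (-x),
    # the two NH nitrogens at +-60 degrees facing the carboxylate
    cz = np.zeros(2)
    atoms.append(at("arg:CZ", "C", "arg", cz, qg["CZ"], 1.7))
    ne = _CN * np.array([-1.0, 0.0])
    atoms.append(at("arg:NE", "N", "arg", ne, qg["NE"], 1.55))
    atoms.append(at("arg:HE", "H-on-N", "arg", ne + _NH * np.array([-1.0, 0.0]),
                    qg["H-on-N"], 1.3))
    for sign, tag in ((+1, "1"), (-1, "2")):
        u = np.array([math.cos(math.radians(60.0)), sign * math.sin(math.radians(60.0))])
        nh = _CN * u
        atoms.append(at(f"arg:NH{tag}", "N", "arg", nh, qg["NH"], 1.55))
        # inner hydrogen points along +x toward the carboxylate; outer
        # hydrogen is rotated 120 degrees away
        h_in = nh + _NH * (_rot2d(-sign * 60.0) @ u)
        h_out = nh + _NH * (_rot2d(sign * 60.0) @ u)
        atoms.append(at(f"arg:HH{tag}1", "H-on-N", "arg", h_in, qg["H-on-N"], 1.3))
        atoms.append(at(f"arg:HH{tag}2", "H-on-N", "arg", h_out, qg["H-on-N"], 1.3))
    # carboxylate: CD on the x axis at distance d, oxygens facing -x
    cd = np.array([d, 0.0])
    atoms.append(at("glu:CD", "C", "glu", cd, qc["CD"], 1.7))
    for sign, tag in ((+1, "1"), (-1, "2")):
        u = np.array([-math.cos(_OCO_HALF), sign * math.sin(_OCO_HALF)])
        atoms.append(at(f"glu:OE{tag}", "O-carboxyl", "glu", cd + _CO * u,
                        qc["O-carboxyl"], 1.5))
    return atoms


def _jitter_and_build(
    template: Sequence[tuple[str, str, str, np.ndarray, float, float]],
    rng: np.random.Generator,
    sigma: float,
    measure: str,
    sep_def: str,
    max_attempts: int = 100,
) -> tuple[MolecularSystem, float]:
    """Apply Gaussian jitter, reject clashing snapshots, re-measure d."""
    tags = [t[2] for t in template]
    base = np.array([t[3] for t in template])
    n = len(template)
    tag_a = tags[0]
    mask_a = np.array([t == tag_a for t in tags])
    for _ in range(max_attempts):
        coords = base + (rng.normal(0.0, sigma, size=(n, 3)) if sigma > 0 else 0.0)
        cross = np.linalg.norm(
            coords[mask_a][:, None, :] - coords[~mask_a][None, :, :], axis=-1
        )
        if np.min(cross) < 0.8:
            continue
        if measure == "com":
            d_meas = float(
                np.linalg.norm(coords[mask_a].mean(axis=0) - coords[~mask_a].mean(axis=0))
            )
        else:  # atom-atom: measure holds "id1|id2"
            id1, id2 = measure.split("|")
            ids = [t[0] for t in template]
            d_meas = float(
                np.linalg.norm(coords[ids.index(id1)] - coords[ids.index(id2)])
            )
        atoms = tuple(
            AtomSite(
                atom_id=t[0],
                class_label=t[1],
                position=coords[k],
                charge=t[4],
                intrinsic_radius=t[5],
                descreen_scale=t[6] if len(t) > 6 else _scale_for(t[1]),
                molecule_tag=t[2],
            )
            for k, t in enumerate(template)
        )
        return (
            MolecularSystem(atoms=atoms, separation=d_meas, separation_definition=sep_def),
            d_meas,
        )
    raise RuntimeError(
        f"could not draw a clash-free snapshot in {max_attempts} attempts "
        "(cross-fragment distance < 0.8 Å)"
    )


def build_salt_bridge_ensemble(
    spec: EnsembleSpec,
) -> list[tuple[MolecularSystem, float]]:
    """Idealized Arg-Glu salt-bridge conformer ensemble.

    A rigid planar guanidinium fragment (CZ, NE, 2 NH, 5 N-bonded H) faces a
    rigid carboxylate fragment (CD, 2 carboxyl O) in the symmetric bidentate
    orientation; the separation coordinate is the CZ-CD distance.  Each
    snapshot applies isotropic Gaussian jitter of width ``spec.sigma`` to
    every atom, rejects clashes (any cross-fragment distance < 0.8 Å, at
    most 100 redraws), and re-measures d on the jittered coordinates.
    """
    if spec.family != "saltbridge":
        raise ValueError(f"spec.family must be 'saltbridge', got {spec.family!r}")
    min_d = 2.0  # below this the rigid fragments always clash
    for d in spec.d_values:
        if d <= min_d:
            raise ValueError(f"target d={d} below fragment contact distance")
    rng = np.random.default_rng(spec.seed)
    out = []
    for d in spec.d_values:
        template = _salt_bridge_template(d)
        for _ in range(spec.snapshots_per_d):
            out.append(
                _jitter_and_build(
                    template, rng, spec.sigma,
                    measure="arg:CZ|glu:CD",
                    sep_def="CZ-CD distance",
                )
            )
    return out


def _toy_cluster(
    rng: np.random.Generator,
    patch: str,
    n_beads: int = 50,
    cluster_radius: float = 10.0,
    patch_radius: float = 12.34,
    core_radius: float = 9.5,
    bead_min_sep: float = 3.0,
    surf_bias: float = 0.1,
    surf_sd: float = 0.5,
    interior_sd: float = 0.35,
    patch_n: int = 2,
) -> list[tuple[str, str, float, float, np.ndarray]]:
    """One rigid spherical bead cluster with a charged interface patch.

    Returns (atom_id_suffix, class, charge, rho, xyz).  The patch
    (``patch_n`` beads: one axial at +x plus a 15-degree ring) carries
    hydrogen-like beads (+0.45 e, rho 1.3, class "H-on-N") when
    ``patch == "pos"`` and oxygen-like beads (-0.82 e, rho 1.5, class
    "O-carboxyl") when ``patch == "neg"``.  The patch protrudes past the
    core surface (``patch_radius`` vs ``core_radius``), emulating interface
    side chains: after centering on the center of mass the axial patch bead
    sits ~10.9 Å from the COM, so two such clusters facing each other form
    close (~2 Å gap) Coulomb-bond contacts at a COM separation near 23.7 Å
    while the cores remain apart.

    The remaining beads emulate a charged protein surface over a polar
    interior: about half sit on the core surface carrying moderate charges
    biased toward the patch sign (the overall surfaces of the two partners
    are charge-complementary), the rest fill the interior with
    backbone-scale polar charges; the interior charges are shifted so each
    cluster nets +1 or -1 e in total, keeping all energy terms decaying to
    zero at large separation.  The surface and interior charge widths put
    the pair in the regime where the outer-cutoff (rmax) dependence of the
    desolvation penalty is visible at desk scale.
    """
    if patch == "pos":
        p_class, p_q, p_rho, net_charge = "H-on-N", 0.45, 1.3, +1.0
        bias = +surf_bias
    elif patch == "neg":
        p_class, p_q, p_rho, net_charge = "O-carboxyl", -0.82, 1.5, -1.0
        bias = -surf_bias
    else:
        raise ValueError(f"patch must be 'pos' or 'neg', got {patch!r}")

    beads: list[tuple[str, str, float, float, np.ndarray]] = []
    # interface patch on the +x pole: one axial bead plus a ring
    beads.append(("p0", p_class, p_q, p_rho, np.array([patch_radius, 0.0, 0.0])))
    ring = math.radians(15.0)
    for k in range(patch_n - 1):
        az = 2.0 * math.pi * k / max(patch_n - 1, 1)
        xyz = patch_radius * np.array(
            [math.cos(ring), math.sin(ring) * math.cos(az), math.sin(ring) * math.sin(az)]
        )
        beads.append((f"p{k + 1}", p_class, p_q, p_rho, xyz))

    placed = [b[4] for b in beads]

    def _pack(n_target, draw):
        out, attempts = [], 0
        while len(out) < n_target:
            attempts += 1
            if attempts > 200_000:
                raise RuntimeError("could not pack toy cluster beads")
            x = draw()
            if any(np.linalg.norm(x - p) < bead_min_sep for p in placed):
                continue
            placed.append(x)
            out.append(x)
        return out

    # charged surface shell, kept clear of the patch cone
    n_surf = (n_beads - len(beads)) // 2

    def _draw_surface():
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if math.acos(min(1.0, max(-1.0, v[0]))) < math.radians(30.0):
            v = -v
        return core_radius * v

    surf_pos = _pack(n_surf, _draw_surface)
    surf_q = bias + surf_sd * rng.normal(size=n_surf)

    # weakly polar interior
    n_int = n_beads - len(beads) - n_surf

    def _draw_interior():
        while True:
            x = rng.uniform(-1.0, 1.0, size=3) * (core_radius - 2.0)
            if np.linalg.norm(x) <= core_radius - 2.0:
                return x

    int_pos = _pack(n_int, _draw_interior)
    int_q = rng.normal(0.0, interior_sd, size=n_int)
    int_q += (net_charge - p_q * patch_n - surf_q.sum() - int_q.sum()) / n_int

    for k, (xyz, q) in enumerate(zip(surf_pos, surf_q)):
        beads.append((f"s{k}", "bead", float(q), 2.0, xyz))
    for k, (xyz, q) in enumerate(zip(int_pos, int_q)):
        beads.append((f"c{k}", "bead", float(q), 2.0, xyz))
    # center on the center of mass (equal bead masses) and pin the axial
    # patch bead at 10.9 Å from the COM so that two facing clusters form a
    # ~1.9 Å contact gap at a COM separation of 23.7 Å
    pos = np.array([b[4] for b in beads])
    target = 10.9
    for _ in range(8):
        pos -= pos.mean(axis=0)
        r_axial = np.linalg.norm(pos[0])
        if abs(r_axial - target) < 1e-12:
            break
        pos[:patch_n] *= target / r_axial
    pos -= pos.mean(axis=0)
    return [
        (aid, lab, q, rho, pos[k]) for k, (aid, lab, q, rho, _) in enumerate(beads)
    ]


def build_toy_protein_pair(
    spec: EnsembleSpec,
) -> list[tuple[MolecularSystem, float]]:
    """Toy charge-complementary two-body pair emulating a protein interface.

    Two rigid ~50-bead spherical clusters: cluster A carries a net-positive
    hydrogen-like interface patch, cluster B a net-negative oxygen-like
    patch, with weakly charged cores of opposite small net charge.  The
    separation coordinate is the center-of-mass distance; the clusters
    approach rigidly along the patch axis with optional per-snapshot jitter.
    """
    if spec.family != "toyprotein":
        raise ValueError(f"spec.family must be 'toyprotein', got {spec.family!r}")
    rng = np.random.default_rng(spec.seed)
    params = dict(spec.params)
    n_beads = int(params.get("n_beads", 50))
    bead_scale = float(params.get("bead_scale", 1.0))
    kw = {
        k: float(params[k])
        for k in ("surf_bias", "surf_sd", "interior_sd")
        if k in params
    }
    if "patch_n" in params:
        kw["patch_n"] = int(params["patch_n"])
    cluster_a = _toy_cluster(rng, "pos", n_beads=n_beads, **kw)
    cluster_b = _toy_cluster(rng, "neg", n_beads=n_beads, **kw)

    def _entry(prefix, tag, aid, lab, q, rho, xyz):
        scale = bead_scale if lab == "bead" else _scale_for(lab)
        return (f"{prefix}:{aid}", lab, tag, xyz, q, rho, scale)

    out = []
    for d in spec.d_values:
        template = []
        for aid, lab, q, rho, xyz in cluster_a:
            template.append(_entry("A", "A", aid, lab, q, rho, xyz))
        for aid, lab, q, rho, xyz in cluster_b:
            # mirror so B's patch faces A, then translate to distance d
            mirrored = np.array([d - xyz[0], xyz[1], xyz[2]])
            template.append(_entry("B", "B", aid, lab, q, rho, mirrored))
        for _ in range(spec.snapshots_per_d):
            out.append(
                _jitter_and_build(
                    template, rng, spec.sigma,
                    measure="com",
                    sep_def="center-of-mass distance",
                )
            )
    return out


def sample_boltzmann_1d(
    potential: tuple[Sequence[float], Sequence[float]],
    T: float,
    n: int,
    seed: int,
    grid_points: int = 4001,
) -> np.ndarray:
    """I.i.d. samples of d from the density proportional to exp(-U(d)/RT).

    ``potential`` is a tabulated (d, U) pair in (Å, kcal/mol); U is
    interpolated linearly onto a fine grid and sampled by inverse transform
    of the trapezoid CDF.  Deterministic for a fixed seed.
    """
    d_tab = np.asarray(potential[0], dtype=float)
    u_tab = np.asarray(potential[1], dtype=float)
    if d_tab.ndim != 1 or d_tab.shape != u_tab.shape or d_tab.size < 2:
        raise ValueError("potential must be two equal-length 1-D arrays")
    if not np.all(np.diff(d_tab) > 0):
        raise ValueError("potential grid must be strictly increasing")
    if not np.all(np.isfinite(u_tab)):
        raise ValueError("potential values must be finite on the support")
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = np.linspace(d_tab[0], d_tab[-1], grid_points)
    u = np.interp(grid, d_tab, u_tab)
    w = np.exp(-(u - u.min()) / (GAS_CONSTANT * T))
    norm = np.trapezoid(w, grid)
    if not (np.isfinite(norm) and norm > 0):
        raise ValueError("potential is not normalizable on its support")
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    return np.interp(rng.random(n), cdf, grid)
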