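"""PQR input/output, run configuration, and result writing.

PQR is the native structure format here because it carries the two
quantities the whole analysis turns on: per-atom charge and radius.  The
whitespace-separated dialect is used; an optional chain column carries the
molecule tag, with sequential TER-separated groups as the fallback.
"""

from __future__ import annotations

import json
import string
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .model import AtomSite, GBConfig, MolecularSystem
from .scans import ProfileTable

__all__ = ["read_pqr", "write_pqr", "write_results", "RunConfig", "class_label_for_name"]

# atom-name <-> class-label rule table for the classes the builders emit
_CLASS_TO_NAME = {
    "H-on-N": "HN",
    "O-carboxyl": "OC",
    "bead": "BD",
    "H": "H",
    "C": "C",
    "N": "N",
    "O": "O",
    "S": "S",
    "P": "P",
}
_NAME_TO_CLASS = {v: k for k, v in _CLASS_TO_NAME.items()}
# real-structure names: guanidinium/amine hydrogens and carboxylate oxygens
_NAME_TO_CLASS.update(
    {n: "H-on-N" for n in ("HH11", "HH12", "HH21", "HH22", "HE", "HZ1", "HZ2", "HZ3")}
)
_NAME_TO_CLASS.update({n: "O-carboxyl" for n in ("OE1", "OE2", "OD1", "OD2")})


def class_label_for_name(name: str) -> str:
    """Parameterization class for a PQR atom name.

    Exact matches in the rule table win; otherwise a leading element letter
    (H/C/N/O/S/P) is used; otherwise the name itself becomes the class.
    """
    if name in _NAME_TO_CLASS:
        return _NAME_TO_CLASS[name]
    if name and name[0].upper() in "HCNOSP":
        return name[0].upper()
    return name


def write_pqr(system: MolecularSystem, path) -> None:
    """Write a whitespace-separated PQR file with chain IDs and TER records.

    Molecules (by ``molecule_tag``, in order of first appearance) receive
    chain letters A, B, C, ... and are separated by TER lines.  Coordinates
    are written at 1e-4 Å precision, charges and radii at 1e-4.
    """
    tags_in_order: list[str] = []
    for atom in system.atoms:
        if atom.molecule_tag not in tags_in_order:
            tags_in_order.append(atom.molecule_tag)
    chain_of = {t: string.ascii_uppercase[i % 26] for i, t in enumerate(tags_in_order)}
    lines = []
    serial = 0
    prev_tag = None
    for atom in system.atoms:
        if prev_tag is not None and atom.molecule_tag != prev_tag:
            lines.append("TER")
        prev_tag = atom.molecule_tag
        serial += 1
        name = _CLASS_TO_NAME.get(atom.class_label, atom.class_label[:4])
        resname = atom.molecule_tag[:4].upper() or "MOL"
        resid = tags_in_order.index(atom.molecule_tag) + 1
        x, y, z = atom.position
        lines.append(
            f"ATOM {serial:6d} {name:<4s} {resname:<4s} "
            f"{chain_of[atom.molecule_tag]} {resid:4d} "
            f"{x:10.4f} {y:10.4f} {z:10.4f} {atom.charge:9.4f} "
            f"{atom.intrinsic_radius:7.4f}"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_float(token: str, what: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"line {lineno}: non-numeric {what} field {token!r}") from None


def read_pqr(path) -> MolecularSystem:
    """Parse a whitespace-separated PQR file into a :class:`MolecularSystem`.

    ATOM/HETATM records must end in charge and radius fields.  Both the
    10-column dialect (no chain) and the 11-column dialect (chain between
    residue name and residue id) are accepted; the chain column, when
    present, becomes the molecule tag, otherwise sequential TER-separated
    groups do.  Class labels are derived from atom names through the
    documented rule table.
    """
    atoms: list[AtomSite] = []
    group = 1
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            rec = line.split(maxsplit=1)[0]
            if rec == "TER":
                group += 1
                continue
            if rec not in ("ATOM", "HETATM"):
                continue
            tok = line.split()
            if len(tok) < 10:
                raise ValueError(
                    f"line {lineno}: expected at least 10 fields "
                    f"(missing charge/radius columns?), got {len(tok)}"
                )
            name, resname = tok[2], tok[3]
            # 11-column dialect has a non-numeric chain token before resid
            has_chain = len(tok) >= 11 and not _is_int(tok[4])
            chain = tok[4] if has_chain else None
            rest = tok[5:] if has_chain else tok[4:]
            if len(rest) < 6:
                raise ValueError(
                    f"line {lineno}: missing charge/radius columns"
                )
            x = _parse_float(rest[1], "x", lineno)
            y = _parse_float(rest[2], "y", lineno)
            z = _parse_float(rest[3], "z", lineno)
            charge = _parse_float(rest[4], "charge", lineno)
            radius = _parse_float(rest[5], "radius", lineno)
            tag = chain if chain is not None else f"mol{group}"
            atom_id = f"{tag}:{name}:{tok[1]}"
            if atom_id in seen_ids:
                atom_id = f"{atom_id}@{lineno}"
            seen_ids.add(atom_id)
            atoms.append(
                AtomSite(
                    atom_id=atom_id,
                    class_label=class_label_for_name(name),
                    position=(x, y, z),
                    charge=charge,
                    intrinsic_radius=radius,
                    molecule_tag=tag,
                )
            )
    if not atoms:
        raise ValueError(f"no ATOM/HETATM records in {path}")
    return MolecularSystem(atoms=tuple(atoms))


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def _profile_filename(profile: ProfileTable, index: int) -> str:
    parts = []
    overrides = profile.metadata.get("rho_overrides") or profile.metadata.get(
        "radius_overrides"
    )
    if overrides:
        for label, rho in sorted(overrides.items()):
            parts.append(f"rho{label.replace('-', '')}={rho:g}")
    rmax = profile.metadata.get("rmax")
    if rmax is not None:
        parts.append(f"rmax={rmax:g}")
    stem = "profile_" + "_".join(parts) if parts else f"profile_{index}"
    return stem + ".csv"


def write_results(
    profiles: Sequence[ProfileTable],
    out_dir,
    config: Optional[GBConfig] = None,
    extra: Optional[dict] = None,
) -> list[Path]:
    """Write one CSV per profile plus a JSON summary, return the file list.

    Filenames embed the parameter labels (rho overrides, rmax); re-running
    with identical inputs produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    entries = []
    for i, prof in enumerate(profiles):
        fname = _profile_filename(prof, i)
        prof.to_csv(out / fname)
        written.append(out / fname)
        entries.append({"file": fname, "metadata": prof.metadata})
    summary = {
        "profiles": entries,
        "config": config.as_dict() if config is not None else None,
    }
    if extra:
        summary["extra"] = extra
    spath = out / "summary.json"
    with open(spath, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    written.append(spath)
    return written


@dataclass
class RunConfig:
    """Serializable description of one analysis run.

    ``source`` selects the input: ``{"kind": "pqr", "path": ...}`` or
    ``{"kind": "builder", "family": "ho"|"saltbridge"|"toyprotein", ...}``.
    ``gb`` holds GBConfig fields, ``scan`` the grid/override/rmax lists.
    A persisted RunConfig re-executes to identical outputs for identical
    inputs.
    """

    source: dict
    gb: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def gb_config(self) -> GBConfig:
        return GBConfig(**self.gb)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".toml", ".tml"):
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        return cls.from_dict(data)

    def run(self) -> list[Path]:
        """Execute the described scan and write results to ``out_dir``."""
        from . import synthetic
        from .scans import parameter_scan

        cfg = self.gb_config()
        scan = dict(self.scan)
        rho_values = {k: list(v) for k, v in scan.get("rho_values", {}).items()}
        rmax_values = list(scan.get("rmax_values", [cfg.rmax]))
        kind = self.source.get("kind")
        if kind == "pqr":
            system = read_pqr(self.source["path"])
            profiles = parameter_scan(
                [(system, system.separation or 0.0)],
                rho_values,
                rmax_values,
                cfg,
                bin_edges=scan.get("bin_edges", [-0.5, 0.5]),
            )
        elif kind == "builder":
            family = self.source.get("family")
            if family == "ho":
                lo, hi, step = scan.get("d_grid", (1.0, 8.0, 0.01))
                import numpy as np

                grid = np.arange(lo, hi + 0.5 * step, step)
                rho_h = float(self.source.get("rho_H", 1.2))
                profiles = parameter_scan(
                    lambda d: synthetic.build_ho_system(d, rho_H=rho_h),
                    rho_values,
                    rmax_values,
                    cfg,
                    d_grid=grid,
                )
            elif family in ("saltbridge", "toyprotein"):
                spec = synthetic.EnsembleSpec(
                    family=family,
                    d_values=tuple(scan.get("d_values", ())),
                    snapshots_per_d=int(scan.get("snapshots_per_d", 1)),
                    sigma=float(scan.get("sigma", 0.1)),
                    seed=self.seed,
                )
                build = (
                    synthetic.build_salt_bridge_ensemble
                    if family == "saltbridge"
                    else synthetic.build_toy_protein_pair
                )
                profiles = parameter_scan(
                    build(spec),
                    rho_values,
                    rmax_values,
                    cfg,
                    bin_edges=scan["bin_edges"],
                )
            else:
                raise ValueError(f"unknown builder family {family!r}")
        else:
            raise ValueError(f"unknown source kind {kind!r}")
        return write_results(profiles, self.out_dir, config=cfg,
                             extra={"run_config": self.to_dict()})
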