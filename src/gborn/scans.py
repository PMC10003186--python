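"""Analysis procedures: distance profiles, rho/rmax parameter scans,
window-averaged ensemble energies, the count-based PMF estimator, and
minimum location."""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .energetics import energy_breakdown
from .model import GAS_CONSTANT, GBConfig, MolecularSystem

__all__ = [
    "ProfileTable",
    "distance_scan",
    "parameter_scan",
    "ensemble_binned_profile",
    "pmf_from_counts",
    "locate_minimum",
    "MinimumResult",
    "ScanError",
]

Ensemble = Sequence[tuple[MolecularSystem, float]]


class ScanError(RuntimeError):
    pass


@dataclass(eq=False)
class ProfileTable:
    """Energies (or PMF values) along the separation coordinate d.

    ``table`` holds a column ``d`` (grid or bin centers, strictly
    increasing) plus one column per quantity; binned profiles carry a
    ``count`` column and flag empty bins as NaN rather than dropping them.
    ``metadata`` records the parameter setting (radius overrides, rmax,
    Born mode) that produced the profile.
    """

    table: pd.DataFrame
    temperature: float = 300.0
    d_ref: Optional[float] = None
    n_ref: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "d" not in self.table.columns:
            raise ValueError("ProfileTable needs a 'd' column")
        d = self.table["d"].to_numpy()
        if d.size > 1 and not np.all(np.diff(d) > 0):
            raise ValueError("d must be strictly increasing")
        if "count" in self.table.columns:
            if np.any(self.table["count"].to_numpy() < 0):
                raise ValueError("counts must be non-negative")

    @property
    def d(self) -> np.ndarray:
        return self.table["d"].to_numpy()

    def column(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise KeyError(f"no column {name!r}; have {list(self.table.columns)}")
        return self.table[name].to_numpy()

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            meta = {
                "temperature": self.temperature,
                "d_ref": self.d_ref,
                "n_ref": self.n_ref,
                **self.metadata,
            }
            fh.write("# " + json.dumps(meta, sort_keys=True, default=str) + "\n")
            self.table.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "ProfileTable":
        with open(path) as fh:
            header = fh.readline()
            meta = json.loads(header.lstrip("# ")) if header.startswith("#") else {}
            df = pd.read_csv(fh)
        temperature = meta.pop("temperature", 300.0)
        d_ref = meta.pop("d_ref", None)
        n_ref = meta.pop("n_ref", None)
        return cls(table=df, temperature=temperature, d_ref=d_ref, n_ref=n_ref,
                   metadata=meta)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "temperature": self.temperature,
                    "d_ref": self.d_ref,
                    "n_ref": self.n_ref,
                    "metadata": self.metadata,
                    "columns": {c: self.table[c].tolist() for c in self.table.columns},
                },
                fh,
                indent=1,
                default=str,
            )


def _row_from_breakdown(eb) -> dict:
    row = {
        "dGself_total": eb.delta_self,
        "E_vac_int": eb.e_vac_int,
        "G_gb_int": eb.g_gb_int,
        "G_int": eb.g_int,
        "coulomb_total": eb.coulomb_total,
    }
    for aid, v in zip(eb.atom_ids, eb.delta_self_atoms):
        row[f"dGself:{aid}"] = float(v)
    if eb.lj is not None:
        row["lj"] = eb.lj
        row["total"] = eb.total
    return row


def distance_scan(
    builder: Callable[[float], MolecularSystem],
    d_grid: Sequence[float],
    config: GBConfig,
    include_lj: Optional[bool] = None,
) -> ProfileTable:
    """Evaluate the full energy decomposition on a grid of separations.

    ``builder`` maps d (Å) to a :class:`MolecularSystem`; each row of the
    resulting profile holds the per-atom and total desolvation energies,
    the vacuum and screening interaction terms, the total Coulomb energy
    and, when LJ parameters are present (or ``include_lj=True``), the LJ
    and total energies.
    """
    d_grid = np.asarray(list(d_grid), dtype=float)
    rows = []
    for d in d_grid:
        try:
            system = builder(float(d))
            eb = energy_breakdown(system, config, include_lj=include_lj)
        except Exception as exc:
            raise ScanError(f"distance_scan failed at d={d:g}: {exc}") from exc
        rows.append({"d": float(d), **_row_from_breakdown(eb)})
    return ProfileTable(
        table=pd.DataFrame(rows),
        temperature=config.temperature,
        metadata={"rmax": config.rmax, "born_mode": config.born_mode,
                  "radius_overrides": dict(config.radius_overrides)},
    )


def _override_combos(rho_values: dict[str, Sequence[float]]):
    labels = list(rho_values)
    for combo in itertools.product(*(rho_values[k] for k in labels)):
        yield dict(zip(labels, (float(v) for v in combo)))


def parameter_scan(
    source: Union[Callable[[float], MolecularSystem], Ensemble],
    rho_values: dict[str, Sequence[float]],
    rmax_values: Sequence[float],
    config: GBConfig,
    d_grid: Optional[Sequence[float]] = None,
    bin_edges: Optional[Sequence[float]] = None,
    include_lj: Optional[bool] = None,
) -> list[ProfileTable]:
    """Cartesian product of rho-override and rmax settings.

    ``source`` is either a builder callable (then ``d_grid`` is required
    and each setting yields a :func:`distance_scan`) or an ensemble of
    (system, d) snapshots (then ``bin_edges`` is required and each setting
    yields an :func:`ensemble_binned_profile`).  Each profile's metadata
    carries the exact override mapping and rmax used.  Scanned class labels
    must exist in the systems being evaluated.
    """
    if not rho_values and not rmax_values:
        raise ValueError("empty parameter lists")
    rmax_values = list(rmax_values) or [config.rmax]

    if callable(source):
        if d_grid is None:
            raise ValueError("d_grid is required when scanning a builder")
        probe = source(float(np.asarray(d_grid)[0]))
    else:
        if bin_edges is None:
            raise ValueError("bin_edges is required when scanning an ensemble")
        if len(source) == 0:
            raise ValueError("empty ensemble")
        probe = source[0][0]
    present = set(probe.class_labels)
    for label in rho_values:
        if label not in present:
            raise KeyError(
                f"override class {label!r} not present in the system "
                f"(classes: {sorted(present)})"
            )

    profiles = []
    for combo in _override_combos(rho_values) if rho_values else [{}]:
        for rmax in rmax_values:
            cfg = replace(
                config,
                rmax=float(rmax),
                radius_overrides={**config.radius_overrides, **combo},
            )
            if callable(source):
                prof = distance_scan(source, d_grid, cfg, include_lj=include_lj)
            else:
                prof = ensemble_binned_profile(source, bin_edges, cfg,
                                               include_lj=include_lj)
            prof.metadata.update({"rho_overrides": dict(combo), "rmax": float(rmax)})
            profiles.append(prof)
    return profiles


def ensemble_binned_profile(
    ensemble: Ensemble,
    bin_edges: Sequence[float],
    config: GBConfig,
    include_lj: Optional[bool] = None,
    headline_window: Optional[tuple[float, float]] = None,
) -> ProfileTable:
    """Bin snapshots by d and average each energy quantity per bin.

    Bins are half-open [lo, hi); empty bins are kept with count 0 and NaN
    means.  If ``headline_window`` is given and no snapshot falls inside
    it, a warning is issued (the corresponding rows stay flagged as empty).
    """
    edges = np.asarray(list(bin_edges), dtype=float)
    if edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be at least two strictly increasing values")
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    centers = 0.5 * (edges[:-1] + edges[1:])
    per_bin_rows: list[list[dict]] = [[] for _ in centers]
    for system, d in ensemble:
        k = int(np.searchsorted(edges, d, side="right")) - 1
        if k < 0 or k >= centers.size or d >= edges[-1]:
            continue
        eb = energy_breakdown(system, config, include_lj=include_lj)
        per_bin_rows[k].append(_row_from_breakdown(eb))
    rows = []
    for center, bucket in zip(centers, per_bin_rows):
        if bucket:
            df = pd.DataFrame(bucket)
            mean = df.mean().to_dict()
        else:
            mean = {}
        rows.append({"d": float(center), "count": len(bucket), **mean})
    table = pd.DataFrame(rows)
    if headline_window is not None:
        lo, hi = headline_window
        in_window = (centers >= lo) & (centers <= hi)
        counts = table["count"].to_numpy()
        if not np.any(counts[in_window] > 0):
            warnings.warn(
                f"no snapshots in the requested window [{lo}, {hi}] Å; "
                "rows are flagged empty",
                RuntimeWarning,
                stacklevel=2,
            )
    return ProfileTable(
        table=table,
        temperature=config.temperature,
        metadata={"rmax": config.rmax, "born_mode": config.born_mode,
                  "radius_overrides": dict(config.radius_overrides),
                  "bin_edges": edges.tolist()},
    )


def pmf_from_counts(
    d_samples: Sequence[float],
    bin_width: float,
    d_ref: float,
    T: float = 300.0,
) -> ProfileTable:
    """Potential of mean force from a distance histogram.

    PMF(d) = -RT ln[n(d) / N_ref], with n(d) the number of samples in the
    half-open bin [d - w/2, d + w/2) of width ``w = bin_width`` and N_ref
    the count in the reference bin centered at ``d_ref``.  Bin centers are
    aligned so that ``d_ref`` is exactly a center, making PMF(d_ref) = 0 by
    construction.  Empty bins are reported as NaN (undefined), never as a
    substituted infinity.  A ``pmf_se`` column gives the per-bin binomial
    standard error RT sqrt(1/n + 1/N_ref).
    """
    samples = np.asarray(list(d_samples), dtype=float)
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if samples.size == 0:
        raise ValueError("no samples")
    # integer bin index relative to the reference-centered grid
    k = np.floor((samples - (d_ref - 0.5 * bin_width)) / bin_width).astype(int)
    k_min, k_max = int(k.min()), int(k.max())
    counts = np.bincount(k - k_min, minlength=k_max - k_min + 1)
    centers = d_ref + np.arange(k_min, k_max + 1) * bin_width
    ref_idx = -k_min
    if ref_idx < 0 or ref_idx >= counts.size or counts[ref_idx] == 0:
        raise ValueError(f"reference bin at d_ref={d_ref} contains no samples")
    n_ref = int(counts[ref_idx])
    rt = GAS_CONSTANT * T
    with np.errstate(divide="ignore"):
        pmf = np.where(counts > 0, -rt * np.log(counts / n_ref), np.nan)
        se = np.where(
            counts > 0, rt * np.sqrt(1.0 / np.maximum(counts, 1) + 1.0 / n_ref), np.nan
        )
    table = pd.DataFrame({"d": centers, "count": counts, "pmf": pmf, "pmf_se": se})
    return ProfileTable(table=table, temperature=T, d_ref=float(d_ref), n_ref=n_ref,
                        metadata={"bin_width": float(bin_width)})


class MinimumResult(NamedTuple):
    d_min: float
    value: float
    boundary: bool


def locate_minimum(profile: ProfileTable, column: str) -> MinimumResult:
    """Grid argmin of a profile column, refined by quadratic interpolation.

    Fits a parabola through the bracketing triple around the grid argmin;
    ties break toward smaller d.  A minimum at the grid boundary (or
    flanked by undefined bins) is returned unrefined with ``boundary``
    set.  NaN entries (flagged empty bins) are ignored.
    """
    d = profile.d
    y = profile.column(column).astype(float)
    valid = np.isfinite(y)
    if np.count_nonzero(valid) < 3:
        raise ValueError("need at least 3 defined rows to locate a minimum")
    idx = np.flatnonzero(valid)
    k_rel = int(np.argmin(y[idx]))  # argmin takes the first -> smaller d on ties
    k = int(idx[k_rel])
    if k_rel == 0 or k_rel == idx.size - 1 or idx[k_rel - 1] != k - 1 or idx[k_rel + 1] != k + 1:
        return MinimumResult(float(d[k]), float(y[k]), True)
    x0, x1, x2 = d[k - 1], d[k], d[k + 1]
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
    if a <= 0:  # degenerate (flat or concave) triple: keep the grid point
        return MinimumResult(float(x1), float(y1), False)
    xv = float(np.clip(-b / (2 * a), x0, x2))
    c = y1 - a * x1 * x1 - b * x1
    return MinimumResult(xv, float(a * xv * xv + b * xv + c), False)
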