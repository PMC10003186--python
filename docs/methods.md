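# Methods

## Model and conventions

The package implements the pairwise-descreening generalized Born (GB)
model. The solute interior dielectric is 1; water enters only through the
bulk dielectric εw (default 78.5). Energies are in kcal/mol, lengths in Å,
charges in units of the elementary charge; the electrostatic conversion
constant is fixed at k = 332.0636 kcal·Å/(mol·e²) and the gas constant at
R = 0.0019872 kcal/(mol·K).

### Descreening integral

The spatial integral of the electric-field energy density around atom *i*,
I = (1/4π)∫ dr/|r|⁴ over the water-excluded volume clipped to the shell
ρᵢ ≤ |r| ≤ rmax, is evaluated per descreening sphere in radial shells: the
fraction of a shell of radius r covered by a sphere of radius a at center
distance d is the spherical-cap solid-angle fraction, and both the
full-coverage and partial-coverage pieces have elementary antiderivatives.
Integrating each piece over its intersection with [ρ, rmax] covers every
geometric case — disjoint exterior, sphere overlapping the inner boundary,
probe engulfed, sphere clipped or excluded by rmax — in one formula, with
no unstable branch and hence no quadrature fallback. For the disjoint case
without cutoff this reduces to the textbook closed form
(1/2)[a/(d²−a²) + (1/2d)·ln((d−a)/(d+a))]. A separate adaptive-quadrature
oracle (radial quadrature of the cap fraction, target 1e−6 relative)
validates the analytic branches in the tests, backed by a 3-D Monte-Carlo
spot check that is independent of the cap geometry altogether.

The sum over descreeners ignores descreener–descreener overlap, as is
standard in pairwise GB models. Overlap overcounting can in principle push
the sum past the physical bound 1/ρᵢ; plain mode then clamps I to
(1/ρᵢ)(1 − 1e−9) and warns, since 1/R = 1/ρ − I has no defined behavior
beyond that point.

### Born-radius modes

- `plain`: 1/Rᵢ = 1/ρᵢ − Iᵢ, with I integrated from ρᵢ.
- `obc2`: the OBC model, second parameter set. The integration lower limit
  and the descreener radii use ρ − offset, and
  1/Rᵢ = 1/ρ̃ᵢ − tanh(αψ − βψ² + γψ³)/ρᵢ with ψ = Iᵢρ̃ᵢ. The coefficients
  (α, β, γ, offset) = (1.0, 0.8, 4.85, 0.09 Å) are configuration fields,
  not constants.

The two-atom analyses use plain mode (the basic GB expressions apply to
the pair directly); the salt-bridge and toy-pair analyses default to obc2,
the variant used for amino-acid- and protein-scale GB work. The
salt-bridge and toy-pair builders also attach HCT-style descreening scale
factors (H 0.85, C 0.72, N 0.79, O 0.85) to their atoms, since the OBC
parameterization is defined with them; without them, scale-1.0 hydrogen
spheres at the 1.01 Å N–H bond distance grossly over-descreen their own
nitrogens and qualitatively distort the radius-scan responses. The
factors are per-atom fields (`descreen_scale`), so the unscaled setting
remains available.

### rmax handling

The outer cutoff is applied by geometrically clipping every descreening
sphere at the shell |r| = rmax (default). An alternative `drop` mode
removes whole descreeners whose center lies beyond rmax and integrates the
rest without clipping; the two are compared in tests. The default 999 Å is
effectively no cutoff at molecular scales.

### Desolvation reference state

ΔG_self,i is taken relative to the intact molecules at infinite separation
in water: the reference Born radius is computed analytically at the same
geometry with the descreening sum restricted to same-molecule pairs. For
single-atom molecules this reduces exactly to R(∞) = ρ (or ρ̃ in obc2).
The alternative — referencing each atom to its bare intrinsic radius —
is exact only for the two-atom system; for multi-atom molecules it adds a
large intra-molecular offset that depends on the scanned radii and buries
the inter-molecular signal, so the molecule-wise reference is used
throughout. Intra-molecular pairs are excluded from G_int, but all atoms
descreen each other, so both molecules contribute to every ΔG_self.

### Scans and estimators

Distance scans evaluate the full energy breakdown on a grid (default step
0.01 Å for two-body scans); parameter scans take the Cartesian product of
per-class ρ overrides and rmax values. Window averages are unweighted
means over snapshots binned half-open [lo, hi). The PMF estimator is
−RT ln[n(d)/N_ref] on bins of width 0.1 Å aligned so the reference
distance is a bin center (PMF(d_ref) = 0 by construction); empty bins are
reported as undefined, never as substituted infinities, and a per-bin
standard error RT·√(1/n + 1/N_ref) is attached. Minima are located by
grid argmin refined with a quadratic through the bracketing triple, ties
broken toward smaller d, boundary minima flagged.

## Synthetic systems

All builders are deterministic given a seed and regenerate bit-identical
coordinates.

**H–O pair.** A carboxylate-type oxygen (q = −0.82 e, ρ = 1.5 Å) and a
nitrogen-bonded hydrogen (q = +0.45 e, ρ scanned over 1.1–1.5 Å) on the x
axis, in different molecules. Lennard-Jones parameters are caller
supplied; `FF99_HO_LJ` ships the parm99 pair (H: rmin/2 = 0.60 Å,
ε = 0.0157; carboxylate O: 1.6612 Å, 0.2100) for the total-energy-minimum
analysis, which reproduces a minimum at 1.56–1.58 Å for every ρ_H.

**Arg–Glu salt bridge.** Rigid idealized fragments: a planar guanidinium
(Cζ, Nε, 2 Nη, 5 N-bonded H; C–N 1.33 Å, N–H 1.01 Å) facing a carboxylate
(Cδ, 2 O; C–O 1.25 Å, O–C–O 126°) in the symmetric bidentate orientation;
the reaction coordinate is the Cζ–Cδ distance. Fragment charges follow the
amber ff99 side-chain convention with the H/O classes at the rounded
+0.45/−0.82 e. Snapshots apply isotropic Gaussian jitter (default
σ = 0.1 Å, a thermal-spread scale that does not change bin assignment
qualitatively), reject cross-fragment clashes below 0.8 Å (≤100 redraws),
and re-measure d.

**Toy protein pair.** Two rigid ~50-bead clusters (bead radius 2.0 Å,
core radius 9.5 Å). Each carries a protruding interface patch (one axial
plus one ring bead, pinned 10.9 Å from the cluster center of mass) of
hydrogen-like (+0.45 e, ρ 1.3) or oxygen-like (−0.82 e, ρ 1.5) beads, so a
center-of-mass separation near 23.7 Å is a genuine contact state with ~2 Å
Coulomb-bond gaps — emulating interface side chains. The remaining beads
form a charged surface shell (charges biased ±0.1 e toward the patch sign,
sd 0.5 e: overall charge-complementary surfaces) over a polar interior
(sd 0.35 e, backbone scale), with interior charges shifted so the clusters
net +1/−1 e and all terms decay to zero at large separation. The charge
widths place the pair in the regime where the cutoff dependence of the
desolvation penalty is visible at this size: the association barrier grows
from ~0 at rmax = 10 Å to ~1 kcal/mol at rmax = 25 Å. It is a stand-in for
a charge-complementary protein complex, not a model of any particular one;
with two orders of magnitude fewer charges and far less excluded volume
than a real complex, its barriers are kcal-scale rather than tens of
kcal/mol, and only the direction of the rmax and ρ responses — not their
magnitudes — carries over.

**Boltzmann sampler.** Inverse-transform sampling of a tabulated 1-D
potential on a 4001-point interpolation grid; serves as the independent
oracle for the PMF estimator.

## What the synthetic ensembles do and do not show

The rigid-fragment ensembles emulate conformer ensembles indexed by a
separation coordinate with small thermal jitter; they do not sample a
force field, so side-chain rotations, solvent-separated configurations and
anharmonic contact fluctuations are absent. Consequences observed here:
the salt-bridge window averages reproduce the component mechanism —
desolvation penalty rising and interaction energy falling with ρ_H, the
interaction response ~−7 kcal/mol over ρ_H 1.1→1.5 — but in the perfectly
bidentate rigid geometry both carboxylate oxygens and the carboxyl carbon
are simultaneously descreened by all five growing hydrogen spheres, so the
desolvation response (~+7 kcal/mol) is roughly double that of a thermal
ensemble and the two responses nearly cancel in the total. Passing the
trend tests therefore demonstrates the mechanism, not quantitative
transferability to MD ensembles.

## Numerical choices

- Descreening integrals clip tiny negative round-off to zero; the
  quadrature oracle raises (carrying its estimate and error bound) if its
  error estimate exceeds 50× the relative target on a non-negligible
  value.
- The infinite-separation reference is analytic (intra-only descreening),
  never a large-d numerical evaluation.
- Profile CSV files embed a one-line JSON metadata header (overrides,
  rmax, mode) and use a fixed float format so identical runs are
  byte-identical.
- PQR I/O uses the whitespace-separated dialect, writes chain letters and
  TER records, and accepts both the 10-column (no chain) and 11-column
  (chain) forms; molecule tags come from the chain column when present,
  else from TER-separated groups. Numeric fields round-trip at 1e−4.

## Known limitations

- The pairwise descreening sum has no analytic overlap correction beyond
  the per-class scale factors; densely overlapping geometries rely on the
  plain-mode clamp or the obc2 tanh saturation.
- No salt/ionic-strength term, no nonpolar (surface-area) solvation term,
  no periodic boundaries; all analyses are open-boundary two-body.
- The toy pair's barrier magnitudes are desk-scale caricatures (see
  above); the salt-bridge total-energy response to ρ_H is suppressed by
  the rigid bidentate geometry.
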