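# gborn

Generalized-Born (GB) electrostatic analysis for charged biomolecular
systems: effective Born radii from the pairwise descreening integral with an
adjustable lower limit (the intrinsic atomic radius ρ) and upper cutoff
(rmax), and the decomposition of the Coulomb energy in water into a self
(desolvation) term and an inter-molecular interaction term.

The package is for modellers who tune implicit-solvent parameters: it makes
explicit *how* the intrinsic radius and the integration cutoff shift the
balance between the desolvation penalty and the Coulomb attraction when an
ionic or hydrogen bond ("Coulomb bond") forms. Everything runs on exactly
regenerable synthetic systems — a two-atom H–O pair, an idealized
arginine–glutamate salt bridge, and a toy charge-complementary protein pair
— or on user structures in PQR format.

## Model

Each atom *i* is a sphere with partial charge *qᵢ* and intrinsic radius
*ρᵢ*. The descreening integral

    Iᵢ = (1/4π) ∫  dr / |r|⁴   over  ρᵢ ≤ |r| ≤ rmax,  r ∈ V_excl

runs over the water-excluded volume contributed by the other atoms
(evaluated as a sum of closed-form per-sphere integrals). It grows from 0
(fully solvated) to 1/ρᵢ (fully desolvated) and sets the effective Born
radius, 1/Rᵢ = 1/ρᵢ − Iᵢ (plain mode) or through the OBC(II) tanh rescaling.
Energies (kcal/mol, charges in e, lengths in Å, k = 332.0636):

- self:        G_self,i = (1/εw − 1) k qᵢ² / (2Rᵢ)
- desolvation: ΔG_self,i = G_self,i(d) − G_self,i(∞), referenced to the
  intact molecules at infinite separation in water
- interaction: G_int = Σ_pairs k qₖqₗ/dₖₗ + (1/εw − 1) k qₖqₗ / f_gb(dₖₗ,Rₖ,Rₗ),
  with f_gb = √(d² + RᵢRⱼ exp(−d²/4RᵢRⱼ)), summed over cross-molecule pairs
- total Coulomb: ΔG_self + G_int

The analysis layer scans these terms along a separation coordinate *d*,
over per-class ρ overrides and over rmax, averages them over conformer
ensembles in distance windows, and estimates potentials of mean force from
distance histograms as −RT ln[n(d)/N_ref].

## Worked example

```python
from gborn.reproduce import ho_contact_table

for rho_h, row in ho_contact_table().items():
    print(rho_h, round(row["dGself_total"], 3), round(row["G_int"], 3))
```

prints, for the H–O pair (qO = −0.82 e, ρO = 1.5 Å, qH = +0.45 e) at its
energy-minimum distance d = 1.57 Å with εw = 78.5 and no cutoff:

```
1.1 6.477 -16.769
1.2 6.379 -17.96
1.3 6.496 -19.112
1.4 6.797 -20.236
1.5 7.261 -21.337
```

Reading: as the hydrogen intrinsic radius grows from 1.1 to 1.5 Å, the
total desolvation penalty barely moves (+0.78 kcal/mol — the oxygen's
rising penalty is offset by the hydrogen's falling one), while the
interaction term deepens by −4.57 kcal/mol. The extra Coulomb-bond
stability at larger ρ comes from the interaction term, not from a relieved
desolvation penalty. `examples/` contains one narrative script per
capability (two-atom mechanism, salt-bridge window averages, toy-pair
rmax/ρ trends, PMF estimation, PQR I/O + Born radii export).

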