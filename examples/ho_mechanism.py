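"""Two-atom (H-O) mechanism: why a larger hydrogen radius stabilizes the
Coulomb bond.

Builds the printed H-O pair (qO = -0.82 e, rhoO = 1.5 Å; qH = +0.45 e),
scans the hydrogen intrinsic radius rho_H from 1.1 to 1.5 Å at the contact
distance d = 1.57 Å with eps_w = 78.5 and no integration cutoff, and
locates the total-energy minimum with the ff99 Lennard-Jones pair attached.
"""

from gborn.reproduce import ho_contact_table, ho_minimum_locations

table = ho_contact_table()
print("H-O pair at d = 1.57 A (kcal/mol):")
print(f"{'rho_H':>6} {'dGself_O':>9} {'dGself_H':>9} {'dGself':>8} "
      f"{'G_int':>9} {'total':>9}")
for rho_h, row in table.items():
    print(f"{rho_h:6.1f} {row['dGself_O']:9.3f} {row['dGself_H']:9.3f} "
          f"{row['dGself_total']:8.3f} {row['G_int']:9.3f} "
          f"{row['coulomb_total']:9.3f}")

d_self = table[1.5]["dGself_total"] - table[1.1]["dGself_total"]
d_gint = table[1.5]["G_int"] - table[1.1]["G_int"]
print(f"\nrho_H 1.1 -> 1.5: desolvation changes by {d_self:+.2f} but the "
      f"interaction term by {d_gint:+.2f} kcal/mol:")
print("the oxygen and hydrogen desolvation changes counterbalance, so the")
print("interaction term, not the desolvation penalty, drives the extra")
print("Coulomb-bond stability at larger rho_H.")

print("\nTotal-energy (Coulomb + LJ) minimum per rho_H:")
for rho_h, (d_min, value) in ho_minimum_locations().items():
    print(f"  rho_H = {rho_h:.1f}: d_min = {d_min:.3f} A, "
          f"E_min = {value:.2f} kcal/mol")
print("The minimum stays at ~1.57 A while deepening with rho_H.")
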