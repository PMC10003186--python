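"""Toy charge-complementary protein pair: the rmax / rho two-way adjustment.

Scans the rigid-approach total Coulomb energy of two ~50-bead clusters with
complementary interface patches at three descreening cutoffs rmax, then
compares contact-window (23.6-23.8 Å center-of-mass) averages for two
intrinsic-radius settings at the small cutoff.
"""

from gborn.reproduce import toy_pair_barriers, toy_pair_window_average

print("Total-Coulomb barrier height (max over approach minus dissociated")
print("plateau), OBC-II Born radii:")
for rmax, barrier in toy_pair_barriers(seed=1).items():
    print(f"  rmax = {rmax:4.0f} A: barrier = {barrier:6.3f} kcal/mol")
print("A larger integration cutoff inflates the desolvation penalty under")
print("the Coulomb-field approximation, raising the association barrier.")

print("\nContact-window averages at rmax = 10 A:")
lo = toy_pair_window_average({"H-on-N": 1.3, "O-carboxyl": 1.5}, seed=1)
hi = toy_pair_window_average({"H-on-N": 1.4, "O-carboxyl": 1.6}, seed=1)
for label, row in (("rho_H 1.3, rho_O 1.5", lo), ("rho_H 1.4, rho_O 1.6", hi)):
    print(f"  {label}: dGself = {row['dGself']:6.3f}, G_int = {row['G_int']:8.3f}, "
          f"total = {row['coulomb_total']:8.3f} (n = {row['n']})")
print("Raising the hydrogen and carboxyl-oxygen radii lowers the window")
print("total: the interaction gain outweighs the added desolvation penalty,")
print("so a small rmax plus larger intrinsic radii favors binding.")
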