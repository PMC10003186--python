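"""Idealized Arg-Glu salt bridge: window-averaged energetics vs rho_H.

Generates the synthetic bidentate guanidinium-carboxylate ensemble
(Gaussian jitter 0.1 Å), averages the GB energy terms over snapshots whose
Czeta-Cdelta distance falls in the 3.9-4.0 Å Coulomb-bond window, and
compares hydrogen intrinsic radii 1.1 / 1.3 / 1.5 Å (OBC-II Born radii,
eps_w = 78.5, rmax = 999 Å).
"""

from gborn.reproduce import salt_bridge_window_average, salt_bridge_window_ensemble

ens = salt_bridge_window_ensemble(seed=1, snapshots_per_d=60)
print(f"ensemble: {len(ens)} snapshots")
print(f"{'rho_H':>6} {'dGself':>8} {'G_int':>9} {'total':>9} {'n':>5}")
rows = {}
for rho_h in (1.1, 1.3, 1.5):
    row = salt_bridge_window_average(rho_h, seed=1, ensemble=ens)
    rows[rho_h] = row
    print(f"{rho_h:6.1f} {row['dGself']:8.3f} {row['G_int']:9.3f} "
          f"{row['coulomb_total']:9.3f} {row['n']:5d}")

print("\nGrowing rho_H raises the desolvation penalty and deepens the")
print("interaction term (the interaction-driven mechanism); in this rigid bidentate")
print("stand-in the two responses nearly cancel in the total:")
diff = rows[1.1]["coulomb_total"] - rows[1.5]["coulomb_total"]
print(f"E(rho_H=1.1) - E(rho_H=1.5) = {diff:+.2f} kcal/mol")
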