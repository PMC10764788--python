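"""Inspect the two model landscapes: minima and barrier heights.

Both are 2D double wells in units of k_B*T (300 K).  The two-wells trap has
a y-independent 5 kBT Gaussian ridge; the modified Faradjian-Elber surface
has a 12 kBT ridge pierced by a narrow 3 kBT saddle at y = 0 -- the textbook
case where the x-coordinate alone is a poor reaction coordinate.
"""

import resetmetad as rm

for family, sections in [("two_wells", [0.0, 10.0]),
                         ("faradjian_elber", [0.0, 25.0])]:
    pot = rm.make_potential(family)
    print(f"\n{family}:")
    for y in sections:
        s = rm.barrier_summary(pot, y=y)
        print(f"  section y={y:5.1f} A: minima at x = "
              f"{s['minima'][0]:+.3f}/{s['minima'][-1]:+.3f} A, "
              f"barrier {s['barrier_height']:.3f} kBT at x = {s['barrier_x']:+.3f} A")

print("\nThe barrier a trajectory must cross is ~5 kBT (two wells) at any y,"
      "\nbut for the Faradjian-Elber surface it is 3 kBT only through the"
      "\nnarrow saddle near y = 0 and 12 kBT elsewhere.")
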