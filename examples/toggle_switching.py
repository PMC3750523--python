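"""Mean switching time of a multimer-regulated genetic toggle switch.

Two genes repress each other through their order-N homomers; the switch
state is whichever gene's multimer is currently more abundant.  The
repression scale C sets the dissociation constant K = 25 C.  Strong
repression (small C) makes states long-lived — and longer-lived the higher
the multimer order — while weak repression lets fluctuations flip the
switch quickly, fastest for the highest order.
"""

import multinoise as mn

result = mn.run_toggle_sweep(orders=(1, 2, 3), C_grid=(1e-3, 1e3),
                             n_samples=60_000, replicates=3, base_seed=5)

for _, row in result.table.iterrows():
    regime = "strong" if row.C < 1 else "weak  "
    print(f"N={row.order}  C={row.C:8.3g} ({regime} repression)  "
          f"switches={row.n_switches:6d}  time/switch={row.time_per_switch:8.2f}")
print("\nTime per switch grows with order under strong repression and is"
      "\nsmallest for the highest order under weak repression.")
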