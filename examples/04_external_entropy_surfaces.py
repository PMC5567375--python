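"""External entropy production in the intercellular gap.

Heat released by the cell and matter exported to the gap both produce
entropy outside the cell; the heat channel dominates by many orders of
magnitude in both cell types.
"""

from cellentropy import builtin_cases, evaluate_case, mixture_rate

for label, case in builtin_cases().items():
    g = case.geometry
    fields = evaluate_case(case)
    print(f"{label} cell, gap [{g.L * 1e6:.0f}, {(g.L + g.gap) * 1e6:.2f}] um:")
    for comp in ("reQ", "re_exch"):
        peak, x_pk, t_pk = fields[comp].peak()
        print(f"  {comp:8s} peak = {peak:.3e} J/(K m^3 s) "
              f"at x-L = {(x_pk - g.L) * 1e9:6.1f} nm, t = {t_pk * 1e6:6.1f} us")
    spot = mixture_rate(case, "reQ", g.L + g.gap, 1e-4)
    print(f"  reQ at the far gap edge, t = 100 us: {spot:.3e} J/(K m^3 s)")
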