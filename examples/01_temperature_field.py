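"""Intracellular temperature field of a normal breast cell.

The cell starts uniformly at T0 = 310 K with cold walls; the Fourier series
solution cools from the boundary inward.  Prints the centre temperature at a
few times and the wall gradient driving the conductive heat flux.
"""

import numpy as np

from cellentropy import builtin_cases, temperature, temperature_gradient

case = builtin_cases()["normal"]
g, e = case.geometry, case.env

print(f"normal cell: L = {g.L * 1e6:.0f} um, kappa = {e.kappa:.3g} m^2/s, T0 = {e.T0:.0f} K")
for t_us in (1, 10, 100, 1000):
    T = temperature(g.L / 2, t_us * 1e-6, g, e)
    print(f"  T(L/2, {t_us:>4d} us) = {T:8.3f} K  ({T / e.T0:.4f} T0)")
# thermal relaxation time L^2/(kappa pi^2) ~ 70 us: by 1 ms the interior has
# essentially equilibrated with the cold walls
grad = temperature_gradient(g.L / 4, 1e-4, g, e)
print(f"  dT/dx(L/4, 100 us) = {grad:.3e} K/m -> conductive heat flux "
      f"J_Q = {-e.K_th * grad:.3e} W/m^2")
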