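# Methods

## Model and assumptions

The cell is treated as an open thermodynamic system in local equilibrium.
Five assumptions fix the geometry of the closed forms: (i) the cell is a
cube of side `L` (any convex shape of equal volume maps onto it); (ii)
flows run along one preferential direction `x`; (iii) irreversible
processes originate at the centre of the cytoplasm, `x = L/2`, where the
mitochondrial/perinuclear region sits; (iv) there are no cross-effects
between heat and matter flows (no Soret/Dufour coupling); (v) the nuclear
volume is negligible.  The membrane (a few Å against µm cell sizes) is
ignored.

The entropy density rate splits into an internal part — the force × flow
sum over heat conduction, species diffusion and reaction advancement — and
an external part in the intercellular gap, `[L, L+g]`, carried by released
heat and exported products.  The README lists the five closed forms; this
note records what goes into them and what the package does with them.

### Temperature field

`T(x,t)` solves the 1D heat equation with the interior initially at `T0`
and both walls clamped to the intercellular baseline, which the model takes
as the zero of its temperature scale.  The odd square-wave Fourier series
and its term-wise cosine derivative are the analytic backbone of the heat
and diffusion terms.  Physically, walls at absolute zero are a strong
idealization; the package implements the series exactly as the model
defines it, and the consequences (below) are reported rather than hidden.

### Chemical potentials, concentrations, fluxes

Each species carries `mu_k(x,t) = u_k e^{-(|x-L/2|/L + t/tau)}`, anchored
at the tabulated standard-state value `u_k` (kJ/mol at 298 K; using
standard values is justified by the near-atmospheric intracellular pressure
via Gibbs–Duhem).  No activity corrections are applied to the charged
species.  Concentrations spread from the origin as the 1D point-source
Gaussian of Fick's law, and the diffusive flux is its exact derivative,
`J_Dk = (x-L/2)/(2t) n_k`.  The Gaussian kernel carries a unit length
`l = 1 m` chosen so that `-D dn/dx` reproduces the diffusion entropy term's
printed flux factor `N_mk (x-L/2) e^{-(x-L/2)^2/4Dt} / (4 sqrt(pi D) V
t^{3/2})` exactly; this is the one normalization convention the closed
forms leave open, and it is fixed once here.

## Parameters (defaults and units)

| parameter | meaning | normal | cancer |
|---|---|---|---|
| `L` | cell side, m | 10e-6 | 20e-6 |
| `gap` | intercellular spacing, m | 0.25e-6 | 1.5e-6 |
| `x0` | exchange-kernel length, m | 10e-6 (normal-cell size) | same |
| `T0` | reference temperature, K | 310 | 310 |
| `K` | thermal conductivity, J/(m s K) | 0.600 | 0.600 |
| `kappa` | thermal diffusivity (water), m²/s | 0.143e-6 | 0.143e-6 |
| `tau` | cell decay time, s | 1e-4 | 1e-4 |
| `p_heat` | heat-term weight | 0.85 | 0.90 |
| `w_resp/w_ferm` | process weights | 0.8/0.2 | 0.1/0.9 |
| `k_kin` | pathway kinetic constant, 1/s | 1e-4 (resp), 1e-5 (ferm) | same |
| `N_m,glucose` | moles processed | 1 | 1 |

`T0` is the one parameter the model leaves unstated; 310 K (body
temperature) is the default, it only rescales the fields, and every output
table records the value used.  Mole numbers of the other species default to
`|nu_k|` per mole of glucose (so `N_mpr = 12` for respiration, 4 for
fermentation), and default export rates are `|nu_k| k_kin` per product with
`dtau1 = 1/k_kin`.  The heat weight `p_heat` and the process weights `w`
are independent: `p_heat` enters only the heat-term prefactor, while `w`
mixes the per-reaction diffusion/reaction/external fields linearly.
`k_B N_A` is taken from scipy.constants.

## Evaluation lattice

Defaults: 201 interior points on `[0.02 L, 0.98 L]`, 101 gap points on
`[L, L+g]`, 200 log-spaced times on `[1 µs, 1 ms]` (the fields vary over
decades in t).  The margins are structural, not cosmetic: `T -> 0` at the
walls makes the `1/T²` factors singular, and the Gaussian kernels are
singular at `t = 0`.  `t = 0` itself is defined only for the temperature
(square initial profile) and the reaction term.

## Numerical design

**Dual series evaluation.**  The sine/cosine sums are Jacobi theta
functions of `a = kappa pi^2 t / L^2`.  For `a >= 1/2` the spectral form
converges in a few terms; for `a < 1/2` its terms are O(1) while the true
value of the cosine series can be `~e^{-1/a}` — catastrophic cancellation.
There the package evaluates the Poisson-resummed method-of-images form
(Gaussians at `x = jL` with alternating signs), which has no cancellation.
Both forms are written in the centre displacement `d = x - L/2` with
mirror-image pairs kept adjacent, so that in floating point `T` is exactly
even and `C` exactly odd about the centre; this is what makes the
evenness/zero invariants hold to machine precision rather than to a loose
tolerance.  Magnitudes below 1e-150 (whose squares would be subnormal) are
flushed to zero; the true series values there are astronomically smaller
still.  Truncation: 200 odd harmonics by default with an adaptive tail
bound `e^{-a(2n+1)^2}`; for `t >= 10 µs` doubling the count changes nothing
at double precision (the acceptance suite asserts < 1e-8).

**Oracles.**  The temperature series is cross-checked against a
Crank–Nicolson solve of the heat equation (2001 nodes, dt = 0.1 µs,
implicit and unconditionally stable; sparse LU factorized once), agreeing
to ~1e-5 relative on `[0.05L, 0.95L] x [10 µs, 1 ms]`.  The concentration
kernel is cross-checked against a Crank–Nicolson solve of Fick's law
started from the exact kernel at 5 µs.  The diffusion and exchange terms
are re-evaluated in 50-digit mpmath arithmetic in the tests (1e-10
agreement).  The heat term satisfies `r_iQ = p K e^{-t/tau} (dT/dx)^2/T^2`
identically; the package asserts it to 1e-10 (observed ~1e-15).

**Force × flow reconstruction of the diffusion term.**  Summing
`mu_k (dT/dx)/T² · J_Dk` over species (dropping the `d(mu)/dx` cross term
per assumption iv) reproduces the diffusion term's shape exactly; the
pointwise ratio is constant (coefficient of variation ~1e-13) but its value
is a model normalization convention, so the verification module reports the
ratio and does not assert a particular constant.

## Late-time behaviour (a property of the closed forms)

With cold walls, `T` decays like `e^{-lambda t}`, `lambda = kappa pi^2 /
L^2` (1.41e4/s normal, 3.5e3/s cancer).  The heat term is neutral in this
decay (`C²/T²` saturates) and decays as `e^{-t/tau}`.  The reaction and
diffusion terms carry fewer powers of the series in the numerator than the
two in the denominator, so they grow like `e^{(2 lambda - 1/tau) t}` and
`e^{(lambda - 1/tau) t}` (plus a growing Gaussian factor) once the wall
cooling penetrates — for the normal cell from roughly 100–400 µs onward.
Consequently:

- monotone decay toward minimum dissipation holds for the heat-flow and
  both external components, but **not** for the diffusion term (both cells)
  or the reaction term (normal cell) on the later part of the default
  window; the invariant suite reports the violating fraction per component,
  and the corresponding acceptance assertions fail by design rather than
  being weakened;
- the lattice peaks of `r_iD` and `r_ir` sit at the late-time corner, so the
  peak normal/cancer contrast of the reaction term (~7.7e9 on the default
  lattice) vastly exceeds the `w k_kin / V` scaling (~62×) that holds at
  early times while `T ≈ T0`; the acceptance script reports both numbers;
- the heat-release term `r_eQ ∝ (x-L)²/t²` is formally *even* in time: the
  time-reversal probe (`formal_time=True`, a fixed truncation of the
  printed forms at `-t`) distinguishes `+t` from `-t` for four of the five
  components but cannot for this one.

These are analytical properties of the closed forms under the stated
parameters, confirmed numerically; none of them is a tunable of this
package.

## What the built-in cases do and do not represent

The built-in configurations are idealized single cells: fixed reagent
pools (`N_mA` does not deplete), one effective first-order step per
pathway, standard-state potentials, 1D transport, no cell–cell
interactions and no NAD⁺/NADH or ATP/ADP bookkeeping (their concentrations
vary over small ranges and the associated reactions are either reversible
or non-spontaneous).  Passing tests therefore validate the closed forms
and their implementation — not quantitative agreement with calorimetry of
real tissue.  Extension to multi-cell aggregates is out of scope.

## Degenerate inputs and edge cases

- `x` outside the relevant region or `t < 0` raise `DomainError`
  (negative `t` is admitted only behind the `formal_time` flag).
- `t = 0`: temperature returns the square initial profile; the gradient and
  the Gaussian kernels are refused (singular).
- The exact centre column of the lattice is an odd-symmetry zero of `r_iQ`
  and `r_iD`; monotonicity checks skip identically-zero columns.
- A reaction with negative affinity flips the sign of `r_ir`; the
  nonnegativity invariant flags it (the suite reports, the model does not
  forbid it).
- Config files are validated field-by-field with errors naming the missing
  or offending key; weights must sum to 1 within 1e-12; writing and
  re-loading a configuration reproduces every SI value bit-exactly (unit
  conversions pick the representable kJ/µm value whose product with the
  unit restores the original float).
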