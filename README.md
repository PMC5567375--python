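# cellentropy

Closed-form space–time fields for the **rate of entropy density production**
of irreversible processes in a single cell, with glucose catabolism in
normal and cancer breast cells as fully parameterized built-in case studies.

Living cells are open thermodynamic systems in local equilibrium: heat
conduction, molecular diffusion and irreversible chemical reactions all
produce entropy, and the *rate* of that production — not just finite
entropy differences between reactants and products — carries the signature
of the cell's metabolic state.  Cancer cells shift glucose catabolism from
oxidative phosphorylation toward lactic fermentation (the Warburg effect)
and change both size and intercellular spacing, so their entropy-rate
fields differ measurably from normal cells.  This package is for
computational biophysicists and systems biologists who want those fields as
concrete, verifiable numbers.

## The model

A cubic cell of side `L` (volume `V = L³`), 1D transport along `x`,
processes originating at the centre `x = L/2`.  The internal rate
`r_i = r_iQ + r_iD + r_ir` is a sum of force × flow products
(Prigogine entropy balance):

- **heat flow**  `r_iQ = α C(x,t)² e^{−t/τ} / T²`, `α = 16 p K T₀²/L²`,
  identically equal to `p K e^{−t/τ} (∂T/∂x)²/T²`;
- **matter diffusion**
  `r_iD = β (x−L/2) e^{−t/τ} t^{−3/2} [Σ_k u_k N_mk e^{−(x−L/2)²/4D_k t}/4√D_k] C e^{−|x−L/2|/L} / T²`,
  `β = T₀/(√π V)`;
- **chemical reaction**
  `r_ir = −(4/π) T₀ k_kin [Σ_k ν_k μ_k(x,t)] N_A^p N_B^q / (V^{p+q} T²)`,

with `T(x,t)` the Fourier sine-series solution of the heat equation (cell
initially at `T₀`, cold walls), `C(x,t)` its damped cosine series,
`μ_k(x,t) = u_k e^{−(|x−L/2|/L + t/τ)}` the damped chemical potentials and
`A = −Σ ν_k μ_k > 0` the affinity of a spontaneous reaction.  Outside the
cell, in the intercellular gap of width `g`:

- **heat release** `r_eQ = (3/8)(k_B N_A / V) N_mpr (x−L)²/(κ t²)`;
- **matter exchange**
  `r_e,exch = −η √t e^{(x−L)²/4κt} Σ_{products} μ_k dN_mk/dτ₁`,
  `η = √(4πκ)/(V x₀ T₀)` — the growing exponential is the inverse of the
  free-space intercellular heat kernel.

Two reactions are built in, weighted by occurrence (`w_resp`, `w_ferm`):

```
respiration:   C6H12O6 + 6 O2 -> 6 CO2 + 6 H2O      A = 2920.23 kJ/mol
fermentation:  C6H12O6 -> 2 C3H5O3⁻ + 2 H⁺           A =  116.00 kJ/mol
```

Normal cell: `L = 10 µm`, gap 0.25 µm, weights 0.8/0.2, heat weight 0.85.
Cancer cell: `L = 20 µm`, gap 1.5 µm, weights 0.1/0.9, heat weight 0.90.
All standard potentials and diffusivities are carried in the built-in
species table; `T₀` defaults to 310 K and is recorded in all output
metadata.

## Worked example

```python
from cellentropy import builtin_cases, evaluate_case, standard_affinity

case = builtin_cases()["normal"]
a = standard_affinity(case.reaction("respiration"), case.species)
print(f"A_resp = {a/1e3:.2f} kJ/mol")
fields = evaluate_case(case)                 # all 7 surfaces, 201 x 200 lattice
peak, x_pk, t_pk = fields["rir"].peak()
print(f"rir peak {peak:.3e} J/(K m^3 s) at x={x_pk*1e6:.2f} um, t={t_pk*1e6:.0f} us")
```

prints

```
A_resp = 2920.23 kJ/mol
rir peak 7.662e+24 J/(K m^3 s) at x=0.20 um, t=1000 us
```

— the respiration affinity is the Gibbs-energy driving force per mole of
glucose, and the reaction-term peak sits at the lattice corner nearest the
wall at the latest time, where the cold-wall temperature denominator is
smallest (see `docs/methods.md` on this late-time behaviour).  The
`examples/` directory has one short script per capability (temperature
field, affinities, internal/external surfaces, normal-vs-cancer contrast,
verification oracles), and the same workflow is scriptable from a shell:

```sh
cellentropy init --case normal --out normal.yaml
cellentropy compute --config normal.yaml --out surfaces/
cellentropy verify --case normal --report verify.txt
cellentropy compare --out compare.txt
```

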