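# saftsol

PC-SAFT solid–liquid-equilibrium solubility of drug molecules in pure and
mixed solvents.

Early in pharmaceutical process development the solubility of an active
pharmaceutical ingredient (API) must be known across many solvents and
cosolvent blends, yet measuring whole solubility curves for every candidate
system is slow and material-hungry.  `saftsol` is for formulators and
thermodynamic modelers who have (or can estimate) PC-SAFT parameters for an
API: given the five-parameter set, the melting properties of the polymorph
and literature solvent parameters, it predicts saturation compositions with
no or a single experimental data point per system.

## Model

The saturation mole fraction x_API at temperature T solves

    x_API · γ_API(x, T) = exp[ −Δh_SL/(R·T) · (T_SL − T)/T_SL
                               − Δc_p_SL/R · (ln(T_SL/T) + (T − T_SL)/T) ]

where T_SL, Δh_SL, Δc_p_SL are the melting temperature, enthalpy and
solid–liquid heat-capacity difference of the polymorph, and the activity
coefficient γ_API comes from the PC-SAFT equation of state (hard chain +
dispersion + 2B association) with the subcooled liquid as reference state.
Binary interaction parameters k_ij correct the cross dispersion energy
u_ij = √(u_i·u_j)(1 − k_ij); a single measured solubility point suffices to
regress k_ij for a system.  Solubility in g/L follows from
S = ρ_solvent · x/(1−x) · M_API/M_solvent.

The package bundles parameter tables for 21 APIs (2B association scheme)
with their melting properties, and literature PC-SAFT sets for 13 common
solvents.  See `docs/methods.md` for the full model description, numerical
choices and limitations.

## Worked example

Ibuprofen (IBU) in ethanol at 298.15 K, with no binary data (k_ij = 0):

```python
from saftsol import default_database, ideal_solubility, solve_solubility

db = default_database()
ibu, etoh = db.component("IBU"), db.component("EtOH")
mp = db.melting_props("IBU")

print(ideal_solubility(mp, 298.15))
res = solve_solubility(ibu, mp, [etoh], [1.0], None, 298.15, compute_gL=True)
print(res.x_API, res.gamma_API, res.S_gL)
```

prints

    0.2354643123071532
    0.053797449514403524 4.376866... 198.5380195803383

The ideal (γ = 1) solubility from the melting properties alone is
x = 0.2355; PC-SAFT finds γ_API ≈ 4.38 in ethanol, reducing the predicted
saturation mole fraction to x ≈ 0.0538, i.e. about 199 g of ibuprofen per
litre of ethanol.  Fitting k_ij to one measured point then sharpens every
other prediction for that system:

```python
from saftsol import fit_kij_single_point

report = fit_kij_single_point(ibu, mp, etoh, T_exp=298.15, x_exp=0.26)
print(report.k_ij, report.converged)   # -0.0393327...  True
```

The same machinery runs from the shell:

    saftsol predict --api IBU --solvent EtOH --temp 278.15:318.15:10
    saftsol fit-kij --api IBU --solvent EtOH --temp 298.15 --solubility 0.26
    saftsol blend --api IBU --solvents EtOH,WAT --temps 298.15 --kij-file kij.csv
    saftsol evaluate --data points.csv --scenario fit1 --out report.json,parity.csv

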