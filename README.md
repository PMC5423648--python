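# shiftbind

Analysis of protein–ligand binding followed residue-by-residue by NMR, with
an isothermal titration calorimetry (ITC) cross-check — built for the common
situation in protein-observed titrations where the protein concentration
(tens to hundreds of μM) is comparable to the dissociation constant, so
ligand depletion cannot be ignored.

It is aimed at structural biologists and biophysicists who titrate a ligand
into an ¹⁵N-labelled protein, follow the amide cross-peaks of a ¹H–¹⁵N HSQC
across the titration, and want per-residue chemical-shift-perturbation (CSP)
maps, a shared dissociation constant from a global fit, exchange-broadening
flags, and thermodynamic comparisons between differently liganded states.

## The model

**Combined CSP.** For each residue the amide shift change between two states
is collapsed to the weighted Euclidean norm

    Δδ = sqrt( Δδ_H² + (Δδ_N / 5)² )        [ppm]

with the conventional factor 5 compensating the wider ¹⁵N range.

**Binding with ligand depletion.** For a 1:1 complex, mass balance gives the
bound fraction exactly:

    [PL] = ( ([P]t + [L]t + K_d) − sqrt( ([P]t + [L]t + K_d)² − 4 [P]t [L]t ) ) / 2

In fast exchange each residue's observed CSP is Δδ_obs = Δδ_max·[PL]/[P]t.
A titration followed for many residues is fitted **globally**: one shared
K_d, one Δδ_max per residue, by bounded least squares, with curvature-based
standard errors.

**ITC.** Integrated injection heats follow the standard one-site
(Wiseman) isotherm with per-injection displacement of the cell volume:
q_i = V₀·ΔH·([PL]_i − [PL]_{i−1}(1 − v_i/V₀)), fitted for (n, K_d, ΔH)
with the small priming injection excluded and a c = n[P]₀/K_d reliability
diagnostic. ΔG = RT ln(K_d/1 M) and −TΔS = ΔG − ΔH follow.

**Cooperativity.** Two liganded states binding the same ligand are compared
by ΔΔG = RT ln(K_d,a/K_d,b) and by fold-change presented the way binding
papers quote them ("10-fold drop").

A seeded synthetic-data generator produces fast-exchange trajectories,
slow-exchange free/bound peak pairs, selective exchange broadening, and
one-site thermograms, so the whole pipeline is verifiable end to end
without any experimental data.

## Worked example

```python
from shiftbind import (SimulationConfig, simulate_fast_exchange, build_trajectories,
                       fit_global, detect_broadened, saturation_percent,
                       simulate_itc, default_itc_design, itc_fit, delta_delta_g)

# a 250 uM protein titrated to 1.75 mM ligand, true Kd 28 uM,
# two residues lost to exchange broadening
cfg = SimulationConfig(kd_true=28.0, n_residues=20, seed=1, broadened_ids=(5, 12))
series = simulate_fast_exchange(cfg)
broadened = detect_broadened(series, alpha=0.1)
trajs = build_trajectories(series, max_jump=0.05)
fit = fit_global({r: t.csp for r, t in trajs.items() if r not in broadened}, series)

exp = simulate_itc(default_itc_design(), kd_true=0.66, dh_true=-60.0, seed=1)
r = itc_fit(exp)
```

This prints (via the f-strings in the example script):

```
broadened residues: [5, 12]
global fit: Kd = 25.8 +/- 2.0 uM (RMS 4.84 mppm, converged=True)
saturation at 8 mM ligand: 99.67 %
ITC fit: n = 1.00, Kd = 0.64 uM, dH = -59.6 kJ/mol, dG = -35.9, -TdS = 23.7 kJ/mol (c = 63)
```

The broadening detector recovers exactly the two residues whose signals
were attenuated; the global fit returns the shared K_d with its standard
error (the truth, 28 μM, is within two standard errors — single noisy
titrations scatter by a few μM); `saturation_percent` confirms that an
8 mM endpoint leaves the enzyme >99.6 % bound, which is what justifies
attributing any remaining line broadening to conformational exchange
rather than incomplete binding; and the ITC fit recovers the tight-binder
parameters with the first injection excluded.

A command-line surface mirrors the library
(`shiftbind simulate-nmr | simulate-itc | csp | fit-nmr | fit-itc | thermo |
annotate-pdb | report`); identical `--seed` and configuration give
byte-identical outputs.

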