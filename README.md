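# micellekit

Micellization descriptors from surfactant titration data.

When an ionic surfactant such as ammonium perfluorooctanoate (APFO) or
sodium dodecyl sulfate (SDS) is titrated into water, four routine bench
measurements each see the critical micellization concentration (CMC) and,
together, characterize the micelles that form:

* **conductivity** κ(C) rises linearly with a slope break at the CMC; the
  post/pre slope ratio α = S₂/S₁ is the degree of counterion dissociation;
* **surface tension** γ falls linearly in log₁₀ C until the interface
  saturates; the Gibbs adsorption isotherm
  Γmax = −(dγ/dlogC)/(2.303 · n · R · T) gives the maximum surface excess,
  Amin = 1/(N_A · Γmax) the minimum headgroup area, and the critical packing
  parameter CPP = V₀/(Amin · l_c) the preferred micelle curvature
  (sphere ≤ 1/3 < cylinder ≤ 1/2 < bilayer ≤ 1);
* **pyrene fluorescence** I1/I3 (the 373/383 nm vibronic band ratio) drops
  from its aqueous value (~1.8) as the probe partitions into micelles; the
  CMC is read from the intersection of the plateau and descent lines;
* **capillary viscometry** gives the relative viscosity
  ηr = 1 + νφ + k₁(νφ)², φ = Vshyd · N_A · (c_s − CMC); the virial fit
  returns the hydrated molecular volume Vshyd, from which hydration-water
  and cosolvent (e.g. urea) solvation counts follow by volume bookkeeping.

micellekit implements this whole chain for chemists studying surfactant
self-assembly — in particular how cosolvents like urea reshape fluorinated
surfactant micelles — plus a seeded synthetic-experiment generator for all
four measurement types, so every estimator can be validated by
parameter recovery without instrument data.

## Worked example

Simulate a full APFO-in-water titration campaign (CMC 26.5 mM, α 0.47,
dγ/dlogC −29.6 mN/m, ν 2.97, Vshyd 0.710 nm³, realistic noise) and analyze
it end to end:

```sh
micellekit simulate --what all --seed 17 --out demo
cat > demo/config.json <<'EOF'
{
  "surfactant": "apfo",
  "nu": 2.97,
  "inputs": {
    "conductivity": "demo/conductivity.csv",
    "tension": "demo/tension.csv",
    "fluorescence": "demo/pyrene.csv",
    "viscosity": "demo/viscosity.csv"
  }
}
EOF
micellekit report demo/config.json --out demo/report.json
```

which prints the summary

```
stage         CMC (mM)  alpha  notes
------------  --------  -----  ----------------------------------
conductivity  26.50     0.47
tension       27.05     -      Amin=64.8 A^2, CPP=0.46 (cylinder)
fluorescence  20.41     -
viscosity     26.50     -      Vshyd=0.712 nm^3 (nu=2.97)
```

Reading: the conductivity break recovers the true CMC and counterion
dissociation exactly at this noise level; the Gibbs chain puts ~65 Å² under
each headgroup, a packing parameter of 0.46, i.e. cylindrical micelles; the
virial fit recovers the hydrated volume (0.712 vs 0.710 nm³ true), which at
0.030 nm³ per water molecule corresponds to 11 hydration waters per
surfactant. The fluorescence intersection estimate sits below the true CMC
because the bound-fraction curve bends smoothly rather than piecewise —
see `docs/methods.md`. Individual stages are also available as
`micellekit conduct|tension|fluor|visc|pack` subcommands and as library
functions (`fit_two_segments`, `analyze_tension`, `cmc_from_ratio_curve`,
`fit_virial`, `hydration_budget`, ...).

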