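# doxrelease

Kinetic and thermodynamic analysis of reversible, electrostatic drug
binding and release — built around doxorubicin carried in the corona of
amphiphilic N-vinyl-2-pyrrolidone/acrylic-acid copolymer nanoparticles,
and applicable to any system whose release follows reversible
first-order kinetics.

Protonated doxorubicin binds ionically to the carboxylate groups of
acrylic-acid residues in the nanoparticle corona and is released again
in a reversible first-order exchange:

    d C_DOX / dt = k1 C_IDOX − k−1 C_DOX,      k−1 = k′−1 · C_COOH

where `C_DOX` is free drug, `C_IDOX` immobilized drug, `k1` the release
and `k−1` the (pseudo-first-order) binding rate constant. Written in
terms of the release conversion ξ = C_DOX / C_DOX^max this integrates
to a single exponential approach to equilibrium,

    ξ(t) = ξ∞ (1 − e^−(k1+k−1) t),   ξ∞ = K / (1 + K),   K = k1 / k−1,

so a measured release curve yields ξ∞, hence K, hence — via the slope
of ln(ξ∞ − ξ) against t or a direct exponential fit — the summed rate
constant, which K splits into k1 and k−1. Rate constants measured
across temperature then give the Arrhenius activation energies of
release and binding, the van't Hoff enthalpy of the release
equilibrium (slope of ln K vs 1/T), and the standard Gibbs energy and
entropy, ΔG°(T) = −RT ln K and ΔS° = (ΔH° − ΔG°)/T.

The package is aimed at formulation and drug-delivery scientists who
fit dialysis release curves: it provides the forward model and its
exact algebra (`doxrelease.models`), curve fitting with diagnostics
(`doxrelease.fitting`), the temperature analysis (`doxrelease.thermo`),
a seeded generator of synthetic dialysis experiments over the published
condition grid (`doxrelease.simulate`), CSV interchange
(`doxrelease.io`), and a thin `doxrelease` command-line pipeline.

## Worked example

`examples/thermodynamics_chain.py` takes the published temperature
series of rate constants (278–323 K at pH 7) and recomputes the whole
thermodynamic chain:

```
E_a(release) = 40.8 kJ/mol (r^2 = 0.975)
E_a(binding) = 5.6 kJ/mol (r^2 = 0.995)
dH(release)  = 35.2 kJ/mol (van't Hoff r^2 = 0.963)
  T =   278 K: dG =  8.67 kJ/mol, dS =  95.3 J/(mol K)
  T =   298 K: dG =  5.89 kJ/mol, dS =  98.3 J/(mol K)
  T =   310 K: dG =  5.74 kJ/mol, dS =  94.9 J/(mol K)
  T =   323 K: dG =  4.16 kJ/mol, dS =  96.0 J/(mol K)
```

Release is strongly thermally activated (≈41 kJ/mol) while binding is
nearly diffusion-limited (≈6 kJ/mol); the positive ΔH° and ΔS° mark an
endothermic, entropy-driven release whose ΔG° falls as temperature
rises. `examples/fit_synthetic_curve.py` fits a single noisy simulated
curve (recovering k1 and k−1 within a few percent and a ≈90% bound
fraction at 310 K / pH 7), and `examples/recovery_benchmark.py` scores
recovery across all 15 preset conditions.

The same chain is available from a shell:

```bash
doxrelease simulate --preset temperature --noise 0 --out curves/
doxrelease fit curves/*.csv --out results.csv
doxrelease thermo results.csv
```

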