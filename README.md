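# guvmech

Membrane mechanics of giant unilamellar vesicles (GUVs): a Python toolkit for
extracting the area compressibility (stretching elasticity) modulus *K*<sub>A</sub>
from micropipette-aspiration image series, quantifying leaflet-asymmetry
fluorescence assays, computing lipid-bilayer trajectory metrics, and running
the accompanying population statistics. Every analysis stage has a matching
synthetic-data generator with known ground truth, so the full pipeline can be
validated end to end without any experimental data.

Intended users: membrane biophysicists analysing aspiration or quench
experiments, and simulators who want desk-scale, testable implementations of
the standard bilayer observables.

## The model

A vesicle aspirated into a pipette of inner radius *R*<sub>p</sub> forms a
spherical outer segment of radius *R*<sub>v</sub> and a tongue of length
*L*<sub>p</sub> (cylinder + hemispherical cap). The suction pressure ΔP sets
the membrane tension through the Laplace relation

τ = ΔP·*R*<sub>p</sub> / (2·(1 − *R*<sub>p</sub>/*R*<sub>v</sub>)),

and the relative area expansion α = (*A* − *A*₀)/*A*₀ is computed from the
measured geometry, referenced to the first (prestressed) step. In the
enthalpic regime (τ above ~0.5 mN/m) the tension is linear in the strain,

τ = *K*<sub>A</sub>·α + const,

and *K*<sub>A</sub> is estimated by linear regression
(`ElasticityModel(points).fit()`). Vesicle radii are measured with a Taubin
algebraic circle fit on the brightest 1, 2 and 3 % of ROI pixels; the tongue
tip is localised sub-pixel from the intensity profile along the pipette axis.
All uncertainties are propagated to first order by numeric central
differences.

The bilayer module implements the standard trajectory observables:
phosphorus-plane thickness *h*<sub>PP</sub> (difference of mean P-atom heights
of the two leaflets), mass-density profiles along the membrane normal,
leaflet interdigitation width w = ∫ 4ρ<sub>u</sub>ρ<sub>l</sub>/(ρ<sub>u</sub>+ρ<sub>l</sub>)² dz,
and a box-area-fluctuation estimator
*K*<sub>A</sub> = k<sub>B</sub>T·⟨A⟩/Var(A). The fluorescence module measures
contour-minus-interior intensity (5-px ring) and classifies dithionite-quench
post/pre ratios into dye-sidedness classes. The stats module provides
inverse-error weighted means, Kruskal–Wallis with tie correction, and Dunn +
Holm post-hoc comparisons.

## Worked example

```python
from guvmech import synthetic as syn
from guvmech.pipeline import analyze_aspiration

# simulate an aspiration experiment with known K_A = 500 mN/m:
# a 10-um GUV, 3-um pipette, 10 pressure steps, noise-free imaging
series = syn.gen_aspiration_series(syn.default_aspiration_spec(ka_true=500.0, seed=1))

# run the full image-analysis chain and fit the elasticity model
result = analyze_aspiration(series.images, series.pressures, series.config)
print(result.fit.summary())
```

prints

```
Stretching elasticity fit (tau = K_A * alpha + c)
-------------------------------------------------
K_A             478.7 +/- 8.2 mN/m
intercept      0.5027 +/- 0.0638 mN/m
n_points            9
R^2           0.99797
tau_min          0.50 mN/m
```

The recovered modulus (478.7 mN/m) agrees with the prescribed 500 mN/m to
about 4 %; the residual deviation is the pixel-grid limit of the
circle-fitting chain at 0.2 µm/px (see `docs/methods.md`). The intercept
reflects the tension already present at the prestressed reference step, and
`result.fit.plot(result.points)` draws the tension–area-expansion plot.

A command-line interface mirrors the library:

```sh
guvmech simulate aspiration --out sim --seed 0
guvmech analyze aspiration --images sim/images.tif --pressures sim/pressures.csv \
    --config sim/config.yaml --out analysis
guvmech simulate bilayer --out bl --seed 0
guvmech analyze bilayer --frames bl/frames.pdb --out bl_metrics
guvmech stats --input vesicles.csv --out report
```

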