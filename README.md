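# gelmech

Quantitative analysis of AFM nanoindentation on soft hydrogels, with
companion tools for cell morphometry and tumour-spheroid cluster
quantification — the measurement chain used to characterise how matrix
stiffness shapes cancer-cell behaviour in 3D culture.

The package converts raw force–distance curves (piezo displacement vs
photodetector voltage) into Young's-modulus maps, and grayscale microscopy
images into shape and cluster statistics. Because raw instrument data of
this kind are rarely deposited, a synthetic-data module generates force
curves, force-volume maps, thermal-noise series and cell/cluster images with
exact ground truth, so the full pipeline is testable end to end.

## The model

A rigid cone of half-angle θ pressed quasi-statically into an elastic
half-space follows Sneddon's law

    P(h) = (2/π) · tanθ · E/(1−ν²) · h²,

with load *P*, indentation *h*, Young's modulus *E* and Poisson's ratio *ν*
(0.5 for an incompressible rubber-like gel). The Oliver–Pharr analysis
inverts this from the **unloading** branch, which is free of plastic
effects: the branch is fitted with a power law *P = α·hᵐ* (m ≈ 1.5–2 for a
cone), giving the contact stiffness at maximum indentation

    S = dP/dh |_h_max = α·m·h_max^(m−1),

and the modulus from the rigid-indenter relation

    E = (1−ν²) · (√π/2) · S/√A,

where *A = π·tan²θ·h_c²* is the projected contact area. The default
convention evaluates *A* at the contact depth *h_c = h_max − ε·P_max/S*
(ε = 2(π−2)/π), which is exact for the Sneddon cone; the alternative
`at_h_max` convention evaluates the cone cross-section at *h_max* itself and
systematically yields (2/π)·E.

Upstream of the fit: photodetector voltage is converted to deflection
through the optical-lever sensitivity (reciprocal slope of the
constant-compliance region of hard-substrate curves), to load through the
spring constant (thermal-noise equipartition, k = k_B·T/⟨d²⟩), the
tip–surface contact point is detected by a baseline-threshold crossing
refined by back-extrapolating the contact fit to zero load, and curves whose
contact point cannot be found are discarded by QC. Downstream: per-gel
moduli are summarised as mean ± SD, compared with the two-sided Mann–Whitney
U test (α = 0.05), and formulations that are statistically indistinguishable
are merged into stiffness categories.

The imaging side measures per-cell area, perimeter, best-fit-ellipse axes,
circularity (4π·Area/Perimeter², capped at 1) and roundness (minor/major
axis), bins cluster sizes into occurrence percentages, and computes cluster
density as the percentage of a cluster footprint occupied by cell pixels
after automatic (Otsu) thresholding.

## Worked example

```python
import gelmech as gm

tip = gm.TipSpec(half_angle_deg=22.0)
cant = gm.Cantilever(spring_constant=0.1, sensitivity=20e-9)
cal = gm.Calibration(sensitivity=20e-9, spring_constant=0.1)

# simulate one noiseless force curve on a 200 kPa gel and analyse it
gel = gm.GelSpec(young_modulus=200e3, poisson_ratio=0.5)
acq = gm.AcquisitionSpec(max_indentation=100e-9, deflection_noise_sd=0.0)
curve = gm.simulate_force_curve(gel, acq, tip, cant)
li = gm.preprocess_curve(curve, cal)          # contact detection + P(h)
res = gm.OliverPharrModel(li, tip=tip, nu=0.5).fit()
print(res.summary())
```

prints

```
Oliver-Pharr conical indentation fit
====================================================
unloading samples                   162
h_max                            100.00 nm
P_max                            0.6859 nN
alpha                         6.859e+04 N/m^m (se 8.2e-07)
exponent m                       2.0000 (se 7.4e-13)
residual rms                  6.429e-13 nN
contact stiffness S             0.01372 N/m
projected area A               0.002078 um^2  (contact_depth)
Poisson ratio nu                   0.50
Young's modulus E                200.00 kPa (se 2.4e-09)
```

i.e. the unloading branch of the simulated 200 kPa gel fits a pure
quadratic (m = 2, as conical contact demands), the peak load at 100 nm
indentation is 0.686 nN, and the recovered modulus matches the ground truth
exactly under the contact-depth convention.

A full simulated stiffness study (several gel formulations, three
force-volume maps each, calibration estimated from synthetic thermal-noise
and glass-substrate data, QC, per-curve fits, Mann–Whitney comparison and
category merging) runs through `gelmech.run_mechanics_pipeline`, or from the
shell:

```bash
gelmech simulate-fv --e-kpa 500 --grid 16 --noise-nm 0.5 --seed 1 --out fv.h5
gelmech fit --in fv.h5 --cal cal.json --out estimates.csv
gelmech stats --estimates estimates.csv --group-by condition --out groups.json
```

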