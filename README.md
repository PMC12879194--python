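# chronotopy

Quantitative tools for studying **chronotopy** in the developing spinal
dorsal horn: the ordered settlement of late-born dorsal interneuron (dIL)
families into laminar positions according to their birthdate. The package
implements, as a tested and reusable pipeline, the bespoke procedures such a
study needs — and ships a synthetic-data module that generates every input
with known ground truth, so the whole pipeline is verifiable end to end
without any microscopy or sequencing data.

It is aimed at developmental neurobiologists and computational biologists
quantifying cell positions on tissue sections, EdU birthdating series,
cell-type composition time courses, and genotype comparisons of laminar
marker distributions.

## What it computes

**Landmark registration (`chronotopy.register`).** Each section carries ten
anatomical anchors (dorsal/lateral dorsal-horn extremes, dorsal-column base,
lateral/ventral ventral-horn extremes, and the midline dorsoventral
junction). Sections are rigidly rotated so both midline anchors share an
x-coordinate (dorsal up), then each hemisection is stretched by a monotone
piecewise-linear map that pins the anchored levels onto an idealized
template: dorsal/ventral extremes at *y* = ±2000 and lateral dorsal-horn
extremes at *x* = ±2000 arbitrary units. The module also mirrors two
genotypes onto opposite hemisections (reference *x* < 0, alternate *x* > 0)
and downsamples the reference per cell type by the ratio of group totals.

**Cumulative birthdating (`chronotopy.birthdate`).** From EdU co-labeling
counts, litter-level fractions *f*<sub>ℓ,t</sub> (embryos averaged within
litter) are turned into cumulative curves via

&nbsp;&nbsp;*p*<sub>t</sub> = 100·*m*<sub>t</sub>/Σ<sub>s</sub>*m*<sub>s</sub>,&nbsp;&nbsp;
*C*<sub>ℓ,t</sub> = 100·*f*<sub>ℓ,t</sub>/Σ<sub>s</sub>*m*<sub>s</sub> + Σ<sub>s&lt;t</sub>*p*<sub>s</sub>,

where *m*<sub>t</sub> is the litter-mean fraction; the litter-mean cumulative
at the final pulse is exactly 100% while within-timepoint spread is
preserved. Curves are fitted with logistic, 4PL
(*y* = *a* + (*d*−*a*)/(1+(*c*/*x*)<sup>*b*</sup>)) or asymmetric 5PL
sigmoids; the half-max time (EC50) is the family's half-birthdate. Pairwise
equal-variance t-tests with Benjamini–Hochberg correction compare inflection
points and steepness across families.

**Temporal similarity (`chronotopy.tempsim`).** Dynamic time warping
(textbook dynamic program: |*a*<sub>i</sub>−*b*<sub>j</sub>| local cost,
unit-weight steps, unnormalized) measures distances between
proportion-vs-time or ranked-expression curves; significance comes from a
permutation null that shuffles the value orderings (default 100,000
permutations), with p = the proportion of permuted distances strictly
greater than the observed one. The test is two-sided in interpretation:
p ≈ 0 means more different than chance, p ≈ 1 means more similar.

**Spatial density (`chronotopy.density`).** 2D Gaussian product-kernel
density estimates (resolution 100, normal-reference bandwidth) with
highest-density contour levels fitting the densest 50/25/15/5/2.5% of
points; 200-bin dorsoventral depth histograms; compression of raw image
profiles to 80 common bins (56-bin dorsal view, quintiles of 16); and
three-way ANOVA (genotype × quintile × cell-type) with Tukey HSD post-hoc
comparisons.

## Worked example

`examples/02_birthdating_curves.py` simulates three families with Gaussian
birth waves centered at E11.0/E11.5/E12.0 (4 litters × 3 embryos × 100
cells, half-day pulses E10.5–E13.5), builds cumulative curves, and fits 4PL
sigmoids:

```
mean cumulative % at final pulse (pinned to 100 by construction):
early    100.0
late     100.0
mid      100.0

family  configured-center  fitted-half-max  model  R^2
early   E11.00            E10.996          4PL  0.9987
mid     E11.50            E11.504          4PL  0.9991
late    E12.00            E12.008          4PL  0.9987
```

The fitted half-max birthdates recover the configured wave centers to within
a hundredth of a day at this design, and every pairwise inflection
comparison is significant after FDR correction. The other examples cover
section normalization (`01`), DTW permutation testing of composition curves
(`03`), highest-density contours (`04`), and genotype depth-profile
statistics (`05`); each prints the numbers it computes and a line on what
they mean.

## Layout

```
src/chronotopy/    synthdata, register, birthdate, tempsim, density
tests/             unit, property and end-to-end suites (pytest)
examples/          one narrative script per capability
docs/methods.md    models, assumptions, numerical choices, limitations
```
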