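# Methods

This note documents the models, the numerical choices, and the limits of
what the test suite demonstrates. It is the package's own account of its
science; nothing here states an empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## 1. Colour pipeline

**Spaces and conventions.** All analysis starts from CIE XYZ tristimulus
values on a Y-in-[0, 1] scale. White points are stored normalised to Y = 1
(supported illuminants: E, D55, D65, D75, CIE 1931 2° observer values).
Storing whites at Y = 1 rather than Y = 100 avoids silent factor-of-100
scale bugs; the L\*a\*b\* conversion operates on ratios to the white point,
so the choice is internally consistent as long as colours and white share a
scale.

**XYZ ↔ LMS.** The Hunt-Pointer-Estevez matrix (equal-energy normalisation)
maps XYZ to cone excitations; its exact numerical inverse maps back. This
is the space in which cone deficiency acts. The matrix is used at its
published 5-decimal precision; a consequence worth knowing is that its
first row sums to 1.00001, so the *XYZ* equal-energy white is a fixed point
of the deficiency simulation only to ≈2·10⁻⁵, while the *LMS* white
(1, 1, 1) is preserved to machine precision. Tests assert both, at their
respective tolerances.

**Chromatic adaptation.** Bradford linear adaptation. The 3×3 XYZ→XYZ
matrix is constructed at call time from the two white points
(M = B⁻¹ diag(ρ_t/ρ_s) B with B the Bradford cone matrix) rather than
transcribed from tables; the construction is regression-tested against the
published D65→D50 matrix (agreement ≈4·10⁻⁸) and against the defining
property that the source white maps exactly to the target white.

**L\*a\*b\* and ΔE₀₀.** Standard CIE 1976 L\*a\*b\* with the cube-root /
linear-segment compression (δ = 6/29), relative to the white of the
illuminant the colours are *currently expressed in* — illuminant E for the
bundled scale unless it has been adapted. Perceptual differences use
CIEDE2000 with kL = kC = kH = 1, implemented in full (chroma-dependent G
factor, hue rotation term, all branch cases of the hue mean). The
implementation reproduces all 34 published worked examples of the metric's
reference paper to < 10⁻⁴ and agrees with scikit-image's independent
implementation to < 10⁻⁹ on random Lab pairs.

**sRGB.** The XYZ ↔ linear sRGB matrix is derived from the primary
chromaticities and the D65 white (the canonical definition) rather than
copied. Display output clips per channel to [0, 1] before gamma encoding.
sRGB is used only for swatch export, never in the analysis.

## 2. Deficiency model

The transfer matrix **T**ₖ is the identity with the deficient cone's row
replaced by (k, q₁, q₂) in the appropriate ordering (protan: L row
(k, q₁, q₂); deutan: M row (q₁, k, q₂); tritan: S row (q₁, q₂, k)). The
row is fixed by two eigenvector conditions with eigenvalue 1 — white
(1, 1, 1) in LMS and a complementary primary: the sRGB blue primary for
protan and deutan, the sRGB red primary for tritan — which give the closed
forms

    q₂ᵖ = (1−k)(M_b−L_b)/(M_b−S_b)
    q₂ᵈ = (1−k)(L_b−M_b)/(L_b−S_b)
    q₂ᵗ = (1−k)(L_r−S_r)/(L_r−M_r)
    q₁  = 1 − k − q₂   (the deficient row always sums to 1)

The closed forms are unit-tested against an independent linear solve of the
two-equation system. Because the conditions are ratios of cone-coordinate
differences, any positive rescaling of the primaries cancels; the primaries
are therefore defined once, as the linear sRGB blue/red columns converted
to LMS, and are *not* re-adapted when a scale is analysed under a daylight
illuminant (one fixed **T**ₖ per deficiency and k, applied identically
under every illuminant).

Properties guaranteed by construction and asserted over the whole grid:
identity at k = 1; white/blue (or red) fixed points to 10⁻¹⁰ in LMS; rank 2
at k = 0 (dichromacy collapses colour space onto a plane); elements affine
in k, so the matrix family is uniformly continuous across the grid.

**Severity grid.** k = 1.00 down to 0.00 inclusive in steps of 0.01
(101 points), stored as exact hundredths. k parametrises the deficient
cone's relative contribution; it is a modelling knob, not a physiological
measurement.

**Monochromacy** (loss of more than one cone class) is outside this
single-cone model and is rejected with an explicit error.

## 3. Discriminability statistics

For a scale of n colours under a vision condition, the confusion matrix is
the symmetric n×n matrix of pairwise ΔE₀₀ (diagonal 0). Summary statistics
(median, minimum, pair counts) run over the n(n−1)/2 unordered off-diagonal
pairs only; the even-count median is the mean of the two central values.

**Thresholds.** 1 JND = 2.3 ΔE₀₀. Classification: *indistinguishable* if
ΔE₀₀/2.3 < 1 (strict — a pair at 2.33 counts as difficult, not
indistinguishable); *difficult* if ≤ 3 JND (inclusive; comparisons are done
in JND units with a 10⁻⁹ epsilon so that a raw value of exactly 6.9 counts
as 3 JND despite 3 × 2.3 ≠ 6.9 in binary floating point); otherwise
*discriminable*.

**Percent reduction** of a deficiency is
100 × (median@k=1 − min over the grid of the median) / median@k=1.

**A note on monotonicity.** For a metamer pair (two colours separated only
along the deficient cone axis) the simulated separation is exactly
proportional to k, so its ΔE₀₀ decreases monotonically to 0 as k → 0; this
is asserted on the full grid. For general pairs no such guarantee exists:
the deficient-row output interpolates linearly between the original
coordinate (k = 1) and its dichromatic replacement (k = 0), so a pair's
separation along that axis can pass through a minimum at intermediate k
(and the deutan row, which replaces M mostly by L, can *increase* a pair's
M-axis separation). The median over pairs consequently shows small local
increases on the way down for some scales, even though it always ends
below its regular-vision value. One can show the three deficiencies'
contraction conditions cannot be satisfied simultaneously by any
non-degenerate ramp, so strict median monotonicity is not a property a
correct implementation can promise in general; the tests assert the net
decrease and, for metamer pairs, the strict version.

## 4. The bundled water-colour scale

The Forel-Ule scale's measured tristimulus values derive from transmission
spectroscopy of the 21 physical pigment solutions and are published
elsewhere; they are not redistributed in this package. The bundled table
(`data/forel_ule_synthetic.csv`, regenerable with
`scripts/build_fu_fixture.py`) is a **synthetic reconstruction** built once
from the scale's documented structure:

* hue angles around the E white point from ≈230° (FU 1, indigo blue)
  through green to ≈23° (FU 21, cola brown), with the rapid blue→green hue
  transition spread over FU 5–9;
* a saturation profile high at the blue end (0.217 in chromaticity distance
  from white), dipping to ≈0.09 at the blue-green transition and recovering
  to ≈0.20 at the brown end (FU 2–3 were desaturated slightly from the
  initial profile so that every entry lies inside the sRGB gamut after D65
  adaptation, matching the scale's documented gamut);
* lightness L\* rising from 43 (FU 1) to 79 (mid greens) and falling to 45
  (FU 21).

The file is version-pinned by SHA-256, verified at load time, and stamped
into every report's provenance block.

**What this implies for the results.** Statistics computed from the
reconstruction characterise the reconstruction. Its coarse geometry is
close to the physical standard's (regular-vision median pair separation
≈33 ΔE₀₀; minimum ≈3.6; every pair above 1 JND), but dichromatic confusion
patterns depend on measurement-level detail that a structural
reconstruction cannot capture: here the red-green deficiencies collapse the
mid-green section (FU 10–16), where the reconstruction's hue spacing is
narrow and its lightness profile flat, whereas the physical scale's
vulnerable regions are reported at the brown end (deutan) and blue end
(tritan). The acceptance tests that assert the physical standard's
published headline values are kept at full strength and fail against the
reconstruction by design; swapping in a measured `label,X,Y,Z` table via
`load_scale(path)` re-runs the identical pipeline on real data.

Illuminant-robustness numbers are likewise fixture-dependent: the
indistinguishable-pair sets of the reconstruction are unchanged under
D55/D65/D75, but its saturated blue end shifts some pair differences by
more than 1 JND under adaptation (worst ≈5 JND under D55), more than is
reported for the physical standard.

## 5. Synthetic generators

All generators are pure functions of their arguments; randomness comes only
from an explicit seed.

* `gen_random_scale(count, seed, luminance_y=0.4)` — chromaticities uniform
  over the sRGB triangle (shrunk 0.7× toward its centroid so the fixed
  luminance stays displayable), lifted to XYZ at Y = 0.4, a mid-tone
  typical of reflective colour charts. Unstructured baseline for property
  tests.
* `gen_metamer_pair(deficiency, seed)` — a base colour near mid grey
  (Y ≈ 0.35, small seeded LMS offset) and a partner offset by 0.12 along
  the deficient cone axis, geometrically shrunk (×0.7, ≤100 attempts) until
  both members are displayable. By construction the pair collapses to
  ΔE₀₀ = 0 at k = 0.
* `gen_hue_ramp(count)` — deterministic hue sweep 230°→25° around the E
  white at saturation 0.17 (dipping mid-ramp) and lightness 45→75→45,
  a miniature of the bundled scale's blue→green→brown progression.
  Adjacent colours are the closest pairs by construction, and complete
  S-cone deficiency erodes neighbour contrast at the blue end more than
  the brown end — both asserted in tests.

What the generators do *not* emulate: measured reflectance/transmission
noise, inter-batch variation of physical charts, non-uniform saturation
structure of real scales. Passing property tests therefore demonstrates
correctness of the pipeline's mathematics, not fidelity to any physical
chart.

## 6. Determinism and I/O

Scale CSVs use header `label,X,Y,Z`, comma separation, period decimals,
`#` comments; floats are written with shortest round-trip `repr` and read
with pandas' `round_trip` parser, so save→load is bit-exact. Report bundles
are written atomically (temp file + rename) with fixed float formatting;
two runs with the same configuration are byte-identical. Every
`headline.json` embeds the input checksum, configuration echo, and package
version, and separates raw values from printed-precision roundings.

## 7. Known limitations

* The deficiency model is the standard computer-graphics linear-transfer
  construction; it does not model wavelength-shifted anomalous pigments,
  chromatic adaptation within the deficient eye, or individual variation
  beyond the single severity parameter.
* ΔE₀₀ thresholds (2.3 per JND, 1/3 JND class boundaries) are population
  averages; individual discrimination varies with viewing conditions.
* The bundled scale is a reconstruction (Section 4); quantitative claims
  about the physical Forel-Ule standard require its measured table.
* Only tristimulus input is supported — no spectral computation, no
  appearance models beyond L\*a\*b\*.
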