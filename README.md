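# cvdscale

**Colour-vision-deficiency auditing of discrete colour scales**, with a
21-step Forel-Ule-style water-colour scale as the bundled case study.

Many measurement protocols — water colour, soil colour, coral health, urine
test strips — ask an observer to match what they see against an ordered
chart of reference colours. Up to 1 in 11 participants has some form of
colour vision deficiency (CVD), which can make neighbouring chart colours
hard or impossible to tell apart and thus silently degrades the precision of
the collected data. `cvdscale` quantifies that effect for any discrete
colour scale: it simulates protan, deutan and tritan vision at every
severity, computes perceptual differences between all pairs of scale
colours, and reports which pairs collapse below the discrimination
threshold.

## Model

A colour with tristimulus values **c** = [X Y Z]ᵀ is mapped to cone
excitations via the Hunt-Pointer-Estevez matrix,

```
[L M S]ᵀ = M_HPE [X Y Z]ᵀ .
```

Cone deficiency is modelled by a transfer matrix **T**ₖ acting in LMS space:
the identity matrix with the deficient cone's row replaced by a mixture row.
For protan (L-cone) deficiency,

```
        ⎡ k   q₁  q₂ ⎤
T_k^p = ⎢ 0   1   0  ⎥ ,        k ∈ [0, 1],
        ⎣ 0   0   1  ⎦
```

and analogously for deutan (M row) and tritan (S row). The severity
parameter *k* runs from 1 (regular trichromacy) through anomalous
trichromacy to 0 (dichromacy). The weights q₁, q₂ are fixed by requiring
that two colours are perceived unchanged: white, **w** = [1 1 1]ᵀ in LMS,
and a complementary primary (the sRGB blue primary for protan/deutan, the
red primary for tritan). Solving `T_k b = b`, `T_k w = w` gives

```
q₂ᵖ = (1−k)(M_b−L_b)/(M_b−S_b),   q₁ = 1 − k − q₂ ,
```

etc. Simulated colours are mapped back to XYZ, converted to CIE L\*a\*b\*
against the scale's illuminant white, and compared pairwise with the
CIEDE2000 difference ΔE₀₀, where **ΔE₀₀ = 2.3 ≈ 1 just-noticeable
difference (JND)**. Pairs below 1 JND are *indistinguishable*, pairs within
3 JND are *difficult*, the rest *discriminable*. Sweeping *k* over a
101-point grid yields the degradation curves (median/minimum ΔE₀₀, pair
counts) per deficiency.

Illuminants E, D55, D65 and D75 are supported; scales are moved between
them with Bradford chromatic adaptation.

> **Note on the bundled scale.** The file
> `src/cvdscale/data/forel_ule_synthetic.csv` is a *synthetic
> reconstruction* of the Forel-Ule scale built from its documented
> structure (hue-angle progression, saturation and lightness profiles); the
> measured tristimulus values of the physical standard are not
> redistributed here. Numbers computed from it therefore characterise the
> reconstruction, not the physical standard — see `docs/methods.md`.

## Worked example

```python
import cvdscale as c

fu = c.load_scale("forel-ule")            # 21 colours, illuminant E
reg = c.summarize(c.confusion_matrix(fu))
print(f"regular vision: median dE00 = {reg.median:.1f}, min = {reg.minimum:.1f}, "
      f"pairs within 3 JND = {reg.n_within_3jnd}")
for d in c.DEFICIENCIES:
    cm = c.confusion_matrix(fu, d, severity_k=0.0)   # dichromacy
    s = c.summarize(cm)
    pairs = sorted(c.indistinguishable_pairs(cm), key=lambda p: (int(p[0]), int(p[1])))
    print(f"{d:7s} k=0: median = {s.median:5.1f}, min = {s.minimum:4.2f}, "
          f"indistinguishable pairs = {[f'{a}-{b}' for a, b in pairs]}")
```

prints

```
regular vision: median dE00 = 33.1, min = 3.6, pairs within 3 JND = 14
protan  k=0: median =  22.7, min = 0.18, indistinguishable pairs = ['10-11', '10-12', '10-13', '11-12', '11-13', '12-13', '13-14', '14-15']
deutan  k=0: median =  20.0, min = 0.24, indistinguishable pairs = ['10-11', '10-12', '10-13', '10-14', '10-15', '11-12', '11-13', '11-14', '12-13', '12-14', '13-14', '14-15', '15-16']
tritan  k=0: median =  28.7, min = 3.20, indistinguishable pairs = []
```

Reading: under regular vision every pair of this scale is at least 3.6 ΔE₀₀
apart (above 1 JND), with a median separation of 33. Complete red-green
deficiencies collapse the mid-green section of the reconstruction — for a
deuteranope, colours 10-16 merge into near-identical groups — while the
blue end stays separable mainly through its lightness gradient.

### Command line

```
cvdscale synth --kind ramp --n 12 --out ramp.csv      # synthetic test scale
cvdscale simulate --deficiency tritan --k 0 --in ramp.csv --out sim.csv
cvdscale confusion --scale forel-ule --deficiency deutan --k 0 --out conf.csv
cvdscale sweep --scale forel-ule --out sweep.csv      # 101-point severity grid
cvdscale report --scale forel-ule --out-dir report/   # full bundle + headline.json
```

`sweep.csv` is long-format (`deficiency,k,median,min,n_lt_1jnd,n_le_3jnd`);
the report bundle adds swatch tables, L\*a\*b\* coordinates, raw and
JND-unit confusion matrices, and a provenance-stamped `headline.json`.

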