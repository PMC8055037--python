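# Forel-Ule 21-step water-colour scale -- SYNTHETIC RECONSTRUCTION
# ---------------------------------------------------------------
# These are NOT the measured tristimulus values of the physical Forel-Ule
# standard (which are published from transmission spectroscopy of the
# original pigment solutions and are not reproduced here). This table is a
# one-off synthetic reconstruction built from the scale's documented
# structure: a hue-angle progression around the equal-energy (E) white point
# from indigo blue (FU 1, ~230 deg) through green (FU 11) to cola brown
# (FU 21, ~23 deg); a saturation profile that dips at the blue-green
# transition; and a lightness profile peaking at the mid greens.
# Illuminant: E (equal energy), white point Y = 1; XYZ on the Y-in-[0,1]
# scale. Regenerate with scripts/build_fu_fixture.py; see docs/methods.md.
# Columns: label, X, Y, Z.
label,X,Y,Z
1,0.152188,0.131578,0.502498
2,0.159105,0.160195,0.471777
3,0.176975,0.201443,0.450358
4,0.196772,0.249227,0.418728
5,0.223109,0.304025,0.380368
6,0.239361,0.353238,0.334481
7,0.261431,0.407494,0.268731
8,0.295820,0.451644,0.208850
9,0.344315,0.498872,0.176434
10,0.389051,0.532120,0.131384
11,0.431792,0.549284,0.132374
12,0.458853,0.549284,0.133395
13,0.469657,0.532120,0.130615
14,0.460372,0.498872,0.114999
15,0.450290,0.467039,0.099367
16,0.425830,0.421875,0.083968
17,0.385743,0.366320,0.067821
18,0.335656,0.304025,0.053478
19,0.286778,0.249227,0.043755
20,0.231838,0.192686,0.034687
21,0.182286,0.145417,0.027655
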