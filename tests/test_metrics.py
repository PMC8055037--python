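"""CIEDE2000, confusion matrices, pair classification and severity sweeps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.color import deltaE_ciede2000

from cvdscale.core import Illuminant, get_illuminant
from cvdscale.metrics import (
    JND_DELTA_E,
    ConfusionMatrix,
    classify_pairs,
    confusion_matrix,
    delta_e00,
    indistinguishable_pairs,
    k_sweep,
    percent_reduction,
    summarize,
)
from cvdscale.synthetic import gen_constant_scale, gen_hue_ramp, gen_random_scale
from .ciede2000_cases import CIEDE2000_CASES

_lab_component = st.floats(min_value=-100, max_value=100, allow_nan=False)
_lightness = st.floats(min_value=0, max_value=100, allow_nan=False)
_lab = st.tuples(_lightness, _lab_component, _lab_component)


class TestDeltaE00:
    def test_published_worked_examples(self):
        got = delta_e00(CIEDE2000_CASES[:, :3], CIEDE2000_CASES[:, 3:6])
        np.testing.assert_allclose(got, CIEDE2000_CASES[:, 6], atol=1e-4)

    def test_zero_for_identical_colours(self, rng):
        lab = rng.uniform(-60, 90, size=(10, 3))
        np.testing.assert_array_equal(delta_e00(lab, lab), np.zeros(10))

    def test_agrees_with_independent_implementation(self, rng):
        a = rng.uniform([0, -80, -80], [100, 80, 80], size=(200, 3))
        b = rng.uniform([0, -80, -80], [100, 80, 80], size=(200, 3))
        np.testing.assert_allclose(
            delta_e00(a, b), deltaE_ciede2000(a, b), atol=1e-9
        )

    @settings(max_examples=150, derandomize=True)
    @given(a=_lab, b=_lab)
    def test_symmetric_and_non_negative(self, a, b):
        d_ab = delta_e00(a, b)
        assert d_ab >= 0
        assert d_ab == pytest.approx(delta_e00(b, a), abs=1e-9)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            delta_e00([50, 0, np.nan], [50, 0, 0])


def _brute_force_summary(scale, deficiency, k):
    """Independent recomputation by explicit pair enumeration."""
    from cvdscale.core import xyz_to_lab
    from cvdscale.cvd import simulate_deficiency

    xyz = scale.xyz if deficiency == "regular" else simulate_deficiency(
        scale.xyz, deficiency, k
    )
    lab = xyz_to_lab(xyz, scale.illuminant)
    values = []
    for i in range(len(scale)):
        for j in range(i + 1, len(scale)):
            values.append(float(delta_e00(lab[i], lab[j])))
    values = sorted(values)
    n = len(values)
    median = (
        values[n // 2] if n % 2 else 0.5 * (values[n // 2 - 1] + values[n // 2])
    )
    return (
        median,
        values[0],
        sum(v < JND_DELTA_E for v in values),
        sum(v <= 3 * JND_DELTA_E for v in values),
    )


class TestConfusionMatrix:
    @pytest.mark.parametrize("deficiency,k", [("regular", 1.0), ("protan", 0.0), ("tritan", 0.35)])
    def test_symmetric_zero_diagonal_non_negative(self, fu_scale, deficiency, k):
        cm = confusion_matrix(fu_scale, deficiency, k)
        np.testing.assert_allclose(cm.values, cm.values.T, atol=1e-12)
        np.testing.assert_array_equal(np.diag(cm.values), np.zeros(cm.n))
        assert np.all(cm.values >= 0)

    def test_identical_colours_give_zero_matrix(self):
        cm = confusion_matrix(gen_constant_scale(5))
        np.testing.assert_array_equal(cm.values, np.zeros((5, 5)))

    @pytest.mark.parametrize("deficiency", ["protan", "deutan", "tritan"])
    def test_k1_equals_regular(self, fu_scale, deficiency):
        reg = confusion_matrix(fu_scale)
        sim = confusion_matrix(fu_scale, deficiency, 1.0)
        np.testing.assert_allclose(sim.values, reg.values, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("deficiency,k", [("regular", 1.0), ("deutan", 0.0)])
    def test_summary_matches_brute_force_on_small_scales(self, seed, deficiency, k):
        scale = gen_random_scale(4, seed=seed)
        got = summarize(confusion_matrix(scale, deficiency, k))
        expected = _brute_force_summary(scale, deficiency, k)
        assert got.median == pytest.approx(expected[0], abs=1e-9)
        assert got.minimum == pytest.approx(expected[1], abs=1e-9)
        assert (got.n_within_1jnd, got.n_within_3jnd) == expected[2:]


def _matrix_from_values(values):
    n = values.shape[0]
    return ConfusionMatrix(
        labels=tuple(str(i) for i in range(n)),
        values=values,
        deficiency="regular",
        severity_k=1.0,
        illuminant=get_illuminant("E"),
    )


class TestClassification:
    def test_boundary_conventions(self):
        # 2.3 itself is 1 JND: difficult, not indistinguishable; 6.9 (3 JND)
        # is still difficult; just above is discriminable.
        values = np.zeros((2, 2))
        for de, expected in [
            (2.2999, "indistinguishable"),
            (2.3, "difficult"),
            (2.33, "difficult"),
            (6.9, "difficult"),
            (6.9001, "discriminable"),
        ]:
            values[0, 1] = values[1, 0] = de
            cls = classify_pairs(_matrix_from_values(values.copy()))
            assert cls[("0", "1")] == expected, de

    def test_classes_are_exhaustive(self, fu_scale):
        cls = classify_pairs(confusion_matrix(fu_scale, "deutan", 0.1))
        assert len(cls) == 21 * 20 // 2
        assert set(cls.values()) <= {"indistinguishable", "difficult", "discriminable"}

    def test_indistinguishable_set_matches_classification(self, fu_scale):
        cm = confusion_matrix(fu_scale, "protan", 0.0)
        pairs = indistinguishable_pairs(cm)
        cls = classify_pairs(cm)
        assert pairs == {p for p, c in cls.items() if c == "indistinguishable"}

    def test_summary_requires_two_colours(self):
        with pytest.raises(ValueError, match="at least 2"):
            summarize(_matrix_from_values(np.zeros((1, 1))))


@pytest.fixture(scope="module")
def ramp_sweep():
    return k_sweep(gen_hue_ramp(10), step=0.05)


class TestSweep:
    def test_grid_and_shape(self, ramp_sweep):
        ks = sorted(ramp_sweep["k"].unique())
        assert len(ks) == 21 and ks[0] == 0.0 and ks[-1] == 1.0
        assert set(ramp_sweep["deficiency"]) == {"protan", "deutan", "tritan"}

    def test_k1_rows_equal_regular_summary(self, ramp_sweep):
        scale = gen_hue_ramp(10)
        reg = summarize(confusion_matrix(scale))
        at1 = ramp_sweep[ramp_sweep["k"] == 1.0]
        for _, row in at1.iterrows():
            assert row["median"] == pytest.approx(reg.median, abs=1e-10)
            assert row["min"] == pytest.approx(reg.minimum, abs=1e-10)
            assert row["n_lt_1jnd"] == reg.n_within_1jnd
            assert row["n_le_3jnd"] == reg.n_within_3jnd

    def test_median_decreases_from_regular_to_dichromacy(self, ramp_sweep):
        # Severity lowers the overall median; the curve itself need not be
        # strictly monotone (pair separations along the deficient axis are
        # interpolated and can pass through a minimum at intermediate k).
        for _, sub in ramp_sweep.groupby("deficiency"):
            sub = sub.sort_values("k", ascending=False)
            med = sub["median"].to_numpy()
            assert med[-1] < med[0]

    def test_minimum_never_exceeds_median(self, ramp_sweep):
        assert (ramp_sweep["min"] <= ramp_sweep["median"] + 1e-12).all()

    def test_counts_within_bounds(self, ramp_sweep):
        n_pairs = 10 * 9 // 2
        for col in ("n_lt_1jnd", "n_le_3jnd"):
            assert ramp_sweep[col].between(0, n_pairs).all()


class TestPercentReduction:
    def test_no_effect_means_zero(self):
        sweep = pd.DataFrame(
            {"deficiency": ["protan"] * 2, "k": [1.0, 0.0], "median": [30.0, 30.0]}
        )
        assert percent_reduction(sweep, "protan") == 0.0

    def test_half_median_means_fifty_percent(self):
        sweep = pd.DataFrame(
            {"deficiency": ["tritan"] * 3, "k": [1.0, 0.5, 0.0], "median": [30.0, 20.0, 15.0]}
        )
        assert percent_reduction(sweep, "tritan") == pytest.approx(50.0)

    def test_missing_endpoints_rejected(self):
        sweep = pd.DataFrame({"deficiency": ["protan"], "k": [1.0], "median": [30.0]})
        with pytest.raises(ValueError, match="k=1 and k=0"):
            percent_reduction(sweep, "protan")

    def test_zero_baseline_rejected(self):
        sweep = pd.DataFrame(
            {"deficiency": ["protan"] * 2, "k": [1.0, 0.0], "median": [0.0, 0.0]}
        )
        with pytest.raises(ValueError, match="baseline"):
            percent_reduction(sweep, "protan")
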