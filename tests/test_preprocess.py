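"""Normalization, mean curves, quadrants, and Cronbach-alpha reliability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import affectfanova as af
from affectfanova.data_model import StructuralError, ValidationError
from affectfanova.preprocess import (
    ReliabilityError,
    apply_reliability_filter,
    classify_quadrant_curve,
    cronbach_alpha,
    denormalize,
    mean_curve,
    normalize,
    pooled_reliability,
    reliability_table,
    write_reliability_report,
)


def alpha_two_way_oracle(X):
    """Cronbach's alpha via brute-force two-way ANOVA (Hoyt's method).

    alpha = (MS_cases - MS_residual) / MS_cases, with time points as cases
    and raters as items; computed with explicit loops as an independent
    route to the variance-ratio formula.
    """
    X = np.asarray(X, dtype=float)
    T, k = X.shape
    grand = X.mean()
    ss_cases = sum(k * (X[t].mean() - grand) ** 2 for t in range(T))
    ss_items = sum(T * (X[:, j].mean() - grand) ** 2 for j in range(k))
    ss_total = sum((X[t, j] - grand) ** 2 for t in range(T) for j in range(k))
    ms_cases = ss_cases / (T - 1)
    ms_resid = (ss_total - ss_cases - ss_items) / ((T - 1) * (k - 1))
    return (ms_cases - ms_resid) / ms_cases


class TestNormalize:
    @pytest.mark.parametrize(
        "value, lo, hi, expected",
        [
            (50.0, 0.0, 100.0, 0.0),  # midpoint -> neutral
            (0.0, 0.0, 100.0, -1.0),
            (100.0, 0.0, 100.0, 1.0),
            (75.0, 0.0, 100.0, 0.5),
            (3.0, 1.0, 5.0, 0.0),
        ],
    )
    def test_affine_map_values(self, value, lo, hi, expected):
        assert normalize([value], lo, hi)[0] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            normalize([1.0], 2.0, 2.0)

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValidationError):
            normalize([12.0], 0.0, 10.0)

    @given(
        st.lists(st.floats(0, 100), min_size=2, max_size=20),
    )
    @settings(max_examples=50, derandomize=True)
    def test_order_preserving_and_invertible(self, values):
        out = normalize(np.sort(values), 0.0, 100.0)
        assert np.all(np.diff(out) >= 0)  # order preserved
        np.testing.assert_allclose(
            denormalize(out, 0.0, 100.0), np.sort(values), atol=1e-9
        )


class TestMeanCurve:
    def _mk(self, pid, values):
        return af.RatingSeries(pid, "s1", "valence", np.arange(len(values)), values)

    def test_single_series_is_identity(self):
        s = self._mk("p1", [0.1, 0.2, 0.3, 0.2, 0.1])
        np.testing.assert_array_equal(mean_curve([s]).values, s.values)

    def test_constant_pair_averages(self):
        out = mean_curve([self._mk("p1", [0.2] * 5), self._mk("p2", [0.4] * 5)])
        np.testing.assert_allclose(out.values, 0.3)

    def test_opposite_curves_cancel(self):
        f = np.sin(np.linspace(0, 3, 8)) * 0.5
        out = mean_curve([self._mk("p1", f), self._mk("p2", -f)])
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(StructuralError, match="grid"):
            mean_curve([self._mk("p1", [0.0] * 5), self._mk("p2", [0.0] * 6)])


class TestQuadrants:
    @pytest.mark.parametrize(
        "valence, arousal, label",
        [
            (0.5, 0.5, "Q1"),
            (-0.3, 0.7, "Q2"),
            (-0.5, -0.5, "Q3"),
            (0.3, -0.7, "Q4"),
            (0.0, 0.0, "neutral"),
            (0.0, 0.9, "neutral"),
            (-0.9, 0.0, "neutral"),
        ],
    )
    def test_sign_partition(self, valence, arousal, label):
        assert af.classify_quadrant(valence, arousal) == label

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValidationError):
            af.classify_quadrant(1.5, 0.0)

    def test_curve_version_tracks_pointwise(self):
        v = [0.5, -0.5, -0.5, 0.5]
        a = [0.5, 0.5, -0.5, -0.5]
        assert classify_quadrant_curve(v, a) == ["Q1", "Q2", "Q3", "Q4"]


class TestCronbachAlpha:
    def test_identical_raters_give_one(self):
        col = np.array([0.1, 0.5, -0.2, 0.8, 0.0, 0.3])
        X = np.column_stack([col, col, col])
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_mirror_raters_are_negative(self, rng):
        # a near-perfect mirror rater: systematic disagreement drives the
        # total variance far below the item variances, hence alpha << 0
        x = rng.normal(size=10)
        X = np.column_stack([x, 0.5 - x + rng.normal(0, 0.1, size=10)])
        val = cronbach_alpha(X)
        assert val == pytest.approx(alpha_two_way_oracle(X), abs=1e-10)
        assert val < 0

    def test_exact_mirror_raters_have_undefined_reliability(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ReliabilityError, match="variance"):
            cronbach_alpha(np.column_stack([x, 0.5 - x]))

    def test_independent_noise_centers_near_zero(self):
        # E[alpha] for pure noise sits slightly below 0 (ratio-of-variances
        # bias at small k, T); the mean over seeds must stay near zero even
        # though single draws scatter widely
        vals = [
            cronbach_alpha(np.random.default_rng(seed).normal(size=(20, 3)))
            for seed in range(200)
        ]
        assert abs(np.mean(vals)) < 0.2

    @pytest.mark.parametrize("shape", [(5, 2), (10, 3), (30, 5)])
    def test_matches_two_way_anova_oracle(self, shape, rng):
        X = rng.normal(size=shape) + rng.normal(size=(shape[0], 1))
        assert cronbach_alpha(X) == pytest.approx(alpha_two_way_oracle(X), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        X = rng.normal(size=(25, 4)) + rng.normal(size=(25, 1))
        expected = pingouin.cronbach_alpha(data=pd.DataFrame(X))[0]
        assert cronbach_alpha(X) == pytest.approx(expected, abs=1e-9)

    def test_shift_and_scale_invariance(self, rng):
        X = rng.normal(size=(15, 4)) + rng.normal(size=(15, 1))
        base = cronbach_alpha(X)
        assert cronbach_alpha(X + 3.7) == pytest.approx(base, abs=1e-9)
        assert cronbach_alpha(X * 2.5) == pytest.approx(base, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ReliabilityError, match="raters"):
            cronbach_alpha(np.zeros((10, 1)))
        with pytest.raises(ReliabilityError, match="variance"):
            cronbach_alpha(np.ones((10, 3)))


# alphas of a 17-stimulus panel as printed in a published reliability report;
# used as input data for the keep/drop screen
PANEL_ALPHAS = {
    ("piece_1", "arousal"): 0.98, ("piece_1", "valence"): 0.94,
    ("piece_2", "arousal"): 0.94, ("piece_2", "valence"): 0.97,
    ("piece_3", "arousal"): 0.99, ("piece_3", "valence"): 0.89,
    ("piece_4", "arousal"): 0.98, ("piece_4", "valence"): 0.98,
    ("piece_5", "arousal"): 0.99, ("piece_5", "valence"): 0.95,
    ("piece_6", "arousal"): 0.93, ("piece_6", "valence"): 0.96,
    ("piece_7", "arousal"): 0.99, ("piece_7", "valence"): 0.98,
    ("piece_8", "arousal"): 0.99, ("piece_8", "valence"): 0.97,
    ("sample_1", "arousal"): 0.99, ("sample_1", "valence"): 0.97,
    ("sample_2", "arousal"): 0.96, ("sample_2", "valence"): 0.95,
    ("sample_3", "arousal"): 0.99, ("sample_3", "valence"): 0.99,
    ("sample_4", "arousal"): 0.99, ("sample_4", "valence"): 0.99,
    ("sample_5", "arousal"): 0.96, ("sample_5", "valence"): 0.97,
    ("sample_6", "arousal"): 0.97, ("sample_6", "valence"): 0.73,
    ("sample_7", "arousal"): 0.96, ("sample_7", "valence"): 0.78,
    ("sample_8", "arousal"): 0.65, ("sample_8", "valence"): 0.89,
    ("sample_9", "arousal"): 0.95, ("sample_9", "valence"): 0.15,
}


def panel_alpha_table():
    return pd.DataFrame(
        [
            {"stimulus_id": s, "dimension": d, "alpha": a, "retained": a >= 0.75}
            for (s, d), a in PANEL_ALPHAS.items()
        ]
    )


class TestReliabilityFilter:
    def test_published_panel_keep_drop_set(self):
        retained, excluded = apply_reliability_filter(panel_alpha_table(), threshold=0.75)
        assert excluded == [
            ("sample_6", "valence"),
            ("sample_8", "arousal"),
            ("sample_9", "valence"),
        ]
        assert ("sample_7", "valence") in retained  # 0.78 stays above the cut
        assert len(retained) == 31

    def test_high_alphas_keep_everything(self):
        table = panel_alpha_table().assign(alpha=0.99)
        retained, excluded = apply_reliability_filter(table, threshold=0.75)
        assert excluded == [] and len(retained) == 34

    def test_threshold_above_one_excludes_everything(self):
        retained, excluded = apply_reliability_filter(panel_alpha_table(), threshold=1.01)
        assert retained == set() and len(excluded) == 34

    def test_reliability_table_on_simulated_panel(self, tiny_study, tmp_path):
        dataset, _ = tiny_study
        table = reliability_table(dataset)
        assert set(table["dimension"]) == {"valence", "arousal"}
        assert len(table) == 4  # 2 stimuli x 2 dimensions
        assert (table["alpha"] <= 1.0).all()
        pooled = pooled_reliability(dataset)
        assert set(pooled) == {"valence", "arousal"}
        out = tmp_path / "reliability.tsv"
        write_reliability_report(table, out)
        report = pd.read_csv(out, sep="\t")
        assert {"alpha_valence", "alpha_arousal"} <= set(report.columns)
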