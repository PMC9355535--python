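"""Contrast engine against independent sums-of-squares and eigen oracles."""

import numpy as np
import pandas as pd
import pytest

from amfspread.contrasts import fit_marginal_means, manova_overall
from amfspread.contrasts import test_bridge_island as bridge_island_contrast
from amfspread.contrasts import test_enrichment as enrichment_contrast
from amfspread.model import Inoculum, Side, Treatment
from conftest import build_proportions_table


def pooled_two_group_F(y1, y2):
    """Classical pooled-variance two-sample comparison from sums of squares."""
    n1, n2 = len(y1), len(y2)
    sse = ((y1 - y1.mean()) ** 2).sum() + ((y2 - y2.mean()) ** 2).sum()
    msw = sse / (n1 + n2 - 2)
    ssb = (n1 * n2 / (n1 + n2)) * (y1.mean() - y2.mean()) ** 2
    F = ssb / msw
    from scipy import stats

    return F, stats.f.sf(F, 1, n1 + n2 - 2)


class TestPairwiseContrasts:
    def test_two_group_contrast_matches_sums_of_squares_oracle(self, two_group_fixture):
        table, y0, y2 = two_group_fixture
        dc = fit_marginal_means(table, "X", "siteA", 1)
        c = dc.contrast(0.0, 2.0)
        F, p = pooled_two_group_F(y0, y2)
        assert c.testable
        assert c.estimate == pytest.approx(y0.mean() - y2.mean(), abs=1e-12)
        assert c.statistic == pytest.approx(F, abs=1e-10)
        assert c.p_value == pytest.approx(p, abs=1e-10)

    def test_constant_response_gives_zero_estimates_everywhere(self):
        rows = [
            {"distance_m": d, "block": b, "otus": {"X": 0.1}}
            for d in (0.0, 0.5, 2.0)
            for b in ("b1", "b2", "b3")
        ]
        table = build_proportions_table(rows)
        dc = fit_marginal_means(table, "X", "siteA", 1)
        for key, c in dc.pairwise.items():
            assert c.estimate == pytest.approx(0.0, abs=1e-12)
            assert not c.significant(0.05)
        assert dc.overall_distance.p_value == pytest.approx(1.0)

    def test_single_distance_level_is_untestable_not_an_error(self):
        rows = [{"distance_m": 0.0, "otus": {"X": v}} for v in (0.1, 0.2, 0.3)]
        table = build_proportions_table(rows)
        dc = fit_marginal_means(table, "X", "siteA", 1)
        assert not dc.contrast(0.0, 2.0).testable
        assert not dc.overall_distance.testable

    def test_level_with_single_sample_flagged_untestable(self):
        rows = [
            {"distance_m": 0.0, "otus": {"X": v}} for v in (0.1, 0.2, 0.3)
        ] + [{"distance_m": 2.0, "otus": {"X": 0.05}}]
        table = build_proportions_table(rows)
        dc = fit_marginal_means(table, "X", "siteA", 1)
        c = dc.contrast(0.0, 2.0)
        assert not c.testable
        assert "untestable" in c.note

    def test_block_adjustment_removes_block_effects(self):
        # strong additive block effect, no true distance effect
        rows = []
        for b, shift in (("b1", 0.0), ("b2", 0.3), ("b3", 0.6)):
            for d in (0.0, 0.5, 2.0):
                rows.append(
                    {"distance_m": d, "block": b, "otus": {"X": 0.05 + shift / 3}}
                )
        table = build_proportions_table(rows)
        dc = fit_marginal_means(table, "X", "siteA", 1)
        assert dc.contrast(0.0, 2.0).estimate == pytest.approx(0.0, abs=1e-12)
        means = list(dc.marginal_means.values())
        assert np.allclose(means, means[0])

    def test_marginal_means_recover_cell_means_in_balanced_design(self, rng):
        truth = {0.0: 0.2, 0.5: 0.15, 2.0: 0.05}
        rows = []
        for b in ("b1", "b2", "b3", "b4"):
            for d, m in truth.items():
                rows.append(
                    {
                        "distance_m": d,
                        "block": b,
                        "otus": {"X": m + rng.normal(0, 0.01)},
                    }
                )
        # proportion column must stay in [0,1]; jitter is small enough
        table = build_proportions_table(rows)
        dc = fit_marginal_means(table, "X", "siteA", 1)
        df = pd.DataFrame(
            {"d": [r["distance_m"] for r in rows], "y": [r["otus"]["X"] for r in rows]}
        )
        cell = df.groupby("d")["y"].mean()
        for d in truth:
            assert dc.marginal_means[d] == pytest.approx(cell[d], abs=1e-10)
        assert dc.trend_sign == 1

    def test_zero_residual_variance_unequal_means_flagged_significant(self):
        rows = [{"distance_m": 0.0, "otus": {"X": 0.3}} for _ in range(3)] + [
            {"distance_m": 2.0, "otus": {"X": 0.1}} for _ in range(3)
        ]
        table = build_proportions_table(rows)
        with pytest.warns(UserWarning, match="zero residual"):
            dc = fit_marginal_means(table, "X", "siteA", 1)
        c = dc.contrast(0.0, 2.0)
        assert c.p_value == 0.0 and c.testable


class TestEnrichment:
    def _table(self, inoc_vals, ctrl_vals):
        rows = [
            {"treatment": "AMF", "distance_m": 0.0, "otus": {"X": v}}
            for v in inoc_vals
        ] + [
            {"treatment": "CONTROL", "distance_m": 0.0, "otus": {"X": v}}
            for v in ctrl_vals
        ]
        return build_proportions_table(rows)

    def test_equal_means_gives_zero_nonsignificant_estimate(self):
        table = self._table([0.1, 0.12, 0.08], [0.12, 0.08, 0.1])
        res = enrichment_contrast(table, "X", "siteA", 1, Inoculum.AMF)
        assert res.contrast.estimate == pytest.approx(0.0, abs=1e-12)
        assert not res.contrast.significant(0.05)

    def test_seven_vs_seven_matches_brute_force_F(self, rng):
        y1 = 0.1 + rng.normal(0, 0.02, 7)
        y2 = 0.02 + rng.normal(0, 0.02, 7).clip(-0.019)
        table = self._table(y1, y2)
        res = enrichment_contrast(table, "X", "siteA", 1, Inoculum.AMF)
        F, p = pooled_two_group_F(np.asarray(y1), np.asarray(y2))
        assert res.contrast.statistic == pytest.approx(F, abs=1e-10)
        assert res.contrast.p_value == pytest.approx(p, abs=1e-10)

    def test_missing_control_arm_is_untestable(self):
        rows = [
            {"treatment": "AMF", "distance_m": 0.0, "otus": {"X": v}}
            for v in (0.1, 0.2)
        ]
        table = build_proportions_table(rows)
        res = enrichment_contrast(table, "X", "siteA", 1, Inoculum.AMF)
        assert not res.contrast.testable
        assert "untestable" in res.contrast.note


class TestBridgeIsland:
    def _table(self, bridge2, island2, bridge05=None, bridge1=None):
        rows = []
        for i, v in enumerate(bridge2):
            rows.append(
                {"distance_m": 2.0, "side": "BRIDGE", "block": f"b{i}", "otus": {"X": v}}
            )
        for i, v in enumerate(island2):
            rows.append(
                {"distance_m": 2.0, "side": "ISLAND", "block": f"b{i}", "otus": {"X": v}}
            )
        for d, vals in ((0.5, bridge05), (1.0, bridge1)):
            for i, v in enumerate(vals or []):
                rows.append(
                    {"distance_m": d, "side": "BRIDGE", "block": f"b{i}", "otus": {"X": v}}
                )
        return build_proportions_table(rows)

    def test_identical_sides_do_not_trigger_override(self):
        table = self._table([0.1, 0.12, 0.08], [0.1, 0.12, 0.08])
        res = bridge_island_contrast(table, "X", "siteA", 1)
        assert res is not None
        assert not res.override(0.05)

    def test_no_side_structure_returns_none(self):
        rows = [{"distance_m": 2.0, "otus": {"X": 0.1}} for _ in range(3)]
        table = build_proportions_table(rows)
        assert bridge_island_contrast(table, "X", "siteA", 1) is None

    def test_within_bridge_differences_veto_the_override(self):
        # bridge >> island at 2 m, but a strong gradient along the bridge
        table = self._table(
            bridge2=[0.30, 0.31, 0.29, 0.30],
            island2=[0.02, 0.03, 0.01, 0.02],
            bridge05=[0.60, 0.61, 0.59, 0.60],
            bridge1=[0.45, 0.44, 0.46, 0.45],
        )
        res = bridge_island_contrast(table, "X", "siteA", 1)
        assert res.side_contrast.significant_positive(0.05)
        assert res.within_bridge_differences
        assert not res.override(0.05)

    def test_flat_bridge_with_strong_side_contrast_overrides(self):
        table = self._table(
            bridge2=[0.30, 0.32, 0.29, 0.31],
            island2=[0.02, 0.03, 0.01, 0.02],
            bridge05=[0.30, 0.29, 0.32, 0.30],
            bridge1=[0.31, 0.30, 0.29, 0.32],
        )
        res = bridge_island_contrast(table, "X", "siteA", 1)
        assert res.override(0.05)


class TestManovaOverall:
    def _fixture(self, rng, shift=0.0, n_per=6):
        rows = []
        for g, treat in enumerate(("AMF", "CONTROL")):
            for i in range(n_per):
                a = 0.10 + g * shift + rng.normal(0, 0.02)
                b = 0.05 + g * shift / 2 + rng.normal(0, 0.02)
                rows.append(
                    {
                        "treatment": treat,
                        "distance_m": 0.0,
                        "otus": {"A": max(a, 1e-4), "B": max(b, 1e-4)},
                    }
                )
        return build_proportions_table(rows)

    @staticmethod
    def pillai_oracle(Y, groups):
        """One-way MANOVA Pillai's trace via explicit SSCP matrices."""
        Y = np.asarray(Y, float)
        grand = Y.mean(axis=0)
        H = np.zeros((Y.shape[1], Y.shape[1]))
        E = np.zeros_like(H)
        for g in np.unique(groups):
            Yg = Y[groups == g]
            d = (Yg.mean(axis=0) - grand)[:, None]
            H += len(Yg) * (d @ d.T)
            R = Yg - Yg.mean(axis=0)
            E += R.T @ R
        return float(np.trace(H @ np.linalg.inv(H + E)))

    def test_pillai_matches_eigen_oracle(self, rng):
        table = self._fixture(rng, shift=0.05)
        res = manova_overall(
            table, ["A", "B"], "siteA", 1,
            treatments=(Treatment.AMF, Treatment.CONTROL),
        )["treatment"]
        groups = table.metadata["treatment"].to_numpy()
        expected = self.pillai_oracle(table.values[["A", "B"]].to_numpy(), groups)
        assert res.testable
        assert res.pillai == pytest.approx(expected, abs=1e-10)

    def test_identical_group_patterns_give_pillai_zero(self):
        pattern = [(0.10, 0.05), (0.12, 0.06), (0.08, 0.04), (0.11, 0.07)]
        rows = []
        for treat in ("AMF", "CONTROL"):
            for a, b in pattern:
                rows.append(
                    {"treatment": treat, "distance_m": 0.0, "otus": {"A": a, "B": b}}
                )
        table = build_proportions_table(rows)
        res = manova_overall(
            table, ["A", "B"], "siteA", 1,
            treatments=(Treatment.AMF, Treatment.CONTROL),
        )["treatment"]
        assert res.pillai == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-8)

    def test_p_values_in_unit_interval_across_random_fixtures(self, rng):
        for _ in range(20):
            table = self._fixture(rng, shift=rng.uniform(0, 0.1), n_per=5)
            res = manova_overall(
                table, ["A", "B"], "siteA", 1,
                treatments=(Treatment.AMF, Treatment.CONTROL),
            )["treatment"]
            assert 0.0 <= res.p_value <= 1.0

    def test_response_reduction_when_samples_scarce(self, rng):
        rows = []
        for treat, n in (("AMF", 3), ("CONTROL", 2)):
            for _ in range(n):
                rows.append(
                    {
                        "treatment": treat,
                        "distance_m": 0.0,
                        "otus": {
                            "A": 0.1 + rng.normal(0, 0.01),
                            "B": 0.05 + rng.normal(0, 0.01),
                        },
                    }
                )
        table = build_proportions_table(rows)
        res = manova_overall(
            table, ["A", "B", "FILL"], "siteA", 1,
            treatments=(Treatment.AMF, Treatment.CONTROL),
        )["treatment"]
        assert res.n_responses == 2
        assert "reduced" in res.note

    def test_far_too_few_samples_is_untestable(self, rng):
        table = self._fixture(rng, shift=0.0, n_per=2)
        res = manova_overall(
            table, ["A", "B"], "siteA", 1,
            treatments=(Treatment.AMF, Treatment.CONTROL),
        )["treatment"]
        assert not res.testable
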