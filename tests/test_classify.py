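"""Decision rules, trial enumeration, tabulation, and the family test."""

import numpy as np
import pytest
from scipy import stats

from amfspread.classify import (
    classify_otu,
    discordance_counts,
    enumerate_trials,
    family_spread_test,
    tabulate_categories,
    transition_matrix,
)
from amfspread.contrasts import (
    BridgeIslandResult,
    ContrastResult,
    DistanceContrasts,
    EnrichmentResult,
)
from amfspread.model import InoculaProfile, Inoculum, SpreadCategory, Trial


def sig(estimate=0.05):
    return ContrastResult(estimate=estimate, statistic=25.0, df=(1, 16),
                          p_value=0.001, testable=True)


def ns(estimate=0.0):
    return ContrastResult(estimate=estimate, statistic=0.5, df=(1, 16),
                          p_value=0.5, testable=True)


def untestable():
    return ContrastResult(note="untestable")


def dc_from(c_0_05, c_0_2, c_05_2, overall=None, trend=0):
    dc = DistanceContrasts(otu="X")
    dc.pairwise = {(0.0, 0.5): c_0_05, (0.0, 2.0): c_0_2, (0.5, 2.0): c_05_2}
    dc.overall_distance = overall if overall is not None else ns()
    dc.trend_sign = trend
    return dc


def enr(significant: bool):
    return EnrichmentResult(otu="X", contrast=sig() if significant else ns())


class TestClassifyOtu:
    """One case per decision rule plus precedence and degeneracy."""

    @pytest.mark.parametrize(
        "dc, enrichment, expected",
        [
            # nurse row above both distances -> no spread
            (dc_from(sig(), sig(), ns()), enr(True), SpreadCategory.NO_SPREAD),
            # flat to 0.5 m, 2 m depleted -> spread to 0.5
            (dc_from(ns(), sig(), sig()), enr(True), SpreadCategory.SPREAD_0_5),
            # gradual decline, only the full 2-m drop resolvable -> decay
            (dc_from(ns(), sig(), ns()), enr(True), SpreadCategory.DISTANCE_DECAY),
            # no pairwise signal but overall distance effect with decline
            (
                dc_from(ns(), ns(), ns(), overall=sig(), trend=1),
                enr(False),
                SpreadCategory.DISTANCE_DECAY,
            ),
            # flat everywhere + enriched over controls -> complete spread
            (dc_from(ns(), ns(), ns()), enr(True), SpreadCategory.SPREAD_2M),
            # flat everywhere, no enrichment -> unknown
            (dc_from(ns(), ns(), ns()), enr(False), SpreadCategory.UNKNOWN),
            # significant increase with distance fits no rule -> unknown
            (dc_from(sig(-0.05), sig(-0.05), ns()), enr(False), SpreadCategory.UNKNOWN),
            # untestable contrasts propagate to unknown
            (dc_from(untestable(), untestable(), untestable()), enr(True),
             SpreadCategory.UNKNOWN),
        ],
    )
    def test_rule_table(self, dc, enrichment, expected):
        assert classify_otu(dc, enrichment, None) is expected

    def test_no_spread_takes_precedence_over_decay(self):
        # both near and far contrasts significant: rules 1 and 3 overlap on
        # the (0,2) contrast; precedence keeps NO_SPREAD
        dc = dc_from(sig(), sig(), sig(), overall=sig(), trend=1)
        assert classify_otu(dc, enr(True), None) is SpreadCategory.NO_SPREAD

    def test_bridge_override_upgrades_to_2m(self):
        dc = dc_from(ns(), ns(), ns())
        bi = BridgeIslandResult(
            otu="X", side_contrast=sig(), within_bridge_differences=False
        )
        assert classify_otu(dc, enr(False), bi) is SpreadCategory.SPREAD_2M

    def test_bridge_override_can_be_disabled(self):
        dc = dc_from(ns(), ns(), ns())
        bi = BridgeIslandResult(
            otu="X", side_contrast=sig(), within_bridge_differences=False
        )
        assert (
            classify_otu(dc, enr(False), bi, bridge_override=False)
            is SpreadCategory.UNKNOWN
        )

    def test_within_bridge_structure_vetoes_override(self):
        dc = dc_from(ns(), ns(), ns())
        bi = BridgeIslandResult(
            otu="X", side_contrast=sig(), within_bridge_differences=True
        )
        assert classify_otu(dc, enr(False), bi) is SpreadCategory.UNKNOWN

    def test_pure_function_identical_inputs_identical_output(self):
        dc = dc_from(ns(), sig(), sig())
        assert classify_otu(dc, enr(True), None) is classify_otu(dc, enr(True), None)


class TestSensitivityOptions:
    """Logit transform and BH adjustment are conservative variants."""

    def _simulated(self):
        import warnings

        from amfspread.model import to_proportions
        from amfspread.simulate import SimConfig, default_kernels, simulate_experiment

        cfg = SimConfig(
            n_blocks=7, n_years=1, n_otus_inocula=5, n_otus_background=20, seed=21
        )
        sim = simulate_experiment(cfg, default_kernels(cfg))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prop = to_proportions(sim.table)
        return prop, sim.profiles["site1"]

    def test_logit_transform_keeps_strong_patterns(self):
        from amfspread.classify import classify_trials

        prop, profile = self._simulated()
        recs = classify_trials(prop, profile, "site1", 1, transform="logit")
        by_otu = {r.trial.otu: r.trial.category for r in recs
                  if r.trial.inoculum is Inoculum.AMF}
        # the unambiguous no-spread kernel survives the transform
        assert by_otu["OTU0001"] is SpreadCategory.NO_SPREAD

    def test_bh_adjustment_only_raises_p_values(self):
        from amfspread.classify import classify_trials
        from amfspread.contrasts import PAIRWISE_KEYS

        prop, profile = self._simulated()
        raw = classify_trials(prop, profile, "site1", 1, p_adjust="none")
        adj = classify_trials(prop, profile, "site1", 1, p_adjust="bh")
        for r0, r1 in zip(raw, adj):
            for key in PAIRWISE_KEYS:
                c0, c1 = r0.distance.pairwise[key], r1.distance.pairwise[key]
                if c0.testable:
                    assert c1.p_value >= c0.p_value - 1e-12

    def test_unknown_adjustment_method_rejected(self):
        from amfspread.classify import classify_trials

        prop, profile = self._simulated()
        with pytest.raises(ValueError, match="p_adjust"):
            classify_trials(prop, profile, "site1", 1, p_adjust="bonferroni")


class TestEnumerateTrials:
    def test_shared_otus_counted_once_per_inoculum(self):
        prof = InoculaProfile(site="s", amf_otus={"A", "B"}, whole_otus={"B", "C"})
        trials = enumerate_trials(prof, "s", 1)
        assert len(trials) == 4
        keys = {(t.otu, t.inoculum) for t in trials}
        assert keys == {
            ("A", Inoculum.AMF), ("B", Inoculum.AMF),
            ("B", Inoculum.WHOLE), ("C", Inoculum.WHOLE),
        }

    @pytest.mark.parametrize(
        "n_amf, n_whole, n_shared, expected",
        [(61, 124, 44, 185), (46, 87, 42, 133), (15, 88, 11, 103)],
    )
    def test_trial_counts_double_count_shared_otus(
        self, n_amf, n_whole, n_shared, expected
    ):
        shared = {f"S{i}" for i in range(n_shared)}
        amf = shared | {f"A{i}" for i in range(n_amf - n_shared)}
        whole = shared | {f"W{i}" for i in range(n_whole - n_shared)}
        prof = InoculaProfile(site="s", amf_otus=amf, whole_otus=whole)
        trials = enumerate_trials(prof, "s", 1)
        assert len(trials) == expected
        assert len(amf | whole) == n_amf + n_whole - n_shared  # union is smaller


class TestTabulation:
    def test_all_unknown_count_vector(self):
        trials = [
            Trial(otu=f"o{i}", inoculum=Inoculum.AMF, site="s", year=1)
            for i in range(10)
        ]
        tab = tabulate_categories(trials)
        assert tab.loc[0, "UNKNOWN"] == 10
        assert tab.loc[0, "NO_SPREAD"] == 0
        assert tab.loc[0, "n_trials"] == 10

    def test_counts_partition_trials(self, rng):
        cats = list(SpreadCategory)
        trials = [
            Trial(
                otu=f"o{i}", inoculum=Inoculum.AMF, site="s", year=1,
                category=cats[rng.integers(len(cats))],
            )
            for i in range(37)
        ]
        tab = tabulate_categories(trials)
        assert tab[[c.value for c in cats]].to_numpy().sum() == 37

    def test_transition_cell_counts_matched_trials(self):
        t1 = Trial(otu="o1", inoculum=Inoculum.AMF, site="s", year=1,
                   category=SpreadCategory.NO_SPREAD)
        t2 = Trial(otu="o1", inoculum=Inoculum.AMF, site="s", year=2,
                   category=SpreadCategory.SPREAD_0_5)
        unmatched = Trial(otu="o2", inoculum=Inoculum.WHOLE, site="s", year=1,
                          category=SpreadCategory.SPREAD_2M)
        mat = transition_matrix([t1, t2, unmatched], 1, 2)
        assert mat.loc["NO_SPREAD", "SPREAD_0_5"] == 1
        assert mat.to_numpy().sum() == 1  # unmatched trial omitted

    def test_discordance_counts_shared_otus_with_differing_categories(self):
        trials = [
            Trial(otu="B", inoculum=Inoculum.AMF, site="s", year=1,
                  category=SpreadCategory.NO_SPREAD),
            Trial(otu="B", inoculum=Inoculum.WHOLE, site="s", year=1,
                  category=SpreadCategory.SPREAD_0_5),
            Trial(otu="C", inoculum=Inoculum.AMF, site="s", year=1,
                  category=SpreadCategory.UNKNOWN),
            Trial(otu="C", inoculum=Inoculum.WHOLE, site="s", year=1,
                  category=SpreadCategory.UNKNOWN),
            Trial(otu="D", inoculum=Inoculum.AMF, site="s", year=1,
                  category=SpreadCategory.UNKNOWN),
        ]
        df = discordance_counts(trials)
        assert df.loc[0, "n_shared_otus"] == 2
        assert df.loc[0, "n_discordant"] == 1


class TestFamilySpreadTest:
    def _trials(self, spec):
        """spec: list of (otu, family?, category)."""
        return [
            Trial(otu=o, inoculum=Inoculum.AMF, site="s", year=1, category=c)
            for o, c in spec
        ]

    def test_homogeneous_table_gives_chi2_zero(self):
        trials = []
        fams = {}
        i = 0
        for fam in ("Glomeraceae", "Claroideoglomeraceae"):
            for cat, n in (
                (SpreadCategory.SPREAD_2M, 10),
                (SpreadCategory.NO_SPREAD, 10),
            ):
                for _ in range(n):
                    otu = f"o{i}"; i += 1
                    fams[otu] = fam
                    trials.append(Trial(otu=otu, inoculum=Inoculum.AMF,
                                        site="s", year=1, category=cat))
        res = family_spread_test(trials, fams)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_2x2_closed_form(self):
        # closed form: chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        a, b, c, d = 20, 5, 5, 20
        trials, fams = [], {}
        i = 0
        for fam, spread_n, nospread_n in (("F1", a, b), ("F2", c, d)):
            for cat, n in ((SpreadCategory.SPREAD_2M, spread_n),
                           (SpreadCategory.NO_SPREAD, nospread_n)):
                for _ in range(n):
                    otu = f"o{i}"; i += 1
                    fams[otu] = fam
                    trials.append(Trial(otu=otu, inoculum=Inoculum.AMF,
                                        site="s", year=1, category=cat))
        res = family_spread_test(trials, fams)
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(expected, abs=1e-10)
        assert res.statistic == pytest.approx(18.0)
        assert res.df == 1

    def test_unknown_trials_are_excluded(self):
        fams = {"o1": "F1", "o2": "F2"}
        trials = [
            Trial(otu="o1", inoculum=Inoculum.AMF, site="s", year=1,
                  category=SpreadCategory.UNKNOWN),
            Trial(otu="o2", inoculum=Inoculum.AMF, site="s", year=1,
                  category=SpreadCategory.UNKNOWN),
        ]
        res = family_spread_test(trials, fams)
        assert not res.testable

    def test_single_family_untestable(self):
        fams = {"o1": "F1", "o2": "F1"}
        trials = [
            Trial(otu="o1", inoculum=Inoculum.AMF, site="s", year=1,
                  category=SpreadCategory.SPREAD_2M),
            Trial(otu="o2", inoculum=Inoculum.AMF, site="s", year=1,
                  category=SpreadCategory.NO_SPREAD),
        ]
        res = family_spread_test(trials, fams)
        assert not res.testable
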