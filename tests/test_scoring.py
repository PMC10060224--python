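import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dropscreen import (
    ScoringConfig,
    ScoringError,
    count_depleted_guides,
    differential_gds,
    filter_min_t0,
    gene_dependency_score,
    guide_log2fc,
    qc_controls,
    score_guides,
    to_frequencies,
)
from dropscreen.scoring import ALT_SELECTIVE, NEITHER, PAN_ESSENTIAL

from conftest import make_count_matrix


@pytest.fixture
def cfg():
    return ScoringConfig()


class TestFilterMinT0:
    def test_strict_lower_than_semantics_at_the_boundary(self, cfg):
        cm = make_count_matrix(
            ["g1", "g2", "g3"],
            {"ALT_T0": [49, 50, 51], "ALT_Tend": [10, 10, 10]},
        )
        res = filter_min_t0(cm, cfg)
        assert res.filtered.loc["g1", "ALT"]
        assert not res.filtered.loc["g2", "ALT"]  # exactly 50 is retained
        assert not res.filtered.loc["g3", "ALT"]
        assert list(res.discards["guide_id"]) == ["g1"]

    def test_all_abundant_means_empty_discard_list(self, cfg):
        cm = make_count_matrix(["g1", "g2"], {"ALT_T0": [50, 500],
                                              "ALT_Tend": [1, 1]})
        res = filter_min_t0(cm, cfg)
        assert res.discards.empty
        assert not res.filtered.to_numpy().any()

    def test_missing_t0_sample_is_an_error(self, cfg):
        cm = make_count_matrix(["g1"], {"ALT_Tend": [10]})
        with pytest.raises(ScoringError, match="T0"):
            filter_min_t0(cm, cfg)

    def test_matches_bruteforce_on_random_matrices(self, cfg, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            ids = [f"g{i}" for i in range(n)]
            cm = make_count_matrix(
                ids,
                {"ALT_T0": rng.integers(0, 120, n),
                 "ALT_Tend": rng.integers(0, 120, n)},
            )
            res = filter_min_t0(cm, cfg)
            expected = {
                g for g in ids if cm.counts.loc[g, "ALT_T0"] < cfg.min_t0_count
            }
            got = set(res.filtered.index[res.filtered["ALT"]])
            assert got == expected


class TestFrequenciesAndLog2FC:
    def test_symmetric_counts_give_half_half(self, cfg):
        cm = make_count_matrix(["g1", "g2"], {"A_T0": [10, 10]})
        freqs = to_frequencies(cm, cfg)
        np.testing.assert_allclose(freqs["A_T0"], [0.5, 0.5])

    def test_pseudocount_formula_on_zero_count(self, cfg):
        cm = make_count_matrix(["g1", "g2"], {"A_T0": [0, 10]})
        freqs = to_frequencies(cm, cfg)
        np.testing.assert_allclose(freqs["A_T0"], [0.5 / 11, 10.5 / 11])

    def test_frequencies_sum_to_one(self, cfg, rng):
        for _ in range(20):
            n = int(rng.integers(2, 50))
            cm = make_count_matrix(
                [f"g{i}" for i in range(n)],
                {"A_T0": rng.integers(0, 1000, n)},
            )
            total = to_frequencies(cm, cfg)["A_T0"].sum()
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sample_is_an_error(self, cfg):
        cm = make_count_matrix(["g1", "g2"], {"A_T0": [0, 0]})
        with pytest.raises(ScoringError, match="zero"):
            to_frequencies(cm, cfg)

    def test_log2fc_identity_and_eightfold_depletion(self):
        assert guide_log2fc(0.25, 0.25) == 0.0
        assert guide_log2fc(0.001, 0.000125) == pytest.approx(-3.0)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ScoringError):
            guide_log2fc(0.0, 0.5)

    def test_sign_convention_depletion_is_negative(self, cfg, rng):
        n = 30
        ids = [f"g{i}" for i in range(n)]
        t0 = rng.integers(100, 1000, n)
        tend = rng.integers(100, 1000, n)
        cm = make_count_matrix(ids, {"A_T0": t0, "A_Tend": tend})
        scores = score_guides(cm, cfg)
        freqs = to_frequencies(cm, cfg)
        dropped = freqs["A_Tend"] < freqs["A_T0"]
        for row in scores.itertuples():
            assert (row.log2fc < 0) == bool(dropped[row.guide_id])


class TestGeneDependencyScore:
    def _scores(self, entries):
        return pd.DataFrame(
            entries,
            columns=["guide_id", "condition", "log2fc", "filtered"],
        )

    def test_gds_is_arithmetic_mean_of_guides(self, small_library):
        scores = self._scores(
            [(f"sgGA#{j}", "ALT", v, False)
             for j, v in zip(range(1, 4), (-2.0, -4.0, -6.0))]
        )
        gds = gene_dependency_score(scores, small_library)
        row = gds[(gds["gene"] == "GENEA") & (gds["condition"] == "ALT")]
        assert row["gds"].iloc[0] == pytest.approx(-4.0)
        assert row["n_guides_used"].iloc[0] == 3

    def test_single_unfiltered_guide(self, small_library):
        scores = self._scores([("sgGA#1", "ALT", -3.2, False)])
        gds = gene_dependency_score(scores, small_library)
        row = gds[gds["gene"] == "GENEA"]
        assert row["gds"].iloc[0] == pytest.approx(-3.2)

    def test_fully_filtered_gene_flagged_absent_not_zero(self, small_library):
        scores = self._scores(
            [(f"sgGB#{j}", "ALT", np.nan, True) for j in range(1, 5)]
        )
        gds = gene_dependency_score(scores, small_library)
        row = gds[gds["gene"] == "GENEB"]
        assert bool(row["absent"].iloc[0])
        assert np.isnan(row["gds"].iloc[0])

    def test_unknown_guide_is_an_error(self, small_library):
        scores = self._scores([("sgZZ#1", "ALT", -1.0, False)])
        with pytest.raises(ScoringError, match="sgZZ#1"):
            gene_dependency_score(scores, small_library)

    @settings(derandomize=True)
    @given(
        values=st.lists(
            st.floats(-10, 10, allow_nan=False), min_size=2, max_size=5
        ),
        c=st.floats(-4, 4, allow_nan=False),
    )
    def test_gds_linearity_under_scaling(self, values, c):
        from dropscreen import GuideRecord, Library

        suffixes = ("AAC", "ACC", "AGC", "ATC", "CAC")
        lib = Library(tuple(
            GuideRecord(f"sgGA#{j}", "GENEA", "targeting",
                        "ATTGCATTGCATTGCAT" + suffixes[j])
            for j in range(5)
        ))
        base = self._scores(
            [(f"sgGA#{j}", "ALT", v, False) for j, v in enumerate(values)]
        )
        scaled = base.assign(log2fc=base["log2fc"] * c)
        g0 = gene_dependency_score(base, lib)["gds"].iloc[0]
        g1 = gene_dependency_score(scaled, lib)["gds"].iloc[0]
        assert g1 == pytest.approx(c * g0, rel=1e-9, abs=1e-9)


class TestCountDepletedGuides:
    def _table(self, per_guide):
        rows = []
        for guide, cond_vals in per_guide.items():
            for cond, v in cond_vals.items():
                rows.append((guide, cond, v, v is None))
        df = pd.DataFrame(rows, columns=["guide_id", "condition", "log2fc",
                                         "filtered"])
        df["log2fc"] = df["log2fc"].astype(float)
        return df

    def test_guide_below_threshold_in_every_condition_qualifies(
        self, small_library
    ):
        table = self._table(
            {"sgGA#1": {"A1": -6.0, "A2": -5.5, "A3": -7.0},
             "sgGA#2": {"A1": -6.0, "A2": -4.9, "A3": -7.0}}
        )
        counts = count_depleted_guides(table, small_library, -5.0,
                                       ["A1", "A2", "A3"])
        assert counts["GENEA"] == 1

    def test_filtered_anywhere_disqualifies(self, small_library):
        table = self._table(
            {"sgGA#1": {"A1": -6.0, "A2": None, "A3": -7.0}}
        )
        counts = count_depleted_guides(table, small_library, -5.0,
                                       ["A1", "A2", "A3"])
        assert counts["GENEA"] == 0

    def test_unknown_condition_label_is_an_error(self, small_library):
        table = self._table({"sgGA#1": {"A1": -6.0}})
        with pytest.raises(ScoringError, match="A9"):
            count_depleted_guides(table, small_library, -5.0, ["A9"])

    def test_matches_bruteforce_on_a_twelve_guide_gene(self, rng):
        # 12-guide gene scored in 3 conditions; count checked by enumeration
        from dropscreen import GuideRecord, Library

        def suffix(j):  # unique 4-mer per guide
            digits = []
            for _ in range(4):
                digits.append("ACGT"[j % 4])
                j //= 4
            return "".join(digits)

        lib = Library(tuple(
            GuideRecord(f"sgK#{j}", "KGENE", "targeting",
                        "ATTGCATTGCATTGCA" + suffix(j))
            for j in range(1, 13)
        ))
        conds = ["A1", "A2", "A3"]
        lfc = rng.uniform(-9, 0, size=(12, 3))
        table = pd.DataFrame(
            [(f"sgK#{j + 1}", conds[c], lfc[j, c], False)
             for j in range(12) for c in range(3)],
            columns=["guide_id", "condition", "log2fc", "filtered"],
        )
        counts = count_depleted_guides(table, lib, -5.0, conds)
        brute = sum(1 for j in range(12) if all(lfc[j, c] < -5.0
                                                for c in range(3)))
        assert counts["KGENE"] == brute


class TestDifferentialGDS:
    def _gene_scores(self, rows):
        return pd.DataFrame(rows, columns=["gene", "condition", "gds"])

    def test_selective_and_pan_essential_and_neither(self, cfg):
        gs = self._gene_scores([
            ("SEL", "ALT", -5.0), ("SEL", "CTRL", -0.2),
            ("PAN", "ALT", -5.0), ("PAN", "CTRL", -5.0),
            ("NEU", "ALT", 0.0), ("NEU", "CTRL", 0.0),
        ])
        out = differential_gds(gs, ["ALT"], ["CTRL"], cfg)
        cls = dict(zip(out["gene"], out["classification"]))
        assert cls == {"SEL": ALT_SELECTIVE, "PAN": PAN_ESSENTIAL,
                       "NEU": NEITHER}
        sel = out[out["gene"] == "SEL"]
        assert sel["delta_gds"].iloc[0] == pytest.approx(-4.8)

    def test_ranked_by_delta_ascending_with_deterministic_ties(self, cfg):
        gs = self._gene_scores([
            ("B", "ALT", -4.0), ("B", "CTRL", 0.0),
            ("A", "ALT", -3.0), ("A", "CTRL", 1.0),
            ("C", "ALT", -5.0), ("C", "CTRL", -1.0),
        ])
        out = differential_gds(gs, ["ALT"], ["CTRL"], cfg)
        # A and B tie at delta -4; the more ALT-depleted (B) ranks first
        assert list(out["gene"]) == ["C", "B", "A"]

    def test_empty_condition_group_is_an_error(self, cfg):
        gs = self._gene_scores([("A", "ALT", -1.0)])
        with pytest.raises(ScoringError, match="non-empty"):
            differential_gds(gs, ["ALT"], [], cfg)

    def test_condition_groups_averaged_unweighted(self, cfg):
        gs = self._gene_scores([
            ("G", "ALT1", -6.0), ("G", "ALT2", -2.0),
            ("G", "CTRL1", 0.5), ("G", "CTRL2", -0.5),
        ])
        out = differential_gds(gs, ["ALT1", "ALT2"], ["CTRL1", "CTRL2"], cfg)
        assert out["gds_alt"].iloc[0] == pytest.approx(-4.0)
        assert out["gds_ctrl"].iloc[0] == pytest.approx(0.0)


class TestQCControls:
    def test_no_controls_reports_not_evaluable(self, cfg):
        from dropscreen import GuideRecord, Library

        lib = Library((GuideRecord("sg1", "G1", "targeting",
                                   "ATTGCATTGCATTGCATTGC"),))
        scores = pd.DataFrame(
            [("sg1", "A", -1.0, False)],
            columns=["guide_id", "condition", "log2fc", "filtered"],
        )
        report = qc_controls(scores, lib, cfg)
        assert not report.evaluable
        assert "no control" in report.message

    def test_simulated_controls_behave_as_designed(self, cfg):
        # neutral negatives center on zero; s*e=0.5 positives all fall
        # below the depletion threshold in deterministic growth
        from dropscreen import screen_scenario, simulate_counts

        scenario, _ = screen_scenario(
            31, alt_conditions=("ALT",), control_conditions=(),
            n_selective=0,
        )
        res = simulate_counts(scenario)
        scores = score_guides(res.counts, cfg)
        report = qc_controls(scores, scenario.library, cfg)
        entry = report.conditions["ALT"]
        assert abs(entry["neg_median"]) < 0.05
        assert entry["pos_frac_depleted"] == 1.0
        assert report.passed
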