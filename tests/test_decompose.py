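"""Tests for absolute abundance, the decomposition statistic and group stats."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from necrosip.decompose import (
    absolute_abundance,
    decomposition_statistic,
    decomposition_table,
    filter_day0_prevalence,
    gram_group_comparison,
    phylum_range_summary,
)
from necrosip._stats import ttest_two_sample

from conftest import make_tables


def welch_p_oracle(a, b):
    """Hand-rolled Welch t-test p (Satterthwaite df, two-sided)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * stats.t.sf(abs(t), df)


class TestAbsoluteAbundance:
    def test_hand_arithmetic(self):
        t = make_tables({"s": [20, 980]}, {"s": 1e8}, {"s": (0, 1, "light", "H2_18O")})
        a = absolute_abundance(t)
        assert a.loc["OTU_1", "s"] == pytest.approx(2e6, rel=1e-12)
        assert a.loc["OTU_2", "s"] == pytest.approx(9.8e7, rel=1e-12)

    def test_zero_qpcr_gives_zero_abundance(self):
        t = make_tables({"s": [10, 10]}, {"s": 0.0}, {"s": (0, 1, "light", "H2_18O")})
        assert (absolute_abundance(t)["s"] == 0).all()

    def test_column_sums_reproduce_qpcr_totals(self, rng):
        counts = {f"s{i}": list(rng.integers(0, 500, size=30)) for i in range(6)}
        qpcr = {f"s{i}": float(rng.uniform(1e7, 1e9)) for i in range(6)}
        meta = {f"s{i}": (0, i + 1, "light", "H2_18O") for i in range(6)}
        t = make_tables(counts, qpcr, meta)
        a = absolute_abundance(t)
        for s in counts:
            assert a[s].sum() == pytest.approx(qpcr[s], rel=1e-12)

    def test_zero_count_column_flagged(self):
        t = make_tables({"s": [0, 0]}, {"s": 1e8}, {"s": (0, 1, "light", "H2_18O")})
        a = absolute_abundance(t)
        assert (a["s"] == 0).all() and a.attrs["zero_count_samples"] == ["s"]


class TestDecompositionStatistic:
    def test_identity_total_loss_and_hand_value(self):
        assert decomposition_statistic(2e6, 2e6) == pytest.approx(0.0, abs=1e-12)
        assert decomposition_statistic(2e6, 0.0) == pytest.approx(100.0, abs=1e-12)
        # A_T0 = 1e8 * 0.02, A_Ti = 5e7 * 0.018 -> D = 55 %
        assert decomposition_statistic(1e8 * 0.02, 5e7 * 0.018) == pytest.approx(
            55.0, abs=1e-12)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            decomposition_statistic(0.0, 1.0)

    @given(a0=st.floats(1e-3, 1e12), ati=st.floats(0, 1e12))
    def test_bounded_above_and_strictly_decreasing(self, a0, ati):
        d = decomposition_statistic(a0, ati)
        assert d <= 100.0
        assert decomposition_statistic(a0, ati + a0 * 0.1) < d

    def test_invariant_to_count_rescaling(self):
        # doubling every count in a sample leaves proportions, hence D, unchanged
        base = make_tables(
            {"s0": [100, 900], "s1": [50, 950]},
            {"s0": 1e8, "s1": 1e8},
            {"s0": (0, 1, "light", "H2_18O"), "s1": (30, 1, "light", "H2_18O")},
        )
        scaled = make_tables(
            {"s0": [300, 2700], "s1": [50, 950]},
            {"s0": 1e8, "s1": 1e8},
            {"s0": (0, 1, "light", "H2_18O"), "s1": (30, 1, "light", "H2_18O")},
        )
        a_base, a_scaled = absolute_abundance(base), absolute_abundance(scaled)
        for otu in a_base.index:
            d1 = decomposition_statistic(a_base.loc[otu, "s0"], a_base.loc[otu, "s1"])
            d2 = decomposition_statistic(a_scaled.loc[otu, "s0"], a_scaled.loc[otu, "s1"])
            assert d1 == pytest.approx(d2, abs=1e-12)


class TestDay0Filter:
    def test_printed_toy_table(self):
        # day-0 proportions 0.10% / 0.05% / 0.30% (+ filler): strict rule keeps 2 of 3
        t = make_tables({"d0": [10, 5, 30, 9955]}, {"d0": 1e8},
                        {"d0": (0, 1, "light", "H2_18O")})
        kept = filter_day0_prevalence(t)
        assert "OTU_1" in kept and "OTU_3" in kept
        assert "OTU_2" not in kept  # exactly 0.05 % -> excluded ("more than")

    def test_requires_day0_samples(self):
        t = make_tables({"s": [1, 1]}, {"s": 1e8}, {"s": (15, 1, "light", "H2_18O")})
        with pytest.raises(ValueError):
            filter_day0_prevalence(t)


def _replicate_tables(a0_props, ati_props, f0=1e8, fi=1e8, day=30):
    """4+4 replicate design from per-replicate proportion vectors."""
    counts, qpcr, meta = {}, {}, {}
    for r, props in enumerate(a0_props, 1):
        s = f"d0r{r}"
        counts[s] = [int(round(p * 1e6)) for p in props]
        qpcr[s], meta[s] = f0, (0, r, "light", "H2_18O")
    for r, props in enumerate(ati_props, 1):
        s = f"d{day}r{r}"
        counts[s] = [int(round(p * 1e6)) for p in props]
        qpcr[s], meta[s] = fi, (day, r, "light", "H2_18O")
    return make_tables(counts, qpcr, meta)


class TestDecompositionTable:
    def test_replicate_example_mean_and_significance(self):
        # per-replicate A: T0 = [10,11,9,10]e5 vs T30 = [5,6,4,5]e5 with F = 1e8
        a0 = [[0.010, 0.99], [0.011, 0.989], [0.009, 0.991], [0.010, 0.99]]
        ati = [[0.005, 0.995], [0.006, 0.994], [0.004, 0.996], [0.005, 0.995]]
        t = _replicate_tables(a0, ati)
        dt = decomposition_table(t).set_index("otu_id")
        row = dt.loc["OTU_1"]
        assert row["d_mean"] == pytest.approx(50.0, abs=1e-9)
        expected_p = welch_p_oracle([10e5, 11e5, 9e5, 10e5], [5e5, 6e5, 4e5, 5e5])
        assert row["p_value"] == pytest.approx(expected_p, rel=1e-9)
        assert expected_p < 0.05 and bool(row["significant"])

    def test_unchanged_otu_excluded_by_positive_filter(self):
        a0 = [[0.02, 0.98]] * 4
        t = _replicate_tables(a0, a0)
        dt = decomposition_table(t).set_index("otu_id")
        assert dt.loc["OTU_1", "d_mean"] == pytest.approx(0.0, abs=1e-9)
        assert not dt.loc["OTU_1", "passed_positive_filter"]
        assert dt.loc["OTU_1", "significant"] is pd.NA

    def test_vanished_otu_gets_full_decomposition(self):
        a0 = [[0.02, 0.98]] * 4
        ati = [[0.0, 1.0]] * 4
        dt = decomposition_table(_replicate_tables(a0, ati)).set_index("otu_id")
        assert dt.loc["OTU_1", "d_mean"] == pytest.approx(100.0, abs=1e-9)

    def test_single_replicate_reports_missing_significance(self):
        a0 = [[0.02, 0.98]] * 4
        ati = [[0.01, 0.99]]
        dt = decomposition_table(_replicate_tables(a0, ati)).set_index("otu_id")
        assert np.isnan(dt.loc["OTU_1", "p_value"])
        assert dt.loc["OTU_1", "d_mean"] == pytest.approx(50.0, abs=1e-6)

    def test_welch_vs_student_option(self):
        a0 = [[0.010, 0.99], [0.013, 0.987], [0.008, 0.992], [0.010, 0.99]]
        ati = [[0.005, 0.995], [0.009, 0.991], [0.002, 0.998], [0.006, 0.994]]
        t = _replicate_tables(a0, ati)
        pw = decomposition_table(t, ttest="welch").set_index("otu_id").loc["OTU_1", "p_value"]
        ps = decomposition_table(t, ttest="student").set_index("otu_id").loc["OTU_1", "p_value"]
        assert pw != ps
        a0v = [10e5, 13e5, 8e5, 10e5]
        ativ = [5e5, 9e5, 2e5, 6e5]
        assert ps == pytest.approx(stats.ttest_ind(a0v, ativ, equal_var=True).pvalue, rel=1e-9)

    def test_bh_qvalues_monotone_in_p(self):
        from necrosip.simulate import SimulationConfig, generate_community, \
            simulate_measurements, simulate_timecourse

        cfg = SimulationConfig(n_taxa=60, rng_seed=8)
        prof = generate_community(cfg)
        dt = decomposition_table(
            simulate_measurements(simulate_timecourse(prof, cfg), prof, cfg))
        sub = dt[(dt.timepoint_day == 30) & dt.passed_day0_filter].sort_values("p_value")
        q = sub["q_value"].values
        assert (np.diff(q[np.isfinite(q)]) >= -1e-12).all()
        assert (q[np.isfinite(q)] >= sub["p_value"].values[np.isfinite(q)] - 1e-12).all()


class TestTTestConventions:
    def test_identical_degenerate_data_gives_p_one(self):
        assert ttest_two_sample([60, 60], [60, 60]) == 1.0

    def test_disjoint_degenerate_data_gives_p_zero(self):
        assert ttest_two_sample([60, 60], [30, 30]) == 0.0


def _toy_dtable(ds_by_otu, day=30):
    rows = []
    for otu, d in ds_by_otu.items():
        rows.append({"otu_id": otu, "timepoint_day": day, "d_mean": float(d),
                     "d_se": 1.0, "d_reps": [d] * 4, "p_value": 0.01, "q_value": 0.02,
                     "significant": d > 50, "passed_day0_filter": True,
                     "passed_positive_filter": d > 0})
    df = pd.DataFrame(rows)
    df["significant"] = df["significant"].astype("boolean")
    return df


def _taxonomy(phyla_by_otu):
    return pd.DataFrame(
        {"phylum": pd.Series(phyla_by_otu),
         "genus": pd.Series({k: f"g_{k}" for k in phyla_by_otu})}
    )


class TestGramComparison:
    def test_separated_groups_highly_significant(self):
        d = {"a": 90, "b": 92, "c": 88, "d": 91, "e": 30, "f": 28, "g": 33, "h": 29}
        ph = {k: "Actinobacteria" for k in "abcd"} | {k: "Proteobacteria" for k in "efgh"}
        res = gram_group_comparison(_toy_dtable(d), _taxonomy(ph))
        assert res["p_value"].iloc[0] < 0.001
        assert res["p_value"].iloc[0] == pytest.approx(
            welch_p_oracle([90, 92, 88, 91], [30, 28, 33, 29]), rel=1e-9)

    def test_identical_degenerate_groups_give_p_one(self):
        d = {"a": 60, "b": 60, "c": 60, "d": 60}
        ph = {"a": "Firmicutes", "b": "Actinobacteria",
              "c": "Proteobacteria", "d": "Acidobacteria"}
        res = gram_group_comparison(_toy_dtable(d), _taxonomy(ph))
        assert res["p_value"].iloc[0] == 1.0

    def test_unnamed_phyla_excluded_and_small_group_missing(self):
        d = {"a": 90, "b": 85, "c": 20, "d": 50}
        ph = {"a": "Actinobacteria", "b": "Actinobacteria",
              "c": "Planctomycetes", "d": "Proteobacteria"}
        res = gram_group_comparison(_toy_dtable(d), _taxonomy(ph))
        assert res["n_gram_negative"].iloc[0] == 1  # Planctomycetes dropped
        assert np.isnan(res["p_value"].iloc[0])


class TestPhylumRangeSummary:
    def test_singleton_and_range(self):
        d = {"a": 51, "b": 70, "c": 92, "d": 40}
        ph = {"a": "Proteobacteria", "b": "Proteobacteria", "c": "Proteobacteria",
              "d": "Firmicutes"}
        res = phylum_range_summary(_toy_dtable(d), _taxonomy(ph)).set_index("phylum")
        assert res.loc["Proteobacteria", "d_min"] == 51
        assert res.loc["Proteobacteria", "d_max"] == 92
        assert res.loc["Proteobacteria", "otu_min"] == "a"
        assert res.loc["Proteobacteria", "genus_max"] == "g_c"
        assert res.loc["Firmicutes", "d_min"] == res.loc["Firmicutes", "d_max"] == 40

    def test_proportion_significant_definition(self):
        d = {"a": 51, "b": 70, "c": 92}  # significant flag is d > 50 in the toy table
        ph = {k: "Acidobacteria" for k in d}
        res = phylum_range_summary(_toy_dtable(d), _taxonomy(ph))
        assert res["prop_significant"].iloc[0] == pytest.approx(1.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            phylum_range_summary(pd.DataFrame(), _taxonomy({}))
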