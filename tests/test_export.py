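import numpy as np
import pandas as pd
import pytest

from mirexport import (
    CountTable,
    ExportAnalysis,
    build_export_table,
    correlation_report,
    distribution_summary,
    load_hek293t_tables,
    log2_ev_cell,
    rpmm,
)
from mirexport.normalize import ExpressionMatrix
from mirexport.simulate import SimulationConfig, simulate_count_tables

# published worked examples: (miRNA, condition, printed decimals)
PRINTED = [
    ("mir-451", "nt", 1),
    ("mir-150", "nt", 1),
    ("mir-146a", "nt", 1),
    ("mir-146a", "tf", 1),
    ("mir-320c", "nt", 1),
    ("mir-486", "nt", 1),
    ("mir-218", "nt", 2),
    ("mir-15a", "nt", 2),
    ("mir-16", "nt", 2),
    ("mir-451", "tf", 1),
]


class TestLog2EvCell:
    @pytest.mark.parametrize("mirna,cond,dp", PRINTED)
    def test_reproduces_printed_ratios(self, mirna, cond, dp):
        df = load_hek293t_tables()
        row = df.loc[mirna]
        got = log2_ev_cell(row[f"{cond}_cell_rpmm"], row[f"{cond}_ev_rpmm"])
        assert round(got, dp) == row[f"{cond}_log2_printed"]

    def test_equal_inputs_give_zero(self):
        for x in (0.4, 1.0, 317863.3):
            assert log2_ev_cell(x, x) == 0.0

    def test_nonpositive_inputs_are_nan_never_zero(self):
        assert np.isnan(log2_ev_cell(0.0, 100.0))
        assert np.isnan(log2_ev_cell(100.0, 0.0))
        assert np.isnan(log2_ev_cell(-1.0, 5.0))

    def test_vectorized_matches_scalar(self):
        cell = np.array([0.4, 10.4, 0.0])
        ev = np.array([3945.0, 1321.2, 5.0])
        got = log2_ev_cell(cell, ev)
        assert got[0] == pytest.approx(np.log2(3945.0 / 0.4))
        assert np.isnan(got[2])

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.lognormal(size=50), rng.lognormal(size=50)
        assert np.allclose(log2_ev_cell(a, b), -log2_ev_cell(b, a))


def _published_export_table(read_threshold=1000):
    """Build an ExportTable from the published RPMM columns.

    The study's libraries held ~1e6 mapped reads, so RPMM values double as
    read counts for thresholding purposes.
    """
    df = load_hek293t_tables()
    pairing = {}
    cols = {}
    for cond in ("nt", "tf"):
        cols[f"cell_{cond}"] = df[f"{cond}_cell_rpmm"]
        cols[f"EV_{cond}"] = df[f"{cond}_ev_rpmm"]
        pairing[cond] = (f"cell_{cond}", f"EV_{cond}")
    values = pd.DataFrame(cols)
    expr = ExpressionMatrix(values=values, denominators=values.sum(axis=0))
    counts = CountTable.from_counts(values)
    return build_export_table(expr, counts, pairing, read_threshold=read_threshold)


class TestExportTable:
    def test_most_released_and_retained_on_published_values(self):
        table = _published_export_table()
        assert table.released("nt").index[0] == "mir-451"
        assert table.retained("nt").index[0] == "mir-218"

    def test_released_and_retained_disjoint_and_exclude_similar(self):
        table = _published_export_table()
        for cond in table.conditions:
            rel = set(table.released(cond).index)
            ret = set(table.retained(cond).index)
            sim = set(
                table.frame(cond).index[table.frame(cond)["class"] == "similar"]
            )
            assert not rel & ret
            assert not (rel | ret) & sim

    def test_expressed_flag_uses_raw_reads_strictly(self):
        counts = CountTable.from_counts(
            pd.DataFrame(
                {"cell": [1000.0, 1001.0, 2e6], "EV": [500.0, 500.0, 2e6]},
                index=["at", "above", "big"],
            )
        )
        table = build_export_table(
            rpmm(counts), counts, {"c": ("cell", "EV")}, read_threshold=1000
        )
        f = table.frame("c")
        assert not f.loc["at", "expressed"]
        assert f.loc["above", "expressed"]

    def test_equal_profiles_classified_similar(self):
        counts = CountTable.from_counts(
            pd.DataFrame(
                {"cell": [5000.0, 3000.0], "EV": [5000.0, 3000.0]}, index=["a", "b"]
            )
        )
        table = build_export_table(rpmm(counts), counts, {"c": ("cell", "EV")})
        assert (table.frame("c")["class"] == "similar").all()
        assert table.released("c").empty and table.retained("c").empty

    def test_swapping_compartments_negates_ratios(self):
        cfg = SimulationConfig(n_mirnas=50, reads_per_library=100_000, spike=None, seed=3)
        counts, pairing, _ = simulate_count_tables(cfg)
        fwd = ExportAnalysis(counts, pairing).fit()
        swapped = {c: (ev, cell) for c, (cell, ev) in pairing.items()}
        rev = ExportAnalysis(counts, swapped).fit()
        a = fwd.log2_ratios("nt")
        b = rev.log2_ratios("nt")
        both = a.notna() & b.notna()
        assert both.equals(a.notna())  # co-detection is symmetric
        assert np.allclose(a[both], -b[both])

    def test_parameter_recovery_on_deep_counts(self):
        """log2 ratios recover the simulated export propensities.

        At 1e6 reads/library, after median-centering (the EV pool is
        compositionally closed), at least 95% of miRNAs expected above
        1000 reads in both compartments land within 0.2 log2 units.
        """
        cfg = SimulationConfig(
            n_mirnas=150, reads_per_library=1_000_000, spike=None, seed=29
        )
        counts, pairing, truth = simulate_count_tables(cfg)
        res = ExportAnalysis(counts, pairing, pseudocount=True).fit()
        est = res.log2_ratios("nt")
        eligible = (truth.cell_props * cfg.reads_per_library >= 1000) & (
            truth.ev_props * cfg.reads_per_library >= 1000
        )
        assert eligible.sum() >= 20
        est_c = est[eligible] - est[eligible].median()
        true_c = truth.e[eligible] - truth.e[eligible].median()
        frac = (np.abs(est_c - true_c) <= 0.2).mean()
        assert frac >= 0.95


class TestDistributionSummary:
    def _frame(self, ratios):
        return pd.DataFrame({"log2_ratio": ratios})

    def test_symmetric_ratios_have_near_zero_skew(self):
        rng = np.random.default_rng(7)
        summ = distribution_summary(self._frame(rng.normal(0, 1, 500)))
        assert abs(summ.skewness) < 0.1
        assert summ.n == 500

    def test_uniform_in_band_gives_fraction_one(self):
        rng = np.random.default_rng(8)
        summ = distribution_summary(self._frame(rng.uniform(-0.99, 0.99, 200)))
        assert summ.fraction_similar == 1.0

    def test_open_vs_closed_interval_at_the_boundary(self):
        ratios = [-1.0, -0.5, 0.0, 0.5, 1.0]
        open_ = distribution_summary(self._frame(ratios), interval="open")
        closed = distribution_summary(self._frame(ratios), interval="closed")
        assert open_.fraction_similar == pytest.approx(3 / 5)
        assert closed.fraction_similar == 1.0

    def test_exported_minority_right_skews_the_distribution(self):
        cfg = SimulationConfig(
            n_mirnas=200, reads_per_library=500_000, spike=None, seed=31
        )
        counts, pairing, _ = simulate_count_tables(cfg)
        res = ExportAnalysis(counts, pairing).fit()
        summ = res.distribution("nt")
        assert summ.skewness > 0.5

    def test_null_export_model_is_centred_and_unskewed(self):
        cfg = SimulationConfig(
            n_mirnas=200,
            reads_per_library=500_000,
            spike=None,
            baseline_sd=0.0,
            p_exported=0.0,
            p_retained=0.0,
            seed=33,
        )
        counts, pairing, _ = simulate_count_tables(cfg)
        res = ExportAnalysis(counts, pairing).fit()
        summ = res.distribution("nt")
        assert abs(summ.fitted_mean) < 0.2
        assert summ.fraction_similar > 0.9

    def test_histogram_frequencies_sum_to_co_detected(self):
        summ = _published_export_table().frames["nt"]
        d = distribution_summary(summ)
        assert d.frequencies.sum() == d.n

    def test_too_few_ratios_is_an_error(self):
        with pytest.raises(ValueError):
            distribution_summary(self._frame([0.5, 0.7]))


class TestCorrelationReport:
    def test_identical_profiles_give_r2_one(self):
        rng = np.random.default_rng(4)
        v = pd.DataFrame({"a": rng.lognormal(3, 2, 100)})
        v["b"] = v["a"]
        rep = correlation_report(v)
        assert rep.r_squared("a", "b") == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(12)
        v = pd.DataFrame(
            {"a": rng.lognormal(3, 2, 200), "b": rng.lognormal(3, 2, 200)}
        )
        rep = correlation_report(v)
        assert rep.r_squared("a", "b") < 0.1

    def test_multinomial_resamples_highly_correlated_on_log_scale(self):
        rng = np.random.default_rng(13)
        props = rng.dirichlet(np.full(200, 0.3))
        c1 = rng.multinomial(1_000_000, props).astype(float)
        c2 = rng.multinomial(1_000_000, props).astype(float)
        counts = CountTable.from_counts(
            pd.DataFrame({"r1": c1, "r2": c2}, index=[f"m{i}" for i in range(200)])
        )
        rep = correlation_report(rpmm(counts), scale="log")
        assert rep.r_squared("r1", "r2") > 0.95

    def test_fewer_than_three_shared_is_an_error(self):
        v = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            correlation_report(v)

    def test_read_threshold_filters_low_count_mirnas(self):
        idx = [f"m{i}" for i in range(10)]
        high = [2000.0, 3000.0, 4500.0, 7000.0, 12000.0]
        counts = CountTable.from_counts(
            pd.DataFrame({"a": high + [10.0] * 5, "b": high + [10.0] * 5}, index=idx)
        )
        rep = correlation_report(
            rpmm(counts), read_threshold=1000, counts_a=counts
        )
        assert rep.pairs[0]["n"] == 5


class TestResultsSurface:
    def test_summary_mentions_conditions_and_top_mirnas(self):
        table = load_hek293t_tables()
        counts = CountTable.from_counts(
            pd.DataFrame(
                {
                    "cell_nt": table["nt_cell_rpmm"],
                    "EV_nt": table["nt_ev_rpmm"],
                }
            )
        )
        res = ExportAnalysis(counts, {"nt": ("cell_nt", "EV_nt")}).fit()
        text = res.summary()
        assert "mir-451" in text and "mir-218" in text
        assert "condition 'nt'" in text

    def test_export_table_tsv_layout(self, tmp_path):
        table = _published_export_table()
        p = tmp_path / "table.tsv"
        table.to_tsv(p)
        out = pd.read_csv(p, sep="\t", header=[0, 1], index_col=0)
        assert ("nt", "RPMM cells") in out.columns
        assert out.loc["mir-451", ("nt", "log2(EV/Cells)")] == pytest.approx(13.27, abs=0.01)

    def test_plot_distribution_smoke(self):
        import matplotlib

        matplotlib.use("Agg")
        cfg = SimulationConfig(n_mirnas=50, reads_per_library=100_000, spike=None, seed=35)
        counts, pairing, _ = simulate_count_tables(cfg)
        ax = ExportAnalysis(counts, pairing).fit().plot_distribution("nt")
        assert ax.get_xlabel() == "log2(EV/cell)"

    def test_exclusion_annotated_in_results(self):
        cfg = SimulationConfig(n_mirnas=30, reads_per_library=50_000, seed=37)
        counts, pairing, truth = simulate_count_tables(cfg)
        spike = truth.spike.mirna_id
        res = ExportAnalysis(
            counts, pairing, exclude=[spike], exclude_libraries=["cell_tf", "EV_tf"]
        ).fit()
        assert res.table.excluded == [spike]
        # the spike keeps its values in the untouched condition
        assert res.frame("nt").loc[spike, "ev_rpmm"] > 0
        assert res.frame("tf").loc[spike, "cell_rpmm"] == 0
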