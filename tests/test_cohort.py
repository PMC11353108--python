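"""Cohort statistics: frequency picking, group summaries, ratio tables,
and the Kruskal-Wallis omnibus test."""

import numpy as np
import pytest
import scipy.integrate
import scipy.stats

import livercond as lc
from livercond.errors import (
    ConfigurationError,
    DegenerateDataError,
    MissingGroupError,
)
from livercond.study_tables import patient_groups_1mhz, patient_table


def sigma_spectrum(hz, sigma):
    return lc.ConductivitySpectrum(
        lc.FrequencyGrid(np.asarray(hz, dtype=float)),
        np.asarray(sigma, dtype=float),
    )


def flat_record(pid, tissue_class, state, value, grid_khz=(3, 30, 300, 607, 1000),
                tumor_type="none"):
    hz = np.array(grid_khz, dtype=float) * 1e3
    return lc.MeasurementRecord(
        pid, tissue_class, state,
        sigma_spectrum(hz, np.full(len(hz), value)),
        tumor_type=tumor_type,
    )


class TestPickFrequencies:
    def test_exact_grid_point_is_used_unchanged(self):
        spec = sigma_spectrum([3e3, 3e4, 1e6], [0.1, 0.2, 0.3])
        picks = lc.pick_frequencies(spec, lc.AnalysisFrequencies((3, 30, 1000)))
        assert [p.used_hz for p in picks] == [3e3, 3e4, 1e6]
        assert [p.value for p in picks] == [0.1, 0.2, 0.3]

    def test_tie_breaks_toward_lower_frequency(self):
        spec = sigma_spectrum([3e3, 5e3], [0.1, 0.2])
        (pick,) = lc.pick_frequencies(spec, lc.AnalysisFrequencies((4,)))
        assert pick.used_hz == 3e3
        assert pick.value == 0.1

    def test_nearest_point_matches_brute_force_oracle(self, default_grid):
        spec = lc.ConductivitySpectrum(
            default_grid, np.linspace(0.1, 0.9, len(default_grid))
        )
        for target_khz in (3, 30, 300, 607, 999, 1000):
            (pick,) = lc.pick_frequencies(
                spec, lc.AnalysisFrequencies((target_khz,))
            )
            # exhaustive scan with the same low-tie rule
            d = np.abs(default_grid.hz - target_khz * 1e3)
            oracle = default_grid.hz[np.argmin(d)]  # argmin takes first minimum
            assert pick.used_hz == oracle

    def test_target_outside_span_rejected(self, default_grid):
        spec = lc.ConductivitySpectrum(default_grid, np.full(256, 0.2))
        with pytest.raises(ConfigurationError):
            lc.pick_frequencies(spec, lc.AnalysisFrequencies((2000,)))


class TestSummarizeGroups:
    def test_hand_computed_mean_and_sd(self):
        records = [
            flat_record(f"p{i}", "normal", "in_vivo", v)
            for i, v in enumerate((0.1, 0.2, 0.3))
        ]
        out = lc.summarize_groups(records, lc.AnalysisFrequencies((3,)))
        (s,) = out
        assert s.n == 3
        assert s.mean == pytest.approx(0.2)
        assert s.sd == pytest.approx(0.1)  # n-1 denominator

    def test_single_record_group_has_no_sd(self):
        out = lc.summarize_groups(
            [flat_record("p0", "cirrhotic", "ex_vivo", 0.16)],
            lc.AnalysisFrequencies((3,)),
        )
        assert out[0].n == 1 and out[0].mean == 0.16 and out[0].sd is None

    def test_permutation_invariance(self, rng):
        records = [
            flat_record(f"p{i}", "tumor", "in_vivo", v, tumor_type="MET")
            for i, v in enumerate(rng.uniform(0.2, 0.8, 10))
        ] + [
            flat_record(f"q{i}", "normal", "in_vivo", v)
            for i, v in enumerate(rng.uniform(0.05, 0.3, 7))
        ]
        a = lc.summarize_groups(records, lc.AnalysisFrequencies((3, 1000)))
        perm = [records[i] for i in rng.permutation(len(records))]
        b = lc.summarize_groups(perm, lc.AnalysisFrequencies((3, 1000)))
        assert a == b

    def test_cirrhotic_not_pooled_with_normal(self):
        records = [
            flat_record("p0", "normal", "in_vivo", 0.13),
            flat_record("p1", "cirrhotic", "in_vivo", 0.09),
        ]
        out = lc.summarize_groups(records, lc.AnalysisFrequencies((3,)))
        by_class = {s.tissue_class: s for s in out}
        assert by_class["normal"].mean == 0.13
        assert by_class["cirrhotic"].mean == 0.09

    def test_bundled_case_table_in_vivo_normal_mean(self):
        """The 15 non-cirrhotic in vivo normal 1 MHz case values average to
        0.497 S/m (with the dropped-decimal cell read as 0.43)."""
        values = patient_groups_1mhz()["in_vivo_normal_non_cirrhotic"]
        assert len(values) == 15
        assert np.mean(values) == pytest.approx(0.497, abs=5e-4)

    def test_by_tumor_type_splits_only_tumor_records(self):
        records = [
            flat_record("p0", "tumor", "in_vivo", 0.4, tumor_type="HCC"),
            flat_record("p1", "tumor", "in_vivo", 0.5, tumor_type="MET"),
            flat_record("p2", "normal", "in_vivo", 0.1),
        ]
        out = lc.summarize_groups(
            records, lc.AnalysisFrequencies((3,)), by_tumor_type=True
        )
        assert {s.tumor_type for s in out} == {"HCC", "MET"}
        assert all(s.n == 1 for s in out)


def summaries_from_published_means(freqs=(3, 1000)):
    """GroupSummary objects carrying the published group means."""
    from livercond.study_tables import group_summary_table

    df = group_summary_table()
    out = []
    for _, row in df[df["frequency_khz"].isin(freqs)].iterrows():
        out.append(
            lc.GroupSummary(
                tissue_class=row["tissue_class"],
                state=row["state"],
                frequency_khz=float(row["frequency_khz"]),
                n=int(row["n"]),
                mean=float(row["mean"]),
                sd=float(row["sd"]),
            )
        )
    return out


class TestRatioTable:
    def test_published_cells_reproduced_by_ratio_of_means(self):
        table = lc.ratio_table(summaries_from_published_means())
        assert table.rounded.loc[3, "Tin/Nin"] == 3.2  # 0.41 / 0.13
        assert table.rounded.loc[3, "Tex/Cin"] == 3.0  # 0.27 / 0.09
        assert table.rounded.loc[1000, "Tin/Nin"] == 1.6  # 0.78 / 0.49

    def test_identical_groups_give_unit_ratio(self):
        records = [
            flat_record("p0", "tumor", "in_vivo", 0.3, tumor_type="HCC"),
            flat_record("p1", "tumor", "ex_vivo", 0.3, tumor_type="HCC"),
            flat_record("p2", "normal", "in_vivo", 0.3),
            flat_record("p3", "cirrhotic", "in_vivo", 0.3),
        ]
        table = lc.ratio_table(
            lc.summarize_groups(records, lc.AnalysisFrequencies((3,)))
        )
        assert (table.raw.loc[3] == 1.0).all()

    def test_transitivity_of_ratio_of_means(self):
        """ratio(A, C) == ratio(A, B) * ratio(B, C) exactly, pre-rounding."""
        table = lc.ratio_table(summaries_from_published_means()).raw
        for f in table.index:
            r = table.loc[f]
            assert r["Tin/Cin"] == pytest.approx(
                r["Tin/Nin"] * r["Nin/Cin"], rel=1e-12
            )
            assert r["Tex/Cin"] == pytest.approx(
                r["Tex/Nin"] * r["Nin/Cin"], rel=1e-12
            )

    def test_missing_group_reported_by_name(self):
        records = [
            flat_record("p0", "tumor", "in_vivo", 0.4, tumor_type="HCC"),
            flat_record("p1", "normal", "in_vivo", 0.13),
        ]
        with pytest.raises(MissingGroupError, match="cirrhotic"):
            lc.ratio_table(lc.summarize_groups(records, lc.AnalysisFrequencies((3,))))

    def test_rounding_half_away_from_zero(self):
        from livercond.cohort import round_half_away

        assert round_half_away(3.15, 1) == 3.2
        assert round_half_away(3.14999, 1) == 3.1
        assert round_half_away(-3.15, 1) == -3.2


class TestKruskalWallis:
    def test_hand_computed_two_group_case(self):
        """{1,2,3} vs {4,5,6}: rank sums 6 and 15 give H = 12/42*(12+75)-21
        = 27/7 = 3.857; p from an independent chi-square tail integration."""
        res = lc.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.h_statistic == pytest.approx(27.0 / 7.0, rel=1e-12)
        assert res.degrees_freedom == 1
        assert not res.tie_corrected
        # independent oracle: numerically integrate the chi2(1) density
        tail, _ = scipy.integrate.quad(
            lambda x: np.exp(-x / 2.0) / np.sqrt(2.0 * np.pi * x),
            27.0 / 7.0,
            np.inf,
        )
        assert res.p_value == pytest.approx(tail, rel=1e-8)
        assert res.p_value == pytest.approx(0.0495, abs=5e-4)

    def test_rank_invariance_under_monotone_transform(self, rng):
        groups = [rng.normal(0, 1, 8), rng.normal(0.5, 1, 6), rng.normal(1, 1, 7)]
        base = lc.kruskal_wallis(groups)
        transformed = [np.exp(3 * g) - 5 for g in groups]
        res = lc.kruskal_wallis(transformed)
        assert res.h_statistic == pytest.approx(base.h_statistic, rel=1e-12)
        assert res.p_value == pytest.approx(base.p_value, rel=1e-12)

    def test_tied_identical_groups(self):
        res = lc.kruskal_wallis([[1, 2], [1, 2]])
        assert res.tie_corrected
        assert res.h_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.9

    def test_matches_scipy_oracle_with_ties(self, rng):
        for _ in range(50):
            groups = [
                np.round(rng.normal(0, 1, rng.integers(3, 12)), 1) for _ in range(3)
            ]
            try:
                res = lc.kruskal_wallis(groups)
            except DegenerateDataError:
                continue
            ref = scipy.stats.kruskal(*groups)
            assert res.h_statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateDataError):
            lc.kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        with pytest.raises(ConfigurationError):
            lc.kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ConfigurationError):
            lc.kruskal_wallis([[1.0], [2.0]])
        with pytest.raises(ConfigurationError):
            lc.kruskal_wallis([[1.0, 2.0], []])


class TestSignificanceReport:
    def _cohort(self, rng):
        recs = []
        for i in range(8):
            recs.append(flat_record(f"t{i}", "tumor", "in_vivo",
                                    rng.uniform(0.35, 0.55), tumor_type="MET"))
            recs.append(flat_record(f"n{i}", "normal", "in_vivo",
                                    rng.uniform(0.08, 0.2)))
        return recs

    def test_separated_groups_flagged_significant(self, rng):
        report = lc.significance_report(
            self._cohort(rng), lc.AnalysisFrequencies((3, 1000)), alpha=0.05
        )
        assert report["significant"].all()
        assert (report["degrees_freedom"] == 1).all()

    def test_alpha_one_is_always_significant(self, rng):
        report = lc.significance_report(
            self._cohort(rng), lc.AnalysisFrequencies((3,)), alpha=1.0
        )
        assert report["significant"].all()

    def test_bundled_case_table_four_groups_significant(self):
        """The four per-patient 1 MHz groups differ significantly at 0.05."""
        groups = patient_groups_1mhz()
        res = lc.kruskal_wallis(list(groups.values()))
        assert res.degrees_freedom == 3
        assert res.tie_corrected  # the printed values contain many ties
        assert res.p_value < 0.05
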