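"""Generator contracts: simplex ground truth, analytic areas, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from venomquant import synthio
from venomquant.records import DEFAULT_GRADIENT, InputError, ParameterError

from conftest import make_venom


class TestGenerateMockVenom:
    def test_single_toxin_is_simplex_vertex(self):
        v = synthio.generate_mock_venom(n_toxins=1, seed=0)
        assert v.true_abundance == {"t01": 1.0}

    @pytest.mark.parametrize("seed", [7, 42, 123])
    def test_abundances_sum_to_one(self, seed):
        v = synthio.generate_mock_venom(n_toxins=12, seed=seed)
        assert abs(math.fsum(v.true_abundance.values()) - 1.0) < 1e-9

    def test_sparser_mixtures_at_low_concentration(self):
        # oracle: empirical Dirichlet order statistics — the expected maximum
        # component grows as the concentration parameter shrinks
        def mean_max(conc, n_seeds=200):
            return np.mean(
                [
                    max(
                        synthio.generate_mock_venom(
                            12, dirichlet_concentration=conc, seed=s
                        ).true_abundance.values()
                    )
                    for s in range(n_seeds)
                ]
            )

        assert mean_max(0.3) > mean_max(5.0)

    def test_peak_assignment_refers_to_known_toxins(self):
        v = synthio.generate_mock_venom(8, seed=3, coelution_prob=0.5)
        ids = {t.id for t in v.toxins}
        assert set(v.peak_assignment) == ids
        toxin_peaks = {p for split in v.peak_split.values() for p in split}
        assert not toxin_peaks & set(v.impurity_peaks)

    def test_family_motif_embedded(self):
        v = synthio.generate_mock_venom(5, seed=1, ensure_all_families=False)
        for t in v.toxins:
            motif = synthio._FAMILY_MOTIFS[t.family][0]
            assert motif in t.mature

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ParameterError):
            synthio.generate_mock_venom(3, dirichlet_concentration=0.0, seed=0)

    def test_zero_weights_rejected(self):
        with pytest.raises(ParameterError):
            synthio.generate_mock_venom(3, family_weights={"3FTx": 0.0}, seed=0)


class TestSimulateChromatogram:
    def test_numeric_area_matches_analytic_emg(self):
        # closed-form EMG area oracle: the pdf integrates to 1, so each
        # peak's trace integral must equal its ground-truth area
        v = make_venom([1.0])
        trace, truth = synthio.simulate_chromatogram(
            v, noise_sd=0.0, baseline_drift=0.0, sampling_interval=0.002, seed=0
        )
        num = np.trapezoid(trace["absorbance_mau"], trace["time_min"])
        ana = truth.peaks["area"].sum()
        assert num == pytest.approx(ana, rel=1e-3)

    def test_disjoint_peak_area_ratio_follows_abundance(self):
        v = make_venom([0.75, 0.25])
        _, truth = synthio.simulate_chromatogram(v, noise_sd=0.0, seed=0)
        areas = truth.peak_areas
        assert areas["P1"] / areas["P2"] == pytest.approx(3.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        v = make_venom([0.5, 0.5])
        t1, _ = synthio.simulate_chromatogram(v, seed=5)
        t2, _ = synthio.simulate_chromatogram(v, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_venom_rejected(self):
        empty = make_venom([1.0])
        object.__setattr__(empty, "toxins", ())
        with pytest.raises(InputError):
            synthio.simulate_chromatogram(empty)

    def test_retention_times_follow_gradient(self):
        v = make_venom([0.6, 0.4])
        rts = synthio.peak_retention_times(v)
        for pid, rt in rts.items():
            b = v.peak_percent_b[pid]
            assert DEFAULT_GRADIENT.percent_b(rt) == pytest.approx(b, abs=1e-9)


class TestSimulateGelAndMs1:
    def test_single_toxin_single_band(self):
        v = make_venom([1.0])
        gel = synthio.simulate_gel_and_ms1(v, seed=0, density_noise_cv=0.0)
        lane = gel.lanes[gel.lanes["peak_id"] == "P1"]
        assert len(lane) == 1
        assert gel.band_truth[("P1", "a")] == {"t01": 1.0}

    def test_cobanded_ms1_ratio_follows_abundance(self):
        v = make_venom(
            [0.9, 0.1], masses=[7.0, 7.5],
            peak_split={"t01": {"P1": 1.0}, "t02": {"P1": 1.0}},
        )
        gel = synthio.simulate_gel_and_ms1(v, seed=0, ms1_noise_sigma=0.0)
        sums = gel.ms1.groupby("toxin_id")["intensity"].sum()
        assert sums["t01"] / sums["t02"] == pytest.approx(9.0, rel=1e-9)

    def test_resolvable_mass_threshold_splits_bands(self):
        # threshold rule by hand: 13 - 7 = 6 kDa > 2 kDa => two bands
        v = make_venom(
            [0.5, 0.5], masses=[7.0, 13.0],
            peak_split={"t01": {"P1": 1.0}, "t02": {"P1": 1.0}},
        )
        gel = synthio.simulate_gel_and_ms1(v, seed=0, resolvable_kda=2.0)
        assert len(gel.lanes[gel.lanes["peak_id"] == "P1"]) == 2

    def test_unidentified_band_carries_requested_fraction(self):
        v = make_venom([1.0])
        gel = synthio.simulate_gel_and_ms1(
            v, seed=0, density_noise_cv=0.0, unidentified_band_fraction=0.1
        )
        lane = gel.lanes[gel.lanes["peak_id"] == "P1"]
        frac = lane.set_index("band_id")["density"]
        assert frac["u"] / frac.sum() == pytest.approx(0.1, abs=1e-12)

    def test_one_run_id_per_band(self):
        v = synthio.generate_mock_venom(8, seed=2, coelution_prob=0.6)
        gel = synthio.simulate_gel_and_ms1(v, seed=0)
        per_band = gel.ms1.groupby(["peak_id", "band_id"])["run_id"].nunique()
        assert (per_band == 1).all()

    def test_non_monotone_mobility_rejected(self):
        v = make_venom([0.5, 0.5], masses=[7.0, 13.0])
        with pytest.raises(ParameterError):
            synthio.simulate_gel_and_ms1(v, mass_to_mobility=lambda m: m, seed=0)

    def test_dynamic_range_floor(self):
        with pytest.raises(ParameterError):
            synthio.simulate_gel_and_ms1(make_venom([1.0]), ms1_dynamic_range=0.5)


class TestSimulateExpressionTable:
    def test_profile_recovered_within_two_points(self):
        table = synthio.simulate_expression_table(
            n_genes=4000, n_toxin_genes=200,
            family_expression_profile={"3FTx": 0.72, "PLA2": 0.16, "other": 0.12},
            seed=0,
        )
        from venomquant import transcriptome

        t = transcriptome.classify_active(table)
        shares = transcriptome.expression_shares(t)["family_share_percent"]
        assert shares["3FTx"] == pytest.approx(72.0, abs=2.0)
        assert shares["PLA2"] == pytest.approx(16.0, abs=2.0)

    def test_all_zero_table_has_no_active_genes(self):
        table = synthio.simulate_expression_table(
            n_genes=50, n_toxin_genes=5, seed=0, zero_fraction=1.0
        )
        from venomquant import transcriptome

        t = transcriptome.classify_active(table)
        assert (t["status"] != "active").all()
        assert transcriptome.count_toxin_genes(t)["n_toxin"] == 0

    def test_deterministic_given_seed(self):
        a = synthio.simulate_expression_table(n_genes=100, n_toxin_genes=10, seed=9)
        b = synthio.simulate_expression_table(n_genes=100, n_toxin_genes=10, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_shares_rejected(self):
        with pytest.raises(ParameterError):
            synthio.simulate_expression_table(
                family_expression_profile={"3FTx": 0.5}, seed=0
            )


def test_writers_roundtrip(tmp_path, fixture_venom):
    gen = synthio.write_fixture(tmp_path / "fx", venom=fixture_venom, seed=3)
    from venomquant import chromatography, densitometry, ms1 as ms1_mod

    trace = chromatography.read_trace(gen["paths"]["trace"])
    assert len(trace) > 1000
    lanes = densitometry.read_lanes(gen["paths"]["lanes"])
    assert {"lane_id", "band_id", "density"} <= set(lanes.columns)
    ms1 = ms1_mod.read_ms1(gen["paths"]["ms1"])
    assert len(ms1) > 0
    import yaml

    with open(gen["paths"]["manifest"]) as fh:
        manifest = yaml.safe_load(fh)
    assert manifest["seed"] == 3
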