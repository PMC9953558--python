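"""Droplet simulator: partition statistics, misreads, amplitude rendering."""

import numpy as np
import pytest

from ddscreen.simulate import (
    CohortConfig,
    SimulationConfig,
    apply_misread,
    lognormal_from_median_iqr,
    partition_templates,
    read_droplet_csv,
    render_amplitudes,
    simulate_cohort,
    simulate_well,
    write_droplet_csv,
)


class TestPartitionTemplates:
    def test_zero_copies_leaves_all_droplets_empty(self):
        occ = partition_templates({"WT": 0}, 50, seed=0)
        assert occ.counts["WT"].sum() == 0

    def test_single_molecule_lands_in_exactly_one_droplet(self):
        occ = partition_templates({"WT": 1}, 10, seed=1)
        assert occ.counts["WT"].sum() == 1
        assert (occ.counts["WT"] > 0).sum() == 1

    @pytest.mark.parametrize("copies", [{"WT": 137}, {"WT": 5000, "M1": 321}])
    def test_template_conservation_exact(self, copies):
        occ = partition_templates(copies, 2000, seed=7)
        for genotype, n in copies.items():
            assert occ.counts[genotype].sum() == n

    def test_occupied_fraction_matches_poisson_limit(self):
        """2000 molecules over 20000 droplets: P(occupied) ~ 1 - e^-0.1."""
        expected = 1 - np.exp(-0.1)
        sd = np.sqrt(expected * (1 - expected) / 20_000)
        for seed in range(5):
            occ = partition_templates({"WT": 2000}, 20_000, seed=seed)
            frac = (occ.counts["WT"] > 0).mean()
            assert abs(frac - expected) < 3 * sd

    def test_negative_copies_rejected(self):
        with pytest.raises(ValueError):
            partition_templates({"WT": -1}, 10, seed=0)


class TestApplyMisread:
    def test_epsilon_zero_flags_nothing(self):
        occ = partition_templates({"WT": 1000}, 500, seed=0)
        occ = apply_misread(occ, 0.0, seed=0)
        assert occ.misread.sum() == 0

    def test_epsilon_one_flags_every_molecule(self):
        occ = partition_templates({"WT": 1000}, 500, seed=0)
        occ = apply_misread(occ, 1.0, seed=0)
        assert occ.misread.sum() == 1000
        assert np.array_equal(occ.misread, occ.counts["WT"])

    def test_misread_count_binomial(self):
        """epsilon=0.003 on 10,000 molecules: ~30 misreads within 3 SD."""
        sd = np.sqrt(10_000 * 0.003 * 0.997)
        for seed in range(5):
            occ = partition_templates({"WT": 10_000}, 20_000, seed=seed)
            occ = apply_misread(occ, 0.003, seed=seed)
            assert abs(occ.misread.sum() - 30) < 3 * sd

    def test_misread_bounded_by_occupancy(self):
        occ = partition_templates({"WT": 500}, 100, seed=3)
        occ = apply_misread(occ, 0.5, seed=3)
        assert np.all(occ.misread <= occ.counts["WT"])


class TestRenderAmplitudes:
    def test_empty_well_stays_in_negative_clusters(self, separated_model):
        occ = partition_templates({"WT": 0}, 1000, seed=0)
        occ = apply_misread(occ, 0.0, seed=0)
        droplets = render_amplitudes(occ, separated_model, seed=0)
        assert droplets.amplitudes.max() < 2000

    def test_positive_droplets_render_high(self, separated_model):
        occ = partition_templates({"WT": 200, "M1": 100}, 1000, seed=1)
        occ = apply_misread(occ, 0.0, seed=1)
        droplets = render_amplitudes(occ, separated_model, seed=1)
        fam_truth = occ.mutant_positive()
        hex_truth = occ.wild_type_positive()
        assert np.all(droplets.fam[fam_truth] > 4500)
        assert np.all(droplets.fam[~fam_truth] < 4500)
        assert np.all(droplets.hex[hex_truth] > 4500)
        assert np.all(droplets.hex[~hex_truth] < 4500)

    def test_misread_molecule_renders_mutant_channel(self, separated_model):
        """A lone misread WT molecule lights FAM, not HEX, in its droplet."""
        occ = partition_templates({"WT": 50}, 1000, seed=2)
        occ = apply_misread(occ, 1.0, seed=2)
        droplets = render_amplitudes(occ, separated_model, seed=2)
        hit = occ.counts["WT"] > 0
        assert np.all(droplets.fam[hit] > 4500)
        assert np.all(droplets.hex[hit] < 4500)


class TestSimulateWell:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(copies={"WT": 500, "M1": 50}, n_droplets=2000,
                               epsilon=0.01, seed=11)
        a, b = simulate_well(cfg), simulate_well(cfg)
        assert np.array_equal(a.amplitudes, b.amplitudes)

    def test_truth_maf_is_input_arithmetic(self):
        cfg = SimulationConfig(copies={"WT": 5000, "M1": 500}, epsilon=0.0)
        assert cfg.true_maf_percent == pytest.approx(100 * 500 / 5500)

    def test_truth_bookkeeping_matches_occupancy(self):
        cfg = SimulationConfig(copies={"WT": 300, "M2": 30}, n_droplets=1000,
                               epsilon=0.0, seed=5)
        well = simulate_well(cfg)
        occ = well.truth.occupancy
        assert occ.counts["WT"].sum() == 300
        assert occ.counts["M2"].sum() == 30
        assert occ.mutant_positive().sum() == (occ.counts["M2"] > 0).sum()


class TestLognormalParameterisation:
    @pytest.mark.parametrize(
        "median, iqr", [(21.61, (8.30, 44.52)), (28.29, (19.03, 38.08))]
    )
    def test_monte_carlo_quantiles_near_targets(self, median, iqr, rng):
        """10,000 draws land near the cohort median/IQR the model encodes."""
        mu, sigma = lognormal_from_median_iqr(median, iqr)
        draws = np.clip(rng.lognormal(mu, sigma, 10_000), None, 100.0)
        q25, q50, q75 = np.percentile(draws, [25, 50, 75])
        assert q50 == pytest.approx(median, rel=0.10)
        assert q25 == pytest.approx(iqr[0], rel=0.15)
        assert q75 == pytest.approx(iqr[1], rel=0.15)

    def test_median_outside_iqr_rejected(self):
        with pytest.raises(ValueError):
            lognormal_from_median_iqr(5.0, (6.0, 10.0))


class TestSimulateCohort:
    def test_default_group_sizes_emit_142_samples(self):
        cfg = CohortConfig(n_droplets=200, dna_input_range=(5, 150), seed=0)
        samples = simulate_cohort(cfg)
        assert len(samples) == 142
        groups = [s.group for s in samples]
        assert groups.count("control") == 50
        assert groups.count("cystitis") == 22
        assert groups.count("UBC") == 70

    def test_non_case_samples_carry_no_true_mutant(self):
        cfg = CohortConfig(n_control=6, n_cystitis=3, n_ubc=0, n_droplets=500,
                           dna_input_range=(50, 400), epsilon=0.0, seed=1)
        for sample in simulate_cohort(cfg):
            for marker, well in sample.wells.items():
                assert not sample.truth_positive[marker]
                assert well.truth.occupancy.mutant_positive().sum() == 0

    def test_positive_samples_record_true_maf(self):
        cfg = CohortConfig(n_control=0, n_cystitis=0, n_ubc=12, n_droplets=500,
                           dna_input_range=(100, 400), seed=2)
        samples = simulate_cohort(cfg)
        positives = [
            (s, m) for s in samples for m in s.truth_positive if s.truth_positive[m]
        ]
        assert positives  # 12 samples at >1/3 positivity: some marker fires
        for sample, marker in positives:
            assert sample.truth_maf[marker] > 0


def test_droplet_csv_round_trip(tmp_path):
    cfg = SimulationConfig(copies={"WT": 100}, n_droplets=300, seed=9)
    well = simulate_well(cfg, well_id="w1", sample_id="s1")
    path = tmp_path / "w1.csv"
    write_droplet_csv(well, path)
    back = read_droplet_csv(path)
    assert back.well_id == "w1" and back.sample_id == "s1"
    assert back.n_droplets == 300
    assert np.allclose(back.amplitudes, well.amplitudes, atol=0.01)
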