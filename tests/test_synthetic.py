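import numpy as np
import pandas as pd
import pytest

from dopop import io
from dopop.breeding import (
    ColonyConfig,
    SchemeParams,
    initial_population,
    simulate_colony,
)
from dopop.genome import FOUNDER_CODES
from dopop.karyotype import call_sex_karyotype
from dopop.monitor import founder_frequency_profile
from dopop.synthetic import (
    NoiseModel,
    SyntheticError,
    anomaly_cohort,
    emit_breeding_records,
    generate_panel,
    genotype_cohort,
    inject_anomaly,
    smooth_diplotypes,
)


def three_se(p, n):
    return 3 * np.sqrt(p * (1 - p) / n)


class TestGeneratePanel:
    def test_deterministic_under_seed(self, small_map):
        a = generate_panel(small_map, seed=5)
        b = generate_panel(small_map, seed=5)
        assert a.markers.equals(b.markers)
        assert np.array_equal(a.consensus, b.consensus)

    def test_full_informativeness_all_private(self, small_map):
        panel = generate_panel(small_map, private_fraction=1.0, seed=6)
        nuclear = panel.markers["compartment"].isin(["auto", "X", "PAR"])
        assert (panel.markers.loc[nuclear, "private_founder"] != "").all()
        # each private marker's minor allele is carried by exactly one founder
        assert (panel.consensus[nuclear.to_numpy()].sum(axis=1) == 1).all()

    def test_private_fraction_binomial(self):
        from dopop.genome import GenomeMap
        gm = GenomeMap.default(n_autosomes=4, markers_per_chrom=250,
                               include_x=False)
        panel = generate_panel(gm, private_fraction=0.3, seed=7)
        nuclear = panel.markers["compartment"] == "auto"
        n = int(nuclear.sum())
        frac = (panel.markers.loc[nuclear, "private_founder"] != "").mean()
        assert abs(frac - 0.3) < three_se(0.3, n)

    def test_probe_subsets_present(self, small_map):
        panel = generate_panel(small_map, seed=8)
        assert len(panel.probe_names("Y")) == 7
        assert len(panel.probe_names("mito")) == 40


@pytest.fixture(scope="module")
def cohort(small_map):
    rng = np.random.default_rng(9)
    scheme = SchemeParams(n_lineages=15, ab_duplicates=False)
    pop = initial_population(small_map, scheme, rng)
    panel = generate_panel(small_map, seed=9)
    return pop, panel


class TestGenotypeCohort:
    def test_zero_noise_round_trip_matches_mosaic_truth(self, cohort):
        """Indicator diplotypes reproduce the mosaic-counting profile."""
        pop, panel = cohort
        clean = NoiseModel(error_rate=0.0, no_call_rate=0.0)
        samples, dip, dip_rows = genotype_cohort(pop, panel, clean, seed=1,
                                                 return_diplotypes=True)
        auto = panel.markers.iloc[dip_rows].reset_index(drop=True)
        keep = np.flatnonzero((auto["chrom"] == "1").to_numpy())
        positions = auto.loc[keep, "bp"].tolist()
        prof_probs = founder_frequency_profile(dip[:, keep],
                                               positions=positions)
        prof_mosaic = founder_frequency_profile(pop.all_individuals,
                                                positions=positions, chrom="1")
        assert np.allclose(prof_probs.to_numpy(), prof_mosaic.to_numpy())

    def test_error_rate_recovered(self, cohort):
        pop, panel = cohort
        noisy = NoiseModel(error_rate=0.02, no_call_rate=0.0)
        clean = NoiseModel(error_rate=0.0, no_call_rate=0.0)
        s_noisy = genotype_cohort(pop, panel, noisy, seed=2)
        s_clean = genotype_cohort(pop, panel, clean, seed=2)
        n = disc = 0
        for a, b in zip(s_noisy, s_clean):
            ok = (a.calls >= 0) & (b.calls >= 0)
            disc += int(np.sum(a.calls[ok] != b.calls[ok]))
            n += int(ok.sum())
        assert abs(disc / n - 0.02) < three_se(0.02, n)

    def test_xo_sample_statistics(self, cohort):
        pop, panel = cohort
        rng = np.random.default_rng(3)
        noise = NoiseModel()
        samples = genotype_cohort(pop, panel, noise, seed=3)
        female = next(s for s in samples if s.nominal_sex == "F")
        inject_anomaly(female, "XO", panel, noise, rng)
        x_idx = panel.markers.index[panel.markers["compartment"] == "X"]
        assert np.mean(female.intensity[x_idx]) == pytest.approx(-0.5, abs=0.1)
        called = female.calls[x_idx] >= 0
        assert np.all(female.calls[x_idx][called] != 1)
        assert call_sex_karyotype(female, panel.markers) == "XO"

    def test_zero_length_duplication_is_identity(self, cohort):
        pop, panel = cohort
        noise = NoiseModel()
        rng = np.random.default_rng(4)
        samples = genotype_cohort(pop, panel, noise, seed=4)
        male = next(s for s in samples if s.nominal_sex == "M")
        before = (male.calls.copy(), male.intensity.copy())
        inject_anomaly(male, "distal_dup", panel, noise, rng, dup_length=0)
        assert np.array_equal(male.calls, before[0])
        assert np.array_equal(male.intensity, before[1])

    def test_incompatible_anomaly_sex_rejected(self, cohort):
        pop, panel = cohort
        noise = NoiseModel()
        rng = np.random.default_rng(5)
        samples = genotype_cohort(pop, panel, noise, seed=5)
        male = next(s for s in samples if s.nominal_sex == "M")
        with pytest.raises(SyntheticError):
            inject_anomaly(male, "XO", panel, noise, rng)

    def test_smoothed_diplotypes_still_normalized(self, cohort):
        pop, panel = cohort
        clean = NoiseModel(error_rate=0.0, no_call_rate=0.0)
        _, dip, _ = genotype_cohort(pop, panel, clean, seed=6,
                                    return_diplotypes=True)
        mixed = smooth_diplotypes(dip, 0.2)
        assert np.allclose(mixed.sum(axis=-1), 1.0)
        assert np.all(mixed > 0)


class TestBreedingRecords:
    def test_row_count_without_failures(self, small_map):
        cfg = ColonyConfig(scheme=SchemeParams(n_lineages=175,
                                               failure_rate=0.0,
                                               ab_duplicates=False),
                           generations=1, seed=10)
        res = simulate_colony(cfg, genome_map=small_map)
        rec = emit_breeding_records(res)
        assert len(rec) == 350  # 175 matings x 2 litters

    def test_failed_flag_fraction(self, small_map):
        cfg = ColonyConfig(scheme=SchemeParams(n_lineages=30,
                                               failure_rate=0.1,
                                               ab_duplicates=False),
                           generations=10, seed=11)
        res = simulate_colony(cfg, genome_map=small_map)
        per_mating = res.records.drop_duplicates(
            ["generation", "lineage", "group", "dam_id"])
        frac = per_mating["failed"].mean()
        assert abs(frac - 0.1) < three_se(0.1, len(per_mating))


class TestRoundTrips:
    def test_records_round_trip(self, small_map, tmp_path):
        cfg = ColonyConfig(scheme=SchemeParams(n_lineages=8,
                                               ab_duplicates=False),
                           generations=2, seed=12)
        res = simulate_colony(cfg, genome_map=small_map)
        path = tmp_path / "records.tsv"
        io.write_records(res.records, path)
        back = io.read_records(path)
        pd.testing.assert_frame_equal(back, res.records)

    def test_panel_round_trip(self, small_map, tmp_path):
        panel = generate_panel(small_map, seed=13)
        path = tmp_path / "panel.tsv"
        io.write_panel(panel, path)
        back = io.read_panel(path)
        pd.testing.assert_frame_equal(back.markers, panel.markers)
        assert np.array_equal(back.consensus, panel.consensus)

    def test_samples_round_trip(self, small_map, tmp_path):
        females, males, panel, _ = anomaly_cohort(3, 3, 1, 1, seed=14,
                                                  genome_map=small_map)
        samples = females + males
        io.write_samples(samples, panel, tmp_path / "c.tsv", tmp_path / "i.tsv")
        back = io.read_samples(tmp_path / "c.tsv", tmp_path / "i.tsv")
        for a, b in zip(samples, back):
            assert a.id == b.id
            assert np.array_equal(a.calls, b.calls)
            assert np.allclose(a.intensity, b.intensity, atol=1e-4)

    def test_diplotypes_round_trip(self, small_map, tmp_path):
        rng = np.random.default_rng(15)
        scheme = SchemeParams(n_lineages=3, ab_duplicates=False)
        pop = initial_population(small_map, scheme, rng)
        panel = generate_panel(small_map, seed=15)
        clean = NoiseModel(error_rate=0.0, no_call_rate=0.0)
        samples, dip, dip_rows = genotype_cohort(pop, panel, clean, seed=7,
                                                 return_diplotypes=True)
        ids = [s.id for s in samples]
        markers = panel.markers.iloc[dip_rows]["marker"].tolist()
        path = tmp_path / "dip.tsv"
        io.write_diplotypes(dip, ids, markers, path)
        arr, sids, mids = io.read_diplotypes(path)
        assert sids == ids and mids == markers
        assert np.allclose(arr, dip, atol=1e-6)

    def test_mask_round_trip(self, small_map, tmp_path):
        panel = generate_panel(small_map, private_fraction=0.5, seed=16)
        mask = panel.private_mask()
        path = tmp_path / "mask.tsv"
        io.write_mask(mask, path)
        back = io.read_mask(path)
        pd.testing.assert_frame_equal(back, mask)
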