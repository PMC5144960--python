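import numpy as np
import pytest
from scipy import stats

from dopop.breeding import (
    ColonyConfig,
    DriveParams,
    LitterModel,
    SchemeParams,
    breed_generation,
    draw_crossovers,
    draw_litter,
    initial_population,
    make_gamete,
    random_mosaic,
    simulate_colony,
)
from dopop.genome import Chromosome, DriveLocus, GenomeMap, w_count
from dopop.purge import PurgePolicy


def three_se(p, n):
    return 3 * np.sqrt(p * (1 - p) / n)


class TestDrawCrossovers:
    def test_zero_genetic_length(self, rng):
        gm = GenomeMap([Chromosome("1", 1000, 0.0)])
        for _ in range(20):
            assert draw_crossovers(gm, "1", rng) == []

    def test_poisson_mean_on_one_morgan(self, rng):
        gm = GenomeMap([Chromosome("1", 10_000_000, 1.0)])
        counts = [len(draw_crossovers(gm, "1", rng)) for _ in range(10_000)]
        se = np.sqrt(1.0 / 10_000)
        assert abs(np.mean(counts) - 1.0) < 3 * se

    def test_positions_uniform_under_uniform_map(self, rng):
        gm = GenomeMap([Chromosome("1", 10_000_000, 1.0)])
        pos = []
        while len(pos) < 10_000:
            pos.extend(draw_crossovers(gm, "1", rng))
        u = np.array(pos[:10_000]) / 10_000_000
        assert stats.kstest(u, "uniform").pvalue > 0.01


@pytest.fixture(scope="module")
def het_dam(small_map, locus):
    rng = np.random.default_rng(7)
    scheme = SchemeParams(n_lineages=2, ab_duplicates=False)
    pop = initial_population(small_map, scheme, rng, locus, p_driven=None)
    for ind in pop.breeders:
        if ind.sex == "F":
            dam = ind
            break
    # force heterozygosity at the locus
    from dopop.breeding import set_founder_at
    m0, m1 = dam.genome[locus.chrom]
    dam.genome[locus.chrom] = (set_founder_at(m0, locus.pos, "H"),
                               set_founder_at(m1, locus.pos, "B"))
    return dam


class TestMakeGamete:

    def _transmission_fraction(self, parent, small_map, locus, tau, n, seed):
        rng = np.random.default_rng(seed)
        drive = DriveParams(tau=tau)
        hits = 0
        for _ in range(n):
            g = make_gamete(parent, small_map, locus, drive, rng)
            if g[locus.chrom].founder_at(locus.pos) == "H":
                hits += 1
        return hits / n

    def test_complete_drive_in_het_dam(self, het_dam, small_map, locus):
        frac = self._transmission_fraction(het_dam, small_map, locus, 1.0,
                                           2000, 1)
        assert frac == 1.0

    def test_intermediate_drive_in_het_dam(self, het_dam, small_map, locus):
        n = 10_000
        frac = self._transmission_fraction(het_dam, small_map, locus, 0.66, n, 2)
        assert abs(frac - 0.66) < three_se(0.66, n)

    def test_no_drive_through_male_germline(self, het_dam, small_map, locus):
        sire = het_dam
        sire.sex = "M"  # reuse the heterozygous genome as a sire
        try:
            n = 10_000
            frac = self._transmission_fraction(sire, small_map, locus, 0.9, n, 3)
            assert abs(frac - 0.5) < three_se(0.5, n)
        finally:
            sire.sex = "F"

    def test_forced_allele_conditioning(self, het_dam, small_map, locus):
        rng = np.random.default_rng(4)
        drive = DriveParams(tau=0.66)
        for want in (True, False):
            for _ in range(50):
                g = make_gamete(het_dam, small_map, locus, drive, rng,
                                force_w=want)
                assert (g[locus.chrom].founder_at(locus.pos) == "H") is want

    def test_gamete_mosaics_validate(self, het_dam, small_map, locus, rng):
        # FounderMosaic construction enforces the tiling invariant
        for _ in range(100):
            g = make_gamete(het_dam, small_map, locus, DriveParams(), rng)
            for chrom, mosaic in g.items():
                assert mosaic.length == small_map.chromosomes[chrom].length_bp


class TestDrawLitter:
    def test_null_effect_recovers_base_mean(self, rng):
        model = LitterModel(base_mean=8.0, wa_dam_effect=0.0)
        draws = [draw_litter(1, model, rng) for _ in range(10_000)]
        se = np.sqrt(np.var(draws) / len(draws))
        assert abs(np.mean(draws) - 8.0) < 3 * se

    def test_additive_wa_dam_reduction(self, rng):
        model = LitterModel(base_mean=8.0, wa_dam_effect=1.0)
        draws = [draw_litter(1, model, rng) for _ in range(10_000)]
        se = np.sqrt(np.var(draws) / len(draws))
        assert abs(np.mean(draws) - 7.0) < 3 * se

    def test_zero_mean_always_zero(self, rng):
        model = LitterModel(base_mean=0.0)
        assert all(draw_litter(0, model, rng) == 0 for _ in range(100))

    def test_sire_genotype_never_enters(self):
        model = LitterModel(base_mean=8.0, wa_dam_effect=2.0)
        assert model.mean_for(0) == model.mean_for(2) == 8.0
        assert model.mean_for(1) == 6.0


class TestBreedGeneration:
    def test_full_scale_lineage_structure(self, small_map, locus):
        """175 lineages with no failures stay 175 lineages, each filled."""
        rng = np.random.default_rng(11)
        scheme = SchemeParams(n_lineages=175, failure_rate=0.0)
        pop = initial_population(small_map, scheme, rng, locus)
        nxt, rec, ped = breed_generation(pop, scheme, LitterModel(), locus,
                                         DriveParams(), rng,
                                         genome_map=small_map)
        assert len(nxt.slots) == 175
        for slot in nxt.slots:
            assert slot.a_female.sex == "F" and slot.a_male.sex == "M"
            assert slot.b_female is not None and slot.b_male is not None
        # offspring lineage follows the dam (matrilineal)
        dams = {ind.id: ind for ind in pop.all_individuals}
        for _, row in ped.iterrows():
            assert row["lineage"] == dams[row["dam"]].lineage

    def test_mito_and_y_conserved_without_failures(self, small_map, locus):
        rng = np.random.default_rng(12)
        scheme = SchemeParams(n_lineages=30, failure_rate=0.0,
                              ab_duplicates=False)
        pop = initial_population(small_map, scheme, rng, locus)
        mito0 = sorted(s.a_female.mito for s in pop.slots)
        y0 = sorted(s.a_male.y for s in pop.slots)
        for _ in range(6):
            pop, _, _ = breed_generation(pop, scheme, LitterModel(), locus,
                                         DriveParams(), rng,
                                         genome_map=small_map)
        assert sorted(s.a_female.mito for s in pop.slots) == mito0
        assert sorted(s.a_male.y for s in pop.slots) == y0

    def test_failures_perturb_mito_frequencies(self, small_map, locus):
        """Failed matings are the only route to mito-frequency change."""
        finals = []
        for rep in range(8):
            rng = np.random.default_rng(100 + rep)
            scheme = SchemeParams(n_lineages=20, failure_rate=0.5,
                                  ab_duplicates=False)
            pop = initial_population(small_map, scheme, rng, locus)
            start = [s.a_female.mito for s in pop.slots]
            for _ in range(6):
                pop, _, _ = breed_generation(pop, scheme, LitterModel(), locus,
                                             DriveParams(), rng,
                                             genome_map=small_map)
            end = [s.a_female.mito for s in pop.slots]
            finals.append(sorted(start) != sorted(end))
        assert any(finals)

    def test_sib_avoidance_in_matings(self, small_map, locus):
        """No mated pair ever consists of full siblings."""
        rng = np.random.default_rng(13)
        scheme = SchemeParams(n_lineages=10, failure_rate=0.0,
                              ab_duplicates=False)
        pop = initial_population(small_map, scheme, rng, locus)
        parents: dict[str, tuple] = {}
        for _ in range(3):
            pop, rec, ped = breed_generation(pop, scheme, LitterModel(), locus,
                                             DriveParams(), rng,
                                             genome_map=small_map)
            for _, row in rec.iterrows():
                dp = parents.get(row["dam_id"])
                sp = parents.get(row["sire_id"])
                if dp is not None:
                    assert dp != sp, "full siblings were mated"
            parents = {row["id"]: (row["dam"], row["sire"])
                       for _, row in ped.iterrows()}


class TestSimulateColony:
    def test_deterministic_under_seed(self, small_map):
        cfg = ColonyConfig(scheme=SchemeParams(n_lineages=12,
                                               ab_duplicates=False),
                           generations=3, seed=42)
        a = simulate_colony(cfg, genome_map=small_map)
        b = simulate_colony(cfg, genome_map=small_map)
        assert a.trajectory.equals(b.trajectory)
        assert a.records.equals(b.records)

    def test_neutral_martingale(self, small_map):
        """Without drive the driven-founder frequency stays at 1/8."""
        finals = []
        for rep in range(20):
            cfg = ColonyConfig(
                scheme=SchemeParams(n_lineages=30, ab_duplicates=False,
                                    failure_rate=0.05),
                drive=DriveParams(tau=0.5), generations=8, seed=500 + rep)
            res = simulate_colony(cfg, genome_map=small_map)
            finals.append(res.trajectory["p_W"].iloc[-1])
        n_hap = 20 * 30 * 2 * 2
        assert abs(np.mean(finals) - 0.125) < three_se(0.125, n_hap)

    def test_strong_drive_sweeps(self, small_map):
        """tau=0.9 carries the driven allele above 0.95 in most replicates."""
        wins = 0
        for rep in range(9):
            cfg = ColonyConfig(
                scheme=SchemeParams(n_lineages=30, ab_duplicates=False,
                                    failure_rate=0.0),
                drive=DriveParams(tau=0.9), generations=30, seed=900 + rep)
            res = simulate_colony(cfg, genome_map=small_map)
            wins += res.trajectory["p_W"].iloc[-1] > 0.95
        assert wins > 9 / 2

    def test_purge_policy_drives_frequency_down(self, small_map):
        cfg = ColonyConfig(
            scheme=SchemeParams(n_lineages=40),
            drive=DriveParams(tau=0.66), generations=5, seed=77,
            p_driven0=0.62, purge_policy=PurgePolicy(),
            purge_start_generation=1)
        res = simulate_colony(cfg, genome_map=small_map)
        traj = res.trajectory["p_W"].to_numpy()
        assert traj[1] < traj[0]
        assert traj[-1] < 0.05

    def test_config_round_trip_from_dict(self):
        cfg = ColonyConfig.from_dict({
            "scheme": {"n_lineages": 10, "failure_rate": 0.0},
            "drive": {"tau": 0.8},
            "litter": {"base_mean": 7.0},
            "purge": {"start_generation": 2, "retained_fraction_ww_wa": 0.1},
            "generations": 4, "seed": 9})
        assert cfg.scheme.n_lineages == 10
        assert cfg.drive.tau == 0.8
        assert cfg.purge_start_generation == 2
        assert cfg.purge_policy.retained_fraction_ww_wa == 0.1


class TestRandomMosaic:
    def test_tiling_and_segment_count(self, rng):
        lengths = []
        for _ in range(200):
            m = random_mosaic("1", 10_000_000, rng, expected_segments=8.0)
            assert m.segments[0][0] == 0 and m.segments[-1][1] == 10_000_000
            lengths.append(len(m.segments))
        # merging adjacent-equal labels is impossible by construction,
        # so the mean segment count tracks the Poisson(7) + 1 target
        assert 7.0 < np.mean(lengths) < 9.0
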