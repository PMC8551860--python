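import numpy as np
import pandas as pd
import pytest

from fixscan.matrix import ELITE_HOM, HET, MISSING, WILD_HOM
from fixscan.simulate import (
    ExperimentConfig,
    PropagationSchedule,
    Season,
    SelectedLocus,
    SelectionModel,
    default_schedule,
    make_bc1s3_population,
    make_founders,
    make_genetic_map,
    meiosis,
    pool_and_call,
    propagate_line,
    simulate_experiment,
)
from fixscan.simulate import _gametes, _map_info

from conftest import make_gmap


class TestFounders:
    def test_rate_one_makes_fully_wild_donors(self):
        gmap = make_gmap(50)
        founders = make_founders(3, gmap, wild_polymorphism_rate=1.0, seed=0)
        assert founders.wild_masks.all()
        assert founders.elite_hap.sum() == 0

    def test_polymorphic_fraction_tracks_rate(self):
        gmap = make_gmap(1000)
        founders = make_founders(1, gmap, wild_polymorphism_rate=0.5, seed=1)
        n_poly = founders.wild_masks.sum()
        # binomial(1000, 0.5): 3 SD band
        assert abs(n_poly - 500) < 3 * np.sqrt(1000 * 0.25)

    @pytest.mark.parametrize("rate", [0.0, -0.1, 1.5])
    def test_degenerate_rates_rejected(self, rate):
        with pytest.raises(ValueError):
            make_founders(2, make_gmap(5), wild_polymorphism_rate=rate, seed=0)

    def test_empty_map_rejected(self):
        empty = pd.DataFrame(columns=["snp", "chrom", "cm"])
        with pytest.raises(ValueError):
            make_founders(2, empty, seed=0)


class TestMeiosis:
    def test_homozygous_parent_yields_parental_haplotype(self):
        gmap = make_gmap(30)
        parent = np.ones((2, 30), dtype=np.int8)
        rng = np.random.default_rng(0)
        gamete = meiosis(parent, gmap, rng)
        assert (gamete == parent[0]).all()

    def test_alleles_conserved_per_locus(self):
        """A gamete never carries an allele absent from its parent."""
        gmap = make_gmap(40)
        rng = np.random.default_rng(1)
        parent = rng.integers(0, 2, size=(2, 40)).astype(np.int8)
        for _ in range(20):
            gamete = meiosis(parent, gmap, rng)
            assert ((gamete == parent[0]) | (gamete == parent[1])).all()

    def test_crossover_rate_matches_map_length(self):
        """~1 observable crossover per 100 cM on a densely marked chromosome."""
        gmap = make_gmap(101, spacing_cm=1.0)  # 100 cM span
        parent = np.zeros((2, 101), dtype=np.int8)
        parent[1] = 1  # fully informative
        rng = np.random.default_rng(2)
        switches = []
        for _ in range(2000):
            gamete = meiosis(parent, gmap, rng)
            switches.append(int(np.count_nonzero(np.diff(gamete))))
        mean = np.mean(switches)
        se = np.std(switches, ddof=1) / np.sqrt(len(switches))
        # marker-observed switches slightly undercount true crossovers
        assert abs(mean - 1.0) < 0.02 + 3 * se

    def test_adjacent_marker_recombination_matches_haldane(self):
        """Both gamete generators give r = (1 - e^(-2d/100))/2 at d = 1 cM."""
        gmap = make_gmap(2, spacing_cm=1.0)
        expected = 0.5 * (1.0 - np.exp(-2 * 1.0 / 100))  # 0.00995
        parent = np.array([[0, 0], [1, 1]], dtype=np.int8)

        rng = np.random.default_rng(3)
        n = 120_000
        batch = _gametes(
            np.broadcast_to(parent, (n, 2, 2)), _map_info(gmap).r_full, rng
        )
        frac_batch = float((batch[:, 0] != batch[:, 1]).mean())

        n2 = 30_000
        rec = sum(
            int(g[0] != g[1]) for g in (meiosis(parent, gmap, rng) for _ in range(n2))
        )
        frac_single = rec / n2

        for frac, m in ((frac_batch, n), (frac_single, n2)):
            se = np.sqrt(expected * (1 - expected) / m)
            assert abs(frac - expected) < 3 * se


class TestBc1s3Population:
    def test_expected_genotype_class_proportions(self):
        """Base-generation lines segregate ~71.9 : 6.25 : 21.9 at family SNPs."""
        gmap = make_gmap(60)
        founders = make_founders(1, gmap, wild_polymorphism_rate=1.0, seed=4)
        _, g0 = make_bc1s3_population(founders, 600, gmap, seed=5)
        calls = g0.calls.to_numpy()
        per_line = np.stack(
            [(calls == c).mean(axis=1) for c in (ELITE_HOM, HET, WILD_HOM)]
        )
        for observed, expected in zip(per_line, (0.71875, 0.0625, 0.21875)):
            se = observed.std(ddof=1) / np.sqrt(len(observed))
            assert abs(observed.mean() - expected) < 3 * se

    def test_family_monomorphic_snps_stay_elite(self):
        gmap = make_gmap(40)
        founders = make_founders(2, gmap, wild_polymorphism_rate=0.5, seed=6)
        _, g0 = make_bc1s3_population(founders, 30, gmap, seed=7)
        for f in range(2):
            fam = f"F{f + 1:02d}"
            block = g0.calls.loc[g0.family == fam].to_numpy()
            mono = ~founders.wild_masks[f]
            assert (block[:, mono] == ELITE_HOM).all()

    def test_line_ids_carry_family_prefix(self):
        gmap = make_gmap(10)
        founders = make_founders(2, gmap, 1.0, seed=8)
        _, g0 = make_bc1s3_population(founders, 3, gmap, seed=9)
        assert list(g0.lines[:3]) == ["F01_001", "F01_002", "F01_003"]
        assert (g0.family.loc[["F02_001"]] == "F02").all()


class TestPropagation:
    def test_homozygous_input_breeds_true(self):
        gmap = make_gmap(20)
        line = np.zeros((2, 20), dtype=np.int8)
        line[:, 10:] = 1  # wild-homozygous block
        cohort = propagate_line(line, gmap, default_schedule(), seed=10)
        assert cohort.shape == (20, 2, 20)
        assert (cohort == line).all()

    def test_heterozygosity_decays_to_expected_residual(self):
        """Across many replicate lines the final het fraction is ~2^-5."""
        gmap = make_gmap(1)
        line = np.array([[0], [1]], dtype=np.int8)
        rng = np.random.SeedSequence(11)
        fracs = []
        for child in rng.spawn(1000):
            cohort = propagate_line(line, gmap, default_schedule(), seed=child)
            dosage = cohort.sum(axis=1)[:, 0]
            fracs.append(float((dosage == 1).mean()))
        mean = np.mean(fracs)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(mean - 0.03125) < 3 * se

    def test_strong_viability_selection_drives_wild_allele_up(self):
        gmap = make_gmap(1)
        line = np.array([[0], [1]], dtype=np.int8)
        sel = SelectionModel((SelectedLocus(gmap["snp"][0], s=5.0, phase="viability"),))
        rng = np.random.SeedSequence(12)
        wins = 0
        n = 200
        for child in rng.spawn(n):
            cohort = propagate_line(line, gmap, default_schedule(), sel, seed=child)
            wins += cohort.mean() > 0.5
        assert wins / n > 0.95

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            Season(n_sown=10, n_ears=11)
        with pytest.raises(ValueError):
            PropagationSchedule(seasons=())


class TestPoolAndCall:
    def _cohort(self, n_elite, n_wild, n_het=0, n_snps=1):
        plants = (
            [np.zeros((2, n_snps))] * n_elite
            + [np.ones((2, n_snps))] * n_wild
            + [np.array([[0] * n_snps, [1] * n_snps])] * n_het
        )
        return np.array(plants, dtype=np.int8)

    def test_balanced_pool_reconstructs_heterozygosity(self):
        calls = pool_and_call(self._cohort(6, 6), pool_size=12, seed=0)
        assert calls[0] == HET

    def test_tolerance_absorbs_minor_contamination(self):
        # 2 of 12 plants opposite-homozygous: minor fraction 1/6 <= 0.2
        calls = pool_and_call(
            self._cohort(10, 2), pool_size=12, minor_tolerance=0.2, seed=0
        )
        assert calls[0] == ELITE_HOM

    def test_unanimous_pool_called_homozygous_at_zero_tolerance(self):
        calls = pool_and_call(self._cohort(0, 12), pool_size=12,
                              minor_tolerance=0.0, seed=0)
        assert calls[0] == WILD_HOM

    def test_pool_larger_than_cohort_rejected(self):
        with pytest.raises(ValueError):
            pool_and_call(self._cohort(3, 3), pool_size=12, seed=0)

    def test_failure_rate_one_blanks_every_call(self):
        calls = pool_and_call(self._cohort(6, 6, n_snps=5), pool_size=12,
                              failure_rate=1.0, seed=0)
        assert (calls == MISSING).all()


class TestSimulateExperiment:
    def test_same_seed_gives_identical_matrices(self):
        gmap = make_genetic_map(60)
        cfg = ExperimentConfig(gmap=gmap, n_families=2, lines_per_family=5, seed=13)
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        assert a.g0.calls.equals(b.g0.calls)
        assert a.g8.calls.equals(b.g8.calls)

    def test_paired_matrices_share_lines_and_snps(self):
        gmap = make_genetic_map(40)
        cfg = ExperimentConfig(gmap=gmap, n_families=2, lines_per_family=4, seed=14)
        res = simulate_experiment(cfg)
        assert list(res.g0.lines) == list(res.g8.lines)
        assert list(res.g0.snps) == list(res.g8.snps)
        assert res.log["n_lines"] == 8

    def test_truth_table_records_selected_loci(self):
        gmap = make_genetic_map(40)
        snp = gmap["snp"].iloc[7]
        sel = SelectionModel((SelectedLocus(snp, s=1.0, h=0.5, phase="harvest"),))
        cfg = ExperimentConfig(gmap=gmap, n_families=1, lines_per_family=3,
                               selection=sel, seed=15)
        res = simulate_experiment(cfg)
        assert list(res.truth["snp"]) == [snp]
        assert res.truth["phase"].iloc[0] == "harvest"
        assert not res.truth["cm"].isna().any()

    def test_unknown_selected_locus_rejected(self):
        gmap = make_genetic_map(20)
        sel = SelectionModel((SelectedLocus("nope", s=1.0),))
        cfg = ExperimentConfig(gmap=gmap, n_families=1, lines_per_family=2,
                               selection=sel, seed=16)
        with pytest.raises(ValueError, match="nope"):
            simulate_experiment(cfg)


def test_selection_model_rejects_lethal_fitness():
    with pytest.raises(ValueError):
        SelectedLocus("x", s=-1.0)
    with pytest.raises(ValueError):
        SelectedLocus("x", s=0.5, h=2.0)
    with pytest.raises(ValueError):
        SelectedLocus("x", s=0.5, phase="meiotic")
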