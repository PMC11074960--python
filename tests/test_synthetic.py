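"""Synthetic-data generator: panel structure, gene-drop genetics, read
damage model, Y-STR walks and mito pileups."""

import numpy as np
import pytest

from kinid.errors import ParameterError
from kinid.fixtures import sibling_pedigree
from kinid.genetic_map import GeneticMap
from kinid.pedigree import FEMALE, MALE, Individual, Pedigree
from kinid.synthetic import (
    DamageModel,
    FrequencySpec,
    SiteObservation,
    gene_drop,
    generate_frequency_panel,
    random_reference,
    simulate_mito_pileup,
    simulate_reads,
    simulate_ystr_profiles,
)


class TestPanel:
    def test_full_scale_panel_counts(self):
        # the 95K-style manifest: 93,559 autosomal + 448 X + 745 Y targets
        panel = generate_frequency_panel(93559, 448, 745, seed=0)
        assert len(panel) == 94752
        assert panel.counts_by_class() == {
            "autosomal": 93559, "X": 448, "Y": 745,
        }

    def test_missing_frequency_fraction(self):
        # 23 of the 93,559 autosomal targets lack reference frequencies,
        # leaving 93,536 kinship-usable SNPs
        spec = FrequencySpec(missing_fraction=23 / 93559)
        panel = generate_frequency_panel(93559, 0, 0, freq_spec=spec, seed=0)
        usable = panel.df[
            (panel.df["chrom_class"] == "autosomal") & panel.df["has_frequency"]
        ]
        assert len(usable) == 93536

    def test_empty_panel(self):
        assert len(generate_frequency_panel(0, 0, 0, seed=0)) == 0

    def test_y_sites_have_no_map_position(self, small_panel):
        y = small_panel.df[small_panel.df["chrom_class"] == "Y"]
        assert y["cm"].isna().all()
        rest = small_panel.df[small_panel.df["chrom_class"] != "Y"]
        assert rest["cm"].notna().all()

    def test_same_seed_identical_output(self):
        a = generate_frequency_panel(500, 20, 10, seed=5)
        b = generate_frequency_panel(500, 20, 10, seed=5)
        assert a.df.equals(b.df)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ParameterError):
            FrequencySpec(missing_fraction=1.5)


class TestGeneDrop:
    def test_mendelian_consistency(self, trio_drop, small_panel):
        auto = small_panel.class_mask("autosomal")
        child = trio_drop.genotypes["child1"][auto]
        father = trio_drop.genotypes["father"][auto]
        mother = trio_drop.genotypes["mother"][auto]
        # paternal copy is one of father's, maternal one of mother's
        assert np.all(
            (child[:, 0] == father[:, 0]) | (child[:, 0] == father[:, 1])
        )
        assert np.all(
            (child[:, 1] == mother[:, 0]) | (child[:, 1] == mother[:, 1])
        )

    def test_parent_child_fully_ibd1(self, trio_drop):
        props = trio_drop.ibd_proportions("father", "child1")
        assert props[1] == pytest.approx(1.0)

    def test_founders_fully_ibd0(self, trio_drop):
        assert trio_drop.ibd_proportions("father", "mother")[0] == pytest.approx(1.0)

    def test_sibling_ibd2_proportion(self, gmap):
        ped = sibling_pedigree(2)
        vals = []
        for seed in range(400):
            drop = gene_drop(ped, gmap=gmap, seed=seed)
            vals.append(drop.ibd_proportions("child1", "child2")[2])
        assert np.mean(vals) == pytest.approx(0.25, abs=0.02)

    def test_x_father_son_zero_and_father_daughter_full(self, gmap):
        ped = sibling_pedigree(2, child_sexes=[MALE, FEMALE])
        drop = gene_drop(ped, gmap=gmap, seed=3)
        segs_son = drop.ibd_segments("father", "child1", "X")
        assert all(s.state == 0 for s in segs_son)
        segs_dau = drop.ibd_segments("father", "child2", "X")
        assert all(s.state == 1 for s in segs_dau)
        assert sum(s.length_cm for s in segs_dau) == pytest.approx(
            gmap.length("X")
        )

    def test_ibd_segments_partition_each_chromosome(self, trio_drop, gmap):
        segs = trio_drop.ibd_segments("child1", "child2")
        for chrom in gmap.autosomes:
            parts = sorted(
                (s for s in segs if s.chrom == chrom), key=lambda s: s.start_cm
            )
            assert parts[0].start_cm == 0.0
            assert parts[-1].end_cm == pytest.approx(gmap.length(chrom))
            for prev, nxt in zip(parts, parts[1:]):
                assert nxt.start_cm == pytest.approx(prev.end_cm)

    def test_determinism(self, small_panel):
        ped = sibling_pedigree(2)
        a = gene_drop(ped, small_panel, seed=7)
        b = gene_drop(ped, small_panel, seed=7)
        for iid in ped.ids:
            assert np.array_equal(a.genotypes[iid], b.genotypes[iid])


class TestCrossoverProcess:
    def test_chi2_interference_underdisperses_counts(self):
        from kinid.synthetic import _crossovers

        rng = np.random.default_rng(42)
        chi = [len(_crossovers(286.3, "chi2", 4, rng)) for _ in range(2000)]
        poi = [len(_crossovers(286.3, "poisson", 4, rng)) for _ in range(2000)]
        # both average ~1 crossover per Morgan, but the gamma renewal
        # process is under-dispersed relative to Poisson
        assert np.mean(chi) == pytest.approx(2.863, abs=0.15)
        assert np.mean(poi) == pytest.approx(2.863, abs=0.15)
        assert np.var(chi) < 0.8 * np.var(poi)


class TestReadSimulation:
    def test_zero_depth_means_empty(self, trio_drop, small_panel):
        obs = simulate_reads(
            {"father": trio_drop.genotypes["father"]}, small_panel, 0.0, seed=1
        )
        assert all(o.coverage == 0 for o in obs["father"])

    def test_clean_deep_reads_match_dosage(self, trio_drop, small_panel):
        dm = DamageModel(0.0, 0.0, 3.0, 0.0)
        obs = simulate_reads(
            {"father": trio_drop.genotypes["father"]}, small_panel, 50.0,
            damage=dm, seed=2,
        )
        auto = np.flatnonzero(small_panel.class_mask("autosomal"))[:300]
        geno = trio_drop.genotypes["father"]
        for i in auto:
            o = obs["father"][i]
            frac = o.alleles.mean()
            dosage = geno[i].sum() / 2
            assert frac == pytest.approx(dosage, abs=0.25)
            if dosage in (0.0, 1.0):
                assert frac == dosage  # no error: homozygotes are pure

    def test_damage_rate_at_terminal_base(self):
        # 1e5 terminal reads from a true-C homozygote at a C/T site:
        # T fraction must match the 5' amplitude
        rng_panel = generate_frequency_panel(1, 0, 0, seed=3)
        rng_panel.df.loc[0, ["ref", "alt"]] = ["C", "T"]
        geno = {"s": np.zeros((1, 2), dtype=np.int8)}
        dm = DamageModel(amplitude5=0.30, amplitude3=0.0, decay_length=3.0,
                         base_error=0.0)
        obs = simulate_reads(geno, rng_panel, 2e5, damage=dm, seed=4)["s"][0]
        terminal = (obs.dists == 0) & (obs.sides == 0)
        assert terminal.sum() > 1e3
        t_frac = obs.alleles[terminal].mean()
        assert t_frac == pytest.approx(0.30, abs=0.02)

    def test_negative_depth_rejected(self, trio_drop, small_panel):
        with pytest.raises(ParameterError):
            simulate_reads(
                {"father": trio_drop.genotypes["father"]}, small_panel, -1.0
            )


class TestYSTR:
    def test_zero_rates_copy_founder_profile(self):
        ped = sibling_pedigree(2)
        rates = {"DYS19": 0.0, "DYS390": 0.0}
        founder = {"DYS19": 14, "DYS390": 24}
        prof = simulate_ystr_profiles(ped, rates, founder, seed=0)
        assert prof["child1"] == founder
        assert prof["child2"] == founder

    def test_random_walk_displacement_over_ten_meioses(self):
        # rate 1 at one locus down a 10-meiosis patriline: mean |displacement|
        # must match a 10-step symmetric +-1 walk simulated directly
        members = [Individual("g0", MALE), Individual("w0", FEMALE)]
        for g in range(1, 11):
            members += [
                Individual(f"g{g}", MALE, f"g{g-1}", f"w{g-1}"),
                Individual(f"w{g}", FEMALE),
            ]
        ped = Pedigree(members)
        disp = []
        for seed in range(600):
            prof = simulate_ystr_profiles(
                ped, {"L": 1.0}, {"L": 15}, seed=seed
            )
            disp.append(abs(prof["g10"]["L"] - 15))
        rng = np.random.default_rng(99)
        walk = np.abs(rng.choice([-1, 1], size=(20000, 10)).sum(axis=1))
        assert np.mean(disp) == pytest.approx(walk.mean(), abs=0.25)

    def test_empty_locus_set(self):
        ped = sibling_pedigree(1)
        prof = simulate_ystr_profiles(ped, {}, {}, seed=0)
        assert prof["child1"] == {}

    def test_bad_rate_rejected(self):
        with pytest.raises(ParameterError):
            simulate_ystr_profiles(
                sibling_pedigree(1), {"L": 1.5}, {"L": 10}, seed=0
            )


class TestMitoPileup:
    def test_clean_pileup_shows_variants_everywhere(self):
        ref = random_reference(120, seed=5)
        pileup = simulate_mito_pileup({30: "T" if ref[29] != "T" else "A"},
                                      ref, depth=25, seed=6)
        row = pileup[pileup["position"] == "30"].iloc[0]
        want = "T" if ref[29] != "T" else "A"
        assert row[want] == row[["A", "C", "G", "T"]].sum()

    def test_zero_depth_empty(self):
        assert simulate_mito_pileup({}, "ACGT", depth=0, seed=0).empty

    def test_deamination_makes_mixed_position(self):
        ref = "A" * 50 + "C" + "A" * 49
        pileup = simulate_mito_pileup(
            {}, ref, depth=60, deamination_rate=0.4,
            deaminated_positions=[51], seed=7,
        )
        row = pileup[pileup["position"] == "51"].iloc[0]
        assert row["T"] / (row["T"] + row["C"]) == pytest.approx(0.4, abs=0.15)
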