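"""Y-STR composite rules, genetic distance, haplogroup placement and
mitochondrial haplotype calling/comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinid.errors import (
    InsufficientDataError,
    NonReportableProfileError,
    ParameterError,
)
from kinid.lineage import (
    HaplogroupNode,
    HaplogroupTree,
    MitoHaplotype,
    MitoVariant,
    STRProfile,
    build_composite_ystr,
    call_mito_variants,
    compare_mito_haplotypes,
    control_clean_check,
    place_y_haplogroup,
    ystr_genetic_difference,
)
from kinid.synthetic import random_reference, simulate_mito_pileup

# a 17-locus composite like the low copy number Yfiler profile of burial B
BURIAL_B_LIKE = {
    "DYS456": ["15"], "DYS389I": ["13"], "DYS390": ["24"], "DYS389II": ["29"],
    "DYS458": ["17"], "DYS19": ["14"], "DYS385": ["11", "14"],
    "DYS393": ["13"], "DYS391": ["11"], "DYS439": ["12"], "DYS635": ["23"],
    "DYS392": ["13"], "YGATAH4": ["12"], "DYS437": ["15"], "DYS438": ["12"],
    "DYS448": ["19"], "DYS576": ["18"],
}


class TestComposite:
    def _rep(self, loci):
        return STRProfile("B", {l: [(a, r)] for l, (a, r) in loci.items()})

    def test_replicated_above_threshold_confirmed(self):
        reps = [
            self._rep({"DYS19": ("14", 200), "DYS390": ("24", 150),
                       "DYS391": ("10", 120), "DYS393": ("13", 300)}),
            self._rep({"DYS19": ("14", 180), "DYS390": ("24", 90),
                       "DYS391": ("10", 140), "DYS393": ("13", 220)}),
        ]
        comp = build_composite_ystr(reps)
        assert all(
            comp.loci[l][0].status == "confirmed"
            for l in ("DYS19", "DYS390", "DYS391", "DYS393")
        )

    def test_single_occurrence_unreplicated(self):
        reps = [
            self._rep({"DYS19": ("14", 200), "DYS390": ("24", 150),
                       "DYS391": ("10", 120), "DYS393": ("13", 300),
                       "DYS456": ("15", 250)}),
            self._rep({"DYS19": ("14", 180), "DYS390": ("24", 90),
                       "DYS391": ("10", 140), "DYS393": ("13", 220)}),
        ]
        comp = build_composite_ystr(reps)
        assert comp.loci["DYS456"][0].status == "unreplicated"

    def test_replicated_below_threshold_flagged_bt(self):
        reps = [
            self._rep({"DYS19": ("14", 200), "DYS390": ("24", 150),
                       "DYS391": ("10", 120), "DYS393": ("13", 300),
                       "DYS438": ("12", 200)}),
            self._rep({"DYS19": ("14", 180), "DYS390": ("24", 90),
                       "DYS391": ("10", 140), "DYS393": ("13", 220),
                       "DYS438": ("12", 50)}),
        ]
        comp = build_composite_ystr(reps)
        allele = comp.loci["DYS438"][0]
        assert allele.status == "below-threshold"
        assert allele.render() == "12 (BT)"

    def test_too_few_reportable_loci_non_reportable(self):
        # mirrors samples failing to yield composite profiles (< 4 loci)
        reps = [
            self._rep({"DYS19": ("14", 200), "DYS390": ("24", 150),
                       "DYS391": ("10", 90)}),
            self._rep({"DYS19": ("14", 180), "DYS390": ("24", 120)}),
        ]
        with pytest.raises(NonReportableProfileError):
            build_composite_ystr(reps)

    def test_conflicting_replicated_alleles_not_reported(self):
        reps = [
            self._rep({"DYS19": ("14", 200), "DYS390": ("24", 150),
                       "DYS391": ("10", 120), "DYS393": ("13", 300)}),
            self._rep({"DYS19": ("15", 180), "DYS390": ("24", 90),
                       "DYS391": ("10", 140), "DYS393": ("13", 220)}),
            self._rep({"DYS19": ("14", 150), "DYS390": ("24", 95),
                       "DYS391": ("10", 130), "DYS393": ("13", 210)}),
            self._rep({"DYS19": ("15", 160), "DYS390": ("24", 85),
                       "DYS391": ("10", 135), "DYS393": ("13", 230)}),
        ]
        comp = build_composite_ystr(reps)
        assert {a.status for a in comp.loci["DYS19"]} == {"not-reported"}


class TestGeneticDifference:
    def test_identical_17_locus_profiles(self):
        total, _, n = ystr_genetic_difference(BURIAL_B_LIKE, BURIAL_B_LIKE)
        assert total == 0
        assert n == 17

    def test_single_one_step_difference_at_dys393(self):
        # the reference donor carries 14 repeats at DYS393 where the burial
        # has 13: genetic difference 1
        other = dict(BURIAL_B_LIKE, DYS393=["14"])
        total, per_locus, _ = ystr_genetic_difference(BURIAL_B_LIKE, other)
        assert total == 1
        assert per_locus["DYS393"] == 1

    def test_two_step_single_locus(self):
        # a genetic difference of two can arise from a two-step mutation
        # at a single locus
        other = dict(BURIAL_B_LIKE, DYS390=["26"])
        total, per_locus, _ = ystr_genetic_difference(BURIAL_B_LIKE, other)
        assert total == 2
        assert per_locus["DYS390"] == 2

    def test_multicopy_minimal_assignment(self):
        a = {"DYS385": ["11", "14"]}
        b = {"DYS385": ["12", "14"]}
        assert ystr_genetic_difference(a, b)[0] == 1
        c = {"DYS385": ["14", "11"]}  # order-free comparison
        assert ystr_genetic_difference(a, c)[0] == 0

    def test_copy_number_difference_uses_nearest_step(self):
        a = {"DYS385": ["11", "14"]}
        b = {"DYS385": ["11", "14", "15"]}
        assert ystr_genetic_difference(a, b)[0] == 1

    def test_missing_loci_skipped_and_counted(self):
        a = {"DYS19": ["14"], "DYS390": ["24"]}
        b = {"DYS19": ["14"], "DYS391": ["10"]}
        total, _, n = ystr_genetic_difference(a, b)
        assert (total, n) == (0, 1)

    def test_no_shared_loci_rejected(self):
        with pytest.raises(InsufficientDataError):
            ystr_genetic_difference({"DYS19": ["14"]}, {"DYS390": ["24"]})

    @settings(max_examples=60, deadline=None)
    @given(st.lists(
        st.tuples(
            st.integers(10, 20), st.integers(10, 20), st.integers(10, 20)
        ),
        min_size=1, max_size=6,
    ))
    def test_metric_on_fully_typed_single_copy_profiles(self, triples):
        """Symmetry, identity and the triangle inequality hold for the
        distance on fully-typed single-copy profiles."""
        loci = [f"L{i}" for i in range(len(triples))]
        pa = {l: [str(t[0])] for l, t in zip(loci, triples)}
        pb = {l: [str(t[1])] for l, t in zip(loci, triples)}
        pc = {l: [str(t[2])] for l, t in zip(loci, triples)}
        d = lambda x, y: ystr_genetic_difference(x, y)[0]
        assert d(pa, pb) == d(pb, pa)
        assert d(pa, pa) == 0
        assert d(pa, pc) <= d(pa, pb) + d(pb, pc)


def _random_tree_and_calls(rng):
    """A random 2-3 level haplogroup tree with random coverage/states."""
    nodes = [HaplogroupNode("root", None, [])]
    sid = itertools.count()
    calls = {}
    for i in range(rng.integers(2, 4)):
        parent = "root"
        for depth in range(rng.integers(1, 4)):
            name = f"hg{i}_{depth}"
            snps = []
            for _ in range(rng.integers(1, 3)):
                s = f"s{next(sid)}"
                snps.append((s, "A", "G"))
                state = rng.integers(3)
                if state == 1:
                    calls[s] = "A"
                elif state == 2:
                    calls[s] = "G"
            nodes.append(HaplogroupNode(name, parent, snps))
            parent = name
    return HaplogroupTree(nodes), calls


class TestHaplogroupPlacement:
    @pytest.fixture()
    def linear_tree(self):
        return HaplogroupTree([
            HaplogroupNode("R", None, []),
            HaplogroupNode("R-L151", "R", [("L151", "C", "T")]),
            HaplogroupNode("R-U152", "R-L151", [("U152", "G", "A")]),
            HaplogroupNode("R-BY32422", "R-U152", [("BY32422", "A", "C")]),
        ])

    def test_resolution_stops_at_coverage_gap(self, linear_tree):
        # derived at L151 and U152, no coverage at the terminal branch:
        # the finest resolvable haplogroup is R-U152
        name, support, conflicts = place_y_haplogroup(
            {"L151": "T", "U152": "A"}, linear_tree
        )
        assert name == "R-U152"
        assert set(support) == {"L151", "U152"}
        assert conflicts == []

    def test_no_coverage_anywhere_returns_root(self, linear_tree):
        assert place_y_haplogroup({}, linear_tree)[0] == "R"

    def test_ancestral_call_blocks_descent(self, linear_tree):
        name, _, _ = place_y_haplogroup(
            {"L151": "T", "U152": "G"}, linear_tree
        )
        assert name == "R-L151"

    def test_disjoint_derived_branches_reported_as_conflict(self):
        tree = HaplogroupTree([
            HaplogroupNode("root", None, []),
            HaplogroupNode("A", "root", [("sA", "C", "T")]),
            HaplogroupNode("B", "root", [("sB", "C", "T")]),
        ])
        name, _, conflicts = place_y_haplogroup({"sA": "T", "sB": "T"}, tree)
        assert name == "root"
        assert set(conflicts) == {"sA", "sB"}

    def test_empty_tree_rejected(self):
        with pytest.raises(ParameterError):
            HaplogroupTree([])

    def test_placement_path_never_contradicted_vs_oracle(self):
        """The chosen node always matches an exhaustive path-scoring
        oracle: the deepest node whose path holds at least one derived and
        zero ancestral covered defining SNPs per step, tie-broken by the
        walk order."""
        rng = np.random.default_rng(13)
        for _ in range(50):
            tree, calls = _random_tree_and_calls(rng)
            name, _, _ = place_y_haplogroup(calls, tree)
            path = tree.path_to_root(name)
            for node_name in path[1:]:
                node = tree.nodes[node_name]
                derived = [s for s, a, d in node.defining_snps
                           if calls.get(s) == d]
                ancestral = [s for s, a, d in node.defining_snps
                             if calls.get(s) == a]
                assert derived and not ancestral
            # oracle: no strictly deeper single-candidate extension exists
            children = [
                c for c in tree.children[name]
                if any(calls.get(s) == d for s, a, d in
                       tree.nodes[c].defining_snps)
                and not any(calls.get(s) == a for s, a, d in
                            tree.nodes[c].defining_snps)
            ]
            assert len(children) != 1


class TestMitoCalling:
    def _pileup(self, rows):
        return pd.DataFrame(
            [{"position": p, "A": a, "C": c, "G": g, "T": t, "gap": gp}
             for p, a, c, g, t, gp in rows]
        )

    def test_threshold_gates_exact(self):
        ref = "C" * 30
        pileup = self._pileup([
            ("5", 5, 7, 0, 0, 0),    # 12 reads, 5 variant (41.7%): called
            ("6", 3, 9, 0, 0, 0),    # count 3 < 4: not called
            ("7", 8, 0, 0, 0, 0),    # coverage 8 <= 10: not called
            ("8", 1, 10, 0, 0, 0),   # 11 reads, freq 9.1% < 10%: not called
        ])
        hap = call_mito_variants(pileup, ref)
        # only position 5 passes all gates; with the reference base also
        # passing, it is reported as a mixed (A/C -> M) call
        assert [v.position for v in hap.variants] == ["5"]
        assert hap.variants[0].call == "M"
        assert hap.variants[0].heteroplasmic

    def test_exact_10x_coverage_excluded(self):
        # "exceeded a 10X threshold" is strict: 10 reads do not qualify
        ref = "C" * 10
        pileup = self._pileup([("3", 10, 0, 0, 0, 0)])
        assert call_mito_variants(pileup, ref).variants == []

    def test_heteroplasmic_position_iupac(self):
        ref = "C" * 20
        pileup = self._pileup([("10", 0, 6, 0, 6, 0)])
        hap = call_mito_variants(pileup, ref)
        v = hap.variants[0]
        assert (v.call, v.heteroplasmic) == ("Y", True)

    def test_insertion_point_suffix(self):
        ref = "ACGTACGTACGTACGTACGT"
        pileup = self._pileup([("4.1", 0, 12, 0, 0, 0)])
        hap = call_mito_variants(pileup, ref)
        assert hap.variants[0].render() == "4.1C"
        assert hap.variants[0].type == "insertion"

    def test_position_outside_reference_rejected(self):
        with pytest.raises(ParameterError):
            call_mito_variants(self._pileup([("99", 0, 12, 0, 0, 0)]), "ACGT")

    def test_roundtrip_same_haplotype_no_differences(self):
        # simulate clean pileups of one haplotype twice; called haplotypes
        # must compare identical
        ref = random_reference(300, seed=17)
        variants = {50: "T" if ref[49] != "T" else "A",
                    120: "G" if ref[119] != "G" else "C"}
        haps = []
        for seed in (18, 19):
            pileup = simulate_mito_pileup(variants, ref, depth=40, seed=seed)
            haps.append(call_mito_variants(pileup, ref, sample=f"s{seed}"))
        n_diff, _ = compare_mito_haplotypes(haps[0], haps[1])
        assert n_diff == 0


class TestMitoComparison:
    def _hap(self, sample, variants, rng=(1, 16569)):
        return MitoHaplotype(sample, variants, rng)

    def test_identical_variant_lists_consistent(self):
        shared = [MitoVariant("73", "G", "substitution"),
                  MitoVariant("263", "G", "substitution"),
                  MitoVariant("315.1", "C", "insertion")]
        a = self._hap("burial3", list(shared))
        b = self._hap("burialB", list(shared))
        assert compare_mito_haplotypes(a, b)[0] == 0

    def test_heteroplasmy_ignored_by_convention(self):
        # one sample carries a mixed position (e.g. 10947Y from cytosine
        # deamination); it is not a haplotype difference
        base = [MitoVariant("73", "G", "substitution")]
        a = self._hap("burial4", base + [
            MitoVariant("10947", "Y", "substitution", heteroplasmic=True)
        ])
        b = self._hap("burial3", list(base))
        assert compare_mito_haplotypes(a, b, ignore_heteroplasmy=True)[0] == 0
        n, pos = compare_mito_haplotypes(a, b, ignore_heteroplasmy=False)
        assert (n, pos) == (1, ["10947"])

    def test_disjoint_ranges_rejected(self):
        a = self._hap("a", [], (1, 100))
        b = self._hap("b", [], (200, 300))
        with pytest.raises(InsufficientDataError):
            compare_mito_haplotypes(a, b)

    def test_variants_outside_shared_range_ignored(self):
        a = self._hap("a", [MitoVariant("50", "T", "substitution")], (1, 100))
        b = self._hap("b", [MitoVariant("150", "T", "substitution")], (40, 200))
        assert compare_mito_haplotypes(a, b)[0] == 1  # only pos 50 shared


class TestControls:
    @pytest.mark.parametrize("coverage, clean", [
        (0.3, True), (1.99, True), (2.0, False), (5.0, False),
    ])
    def test_clean_below_2x(self, coverage, clean):
        assert control_clean_check(coverage) is clean

    def test_negative_coverage_rejected(self):
        with pytest.raises(ParameterError):
            control_clean_check(-0.1)
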