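"""Site-to-column mapping, conservation calls, distal closure, rates,
reference baselines, the conservation index, classification and profile
clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phosmotif import (
    ConservationProfile,
    GroupIndex,
    ReferenceProfile,
    SpeciesLadder,
    category_transition_profiles,
    classify_pattern,
    cluster_profiles,
    conservation_index,
    conservation_profile,
    cut_profiles,
    distal_closure,
    map_site_column,
    reference_profile,
    residue_conserved,
    transitions,
)
from phosmotif.core import AMINO_ACIDS

from conftest import make_group


def profile(rates, species=None, motif_id="m", n=10):
    species = species or tuple(f"s{i}" for i in range(len(rates) - 1)) + ("hsa",)
    return ConservationProfile(motif_id, tuple(species), tuple(rates), n)


class TestMapSiteColumn:
    def test_gaps_are_skipped_when_counting(self):
        g = make_group("g", {"hsa": ("p", "M-KRS")})
        assert map_site_column(g, 3) == 4  # M, K, [R] -> column 4

    def test_identity_when_ungapped(self):
        g = make_group("g", {"hsa": ("p", "MKRS")})
        assert all(map_site_column(g, i) == i for i in range(1, 5))

    def test_position_beyond_sequence_raises(self):
        g = make_group("g", {"hsa": ("p", "MKRS")})
        with pytest.raises(ValueError, match="beyond"):
            map_site_column(g, 99)

    def test_missing_human_member_raises(self):
        g = make_group("g", {"fly": ("p", "MKRS")})
        with pytest.raises(ValueError, match="no hsa member"):
            map_site_column(g, 1)


class TestResidueConserved:
    G = make_group("g", {
        "hsa": ("p", "AKSDE"),
        "wrm": ("q", "AKTDE"),
        "cel": ("r", "AK-DE"),
    })

    def test_any_sty_accepts_cross_class_residue(self):
        # human S aligned to a worm T: conserved under the literal rule
        assert residue_conserved(self.G, 3, "wrm", "any_STY")

    def test_class_matched_keeps_tyrosine_separate(self):
        g = make_group("g", {"hsa": ("p", "AKYDE"), "wrm": ("q", "AKSDE")})
        assert not residue_conserved(g, 3, "wrm", "class_matched")
        assert residue_conserved(g, 3, "wrm", "any_STY")

    def test_gap_is_not_conserved(self):
        assert not residue_conserved(self.G, 3, "cel")

    def test_absent_species_is_not_conserved(self):
        assert not residue_conserved(self.G, 3, "dre")

    def test_unknown_species_raises_when_ladder_given(self):
        with pytest.raises(KeyError):
            residue_conserved(self.G, 3, "xyz", valid_species=("hsa", "wrm"))

    def test_any_paralog_may_conserve(self):
        g = make_group("g", {"hsa": ("p", "AKSDE")})
        from phosmotif import GroupMember, OrthologGroup

        g = OrthologGroup("g", g.members + (
            GroupMember("wrm", "q1", "AKADE"),
            GroupMember("wrm", "q2", "AKSDE"),
        ))
        assert residue_conserved(g, 3, "wrm")


class TestDistalClosure:
    def test_intermediate_gap_is_closed(self):
        raw = [0, 0, 1, 0, 1, 1, 1, 1, 1]
        assert distal_closure(raw).tolist() == [0, 0, 1, 1, 1, 1, 1, 1, 1]

    def test_human_only_profile_unchanged(self):
        raw = [0] * 8 + [1]
        assert distal_closure(raw).tolist() == raw

    @given(st.lists(st.booleans(), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_monotone(self, raw):
        once = distal_closure(raw)
        assert distal_closure(once).tolist() == once.tolist()
        assert all(a <= b for a, b in zip(once, once[1:]))


class TestConservationProfile:
    def test_hand_counted_toy_rates(self, toy_groups, toy_index, toy_ladder,
                                    toy_sites):
        prof = conservation_profile("toy", toy_sites, toy_index, toy_ladder)
        assert prof.rates == pytest.approx((1 / 3, 1 / 3, 2 / 3, 1.0))
        assert prof.n_human_sites == 3

    def test_protein_level_counts_each_protein_once(self, toy_index,
                                                    toy_ladder):
        # two sites on p1 (pos 3 via closure everywhere, pos 5 nowhere):
        # at site level rates dilute, at protein level p1 counts once as
        # conserved wherever any of its sites is
        sites = [("p1", 3), ("p1", 5)]
        by_site = conservation_profile("m", sites, toy_index, toy_ladder,
                                       level="site")
        by_protein = conservation_profile("m", sites, toy_index, toy_ladder,
                                          level="protein")
        assert by_site.rates[:3] == pytest.approx((0.5, 0.5, 0.5))
        assert by_protein.rates == pytest.approx((1.0, 1.0, 1.0, 1.0))
        assert by_protein.n_human_sites == 1

    def test_profiles_monotone_toward_human(self, bundle):
        index = GroupIndex(bundle.groups)
        known = bundle.sites[bundle.sites.status == "known"]
        sites = [(r.protein_id, int(r.position))
                 for r in known.itertuples(index=False)]
        prof = conservation_profile("all", sites, index, bundle.ladder)
        assert all(a <= b for a, b in zip(prof.rates, prof.rates[1:]))
        assert prof.rates[-1] == 1.0

    def test_no_sites_raises(self, toy_index, toy_ladder):
        with pytest.raises(ValueError):
            conservation_profile("m", [], toy_index, toy_ladder)


class TestReferenceProfile:
    def test_zero_divergence_gives_unit_rates(self):
        ladder = SpeciesLadder(("aaa", "bbb", "hsa"), (0.0, 0.0))
        from phosmotif import evolve_families

        groups, _ = evolve_families(ladder, 10, (40, 60), seed=5)
        index = GroupIndex(groups)
        rows = []
        for g in groups:
            hm = g.member("hsa")
            for i, ch in enumerate(hm.ungapped):
                if ch in "STY":
                    rows.append((hm.protein_id, i + 1, ch, "potential"))
        sites = pd.DataFrame(rows, columns=["protein_id", "position",
                                            "residue", "status"])
        ref = reference_profile(sites, index, ladder)
        assert ref.rates == pytest.approx((1.0, 1.0, 1.0))

    def test_single_branch_retention_matches_binomial_oracle(self):
        # two-step ladder with substitutions only on the branch to "out"
        d = 0.3
        ladder = SpeciesLadder(("out", "mid", "hsa"), (d, 0.0))
        from phosmotif import blosum62, evolve_families

        groups, _ = evolve_families(ladder, 120, (60, 90), seed=8)
        index = GroupIndex(groups)
        rows = []
        for g in groups:
            hm = g.member("hsa")
            for i, ch in enumerate(hm.ungapped):
                if ch in "STY":
                    rows.append((hm.protein_id, i + 1, ch, "potential"))
        sites = pd.DataFrame(rows, columns=["protein_id", "position",
                                            "residue", "status"])
        ref = reference_profile(sites, index, ladder)
        # analytic retention: stay put, or substitute into another acceptor
        # under the BLOSUM62 exchange propensities (2**(score/2), diag excl.)
        mat = blosum62()
        per_res = {}
        for r in "STY":
            weights = {b: 2.0 ** (mat[(r, b)] / 2.0)
                       for b in AMINO_ACIDS if b != r}
            total = sum(weights.values())
            into_sty = sum(v for b, v in weights.items() if b in "STY")
            per_res[r] = (1 - d) + d * into_sty / total
        counts = sites["residue"].value_counts()
        expect = sum(per_res[r] * counts[r] for r in "STY") / counts.sum()
        n = counts.sum()
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(ref.rates[0] - expect) <= 3 * se
        assert ref.rates[1] == pytest.approx(1.0)  # zero-divergence branch

    def test_empty_residue_class_raises(self, toy_index, toy_ladder):
        sites = pd.DataFrame(
            [("p1", 3, "S", "known")],
            columns=["protein_id", "position", "residue", "status"])
        with pytest.raises(ValueError):
            reference_profile(sites, toy_index, toy_ladder, residue_class="Y")


class TestConservationIndex:
    def ref(self, rates, species=None):
        p = profile(rates, species)
        return ReferenceProfile("STY", p.species, p.rates, 100)

    def test_equal_profiles_give_zero(self):
        rates = (0.2, 0.5, 0.9, 1.0)
        assert conservation_index(profile(rates), self.ref(rates)).value == 0.0

    def test_maximal_contrast_over_eight_species(self):
        c = profile((1.0,) * 9)
        r = self.ref((0.0,) * 8 + (1.0,), species=c.species)
        assert conservation_index(c, r).value == pytest.approx(8.0)

    def test_elementwise_sum_example(self):
        c = profile((0.1, 0.1, 0.2, 0.2, 0.4, 0.6, 0.8, 1.0, 1.0))
        r = self.ref((0.1, 0.1, 0.2, 0.2, 0.3, 0.5, 0.6, 0.9, 1.0),
                     species=c.species)
        # independent elementwise sum over the 8 non-human species
        expect = sum(ci - ri for ci, ri in zip(c.rates[:-1], r.rates[:-1]))
        got = conservation_index(c, r).value
        assert got == pytest.approx(expect) == pytest.approx(0.5)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a = np.sort(rng.random(8)).tolist() + [1.0]
        b = np.sort(rng.random(8)).tolist() + [1.0]
        c1 = profile(tuple(a))
        r1 = self.ref(tuple(b), species=c1.species)
        c2 = profile(tuple(b), species=c1.species)
        r2 = self.ref(tuple(a), species=c1.species)
        assert conservation_index(c1, r1).value == pytest.approx(
            -conservation_index(c2, r2).value)

    def test_ladder_mismatch_raises(self):
        c = profile((0.5, 1.0, 1.0))
        r = self.ref((0.5, 1.0, 1.0),
                     species=("other", "pair", "hsa"))
        with pytest.raises(ValueError):
            conservation_index(c, r)


class TestTransitionsAndClassification:
    def test_constant_profile_has_zero_transitions(self):
        t = transitions(profile((0.6,) * 9))
        assert t.tolist() == [0.0] * 8

    def test_step_profile_has_single_unit_jump(self):
        rates = (0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
        t = transitions(profile(rates))
        assert t[2] == 1.0 and np.count_nonzero(t) == 1

    def test_transition_length_is_ladder_minus_one(self):
        for n in (3, 5, 9):
            assert transitions(profile((1.0,) * n)).size == n - 1

    def test_jump50_calls_sigmoid_and_names_acquisition(self):
        # distal-ordered: jump of 0.7 between dme and dre -> acquired at dre
        rates = (0.0, 0.0, 0.1, 0.2, 0.9, 0.95, 0.95, 1.0, 1.0)
        species = ("sce", "spo", "cel", "dme", "dre", "cfa", "mmu", "ptr",
                   "hsa")
        call = classify_pattern(profile(rates, species))
        assert call.call == "sigmoid"
        assert call.acquisition_species == "dre"

    def test_flat_profile_is_linear(self):
        call = classify_pattern(profile((0.6,) * 9))
        assert call.call == "linear" and call.acquisition_species is None

    def test_jump_of_exactly_half_is_linear(self):
        rates = (0.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 1.0, 1.0)
        call = classify_pattern(profile(rates))
        assert call.call == "linear"  # strict > 0.5

    def test_tie_breaks_toward_the_more_distal_pair(self):
        rates = (0.0, 0.6, 0.6, 0.6, 1.0, 1.0, 1.0, 1.0, 1.0)
        species = ("sce", "spo", "cel", "dme", "dre", "cfa", "mmu", "ptr",
                   "hsa")
        call = classify_pattern(profile(rates, species))
        assert call.acquisition_species == "spo"

    def test_mean_sd_rule_needs_cohort(self):
        with pytest.raises(ValueError):
            classify_pattern(profile((0.5,) * 9), rule="mean_sd")

    def test_mean_sd_threshold_from_pooled_cohort(self):
        flat = [profile((0.5,) * 9, motif_id=f"f{i}") for i in range(8)]
        steppy = profile((0.0, 0.0, 0.0, 0.0, 0.8, 0.9, 1.0, 1.0, 1.0),
                         motif_id="s")
        cohort = flat + [steppy]
        call = classify_pattern(steppy, rule="mean_sd", k=2.0, cohort=cohort)
        assert call.call == "sigmoid"
        flat_call = classify_pattern(flat[0], rule="mean_sd", k=2.0,
                                     cohort=cohort)
        assert flat_call.call == "linear"


def ward_linkage_oracle(x):
    """Brute-force Ward agglomeration via the Lance-Williams update."""
    n = len(x)
    sizes = {i: 1 for i in range(n)}
    d = {(i, j): float(np.linalg.norm(x[i] - x[j]))
         for i in range(n) for j in range(i + 1, n)}
    heights = []
    next_id = n
    while len(sizes) > 1:
        (i, j), dij = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(dij)
        ni, nj = sizes.pop(i), sizes.pop(j)
        new = {}
        for k in sizes:
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            nk = sizes[k]
            val = np.sqrt(((ni + nk) * dik**2 + (nj + nk) * djk**2
                           - nk * dij**2) / (ni + nj + nk))
            new[k] = float(val)
        d = {key: v for key, v in d.items() if i not in key and j not in key}
        for k, v in new.items():
            d[(min(k, next_id), max(k, next_id))] = v
        sizes[next_id] = ni + nj
        next_id += 1
    return heights


class TestClusterProfiles:
    def test_two_identical_groups_separate_at_k2(self):
        a = [profile((0.9,) * 9, motif_id=f"a{i}") for i in range(3)]
        b = [profile((0.1,) * 8 + (1.0,), motif_id=f"b{i}") for i in range(3)]
        z = cluster_profiles(a + b)
        labels = cut_profiles(z, 2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_duplicate_profiles_merge_at_zero_height(self):
        z = cluster_profiles([profile((0.5,) * 9)] * 3)
        assert z[0, 2] == 0.0

    def test_agreement_with_brute_force_ward(self):
        rng = np.random.default_rng(4)
        profs = [profile(tuple(np.sort(rng.random(8))) + (1.0,),
                         motif_id=f"m{i}") for i in range(6)]
        z = cluster_profiles(profs)
        x = np.array([p.rates for p in profs])
        assert np.allclose(sorted(z[:, 2]), sorted(ward_linkage_oracle(x)))

    def test_fewer_than_two_profiles_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles([profile((1.0,) * 9)])


class TestCategoryTransitions:
    def test_identical_member_sites_give_identical_curves(self, toy_index,
                                                          toy_ladder,
                                                          toy_sites):
        cat = {"p1": "a", "p2": "a", "p3": "a"}
        curves = category_transition_profiles(toy_sites, cat, toy_index,
                                              toy_ladder)
        assert curves["a"].transition == curves["all"].transition

    def test_all_category_pools_every_site(self, toy_index, toy_ladder,
                                           toy_sites):
        curves = category_transition_profiles(toy_sites, {"p1": "only"},
                                              toy_index, toy_ladder)
        assert curves["all"].profile.n_human_sites == 3

    def test_empty_category_warns_and_is_skipped(self, toy_index, toy_ladder,
                                                 toy_sites):
        with pytest.warns(UserWarning, match="ghost"):
            curves = category_transition_profiles(
                toy_sites, {"p1": "a", "zzz": "ghost"}, toy_index, toy_ladder)
        assert "ghost" not in curves

    def test_planted_category_shows_its_acquisition_jump(self, bundle):
        # proteins carrying the fish-acquired motif must out-jump the
        # all-sites control at the fly->fish transition
        index = GroupIndex(bundle.groups)
        fish_motif = next(m for m, sp in bundle.truth.acquisition.items()
                          if sp == "dre")
        fish = {p for p, _, m in bundle.truth.planted_sites if m == fish_motif}
        other = {p for p, _, m in bundle.truth.planted_sites
                 if m != fish_motif}
        cat = {p: "fish" for p in fish - other}  # exclusively fish-motif proteins
        known = bundle.sites[bundle.sites.status == "known"]
        sites = [(r.protein_id, int(r.position))
                 for r in known.itertuples(index=False)]
        curves = category_transition_profiles(sites, cat, index,
                                              bundle.ladder)
        j = bundle.ladder.index("dre") - 1  # dme->dre transition entry
        assert curves["fish"].transition[j] > curves["all"].transition[j] + 0.4
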