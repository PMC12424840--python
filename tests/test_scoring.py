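"""Association statistics: worked examples, invariants, oracle equivalence."""

import math

import pytest

import bruteforce
from pipermine.dictionary import categorize_dataset
from pipermine.ingest import FormulaRecord
from pipermine.scoring import (
    AssociationProfile,
    association_profile,
    candidate_filter,
    compound_index,
    compound_source_counts,
    species_enrichment,
    species_indication_linkages,
)
from pipermine.synthetic import GeneratorSpec, generate_gims_dataset

from conftest import make_dataset


def categories_of(ds, default_dictionary):
    return categorize_dataset(ds, default_dictionary)


class TestAssociationProfile:
    def test_hand_enumeration(self, hand_dataset, default_dictionary):
        # c1 in 4 formulas with categories {Pain},{Pain},{Pain,Sleep},{}
        cats = categories_of(hand_dataset, default_dictionary)
        p = association_profile(hand_dataset, "c1", cats)
        assert p.n_formulas == 4
        assert p.pct_by_category == {
            "Pain": 75.0, "Sleep": 25.0, "Anxiety/Mood": 0.0,
            "Movement/Seizure": 0.0,
        }
        assert p.pct_sum == 100.0
        assert not p.passes_filter

    def test_all_four_categories_saturates(self, default_dictionary):
        ds = make_dataset(
            {f"f{i}": ({"Piper nigrum"},
                       ["pain", "panic", "spasm", "insomnia"])
             for i in range(3)},
            {"Piper nigrum": {"c1"}},
        )
        p = association_profile(ds, "c1", categories_of(ds, default_dictionary))
        assert all(v == 100.0 for v in p.pct_by_category.values())
        assert p.pct_sum == 400.0 and p.passes_filter

    def test_empty_category_formulas(self, default_dictionary):
        ds = make_dataset(
            {"f1": ({"Piper nigrum"}, ["cough"])},
            {"Piper nigrum": {"c1"}},
        )
        p = association_profile(ds, "c1", categories_of(ds, default_dictionary))
        assert p.pct_sum == 0.0 and not p.passes_filter

    def test_compound_in_no_formula_is_flagged_undefined(self, default_dictionary):
        ds = make_dataset(
            {"f1": ({"Piper nigrum"}, ["pain"])},
            {"Piper nigrum": {"c1"}, "Piper longum": {"c9"}},
        )
        p = association_profile(ds, "c9", categories_of(ds, default_dictionary))
        assert p.undefined and p.n_formulas == 0 and not p.passes_filter

    def test_unknown_compound_raises(self, hand_dataset, default_dictionary):
        with pytest.raises(KeyError):
            association_profile(
                hand_dataset, "nope",
                categories_of(hand_dataset, default_dictionary),
            )


class TestCompoundIndex:
    def test_ubiquitous_compound_scores_100(self, default_dictionary):
        ds = make_dataset(
            {
                "f1": ({"Piper nigrum"}, ["pain"]),
                "f2": ({"Piper nigrum"}, ["panic"]),
                "f3": ({"Piper nigrum"}, ["spasm"]),
                "f4": ({"Piper nigrum"}, ["insomnia"]),
            },
            {"Piper nigrum": {"c1"}},
        )
        ci = compound_index(ds, "c1", categories_of(ds, default_dictionary))
        assert ci.index == 100.0

    def test_absent_compound_scores_0(self, default_dictionary):
        ds = make_dataset(
            {
                "f1": ({"Piper nigrum"}, ["pain"]),
                "f2": ({"Piper nigrum"}, ["panic"]),
                "f3": ({"Piper nigrum"}, ["spasm"]),
                "f4": ({"Piper nigrum"}, ["insomnia"]),
            },
            {"Piper nigrum": {"c1"}, "Piper longum": {"c2"}},
        )
        ci = compound_index(ds, "c2", categories_of(ds, default_dictionary))
        assert ci.index == 0.0

    def test_brute_force_example(self, default_dictionary):
        # compound in 2 of 4 Pain formulas, 1 of 2 Sleep formulas,
        # 0 of 2 Anxiety formulas, 0 of 2 Movement formulas -> 25.0
        defs = {}
        links = {}
        for i, (cat_phrase, sp) in enumerate([
            ("joint pain", "Piper a"), ("joint pain", "Piper a"),
            ("joint pain", "Piper b"), ("joint pain", "Piper b"),
            ("insomnia", "Piper a"), ("insomnia", "Piper b"),
            ("panic", "Piper c"), ("panic", "Piper c"),
            ("spasm", "Piper d"), ("spasm", "Piper d"),
        ]):
            defs[f"f{i}"] = ({sp}, [cat_phrase])
        links = {"Piper a": {"cx"}, "Piper b": set(), "Piper c": set(),
                 "Piper d": set()}
        ds = make_dataset(defs, links)
        ci = compound_index(ds, "cx", categories_of(ds, default_dictionary))
        assert ci.index == pytest.approx((50 + 50 + 0 + 0) / 4)

    def test_strict_mode_errors_on_empty_category(self, default_dictionary):
        ds = make_dataset(
            {"f1": ({"Piper nigrum"}, ["pain"])},
            {"Piper nigrum": {"c1"}},
        )
        cats = categories_of(ds, default_dictionary)
        with pytest.raises(ValueError, match="Anxiety/Mood"):
            compound_index(ds, "c1", cats, strict=True)
        ci = compound_index(ds, "c1", cats)
        assert "Sleep" in ci.excluded_categories
        assert ci.index == 100.0  # only Pain is defined


class TestCandidateFilter:
    def _profile(self, key, pcts, n=5):
        return AssociationProfile(
            key, n, dict(zip(bruteforce.CATEGORIES, pcts))
        )

    def test_strict_inequality_at_threshold(self):
        exactly = self._profile("a", (100.0, 100.0, 100.0, 0.0))
        assert exactly.pct_sum == 300.0
        assert candidate_filter([exactly]) == []

    def test_full_score_included(self):
        full = self._profile("a", (100.0,) * 4)
        assert candidate_filter([full]) == [full]

    def test_sort_order_documented(self):
        profiles = [
            self._profile("b", (90.0, 90.0, 90.0, 40.0), n=2),
            self._profile("a", (90.0, 90.0, 90.0, 40.0), n=2),
            self._profile("c", (100.0, 100.0, 100.0, 20.0), n=1),
            self._profile("d", (90.0, 90.0, 90.0, 40.0), n=9),
            self._profile("low", (10.0, 10.0, 10.0, 10.0), n=99),
        ]
        out = candidate_filter(profiles)
        assert [p.compound_key for p in out] == ["c", "d", "a", "b"]


class TestLinkages:
    def test_caption_counting_rule(self, default_dictionary):
        ds = make_dataset(
            {"f1": ({"Piper longum", "Piper nigrum"},
                    ["pain", "panic", "spasm", "insomnia"])},
            {"Piper longum": set(), "Piper nigrum": set()},
        )
        out = species_indication_linkages(
            ds, categories_of(ds, default_dictionary)
        )
        assert sum(l.linkages for l in out) == 8
        assert len(out) == 8 and all(l.linkages == 1 for l in out)

    def test_no_categories_no_linkages(self, default_dictionary):
        ds = make_dataset(
            {"f1": ({"Piper nigrum"}, [])}, {"Piper nigrum": set()}
        )
        assert species_indication_linkages(
            ds, categories_of(ds, default_dictionary)
        ) == []

    def test_genus_filter(self, default_dictionary):
        ds = make_dataset(
            {"f1": ({"Piper nigrum", "Zingiber officinale"}, ["pain"])},
            {"Piper nigrum": set(), "Zingiber officinale": set()},
        )
        cats = categories_of(ds, default_dictionary)
        assert sum(
            l.linkages
            for l in species_indication_linkages(ds, cats, genus_filter="Piper")
        ) == 1

    def test_formula_order_invariance(self, default_dictionary):
        ds, _ = generate_gims_dataset(
            GeneratorSpec(n_formulas=30, n_species=8, n_compounds=5, seed=2)
        )
        cats = categories_of(ds, default_dictionary)
        base = species_indication_linkages(ds, cats)
        ds.formulas = dict(reversed(list(ds.formulas.items())))
        assert species_indication_linkages(ds, cats) == base


class TestEnrichment:
    def test_uniform_species_ratio_1(self, default_dictionary):
        ds = make_dataset(
            {
                "f1": ({"Piper a", "Piper b"}, ["pain"]),
                "f2": ({"Piper a", "Piper b"}, ["cough"]),
            },
            {"Piper a": set(), "Piper b": set()},
        )
        assert species_enrichment(
            ds, categories_of(ds, default_dictionary), "Piper a"
        ) == pytest.approx(1.0)

    def test_category_only_species_ratio_2(self, default_dictionary):
        # half of all memberships are category-linked; the species holds
        # only category-linked memberships -> ratio exactly 2
        ds = make_dataset(
            {
                "f1": ({"Piper a", "Piper b"}, ["pain"]),
                "f2": ({"Piper c", "Piper d"}, ["cough"]),
            },
            {sp: set() for sp in ("Piper a", "Piper b", "Piper c", "Piper d")},
        )
        assert species_enrichment(
            ds, categories_of(ds, default_dictionary), "Piper a"
        ) == pytest.approx(2.0)

    def test_never_linked_species_ratio_0(self, default_dictionary):
        ds = make_dataset(
            {
                "f1": ({"Piper a"}, ["pain"]),
                "f2": ({"Piper b"}, ["cough"]),
            },
            {"Piper a": set(), "Piper b": set()},
        )
        assert species_enrichment(
            ds, categories_of(ds, default_dictionary), "Piper b"
        ) == 0.0

    def test_unknown_species_errors(self, hand_dataset, default_dictionary):
        with pytest.raises(ValueError):
            species_enrichment(
                hand_dataset,
                categories_of(hand_dataset, default_dictionary),
                "Piper missing",
            )


class TestSourceCounts:
    def test_genus_split(self, default_dictionary):
        ds = make_dataset(
            {"f1": ({"Piper nigrum"}, [])},
            {
                "Piper nigrum": {"c1"}, "Piper longum": {"c1"},
                "Zingiber officinale": {"c1"},
            },
        )
        sc = compound_source_counts(ds, "c1")
        assert (sc.n_piper_species, sc.n_non_piper_species) == (2, 1)

    def test_unknown_compound_errors(self, hand_dataset):
        with pytest.raises(KeyError):
            compound_source_counts(hand_dataset, "nope")


class TestInvariants:
    def test_percentage_bounds_and_linkage_total(self, default_dictionary):
        ds, _ = generate_gims_dataset(
            GeneratorSpec(n_formulas=60, n_species=15, n_compounds=12, seed=9)
        )
        cats = categories_of(ds, default_dictionary)
        for ck in ds.compounds:
            p = association_profile(ds, ck, cats)
            assert all(0.0 <= v <= 100.0 for v in p.pct_by_category.values())
            assert 0.0 <= p.pct_sum <= 400.0
        total = sum(
            l.linkages for l in species_indication_linkages(ds, cats)
        )
        expected = sum(
            len(f.species) * len(cats[fid])
            for fid, f in ds.formulas.items()
        )
        assert total == expected

    def test_duplicating_formulas_is_scale_equivariant(self, default_dictionary):
        ds, _ = generate_gims_dataset(
            GeneratorSpec(n_formulas=40, n_species=10, n_compounds=8, seed=4)
        )
        cats = categories_of(ds, default_dictionary)
        doubled = make_dataset({}, {})
        doubled.compounds = ds.compounds
        doubled.species_compounds = ds.species_compounds
        for sp in ds.species:
            doubled.add_species(sp)
        for fid, f in ds.formulas.items():
            for tag in ("a", "b"):
                doubled.formulas[f"{fid}{tag}"] = FormulaRecord(
                    formula_id=f"{fid}{tag}", species=set(f.species),
                    indications=list(f.indications),
                )
        dcats = categories_of(doubled, default_dictionary)
        for ck in ds.compounds:
            p1 = association_profile(ds, ck, cats)
            p2 = association_profile(doubled, ck, dcats)
            assert p2.n_formulas == 2 * p1.n_formulas
            if not p1.undefined:
                for cat in p1.pct_by_category:
                    assert p2.pct_by_category[cat] == pytest.approx(
                        p1.pct_by_category[cat]
                    )
            i1 = compound_index(ds, ck, cats)
            i2 = compound_index(doubled, ck, dcats)
            if not math.isnan(i1.index):
                assert i2.index == pytest.approx(i1.index)
        base_link = {
            (l.species, l.category): l.linkages
            for l in species_indication_linkages(ds, cats)
        }
        for l in species_indication_linkages(doubled, dcats):
            assert l.linkages == 2 * base_link[(l.species, l.category)]


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, default_dictionary, seed):
        ds, _ = generate_gims_dataset(GeneratorSpec(
            n_formulas=25 + seed, n_species=8, n_compounds=10,
            seed=1000 + seed,
        ))
        cats = categorize_dataset(ds, default_dictionary)
        fs = {fid: set(f.species) for fid, f in ds.formulas.items()}
        sc = {sp: set(cks) for sp, cks in ds.species_compounds.items()}
        genus_of = {sp: rec.genus for sp, rec in ds.species.items()}
        for ck in ds.compounds:
            n, pct = bruteforce.association_profile(fs, sc, cats, ck)
            p = association_profile(ds, ck, cats)
            assert (p.n_formulas, p.pct_by_category) == (n, pct)
            idx, _ = bruteforce.compound_index(fs, sc, cats, ck)
            ci = compound_index(ds, ck, cats)
            assert ci.index == pytest.approx(idx, abs=1e-12)
            t, o = bruteforce.source_counts(sc, genus_of, ck)
            counts = compound_source_counts(ds, ck)
            assert (counts.n_piper_species, counts.n_non_piper_species) == (t, o)
        brute_links = bruteforce.linkages(fs, cats, genus_of)
        ours = {
            (l.species, l.category): l.linkages
            for l in species_indication_linkages(ds, cats)
        }
        assert ours == brute_links
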