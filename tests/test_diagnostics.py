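"""Diagnostic-site discovery: fixation, uniqueness, scopes, exceptions."""

import random

import pytest
from hypothesis import given, strategies as st

from barcodiag.alignment import AlignedSequence, Alignment, Scope, SpeciesMap
from barcodiag.diagnostics import (
    diagnostics_all_species,
    find_diagnostic_sites,
    fixed_state,
    format_diagnosis,
)

from conftest import naive_diagnostic_sites, random_alignment


def pairs(sites):
    return [(s.position, s.state) for s in sites]


class TestFixedState:
    def build(self, *rows):
        aln = Alignment([AlignedSequence(f"m{i}", r) for i, r in enumerate(rows)])
        sm = SpeciesMap(assignment={f"m{i}": "sp" for i in range(len(rows))})
        return aln, sm

    def test_all_same_base(self):
        aln, sm = self.build("AC", "AG")
        assert fixed_state(aln, sm, "sp", 1) == "A"
        assert fixed_state(aln, sm, "sp", 2) is None

    def test_missing_blocks_fixation_by_default(self):
        aln, sm = self.build("A", "A", "N")
        assert fixed_state(aln, sm, "sp", 1) is None

    def test_ambiguity_blocks_fixation(self):
        aln, sm = self.build("A", "R")
        assert fixed_state(aln, sm, "sp", 1) is None

    def test_min_observed_permissive_mode(self):
        aln, sm = self.build("A", "A", "N")
        assert fixed_state(aln, sm, "sp", 1, min_observed=2) == "A"
        assert fixed_state(aln, sm, "sp", 1, min_observed=3) is None

    def test_bad_position_raises(self):
        aln, sm = self.build("A")
        with pytest.raises(Exception, match="position"):
            fixed_state(aln, sm, "sp", 2)


class TestFindDiagnosticSites:
    def test_planted_toy_recovered_exactly(self):
        # 3 species x 2 identical members; one reserved column per species
        # carries a species-unique base, the rest is shared background
        background = "ACGTACGTA"
        rows = {}
        planted = {"sp1": (1, "T"), "sp2": (4, "C"), "sp3": (7, "A")}
        for k, sp in enumerate(planted, start=1):
            pos, state = planted[sp]
            res = background[: pos - 1] + state + background[pos:]
            rows[f"{sp}x"] = (sp, res)
            rows[f"{sp}y"] = (sp, res)
        aln = Alignment([AlignedSequence(i, r) for i, (_, r) in rows.items()])
        sm = SpeciesMap(assignment={i: sp for i, (sp, _) in rows.items()})
        scope = Scope.full(sm)
        for sp, site in planted.items():
            assert pairs(find_diagnostic_sites(aln, sm, sp, scope)) == [site]

    def test_stricter_scope_can_only_add_sites(self):
        # spA's 'A' at column 1 is shared with spC, so it is diagnostic
        # only once spC leaves the scope
        aln = Alignment([
            AlignedSequence("a1", "AT"), AlignedSequence("a2", "AT"),
            AlignedSequence("b1", "CT"), AlignedSequence("b2", "CT"),
            AlignedSequence("c1", "AG"),
        ])
        sm = SpeciesMap(assignment={
            "a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB", "c1": "spC",
        })
        full = find_diagnostic_sites(aln, sm, "spA", Scope.full(sm))
        sub = find_diagnostic_sites(
            aln, sm, "spA", Scope.from_species("pair", ["spA", "spB"])
        )
        assert pairs(full) == []
        assert pairs(sub) == [(1, "A")]
        assert set(pairs(full)) <= set(pairs(sub))

    def test_max_exceptions_reports_ids(self):
        aln = Alignment([
            AlignedSequence("a1", "G"), AlignedSequence("a2", "G"),
            AlignedSequence("b1", "C"), AlignedSequence("b2", "C"),
            AlignedSequence("c1", "G"),
        ])
        sm = SpeciesMap(assignment={
            "a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB", "c1": "spC",
        })
        scope = Scope.full(sm)
        assert find_diagnostic_sites(aln, sm, "spA", scope) == []
        relaxed = find_diagnostic_sites(aln, sm, "spA", scope, max_exceptions=1)
        assert pairs(relaxed) == [(1, "G")]
        assert relaxed[0].exceptions == ("c1",)

    def test_outside_ambiguity_containing_state_counts_against(self):
        # R expands to {A,G}: it could be the G we require, so it blocks
        aln = Alignment([
            AlignedSequence("a1", "G"), AlignedSequence("b1", "R"),
            AlignedSequence("b2", "C"),
        ])
        sm = SpeciesMap(assignment={"a1": "spA", "b1": "spB", "b2": "spB"})
        assert find_diagnostic_sites(aln, sm, "spA", Scope.full(sm)) == []

    def test_outside_gap_and_n_are_unscored_not_compatible(self):
        aln = Alignment([
            AlignedSequence("a1", "G"), AlignedSequence("b1", "N"),
            AlignedSequence("b2", "-"), AlignedSequence("b3", "C"),
        ])
        sm = SpeciesMap(assignment={
            "a1": "spA", "b1": "spB", "b2": "spB", "b3": "spB",
        })
        sites = find_diagnostic_sites(aln, sm, "spA", Scope.full(sm))
        assert pairs(sites) == [(1, "G")]
        assert sites[0].unscored_outside == 2
        assert sites[0].exceptions == ()

    def test_scope_of_focal_species_alone_is_vacuous_with_warning(self):
        aln = Alignment([
            AlignedSequence("a1", "AC"), AlignedSequence("a2", "AG"),
            AlignedSequence("b1", "AC"),
        ])
        sm = SpeciesMap(assignment={"a1": "spA", "a2": "spA", "b1": "spB"})
        with pytest.warns(UserWarning, match="vacuous"):
            sites = find_diagnostic_sites(
                aln, sm, "spA", Scope.from_species("self", ["spA"])
            )
        assert pairs(sites) == [(1, "A")]

    def test_species_outside_scope_rejected(self):
        aln = Alignment([AlignedSequence("a1", "A"), AlignedSequence("b1", "C")])
        sm = SpeciesMap(assignment={"a1": "spA", "b1": "spB"})
        with pytest.raises(ValueError, match="not in scope"):
            find_diagnostic_sites(
                aln, sm, "spA", Scope.from_species("other", ["spB"])
            )

    @given(st.integers(0, 2**31 - 1), st.integers(0, 2))
    def test_matches_exhaustive_scan_on_random_alignments(self, seed, k):
        rng = random.Random(seed)
        aln, sm = random_alignment(
            rng, rng.randint(3, 15), rng.randint(5, 60), n_species=rng.randint(2, 4)
        )
        residues = {s.id: s.residues for s in aln}
        scope = Scope.full(sm)
        for sp in sm.species:
            got = pairs(
                find_diagnostic_sites(aln, sm, sp, scope, max_exceptions=k)
            )
            want = naive_diagnostic_sites(
                residues, sm.assignment, sp, set(sm.species), max_exceptions=k
            )
            assert got == want

    @given(st.integers(0, 2**31 - 1))
    def test_soundness_of_reported_sites(self, seed):
        """Every reported site re-checks: fixation inside the species and
        at most max_exceptions compatible outsiders, all named."""
        rng = random.Random(seed)
        aln, sm = random_alignment(rng, 10, 30, n_species=3)
        scope = Scope.full(sm)
        for sp in sm.species:
            for site in find_diagnostic_sites(aln, sm, sp, scope, max_exceptions=1):
                assert fixed_state(aln, sm, sp, site.position) == site.state
                col = aln.column(site.position)
                from conftest import AMBIG_EXPANSION
                compatible = [
                    i for i in aln.ids
                    if sm.species_of(i) != sp
                    and (
                        aln[i].residues[site.position - 1] == site.state
                        or site.state in AMBIG_EXPANSION.get(
                            aln[i].residues[site.position - 1], ""
                        )
                    )
                ]
                assert sorted(compatible) == sorted(site.exceptions)
                assert len(compatible) <= 1


class TestAllSpecies:
    def test_empty_lists_reported_not_omitted(self, toy_alignment, toy_species_map):
        result = diagnostics_all_species(
            toy_alignment, toy_species_map, Scope.full(toy_species_map)
        )
        assert set(result) == {"spA", "spB", "spC"}
        assert pairs(result["spA"]) == [(1, "A")]
        assert pairs(result["spB"]) == [(2, "G")]
        assert result["spC"] == []

    def test_formatted_diagnosis_mentions_positions_and_exceptions(
        self, toy_alignment, toy_species_map
    ):
        scope = Scope.full(toy_species_map)
        result = diagnostics_all_species(
            toy_alignment, toy_species_map, scope, max_exceptions=0
        )
        text = format_diagnosis("spA", {"all": result["spA"]})
        assert "1 (A)" in text
        text_empty = format_diagnosis("spC", {"all": result["spC"]})
        assert "no unique diagnostic" in text_empty


@given(st.integers(0, 2**31 - 1))
def test_scope_monotonicity_random(seed):
    """Diagnostics under a superset scope are a subset of diagnostics under
    any smaller scope still containing the species."""
    rng = random.Random(seed)
    aln, sm = random_alignment(rng, 12, 40, n_species=4)
    species = sm.species
    focal = rng.choice(species)
    others = [s for s in species if s != focal]
    rng.shuffle(others)
    cut = rng.randint(0, len(others))
    small = Scope.from_species("small", [focal] + others[:cut])
    big = Scope.from_species("big", [focal] + others)
    sub = find_diagnostic_sites(aln, sm, focal, small, warn_vacuous=False)
    sup = find_diagnostic_sites(aln, sm, focal, big, warn_vacuous=False)
    assert set(pairs(sup)) <= set(pairs(sub))


@given(st.integers(0, 2**31 - 1), st.integers(0, 3))
def test_exception_monotonicity_random(seed, k):
    """Sites at max_exceptions=k are a subset of sites at k+1."""
    rng = random.Random(seed)
    aln, sm = random_alignment(rng, 10, 40, n_species=3)
    scope = Scope.full(sm)
    for sp in sm.species:
        at_k = pairs(find_diagnostic_sites(aln, sm, sp, scope, max_exceptions=k))
        at_k1 = pairs(find_diagnostic_sites(aln, sm, sp, scope, max_exceptions=k + 1))
        assert set(at_k) <= set(at_k1)
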