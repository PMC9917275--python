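"""Taxonomy cascade, LCA resolution, overrides, and diet metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wrenprey.diet import (
    ARMADILLIDIIDAE_OVERRIDE,
    Candidate,
    EmptyProfileError,
    MalformedTaxonomyError,
    OtuMatch,
    RANKS,
    TaxonPath,
    assign_taxonomy,
    designate_prey,
    diet_profile,
)


def _cand(sim, order="Diptera", family="Tipulidae", genus="Tipula", species="Tipula sp1"):
    return Candidate(TaxonPath(order, family, genus, species), sim)


class TestThresholdCascade:
    @pytest.mark.parametrize(
        "similarity, expected_rank",
        [
            (99.5, "species"),
            (99.3, "species"),  # cutoffs are inclusive operating points
            (97.0, "genus"),
            (92.5, "family"),
            (86.0, "order"),
        ],
    )
    def test_single_complete_candidate(self, similarity, expected_rank):
        a = assign_taxonomy(OtuMatch("o1", (_cand(similarity),)), overrides=())
        assert a.resolved_rank == expected_rank
        assert not a.excluded
        assert a.provenance == "threshold"

    def test_below_order_cutoff_is_excluded(self):
        a = assign_taxonomy(OtuMatch("o1", (_cand(84.0),)), overrides=())
        assert a.resolved_rank == "unresolved"
        assert a.resolved_name == ""
        assert a.excluded

    def test_no_candidates_is_excluded(self):
        a = assign_taxonomy(OtuMatch("o1", ()))
        assert a.excluded

    def test_tied_same_genus_resolves_to_genus(self):
        c1 = _cand(99.4, species="Tipula sp1")
        c2 = _cand(99.4, species="Tipula sp2")
        a = assign_taxonomy(OtuMatch("o1", (c1, c2)), overrides=())
        assert a.resolved_rank == "genus"
        assert a.resolved_name == "Tipula"
        assert a.provenance == "lca"

    def test_tied_conflict_at_order_is_excluded(self):
        c1 = _cand(96.0, order="Diptera")
        c2 = _cand(96.0, order="Lepidoptera", family="Erebidae", genus="Arachnis",
                   species="Arachnis picta")
        a = assign_taxonomy(OtuMatch("o1", (c1, c2)), overrides=())
        assert a.excluded

    def test_armadillidiidae_override_assigns_species(self):
        c = Candidate(TaxonPath("Isopoda", "Armadillidiidae"), 96.0)
        a = assign_taxonomy(OtuMatch("o1", (c,)), overrides=(ARMADILLIDIIDAE_OVERRIDE,))
        assert a.resolved_rank == "species"
        assert a.resolved_name == "Armadillidium vulgare"
        assert a.provenance == "override"

    def test_incomplete_path_caps_resolution_depth(self):
        # similarity allows species but only the family is known
        c = Candidate(TaxonPath("Diptera", "Syrphidae"), 99.6)
        a = assign_taxonomy(OtuMatch("o1", (c,)), overrides=())
        assert a.resolved_rank == "family"
        assert a.resolved_name == "Syrphidae"

    def test_missing_order_raises(self):
        with pytest.raises(MalformedTaxonomyError):
            assign_taxonomy(OtuMatch("o1", (Candidate(TaxonPath(""), 99.0),)))


@st.composite
def candidate_sets(draw):
    n = draw(st.integers(1, 5))
    orders = ["Diptera", "Lepidoptera"]
    cands = []
    for _ in range(n):
        o = draw(st.sampled_from(orders))
        f = draw(st.sampled_from([f"{o[:3]}fam{i}" for i in range(2)]))
        g = draw(st.sampled_from([f"{f}gen{i}" for i in range(2)]))
        s = f"{g} sp{draw(st.integers(1, 3))}"
        sim = draw(st.floats(80.0, 100.0, allow_nan=False))
        cands.append(Candidate(TaxonPath(o, f, g, s), sim))
    return OtuMatch("otu", tuple(cands))


class TestCascadeProperties:
    @given(candidate_sets(), st.floats(0.1, 10.0))
    @settings(max_examples=200, derandomize=True)
    def test_raising_best_similarity_never_lowers_rank(self, match, delta):
        """Monotonicity: lifting the best-tied candidates' similarity can
        only deepen (or keep) the resolved rank."""
        depth = {r: i for i, r in enumerate(RANKS)}
        depth["unresolved"] = -1
        before = assign_taxonomy(match, overrides=())
        best = max(c.similarity for c in match.candidates)
        bumped = tuple(
            Candidate(c.path, min(100.0, c.similarity + delta))
            if best - c.similarity <= 1e-9
            else c
            for c in match.candidates
        )
        after = assign_taxonomy(OtuMatch(match.otu_id, bumped), overrides=())
        assert depth[after.resolved_rank] >= depth[before.resolved_rank]

    @given(candidate_sets())
    @settings(max_examples=200, derandomize=True)
    def test_resolved_path_is_ancestor_of_every_tied_candidate(self, match):
        a = assign_taxonomy(match, overrides=())
        if a.excluded:
            return
        best = max(c.similarity for c in match.candidates)
        tied = [c.path for c in match.candidates if best - c.similarity <= 1e-9]
        assert all(a.path.contains(p) for p in tied)


def _mini_profile():
    """4 positive samples; Diptera in 3, Lepidoptera in 1."""
    assignments = [
        assign_taxonomy(OtuMatch("d1", (_cand(99.5),)), overrides=()),
        assign_taxonomy(
            OtuMatch("l1", (_cand(99.5, "Lepidoptera", "Erebidae", "Arachnis",
                                  "Arachnis picta"),)),
            overrides=(),
        ),
    ]
    otu = pd.DataFrame(
        {"d1": [10, 5, 2, 0], "l1": [0, 0, 0, 7]},
        index=["s1", "s2", "s3", "s4"],
    )
    return assignments, otu


class TestDietProfile:
    def test_fo_is_share_of_positive_samples(self):
        assignments, otu = _mini_profile()
        prof = diet_profile(assignments, otu)
        assert prof.n_samples_positive == 4
        assert prof.fo("Diptera") == 75.0
        assert prof.fo("Lepidoptera") == 25.0

    def test_single_order_sample_has_rra_one(self):
        assignments, otu = _mini_profile()
        prof = diet_profile(assignments, otu.loc[["s1"]])
        assert prof.fo("Diptera") == 100.0
        assert prof.per_order.set_index("order").loc["Diptera", "rra"] == 1.0

    def test_printed_fo_example_rounds_to_one_decimal(self):
        """25 detections among 28 positive samples prints as FO 89.3%."""
        assert round(100 * 25 / 28, 1) == 89.3

    def test_fo_invariant_to_within_sample_read_rescaling(self):
        assignments, otu = _mini_profile()
        prof1 = diet_profile(assignments, otu)
        prof2 = diet_profile(assignments, otu * 50)
        pd.testing.assert_frame_equal(prof1.per_order, prof2.per_order)

    def test_no_positive_samples_raises(self):
        assignments, otu = _mini_profile()
        with pytest.raises(EmptyProfileError):
            diet_profile(assignments, otu * 0)

    def test_fo_converges_to_detection_probability(self):
        """On large synthetic diets, FO approaches the generator's per-order
        detection probability within 3 binomial SEs."""
        from wrenprey import generate_study, nominal_config
        from wrenprey.io import match_table_to_otu_matches
        from wrenprey.diet import assign_taxonomy as assign

        cfg = nominal_config(23)
        cfg.n_diet_samples = 3000
        cfg.amplification_prob = 1.0
        bundle = generate_study(cfg)
        matches = match_table_to_otu_matches(bundle.match_table)
        prof = diet_profile([assign(m) for m in matches], bundle.otu_table)
        n = prof.n_samples_positive
        for order, p in cfg.diet_detection_prob.items():
            if p in (0.0,):
                continue
            se = np.sqrt(p * (1 - p) / n)
            assert abs(prof.fo(order) / 100 - p) < 3 * se + 1e-3, order


class TestPreyDesignation:
    def test_two_samples_included_one_excluded(self):
        assignments, otu = _mini_profile()
        prof = diet_profile(assignments, otu)
        prey, excluded = designate_prey(prof)
        assert "Diptera" in prey  # 3 samples
        assert "Lepidoptera" not in prey  # exactly 1 sample
        assert "Lepidoptera" in excluded

    def test_empty_profile_yields_empty_set(self):
        from wrenprey.diet import DietProfile

        empty = DietProfile(
            per_order=pd.DataFrame(
                columns=["order", "n_samples_detected", "fo_percent", "rra",
                         "n_otus", "n_species"]
            ),
            n_samples_positive=0,
        )
        prey, excluded = designate_prey(empty)
        assert prey == set() and excluded == {}
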