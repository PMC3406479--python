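import pytest

from wikifieldnotes.errors import ConfigurationError
from wikifieldnotes.referencing import (
    ReconcileConfig,
    attach_taxonomy,
    load_authority,
    match_name,
    normalize_name,
    reconcile,
)


def levenshtein(a: str, b: str) -> int:
    """Independent DP oracle for the edit distance used in fuzzy scoring."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestNormalizeName:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("Say [sic] Phoebe", "say phoebe"),
            ("Sayornis saya", "sayornis saya"),
            ("[American] Robins", "american robin"),
            ("siskins", "siskin"),
            ("Carduelis pinus", "carduelis pinus"),   # -us retained
            ("Oreohelix strigosa", "oreohelix strigosa"),
            ("  Mule   Deer ", "mule deer"),
        ],
    )
    def test_normalization(self, text, expected):
        assert normalize_name(text) == expected

    def test_empty_after_normalization_errors(self):
        with pytest.raises(ValueError):
            normalize_name("[sic]")


class TestMatchName:
    def test_exact_scientific_scores_one(self, authorities):
        eol, _ = authorities
        ranked = match_name(eol, "sayornis saya")
        assert ranked[0].score == 1.0
        assert ranked[0].match_type == "exact_scientific"
        assert ranked[0].record.name == "Sayornis saya"

    def test_exact_vernacular_scores_point_nine(self, authorities):
        _, itis = authorities
        ranked = match_name(itis, "american robin")
        assert ranked[0].score == 0.9
        assert ranked[0].match_type == "exact_vernacular"
        assert ranked[0].record.name == "Turdus migratorius"

    def test_ambiguous_vernacular_surfaces_all_candidates(self, authorities):
        """"siskin" is shared by 18 species in the EOL-like snapshot."""
        eol, _ = authorities
        ranked = match_name(eol, "siskin")
        assert len(ranked) == 18
        assert len({c.score for c in ranked}) == 1  # all tied

    def test_fuzzy_score_matches_oracle(self, authorities):
        eol, _ = authorities
        query = "sayornis sayaa"
        ranked = match_name(eol, query, fuzzy_threshold=2)
        assert ranked[0].match_type == "fuzzy_scientific"
        name = normalize_name(ranked[0].record.name)
        dist = levenshtein(query, name)
        assert dist == 1
        assert ranked[0].score == pytest.approx(1 - dist / max(len(query), len(name)))

    def test_fuzzy_outside_threshold_is_no_match(self, authorities):
        eol, _ = authorities
        assert match_name(eol, "zzyzzx qqqq", fuzzy_threshold=2) == []

    def test_fuzzy_vernacular_opt_in(self, authorities):
        _, itis = authorities
        assert match_name(itis, "marmut") == []  # off by default
        ranked = match_name(itis, "marmut", fuzzy_vernacular_threshold=1)
        assert ranked and ranked[0].record.name == "Marmota flaviventris"

    def test_score_symmetry_via_oracle(self, authorities):
        # score is 1 iff strings are equal after normalization; the distance
        # term is symmetric, checked against the DP oracle both ways
        for a, b in [("sayornis saya", "sayornis sayaa"),
                     ("mule deer", "mule dee")]:
            assert levenshtein(a, b) == levenshtein(b, a)
        eol, _ = authorities
        assert match_name(eol, "sayornis saya")[0].score == 1.0


class TestReconcile:
    def test_consistent_in_both(self, authorities):
        res = reconcile("Sayornis saya", *authorities)
        assert res.consensus == "consistent"
        assert res.accepted_name == "Sayornis saya"
        assert res.resolution_method == "EOL & ITIS"
        assert not res.review_needed

    def test_only_one_authority(self, authorities):
        res = reconcile("Selasphorus platycercus", *authorities)  # EOL-only
        assert res.consensus == "authority_a_preferred"
        assert res.resolution_method == "EOL"
        res = reconcile("Cervus canadensis", *authorities)  # ITIS-only
        assert res.consensus == "authority_b_preferred"
        assert res.resolution_method == "ITIS"

    def test_neither_authority(self, authorities):
        res = reconcile("xyzzy", *authorities)
        assert res.consensus == "unresolved"
        assert res.accepted_name is None

    def test_vernacular_disagreement_flagged_not_accepted(self, authorities):
        """One snapshot maps "mouse" to the mouse moth, the other to the
        house mouse: surfaced for review, never silently accepted."""
        res = reconcile("mouse", *authorities)
        assert res.consensus == "unresolved"
        assert res.review_needed
        names = {res.per_authority_best["EOL"].record.name,
                 res.per_authority_best["ITIS"].record.name}
        assert names == {"Amphipyra tragopoginis", "Mus musculus"}

    def test_cross_kingdom_homonym_never_merged(self, authorities):
        res = reconcile("Crucibulum", *authorities)
        assert res.consensus == "unresolved"
        assert res.review_needed
        kingdoms = {c.record.higher_taxonomy["kingdom"]
                    for c in res.per_authority_best.values()}
        assert kingdoms == {"Fungi", "Animalia"}

    def test_decisions_file_resolves_disagreement(self, authorities):
        config = ReconcileConfig(decisions={"mouse": "B"})
        res = reconcile("mouse", *authorities, config)
        assert res.consensus == "authority_b_preferred"
        assert res.accepted_name == "Mus musculus"
        config = ReconcileConfig(decisions={"mouse": "neither"})
        assert reconcile("mouse", *authorities, config).consensus == "unresolved"

    def test_reconcile_is_pure(self, authorities):
        a = reconcile("Say [sic] Phoebe", *authorities)
        b = reconcile("Say [sic] Phoebe", *authorities)
        assert (a.consensus, a.accepted_name, a.resolution_method) == \
               (b.consensus, b.accepted_name, b.resolution_method)

    def test_partition_into_four_classes(self, authorities):
        queries = {
            "Sayornis saya": "consistent",
            "Turdus migratorius": "consistent",
            "Selasphorus platycercus": "authority_a_preferred",
            "Aquilegia coerulea": "authority_a_preferred",
            "Mus musculus": "authority_b_preferred",
            "Branta canadensis": "authority_b_preferred",
            "Fictusaurus nullius": "unresolved",
        }
        for query, expected in queries.items():
            assert reconcile(query, *authorities).consensus == expected


class TestAttachTaxonomy:
    def test_consistent_uses_identifier_bearing_authority(self, authorities):
        res = attach_taxonomy(reconcile("Sayornis saya", *authorities),
                              *authorities)
        assert res.higher_taxonomy["class"] == "Aves"
        assert res.higher_taxonomy["family"] == "Tyrannidae"
        assert res.vernacular_name == "Say's Phoebe"
        # taxonomy drawn from the TSN-bearing snapshot
        assert res.per_authority_best["ITIS"].record.identifier == "178344"

    def test_unresolved_passes_through(self, authorities):
        res = attach_taxonomy(reconcile("xyzzy", *authorities), *authorities)
        assert res.higher_taxonomy == {}

    def test_genus_rank_populates_to_genus(self, authorities):
        res = attach_taxonomy(reconcile("Populus", *authorities), *authorities)
        assert res.higher_taxonomy["genus"] == "Populus"
        assert res.higher_taxonomy["kingdom"] == "Plantae"


def test_missing_snapshot_is_fatal(tmp_path):
    with pytest.raises(ConfigurationError):
        load_authority(tmp_path / "nope.tsv")
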