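"""PTM-to-PrLD mapping and composition-controlled enrichment statistics."""

import math

import numpy as np
import pytest

import helpers
from prionscan import (
    ContingencyCounts,
    PrLD,
    ProteinRecord,
    PTMSite,
    analyze_ptm_enrichment,
    bh_adjust,
    build_contingency,
    enrichment,
    load_ptm_residue_map,
    map_ptms_to_prlds,
)
from prionscan.ptm import PTMEnrichmentResult


def _domain(acc, start, end, seq="Q"):
    return PrLD(
        accession=acc, start=start, end=end, peak_score=0.1,
        domain_sequence=seq * (end - start + 1),
    )


class TestResidueMap:
    def test_packaged_types_and_targets(self):
        mapping = load_ptm_residue_map()
        assert mapping["serine-phosphorylation"] == frozenset("S")
        assert mapping["arginine-methylation"] == frozenset("R")
        assert mapping["lysine-ubiquitination"] == frozenset("K")
        assert len(mapping) == 8


class TestMapPtmsToPrlds:
    @pytest.fixture
    def setting(self):
        protein = ProteinRecord("P1", "S" * 100)
        prlds = {"P1": [_domain("P1", 40, 60, "S")]}
        return protein, prlds

    @pytest.mark.parametrize(
        "position,inside",
        [(40, True), (60, True), (39, False), (61, False), (50, True)],
    )
    def test_inclusive_interval_membership(self, setting, position, inside):
        protein, prlds = setting
        sites = [PTMSite("P1", position, "S", "serine-phosphorylation")]
        annotated, per_prld = map_ptms_to_prlds(sites, prlds, {"P1": protein})
        assert annotated[0][1] is inside
        key = ("P1", 40, 60, "serine-phosphorylation")
        assert per_prld.get(key, 0) == (1 if inside else 0)

    def test_site_beyond_length_rejected_with_log(self, setting, caplog):
        protein, prlds = setting
        sites = [PTMSite("P1", 500, "S", "serine-phosphorylation")]
        annotated, _ = map_ptms_to_prlds(sites, prlds, {"P1": protein})
        assert annotated == []
        assert "beyond protein length" in caplog.text

    def test_counts_match_brute_recount(self, table, small_proteome):
        from prionscan import find_prlds
        from prionscan.fixtures import generate_ptm_table

        records, _, _ = small_proteome
        prlds = {r.accession: find_prlds(r, table, threshold=0.0) for r in records}
        intervals = {
            acc: [(d.start, d.end) for d in ds] for acc, ds in prlds.items()
        }
        from prionscan.fixtures import FixtureSpec

        spec = FixtureSpec(
            seed=7, n_proteins=20,
            ptm_plan={"serine-phosphorylation": (150, 2.0)},
        )
        sites, _ = generate_ptm_table(spec, records, intervals)
        annotated, per_prld = map_ptms_to_prlds(sites, prlds, {
            r.accession: r for r in records
        })
        # brute recount by direct interval membership
        for (acc, start, end, ptm_type), count in per_prld.items():
            recount = sum(
                1 for s in sites
                if s.accession == acc and s.ptm_type == ptm_type
                and start <= s.position <= end
            )
            assert count == recount
        n_inside = sum(1 for _, inside in annotated if inside)
        brute_inside = sum(
            1 for s in sites
            if any(a <= s.position <= b for a, b in intervals[s.accession])
        )
        assert n_inside == brute_inside


class TestBuildContingency:
    def test_planted_counts_recovered_exactly(self):
        # 100 serines inside the domain, 1000 outside; 10 and 50 modified
        protein = ProteinRecord("P1", "S" * 1100)
        prlds = {"P1": [_domain("P1", 1, 100, "S")]}
        sites = [
            PTMSite("P1", i, "S", "serine-phosphorylation")
            for i in list(range(1, 11)) + list(range(101, 151))
        ]
        counts = build_contingency(
            sites, {"P1": protein}, prlds, "serine-phosphorylation"
        )
        assert (counts.mod_in_prld, counts.unmod_in_prld) == (10, 90)
        assert (counts.mod_outside, counts.unmod_outside) == (50, 950)

    def test_doubling_proteome_doubles_counts(self):
        protein = ProteinRecord("P1", "S" * 200)
        clone = ProteinRecord("P2", "S" * 200)
        prlds = {
            "P1": [_domain("P1", 1, 50, "S")],
            "P2": [_domain("P2", 1, 50, "S")],
        }
        sites1 = [PTMSite("P1", i, "S", "serine-phosphorylation") for i in (5, 80)]
        sites2 = sites1 + [
            PTMSite("P2", i, "S", "serine-phosphorylation") for i in (5, 80)
        ]
        c1 = build_contingency(
            sites1, {"P1": protein}, {"P1": prlds["P1"]}, "serine-phosphorylation"
        )
        c2 = build_contingency(
            sites2, {"P1": protein, "P2": clone}, prlds, "serine-phosphorylation"
        )
        for attr in ("mod_in_prld", "unmod_in_prld", "mod_outside", "unmod_outside"):
            assert getattr(c2, attr) == 2 * getattr(c1, attr)

    def test_no_target_residues_gives_zero_table(self):
        protein = ProteinRecord("P1", "Q" * 100)
        counts = build_contingency(
            [], {"P1": protein}, {"P1": []}, "arginine-methylation"
        )
        assert counts.modifiable_in_prld == counts.modifiable_outside == 0
        result = enrichment(counts)
        assert result.undefined
        assert math.isnan(result.odds_ratio)

    def test_conservation_of_site_totals(self, table, small_proteome):
        from prionscan import find_prlds
        from prionscan.fixtures import FixtureSpec, generate_ptm_table

        records, _, _ = small_proteome
        prlds = {r.accession: find_prlds(r, table, threshold=0.0) for r in records}
        intervals = {a: [(d.start, d.end) for d in ds] for a, ds in prlds.items()}
        spec = FixtureSpec(
            seed=7, n_proteins=20,
            ptm_plan={"arginine-methylation": (120, 1.5)},
        )
        sites, _ = generate_ptm_table(spec, records, intervals)
        counts = build_contingency(
            sites, {r.accession: r for r in records}, prlds, "arginine-methylation"
        )
        assert counts.n_sites_proteome == len(sites)
        direct_r = sum(r.sequence.count("R") for r in records)
        assert counts.modifiable_in_prld + counts.modifiable_outside == direct_r


class TestEnrichment:
    def test_worked_example_arithmetic(self):
        counts = ContingencyCounts("t", 10, 90, 50, 950)
        result = enrichment(counts)
        assert result.odds_ratio == pytest.approx(2.111, abs=1e-3)
        assert result.log_enrichment == pytest.approx(0.747, abs=1e-3)
        assert result.f_mod_prld == pytest.approx(0.10)
        assert result.f_mod_nonprld == pytest.approx(0.05)
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 50 + 1 / 950)
        assert result.log_enrichment_se == pytest.approx(se, abs=1e-12)

    def test_equal_fractions_give_zero_enrichment(self):
        result = enrichment(ContingencyCounts("t", 20, 180, 100, 900))
        assert result.odds_ratio == pytest.approx(1.0)
        assert result.log_enrichment == pytest.approx(0.0, abs=1e-12)

    def test_row_swap_negates_enrichment_keeps_p(self):
        a = enrichment(ContingencyCounts("t", 10, 90, 50, 950))
        b = enrichment(ContingencyCounts("t", 50, 950, 10, 90))
        assert b.log_enrichment == pytest.approx(-a.log_enrichment, abs=1e-12)
        assert b.fisher_p == pytest.approx(a.fisher_p, rel=1e-9)

    def test_sign_consistency(self):
        for cells in [(10, 90, 50, 950), (50, 950, 10, 90), (5, 5, 5, 5)]:
            r = enrichment(ContingencyCounts("t", *cells))
            assert np.sign(r.log_enrichment) == np.sign(r.odds_ratio - 1)

    def test_zero_cell_flagged_and_continuity_option(self):
        counts = ContingencyCounts("t", 0, 100, 50, 950)
        plain = enrichment(counts)
        assert plain.undefined and math.isnan(plain.odds_ratio)
        assert math.isfinite(plain.fisher_p)
        corrected = enrichment(counts, continuity_correction=True)
        assert corrected.undefined  # still flagged as a zero-cell table
        assert math.isfinite(corrected.odds_ratio)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_fisher_p_matches_hypergeometric_tail_sum(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            a, b, c, d = (int(rng.integers(0, 26)) for _ in range(4))
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            result = enrichment(ContingencyCounts("t", a, b, c, d))
            oracle = helpers.fisher_two_sided_p(a, b, c, d)
            assert result.fisher_p == pytest.approx(oracle, rel=1e-8, abs=1e-12)


def _result(ptm_type, p, excluded=False):
    from dataclasses import replace

    base = enrichment(ContingencyCounts(ptm_type, 10, 90, 50, 950))
    return replace(
        base, ptm_type=ptm_type, fisher_p=p, excluded_lowcount=excluded
    )


class TestBHAdjust:
    def test_single_test_q_equals_p(self):
        out = bh_adjust([_result("a", 0.013)])
        assert out[0].bh_q == pytest.approx(0.013)

    def test_all_equal_p(self):
        out = bh_adjust([_result(t, 0.02) for t in "abcd"])
        assert all(r.bh_q == pytest.approx(0.02) for r in out)

    def test_mixed_vector_matches_step_up_oracle(self):
        pvals = [0.001, 0.008, 0.039, 0.041, 0.27, 0.6, 1.0]
        out = bh_adjust([_result(f"t{i}", p) for i, p in enumerate(pvals)])
        oracle = helpers.bh_step_up(pvals)
        for r, q in zip(out, oracle):
            assert r.bh_q == pytest.approx(q, abs=1e-12)

    def test_excluded_types_do_not_participate(self):
        results = [
            _result("a", 0.01),
            _result("b", 0.0001, excluded=True),
            _result("c", 0.04),
        ]
        out = bh_adjust(results)
        assert math.isnan(out[1].bh_q) and not out[1].significant
        oracle = helpers.bh_step_up([0.01, 0.04])
        assert out[0].bh_q == pytest.approx(oracle[0])
        assert out[2].bh_q == pytest.approx(oracle[1])

    def test_empty_input(self):
        assert bh_adjust([]) == []


class TestPipeline:
    def test_low_count_type_flagged(self, table):
        protein = ProteinRecord("P1", "S" * 500)
        prlds = {"P1": [_domain("P1", 1, 100, "S")]}
        sites = [PTMSite("P1", i, "S", "serine-phosphorylation") for i in range(1, 60)]
        results = analyze_ptm_enrichment(sites, {"P1": protein}, prlds)
        assert len(results) == 1
        assert results[0].excluded_lowcount
        assert math.isnan(results[0].bh_q)

    def test_planted_odds_ratio_recovered_single_replicate(self, table):
        from prionscan import find_prlds
        from prionscan.fixtures import FixtureSpec, generate_proteome, generate_ptm_table

        spec = FixtureSpec(seed=11, n_proteins=60)
        records, _, _ = generate_proteome(spec)
        prlds = {r.accession: find_prlds(r, table, threshold=0.0) for r in records}
        intervals = {a: [(d.start, d.end) for d in ds] for a, ds in prlds.items()}
        sites, realized = generate_ptm_table(spec, records, intervals)
        results = analyze_ptm_enrichment(
            sites, {r.accession: r for r in records}, prlds
        )
        by_type = {r.ptm_type: r for r in results}
        planted = by_type["arginine-methylation"]
        assert abs(planted.log_enrichment - math.log(3)) <= 2 * planted.log_enrichment_se
        assert planted.significant
        for name, r in by_type.items():
            assert r.odds_ratio == pytest.approx(realized[name], rel=1e-9)
            if name != "arginine-methylation":
                assert not r.significant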