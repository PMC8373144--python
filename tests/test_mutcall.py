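"""Rare-variant caller: pileup vs a string-comparison oracle, the
two-mutant-read filter, coverage formulas, and the colony-normalized Fisher
test against exhaustive hypergeometric enumeration."""

import math

import numpy as np
import pytest

from breakscan import mapcov, mutcall, simdata
from breakscan.mutcall import (
    LibraryStats,
    SiteVariantCounts,
    compute_library_stats,
    filter_min_mutant_reads,
    fisher_many,
    fisher_offtarget,
    pileup_variants,
)
from breakscan.sitefinder import OffTargetSite


def _site(chrom="chrI", start=80, end=100):
    return OffTargetSite(chrom, start, end, "+", "N" * (end - start), "NGG", 0, ())


def _aln(rid, start, seq):
    return mapcov.AlignmentRecord(rid, "chrI", start, (("=", len(seq)),), "+", True, seq)


@pytest.fixture(scope="module")
def toy_ref():
    rng = np.random.default_rng(77)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
    # embed a (CTG)8 run covering the site region
    seq = seq[:76] + "CTG" * 8 + seq[100:]
    return simdata.ReferenceGenome({"chrI": seq})


class TestPileup:
    def test_error_free_reads_no_mutants(self, toy_ref):
        ref = toy_ref["chrI"]
        reads = [_aln(f"r{i}", 10 * i, ref[10 * i : 10 * i + 150]) for i in range(10)]
        (svc,) = pileup_variants(reads, toy_ref, [_site()])
        assert svc.n_mutant_reads == 0
        assert svc.total_covering_reads == sum(
            1 for i in range(10) if 10 * i < 100 and 10 * i + 150 > 80
        )

    def test_point_substitution_counted_and_classified(self, toy_ref):
        ref = toy_ref["chrI"]
        seq = ref[20:170]
        mutated = seq[:70] + ("A" if seq[70] != "A" else "C") + seq[71:]  # genome pos 90
        (svc,) = pileup_variants([_aln("m", 20, mutated)], toy_ref, [_site()])
        assert svc.n_mutant_reads == 1
        assert svc.class_tally == {"point": 1}
        (pos,) = [p for p in svc.positions if p.alt_counts]
        assert pos.pos == 90

    def test_triplet_deletion_in_repeat_classified(self, toy_ref):
        ref = toy_ref["chrI"]
        # remove one CTG unit from the run at 76..100
        seq = ref[20:88] + ref[91:173]
        (svc,) = pileup_variants([_aln("d", 20, seq)], toy_ref, [_site()])
        assert svc.n_mutant_reads == 1
        assert svc.class_tally == {"deletion_triplet_multiple": 1}

    def test_non_triplet_deletion_is_other_indel(self, toy_ref):
        ref = toy_ref["chrI"]
        seq = ref[20:88] + ref[90:172]  # 2-nt deletion
        (svc,) = pileup_variants([_aln("d", 20, seq)], toy_ref, [_site()])
        assert svc.class_tally == {"other_indel": 1}

    def test_one_nt_insertion_classified(self, toy_ref):
        ref = toy_ref["chrI"]
        seq = ref[20:90] + "G" + ref[90:169]
        (svc,) = pileup_variants([_aln("i", 20, seq)], toy_ref, [_site()])
        assert svc.class_tally == {"insertion_1nt": 1}

    def test_read_with_two_substitutions_counted_once(self, toy_ref):
        ref = toy_ref["chrI"]
        seq = list(ref[20:170])
        for off in (62, 70):  # genome pos 82 and 90, both inside the site
            seq[off] = "A" if seq[off] != "A" else "C"
        (svc,) = pileup_variants([_aln("m", 20, "".join(seq))], toy_ref, [_site()])
        assert svc.n_mutant_reads == 1

    def test_per_position_counts_match_string_comparison_oracle(self, toy_ref):
        ref = toy_ref["chrI"]
        rng = np.random.default_rng(123)
        reads = []
        truth_subs = {}  # genome pos -> count
        for i in range(20):
            start = int(rng.integers(0, 200))
            seq = list(ref[start : start + 150])
            if i % 3 == 0:
                off = int(rng.integers(30, 120))
                old = seq[off]
                seq[off] = "ACGT"[("ACGT".index(old) + 1) % 4]
                pos = start + off
                if 80 <= pos < 100:
                    truth_subs[pos] = truth_subs.get(pos, 0) + 1
            reads.append(_aln(f"r{i}", start, "".join(seq)))
        (svc,) = pileup_variants(reads, toy_ref, [_site()])
        got = {
            p.pos: sum(p.alt_counts.values()) for p in svc.positions if p.alt_counts
        }
        assert got == truth_subs
        # per-position covering depth equals brute-force interval stabbing
        for p in svc.positions:
            brute = sum(1 for r in reads if r.start <= p.pos < r.start + 150)
            assert p.total_covering == brute

    def test_site_outside_genome_rejected(self, toy_ref):
        with pytest.raises(ValueError):
            pileup_variants([], toy_ref, [_site(start=390, end=410)])

    def test_tagged_read_leak_warns(self, toy_ref):
        import pandas as pd

        ref = toy_ref["chrI"]
        truth = pd.DataFrame(
            {"read_id": ["t0"], "tagged": [True]}
        )
        with pytest.warns(UserWarning, match="tagged"):
            pileup_variants([_aln("t0", 20, ref[20:170])], toy_ref, [_site()], truth=truth)


class TestFilter:
    def test_threshold_behaviour(self):
        sites = [
            SiteVariantCounts("a", "chrI", 0, 20, n_mutant_reads=0),
            SiteVariantCounts("b", "chrI", 0, 20, n_mutant_reads=1),
            SiteVariantCounts("c", "chrI", 0, 20, n_mutant_reads=2),
            SiteVariantCounts("d", "chrI", 0, 20, n_mutant_reads=9),
        ]
        kept, discarded = filter_min_mutant_reads(sites)
        assert [s.site_id for s in kept] == ["c", "d"]
        assert discarded == 2

    def test_empty_input(self):
        assert filter_min_mutant_reads([]) == ([], 0)


class TestLibraryStats:
    def test_printed_formula_example(self):
        s = compute_library_stats(1_000_000, 150, 12_500_000, 1000)
        assert s.genome_coverage == pytest.approx(12.0)
        assert s.mean_coverage_per_cfu == pytest.approx(0.012)

    def test_definitional_identities(self):
        s = compute_library_stats(12_500_000 // 150 * 1, 150, 12_500_000, 1)
        assert s.genome_coverage == pytest.approx(1.0, rel=1e-4)
        s2 = compute_library_stats(1_000_000, 150, 12_500_000, 12)
        assert s2.mean_coverage_per_cfu == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            compute_library_stats(0, 150, 1000, 1)


def _fisher_oracle(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(
        prob(k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(k) <= p_obs * (1 + 1e-9)
    )


def _svc(site_id, mutant, covering):
    return SiteVariantCounts(site_id, "chrI", 0, 20, n_mutant_reads=mutant,
                             total_covering_reads=covering)


EQUAL_STATS = LibraryStats("x", 1_000_000, 1000)


class TestFisher:
    def test_matches_enumeration_on_fixed_and_random_tables(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(2024)
        tables = [
            [[5, 995], [0, 1000]],
            [[2, 48], [0, 50]],
            [[0, 10], [0, 10]],
            [[10, 0], [0, 10]],
            [[3, 3], [3, 3]],
        ]
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 26, 4))
            if (a + b) and (c + d):
                tables.append([[a, b], [c, d]])
        for t in tables:
            _, p = fisher_exact(t, alternative="two-sided")
            assert p == pytest.approx(_fisher_oracle(t), rel=1e-6, abs=1e-12)

    def test_identity_normalization_keeps_raw_counts(self):
        r = fisher_offtarget(_svc("s", 5, 100), _svc("s", 1, 110), EQUAL_STATS, EQUAL_STATS)
        assert r.normalization_factor == 1.0
        assert (r.norm_lib_mutant, r.norm_lib_covering) == (5, 100)

    def test_identical_tables_not_significant(self):
        r = fisher_offtarget(_svc("s", 3, 100), _svc("s", 3, 100), EQUAL_STATS, EQUAL_STATS)
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant

    def test_normalization_scales_both_margins_with_rounding(self):
        lib = LibraryStats("lib", 1_000_000, 1000)   # mcpc 0.012
        ctrl = LibraryStats("ctrl", 1_000_000, 800)  # mcpc 0.015
        r = fisher_offtarget(_svc("s", 3, 100), _svc("s", 0, 120), lib, ctrl)
        assert r.normalization_factor == pytest.approx(1.25)
        assert (r.norm_lib_mutant, r.norm_lib_covering) == (4, 125)  # 3.75 -> 4

    def test_zero_library_coverage_untestable(self):
        r = fisher_offtarget(_svc("s", 0, 0), _svc("s", 0, 100), EQUAL_STATS, EQUAL_STATS)
        assert not r.testable and r.p_value is None

    def test_bh_adjustment_reported_significance_on_raw_p(self):
        pairs = [
            (_svc("hot", 10, 100), _svc("hot", 0, 100)),
            (_svc("cold", 1, 100), _svc("cold", 1, 100)),
        ]
        results = fisher_many(pairs, EQUAL_STATS, EQUAL_STATS)
        by_id = {r.site_id: r for r in results}
        assert by_id["hot"].significant
        assert not by_id["cold"].significant
        assert all(r.bh_adjusted_p >= r.p_value - 1e-12 for r in results)

    def test_type_i_error_at_most_alpha_under_shared_null(self):
        """Library and control drawn from one error-only model: the raw
        Fisher false-positive rate over 1000 sites stays at or below the
        0.05 significance level (plus 3 binomial SE)."""
        n_sites = 1000
        lib_tbl = simdata.simulate_error_only_site_counts(n_sites, 100, 0.004, seed=100)
        ctrl_tbl = simdata.simulate_error_only_site_counts(n_sites, 100, 0.004, seed=200)
        lib = LibraryStats("lib", 1_000_000, 1000)
        ctrl = LibraryStats("ctrl", 900_000, 800)
        pairs = [
            (_svc(f"s{i}", int(lib_tbl.mutant[i]), int(lib_tbl.covering[i])),
             _svc(f"s{i}", int(ctrl_tbl.mutant[i]), int(ctrl_tbl.covering[i])))
            for i in range(n_sites)
        ]
        results = fisher_many(pairs, lib, ctrl)
        rate = sum(r.significant for r in results) / n_sites
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_sites)

    def test_power_spiked_sites_recovered(self):
        """Sites spiked with >= 5 mutant reads (6 planted here) against a
        clean control at ~100x depth are significant in >= 95% of runs."""
        rng = np.random.default_rng(7)
        hits = 0
        n_runs = 60
        for _ in range(n_runs):
            cov_lib = max(1, int(rng.poisson(100)))
            cov_ctrl = max(1, int(rng.poisson(100)))
            r = fisher_offtarget(
                _svc("s", 6, cov_lib), _svc("s", 0, cov_ctrl), EQUAL_STATS, EQUAL_STATS
            )
            hits += r.significant
        assert hits / n_runs >= 0.95
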