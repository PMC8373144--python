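"""Off-target scanner vs an exhaustive Hamming oracle; microsatellite
scanner vs a character-by-character run finder; repeat-class tallies."""

import numpy as np
import pytest

from breakscan import sitefinder, simdata
from breakscan.sitefinder import GuideSpec, IUPAC, canonical_motif_key
from breakscan.simdata import ReferenceGenome, revcomp


def _random_genome(seed, length):
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    return ReferenceGenome({"chrI": seq})


def _oracle_scan(genome, guide):
    """Exhaustive sliding-window Hamming scan at every offset and strand."""
    hits = set()
    P, M = len(guide.protospacer), len(guide.pam_pattern)
    for chrom, seq in genome.chromosomes.items():
        for strand in "+-":
            work = seq if strand == "+" else revcomp(seq)
            for i in range(len(work) - P + 1):
                pam_start = i + P if guide.pam_side == "three_prime" else i - M
                if pam_start < 0 or pam_start + M > len(work):
                    continue
                pam = work[pam_start : pam_start + M]
                if not all(b in IUPAC[s] for b, s in zip(pam, guide.pam_pattern)):
                    continue
                mm = sum(a != b for a, b in zip(work[i : i + P], guide.protospacer))
                if mm <= guide.max_mismatches:
                    if strand == "+":
                        hits.add((chrom, i, i + P, strand, mm))
                    else:
                        N = len(work)
                        hits.add((chrom, N - i - P, N - i, strand, mm))
    return hits


class TestScanOfftargets:
    def test_exact_planted_site_found_with_zero_mismatches(self):
        proto = "CTGACGTAGCTAGCTAACGT"
        genome = ReferenceGenome({"chrI": "A" * 50 + proto + "TGG" + "A" * 50})
        guide = GuideSpec(proto, "NGG", "three_prime", 4)
        sites = sitefinder.scan_offtargets(genome, guide)
        exact = [s for s in sites if s.n_mismatches == 0 and s.strand == "+"]
        assert len(exact) == 1
        assert (exact[0].start, exact[0].end) == (50, 70)
        assert exact[0].pam == "TGG"

    def test_planted_two_mismatch_site_found(self):
        proto = "CTGACGTAGCTAGCTAACGT"
        variant = "CAGACGTAGCTAGCTAACCT"  # positions 2 and 19 changed
        genome = ReferenceGenome(
            {"chrI": "T" * 40 + variant + "AGG" + "T" * 40}
        )
        guide = GuideSpec(proto, "NGG", "three_prime", 4)
        hits = [s for s in sitefinder.scan_offtargets(genome, guide)
                if s.strand == "+" and s.start == 40]
        assert len(hits) == 1
        assert hits[0].n_mismatches == 2
        assert hits[0].mismatch_positions == (2, 19)

    def test_wrong_pam_excludes_perfect_protospacer(self):
        proto = "CTGACGTAGCTAGCTAACGT"
        genome = ReferenceGenome({"chrI": "A" * 50 + proto + "TTT" + "A" * 50})
        guide = GuideSpec(proto, "NGG", "three_prime", 4)
        assert all(
            not (s.strand == "+" and s.start == 50)
            for s in sitefinder.scan_offtargets(genome, guide)
        )

    @pytest.mark.parametrize("pam_side", ["three_prime", "five_prime"])
    def test_matches_exhaustive_oracle(self, pam_side):
        genome = _random_genome(41, 3000)
        guide = GuideSpec("CTGCTGCTGCTGCTGCTGCT", "NGG" if pam_side == "three_prime" else "TTN",
                          pam_side, 6 if pam_side == "five_prime" else 4)
        got = {
            (s.chrom, s.start, s.end, s.strand, s.n_mismatches)
            for s in sitefinder.scan_offtargets(genome, guide)
        }
        assert got == _oracle_scan(genome, guide)

    def test_strand_involution(self):
        """Scanning the reverse-complemented genome mirrors every site."""
        genome = _random_genome(43, 2000)
        flipped = ReferenceGenome({"chrI": revcomp(genome["chrI"])})
        guide = GuideSpec("ACGTACGTACGTACGTACGT", "NGG", "three_prime", 5)
        N = len(genome["chrI"])
        a = {
            (s.start, s.end, s.strand, s.n_mismatches)
            for s in sitefinder.scan_offtargets(genome, guide)
        }
        b = {
            (N - s.end, N - s.start, "-" if s.strand == "+" else "+", s.n_mismatches)
            for s in sitefinder.scan_offtargets(flipped, guide)
        }
        assert a == b

    def test_mismatch_budget_monotonicity(self):
        genome = _random_genome(47, 2000)
        proto = "ACGTACGTACGTACGTACGT"
        keys = []
        for mm in (2, 3, 4):
            sites = sitefinder.scan_offtargets(genome, GuideSpec(proto, "NGG", "three_prime", mm))
            keys.append({(s.chrom, s.start, s.strand) for s in sites})
        assert keys[0] <= keys[1] <= keys[2]

    def test_sorted_by_mismatches_then_coordinate(self):
        genome = _random_genome(53, 4000)
        sites = sitefinder.scan_offtargets(
            genome, GuideSpec("ACGTACGTACGTACGTACGT", "NNG", "three_prime", 6)
        )
        ranks = [(s.n_mismatches, s.chrom, s.start, s.strand) for s in sites]
        assert ranks == sorted(ranks)


def _oracle_msat(seq, motif, min_units):
    """Character-comparison run finder for perfect repeats of a motif class."""
    p = len(motif)
    units = set()
    for m in (motif, revcomp(motif)):
        units.update(m[i:] + m[:i] for i in range(p))
    out = []
    i = 0
    while i + p <= len(seq):
        if seq[i : i + p] not in units:
            i += 1
            continue
        j = i + p
        while j < len(seq) and seq[j] == seq[j - p]:
            j += 1
        n_units = (j - i) // p
        if n_units >= min_units:
            out.append((i, i + n_units * p, n_units))
        i = j - p + 1 if j - p + 1 > i else i + 1
    # deduplicate overlapping reports of the same run
    dedup = []
    for s, e, n in out:
        if dedup and s < dedup[-1][1]:
            continue
        dedup.append((s, e, n))
    return dedup


class TestScanMicrosatellites:
    def test_planted_repeat_and_class_identity(self, small_genome):
        genome, _ = small_genome
        ctg = sitefinder.scan_microsatellites(genome, "CTG", min_units=8)
        cag = sitefinder.scan_microsatellites(genome, "CAG", min_units=8)
        ctg_hits = [l for l in ctg if l.start == 5000]
        assert len(ctg_hits) == 1
        assert ctg_hits[0].unit_count == 10
        assert ctg_hits[0].canonical_motif == canonical_motif_key("CAG")
        # CAG and CTG are one class: same loci either way
        assert [(l.start, l.end) for l in ctg] == [(l.start, l.end) for l in cag]

    def test_two_units_plus_partial_below_threshold(self):
        genome = ReferenceGenome({"chrI": "AAAACTGCTGCTAAAA"})
        assert sitefinder.scan_microsatellites(genome, "CTG", min_units=3) == []

    def test_matches_brute_force_on_random_sequence(self):
        rng = np.random.default_rng(3)
        # AT-rich random sequence makes short spurious runs likely
        seq = "".join(np.array(list("ATAC"))[rng.integers(0, 4, 5000)])
        genome = ReferenceGenome({"chrI": seq})
        for motif, min_units in [("AT", 3), ("TA", 3), ("ACT", 2), ("A", 5)]:
            got = [
                (l.start, l.end, l.unit_count)
                for l in sitefinder.scan_microsatellites(genome, motif, min_units)
            ]
            assert got == _oracle_msat(seq, motif, min_units)

    def test_min_units_monotonicity(self):
        rng = np.random.default_rng(9)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)]) + "CTG" * 12
        genome = ReferenceGenome({"chrI": seq})
        prev = None
        for mu in (2, 3, 5, 8):
            loci = {(l.start, l.end) for l in sitefinder.scan_microsatellites(genome, "CTG", mu)}
            if prev is not None:
                assert loci <= prev
            prev = loci


class TestTallyRepeatClasses:
    def test_census_mapping_totals(self):
        counts = sitefinder.tally_repeat_classes(
            {"CAG/CTG": 88, "GAA/CTT": 133}, ["CAG/CTG", "GAA/CTT"]
        )
        assert counts == {"CAG/CTG": 88, "GAA/CTT": 133, "total": 221}

    def test_empty_loci_all_zero(self):
        counts = sitefinder.tally_repeat_classes([], ["CAG/CTG", "GAA/CTT"])
        assert counts == {"CAG/CTG": 0, "GAA/CTT": 0, "total": 0}

    def test_locus_list_recount(self, small_genome):
        genome, _ = small_genome
        loci = sitefinder.scan_microsatellites(genome, "CTG", 8)
        loci += sitefinder.scan_microsatellites(genome, "GAA", 8)
        counts = sitefinder.tally_repeat_classes(loci, ["CTG", "GAA"])
        assert counts["total"] == counts["CTG"] + counts["GAA"] == len(loci)

    def test_unknown_class_key_rejected(self):
        with pytest.raises(KeyError):
            sitefinder.tally_repeat_classes({"XYZ!": 1}, ["CAG/CTG"])


def test_canonical_motif_closed_under_rotation_and_revcomp():
    for motif in ("CAG", "CTG", "GAA", "TTC", "AT", "ACGGT"):
        key = canonical_motif_key(motif)
        for rot in range(len(motif)):
            rotated = motif[rot:] + motif[:rot]
            assert canonical_motif_key(rotated) == key
            assert canonical_motif_key(revcomp(rotated)) == key
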