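"""Rare off-target mutation calling at predicted sites.

Off-target mutations are rare events — a few mutant reads over thousands of
covering reads — so classical frequency-based variant callers do not apply.
Instead, every read from the *untagged* partition that overlaps a predicted
site is compared to the reference, variant reads are counted per site, sites
with fewer than two mutant reads are discarded, and each surviving site is
tested against the same position in a control library with Fisher's exact
test after normalizing the library counts by mean coverage per colony
(genome coverage / CFU).

Variant extraction realigns each overlapping read against the local
reference window with edlib and parses the extended CIGAR, so substitutions
and indels are recovered regardless of how the upstream aligner expressed
them (soft clips included).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import edlib
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .mapcov import AlignmentRecord
from .sitefinder import OffTargetSite
from .simdata import ReferenceGenome

HAPLOID_GENOME_LENGTH = 12_500_000  # nt, haploid yeast genome
DEFAULT_READ_LENGTH = 150

MUTATION_CLASS_ORDER = ("point", "insertion_1nt", "deletion_triplet_multiple", "other_indel")


@dataclass(frozen=True)
class LibraryStats:
    """Per-library sequencing/transformation statistics.

    genome_coverage = n_reads x read_length / genome_length;
    mean_coverage_per_cfu = genome_coverage / cfu.
    """

    library_id: str
    n_reads: int
    cfu: int
    read_length: int = DEFAULT_READ_LENGTH
    genome_length: int = HAPLOID_GENOME_LENGTH

    def __post_init__(self) -> None:
        if min(self.n_reads, self.cfu, self.read_length, self.genome_length) <= 0:
            raise ValueError("all LibraryStats primaries must be positive")

    @property
    def genome_coverage(self) -> float:
        return self.n_reads * self.read_length / self.genome_length

    @property
    def mean_coverage_per_cfu(self) -> float:
        return self.genome_coverage / self.cfu


def compute_library_stats(
    n_reads: int,
    read_length: int = DEFAULT_READ_LENGTH,
    genome_length: int = HAPLOID_GENOME_LENGTH,
    cfu: int = 1,
    library_id: str = "",
) -> LibraryStats:
    """LibraryStats from the two coverage formulas (see class docstring)."""
    return LibraryStats(
        library_id=library_id, n_reads=n_reads, cfu=cfu,
        read_length=read_length, genome_length=genome_length,
    )


@dataclass
class PositionCounts:
    chrom: str
    pos: int  # 0-based
    ref_base: str
    alt_counts: Counter = field(default_factory=Counter)
    total_covering: int = 0


@dataclass
class SiteVariantCounts:
    """Per-site mutant-read tally.

    A read is counted once per site no matter how many variant positions it
    carries; ``class_tally`` classifies each mutant read by its variant
    (indel takes precedence over co-occurring substitutions).
    """

    site_id: str
    chrom: str
    start: int
    end: int
    positions: list[PositionCounts] = field(default_factory=list)
    n_mutant_reads: int = 0
    total_covering_reads: int = 0
    class_tally: Counter = field(default_factory=Counter)
    mutant_read_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class FisherResult:
    """Colony-normalized Fisher comparison of one site against the control."""

    site_id: str
    lib_mutant: int
    lib_covering: int
    ctrl_mutant: int
    ctrl_covering: int
    normalization_factor: float
    norm_lib_mutant: int
    norm_lib_covering: int
    p_value: float | None
    bh_adjusted_p: float | None = None
    significant: bool = False
    testable: bool = True

    @property
    def table(self) -> list[list[int]]:
        return [
            [self.norm_lib_mutant, self.norm_lib_covering - self.norm_lib_mutant],
            [self.ctrl_mutant, self.ctrl_covering - self.ctrl_mutant],
        ]


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

def pileup_variants(
    alignments: Iterable[AlignmentRecord],
    genome: ReferenceGenome,
    sites: Sequence[OffTargetSite],
    min_base_quality: int = 0,
    truth: pd.DataFrame | None = None,
) -> list[SiteVariantCounts]:
    """Compare every read overlapping each predicted site to the reference.

    ``alignments`` must come from the untagged partition; when a simulation
    truth table is supplied, tagged read ids found among the alignments
    trigger a warning.  ``min_base_quality`` is accepted for interface
    parity; the synthetic libraries carry constant qualities, so it only
    takes effect when per-base qualities are attached to the records.

    Variant classes: single-base substitution -> ``point``; 1-nt insertion
    -> ``insertion_1nt``; deletion whose length is a positive multiple of 3
    and whose removed sequence lies inside a period-3 tandem run ->
    ``deletion_triplet_multiple``; any other indel -> ``other_indel``.
    """
    alignments = list(alignments)
    for site in sites:
        if site.chrom not in genome.chromosomes or site.end > len(genome[site.chrom]):
            raise ValueError(f"site {site.site_id} outside the genome")
    if truth is not None:
        tagged_ids = set(truth.loc[truth["tagged"], "read_id"])
        leaked = [a.read_id for a in alignments if a.read_id in tagged_ids]
        if leaked:
            warnings.warn(
                f"{len(leaked)} tagged reads present in the untagged partition "
                f"(e.g. {leaked[0]})"
            )

    by_chrom: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        if a.mapped:
            by_chrom[a.chrom].append(a)
    for lst in by_chrom.values():
        lst.sort(key=lambda a: a.start)

    out: list[SiteVariantCounts] = []
    for site in sites:
        svc = SiteVariantCounts(
            site_id=site.site_id, chrom=site.chrom, start=site.start, end=site.end,
            positions=[
                PositionCounts(site.chrom, p, genome[site.chrom][p])
                for p in range(site.start, site.end)
            ],
        )
        pos_index = {p.pos: p for p in svc.positions}
        ref = genome[site.chrom]
        for a in by_chrom.get(site.chrom, ()):
            # generous overlap test: soft clips may hide indel-shifted bases
            if a.start >= site.end + len(a.seq) or a.end + len(a.seq) <= site.start:
                continue
            variants, covered = _read_variants(a, ref, site.start, site.end)
            if covered is None:
                continue
            svc.total_covering_reads += 1
            for p in range(covered[0], covered[1]):
                if p in pos_index:
                    pos_index[p].total_covering += 1
            # indels inside tandem repeats have ambiguous placement; a
            # variant belongs to the site if any equivalent placement
            # overlaps the site interval
            in_site = [
                v for v in variants
                if _overlaps(_ambiguity_interval(ref, v), site.start, site.end)
            ]
            if in_site:
                svc.n_mutant_reads += 1
                svc.mutant_read_ids.append(a.read_id)
                # classify from the read's full variant set: aligners may
                # fragment one repeat-unit deletion across the site edge
                svc.class_tally[_classify_read(variants, ref)] += 1
                for pos, kind, refpart, altpart in in_site:
                    if pos in pos_index:
                        pos_index[pos].alt_counts[f"{kind}:{refpart}>{altpart}"] += 1
        out.append(svc)
    return out


def _read_variants(
    a: AlignmentRecord, ref: str, site_start: int, site_end: int
) -> tuple[list[tuple[int, str, str, str]], tuple[int, int] | None]:
    """Variants of one read vs the local reference, by edlib realignment.

    Returns (variants, (ref_cov_start, ref_cov_end)); each variant is
    (ref_pos, kind, ref_alleles, alt_alleles) with kind in {sub, ins, del}.
    ``None`` coverage means the read could not be anchored near the site.
    """
    if not a.seq:
        return [], (a.start, a.end)
    pad = len(a.seq) + 10
    w0 = max(0, a.start - pad)
    w1 = min(len(ref), a.end + pad)
    window = ref[w0:w1]
    aln = edlib.align(a.seq, window, mode="HW", task="path")
    if aln["editDistance"] < 0 or not aln["locations"]:
        return [], None
    loc_start, loc_end = aln["locations"][0]
    cigar = aln["cigar"]
    variants: list[tuple[int, str, str, str]] = []
    rpos = w0 + loc_start
    qpos = 0
    for n, op in _iter_cigar(cigar):
        if op == "=":
            rpos += n
            qpos += n
        elif op == "X":
            for k in range(n):
                variants.append((rpos + k, "sub", ref[rpos + k], a.seq[qpos + k]))
            rpos += n
            qpos += n
        elif op == "I":  # extra bases in the read: insertion
            variants.append((rpos, "ins", "", a.seq[qpos : qpos + n]))
            qpos += n
        elif op == "D":  # bases missing from the read: deletion from the reference
            variants.append((rpos, "del", ref[rpos : rpos + n], ""))
            rpos += n
    cov = (w0 + loc_start, w0 + loc_end + 1)
    return variants, cov


def _overlaps(interval: tuple[int, int], start: int, end: int) -> bool:
    return interval[0] < end and start < interval[1]


def _ambiguity_interval(ref: str, variant: tuple[int, str, str, str]) -> tuple[int, int]:
    """Reference interval covered by all equivalent placements of a variant.

    Substitutions occupy one base.  A deletion of length d can shift left
    while ref[lo-1] == ref[lo-1+d] and right while ref[r] == ref[r+d]; an
    insertion of S can shift while the reference tracks the rotated insert.
    """
    pos, kind, refpart, altpart = variant
    if kind == "sub":
        return pos, pos + 1
    if kind == "del":
        d = len(refpart)
        lo = pos
        while lo > 0 and ref[lo - 1] == ref[lo - 1 + d]:
            lo -= 1
        r = pos
        while r + d < len(ref) and ref[r] == ref[r + d]:
            r += 1
        return lo, r + d
    # insertion
    s = altpart
    lo = pos
    while lo > 0 and ref[lo - 1] == s[(lo - 1 - pos) % len(s)]:
        lo -= 1
    r = pos
    while r < len(ref) and ref[r] == s[(r - pos) % len(s)]:
        r += 1
    return lo, max(r, pos + 1)


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _classify_read(variants: list[tuple[int, str, str, str]], ref: str) -> str:
    """One class per mutant read; indels dominate substitutions.

    A repeat-length deletion may be reported by the aligner as several
    equally-optimal fragments interleaved with matches, so deletions are
    aggregated: when the combined deleted length is a positive multiple of 3
    and the whole deleted span sits inside a period-3 tandem run, the read
    is a triplet-multiple deletion.
    """
    ins = [v for v in variants if v[1] == "ins"]
    dels = [v for v in variants if v[1] == "del"]
    if not ins and not dels:
        return "point"
    if ins and not dels and sum(len(v[3]) for v in ins) == 1:
        return "insertion_1nt"
    if dels and not ins:
        total = sum(len(v[2]) for v in dels)
        if total % 3 == 0 and total > 0 and _is_triplet_deletion(ref, dels, total):
            return "deletion_triplet_multiple"
    return "other_indel"


def _is_triplet_deletion(ref: str, dels: list[tuple[int, str, str, str]], total: int) -> bool:
    """True when the (possibly fragmented) deletions are equivalent to
    removing one contiguous block of ``total`` bases lying inside a
    period-3 tandem run."""
    span_start = min(v[0] for v in dels)
    span_end = max(v[0] + len(v[2]) for v in dels)
    lo = max(0, span_start - 30)
    hi = min(len(ref), span_end + 30)
    local = ref[lo:hi]
    gone = {i for v in dels for i in range(v[0] - lo, v[0] - lo + len(v[2]))}
    observed = "".join(ch for i, ch in enumerate(local) if i not in gone)
    for q in range(0, len(local) - total + 1):
        if local[:q] + local[q + total :] == observed and _in_triplet_run(ref, lo + q, total):
            return True
    return False


def _in_triplet_run(ref: str, pos: int, span: int) -> bool:
    """True when [pos, pos+span) sits inside a period-3 tandem run (every
    base reappears three positions downstream)."""
    seg = ref[pos : pos + span + 3]
    if len(seg) < span + 3:
        seg = ref[max(0, pos - 3) : pos + span]
    return all(seg[i] == seg[i + 3] for i in range(len(seg) - 3))


# ---------------------------------------------------------------------------
# Filters and the Fisher comparison
# ---------------------------------------------------------------------------

def filter_min_mutant_reads(
    counts: Sequence[SiteVariantCounts], min_reads: int = 2
) -> tuple[list[SiteVariantCounts], int]:
    """Keep sites with at least ``min_reads`` mutant reads (default two:
    single-mutant-read positions are noise and are discarded).  Returns the
    retained list and the number of discarded sites."""
    kept = [c for c in counts if c.n_mutant_reads >= min_reads]
    return kept, len(counts) - len(kept)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fisher_offtarget(
    lib_counts: SiteVariantCounts,
    ctrl_counts: SiteVariantCounts,
    lib_stats: LibraryStats,
    ctrl_stats: LibraryStats,
    alpha: float = 0.05,
    scale_both_margins: bool = True,
) -> FisherResult:
    """Colony-normalized Fisher exact test of one site against the control.

    Library counts are scaled by f = control mean-coverage-per-CFU / library
    mean-coverage-per-CFU (rounded half-away-from-zero to integers, since the
    exact test needs integer tables), then the 2x2 table
    [[mutant, covering - mutant] (library), [mutant, covering - mutant]
    (control)] is tested two-sided.  Significance is flagged on the raw
    p-value at ``alpha``.  With ``scale_both_margins=False`` only the mutant
    count is scaled.
    """
    if ctrl_counts.total_covering_reads <= 0:
        raise ValueError("control covering reads must be > 0")
    if lib_counts.total_covering_reads == 0:
        return FisherResult(
            site_id=lib_counts.site_id,
            lib_mutant=lib_counts.n_mutant_reads, lib_covering=0,
            ctrl_mutant=ctrl_counts.n_mutant_reads,
            ctrl_covering=ctrl_counts.total_covering_reads,
            normalization_factor=float("nan"),
            norm_lib_mutant=0, norm_lib_covering=0,
            p_value=None, testable=False,
        )
    f = ctrl_stats.mean_coverage_per_cfu / lib_stats.mean_coverage_per_cfu
    nm = _round_half_away(lib_counts.n_mutant_reads * f)
    nc = (
        _round_half_away(lib_counts.total_covering_reads * f)
        if scale_both_margins
        else lib_counts.total_covering_reads
    )
    if nm > nc:
        raise ValueError(
            f"site {lib_counts.site_id}: normalized mutant count {nm} exceeds "
            f"normalized covering count {nc}"
        )
    table = [
        [nm, nc - nm],
        [ctrl_counts.n_mutant_reads,
         ctrl_counts.total_covering_reads - ctrl_counts.n_mutant_reads],
    ]
    _, p = fisher_exact(table, alternative="two-sided")
    return FisherResult(
        site_id=lib_counts.site_id,
        lib_mutant=lib_counts.n_mutant_reads,
        lib_covering=lib_counts.total_covering_reads,
        ctrl_mutant=ctrl_counts.n_mutant_reads,
        ctrl_covering=ctrl_counts.total_covering_reads,
        normalization_factor=f,
        norm_lib_mutant=nm, norm_lib_covering=nc,
        p_value=float(p),
        significant=bool(p < alpha),
    )


def fisher_many(
    pairs: Sequence[tuple[SiteVariantCounts, SiteVariantCounts]],
    lib_stats: LibraryStats,
    ctrl_stats: LibraryStats,
    alpha: float = 0.05,
    scale_both_margins: bool = True,
) -> list[FisherResult]:
    """Fisher test per site with Benjamini-Hochberg adjusted p-values
    reported alongside; the significance flag stays on the raw p."""
    results = [
        fisher_offtarget(lc, cc, lib_stats, ctrl_stats, alpha, scale_both_margins)
        for lc, cc in pairs
    ]
    testable = [r for r in results if r.testable]
    if testable:
        _, adj, _, _ = multipletests([r.p_value for r in testable], method="fdr_bh")
        adj_by_id = {r.site_id: a for r, a in zip(testable, adj)}
        results = [
            replace(r, bh_adjusted_p=float(adj_by_id[r.site_id])) if r.testable else r
            for r in results
        ]
    return results


def results_frame(results: Sequence[FisherResult]) -> pd.DataFrame:
    """Fisher results as a table with one row per site (mirrors the
    per-site statistical summary of the analysis)."""
    return pd.DataFrame(
        [
            {
                "site": r.site_id,
                "mutant_reads": r.lib_mutant,
                "covering_reads": r.lib_covering,
                "ctrl_mutant_reads": r.ctrl_mutant,
                "ctrl_covering_reads": r.ctrl_covering,
                "normalization_factor": r.normalization_factor,
                "norm_mutant": r.norm_lib_mutant,
                "norm_covering": r.norm_lib_covering,
                "p_value": r.p_value,
                "bh_adjusted_p": r.bh_adjusted_p,
                "significant": r.significant,
                "testable": r.testable,
            }
            for r in results
        ]
    )
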