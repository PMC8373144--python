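"""Read mapping, coverage tracks and coverage-peak calling.

The built-in mapper is deliberately small: exact 31-mer seeding with
unique-seed placement and ungapped extension (+1 match / -1 mismatch) with
soft-clipping of the worst-scoring prefix/suffix.  It never emits secondary
alignments, mirroring the ``-ax sr --secondary=no`` contract of a production
short-read aligner.  Externally produced SAM files can be fed through the
same coverage/peak path via :func:`read_sam` / :func:`write_sam` (pysam).

Integration peaks are called with the twice-median rule: a peak is a maximal
run of positions whose depth is at least twice the genome-wide median
coverage (with a floor parameter rescuing the degenerate sparse case where
the median is 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pysam

from .simdata import Locus, ReferenceGenome, revcomp

SEED_LENGTH = 31

# CIGAR ops: sequence-match '=', mismatch 'X', insertion 'I', deletion 'D',
# soft clip 'S' (pysam numeric codes 7, 8, 1, 2, 4)
_OP_TO_PYSAM = {"=": 7, "X": 8, "I": 1, "D": 2, "S": 4}
_PYSAM_TO_OP = {v: k for k, v in _OP_TO_PYSAM.items()}
_PYSAM_TO_OP[0] = "="  # plain M from external aligners treated as aligned

_REF_OPS = {"=", "X", "D"}
_READ_OPS = {"=", "X", "I", "S"}


@dataclass(frozen=True)
class AlignmentRecord:
    """One primary alignment (or an unmapped read).

    ``segments`` is a CIGAR-like list of (op, length) with ops in
    {'=', 'X', 'I', 'D', 'S'}.  ``start`` is 0-based on the reference.
    """

    read_id: str
    chrom: str = ""
    start: int = 0
    segments: tuple[tuple[str, int], ...] = ()
    strand: str = "+"
    mapped: bool = False
    seq: str = ""

    @property
    def reference_span(self) -> int:
        return sum(n for op, n in self.segments if op in _REF_OPS)

    @property
    def end(self) -> int:
        return self.start + self.reference_span

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.segments) if self.segments else "*"


@dataclass
class CoverageTrack:
    """Per-chromosome integer depth arrays plus the genome-wide median
    (computed over every reference position, zeros included)."""

    depths: dict[str, np.ndarray]

    @property
    def median_depth(self) -> float:
        return float(np.median(np.concatenate(list(self.depths.values()))))


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    max_depth: int
    mean_depth: float
    labels: tuple[str, ...] = ()


class GenomeIndex:
    """Exact k-mer index of a genome: kmer -> (count, first placement)."""

    def __init__(self, genome: ReferenceGenome, k: int = SEED_LENGTH):
        self.genome = genome
        self.k = k
        index: dict[str, tuple[int, str, int]] = {}
        for chrom, seq in genome.chromosomes.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                hit = index.get(kmer)
                if hit is None:
                    index[kmer] = (1, chrom, i)
                else:
                    index[kmer] = (hit[0] + 1, hit[1], hit[2])
        self._index = index

    def lookup_unique(self, kmer: str) -> tuple[str, int] | None:
        hit = self._index.get(kmer)
        if hit is not None and hit[0] == 1:
            return hit[1], hit[2]
        return None


def map_reads(
    reads: Iterable[tuple[str, str]],
    genome: ReferenceGenome,
    index: GenomeIndex | None = None,
) -> list[AlignmentRecord]:
    """Map (read_id, sequence) pairs with the built-in seed-and-extend mapper.

    For each read the first exact 31-mer occurring uniquely in the genome
    places the read (forward strand first, then reverse complement); an
    ungapped comparison along that diagonal scores +1/-1 per base and the
    best-scoring window is kept, with the flanks soft-clipped.  Reads with no
    unique seed on either strand are reported unmapped.  At most one record
    per read; secondary alignments are never produced.
    """
    if index is None:
        index = GenomeIndex(genome)
    k = index.k
    out: list[AlignmentRecord] = []
    for rid, seq in reads:
        seq = seq.upper()
        if len(seq) < k:
            out.append(AlignmentRecord(read_id=rid, mapped=False, seq=seq))
            continue
        rec = None
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            placement = _place(s, index, k)
            if placement is not None:
                chrom, diag_start = placement
                rec = _extend(rid, s, chrom, diag_start, strand, index.genome)
                break
        out.append(rec if rec is not None else AlignmentRecord(read_id=rid, mapped=False, seq=seq))
    return out


def _place(seq: str, index: GenomeIndex, k: int) -> tuple[str, int] | None:
    for off in range(0, len(seq) - k + 1):
        hit = index.lookup_unique(seq[off : off + k])
        if hit is not None:
            chrom, pos = hit
            return chrom, pos - off
    return None


def _extend(rid: str, seq: str, chrom: str, diag_start: int, strand: str,
            genome: ReferenceGenome) -> AlignmentRecord:
    ref = genome[chrom]
    L = len(seq)
    # clip the read to the chromosome
    lead_clip = max(0, -diag_start)
    tail_clip = max(0, diag_start + L - len(ref))
    core = range(lead_clip, L - tail_clip)
    scores = [1 if seq[i] == ref[diag_start + i] else -1 for i in core]
    # best-scoring contiguous window (max subarray, first-longest on ties)
    best_sum, best = -1, None
    cur_sum, cur_start = 0, 0
    for i, s in enumerate(scores):
        if cur_sum <= 0:
            cur_sum, cur_start = s, i
        else:
            cur_sum += s
        if cur_sum > best_sum:
            best_sum, best = cur_sum, (cur_start, i + 1)
    if best is None or best_sum <= 0:
        return AlignmentRecord(read_id=rid, mapped=False, seq=seq)
    w0, w1 = best[0] + lead_clip, best[1] + lead_clip
    segments: list[tuple[str, int]] = []
    if w0 > 0:
        segments.append(("S", w0))
    run_op, run_len = None, 0
    for i in range(w0, w1):
        op = "=" if seq[i] == ref[diag_start + i] else "X"
        if op == run_op:
            run_len += 1
        else:
            if run_op is not None:
                segments.append((run_op, run_len))
            run_op, run_len = op, 1
    segments.append((run_op, run_len))
    if w1 < L:
        segments.append(("S", L - w1))
    return AlignmentRecord(
        read_id=rid, chrom=chrom, start=diag_start + w0,
        segments=tuple(segments), strand=strand, mapped=True, seq=seq,
    )


# ---------------------------------------------------------------------------
# SAM interchange (external-aligner pluggability)
# ---------------------------------------------------------------------------

def write_sam(alignments: Sequence[AlignmentRecord], genome: ReferenceGenome, path: str) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.chromosomes.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for rec in alignments:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rec.read_id
            a.query_sequence = rec.seq or None
            if rec.mapped:
                a.reference_name = rec.chrom
                a.reference_start = rec.start
                a.cigartuples = [(_OP_TO_PYSAM[op], n) for op, n in rec.segments]
                a.is_reverse = rec.strand == "-"
                a.mapping_quality = 60
            else:
                a.is_unmapped = True
            fh.write(a)


def read_sam(path: str) -> list[AlignmentRecord]:
    """Load primary alignments from a SAM/BAM file into AlignmentRecords.

    Secondary and supplementary records are skipped so the no-secondary
    contract holds regardless of the producing aligner.
    """
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for a in fh:
            if a.is_secondary or a.is_supplementary:
                continue
            if a.is_unmapped:
                out.append(AlignmentRecord(read_id=a.query_name, mapped=False,
                                           seq=a.query_sequence or ""))
                continue
            segments = tuple(
                (_PYSAM_TO_OP[op], n) for op, n in a.cigartuples if op in _PYSAM_TO_OP
            )
            out.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    chrom=a.reference_name,
                    start=a.reference_start,
                    segments=segments,
                    strand="-" if a.is_reverse else "+",
                    mapped=True,
                    seq=a.query_sequence or "",
                )
            )
    return out


# ---------------------------------------------------------------------------
# Coverage and peaks
# ---------------------------------------------------------------------------

def compute_coverage(alignments: Iterable[AlignmentRecord], genome: ReferenceGenome) -> CoverageTrack:
    """Per-base depth: each position covered by an alignment's reference span
    counts that read once.  Deleted positions inside a read still count (the
    read evidence spans them); insertions add no reference positions."""
    diffs = {c: np.zeros(len(s) + 1, dtype=np.int64) for c, s in genome.chromosomes.items()}
    for rec in alignments:
        if not rec.mapped:
            continue
        if rec.chrom not in diffs:
            raise ValueError(f"alignment {rec.read_id} on unknown chromosome {rec.chrom}")
        if rec.end > len(genome[rec.chrom]) or rec.start < 0:
            raise ValueError(
                f"alignment {rec.read_id} at {rec.chrom}:{rec.start}-{rec.end} "
                f"exceeds chromosome bounds"
            )
        diffs[rec.chrom][rec.start] += 1
        diffs[rec.chrom][rec.end] -= 1
    return CoverageTrack({c: np.cumsum(d[:-1]) for c, d in diffs.items()})


def call_peaks(track: CoverageTrack, min_floor: int = 5, min_width: int = 1) -> list[Peak]:
    """Maximal runs of depth >= max(2 x median, min_floor), width >= min_width.

    The floor guards the degenerate sparse-genome case: with median 0 the
    twice-median threshold would be 0 and the whole genome would qualify.
    """
    med = track.median_depth
    threshold = max(2.0 * med, float(min_floor))
    if med == 0 and min_floor <= 0:
        warnings.warn("median depth is 0 and no floor set: every covered position qualifies")
    peaks: list[Peak] = []
    for chrom, depth in track.depths.items():
        above = depth >= threshold
        if not above.any():
            continue
        padded = np.diff(np.concatenate([[0], above.view(np.int8), [0]]))
        starts = np.nonzero(padded == 1)[0]
        ends = np.nonzero(padded == -1)[0]
        for s, e in zip(starts, ends):
            if e - s < min_width:
                continue
            seg = depth[s:e]
            peaks.append(Peak(chrom, int(s), int(e), int(seg.max()), float(seg.mean())))
    peaks.sort(key=lambda p: (_chrom_key(track, p.chrom), p.start))
    return peaks


def _chrom_key(track: CoverageTrack, chrom: str) -> int:
    return list(track.depths).index(chrom)


def annotate_peaks(peaks: Sequence[Peak], loci: Sequence[Locus]) -> list[Peak]:
    """Label each peak with every locus it overlaps (half-open intervals;
    a shared boundary is not an overlap).  Unlabeled peaks are retained."""
    out = []
    for p in peaks:
        labels = tuple(
            l.locus_id
            for l in loci
            if l.chrom == p.chrom and p.start < l.end and l.start < p.end
        )
        out.append(replace(p, labels=labels))
    return out


def write_peaks_bed(peaks: Sequence[Peak], path: str) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            name = ",".join(p.labels) if p.labels else "."
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.max_depth}\t.\n")
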