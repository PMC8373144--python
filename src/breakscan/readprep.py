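"""Tag-based library splitting.

Each tag-integration sequencing library is partitioned into reads that
contain the dsODN tag (break-derived amplification products) and reads that
do not (bulk genomic background).  Matching is exact-substring on both
orientations of the full tag; a ``forward_only`` switch restores plain
single-orientation grep behaviour.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simdata import DNA_ALPHABET, revcomp


class FastqFormatError(ValueError):
    """Malformed FASTQ input, with the offending record index when known."""


@dataclass
class TagSplitResult:
    """Outcome of splitting one library by tag presence."""

    n_total: int
    n_tagged: int
    n_untagged: int
    orientations: list[str] = field(default_factory=list, repr=False)

    @property
    def tagged_fraction(self) -> float:
        if self.n_total == 0:
            raise ZeroDivisionError("empty library has no tagged fraction")
        return self.n_tagged / self.n_total

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_total": self.n_total,
                "n_tagged": self.n_tagged,
                "n_untagged": self.n_untagged,
                "tagged_fraction": self.tagged_fraction,
                "tagged_percent": tagged_percentage(self.n_tagged, self.n_total),
            }
        )

    def to_tsv_line(self) -> str:
        return (
            f"{self.n_total}\t{self.n_tagged}\t{self.n_untagged}\t"
            f"{tagged_percentage(self.n_tagged, self.n_total)}"
        )


def _check_tag(tag: str) -> str:
    tag = tag.upper()
    if not tag:
        raise ValueError("tag must be non-empty")
    bad = set(tag) - set(DNA_ALPHABET)
    if bad:
        raise ValueError(f"tag contains ambiguous/non-DNA symbols: {sorted(bad)}")
    return tag


def find_tag(read_seq: str, tag: str, forward_only: bool = False) -> str:
    """Orientation of an exact tag match in ``read_seq``.

    Returns ``"forward"`` if the tag is a substring, else ``"reverse"`` if its
    reverse complement is (unless ``forward_only``), else ``"none"``.
    One mismatch anywhere inside the tag region means no match: the contract
    is exact containment, as in the original grep-based partition.
    """
    tag = _check_tag(tag)
    if tag in read_seq.upper():
        return "forward"
    if not forward_only and revcomp(tag) in read_seq.upper():
        return "reverse"
    return "none"


def _open_maybe_gzip(path: str, mode: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def iter_fastq(path: str) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from a FASTQ file, raising
    :class:`FastqFormatError` with the record index on malformed input."""
    n = 0
    try:
        with _open_maybe_gzip(path, "r") as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq, qual
                n += 1
    except ValueError as exc:
        raise FastqFormatError(f"malformed FASTQ near record {n}: {exc}") from exc


def split_fastq(
    library_path: str,
    tag: str,
    tagged_path: str,
    untagged_path: str,
    forward_only: bool = False,
    trim_tag: bool = False,
) -> TagSplitResult:
    """Partition a FASTQ library into tagged and untagged files.

    Every input read lands in exactly one output file, in input order.
    Quality strings are carried through untouched.  With ``trim_tag``, the
    tag and everything on its amplification-primer side (5' of the genomic
    junction for forward matches, 3' for reverse matches) are removed from
    tagged reads before writing.
    """
    tag = _check_tag(tag)
    n_total = n_tagged = 0
    orientations: list[str] = []
    with _open_maybe_gzip(tagged_path, "w") as ftag, _open_maybe_gzip(untagged_path, "w") as fun:
        for rid, seq, qual in iter_fastq(library_path):
            orient = find_tag(seq, tag, forward_only=forward_only)
            orientations.append(orient)
            n_total += 1
            if orient == "none":
                fun.write(f"@{rid}\n{seq}\n+\n{qual}\n")
                continue
            n_tagged += 1
            if trim_tag:
                seq, qual = _trim(seq, qual, tag, orient)
            ftag.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    if n_total == 0:
        raise FastqFormatError(f"empty library: {library_path}")
    return TagSplitResult(n_total, n_tagged, n_total - n_tagged, orientations)


def _trim(seq: str, qual: str, tag: str, orient: str) -> tuple[str, str]:
    if orient == "forward":
        cut = seq.upper().index(tag) + len(tag)
        return seq[cut:], qual[cut:]
    cut = seq.upper().index(revcomp(tag))
    return seq[:cut], qual[:cut]


def tagged_percentage(n_tagged: int, n_total: int) -> float:
    """Percentage of tagged reads, half-up rounded to one decimal.

    ``tagged_percentage(1_500_000, 78_000_000)`` prints 1.9 — the observed
    fraction of dsODN-containing reads in the emulated experiment.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if n_tagged > n_total or n_tagged < 0:
        raise ValueError("n_tagged must be in [0, n_total]")
    pct = Decimal(100 * n_tagged) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
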