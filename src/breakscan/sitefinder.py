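"""Candidate off-target enumeration and microsatellite scanning.

``scan_offtargets`` enumerates every genomic window, on both strands, whose
PAM matches an IUPAC pattern and whose protospacer-aligned sequence is
within a Hamming-distance budget of the guide (substitutions only, no
bulges) — the candidate definition used by guide-design tools at this scale.

``scan_microsatellites`` finds maximal perfect tandem repeats of a motif
class, where a class is closed under rotation and reverse complement
(CAG and CTG are one class, reported under a shared canonical key).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .simdata import ReferenceGenome, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class GuideSpec:
    """A guide: 20-21 nt protospacer plus a PAM pattern on one side.

    ``pam_side`` is an explicit parameter (``three_prime`` for Cas9-style
    NGG after the protospacer, ``five_prime`` for Cas12a-style TTN before
    it) and is never inferred from the nuclease name.
    """

    protospacer: str
    pam_pattern: str = "NGG"
    pam_side: str = "three_prime"
    max_mismatches: int = 4

    def __post_init__(self) -> None:
        proto = self.protospacer.upper()
        if len(proto) not in (20, 21):
            raise ValueError(f"protospacer must be 20 or 21 nt, got {len(proto)}")
        if set(proto) - set("ACGT"):
            raise ValueError("protospacer must be plain ACGT")
        if set(self.pam_pattern.upper()) - set(IUPAC):
            raise ValueError(f"invalid IUPAC symbols in PAM {self.pam_pattern!r}")
        if self.pam_side not in ("three_prime", "five_prime"):
            raise ValueError("pam_side must be three_prime or five_prime")
        if not 0 <= self.max_mismatches <= len(proto):
            raise ValueError("max_mismatches out of range")
        object.__setattr__(self, "protospacer", proto)
        object.__setattr__(self, "pam_pattern", self.pam_pattern.upper())


@dataclass(frozen=True)
class OffTargetSite:
    """A protospacer-length genomic window with a matching PAM.

    ``start``/``end`` delimit the protospacer interval (0-based half-open,
    reference coordinates); mismatch positions are 1-based counted from the
    PAM-distal end of the protospacer.
    """

    chrom: str
    start: int
    end: int
    strand: str
    protospacer_match: str
    pam: str
    n_mismatches: int
    mismatch_positions: tuple[int, ...]

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class MicrosatelliteLocus:
    chrom: str
    start: int
    end: int
    canonical_motif: str
    unit_count: int
    strand_of_report: str = "+"


def canonical_motif_key(motif: str) -> str:
    """Lexicographically smallest string over all rotations of the motif and
    of its reverse complement — one key per repeat class (CAG/CTG -> 'AGC')."""
    motif = motif.upper()
    candidates = []
    for m in (motif, revcomp(motif)):
        candidates.extend(m[i:] + m[:i] for i in range(len(m)))
    return min(candidates)


def class_display_name(motif: str) -> str:
    """Human-readable class name 'MOTIF/REVCOMP' with the smaller rotation of
    each strand, e.g. 'CAG/CTG' and 'CTG/CAG' both normalize to 'AGC'."""
    return canonical_motif_key(motif)


# ---------------------------------------------------------------------------
# Off-target scan
# ---------------------------------------------------------------------------

_BASE_CODE = {b: i for i, b in enumerate("ACGT")}


def scan_offtargets(genome: ReferenceGenome, guide: GuideSpec) -> list[OffTargetSite]:
    """All windows on both strands with a matching PAM and at most
    ``guide.max_mismatches`` substitutions against the protospacer, sorted by
    (n_mismatches, coordinate)."""
    sites: list[OffTargetSite] = []
    for chrom, seq in genome.chromosomes.items():
        sites.extend(_scan_strand(chrom, seq, guide, "+"))
        sites.extend(_scan_strand(chrom, seq, guide, "-"))
    sites.sort(key=lambda s: (s.n_mismatches, s.chrom, s.start, s.strand))
    return sites


def _scan_strand(chrom: str, seq: str, guide: GuideSpec, strand: str) -> list[OffTargetSite]:
    work = seq if strand == "+" else revcomp(seq)
    N = len(work)
    P = len(guide.protospacer)
    M = len(guide.pam_pattern)
    if N < P + M:
        return []
    arr = np.frombuffer(work.encode(), dtype=np.uint8)
    # mismatch count per protospacer window start
    n_windows = N - P + 1
    mm = np.zeros(n_windows, dtype=np.int16)
    for j, base in enumerate(guide.protospacer):
        mm += arr[j : j + n_windows] != ord(base)
    # PAM match per PAM window start
    pam_windows = N - M + 1
    pam_ok = np.ones(pam_windows, dtype=bool)
    for j, sym in enumerate(guide.pam_pattern):
        allowed = IUPAC[sym]
        col = arr[j : j + pam_windows]
        ok = np.zeros(pam_windows, dtype=bool)
        for b in allowed:
            ok |= col == ord(b)
        pam_ok &= ok
    sites = []
    for i in range(n_windows):
        if mm[i] > guide.max_mismatches:
            continue
        if guide.pam_side == "three_prime":
            pam_start = i + P
        else:
            pam_start = i - M
        if not (0 <= pam_start < pam_windows) or not pam_ok[pam_start]:
            continue
        window = work[i : i + P]
        mismatches = tuple(
            _pam_distal_position(j, P, guide.pam_side)
            for j in range(P)
            if window[j] != guide.protospacer[j]
        )
        if strand == "+":
            start, end = i, i + P
        else:
            start, end = N - (i + P), N - i
        sites.append(
            OffTargetSite(
                chrom=chrom, start=start, end=end, strand=strand,
                protospacer_match=window, pam=work[pam_start : pam_start + M],
                n_mismatches=int(mm[i]), mismatch_positions=tuple(sorted(mismatches)),
            )
        )
    return sites


def _pam_distal_position(j: int, P: int, pam_side: str) -> int:
    # protospacer index j (5'->3' on the matched strand) to 1-based
    # PAM-distal numbering
    if pam_side == "three_prime":
        return j + 1  # PAM after the protospacer: position 1 is the 5' end
    return P - j  # PAM before: position 1 is the 3' end


# ---------------------------------------------------------------------------
# Microsatellite scan
# ---------------------------------------------------------------------------

def scan_microsatellites(
    genome: ReferenceGenome, motif_class: str, min_units: int = 8
) -> list[MicrosatelliteLocus]:
    """Maximal perfect tandem repeats of any rotation of ``motif_class`` or
    its reverse complement, with at least ``min_units`` complete units.

    A locus spans only complete units (a trailing partial unit is excluded)
    and is maximal: it cannot be extended by one more unit on either side.
    """
    motif_class = motif_class.upper()
    if not 1 <= len(motif_class) <= 6:
        raise ValueError("motif length must be 1-6")
    if min_units < 2:
        raise ValueError("min_units must be >= 2")
    key = canonical_motif_key(motif_class)
    p = len(motif_class)
    units = set()
    for m in (motif_class, revcomp(motif_class)):
        units.update(m[i:] + m[:i] for i in range(p))

    out: list[MicrosatelliteLocus] = []
    for chrom, seq in genome.chromosomes.items():
        N = len(seq)
        if N < p * min_units:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        periodic = arr[:-p] == arr[p:]  # seq[i] == seq[i+p]
        # maximal runs of the periodicity condition
        padded = np.diff(np.concatenate([[0], periodic.view(np.int8), [0]]))
        starts = np.nonzero(padded == 1)[0]
        ends = np.nonzero(padded == -1)[0]
        for s, e in zip(starts, ends):
            run_len = (e - s) + p  # positions s .. e+p-1 form the repeat run
            if run_len < p * min_units:
                continue
            if seq[s : s + p] not in units:
                continue
            n_units = run_len // p
            out.append(
                MicrosatelliteLocus(
                    chrom=chrom, start=int(s), end=int(s + n_units * p),
                    canonical_motif=key, unit_count=int(n_units),
                )
            )
    out.sort(key=lambda l: (l.chrom, l.start))
    return out


def tally_repeat_classes(
    loci: Iterable[MicrosatelliteLocus] | Mapping[str, int],
    classes: Sequence[str],
) -> dict[str, int]:
    """Per-class counts and their total.

    ``loci`` is either a list of scanned loci (counted by canonical motif)
    or an already-tabulated mapping of class name -> count, e.g. the
    published census {'CAG/CTG': 88, 'GAA/CTT': 133} whose total is 221.
    Class names are normalized through rotation/reverse-complement
    canonicalization, so 'CAG/CTG', 'CTG' and 'AGC' are the same key.
    Unknown class keys in a mapping raise ``KeyError``.
    """
    wanted = {}
    for cls in classes:
        wanted[_normalize_class(cls)] = cls
    counts = Counter()
    if isinstance(loci, Mapping):
        for cls, n in loci.items():
            norm = _normalize_class(cls)
            if norm not in wanted:
                raise KeyError(f"unknown repeat class {cls!r}")
            counts[wanted[norm]] += int(n)
    else:
        for locus in loci:
            norm = canonical_motif_key(locus.canonical_motif)
            if norm in wanted:
                counts[wanted[norm]] += 1
    result = {wanted[k]: counts.get(wanted[k], 0) for k in wanted}
    result["total"] = sum(result.values())
    return result


def _normalize_class(cls: str) -> str:
    first = cls.split("/")[0].strip().upper()
    if not first or set(first) - set("ACGT"):
        raise KeyError(f"unknown repeat class {cls!r}")
    return canonical_motif_key(first)


def write_sites_bed(sites: Sequence[OffTargetSite], path: str) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.protospacer_match}\t"
                f"{s.n_mismatches}\t{s.strand}\t{s.pam}\n"
            )
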