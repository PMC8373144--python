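"""Synthetic-data generation for the whole pipeline.

Everything the downstream stages consume — reference genome, locus tables,
FASTQ libraries with embedded dsODN tags and spiked rare mutations, qPCR Ct
pairs for resection assays, flow-cytometry event tables — is generated here
from a seeded random source, so every run of the pipeline is exercisable
without any external data.

The generator emulates the statistical structure of a GUIDE-seq-style yeast
experiment: 150-nt single-end reads covering a small genome roughly
uniformly, a ~2% subpopulation of reads carrying a 34-nt dsODN tag
concentrated at nuclease cut sites (plus a "hot background" of tagged reads
at break-prone loci such as rDNA), and a handful of mutant reads planted at
predicted off-target microsatellites.  Mutant read counts are planted
exactly, not sampled, so the truth table is an exact oracle for the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MUTATION_CLASSES = ("point", "insertion_1nt", "deletion_triplet_multiple", "other_indel")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class LocusError(ValueError):
    """A locus request violates genome bounds or overlaps another locus."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceGenome:
    """Ordered map of chromosome name -> upper-case ACGT sequence."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            if set(seq) - set(DNA_ALPHABET):
                bad = sorted(set(seq) - set(DNA_ALPHABET))
                raise ValueError(f"chromosome {name!r} contains non-ACGT symbols {bad}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def __getitem__(self, chrom: str) -> str:
        return self.chromosomes[chrom]

    def to_fasta(self, path: str, width: int = 60) -> None:
        """Write the genome as FASTA wrapped at ``width`` columns."""
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str) -> "ReferenceGenome":
        chroms: dict[str, str] = {}
        name = None
        parts: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        chroms[name] = "".join(parts)
                    name = line[1:].split()[0]
                    parts = []
                elif line:
                    parts.append(line.upper())
        if name is not None:
            chroms[name] = "".join(parts)
        return cls(chroms)


@dataclass(frozen=True)
class Locus:
    """A genomic interval with a pipeline role.

    ``class_label`` is one of {on_target, off_target_candidate,
    microsatellite, hot_background}; ``motif``/``unit_count`` describe planted
    perfect repeats (``end - start == unit_count * len(motif)``).
    Coordinates are 0-based half-open.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    class_label: str = "off_target_candidate"
    motif: str = ""
    unit_count: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise LocusError(f"locus {self.locus_id}: invalid interval [{self.start}, {self.end})")
        if self.motif and self.unit_count > 0:
            if self.end - self.start != self.unit_count * len(self.motif):
                raise LocusError(
                    f"locus {self.locus_id}: span {self.end - self.start} != "
                    f"{self.unit_count} x |{self.motif}|"
                )


LOCUS_COLUMNS = ["chrom", "start", "end", "locus_id", "strand", "class_label", "motif", "unit_count"]


def loci_to_frame(loci: Sequence[Locus]) -> pd.DataFrame:
    """Locus table as a BED-prefixed DataFrame (chrom/start/end first)."""
    return pd.DataFrame(
        [
            (l.chrom, l.start, l.end, l.locus_id, l.strand, l.class_label, l.motif, l.unit_count)
            for l in loci
        ],
        columns=LOCUS_COLUMNS,
    )


def write_locus_table(loci: Sequence[Locus], path: str) -> None:
    loci_to_frame(loci).to_csv(path, sep="\t", index=False)


def read_locus_table(path: str) -> list[Locus]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        Locus(
            locus_id=str(r.locus_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            class_label=str(r.class_label),
            motif=str(r.motif),
            unit_count=int(r.unit_count),
        )
        for r in df.itertuples()
    ]


@dataclass(frozen=True)
class Spike:
    """A planted rare mutation: ``mutant_read_count`` reads carrying one
    mutation of ``mutation_class`` at locus ``locus_id``."""

    locus_id: str
    mutation_class: str
    mutant_read_count: int

    def __post_init__(self) -> None:
        if self.mutation_class not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mutation_class!r}")
        if self.mutant_read_count < 0:
            raise ValueError("mutant_read_count must be >= 0")


@dataclass(frozen=True)
class SimParams:
    """Library-simulation parameters.

    Defaults encode the emulated experiment: 150-nt reads and a tagged-read
    fraction around 2% of the library, concentrated at cut sites.
    """

    seed: int
    n_reads: int
    read_length: int = 150
    tag_fraction_at_cuts: float = 0.016
    background_tag_fraction: float = 0.003
    seq_error_rate: float = 0.0
    spike_table: tuple[Spike, ...] = ()
    cfu: int = 1000

    def __post_init__(self) -> None:
        for name in ("tag_fraction_at_cuts", "background_tag_fraction", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_reads < 0 or self.cfu <= 0:
            raise ValueError("n_reads must be >= 0 and cfu > 0")
        if self.read_length < 2:
            raise ValueError("read_length too small")


TRUTH_COLUMNS = [
    "read_id", "chrom", "start", "tagged", "tag_orientation", "spike_id", "mutation_class",
]


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def make_genome(
    params: SimParams,
    n_chrom: int = 2,
    lengths: Sequence[int] = (120_000, 80_000),
    loci_spec: Sequence[Locus] = (),
) -> tuple[ReferenceGenome, list[Locus]]:
    """Build a random genome and plant the requested loci verbatim.

    Repeat loci (non-empty ``motif``) are written as perfect tandem repeats at
    their coordinates; other loci only reserve their interval.  Requests that
    fall outside a chromosome or overlap each other are rejected with the
    offending loci named.  Same seed, same requests -> byte-identical genome.
    """
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have n_chrom entries")
    if any(L <= 0 for L in lengths):
        raise ValueError("chromosome lengths must be positive")

    names = [f"chr{_roman(i + 1)}" for i in range(n_chrom)]
    sizes = dict(zip(names, lengths))

    by_chrom: dict[str, list[Locus]] = {n: [] for n in names}
    for loc in loci_spec:
        if loc.chrom not in sizes:
            raise LocusError(f"locus {loc.locus_id}: unknown chromosome {loc.chrom}")
        if loc.end > sizes[loc.chrom]:
            raise LocusError(
                f"locus {loc.locus_id}: [{loc.start}, {loc.end}) exceeds "
                f"{loc.chrom} length {sizes[loc.chrom]}"
            )
        by_chrom[loc.chrom].append(loc)
    for chrom, locs in by_chrom.items():
        locs.sort(key=lambda l: l.start)
        for a, b in zip(locs, locs[1:]):
            if b.start < a.end:
                raise LocusError(
                    f"loci {a.locus_id} and {b.locus_id} overlap on {chrom}: "
                    f"[{a.start},{a.end}) vs [{b.start},{b.end})"
                )

    rng = np.random.default_rng(params.seed)
    chroms: dict[str, str] = {}
    for name in names:
        arr = rng.integers(0, 4, size=sizes[name])
        seq = np.array(list(DNA_ALPHABET))[arr]
        for loc in by_chrom[name]:
            if loc.motif:
                planted = (loc.motif * loc.unit_count) if loc.unit_count else loc.motif
                if len(planted) != loc.end - loc.start:
                    planted = (loc.motif * ((loc.end - loc.start) // len(loc.motif) + 1))[
                        : loc.end - loc.start
                    ]
                seq[loc.start : loc.end] = list(planted)
        chroms[name] = "".join(seq)
    return ReferenceGenome(chroms), list(loci_spec)


def _roman(n: int) -> str:
    numerals = [(10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for val, sym in numerals:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

def simulate_library(
    genome: ReferenceGenome,
    loci: Sequence[Locus],
    params: SimParams,
    dsodn: str,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate a single-end FASTQ library with dsODN-tagged reads and spikes.

    Returns ``(reads, truth)`` where ``reads`` is a list of (read_id,
    sequence) and ``truth`` a DataFrame with one row per read recording the
    origin coordinates, tag presence/orientation and planted mutation, if any.

    Read model:

    * spiked mutant reads (exact counts from ``params.spike_table``) are
      untagged reads spanning their locus with one planted mutation;
    * a ``tag_fraction_at_cuts`` fraction of the remainder carries the dsODN
      embedded at the junction of an ``on_target`` cut locus, in either
      orientation with equal probability;
    * a ``background_tag_fraction`` fraction carries the tag at a random
      position inside a ``hot_background`` locus (break-prone regions such as
      rDNA, unlinked to the nuclease);
    * all other reads are uniform exact genome substrings.

    Sequencing errors are applied per base at ``seq_error_rate`` to
    non-spiked reads; spiked reads are left intact so planted mutant counts
    stay exact.
    """
    if not dsodn:
        raise ValueError("dsodn must be non-empty")
    if len(dsodn) >= params.read_length:
        raise ValueError("dsodn must be shorter than read_length")

    locus_by_id = {l.locus_id: l for l in loci}
    for spike in params.spike_table:
        if spike.locus_id not in locus_by_id:
            raise LocusError(f"spike targets unknown locus {spike.locus_id!r}")

    cut_loci = [l for l in loci if l.class_label == "on_target"]
    hot_loci = [l for l in loci if l.class_label == "hot_background"]

    rng = np.random.default_rng(params.seed)
    chrom_names = list(genome.chromosomes)
    chrom_lengths = np.array([len(genome[c]) for c in chrom_names], dtype=float)
    chrom_weights = chrom_lengths / chrom_lengths.sum()
    L = params.read_length

    reads: list[tuple[str, str]] = []
    truth_rows: list[tuple] = []
    idx = 0

    def add(seq: str, chrom: str, start: int, tagged: bool, orient: str,
            spike_id: str, mclass: str) -> None:
        nonlocal idx
        rid = f"read{idx:07d}"
        reads.append((rid, seq))
        truth_rows.append((rid, chrom, start, tagged, orient, spike_id, mclass))
        idx += 1

    # --- spiked mutant reads: planted exactly ---
    for si, spike in enumerate(params.spike_table):
        loc = locus_by_id[spike.locus_id]
        ref = genome[loc.chrom]
        mid = (loc.start + loc.end) // 2
        for k in range(spike.mutant_read_count):
            # stagger read starts so spiked reads are not PCR-duplicate-like
            jitter = (7 * k) % max(1, L // 2 - 20)
            start = mid - L // 2 + jitter - (L // 4 - 10)
            start = max(0, min(start, len(ref) - L))
            start = max(mid - L + 6, min(start, mid - 5))  # mutation well inside the read
            seq, mclass = _apply_mutation(ref, start, L, loc, spike.mutation_class, rng)
            add(seq, loc.chrom, start, False, "none", f"{spike.locus_id}:{si}", mclass)

    n_spiked = idx
    n_rest = params.n_reads - n_spiked
    if n_rest < 0:
        raise ValueError("spike_table plants more reads than n_reads")

    # --- tagged and background reads ---
    u = rng.random(n_rest)
    p_cut = params.tag_fraction_at_cuts if cut_loci else 0.0
    p_hot = params.background_tag_fraction if hot_loci else 0.0
    for i in range(n_rest):
        if u[i] < p_cut:
            loc = cut_loci[rng.integers(len(cut_loci))]
            seq, chrom, start, orient = _tagged_read(genome, loc, (loc.start + loc.end) // 2,
                                                     dsodn, L, rng)
            seq = _seq_errors(seq, params.seq_error_rate, rng)
            add(seq, chrom, start, True, orient, "", "")
        elif u[i] < p_cut + p_hot:
            loc = hot_loci[rng.integers(len(hot_loci))]
            junction = int(rng.integers(loc.start, loc.end))
            seq, chrom, start, orient = _tagged_read(genome, loc, junction, dsodn, L, rng)
            seq = _seq_errors(seq, params.seq_error_rate, rng)
            add(seq, chrom, start, True, orient, "", "")
        else:
            ci = rng.choice(len(chrom_names), p=chrom_weights)
            chrom = chrom_names[ci]
            ref = genome[chrom]
            start = int(rng.integers(0, max(1, len(ref) - L + 1)))
            seq = _seq_errors(ref[start : start + L], params.seq_error_rate, rng)
            add(seq, chrom, start, False, "none", "", "")

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth


def _tagged_read(genome: ReferenceGenome, loc: Locus, junction: int, dsodn: str,
                 L: int, rng: np.random.Generator) -> tuple[str, str, int, str]:
    """Genomic segment with the dsODN embedded at ``junction``; the genomic
    part keeps total read length at L."""
    ref = genome[loc.chrom]
    tag = dsodn if rng.random() < 0.5 else revcomp(dsodn)
    orient = "forward" if tag == dsodn else "reverse"
    left_len = int(rng.integers(20, L - len(dsodn) - 19))
    right_len = L - len(dsodn) - left_len
    start = max(0, junction - left_len)
    left = ref[start : start + left_len]
    right = ref[junction : junction + right_len]
    seq = (left + tag + right)[:L]
    if len(seq) < L:  # chromosome edge: pad from the reference downstream
        seq = (seq + ref[junction + right_len : junction + right_len + L])[:L]
    return seq, loc.chrom, start, orient


def _apply_mutation(ref: str, start: int, L: int, loc: Locus, mclass: str,
                    rng: np.random.Generator) -> tuple[str, str]:
    """Copy ref[start:start+L] and plant one mutation of ``mclass`` inside
    the locus interval. The mutation site is the locus midpoint so every
    spiked read at a locus carries the same variant (one mutant molecule
    amplified into several reads)."""
    pos = (loc.start + loc.end) // 2  # genomic coordinate of the mutation
    off = pos - start
    if not 5 <= off < L - 5:
        raise LocusError(f"spiked read at {loc.locus_id} does not span the mutation site")
    if mclass == "point":
        refbase = ref[start + off]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[refbase]
        seq = ref[start : start + L]
        return seq[:off] + alt + seq[off + 1 :], mclass
    if mclass == "insertion_1nt":
        seq = ref[start : start + L - 1]
        base = loc.motif[0] if loc.motif else "A"
        return seq[:off] + base + seq[off:], mclass
    if mclass == "deletion_triplet_multiple":
        if not loc.motif or len(loc.motif) != 3:
            raise LocusError(f"triplet deletion spike requires a trinucleotide locus, got {loc.locus_id}")
        # delete one full unit, aligned to the repeat register
        unit_off = loc.start + ((pos - loc.start) // 3) * 3 - start
        seq = ref[start : start + L + 3]
        return (seq[:unit_off] + seq[unit_off + 3 :])[:L], mclass
    if mclass == "other_indel":
        seq = ref[start : start + L + 2]
        return (seq[:off] + seq[off + 2 :])[:L], mclass
    raise ValueError(f"unknown mutation class {mclass!r}")


def _seq_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if not hit.any():
        return seq
    codes = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)
    for i in np.nonzero(hit)[0]:
        choices = codes[codes != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def write_fastq(reads: Iterable[tuple[str, str]], path: str, quality_char: str = "I") -> int:
    """Write (read_id, seq) pairs as 4-line Phred+33 FASTQ with constant
    quality. Returns the number of records written."""
    n = 0
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


def simulate_error_only_site_counts(
    n_sites: int,
    mean_covering: float,
    per_read_mutant_prob: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-site (mutant, covering) read counts under a sequencing-error-only
    model: covering depth ~ Poisson(mean_covering), mutant reads ~
    Binomial(covering, per_read_mutant_prob).  This is the shared null used
    to check the false-positive behaviour of the site-level Fisher test when
    library and control contain no real mutations."""
    rng = np.random.default_rng(seed)
    covering = rng.poisson(mean_covering, n_sites)
    covering = np.maximum(covering, 1)
    mutant = rng.binomial(covering, per_read_mutant_prob)
    return pd.DataFrame(
        {"site_id": [f"site{i:04d}" for i in range(n_sites)],
         "mutant": mutant, "covering": covering}
    )


# ---------------------------------------------------------------------------
# qPCR resection and flow-cytometry simulators
# ---------------------------------------------------------------------------

def simulate_resection_ct(
    true_resected_fraction: float,
    dsb_fraction: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    ct_mock_baseline: float = 20.0,
) -> tuple[float, float]:
    """Generate a (Ct_StyI, Ct_mock) pair whose noiseless ΔCt inverts the
    restriction-protection estimator back to ``true_resected_fraction``.

    The protected (resected) fraction r relates to the cycle-threshold shift
    as r = 2 / (1 + 2^ΔCt); this simulator solves for ΔCt at
    r = true_resected_fraction * dsb_fraction and adds independent Gaussian
    noise of ``noise_sd`` cycles to each Ct.
    """
    if not 0.0 < true_resected_fraction <= 1.0:
        raise ValueError("true_resected_fraction must be in (0, 1]")
    if not 0.0 < dsb_fraction <= 1.0:
        raise ValueError("dsb_fraction must be in (0, 1]")
    raw = true_resected_fraction * dsb_fraction
    delta_ct = math.log2(2.0 / raw - 1.0)
    rng = np.random.default_rng(seed)
    ct_mock = ct_mock_baseline + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    ct_styi = ct_mock_baseline + delta_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    return ct_styi, ct_mock


def simulate_flow_events(
    n_events: int,
    positive_fraction: float,
    separation_log10: float = 1.5,
    seed: int | None = None,
    negative_mode_log10: float = 2.0,
    mode_sd_log10: float = 0.25,
) -> pd.DataFrame:
    """Simulate a flow-cytometry event table with two log-normal fluorescence
    modes separated by ``separation_log10`` decades (GFP- and GFP+ cells).

    Returns a DataFrame with columns event_id, log10_fluorescence, fsc, ssc
    and the truth label ``is_positive``.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must be in [0, 1]")
    if separation_log10 <= 0:
        raise ValueError("separation_log10 must be > 0")
    rng = np.random.default_rng(seed)
    labels = rng.random(n_events) < positive_fraction
    means = np.where(labels, negative_mode_log10 + separation_log10, negative_mode_log10)
    fluo = rng.normal(means, mode_sd_log10)
    fsc = rng.normal(5.0, 0.3, n_events)
    ssc = rng.normal(4.5, 0.3, n_events)
    return pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "log10_fluorescence": fluo,
            "fsc": fsc,
            "ssc": ssc,
            "is_positive": labels,
        }
    )
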