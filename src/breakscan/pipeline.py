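"""End-to-end pipeline orchestration.

One configuration object drives the full chain
simulate -> tag split -> map/coverage/peaks -> site scan -> pileup ->
filter -> colony-normalized Fisher, writing every intermediate artifact and
a machine-readable manifest (parameters echoed verbatim, per-stage row
counts, output checksums) into the output directory.

:func:`demo_config` encodes the bundled demonstration experiment: a 200-kb
two-chromosome genome carrying a (CTG)20 cut cassette, CTG and GAA
off-target microsatellites with planted rare mutations, a break-prone
background locus, a ~2% dsODN-tagged read population, and a no-spike
control library with its own colony count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any

import yaml

from . import DSODN_SEQUENCE, __version__
from . import mapcov, mutcall, readprep, sitefinder, simdata

# guide protospacers are the 20-nt suffix of a repeat run read in register,
# so a perfect repeat locus followed by an NGG PAM is a 0-mismatch site
CTG_PROTOSPACER = ("CTG" * 8)[-20:]
GAA_PROTOSPACER = ("GAA" * 8)[-20:]


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 1
    dsodn: str = DSODN_SEQUENCE
    genome_lengths: tuple[int, ...] = (120_000, 80_000)
    loci: list[simdata.Locus] = field(default_factory=list)
    guides: list[sitefinder.GuideSpec] = field(default_factory=list)
    n_reads: int = 40_000
    read_length: int = 150
    tag_fraction_at_cuts: float = 0.016
    background_tag_fraction: float = 0.003
    seq_error_rate: float = 0.0
    cfu: int = 1200
    spikes: list[simdata.Spike] = field(default_factory=list)
    ctrl_n_reads: int = 36_000
    ctrl_cfu: int = 900
    peak_min_floor: int = 5
    peak_min_width: int = 1
    min_mutant_reads: int = 2
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if "loci" in raw:
            raw["loci"] = [simdata.Locus(**l) for l in raw["loci"]]
        if "guides" in raw:
            raw["guides"] = [sitefinder.GuideSpec(**g) for g in raw["guides"]]
        if "spikes" in raw:
            raw["spikes"] = [simdata.Spike(**s) for s in raw["spikes"]]
        if "genome_lengths" in raw:
            raw["genome_lengths"] = tuple(raw["genome_lengths"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def echo(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["genome_lengths"] = list(d["genome_lengths"])
        return d


def demo_config(seed: int = 1) -> RunConfig:
    """The bundled demonstration experiment (see module docstring).

    Spiked truth: a CTG off-target with 8 triplet-deletion reads and a GAA
    off-target with 6 point-mutation reads (both significant against the
    control), a 2-read insertion site (passes the read filter, not
    significant) and a 1-read site (removed by the filter).
    """
    loci = [
        simdata.Locus("cassette", "chrI", 50_000, 50_060, "+", "on_target", "CTG", 20),
        simdata.Locus("pam_cassette", "chrI", 50_060, 50_063, "+", "microsatellite", "TGG", 1),
        simdata.Locus("ot_ctg_del", "chrI", 20_000, 20_036, "+", "off_target_candidate", "CTG", 12),
        simdata.Locus("pam_ctg_del", "chrI", 20_036, 20_039, "+", "microsatellite", "TGG", 1),
        simdata.Locus("ot_ctg_1read", "chrI", 80_000, 80_030, "+", "off_target_candidate", "CTG", 10),
        simdata.Locus("pam_ctg_1read", "chrI", 80_030, 80_033, "+", "microsatellite", "TGG", 1),
        simdata.Locus("ot_gaa_point", "chrII", 10_000, 10_030, "+", "off_target_candidate", "GAA", 10),
        simdata.Locus("pam_gaa_point", "chrII", 10_030, 10_033, "+", "microsatellite", "TGG", 1),
        simdata.Locus("ot_gaa_ins", "chrII", 60_000, 60_030, "+", "off_target_candidate", "GAA", 10),
        simdata.Locus("pam_gaa_ins", "chrII", 60_030, 60_033, "+", "microsatellite", "TGG", 1),
        simdata.Locus("hot_rdna", "chrII", 30_000, 39_000, "+", "hot_background", "", 0),
    ]
    guides = [
        sitefinder.GuideSpec(CTG_PROTOSPACER, "NGG", "three_prime", 4),
        sitefinder.GuideSpec(GAA_PROTOSPACER, "NGG", "three_prime", 4),
    ]
    spikes = [
        simdata.Spike("ot_ctg_del", "deletion_triplet_multiple", 8),
        simdata.Spike("ot_gaa_point", "point", 6),
        simdata.Spike("ot_gaa_ins", "insertion_1nt", 2),
        simdata.Spike("ot_ctg_1read", "point", 1),
    ]
    return RunConfig(seed=seed, loci=loci, guides=guides, spikes=spikes)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str) -> dict[str, Any]:
    """Execute all stages and return the manifest (also written to
    ``manifest.json`` in ``outdir``).  Any stage failure propagates with
    partial outputs left in place."""
    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    manifest: dict[str, Any] = {
        "tool": "breakscan",
        "version": __version__,
        "config": config.echo(),
        "stages": {},
        "checksums": {},
    }

    # --- simulate ---
    params = simdata.SimParams(
        seed=config.seed, n_reads=config.n_reads, read_length=config.read_length,
        tag_fraction_at_cuts=config.tag_fraction_at_cuts,
        background_tag_fraction=config.background_tag_fraction,
        seq_error_rate=config.seq_error_rate,
        spike_table=tuple(config.spikes), cfu=config.cfu,
    )
    genome, loci = simdata.make_genome(
        params, n_chrom=len(config.genome_lengths),
        lengths=config.genome_lengths, loci_spec=config.loci,
    )
    genome.to_fasta(p("genome.fa"))
    simdata.write_locus_table(loci, p("loci.tsv"))
    reads, truth = simdata.simulate_library(genome, loci, params, config.dsodn)
    simdata.write_fastq(reads, p("library.fastq"))
    truth.to_csv(p("truth.tsv"), sep="\t", index=False)
    ctrl_params = dataclasses.replace(
        params, seed=config.seed + 1, n_reads=config.ctrl_n_reads,
        spike_table=(), cfu=config.ctrl_cfu,
    )
    ctrl_reads, ctrl_truth = simdata.simulate_library(genome, loci, ctrl_params, config.dsodn)
    simdata.write_fastq(ctrl_reads, p("control.fastq"))
    manifest["stages"]["simulate"] = {
        "n_reads": len(reads), "n_ctrl_reads": len(ctrl_reads), "n_loci": len(loci),
    }

    # --- tag split ---
    split = readprep.split_fastq(p("library.fastq"), config.dsodn,
                                 p("tagged.fastq"), p("untagged.fastq"))
    ctrl_split = readprep.split_fastq(p("control.fastq"), config.dsodn,
                                      p("ctrl_tagged.fastq"), p("ctrl_untagged.fastq"))
    with open(p("tagsplit.json"), "w") as fh:
        fh.write(split.to_json())
    manifest["stages"]["tagsplit"] = {
        "n_total": split.n_total, "n_tagged": split.n_tagged,
        "tagged_percent": readprep.tagged_percentage(split.n_tagged, split.n_total),
        "ctrl_n_tagged": ctrl_split.n_tagged,
    }

    # --- map / coverage / peaks (tagged reads locate integration sites) ---
    index = mapcov.GenomeIndex(genome)
    tagged_reads = [(rid, seq) for rid, seq, _ in readprep.iter_fastq(p("tagged.fastq"))]
    tagged_aln = mapcov.map_reads(tagged_reads, genome, index)
    track = mapcov.compute_coverage(tagged_aln, genome)
    peaks = mapcov.annotate_peaks(
        mapcov.call_peaks(track, config.peak_min_floor, config.peak_min_width), loci
    )
    mapcov.write_peaks_bed(peaks, p("peaks.bed"))
    manifest["stages"]["peaks"] = {
        "median_tagged_depth": track.median_depth,
        "n_peaks": len(peaks),
        "top_peak_labels": list(max(peaks, key=lambda q: q.max_depth).labels) if peaks else [],
    }

    # --- candidate sites ---
    sites: list[sitefinder.OffTargetSite] = []
    for guide in config.guides:
        sites.extend(sitefinder.scan_offtargets(genome, guide))
    # dedupe identical intervals found by several guides
    seen = set()
    sites = [s for s in sites if (key := (s.chrom, s.start, s.end, s.strand)) not in seen
             and not seen.add(key)]
    sitefinder.write_sites_bed(sites, p("sites.bed"))
    manifest["stages"]["sites"] = {"n_sites": len(sites)}

    # --- pileup on the untagged partitions ---
    untagged = [(rid, seq) for rid, seq, _ in readprep.iter_fastq(p("untagged.fastq"))]
    lib_aln = mapcov.map_reads(untagged, genome, index)
    lib_counts = mutcall.pileup_variants(lib_aln, genome, sites, truth=truth)
    ctrl_untagged = [(rid, seq) for rid, seq, _ in readprep.iter_fastq(p("ctrl_untagged.fastq"))]
    ctrl_aln = mapcov.map_reads(ctrl_untagged, genome, index)
    ctrl_counts = mutcall.pileup_variants(ctrl_aln, genome, sites)

    kept, n_discarded = mutcall.filter_min_mutant_reads(lib_counts, config.min_mutant_reads)
    kept_ids = {c.site_id for c in kept}
    ctrl_by_id = {c.site_id: c for c in ctrl_counts}
    manifest["stages"]["pileup"] = {
        "n_sites_with_mutant_reads": sum(1 for c in lib_counts if c.n_mutant_reads > 0),
        "n_discarded_single_read": n_discarded,
        "n_tested": len(kept),
    }

    # --- colony-normalized Fisher vs control ---
    lib_stats = mutcall.compute_library_stats(
        n_reads=config.n_reads, read_length=config.read_length,
        genome_length=genome.total_length, cfu=config.cfu, library_id="library",
    )
    ctrl_stats = mutcall.compute_library_stats(
        n_reads=config.ctrl_n_reads, read_length=config.read_length,
        genome_length=genome.total_length, cfu=config.ctrl_cfu, library_id="control",
    )
    results = mutcall.fisher_many(
        [(c, ctrl_by_id[c.site_id]) for c in kept], lib_stats, ctrl_stats, config.alpha
    )
    frame = mutcall.results_frame(results)
    frame.to_csv(p("fisher.tsv"), sep="\t", index=False)
    _write_variant_report(kept, p("variants.tsv"))
    manifest["stages"]["fisher"] = {
        "n_tested": len(results),
        "n_significant": int(sum(r.significant for r in results)),
        "significant_sites": [r.site_id for r in results if r.significant],
        "mutation_classes": {
            c.site_id: dict(c.class_tally) for c in kept if c.site_id in kept_ids
        },
    }

    for name in sorted(os.listdir(outdir)):
        if name != "manifest.json":
            manifest["checksums"][name] = _sha256(p(name))
    with open(p("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_variant_report(counts, path: str) -> None:
    """Per-position variant table (1-based positions, REF/ALT columns)."""
    with open(path, "w") as fh:
        fh.write("site\tchrom\tpos\tref\talt\tcount\tcovering\n")
        for c in counts:
            for pos in c.positions:
                for alt, n in sorted(pos.alt_counts.items()):
                    fh.write(
                        f"{c.site_id}\t{pos.chrom}\t{pos.pos + 1}\t{pos.ref_base}\t"
                        f"{alt}\t{n}\t{pos.total_covering}\n"
                    )
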