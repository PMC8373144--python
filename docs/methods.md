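# Methods

This note records the models implemented in `breakscan`, the parameter
choices that matter, what the synthetic data does and does not emulate, and
the numerical conventions. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic data (`simdata`)

The generator emulates a GUIDE-seq-style experiment in budding yeast:
single-end 150-nt reads covering a small genome approximately uniformly,
with a minority subpopulation carrying an integrated 34-nt dsODN tag, and a
handful of mutant reads planted at repeat loci.

* **Genome.** Default two chromosomes totalling 200 kb of i.i.d. uniform
  ACGT with requested loci planted verbatim — large enough for a
  meaningful median-coverage baseline and a realistic unique-31-mer
  landscape, small enough for seconds-scale runs. Loci that overlap or
  exceed chromosome bounds are rejected, naming the offenders.
* **Tagged reads.** A read is tag-carrying with probability
  `tag_fraction_at_cuts` (default 0.016, origin at an `on_target` cut
  locus, tag embedded at the cut junction) or `background_tag_fraction`
  (default 0.003, origin inside a `hot_background` locus modelling
  break-prone regions such as rDNA and mitochondrial DNA, where tag capture
  is unlinked to the nuclease). The defaults sum to ~1.9% tagged reads, the
  fraction observed in the emulated experiment. Both tag orientations are
  equally likely; orientation bias is a parameter, not an assumption,
  because the underlying capture chemistry does not fix it. The 5'-P and
  phosphorothioate marks on the physical dsODN are sequence-irrelevant and
  dropped.
* **Spiked mutations.** Planted *exactly* (not sampled): each spike row
  produces precisely its configured number of untagged reads carrying one
  mutation at the locus midpoint, staggered in start position. All spiked
  reads at a locus carry the same variant, emulating one mutant molecule
  amplified into several reads. Spiked reads receive no additional
  sequencing errors so the truth table stays an exact oracle.
* **Errors.** Uniform per-base substitution at `seq_error_rate`
  (default 0 in the demo; the error model is exercised separately).
* **Not modelled** (known limitations): PCR duplicates (the real protocol
  used three PCR rounds), paired ends, quality-score variation, indel
  sequencing errors, coverage bias from library prep. Passing tests on
  this generator therefore demonstrate the pipeline's logic and its
  statistical calibration under idealized noise, not performance on real
  libraries.
* The resection-Ct simulator inverts `raw = 2/(1+2^ΔCt)` at
  `raw = fraction × dsb_fraction` and adds Gaussian cycle noise; the flow
  simulator draws two Gaussian log10-fluorescence modes (negative mode at
  2.0 decades, sd 0.25) separated by `separation_log10` (default 1.5, the
  middle of the observed one-to-two-decade separation).

## Tag splitting (`readprep`)

Exact substring containment of the full tag, searched in both orientations
(amplification primes off both dsODN ends; `forward_only` restores literal
one-orientation grep behaviour). The tag sequence is always an explicit
parameter. No trimming by default — the mapper tolerates the tag as a
soft-clipped segment; `trim_tag` removes the tag and everything on its
primer side. The tagged-read percentage uses half-up rounding to one
decimal, matching how such values are printed.

## Mapping, coverage, peaks (`mapcov`)

The built-in mapper is intentionally minimal: the first exact 31-mer of the
read that occurs uniquely in the genome places it (forward strand first,
then reverse complement); an ungapped ±1 scoring pass along that diagonal
keeps the best-scoring window and soft-clips the flanks. No secondary
alignments, no gapped alignment, no mapping-quality model. Indel-carrying
reads map with one side clipped; variant extraction downstream does not
rely on mapper CIGARs (see below). External aligners plug in through SAM
(secondary/supplementary records are dropped on read).

Coverage counts each alignment once at every reference position it spans;
deletions inside a read count as covered (the read evidence spans them),
insertions contribute nothing — standard pileup-engine depth semantics.
The median is taken over every reference position, zeros included.

Peaks are maximal runs of depth ≥ `max(2 × median, min_floor)`. The floor
(default 5) exists because sparse toy tracks have median 0, where twice the
median degenerates to 0 and would call the whole genome; at realistic depth
the twice-median rule is binding and the floor is inert. Interval
conventions are 0-based half-open everywhere internally; a peak touching a
locus boundary does not overlap it.

## Candidate sites and repeat scanning (`sitefinder`)

Off-target candidates are all windows, both strands, whose PAM matches an
IUPAC pattern and whose protospacer-aligned sequence is within
`max_mismatches` (default 4) substitutions of the guide. Substitutions
only, no bulges — the standard candidate definition at this scale.
`pam_side` is an explicit parameter (three-prime for Cas9-type NGG/NNGRRT,
five-prime for Cas12a-type TTN) and is never inferred, because textual
conventions for the Cas12a PAM side conflict. Mismatch positions are
numbered 1-based from the PAM-distal end.

Microsatellite classes are closed under rotation and reverse complement —
CAG and CTG name the same class — via a canonical key (the
lexicographically smallest rotation over both strands; CAG/CTG ↦ `AGC`).
A locus is a maximal perfect period-|motif| run trimmed to complete units;
interrupted repeats are excluded. `min_units` defaults to 8 for
trinucleotides — an explicit, deliberately conservative choice exposed as
a flag, since published census definitions vary; the package makes no
attempt to reproduce any particular census by scanning.

## Rare-variant calling and the Fisher test (`mutcall`)

Every untagged read overlapping a candidate site is realigned to the local
reference window with edlib and its extended CIGAR parsed, so
substitutions and indels are recovered uniformly regardless of how the
upstream aligner expressed them. A read is counted at most once per site.
Because optimal alignments of repeat-unit deletions are degenerate, two
normalizations are applied: (1) a variant belongs to a site if *any*
equivalent placement of it (its ambiguity interval) overlaps the site;
(2) read classification aggregates fragmented deletions and asks whether
they are jointly equivalent to removing one contiguous block that is a
positive multiple of 3 long inside a period-3 run (`deletion_triplet_multiple`);
single-base substitutions are `point`, 1-nt insertions `insertion_1nt`,
everything else `other_indel`. The manual inspect-and-validate step of the
original protocol is replaced by two optional automatable proxies
(minimum base quality; both off by default).

Sites with fewer than two mutant reads are discarded before testing —
single-read positions are indistinguishable from amplified sequencing
error. The Fisher construction: mutant vs non-mutant covering reads,
library vs control, with the library column scaled by
`f = (mean coverage/CFU)_ctrl / (mean coverage/CFU)_lib` — the reading of
"mean coverage per colony normalizes read number" in which colonies are
the replication unit. Both margins are scaled by default (single-margin
scaling is a flag); scaled counts are rounded half-away-from-zero because
the exact test needs integers; raw and normalized tables are both kept for
audit. Significance is flagged on the raw p at α = 0.05 to mirror the
original 14-test setting; BH-adjusted values are always reported
alongside. Sites with zero covering reads in the library are reported
untestable rather than dropped silently. Both position-level and
site(gene)-level readings of the aggregation are available since the
counts are kept per position and per site.

## Resection (`resection`)

`raw = 2/(1+2^ΔCt)` with ΔCt from replicate-mean Ct values (replicates are
averaged *before* differencing). Values above 1 are mathematically
possible (negative ΔCt) but biologically impossible and are returned with
a warning. The DSB denominator of relative resection is consumed as a
fraction in (0, 1]; tables carrying percent divide by 100 at the interface,
with the unit declared in the header — this guards against the silent
100-fold error the percent wording invites. The internal-control amplicon
is accepted as an optional QC column only and never enters the formula.
The two-sided ratio is normalized to the non-repeated control, whose own
ratio is exactly 1 by construction.

## Efficacy statistics (`efficacy`)

Lane percentages are `100 × (band − background)/Σ(bands − background)`
with a single per-lane background scalar (the original description does
not specify a shape) and negative corrected bands clipped to zero with a
warning. GFP gating places the threshold at the KDE density minimum
between the two highest modes, requiring each mode to reach ≥ 10% of the
maximum density and the valley to dip below 80% of the smaller mode;
otherwise the data are treated as unimodal and a fixed threshold
(default 3.0 log10 units, above the negative mode) is used. Cumulative
DSB over a time course is the plain sum of per-timepoint percentages
("total signal accumulated"); a trapezoidal time-integral is provided for
sensitivity analysis. Regression is ordinary least squares with the
two-sided slope p; the energy ANOVA is classical one-way, with the default
grouping of a continuous ΔG predictor being tertiles (plus an
"unstructured" group), since per-repeat groups would be degenerate at
n = 1 — the grouping rule travels with the output.

## Guide folding (`rnafold`)

A Zuker-style dynamic program over pseudoknot-free structures:
Watson–Crick and GU pairs, hairpin loops ≥ 3 nt, nearest-neighbor stack
energies, linear hairpin/interior penalties, affine multiloops, interior
loops capped at 20 unpaired nt. Temperature enters through
ΔG(T) = ΔH − T·ΔS per stack (ΔH approximated as 3.4 × ΔG37; loop
penalties temperature-independent); default 30 °C, the assay growth
temperature. The parameter set is reduced (ten WC stack values plus flat
GU terms, recorded in the source) and is *not* expected to reproduce any
external engine's kcal values — conclusions drawn from it are rank-level,
and an external engine can be substituted via the `backend` hook
(an adapter for the ViennaRNA CLI is included). One consequence of the
reduced set: isolated base pairs gain no stacking energy, so CNG-repeat
hairpins (stabilized in fuller models by non-canonical pairs and
single-pair stems) fold to "no structure" here; purine-only and
pyrimidine-only guides are unconditionally unstructured, which is exact.

Energies are integers in 1/100 kcal/mol internally, making co-optimality
exact; among co-optimal structures the lexicographically smallest
dot-bracket is returned, implemented by running the DP over
(energy, structure) tuples — correct because sub-structures occupy fixed
substrings, so tuple-minimality composes. `structure_energy` scores an
explicit pair set with the same tables and is what the enumeration tests
use as the independent scorer. Stability classes: ΔG < −4 kcal/mol is
"stable" (strict inequality at the boundary), no negative-energy
structure is "unstructured", else "unstable".

## Demo experiment and problem sizes

The bundled demo uses a 200-kb genome, 40 000 library reads and 36 000
control reads (30× and 27× coverage; CFU 1200 vs 900, so the
normalization factor is a non-trivial 1.2), chosen to keep a full run in
seconds while leaving every statistical decision non-degenerate. The
spiked significant sites carry 8 and 6 mutant reads: against a clean
control at these depths the two-sided Fisher p is ~0.01–0.03, comfortably
significant, whereas 5 mutant reads at equal 100× depth would sit at
p ≈ 0.06 — below-threshold spikes (2 reads) and filter fodder (1 read)
are planted to exercise both rejection paths. Acceptance-level
calibration uses 1000 simulated null sites at mean depth 100 and per-read
mutant probability 0.004 (≈ 20 nt × 2×10⁻⁴ per-base error).

## Determinism

Every generator consumes a `numpy` `default_rng` seeded from the
configuration; the pipeline derives its control-library seed as
`seed + 1`. Reruns with the same configuration produce byte-identical
outputs (checked via manifest checksums).
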