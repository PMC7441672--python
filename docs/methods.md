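# Methods

This note documents the models implemented in `ocpmd`, the defaults and why
they were chosen, what the simulators do and do not emulate, and the
numerical choices that matter. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The forged gene and the retention junction

`synthetic.forge_gene_model` builds a TNNT1-like gene: 15 exons summing to
a 1001-nt cDNA, a 263-residue protein (CDS = 3×264 nt including the stop)
translated from exon 2 through exon 14, all introns opening GT and closing
AG, and intron 13 (810 nt) designated for retention. Exon lengths are laid
out automatically: pure-UTR exons get a fixed length (50 nt; 51 nt for
trailing 3′UTR exons), the ATG sits 10 nt into its exon, and coding exons
are split evenly subject to one pin: the CDS coordinate of the retained
intron's donor.

That pin defaults to **614**, so the planted deletion of the donor +1 G is
named `c.614+1delG` by the consequence module. A note on an internal
tension this resolves: a donor after CDS position 614 of a 792-nt CDS puts
the junction inside codon 205, so a retained intron contributing 12 novel
sense codons yields a 216-residue mutant protein. The alternative
accounting — wild-type 263 aa, mutant 261 aa, a shared 249-residue body,
the terminal 14 residues (encoded by the last coding exon) replaced by 12
intron-encoded residues — requires the junction on the codon boundary at
c.747+1. Both descriptions circulate for this locus and cannot hold in a
single gene model, so the package supports both: the default configuration
pins the donor at c.614+1 (the coordinate used in the variant name), and
`GeneForgeConfig(donor_cds_position=747)` reproduces the 263/261/14/12 tail
arithmetic. The protein-report invariant
`mut_length = wt_length − replaced_tail + novel_tail` holds in every
configuration.

The retained intron is forged so that the *disease-allele* reading frame —
the intron minus its deleted +1 G — yields exactly `novel_aa_before_stop`
(default 12) sense codons and then TAA. A few codons at the junction are
fixed (the straddling or first downstream wild-type codon is set to AAA,
and the exonic base 5′ of the donor is kept non-G) so that (a) the first
post-junction mutant residue provably differs from wild-type, making the
novel tail fully attributable to the intron, and (b) the donor-G deletion
left-aligns to the canonical +1 position rather than into the exon.

Intron 13 is 810 nt in the wild-type allele; the retained intron in the
mutant transcript is therefore 809 nt. `model_intron_retention` defaults to
inserting the full intron (length arithmetic 1001 + 810 = 1811 nt, the
"~1.8 kb" RT-PCR product) and takes `donor_deletion=True` for the
one-base-shorter disease transcript used in protein prediction; both
constants are thereby exposed without asserting either as the unique truth.

## Cohort simulation

`simulate_cohort` mirrors the discovery design: 2 affected samples with
deep-coverage variant calls (per-sample VCFs), 4 affected and 8 unrelated
controls summarized as low-coverage pileups, and 2 carriers (emitted as
extra pileup samples, never used as controls by default). Background
variants are a Poisson process along the contig (default 0.1/kb on a 2-Mb
contig, i.e. ~200 variants) with a uniform(0.1, 0.9) population allele
frequency and Hardy–Weinberg genotypes independent of status — emulating
breed-vs-reference differences rather than pathogenic variation. Deep-call
annotations are DP ~ Poisson(50) and QD ~ Normal(30, 4); the planted
variant's DP and QD are redrawn until above the hard-filter thresholds,
making truth recovery a property of the cascade, not of quality-score luck.
Low-coverage depth is Poisson(5) per sample per locus — the simplest law
matching the nominal 5× coverage — with het read counts split
Binomial(depth, ½). Not emulated: read-level errors, mapping artefacts,
indel-realignment noise, linkage between background variants, and real
pedigree meiosis; passing tests therefore demonstrate the logic of the
cascade, not robustness to caller noise.

## SNP array and ROH

`simulate_snp_array` places markers every 20 kb (matching ~50k markers
genome-wide at ovine density) with uniform(0.2, 0.8) allele frequencies. A
single identical-by-descent haplotype spans a window of ±600 kb around the
causal locus: affected animals are homozygous for it, carriers carry it
plus a population haplotype, controls follow Hardy–Weinberg everywhere. A
marker is planted at the causal locus itself (at its left-aligned VCF
coordinate) so array zygosity and VCF genotypes agree by construction.

The ROH caller's run definition is a design choice (the original analysis
script is unpublished): maximal marker windows containing at most `max_het`
heterozygous calls, trimmed to homozygous endpoints, with overlapping
maximal windows resolved by greedy leftmost selection so per-individual
segments never overlap; segments must span ≥ `min_length_bp` (1 Mb) and
contain ≥ `min_snps` (20) non-missing markers. Missing calls neither break
a run nor count toward the marker minimum — array no-calls are noise, not
heterozygosity. `rank_regions` sweeps segment breakpoints and classifies
elementary intervals: covered by **all** affected and no carrier →
`affected_only`; by all affected and ≥1 carrier → `shared_with_carriers`
(ranked below); carrier-only → `excluded`. No claim is made of matching the
original script's exact segment boundaries.

## Prioritization cascade

Thresholds are strict inequalities (QD > 20, DP > 10); boundary values are
dropped. Records missing QD or DP are excluded and tallied, not raised.
Variant identity is (chrom, pos, ref, alt) after left-alignment;
multi-allelic sites are split into biallelics before filtering. The
low-coverage rule is evaluated at the locus position (not a surrounding
window), and refutation checks run before the coverage check, so a
confidently refuted variant is never reported as merely under-covered.
Severity uses a fixed four-class table (splice donor/acceptor >
stop-gain/frameshift > other coding > intronic/other) rather than an
external annotation service; ties break by position. The consequence term
set is a closed eight-term list with no UTR term; non-coding exonic
positions are deliberately coarse-grained into the lowest in-gene class.

## Contractility

Forces are normalized to the pCa 4.5 measurement, so the Hill model is
parameterized with a unit plateau and no baseline offset:
`F = 1/(1 + 10^(nH(pCa − pCa50)))`. Fits are per fibre by bounded
least squares (pCa50 ∈ [4.5, 7.5], nH ∈ [0.1, 10]; initialized at nH = 2
and the grid pCa nearest half-maximal force); group statistics are computed
over per-fibre estimates, with pooled-curve fitting available as an option
since the per-animal pooling of the original analysis is not stated.
Submaximal points derive in closed form,
`pCa_x = pCa50 + log10((1−x)/x)/nH`, and calcium concentrations are
reported in mM (`10^(−pCa) × 1000`). Group comparisons default to the
equal-variance two-tailed unpaired t-test, with Welch's correction behind a
flag; zero-variance degenerate groups return the limit values (t = 0,
p = 1 for equal means). Fibre CSA is the mean over three measurement points
of π·(width/2)·(depth/2).

The fibre simulator draws noise as truncated (≥0) Gaussian with σ = 0.02 of
maximal force, re-normalizes to the noisy pCa 4.5 point, and gives both
groups the same geometry and specific-force distributions (these did not
differ between genotypes). Generative parameters default to ten fibres per
group at pCa50 5.804 (wild-type) vs 6.056 (affected), nH 2.0, on the grid
{9.0, 6.4, 6.2, 6.0, 5.8, 5.6, 5.4, 5.2, 5.0, 4.5}.

## Problem sizes and numerical notes

Default problem sizes — 2-Mb contig, ~200 background variants, 100-odd
array markers, 10 fibres per group, 20-seed end-to-end recovery runs and
100-seed ROH recovery runs — were chosen as the smallest scales at which
each statistical property is comfortably resolved; a full cascade run takes
tens of milliseconds. All simulators consume a single integer seed through
`numpy.random.default_rng` and are bit-reproducible; the pipeline derives
per-stage seeds as fixed offsets of the master seed. In-silico PCR is
exact-substring matching (no mismatch or thermodynamic model) and reports
all products when a primer is ambiguous. Protein masses use average (not
monoisotopic) residue masses, matching gel-estimated kilodalton values.

## Known limitations

- No real genomes or annotation releases are consulted; accession-derived
  constants (e.g. the real TNNT1 terminal-14 basic-residue count and the
  31.4 kDa wild-type mass) are properties of the real sequences and are not
  asserted against forged fixtures, whose random codons have different
  composition.
- The variant caller itself, read alignment, linkage analysis and
  association testing are out of scope; the pipeline starts from VCFs and
  pileup summaries.
- HGVS naming implements only the donor-region deletion subset
  (`c.N+MdelX`) needed for this locus.
- Splice-strength scoring, cryptic-site discovery, exon skipping and NMD
  prediction are not modelled; the consequence module models retention
  only.
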