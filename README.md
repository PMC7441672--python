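# ocpmd

A disease-gene discovery and validation toolkit built around the genetics of
**ovine congenital progressive muscular dystrophy (OCPMD)** — a recessive
congenital myopathy of Merino sheep caused by a single-base deletion in the
essential splice donor site of intron 13 of *TNNT1*, the gene for slow
skeletal muscle troponin T. The package is aimed at researchers who want a
tested, reusable implementation of the four analysis stages of such a study,
plus a simulator that generates every input the stages consume, so the whole
chain can be exercised and validated without any external data:

1. **Homozygosity mapping** (`ocpmd.roh`) — runs of homozygosity (ROH) from
   SNP-array genotypes (PED/MAP), with carrier-aware ranking: regions
   homozygous in all affected and no carrier outrank regions shared with
   carriers; carrier-only regions are excluded.
2. **Variant prioritization** (`ocpmd.prioritize`) — the recessive filtering
   cascade: per-sample hard filtering of homozygous calls (QD > 20, DP > 10,
   strict), intersection across deep-sequenced affected animals, restriction
   to gene bodies, adjudication against low-coverage (~5×) read support
   (any alt read in a control, or any ref read in an additional affected,
   refutes; ≥75 % of each subset must be covered), and severity-ranked
   output.
3. **Splice consequence modelling** (`ocpmd.splice`) — variant
   classification (splice donor/acceptor ±1–2, stop-gain, frameshift,
   missense, …), intron-retention transcript construction, translation to
   the premature stop, C-terminal comparison with basic (K/R/H) and acidic
   (D/E) residue accounting and average protein masses, and exact-match
   in-silico RT-PCR.
4. **Contractility analysis** (`ocpmd.contractility`) — elliptical fibre
   cross-sectional area, force normalization to saturating calcium, Hill
   fits of force–pCa curves, and two-tailed unpaired t-tests between
   genotype groups.

The force–pCa relation is modelled as

```
F(pCa) = 1 / (1 + 10^(nH · (pCa − pCa50)))
```

with `pCa = −log10 [Ca²⁺]`; derived submaximal points follow in closed form,
`pCa_x = pCa50 + log10((1 − x)/x) / nH`.

The synthetic-data module (`ocpmd.synthetic`) forges a TNNT1-like gene
(15 exons, 1001-nt cDNA, 263-residue protein, translation from exon 2 to
exon 14, 810-nt intron 13, canonical GT/AG introns) with the causal donor
+1 G deletion planted homozygous in affected animals, an
identical-by-descent autozygous block around the locus, Hardy–Weinberg
background variation, Poisson low-coverage pileups, and Hill-model fibre
measurements — all bit-reproducible under a fixed seed.

## Worked example

Run the full discovery chain on a simulated cohort (2 affected at deep
coverage, 4 affected and 8 unrelated controls at ~5×, 2 carriers, ~200
background variants on a 2-Mb contig):

```bash
$ ocpmd discover --outdir demo --seed 1
top candidate: chr1:1001418 AG>A splice_donor_variant c.614+1delG (gene TNNT1L)
protein: wt 263 aa (29.6 kDa) -> mut 216 aa (24.1 kDa); novel tail 12 aa
```

The cascade recovers the planted donor deletion as the top-ranked candidate,
names it `c.614+1delG` from the gene model's CDS coordinates, and predicts
the intron-retention protein: the reading frame runs into the retained
(G-deleted) intron and terminates after 12 novel residues. Stage counts and
all intermediate files (FASTA, GFF3, VCFs, pileup TSV, PED/MAP, ROH BED,
candidate table, JSON report) are written to `demo/`.

Contractility on simulated fibres (10 per group, wild-type pCa50 5.804 vs
affected 6.056, nH 2.0, 2 % noise):

```python
>>> from ocpmd import RunConfig, run_contractility
>>> fits, cmp = run_contractility(RunConfig(seed=1))
>>> cmp[["metric", "mean_WT", "mean_AF", "t", "p"]]
    metric    mean_WT    mean_AF        t          p
     pCa50     5.7997     6.0590  -28.904  1.546e-16
   Ca50_mM  0.0015869 0.00087428   31.035  4.402e-17
        nH     1.9866     2.0339  -0.8557    0.40341
```

The affected group needs roughly half the free calcium of wild-type to reach
half-maximal force (0.00087 vs 0.00159 mM, p ≪ 10⁻⁴) while the Hill
coefficient and fibre geometry do not differ — a leftward shift of the
force–pCa curve, i.e. increased calcium sensitivity.

Individual verbs: `ocpmd simulate`, `ocpmd roh`, `ocpmd prioritize`,
`ocpmd consequence`, `ocpmd ispcr`, `ocpmd pca-fit`; all accept `--seed`
and most a YAML `--config` with per-module blocks.

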