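# ascna

Allele-specific somatic copy-number analysis for matched tumor/normal
sequencing: per-segment **beta** (the fraction of allelically neutral
reads), sample **ploidy** and **DNA admixture** (1 − purity),
**allele-specific copy numbers**, and the **clonality** of somatic
copy-number aberrations and SNVs. A synthetic tumor simulator with
fully known truth backs every estimator.

## Who this is for

Cancer-genomics analysts who already have (i) a segmented copy-number
table (the output shape of Circular Binary Segmentation or any
comparable segmenter: chromosome, start, end, log2 tumor/normal
coverage ratio), (ii) tumor and normal pileups over candidate SNP
positions (allelic fraction and coverage per position), and
(iii) optionally an SNV read-count table. No BAM or FASTQ processing
happens here — the package is deliberately agnostic to the aligner,
segmenter and mutation caller upstream.

## The model in brief

Reads over a segment split into a *neutral* set drawn equally from both
parental chromosomes and an *active* set from one parent only. At SNPs
that are heterozygous in the matched normal ("informative SNPs"), the
tumor allelic fractions concentrate at `β/2` and `1 − β/2`, where β is
the neutral-read fraction: 1 for balanced segments, 0 for a pure clonal
hemizygous deletion. β is estimated per segment by maximizing the
folded binomial-mixture likelihood.

With the wild-type logR displacement (*shift*) located on balanced
segments,

    ploidy = 2 · 2^(−shift)

and, from the most clonal hemizygous deletions, the apparent admixture
`G' = β/(2 − β)` designates the sample DNA admixture G. Given ploidy
and G, allele-specific copy numbers follow from

    cnP = (β·2^logRp − G) / (1 − G)
    cnM = ((2 − β)·2^logRp − G) / (1 − G),      logRp = logR − shift

reported as major/minor (cnA ≥ cnB) with integer calls where the
fractional value is close to an integer. Clonality of an aberration
(a, b) carried by a fraction c of tumor cells is fitted by inverting
the three-population read mixture

    rA = G + (1 − G)(c·a + 1 − c),   rB = G + (1 − G)(c·b + 1 − c)
    β = 2·min(rA, rB)/(rA + rB),     logR = log2((rA + rB)/2) + shift

and SNV clonality from `vaf = m·c·(1 − G) / (2G + (1 − G)·cnT)` with
multiplicity m. See `docs/methods.md` for assumptions, defaults and
numerical details.

## Worked example

Simulate an aneuploid tumor (wild-type and tetraploid blocks plus two
deletions; truth: admixture 0.200, sample-average ploidy 2.520) and run
the full chain:

```sh
ascna simulate --preset aneuploid-shifted --out-dir demo --seed 1
ascna beta --seg demo/aneuploid-shifted.seg.tsv \
           --tumor-pileup demo/aneuploid-shifted.tumor_pileup.tsv \
           --normal-pileup demo/aneuploid-shifted.normal_pileup.tsv \
           --out demo/bt.tsv
ascna ploidy --beta-table demo/bt.tsv
ascna admixture --beta-table demo/bt.tsv
ascna ascn --beta-table demo/bt.tsv --out demo/ascn.tsv
```

which prints

```
Number of processed segments: 40
Number of segments with valid beta: 40 (100%)
...
ploidy 2.52 (logR shift -0.335)
DNA admixture 0.20 [0.15, 0.24] (2 supporting deletions)
```

The ploidy line says the wild-type logR mode sits at −0.335, i.e. the
sample averages 2.52 DNA copies per cell (truth 2.52); the admixture
line recovers the simulated 20% non-tumor DNA with error-propagated
bounds. `demo/ascn.tsv` then carries `log2.corr` (the logR each segment
would have in a diploid, 100% pure sample), fractional `cnA`/`cnB`, and
integer calls — wild-type segments land on (1, 1), tetraploid blocks on
(2, 2).

`ascna check-plot` draws the diagnostic beta-vs-logR scatter with the
expected lattice of integer allele-specific states, the standard way to
vet conflicting ploidy/admixture interpretations before trusting any
downstream clonality call; `ascna clonality-scna` / `ascna
clonality-snv` add discretized clonality (`clonal`, `uncertain.clonal`,
`uncertain.subclonal`, `subclonal`, `not.analysed`).

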