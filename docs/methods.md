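# Methods

## Problem setting

After allogeneic hematopoietic stem cell transplantation (HSCT), the
clinically central quantity is **donor chimerism**: the percentage of a
recipient's cells — in whole blood or in flow-sorted subsets such as T
cells or granulocytes — that derive from the donor graft. `chimerseq`
implements the sequencing-based measurement of that quantity from short
PCR amplicons spanning single-nucleotide polymorphisms (SNPs) that
differ between donor and recipient, plus the companion MHC
amplicon-genotyping workflow used to select transplant pairs in
Mauritian-origin cynomolgus macaques (MCM), whose founder-bottlenecked
population carries only seven characterized MHC haplotypes (M1–M7).

## Informative-SNP selection

Each animal is genotyped on a biallelic SNP panel. For a donor/recipient
pair, a locus is classified into one of four configurations:

| configuration | donor | recipient | formula |
|---|---|---|---|
| het/hom | a/b | a/a | `percent = 2·d` |
| hom/het | a/a | a/b | `percent = 100 − 2·r` |
| hom/hom-different | b/b | a/a | `percent = d` |
| uninformative | otherwise | | none |

where `d` and `r` are the percentages of effective reads carrying the
donor-specific and recipient-specific nucleotide respectively. The ×2
**zygosity correction** arises because a private allele on one of a
heterozygote's two chromosomes appears in only half of a pure sample's
reads.

Pairs with identical genotypes are uninformative, as are all
both-heterozygous pairs: the assay's selection rule requires at least
one homozygote. (A both-het pair with disjoint alleles does expose a
private nucleotide in principle, but no formula case of the assay covers
it and such loci are never selected; we classify them uninformative and
state the restriction explicitly in the tests.) When a heterozygote
shares no allele with the opposing homozygote, either of its two private
alleles serves the formula; the lexicographically smaller is used for
determinism.

## Read assignment and counting

Reads are not coordinate-mapped. A read is assigned to a locus when it
contains an exact match to the `anchor_length` (default 12) bases
immediately 5′ of the SNP, then exactly one base, then an exact match to
the 3′ anchor; the read's reverse complement is searched symmetrically,
and the enclosed base — complemented back to the amplicon's forward
strand when needed — is the SNP base. Exactness makes assignment
unambiguous and conservative: a sequencing error inside an anchor loses
the read (at error rate ε the loss is `1 − (1−ε)^(2·anchor_length)` ≈
4.7% at ε = 0.002), and because the loss is independent of read origin
it does not bias the estimated fraction. Panels in which two loci share
an identical anchor pair are rejected at load. SNP bases below
`min_base_quality` (default Phred 20) are tallied as N and excluded from
the denominator (`effective_reads`); mates of a fragment that both cover
the SNP are counted once, using mate 1's base when the mates agree and N
when they disagree. No quality trimming precedes assignment in the SNP
pipeline — the exact-anchor requirement already filters — while the MHC
workflow trims first (below), mirroring the original workflows.

## Estimation, uncertainty, aggregation

The counted fraction is pushed through the affine formula above. Raw
values can leave [0, 100] under sampling noise; they are clamped with a
`clamped` flag preserved in the output. A 95% Wilson score interval on
the counted fraction (statsmodels) is mapped through the same affine
transform and clamped, giving a per-SNP interval. Estimates with fewer
than `min_coverage` (default 100) effective reads are flagged
`no_coverage` and excluded from aggregation; reads carrying a nucleotide
neither animal's genotype explains trigger a contamination warning above
a 2% fraction (warning only, never corrected). Across SNPs the aggregate
is the unweighted mean with the standard error of the mean when n ≥ 2;
single-SNP mode — the assay's routine practice once accuracy was
established — reports the mean with SEM not-available. The tidy
longitudinal table (animal × day post-HSCT × cell subset) is sorted,
never interpolated, and rejects duplicate keys.

## MHC typing

Reads are quality-trimmed with a 4-base sliding window (mean Phred ≥ 20,
scanning 5′→3′ and cutting at the first failing window while retaining
its leading above-threshold bases); reads shorter than 100 bases are
dropped and counted. A trimmed read supports a reference allele only by
**perfect match**: the read (or its reverse complement) contains the
allele's exon-2 sequence as an exact substring, or is contained in it
with ≥ 100 bases of overlap. A read may support several alleles — shared
exon-2 motifs among MHC alleles are real — and alleles with identical
exon-2 sequences are collapsed into a jointly-reported group, so perfect-
match counts are never split. Class I (191 bp) and class II (169 bp)
amplicons are scored against one combined library; with exact-substring
semantics the two length classes cannot cross-match, so a per-class
split would change nothing.

An allele is called present when its count is ≥ `min_count` (10) and its
fraction of assigned reads is ≥ `min_fraction` (0.005), both inclusive.
Haplotype inference scores all 28 unordered pairs (including self-pairs)
of the seven definitions:

    score(Hi, Hj) = |P ∩ U| − λ·|U \ P| − μ·|P \ U|,   U = Hi ∪ Hj

with P the present-allele set and λ = μ = 1. Ties break toward fewer
unexplained alleles, then the lexicographically first pair, and are
flagged on the call. With λ = μ the arg-max is unique whenever the 28
union sets are distinct, which holds as soon as every haplotype carries
at least one private allele. Donor–recipient match grade follows
directly: identical unordered pairs are a full match, one shared
haplotype is haploidentical, none is a mismatch; a no-call on either
side grades indeterminate.

### Synthetic reference

The real M1–M7 allele compositions are published reference data not
bundled here. The shipped reference (`data/synthetic_*`) is **synthetic**,
generated deterministically by `synthetic.synthetic_mcm_reference()`:
seven haplotypes, each with three private class I alleles, one class I
allele shared with the adjacent haplotype (exercising multi-haplotype
read support), and two private class II alleles; sequences are 191/169 bp
with ≥ 6 substitutions between alleles. It preserves the structural
properties the algorithms depend on, not the real sequences; analyses of
real MCM data must substitute the published library via `--library` /
`--definitions`.

## Synthetic data generator

The generator is first-class, tested code and defines the conditions
under which the estimators are validated:

* **Genotype pairs** — independent Hardy–Weinberg draws per animal per
  locus at alternate-allele frequency `maf`; random ~220 bp amplicons
  with the SNP at offset 110. At `maf` = 0.5 the closed-form informative
  fraction is 0.625.
* **Mixture reads** — per locus, each read's origin is donor with
  probability c/100; the SNP base is drawn uniformly from the origin
  animal's two alleles; every base is independently substituted with
  probability `error_rate` (default 0.002, a MiSeq-like substitution
  rate) uniformly to one of the other three bases; half the reads are
  emitted reverse-complemented. Reads are full amplicons: on 2×250
  chemistry a ~220 bp insert is spanned end-to-end, so fragmentation is
  not modelled. Qualities are constant Phred 35 by default, with a
  low-quality-tail option to exercise trimming and the N-gate. Truth
  labels (per-read origin) are recorded for every read.
* **MHC reads** — full-length exon-2 amplicons drawn uniformly at
  `depth_per_allele` per allele of the generating pair's union set, with
  the same substitution model.

Identical seed and configuration give byte-identical FASTQ. Not
modelled, deliberately: indels, PCR chimeras and per-allele
amplification bias, duplicate reads, and position-dependent error
profiles. Consequently, passing recovery tests demonstrate correctness
of the estimators under substitution-dominated noise with unbiased
amplification; they do not bound errors from PCR allele bias in real
libraries (a per-allele efficiency multiplier would be the natural
extension point).

## Validation conditions and problem sizes

The recovery checks simulate c ∈ {0, 5, …, 100} at depth 10,000 reads
per locus, error rate 0.002, 20 replicates per point per configuration
(1,260 simulations); mean absolute error is required below 1.5
percentage points per configuration and the three configurations' per-
point means must agree within 1 point. Boundary recovery at c = 0 and
c = 100 compares the mean *unclamped* estimate over 50 replicates to
within 0.5 points: the heterozygote configurations carry ~1 point of
binomial noise per replicate at this depth, and clamping makes a single
boundary draw one-sided, so the unclamped mean is the unbiased recovery
measure (the clamping rule itself is asserted on an injected raw value
of 102). MHC recovery simulates all 28 pairs at depth 500 per allele,
error 0.001. The toy end-to-end pipeline uses 4 loci, 3 timepoints, 800
reads per locus. All seeds are fixed.

## Numerical and degenerate-input choices

* Estimation denominators exclude N-gated bases; whether the original
  assay did so is not documented, so the choice is stated rather than
  presumed.
* `aggregate()` with zero usable per-SNP estimates returns a flagged
  no-estimate (None) instead of raising, so longitudinal tables simply
  omit the sample.
* Loci with more than two observed alleles are rejected at selection
  (the panel is biallelic by design); loci monomorphic across a pair are
  representable and simply uninformative.
* An empty FASTQ yields zero-total counts flagged downstream as
  no-coverage, not an error; malformed FASTQ records fail naming the
  record.
* Reads matching zero or ≥ 2 loci, or matching one locus ambiguously
  twice, are unassigned (conservation: assigned + unassigned = total).

## Known limitations

* Anchor matching tolerates no mismatches; heavily degraded runs lose
  depth rather than accuracy. The anchor length (12) trades uniqueness
  against loss and assumes locus-specific flanks.
* Haplotype inference searches only the supplied definitions;
  recombinant haplotypes outside them cannot be called.
* Perfect-match MHC scoring discards any read with an error inside the
  matched allele span; depth requirements scale accordingly.
* The chimerism CI reflects read-sampling uncertainty only, not
  biological or PCR variance between SNPs — which is what the cross-SNP
  SEM captures.
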