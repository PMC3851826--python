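# Methods

## Model and assumptions

`homeosplit` operates on per-accession nucleotide counts (`Nb`, an
M×N×4 array per contig) rather than on reads or called genotypes: counts
retain the allele-dosage signal that genotypes discard, while staying
O(NM) in time and O(Nl·M) in memory (Nl = longest contig).  The model
rests on three assumptions:

1. **Heterozygote excess marks merged homeologs.**  In a (near-)selfing
   panel, a site where many accessions carry two well-supported
   nucleotides is far more likely to be fixed divergence between two
   merged gene copies than genuine heterozygosity.
2. **Exactly two copies.**  A questionable contig is modelled as a mix of
   two homeologs; higher copy numbers are out of scope.
3. **Constant within-accession expression ratio.**  The two copies may be
   expressed very unevenly, and unevenly in different directions across
   accessions, but within one accession the ratio is roughly constant
   along the contig.  This is what lets a per-accession proportion
   `p1[a]`, averaged across sites, act as the binomial parameter at every
   site.

Under these assumptions, the probability of an accession's counts at a
questionable site is a product of two binomials (one per copy), and the
split likelihood is the product over sites and accessions.  The two
binomial terms are deliberately kept together: a rare sequencing-error
nucleotide can make one term large, but its complement term then collapses
(the "49 A, 50 C, 1 T" situation), which is exactly what prevents error
nucleotides from being picked as a homeolog.

The binomial coefficients are retained in the likelihood even though they
do not cancel across candidate splits (k1 and k2 depend on the pattern);
the formula is used as stated.

## Screening rules and their parameters

| parameter | default | meaning |
|---|---|---|
| `min_allele_count` | 5 reads | per-accession support for each of two nucleotides to call a site heterozygous; absorbs sequencing error |
| `het_fraction` | 1/8 | fraction of genotyped accessions that must be heterozygous for a site to be questionable; tuned to near-fixed lines |
| `min_genotyped_coverage` | 10 reads | site coverage for an accession to count as genotyped (the denominator of the 1/8 rule) |
| `min_mean_coverage` | 5X | contig mean coverage to be splittable |
| `min_site_coverage` (p1) | 10 reads | per-site coverage for an accession's proportion to enter the `p1[a]` average |
| `min_call_coverage` (genotypes) | > 10 reads | strict inequality, per the genotyping rule |

All comparisons are inclusive (`≥`, "at least"), except the genotype-call
coverage which is strictly `> 10` by its own wording.  The denominator of
the 1/8 rule counts only genotyped accessions (coverage ≥ 10): counting
uncovered accessions as "not heterozygous" would dilute the rule exactly
where data are missing.  A fixed-denominator mode over all M accessions is
available via `denominator="all"` for users who prefer the stricter
reading.

Ties in "most frequent nucleotide" are broken toward the smallest index
(A < C < G < T) everywhere, making every result deterministic.

## Likelihood details and numerical choices

* `p1[a]` can be exactly 0 or 1 (an accession expressing only one copy);
  it is clamped to [1e-6, 1 − 1e-6] before the log-likelihood.  Clamping
  preserves the ordering of candidate splits and keeps every
  log-likelihood finite.
* Accessions with no questionable site at coverage ≥ 10 have no defined
  `p1[a]`; they are excluded from the likelihood (reported as NaN) rather
  than given a default proportion — the minimal-assumption choice.
* All binomial terms are computed in log space via `scipy.special.gammaln`;
  a site with zero coverage contributes log 1 = 0.
* Candidate scoring is vectorised across patterns; the scalar operations
  (`estimate_p1`, `site_log_prob`) use the same definitions and the test
  suite pins the two routes together, and both against a brute-force
  direct probability product (no log-space) at small counts.
* **Tie-breaking.**  Among equal-likelihood candidates the global-majority
  pattern wins, then the lexicographically smallest pattern.  When only
  two nucleotides are observed at every site, a pattern and its
  orientation swap have *mathematically identical* likelihoods, but the
  vectorised summation leaves ~1e-14 of float residue; equality is
  therefore taken within `1e-9 + 1e-12·|logL|`, far below any genuine
  model signal (a third observed nucleotide separates the orientations by
  whole log units).
* The exhaustive search is capped at 2^20 combinations (the product of
  per-site alphabet sizes) and raises a descriptive error beyond that;
  `mode="auto"` falls back to the heuristic.  The heuristic scores at most
  M+1 patterns and, because each accession's majority sequence is the
  maximum-likelihood pattern for that accession's own reads, it contains
  the true pattern whenever some accession expresses one copy dominantly.
* Identical accession-majority patterns are deduplicated before scoring;
  this cannot change the selected split.

## Genotype caller

The genotype caller is a simple count-threshold rule (coverage > 10;
alleles need ≥ 5 reads and ≥ 10% of the pileup; one passing allele =
homozygote, two = heterozygote, otherwise missing).  It is a documented
stand-in for probabilistic genotypers: the Fis machinery downstream
(`Fis = 1 − Hobs/(2p(1−p))`, bi-allelic sites only, frequencies over
called accessions) is independent of how genotypes were produced.  The
SNP classification bounds are: homologous for Fis > 0.6 (the empirical
bound for usable selfing-panel SNPs), homeologous for Fis ≤ −0.5 (our own
binning of the −1 mode; not an externally given value), intermediate
between.  Fis can stray below −1 for unbalanced heterozygote excess; the
histogram clips to [−1, 1], the per-SNP table does not.

## The simulator

`simulate_contig`/`simulate_dataset` generate the study conditions the
package is designed for:

* two homeolog sequences diverged at 2.5% of sites by default (the typical
  identity of the two diploid-progenitor transcriptomes), planted at
  uniformly drawn positions;
* M = 30 accessions, per-site total coverage Poisson(λ = 30), reads
  allocated to the copies Binomial(total, bias[a]);
* per-accession biases Beta(6, 2) (mean 0.75), orientation-flipped with
  probability 1/2 — strong but inconsistent expression dominance, the
  regime where pooled majorities blur and the likelihood is needed;
* sequencing error 0.005 per base, uniform over the other three
  nucleotides;
* homologous SNPs (dataset-level default rate 0.005 per site, MAF uniform
  in [0.1, 0.5]) as derived alleles on one copy, fixed within carrier
  accessions — the selfing regime with Fis near 1;
* clean (non-mixed) contigs are single-copy: zero divergent sites, all
  reads from one homeolog.

The contig handed to the pipeline carries the *global consensus* of the
simulated counts as its reference sequence, i.e. the sequence a de novo
assembly of the pooled reads would produce.

What the simulator does **not** emulate: read-length effects (counts are
per-site; no linkage between neighbouring sites within a read), mapping
bias and multi-mapping losses, alternative splicing, coverage variation
along transcripts, and genotyping uncertainty beyond count thresholds.
Passing tests therefore demonstrate correctness of the count-level model
and search, not robustness to alignment artefacts in real mappings.

**Re-mapping emulation.**  Measuring the Fis spectrum "after splitting"
requires re-mapping reads onto the split contigs, an upstream step outside
the package.  `remap_split_counts` emulates it at count level: the
simulator records which copy each counted base came from, and each
(accession, copy) read population is assigned wholly to the split
sequence it matches best at the questionable sites — the count-level
analogue of a mapper's best-hit choice, exact here because all reads of
one copy in one accession are identical up to error.  A chimeric split
attracts both copies to the same output contig and keeps the heterozygote
excess, so the measure penalises bad splits.  This function needs the
simulation truth and lives in `simgen`.

## Evaluation choices

* diffSym requires pre-aligned sequences on common coordinates; alignment
  is kept outside the method core (any aligner can feed it), and overlaps
  below 100 bp make the value undefined rather than unreliable.
* The per-site random baseline redraws every questionable site uniformly
  among the nucleotides observed there; the same-count baseline flips a
  fixed number of sites.  Both are seeded and scored with the same
  likelihood as real splits.  With zero flips the same-count baseline *is*
  the majority split, so its diffSym is the (generally positive) majority
  gain, not zero.
* "Same split" between the exhaustive and heuristic searches is compared
  as the unordered pair {Ck1, Ck2}: the deliverable is the pair of
  sequences, and the two orientations are near-exact likelihood ties.
* Paired method comparisons use a sign test over per-contig diffSym
  differences; the per-contig table is exposed for users who prefer a
  paired t-test in their own stats environment.

## Problem sizes used in the shipped analyses

The test-suite acceptance analyses use desk-scale versions of the study
conditions, chosen a priori: 500 replicates (M = 12, L = 60, 2–8
divergent sites, biases uniform in [0.7, 0.95] with random orientation)
for the search-agreement study, and one shared dataset of 100 mixed + 50
clean contigs (L = 300, 10 divergent sites, M = 30, λ = 30, e = 0.005)
for recovery, Fis-shift and diffSym analyses.  The splitting driver uses
the heuristic search (the default strategy); the agreement study runs
both searches.

## Known limitations

* Exactly two copies per questionable contig; higher ploidy and
  copy-number variation are not modelled.
* Balanced expression (all biases near 1/2) leaves the two orientations —
  and many partial patterns — nearly tied; the report flags near-tie
  likelihoods (`near_tie`) instead of attempting a formal test.
* Paired-end/read-level phasing information is ignored by design; counts
  carry no within-read linkage.
* The ALR dialect is defined by this package (header line, `#accessions`
  line, 1-based positions, `a/c/g/t` count fields); files from other
  tools' ALR variants may need reformatting.
* The genotype caller is threshold-based; rare alleles riding on low
  coverage are called conservatively (missing rather than wrong).
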