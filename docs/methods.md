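# Methods

This note documents the statistical models implemented in `editome`, the
conventions and numerical choices behind them, and what the synthetic-data
generator does and does not emulate.

## Detection model

A candidate site is an adenosine on the transcript strand (genomic A under
a + gene, genomic T under a − gene).  Under the null hypothesis that every
A→G read is sequencing error, the per-library evidence is the upper
binomial tail P_k(E0) = P[X ≥ L_k], X ~ Binomial(C_k, ε), evaluated with
the scipy survival function (never by naive summation, which loses
precision in the far tail).  The error rate ε is a single global scalar
obtained by rescaling a platform error ε0 to the A→G mismatch class,
ε = (ε0/3)/(1 − (2/3)ε0); at the default ε0 = 0.005 this is ≈ 0.00167.
Per-base quality scores are deliberately not integrated: the count tables
are assumed pre-cleaned upstream (mapping quality filtering, removal of
reads with non-A→G mismatches), and a fixed ε keeps the null model
transparent and portable across libraries.

Evidence combines multiplicatively across libraries in log space:
log P(E0) = Σ_k log P_k(E0), with zero-coverage libraries contributing
log 1 = 0 (no evidence, not evidence of absence).  Sites covered in no
library are excluded as unexpressed.  Joint null probabilities are
Benjamini–Hochberg adjusted once across all expressed candidates; the two
detection classes then threshold the same q-values at different levels
rather than re-running BH on a remainder set, which keeps q-values
well-defined per site.

Classes are assigned exclusively, in order:

* **I** — q ≤ 0.001, C_max ≥ 10, C_total ≥ 40, detected in ≥ 2 libraries;
* **II** — among the remainder detected in ≥ 2 libraries: q ≤ 0.01,
  C_max ≥ 5, C_total ≥ 16;
* **III** — remainder with joint P(E1) > 0.99;
* **IV** — remainder detected in ≥ 1 library with P(E1) ≤ 0.99;
* **V** — covered but nothing detected.

"Detected in a library" means the per-library high-confidence filter:
level > 0.01, coverage ≥ 5, edited reads ≥ 2 and P_k(E0) < 1e-4.  Raw
L_k > 0 would count single error reads as detections and make the
two-library requirement nearly vacuous at depth; the filtered definition
is the one under which the class sizes behave sensibly.

The false-positive rate of a call set is estimated from a paired
wild-type / editing-null experiment as N2/N1, where N1 counts calls with
editing signal in the wild type and N2 those that also show A→G signal in
the null mutant, where no real editing can occur.

## Non-detection model

For confident absence the relevant quantity is the probability of seeing
zero edited reads at an edited site: with assumed level l and depth C,

    P_m(D0) = Σ_{i=0..C} C(C,i) · l^i (1−l)^{C−i} · ε^i (1−ε)^{C−i}
            = ((1−l)(1−ε) + l·ε)^C,

the closed form following from the binomial theorem; it is evaluated in
log space and is exactly the series summed term by term (the test suite
checks this to 1e-12).  The series couples the sampling and error terms
inside one sum and ignores error-generated G reads on unedited molecules;
it is implemented as stated rather than "corrected", because the joint
calls downstream are calibrated against this definition.  At ε = 0 it
reduces to (1−l)^C.

Joint over the libraries with zero edited reads, P(D0) = Π_m P_m(D0).
Three calls use it:

* **conservation** over the fixed species tree ((mel, sim), pse): focal
  sites need level ≥ 0.05 and per-species ortholog coverage ≥ 200 reads;
  absence requires significance after BH at FDR 0.05 (a fixed cutoff of
  2e-4 is available by flag).  Parsimony mapping: present everywhere →
  conserved; present in focal+sister, absent in outgroup → loss on the
  outgroup branch (a gain preceding the focal/sister split is equally
  parsimonious and is reported under the same label); absent in both
  others → gain on the focal branch; anything involving an undetermined
  status, or the ambiguous sister-absent/outgroup-present pattern, is
  undetermined rather than forced.
* **polymorphic editing** across strains (per sex): a candidate needs one
  strain with P_k(E1) > 0.999 and one covered strain with zero edited
  reads, after removing sites edited in the outgroup species.  The assumed
  level in non-detected strains is the mean level of the reliably detected
  strains (Level I) or that mean capped at 0.05 (Level II — conservative
  when the detected strains are strongly edited).  Significance follows
  the same BH-or-fixed-cutoff convention.
* **fixed editing**: P_k(E1) > 0.95 in *every* strain (sites with an
  uncovered strain are not callable) plus detection at the orthologous
  site in the same-sex outgroup library.

## SNP–editing association

For sites polymorphic in both sexes, each SNP within ±10 kb is tested per
sex for association between its 0/1 genotype and the per-strain editing
level.  At n = 5 strains normal-theory p-values are fragile, so the
default test is exact enumeration: the correlation of the observed
genotype with the levels is compared against all 2^5 possible genotype
assignments, one-sided in the observed direction (monomorphic assignments
cannot exceed and stay in the denominator).  The minimum attainable p is
1/32 ≈ 0.031, so a pair can only be reported when the effect direction
also replicates across sexes with p < 0.05 in both — direction
consistency is the second, independent guard.  A full two-sided label
permutation can never reach 0.05 at this n, which is why the one-sided
enumeration convention was chosen.

## Selection framework

The neutral background tallies every CDS adenosine of the genes carrying
at least one editing event, classifying a hypothetical A→G at each
position as nonsynonymous or synonymous on the canonical transcript.
Stop-codon positions (stop-retained or stop-lost edits) are excluded from
both tallies and reported separately.  With a conserved-adenosine filter
the same tally runs over cross-species conserved positions only.

The selection test compares observed (N, S) to the background by a
two-sided Fisher exact test — two-sided because depleted ratios (purifying
selection) are as meaningful as enriched ones — and reports
α = 1 − expected/observed.  Uncertainty comes from a single label
bootstrap: N+S labels resampled with replacement, ratio and α recomputed
per replicate, intervals as the 2.5%/97.5% empirical type-1 (inverse-CDF)
quantiles.  Replicates with zero resampled S sites yield +inf ratios that
sort above all finite values, preserving quantile ordering without
discarding replicates; an observed S of zero flags the result degenerate
(unbounded ratio, no interval).

Per-gene classification: a gene is "positively selected editing" when its
high-confidence CDS editing N/S exceeds 5, with S = 0, N ≥ 1 counting as
unbounded and qualifying.  Stratified tests (X vs autosome, expression
halves by median rank of RPKM among edited genes, editing-level cutoff
grids, fixed vs polymorphic) reuse the same machinery per stratum against
stratum-matched backgrounds.  Where two strata have different neutral
expectations (fixed vs polymorphic sites), the comparison rescales one S
margin by the ratio of the two expectations before the Fisher test — a
stated convention, flagged as such.

## Detection-bias simulations

Editing levels of S sites run lower than N sites, so finite depth censors
S sites more often and inflates observed N/S.  Two resampling schemes
bound the effect:

* **site resampling** — per retained site, redraw the edited count as
  Binomial(C_j, L_j/C_j) (exactly equivalent to resampling C_j reads with
  replacement, without storing read lists) and drop sites whose simulated
  level falls below l_min; defaults scan C_min 5–20 and
  l_min ∈ {0.01, 0.02, 0.05}.  Run per library by default (a site present
  in several libraries is resampled in each); pooled input is a caller
  choice.
* **fraction resampling** — pool libraries and redraw each site at depth
  round(f·C) for f from 0.05 to 1 in steps of 0.025.  Rounding is
  half-even so outputs are bit-reproducible; a rounded depth of zero
  contributes nothing that replicate.

Replicate ratios with no surviving S site are +inf and participate in the
quantiles as above.  All replicate streams run off one seeded generator:
identical config + seed reproduces tables exactly.

## Sequence context

The position probability matrix covers offsets −3..+3 around the edited A
(the central base is constant and excluded).  The default pseudocount is
0 — direct frequencies — so a base never observed at a position scores
−inf; a +0.5 pseudocount flag exists for small site sets.  7-mer scores
are Σ_i log2(P_i(N_i)/0.25).  The background scan scores every A-centered
7-mer in the mRNAs of edited genes, each window counted once; the cutoff
is the type-1 (1 − 0.9) quantile of the editing-site scores, so at least
⌈0.9·n⌉ sites score at or above it, ties included.  Flanks are
transcript-strand (reverse-complemented under − genes).

## Density, structure and clustering analyses

All binning is by rank into equal-sized bins (default 20) with ties
broken by genomic coordinate and then input order, so every binned output
is reproducible.  Editing density in a bin is edited/total background
adenosines, optionally weighting edited sites by level, with both raw and
per-million columns emitted.  Trends are Spearman correlations (average
ranks for ties; a tie flag fires when more than 20% of densities tie, and
an all-equal density vector is reported as rho 0 rather than undefined).
Paired 5'/3' half-gene and conservation-matched contrasts use paired
t-tests across bins.  Hairpin enrichment is a permutation test sampling
|sites| background positions with replacement per replicate, with
(r+1)/(n+1)-smoothed empirical p-values so p is never exactly zero.
Library clustering uses 1 − Pearson r distance with average linkage
(neither is dictated by the analysis; both are configuration surfaced in
the output) and emits a newick dendrogram.

## Coordinate and strand conventions

Files are 1-based (VCF/GFF convention); everything in memory is 0-based
half-open, converted only at I/O boundaries.  Annotation uses canonical
transcripts only; when overlapping genes disagree, CDS beats UTR beats
intron.  SNP masking applies before any probability computation.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes:
random-codon genes (ATG start, single stop, no internal stops, ~50/50
strands, optional single intron inside the CDS), editing sites placed on
transcript-strand adenosines, true levels Beta(2,4) for N sites versus
Beta(1.2,6) for all other categories (means ≈ 0.33 vs 0.17, reproducing
the direction and rough size of the observed N-vs-S level gap),
negative-binomial coverage (mean 7, dispersion 0.35 — the defaults put
the median per-site library coverage in the 5–9 band typical of brain
libraries), per-read A→G error at 0.00167, genomic SNPs emitted to a VCF,
presence patterns over ((mel, sim), pse) with sharing probabilities 0.47
and 0.21, and a five-strain two-sex panel with planted polymorphic/fixed
sites and editing-QTL SNPs whose alternative allele marks exactly the
edited strains.  An optional wild-type/editing-null library pair supports
FPR estimation.  The edited-read probability is l(1−ε) + (1−l)ε — error
both erases and fabricates edited reads — which is deliberately richer
than the detection model's null and stress-tests it.

What the generator does **not** emulate: alignment artifacts and mapping
bias, PCR duplicates, base-quality variation, non-uniform coverage along
transcripts, isoform complexity, linkage structure among SNPs, and
realistic codon usage (composition is uniform over non-stop codons, so
synthetic neutral N/S backgrounds sit near 2.3–2.4 rather than the ~3.8
of a real transcriptome).  Passing calibration tests therefore
demonstrates that the statistics are implemented correctly and calibrated
under their own assumptions, not that those assumptions hold in any
particular real library.

## Study sizes used by the test and acceptance runs

Chosen to give stable Monte-Carlo behaviour at desk scale: null FDR
calibration uses 100 replicates of 120 sites × 4 libraries; planted-site
recovery uses 20 genes at coverage 30 with levels concentrated near 0.3;
adaptive-fraction recovery averages 10 generator replicates of ~900–1000
detected N+S sites each (a single replicate's α̂ has Monte-Carlo sd near
0.07 at these counts, so the mean over replicates is the meaningful
recovery check), with equal N and S level distributions so the estimator
is isolated from the detection bias quantified separately; strain-call
recovery uses 20 panels with depth floored at 50 reads, the stated panel
condition.  Bootstrap checks run 1000 replicates, matching the published
procedure.

## Known limitations

* ε is global; libraries with atypical error profiles would need their
  own ε0.
* Canonical-transcript annotation misclassifies sites that are exonic
  only in non-canonical isoforms.
* The P_m(D0) series understates non-detection slightly by ignoring
  error-generated G reads on unedited molecules (kept as stated; see
  above).
* The fixed-vs-polymorphic background adjustment and the 2^5 one-sided
  association enumeration are conventions; both are flagged in the API
  documentation and here.
* Orthology maps, hairpin/pseudoknot intervals, RPKM tables, dN/dS values
  and phyloP scores are consumed as inputs; constructing them is upstream
  of this package.
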