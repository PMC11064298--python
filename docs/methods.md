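# Methods

## Coverage-based sex-chromosome detection

For each sample the per-base **median** depth of every chromosome is
computed (zero-depth bases included — no exclusion rule is applied), then
divided by the mean of that sample's chromosome medians. This removes
library size exactly: multiplying any one sample's depths by a positive
constant leaves its normalized profile unchanged. Normalized depths are
averaged within each sex and compared as

log2(M:F) = log2((M + ε) / (F + ε)),  ε = 0.01 by default.

The pseudocount exists because the W has essentially zero male coverage
and the ratio must stay finite and plottable; at ε = 0.01 a true Z
(expectation 1) reads ≈ 0.99 rather than 1.00 under typical normalized
depths, well inside any sensible classification band.

Classification bands are artifact choices around the idealized
expectations (0 for autosomes, 1 for Z, strongly negative for W):
autosome if |log2| < 0.25; Z if log2 ≥ 0.75 with male normalized depth
≥ 0.5; W if log2 ≤ −0.75 or male depth < 0.25 with female depth ≥ 0.5;
anything else is reported `ambiguous` rather than forced. The windowed
statistic repeats the same normalization per non-overlapping window
(default 1000 bp; 500 bp available via the window flag), retaining and
flagging a final partial window. The per-sample normalizer includes all
chromosomes, Z and W included; with few chromosomes this pulls autosome
values slightly off 0 in absolute depth but cancels in the M:F ratio.

## Synthetic ZW genomes

The generator emulates the data such a study consumes, not the
sequencing process. Defaults: 3 autosomes + Z + W of 100 kb; 15 CDS-only
genes per autosome/Z with 1–6 exons (introns 60–200 bp, GT..AG), CDS of
150–400 codons with no internal stops; 40 W genes copied from unique
donors genome-wide; retro fraction 0.42 and silenced fraction 0.8,
chosen to echo the published ZW pattern of a minority of intron-reduced
retrocopies and a largely silenced W; pseudogene fraction 0.4;
duplicate divergence exponential with mean dS 0.4 (most duplicates
young, a tail approaching saturation); 5 samples per sex at 25× for a
two-copy locus, matching a typical resequencing design of five pupae
per sex at ~25-fold coverage.

**Divergence realization.** Synonymous and nonsynonymous substitution
events are drawn as Poisson counts at rates d·S and ω·d·N (ω = 0.2,
transition:transversion ratio κ = 2.0), where S/N are the sequence's
Nei–Gojobori site counts, and applied sequentially; stop-creating
changes are rejected and multiple hits at a site arise naturally. The
recorded truth is realized synonymous events divided by the mean of the
start and end synonymous site counts — a counting definition that is
independent of the estimator and uses the same site convention, so
site-counting idiosyncrasies cancel between truth and estimate.

**Lesions.** Pseudogenized copies receive exactly one lesion placed in
the interior 10–90% of the CDS: a single-base substitution creating a
stop codon, or a 1–2 bp insertion/deletion. One unambiguous lesion per
gene keeps sensitivity/specificity of the detector interpretable.

**Coverage.** Independent Poisson per base with mean
`mean_depth_x × copy_number / 2`; no mappability, GC or repeat bias —
the statistic under test is the copy-number signal, not platform noise.
Consequently the simulated W lacks the repeat-driven coverage variance
real Ws show; passing tests demonstrate the estimator, not robustness
to repeats.

**Expression.** W genes flagged expressed draw FPKM strictly above the
0.5 threshold in every condition (0.5 + log-normal); silenced or
pseudogenized W genes draw uniformly below 0.45; autosomal/Z genes draw
from a log-normal background (meanlog 1.5, sdlog 1.2, median ≈ 4.5
FPKM). Introns of DNA-duplicated copies are copied verbatim from the
donor; intron divergence carries no signal for any stage here.

Determinism: one global seed is split hierarchically into independent
streams (genome, coverage keyed additionally by sex and sample index,
expression, annotation), so identical seeds give byte-identical outputs
and any stage can be regenerated without replaying the others.

Coordinates are 0-based half-open internally and in bedGraph; GFF3 is
written 1-based inclusive; CDS are always reported 5'→3' on the coding
strand, and genes are simulated on both strands.

## Reciprocal best hits

Local alignment with BLOSUM62 and affine gaps (open 11, extend 1);
ranking by raw score with a minimum-score floor of 50 is the
deterministic counterpart of a seeded search with an e-value cutoff.
Ties break by higher percent identity, then lexicographic gene id, so
results are order-independent. Identity is identical pairs over aligned
(ungapped) columns. Only the longest isoform per gene should be
supplied; mitochondrial targets are excluded by default when a
gene→chromosome map is given. The pairing is one-to-one by
construction.

## Synonymous divergence

The estimator is NG86 + Jukes–Cantor rather than a maximum-likelihood
codon model: every quantity is exhaustively checkable (the test suite
verifies site and difference counts against brute-force pathway
enumeration), and the accuracy claim is parameter recovery on
simulation, not equality with any particular ML implementation.

Steps: trim terminal stop codons and verify frame (internal stops and
broken frames are routed to pseudogene handling, not aligned); globally
align the translations and thread codons through the protein alignment,
so gaps occur in whole-codon units; drop codon columns containing a
gap, a non-ACGT base, or a stop — a deterministic stand-in for
conserved-block extraction; count sites per codon position as the
fraction of the three changes that are synonymous (changes to stops are
nonsynonymous), averaging site totals between the two sequences; count
differences by averaging over all orderings of multi-hit codons with
equal weight, scoring any step into or through a stop codon as
nonsynonymous; correct with d = −¾ ln(1 − 4p/3).

Degenerate cases: p ≥ ¾ leaves the distance undefined (flagged, no dS
value); an alignment with no surviving columns is undefined; dS > 3 is
flagged saturated with **strict** inequality — dS = 3.0 exactly is
retained, 3.0 + ε is not.

At κ = 2 the NG86 equal-rate site convention and Jukes–Cantor's
four-state reversion model are both mildly misspecified for the
simulator's transition-biased process; because the recorded truth uses
the same site convention the first-order effects cancel, and measured
recovery bias stays within a few percent for dS ≤ 0.5 (it grows beyond
dS ≈ 1 where the correction's curvature dominates).

## Pseudogene and retrocopy classification

The detector aligns the W CDS (nucleotides) against the partner protein
with a dynamic program whose moves consume 3 nt per amino acid (codon
match, stops allowed at a fixed penalty), 1/2/4/5 nt per amino acid
(frameshift steps at penalty −15), a whole-codon deletion or an
amino-acid insertion (−11, linear). A 1–2 bp indel makes the total
nucleotide/amino-acid balance irreconcilable modulo 3, so at least one
frameshift step is forced onto the optimal path; conversely the path
realigns the downstream sequence in its true frame, so an indel does
not masquerade as a wall of premature stops. Reasons reported:
`premature_stop` for an in-frame stop before the final codon,
`frameshift` for a non-codon step in the CDS body; indels within the
terminal 5% are ignored as annotation-edge noise. Intact in-frame
sequences short-circuit before the DP. Penalties are fixed, not fitted:
they only need frameshift steps to beat garbled-frame codon matches,
which holds comfortably at the divergences where partners are
recognizable at all.

Retrocopy calls use intron counts (exons − 1): fewer introns than the
partner → `retro_candidate`; equal (or more) with an intron-bearing
partner → `dna_duplication`; an intronless partner is `uninformative`.

Expression: FPKM = fragments × 10⁹ / (exonic length × total mapped
fragments); a gene is expressed iff its (replicate-mean) FPKM strictly
exceeds 0.5. The mean uses correctly-rounded summation and a 1e-12
rounding guard so a mean landing exactly on the threshold is silent
regardless of summation order. "Pseudogene" and "silent" are distinct
labels: an intact gene below threshold is silent, not pseudogenized.

Copy number: genes are assigned symbols by best hit against a reference
protein set (same scoring and floor as RBH); a symbol is kept only when
a W gene and its reciprocal partner map to the same reference protein,
and copies are counted per compartment (W vs Z/autosomes).

## Enrichment

One-sided hypergeometric upper tail per term (exact, via the standard
survival function) over a background of all annotated genes (genes with
no terms still count in totals), Benjamini–Hochberg step-up across
terms. BH is used because enrichment tables conventionally report an
FDR column; no ontology-graph propagation is performed — terms are
taken as annotated.

## Problem sizes and known limitations

Tests and the acceptance script run on deliberately small genomes
(tens of kb, tens of genes, ≤ 200 replicate pairs): the statistics under
test — medians of Poisson depth, RBH ranking, per-pair dS, per-gene
lesion detection — are per-locus quantities whose behaviour does not
change with genome size, only their count does. Known limitations: no
read-level simulation, mappability or repeat structure; no
compensated (net in-frame) frameshift detection on the fast path; the
divergence truth is substitution-only (no intron or indel divergence);
the enrichment module tests over-representation only, without term
hierarchy.
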