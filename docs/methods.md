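# Methods

## The classification problem

Coeliac disease (CeD) is driven by gluten-reactive CD4+ T cells whose
receptors (TCRs) recognise HLA-DQ2/DQ8-restricted deamidated gliadin
peptides. Many gluten-specific TCR CDR3 amino-acid sequences have been
published from tetramer-sorting experiments, and because individuals
responding to the same antigen share receptors more often than chance, the
presence of such *public* sequences in a patient's mucosal repertoire is a
candidate diagnostic signal — one that, unlike serology or histology under
gluten challenge, may persist on a gluten-free diet.

`ced-tcr` implements an interpretable decision rule over bulk TCR
repertoires: a sample is called CeD iff it contains at least one
*coeliac-predictive* sequence from a curated catalog of published
gluten-specific CDR3s, at a sufficiently high abundance rank.

## Ranked clonotype frequency

A clonotype is a (V segment, J segment, CDR3 amino-acid) triple with a read
count. Ordering the N clonotypes of a sample from most to least frequent,
the i-th gets the ranked frequency

    r_i = i / N,   i = 1 … N.

This normalises for sequencing depth and clone-size scale: the most
expanded clone has r = 1/N near 0, the rarest r = 1. Presence of a
sequence "at threshold t" means r ≤ t (inclusive, so t = 1 is exactly a
presence/absence test). Catalog matching is at the CDR3 level on one chain;
a CDR3 carried by several clones gets the minimum r among them. Count ties
are broken by ascending (CDR3, V, J) so the ranking is a deterministic
bijection onto {1/N, …, N/N} regardless of input order.

## Training

Given a labelled training cohort, a threshold t selects the
coeliac-predictive set: catalog sequences with r ≤ t in **at least one CeD
sample and in no control**. A control occurrence with r > t does *not*
disqualify a sequence — only highly ranked control occurrences are
disqualifying. t is tuned over a grid (default 0.1, 0.2, …, 1.0) to
maximise resubstitution accuracy; all grid members attaining the maximum
form the *plateau*. Percentile 95% bootstrap confidence intervals
(sample-level resampling with per-replicate refitting of the selection,
B = 1000 by default, seeded) are computed for each plateau member, and the
working threshold is the plateau member with the narrowest accuracy CI,
remaining ties resolved by the plateau median (lower of two middles). The
tie-break is a design choice of this package: "central value" and
"tightest CI" are both sensible desiderata and no unique rule follows from
them; our rule is deterministic and stated.

Multi-chain models take the union rule: per-chain predictive sets with one
shared threshold optimised jointly; an individual (chains linked by sample
id) is called CeD if either chain fires.

## Validation and testing

*Leave-one-out cross-validation* reruns the entire protocol — scan,
CI-based threshold choice, selection — on each n−1 subset and classifies
the held-out individual; sensitivity/specificity/balanced accuracy are
pooled over the held-out predictions (not averaged per fold), and each
sequence's fold-selection count measures the stability of the feature set.
Folds whose training part loses a class are skipped with a warning.

The trained model is applied to an independent testing cohort blinded to
labels; labels enter only afterwards, for evaluation and for counting, per
sequence, the test CeD samples carrying it at r ≤ t. Sequences present in
≥ 1 test CeD sample and no test control are "confirmed" and prioritised by
testing CeD count, then training CeD count, with competition ranking
('='-suffixed shared labels, next rank skipped).

Evaluation measures: sensitivity TP/(TP+FN), specificity TN/(TN+FP),
accuracy (TP+TN)/total, balanced accuracy (sensitivity+specificity)/2. A
measure whose class is absent from the truth is reported missing rather
than coerced.

## Repertoire summaries

Richness (clone count), Shannon diversity (−Σ p ln p, nats) and
Gini–Simpson diversity (1 − Σ p²) are computed on read-fraction weights;
the Gini–Simpson variant and natural logarithm are package choices where
the convention is ambiguous. V/J segment usage is read-weighted by default
(clone-weighted behind a flag), aggregated at the gene level after allele
suffixes are stripped. CeD-vs-control comparisons use two-sided
equal-variance Student t-tests with Bonferroni adjustment min(1, m·p); the
family is all testable segments of one family for one chain (segments
absent from all samples of either group are excluded from testing and from
m), and the three diversity measures form their own family of m = 3.

## Synthetic cohorts

The generator emulates the statistical structure the analysis relies on,
so the whole pipeline is testable without any sequencing data:

* **Cohort layout** — 12 CeD (7 gluten-containing, 5 gluten-free diet) and
  8 controls by default, matching the training cohort; clone numbers per
  sample drawn uniformly from 800–16,000, spanning the reported per-sample
  clone range.
* **Clone sizes** — a Zipf rank-frequency law, size(i) ∝ (N/i)^s with
  multiplicative lognormal jitter (s = 1.2 by default), plus a strictly
  decreasing rank offset making counts pairwise distinct. The offset is a
  deliberate idealisation: real repertoires tie heavily at count 1 and the
  rank inside a tie block is controlled by the lexicographic tie-break, so
  precise spike placement would be impossible; distinct counts let any rank
  be hit exactly by an integer count. The lexicographic tie-break itself is
  exercised separately by unit tests on constructed ties.
* **Planting** — catalog sequences are spiked into CeD samples at target
  ranks below a ceiling (0.5), drawn from a per-chain pool (44 TRA / 28 TRB
  by default) that includes 2 core sequences common to every CeD sample;
  per-sample planted numbers are Poisson around per-diet targets (TRA:
  median 14 gluten-containing vs 2 gluten-free; TRB: 9 vs 1), floored at
  the core size, reproducing the reported contrast between diets (the
  floor means the realised TRB gluten-free median is 2 rather than 1).
  Controls receive only decoy occurrences above a floor (0.8) at rate 0.1
  per catalog sequence — these realise the rule that control occurrences
  above threshold do not disqualify. Background CDR3s are generated
  disjoint from the catalog, so for every t in [ceiling, floor) the
  planted union is exactly the selectable set: the parameter-recovery
  surface used by the tests.
* **Spike precision** — a planted count is chosen against the sorted
  background counts so the realised rank lands within one position of the
  target (colliding targets are shifted to adjacent free positions first,
  displacing each by at most the run length); targets keep a 0.01 margin
  from the ceiling/floor so the separation invariant holds exactly.
* **Determinism** — all sampling flows through one seeded numpy
  `SeedSequence` tree; a fixed config seed gives byte-identical cohorts.

What the generator does **not** emulate: V(D)J recombination statistics,
sequencing error, shared background clonotypes between individuals, HLA
structure, or any biological association between CDR3 motif content and
disease. Passing tests therefore demonstrate correctness of the algorithmic
machinery and recoverability of planted structure under the stated noise
model, not clinical performance on real repertoires.

## Numerical choices and degenerate inputs

* Threshold comparisons use r ≤ t + 1e−12 to keep grid values like 0.3
  exact under binary floating point.
* Plateau membership uses the same absolute guard on accuracy equality.
* Empty repertoires rank to an empty map, classify as control, and score
  zero on all diversity measures — each with a logged warning.
* Bootstrap replicates that lose a class contribute only their defined
  measures to the percentile CIs.
* Unreadable or malformed tables raise format errors naming the missing
  column; unproductive CDR3s (any character outside the 20-letter amino
  acid alphabet, covering `*` stops and `_` frameshifts) are dropped on
  read, which is this package's operational definition of "productive".
* MiXCR multi-hit segment fields keep the first (best-scoring) hit; allele
  suffixes and score annotations are stripped.

## Problem sizes

The acceptance script and the test suite run the planted-cohort analyses
at the generator's default scale (20 individuals, two chains, 800–16,000
clones per sample, 100-entry catalog for the recovery experiment,
B = 200–1000 bootstrap replicates); unit tests and the determinism check
use reduced clone numbers (300–800) since they exercise logic, not scale.
The per-diet median measurement pools 20 replicate single-chain cohorts.

## Known limitations

* Exact CDR3 matching only: no mismatch tolerance, partial matches, or
  CDR1/CDR2 context; no paired-chain (single-cell) information.
* The threshold tie-break may differ from the original study's unstated
  rule, so the chosen plateau member (not the plateau itself) can differ.
* The selection rule's asymmetry (one CeD hit suffices, one control hit
  vetoes) makes the predictive set sensitive to single control samples;
  LOOCV quantifies but does not remove this.
* Bonferroni families are per segment family; a global correction across
  all families would be stricter.
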