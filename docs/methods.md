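# Methods

## Overview

`primeforest` models transcription-factor (TF) specific cis-regulatory
modules (CRMs) and scores the regulatory impact of sequence variants.  The
pipeline has three layers:

1. **Motif-cluster features.** Each candidate window is represented by
   Cluster-Buster-style motif-cluster scores for an ordered list of
   position weight matrices (PWMs), optionally extended with epigenome
   track features (max peak signalValue overlapping the window).
2. **Random Forest CRM classifier.** 151 Gini decision trees with
   `max_features = sqrt(p)` and bootstrap resampling map a feature vector
   to a score in [0, 1] (fraction of trees voting positive, resolution
   1/151).  Negatives are sampled genome-wide at 1:20, matched to the
   positives in length and GC.
3. **PRIME variant scoring.** A variant's PRIME score is the classifier
   score of the mutated window minus that of the reference window, each
   maximized over a grid of windows shifted by 10% of the window length.
   Empirical z-scores against a background distribution of control-variant
   PRIMEs provide significance.

## Background model and motif scoring

A first-order Markov background is fitted from dinucleotide counts with +1
smoothing; its initial distribution is the stationary distribution of the
transition matrix.  All motif log-likelihood ratios (llr) are computed
against the order-0 stationary distribution — including the single-PWM
best-site score — so that hit scores are position-independent and the
min-max normalization bounds of the best-site score do not depend on the
local context.  The order-1 transitions are retained for background
sequence simulation.  Natural logarithms throughout.

**Best-site score (M0).** The PWM is slid over both strands; the raw window
score is the summed llr, and the reported score is min-max normalized by
the best and worst raw scores achievable by the PWM under the background
(the bounds are strand-independent because each reverse-complement column
is a permutation of a forward column).  There is no score threshold: the
best window is always returned.

**Motif-cluster score (M1/M3 features).** Candidate hits are PWM
placements with llr > 0 on either strand.  A cluster is a chain of
non-overlapping hits; its score is the summed hit llr minus a gap cost of
`gamma = log(1 + 1/g)` nats per background nucleotide between consecutive
hits, a geometric gap-length model with mean `g` (default 35 nt, the
documented Cluster-Buster default).  The sequence score is the best single
cluster, floored at zero (local, Smith-Waterman style), computed by an
O(H log H) sweep that is verified against exhaustive enumeration over hit
subsets in the test suite.  A summed mode is also exposed; without a
cluster-score threshold, splitting a chain is never penalized, so the
summed mode reduces to maximum-weight non-overlapping hit selection.
Numeric parity with the original Cluster-Buster binary is not a goal;
parity with the exhaustive oracle is.

Bases outside A/C/G/T receive a large negative llr (-50) so hits never
cross them; windows with more than 10% N are skipped in genome scans.

## Training sets

Negatives are drawn by rejection sampling: each negative copies the length
of a positive drawn with replacement and must match that positive's GC
fraction within 0.02 (cap 10,000 attempts per negative).  Negatives never
overlap a positive (or an explicit exclusion list) but may overlap each
other.  No class reweighting is applied at 1:20 imbalance; area under the
precision-recall curve (AuPR) is the reported headline metric, since AuROC
is insensitive to false positives among 20-fold excess negatives.

Model classes: M0 (one PWM, best-site score), M1 (20 motif-cluster
features: 10 query-TF motifs, 10 co-regulatory motifs), M2 (15 track
features), M3 (all 35).

## Cross-validation and introspection

5-fold stratified cross-validation; AuPR (step interpolation / average
precision) and AuROC (trapezoid) are computed on pooled out-of-fold
predictions, which is stable for very small positive sets.  The M0
baseline needs no training; its curves come from varying the score
threshold.  Feature importances are Gini impurity decreases averaged
across trees (summing to 1), reported per feature with the across-tree
standard deviation and summed per group (query motifs, co-regulatory
motifs, tracks).

## Genome scanning

Windows of the model's window length (mean positive training-region
length) tile each contig with a 200 bp overlap between consecutive
windows; a final partial window is kept iff it is at least half a window
long.  Windows overlapping a training region by >= 1 bp are excluded.
Prediction is batched over windows.

## Variant scoring

Candidate windows place the variant at fractions 0.1 ... 0.9 of the window
(nine windows for interior variants; windows are clipped at contig ends
and deduplicated).  The same reference-axis window set serves both
alleles; for the alternate allele the edit is applied to the window
sequence before feature extraction, and insertion windows keep their
realized (longer) length — the features are length-tolerant.  Each
allele's score is the maximum over its windows; PRIME = alt - ref, in
[-1, 1] with granularity 1/151.

Significance: z = (PRIME - mean) / sd against an empirical background of
control-variant PRIMEs, fitted separately per variant class (SNV,
insertion), signed PRIME with significance on |z|.  Default thresholds:
|z| >= 9.65 (SNV) and 14.03 (insertion), or |PRIME| >= 0.3 in the
simple-threshold mode.  Saturation mutagenesis scores all three
substitutions at every position of a region (3L rows), reusing the shared
reference windows across substitutions, and reports a per-position
max-|PRIME| summary.

## Cross-sample activity z-scores

A region's activity under one sample's peak track is the peak signal
multiplied by the fraction of the *peak* length overlapping the region,
averaged over overlapping peaks.  Per-region z-scores across >= 2 samples
use the sample (n-1) standard deviation; zero-variance rows are flagged
and zeroed rather than dropped.

## Synthetic benchmark design

The generator is first-class code: it defines the study conditions under
which the method's properties are demonstrated.  All randomness flows from
one seed through named substreams (PWMs, genome, implants, panel, tracks).

**Genome.** i.i.d. background at GC 0.41 (human-like), 2 Mb by default; an
order-1 Markov background can be supplied instead.

**Motifs.** 12-column PWMs with a mixed column profile, as real motifs
have: one near-invariant core column (consensus probability 0.99999),
eight strong columns (0.96) and three weak columns (0.75), with the
consensus drawn from the genome's base composition so implanted sites do
not shift a region's GC.  The near-invariant core reflects the fact that
real binding sites have obligate core contacts: a core substitution
abolishes the site (llr drop ~13 nats), whereas any other single-base
change merely weakens it.  The query-TF feature group holds the true
motif plus nine jittered derivatives (log-normal per-cell noise),
emulating a motif collection that carries several similar PWMs per TF.

**Positives.** 200 regions of 300 bp. Homotypic grammar: three query-TF
sites per region, sampled from the PWM at temperature 0.6 (sharpened —
functional sites are high-affinity).  Heterotypic grammar: one query site
(sampled at temperature 1.0, i.e. the motif's natural fidelity — the
pattern of TFs whose own motif is only weakly enriched) amid all three
co-factor sites.

**Decayed clusters and decoys.**  Two background structures are essential
to the method's behavior and mirror real genomes:

* *Decayed distractor clusters* (100 loci, homotypic): positive-like
  clusters in which one site carries a deep (core) or, for one third of
  loci, a shallow (strong-column) break.  Left unlabeled, they are picked
  up by genome-wide negative sampling, and they position the forest's
  decision thresholds densely between "intact cluster" and "one functional
  site short".  Without them the forest is a step function far below the
  positives, and single-base edits score ~0: a cleanly separable training
  set produces an insensitive variant scorer.
* *Decoy near-sites* (6000, >= 150 bp apart): the query consensus with a
  broken core, isolated in the background.  They are invisible to cluster
  scoring (llr ~ 2 nats) but every SNV that repairs a decoy core is a
  large single-PWM score gain — the degenerate near-sites that make PWM
  scanning notoriously false-positive-prone.  The >= 150 bp spacing keeps
  chains of decoys below the classifier boundary via the gap penalty.

In the heterotypic grammar the distractors are instead query-only loci
(two per positive, one query site each) and co-factor-only loci (one per
positive, the co-factor pair/trio), so that neither motif group alone
separates positives from negatives and the forest must learn the
combination.

**Variant panel.** Loss variants flip a consensus-matching core base of an
implanted query site to the least likely base.  Gain loci are unlabeled
regions holding a partial cluster plus a near-miss site (a sampled site
with the wrong core base); the gain variant repairs the core.  Neutral
variants lie >= 50 bp from every implanted cluster site.  For strict
control sets (background distributions, specificity counts) the margin is
raised to one region length plus 50 bp so that no scoring window contains
an implanted cluster; background decoys are part of the background and are
not avoided.

**Loci layout.** Implant loci occupy non-overlapping slots separated by
one region length, so shifted scoring windows never reach a neighboring
cluster, and only GC-typical slots (within 0.04 of the target GC) host
loci, so GC-matched negative sampling always terminates.

**Tracks** (optional): peaks over a random 70% of positives with
log-normal signals, plus equally many background peaks with weaker
signals.

## What the benchmark does and does not show

Passing the packaged benchmarks shows that the implementation is
internally correct (oracle-verified cluster scoring, exact structural
identities), that the classifier recovers implanted cluster grammar from
realistic 1:20 training sets, that PRIME responds strongly and in the
right direction to single-base gains and losses while staying silent on
background SNVs, and that the forest's specificity advantage over
single-PWM deltas emerges from cluster context.  It does not show
performance on real genomes: the background lacks repeats, CpG islands,
conservation structure and assay noise; implanted sites follow the exact
generating PWM; and the decayed-cluster/decoy densities, though
qualitatively realistic, are chosen rather than measured.  Real AuPR
values for motif-only enhancer classifiers are typically far below the
benchmark's near-perfect separation, and real PRIME score distributions
are broader.

## Numerical choices

* Laplace pseudocount 1.0 per PWM cell on reading count matrices;
  probability-matrix inputs use a vanishing pseudocount.
* Gap parameter 35 nt; candidate-hit threshold llr > 0; natural log.
* Vote-fraction predictions (not averaged leaf probabilities) give PRIME a
  fixed 1/151 granularity; averaged probabilities are available via a
  flag.
* Ties in top-window ranking break by genomic order; identical fixed-seed
  runs are byte-identical.
* Window-shift grid: 9 offsets (variant at 10% ... 90% of the window),
  two-sided, fixed.
* The scanned region for saturation summaries in the standard evaluation
  is the positive with the median query-motif cluster score — an
  outlier-strong cluster sits so far above the decision boundary that
  non-core damage barely moves the classifier.

## Known limitations

* Exact numeric parity with MotifLocator/Cluster-Buster binaries is out of
  scope; scoring semantics (double-strand scan, min-max normalization,
  local cluster DP with geometric gaps) follow their documented models.
* M2/M3 variant scoring uses reference-coordinate track features for both
  alleles; variants cannot alter track features.
* The empirical z-score backgrounds are benchmark- or cohort-specific and
  must be refitted per model and variant class.
* Genome scanning is single-threaded and holds per-window features in
  memory; scanning mammalian-genome scale data would need chunking.
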