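# Methods

## Coordinates and data model

All intervals are 0-based half-open internally. Tables arriving in 1-based
inclusive coordinates (the common convention of curated prophage coordinate
tables) are converted at ingestion via a `dialect` flag on `read_regions`;
BED input is used as-is. Round-tripping any dialect through read/write is
the identity on normalized coordinates. Sequences are uppercased on ingest
and restricted to A/C/G/T/N; N counts as non-GC in composition statistics.
Genome ids are matched exactly; a `strip_version` flag handles
`NC_003143.1` versus `NC_003143`. Overlap between intervals always means at
least one shared base under half-open semantics — touching intervals do not
overlap.

## Signal extraction

A detector scans a genome with fixed-length windows at 50% overlap and
emits one phage probability per window. Extraction proceeds in five steps:

1. **Collapse.** The genome is tiled by step-sized segments; each segment's
   score is the arithmetic mean of the probabilities of the windows covering
   it (edge segments inherit their single covering window). With 50%
   overlap at most two windows cover a segment, so the mean coincides with
   majority voting of binarized window calls except at ties, which the
   downstream `>= threshold` rule resolves toward phage. The mean
   formulation stays well defined for any overlap factor.
2. **Per-genome normalization.** The baseline level of phage-like signal
   varies between genomes, so scores are normalized within each genome:
   z-score `(v − mean)/std` (population std; an all-equal input maps to
   zeros), robust z-score `(v − median)/(1.4826·MAD)` (MAD = 0 falls back
   to z-score), median subtraction, or none. The 1.4826 factor makes the
   MAD a consistent estimate of the standard deviation under a normal model.
   Statistics are computed over all of a genome's segments, with no masking
   of truth regions.
3. **Bidirectional EWM smoothing.** The exponentially weighted mean
   recursion `f_i = α·v_i + (1−α)·f_{i−1}` with `α = 2/(span+1)` (the
   standard adjust-free recursion, delegated to pandas) is run forward and
   on the reversed series, and the two passes are averaged — a symmetric
   filter by construction; span 1 is the identity.
4. **Threshold and gap merge.** Segments at or above the threshold (on the
   normalized scale) are positive; maximal positive runs separated by at
   most `max_gap` negative segments merge into one region, absorbing the
   gap. A region's score is the mean value of all its segments, gaps
   included.
5. **Length filter.** Regions shorter than `min_length` nt are dropped.

Defaults: z-score normalization, span 5, threshold 1.0 σ, max gap 2
segments, minimum length 8 kb — bracketing typical intact-prophage scales
(tens of kb) at a 1 kb step. The grid search (`tune_config`) enumerates
normalization × span {1,3,5,9,15} × threshold (0.5–2.0 σ in 0.25 steps for
normalized strategies, 0.5–0.9 for raw probabilities) × gap {0,1,2,3} ×
minimum length {4, 8, 10, 15} kb, macro-averages a chosen metric over
genomes, and breaks ties by higher recall, then smaller grid index.

The order is fixed as normalize → smooth → threshold → merge; thresholds
apply after smoothing. Useful invariants follow: calls under the
translation-invariant normalizations are unchanged by adding any constant
to a genome's collapsed scores; increasing the length filter never adds
regions; increasing the gap tolerance never adds regions and never removes
covered bases; calling is idempotent under re-merging.

## Evaluation

Region-level evaluation is realized on a step-sized grid: a grid segment is
positive when at least 50% of its bases (configurable) fall inside the
union of regions. Truth and prediction labels are cross-tabulated per
genome into confusion counts; MCC and ratio metrics derive from the counts,
with the 0/0 → 0 convention and MCC = 0 whenever a denominator factor
vanishes, keeping macro-averages total. The macro summary is the unweighted
mean over genomes; genomes with no true prophage are excluded from the
recall and FNR means (undefined there) but contribute to FPR, specificity,
precision, F1 and MCC. The grid realization makes the evaluation symmetric
and resolution-matched to the scan, and damps the boundary sensitivity
inherent in prophage annotation; absolute numbers therefore depend on the
grid step, which must be reported alongside them.

CDS-level sensitivity stratification groups phage genes by PHROG functional
category (head & packaging, tail, connector, lysis, integration & excision,
…) and reports the fraction of each category's genes called phage, ordered
by descending sensitivity. The GC-bias check computes the MCC of a model's
predictions on a GC-preserving shuffled control, where the ideal score is
0.00 and positive values flag compositional shortcuts.

## Dataset construction

Contamination filtering excludes a bacterial genome when any alignment hit
against the phage set reaches both 200 bp and 90% identity (both hit
orientations accepted). Segment sampling places `max(1, ⌊length/10 kbp⌋)`
non-overlapping fixed-length segments per genome by rejection sampling
(up to 1000 attempts per segment), topping up deterministically from free
gaps so the returned count is the maximum feasible; floor rounding treats
the rate as a density ceiling, with the stated minimum of one. Balancing
allocates bacterial segments round-robin across genomes (uniform per genome
up to the remainder, skipping genomes at capacity) until the phage count is
matched exactly; per-genome uniformity was chosen over length-proportional
sampling to maximize taxonomic breadth. Splitting assigns whole clusters —
ANI clusters for phages, genera for bacteria, each class independently — to
train/dev/test greedily, largest cluster first, into the split with the
largest remaining deficit against the 8:1:1 targets; when the number of
unassigned clusters equals the number of still-empty splits, those splits
are filled first, so all three partitions are always populated (at least
three clusters per class are required). Exact ratio fidelity is impossible
when clusters are large; the greedy rule minimizes deviation in practice
but is not a global optimizer.

Controls: the GC control permutes each sequence's characters uniformly at
random (multiset-identical, higher-order structure destroyed); single-class
controls select genomes one per cluster while possible to maximize breadth;
the CDS control cuts one variable-length segment per coding sequence
carrying its PHROG category.

## Probes

Probes are trained on frozen embedding matrices: a linear probe (affine map
+ sigmoid) and an MLP with two ReLU hidden layers (256, 64). Both minimize
binary cross-entropy with Adam (lr 1e-3, batch 64, ≤ 100 epochs), keeping
the parameters of the epoch with the best dev MCC and stopping after 10
epochs without improvement; ties keep the later epoch, since additional
optimization at equal dev performance generalizes better when the dev split
is small and saturates early. Class prediction uses a fixed 0.5 threshold —
the probe measures accessibility of the signal, not a calibrated
classifier. Embedding standardization and class weighting exist as options
and default to off. ΔMCC is the test MCC of a probe on strong
("pretrained") embeddings minus that of the same probe kind on weak
("random-init") embeddings.

## Candidate screening

Predictions overlapping any truth region are removed whole (no trimming).
The remainder, pooled over models, merge transitively wherever they share a
base; a candidate's support is the number of distinct contributing models,
and candidates below the support floor (default 2) are discarded. A
candidate is novel when no reference tool's calls overlap it. Gene-content
classification: likely phage at ≥ 10% structural genes (head & packaging +
tail + connector) with head/tail evidence; weak signal with only 1–2
structural genes (a degraded-prophage signature — this rule takes
precedence over the percentage band, which a 2-gene candidate can
technically enter); possible phage in the [5%, 10%) band; integrase plus
conjugation machinery → genomic island/ICE; integrase alone → genomic
island; otherwise unlikely phage. The rule set formalizes a manual review
protocol; boundary conventions (≥ at 10%, half-open band at 5%) are stated
choices where the narrative thresholds are ambiguous.

## Synthetic fixtures

Generators are pure functions of their seeds. Genomes are i.i.d. base
sequences at a target GC; prophage implants replace non-overlapping blocks
with composition-shifted sequence (default 0.40 versus a 0.50 host,
mirroring the common phage-below-host GC offset) and record truth
intervals. Score tracks are generated from the truth, not from a sequence
classifier: a window scores `signal_mean` when at least half of it lies in
an implant and `1 − signal_mean` otherwise, plus one genome-level baseline
offset ~ N(0, `baseline_shift_sd`) and per-window N(0, `noise_sd`) noise,
clipped to [0, 1]. This decouples tests of the extraction algorithm from
any model while reproducing the statistical structure the algorithm
assumes — elevated in-prophage scores over a genome-specific baseline.
Embedding clouds are unit-variance isotropic Gaussians with class means
`separation` apart (strong) and a fifth of that (weak), split 8:1:1.

Default conditions: 5 genomes × 300 kb, 2 implants × 40 kb each, 2 kb
windows at 1 kb step, signal mean 0.9, noise sd 0.1, baseline shift sd 0.1.
These sizes keep the full pipeline suite fast while leaving ~27% of each
genome phage, enough background for stable per-genome statistics. What the
fixtures deliberately omit: gene content, codon structure, mosaicism,
degraded prophages and other hard-negative mobile elements. Passing on
synthetic data therefore demonstrates the correctness of the machinery —
collapse arithmetic, normalization, merging, metrics, splits — not
real-genome detection accuracy, which depends on the upstream classifier.

Two synthetic stand-in tables reproduce published bookkeeping shapes for
ingestion tests: a genome-wide annotation table (80 genomes, 386 prophage
locations, 2–6 Mb hosts, 15–60 kb prophages) and a candidate review table
(305 gene-content records realizing the label distribution
22 likely / 92 possible / 113 weak / 31 island-ICE / 16 island /
31 unlikely, sampled inside each rule's region of input space). They are
synthetic fixtures — generated, not curated data.

## Numerical conventions and limitations

Population (ddof 0) standard deviations throughout; MCC computed in float
with exact zero guards; probabilities validated to [0, 1] at parse time;
score-track spacing must be constant and the step must divide the window
length for collapsing. The greedy split heuristic and the rejection-based
segment placement are reproducible but not globally optimal. Evaluation
numbers are grid-step dependent. The probe trainer is a compact numpy
implementation adequate for probing-sized problems (thousands of samples,
hundreds of dimensions); it is not a general-purpose deep-learning stack.
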