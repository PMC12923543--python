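# Methods

## Problem and approach

Oxford Nanopore direct RNA sequencing (dRNA-seq) reads native RNA 3'→5'. The
kit's ~70 bp DNA adapter is basecalled under an RNA model, so it appears in
the read as a corrupted, low-quality insert. In a normal read it sits at the
3' end after the polyA tail; when two molecules traverse the pore without the
software registering the open-pore gap, the adapter ends up *inside* a single
read, bridging two unrelated transcripts — a chimera artifact that aligners
report as a chimeric alignment indistinguishable from a genuine fusion.

nanochop addresses this as per-base token classification followed by
rule-based surgery:

1. **Classify** every base of a read as adapter/non-adapter with a
   quality-aware neural network.
2. **Smooth** the raw labels with a sliding-window strict-majority vote.
3. **Chop**: extract maximal adapter runs, filter them, excise them, and emit
   the remaining segments as independent reads.
4. **Validate** (for study-level evaluation): compare chimeric alignments
   against an orthogonal platform via interval concordance.

## Classifier

Single-nucleotide tokenization over {A, C, G, T, N} plus PAD; reads longer
than 32,770 nt are excluded from analysis. Architecture:

* **Embedding** of each token into a `embed_dim`-dimensional vector.
* **Quality block**: per-read z-scored Phred qualities (population SD; a
  constant read maps to zeros) pass through two ReLU MLPs, the second with a
  residual connection, are projected to the embedding width and *added* to
  the sequence embeddings. The wiring is project-then-add, so zeroing the
  quality input leaves a valid sequence-only path; the ablated variant simply
  omits the block. Whether the original design adds or concatenates quality
  features is not decidable from its description; project-then-add was chosen
  as the simplest wiring satisfying the residual contract.
* **Backbone**: a stack of gated dilated 1-D convolutions with residual
  connections (WaveNet-style `tanh × sigmoid` gating), dilation `4^l` at
  layer `l`. This is an attention-free long-receptive-field feature extractor
  standing in for a pretrained genomic language model; the downstream
  smoothing and chopping logic is backbone-agnostic. At the default widths
  (kernel 5, 4 layers) the receptive field is 341 nt — enough to see an
  entire adapter plus the polyA anchor and flanking transcript context from
  any position near a boundary.
* **Head**: two-layer MLP to 2 logits, softmax over (adapter, non-adapter).
  A base is called adapter when P(adapter) > 0.5 (argmax); the threshold is
  fixed, never tuned.

The loss is binary cross-entropy averaged per read over its own unpadded
tokens, then averaged *unweighted* over the reads of the mini-batch (a long
read does not dominate a short one). Probabilities are clipped to
[1e-7, 1 − 1e-7] inside the logs. Padding positions are masked out of loss
and metrics. Metrics pool TP/FP/FN/TN over all base positions of all reads;
zero-denominator metrics are defined as 0.

The network and its backward pass are implemented directly in numpy
(convolutions as im2col + GEMM with the filter and gate fused into one weight
matrix), with Adam (β₁ = 0.9, β₂ = 0.999), global gradient-norm clipping at
5.0, a plateau scheduler that halves the learning rate when validation loss
stops improving, checkpoint selection by best validation F1, and early
stopping on validation F1. All randomness (initialization, batch order,
validation subsampling) flows from explicit seeds; runs are reproducible in
single-threaded numerics.

### Scales and training recipes

Two presets share one architecture:

| preset | embed / hidden | layers | params | intended use |
|---|---|---|---|---|
| `ModelConfig()` | 256 | 4 | ~2.9 M | reference-scale width |
| `ModelConfig.small()` | 24 | 4 | ~26 k | CPU-scale experiments |

`TrainConfig()` defaults carry the reference optimization settings (batch 64,
initial lr 2e-5, validation every 20,000 steps, up to 60 epochs) — a recipe
suited to fine-tuning a large pretrained backbone. Training the small model
from scratch uses `TrainConfig.desk_scale()`: lr 1e-2, batch 32, validation
every 250 steps, 2 epochs, early-stop patience 6. These values came from
pilot runs at a few thousand reads and are the package's own scaled recipe,
exposed as an explicit preset rather than silently replacing the reference
defaults. Under this recipe the small model passes per-base F1 0.99 on the
default 20,000-read simulation within ~1,000 optimizer steps (the benchmark
`scripts/acceptance.py` reruns from scratch).

Benchmark problem sizes: the classifier benchmark simulates 20,000 reads and
the ablation benchmark 10,000 reads, both split 8:1:1 — the same conditions
at a size a single CPU trains in minutes.

## Synthetic data generator

Each read is assembled from parts, with ground-truth labels fixed by
construction (adapter bases 1, everything else 0):

* `negative`: body + polyA
* `end3`: body + polyA + adapter
* `internal`: body₁ + polyA + adapter + body₂

The polyA tail is biological signal, not adapter: it is labeled 0 and kept in
retained segments, and it precedes every adapter occurrence, mirroring real
dRNA-seq read structure where the adapter follows the tail.

Defaults and their provenance:

* **Bodies**: log-normal length, median 700 nt, σ = 0.6, clipped to
  [20, 3000] (mean dRNA-seq read lengths run ~680–1150 bp; the 20 nt floor
  guarantees bodies survive the chopper's segment filter by construction).
  Uniform base composition; qualities Normal(12, 3) clipped to [0, 93].
* **PolyA**: geometric length, mean 30; body quality model.
* **Adapter**: a fixed arbitrary 70-mer template (the real kit adapter's
  sequence is proprietary; the method detects a learned pattern, not a
  specific sequence, and any template can be supplied). Corruption:
  substitution rate 0.07 + indel rate 0.03 ≈ 10% per-base error, matching
  the ~Q10 mean quality observed for real internal adapters; qualities
  Normal(10, 3).
* **Category mix**: 9:1 positive:negative, 1:1 internal:3'-end within
  positives; largest-remainder rounding makes the counts exact (600,000
  reads split 8:1:1 give exactly 480,000/60,000/60,000) and the split is
  stratified per category.
* **Ablation dataset** (`ablation_adapter_model()`): substitution rate raised
  to 0.20 so the adapter's residual sequence signal is weak at the
  boundaries, and adapter quality mean lowered to 8.0 (the low end of real
  internal-adapter qualities) against the body's 12.0. This follows the
  prescription that the ablation condition be sequence-ambiguous but
  quality-separable: the sequence-only model plateaus near F1 0.97 and the
  quality block recovers most of the remainder.

What the generator does **not** emulate: real transcript sequence (bodies are
random, so homopolymers, repeats and genomic adapter look-alikes are absent);
position-dependent error profiles; truncated or degraded adapters; more than
one adapter per positive read in the default mix (a multi-adapter builder
exists for chopper testing). Passing benchmarks on this simulation therefore
demonstrates that the architecture can learn and localize a corrupted,
low-quality insert to near-base precision — not field performance on real
flow-cell data, which depends on harvesting genuine adapter instances.

## Refinement

For position *i* with half-width *k* = (W−1)/2, the refined label is 1 iff
the sum of raw labels in [i−k, i+k] exceeds W/2 (strict). The vote always
reads the raw track, never its own output, so there is no error propagation
and the result is order-independent. At read boundaries the window truncates
to valid indices and the threshold becomes half the truncated size — still
strict, so an exact half votes 0. W defaults to 21 (`--smooth-window`),
W = 1 is the identity. Implementation is a cumulative-sum pass; tests hold it
equal to a literal per-position vote.

## Chopper

Rules, in order, with their CLI flags:

1. calls shorter than 13 nt are not adapters (`--min-adapter-len`);
2. more than 4 surviving calls ⇒ retain the whole read untouched
   (`--max-adapters`) — the count refers to calls that survived rule 1, the
   natural sequential reading;
3. otherwise excise the calls and keep the between-cut segments with their
   original qualities;
4. drop segments shorter than 20 nt (`--min-segment-len`).

Segments are named `source_id:ordinal` (1-based over emitted segments).
Calls touching the read ends follow the same rules; 3'-end versus internal is
a reporting distinction only. Every base is accounted for: segments + removed
spans + discarded short segments partition the read, an invariant the tests
enforce on random inputs. Coordinates are 0-based half-open throughout; BED
output is native.

## Validation utilities

Chimeric alignments are primary SAM records bearing an SA tag; each becomes
an ordered interval list (primary first, then SA entries, spans from
reference-consuming CIGAR operations, SAM's 1-based POS converted to 0-based
half-open). Two chimeras are concordant when their interval lists have equal
length and admit a one-to-one matching with equal chromosome and strand and
both endpoint offsets strictly below the tolerance (default 1000 bp). The
"distance difference" rule is ambiguous between endpoints, midpoints and
junctions; the endpoint reading is the strictest common interpretation and
the tolerance is configurable so alternatives remain testable. Equal-length
matching is deliberate: a 2-part chimera never supports a 3-part one. The
support rate is the fraction of query chimeras concordant with at least one
reference chimera (0 for an empty query).

BLAT-style identity is match length over query length; the package computes
the ratio from caller-supplied counts and offers an edit-distance
approximation (via edlib, infix mode) for self-contained tests — running an
actual aligner is out of scope.

## Numerical and degenerate-input choices

* float32 parameters and activations; loss accumulations in float64.
* Zero-variance quality reads z-score to all zeros.
* Empty FASTQ, empty reads, and empty candidate lists flow through every
  stage producing empty outputs rather than errors.
* Overlapping adapter candidates are an upstream-bug hard error, not silently
  merged.
* Largest-remainder apportionment breaks ties by larger fractional part,
  then lower category index — deterministic.
* `U` → `T` happens once at FASTQ ingest; one alphabet flows through the
  tokenizer.

## Known limitations

* The backbone is trained from scratch per run; there is no pretrained
  transfer, so very small training sets underperform until a few hundred
  optimizer steps have accumulated.
* The quality block's wiring (project-then-add) is one of several residual
  designs consistent with its description.
* Multi-adapter reads beyond 4 calls are retained whole by design; reads
  whose adapter was only partially detected can yield boundary slop that the
  13 nt / 20 nt filters do not catch.
* `is_concordant` enumerates matchings exactly up to 6 intervals and falls
  back to sorted-order pairing beyond that.
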