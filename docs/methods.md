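# Methods

## The problem and the training signal

Inserting a whole domain into a host protein usually destroys it; a few
surface positions, typically in flexible loops, tolerate the insertion and
can couple the two domains allosterically. Screening all positions
experimentally is expensive, so `dominsert` learns tolerance from a signal
evolution already provides: proteins in which one domain's annotation is
interrupted by a second, nested domain. Deleting the nested insert leaves
the *parent_only* sequence together with a junction position that
demonstrably tolerated a domain-sized insertion.

## Curation model

Coordinates are 0-based half-open throughout; the junction `j` counts the
residues N-terminal of the deleted insert, so the insert sat between
parent_only indices `j−1` and `j`. An insertion event requires a parent
annotation with exactly two segments and a contiguous insert annotation
filling the inter-segment gap exactly (a `gap_slack` parameter, default 0,
absorbs boundary imprecision when enabled). Deliberately skipped and
logged rather than guessed: parents with more than two segments, gaps
matched by multiple candidate inserts, and overlapping same-superfamily
segment sets. Multiple events in one protein each yield an independent
record, deduplicated by (accession, insert span).

Filters, in order: duplicate removal; full-protein length strictly less
than 2,048 residues; records with non-canonical residues dropped (the
one-hot encoder is defined over the 20 canonical codes; configurable);
redundancy reduction to at most one record per cluster of an externally
supplied UniRef50-style cluster map, with unmapped accessions dropped
(intersection semantics). The package never computes sequence identity
itself — identity clustering is a solved, external problem.

Positive labels are the junction-centred window {j−1, j, j+1} (radius
configurable, default 1): annotation boundaries are imprecise and
experimentally tolerant sites come in short stretches. Every other
position is *unknown*, not negative.

## Splits

All three strategies share one test set sampled first as whole
(parent, insert) combinations until it holds ≥10% of records. Sampling
test combinations before building any split guarantees that no strategy
ever trains on a test combination, and makes the test set byte-identical
across strategies — the property that lets models trained under different
regimes be compared side by side. The `combination` strategy packs whole
combinations greedily (largest first, lexicographic tie-break) toward the
70:20 record targets; `single` draws one seeded-uniform representative per
combination and divides them 79:21, the ratio implied by reported
train/validation sizes of 174 and 46. The "at most one record per
combination" guarantee of `single` applies to train ∪ validation; the
shared test set intentionally keeps whole combinations.

## Encodings

One-hot (D = 20, columns alphabetical by one-letter code) is the baseline.
Richer encoders plug in behind a provider contract: deterministic,
exactly L rows for an L-residue sequence (special begin/end token rows
must be stripped), dimension fixed per encoder. An ESM-2-style language
model (D = 2560) is the intended production provider but is not bundled —
no network or GPU is needed to build or test the package. Providers are
cached on disk as `.npy` + JSON sidecar keyed by (encoder id, sequence
hash); round-trips are bitwise.

The **fixture embedder** exists for testing: each position's row is the
scaled sum of seeded pseudo-random basis vectors keyed by (residue,
offset) over a centred 5-residue window, with per-side boundary symbols.
Identical 5-mer contexts therefore give identical rows, and any motif
spanning the window is linearly separable from background. One boundary
consequence: the first position of "AAA" and "AAAA" sees the same padded
window in both sequences and embeds identically, while positions 1–3
differ — the tests assert this closed form.

## Classifier head and training

A two-layer perceptron with ReLU (D → H → 2, H = 512 by default — the
hidden width is a free design choice; 512 keeps the head CPU-fast at every
D the package supports) maps each residue independently to two logits; the
insertion score is the softmax probability of the tolerant class, so a
zero-initialized head scores 0.5 everywhere and all scores are strictly
inside (0, 1).

Training: Adam (default moments, lr 1e-5), one sequence per step drawn by
seeded shuffle and reshuffled each epoch, 1,500 steps by default. The loss
is a mean two-class cross-entropy over a per-step mask: all positive
positions plus **one** unknown position sampled uniformly afresh at every
visit, serving as that step's negative. Positions outside the mask
contribute exactly zero — gradients flow only through masked rows (the
implementation computes the forward/backward pass on the masked rows
only). Per-visit negative resampling is used rather than a fixed negative
per sequence; it is the most literal reading of "one randomly selected
site per iteration" and exposes the model to more of the unknown
background. Checkpoints (weights as `.npz` + JSON sidecar with encoder id,
dimensions, step and config) are written on a ladder every
`checkpoint_every` steps; step count controls stringency — longer training
sharpens traces at some cost in sensitivity — so checkpoint selection is
left to the user rather than hard-coded. Validation AUROC (positive vs
unknown positions, pooled) is recorded at every checkpoint.

Fine-tuning on experimental points continues the same optimization, but
the per-step mask is the full set of assayed positions of one sequence
with both classes given explicitly — no random negative sampling, since a
screen provides true negatives.

The head, gradients and Adam are implemented directly in NumPy: the model
is small enough that a framework adds nothing, and a self-contained
implementation keeps the entire trajectory bit-reproducible from one seed
on one device (reproducibility across BLAS builds is not claimed).

## Evaluation conventions

Screen tables are 1-based per-position TSVs with one column per insert
domain. `ge1_of_k` marks a position tolerant if any insert has strictly
positive enrichment, everything else negative; `ge1_of_k_with_unknown`
sends unassayed positions to UNKNOWN instead; `m_of_n` requires ≥ m
tolerated inserts for POS and ≥ m intolerant for NEG (UNKNOWN otherwise) —
parameterized because published tolerated/intolerant codings vary. AUROC
is the Mann–Whitney statistic (ties 0.5) computed by ranking, equal to
exhaustive pairwise concordance and invariant under monotone transforms of
the trace. Traces are never smoothed by default. Normalized site scores
(site ÷ trace mean) compare engineered sites across orthologs with
different baseline score levels. Concatemer prediction slices the trace of
a head-to-tail n-mer back into per-copy windows and reports their
positionwise mean; with a context radius r encoder, copies can differ only
within r residues of the copy junctions.

## The synthetic world

`generate_synthetic_corpus` emulates the mined corpus: uniform-background
proteins of 150–400 residues, a planted 5-mer motif (`GSGSG`) whose centre
coincides with the junction, insert domains of 60–140 random residues
spliced in immediately after the motif centre, two-segment parent plus
gap-filling insert annotations, Zipf-skewed superfamily identifiers
(unequal combination sizes exercise the split logic), 20% decoy proteins
without events, and a one-cluster-per-protein map with optional duplicate
clusters. Screen tables mark the junction window tolerant across all
pseudo-inserts with configurable label-flip noise.

What a green pipeline test establishes: curation is lossless against the
planted truth; the masking objective can recover a local sequence signal
(held-out AUROC ≥ 0.85 with the D = 64 fixture embedder at 1,500 steps);
everything is deterministic. What it does not establish: performance on
real proteins, where the tolerance signal is structural and distributed
rather than a literal motif — real-data accuracy depends on the embedding
provider and corpus supplied by the user.

## Numerical choices and limitations

- Softmax and cross-entropy are computed with max-shifting;
  log-probabilities are floored at 1e-300 before `log`.
- Quartile summaries use linear interpolation (NumPy default, type 7).
- `reduce_redundancy` keeps the first record per cluster in sorted record
  order — deterministic and idempotent, not identity-aware.
- Screen positions are validated against the stated sequence length;
  conflicting duplicate rows are an error, exact duplicates are collapsed.
- Known limitations: no transformer head (the head is pluggable but only
  the perceptron is implemented); no bundled language-model provider; no
  SASA/conservation computation (consumed as external annotations only);
  oligomer handling is limited to sequence concatemers.
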