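# Methods

## Problem setting

A missense variant replaces one amino acid in a protein; most other
non-synonymous classes (stop-gain, frameshift, start-lost, in-frame
deletion) truncate or excise part of the chain. The package predicts a
probability that a variant is pathogenic from three aligned views of the
local sequence: the wild-type window, the mutant window, and the
evolutionary conservation profile of the same residues. Because curated
clinical labels are scarce relative to the input dimensionality, the
model is additionally trained on simulated variants labelled from
conservation alone, through a second classifier head on a shared encoder
(multitask learning). Reported scores always come from the clinical head.

## Curation rules

Reports carry one of five classes (P, LP, VUS, LB, B) plus a free-text
review status. Reports whose review status is one of

* `no assertion for the individual variant`
* `no assertion criteria provided`
* `no assertion provided`

are dropped before merging (exact string match after case/whitespace
normalization — substring matching would over-filter statuses such as
"criteria provided, single submitter"). Merging is order-independent:
any P/LP with no B/LB ⇒ pathogenic; any B/LB with no P/LP ⇒ benign;
contrary reports or VUS-only evidence ⇒ excluded. Common population
variants with allele frequency strictly above 0.1% ("higher than"
is read as a strict inequality) are added as benign unless the same
(transcript, normalized one-letter term) already occurs in the clinical
set. During training, pathogenic examples are oversampled 4-fold to
balance the class ratio.

## Conservation profiles

Alignment rows are kept when identity > 30% (identical residues over the
row's aligned positions) and overlap ≥ 80% (non-gap positions over query
length). The identity inequality is strict ("over 30%"); overlap is
inclusive. A column is *reliable* when more than 10 non-query rows align
a residue there; unreliable columns yield all-zero frequency rows.
Frequencies are normalized counts over the 20 canonical amino acids; the
query is included in the counts by default (the human residue is part of
the conservation evidence) but never in the depth; both behaviours are
configurable because the convention is genuinely open. Non-canonical
residues (B, Z, X, U) count toward depth but occupy no frequency bin; in
the degenerate case of a deep column composed entirely of non-canonical
residues the column is treated as unreliable so that the row-sum
invariant (reliable rows sum to 1) holds unconditionally.

## Simulated variants

For each residue, the nine single-nucleotide substitutions of its codon
are enumerated; resulting amino acids other than the reference and stop
define the reachable missense set. Candidates are labelled:

* **benign-like** — mutant residue frequency at the column > 10%
  (observed tolerance);
* **pathogenic-like** — the column is conserved: its maximum frequency
  > 50%.

When both rules fire (a conserved column with a tolerated minor residue)
the benign rule wins by default: observed tolerance is direct evidence,
whereas conservation is indirect. The precedence is configurable and the
alternative is exercised in tests. Stop-gain substitutions are discarded
(the simulator covers missense only). A seeded uniform subsample
(default 10%) keeps training cost reasonable; a hook accepts an optional
64×3 substitution-rate table for rate-weighted sampling, but uniform
sampling is the default because reachability is the only hard constraint
of the data-generating story.

## Featurization

Windows are `L` residues centred on the variant (default 201; desk-scale
experiments use 41), with `(L-1)/2` positions either side; positions
outside the protein encode as all-zero rows. Centering anchors per
class: missense — the substituted residue; start-lost — the new
initiation site (for `p.Gly2_Met46del`, residue 46); stop-gain — the new
termination site; frameshift — the indel site, treated as a termination;
deletion — the first deleted residue. Mutant windows: missense
substitutes the centre; stop-gain/frameshift pad from the centre
(inclusive: a stop codon contributes no residue — keeping the centre
residue is available as a flag) to the window end; start-lost pads
everything before the centre; deletions pad the deleted span in place
rather than shifting downstream sequence into the gap (shifting would
misalign the profile slice, which is indexed by wild-type coordinates).
The alphabet order is fixed (alphabetical one-letter codes,
`ACDEFGHIKLMNPQRSTVWY`) so serialized tensors are portable. The optional
85-dimensional substitution-descriptor vector is zero-filled when a
variant is missing from the feature table. Internally all coordinates
are 0-based half-open; I/O is 1-based HGVS.

## Network

Three bidirectional LSTM encoders (one each for wild-type, mutant,
profile; hidden size `H` per direction) produce per-residue features.
For each branch (wild-type, mutant) the encoder output is concatenated
residue-wise with the profile encoder output and passed through a second,
unidirectional LSTM of which only the final state is kept; the two branch
vectors concatenate into the extracted feature vector (length `2H`). The
second stage is unidirectional by default because only the last state is
consumed; a bidirectional option doubles the width. Each task head is
two fully connected layers (ReLU, dropout 0.3 after the first, 2-way
softmax). With the substitution-feature branch enabled, the extracted
vector and the 85-vector each pass a separate linear layer with sigmoid
activation before concatenation, compensating the scale difference
between the two inputs. Loss is softmax cross-entropy.

**Initialization.** Weights are uniform `±1/√H`, with two deliberate
exceptions. First-stage input projections are uniform `±1`: the inputs
are one-hot or frequency rows of at most unit norm, and unit-scale
projections give the encoders a diverse bank of nonlinear per-residue
features (e.g. column-peakedness detectors) from the first step, which
small-scale init only develops after many epochs. Gate biases are set
chrono-style — forget `+3`, input `−3` — so each LSTM starts with a
memory horizon comparable to the window length and behaves as a slow
integrator of per-residue features rather than a short-memory filter.
Both choices matter at desk scale: with standard initialization the
window-level conservation composition is invisible to the readout and
five-epoch training stalls at the base rate.

**Multitask schedule.** Default is alternating batches (one clinical,
one conservation, repeat; the longer stream finishes unpaired). A joint
mode sums the two losses per step with a configurable conservation
weight. Optimizer is Adam with fixed defaults (β₁ 0.9, β₂ 0.999,
ε 1e-8). All randomness (shuffling, dropout, init) flows from explicit
integer seeds, so loss logs and scores are bit-reproducible.

## Evaluation

ROC-AUC uses the pairwise-concordance definition (ties one half);
PR-AUC is the step-interpolated area (precision constant moving right to
left), i.e. average precision over the threshold sweep. Both delegate to
scikit-learn, which implements exactly these definitions; the test suite
checks them against brute-force oracles to 1e-9 on instances up to
n = 1000. Cross-validation folds are drawn only from clinical-source
examples; common-population and conservation examples may join every
training fold but are never test points, and pathogenic oversampling is
applied inside training folds only so duplicates cannot straddle the
split. Top-k recall ranks each patient's variants by descending score
(ties broken by stable input order) and reports the fraction of all
causal variants ranked within the top k of their own patient; a
recessive patient with two causal variants contributes two to the
denominator. A per-patient variant of the metric is a documented option.

## Synthetic study conditions

The fixture generator produces every input the pipeline consumes, as a
pure function of a config and a seed. Defaults: 30 transcripts of 200
residues, 60-row alignments, 41-residue windows, ~2000 clinical and
~6000 conservation examples, 10% clinical label noise, 20 patients with
50 background variants each.

Alignment columns are planted in contiguous segments (geometric lengths,
mean 60 residues) of three kinds: *conserved* (every row carries the
query residue), *polymorphic* (a single-nucleotide-reachable alternative
residue appears at 30% frequency), and *background* (query residue at
45%, otherwise random). Segmental structure emulates protein domains,
where conservation is spatially autocorrelated; it is also what makes
the planted signal learnable at desk scale, since the window-level
composition of conservation then carries label information. Each
alignment additionally contains two low-overlap rows and one
low-identity row that the row filter must remove. Clinical truth is
planted from the same structure — substitutions at conserved residues
pathogenic, tolerated polymorphisms benign — with each label flipped
with probability 0.1, which caps the attainable held-out ROC-AUC near
0.90. Report tables wrap the planted truth in ClinVar-like rows and
inject VUS-only, conflicting, excluded-review-status and "rescued"
records (a contrary report that is filtered out by review status) with
known expected outcomes.

Because the labeled candidate pool at desk scale (~16k) is far smaller
than genome scale, the training bundle samples conservation examples to
an explicit target count (6000) rather than the fixed 10% fraction used
for genome-scale simulation; the simulator's own default fraction is
unchanged.

What passing on these fixtures does **not** show: real MSAs have
phylogenetic correlation between rows, alignment errors and length
variation; real pathogenicity depends on structure and function beyond
local conservation; real label noise is not symmetric. Results on the
fixtures validate the machinery and the learnability of
conservation-shaped signal, not clinical performance.

## Desk-scale experiment sizes

The reference experiments (`varcons.experiments`) use a 32-unit encoder,
batch 64, learning rate 3e-3, 5 epochs, 4-fold pathogenic oversampling,
an 80/20 train/test split of the clinical examples, and — for the
transfer comparison — clinical training sets of 200 examples and three
seeds per arm. These sizes give each run a few minutes on one CPU while
leaving the transfer effect (multitask ≥ single-task with scarce
clinical data) clearly measurable.

## Known limitations

* Windows longer than the protein are padded, never tiled; variants in
  proteins shorter than the window see mostly padding.
* The simulator ignores mutation-rate heterogeneity (the rate-table hook
  exists but no rates ship with the package).
* The NumPy autodiff engine is eager and single-threaded; it is sized
  for desk-scale experiments, not genome-scale training.
* One-letter and three-letter HGVS substitutions are parsed; exotic
  terms (extensions, duplications, delins) are not.
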