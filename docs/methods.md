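# Methods

## Problem setting

Single-strand breaks (SSBs) are single-nucleotide lesions mapped genome-wide
by assays such as S1 END-seq (non-strand-specific) and SSiNGLe-ILM
(strand-specific). Given a reference genome and a BED of break summits, the
package frames SSB prediction as binary classification of 251 bp windows:
does the center nucleotide carry a break? All coordinates are 0-based; BED
input is 0-based half-open with the summit at `start`.

## Dataset construction

**Positives.** Each usable summit contributes the 125 bp context on either
side (251 bp total). In non-strand-specific mode every site contributes the
window *and* its reverse complement (the assay cannot distinguish strands),
doubling the positive count; in strand-specific mode minus-strand sites are
reverse-complemented instead. Windows that would cross a chromosome end or
contain N are skipped and tallied — the behaviour at chromosome edges is a
package decision, since summit sets in the wild do occasionally sit near
contig boundaries.

**Negatives.** For N positives and imbalance ratio Q, N × Q windows are drawn
uniformly over eligible centers. A center is eligible when its window fits
the chromosome and it lies at least `exclusion_radius` bp (default 125, i.e.
no overlap between a negative's center and any positive's window center) from
every break site. The radius is configurable down to 0, which reproduces the
literal "exclude the positive positions" reading; the wider default prevents
label contamination from windows that overlap true break contexts. Windows
containing N are rejected and redrawn. An optional dinucleotide-shuffle mode
replaces genomic negatives with Euler-path (last-exit-tree) shuffles of the
positive windows, which preserve each window's exact dinucleotide multiset —
useful for testing whether a model learns more than local composition.

**Split.** Evaluation is leave-one-chromosome-out: all examples on the test
chromosomes (default chr1) are held out; negatives are sampled per split side
so |negatives| = Q·|positives| holds exactly within train and test.

## Architecture

Input windows are one-hot encoded (4 × L, rows [A, C, G, T]; N columns are
zero). The classifier is two-stream:

* full stream: 1×3 stem convolution (4→16 channels) → 15 residual units at 16
  filters → 1×1 transition (16→32) → 15 residual units at 32 filters → 1×5
  average pooling (stride 5, 251→50) → 1×1 projection (32→64) → multi-head
  self-attention (h = 8, d_k = d_v = 512, d_model = 64) → flatten (3200);
* center stream: middle 9 bp → inception block (1×1/1×3/1×5 convolutions, 4
  filters each, concatenated with the input to 16 channels) → self-attention
  with d_model = 16 → flatten (144);
* head: concatenation (3344) → 128 → 64 → 1 with ELU activations, dropout
  0.5/0.3 after the hidden layers, sigmoid output.

Each residual unit computes `ELU(x + conv3(ELU(conv5(x))))` with same
padding. Channel changes between stages use 1×1 convolutions — the minimal
choice that keeps residual units homogeneous and reconciles d_model = 64
with the 32 stage-2 filters. The center stream carries its own attention
block by default; `center_attention=False` gives the convolution-only
variant. How features reach the MLP is a genuinely open design point; we
flatten. The default configuration totals 1,929,917 trainable parameters
(1.9 M at one decimal).

### Numerical core

The network runs on a small reverse-mode autodiff engine over NumPy float32
arrays (same-padded im2col convolutions, batched matmul, ELU/sigmoid/softmax,
average pooling, dropout). Two numerical choices matter:

* **Attention factorization.** Because d_model (64) ≪ d_k (512), attention
  logits are evaluated as `M (W^Q W^K^T) M^T / sqrt(d_k)` plus the exact
  rank-one bias terms, and the value/output path as `Σ_i attn_i M (W_i^V W_i^O)`
  (projection biases pass through unchanged since softmax rows sum to 1).
  This is an algebraic identity — identical parameters, function and
  gradients — that avoids materializing (B, L, h·d_k) arrays and dominates
  the speedup that makes CPU training practical.
* **Initialization.** He-style uniform fan-in initialization, with the second
  convolution of every residual unit scaled by 1/sqrt(2·depth) (Fixup-style)
  so activation variance stays bounded through the unnormalized residual
  stack; biases start at zero. All weights derive from `ModelConfig.seed`.

Training minimizes binary cross-entropy computed from logits in the stable
`max(l,0) − l·y + log(1+exp(−|l|))` form (the score-space form with its
1e-7 clamp is exposed for evaluation); the optimizer is Adam at lr 1e-3, no
weight decay, batch size 256 by default. No class weighting is applied even
at Q = 100: the imbalance analysis depends on the raw class prior shifting
the score distribution, and weighting would cancel exactly that effect.
Model selection keeps the epoch with the best validation AUPRC (robust under
imbalance); validation is a stratified 10% split of the training
chromosomes. Early stopping triggers after `early_stop_patience` epochs
without strict improvement. The loss, optimizer, learning rate and epoch
budget are package defaults, documented here precisely because they are
choices, not published values.

## Metrics

AUROC uses the Mann–Whitney midrank identity (ties count half); AUPRC is
average precision with tied score blocks treated as single thresholds. Both
are validated against exhaustive all-pairs / rank-walk oracles to 1e-12 and
cross-checked against scikit-learn.

## Attribution

Integrated gradients with the GC-content baseline (every column
0.3/0.2/0.2/0.3 over A/C/G/T) and a midpoint Riemann rule:
`IG = (x − x') · mean_t ∂F(x' + (t−0.5)/m (x − x'))/∂x`, default m = 64 for
reports and m = 256 where completeness is asserted (|ΣIG − (F(x) − F(x'))|
within 1% + 1e-4, with m = 4096 as the high-resolution oracle). The center
stream is attributed as a view of the full window's middle columns, so both
streams' gradients land on the same genomic nucleotides. Per-nucleotide
tracks take the observed-channel entry (not the channel sum), matching
sequence-logo practice; whether the original analyses summed channels is not
documented anywhere we could check, so this is a stated package convention.
Motif aggregation finds each track's maximal-contribution window (ties →
leftmost), reports the offset distribution of window centers from the
sequence center, and accumulates a position-frequency matrix with consensus.

## Scanning and landscapes

`scan_sequence` scores every stride-th window center; window counts follow
`floor((len − 251)/stride) + 1` exactly. Windows containing N are scored on
zero columns and flagged. Putative sites are centers scoring ≥ 0.5 by
default — the calling threshold is exposed because no principled value
exists without calibration data. Variant analysis rescans the 501 bp region
centered on a SNP, so every window overlapping the variant is covered exactly
once and all other deltas are exactly zero. Species landscapes draw a fixed
number of random N-free windows per genome (normalized sampling, removing
genome-size bias), count windows scoring above threshold, and correlate that
count with mean CpG content across species (Pearson r with the t-transform
p-value).

## Synthetic benchmark

The generator emulates the two sequence signals the classifier is meant to
detect: an i.i.d. background with composition (0.3, 0.2, 0.2, 0.3) over
(A, C, G, T); 2,000 break sites (default) placed ≥ 250 bp apart and ≥ 125 bp
from chromosome ends across two 500 kb chromosomes; a GGC trinucleotide
written with its middle base on the site coordinate (window indices 124–126)
with probability `motif_strength` (default 1); and CpG enrichment within
± 50 bp of the site, implemented by importance resampling — 24 candidate
flank segments are drawn i.i.d. and one is kept with probability
proportional to 3^(CpG count) (default enrichment 3). The default spacing of
250 bp is the widest that lets 2,000 sites fit two 500 kb chromosomes with
edge margins.

What the benchmark does **not** emulate: chromatin and replication-timing
structure, strand-asymmetric damage, sequencing noise in summit calls,
genome-scale linkage between CpG islands and other features. Passing the
end-to-end checks therefore demonstrates that the pipeline is correct and
that the architecture can learn and explain localized sequence signals at
realistic imbalance — not that real SSB landscapes are predicted at any
particular accuracy. Published real-data figures require the original
sequencing datasets and reference genomes and are out of scope here.

## Problem sizes used by the test suite and acceptance script

The end-to-end checks train the reduced-depth configuration
(`blocks_per_stage = 4`, all other hyperparameters at their defaults) on the
default 2,000-site benchmark with Q = 1, batch size 64, up to 4 epochs —
chosen as the smallest run that cleanly separates the held-out chromosome
(AUROC > 0.99 in our runs). The imbalance comparison uses a 200 kb / 60-site
benchmark and a one-block, d_k = 16 model over three seeds; it measures
background false-positive rates at threshold 0.5 on ~3,000 sampled windows
per seed. The landscape statistic uses five synthetic species whose
genome-wide GC content rises from 0.30 to 0.62, 1,000 windows each: higher
GC simultaneously raises CpG density and the frequency of high-scoring
center motifs, so the trained model's predicted break counts should rise
with mean CpG (r > 0).

## Known limitations

* The autodiff core implements exactly the operations this architecture
  needs; it is not a general framework (no higher-order gradients, no GPU).
* Scanning a full mammalian chromosome at stride 1 is CPU-bound; use strides
  or region restriction for interactive work.
* Dinucleotide-shuffle negatives preserve composition but not positional
  genomic context; conclusions drawn from them are about sequence content
  only.
* `N` handling is asymmetric by design: dataset construction rejects windows
  with N (clean labels), while scanning scores them on zero columns and
  flags them (robust inference).
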