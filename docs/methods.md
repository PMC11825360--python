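# Methods

`svcompare` discovers structural variants (SVs) in a *case* long-read genome
by direct comparison against one or more *control* genomes. Instead of
fitting per-SV-type inference models to alignment signatures, it renders the
alignment evidence of case and control into a single RGB image and delegates
recognition to a pixel-level instance-segmentation step whose mask is then
decoded into components, breakpoints, allele fractions (AFs), genotypes and
case-vs-control categories.

## 1. Read symbol series

Every read is summarised as an ordered series over {M, V, I}: M for a
forward-mapped segment (from the primary or a supplementary alignment, or
from splitting a CIGAR with a deletion ≥ `min_sv_size`), V for a
reverse-mapped segment, I for sequence present in the read but absent from
the reference (a CIGAR insertion ≥ `min_sv_size`, or an unmapped stretch
between split alignments). A read whose series is exactly `M` is normal;
anything else is aberrant. Supplementary records are normalised to
forward-read coordinates, counting hard clips as consumed read positions.

If an unmapped inserted sequence realigns locally (≥ 80% identity over
≥ 80% of its length, searched within ±10× the insertion length, capped at
20 kb), the symbol becomes a *mapped I* carrying the source span: a forward
hit is duplication evidence, a reverse-complement hit inverted-duplication
evidence. An exact-substring fast path handles error-free copies; otherwise
a local pairwise alignment decides.

Parameters: `min_sv_size` = 50 bp (the conventional SV floor; applied to
CIGAR ops and inter-alignment gaps alike), mapping-quality floor 20
(configurable; applied before extraction).

## 2. Candidate loci

Aberrant series are grouped by signature string and single-linkage
clustered on their breakpoint vectors (V-symbol boundaries, I anchors,
reference gaps/overlaps between mapped symbols) with a 500 bp position
tolerance. A cluster becomes a candidate locus when its number of
*spanning* supporting reads — reads whose mapped extent covers the
aberrant span plus a 100 bp margin — reaches the minimum support (10 in
germline/de novo mode, 2 in somatic mode). Counting only spanning reads is
a deliberate choice: reads that end inside an event produce truncated
signatures (e.g. `MV` at an inversion) that would otherwise nucleate
spurious sub-clusters at the same position. Loci within 1 kb are merged
(boundary inclusive), keeping their per-signature clusters so a
multi-allelic site yields one call per allele.

## 3. Image encoding

A locus window is the aberrant span padded by 20% of its length (minimum
300 bp) per side. Three image sizes are supported — 256, 512, 1024 pixels —
with fixed ACT track heights 25, 50, 100; the minimum detectable AF is one
pixel per track height: 0.04, 0.02, 0.01 respectively.

**Structure sketching.** The representative read (the widest spanning read
of the dominant cluster) is drawn as a similarity plot: reference window on
x, read coordinates on y; M symbols are diagonals, V symbols
anti-diagonals, mapped I symbols segments over their source span, unmapped
I symbols vertical gaps. Elements not derived from plain M carry aberrant
flags. Lines are drawn 2 px thick in a reserved grey (200,200,200) on a
black background so the structure survives the network's initial 2×
pooling.

**Augmented coverage tracks.** Per-base coverage over gapless aligned
blocks is counted per mapping condition: forward, reversed, duplicated (an
alignment whose reference span is encompassed by a longer alignment of the
same read) and reverse-duplicated. The four conditions colour an RGB
stacked barplot: forward (135, 206, 255); reversed subtracts 100 from the
second channel; duplicated subtracts 100 from the third; reverse-duplicated
subtracts both. The control genome's ACT fills the fixed-height track at
the top of the image, the case genome's the track at the bottom; bars are
anchored at the track edge nearest the sketch and grow outward, so a
coverage deficit (deletion evidence) sits at the outer track edge.

Each genome's ACT is normalised by its own flank coverage, estimated as the
85th percentile of per-position totals in the window. Per-genome (rather
than joint) normalisation is required for the AF ↔ bar-height semantics to
survive unequal sequencing depths (e.g. 300× tumor vs 30× normal); the 85th
percentile rather than the median is required because a variant may span
more than half the window, while the 20%-per-side padding guarantees at
least the top 15% of positions lie in the flanks.

**Insertion-associated representation.** Insertions consume read but not
reference, leaving vertical gaps in the sketch. For every I element, two
vertical tracks flank the gap — control on the left, case on the right —
filled with a bar whose width is `track_height ×` (insertion-carrying reads
/ flank coverage), counting reads at read level: a read carries the
insertion if one of its I symbols (length ≥ `min_sv_size`) anchors within
500 bp.

**One-to-N mode.** With N controls, N images are produced per locus; the
case content (sketch, case ACT) is identical in each.

## 4. Segmentation

Seven pixel classes: Background, DEL, INS, INV, DUP, invDUP, REF (wild-type
track regions). The default network, Lite-Unet, is a reduced U-Net
implemented directly in numpy (the execution environment provides no deep
learning framework): a stride-2 average-pool stem, four single-convolution
encoder levels of widths 16/32/64/128, a mirrored decoder with skip
connections, and a 1×1 head — ~243 k parameters versus ~7.8 M for the full
U-Net configuration built by the same code. Logits live at half
resolution; masks are upsampled back, so mask quantisation is 2 px. Labels
are pooled class-preservingly (SV classes win inside a 2×2 block) so
single-pixel low-AF bands survive in the training targets.

Training: pixel-wise cross-entropy weighted by inverse class frequency
(clipped at 150× — Background covers ~99% of pixels and the rarest class
bands are one pixel tall), Adam (lr 2·10⁻³), random 256 px crops biased to contain
SV pixels (which makes 1024 px images as cheap as 256 px ones and keeps the
net fully convolutional across sizes), 10% held-out validation, early
stopping on validation pixel accuracy. Training is deterministic given
(data, hyperparameters, seed).

Training images are fabricated through the production renderer from
sampled read-interval depth fields (so coverage noise has the long-range
correlation of real pileups) rather than from BAMs; carrier reads are
position-stratified so rendered evidence matches the nominal AF to within
one read. The mix covers all five component types, five complex layouts,
germline/new-allele/new-component control states, and a somatic-style
low-AF stratum rendered at image size 1024.

A deterministic *oracle segmenter* returns the ground-truth mask for
simulated loci. It isolates the decoder: every pipeline property that the
oracle suite establishes (type recovery, breakpoint/AF quantisation,
category assignment) is a property of the representation and decoding,
independent of network capacity.

## 5. Decoding and comparison

Connected regions of each SV class inside the track regions become
components: the x-span maps back to reference coordinates, and the extent
across the track (height in horizontal tracks, bar width in vertical
insertion tracks) divided by track height is the AF, clipped to
[1/track_height, 1]. Decoding hardening, all deterministic:

* horizontal regions are closed with a 3×9 footprint and discarded when
  narrower than 4 px, or ≤ 2 px tall and < 60 px wide (ragged bar-top
  slivers);
* a case-track DEL/INV component must be corroborated by the sketched
  structure (a reference gap, resp. an anti-diagonal segment, overlapping
  its span ± 500 bp); fragments sharing one evidence interval are merged,
  keeping the tallest fragment's AF;
* all insertion-class pixels in one vertical track side form a single
  component whose class label is taken from the mapped-I realignment
  orientation recorded in the geometry (INS / DUP / invDUP), with a
  pixel-majority fallback — the realignment is deterministic alignment
  evidence, where a small network is unreliable at distinguishing visually
  similar vertical bars;
* when the segmenter is a network, component AFs are re-measured from the
  rendered ACT itself (median deficit height for DEL, reversed-colour
  stack for INV, bar width for insertions) over the mask's span — the mask
  supplies presence, type and span; the image supplies the quantity. With
  the oracle segmenter masks are exact and no refinement is applied.

Genotypes follow conventional diploid AF bands: < 0.25 → 0/0, < 0.75 →
0/1, else 1/1. Case components are joined in reference order (insertions
before deletions at a shared breakpoint) into the final, possibly complex,
type string (e.g. `DEL+INV`).

Each case component is contrasted with the control track of the same
image: no same-type overlapping control component → **New component**;
matched but either endpoint off by more than max(50 bp, 2 px) → **New
breakpoint**; AF differing by more than max(0.1, 2/track_height) → **New
allele**; otherwise **Germline**. Precedence: New component > New
breakpoint > New allele > Germline. A call is *de novo* when every
component is New component against every parental control; *somatic* when
New component against the matched normal with ≥ 2 supporting reads and
AF ≥ 0.01. Mendelian consistency is the fraction of trio records whose
child genotype can draw one allele from each parent; twin discordancy the
fraction of records where the twins' genotypes differ.

## 6. Simulator

The simulator emits everything the pipeline consumes, offline. A genome is
K equally weighted haplotypes; a variant with AF f occupies round(f·K) of
them (K=2 diploid; K=100 subclonal tumor, AF granularity 0.01). Haplotypes
are block lists over the reference; reads are substrings whose alignment
records are derived analytically: deletions become D ops, insertions and
tandem (inverted) duplications I ops whose sequence realigns locally,
inversions forward/reverse/forward split records with soft clips.
Sequencing error profiles are independent substitutions plus single-base
indels: perfect (0/0), hifi_like (0.5%/0.5%), ont_like (3%/4%) —
representative published orders of magnitude, not a full error-structure
model.

Scenario builders use exact-proportion haplotype interleaving (evenly
spaced starts, largest-remainder haplotype cycling) so carrier counts at
every locus are deterministic to within one read — matching how read-mixing
benchmarks are constructed and making the oracle acceptance criteria
(precision = recall = 1.0) well-posed at support-floor boundaries. Plain
`synthesize_alignments` defaults to binomial sampling, and that invariant
is property-tested. Scenario defaults (all overridable): 8 kb reads with
one variant per read-length-plus-4-kb tile; sv_panel 160×/K=10;
trios 40×/K=2; tumor 300× (normal 30×)/K=100 — tumor depth is set by the
AF floor: at AF 0.01, ≥ 2 supporting reads require ≥ 200 spanning reads.

Scoring matches calls to truth by start distance ≤ 500 bp plus ≥ 50%
reciprocal overlap for span events (point matching for insertion-only
events), greedy one-to-one; a matched complex call is *subcomponent
accurate* when every truth component type occurs among its called
components.

## 7. What a green test does and does not establish

The oracle suite proves the representation and decoder are exact up to
pixel quantisation on clean, deterministic simulations. The trained-model
suite additionally shows a ~243 k-parameter network trained on 500
renderer-level simulations reproduces the paper-scale detection metrics on
*synthetic hifi-like reads* — reads with uniform coverage, fixed length, no
chimeras, no mappability artifacts and exactly the error rates stated
above. Neither establishes performance on real sequencing data, real
aligner output, repeat-dense references, nor ONT-scale error structure.
Dispersed (inter-chromosomal) events and translocation pairing are out of
scope; dispersed duplications are handled only through the mapped-I route.

## 8. Known limitations

* Multi-allelic loci produce one call per signature cluster, but mask
  decoding attributes all same-type evidence at the locus to each call, so
  component lists of co-located alleles can bleed into each other.
* The AF read off coverage is the carrier-read fraction, a slightly biased
  estimator of the true allele fraction (insertion carriers span less
  reference, deletion carriers more; bias ~ event/read length).
* Insertion length is estimated from the vertical gap's read-axis extent
  and is quantised accordingly.
* The control track carries no sketch, so control-side components rest on
  ACT evidence alone.
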