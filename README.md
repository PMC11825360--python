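# svcompare

Comparative structural-variant (SV) discovery from long-read alignments.
`svcompare` detects and genotypes SVs in a **case** genome (a child, a
tumor) by directly contrasting it with one or more **control** genomes (the
parents, the matched normal) inside a single image per candidate locus —
instead of calling each genome separately and merging callsets, the usual
source of false de novo and somatic calls.

For whom: method developers and analysts working on de novo SV discovery in
trios and somatic SV discovery in tumor–normal pairs from PacBio
HiFi / ONT-style long reads.

## Method in brief

1. **Symbol series.** Each read becomes an ordered series over
   {M, V, I} — forward-mapped segment, reverse-mapped segment, inserted
   sequence — straight from primary/supplementary alignments and CIGARs,
   with no SV-type-specific pattern matching. A read spanning a deletion
   reads `MM` (reference gap between the Ms), an inversion `MVM`, an
   insertion `MIM`. Inserted sequence that realigns locally becomes a
   *mapped I* (forward hit → duplication, reverse → inverted duplication).
2. **Candidate loci.** Aberrant series (anything ≠ `M`) are clustered by
   signature and breakpoint position; ≥ 10 spanning reads (2 in somatic
   mode) make a candidate locus.
3. **Image encoding.** Each locus is rendered as one RGB image: the case
   read structure sketched as segments/gaps (reference on x, read on y),
   plus *augmented coverage tracks* (ACTs) — RGB stacked barplots of
   per-position coverage split by mapping condition, with forward coverage
   coloured (135, 206, 255), reversed subtracting 100 in channel 2,
   duplicated subtracting 100 in channel 3. The control ACT fills the top
   track, the case ACT the bottom track; insertions get vertical tracks
   left (control) / right (case) of their gap. Image sizes 256/512/1024
   have track heights 25/50/100, so the minimum detectable allele fraction
   (AF) is 0.04/0.02/0.01 — one pixel per track.
4. **Segmentation.** A small encoder–decoder network (Lite-Unet, ~243 k
   parameters, implemented in numpy) labels each pixel as
   DEL/INS/INV/DUP/invDUP/REF/Background. The horizontal span of a masked
   region is the component's breakpoint span; its extent across the track,
   divided by track height, is its AF.
5. **Comparison.** Case components are joined in read order into the final
   (possibly complex) type, e.g. `DEL+INV`; each component is classified
   against every control as **Germline / New allele / New breakpoint /
   New component**. De novo = New component vs both parents; somatic =
   New component vs the normal with ≥ 2 reads and AF ≥ 0.01. Genotypes
   (0/0, 0/1, 1/1) derive from AF.

A built-in simulator fabricates references, haplotypes with implanted
simple/complex SVs, and analytically-derived BAMs (plus truth masks and
scoring), so the entire pipeline trains and tests offline. See
`docs/methods.md` for the full model description and design decisions.

## Worked example

Simulate a tumor–normal pair with subclonal somatic SVs (AF 0.01–0.10),
call somatic variants with the deterministic oracle segmenter, and score:

```python
from svcompare.pipeline import run_comparative_calling, select_somatic
from svcompare.simulate import OracleSegmenter, build_scenario, score_calls
from svcompare.vcf import write_vcf

scen = build_scenario("tumor_normal", "demo_tn", seed=21)
calls = run_comparative_calling(
    scen.bams["tumor"], [scen.bams["normal"]], scen.ref_path,
    OracleSegmenter(scen), case_name="tumor", control_names=["normal"],
    mode="somatic", image_size=1024)
somatic = select_somatic(calls, min_support=2, min_af=0.01)
res = score_calls(somatic, [t for t in scen.truth if t.stratum.startswith("af=")])
print(f"somatic: {len(somatic)} calls, precision={res.precision:.2f} "
      f"recall={res.recall:.2f} f1={res.f1:.2f}")
for c in somatic[:3]:
    print(c.chrom, c.ref_start, c.joined_type, c.genotype_case,
          f"AF={c.allele_fraction:.2f}", f"support={c.support}")
write_vcf(somatic, "somatic.vcf", case_name="tumor", control_names=["normal"])
```

Output:

```
somatic: 20 calls, precision=1.00 recall=1.00 f1=1.00
chrS 9998 DEL 0/0 AF=0.01 support=3
chrS 21924 INS 0/0 AF=0.01 support=3
chrS 34145 INV 0/0 AF=0.01 support=3
```

Each line is one somatic call: position, joined component type, genotype
from AF (a 1% subclone is genotyped 0/0 — present below the heterozygous
band — yet still reported as a somatic New component), the decoded allele
fraction and the number of supporting reads.

The same pipeline runs from the shell with a trained model:

```bash
svcompare train --n-examples 500 --seed 42 --out model.npz
svcompare simulate --kind trio_denovo --outdir demo_trio --seed 7
svcompare call --case demo_trio/child.bam --control demo_trio/father.bam \
    --control demo_trio/mother.bam --ref demo_trio/ref.fa \
    --mode denovo --image-size 256 --model model.npz --out denovo.vcf
svcompare eval --vcf denovo.vcf --truth demo_trio/truth.json
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the core pipeline from scratch — simulates a case/control pair with
20 implanted SSVs and CSVs at AFs 0.1/0.5/1.0, fabricates the alignments,
discovers loci, encodes the comparison images, decodes them with the oracle
segmenter and scores the calls against the implanted truth — printing the
resulting precision/recall/F1 to stderr and writing the JSON report to
`--out`.
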