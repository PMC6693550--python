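# netprism

Analysis toolkit for nascent-transcription sequencing (NET-seq / NET-prism
style libraries): from strand-specific aligned nascent-RNA reads to
single-nucleotide RNA polymerase II occupancy tracks, promoter-proximal
pausing metrics, splice-site profiles, and enhancer transcription
statistics — together with a simulator that generates UMI-tagged reads with
known ground truth for validating every step.

## The problem

NET-seq-family protocols sequence the 3′ ends of nascent RNAs still engaged
with RNA polymerase II, placing the polymerase active site at single-base
resolution: the **5′ end of each sequencing read corresponds to the 3′ end
of the nascent RNA**. Turning raw alignments into interpretable occupancy
signal requires a chain of read-level corrections:

1. **PCR-duplicate removal** using the random barcode (UMI) ligated to each
   molecule — one representative per (chromosome, 5′ position, alignment
   strand, UMI).
2. **RT-mispriming removal** — reads whose genomic context immediately
   3′-adjacent to the aligned read end matches the RT-primer prefix arose
   from the primer annealing to genomic sequence, not to the adapter.
3. **3′-end extraction** — each read is collapsed to its 5′-end coordinate;
   under the standard library geometry the read aligns antisense to the
   transcript, so the transcript strand is the opposite of the alignment
   strand.
4. **Splicing-intermediate removal** — co-purifying splicing intermediates
   carry free 3′-OH ends exactly at the last nucleotide of each exon
   (cleaved 5′ splice site) or intron (lariat); positions falling exactly on
   these terminal nucleotides are discarded.

The retained positions are binned at 1 bp per strand, scaled to 1× depth
(genome-wide mean coverage of 1, both strands summed), and fed to the
downstream statistics.

## Core statistics

**Travelling ratio (TR)** — the pausing index of a gene:

```
TR = mean coverage over [TSS−30, TSS+250)  /  mean coverage over [TSS+300, TES−200)
```

computed on sense-strand signal with strand-oriented half-open windows. A
high TR means polymerase accumulates at the promoter relative to the gene
body. Genes with another gene within 2.5 kb upstream of the TSS are excluded
(promoter-clash filter), and profile rows dominated by a concentrated
high-occupancy spike inside a <100 bp span are removed as unannotated short
non-coding RNAs before metaplotting.

**Exon-boundary pausing** — Pol II density over internal exons vs introns
(first and last exons excluded), and metaplots anchored at 3′/5′ splice
sites with 95% confidence bands.

**Enhancer transcription** — enhancers farther than 2 kb from any gene are
"distal"; eRNA density (both strands summed, per bp) is tabulated per
enhancer class, libraries are compared by Pearson correlation, and distal vs
super-enhancer densities by a two-sided Wilcoxon rank-sum test.

## Worked example

Simulate a small library (6 genes, 4 enhancers, PCR duplication, planted
mispriming and splicing intermediates), run the filter chain, and compute
travelling ratios:

```python
from netprism import simulate as sim, annotation, reads, metrics
from netprism.tracks import build_track, normalize_1x

model, truth, paths = sim.simulate("demo", preset="total", seed=1,
                                   n_genes=6, n_enhancers=4)
terminals = annotation.terminal_nucleotides(model.genes)
positions, report = reads.process_alignments(
    paths["sam"], terminals,
    reference_path=paths["reference"], primer_prefix=truth.primer)
print(report.to_dict())
```

prints the per-stage audit trail:

```
n_input=42174  n_after_dedup=14147  n_after_mispriming=13488  n_after_intermediates=13332
removed: pcr_duplicates=28027, mispriming=659, splicing_intermediates=156
```

42,174 aligned reads collapse to 14,147 unique molecules; 659 RT artifacts
and 156 splicing-intermediate positions are then discarded. Continuing:

```python
track = normalize_1x(build_track(positions, model.chrom_sizes))
for g in model.genes[:3]:
    r = metrics.travelling_ratio(g, track)
    print(g.gene_id, round(r.promoter_density, 2), round(r.body_density, 2), round(r.tr, 2))
```

```
g001  promoter=32.63  body=4.35  TR=7.50
g002  promoter=49.50  body=2.37  TR=20.90
g003  promoter=92.42  body=3.10  TR=29.83
```

Each gene's promoter window carries far more normalized coverage per bp than
its body (median TR ≈ 21.9 in this run), reflecting the strong
promoter-proximal pause peaks the simulator programmed relative to its body
elongation rate.

The same analysis is available from the shell:

```bash
netprism simulate --preset total --seed 1 --out demo
netprism all --bam demo/reads.sam --gtf demo/genes.gtf \
    --chrom-sizes demo/chrom.sizes --enhancers-bed demo/enhancers.bed \
    --super-enhancers-bed demo/super_enhancers.bed \
    --reference demo/reference.fa --primer GATCGG --out demo_out
```

which writes `tr.tsv`, `density.tsv`, `directionality.tsv`, strand-separated
bedGraphs, TSS metaplots and enhancer statistics, plus a `manifest.json`
with a SHA-256 checksum per output.

## Layout

| module | contents |
|---|---|
| `netprism.annotation` | GTF/BED/chrom.sizes I/O, gene models, introns, terminal nucleotides, internal exons, promoter-clash and distal-enhancer filters |
| `netprism.simulate` | toy-genome builder, NET-seq-geometry read simulator with ground truth |
| `netprism.reads` | UMI dedup, mispriming filter, 3′-end extraction, intermediate filter |
| `netprism.tracks` | single-base strand tracks, 1× normalization, smoothing, bedGraph I/O |
| `netprism.metrics` | travelling ratio, ECDF, RPKM, feature density, sense/antisense split |
| `netprism.profiles` | anchored matrices, artifact-row filter, metaplots with CIs |
| `netprism.enhancers` | enhancer density tables, library correlation, rank tests |
| `netprism.pipeline` / `netprism.cli` | orchestration, config, manifest, `netprism` command |
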