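# episegsom

Annotation-independent exploration of combinatorial histone-modification
patterns: binary discretization of ChIP-seq enrichment into modification
states, combinatorial genome segmentation (ES or EV mode), deterministic
self-organizing-map clustering of the resulting epigenetic profiles, and a
full suite of per-node SOM-images and supporting maps.

## What it does

1. **Discretize** (`episegsom.discretize`): per-position enrichment =
   modification reads / whole-cell-extract reads (optional H3 validation);
   positions with enrichment ≥ 3 are joined into modified regions when less
   than 100 nt apart; regions shorter than 100 nt are discarded. The result is
   one binary *modification state* (MS) per mark and cell type.
2. **Segment** (`episegsom.segmentation`): project the boundaries of all
   reference states (all marks of one cell type — *ES*; or one mark across all
   cell types — *EV*) onto the genome. Segments shorter than 200 bp are
   omitted. Each retained segment carries an n-bit *combinatorial epigenetic
   profile* (CEP) over the reference states plus fractional coverage values
   for every complementary state; the concatenation (coverage weighted by a
   factor *w*, default 1) is the *epigenetic profile* (EP).
3. **Train** (`episegsom.som_core`): a 40×40 (configurable) Kohonen SOM with
   linear PCA initialization, Gaussian neighborhood, linearly decaying gain
   and radius, and ~200,000 profile presentations by default. Training is
   fully deterministic: identical inputs give byte-identical codebooks.
4. **Maps** (`episegsom.som_maps`): population map, CEP island labeling
   (connected components of nodes with more than 10 EPs), per-state coverage
   atlas, mean segment length, CpG density, present-call and gene-set
   fractions, and per-chromosome population / hypergeometric log2-enrichment
   maps.
5. **Render** (`episegsom.viz`): mosaic heatmaps (blue–green–red scale,
   optional log/inverted scales, white masked tiles, island borders).

`episegsom.synthetic_data` generates complete toy inputs (region panels with
planted CEP blocks and ground truth, Poisson count tracks, genes, expression
flags, and genomes with tunable CpG density) so the whole pipeline is testable
offline.

## CLI

```sh
# synthetic fixtures with planted combinatorial structure
episegsom synth --seed 7 --repeats 2 -o fixtures/

# region calling from bedGraph counts
episegsom discretize --mod mod.bedGraph --wce wce.bedGraph \
    --chrom-sizes sizes.tsv --threshold 3 --max-gap 100 --min-len 100 -o MS.bed

# ES-segmentation of a panel (TSV: mark <TAB> cell <TAB> bed-path)
episegsom segment --mode ES --reference ESC --panel panel.tsv \
    --chrom-sizes sizes.tsv --min-len 200 --weight 1.0 \
    -o segments.bed -p profiles.tsv

# deterministic SOM training
episegsom train --profiles profiles.tsv --width 40 --height 40 \
    --alpha 0.05:0.005 --sigma 10:1 -o som.tsv -a assignment.tsv

# supporting maps and rendering
episegsom maps --som som.tsv --assignment assignment.tsv \
    --segments segments.bed --profiles profiles.tsv \
    --genome genome.fa --genes genes.bed --expr expression.tsv \
    --gene-set set.txt --chrom-sizes sizes.tsv -o maps/
episegsom render --matrix maps/population.tsv --meta maps/population.json \
    -o population.png

# or everything at once from a JSON/YAML config
episegsom run --config fixtures/config.json -o out/
```

All interval handling is 0-based half-open (BED convention); GTF input is
converted on read. Chromosome names are matched exactly.

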