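# pol2topo

Spike-in-normalized HiChIP topology analysis: contact filtering and binning,
AQuA (reference-reads-per-million) normalization, clustering of thresholded
contacts into 3D peaks/loops/clusters, TF/CpG/TSS annotation, two-condition
differential contact analysis with APA, and gene-level Pol2 pausing
(traveling ratio) and unloading (PULR) metrics. A synthetic-data module
generates miniature genomes with planted cluster architecture and
condition-dependent collapse effects, plus ground-truth tables, so every
stage can be validated by recovery tests without external data.

## Layout

| module | purpose |
|---|---|
| `pol2topo.io_formats` | allValidPairs / BED / BED12 / bedGraph / BEDPE / TSV readers and writers; core coordinate types |
| `pol2topo.synthetic_data` | miniature genome + valid-pair + coverage simulator with truth tables |
| `pol2topo.aqua_norm` | 1000-bp distance filter, spike-in stats, 5-kb binning, RRPM normalization, delta tracks |
| `pol2topo.contact_features` | anchor-graph construction, connected-component features (peak/loop/cluster), ranking, cluster stats |
| `pol2topo.annotation` | peak-overlap counting, TSS proximity, CpG/TF loop categories, gene-to-cluster assignment |
| `pol2topo.differential` | per-unit L2FC tables, category summaries, long-range window, rank plots, APA matrices |
| `pol2topo.pol2_gene_metrics` | promoter/TSSR/body/TESR regions, traveling ratio, PULR, condition comparison, decile joins |

Conventions: all internal coordinates are 0-based half-open; allValidPairs
positions (1-based) are converted on read. Contacts are binned at 5 kb by
default; cis pairs at separation ≤ 1000 bp are removed; PCR duplicates are
retained by default (punctate pull-down behavior) with a `--drop-duplicates`
escape hatch. `aqua_cpm = raw_count × 10⁶ / spike-in valid pairs`.

## CLI

```sh
# simulate two conditions with a planted collapse effect
pol2topo --seed 7 simulate --outdir sim --n-clusters 10 \
    --collapse-distal-factor 0.5 --tesr-depletion-factor 0.5

# filter + bin + normalize
pol2topo normalize --pairs sim/control.allValidPairs --out control.bedpe

# cluster into peaks/loops/clusters and rank
pol2topo cluster --contacts control.bedpe --threshold 0 --out-prefix control

# annotate features
pol2topo annotate --contacts control.bedpe --p3f sim/p3f_peaks.bed \
    --p300 sim/p300_peaks.bed --cpg sim/cpg_islands.bed \
    --genes sim/genes.tsv --out control.annot.tsv

# differential contacts between conditions, split by category
pol2topo delta --ctrl sim/control.allValidPairs --trt sim/treated.allValidPairs \
    --p3f sim/p3f_peaks.bed --p300 sim/p300_peaks.bed \
    --cpg sim/cpg_islands.bed --genes sim/genes.tsv \
    --split-by collapse --out-prefix delta

# aggregate peak analysis
pol2topo apa --contacts control.bedpe --loops control.edges.bedpe --out apa.tsv

# gene metrics (TR, PULR) and condition comparison
pol2topo genemetrics --coverage sim/control.pol2_coverage.bedGraph \
    --genes sim/genes.tsv --compare sim/treated.pol2_coverage.bedGraph \
    --out-prefix metrics
```

Global flags `--config FILE` (flat `key = value`, see
`pol2topo/config.py` for keys and defaults), `--seed`, `--log-level`.

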