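# redseq

Restriction-enzyme accessibility profiling: an implementation of the
RED-seq computational method (restriction endonuclease digestion of
chromatin coupled to deep sequencing).

## The problem

Chromatin accessibility controls which regulatory sequences are available
to transcription factors and enzymes. RED-seq measures accessibility at
single-site resolution by digesting native chromatin with a frequent-cutting
restriction enzyme — Sau96I, recognition motif GGNCC, cut G^GNCC — and
sequencing the cut ends. Because a biotinylated adaptor is ligated at the
cut before sonication, only the cut-containing end of each fragment is
sequenced, so the 5′ end of every aligned read pinpoints one cleavage event
at one restriction site (RS). Accessibility at a site is its **relative cut
frequency**:

```
RPM_i = raw_i × 10^6 / Σ_j raw_j
```

the read count assigned to site *i*, normalized to reads per million over
the library. Regional accessibility is the average RPM in 50-bp windows
around feature centers (DHS peaks, CTCF sites, …), divided by the number of
features — always read against the **RS-density baseline** obtained by
assigning one pseudo-read to every site, since the motif itself is
non-uniformly distributed. Differential accessibility between two libraries
is tested per site with Fisher's exact test on (site vs. rest-of-library) ×
(library A vs. B) with Benjamini–Hochberg correction, and at feature-set
level with the Wilcoxon signed-rank test on paired per-feature scores.

The package covers the full computational workflow:

| stage | module | CLI |
|---|---|---|
| degenerate-motif genome scan, site index, density baseline | `redseq.restriction_map` | `redseq scan` |
| barcode demultiplexing + cleavage-signature QC | `redseq.readproc` | `redseq demux` |
| read-to-site assignment, RPM normalization, motif-variant bias | `redseq.assign_count` | `redseq count` |
| metaprofiles and ±200 bp window scores | `redseq.aggregate` | `redseq profile`, `redseq score` |
| per-site and feature-level differential tests, nearest annotation | `redseq.differential` | `redseq diff`, `redseq compare-features` |
| ground-truthed chromatin/digestion simulator | `redseq.simulate` | `redseq simulate` |

Read alignment is external (the package consumes SAM/BAM or BED of aligned
read ends). The simulator generates nucleosome arrays (147-bp cores, ~30-bp
linkers), nucleosome-free regions, histone-variant nucleosomes with
elevated cleavage probability, sonication (~200 bp) and 200–350 bp size
selection, so every stage is testable without external data.

## Worked example

Simulate an ESC-like chromatin library over 200 kb with nucleosome-free
regions every 10 kb, then run the pipeline:

```python
import redseq as rs

genome = rs.simulate_genome(seed=7, length=200_000)
enzyme = rs.BUILTIN_ENZYMES["Sau96I"]
index = rs.build_index(genome, [enzyme])

model = rs.build_chromatin_model(
    {"chr1": 200_000}, seed=8,
    nfr_centers={"chr1": list(range(20_000, 190_000, 10_000))},
)
cfg = rs.SimulationConfig(seed=9, n_molecules=50_000, p0=0.05)
probs = rs.cut_probabilities(index, model, cfg)
reads, truth = rs.generate_library(genome, index, probs, cfg)

bins, report = rs.demultiplex(iter(reads), rs.BarcodeMap({"esc": "ACGT"}), [enzyme])
table = rs.normalize_rpm(
    rs.assign_arrays(truth.read_chrom, truth.read_strand,
                     truth.read_five_prime, index, library="esc")
)
nfrs = model.nfr_features()
prof = rs.metaprofile(table, nfrs, index=index)
dens = rs.metaprofile(rs.normalize_rpm(rs.density_counts(index)), nfrs, index=index)
```

Output:

```
373 Sau96I sites in 200 kb
197799 reads pass size selection
signature fraction: 1.000
assigned 197799, unassigned 0
accessibility RPM/feature: center bins 1276, distal bins 209
site-density baseline:     center bins 276, distal bins 256
```

Every simulated read begins (after its 4-bp barcode) with the GNCC
signature of a cleaved, blunt-ended Sau96I site — the library-quality
check, which here matches 100% because the simulator adds no sequencing
error. Accessibility over the planted nucleosome-free regions is ~6-fold
above the distal bins, while the site-density baseline is flat (276 vs.
256), showing the enrichment is chromatin signal, not motif clustering.

The same workflow is available from the shell:

```
redseq simulate --seed 7 --length 200000 --outdir sim/
redseq scan  --fasta sim/genome.fa --enzyme Sau96I --out sites.bed
redseq demux --fastq sim/reads.fastq --barcodes bc.tsv --enzyme Sau96I --outdir demux/
redseq count --align sim/truth_reads.bed --sites sim/sites.tsv --out counts.tsv
redseq profile --counts counts.tsv --sites sim/sites.tsv --features nfr.bed --out profile.tsv
redseq diff  --a countsA.tsv --b countsB.tsv --sites sim/sites.tsv --out diff.tsv
```

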