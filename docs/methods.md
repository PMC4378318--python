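# Methods

## The measurement model

RED-seq treats each occurrence of a restriction enzyme's recognition motif
as a probe of local chromatin accessibility. A digestion reaction exposes
every restriction site (RS) to the enzyme; the probability that a given
genome copy is cleaved at a given site depends on sequence-intrinsic
enzyme efficiency and on whether chromatin occludes the site. Cut ends are
captured via a biotinylated adaptor ligated directly at the cut, so each
sequenced read's 5′ end marks one cleavage event, and the per-site read
count — normalized to reads per million (RPM) — estimates relative cut
frequency.

### Cut chemistry and expected read ends

For a palindromic motif of length *L* cut at offset *c* from the motif
start (Sau96I: GGNCC, *c* = 1), cleavage leaves 5′ overhangs that are
end-filled to blunt. A read sequenced from the downstream fragment aligns
on the + strand with 5′ end at `motif_start + c` and begins with the motif
suffix (GNCC); a read from the upstream fragment aligns on the − strand
with (exclusive) 5′ coordinate `motif_start + L − c`. These two
coordinates are the only read ends a clean cut can generate, which is the
basis for read-to-site assignment. Coordinates are 0-based, half-open
throughout; the 5′ end of a − strand read is represented by the exclusive
end of its alignment (SAM `reference_end`), which keeps both strand
formulas integer-exact. For non-palindromic motifs both strands are
scanned (occurrences of the reverse-complement motif are reported at their
forward coordinates); the symmetric-cut end formula is retained, a
documented approximation that is exact for every palindromic enzyme and
both built-ins (Sau96I and DdeI, C^TNAG).

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| assignment tolerance | 2 | bp | absorbs end-repair/A-tailing raggedness; exposed as `--tolerance` |
| metaprofile flank | 1000 | bp | 2-kb window around feature centers |
| metaprofile bin | 50 | bp | resolution of regional accessibility |
| window-score halfwidth | 200 | bp | replicate-level quantification window, endpoints inclusive |
| differential pseudo-RPM | 1 | RPM | keeps log2 effects finite; enters effects only, never the test |
| barcode length | 4 | nt | inline sample barcode, exact match only |

Exact barcode matching is deliberate: a 4-bp barcode has no Hamming slack,
so mismatch rescue would cross-assign samples. Signature filtering
(post-barcode prefix must match the enzyme's post-cut sequence) is
report-only by default — the signature is a library-quality statistic, not
a stated read filter — and can be enforced with `strict_signature`.

Assignment ties (a read 5′ end equidistant from two sites, including sites
of different enzymes in a dual digest) resolve to the lower `motif_start`;
the same rule orders site ids (chromosome lexicographic, then coordinate),
making every output byte-deterministic. Overlapping motif matches are
distinct sites. Genome N bases match no motif code, so assembly gaps
cannot produce phantom sites. Reads are not deduplicated by default; a
`dedup` flag collapses identical (chrom, strand, 5′ end, sample) tuples.

## Statistical choices

**Per-site differential test.** Fisher's exact test on the 2×2 table
(site count vs. remainder of library) × (library A vs. B), two-sided, with
Benjamini–Hochberg correction across tested sites. Exact at low counts and
assumption-free; sites with zero counts in both libraries are excluded
from testing (they carry no information and would dilute the FDR). The
test is conditionally exact and therefore conservative at small counts:
its size approaches the nominal level only as per-site expected counts
grow. The null-calibration study accordingly uses 250 expected reads per
site (2.5 × 10^6 reads over 10^4 sites, a realistic deep-library regime),
where the realized false-positive rate at p < 0.05 sits near 4–5%.

**Feature-level test.** Wilcoxon signed-rank on paired per-feature window
scores — robust to the heavy right tail of accessibility scores and to
monotone distortions; degenerate input (all paired differences zero)
reports p = 1 with an explicit flag rather than an error.

**Effect size.** log2((RPM_A + 1)/(RPM_B + 1)). The pseudo-count is in
RPM units so it is depth-invariant.

## The simulator

The generator emulates the physical assay stage by stage so that each
pipeline stage has checkable ground truth.

*Genome*: i.i.d. bases at a set GC content (default 0.42, mammalian-like),
with optional motif planting at exact coordinates. *Chromatin*: 147-bp
nucleosome cores tiled with linkers drawn from a normal distribution
(mean 30 bp, sd 10, floor 2 — matching the short linkers typical of ESC
chromatin), optionally at fixed spacing to create phased arrays;
nucleosome-free regions (default 200 bp) planted at designated centers; a
fraction of cores (default 5%) labeled as histone-variant cores.
*Cleavage*: per molecule, each site cuts independently with probability
`p0 × w(variant) × a(site)` where `w` is a per-motif-variant efficiency
weight (models the GGTCC > GGACC/GGGCC/GGCCC bias observable in real
digests), and the accessibility factor `a` is 1 in linkers/NFRs, 0.05
under canonical cores, and `min(1, m × 0.05)` under variant cores
(default multiplier m = 5). The occlusion factor 0.05 makes chromatin
libraries dominated by accessible-region reads, as in real chromatin
digests; naked-DNA mode sets `a ≡ 1`. The default `p0 = 0.02` represents
partial digestion of chromatin in a 1-hour reaction; naked-DNA studies
pass higher values explicitly.

*Library construction*: fragments run cut-to-cut; from each cut end the
sequenced fragment extends to a sonication break (truncated normal, mean
200 bp, sd 50, min 1 — only the mean is a protocol-stated quantity, the
spread is a modeling choice) or to the neighboring cut if nearer;
fragments outside the 200–350 bp size-selection window are discarded; each
surviving fragment yields exactly one read from its cut end (the
biotin-selection design sequences only that end), composed of the sample
barcode plus genomic sequence beginning with the enzyme's post-cut
signature. This reproduces the close-cut artifact: in efficiently digested
naked DNA, site pairs closer than the lower size bound lose their
cut-to-cut fragments to size selection and appear depleted.

What the simulator does **not** model by default: sequencing error (an
optional uniform substitution rate is available for robustness studies;
the default 0 is what makes the signature-fraction check exact), PCR
duplicates, GC amplification bias, digestion kinetics beyond per-site
Bernoulli, and inter-molecule heterogeneity in nucleosome positioning
(all molecules share one chromatin model). Passing tests therefore
demonstrate correctness of the computational pipeline under an idealized
assay, not robustness to platform noise — on real data the signature
fraction will be < 1 and assignment tolerance matters more.

A count-level sampler (`sample_count_table`) draws per-site read counts
multinomially from a probability vector, bypassing fragment physics. It is
the appropriate input for purely statistical studies (null calibration)
where fragment-length structure is irrelevant.

## Problem sizes in the validation studies

Scanner and assignment oracles run at 1,000 sequences × 500 bp and 1,000
reads × 100 sites; null calibration at 10,000 sites × 2.5 × 10^6 reads per
library; multiplier recovery on a 1 Mb genome digested in 10^6 molecules
(~9 × 10^6 reads); the size-selection study on 200 kb × 5,000 molecules at
p0 = 0.5; metaprofile flatness over 10,000 features on a 2,000-site
uniform genome. The end-to-end rank-correlation study includes
per-motif-variant efficiency weights because with only the three discrete
occlusion levels the truth probabilities are heavily tied, and rank ties
alone cap the achievable Spearman correlation well below 1 even under
perfect recovery. The flatness check needs that many features because
100-bp site spacing resonates with 50-bp bins: individual profiles
alternate between site-bearing and empty bins, and only averaging over
many random phases flattens the curve (residual CV ≈ 1/√n_features).

## Known limitations

- Type IIS enzymes (cut site outside the recognition motif) are not
  supported; `cut_offset` must lie within the motif.
- Non-palindromic motifs get symmetric-cut end coordinates (see above).
- `annotate_nearest` ignores feature strand when signing distances
  (negative = upstream of interval start in + orientation).
- The variant-nucleosome multiplier is a modeling device for parameter
  recovery, not a biological estimate of histone-variant dynamics.
- Differential testing has no replicate-aware dispersion model; biological
  replicates should be compared at feature level.
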