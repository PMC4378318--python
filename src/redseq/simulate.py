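"""Synthetic genomes, chromatin models, and simulated digestion libraries.

The simulator emulates the physical assay well enough that every pipeline
stage can be validated against known ground truth:

1. a random genome (i.i.d. bases at a chosen GC content, with optional
   motif planting at fixed coordinates);
2. a chromatin model per chromosome — arrays of 147-bp nucleosome cores
   separated by ~30-bp linkers, interrupted by nucleosome-free regions
   (NFRs) at designated feature positions; a configurable fraction of
   cores carry a histone-variant label with elevated cleavage probability;
3. per-site cleavage probabilities: a baseline per-molecule cut
   probability p0, scaled by a per-motif-variant efficiency weight and,
   in chromatin mode, by the local occlusion (1 in NFRs and linkers, a
   small occlusion factor under canonical cores, min(1, m x occlusion)
   under variant cores);
4. library generation: each molecule is an independent full-length copy of
   the genome; each site cuts independently with its probability;
   fragments run cut-to-cut; the sequenced fragment extends from a cut end
   to a sonication break (truncated normal, mean 200 bp, sd 50) or to the
   nearer neighboring cut, whichever comes first; fragments outside the
   200-350 bp size-selection window are discarded; each surviving fragment
   yields one read from its cut end (only the cut end carries the
   biotinylated adaptor, so only it is sequenced) — barcode plus genomic
   sequence starting at the expected cut coordinate, hence beginning with
   the enzyme's post-cut signature.

Everything is driven by one integer seed; identical configurations produce
byte-identical outputs.  Ground truth (per-read source site and strand) is
retained so downstream estimates can be compared with the generating model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .restriction_map import EnzymeSpec, RSIndex, build_index

__all__ = [
    "SimulationConfig",
    "ChromatinModel",
    "SimTruth",
    "simulate_genome",
    "write_fasta",
    "build_chromatin_model",
    "cut_probabilities",
    "generate_library",
    "sample_count_table",
]

NUCLEOSOME_CORE_BP = 147
DEFAULT_LINKER_MEAN = 30.0
DEFAULT_LINKER_SD = 10.0
DEFAULT_OCCLUSION = 0.05
DEFAULT_VARIANT_MULTIPLIER = 5.0
DEFAULT_VARIANT_FRACTION = 0.05
DEFAULT_NFR_LENGTH = 200
DEFAULT_SONICATION_MEAN = 200.0
DEFAULT_SONICATION_SD = 50.0
DEFAULT_SIZE_SELECT = (200, 350)
DEFAULT_P0 = 0.02
DEFAULT_READ_LENGTH = 50


@dataclass
class SimulationConfig:
    """Parameters of one simulated library."""

    seed: int
    n_molecules: int = 100_000
    p0: float = DEFAULT_P0  # baseline per-site, per-molecule cut probability
    naked_dna: bool = False
    sonication_mean: float = DEFAULT_SONICATION_MEAN
    sonication_sd: float = DEFAULT_SONICATION_SD
    size_select: tuple[int, int] = DEFAULT_SIZE_SELECT
    barcode: str = "ACGT"
    read_length: int = DEFAULT_READ_LENGTH
    error_rate: float = 0.0  # uniform substitution rate; 0 = error-free reads

    def __post_init__(self) -> None:
        if not 0 < self.p0 <= 1:
            raise ValueError("p0 must be in (0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        lo, hi = self.size_select
        if lo <= 0 or hi <= lo:
            raise ValueError("size-selection window must be positive and ordered")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def simulate_genome(
    seed: int,
    length: int | Mapping[str, int],
    gc_fraction: float = 0.42,
    plant: Mapping[str, Sequence[tuple[int, str]]] | None = None,
) -> dict[str, str]:
    """Random genome as chrom -> sequence (i.i.d. bases, given GC content).

    ``length`` is a single length (one chromosome ``chr1``) or a mapping of
    chromosome name to length.  ``plant`` optionally overwrites stated
    coordinates with concrete motifs, chrom -> [(start, sequence), ...] —
    used to position restriction sites exactly.
    """
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    if isinstance(length, int):
        if length < 1000:
            raise ValueError("chromosomes shorter than 1 kb are not supported")
        lengths = {"chr1": length}
    else:
        lengths = dict(length)
        if any(v < 1000 for v in lengths.values()):
            raise ValueError("chromosomes shorter than 1 kb are not supported")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    bases = np.array(list("ACGT"))
    genome: dict[str, str] = {}
    for chrom in sorted(lengths):
        draw = rng.choice(4, size=lengths[chrom], p=[at, gc, gc, at])
        seq = np.array(bases)[draw]
        if plant and chrom in plant:
            for start, motif in plant[chrom]:
                if start < 0 or start + len(motif) > lengths[chrom]:
                    raise ValueError(f"planted motif at {chrom}:{start} out of bounds")
                seq[start : start + len(motif)] = list(motif.upper())
        genome[chrom] = "".join(seq)
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class ChromatinModel:
    """Ground-truth chromatin organization for one simulated genome.

    Cores are non-overlapping 147-bp intervals per chromosome with a class
    label (0 canonical, 1 variant); everything not covered by a core
    (linkers, NFRs, chromosome ends) is fully accessible.
    """

    core_start: dict[str, np.ndarray]
    core_class: dict[str, np.ndarray]  # 0 canonical, 1 variant
    nfr: dict[str, list[tuple[int, int]]]
    occlusion: float = DEFAULT_OCCLUSION
    variant_multiplier: float = DEFAULT_VARIANT_MULTIPLIER
    variant_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.occlusion <= 1:
            raise ValueError("occlusion factor must be in [0, 1]")
        if self.variant_multiplier <= 0:
            raise ValueError("variant multiplier must be > 0")
        if any(w <= 0 for w in self.variant_weights.values()):
            raise ValueError("motif-variant weights must be > 0")

    def accessibility(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Accessibility factor a(pos): 1 outside cores, occlusion under
        canonical cores, min(1, m * occlusion) under variant cores."""
        pos = np.asarray(pos, dtype=np.int64)
        a = np.ones(len(pos), dtype=float)
        starts = self.core_start.get(chrom)
        if starts is None or len(starts) == 0:
            return a
        j = np.searchsorted(starts, pos, side="right") - 1
        jc = np.clip(j, 0, None)
        in_core = (j >= 0) & (pos < starts[jc] + NUCLEOSOME_CORE_BP)
        cls = self.core_class[chrom][jc]
        a_canonical = self.occlusion
        a_variant = min(1.0, self.variant_multiplier * self.occlusion)
        a[in_core & (cls == 0)] = a_canonical
        a[in_core & (cls == 1)] = a_variant
        return a

    def nfr_features(self):
        """Planted NFRs as a FeatureSet (for metaprofile validation)."""
        from .aggregate import Feature, FeatureSet

        feats = [
            Feature(chrom, s, e, name=f"nfr_{chrom}_{s}")
            for chrom in sorted(self.nfr)
            for s, e in self.nfr[chrom]
        ]
        return FeatureSet(feats)

    def to_json(self, path: str | Path) -> None:
        data = {
            "occlusion": self.occlusion,
            "variant_multiplier": self.variant_multiplier,
            "variant_weights": self.variant_weights,
            "core_start": {c: v.tolist() for c, v in self.core_start.items()},
            "core_class": {c: v.tolist() for c, v in self.core_class.items()},
            "nfr": {c: list(map(list, v)) for c, v in self.nfr.items()},
        }
        Path(path).write_text(json.dumps(data) + "\n")


def build_chromatin_model(
    chrom_sizes: Mapping[str, int],
    seed: int,
    nfr_centers: Mapping[str, Sequence[int]] | None = None,
    nfr_length: int = DEFAULT_NFR_LENGTH,
    linker_mean: float = DEFAULT_LINKER_MEAN,
    linker_sd: float = DEFAULT_LINKER_SD,
    occlusion: float = DEFAULT_OCCLUSION,
    variant_fraction: float = DEFAULT_VARIANT_FRACTION,
    variant_multiplier: float = DEFAULT_VARIANT_MULTIPLIER,
    variant_weights: Mapping[str, float] | None = None,
    regular_spacing: bool = False,
) -> ChromatinModel:
    """Tile each chromosome with nucleosome arrays around planted NFRs.

    Cores are 147 bp; linker lengths are drawn from a normal distribution
    (mean ~30 bp, floored at 2 bp) unless ``regular_spacing`` fixes them at
    the mean, which produces phased arrays.  NFR intervals of
    ``nfr_length`` are centered on ``nfr_centers`` and left core-free.
    Each core is independently labeled variant with ``variant_fraction``.
    """
    rng = np.random.default_rng(seed)
    core_start: dict[str, np.ndarray] = {}
    core_class: dict[str, np.ndarray] = {}
    nfr: dict[str, list[tuple[int, int]]] = {}
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        centers = sorted(nfr_centers.get(chrom, [])) if nfr_centers else []
        intervals = [
            (max(0, c - nfr_length // 2), min(size, c + (nfr_length + 1) // 2))
            for c in centers
        ]
        nfr[chrom] = intervals
        starts: list[int] = []
        pos = 0
        blocked = intervals + [(size, size)]
        bi = 0
        while pos + NUCLEOSOME_CORE_BP <= size:
            while bi < len(intervals) and pos >= intervals[bi][1]:
                bi += 1
            if bi < len(intervals) and pos + NUCLEOSOME_CORE_BP > intervals[bi][0]:
                pos = intervals[bi][1]  # jump past the NFR
                continue
            starts.append(pos)
            if regular_spacing:
                linker = int(round(linker_mean))
            else:
                linker = max(2, int(round(rng.normal(linker_mean, linker_sd))))
            pos += NUCLEOSOME_CORE_BP + linker
        arr = np.array(starts, dtype=np.int64)
        core_start[chrom] = arr
        core_class[chrom] = (rng.random(len(arr)) < variant_fraction).astype(np.int8)
    return ChromatinModel(
        core_start=core_start,
        core_class=core_class,
        nfr=nfr,
        occlusion=occlusion,
        variant_multiplier=variant_multiplier,
        variant_weights=dict(variant_weights or {}),
    )


def cut_probabilities(
    index: RSIndex,
    model: ChromatinModel | None,
    config: SimulationConfig,
) -> np.ndarray:
    """Per-site per-molecule cleavage probability.

    Naked mode: ``p0 * w(variant)``.  Chromatin mode: additionally scaled
    by the accessibility factor at the site's cut coordinate.  Sites on
    chromosomes absent from the model are treated as fully accessible
    (linker).  Probabilities are clipped to 1.
    """
    w = np.ones(len(index), dtype=float)
    weights = model.variant_weights if model is not None else {}
    if weights:
        for variant, weight in weights.items():
            w[index.variant == variant] = weight
    p = config.p0 * w
    if not config.naked_dna:
        if model is None:
            raise ValueError("chromatin mode requires a ChromatinModel")
        a = np.ones(len(index), dtype=float)
        cutpos = index.expected_end_plus()
        import pandas as pd

        for chrom in pd.unique(index.chrom):
            sl = index.chrom_slice(str(chrom))
            a[sl] = model.accessibility(str(chrom), cutpos[sl])
        p = p * a
    return np.clip(p, 0.0, 1.0)


@dataclass
class SimTruth:
    """Ground truth behind one simulated library.

    ``read_site`` / ``read_strand`` give, per emitted read, the source site
    (dense site_id into the index) and the read strand; every read traces
    to exactly one cut event.
    """

    probs: np.ndarray  # realized per-site cleavage probability
    read_site: np.ndarray  # int64 site ids, one per read
    read_strand: np.ndarray  # '+'/'-' per read
    read_chrom: np.ndarray
    read_five_prime: np.ndarray  # 5' coordinate (exclusive for '-')
    n_molecules: int = 0
    n_cut_events: int = 0

    def site_counts(self, n_sites: int) -> np.ndarray:
        return np.bincount(self.read_site, minlength=n_sites)

    def write_read_bed(self, path: str | Path, read_length: int = 1) -> None:
        """Truth alignments as 6-column BED of read ends (name = site id)."""
        with open(path, "w") as fh:
            for chrom, fp, strand, sid in zip(
                self.read_chrom, self.read_five_prime, self.read_strand, self.read_site
            ):
                if strand == "+":
                    fh.write(f"{chrom}\t{fp}\t{fp + read_length}\tsite{sid}\t0\t+\n")
                else:
                    fh.write(f"{chrom}\t{max(0, fp - read_length)}\t{fp}\tsite{sid}\t0\t-\n")

    def write_provenance_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_index\tsite_id\tchrom\tfive_prime\tstrand\n")
            for i, (sid, chrom, fp, strand) in enumerate(
                zip(self.read_site, self.read_chrom, self.read_five_prime, self.read_strand)
            ):
                fh.write(f"{i}\t{sid}\t{chrom}\t{fp}\t{strand}\n")


def _sonication_lengths(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    """Truncated-normal sonication offsets (mean ~200 bp, floored at 1)."""
    draw = rng.normal(cfg.sonication_mean, cfg.sonication_sd, size=n)
    return np.maximum(1, np.rint(draw)).astype(np.int64)


def generate_library(
    genome: Mapping[str, str],
    index: RSIndex,
    probs: np.ndarray,
    config: SimulationConfig,
    emit_fastq: bool = True,
) -> tuple[list, SimTruth]:
    """Digest ``n_molecules`` genome copies and build a sequencing library.

    Returns (reads, truth): ``reads`` is a list of
    :class:`~redseq.readproc.FastqRead` (empty when ``emit_fastq`` is
    False — counts-only studies at high depth skip sequence
    materialization), ``truth`` records per-read provenance either way.
    """
    from .readproc import FastqRead

    if len(probs) != len(index):
        raise ValueError("probability vector does not match the index")
    rng = np.random.default_rng(config.seed)
    chrom_names = sorted(genome)
    chrom_code = {c: k for k, c in enumerate(chrom_names)}
    sizes = np.array([len(genome[c]) for c in chrom_names], dtype=np.int64)

    # sparse cut events: for each site, which molecules cut it
    ev_site: list[np.ndarray] = []
    ev_mol: list[np.ndarray] = []
    n_events_per_site = rng.binomial(config.n_molecules, probs)
    for i in np.flatnonzero(n_events_per_site):
        ids = rng.integers(0, config.n_molecules, size=n_events_per_site[i])
        ev_site.append(np.full(len(ids), i, dtype=np.int64))
        ev_mol.append(ids)
    if not ev_site:
        raise ValueError("no cuts occurred; increase n_molecules or p0")
    site = np.concatenate(ev_site)
    mol = np.concatenate(ev_mol)

    site_chrom_code = np.array(
        [chrom_code[str(c)] for c in index.chrom], dtype=np.int64
    )[site]
    # fiber = one chromosome copy within one molecule
    fiber = mol * len(chrom_names) + site_chrom_code
    cut_plus = index.expected_end_plus()[site]  # right-fragment start
    cut_minus = index.expected_end_minus()[site]  # left-fragment (excl.) end

    # a molecule cannot be cut twice at the same site
    order = np.lexsort((site, fiber))
    site, fiber = site[order], fiber[order]
    cut_plus, cut_minus = cut_plus[order], cut_minus[order]
    site_chrom_code = site_chrom_code[order]
    keep = np.ones(len(site), dtype=bool)
    keep[1:] = (fiber[1:] != fiber[:-1]) | (site[1:] != site[:-1])
    site, fiber = site[keep], fiber[keep]
    cut_plus, cut_minus = cut_plus[keep], cut_minus[keep]
    site_chrom_code = site_chrom_code[keep]
    # per-fiber coordinate order for neighboring-cut bookkeeping
    order = np.lexsort((cut_plus, fiber))
    site, fiber = site[order], fiber[order]
    cut_plus, cut_minus = cut_plus[order], cut_minus[order]
    site_chrom_code = site_chrom_code[order]
    n_events = len(site)

    chrom_len = sizes[site_chrom_code]
    same_next = np.zeros(n_events, dtype=bool)
    same_next[:-1] = fiber[:-1] == fiber[1:]
    same_prev = np.zeros(n_events, dtype=bool)
    same_prev[1:] = same_next[:-1]
    # room available before the neighboring cut (or chromosome end)
    next_bound = np.where(same_next, np.roll(cut_minus, -1), chrom_len)
    prev_bound = np.where(same_prev, np.roll(cut_plus, 1), 0)
    avail_right = np.maximum(0, next_bound - cut_plus)
    avail_left = np.maximum(0, cut_minus - prev_bound)

    lo, hi = config.size_select
    frag_right = np.minimum(_sonication_lengths(rng, n_events, config), avail_right)
    frag_left = np.minimum(_sonication_lengths(rng, n_events, config), avail_left)
    keep_right = (frag_right >= lo) & (frag_right <= hi)
    keep_left = (frag_left >= lo) & (frag_left <= hi)

    r_site = np.concatenate([site[keep_right], site[keep_left]])
    r_strand = np.concatenate(
        [
            np.full(int(keep_right.sum()), "+", dtype=object),
            np.full(int(keep_left.sum()), "-", dtype=object),
        ]
    )
    r_fp = np.concatenate([cut_plus[keep_right], cut_minus[keep_left]])
    r_chrom_code = np.concatenate(
        [site_chrom_code[keep_right], site_chrom_code[keep_left]]
    )
    if len(r_site) == 0:
        raise ValueError(
            "no fragments survived size selection; increase n_molecules"
        )
    # deterministic read order: by (chrom, coordinate, strand, site)
    strand_code = (r_strand == "-").astype(np.int8)
    ro = np.lexsort((r_site, strand_code, r_fp, r_chrom_code))
    r_site, r_strand, r_fp, r_chrom_code = (
        r_site[ro],
        r_strand[ro],
        r_fp[ro],
        r_chrom_code[ro],
    )
    r_chrom = np.array(chrom_names, dtype=object)[r_chrom_code]

    truth = SimTruth(
        probs=probs,
        read_site=r_site,
        read_strand=r_strand,
        read_chrom=r_chrom,
        read_five_prime=r_fp,
        n_molecules=config.n_molecules,
        n_cut_events=n_events,
    )

    reads: list = []
    if emit_fastq:
        from .restriction_map import reverse_complement

        qual = "I" * (len(config.barcode) + config.read_length)
        bases = "ACGT"
        for i in range(len(r_site)):
            chrom = str(r_chrom[i])
            seq = genome[chrom]
            fp = int(r_fp[i])
            if r_strand[i] == "+":
                insert = seq[fp : fp + config.read_length]
            else:
                insert = reverse_complement(seq[max(0, fp - config.read_length) : fp])
            if config.error_rate > 0:
                chars = list(insert)
                for j in np.flatnonzero(rng.random(len(chars)) < config.error_rate):
                    chars[j] = bases[(bases.index(chars[j]) + int(rng.integers(1, 4))) % 4]
                insert = "".join(chars)
            full = config.barcode + insert
            reads.append(
                FastqRead(f"sim_{i}_site{r_site[i]}", full, qual[: len(full)])
            )
    return reads, truth


def sample_count_table(
    probs: np.ndarray,
    n_reads: int,
    seed: int,
    library: str = "sampled",
):
    """Count-level sampler: multinomial reads over relative cut probabilities.

    Bypasses molecule/fragment bookkeeping: read counts are drawn directly
    proportional to per-site cleavage probabilities.  This is the fast path
    for statistical studies (e.g. null calibration of the differential
    test) where fragment-length physics is irrelevant.
    """
    from .assign_count import CutCountTable

    probs = np.asarray(probs, dtype=float)
    if probs.sum() <= 0:
        raise ValueError("probabilities sum to zero")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, probs / probs.sum())
    return CutCountTable(library=library, raw=counts.astype(np.int64))
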