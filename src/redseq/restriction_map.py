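"""Restriction-site discovery and indexing.

RED-seq quantifies chromatin accessibility as the cut frequency at every
occurrence of a restriction enzyme's recognition motif.  This module turns a
degenerate IUPAC motif (e.g. Sau96I's GGNCC) into a genome-wide index of
restriction sites (RSs): each site carries its coordinates, the concrete
motif variant present in the genome (GGTCC, GGACC, ...), and the enzyme of
origin.  The index is the coordinate system every downstream stage (read
assignment, normalization, metaprofiles, differential tests) works in.

Coordinates are 0-based, half-open (BED convention) throughout.
"""

from __future__ import annotations

import io
import json
import re
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

__all__ = [
    "EnzymeSpec",
    "RestrictionSite",
    "RSIndex",
    "MotifMatcher",
    "compile_motif",
    "scan_sequence",
    "build_index",
    "density_counts",
    "BUILTIN_ENZYMES",
    "get_enzyme",
    "load_enzyme_config",
]

# IUPAC code -> set of concrete bases.  Genome N never matches any motif
# code (including N itself): assembly gaps must not produce phantom sites,
# so matching is defined over concrete A/C/G/T only.
IUPAC: Mapping[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}

_VALID_IUPAC = frozenset(IUPAC)


class InvalidMotifError(ValueError):
    """A motif contains a character that is not an IUPAC nucleotide code."""


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition motif plus cut chemistry.

    ``cut_offset`` is the number of bases from the motif start to the
    top-strand cut point, so Sau96I (G^GNCC) has motif ``GGNCC`` and
    ``cut_offset`` 1.  ``read_prefix`` is the sequence a cleaved,
    end-repaired fragment starts with: the motif from the cut point onward
    (GNCC for Sau96I), which is the library-quality signature checked by
    :mod:`redseq.readproc`.
    """

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        motif = self.motif.upper()
        object.__setattr__(self, "motif", motif)
        if len(motif) < 4:
            raise InvalidMotifError(
                f"enzyme {self.name}: motif {motif!r} shorter than 4 bases"
            )
        bad = [c for c in motif if c not in _VALID_IUPAC]
        if bad:
            raise InvalidMotifError(
                f"enzyme {self.name}: invalid IUPAC character {bad[0]!r} in motif"
            )
        if not 0 <= self.cut_offset <= len(motif):
            raise ValueError(
                f"enzyme {self.name}: cut_offset {self.cut_offset} outside motif"
            )

    @property
    def read_prefix(self) -> str:
        return self.motif[self.cut_offset :]

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    @property
    def is_palindromic(self) -> bool:
        """True iff the motif equals its own IUPAC reverse complement."""
        return self.motif == reverse_complement(self.motif)


#: Built-in enzymes.  Sau96I chemistry (G^GNCC) is the primary enzyme of the
#: assay; DdeI (C^TNAG) is the second enzyme of the dual-digestion mode.
#: Both definitions can be overridden via an enzyme config file.
BUILTIN_ENZYMES: dict[str, EnzymeSpec] = {
    "Sau96I": EnzymeSpec("Sau96I", "GGNCC", 1),
    "DdeI": EnzymeSpec("DdeI", "CTNAG", 1),
}


def get_enzyme(name: str, config: Mapping[str, EnzymeSpec] | None = None) -> EnzymeSpec:
    """Look up an enzyme by name in ``config`` then in the built-ins."""
    if config and name in config:
        return config[name]
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; define it in an enzyme config file"
        ) from None


def load_enzyme_config(path: str | Path) -> dict[str, EnzymeSpec]:
    """Read enzyme definitions from a YAML/JSON file.

    Expected layout: a mapping of name -> {motif, cut_offset} or a list of
    {name, motif, cut_offset} records.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    specs: dict[str, EnzymeSpec] = {}
    if isinstance(data, Mapping):
        items = [{"name": k, **v} for k, v in data.items()]
    else:
        items = list(data)
    for rec in items:
        spec = EnzymeSpec(rec["name"], rec["motif"], int(rec["cut_offset"]))
        specs[spec.name] = spec
    return specs


class MotifMatcher:
    """Compiled matcher for one degenerate IUPAC motif.

    Accepts exactly the concrete A/C/G/T k-mers consistent with the code
    and scans sequences for (possibly overlapping) occurrences.
    """

    def __init__(self, motif: str):
        motif = motif.upper()
        if not motif:
            raise InvalidMotifError("empty motif")
        for c in motif:
            if c not in _VALID_IUPAC:
                raise InvalidMotifError(f"invalid IUPAC character {c!r} in motif")
        self.motif = motif
        self._sets = [IUPAC[c] for c in motif]
        # lookahead regex reports overlapping matches as distinct sites
        body = "".join(
            c if len(IUPAC[c]) == 1 else "[" + "".join(sorted(IUPAC[c])) + "]"
            for c in motif
        )
        self._re = re.compile(f"(?=({body}))")

    def __len__(self) -> int:
        return len(self.motif)

    @property
    def n_expansions(self) -> int:
        """Number of concrete k-mers the code expands to."""
        n = 1
        for s in self._sets:
            n *= len(s)
        return n

    def expansions(self) -> list[str]:
        kmers = [""]
        for s in self._sets:
            kmers = [k + b for k in kmers for b in sorted(s)]
        return kmers

    def accepts(self, kmer: str) -> bool:
        kmer = kmer.upper()
        if len(kmer) != len(self.motif):
            return False
        return all(b in s for b, s in zip(kmer, self._sets))

    def finditer(self, seq: str) -> Iterator[tuple[int, str]]:
        """Yield (start, matched variant) for every occurrence in ``seq``."""
        for m in self._re.finditer(seq):
            yield m.start(), m.group(1)


def compile_motif(motif: str) -> MotifMatcher:
    """Compile a degenerate IUPAC motif into a :class:`MotifMatcher`."""
    return MotifMatcher(motif)


@dataclass(frozen=True)
class RestrictionSite:
    """One occurrence of an enzyme's recognition motif in the genome."""

    site_id: int
    chrom: str
    motif_start: int  # 0-based
    enzyme: str
    variant: str  # concrete matched sequence, degenerate positions resolved

    @property
    def motif_end(self) -> int:
        return self.motif_start + len(self.variant)


def scan_sequence(seq: str, enzyme: EnzymeSpec, chrom: str = "chr") -> list[RestrictionSite]:
    """Find all restriction sites of ``enzyme`` in one sequence.

    Both strands are covered: occurrences of the motif's reverse complement
    on the forward strand are minus-strand sites and are reported at their
    forward-strand coordinates.  For a palindromic motif (GGNCC, CTNAG) the
    reverse-complement scan finds nothing new, so forward scanning is
    complete.  Duplicates are collapsed on (chrom, motif_start).  Returned
    ``site_id`` values are provisional (position order within this call);
    :func:`build_index` reassigns dense genome-wide ids.
    """
    seq = seq.upper()
    fwd = compile_motif(enzyme.motif)
    hits: dict[int, str] = {}
    for start, variant in fwd.finditer(seq):
        hits[start] = variant
    if not enzyme.is_palindromic:
        rev = compile_motif(reverse_complement(enzyme.motif))
        for start, variant in rev.finditer(seq):
            # report the motif as seen on the minus strand
            hits.setdefault(start, reverse_complement(variant))
    return [
        RestrictionSite(i, chrom, start, enzyme.name, hits[start])
        for i, start in enumerate(sorted(hits))
    ]


@dataclass
class RSIndex:
    """All restriction sites of one or more enzymes in a genome.

    Sites are stored as parallel columns sorted by (chrom, motif_start) with
    dense ``site_id`` 0..n-1 assigned in that order (chromosome names
    lexicographic, then coordinate), which makes the index deterministic for
    a given genome + enzyme set.
    """

    chrom: np.ndarray  # object array of chromosome names
    motif_start: np.ndarray  # int64
    enzyme: np.ndarray  # object
    variant: np.ndarray  # object
    motif_length: np.ndarray  # int64
    cut_offset: np.ndarray  # int64
    enzymes: dict[str, EnzymeSpec] = field(default_factory=dict)
    genome_id: str = ""
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.motif_start)
        for arr in (self.chrom, self.enzyme, self.variant, self.motif_length, self.cut_offset):
            if len(arr) != n:
                raise ValueError("RSIndex columns have unequal lengths")

    def __len__(self) -> int:
        return len(self.motif_start)

    @property
    def site_id(self) -> np.ndarray:
        return np.arange(len(self), dtype=np.int64)

    @property
    def motif_end(self) -> np.ndarray:
        return self.motif_start + self.motif_length

    def expected_end_plus(self) -> np.ndarray:
        """Per-site 5' coordinate of a plus-strand read from a cut at the site."""
        return self.motif_start + self.cut_offset

    def expected_end_minus(self) -> np.ndarray:
        """Per-site (exclusive) 5' coordinate of a minus-strand read."""
        return self.motif_start + self.motif_length - self.cut_offset

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous slice of sites on one chromosome (sorted storage)."""
        lo = int(np.searchsorted(self.chrom, chrom, side="left"))
        hi = int(np.searchsorted(self.chrom, chrom, side="right"))
        return slice(lo, hi)

    def sites(self) -> Iterator[RestrictionSite]:
        for i in range(len(self)):
            yield RestrictionSite(
                i,
                str(self.chrom[i]),
                int(self.motif_start[i]),
                str(self.enzyme[i]),
                str(self.variant[i]),
            )

    @classmethod
    def from_sites(
        cls,
        sites: Iterable[RestrictionSite],
        enzymes: Iterable[EnzymeSpec],
        genome_id: str = "",
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> "RSIndex":
        enz = {e.name: e for e in enzymes}
        recs = sorted(sites, key=lambda s: (s.chrom, s.motif_start, s.enzyme))
        # no duplicate (chrom, motif_start, enzyme)
        seen: set[tuple[str, int, str]] = set()
        uniq = []
        for s in recs:
            key = (s.chrom, s.motif_start, s.enzyme)
            if key in seen:
                continue
            seen.add(key)
            uniq.append(s)
        n = len(uniq)
        return cls(
            chrom=np.array([s.chrom for s in uniq], dtype=object),
            motif_start=np.array([s.motif_start for s in uniq], dtype=np.int64),
            enzyme=np.array([s.enzyme for s in uniq], dtype=object),
            variant=np.array([s.variant for s in uniq], dtype=object),
            motif_length=np.array([len(s.variant) for s in uniq], dtype=np.int64),
            cut_offset=np.array([enz[s.enzyme].cut_offset for s in uniq], dtype=np.int64),
            enzymes=enz,
            genome_id=genome_id,
            chrom_sizes=dict(chrom_sizes or {}),
        )

    # ---- I/O -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "chrom": self.chrom,
                "motif_start": self.motif_start,
                "motif_end": self.motif_end,
                "enzyme": self.enzyme,
                "variant": self.variant,
            }
        )

    def write_bed(self, path: str | Path) -> None:
        """BED6: chrom, start, end, 'enzyme|variant', 0, '+'."""
        with open(path, "w") as fh:
            for i in range(len(self)):
                fh.write(
                    f"{self.chrom[i]}\t{self.motif_start[i]}\t"
                    f"{self.motif_start[i] + self.motif_length[i]}\t"
                    f"{self.enzyme[i]}|{self.variant[i]}\t0\t+\n"
                )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()[["site_id", "chrom", "motif_start", "enzyme", "variant"]]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        enzymes: Iterable[EnzymeSpec] | None = None,
        genome_id: str = "",
    ) -> "RSIndex":
        df = pd.read_csv(path, sep="\t")
        enz = {e.name: e for e in (enzymes or [])}
        for name in pd.unique(df["enzyme"]):
            if name not in enz:
                enz[name] = get_enzyme(str(name))
        sites = [
            RestrictionSite(
                int(r.site_id), str(r.chrom), int(r.motif_start), str(r.enzyme), str(r.variant)
            )
            for r in df.itertuples()
        ]
        return cls.from_sites(sites, enz.values(), genome_id=genome_id)


def _iter_fasta(genome) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTA path, pyfaidx.Fasta, or mapping."""
    if isinstance(genome, Mapping):
        for name in genome:
            yield str(name), str(genome[name])
        return
    if isinstance(genome, (str, Path)):
        if str(genome).endswith(".gz"):
            import gzip

            from Bio import SeqIO

            with gzip.open(str(genome), "rt") as fh:
                for rec in SeqIO.parse(fh, "fasta"):
                    yield rec.id, str(rec.seq)
            return
        import pyfaidx

        fa = pyfaidx.Fasta(str(genome))
        for name in fa.keys():
            yield name, str(fa[name][:])
        return
    # pyfaidx.Fasta or similar keyed object
    for name in genome.keys():
        yield str(name), str(genome[name][:])


def build_index(
    genome,
    enzymes: Sequence[EnzymeSpec],
    genome_id: str = "",
) -> RSIndex:
    """Scan a genome for all sites of all enzymes and build the index.

    ``genome`` may be a FASTA path, a ``pyfaidx.Fasta``, or a plain mapping
    of chromosome name to sequence.  Dual-enzyme digests pass two specs;
    every site keeps its enzyme of origin.
    """
    if not enzymes:
        raise ValueError("at least one enzyme is required")
    names = [e.name for e in enzymes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate enzyme names")
    all_sites: list[RestrictionSite] = []
    chrom_sizes: dict[str, int] = {}
    for chrom, seq in _iter_fasta(genome):
        if chrom in chrom_sizes:
            raise ValueError(f"duplicate chromosome name {chrom!r}")
        chrom_sizes[chrom] = len(seq)
        for enzyme in enzymes:
            all_sites.extend(scan_sequence(seq, enzyme, chrom))
    if not all_sites:
        warnings.warn("no restriction sites found; index is empty", stacklevel=2)
    return RSIndex.from_sites(
        all_sites, enzymes, genome_id=genome_id, chrom_sizes=chrom_sizes
    )


def density_counts(index: RSIndex):
    """One pseudo-read per site: the restriction-site density baseline.

    RSs are non-uniformly distributed, so average accessibility around a
    feature set is only interpretable against the local density of sites.
    Assigning a single read to every site and pushing the result through the
    same RPM normalization and metaprofile machinery yields that baseline.
    """
    from .assign_count import CutCountTable

    if len(index) == 0:
        raise ValueError("density is undefined for an empty index")
    table = CutCountTable(
        library="rs_density",
        raw=np.ones(len(index), dtype=np.int64),
    )
    return table
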