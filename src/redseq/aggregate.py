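"""Metaprofiles and windowed accessibility scores around genomic features.

Average accessibility around a feature set (DHS peaks, CTCF sites, planted
nucleosome-free regions, ...) is computed by binning the flanking region in
fixed-width windows (50 bp by default), summing normalized reads (RPM) per
window, and dividing by the number of features.  Because restriction sites
are non-uniformly distributed, the same machinery applied to a density
table (one pseudo-read per site) yields the site-density baseline that the
accessibility curve must be read against.

A per-feature scalar score — summed RPM within ±200 bp of the feature
center by default — supports replicate-level comparisons between
conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assign_count import CutCountTable, normalize_rpm
from .restriction_map import RSIndex

__all__ = [
    "Feature",
    "FeatureSet",
    "MetaProfile",
    "metaprofile",
    "window_score",
    "table_point_masses",
]

DEFAULT_FLANK = 1000
DEFAULT_BIN = 50
DEFAULT_HALFWIDTH = 200


@dataclass(frozen=True)
class Feature:
    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"feature {self.name!r}: start must be < end")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


class FeatureSet:
    """An ordered set of genomic intervals with precomputed centers."""

    def __init__(self, features: Sequence[Feature]):
        self.features = list(features)
        if not self.features:
            raise ValueError("empty feature set")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features], dtype=np.int64)

    @classmethod
    def read_bed(cls, path: str | Path) -> "FeatureSet":
        feats = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                p = line.rstrip("\n").split("\t")
                feats.append(
                    Feature(
                        p[0],
                        int(p[1]),
                        int(p[2]),
                        p[3] if len(p) > 3 else "",
                        p[5] if len(p) > 5 else ".",
                    )
                )
        return cls(feats)

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in self.features:
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.name or '.'}\t0\t{f.strand}\n")


@dataclass
class MetaProfile:
    """Binned average accessibility around feature centers.

    ``values[k]`` is the average per-feature RPM mass in the bin covering
    offsets ``[offsets[k], offsets[k] + bin_size)`` relative to feature
    centers.  ``n_features`` is the divisor: duplicating every feature
    leaves the profile unchanged.
    """

    offsets: np.ndarray  # bin start offsets, -flank .. flank-bin
    values: np.ndarray
    bin_size: int
    flank: int
    n_features: int
    n_clipped: int = 0  # features whose window overhung a chromosome end

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start_offset": self.offsets, "value": self.values})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def table_point_masses(
    table: CutCountTable, index: RSIndex
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Cut counts as point masses at each site's cut coordinate.

    Each site's RPM is placed at its plus-strand expected cut coordinate
    (motif_start + cut_offset); the site, not the read strand, is the unit
    of accessibility.  Returns chrom -> (sorted positions, values).
    """
    if len(table) != len(index):
        raise ValueError("table/index length mismatch")
    values = table.rpm
    if values is None:
        values = normalize_rpm(table).rpm
    pos = index.expected_end_plus()
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in pd.unique(index.chrom):
        sl = index.chrom_slice(str(chrom))
        p, v = pos[sl], values[sl]
        order = np.argsort(p, kind="stable")  # mixed cut offsets can unsort
        out[str(chrom)] = (p[order], v[order])
    return out


def _as_point_masses(signal, index: RSIndex | None):
    """Accept a CutCountTable (requires index) or a ready point-mass dict."""
    if isinstance(signal, CutCountTable):
        if index is None:
            raise ValueError("an RSIndex is required to place cut counts")
        return table_point_masses(signal, index)
    out = {}
    for chrom, (p, v) in signal.items():
        p = np.asarray(p, dtype=np.int64)
        v = np.asarray(v, dtype=float)
        order = np.argsort(p, kind="stable")
        out[chrom] = (p[order], v[order])
    return out


def _oriented_offsets(pos: np.ndarray, center: int, strand: str, flip: bool) -> np.ndarray:
    off = pos - center
    if flip and strand == "-":
        off = -off - 1  # mirror; base at -1 maps to offset 0
    return off


def metaprofile(
    signal,
    features: FeatureSet,
    index: RSIndex | None = None,
    flank: int = DEFAULT_FLANK,
    bin_size: int = DEFAULT_BIN,
    strand_aware: bool = False,
    chrom_sizes: dict[str, int] | None = None,
) -> MetaProfile:
    """Average binned signal in ``[-flank, +flank)`` around feature centers.

    ``signal`` is a :class:`CutCountTable` (cut counts placed at site cut
    coordinates; pass the index) or a mapping chrom -> (positions, values)
    for generic coverage-style tracks.  A mass at offset ``o`` from a
    center lands in bin ``floor((o + flank) / bin_size)`` (left-closed,
    right-open bins).  Features are unstranded peak centers by default;
    ``strand_aware`` mirrors minus-strand features for TSS-style input.
    Overlapping features each receive full, independent contributions.
    """
    if 2 * flank % bin_size != 0:
        raise ValueError("2*flank must be a multiple of bin_size")
    masses = _as_point_masses(signal, index)
    chrom_sizes = chrom_sizes or (index.chrom_sizes if index is not None else {})
    n_bins = 2 * flank // bin_size
    offsets = np.arange(-flank, flank, bin_size, dtype=np.int64)
    total = np.zeros(n_bins, dtype=float)
    n_clipped = 0
    for f in features:
        if chrom_sizes.get(f.chrom) is not None:
            if f.center - flank < 0 or f.center + flank > chrom_sizes[f.chrom]:
                n_clipped += 1
        pos_vals = masses.get(f.chrom)
        if pos_vals is None:
            continue
        pos, vals = pos_vals
        lo = np.searchsorted(pos, f.center - flank, side="left")
        hi = np.searchsorted(pos, f.center + flank, side="right")
        if lo == hi:
            continue
        off = _oriented_offsets(pos[lo:hi], f.center, f.strand, strand_aware)
        inside = (off >= -flank) & (off < flank)
        bins = (off[inside] + flank) // bin_size
        np.add.at(total, bins, vals[lo:hi][inside])
    if n_clipped:
        warnings.warn(
            f"{n_clipped} feature window(s) overhang a chromosome end; "
            "their bins are computed from available data",
            stacklevel=2,
        )
    return MetaProfile(
        offsets=offsets,
        values=total / len(features),
        bin_size=bin_size,
        flank=flank,
        n_features=len(features),
        n_clipped=n_clipped,
    )


def window_score(
    signal,
    features: FeatureSet,
    index: RSIndex | None = None,
    halfwidth: int = DEFAULT_HALFWIDTH,
) -> pd.DataFrame:
    """Per-feature summed RPM within ``[center - halfwidth, center + halfwidth]``.

    The window includes both endpoints (a site exactly ``halfwidth`` bases
    downstream still counts).  Returns a DataFrame ordered as the input
    features with columns feature, chrom, center, score.
    """
    masses = _as_point_masses(signal, index)
    rows = []
    for i, f in enumerate(features):
        score = 0.0
        pos_vals = masses.get(f.chrom)
        if pos_vals is not None:
            pos, vals = pos_vals
            lo = np.searchsorted(pos, f.center - halfwidth, side="left")
            hi = np.searchsorted(pos, f.center + halfwidth, side="right")
            score = float(vals[lo:hi].sum())
        rows.append(
            {"feature": f.name or f"feature_{i}", "chrom": f.chrom, "center": f.center, "score": score}
        )
    return pd.DataFrame(rows)
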