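"""Differential cut analysis between libraries and feature-level comparisons.

Per-site differential accessibility between two libraries is tested with
Fisher's exact test on the 2x2 table (reads at the site vs. the remainder
of the library, library A vs. library B) — exact at low counts and free of
distributional assumptions — with Benjamini-Hochberg correction across all
tested sites.  Effect sizes are log2 ratios of RPM with a small pseudo-RPM
added on both sides (the pseudo-count enters the effect only, never the
test).

Feature-set-level comparisons (paired per-feature accessibility scores for
two conditions) use the Wilcoxon signed-rank test.  A nearest-interval
annotation utility attaches each site to its closest feature with a signed
distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .aggregate import FeatureSet
from .assign_count import CutCountTable, normalize_rpm
from .restriction_map import RSIndex

__all__ = [
    "site_differential",
    "featureset_comparison",
    "annotate_nearest",
    "FeatureComparison",
    "DEFAULT_PSEUDO_RPM",
]

DEFAULT_PSEUDO_RPM = 1.0


def site_differential(
    table_a: CutCountTable,
    table_b: CutCountTable,
    pseudo: float = DEFAULT_PSEUDO_RPM,
) -> pd.DataFrame:
    """Per-site Fisher's exact test of cut counts, A vs. B.

    Both tables must cover the same site universe (same index).  Sites with
    zero counts in both libraries are excluded from testing (``tested``
    False, p and q NaN) — they carry no information and would only dilute
    the multiple-testing correction.  Returns a DataFrame aligned to
    site_id with raw counts, RPM, ``effect_log2`` =
    log2((RPM_A + pseudo) / (RPM_B + pseudo)), two-sided ``p`` and BH ``q``.
    """
    if len(table_a) != len(table_b):
        raise ValueError("tables cover different site universes")
    if pseudo <= 0:
        raise ValueError("pseudo-RPM must be > 0 (keeps effects finite)")
    a = table_a.raw
    b = table_b.raw
    tot_a, tot_b = table_a.total, table_b.total
    if tot_a == 0 or tot_b == 0:
        raise ValueError("both libraries must contain assigned reads")
    rpm_a = a * (1e6 / tot_a)
    rpm_b = b * (1e6 / tot_b)
    tested = (a + b) > 0
    n = len(a)
    p = np.full(n, np.nan)
    idx = np.flatnonzero(tested)
    # Fisher 2x2: [[a_i, tot_a - a_i], [b_i, tot_b - b_i]]
    p[idx] = [
        stats.fisher_exact(
            [[int(a[i]), tot_a - int(a[i])], [int(b[i]), tot_b - int(b[i])]],
            alternative="two-sided",
        ).pvalue
        for i in idx
    ]
    q = np.full(n, np.nan)
    if len(idx):
        q[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "site_id": np.arange(n, dtype=np.int64),
            "raw_a": a,
            "raw_b": b,
            "rpm_a": rpm_a,
            "rpm_b": rpm_b,
            "effect_log2": np.log2((rpm_a + pseudo) / (rpm_b + pseudo)),
            "p": p,
            "q": q,
            "tested": tested,
        }
    )


def write_site_differential(
    diff: pd.DataFrame, index: RSIndex, path: str | Path
) -> None:
    """TSV with site coordinates joined onto the differential table."""
    out = diff.copy()
    out.insert(1, "chrom", index.chrom)
    out.insert(2, "pos", index.motif_start)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class FeatureComparison:
    """Paired feature-level comparison of two conditions."""

    n_features: int
    mean_a: float
    mean_b: float
    p_value: float
    statistic: float
    degenerate: bool  # all paired differences were zero

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "p_value": self.p_value,
            "statistic": self.statistic,
            "degenerate": self.degenerate,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def featureset_comparison(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> FeatureComparison:
    """Wilcoxon signed-rank test on paired per-feature accessibility scores.

    Vectors must be feature-aligned (same features, same order).  When all
    paired differences are zero the test statistic is undefined; p is
    reported as 1 with the ``degenerate`` flag set.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1-D and feature-aligned")
    if len(a) < 10:
        raise ValueError("need at least 10 paired features")
    diffs = a - b
    if np.all(diffs == 0):
        return FeatureComparison(
            n_features=len(a),
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
            p_value=1.0,
            statistic=float("nan"),
            degenerate=True,
        )
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return FeatureComparison(
        n_features=len(a),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        degenerate=False,
    )


def annotate_nearest(
    chroms: Sequence[str] | np.ndarray,
    positions: Sequence[int] | np.ndarray,
    annotations: FeatureSet,
) -> pd.DataFrame:
    """Nearest annotation interval and signed distance for each position.

    Distance is 0 for a position inside an interval; otherwise the signed
    offset to the nearest interval edge — negative when the position lies
    upstream of the interval start (plus orientation), positive when
    downstream of its end.  Equidistant intervals resolve to the leftmost
    (lowest start).  Positions on chromosomes without annotations get a
    missing (NaN) distance.
    """
    if len(annotations) == 0:
        raise ValueError("empty annotation set")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str], np.ndarray, np.ndarray]] = {}
    for chrom in {f.chrom for f in annotations}:
        ivals = sorted(
            ((f.start, f.end, f.name) for f in annotations if f.chrom == chrom)
        )
        starts = np.array([v[0] for v in ivals], dtype=np.int64)
        ends = np.array([v[1] for v in ivals], dtype=np.int64)
        names = [v[2] for v in ivals]
        cummax_end = np.maximum.accumulate(ends)
        # index of the interval that first achieved the running max end;
        # first occurrence = lowest start, which is the documented tie-break
        jumps = np.empty(len(ends), dtype=np.int64)
        jumps[0] = 0
        for i in range(1, len(ends)):
            jumps[i] = i if ends[i] > cummax_end[i - 1] else jumps[i - 1]
        by_chrom[chrom] = (starts, ends, names, cummax_end, jumps)
    rows = []
    for chrom, pos in zip(chroms, positions):
        pos = int(pos)
        entry = by_chrom.get(str(chrom))
        if entry is None:
            rows.append({"chrom": chrom, "pos": pos, "nearest": None, "distance": np.nan})
            continue
        starts, ends, names, cummax_end, jumps = entry
        j = int(np.searchsorted(starts, pos, side="right")) - 1  # rightmost start <= pos
        best_name, signed = None, 0
        if j >= 0 and cummax_end[j] > pos:
            # contained; leftmost containing interval = first index whose
            # running-max end exceeds pos (all earlier ends are <= pos)
            i = int(np.searchsorted(cummax_end[: j + 1], pos, side="right"))
            best_name, signed = names[i], 0
        else:
            dl = pos - int(cummax_end[j]) + 1 if j >= 0 else None
            dr = int(starts[j + 1]) - pos if j + 1 < len(starts) else None
            if dl is not None and (dr is None or dl <= dr):
                best_name, signed = names[int(jumps[j])], dl
            else:
                best_name, signed = names[j + 1], -dr
        rows.append({"chrom": chrom, "pos": pos, "nearest": best_name, "distance": signed})
    return pd.DataFrame(rows)
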