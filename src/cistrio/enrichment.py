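"""Chromatin-state and genomic-location enrichment of classified QTLs.

Two summaries are produced for QTLs grouped by regulatory pattern:

* a relative-ratio matrix over chromatin states,
  ``ratio_ij = (n_ij / n_j) / (n_i / n)`` for state ``i`` and pattern
  ``j`` — the share of pattern-``j`` QTLs in state ``i`` relative to the
  state's overall share;
* an upper-tail hypergeometric test for overrepresentation of each
  genomic location class (promoter, exon, ...) within each pattern,
  Benjamini-Hochberg corrected across all cells.

Segmentations use BED conventions: 0-based half-open intervals,
non-overlapping per chromosome.  Variant positions arrive 1-based and
are converted explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import FormatError, ParameterError
from .qtl import bh_threshold

DEFAULT_REGION_PRECEDENCE = ("promoter", "exon", "intron", "upstream", "downstream")


@dataclass
class StateSegmentation:
    """Sorted, non-overlapping labeled intervals per chromosome."""

    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]
    state_names: tuple[str, ...]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StateSegmentation":
        """Build from a table with columns chrom, start, end, state
        (BED-style 0-based half-open)."""
        required = {"chrom", "start", "end", "state"}
        if not required.issubset(frame.columns):
            raise FormatError(f"segmentation table needs columns {sorted(required)}")
        starts, ends, labels = {}, {}, {}
        for chrom, grp in frame.groupby("chrom", sort=True):
            grp = grp.sort_values("start")
            s = grp["start"].to_numpy(dtype=np.int64)
            e = grp["end"].to_numpy(dtype=np.int64)
            if (s >= e).any():
                raise FormatError(f"{chrom}: empty or inverted interval")
            if (s[1:] < e[:-1]).any():
                raise FormatError(f"{chrom}: overlapping intervals")
            starts[chrom], ends[chrom] = s, e
            labels[chrom] = grp["state"].to_numpy(dtype=object)
        names = tuple(sorted(frame["state"].unique()))
        return cls(starts, ends, labels, names)

    def assign(self, chrom: str, pos_1based: int) -> str | None:
        """State label covering a 1-based position, or None if uncovered."""
        if chrom not in self.starts:
            return None
        pos0 = pos_1based - 1  # to 0-based
        s, e = self.starts[chrom], self.ends[chrom]
        idx = np.searchsorted(s, pos0, side="right") - 1
        if idx >= 0 and s[idx] <= pos0 < e[idx]:
            return str(self.labels[chrom][idx])
        return None


def assign_state(
    chrom: str, pos_1based: int, segmentation: StateSegmentation
) -> str | None:
    """Functional wrapper around :meth:`StateSegmentation.assign`."""
    return segmentation.assign(chrom, pos_1based)


@dataclass
class EnrichmentTable:
    """Relative-ratio matrix with its supporting counts.

    ``ratio.loc[i, j]`` is NaN (flagged undefined) when the state or the
    pattern has no QTLs.
    """

    ratio: pd.DataFrame  # states x patterns
    n_ij: pd.DataFrame
    n_i: pd.Series
    n_j: pd.Series
    n: int


def chromatin_ratio_matrix(
    states: pd.Series, patterns: pd.Series
) -> EnrichmentTable:
    """Relative ratio of chromatin state occupancy per regulatory pattern.

    ``states`` and ``patterns`` are aligned per-QTL labels; QTLs whose
    state is missing (annotation gap) are excluded from every count.
    Satisfies the conservation identity
    ``sum_j (n_j / n) ratio_ij = 1`` for every covered state.
    """
    states = pd.Series(states).reset_index(drop=True)
    patterns = pd.Series(patterns).reset_index(drop=True)
    if len(states) != len(patterns):
        raise ParameterError("states and patterns must align")
    keep = states.notna()
    states, patterns = states[keep], patterns[keep]
    n = int(len(states))
    if n == 0:
        raise ParameterError("no QTLs with an assigned chromatin state")

    n_ij = pd.crosstab(states, patterns)
    n_i = n_ij.sum(axis=1)
    n_j = n_ij.sum(axis=0)
    # crosstab only materializes observed categories, so n_i > 0 and
    # n_j > 0 for every row/column; absent margins simply have no cell
    ratio = (n_ij.div(n_j, axis=1)).div(n_i / n, axis=0)
    return EnrichmentTable(ratio=ratio, n_ij=n_ij, n_i=n_i, n_j=n_j, n=n)


def location_hypergeom(
    regions: pd.Series, patterns: pd.Series, fdr: float = 0.1
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation of each region class
    within each pattern, BH-corrected across all (region, pattern) cells.

    Region classes must partition the analyzed QTLs (one class per QTL).
    Returns a long table: region, pattern, n_overlap, n_region,
    n_pattern, n, p_value, p_adj, significant (at the supplied FDR).
    """
    regions = pd.Series(regions).reset_index(drop=True)
    patterns = pd.Series(patterns).reset_index(drop=True)
    if len(regions) != len(patterns):
        raise ParameterError("regions and patterns must align")
    keep = regions.notna()
    regions, patterns = regions[keep], patterns[keep]
    n = int(len(regions))
    if n == 0:
        raise ParameterError("no QTLs with a region class")

    counts = pd.crosstab(regions, patterns)
    rows = []
    for region in counts.index:
        n_r = int(counts.loc[region].sum())
        for pattern in counts.columns:
            n_p = int(counts[pattern].sum())
            k = int(counts.loc[region, pattern])
            # P(X >= k) drawing n_p from population n with n_r successes
            p = float(stats.hypergeom.sf(k - 1, n, n_r, n_p))
            rows.append(
                {
                    "region": region,
                    "pattern": pattern,
                    "n_overlap": k,
                    "n_region": n_r,
                    "n_pattern": n_p,
                    "n": n,
                    "p_value": p,
                }
            )
    table = pd.DataFrame(rows)
    m = len(table)
    p = table["p_value"].to_numpy()
    order = np.argsort(p, kind="mergesort")
    cummin = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(cummin, 1.0)
    table["p_adj"] = adj
    cutoff = bh_threshold(table["p_value"].to_numpy(), fdr).p_cutoff
    table["significant"] = table["p_value"] <= cutoff if cutoff > 0 else False
    return table


def classify_region(
    chrom: str,
    pos_1based: int,
    region_intervals: pd.DataFrame,
    precedence: tuple[str, ...] = DEFAULT_REGION_PRECEDENCE,
) -> str | None:
    """Assign one location class to a variant position.

    ``region_intervals`` has BED-style columns chrom, start, end, region
    (0-based half-open); overlapping annotations resolve by ``precedence``
    order (first match wins), unknown labels rank last.
    """
    pos0 = pos_1based - 1
    sub = region_intervals[
        (region_intervals["chrom"] == chrom)
        & (region_intervals["start"] <= pos0)
        & (pos0 < region_intervals["end"])
    ]
    if sub.empty:
        return None
    rank = {name: i for i, name in enumerate(precedence)}
    hits = sorted(sub["region"], key=lambda r: rank.get(r, len(precedence)))
    return str(hits[0])
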