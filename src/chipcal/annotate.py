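"""Classify peak midpoints against gene models and profile TSS distances.

Categories form a strict partition with priority
promoter > exonic > intronic > intergenic. A promoter is the closed window
[tss − hw, tss + hw] around any transcript's strand-aware TSS (hw defaults
to 1000 bp), and overrides gene-body status: a midpoint inside exon 1 but
within the window is a promoter call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusPeak
from .intervals import GeneModel

CATEGORIES = ("promoter", "exonic", "intronic", "intergenic")


@dataclass(frozen=True)
class PeakAnnotation:
    chrom: str
    start: int
    end: int
    midpoint: int
    category: str
    nearest_gene_id: str | None
    tss_distance: int | None  # signed, strand-aware; None if no TSS on chrom


class GeneIndex:
    """Per-chromosome lookup structure for TSSs, exons and gene spans."""

    def __init__(self, gene_models: Iterable[GeneModel]):
        self._tss: dict[str, list[tuple[int, str, str]]] = {}
        self._exons: dict[str, list[tuple[int, int]]] = {}
        self._spans: dict[str, list[tuple[int, int]]] = {}
        for gm in gene_models:
            self._tss.setdefault(gm.chrom, []).append((gm.tss, gm.strand, gm.gene_id))
            self._exons.setdefault(gm.chrom, []).extend(gm.exons)
            self._spans.setdefault(gm.chrom, []).append(gm.span)
        for d in (self._tss, self._exons, self._spans):
            for chrom in d:
                d[chrom].sort()

    @property
    def chroms(self) -> list[str]:
        return sorted(self._tss)

    def tss_list(self, chrom: str) -> list[tuple[int, str, str]]:
        return self._tss.get(chrom, [])

    def in_any(self, table: dict, chrom: str, pos: int) -> bool:
        for s, e in table.get(chrom, []):
            if s <= pos < e:
                return True
            if s > pos:
                break
        return False

    def in_exon(self, chrom: str, pos: int) -> bool:
        return self.in_any(self._exons, chrom, pos)

    def in_gene(self, chrom: str, pos: int) -> bool:
        return self.in_any(self._spans, chrom, pos)


def nearest_tss(
    midpoint: int, tss_list: Sequence[tuple[int, str, str]]
) -> tuple[int, str]:
    """Signed distance to the closest TSS, plus its gene id.

    Sign is relative to gene strand: positive downstream of the TSS (into
    the gene body on '+', toward lower coordinates being downstream on '−'),
    negative upstream. Ties on |distance| go to the lexicographically
    smaller gene_id.
    """
    if not tss_list:
        raise ValueError("no TSS on chromosome")
    best = min(
        tss_list, key=lambda t: (abs(midpoint - t[0]), t[2])
    )
    pos, strand, gene_id = best
    dist = midpoint - pos if strand == "+" else pos - midpoint
    return dist, gene_id


def classify_midpoint(
    midpoint: int,
    chrom: str,
    index: GeneIndex,
    promoter_halfwidth: int = 1000,
    unknown_chrom: str = "warn",
) -> str:
    """Assign one of promoter/exonic/intronic/intergenic to a midpoint."""
    tss = index.tss_list(chrom)
    if not tss and chrom not in index.chroms:
        if unknown_chrom == "error":
            raise ValueError(f"chromosome {chrom!r} has no gene models")
        warnings.warn(f"chromosome {chrom!r} has no gene models; calling intergenic")
        return "intergenic"
    if any(abs(midpoint - pos) <= promoter_halfwidth for pos, _, _ in tss):
        return "promoter"
    if index.in_exon(chrom, midpoint):
        return "exonic"
    if index.in_gene(chrom, midpoint):
        return "intronic"
    return "intergenic"


def annotate_peaks(
    peaks: Sequence[ConsensusPeak],
    gene_models: Sequence[GeneModel],
    promoter_halfwidth: int = 1000,
    unknown_chrom: str = "warn",
) -> list[PeakAnnotation]:
    index = GeneIndex(gene_models)
    out = []
    for pk in peaks:
        iv = pk.interval
        cat = classify_midpoint(pk.midpoint, iv.chrom, index, promoter_halfwidth, unknown_chrom)
        tss = index.tss_list(iv.chrom)
        if tss:
            dist, gene_id = nearest_tss(pk.midpoint, tss)
        else:
            dist, gene_id = None, None
        out.append(
            PeakAnnotation(iv.chrom, iv.start, iv.end, pk.midpoint, cat, gene_id, dist)
        )
    return out


def category_summary(annotations: Sequence[PeakAnnotation]) -> pd.DataFrame:
    """Counts and percentages per category; percentages sum to 100."""
    counts = {c: 0 for c in CATEGORIES}
    for a in annotations:
        counts[a.category] += 1
    total = sum(counts.values())
    rows = []
    for c in CATEGORIES:
        pct = 100.0 * counts[c] / total if total else float("nan")
        rows.append({"category": c, "count": counts[c], "percent": pct})
    df = pd.DataFrame(rows)
    return df[df["count"] > 0].reset_index(drop=True) if total == 0 else df


def summarize_counts(counts: dict[str, int]) -> pd.DataFrame:
    """Percentage table from raw per-class counts (for externally tallied data)."""
    total = sum(counts.values())
    if total == 0:
        return pd.DataFrame(columns=["category", "count", "percent"])
    return pd.DataFrame(
        [{"category": k, "count": v, "percent": 100.0 * v / total} for k, v in counts.items()]
    )


def tss_distance_histogram(
    annotations: Sequence[PeakAnnotation], binwidth: int = 500
) -> pd.DataFrame:
    """Histogram of signed midpoint-to-nearest-TSS distances.

    Bins are [k·binwidth, (k+1)·binwidth); peaks with undefined distance
    (no TSS on their chromosome) are excluded.
    """
    dists = np.array([a.tss_distance for a in annotations if a.tss_distance is not None])
    if dists.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    lo = int(np.floor(dists.min() / binwidth) * binwidth)
    hi = int(np.ceil((dists.max() + 1) / binwidth) * binwidth)
    edges = np.arange(lo, hi + binwidth, binwidth)
    counts, _ = np.histogram(dists, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def annotations_to_frame(annotations: Sequence[PeakAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": a.chrom, "start": a.start, "end": a.end,
                "midpoint": a.midpoint, "category": a.category,
                "nearest_gene": a.nearest_gene_id if a.nearest_gene_id else ".",
                "tss_distance": a.tss_distance if a.tss_distance is not None else "NA",
            }
            for a in annotations
        ]
    )
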