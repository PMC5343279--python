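"""Replicate consensus: high-confidence peaks present in every replicate.

A consensus peak is a maximal genomic run of bases covered by at least one
peak in *every* replicate set — the base-wise boolean AND of the replicate
coverages. The consensus interval is that intersection (the most
conservative choice: the region every antibody supports); its score is the
minimum of the per-replicate scores, where each replicate contributes the
maximum score among its peaks overlapping the consensus region.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval, merge_intervals


@dataclass(frozen=True)
class ConsensusPeak:
    interval: GenomicInterval
    replicate_scores: tuple[float, ...]
    min_score: float
    midpoint: int


def _intersect_two(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intersection of two sorted, merged interval lists (two-pointer sweep)."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_replicates(
    peak_sets: Sequence[Sequence[GenomicInterval]],
    min_overlap: int = 1,
) -> list[ConsensusPeak]:
    """Intersect >= 2 replicate peak sets into consensus peaks.

    Each input set is merged first (overlapping or book-ended peaks from one
    replicate count as a single covered region), so a consensus region is
    never split by a within-replicate peak boundary. Runs shorter than
    ``min_overlap`` bp are discarded. The result is ordered by
    (chrom, start) and invariant under permutation of the input sets.
    """
    if len(peak_sets) < 2:
        raise ValueError(f"need >= 2 replicate sets, got {len(peak_sets)}")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    chroms = sorted({p.chrom for peaks in peak_sets for p in peaks})
    out: list[ConsensusPeak] = []
    for chrom in chroms:
        per_set = [
            merge_intervals((p.start, p.end) for p in peaks if p.chrom == chrom)
            for peaks in peak_sets
        ]
        if any(not segs for segs in per_set):
            continue
        runs = reduce(_intersect_two, per_set)
        for s, e in runs:
            if e - s < min_overlap:
                continue
            scores = tuple(
                max(
                    (p.score if p.score is not None else 0.0)
                    for p in peaks
                    if p.chrom == chrom and p.start < e and s < p.end
                )
                for peaks in peak_sets
            )
            iv = GenomicInterval(chrom, s, e, score=min(scores))
            out.append(ConsensusPeak(iv, scores, min(scores), iv.midpoint))
    return out


def score_to_pvalue(score: float) -> float:
    """Invert the MACS convention score = −10·log10(p)."""
    if score < 0:
        raise ValueError(f"score must be >= 0, got {score}")
    return float(10.0 ** (-score / 10.0))


def pvalue_to_score(p: float) -> float:
    """MACS convention: score = −10·log10(p), for p in (0, 1]."""
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return float(-10.0 * np.log10(p))
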