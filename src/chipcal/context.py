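"""Chromatin-context scoring: mark signal over peaks, per-category means,
and a genome-wide baseline.

Each peak gets one score per mark track: by default the maximum value among
track segments overlapping the peak by >= 1 bp (the score of the strongest
called mark peak it touches), 0 when none overlap. Per-category means over
the peak annotation produce the heat-map matrix; the baseline row is the
expected score of a uniformly random genomic base.
"""

from __future__ import annotations

from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import CATEGORIES, PeakAnnotation
from .intervals import SignalTrack

BASELINE_ROW = "genome baseline"


def peak_mark_score(
    chrom: str,
    start: int,
    end: int,
    track: SignalTrack,
    agg: Literal["max", "coverage_mean"] = "max",
) -> float:
    """Score of one mark over one peak.

    ``max``: maximum overlapping segment value (0 if none overlap).
    ``coverage_mean``: mean per-bp value over the peak, uncovered bases = 0.
    """
    segs = track.overlapping(chrom, start, end)
    if agg == "max":
        return max((v for _, _, v in segs), default=0.0)
    if agg == "coverage_mean":
        total = sum((min(e, end) - max(s, start)) * v for s, e, v in segs)
        return total / (end - start)
    raise ValueError(f"unknown agg {agg!r}")


def genome_baseline(
    track: SignalTrack,
    genome_size: int,
    mode: Literal["random_base", "segment_mean"] = "random_base",
) -> float:
    """Genome-wide average mark score.

    ``random_base`` (default): Σ(value × length) / genome_size — the
    expected score of a uniformly random base, counting uncovered bases
    as 0. ``segment_mean``: length-weighted mean over covered bases only.
    """
    covered = track.covered_length()
    if covered > genome_size:
        raise ValueError(
            f"track covers {covered} bp but genome_size is {genome_size}"
        )
    if mode == "random_base":
        return track.weighted_sum() / genome_size
    if mode == "segment_mean":
        return track.weighted_sum() / covered if covered else 0.0
    raise ValueError(f"unknown mode {mode!r}")


def category_means(
    annotations: Sequence[PeakAnnotation],
    tracks: Mapping[str, SignalTrack],
    genome_size: int | None = None,
    agg: Literal["max", "coverage_mean"] = "max",
) -> pd.DataFrame:
    """The context matrix: rows = categories (+ baseline), columns = marks.

    Cells are mean per-peak scores; a category with no peaks yields NaN
    (flagged empty, not 0). With ``genome_size`` a baseline row holding
    :func:`genome_baseline` per mark is appended.
    """
    names = list(tracks)
    if len(set(names)) != len(names):
        raise ValueError("mark name collision")
    by_cat: dict[str, list[PeakAnnotation]] = {c: [] for c in CATEGORIES}
    for a in annotations:
        by_cat[a.category].append(a)
    rows = {}
    for cat in CATEGORIES:
        anns = by_cat[cat]
        row = {}
        for name, track in tracks.items():
            if not anns:
                row[name] = np.nan
            else:
                row[name] = float(
                    np.mean([peak_mark_score(a.chrom, a.start, a.end, track, agg) for a in anns])
                )
        rows[cat] = row
    if genome_size is not None:
        rows[BASELINE_ROW] = {
            name: genome_baseline(track, genome_size) for name, track in tracks.items()
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "category"
    df["n"] = [len(by_cat.get(cat, [])) if cat in by_cat else 0 for cat in df.index]
    return df
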