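"""Core genomic domain types.

All coordinates are 0-based half-open (BED convention). Conversion to the
1-based closed coordinates seen in genome browsers happens only at display
time (:func:`GenomicInterval.browser_str`).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional strand and score.

    For ChIP-seq peaks the score is the MACS convention −10·log10(p-value).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")
        if self.score is not None:
            if not np.isfinite(self.score):
                raise ValueError("score must be finite")
            if self.score < 0:
                raise ValueError(f"score must be >= 0, got {self.score}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """floor((start + end) / 2)."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)

    def browser_str(self) -> str:
        """1-based closed coordinates, as printed in genome browsers."""
        return f"{self.chrom}: {self.start + 1}-{self.end}"


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: strand, exons, and a strand-aware TSS.

    Exons are half-open intervals sorted by start; introns are the gaps
    between consecutive exons. The TSS is the 5' end of the transcript:
    span start on '+', span end − 1 on '−'.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        prev_end = -1
        for s, e in self.exons:
            if s < 0 or e <= s:
                raise ValueError(f"gene {self.gene_id}: invalid exon [{s}, {e})")
            if s < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons out of order or overlapping"
                )
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def tss(self) -> int:
        s, e = self.span
        return s if self.strand == "+" else e - 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return tuple(out)


class SignalTrack:
    """Per-chromosome sorted, non-overlapping scored segments.

    Backs histone-mark, CTCF, conservation (PhyloP-like) and binding-score
    tracks. Segments are (start, end, value) with half-open coordinates.
    """

    def __init__(self, segments: Mapping[str, Sequence[tuple[int, int, float]]] | None = None):
        self._segs: dict[str, list[tuple[int, int, float]]] = {}
        if segments:
            for chrom, segs in segments.items():
                for s, e, v in segs:
                    self.add(chrom, s, e, v, _validate=False)
        self._sort_and_validate()

    def add(self, chrom: str, start: int, end: int, value: float, _validate: bool = True) -> None:
        if start < 0 or end <= start:
            raise ValueError(f"invalid segment [{start}, {end})")
        if not np.isfinite(value):
            raise ValueError("segment value must be finite")
        self._segs.setdefault(chrom, []).append((int(start), int(end), float(value)))
        if _validate:
            self._sort_and_validate()

    def _sort_and_validate(self) -> None:
        for chrom, segs in self._segs.items():
            segs.sort()
            for (s0, e0, _), (s1, _, _) in zip(segs, segs[1:]):
                if s1 < e0:
                    raise ValueError(
                        f"overlapping segments on {chrom}: "
                        f"[{s0}, {e0}) and starting at {s1}"
                    )

    @property
    def chroms(self) -> list[str]:
        return sorted(self._segs)

    def segments(self, chrom: str) -> list[tuple[int, int, float]]:
        return list(self._segs.get(chrom, []))

    def iter_segments(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            for s, e, v in self._segs[chrom]:
                yield chrom, s, e, v

    def __len__(self) -> int:
        return sum(len(v) for v in self._segs.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        return self._segs == other._segs

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int, float]]:
        """Segments overlapping [start, end) by >= 1 bp."""
        segs = self._segs.get(chrom, [])
        if not segs:
            return []
        starts = [s for s, _, _ in segs]
        i = bisect.bisect_right(starts, start)
        # segment i-1 may extend past `start`
        if i > 0 and segs[i - 1][1] > start:
            i -= 1
        out = []
        while i < len(segs) and segs[i][0] < end:
            if segs[i][1] > start:
                out.append(segs[i])
            i += 1
        return out

    def per_bp(self, chrom: str, start: int, end: int, fill: float = 0.0) -> np.ndarray:
        """Expand the track to one value per base over [start, end).

        Positions not covered by any segment take ``fill`` (default 0).
        """
        out = np.full(end - start, fill, dtype=float)
        for s, e, v in self.overlapping(chrom, start, end):
            out[max(s, start) - start : min(e, end) - start] = v
        return out

    def weighted_sum(self) -> float:
        """Sum over segments of value × length."""
        return float(sum((e - s) * v for _, s, e, v in self.iter_segments()))

    def covered_length(self) -> int:
        return sum(e - s for _, s, e, _ in self.iter_segments())


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching half-open intervals into maximal runs."""
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]
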