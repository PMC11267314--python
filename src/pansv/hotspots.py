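"""Sliding-window SV density scan and hotspot calling.

An SV is assigned to every window containing its POS (spans are ignored, so
large deletions are not double counted ambiguously). Windows tile
``[1, chrom_len]``; the final window may be truncated and is flagged.
Hotspots are windows whose count strictly exceeds ``min_count``;
overlapping or adjacent qualifying windows on one chromosome are merged
into maximal spans.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import ValidationError


@dataclass(frozen=True)
class Hotspot:
    chrom: str
    start: int
    end: int
    n_windows: int
    n_svs: int


def _positions_by_chrom(catalog) -> dict[str, np.ndarray]:
    pos: dict[str, list[int]] = {}
    for sv in catalog:
        pos.setdefault(sv.chrom, []).append(sv.pos)
    return {c: np.sort(np.asarray(p, dtype=int)) for c, p in pos.items()}


def windowed_counts(
    catalog: Sequence,
    chrom_lengths: Mapping[str, int],
    window: int = 400_000,
    step: int = 200_000,
) -> pd.DataFrame:
    """Per-window SV counts; columns chrom/start/end/count/truncated."""
    if not (1 <= step <= window):
        raise ValidationError("need window >= step >= 1")
    positions = _positions_by_chrom(catalog)
    unknown = set(positions) - set(chrom_lengths)
    if unknown:
        raise ValidationError(f"SVs on chromosomes without lengths: {sorted(unknown)}")
    rows = []
    for chrom, length in chrom_lengths.items():
        pos = positions.get(chrom, np.empty(0, dtype=int))
        start = 1
        while start <= length:
            end = min(start + window - 1, length)
            count = int(
                np.searchsorted(pos, end, side="right")
                - np.searchsorted(pos, start, side="left")
            )
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "count": count,
                    "truncated": end - start + 1 < window,
                }
            )
            if end == length:
                break
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count", "truncated"])


def call_hotspots(
    counts: pd.DataFrame,
    min_count: int = 80,
    merge_contiguous: bool = True,
    catalog: Sequence | None = None,
) -> list[Hotspot]:
    """Merge qualifying windows (count strictly greater than ``min_count``)
    into maximal disjoint spans per chromosome.

    When ``catalog`` is given, ``n_svs`` counts the distinct catalog entries
    whose POS falls in each span; otherwise it is the sum of window counts
    (which double-counts under overlapping windows).
    """
    positions = _positions_by_chrom(catalog) if catalog is not None else None
    selected = counts[counts["count"] > min_count]
    out: list[Hotspot] = []
    for chrom, sub in selected.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        spans: list[list] = []  # [start, end, n_windows, sum_counts]
        for row in sub.itertuples():
            if merge_contiguous and spans and row.start <= spans[-1][1] + 1:
                spans[-1][1] = max(spans[-1][1], row.end)
                spans[-1][2] += 1
                spans[-1][3] += row.count
            else:
                spans.append([row.start, row.end, 1, row.count])
        for start, end, n_windows, total in spans:
            if positions is not None:
                pos = positions.get(chrom, np.empty(0, dtype=int))
                n_svs = int(
                    np.searchsorted(pos, end, side="right")
                    - np.searchsorted(pos, start, side="left")
                )
            else:
                n_svs = int(total)
            out.append(Hotspot(str(chrom), int(start), int(end), n_windows, n_svs))
    return out


def hotspots_to_frame(hotspots: Sequence[Hotspot]) -> pd.DataFrame:
    return pd.DataFrame(
        [h.__dict__ for h in hotspots],
        columns=["chrom", "start", "end", "n_windows", "n_svs"],
    )
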