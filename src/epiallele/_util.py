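"""Small shared helpers: interval unions, membership tests, context masks."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: contexts accepted by level/gain operations; CWA and CHH_nonCWA are
#: subdivisions of CHH by trinucleotide, ``None`` pools all contexts.
CONTEXTS = ("CG", "CHG", "CHH", "CWA", "CHH_nonCWA")

_CWA_TRIS = ("CAA", "CTA")


def context_mask(sites: pd.DataFrame, context: str | None) -> np.ndarray:
    """Boolean mask of sites in ``context`` (None = all contexts pooled)."""
    if context is None:
        return np.ones(len(sites), dtype=bool)
    if context in ("CG", "CHG", "CHH"):
        return (sites["context"] == context).to_numpy()
    if context == "CWA":
        return sites["tri_context"].isin(_CWA_TRIS).to_numpy()
    if context == "CHH_nonCWA":
        return (
            (sites["context"] == "CHH") & ~sites["tri_context"].isin(_CWA_TRIS)
        ).to_numpy()
    raise ValueError(f"unknown context {context!r}")


def union_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping half-open intervals into a sorted union."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def positions_in_intervals(pos: np.ndarray, union: Sequence[tuple[int, int]]) -> np.ndarray:
    """Membership of positions in a sorted non-overlapping interval union."""
    if not len(union):
        return np.zeros(len(pos), dtype=bool)
    edges = np.fromiter((x for iv in union for x in iv), dtype=np.int64, count=2 * len(union))
    idx = np.searchsorted(edges, pos, side="right")
    return idx % 2 == 1
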