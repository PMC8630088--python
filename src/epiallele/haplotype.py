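"""epiRIL haplotype reconstruction from DMR markers.

Each line of an epigenetic recombinant inbred population inherits a mosaic
of chromosome segments from a methylated wild-type parent and a globally
hypomethylated (ddm1-like) parent.  Stably inherited differentially
methylated regions act as physical markers: a marker is called U
(ddm1-derived, unmethylated) when its pooled methylation level is below
0.5, else M (wild-type).  The hypomethylation index h is the mean marker
value (M=0, U=1) and proxies the ddm1-derived genome fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import positions_in_intervals, union_intervals
from .io import GeneModel, GenomicInterval
from .methylome import weighted_level

__all__ = [
    "DMRMarker",
    "EpiRILHaplotype",
    "call_marker_state",
    "call_marker_states",
    "reconstruct_haplotype",
    "hypomethylation_index",
    "haplotype_segments",
    "assign_gene_parent",
    "find_met1_derived_regions",
]

_STATE_VALUE = {"M": 0.0, "U": 1.0}


@dataclass
class DMRMarker:
    """A differentially methylated region used as a physical marker."""

    id: str
    interval: GenomicInterval
    genetic_pos_cM: Optional[float] = None


@dataclass
class EpiRILHaplotype:
    """One line's marker states, hypomethylation index and parent segments."""

    line_id: str
    states: pd.Series  # marker id -> {M, U, NA}
    h: float
    segments: list[tuple[GenomicInterval, str]]  # parent in {WT, ddm1, unknown}


def call_marker_state(
    sites: pd.DataFrame, marker: DMRMarker, context: str | None = None
) -> str:
    """U if the marker's weighted level < 0.5, M if >= 0.5, NA if uncovered.

    All contexts are pooled by default (the markers are region-level
    methylated-vs-unmethylated differences); pass ``context="CG"`` to
    restrict.
    """
    level = weighted_level(sites, marker.interval, context=context)
    if np.isnan(level):
        return "NA"
    return "U" if level < 0.5 else "M"


def call_marker_states(
    sites: pd.DataFrame, markers: Sequence[DMRMarker], context: str | None = None
) -> pd.Series:
    """Vectorised :func:`call_marker_state` over a marker panel."""
    from ._util import context_mask

    covered = sites.loc[context_mask(sites, context) & (sites["total"] >= 1).to_numpy()]
    by_chrom = {}
    for chrom, sub in covered.groupby("chrom"):
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        mc = sub["mc"].to_numpy()[order].astype(float)
        tot = sub["total"].to_numpy()[order].astype(float)
        by_chrom[chrom] = (
            pos[order],
            np.concatenate([[0.0], np.cumsum(mc)]),
            np.concatenate([[0.0], np.cumsum(tot)]),
        )
    out = {}
    for m in markers:
        entry = by_chrom.get(m.interval.chrom)
        if entry is None:
            out[m.id] = "NA"
            continue
        pos, mc_cum, tot_cum = entry
        a = np.searchsorted(pos, m.interval.start, side="left")
        b = np.searchsorted(pos, m.interval.end, side="left")
        tot = tot_cum[b] - tot_cum[a]
        if tot == 0:
            out[m.id] = "NA"
        else:
            out[m.id] = "U" if (mc_cum[b] - mc_cum[a]) / tot < 0.5 else "M"
    return pd.Series(out, name="state")


def hypomethylation_index(states: pd.Series | Sequence[str]) -> float:
    """Mean marker value over non-NA markers (M=0, U=1)."""
    vals = [_STATE_VALUE[s] for s in states if s in _STATE_VALUE]
    if not vals:
        raise ValueError("all marker states are NA")
    return float(np.mean(vals))


def reconstruct_haplotype(
    line_id: str,
    sites: pd.DataFrame,
    markers: Sequence[DMRMarker],
    chrom_lengths: Mapping[str, int],
    context: str | None = None,
) -> EpiRILHaplotype:
    """Marker states, hypomethylation index and parent segments for one line."""
    states = call_marker_states(sites, markers, context=context)
    return EpiRILHaplotype(
        line_id=line_id,
        states=states,
        h=hypomethylation_index(states),
        segments=haplotype_segments(markers, states, chrom_lengths),
    )


def haplotype_segments(
    markers: Sequence[DMRMarker],
    states: pd.Series | Mapping[str, str],
    chrom_lengths: Mapping[str, int],
) -> list[tuple[GenomicInterval, str]]:
    """Tile each chromosome with WT / ddm1 / unknown parent segments.

    A marker's own interval carries its parent (M -> WT, U -> ddm1).  The
    span between concordant informative markers inherits that parent;
    between discordant markers the breakpoint is the midpoint of the gap;
    spans flanking NA markers, and the regions beyond the terminal markers,
    are unknown.
    """
    parent_of = {"M": "WT", "U": "ddm1", "NA": "unknown"}
    segments: list[tuple[GenomicInterval, str]] = []
    by_chrom: dict[str, list[DMRMarker]] = {}
    for m in markers:
        by_chrom.setdefault(m.interval.chrom, []).append(m)

    for chrom, length in chrom_lengths.items():
        ms = sorted(by_chrom.get(chrom, []), key=lambda m: m.interval.start)
        if not ms:
            segments.append((GenomicInterval(chrom, 0, length), "unknown"))
            continue
        raw: list[tuple[int, int, str]] = []
        first = ms[0]
        if first.interval.start > 0:
            raw.append((0, first.interval.start, "unknown"))
        for i, m in enumerate(ms):
            p = parent_of[states[m.id]]
            raw.append((m.interval.start, m.interval.end, p))
            if i + 1 < len(ms):
                nxt = ms[i + 1]
                gap = (m.interval.end, nxt.interval.start)
                p_next = parent_of[states[nxt.id]]
                if gap[0] >= gap[1]:
                    continue
                if p == p_next and p != "unknown":
                    raw.append((gap[0], gap[1], p))
                elif p == "unknown" or p_next == "unknown":
                    raw.append((gap[0], gap[1], "unknown"))
                else:
                    mid = (gap[0] + gap[1]) // 2
                    if mid > gap[0]:
                        raw.append((gap[0], mid, p))
                    if gap[1] > mid:
                        raw.append((mid, gap[1], p_next))
        last = ms[-1]
        if last.interval.end < length:
            raw.append((last.interval.end, length, "unknown"))
        # merge adjacent same-parent pieces
        merged: list[list] = []
        for s, e, p in raw:
            if merged and merged[-1][2] == p and merged[-1][1] == s:
                merged[-1][1] = e
            else:
                merged.append([s, e, p])
        segments.extend((GenomicInterval(chrom, s, e), p) for s, e, p in merged)
    return segments


def assign_gene_parent(
    gene: GeneModel, segments: Sequence[tuple[GenomicInterval, str]]
) -> str:
    """Parent of origin of the segment containing the gene midpoint."""
    mid = gene.midpoint
    for iv, parent in segments:
        if iv.chrom == gene.chrom and iv.start <= mid < iv.end:
            return parent
    return "unknown"


def find_met1_derived_regions(
    sample_sites: pd.DataFrame,
    control_sites: pd.DataFrame,
    gbm_genes: Sequence[GeneModel],
    min_exons: int = 10,
    reduction: float = 0.25,
) -> list[GenomicInterval]:
    """Chromosome segments whose gbM-exon mCG dropped by > ``reduction``.

    Exons of gbM genes (defined on the control, wild-type-like sample) are
    accumulated left-to-right into bins of ``min_exons`` exons (a short last
    bin merges into its predecessor).  A bin is flagged when its pooled
    exonic CG level in the sample is below ``(1 - reduction)`` times the
    control level; adjacent flagged bins merge into maximal intervals.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in gbm_genes:
        by_chrom.setdefault(g.chrom, []).extend(g.cds_intervals)

    out: list[GenomicInterval] = []
    for chrom, exons in by_chrom.items():
        exons = sorted(exons)
        bins: list[list[tuple[int, int]]] = [
            exons[i : i + min_exons] for i in range(0, len(exons), min_exons)
        ]
        if len(bins) > 1 and len(bins[-1]) < min_exons:
            bins[-2].extend(bins.pop())

        flags: list[tuple[int, int, bool]] = []
        for b in bins:
            union = union_intervals(b)
            span = (b[0][0], max(e for _, e in b))
            lv_s = _exonic_cg_level(sample_sites, chrom, union)
            lv_c = _exonic_cg_level(control_sites, chrom, union)
            if not np.isfinite(lv_c) or lv_c == 0:
                warnings.warn(f"{chrom}:{span[0]}-{span[1]}: control mCG level is 0; bin skipped")
                flags.append((span[0], span[1], False))
                continue
            flagged = np.isfinite(lv_s) and lv_s < (1.0 - reduction) * lv_c
            flags.append((span[0], span[1], bool(flagged)))

        cur: Optional[list[int]] = None
        for s, e, f in flags:
            if f:
                if cur is None:
                    cur = [s, e]
                else:
                    cur[1] = e
            elif cur is not None:
                out.append(GenomicInterval(chrom, cur[0], cur[1]))
                cur = None
        if cur is not None:
            out.append(GenomicInterval(chrom, cur[0], cur[1]))
    return out


def _exonic_cg_level(sites: pd.DataFrame, chrom: str, union) -> float:
    sub = sites[(sites["chrom"] == chrom) & (sites["context"] == "CG") & (sites["total"] >= 1)]
    if sub.empty:
        return float("nan")
    sel = sub.loc[positions_in_intervals(sub["pos"].to_numpy(), union)]
    if sel.empty:
        return float("nan")
    return float(sel["mc"].sum()) / float(sel["total"].sum())
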