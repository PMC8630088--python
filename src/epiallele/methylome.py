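"""Per-site methylation calling and windowed methylation levels.

Read counts from whole-genome bisulfite sequencing contain a background of
apparently-methylated reads caused by incomplete bisulfite conversion.  The
non-conversion rate is estimated from an unmethylated control contig
(chloroplast DNA in plants) and used as the null success probability of a
one-sided binomial test per cytosine; q-values control the FDR over all
tested sites.  Region-level summaries use the weighted methylation level:
total methylated reads over total reads across a region's cytosines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import context_mask
from .io import GeneModel, GenomicInterval

__all__ = [
    "NonConversionRate",
    "MethylationProfile",
    "estimate_nonconversion",
    "call_site_methylation",
    "weighted_level",
    "gene_window_profile",
    "aggregate_profiles",
]


@dataclass
class NonConversionRate:
    """Fraction of unmethylated cytosines escaping bisulfite conversion."""

    rate: float
    control_contig: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError(f"rate outside [0, 1]: {self.rate}")


@dataclass
class MethylationProfile:
    """60-window methylation profile: 20 upstream, 20 body, 20 downstream.

    Index 0 is always the 5'-most upstream window regardless of gene strand;
    undefined windows are NaN.
    """

    id: str
    context: str | None
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.shape != (60,):
            raise ValueError("profile must have exactly 60 windows")
        defined = self.levels[~np.isnan(self.levels)]
        if len(defined) and ((defined < 0).any() or (defined > 1).any()):
            raise ValueError("levels outside [0, 1]")


def estimate_nonconversion(sites: pd.DataFrame, control_contig: str) -> NonConversionRate:
    """Pooled mc/total over all covered sites of the unmethylated control contig."""
    sub = sites[(sites["chrom"] == control_contig) & (sites["total"] > 0)]
    if sub.empty:
        raise ValueError(f"no covered sites on control contig {control_contig!r}")
    rate = float(sub["mc"].sum()) / float(sub["total"].sum())
    return NonConversionRate(rate=rate, control_contig=control_contig)


def call_site_methylation(
    sites: pd.DataFrame,
    rate: NonConversionRate | float,
    min_cov: int = 3,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Binomial methylation calls per cytosine, BH-corrected across the sample.

    Sites with fewer than ``min_cov`` reads stay ``uncalled``.  For the rest
    the one-sided p-value P(X >= mc | n=total, p=rate) is BH-adjusted over
    all tested sites; a site is ``methylated`` iff q < ``fdr``.
    """
    nc = rate.rate if isinstance(rate, NonConversionRate) else float(rate)
    if not (0.0 <= nc < 1.0):
        raise ValueError(f"non-conversion rate outside [0, 1): {nc}")
    out = sites.copy()
    tested = (out["total"] >= min_cov).to_numpy()
    call = np.full(len(out), "uncalled", dtype=object)
    if tested.any():
        mc = out.loc[tested, "mc"].to_numpy()
        total = out.loc[tested, "total"].to_numpy()
        p = stats.binom.sf(mc - 1, total, nc)
        q = multipletests(p, method="fdr_bh")[1]
        call[tested] = np.where(q < fdr, "methylated", "unmethylated")
    out["call"] = call
    return out


def weighted_level(
    sites: pd.DataFrame,
    interval: GenomicInterval,
    context: str | None = None,
) -> float:
    """Weighted methylation level over an interval: sum(mc)/sum(total).

    Returns NaN (missing) when the interval holds no covered in-context
    site — distinct from a level of 0.
    """
    mask = (
        (sites["chrom"] == interval.chrom).to_numpy()
        & (sites["pos"].to_numpy() >= interval.start)
        & (sites["pos"].to_numpy() < interval.end)
        & (sites["total"].to_numpy() >= 1)
        & context_mask(sites, context)
    )
    if not mask.any():
        return float("nan")
    sub = sites.loc[mask]
    return float(sub["mc"].sum()) / float(sub["total"].sum())


def _window_levels(pos, mc, total, edges) -> np.ndarray:
    """Weighted level per window for windows given as a sorted edge array."""
    n_win = len(edges) - 1
    idx = np.searchsorted(edges, pos, side="right") - 1
    ok = (idx >= 0) & (idx < n_win) & (pos < edges[-1]) & (total >= 1)
    mc_sum = np.bincount(idx[ok], weights=mc[ok], minlength=n_win)
    tot_sum = np.bincount(idx[ok], weights=total[ok], minlength=n_win)
    with np.errstate(invalid="ignore", divide="ignore"):
        lv = mc_sum / tot_sum
    lv[tot_sum == 0] = np.nan
    return lv


def gene_window_profile(
    gene: GeneModel,
    sites: pd.DataFrame,
    context: str | None = None,
    flank_bp: int = 1000,
    body_windows: int = 20,
    flank_window_bp: int = 50,
) -> MethylationProfile:
    """Windowed methylation profile over a gene and its flanks.

    The gene span is cut into ``body_windows`` equal windows (remainder bases
    in the last window); each 1-kb flank into 20 windows of 50 bp.  For
    minus-strand genes the 60-vector is reversed so index 0 is 5' upstream.
    """
    n_flank = flank_bp // flank_window_bp
    mask = (sites["chrom"] == gene.chrom).to_numpy() & context_mask(sites, context)
    sub = sites.loc[mask]
    pos = sub["pos"].to_numpy()
    mc = sub["mc"].to_numpy().astype(float)
    total = sub["total"].to_numpy().astype(float)

    left_edges = gene.start - flank_bp + flank_window_bp * np.arange(n_flank + 1)
    left = _window_levels(pos, mc, total, left_edges)

    glen = len(gene)
    if glen < body_windows:
        warnings.warn(f"gene {gene.id} shorter than {body_windows} bp; body windows missing")
        body = np.full(body_windows, np.nan)
    else:
        w = glen // body_windows
        body_edges = gene.start + w * np.arange(body_windows + 1)
        body_edges[-1] = gene.end  # remainder bases to the last window
        body = _window_levels(pos, mc, total, body_edges)

    right_edges = gene.end + flank_window_bp * np.arange(n_flank + 1)
    right = _window_levels(pos, mc, total, right_edges)

    levels = np.concatenate([left, body, right])
    if gene.strand == "-":
        levels = levels[::-1]
    return MethylationProfile(id=gene.id, context=context, levels=levels)


def aggregate_profiles(profiles: list[MethylationProfile]) -> MethylationProfile:
    """Per-window mean over a group of profiles, ignoring missing windows."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    contexts = {p.context for p in profiles}
    if len(contexts) > 1:
        raise ValueError(f"mixed contexts in aggregation: {sorted(map(str, contexts))}")
    mat = np.vstack([p.levels for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows stay NaN
        mean = np.nanmean(mat, axis=0)
    return MethylationProfile(id=f"mean_of_{len(profiles)}", context=profiles[0].context,
                              levels=mean)
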