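"""Ectopic non-CG methylation gain calling and association screens.

A gene gains ectopic methylation in a line when, over cytosines covered in
both the line and the wild-type parent, the mean per-site methylation
level is at least 10 percentage points higher, with a floor of three such
sites.  Gains are screened for enrichment by gene class (one-sided Fisher)
and, per gene, for correlation of the methylation change with the line's
hypomethylation index (|r| > 0.35 flags a responsive gene).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import context_mask
from .io import GeneModel

__all__ = [
    "GainCall",
    "GeneIndexAssociation",
    "call_gene_gain",
    "gain_table",
    "gain_matrix",
    "fisher_enrichment_one_sided",
    "class_enrichment",
    "delta_index_correlation",
]

GAIN_CONTEXTS = ("CHG", "CWA", "CHH_nonCWA")


@dataclass
class GainCall:
    """One gene x line ectopic gain decision."""

    gene_id: str
    line_id: str
    context: str
    n_sites: int
    delta: float  # mean per-site level difference, sample - control
    is_gain: bool


@dataclass
class GeneIndexAssociation:
    """Pearson screen of per-line methylation change vs hypomethylation index."""

    gene_id: str
    stratum: str  # parent-of-origin stratum, WT or ddm1
    r: float
    n_lines: int
    flagged: bool


def _merge_covered(
    sample: pd.DataFrame,
    control: pd.DataFrame,
    context: str,
    min_cov: int,
) -> pd.DataFrame:
    """Inner-join in-context sites covered >= min_cov in both samples."""
    s = sample.loc[context_mask(sample, context) & (sample["total"] >= min_cov),
                   ["chrom", "pos", "strand", "mc", "total"]]
    c = control.loc[context_mask(control, context) & (control["total"] >= min_cov),
                    ["chrom", "pos", "strand", "mc", "total"]]
    m = s.merge(c, on=["chrom", "pos", "strand"], suffixes=("_s", "_c"))
    m["delta"] = m["mc_s"] / m["total_s"] - m["mc_c"] / m["total_c"]
    return m


def call_gene_gain(
    gene: GeneModel,
    sample_sites: pd.DataFrame,
    control_sites: pd.DataFrame,
    context: str,
    min_sites: int = 3,
    min_delta: float = 0.1,
    min_cov: int = 3,
    line_id: str = "sample",
) -> GainCall:
    """Ectopic gain call for one gene: >= 3 shared sites, mean delta >= 0.1.

    The gene body is the full gene span.  ``context`` is one of CHG, CWA or
    CHH_nonCWA.
    """
    if context not in GAIN_CONTEXTS:
        raise ValueError(f"context must be one of {GAIN_CONTEXTS}, got {context!r}")
    m = _merge_covered(sample_sites, control_sites, context, min_cov)
    m = m[(m["chrom"] == gene.chrom) & (m["pos"] >= gene.start) & (m["pos"] < gene.end)]
    n = len(m)
    delta = float(m["delta"].mean()) if n else float("nan")
    is_gain = bool(n >= min_sites and np.isfinite(delta) and delta >= min_delta)
    return GainCall(gene.id, line_id, context, n, delta, is_gain)


def _gene_slices(genes: Sequence[GeneModel], chrom: np.ndarray, pos: np.ndarray):
    """Index ranges of (sorted) sites falling in each gene's span."""
    order = np.lexsort((pos, chrom))
    chrom_s, pos_s = chrom[order], pos[order]
    out = []
    for g in genes:
        lo = np.searchsorted(chrom_s, g.chrom, side="left")
        hi = np.searchsorted(chrom_s, g.chrom, side="right")
        a = lo + np.searchsorted(pos_s[lo:hi], g.start, side="left")
        b = lo + np.searchsorted(pos_s[lo:hi], g.end, side="left")
        out.append((a, b))
    return order, out


def gain_table(
    genes: Sequence[GeneModel],
    sample_sites: pd.DataFrame,
    control_sites: pd.DataFrame,
    context: str = "CHG",
    min_sites: int = 3,
    min_delta: float = 0.1,
    min_cov: int = 3,
    line_id: str = "sample",
) -> pd.DataFrame:
    """Vectorised :func:`call_gene_gain` over all genes for one line."""
    if context not in GAIN_CONTEXTS:
        raise ValueError(f"context must be one of {GAIN_CONTEXTS}, got {context!r}")
    m = _merge_covered(sample_sites, control_sites, context, min_cov)
    chrom = m["chrom"].to_numpy(dtype=object).astype(str)
    pos = m["pos"].to_numpy()
    delta_site = m["delta"].to_numpy()
    order, slices = _gene_slices(genes, chrom, pos)
    delta_sorted = delta_site[order]
    rows = []
    for g, (a, b) in zip(genes, slices):
        n = b - a
        d = float(delta_sorted[a:b].mean()) if n else float("nan")
        rows.append(
            (g.id, line_id, context, int(n), d,
             bool(n >= min_sites and np.isfinite(d) and d >= min_delta))
        )
    return pd.DataFrame(rows, columns=["gene_id", "line_id", "context", "n_sites",
                                       "delta", "is_gain"])


def gain_matrix(
    genes: Sequence[GeneModel],
    line_sites: Mapping[str, pd.DataFrame],
    control_sites: pd.DataFrame,
    context: str = "CHG",
    min_sites: int = 3,
    min_delta: float = 0.1,
    min_cov: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gain calls for every line, plus the QTL phenotype summaries.

    Returns ``(calls, summary, levels)``:

    * ``calls`` — tidy table of per-line per-gene :class:`GainCall` fields;
    * ``summary`` — per line: ``n_gain`` (count of gaining genes),
      ``mean_genic_level`` (mean in-context weighted level over gene
      bodies) and ``global_level`` (genome-wide weighted in-context level) —
      the "mCHG #" / "ave. mCHG" / "global mCHG" interval-mapping traits;
    * ``levels`` — genes x lines matrix of per-gene weighted in-context
      levels, the per-gene mapping phenotypes.
    """
    calls_parts = []
    summary_rows = []
    level_cols: dict[str, np.ndarray] = {}
    for line_id, sites in line_sites.items():
        if sites is None or len(sites) == 0:
            warnings.warn(f"line {line_id}: missing methylome; excluded")
            continue
        t = gain_table(genes, sites, control_sites, context,
                       min_sites, min_delta, min_cov, line_id=line_id)
        calls_parts.append(t)
        lv = _genic_levels(genes, sites, context)
        level_cols[line_id] = lv
        cm = context_mask(sites, context) & (sites["total"] >= 1).to_numpy()
        glob = (
            float(sites.loc[cm, "mc"].sum()) / float(sites.loc[cm, "total"].sum())
            if cm.any()
            else float("nan")
        )
        summary_rows.append(
            (line_id, int(t["is_gain"].sum()), float(np.nanmean(lv)), glob)
        )
    calls = (
        pd.concat(calls_parts, ignore_index=True)
        if calls_parts
        else pd.DataFrame(columns=["gene_id", "line_id", "context", "n_sites", "delta", "is_gain"])
    )
    summary = pd.DataFrame(
        summary_rows, columns=["line_id", "n_gain", "mean_genic_level", "global_level"]
    )
    levels = pd.DataFrame(level_cols, index=[g.id for g in genes])
    return calls, summary, levels


def _genic_levels(genes: Sequence[GeneModel], sites: pd.DataFrame, context: str) -> np.ndarray:
    sel = sites.loc[context_mask(sites, context) & (sites["total"] >= 1).to_numpy()]
    chrom = sel["chrom"].to_numpy(dtype=object).astype(str)
    pos = sel["pos"].to_numpy()
    mc = sel["mc"].to_numpy().astype(float)
    total = sel["total"].to_numpy().astype(float)
    order, slices = _gene_slices(genes, chrom, pos)
    mc_s, tot_s = mc[order], total[order]
    mc_cum = np.concatenate([[0.0], np.cumsum(mc_s)])
    tot_cum = np.concatenate([[0.0], np.cumsum(tot_s)])
    out = np.full(len(genes), np.nan)
    for i, (a, b) in enumerate(slices):
        t = tot_cum[b] - tot_cum[a]
        if t > 0:
            out[i] = (mc_cum[b] - mc_cum[a]) / t
    return out


def fisher_enrichment_one_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided Fisher exact test (alternative: odds ratio > 1).

    Returns ``(odds_ratio, p)`` where the odds ratio is the sample ad/bc
    (inf when bc = 0 and ad > 0, NaN for 0/0) and p is the hypergeometric
    upper tail over tables with first cell >= a at fixed margins.
    """
    cells = (a, b, c, d)
    if any((not float(x).is_integer()) or x < 0 for x in cells):
        raise ValueError(f"cell counts must be non-negative integers, got {cells}")
    if sum(cells) == 0:
        raise ValueError("all-zero contingency table")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = float("nan") if ad == 0 else float("inf")
    else:
        odds = ad / bc
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
    return odds, p


def class_enrichment(
    gain_flags: pd.Series, classes: pd.Series, collapse_tem: bool = False
) -> pd.DataFrame:
    """Per-class enrichment of gaining genes (one-sided Fisher).

    ``gain_flags`` and ``classes`` are gene-indexed; the universe is the
    genes present in both.  With ``collapse_tem`` the two teM subclasses
    are pooled.
    """
    common = gain_flags.index.intersection(classes.index)
    flags = gain_flags.loc[common].astype(bool)
    cls = classes.loc[common].astype(str)
    if collapse_tem:
        cls = cls.replace({"teM_mCHG": "teM", "teM_mCHH": "teM"})
    rows = []
    for label in sorted(cls.unique()):
        in_cls = cls == label
        if in_cls.all():
            warnings.warn(f"class {label} is the whole universe; skipped")
            continue
        a = int((flags & in_cls).sum())
        b = int((flags & ~in_cls).sum())
        c = int((~flags & in_cls).sum())
        d = int((~flags & ~in_cls).sum())
        odds, p = fisher_enrichment_one_sided(a, b, c, d)
        rows.append((label, int(in_cls.sum()), a / max(a + c, 1), odds, p))
    return pd.DataFrame(rows, columns=["label", "n_genes", "prop_gaining", "odds_ratio", "p"])


def delta_index_correlation(
    gene_id: str,
    deltas: pd.Series,
    h: pd.Series,
    stratum: str = "all",
    r_cutoff: float = 0.35,
    min_lines: int = 3,
) -> GeneIndexAssociation:
    """Pearson r of a gene's per-line methylation change against h.

    Flagged when |r| exceeds ``r_cutoff``; undefined (zero-variance input)
    correlations are never flagged.
    """
    common = deltas.index.intersection(h.index)
    x = deltas.loc[common].astype(float)
    y = h.loc[common].astype(float)
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    if len(x) < min_lines:
        raise ValueError(f"gene {gene_id}: fewer than {min_lines} lines with defined change")
    if np.ptp(x.to_numpy()) == 0 or np.ptp(y.to_numpy()) == 0:
        return GeneIndexAssociation(gene_id, stratum, float("nan"), len(x), False)
    r = float(stats.pearsonr(x, y)[0])
    return GeneIndexAssociation(gene_id, stratum, r, len(x), bool(abs(r) > r_cutoff))
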