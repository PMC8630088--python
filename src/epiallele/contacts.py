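"""Three-dimensional contact relationships between genes and H3K9me2 regions.

Significant Hi-C contacts (precomputed, e.g. by Fit-Hi-C) are intersected
with H3K9me2 peak intervals and gene models: a contact links a gene to the
heterochromatin mark when one anchor overlaps a peak and the other overlaps
the gene.  Downstream, gene classes are tested for enrichment of contacted
genes (one-sided Fisher) and contact-count / distance distributions are
compared between groups with two-sided rank-sum tests, unadjusted, as is
conventional for these pairwise panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .gains import fisher_enrichment_one_sided
from .io import ContactRecord, GeneModel, GenomicInterval

__all__ = [
    "GeneContactSummary",
    "summarize_gene_contacts",
    "contact_class_enrichment",
    "compare_groups",
    "rank_sum_test",
]


@dataclass
class GeneContactSummary:
    """Per-gene count of peak-linked contacts and distance to the nearest peak."""

    gene_id: str
    n_contacts: int
    min_distance_bp: Optional[float]  # NaN/None when no intra-chromosomal contacted peak
    label: Optional[str] = None
    gain_flag: Optional[bool] = None


def _trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Nearest-edge gap between two intervals on the same contig (0 if overlapping)."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def summarize_gene_contacts(
    contacts: Sequence[ContactRecord],
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    q_threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Count, per gene, the significant contacts linking it to any peak.

    A contact counts for a gene when one anchor overlaps >= 1 bp of a peak
    and the other anchor overlaps >= 1 bp of the gene; multi-peak or
    multi-overlap anchors still count once per contact per gene.  The
    distance column is the nearest-edge gap between the gene and any
    contacted peak on the same chromosome (NaN when none).
    """
    peak_trees = _trees(peaks)
    gene_ivs = [GenomicInterval(g.chrom, g.start, g.end, g.id) for g in genes]
    gene_trees = _trees(gene_ivs)

    n_contacts = np.zeros(len(genes), dtype=int)
    min_dist = np.full(len(genes), np.nan)

    for rec in contacts:
        if q_threshold is not None and rec.q_value is not None and rec.q_value > q_threshold:
            continue
        for peak_anchor, gene_anchor in ((rec.anchor_a, rec.anchor_b),
                                         (rec.anchor_b, rec.anchor_a)):
            ptree = peak_trees.get(peak_anchor.chrom)
            if ptree is None:
                continue
            peak_hits = ptree.overlap(peak_anchor.start, peak_anchor.end)
            if not peak_hits:
                continue
            gtree = gene_trees.get(gene_anchor.chrom)
            if gtree is None:
                continue
            gene_hits = {h.data for h in gtree.overlap(gene_anchor.start, gene_anchor.end)}
            for gi in gene_hits:
                n_contacts[gi] += 1
                g = genes[gi]
                for ph in peak_hits:
                    pk = peaks[ph.data]
                    if pk.chrom != g.chrom:
                        continue
                    d = _gap(g.start, g.end, pk.start, pk.end)
                    if np.isnan(min_dist[gi]) or d < min_dist[gi]:
                        min_dist[gi] = d
    return pd.DataFrame(
        {
            "gene_id": [g.id for g in genes],
            "n_contacts": n_contacts,
            "min_distance_bp": min_dist,
        }
    )


def contact_class_enrichment(summary: pd.DataFrame, class_col: str = "label") -> pd.DataFrame:
    """Per-class enrichment of contacted genes (one-sided Fisher, OR > 1)."""
    contacted = summary["n_contacts"].to_numpy() > 0
    cls = summary[class_col].astype(str).to_numpy()
    rows = []
    for label in sorted(pd.unique(cls)):
        in_cls = cls == label
        if not in_cls.any():
            continue
        a = int((contacted & in_cls).sum())
        b = int((contacted & ~in_cls).sum())
        c = int((~contacted & in_cls).sum())
        d = int((~contacted & ~in_cls).sum())
        if a + b + c + d == 0:
            continue
        odds, p = fisher_enrichment_one_sided(a, b, c, d)
        rows.append((label, int(in_cls.sum()), a / max(a + c, 1), odds, p))
    return pd.DataFrame(
        rows, columns=["label", "n_genes", "prop_contacted", "odds_ratio", "p"]
    )


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when min(n1, n2) <= 8 and there are no ties;
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group in rank-sum comparison")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method)[1])


def compare_groups(
    summary: pd.DataFrame,
    group_col: str,
    measure: str = "n_contacts",
) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests between groups, no adjustment.

    ``measure`` is ``n_contacts`` or ``min_distance_bp`` (NaN distances,
    i.e. never-contacted genes, are dropped from distance comparisons).
    """
    if measure not in ("n_contacts", "min_distance_bp"):
        raise ValueError(f"unknown measure {measure!r}")
    groups: dict[str, np.ndarray] = {}
    for label, sub in summary.groupby(group_col):
        vals = sub[measure].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals):
            groups[str(label)] = vals
    rows = []
    for g1, g2 in combinations(sorted(groups), 2):
        p = rank_sum_test(groups[g1], groups[g2])
        rows.append((g1, g2, len(groups[g1]), len(groups[g2]), p))
    return pd.DataFrame(rows, columns=["group1", "group2", "n1", "n2", "p"])
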