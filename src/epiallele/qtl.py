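"""Methylation QTL interval mapping on binary DMR-marker genotypes.

A genetic map is assembled from the marker genotype matrix of the epiRIL
population: markers showing cross-chromosome association are rejected,
adjacent-marker recombination fractions are estimated from observed
discordance with the selfed-RIL correction r = R / (2(1 - R)), and cM
positions accumulate Haldane distances d = -50 ln(1 - 2r).  Single-QTL
scans use Haley-Knott regression of the phenotype on the conditional
probability of the ddm1 allele at each grid position,
LOD = (n/2) log10(RSS0/RSS1), with genome-wide significance from
permutation of the phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomicInterval

__all__ = [
    "GeneticMap",
    "LODCurve",
    "QTLHit",
    "haldane_cM",
    "haldane_inv",
    "estimate_rf",
    "build_map",
    "genotype_probabilities",
    "hk_lod",
    "hk_scan",
    "permutation_threshold",
    "find_peaks_and_classify",
    "scan_all_genes",
]

LOD_CAP = 50.0


def haldane_cM(r: float | np.ndarray) -> float | np.ndarray:
    """Haldane map distance in cM for recombination fraction r < 0.5."""
    return -50.0 * np.log(1.0 - 2.0 * np.minimum(r, 0.4999999))


def haldane_inv(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a Haldane distance in cM."""
    return 0.5 * (1.0 - np.exp(-np.asarray(d_cM, dtype=float) / 50.0))


def _apparent_rf(r: float | np.ndarray) -> float | np.ndarray:
    """Observed discordance in a selfed RIL for meiotic fraction r: 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


def estimate_rf(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float]:
    """Observed discordance R and corrected meiotic fraction r for two markers.

    Genotypes are 0/1 with NaN for missing; r = R / (2(1 - R)), capped at
    0.5 (the inverse of the selfed-RIL map expansion R = 2r/(1+2r)).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no lines with both markers called")
    if n < 10:
        warnings.warn(f"only {n} complete line pairs for rf estimation")
    R = float((g1[ok] != g2[ok]).mean())
    if R >= 0.5:
        return R, 0.5
    return R, min(R / (2.0 * (1.0 - R)), 0.5)


@dataclass
class GeneticMap:
    """Ordered markers with physical (bp) and genetic (cM) positions."""

    markers: pd.DataFrame  # columns: marker, chrom, bp, cM
    map_function: str = "haldane"

    def __post_init__(self) -> None:
        for chrom, sub in self.markers.groupby("chrom"):
            cm = sub["cM"].to_numpy()
            if len(cm) and cm[0] != 0:
                raise ValueError(f"{chrom}: first marker must sit at 0 cM")
            if (np.diff(cm) < 0).any():
                raise ValueError(f"{chrom}: cM positions must be non-decreasing")

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))


@dataclass
class LODCurve:
    """An interval-mapping scan: grid positions, LOD values, threshold."""

    trait: str
    grid: pd.DataFrame  # columns: chrom, cM, bp
    lod: np.ndarray
    threshold: Optional[float] = None


@dataclass
class QTLHit:
    """A significant scan peak with its support interval and labels."""

    trait: str
    chrom: str
    peak_cM: float
    peak_bp: int
    lod: float
    support_cM: tuple[float, float]
    relation: Optional[str] = None  # cis / trans
    compartment: Optional[str] = None  # euchromatin / heterochromatin


def _cross_chrom_assoc_p(g1: np.ndarray, g2: np.ndarray) -> float:
    """Smaller of the two one-sided Fisher p's for association of two markers."""
    ok = ~(np.isnan(g1) | np.isnan(g2))
    a = int(((g1 == 1) & (g2 == 1))[ok].sum())
    b = int(((g1 == 1) & (g2 == 0))[ok].sum())
    c = int(((g1 == 0) & (g2 == 1))[ok].sum())
    d = int(((g1 == 0) & (g2 == 0))[ok].sum())
    p_pos = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
    p_neg = stats.fisher_exact([[b, a], [d, c]], alternative="greater")[1]
    return float(min(p_pos, p_neg))


def build_map(
    genotypes: pd.DataFrame,
    marker_positions: pd.DataFrame,
    cross_chrom_alpha: float = 1e-4,
) -> GeneticMap:
    """Assemble a genetic map from the marker genotype matrix.

    ``genotypes`` is lines x markers (0 = WT, 1 = ddm1, NaN = missing);
    ``marker_positions`` has columns ``marker``, ``chrom``, ``bp``.  Markers
    are stepped in by bp order; a candidate is rejected when it associates
    (one-sided Fisher in either direction, p < ``cross_chrom_alpha``) with
    any accepted marker on another chromosome.  cM positions accumulate
    Haldane distances between adjacent retained markers.
    """
    pos = marker_positions.sort_values(["chrom", "bp"]).reset_index(drop=True)
    accepted: list[str] = []
    accepted_chrom: dict[str, str] = {}
    for row in pos.itertuples(index=False):
        g = genotypes[row.marker].to_numpy(dtype=float)
        reject = False
        for other in accepted:
            if accepted_chrom[other] == row.chrom:
                continue
            if _cross_chrom_assoc_p(g, genotypes[other].to_numpy(dtype=float)) < cross_chrom_alpha:
                reject = True
                break
        if reject:
            warnings.warn(f"marker {row.marker} rejected: cross-chromosome association")
            continue
        accepted.append(row.marker)
        accepted_chrom[row.marker] = row.chrom

    rows = []
    for chrom, sub in pos[pos["marker"].isin(accepted)].groupby("chrom", sort=False):
        sub = sub.sort_values("bp")
        if len(sub) < 2:
            warnings.warn(f"{chrom}: fewer than 2 retained markers; excluded from scans")
            continue
        names = sub["marker"].tolist()
        cm = [0.0]
        for m1, m2 in zip(names[:-1], names[1:]):
            _, r = estimate_rf(
                genotypes[m1].to_numpy(dtype=float), genotypes[m2].to_numpy(dtype=float)
            )
            d = float(haldane_cM(r)) if r < 0.5 else float(haldane_cM(0.4999))
            cm.append(cm[-1] + d)
        for name, bp, c in zip(names, sub["bp"], cm):
            rows.append((name, chrom, int(bp), float(c)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cM"]))


def genotype_probabilities(
    marker_cM: np.ndarray,
    states: np.ndarray,
    grid_cM: np.ndarray,
) -> np.ndarray:
    """P(ddm1 allele) at grid positions for one line on one chromosome.

    Markov interpolation between the nearest informative flanking markers,
    using the apparent (selfed-RIL) recombination probability from the
    inverse Haldane map; falls back to the single informative flank at
    chromosome ends and across missing calls.
    """
    states = np.asarray(states, dtype=float)
    ok = ~np.isnan(states)
    if not ok.any():
        return np.full(len(grid_cM), 0.5)
    m_cm = np.asarray(marker_cM, dtype=float)[ok]
    m_st = states[ok]
    out = np.empty(len(grid_cM))
    idx = np.searchsorted(m_cm, grid_cM, side="right")
    for j, (g, i) in enumerate(zip(grid_cM, idx)):
        left = i - 1 if i > 0 else None
        right = i if i < len(m_cm) else None
        if left is not None and right is not None:
            rl = _apparent_rf(haldane_inv(g - m_cm[left]))
            rr = _apparent_rf(haldane_inv(m_cm[right] - g))
            tl1 = rl if m_st[left] == 0 else 1.0 - rl
            tl0 = 1.0 - tl1
            tr1 = rr if m_st[right] == 0 else 1.0 - rr
            tr0 = 1.0 - tr1
            num = tl1 * tr1
            den = num + tl0 * tr0
            out[j] = 0.5 if den == 0 else num / den
        elif left is not None:
            rl = _apparent_rf(haldane_inv(g - m_cm[left]))
            out[j] = rl if m_st[left] == 0 else 1.0 - rl
        else:
            rr = _apparent_rf(haldane_inv(m_cm[right] - g))
            out[j] = rr if m_st[right] == 0 else 1.0 - rr
    return out


def _scan_grid(gmap: GeneticMap, step_cM: float) -> pd.DataFrame:
    rows = []
    for chrom in gmap.chromosomes:
        sub = gmap.markers[gmap.markers["chrom"] == chrom]
        top = float(sub["cM"].max())
        grid = np.arange(0.0, top + step_cM / 2, step_cM)
        bp = np.interp(grid, sub["cM"], sub["bp"]).astype(np.int64)
        for c, b in zip(grid, bp):
            rows.append((chrom, float(c), int(b)))
    return pd.DataFrame(rows, columns=["chrom", "cM", "bp"])


def _prob_matrix(gmap: GeneticMap, genotypes: pd.DataFrame, grid: pd.DataFrame) -> np.ndarray:
    """Lines x grid matrix of P(ddm1) across all chromosomes."""
    n = len(genotypes)
    X = np.empty((n, len(grid)))
    for chrom in gmap.chromosomes:
        sub = gmap.markers[gmap.markers["chrom"] == chrom]
        gsel = (grid["chrom"] == chrom).to_numpy()
        if not gsel.any():
            continue
        gcm = grid.loc[gsel, "cM"].to_numpy()
        states = genotypes[sub["marker"].tolist()].to_numpy(dtype=float)
        mcm = sub["cM"].to_numpy()
        for i in range(n):
            X[i, gsel] = genotype_probabilities(mcm, states[i], gcm)
    return X


def hk_lod(prob: np.ndarray, phenotype: np.ndarray) -> float:
    """Haley-Knott LOD of a phenotype on one genotype-probability vector."""
    y = np.asarray(phenotype, dtype=float)
    x = np.asarray(prob, dtype=float)
    n = len(y)
    yc = y - y.mean()
    xc = x - x.mean()
    sxx = float(xc @ xc)
    rss0 = float(yc @ yc)
    if sxx == 0 or rss0 == 0:
        return 0.0
    beta = float(xc @ yc) / sxx
    rss1 = rss0 - beta * float(xc @ yc)
    if rss1 <= 0:
        return LOD_CAP
    return min((n / 2.0) * np.log10(rss0 / rss1), LOD_CAP)


def _lod_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """LOD of each phenotype column of Y on each grid column of X.

    Returns grid x traits; uses LOD = -(n/2) log10(1 - r^2).
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Yc) / np.outer(sx, sy)
    r = np.nan_to_num(r, nan=0.0)
    r2 = np.clip(r**2, 0.0, 1.0 - 1e-16)
    lod = -(n / 2.0) * np.log10(1.0 - r2)
    return np.minimum(lod, LOD_CAP)


def hk_scan(
    gmap: GeneticMap,
    genotypes: pd.DataFrame,
    phenotype: pd.Series | np.ndarray,
    step_cM: float = 1.0,
    trait: str = "trait",
) -> LODCurve:
    """Single-QTL Haley-Knott scan over a uniform cM grid."""
    y = np.asarray(phenotype, dtype=float)
    ok = ~np.isnan(y)
    if ok.sum() < 20:
        warnings.warn(f"{trait}: only {int(ok.sum())} lines with phenotype")
    if np.nanstd(y) == 0:
        warnings.warn(f"{trait}: constant phenotype; all-zero LOD curve")
        grid = _scan_grid(gmap, step_cM)
        return LODCurve(trait, grid, np.zeros(len(grid)))
    grid = _scan_grid(gmap, step_cM)
    X = _prob_matrix(gmap, genotypes.loc[np.asarray(ok)], grid)
    lod = _lod_matrix(X, y[ok, None])[:, 0]
    return LODCurve(trait, grid, lod)


def permutation_threshold(
    gmap: GeneticMap,
    genotypes: pd.DataFrame,
    phenotype: pd.Series | np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    step_cM: float = 1.0,
) -> float:
    """Genome-wide (1 - alpha) LOD threshold by phenotype permutation.

    Uses the conservative order-statistic quantile
    ceil((n_perm + 1)(1 - alpha)); deterministic given the seed.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; threshold will be noisy")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    ok = ~np.isnan(y)
    y = y[ok]
    grid = _scan_grid(gmap, step_cM)
    X = _prob_matrix(gmap, genotypes.loc[np.asarray(ok)], grid)
    perms = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    maxima = _lod_matrix(X, perms).max(axis=0)
    maxima.sort()
    k = max(int(np.ceil((n_perm + 1) * (1.0 - alpha))), 1)
    return float(maxima[min(k, n_perm) - 1])


def find_peaks_and_classify(
    curve: LODCurve,
    threshold: float,
    gene_locus: Optional[tuple[str, int]] = None,
    het_intervals: Optional[Sequence[GenomicInterval]] = None,
    cis_window_bp: float = 1e6,
    drop: float = 1.5,
) -> list[QTLHit]:
    """Peaks above threshold with 1.5-LOD support intervals and labels.

    Within a chromosome, two peaks are distinct only when the valley
    between them drops at least ``drop`` LOD below the lower peak.  A peak
    is cis when the scanned gene lies on the same chromosome within
    ``cis_window_bp`` of the peak, else trans; the compartment is read from
    the heterochromatin intervals.
    """
    hits: list[QTLHit] = []
    for chrom in curve.grid["chrom"].unique():
        sel = (curve.grid["chrom"] == chrom).to_numpy()
        lod = curve.lod[sel]
        cm = curve.grid.loc[sel, "cM"].to_numpy()
        bp = curve.grid.loc[sel, "bp"].to_numpy()
        order = np.argsort(lod)[::-1]
        peaks: list[int] = []
        for i in order:
            if lod[i] < threshold:
                break
            distinct = True
            for j in peaks:
                a, b = (i, j) if i < j else (j, i)
                valley = lod[a : b + 1].min()
                if valley > min(lod[i], lod[j]) - drop:
                    distinct = False
                    break
            if distinct:
                peaks.append(i)
        for i in sorted(peaks):
            lo = i
            while lo > 0 and lod[lo - 1] > lod[i] - drop:
                lo -= 1
            hi = i
            while hi < len(lod) - 1 and lod[hi + 1] > lod[i] - drop:
                hi += 1
            relation = None
            if gene_locus is not None:
                g_chrom, g_bp = gene_locus
                relation = (
                    "cis"
                    if g_chrom == chrom and abs(int(bp[i]) - int(g_bp)) <= cis_window_bp
                    else "trans"
                )
            compartment = None
            if het_intervals is not None:
                in_het = any(
                    iv.chrom == chrom and iv.start <= bp[i] < iv.end for iv in het_intervals
                )
                compartment = "heterochromatin" if in_het else "euchromatin"
            hits.append(
                QTLHit(
                    trait=curve.trait,
                    chrom=str(chrom),
                    peak_cM=float(cm[i]),
                    peak_bp=int(bp[i]),
                    lod=float(lod[i]),
                    support_cM=(float(cm[lo]), float(cm[hi])),
                    relation=relation,
                    compartment=compartment,
                )
            )
    return hits


def scan_all_genes(
    gmap: GeneticMap,
    genotypes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    threshold: float,
    gene_loci: Optional[Mapping[str, tuple[str, int]]] = None,
    het_intervals: Optional[Sequence[GenomicInterval]] = None,
    cis_window_bp: float = 1e6,
    step_cM: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """One Haley-Knott scan per gene phenotype at a shared LOD threshold.

    ``phenotypes`` is genes x lines.  Returns the hit table and summary
    counts: genes with >= 1 hit, hits per compartment, hits-per-gene
    histogram.
    """
    grid = _scan_grid(gmap, step_cM)
    Y = phenotypes.to_numpy(dtype=float).T  # lines x genes
    keep = ~np.isnan(Y).any(axis=0)
    const = np.nanstd(Y, axis=0) == 0
    usable = keep & ~const
    X = _prob_matrix(gmap, genotypes, grid)
    hit_rows = []
    hits_per_gene: dict[str, int] = {}
    lod_mat = _lod_matrix(X, Y[:, usable])
    for col, gene in enumerate(np.asarray(phenotypes.index)[usable]):
        curve = LODCurve(str(gene), grid, lod_mat[:, col], threshold)
        locus = gene_loci.get(str(gene)) if gene_loci else None
        hits = find_peaks_and_classify(
            curve, threshold, locus, het_intervals, cis_window_bp
        )
        hits_per_gene[str(gene)] = len(hits)
        for h in hits:
            hit_rows.append(
                (h.trait, h.chrom, h.peak_cM, h.peak_bp, h.lod,
                 h.support_cM[0], h.support_cM[1], h.relation, h.compartment)
            )
    table = pd.DataFrame(
        hit_rows,
        columns=["trait", "chrom", "peak_cM", "peak_bp", "lod",
                 "support_lo_cM", "support_hi_cM", "relation", "compartment"],
    )
    counts = np.array(list(hits_per_gene.values()), dtype=int)
    summary = {
        "n_genes_scanned": int(usable.sum()),
        "n_genes_with_hit": int((counts > 0).sum()),
        "hits_per_compartment": table["compartment"].value_counts(dropna=False).to_dict(),
        "hits_per_gene_hist": {
            int(k): int(v) for k, v in zip(*np.unique(counts, return_counts=True))
        },
    }
    return table, summary
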