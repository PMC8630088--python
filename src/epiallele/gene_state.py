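"""Gene methylation-state classification: gbM, teM (mCHG/mCHH), UM.

Per gene and sequence context, the number of methylated site calls among
called CDS cytosines is compared against the genome-wide CDS background
rate with an upper-tail binomial test; Benjamini-Hochberg q-values are
computed per context across genes.  Class rules (alpha = 0.05, site floor
20 per tested context):

* teM_mCHH: q_CHH < alpha (CG/CHG free — both accompany mCHH)
* teM_mCHG: q_CHG < alpha and q_CHH >= alpha (CG free — mCG accompanies mCHG)
* gbM:      q_CG < alpha, q_CHG >= alpha, q_CHH >= alpha
* UM:       all q >= alpha and at most 2 symmetric mCG dyads
* otherwise unclassified

teM rules take precedence over gbM, which precedes UM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import positions_in_intervals, union_intervals
from .io import GeneModel

__all__ = [
    "BackgroundRates",
    "GeneMethylationState",
    "CLASS_LABELS",
    "cds_background_rate",
    "background_rates",
    "gene_binomial_p",
    "bh_adjust",
    "count_symmetric_mcg",
    "classify_genes",
]

CLASS_LABELS = ("gbM", "teM_mCHG", "teM_mCHH", "UM", "unclassified")

_CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class BackgroundRates:
    """Genome-wide fraction of methylated calls among called CDS sites."""

    p0_CG: float
    p0_CHG: float
    p0_CHH: float

    def __post_init__(self) -> None:
        for c in _CONTEXTS:
            v = getattr(self, f"p0_{c}")
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"p0_{c} outside [0, 1]: {v}")

    def __getitem__(self, context: str) -> float:
        return getattr(self, f"p0_{context}")


@dataclass
class GeneMethylationState:
    """Per-gene per-context counts, p/q-values and the class label."""

    gene_id: str
    n_CG: int
    k_CG: int
    p_CG: float
    q_CG: float
    n_CHG: int
    k_CHG: int
    p_CHG: float
    q_CHG: float
    n_CHH: int
    k_CHH: int
    p_CHH: float
    q_CHH: float
    n_sym_mCG: int
    label: str


def _called_cds_mask(sites: pd.DataFrame, genes: list[GeneModel]) -> np.ndarray:
    """Mask of sites inside the union of all genes' CDS (each site once)."""
    mask = np.zeros(len(sites), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).extend(g.cds_intervals)
    pos = sites["pos"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    for chrom, ivs in by_chrom.items():
        cmask = chroms == chrom
        if not cmask.any():
            continue
        mask[cmask] = positions_in_intervals(pos[cmask], union_intervals(ivs))
    return mask


def cds_background_rate(
    sites: pd.DataFrame, genes: list[GeneModel], context: str
) -> float:
    """Methylated fraction of called in-context sites across all CDS.

    A site under two overlapping CDS annotations is counted once.
    """
    if context not in _CONTEXTS:
        raise ValueError(f"context must be one of {_CONTEXTS}, got {context!r}")
    in_cds = _called_cds_mask(sites, genes)
    called = sites["call"].isin(["methylated", "unmethylated"]).to_numpy()
    sel = in_cds & called & (sites["context"] == context).to_numpy()
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"no called CDS sites in context {context}")
    k = int((sites["call"].to_numpy()[sel] == "methylated").sum())
    return k / n


def background_rates(sites: pd.DataFrame, genes: list[GeneModel]) -> BackgroundRates:
    return BackgroundRates(
        p0_CG=cds_background_rate(sites, genes, "CG"),
        p0_CHG=cds_background_rate(sites, genes, "CHG"),
        p0_CHH=cds_background_rate(sites, genes, "CHH"),
    )


def gene_binomial_p(n: int, k: int, p0: float) -> float:
    """Upper-tail binomial probability P(X >= k), X ~ Binomial(n, p0)."""
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"p0 outside [0, 1]: {p0}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def count_symmetric_mcg(sites: pd.DataFrame, gene: GeneModel) -> int:
    """CG dyads in the gene's CDS with methylated calls on both strands.

    A plus-strand CG site at position p pairs with the minus-strand site at
    p+1; dyads with either strand uncalled do not count.
    """
    union = union_intervals(gene.cds_intervals)
    sub = sites[(sites["chrom"] == gene.chrom) & (sites["context"] == "CG")]
    if sub.empty:
        return 0
    sub = sub.loc[positions_in_intervals(sub["pos"].to_numpy(), union)]
    meth = sub[sub["call"] == "methylated"]
    plus = set(meth.loc[meth["strand"] == "+", "pos"].to_numpy())
    minus = set(meth.loc[meth["strand"] == "-", "pos"].to_numpy())
    return sum(1 for p in plus if p + 1 in minus)


def classify_genes(
    genes: list[GeneModel],
    sites: pd.DataFrame,
    rates: BackgroundRates | None = None,
    min_sites: int = 20,
    alpha: float = 0.05,
    max_sym_mcg: int = 2,
) -> pd.DataFrame:
    """Classify genes as gbM / teM_mCHG / teM_mCHH / UM / unclassified.

    ``sites`` must carry per-site calls (see
    :func:`~epiallele.methylome.call_site_methylation`).  Returns one row per
    gene with the :class:`GeneMethylationState` fields.
    """
    if rates is None:
        rates = background_rates(sites, genes)

    called = sites[sites["call"].isin(["methylated", "unmethylated"])]
    pos_by_chrom = {c: g for c, g in called.groupby("chrom")}
    # symmetric-mCG dyads: precompute methylated CG positions per chrom/strand
    meth_cg = called[(called["context"] == "CG") & (called["call"] == "methylated")]
    mcg_by_chrom = {
        c: (
            np.sort(g.loc[g["strand"] == "+", "pos"].to_numpy()),
            frozenset(g.loc[g["strand"] == "-", "pos"].to_numpy()),
        )
        for c, g in meth_cg.groupby("chrom")
    }

    counts = {c: np.zeros((len(genes), 2), dtype=int) for c in _CONTEXTS}
    n_sym = np.zeros(len(genes), dtype=int)
    for i, g in enumerate(genes):
        sub = pos_by_chrom.get(g.chrom)
        if sub is None or not g.cds_intervals:
            if not g.cds_intervals:
                warnings.warn(f"gene {g.id} has no CDS; left unclassified")
            continue
        union = union_intervals(g.cds_intervals)
        in_cds = positions_in_intervals(sub["pos"].to_numpy(), union)
        gsub = sub.loc[in_cds]
        for c in _CONTEXTS:
            csub = gsub[gsub["context"] == c]
            counts[c][i, 0] = len(csub)
            counts[c][i, 1] = int((csub["call"] == "methylated").sum())
        plus, minus = mcg_by_chrom.get(g.chrom, (np.empty(0, dtype=int), frozenset()))
        if len(plus):
            cds_plus = plus[positions_in_intervals(plus, union)]
            n_sym[i] = sum(1 for p in cds_plus if p + 1 in minus)

    res: dict[str, np.ndarray] = {"gene_id": np.array([g.id for g in genes], dtype=object)}
    for c in _CONTEXTS:
        n = counts[c][:, 0]
        k = counts[c][:, 1]
        p = np.array([gene_binomial_p(int(ni), int(ki), rates[c]) for ni, ki in zip(n, k)])
        q = bh_adjust(p) if len(p) else p
        res[f"n_{c}"], res[f"k_{c}"], res[f"p_{c}"], res[f"q_{c}"] = n, k, p, q
    res["n_sym_mCG"] = n_sym

    df = pd.DataFrame(res)
    sig = {c: (df[f"q_{c}"] < alpha) & (df[f"n_{c}"] >= 0) for c in _CONTEXTS}
    floor = {c: df[f"n_{c}"] >= min_sites for c in _CONTEXTS}

    tem_chh = floor["CHH"] & sig["CHH"]
    tem_chg = floor["CHG"] & sig["CHG"] & ~sig["CHH"]
    gbm = floor["CG"] & sig["CG"] & ~sig["CHG"] & ~sig["CHH"]
    um = (
        floor["CHH"]
        & ~sig["CG"]
        & ~sig["CHG"]
        & ~sig["CHH"]
        & (df["n_sym_mCG"] <= max_sym_mcg)
    )

    label = np.full(len(df), "unclassified", dtype=object)
    label[um] = "UM"
    label[gbm] = "gbM"
    label[tem_chg] = "teM_mCHG"
    label[tem_chh] = "teM_mCHH"
    no_cds = np.array([not g.cds_intervals for g in genes])
    label[no_cds] = "unclassified"
    df["label"] = label
    return df
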