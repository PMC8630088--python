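"""Synthetic epiRIL methylome generator with ground-truth tables.

Emulates the inputs of the analysis: two parental methylomes (a
methylated wild-type and a globally hypomethylated ddm1-like parent), an
epiRIL population segregating DMR-marker states through a recombination
mosaic, planted ectopic mCHG/mCWA gains in gbM genes whose probability
rises with the line's hypomethylation index and with the ddm1 allele at
designated pericentromeric trans-QTL markers, binomial read sampling with
a bisulfite non-conversion background, and a significant-contact list in
which flagged genes touch H3K9me2 peaks at elevated frequency.

Cytosine positions are placed at fixed spacings within annotated features
(genes, DMR markers, heterochromatin blocks, an unmethylated control
contig); no genome sequence is modelled.  Everything is deterministic
given a config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import ContactRecord, GeneModel, GenomicInterval, SITE_COLUMNS
from .haplotype import DMRMarker

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulationResult",
    "simulate_annotation",
    "simulate_population",
    "plant_gains",
    "emit_allc",
    "simulate_contacts",
    "simulate_experiment",
]

_CHG_TRIS = ("CAG", "CTG", "CCG")
_CWA_TRIS = ("CAA", "CTA")
_CHH_OTHER_TRIS = ("CAC", "CCT", "CTT", "CCA")
_CG_TRIS = ("CGA", "CGT", "CGC")


@dataclass
class SimulationConfig:
    """Study-condition knobs of the generator (defaults are the test bench).

    Rates are per-class (CG, CHG, CHH) per-site methylation probabilities
    of the wild-type parent; the ddm1-like parent attenuates
    heterochromatic rates (markers and intergenic heterochromatin) by
    ``ddm1_attenuation``.  The gain model is logistic in the line's
    hypomethylation index h and its genotype at the designated
    pericentromeric trans-QTL marker(s).
    """

    n_chromosomes: int = 5
    chrom_length_bp: int = 3_000_000
    control_contig: str = "ChrC"
    n_control_sites: int = 1000
    # gene complement
    n_gbm: int = 300
    n_tem: int = 100
    n_um: int = 200
    gene_log_mean: float = 7.3
    gene_log_mean_gbm: float = 7.7
    gene_log_sd: float = 0.45
    min_gene_bp: int = 500
    max_gene_bp: int = 8000
    # cytosine spacings within features (bp)
    cg_spacing_bp: int = 40
    chg_spacing_bp: int = 25
    chh_spacing_bp: int = 15
    # heterochromatin
    het_fraction: float = 0.2
    n_het_sites_per_chrom: int = 500
    # per-class WT rates (CG, CHG, CHH)
    rate_gbm: tuple = (0.8, 0.02, 0.02)
    rate_tem: tuple = (0.9, 0.7, 0.15)
    rate_um: tuple = (0.005, 0.005, 0.005)
    rate_het: tuple = (0.9, 0.7, 0.2)
    ddm1_attenuation: float = 0.1
    # DMR markers
    n_markers: int = 100
    marker_width_bp: int = 300
    marker_sites: int = 15
    # population
    n_lines: int = 150
    crossovers_per_chrom: float = 2.0  # expected mosaic breakpoints per chromosome
    # read sampling
    depth: float = 20.0
    nonconversion: float = 0.005
    # ectopic gain model (logistic scale)
    gain_base: float = -3.0
    gain_slope: float = 2.5
    n_qtl: int = 1
    qtl_effect: float = 2.0
    gain_delta: float = 0.25
    um_gain_fraction: float = 0.1
    # contact model
    contact_background: float = 1.0
    contact_multiplier: float = 2.0
    bin_size_bp: int = 2000
    n_peaks_per_chrom: int = 60
    contact_q_max: float = 0.01
    intra_chrom_prob: float = 0.9

    def __post_init__(self) -> None:
        for name in ("het_fraction", "nonconversion", "um_gain_fraction",
                     "intra_chrom_prob", "ddm1_attenuation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]: {v}")
        for rates in (self.rate_gbm, self.rate_tem, self.rate_um, self.rate_het):
            if any(not (0.0 <= r <= 1.0) for r in rates):
                raise ValueError(f"methylation rates outside [0, 1]: {rates}")

    @property
    def chromosomes(self) -> list[str]:
        return [f"Chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chromosomes}


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside the data for recovery tests."""

    genotypes: pd.DataFrame  # lines x markers; 0 = WT allele, 1 = ddm1 allele
    h: pd.Series  # per-line ddm1 fraction at the markers
    breakpoints: dict  # line -> chrom -> (start_parent, positions array)
    gains: pd.DataFrame  # lines x genes boolean, planted ectopic gains
    qtl_markers: list
    classes: pd.Series  # gene -> {gbM, teM, UM}
    contact_flags: Optional[pd.Series] = None


@dataclass
class SimulationResult:
    config: SimulationConfig
    genes: list
    markers: list
    het_intervals: list
    truth: SimulationTruth
    wt_sites: pd.DataFrame
    ddm1_sites: pd.DataFrame
    line_sites: dict
    peaks: Optional[list] = None
    contacts: Optional[list] = None


# ---------------------------------------------------------------------------
# annotation


def _arms(cfg: SimulationConfig) -> tuple[int, int]:
    """Start/end of the pericentromeric heterochromatin block."""
    L = cfg.chrom_length_bp
    het_len = int(L * cfg.het_fraction)
    start = (L - het_len) // 2
    return start, start + het_len


def simulate_annotation(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[list[GeneModel], list[GenomicInterval], list[DMRMarker], pd.Series]:
    """Place genes (euchromatic arms), heterochromatin blocks and markers.

    Returns ``(genes, het_intervals, markers, classes)``; gene lengths are
    log-normal with gbM genes drawn longer on average.
    """
    het_start, het_end = _arms(cfg)
    het_intervals = (
        [GenomicInterval(c, het_start, het_end, "pericentromere") for c in cfg.chromosomes]
        if het_end > het_start
        else []
    )

    # markers: quasi-even along each chromosome, spanning the pericentromere
    markers: list[DMRMarker] = []
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes)
    per_chrom[: cfg.n_markers % cfg.n_chromosomes] += 1
    k = 0
    for chrom, nm in zip(cfg.chromosomes, per_chrom):
        centers = np.linspace(0.03, 0.97, nm) * cfg.chrom_length_bp
        for c in centers:
            s = int(c) - cfg.marker_width_bp // 2
            markers.append(
                DMRMarker(f"m{k:03d}", GenomicInterval(chrom, s, s + cfg.marker_width_bp))
            )
            k += 1

    # class labels, shuffled so classes interleave along chromosomes
    labels = np.array(
        ["gbM"] * cfg.n_gbm + ["teM"] * cfg.n_tem + ["UM"] * cfg.n_um, dtype=object
    )
    rng.shuffle(labels)
    n_genes = len(labels)
    chrom_of = np.sort(rng.integers(0, cfg.n_chromosomes, size=n_genes))

    marker_blocks: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chromosomes}
    for m in markers:
        marker_blocks[m.interval.chrom].append((m.interval.start, m.interval.end))

    genes: list[GeneModel] = []
    gi = 0
    for ci, chrom in enumerate(cfg.chromosomes):
        idx = np.where(chrom_of == ci)[0]
        if not len(idx):
            continue
        lengths = []
        for j in idx:
            mu = cfg.gene_log_mean_gbm if labels[j] == "gbM" else cfg.gene_log_mean
            L = int(np.clip(rng.lognormal(mu, cfg.gene_log_sd), cfg.min_gene_bp,
                            cfg.max_gene_bp))
            lengths.append(L)
        # free euchromatic segments (arms minus marker intervals)
        segments = []
        for arm in ((0, het_start), (het_end, cfg.chrom_length_bp)):
            cur = arm[0]
            for bs, be in sorted(marker_blocks[chrom]):
                if be <= arm[0] or bs >= arm[1]:
                    continue
                if bs > cur:
                    segments.append((cur, bs))
                cur = max(cur, be)
            if cur < arm[1]:
                segments.append((cur, arm[1]))
        seg_len = np.array([e - s for s, e in segments], dtype=float)
        share = np.floor(seg_len / seg_len.sum() * len(idx)).astype(int)
        while share.sum() < len(idx):
            share[int(np.argmax(seg_len / (share + 1)))] += 1
        pos = 0
        for (s, e), n_here in zip(segments, share):
            sub = list(range(pos, pos + n_here))
            pos += n_here
            total_gene = sum(lengths[i] for i in sub)
            free = (e - s) - total_gene
            if free < len(sub) + 1:
                raise ValueError("genes do not fit in euchromatic arms; shrink the gene set")
            gaps = rng.dirichlet(np.ones(len(sub) + 1)) * free
            cursor = s
            for i, g_idx in enumerate(sub):
                cursor += int(gaps[i])
                L = lengths[g_idx]
                start, end = cursor, cursor + L
                inset = min(100, L // 10)
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    GeneModel(
                        id=f"g{gi:04d}",
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        cds_intervals=[(start + inset, end - inset)],
                    )
                )
                gi += 1
                cursor = end
    classes = pd.Series(
        {g.id: labels[i] for i, g in enumerate(genes)}, name="class"
    )
    return genes, het_intervals, markers, classes


# ---------------------------------------------------------------------------
# population


def simulate_population(
    cfg: SimulationConfig, markers: Sequence[DMRMarker], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Recombination mosaics and marker genotypes for the epiRIL panel.

    Breakpoints follow a Poisson process (expected ``crossovers_per_chrom``
    per chromosome, the inbred-mosaic density); each chromosome starts from
    either parent with probability 1/2.  Returns ``(genotypes, h_true,
    breakpoints)`` with genotypes 0 = WT, 1 = ddm1.
    """
    line_ids = [f"L{i + 1:03d}" for i in range(cfg.n_lines)]
    marker_mid = {m.id: m.interval.midpoint for m in markers}
    by_chrom: dict[str, list[DMRMarker]] = {}
    for m in markers:
        by_chrom.setdefault(m.interval.chrom, []).append(m)

    geno = np.zeros((cfg.n_lines, len(markers)), dtype=int)
    marker_order = [m.id for m in markers]
    col_of = {mid: i for i, mid in enumerate(marker_order)}
    breakpoints: dict[str, dict[str, tuple[int, np.ndarray]]] = {}
    for li, line in enumerate(line_ids):
        breakpoints[line] = {}
        for chrom in cfg.chromosomes:
            n_bk = rng.poisson(cfg.crossovers_per_chrom)
            bks = np.sort(rng.integers(0, cfg.chrom_length_bp, size=n_bk))
            start_parent = int(rng.random() < 0.5)
            breakpoints[line][chrom] = (start_parent, bks)
            for m in by_chrom.get(chrom, []):
                n_before = int(np.searchsorted(bks, marker_mid[m.id]))
                geno[li, col_of[m.id]] = (start_parent + n_before) % 2
    genotypes = pd.DataFrame(geno, index=line_ids, columns=marker_order)
    h_true = genotypes.mean(axis=1).rename("h")
    return genotypes, h_true, breakpoints


def parent_at(breakpoints: tuple[int, np.ndarray], pos: np.ndarray) -> np.ndarray:
    """Parent of origin (0 = WT, 1 = ddm1) at positions, from a line mosaic."""
    start, bks = breakpoints
    return (start + np.searchsorted(bks, np.asarray(pos))) % 2


def plant_gains(
    cfg: SimulationConfig,
    genotypes: pd.DataFrame,
    h: pd.Series,
    classes: pd.Series,
    qtl_markers: Sequence[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Plant ectopic-gain events: logistic in h and the trans-QTL genotype.

    Returns a lines x genes boolean frame.  UM genes gain at
    ``um_gain_fraction`` of the gbM probability; teM genes never (their
    non-CG methylation is already high).
    """
    qtl_allele = (
        genotypes[list(qtl_markers)].max(axis=1).to_numpy(dtype=float)
        if len(qtl_markers)
        else np.zeros(len(genotypes))
    )
    logit = cfg.gain_base + cfg.gain_slope * h.to_numpy() + cfg.qtl_effect * qtl_allele
    p_line = 1.0 / (1.0 + np.exp(-logit))
    gene_ids = classes.index.to_numpy()
    scale = np.where(
        classes.to_numpy() == "gbM", 1.0,
        np.where(classes.to_numpy() == "UM", cfg.um_gain_fraction, 0.0),
    )
    P = np.clip(np.outer(p_line, scale), 0.0, 1.0)
    draws = rng.random(P.shape) < P
    return pd.DataFrame(draws, index=genotypes.index, columns=gene_ids)


# ---------------------------------------------------------------------------
# sites


def _site_template(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    markers: Sequence[DMRMarker],
    classes: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """All cytosine positions with WT rates and feature annotations.

    Extra columns beyond the sites schema: ``rate`` (WT methylation
    probability), ``gene_idx`` (-1 intergenic), ``marker_idx`` (-1), and
    ``het`` (heterochromatic intergenic flag).
    """
    rate_of = {"gbM": cfg.rate_gbm, "teM": cfg.rate_tem, "UM": cfg.rate_um}
    rows_chrom, rows_pos, rows_strand, rows_tri = [], [], [], []
    rows_rate, rows_gene, rows_marker, rows_het = [], [], [], []

    def add(chrom, pos, strand, tri, rate, gene_idx=-1, marker_idx=-1, het=False):
        rows_chrom.append(chrom)
        rows_pos.append(pos)
        rows_strand.append(strand)
        rows_tri.append(tri)
        rows_rate.append(rate)
        rows_gene.append(gene_idx)
        rows_marker.append(marker_idx)
        rows_het.append(het)

    for gi, g in enumerate(genes):
        r_cg, r_chg, r_chh = rate_of[classes[g.id]]
        # CG dyads
        for p in range(g.start + 2, g.end - 2, cfg.cg_spacing_bp):
            tri = _CG_TRIS[rng.integers(len(_CG_TRIS))]
            add(g.chrom, p, "+", tri, r_cg, gi)
            add(g.chrom, p + 1, "-", tri, r_cg, gi)
        for p in range(g.start + 7, g.end - 2, cfg.chg_spacing_bp):
            tri = _CHG_TRIS[rng.integers(len(_CHG_TRIS))]
            add(g.chrom, p, "+" if rng.random() < 0.5 else "-", tri, r_chg, gi)
        for p in range(g.start + 13, g.end - 2, cfg.chh_spacing_bp):
            tris = _CWA_TRIS if rng.random() < 0.5 else _CHH_OTHER_TRIS
            tri = tris[rng.integers(len(tris))]
            add(g.chrom, p, "+" if rng.random() < 0.5 else "-", tri, r_chh, gi)

    r_cg, r_chg, r_chh = cfg.rate_het
    het_rate = {"CG": r_cg, "CHG": r_chg, "CHH": r_chh}
    for mi, m in enumerate(markers):
        step = max(1, (len(m.interval) - 4) // cfg.marker_sites)
        for j, p in enumerate(range(m.interval.start + 2, m.interval.end - 2, step)):
            kind = ("CG", "CHG", "CHH")[j % 3]
            tri = {"CG": _CG_TRIS, "CHG": _CHG_TRIS, "CHH": _CWA_TRIS + _CHH_OTHER_TRIS}[kind]
            tri = tri[rng.integers(len(tri))]
            add(m.interval.chrom, p, "+" if rng.random() < 0.5 else "-", tri,
                het_rate[kind], -1, mi)

    het_start, het_end = _arms(cfg)
    for chrom in cfg.chromosomes:
        pos = np.sort(rng.integers(het_start, het_end, size=cfg.n_het_sites_per_chrom))
        for p in pos:
            kind = ("CG", "CHG", "CHH")[int(rng.integers(3))]
            tri = {"CG": _CG_TRIS, "CHG": _CHG_TRIS, "CHH": _CWA_TRIS + _CHH_OTHER_TRIS}[kind]
            tri = tri[rng.integers(len(tri))]
            add(chrom, int(p), "+" if rng.random() < 0.5 else "-", tri, het_rate[kind],
                -1, -1, True)

    # unmethylated control contig (chloroplast-like)
    pos = np.sort(rng.choice(100_000, size=cfg.n_control_sites, replace=False))
    for p in pos:
        tri = _CHH_OTHER_TRIS[int(rng.integers(len(_CHH_OTHER_TRIS)))]
        add(cfg.control_contig, int(p), "+", tri, 0.0)

    df = pd.DataFrame(
        {
            "chrom": rows_chrom,
            "pos": np.array(rows_pos, dtype=np.int64),
            "strand": rows_strand,
            "tri_context": rows_tri,
            "rate": np.array(rows_rate, dtype=float),
            "gene_idx": np.array(rows_gene, dtype=np.int32),
            "marker_idx": np.array(rows_marker, dtype=np.int32),
            "het": np.array(rows_het, dtype=bool),
        }
    )
    second = df["tri_context"].str[1]
    third = df["tri_context"].str[2]
    df["context"] = np.where(second == "G", "CG", np.where(third == "G", "CHG", "CHH"))
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    return df


def emit_allc(
    rates: np.ndarray,
    template: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    depth: Optional[float] = None,
) -> pd.DataFrame:
    """Sample read counts at every template site given per-site rates.

    total ~ Poisson(depth); mc ~ Binomial(total, rate(1-nc) + (1-rate)nc)
    where nc is the bisulfite non-conversion rate.
    """
    depth = cfg.depth if depth is None else depth
    nc = cfg.nonconversion
    total = rng.poisson(depth, size=len(template))
    p_eff = rates * (1.0 - nc) + (1.0 - rates) * nc
    mc = rng.binomial(total, p_eff)
    out = template[["chrom", "pos", "strand", "tri_context", "context"]].copy()
    out["mc"] = mc
    out["total"] = total
    out["call"] = "uncalled"
    return out[SITE_COLUMNS]


def _wt_rates(template: pd.DataFrame) -> np.ndarray:
    return template["rate"].to_numpy().copy()


def _ddm1_rates(cfg: SimulationConfig, template: pd.DataFrame) -> np.ndarray:
    rates = _wt_rates(template)
    hetero = (template["marker_idx"].to_numpy() >= 0) | template["het"].to_numpy()
    rates[hetero] *= cfg.ddm1_attenuation
    return rates


def _line_rates(
    cfg: SimulationConfig,
    template: pd.DataFrame,
    genotype: pd.Series,
    line_breakpoints: Mapping[str, tuple[int, np.ndarray]],
    gained_genes: np.ndarray,
) -> np.ndarray:
    """Per-site rates for one line: marker alleles, mosaic heterochromatin,
    and planted gains on the CHG/CWA sites of gained genes."""
    rates = _wt_rates(template)
    midx = template["marker_idx"].to_numpy()
    has_marker = midx >= 0
    allele = genotype.to_numpy()
    atten = has_marker & (allele[np.clip(midx, 0, None)] == 1)
    rates[atten] *= cfg.ddm1_attenuation

    het = template["het"].to_numpy()
    if het.any():
        for chrom, sub_idx in template.loc[het].groupby("chrom").groups.items():
            par = parent_at(line_breakpoints[chrom], template.loc[sub_idx, "pos"].to_numpy())
            sel = np.asarray(sub_idx)[par == 1]
            rates[sel] *= cfg.ddm1_attenuation

    if gained_genes.any():
        gidx = template["gene_idx"].to_numpy()
        in_gained = (gidx >= 0) & gained_genes[np.clip(gidx, 0, None)]
        ctx_ok = (template["context"].to_numpy() == "CHG") | template["tri_context"].isin(
            _CWA_TRIS
        ).to_numpy()
        rates[in_gained & ctx_ok] = np.clip(
            rates[in_gained & ctx_ok] + cfg.gain_delta, 0.0, 1.0
        )
    return rates


# ---------------------------------------------------------------------------
# contacts


def simulate_contacts(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    het_intervals: Sequence[GenomicInterval],
    flags: pd.Series,
    rng: np.random.Generator,
) -> tuple[list[ContactRecord], list[GenomicInterval]]:
    """Significant gene-peak contacts with Poisson counts per gene.

    Peaks are 2-kb bins inside the pericentromeric blocks; a flagged gene's
    contact count multiplies the background by ``contact_multiplier``.
    """
    bs = cfg.bin_size_bp
    peaks: list[GenomicInterval] = []
    for iv in het_intervals:
        first = (iv.start // bs + 1) * bs
        bins = np.arange(first, iv.end - bs, bs)
        take = min(cfg.n_peaks_per_chrom, len(bins))
        chosen = np.sort(rng.choice(bins, size=take, replace=False))
        peaks.extend(
            GenomicInterval(iv.chrom, int(b), int(b) + bs, f"peak_{iv.chrom}_{j}")
            for j, b in enumerate(chosen)
        )
    peaks_by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)

    contacts: list[ContactRecord] = []
    if not peaks:
        return contacts, peaks
    for g in genes:
        lam = cfg.contact_background * (
            cfg.contact_multiplier if bool(flags.get(g.id, False)) else 1.0
        )
        n = int(rng.poisson(lam))
        gene_bin_start = (g.midpoint // bs) * bs
        gene_anchor = GenomicInterval(g.chrom, gene_bin_start, gene_bin_start + bs)
        for _ in range(n):
            same = rng.random() < cfg.intra_chrom_prob and g.chrom in peaks_by_chrom
            pool = peaks_by_chrom[g.chrom] if same else peaks
            pk = pool[int(rng.integers(len(pool)))]
            if (
                pk.chrom == gene_anchor.chrom
                and pk.start == gene_anchor.start
            ):
                continue  # identical bins would not be a valid contact
            contacts.append(
                ContactRecord(
                    anchor_a=gene_anchor,
                    anchor_b=GenomicInterval(pk.chrom, pk.start, pk.end),
                    q_value=float(rng.uniform(0.0, cfg.contact_q_max)),
                )
            )
    return contacts, peaks


# ---------------------------------------------------------------------------
# end-to-end


def default_qtl_markers(cfg: SimulationConfig, markers: Sequence[DMRMarker]) -> list[str]:
    """The marker(s) nearest the centromere of the first chromosome(s)."""
    het_start, het_end = _arms(cfg)
    center = (het_start + het_end) // 2
    out = []
    for chrom in cfg.chromosomes[: cfg.n_qtl]:
        cands = [m for m in markers if m.interval.chrom == chrom]
        out.append(min(cands, key=lambda m: abs(m.interval.midpoint - center)).id)
    return out


def simulate_experiment(
    cfg: Optional[SimulationConfig] = None,
    seed: int = 0,
    with_contacts: bool = True,
    contact_flags: Optional[pd.Series] = None,
) -> SimulationResult:
    """Generate a full synthetic study: annotation, parents, population,
    per-line methylomes with planted gains, and (optionally) contacts.

    Per-line site frames carry the non-CG genic sites, marker sites,
    heterochromatic intergenic sites and the control contig; the parental
    frames carry all sites including genic CG (needed for classification).
    Deterministic given ``cfg`` and ``seed``.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    genes, het_intervals, markers, classes = simulate_annotation(cfg, rng)
    template = _site_template(cfg, genes, markers, classes, rng)
    genotypes, h_true, breakpoints = simulate_population(cfg, markers, rng)
    qtl_markers = default_qtl_markers(cfg, markers)
    gains = plant_gains(cfg, genotypes, h_true, classes, qtl_markers, rng)

    wt_sites = emit_allc(_wt_rates(template), template, cfg, rng)
    ddm1_sites = emit_allc(_ddm1_rates(cfg, template), template, cfg, rng)

    # per-line frames: drop genic CG sites (not consumed by per-line stages)
    keep = ~(
        (template["gene_idx"].to_numpy() >= 0)
        & (template["context"].to_numpy() == "CG")
    )
    line_template = template.loc[keep].reset_index(drop=True)
    gene_ids = np.array([g.id for g in genes])
    line_sites: dict[str, pd.DataFrame] = {}
    for line in genotypes.index:
        gained = gains.loc[line].reindex(gene_ids).to_numpy(dtype=bool)
        rates = _line_rates(cfg, line_template, genotypes.loc[line],
                            breakpoints[line], gained)
        line_sites[line] = emit_allc(rates, line_template, cfg, rng)

    truth = SimulationTruth(
        genotypes=genotypes,
        h=h_true,
        breakpoints=breakpoints,
        gains=gains,
        qtl_markers=qtl_markers,
        classes=classes,
    )
    peaks = contacts = None
    if with_contacts:
        if contact_flags is None:
            contact_flags = (classes == "teM").rename("flag")
        truth.contact_flags = contact_flags
        contacts, peaks = simulate_contacts(cfg, genes, het_intervals, contact_flags, rng)
    return SimulationResult(
        config=cfg,
        genes=genes,
        markers=markers,
        het_intervals=het_intervals,
        truth=truth,
        wt_sites=wt_sites,
        ddm1_sites=ddm1_sites,
        line_sites=line_sites,
        peaks=peaks,
        contacts=contacts,
    )
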