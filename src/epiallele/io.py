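"""Readers and writers for the file formats the pipeline touches.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open ``[start, end)`` — including
per-cytosine positions (``pos`` column of a sites frame) and gene models.
Conversion to/from the 1-based conventions of allc tables and GFF3 happens
only inside the functions in this module.

Sites frames
------------
Per-cytosine methylomes are held as a :class:`pandas.DataFrame` with columns

==============  =====================================================
``chrom``       contig name (str)
``pos``         0-based position of the cytosine (int)
``strand``      ``+`` or ``-``
``tri_context`` 3-mer read 5'->3' on the cytosine's strand
``context``     derived: ``CG``, ``CHG`` or ``CHH``
``mc``          methylated read count
``total``       total read count
``call``        ``methylated`` / ``unmethylated`` / ``uncalled``
==============  =====================================================

sorted by ``(chrom, pos, strand)``.  :class:`CytosineSite` is the row-level
view of the same record; :func:`sites_to_frame` / :func:`frame_to_sites`
convert between the two.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CytosineSite",
    "GeneModel",
    "GenomicInterval",
    "ContactRecord",
    "SITE_COLUMNS",
    "context_class",
    "is_cwa",
    "read_allc",
    "write_allc",
    "sites_to_frame",
    "frame_to_sites",
    "read_gene_models",
    "read_intervals",
    "write_intervals",
    "read_contacts",
    "write_contacts",
    "write_results_table",
]

SITE_COLUMNS = ["chrom", "pos", "strand", "tri_context", "context", "mc", "total", "call"]

_CALL_VALUES = ("methylated", "unmethylated", "uncalled")


def context_class(tri_context: str) -> str:
    """CG if the 2nd base is G; CHG if the 3rd is G and the 2nd is not; else CHH."""
    if len(tri_context) != 3 or tri_context[0] != "C":
        raise ValueError(f"not a cytosine trinucleotide context: {tri_context!r}")
    if tri_context[1] == "G":
        return "CG"
    if tri_context[2] == "G":
        return "CHG"
    return "CHH"


def is_cwa(tri_context: str) -> bool:
    """CWA (W = A or T) is the CMT2-preferred CHH subcontext: CAA or CTA."""
    return tri_context in ("CAA", "CTA")


@dataclass
class CytosineSite:
    """One cytosine: position, strand, context and read counts.

    ``pos`` is 0-based (internal convention); :func:`read_allc` converts
    from the table's 1-based positions.
    """

    chrom: str
    pos: int
    strand: str
    tri_context: str
    mc: int
    total: int
    call: str = "uncalled"
    context: str = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.mc <= self.total):
            raise ValueError(
                f"mc_reads must satisfy 0 <= mc <= total, got mc={self.mc} total={self.total}"
            )
        if self.call not in _CALL_VALUES:
            raise ValueError(f"bad call {self.call!r}")
        self.context = context_class(self.tri_context)

    @property
    def is_cwa(self) -> bool:
        return is_cwa(self.tri_context)


@dataclass
class GenomicInterval:
    """0-based half-open interval (BED convention), optionally labelled."""

    chrom: str
    start: int
    end: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"interval must satisfy 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GeneModel:
    """A gene with the CDS intervals of its primary transcript.

    Coordinates are 0-based half-open (converted from GFF3 at read time).
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")
        self.cds_intervals = sorted(tuple(iv) for iv in self.cds_intervals)
        prev_end = -1
        for s, e in self.cds_intervals:
            if s >= e:
                raise ValueError(f"gene {self.id}: empty CDS interval [{s}, {e})")
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.id}: CDS outside gene span")
            if s < prev_end:
                raise ValueError(f"gene {self.id}: overlapping CDS intervals")
            prev_end = e

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ContactRecord:
    """A significant chromatin contact between two anchor bins."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    q_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.q_value is not None and not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"q_value outside [0, 1]: {self.q_value}")
        if (
            self.anchor_a.chrom == self.anchor_b.chrom
            and self.anchor_a.start == self.anchor_b.start
            and self.anchor_a.end == self.anchor_b.end
        ):
            raise ValueError("intra-chromosomal contact with identical anchor bins")


# ---------------------------------------------------------------------------
# allc tables


def _derive_context(tri: pd.Series) -> pd.Series:
    second = tri.str[1]
    third = tri.str[2]
    out = pd.Series(np.where(second == "G", "CG", np.where(third == "G", "CHG", "CHH")),
                    index=tri.index)
    return out


def read_allc(path: str | os.PathLike) -> pd.DataFrame:
    """Read an allc-style per-cytosine TSV into a sites frame.

    Expected columns (no header): chrom, 1-based position, strand,
    trinucleotide context, methylated reads, total reads, and an optional
    call flag (``1`` methylated / ``0`` unmethylated / ``-`` uncalled).
    Positions are converted to the internal 0-based convention.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype={0: str, 2: str, 3: str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=SITE_COLUMNS)
    if df.shape[1] not in (6, 7):
        raise ValueError(f"{path}: expected 6 or 7 tab-separated columns, got {df.shape[1]}")
    df.columns = ["chrom", "pos", "strand", "tri_context", "mc", "total"] + (
        ["flag"] if df.shape[1] == 7 else []
    )
    for col in ("pos", "mc", "total"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 1
            raise ValueError(f"{path}: malformed numeric field in column {col!r} at line {line}")
        df[col] = vals.astype(np.int64)
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: bad strand at line {int(df.index[bad][0]) + 1}")
    bad = (df["mc"] < 0) | (df["mc"] > df["total"])
    if bad.any():
        raise ValueError(
            f"{path}: mc_reads > total_reads at line {int(df.index[bad][0]) + 1}"
        )
    if (df["pos"] < 1).any():
        raise ValueError(f"{path}: positions must be 1-based (>= 1)")
    df["pos"] = df["pos"] - 1
    df["context"] = _derive_context(df["tri_context"])
    if "flag" in df.columns:
        mapping = {"1": "methylated", "0": "unmethylated", "-": "uncalled"}
        call = df["flag"].astype(str).map(mapping)
        if call.isna().any():
            line = int(call.index[call.isna()][0]) + 1
            raise ValueError(f"{path}: bad call flag at line {line}")
        df["call"] = call
        df = df.drop(columns="flag")
    else:
        df["call"] = "uncalled"
    df = df[SITE_COLUMNS].sort_values(["chrom", "pos", "strand"], kind="mergesort")
    return df.reset_index(drop=True)


def write_allc(sites: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a sites frame as an allc-style TSV (positions back to 1-based).

    The call flag column is always emitted (``-`` for uncalled) so that
    ``read_allc(write_allc(x)) == x``.
    """
    out = sites.copy()
    out["pos"] = out["pos"] + 1
    out["flag"] = out["call"].map({"methylated": "1", "unmethylated": "0", "uncalled": "-"})
    out[["chrom", "pos", "strand", "tri_context", "mc", "total", "flag"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def sites_to_frame(sites: Iterable[CytosineSite]) -> pd.DataFrame:
    rows = [
        (s.chrom, s.pos, s.strand, s.tri_context, s.context, s.mc, s.total, s.call)
        for s in sites
    ]
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def frame_to_sites(df: pd.DataFrame) -> list[CytosineSite]:
    return [
        CytosineSite(r.chrom, int(r.pos), r.strand, r.tri_context, int(r.mc), int(r.total), r.call)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gene_models(path: str | os.PathLike, primary_suffix: str = ".1") -> list[GeneModel]:
    """Read gene models from GFF3, keeping the CDS of the primary transcript.

    The primary transcript is the mRNA whose ID ends in ``primary_suffix``
    if one exists, else the first mRNA of the gene.  Genes without CDS are
    skipped with a warning.
    """
    import gffutils

    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.start > gene.end:
            raise ValueError(f"gene {gene.id}: inverted coordinates")
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        primary = None
        for m in mrnas:
            if m.id.endswith(primary_suffix):
                primary = m
                break
        if primary is None and mrnas:
            primary = mrnas[0]
        if primary is not None:
            cds_feats = list(db.children(primary, featuretype="CDS", order_by="start"))
        else:
            cds_feats = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not cds_feats:
            warnings.warn(f"gene {gene.id} has no CDS; skipped")
            continue
        for c in cds_feats:
            if c.start > c.end:
                raise ValueError(f"gene {gene.id}: inverted CDS coordinates")
        cds = [(c.start - 1, c.end) for c in cds_feats]
        genes.append(
            GeneModel(
                id=gene.id,
                chrom=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand if gene.strand in ("+", "-") else "+",
                cds_intervals=cds,
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as minimal GFF3 (gene / mRNA / CDS rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.id}"
            fh.write(
                f"{g.chrom}\tepiallele\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mid = f"{g.id}.1"
            fh.write(
                f"{g.chrom}\tepiallele\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={g.id}\n"
            )
            for i, (s, e) in enumerate(g.cds_intervals):
                fh.write(
                    f"{g.chrom}\tepiallele\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mid}.cds{i};Parent={mid}\n"
                )


# ---------------------------------------------------------------------------
# BED / BEDPE


def read_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3+ intervals (0-based half-open preserved verbatim)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED row needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            label = parts[3] if len(parts) > 3 else None
            out.append(GenomicInterval(chrom, start, end, label))
    return out


def write_intervals(intervals: Sequence[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label is not None:
                cols.append(iv.label)
            fh.write("\t".join(cols) + "\n")


def read_contacts(path: str | os.PathLike) -> list[ContactRecord]:
    """Read a BEDPE of significant contacts; optional 7th column is a q-value."""
    out: list[ContactRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BEDPE row needs >= 6 columns")
            a = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            b = GenomicInterval(parts[3], int(parts[4]), int(parts[5]))
            q = None
            if len(parts) > 6 and parts[6] not in (".", ""):
                q = float(parts[6])
            out.append(ContactRecord(a, b, q))
    return out


def write_contacts(contacts: Sequence[ContactRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for c in contacts:
            q = "." if c.q_value is None else format(c.q_value, ".6g")
            fh.write(
                f"{c.anchor_a.chrom}\t{c.anchor_a.start}\t{c.anchor_a.end}\t"
                f"{c.anchor_b.chrom}\t{c.anchor_b.start}\t{c.anchor_b.end}\t{q}\n"
            )


# ---------------------------------------------------------------------------
# Result tables


def write_results_table(
    records: Sequence, path: str | os.PathLike, record_type: type | None = None
) -> None:
    """Write a homogeneous sequence of result dataclasses (or a DataFrame) as TSV.

    Columns follow dataclass field order; floats are printed at 6 significant
    digits.  An empty sequence produces a header-only file (pass
    ``record_type`` so the header is known).
    """
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return
    records = list(records)
    if not records:
        cols = [f.name for f in fields(record_type)] if record_type is not None else []
        with open(path, "w") as fh:
            if cols:
                fh.write("\t".join(cols) + "\n")
        return
    first_type = type(records[0])
    if record_type is not None and first_type is not record_type:
        raise TypeError(f"records are {first_type.__name__}, expected {record_type.__name__}")
    if not all(type(r) is first_type for r in records):
        raise TypeError("mixed record types in results table")
    if not hasattr(first_type, "__dataclass_fields__"):
        raise TypeError(f"unsupported record type {first_type.__name__}")
    cols = [f.name for f in fields(first_type)]
    df = pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
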