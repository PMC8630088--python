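"""Shared fixtures: a small synthetic study reused across module tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epiallele.simulate import SimulationConfig, simulate_experiment


def small_config(**overrides) -> SimulationConfig:
    base = dict(
        n_chromosomes=2,
        chrom_length_bp=600_000,
        n_gbm=30,
        n_tem=10,
        n_um=20,
        n_markers=20,
        n_lines=12,
        n_het_sites_per_chrom=150,
        n_control_sites=300,
        n_peaks_per_chrom=20,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """A 2-chromosome, 60-gene, 12-line study with contacts."""
    return simulate_experiment(small_config(), seed=42)


@pytest.fixture(scope="session")
def called_wt(small_sim):
    """WT parent sites with per-site methylation calls."""
    from epiallele.methylome import call_site_methylation, estimate_nonconversion

    nc = estimate_nonconversion(small_sim.wt_sites, "ChrC")
    return call_site_methylation(small_sim.wt_sites, nc)


def make_sites(rows) -> pd.DataFrame:
    """Sites frame from (chrom, pos, strand, tri, mc, total[, call]) tuples."""
    from epiallele.io import SITE_COLUMNS, context_class

    out = []
    for r in rows:
        chrom, pos, strand, tri, mc, total = r[:6]
        call = r[6] if len(r) > 6 else "uncalled"
        out.append((chrom, pos, strand, tri, context_class(tri), mc, total, call))
    df = pd.DataFrame(out, columns=SITE_COLUMNS)
    return df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
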