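"""DMR-marker states, hypomethylation index, segments, met1 regions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epiallele.haplotype import (
    DMRMarker,
    assign_gene_parent,
    call_marker_state,
    call_marker_states,
    find_met1_derived_regions,
    haplotype_segments,
    hypomethylation_index,
)
from epiallele.io import GeneModel, GenomicInterval

from conftest import make_sites


def _marker(mid, chrom, start, end):
    return DMRMarker(mid, GenomicInterval(chrom, start, end))


class TestMarkerState:
    def test_level_below_half_is_u(self):
        sites = make_sites([("Chr1", 50, "+", "CGA", 49, 100)])
        assert call_marker_state(sites, _marker("m", "Chr1", 0, 100)) == "U"

    def test_level_exactly_half_is_m(self):
        sites = make_sites([("Chr1", 50, "+", "CGA", 50, 100)])
        assert call_marker_state(sites, _marker("m", "Chr1", 0, 100)) == "M"

    def test_uncovered_is_na(self):
        sites = make_sites([("Chr1", 500, "+", "CGA", 10, 10)])
        assert call_marker_state(sites, _marker("m", "Chr1", 0, 100)) == "NA"

    def test_vectorised_matches_scalar(self, small_sim):
        line = next(iter(small_sim.line_sites))
        sites = small_sim.line_sites[line]
        vec = call_marker_states(sites, small_sim.markers)
        for m in small_sim.markers[::5]:
            assert vec[m.id] == call_marker_state(sites, m)


class TestHypomethylationIndex:
    @pytest.mark.parametrize(
        "states,expected",
        [
            (["M"] * 10, 0.0),
            (["U"] * 10, 1.0),
            (["U"] * 72 + ["M"] * 72, 0.5),
            (["U", "M", "NA", "NA"], 0.5),
        ],
    )
    def test_values(self, states, expected):
        assert hypomethylation_index(states) == pytest.approx(expected)

    def test_all_na_errors(self):
        with pytest.raises(ValueError):
            hypomethylation_index(["NA", "NA"])

    def test_marker_order_invariance(self):
        rng = np.random.default_rng(2)
        states = list(rng.choice(["M", "U", "NA"], size=50))
        assert hypomethylation_index(states) == pytest.approx(
            hypomethylation_index(states[::-1])
        )


class TestSegments:
    LEN = {"Chr1": 3_000_000}

    def test_concordant_markers_merge(self):
        markers = [_marker("a", "Chr1", 1_000_000, 1_000_100),
                   _marker("b", "Chr1", 2_000_000, 2_000_100)]
        states = pd.Series({"a": "M", "b": "M"})
        segs = haplotype_segments(markers, states, self.LEN)
        wt = [iv for iv, p in segs if p == "WT"]
        assert len(wt) == 1
        assert (wt[0].start, wt[0].end) == (1_000_000, 2_000_100)

    def test_discordant_markers_split_at_midpoint(self):
        markers = [_marker("a", "Chr1", 1_000_000, 1_000_100),
                   _marker("b", "Chr1", 2_000_000, 2_000_100)]
        states = pd.Series({"a": "M", "b": "U"})
        segs = haplotype_segments(markers, states, self.LEN)
        mid = (1_000_100 + 2_000_000) // 2
        wt = next(iv for iv, p in segs if p == "WT")
        dd = next(iv for iv, p in segs if p == "ddm1")
        assert wt.end == mid and dd.start == mid

    def test_chromosome_ends_unknown(self):
        markers = [_marker("a", "Chr1", 1_000_000, 1_000_100)]
        states = pd.Series({"a": "M"})
        segs = haplotype_segments(markers, states, self.LEN)
        assert segs[0].__class__  # tiling exists
        assert [p for _, p in segs] == ["unknown", "WT", "unknown"]

    def test_na_marker_breaks_tiling(self):
        markers = [_marker("a", "Chr1", 1_000_000, 1_000_100),
                   _marker("b", "Chr1", 1_500_000, 1_500_100),
                   _marker("c", "Chr1", 2_000_000, 2_000_100)]
        states = pd.Series({"a": "M", "b": "NA", "c": "M"})
        segs = haplotype_segments(markers, states, self.LEN)
        # the span around the NA marker is unknown
        parents = [p for iv, p in segs if iv.start >= 1_000_100 and iv.end <= 2_000_000]
        assert set(parents) == {"unknown"}

    def test_segments_tile_without_overlap(self):
        markers = [_marker("a", "Chr1", 100_000, 100_300),
                   _marker("b", "Chr1", 900_000, 900_300),
                   _marker("c", "Chr1", 1_800_000, 1_800_300)]
        states = pd.Series({"a": "U", "b": "M", "c": "NA"})
        segs = haplotype_segments(markers, states, self.LEN)
        cursor = 0
        for iv, _ in segs:
            assert iv.start == cursor
            cursor = iv.end
        assert cursor == self.LEN["Chr1"]


class TestGeneParent:
    SEGS = [
        (GenomicInterval("Chr1", 0, 1_000_000), "WT"),
        (GenomicInterval("Chr1", 1_000_000, 2_000_000), "ddm1"),
        (GenomicInterval("Chr1", 2_000_000, 3_000_000), "unknown"),
    ]

    def test_wholly_inside(self):
        g = GeneModel("g", "Chr1", 1_200_000, 1_202_000, "+", [(1_200_000, 1_202_000)])
        assert assign_gene_parent(g, self.SEGS) == "ddm1"

    def test_spanning_breakpoint_uses_midpoint(self):
        g = GeneModel("g", "Chr1", 999_000, 1_000_500, "+", [(999_000, 1_000_500)])
        # midpoint 999_750 is in the WT segment
        assert assign_gene_parent(g, self.SEGS) == "WT"

    def test_unmapped_contig_unknown(self):
        g = GeneModel("g", "Chr9", 10, 2000, "+", [(10, 2000)])
        assert assign_gene_parent(g, self.SEGS) == "unknown"


class TestMet1Regions:
    def _genes(self, n, chrom="Chr1", start=0, glen=1000, gap=1000):
        out = []
        for i in range(n):
            s = start + i * (glen + gap)
            out.append(GeneModel(f"g{i}", chrom, s, s + glen, "+", [(s, s + glen)]))
        return out

    def _sites_for(self, genes, level, depth=100):
        rows = []
        for g in genes:
            for p in range(g.start + 10, g.end, 200):
                rows.append((g.chrom, p, "+", "CGA", int(level * depth), depth))
        return make_sites(rows)

    def test_reduced_bin_flagged(self):
        genes = self._genes(10)  # one bin of 10 exons
        control = self._sites_for(genes, 0.50)
        sample = self._sites_for(genes, 0.05)
        regions = find_met1_derived_regions(sample, control, genes)
        assert len(regions) == 1
        assert regions[0].start == genes[0].start

    def test_equal_levels_not_flagged(self):
        genes = self._genes(10)
        control = self._sites_for(genes, 0.5)
        sample = self._sites_for(genes, 0.5)
        assert find_met1_derived_regions(sample, control, genes) == []

    def test_remainder_exons_merge_into_last_bin(self):
        """25 exons split as 10 + 15: the short tail joins its predecessor."""
        genes = self._genes(25)
        control = self._sites_for(genes, 0.5)
        # reduce mCG only over the last 15 genes (second bin incl. remainder)
        sample_rows = []
        for i, g in enumerate(genes):
            lv = 0.5 if i < 10 else 0.05
            for p in range(g.start + 10, g.end, 200):
                sample_rows.append((g.chrom, p, "+", "CGA", int(lv * 100), 100))
        regions = find_met1_derived_regions(make_sites(sample_rows), control, genes)
        assert len(regions) == 1
        assert regions[0].start == genes[10].start
        assert regions[0].end == genes[24].end

    def test_adjacent_flagged_bins_merge(self):
        genes = self._genes(20)  # two bins, both reduced
        control = self._sites_for(genes, 0.5)
        sample = self._sites_for(genes, 0.1)
        regions = find_met1_derived_regions(sample, control, genes)
        assert len(regions) == 1


class TestRecoveryOnGenerator:
    def test_h_matches_truth(self, small_sim):
        for line in list(small_sim.line_sites)[:6]:
            states = call_marker_states(small_sim.line_sites[line], small_sim.markers)
            h = hypomethylation_index(states)
            assert abs(h - small_sim.truth.h[line]) <= 0.05

    def test_breakpoints_within_half_marker_spacing(self, small_sim):
        """Reconstructed parent flips sit within half the local inter-marker
        gap of the true mosaic breakpoints."""
        chrom_lengths = small_sim.config.chrom_lengths
        for line in list(small_sim.line_sites)[:4]:
            states = call_marker_states(small_sim.line_sites[line], small_sim.markers)
            segs = haplotype_segments(small_sim.markers, states, chrom_lengths)
            for chrom in chrom_lengths:
                start_parent, bks = small_sim.truth.breakpoints[line][chrom]
                mids = sorted(
                    m.interval.midpoint for m in small_sim.markers
                    if m.interval.chrom == chrom
                )
                csegs = [(iv, p) for iv, p in segs
                         if iv.chrom == chrom and p in ("WT", "ddm1")]
                flips = [
                    a[0].end for a, b in zip(csegs[:-1], csegs[1:])
                    if a[1] != b[1] and a[0].end == b[0].start
                ]
                # breakpoints between the terminal markers must be recovered
                inner = [b for b in bks if mids[0] < b < mids[-1]]
                # collapse breakpoint pairs falling between the same markers
                informative = [
                    b for b in inner
                    if sum(1 for x in inner if
                           np.searchsorted(mids, x) == np.searchsorted(mids, b)) % 2 == 1
                ]
                for b in informative:
                    i = int(np.searchsorted(mids, b))
                    half_gap = (mids[i] - mids[i - 1]) / 2
                    assert flips and min(abs(f - b) for f in flips) <= half_gap + 1
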