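"""Region schema, pausing indices, and cross-condition change classes."""

import math

import numpy as np
import pytest

from circarch import classify as clf
from circarch import pausing
from circarch.genomeio import CoverageTrack
from circarch.model import GeneModel, Interval, JunctionCall


def make_gene(strand="+", n_exons=5, exon_len=100, intron_len=200, offset=0):
    exons, pos = [], offset
    for _ in range(n_exons):
        exons.append(Interval("chr1", pos, pos + exon_len, strand))
        pos += exon_len + intron_len
    return GeneModel("g", "g.t", "chr1", strand, exons)


def circ_for(gene, acc, don):
    circ_exons = [gene.exons[i] for i in range(acc, don + 1)]
    start = min(e.start for e in circ_exons)
    end = max(e.end for e in circ_exons)
    j = JunctionCall(gene.chrom, start, end, gene.strand, condition="WT")
    cls = clf.EXONIC_SINGLE if acc == don else clf.EXONIC_MULTI
    return clf.CircRNA(j, cls, gene.gene_id, acc, don)


def uniform_track(gene, depth=10.0, length=5000):
    track = CoverageTrack()
    for strand in "+-":
        arr = np.zeros(length)
        if strand == gene.strand:
            arr[gene.span.start:gene.span.end] = depth
        track.set_array(gene.chrom, strand, arr)
    return track


class TestDefineRegions:
    def test_five_exon_gene_labels(self):
        gene = make_gene()
        schema = pausing.define_regions(circ_for(gene, 1, 3), gene)
        assert schema.regions["E1"] == [gene.exons[0]]
        assert schema.regions["A"] == [gene.exons[1]]
        assert schema.regions["I"] == [gene.exons[2]]
        assert schema.regions["D"] == [gene.exons[3]]
        assert schema.regions["dsE"] == [gene.exons[4]]

    def test_single_exon_circ_empty_internal(self):
        gene = make_gene()
        schema = pausing.define_regions(circ_for(gene, 2, 2), gene)
        assert schema.regions["I"] == []
        assert "single_exon_circ" in schema.flags

    def test_terminal_flags(self):
        gene = make_gene()
        schema = pausing.define_regions(circ_for(gene, 0, 2), gene)
        assert "E1" not in schema.regions and "E1_is_acceptor" in schema.flags
        schema = pausing.define_regions(circ_for(gene, 1, 4), gene)
        assert "dsE" not in schema.regions and "donor_is_last_exon" in schema.flags

    def test_minus_strand_mirror_same_labels(self):
        plus, minus = make_gene("+"), make_gene("-")
        sp = pausing.define_regions(circ_for(plus, 1, 3), plus)
        sm = pausing.define_regions(circ_for(minus, 1, 3), minus)
        for label in ("E1", "A", "I", "D", "dsE"):
            assert [iv.length for iv in sp.regions[label]] == \
                   [iv.length for iv in sm.regions[label]]
        # E1 of the minus-strand gene is the genomic-rightmost exon
        assert sm.regions["E1"][0].start > sm.regions["dsE"][0].start

    def test_intronic_circ_rejected(self):
        gene = make_gene()
        circ = clf.CircRNA(JunctionCall("chr1", 110, 130, "+"), clf.INTRONIC, "g")
        with pytest.raises(ValueError):
            pausing.define_regions(circ, gene)

    def test_labels_non_overlapping_after_clipping(self):
        gene = make_gene(intron_len=150)  # narrower than two 300 bp flanks
        schema = pausing.define_regions(circ_for(gene, 1, 3), gene)
        ivs = [iv for ivs in schema.regions.values() for iv in ivs]
        for i, a in enumerate(ivs):
            for b in ivs[i + 1:]:
                assert not a.overlaps(b), (a, b)


class TestPausingIndex:
    def test_uniform_coverage_gives_exactly_one(self):
        gene = make_gene()
        track = uniform_track(gene, depth=7.0)
        schema = pausing.define_regions(circ_for(gene, 1, 3), gene)
        prof = pausing.gene_profile(track, gene, schema)
        assert all(v == 1.0 for v in prof.values())
        ie = pausing.intron_exon_pausing(gene, track)
        assert ie["exon_index"] == 1.0 and ie["intron_index"] == 1.0

    def test_region_over_body_arithmetic(self):
        track = CoverageTrack()
        arr = np.zeros(100)
        arr[0:100] = 10.0
        arr[20:30] = 30.0
        track.set_array("chr1", "+", arr)
        body = Interval("chr1", 0, 100, "+")
        region = Interval("chr1", 20, 30, "+")
        norm = track.mean(body)
        assert pausing.pausing_index(track, [region], norm) == pytest.approx(30.0 / norm)

    def test_scaling_invariance(self):
        gene = make_gene()
        track = uniform_track(gene, depth=4.0)
        schema = pausing.define_regions(circ_for(gene, 1, 3), gene)
        a = pausing.gene_profile(track, gene, schema)
        b = pausing.gene_profile(track.scaled(13.7), gene, schema)
        for label in a:
            assert a[label] == pytest.approx(b[label])

    def test_zero_body_coverage_excluded(self):
        gene = make_gene()
        track = uniform_track(gene, depth=0.0)
        schema = pausing.define_regions(circ_for(gene, 1, 3), gene)
        assert pausing.gene_profile(track, gene, schema) is None

    def test_exon_only_coverage_zero_intron_index(self):
        gene = make_gene()
        track = CoverageTrack()
        arr = np.zeros(5000)
        for e in gene.exons:
            arr[e.start:e.end] = 10.0
        track.set_array("chr1", "+", arr)
        track.set_array("chr1", "-", np.zeros(5000))
        ie = pausing.intron_exon_pausing(gene, track)
        assert ie["intron_index"] == 0.0 and ie["exon_index"] > 1.0

    def test_intronless_gene_flagged(self):
        gene = make_gene(n_exons=1)
        ie = pausing.intron_exon_pausing(gene, uniform_track(gene))
        assert not ie["intron_defined"] and math.isnan(ie["intron_index"])


class TestMetaprofile:
    def test_identical_genes_zero_sem(self):
        genes = [make_gene(offset=i * 3000) for i in range(4)]
        track = CoverageTrack()
        arr = np.zeros(15000)
        for g in genes:
            arr[g.span.start:g.span.end] = 5.0
        track.set_array("chr1", "+", arr)
        track.set_array("chr1", "-", np.zeros(15000))
        cohort = [(circ_for(g, 1, 3), g) for g in genes]
        prof = pausing.metaprofile(cohort, track)
        assert (prof["sem"] == 0.0).all()
        assert (prof["mean_index"] == 1.0).all()

    def test_mean_matches_brute_force(self, bundle, genes_by_id):
        from circarch.simulate import _truth_circ
        cohort = [(_truth_circ(genes_by_id[gid], rec), genes_by_id[gid])
                  for gid, rec in bundle.truth.host.items()]
        track = bundle.tracks["WT"]
        prof = pausing.metaprofile(cohort, track)
        per_gene = prof.attrs["per_gene"]
        for label in ("A", "D"):
            row = prof[prof.region == label].iloc[0]
            vals = per_gene[label].dropna()
            assert row["mean_index"] == pytest.approx(vals.mean())

    def test_empty_cohort_rejected(self):
        gene = make_gene()
        with pytest.raises(ValueError):
            pausing.metaprofile([], uniform_track(gene))

    def test_planted_cohort_difference_detected(self):
        """Cohorts with planted A multipliers 3 vs 1 differ significantly."""
        rng = np.random.default_rng(4)
        def build(mult, n=60, offset=0):
            genes, cohort = [], []
            track = CoverageTrack()
            arr = np.zeros(3000 * (n + 1))
            for i in range(n):
                g = make_gene(offset=offset + i * 3000)
                g = GeneModel(f"g{i}", f"g{i}.t", g.chrom, g.strand, g.exons)
                a_exon = g.exons[1]
                rate = np.full(g.span.length, 10.0)
                rate[a_exon.start - g.span.start:a_exon.end - g.span.start] *= mult
                arr[g.span.start:g.span.end] = rng.poisson(rate)
                cohort.append((circ_for(g, 1, 3), g))
            track.set_array("chr1", "+", arr)
            track.set_array("chr1", "-", np.zeros_like(arr))
            return cohort, track
        c_hi, t_hi = build(3.0)
        c_lo, t_lo = build(1.0)
        p_hi = pausing.metaprofile(c_hi, t_hi)
        p_lo = pausing.metaprofile(c_lo, t_lo)
        cmp = pausing.compare_profiles(p_hi, p_lo)
        row = cmp[cmp.region == "A"].iloc[0]
        assert row["p"] < 1e-6
        assert row["mean_a"] > 2.0 > row["mean_b"]


class TestDeltaPausing:
    def test_identical_tracks_no_change(self):
        gene = make_gene()
        track = uniform_track(gene)
        schema = pausing.define_regions(circ_for(gene, 1, 3), gene)
        prof = pausing.gene_profile(track, gene, schema)
        delta = pausing.delta_pausing(prof, prof)
        assert (delta["log2_delta"] == 0.0).all()
        assert (delta["change"] == pausing.NO_CHANGE).all()

    def test_classify_change_thresholds(self):
        tau = pausing.DEFAULT_TAU
        assert pausing.classify_change(tau + 0.01) == pausing.INCREASED
        assert pausing.classify_change(-tau - 0.01) == pausing.DECREASED
        assert pausing.classify_change(tau - 0.01) == pausing.NO_CHANGE
        assert pausing.classify_change(-tau + 0.01) == pausing.NO_CHANGE

    def test_planted_dse_ratio_classified_increased(self):
        """A 2x KD/WT multiplier at dsE is called increased for >=95% of genes."""
        rng = np.random.default_rng(8)
        genes = [make_gene(offset=i * 3000) for i in range(80)]
        genes = [GeneModel(f"g{i}", f"g{i}.t", g.chrom, g.strand, g.exons)
                 for i, g in enumerate(genes)]
        L = 3000 * 81
        def track_with(mult):
            arr = np.zeros(L)
            for g in genes:
                rate = np.full(g.span.length, 20.0)
                dse = g.exons[4]
                rate[dse.start - g.span.start:dse.end - g.span.start] *= mult
                arr[g.span.start:g.span.end] = rng.poisson(rate)
            t = CoverageTrack()
            t.set_array("chr1", "+", arr)
            t.set_array("chr1", "-", np.zeros(L))
            return t
        t_wt, t_kd = track_with(1.0), track_with(2.0)
        mean_wt = pausing.track_gene_mean(t_wt, genes)
        mean_kd = pausing.track_gene_mean(t_kd, genes)
        hits = 0
        for g in genes:
            schema = pausing.define_regions(circ_for(g, 1, 3), g)
            p_wt = pausing.gene_profile(t_wt, g, schema, "track", mean_wt)
            p_kd = pausing.gene_profile(t_kd, g, schema, "track", mean_kd)
            delta = pausing.delta_pausing(p_wt, p_kd)
            if delta[delta.region == "dsE"].iloc[0]["change"] == pausing.INCREASED:
                hits += 1
        assert hits / len(genes) >= 0.95
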