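"""G-quadruplex scanning, composition, and enrichment statistics."""

import re

import numpy as np
import pandas as pd
import pytest

from circarch import seqbias
from circarch.model import Interval


def regex_oracle(seq, r=3, l=7, k=4, base="G"):
    """Independent greedy-regex reference for the scanner."""
    loop = {"G": "[ACTN]", "C": "[AGTN]"}[base]
    pat = re.compile(f"{base}{{{r},}}(?:{loop}{{1,{l}}}{base}{{{r},}}){{{k - 1},}}")
    return [(m.start(), m.end()) for m in pat.finditer(seq)]


class TestScanG4:
    def test_canonical_quadruplex(self):
        motifs = seqbias.scan_g4("GGGAGGGTGGGCGGG", both_strands=False)
        assert len(motifs) == 1
        m = motifs[0]
        assert (m.start, m.end, m.strand, m.n_runs) == (0, 15, "+", 4)
        assert m.loop_lengths == (1, 1, 1)

    def test_minus_strand_complement(self):
        motifs = seqbias.scan_g4("CCCACCCTCCCACCC")
        assert len(motifs) == 1
        assert motifs[0].strand == "-"

    def test_n_never_matches_a_run(self):
        assert seqbias.scan_g4("GGNAGGGTGGGCGGGTGGG", both_strands=False) == \
            seqbias.scan_g4("TTTAGGGTGGGCGGGTGGG", both_strands=False)

    def test_long_gap_breaks_motif(self):
        seq = "GGGA" * 3 + "GGG" + "T" * 8 + "GGGAGGGTGGGCGGG"
        motifs = seqbias.scan_g4(seq, both_strands=False)
        assert [(m.start, m.end) for m in motifs] == regex_oracle(seq)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            seqbias.scan_g4("GGG", r=1)
        with pytest.raises(ValueError):
            seqbias.scan_g4("GGG", k=1)

    @pytest.mark.parametrize("gc_weight", [0.25, 0.45])
    def test_equivalent_to_regex_oracle(self, gc_weight):
        """Scanner output equals the greedy-regex oracle, both strands."""
        rng = np.random.default_rng(17)
        p = np.array([(1 - 2 * gc_weight) / 2, gc_weight, gc_weight, (1 - 2 * gc_weight) / 2])
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), p=p, size=500))
            mine_p = [(m.start, m.end) for m in seqbias.scan_g4(seq) if m.strand == "+"]
            mine_m = [(m.start, m.end) for m in seqbias.scan_g4(seq) if m.strand == "-"]
            assert mine_p == regex_oracle(seq, base="G")
            assert mine_m == regex_oracle(seq, base="C")

    def test_strand_duality_under_reverse_complement(self):
        """Motifs on the reverse complement appear at mirrored coordinates."""
        rng = np.random.default_rng(3)
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), p=[0.15, 0.35, 0.35, 0.15], size=400))
            rc = seq.translate(comp)[::-1]
            fwd = {(m.start, m.end, m.strand) for m in seqbias.scan_g4(seq)}
            flip = {"+": "-", "-": "+"}
            mirrored = {(len(seq) - e, len(seq) - s, flip[st])
                        for s, e, st in ((m.start, m.end, m.strand)
                                         for m in seqbias.scan_g4(rc))}
            assert fwd == mirrored


class TestG4Density:
    def test_arithmetic(self):
        regions = [Interval("c", 0, 10_000)]
        assert seqbias.g4_density([object()] * 5, regions) == 0.5
        assert seqbias.g4_density([], regions) == 0.0

    def test_zero_length_region_set_rejected(self):
        with pytest.raises(ValueError):
            seqbias.g4_density([], [])

    def test_planted_density_recovered(self, bundle, genes_by_id, small_config):
        """Flank-intron G4 density ~= configured motifs/kb (Poisson CI)."""
        flanks = []
        for gid, rec in bundle.truth.host.items():
            gene = genes_by_id[gid]
            flanks.append(gene.introns[rec["acceptor_exon_index"] - 1])
            flanks.append(gene.introns[rec["donor_exon_index"]])
        planted = [r for r in bundle.truth.g4 if r["region"] == "flank_intron"]
        dens = seqbias.g4_density(planted, flanks)
        kb = sum(iv.length for iv in flanks) / 1000
        expect = small_config.g4_density_per_kb
        assert abs(dens - expect) < 3 * np.sqrt(expect / kb) + 1 / kb


class TestComposition:
    def test_extreme_gc(self):
        assert seqbias.composition("GGCC").iloc[0]["GC"] == 1.0
        assert seqbias.composition("ATAT").iloc[0]["GC"] == 0.0

    def test_fractions_sum_to_one_and_match_tally(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGTN"), p=[0.3, 0.2, 0.2, 0.2, 0.1], size=2200))
        df = seqbias.composition(seq, window=500)
        for row in df.itertuples():
            sub = seq[row.start:row.end]
            denom = sum(sub.count(b) for b in "ACGT")
            for b in "ACGT":
                assert getattr(row, b) == pytest.approx(sub.count(b) / denom)
            assert row.A + row.C + row.G + row.T == pytest.approx(1.0, abs=1e-9)
            assert row.GC == pytest.approx(row.G + row.C)
        assert df.iloc[-1]["clipped"]

    def test_all_n_window_flagged(self):
        df = seqbias.composition("N" * 10, window=10)
        assert not df.iloc[0]["defined"]


class TestRepeatEnrichment:
    def _repeats(self):
        rows = [("c", 0, 100, "Sat"), ("c", 500, 650, "Sat"), ("c", 900, 1000, "LINE")]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    def test_background_vs_itself_fold_one(self):
        introns = [Interval("c", 0, 400), Interval("c", 450, 1000)]
        df = seqbias.repeat_enrichment(introns, introns, self._repeats(), n_boot=10, seed=0)
        assert df["fold"].tolist() == pytest.approx([1.0] * len(df))

    def test_overlap_bp_matches_brute_force(self):
        """Interval intersection equals a per-base counting oracle."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            targets = [Interval("c", int(s), int(s) + int(l))
                       for s, l in zip(rng.integers(0, 900, 8), rng.integers(1, 120, 8))]
            feats = [Interval("c", int(s), int(s) + int(l))
                     for s, l in zip(rng.integers(0, 900, 8), rng.integers(1, 120, 8))]
            fast = seqbias.interval_overlap_bp(targets, feats)
            covered = np.zeros(1200, dtype=bool)
            for f in feats:
                covered[f.start:f.end] = True
            slow = sum(int(covered[t.start:t.end].sum()) for t in targets)
            assert fast == slow

    def test_absent_class_flagged_not_infinite(self):
        target = [Interval("c", 0, 100)]
        bg = [Interval("c", 2000, 3000)]
        df = seqbias.repeat_enrichment(target, bg, self._repeats(), n_boot=0, seed=0)
        sat = df[df.repeat_class == "Sat"].iloc[0]
        assert not sat["fold_defined"] and np.isnan(sat["fold"])

    def test_planted_flank_enrichment_recovered(self, bundle, genes_by_id, small_config):
        """Satellite bp-fraction fold in flanks ~= planted 3x within the CI."""
        flanks, background = [], []
        for gene in bundle.genes:
            rec = bundle.truth.host.get(gene.gene_id)
            flank_idx = ({rec["acceptor_exon_index"] - 1, rec["donor_exon_index"]}
                         if rec else set())
            for i, iv in enumerate(gene.introns):
                (flanks if i in flank_idx else background).append(iv)
        df = seqbias.repeat_enrichment(flanks, background, bundle.repeats,
                                       n_boot=300, seed=1)
        sat = df[df.repeat_class == "Satellite"].iloc[0]
        planted = small_config.repeat_flank_fold["Satellite"]
        assert sat["ci_low"] < planted < sat["ci_high"] or \
            abs(sat["fold"] - planted) / planted < 0.25


class TestMotifEnrichment:
    def test_planted_motif_symmetric(self):
        rng = np.random.default_rng(2)
        def rand(n):
            return "".join(rng.choice(list("ACGT"), size=n))
        motif = "ACTAAC"
        flank = {"upstream": [], "downstream": []}
        for side in flank:
            for _ in range(20):
                seq = rand(400) + motif + rand(50) + motif + rand(400)
                flank[side].append(seq)
        bg = [rand(2000) for _ in range(30)]
        res = seqbias.motif_enrichment({"m1": motif, "m2": "TTTTTTTT"}, flank, bg)
        m1 = res[res.motif_id == "m1"].iloc[0]
        assert m1["symmetric"] and m1["q_upstream"] < 0.05 and m1["q_downstream"] < 0.05

    def test_absent_motif_not_symmetric(self):
        flank = {"upstream": ["ACGT" * 100], "downstream": ["ACGT" * 100]}
        res = seqbias.motif_enrichment({"m": "AAAAAAAA"}, flank, ["ACGT" * 200])
        row = res.iloc[0]
        assert row["count_upstream"] == 0 and row["p_upstream"] == 1.0
        assert not row["symmetric"]

    def test_motif_longer_than_region(self):
        flank = {"upstream": ["ACG"], "downstream": ["ACG"]}
        res = seqbias.motif_enrichment({"m": "ACGTACGT"}, flank, ["ACGT" * 50])
        assert res.iloc[0]["count_upstream"] == 0

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError):
            seqbias.iupac_regex("ACX")
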