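"""Probe-count normalization, differential expression, and C:L classes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circarch import nanostring as ns


def toy_matrix(values=None):
    """Two genes (circ+linear) and two housekeeping probes, 2x3 samples."""
    rows = []
    base = {"gA_circ": 100, "gA_linear": 200, "gB_circ": 50, "gB_linear": 400,
            "hk1": 800, "hk2": 600}
    for pid, mean in base.items():
        gene = pid.split("_")[0] if "_" in pid else pid
        ptype = pid.split("_")[1] if "_" in pid else ns.HOUSEKEEPING
        row = {"probe_id": pid, "gene_id": gene, "probe_type": ptype}
        for cond in ("WT", "KD"):
            for rep in (1, 2, 3):
                row[f"{cond}_{rep}"] = (values or {}).get((pid, cond, rep), mean)
        rows.append(row)
    return ns.ProbeCountMatrix(pd.DataFrame(rows))


class TestNormalize:
    def test_identical_samples_unchanged(self):
        mat = toy_matrix()
        norm = ns.normalize(mat)
        pd.testing.assert_frame_equal(
            norm.df[norm.samples].astype(float), mat.df[mat.samples].astype(float))

    def test_doubled_sample_scaled_back(self):
        values = {}
        for pid in ("gA_circ", "gA_linear", "gB_circ", "gB_linear", "hk1", "hk2"):
            base = {"gA_circ": 100, "gA_linear": 200, "gB_circ": 50,
                    "gB_linear": 400, "hk1": 800, "hk2": 600}[pid]
            values[(pid, "KD", 1)] = base * 2
        mat = toy_matrix(values)
        norm = ns.normalize(mat)
        # housekeeping geometric means equalized across samples
        hk = norm.housekeeping()[norm.samples].to_numpy(dtype=float)
        geo = np.exp(np.log(hk).mean(axis=0))
        assert geo == pytest.approx([geo[0]] * len(geo))
        # the doubled sample is scaled down by 1/2 x (grand-mean shift 2^(1/6))
        expected = 200 * 2 ** (1 / 6) / 2
        assert norm.df.loc[norm.df.probe_id == "gA_circ", "KD_1"].iloc[0] == \
            pytest.approx(expected)

    def test_zero_housekeeping_dropped_with_warning(self):
        mat = toy_matrix({("hk1", "KD", 2): 0})
        with pytest.warns(UserWarning, match="dropped"):
            norm = ns.normalize(mat)
        assert norm is not None

    def test_all_zero_housekeeping_rejected(self):
        values = {(f"hk{h}", c, r): 0 for h in (1, 2) for c in ("WT", "KD")
                  for r in (1, 2, 3)}
        mat = toy_matrix(values)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="housekeeping"):
                ns.normalize(mat)

    def test_missing_housekeeping_rejected(self):
        mat = toy_matrix()
        mat = ns.ProbeCountMatrix(mat.df[mat.df.probe_type != ns.HOUSEKEEPING])
        with pytest.raises(ValueError):
            ns.normalize(mat)


class TestLog2FC:
    def test_identical_conditions_zero_lfc_p_one(self):
        changes = ns.log2fc(toy_matrix(), "KD", ref="WT")
        assert changes["log2fc"].tolist() == pytest.approx([0.0] * len(changes))
        assert (changes["p"] == 1.0).all()

    def test_planted_fourfold_effect(self):
        values = {("gA_circ", "KD", r): int(400 * m)
                  for r, m in ((1, 0.95), (2, 1.0), (3, 1.05))}
        changes = ns.log2fc(toy_matrix(values), "KD", ref="WT")
        row = changes[changes.probe_id == "gA_circ"].iloc[0]
        assert row["log2fc"] == pytest.approx(2.0, abs=0.05)
        assert row["p"] < 0.01

    def test_welch_and_bh_match_hand_computation(self):
        """t and BH q on a toy matrix equal textbook formulas."""
        values = {("gA_circ", "KD", r): v for r, v in ((1, 210), (2, 240), (3, 270))}
        values.update({("gB_circ", "KD", r): v for r, v in ((1, 55), (2, 60), (3, 45))})
        mat = toy_matrix(values)
        changes = ns.log2fc(mat, "KD", ref="WT")
        a = np.log2(np.array([210, 240, 270]) + 0.5)
        b = np.log2(np.array([100, 100, 100]) + 0.5)
        t_hand = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        df_hand = (a.var(ddof=1) / 3 + b.var(ddof=1) / 3) ** 2 / (
            (a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2)
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        row = changes[changes.probe_id == "gA_circ"].iloc[0]
        assert row["p"] == pytest.approx(p_hand)
        # BH: q_i = min_{j>=i} p_(j) * m / j over sorted p-values
        ps = changes["p"].to_numpy()
        order = np.argsort(ps)
        m = len(ps)
        q_sorted = ps[order] * m / (np.arange(m) + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        q_hand = np.empty(m)
        q_hand[order] = np.minimum(q_sorted, 1.0)
        assert changes["q"].to_numpy() == pytest.approx(q_hand)

    def test_single_replicate_flagged(self):
        mat = toy_matrix()
        keep = [c for c in mat.df.columns if c != "KD_2" and c != "KD_3"]
        single = ns.ProbeCountMatrix(mat.df[keep])
        changes = ns.log2fc(single, "KD", ref="WT")
        assert not changes["p_defined"].any()
        assert changes["p"].isna().all()

    def test_scale_invariance(self):
        """Multiplying every count by a constant changes nothing downstream."""
        mat = toy_matrix({("gA_circ", "KD", r): v for r, v in ((1, 390), (2, 400), (3, 410))})
        scaled = ns.ProbeCountMatrix(mat.df.copy())
        scaled.df[scaled.samples] = scaled.df[scaled.samples] * 10
        a = ns.log2fc(ns.normalize(mat), "KD")
        b = ns.log2fc(ns.normalize(scaled), "KD")
        assert a["log2fc"].to_numpy() == pytest.approx(b["log2fc"].to_numpy(), abs=0.01)
        cla = ns.cl_ratio_classes(a)
        clb = ns.cl_ratio_classes(b)
        assert cla["cl_class"].tolist() == clb["cl_class"].tolist()


class TestClassifyExpression:
    def test_no_signal_zero_percent(self):
        res = ns.classify_expression(ns.log2fc(toy_matrix(), "KD"))
        assert res["pct_altered"] == 0 and res["altered_genes"] == set()

    def test_gene_altered_if_either_probe_altered(self):
        values = {("gA_linear", "KD", r): int(2000 * m)
                  for r, m in ((1, 0.95), (2, 1.0), (3, 1.05))}
        res = ns.classify_expression(ns.log2fc(toy_matrix(values), "KD"))
        assert res["altered_genes"] == {"gA"}
        assert res["pct_altered"] == 50


class TestCLRatio:
    def test_equal_changes_no_change(self):
        values = {}
        for pid in ("gA_circ", "gA_linear"):
            base = 100 if pid == "gA_circ" else 200
            for r, m in ((1, 0.95), (2, 1.0), (3, 1.05)):
                values[(pid, "KD", r)] = int(base * 8 * m)
        cl = ns.cl_ratio_classes(ns.log2fc(toy_matrix(values), "KD"))
        row = cl[cl.gene_id == "gA"].iloc[0]
        assert abs(row["delta_cl"]) < 0.1 and row["cl_class"] == ns.NO_CHANGE

    def test_circ_only_increase(self):
        values = {("gA_circ", "KD", r): int(800 * m)
                  for r, m in ((1, 0.95), (2, 1.0), (3, 1.05))}
        cl = ns.cl_ratio_classes(ns.log2fc(toy_matrix(values), "KD"))
        assert cl[cl.gene_id == "gA"].iloc[0]["cl_class"] == ns.INCREASED

    def test_classes_partition_genes(self):
        cl = ns.cl_ratio_classes(ns.log2fc(toy_matrix(), "KD"))
        pct = ns.cl_class_percentages(cl)
        assert len(cl) == 2
        assert cl["cl_class"].isin([ns.INCREASED, ns.DECREASED, ns.NO_CHANGE]).all()
        assert sum(pct.values()) == 100


class TestCrosstab:
    def test_margins_and_association(self):
        cl = pd.DataFrame({"gene_id": [f"g{i}" for i in range(40)],
                           "delta_cl": 0.0,
                           "cl_class": ["increased"] * 20 + ["decreased"] * 20})
        concordant = pd.DataFrame({"gene_id": [f"g{i}" for i in range(40)],
                                   "exon_change": ["increased"] * 20 + ["decreased"] * 20})
        res = ns.crosstab(cl, concordant)
        assert res["table"].to_numpy().sum() == 40
        assert res["table"].sum(axis=1).tolist() == [20, 20]
        assert res["p"] < 1e-6
        rng = np.random.default_rng(0)
        independent = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(40)],
            "exon_change": rng.permutation(["increased"] * 20 + ["decreased"] * 20)})
        res2 = ns.crosstab(cl, independent)
        assert res2["p"] > res["p"]

    def test_empty_intersection_rejected(self):
        cl = pd.DataFrame({"gene_id": ["a"], "delta_cl": [0.0], "cl_class": ["increased"]})
        pc = pd.DataFrame({"gene_id": ["b"], "exon_change": ["increased"]})
        with pytest.raises(ValueError):
            ns.crosstab(cl, pc)

    def test_fisher_p_uniform_under_null(self):
        """Independent binary labels give roughly uniform Fisher p-values."""
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(200):
            n = 60
            cl = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                               "delta_cl": 0.0,
                               "cl_class": rng.choice(["increased", "decreased"], n)})
            pc = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                               "exon_change": rng.choice(["increased", "decreased"], n)})
            try:
                ps.append(ns.crosstab(cl, pc)["p"])
            except ValueError:
                continue
        ps = np.array(ps)
        # Fisher p is discrete and conservative; check no excess of small p
        assert (ps < 0.05).mean() <= 0.07
        assert ps.mean() > 0.3
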