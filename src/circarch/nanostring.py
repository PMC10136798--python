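"""Circular-to-linear output analysis from digital probe counts.

Emulates an nCounter-style workflow: per-gene circular-junction and
linear-junction probes counted across condition x replicate samples,
normalized by housekeeping geometric means, tested for differential
expression against a reference condition, and summarized as
circular-to-linear (C:L) ratio change classes. The C:L change of a gene
is Delta_CL = log2FC(circ) - log2FC(linear).
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CIRC = "circ"
LINEAR = "linear"
HOUSEKEEPING = "housekeeping"
INCREASED = "increased"
DECREASED = "decreased"
NO_CHANGE = "no_change"

META_COLUMNS = ["probe_id", "gene_id", "probe_type"]
_SAMPLE_RE = re.compile(r"^(?P<condition>.+)_(?P<rep>\d+)$")


class ProbeCountMatrix:
    """Probe x sample count table.

    Wraps a DataFrame with metadata columns (probe_id, gene_id,
    probe_type in {circ, linear, housekeeping}) and one column per sample
    named ``<condition>_<rep>``.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        missing = set(META_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"probe table missing columns {sorted(missing)}")
        self.df = df.reset_index(drop=True)
        samples = [c for c in df.columns if c not in META_COLUMNS]
        bad = [c for c in samples if not _SAMPLE_RE.match(c)]
        if bad:
            raise ValueError(f"sample columns must be '<condition>_<rep>': {bad}")
        if (self.df[samples].to_numpy(dtype=float) < 0).any():
            raise ValueError("counts must be >= 0")
        self.samples = samples

    @property
    def conditions(self) -> list[str]:
        return sorted({_SAMPLE_RE.match(c)["condition"] for c in self.samples})

    def sample_columns(self, condition: str) -> list[str]:
        cols = [c for c in self.samples if _SAMPLE_RE.match(c)["condition"] == condition]
        if not cols:
            raise ValueError(f"condition {condition!r} not present")
        return cols

    def housekeeping(self) -> pd.DataFrame:
        return self.df[self.df["probe_type"] == HOUSEKEEPING]

    def copy(self) -> "ProbeCountMatrix":
        return ProbeCountMatrix(self.df.copy())

    @classmethod
    def from_tsv(cls, path: str) -> "ProbeCountMatrix":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def normalize(matrix: ProbeCountMatrix) -> ProbeCountMatrix:
    """Housekeeping geometric-mean scaling.

    Per-sample factor = (grand geometric mean of housekeeping counts) /
    (sample geometric mean of housekeeping counts); all counts in the
    sample are multiplied by the factor. Housekeeping probes with a zero
    count in any sample are dropped from factor computation with a
    warning.
    """
    hk = matrix.housekeeping()
    if hk.empty:
        raise ValueError("normalization requires at least one housekeeping probe")
    counts = hk[matrix.samples].to_numpy(dtype=float)
    keep = (counts > 0).all(axis=1)
    if not keep.all():
        dropped = hk.loc[~keep, "probe_id"].tolist()
        warnings.warn(f"housekeeping probes with zero counts dropped from factors: {dropped}")
    counts = counts[keep]
    if counts.size == 0:
        raise ValueError("all housekeeping probes have zero counts; cannot normalize")
    sample_geo = np.exp(np.log(counts).mean(axis=0))
    grand_geo = np.exp(np.log(counts).mean())
    factors = grand_geo / sample_geo
    out = matrix.copy()
    out.df[matrix.samples] = out.df[matrix.samples].to_numpy(dtype=float) * factors
    return out


def log2fc(matrix: ProbeCountMatrix, condition: str, ref: str = "WT",
           pseudo: float = 0.5) -> pd.DataFrame:
    """Per-probe log2 fold change and Welch p vs the reference condition.

    log2FC = log2(mean_cond + c) - log2(mean_ref + c); p from a
    two-sample Welch t on log2(count + c) replicate values, BH-corrected
    across probes. With fewer than 2 replicates on either side the p is
    NaN and flagged.
    """
    cond_cols = matrix.sample_columns(condition)
    ref_cols = matrix.sample_columns(ref)
    df = matrix.df
    cond_counts = df[cond_cols].to_numpy(dtype=float)
    ref_counts = df[ref_cols].to_numpy(dtype=float)
    lfc = np.log2(cond_counts.mean(axis=1) + pseudo) - np.log2(ref_counts.mean(axis=1) + pseudo)
    out = df[META_COLUMNS].copy()
    out["condition"] = condition
    out["log2fc"] = lfc
    if len(cond_cols) >= 2 and len(ref_cols) >= 2:
        with warnings.catch_warnings():
            # near-constant replicate vectors trip scipy's precision-loss
            # warning; the resulting p of 1 (or NaN, mapped below) is what
            # "no evidence of change" should yield
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(np.log2(cond_counts + pseudo), np.log2(ref_counts + pseudo),
                                  axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        # identical replicate vectors: no evidence of change
        p = np.where(np.isnan(p), 1.0, p)
        out["p"] = p
        out["p_defined"] = True
    else:
        out["p"] = np.nan
        out["p_defined"] = False
    mask = out["p"].notna()
    out["q"] = np.nan
    if mask.any():
        out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


def classify_expression(changes: pd.DataFrame, alpha: float = 0.05,
                        lfc_threshold: float = 2.0, use_q: bool = False) -> dict:
    """Flag altered probes and genes.

    A probe is altered when |log2FC| > threshold and its p (q with
    ``use_q``) is below alpha; a gene is altered when either of its
    probes is. Returns the flagged table, the altered gene set, and the
    percentage over profiled genes (rounded to integer).
    """
    work = changes[changes["probe_type"] != HOUSEKEEPING].copy()
    stat = work["q"] if use_q else work["p"]
    work["altered"] = (work["log2fc"].abs() > lfc_threshold) & (stat < alpha)
    genes = sorted(work["gene_id"].unique())
    altered_genes = sorted(work.loc[work["altered"], "gene_id"].unique())
    pct = round(100.0 * len(altered_genes) / len(genes)) if genes else 0
    return {
        "table": work,
        "altered_genes": set(altered_genes),
        "n_genes": len(genes),
        "n_altered": len(altered_genes),
        "pct_altered": pct,
    }


def cl_ratio_classes(changes: pd.DataFrame, delta: float = 1.0,
                     alpha: float = 0.05, use_q: bool = False) -> pd.DataFrame:
    """Per-gene C:L ratio change class.

    increased: Delta_CL > delta with a significant circular change;
    decreased: Delta_CL < -delta with a significant circular change;
    otherwise no_change. Genes missing either probe are excluded.
    """
    rows = []
    stat_col = "q" if use_q else "p"
    for gene, grp in changes[changes["probe_type"] != HOUSEKEEPING].groupby("gene_id"):
        by_type = {t: g for t, g in grp.groupby("probe_type")}
        if CIRC not in by_type or LINEAR not in by_type:
            continue
        circ = by_type[CIRC].iloc[0]
        lin = by_type[LINEAR].iloc[0]
        if not np.isfinite(circ["log2fc"]) or not np.isfinite(lin["log2fc"]):
            continue
        d_cl = circ["log2fc"] - lin["log2fc"]
        circ_sig = bool(circ[stat_col] < alpha) if np.isfinite(circ[stat_col]) else False
        if d_cl > delta and circ_sig:
            cls = INCREASED
        elif d_cl < -delta and circ_sig:
            cls = DECREASED
        else:
            cls = NO_CHANGE
        rows.append({"gene_id": gene, "delta_cl": d_cl, "cl_class": cls})
    return pd.DataFrame(rows, columns=["gene_id", "delta_cl", "cl_class"])


def cl_class_percentages(cl_table: pd.DataFrame) -> dict[str, int]:
    n = len(cl_table)
    out = {}
    for label in (INCREASED, DECREASED, NO_CHANGE):
        cnt = int((cl_table["cl_class"] == label).sum())
        out[label] = round(100.0 * cnt / n) if n else 0
    return out


def crosstab(cl_classes: pd.DataFrame, pausing_classes: pd.DataFrame,
             pausing_col: str = "exon_change") -> dict:
    """Cross-tabulate C:L classes with pausing-change classes.

    Returns the contingency table, row percentages, and an association p:
    Fisher's exact test for 2x2 tables, chi-squared otherwise.
    """
    merged = cl_classes.merge(pausing_classes, on="gene_id", how="inner")
    merged = merged[merged[pausing_col] != ""]
    if merged.empty:
        raise ValueError("no shared genes between C:L and pausing classifications")
    table = pd.crosstab(merged["cl_class"], merged[pausing_col])
    row_pct = table.div(table.sum(axis=1), axis=0) * 100.0
    arr = table.to_numpy()
    if arr.shape == (2, 2):
        p = float(stats.fisher_exact(arr)[1])
    elif min(arr.shape) < 2:
        p = np.nan
    else:
        p = float(stats.chi2_contingency(arr)[1])
    return {"table": table, "row_percentages": row_pct, "p": p, "n": len(merged)}
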