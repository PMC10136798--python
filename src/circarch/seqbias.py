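"""Sequence bias in circRNA flanking introns.

G-quadruplex scanning and density, nucleotide composition in fixed
windows, repeat-class bp-fraction enrichment with bootstrap CIs, and a
symmetric RBP-motif occurrence test.

G4 definition ("R4" default): k >= 4 runs of r >= 3 guanines separated by
loops of 1..l (default 7) non-G bases. Restricting loops to non-G bases
makes the decomposition into runs and loops unique, so the left-greedy,
maximal, non-overlapping scan is deterministic and bit-reproducible.
Minus-strand motifs are the C-run mirror pattern on the reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import Interval

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[GC]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class G4Motif:
    chrom: str
    start: int
    end: int
    strand: str
    n_runs: int
    run_lengths: tuple[int, ...]
    loop_lengths: tuple[int, ...]


def _scan_runs(sequence: str, base: str, r: int, l: int, k: int):
    """Left-greedy maximal chains of >= k base-runs (>= r) with gaps 1..l.

    Chains walk consecutive maximal base-runs; a run shorter than r or a
    gap longer than l breaks the chain (loops cannot contain the run
    base, so short runs can never be absorbed into a loop).
    """
    all_runs = [(m.start(), m.end()) for m in re.finditer(f"{base}+", sequence)]
    motifs = []
    i, n = 0, len(all_runs)
    while i < n:
        s, e = all_runs[i]
        if e - s < r:
            i += 1
            continue
        chain = [(s, e)]
        j = i
        while j + 1 < n:
            ns, ne = all_runs[j + 1]
            if ne - ns >= r and 1 <= ns - all_runs[j][1] <= l:
                chain.append((ns, ne))
                j += 1
            else:
                break
        if len(chain) >= k:
            motifs.append(chain)
            i = j + 1
        else:
            i += 1
    return motifs


def scan_g4(sequence: str, chrom: str = "", r: int = 3, l: int = 7, k: int = 4,
            both_strands: bool = True, offset: int = 0) -> list[G4Motif]:
    """Maximal non-overlapping G-quadruplex motifs, left-greedy per strand.

    ``offset`` shifts reported coordinates (useful when scanning a slice).
    N never matches a run; loops are non-G (plus strand) / non-C (minus).
    """
    if r < 2 or k < 2:
        raise ValueError("G4 parameters require r >= 2 and k >= 2")
    if l < 1:
        raise ValueError("G4 loop length must be >= 1")
    seq = sequence.upper()
    out = []
    strands = [("G", "+")] + ([("C", "-")] if both_strands else [])
    for base, strand in strands:
        for chain in _scan_runs(seq, base, r, l, k):
            starts = [s for s, _ in chain]
            ends = [e for _, e in chain]
            out.append(
                G4Motif(
                    chrom=chrom,
                    start=chain[0][0] + offset,
                    end=chain[-1][1] + offset,
                    strand=strand,
                    n_runs=len(chain),
                    run_lengths=tuple(e - s for s, e in chain),
                    loop_lengths=tuple(s2 - e1 for e1, s2 in zip(ends[:-1], starts[1:])),
                )
            )
    return sorted(out, key=lambda m: (m.start, m.strand))


def scan_g4_regions(sequences: dict[str, str], regions: Iterable[Interval],
                    r: int = 3, l: int = 7, k: int = 4) -> list[G4Motif]:
    motifs = []
    for iv in regions:
        sub = sequences[iv.chrom][iv.start:iv.end]
        motifs.extend(scan_g4(sub, chrom=iv.chrom, r=r, l=l, k=k, offset=iv.start))
    return motifs


def g4_density(motifs: Sequence, regions: Sequence[Interval]) -> float:
    """Motifs per kb over the pooled region length."""
    total_bp = sum(iv.length for iv in regions)
    if total_bp == 0:
        raise ValueError("g4_density needs a region set of nonzero length")
    return len(motifs) / (total_bp / 1000.0)


# ---------------------------------------------------------------------------
# Composition


def composition(sequence: str, window: int = 500) -> pd.DataFrame:
    """Per-window A/C/G/T fractions and GC; Ns excluded from denominators.

    The final window is clipped at the sequence end (``clipped`` column).
    An all-N window is flagged ``defined=False``.
    """
    seq = sequence.upper()
    rows = []
    for w_start in range(0, max(len(seq), 1), window):
        sub = seq[w_start : w_start + window]
        if not sub:
            break
        counts = {b: sub.count(b) for b in "ACGT"}
        denom = sum(counts.values())
        row = {
            "start": w_start,
            "end": w_start + len(sub),
            "clipped": len(sub) < window,
            "defined": denom > 0,
        }
        for b in "ACGT":
            row[b] = counts[b] / denom if denom else np.nan
        row["GC"] = (counts["G"] + counts["C"]) / denom if denom else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def region_gc(sequences: dict[str, str], regions: Iterable[Interval],
              window: int = 500) -> pd.DataFrame:
    """Windowed composition over each region, clipped at region boundaries."""
    frames = []
    for iv in regions:
        df = composition(sequences[iv.chrom][iv.start:iv.end], window=window)
        df.insert(0, "chrom", iv.chrom)
        df["start"] += iv.start
        df["end"] += iv.start
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Repeat enrichment


def interval_overlap_bp(targets: Sequence[Interval], features: Sequence[Interval]) -> int:
    """Total bp of ``targets`` covered by the union of ``features``."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        acc = []
        for s, e in ivs:
            if acc and s <= acc[-1][1]:
                acc[-1] = (acc[-1][0], max(acc[-1][1], e))
            else:
                acc.append((s, e))
        merged[chrom] = acc
    total = 0
    for t in targets:
        for s, e in merged.get(t.chrom, []):
            if s >= t.end:
                break
            total += max(0, min(e, t.end) - max(s, t.start))
    return total


def _class_fraction(introns: Sequence[Interval], class_features: Sequence[Interval]) -> float:
    total = sum(iv.length for iv in introns)
    if total == 0:
        return np.nan
    return interval_overlap_bp(introns, class_features) / total


def repeat_enrichment(target_introns: Sequence[Interval],
                      background_introns: Sequence[Interval],
                      repeats: pd.DataFrame,
                      n_boot: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """Per-class bp-fraction enrichment of target vs background introns.

    ``repeats`` is a BED6 frame with the class in ``name``. Fold is the
    ratio of covered-bp fractions; the 95% CI comes from bootstrap
    resampling of target introns (background held fixed). A class absent
    from the background yields an undefined (NaN) fold, flagged.
    """
    rng = np.random.default_rng(seed)
    rows = []
    classes = sorted(repeats["name"].unique())
    target_introns = list(target_introns)
    for cls in classes:
        feats = [Interval(r.chrom, int(r.start), int(r.end))
                 for r in repeats[repeats["name"] == cls].itertuples()]
        t_frac = _class_fraction(target_introns, feats)
        b_frac = _class_fraction(background_introns, feats)
        defined = bool(b_frac and np.isfinite(b_frac) and b_frac > 0)
        fold = t_frac / b_frac if defined else np.nan
        lo = hi = np.nan
        if defined and target_introns and n_boot > 0:
            idx = np.arange(len(target_introns))
            boots = np.empty(n_boot)
            for b in range(n_boot):
                sample = [target_introns[i] for i in rng.choice(idx, size=len(idx))]
                boots[b] = _class_fraction(sample, feats) / b_frac
            lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(
            {
                "repeat_class": cls,
                "target_fraction": t_frac,
                "background_fraction": b_frac,
                "fold": fold,
                "fold_defined": defined,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def repeat_enrichment_by_side(flanks: dict[str, Sequence[Interval]],
                              background_introns: Sequence[Interval],
                              repeats: pd.DataFrame,
                              n_boot: int = 1000,
                              seed: int = 0) -> pd.DataFrame:
    """Run :func:`repeat_enrichment` separately per flank side."""
    frames = []
    for side, introns in flanks.items():
        df = repeat_enrichment(introns, background_introns, repeats, n_boot=n_boot, seed=seed)
        df.insert(0, "side", side)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Motif enrichment (symmetric RBP motifs)


def iupac_regex(pattern: str) -> re.Pattern:
    try:
        return re.compile("".join(IUPAC[c] for c in pattern.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in motif {pattern!r}") from exc


def count_motif(sequences: Iterable[str], pattern: re.Pattern) -> int:
    """Occurrences across sequences (overlapping matches counted)."""
    total = 0
    for seq in sequences:
        pos = 0
        while True:
            m = pattern.search(seq, pos)
            if m is None:
                break
            total += 1
            pos = m.start() + 1
    return total


def motif_enrichment(motifs: dict[str, str],
                     flank_seqs: dict[str, list[str]],
                     background_seqs: list[str],
                     alpha: float = 0.05) -> pd.DataFrame:
    """Binomial occurrence test per motif and flank side, BH-corrected.

    ``flank_seqs`` maps side ('upstream'/'downstream') to sequence lists.
    A motif is *symmetric* when significant (q < alpha) in both flanks.
    The background rate is occurrences per bp over ``background_seqs``.
    """
    bg_bp = sum(len(s) for s in background_seqs)
    if bg_bp == 0:
        raise ValueError("motif_enrichment needs non-empty background sequence")
    rows = []
    for motif_id, pat_str in motifs.items():
        pat = iupac_regex(pat_str)
        bg_rate = count_motif(background_seqs, pat) / bg_bp
        rec = {"motif_id": motif_id, "pattern": pat_str, "background_rate": bg_rate}
        for side, seqs in flank_seqs.items():
            n_bp = sum(len(s) for s in seqs)
            count = count_motif(seqs, pat)
            if n_bp == 0 or bg_rate == 0:
                p = 1.0 if count == 0 else 0.0
            else:
                p = float(stats.binomtest(count, n_bp, min(bg_rate, 1.0),
                                          alternative="greater").pvalue)
            rec[f"count_{side}"] = count
            rec[f"p_{side}"] = p
        rows.append(rec)
    df = pd.DataFrame(rows)
    sides = list(flank_seqs)
    sig = np.ones(len(df), dtype=bool)
    for side in sides:
        df[f"q_{side}"] = multipletests(df[f"p_{side}"], method="fdr_bh")[1]
        sig &= df[f"q_{side}"].to_numpy() < alpha
    df["symmetric"] = sig
    return df
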