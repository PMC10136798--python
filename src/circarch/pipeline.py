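"""End-to-end orchestration: classify -> architecture -> seqbias ->
pausing -> output-ratio, from one config, with a JSON report.

The run config (YAML or dict) names the input files, the condition
labels with a designated reference, per-stage parameter overrides, a
seed, and an output directory. Stage outputs are TSVs; the report
collects counts, means, percentages, and p-values, plus the config
itself for provenance.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd
import yaml

from . import architecture, classify as clf, genomeio, nanostring, pausing, seqbias
from .model import CircArchError
from .simulate import GroundTruth

log = logging.getLogger("circarch")

STAGES = ("classify", "architecture", "seqbias", "pausing", "output_ratio")


class PipelineError(CircArchError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    cfg.setdefault("reference", "WT")
    cfg.setdefault("seed", 0)
    cfg.setdefault("params", {})
    for key in ("gtf", "outdir"):
        if key not in cfg:
            raise CircArchError(f"run config missing required key {key!r}")
    for key, path in cfg.items():
        if key in ("gtf", "fasta", "junctions", "repeats", "counts") and not os.path.exists(path):
            raise CircArchError(f"config input {key}={path!r} does not exist")
    return cfg


def _write(df: pd.DataFrame, outdir: str, name: str) -> str:
    path = os.path.join(outdir, name)
    df.to_csv(path, sep="\t", index=False)
    return path


def run_all(config) -> dict:
    """Execute every configured stage; returns the report dict."""
    cfg = load_config(config)
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    report: dict = {"config": {k: v for k, v in cfg.items() if k != "params" or v},
                    "stages": {}}
    state: dict = {}
    for stage in STAGES:
        runner = globals()[f"_stage_{stage}"]
        try:
            result = runner(cfg, state, outdir)
        except Exception as exc:
            # retain whatever was produced so far, clearly marked partial
            partial = os.path.join(outdir, "report.partial.json")
            with open(partial, "w") as fh:
                json.dump(report, fh, indent=1, sort_keys=True, default=_jsonable)
            if isinstance(exc, CircArchError):
                raise
            raise PipelineError(stage, str(exc)) from exc
        if result is not None:
            report["stages"][stage] = result
            log.info("stage %s done", stage)
        else:
            log.info("stage %s skipped (inputs not configured)", stage)
    report_path = os.path.join(outdir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_jsonable)
    report["report_path"] = report_path
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage_classify(cfg, state, outdir):
    if "junctions" not in cfg:
        raise PipelineError("classify", "no junction table configured")
    genes = genomeio.read_gtf(cfg["gtf"])
    junctions = genomeio.read_junctions(cfg["junctions"])
    tol = int(cfg["params"].get("tolerance", 0))
    circs = clf.classify_all(junctions, genes, tol=tol)
    state["genes"] = genes
    state["genes_by_id"] = {g.gene_id: g for g in genes}
    state["circs"] = circs
    table = clf.circs_to_table(circs)
    _write(table, outdir, "classified.tsv")
    by_class = table["circ_class"].value_counts().to_dict()
    per_condition = {}
    for cond in sorted({c.condition for c in circs}):
        ids = {c.identity for c in circs if c.condition == cond}
        per_condition[cond] = len(ids)
    sets = {cond: [c.identity for c in circs if c.condition == cond]
            for cond in per_condition}
    overlap = clf.overlap_summary(clf.condition_overlap(sets)) if 2 <= len(sets) <= 3 else {}
    return {
        "n_junctions": len(circs),
        "n_unique_junctions": len({c.identity for c in circs}),
        "by_class": by_class,
        "per_condition": per_condition,
        "overlap": overlap,
        "n_host_genes": len({c.host_gene_id for c in circs if c.host_gene_id}),
    }


def _stage_architecture(cfg, state, outdir):
    circs = state["circs"]
    genes_by_id = state["genes_by_id"]
    records = architecture.build_records(circs, genes_by_id)
    host_ids = set(records["host_gene_id"])
    background = [g for g in state["genes"] if g.gene_id not in host_ids]
    state["records"] = records
    state["background_genes"] = background
    flat = records.copy()
    flat["internal_intron_lengths"] = flat["internal_intron_lengths"].map(
        lambda xs: ",".join(map(str, xs)))
    flat["circ_exon_lengths"] = flat["circ_exon_lengths"].map(
        lambda xs: ",".join(map(str, xs)))
    _write(flat, outdir, "architecture.tsv")
    summary = architecture.summarize(records, background)
    _write(summary, outdir, "architecture_summary.tsv")
    out = {"summary": summary.to_dict(orient="records"), "asymmetry": {}}
    for cond, grp in records.groupby("condition"):
        try:
            out["asymmetry"][cond] = architecture.asymmetry(grp)
        except ValueError:
            out["asymmetry"][cond] = None
    return out


def _stage_seqbias(cfg, state, outdir):
    if "fasta" not in cfg:
        return None
    sequences = genomeio.read_fasta(cfg["fasta"])
    records = state["records"]
    genes_by_id = state["genes_by_id"]
    circs = [c for c in state["circs"] if c.is_exonic and c.host_gene_id in genes_by_id]
    flanks = {"upstream": [], "downstream": []}
    for c in circs:
        up, dn = architecture.flanking_introns(c, genes_by_id[c.host_gene_id])
        if up:
            flanks["upstream"].append(up)
        if dn:
            flanks["downstream"].append(dn)
    background_introns = [iv for g in state["background_genes"] for iv in g.introns]
    out: dict = {}
    flank_all = flanks["upstream"] + flanks["downstream"]
    if flank_all:
        g4_host = seqbias.scan_g4_regions(sequences, flank_all)
        out["g4_density_flanks_per_kb"] = seqbias.g4_density(g4_host, flank_all)
    if background_introns:
        g4_bg = seqbias.scan_g4_regions(sequences, background_introns)
        out["g4_density_background_per_kb"] = seqbias.g4_density(g4_bg, background_introns)
    if "repeats" in cfg and flank_all and background_introns:
        repeats = genomeio.read_bed(cfg["repeats"])
        enr = seqbias.repeat_enrichment_by_side(
            flanks, background_introns, repeats,
            n_boot=int(cfg["params"].get("n_boot", 200)), seed=int(cfg["seed"]))
        _write(enr, outdir, "repeat_enrichment.tsv")
        out["repeat_enrichment"] = enr.to_dict(orient="records")
    if "motifs" in cfg and flank_all and background_introns:
        motif_df = pd.read_csv(cfg["motifs"], sep="\t", names=["motif_id", "pattern"])
        motifs = dict(zip(motif_df["motif_id"], motif_df["pattern"]))
        flank_seqs = {side: [sequences[iv.chrom][iv.start:iv.end] for iv in ivs]
                      for side, ivs in flanks.items()}
        bg_seqs = [sequences[iv.chrom][iv.start:iv.end] for iv in background_introns]
        enr = seqbias.motif_enrichment(motifs, flank_seqs, bg_seqs)
        _write(enr, outdir, "motif_enrichment.tsv")
        out["n_symmetric_motifs"] = int(enr["symmetric"].sum())
    gc = seqbias.region_gc(sequences, flank_all) if flank_all else pd.DataFrame()
    if not gc.empty:
        _write(gc, outdir, "flank_gc.tsv")
        out["flank_gc_mean"] = float(gc.loc[gc["defined"], "GC"].mean())
    return out


def _coverage_tracks(cfg):
    tracks = {}
    for cond, pair in cfg.get("coverage", {}).items():
        plus, minus = pair
        for p in (plus, minus):
            if not os.path.exists(p):
                raise PipelineError("pausing", f"coverage input {p!r} missing")
        tracks[cond] = genomeio.read_bedgraph_pair(plus, minus)
    return tracks


def _stage_pausing(cfg, state, outdir):
    if "coverage" not in cfg:
        return None
    tracks = _coverage_tracks(cfg)
    ref = cfg["reference"]
    if ref not in tracks:
        raise PipelineError("pausing", f"reference condition {ref!r} has no coverage")
    genes_by_id = state["genes_by_id"]
    cohort = [(c, genes_by_id[c.host_gene_id]) for c in state["circs"]
              if c.is_exonic and c.host_gene_id in genes_by_id]
    # one schema per distinct host gene (first circRNA wins) keeps the
    # metaprofile gene-weighted rather than junction-weighted
    seen = set()
    cohort = [x for x in cohort if not (x[1].gene_id in seen or seen.add(x[1].gene_id))]
    if not cohort:
        raise PipelineError("pausing", "no exonic circRNAs with host genes")
    out: dict = {"metaprofiles": {}, "delta_classes": {}}
    profiles = {}
    for cond, track in tracks.items():
        prof = pausing.metaprofile(cohort, track)
        profiles[cond] = prof
        _write(prof, outdir, f"pausing_profile_{cond}.tsv")
        out["metaprofiles"][cond] = prof.drop(columns=[]).to_dict(orient="records")
    host_genes = [g for _, g in cohort]
    for cond, track in tracks.items():
        if cond == ref:
            continue
        classes = pausing.intron_exon_delta_classes(
            host_genes, tracks[ref], track, state["genes"],
            tau=float(cfg["params"].get("tau", pausing.DEFAULT_TAU)))
        _write(classes, outdir, f"pausing_delta_{cond}.tsv")
        state.setdefault("pausing_classes", {})[cond] = classes
        out["delta_classes"][cond] = {
            "exon": pausing.class_percentages(classes["exon_change"]),
            "intron": pausing.class_percentages(classes["intron_change"]),
        }
    return out


def _stage_output_ratio(cfg, state, outdir):
    if "counts" not in cfg:
        return None
    matrix = nanostring.ProbeCountMatrix.from_tsv(cfg["counts"])
    ref = cfg["reference"]
    norm = nanostring.normalize(matrix)
    alpha = float(cfg["params"].get("alpha", 0.05))
    lfc_thr = float(cfg["params"].get("lfc_threshold", 2.0))
    delta = float(cfg["params"].get("delta_cl", 1.0))
    out = {}
    for cond in norm.conditions:
        if cond == ref:
            continue
        changes = nanostring.log2fc(norm, cond, ref=ref)
        _write(changes, outdir, f"expression_{cond}.tsv")
        flags = nanostring.classify_expression(changes, alpha=alpha, lfc_threshold=lfc_thr)
        cl = nanostring.cl_ratio_classes(changes, delta=delta, alpha=alpha)
        _write(cl, outdir, f"cl_ratio_{cond}.tsv")
        entry = {
            "n_genes": flags["n_genes"],
            "n_altered": flags["n_altered"],
            "pct_altered": flags["pct_altered"],
            "cl_percentages": nanostring.cl_class_percentages(cl),
        }
        p_classes = state.get("pausing_classes", {}).get(cond)
        if p_classes is not None and not cl.empty:
            try:
                xt = nanostring.crosstab(cl, p_classes)
                entry["pausing_crosstab_p"] = xt["p"]
                entry["pausing_crosstab"] = {
                    str(k): v for k, v in xt["table"].to_dict(orient="index").items()
                }
            except ValueError:
                pass
        out[cond] = entry
    return out


def report_validate(report: dict, truth: GroundTruth | str) -> pd.DataFrame:
    """Planted vs recovered parameters with z-scores.

    Compares the planted flanking-intron lengths in the ground truth with
    the architecture-stage means; |z| < 2 indicates recovery within the
    cohort's sampling error.
    """
    if isinstance(truth, str):
        truth = GroundTruth.from_json(truth)
    rows = []
    if not truth.host:
        return pd.DataFrame(columns=["parameter", "planted", "recovered", "sem", "z"])
    summary = report.get("stages", {}).get("architecture", {}).get("summary", [])
    planted_up = float(np.mean([h["flank_up_length"] for h in truth.host.values()]))
    planted_dn = float(np.mean([h["flank_down_length"] for h in truth.host.values()]))
    for length_class, planted in (("upstream_intron", planted_up),
                                  ("downstream_intron", planted_dn)):
        recs = [r for r in summary if r["length_class"] == length_class and r["n"] > 1]
        if not recs:
            continue
        n = sum(r["n"] for r in recs)
        mean = sum(r["mean"] * r["n"] for r in recs) / n
        sem = float(np.sqrt(sum((r["sem"] * r["n"]) ** 2 for r in recs)) / n)
        z = (mean - planted) / sem if sem > 0 else np.nan
        rows.append({"parameter": length_class, "planted": planted,
                     "recovered": mean, "sem": sem, "z": z})
    return pd.DataFrame(rows, columns=["parameter", "planted", "recovered", "sem", "z"])
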