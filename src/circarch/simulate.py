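"""Synthetic genome, junction, coverage, and probe-count generator.

Emits a miniature annotated genome with two gene populations — circRNA
host genes carrying long (optionally asymmetric) flanking introns around
a planted backsplice, and background genes with typical intron/exon
lengths — plus planted repeats and G-quadruplexes in flanking introns,
per-region RNAPII pause multipliers with Poisson read noise, and
negative-binomial probe counts with planted condition effects. Every
planted parameter is recorded in a ground-truth sidecar so estimators
can be checked for recovery. A fixed seed determines every emitted byte.

Lengths are drawn lognormal, parameterized by the arithmetic mean and a
log-scale dispersion; intron-length distributions are heavy-tailed and
the mean is the quantity the downstream summaries estimate.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import genomeio
from .classify import CircRNA, EXONIC_MULTI, EXONIC_SINGLE, INTRONIC
from .genomeio import CoverageTrack
from .model import ConfigError, GeneModel, Interval, JunctionCall
from .nanostring import CIRC, HOUSEKEEPING, LINEAR, ProbeCountMatrix
from .pausing import CORE_LABELS, define_regions

PAUSE_LABELS = set(CORE_LABELS) | {"flank", "body"}
BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions."""

    n_host_genes: int = 60
    n_background_genes: int = 240
    exons_per_gene: tuple[int, int] = (4, 9)
    background_intron_mean: float = 1832.0
    background_exon_mean: float = 292.0
    host_flank_up_mean: float = 9131.0
    host_flank_down_mean: float = 9355.0
    length_distribution: str = "lognormal"
    dispersion: float = 0.6  # log-scale sd of length draws
    intergenic_mean: float = 2000.0
    min_exon: int = 50
    min_intron: int = 60
    n_chromosomes: int = 1
    # sequence features (planted in host flanking introns / background introns)
    repeat_class_densities: dict = field(
        default_factory=lambda: {"Satellite": 0.02, "LINE": 0.02, "LTR": 0.01,
                                 "Simple_repeat": 0.05}
    )
    repeat_flank_fold: dict = field(
        default_factory=lambda: {"Satellite": 3.0, "LINE": 2.0, "LTR": 2.0,
                                 "Simple_repeat": 0.5}
    )
    g4_density_per_kb: float = 0.2      # host flanking introns
    g4_background_per_kb: float = 0.5   # background introns
    # coverage
    pause_multipliers: dict = field(
        default_factory=lambda: {
            "WT": {"E1": 3.0, "A": 3.0, "I": 1.5, "D": 1.5, "dsE": 1.0,
                   "flank": 1.0, "body": 1.0},
            "KD": {"E1": 1.0, "A": 1.0, "I": 1.5, "D": 1.5, "dsE": 3.0,
                   "flank": 1.0, "body": 1.0},
        }
    )
    coverage_depth: float = 20.0
    # probe counts
    n_probe_genes: int = 26
    n_housekeeping: int = 5
    nb_mean: float = 500.0
    nb_dispersion: float = 0.1
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("WT", "PARPi", "KD")
    reference: str = "WT"
    condition_logfc: dict = field(default_factory=dict)  # (gene, probe_type, cond) -> lfc
    intronic_junction_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        positive = [
            ("background_intron_mean", self.background_intron_mean),
            ("background_exon_mean", self.background_exon_mean),
            ("host_flank_up_mean", self.host_flank_up_mean),
            ("host_flank_down_mean", self.host_flank_down_mean),
            ("intergenic_mean", self.intergenic_mean),
            ("nb_mean", self.nb_mean),
        ]
        for name, val in positive:
            if val <= 0:
                raise ConfigError(f"{name} must be > 0, got {val}")
        if self.coverage_depth < 0:
            raise ConfigError("coverage_depth must be >= 0")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.length_distribution != "lognormal":
            raise ConfigError(f"unsupported length distribution {self.length_distribution!r}")
        lo, hi = self.exons_per_gene
        if lo < 1 or hi < lo:
            raise ConfigError(f"invalid exons_per_gene range {self.exons_per_gene}")
        if self.n_host_genes > 0 and lo < 4:
            raise ConfigError("host genes need at least 4 exons (exons_per_gene min >= 4)")
        for cls, frac in self.repeat_class_densities.items():
            if not 0 <= frac <= 1:
                raise ConfigError(f"repeat density for {cls} must be in [0,1]")
            fold = self.repeat_flank_fold.get(cls, 1.0)
            if frac * fold > 0.6:
                raise ConfigError(f"repeat class {cls}: flank density {frac * fold:.2f} too high")
        if self.g4_density_per_kb < 0 or self.g4_background_per_kb < 0:
            raise ConfigError("G4 densities must be >= 0")
        if self.reference not in self.conditions:
            raise ConfigError(f"reference condition {self.reference!r} not in conditions")
        for cond, mults in self.pause_multipliers.items():
            missing = PAUSE_LABELS - set(mults)
            if missing:
                raise ConfigError(f"pause_multipliers[{cond!r}] missing labels {sorted(missing)}")
            if any(m < 0 for m in mults.values()):
                raise ConfigError("pause multipliers must be >= 0")
        if self.background_exon_mean >= self.background_intron_mean * (self.exons_per_gene[1] + 1) * 100:
            raise ConfigError("exon mean incompatible with gene budget")


@dataclass
class GroundTruth:
    """Sidecar recording every planted parameter."""

    host: dict = field(default_factory=dict)       # gene -> planted circ + flank lengths
    junction_classes: dict = field(default_factory=dict)  # "chrom:start-end:strand" -> class
    g4: list = field(default_factory=list)         # planted G4 intervals
    repeats: list = field(default_factory=list)    # planted repeat intervals
    pause_multipliers: dict = field(default_factory=dict)
    probe_effects: dict = field(default_factory=dict)  # cond -> gene -> probe_type -> lfc

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        expected = {f.name for f in dataclasses.fields(cls)}
        if not isinstance(data, dict) or not set(data) <= expected:
            raise ConfigError(f"{path}: not a ground-truth file")
        return cls(**data)


def _lognormal(rng: np.random.Generator, mean: float, sigma: float, minimum: int,
               size: int) -> np.ndarray:
    mu = np.log(mean) - sigma**2 / 2.0
    draws = rng.lognormal(mu, sigma, size=size)
    return np.maximum(np.rint(draws).astype(int), minimum)


# ---------------------------------------------------------------------------
# Genome


def simulate_genome(config: SimConfig,
                    rng: Optional[np.random.Generator] = None
                    ) -> tuple[list[GeneModel], dict[str, str], GroundTruth,
                               list[JunctionCall]]:
    """Build annotation, sequence, planted junction calls, and ground truth."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    sigma = config.dispersion
    lo, hi = config.exons_per_gene
    n_total = config.n_host_genes + config.n_background_genes
    chrom_names = [f"chrS{i + 1}" for i in range(config.n_chromosomes)]
    truth = GroundTruth()
    truth.pause_multipliers = {c: dict(m) for c, m in config.pause_multipliers.items()}

    genes: list[GeneModel] = []
    junctions: list[JunctionCall] = []
    cursors = {c: 0 for c in chrom_names}
    cond_cycle = list(config.conditions)

    for gi in range(n_total):
        is_host = gi < config.n_host_genes
        gene_id = f"host{gi + 1:04d}" if is_host else f"bg{gi - config.n_host_genes + 1:04d}"
        chrom = chrom_names[gi % config.n_chromosomes]
        n_ex = int(rng.integers(lo, hi + 1))
        exon_lens = _lognormal(rng, config.background_exon_mean, sigma, config.min_exon, n_ex)
        intron_lens = _lognormal(rng, config.background_intron_mean, sigma,
                                 config.min_intron, max(n_ex - 1, 0))
        host_rec = None
        if is_host:
            acc = int(rng.integers(1, n_ex - 2))          # not the first exon
            don = int(rng.integers(acc, n_ex - 1))        # not the last exon
            intron_lens[acc - 1] = _lognormal(rng, config.host_flank_up_mean, sigma,
                                              config.min_intron, 1)[0]
            intron_lens[don] = _lognormal(rng, config.host_flank_down_mean, sigma,
                                          config.min_intron, 1)[0]
            host_rec = {"acceptor_exon_index": acc, "donor_exon_index": don,
                        "flank_up_length": int(intron_lens[acc - 1]),
                        "flank_down_length": int(intron_lens[don])}
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(_lognormal(rng, config.intergenic_mean, sigma, 100, 1)[0])
        start = cursors[chrom] + gap

        # transcript-orientation element lengths -> genomic layout
        elements = []
        for i in range(n_ex):
            elements.append(("exon", i, int(exon_lens[i])))
            if i < n_ex - 1:
                elements.append(("intron", i, int(intron_lens[i])))
        if strand == "-":
            elements = elements[::-1]
        pos = start
        exon_ivs: dict[int, Interval] = {}
        for kind, idx, length in elements:
            if kind == "exon":
                exon_ivs[idx] = Interval(chrom, pos, pos + length, strand)
            pos += length
        cursors[chrom] = pos
        gene = GeneModel(gene_id=gene_id, transcript_id=f"{gene_id}.t1", chrom=chrom,
                         strand=strand, exons=[exon_ivs[i] for i in range(n_ex)])
        genes.append(gene)

        if is_host:
            acc, don = host_rec["acceptor_exon_index"], host_rec["donor_exon_index"]
            circ_exons = [gene.exons[i] for i in range(acc, don + 1)]
            j_start = min(e.start for e in circ_exons)
            j_end = max(e.end for e in circ_exons)
            condition = cond_cycle[gi % len(cond_cycle)]
            host_rec["condition"] = condition
            host_rec["circ_class"] = EXONIC_SINGLE if acc == don else EXONIC_MULTI
            host_rec["junction"] = [chrom, j_start, j_end, strand]
            truth.host[gene_id] = host_rec
            jc = JunctionCall(chrom, j_start, j_end, strand, condition=condition,
                             gene_hint=gene_id)
            junctions.append(jc)
            truth.junction_classes[f"{chrom}:{j_start}-{j_end}:{strand}"] = host_rec["circ_class"]
            if rng.random() < config.intronic_junction_rate:
                # an intronic (lariat-derived) junction strictly inside a
                # non-flank intron, when one is long enough
                candidates = [i for i in range(n_ex - 1)
                              if i not in (acc - 1, don) and intron_lens[i] >= 40]
                if candidates:
                    idx = int(rng.choice(candidates))
                    intron = gene.introns[idx]
                    margin = 5
                    s = int(rng.integers(intron.start + margin, intron.end - margin - 20))
                    e = int(rng.integers(s + 10, intron.end - margin))
                    ji = JunctionCall(chrom, s, e, strand, condition=condition,
                                     gene_hint=gene_id)
                    junctions.append(ji)
                    truth.junction_classes[f"{chrom}:{s}-{e}:{strand}"] = INTRONIC

    sequences = {}
    for chrom in chrom_names:
        length = cursors[chrom] + 500
        seq = BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        sequences[chrom] = seq
    return genes, sequences, truth, junctions


# ---------------------------------------------------------------------------
# Sequence features


def _place_nonoverlapping(rng: np.random.Generator, region_len: int,
                          lengths: list[int], min_gap: int) -> list[int]:
    """Random non-overlapping offsets for elements of given lengths."""
    n = len(lengths)
    occupied = sum(lengths) + (n + 1) * min_gap
    free = region_len - occupied
    if free < 0:
        raise ConfigError("feature density too high for region length")
    extra = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1))) if n >= 0 else []
    offsets = []
    pos = 0
    for i, ln in enumerate(lengths):
        pos += min_gap + int(extra[i])
        offsets.append(pos)
        pos += ln
    return offsets


def _make_g4(rng: np.random.Generator, r: int = 3, k: int = 4, l: int = 7) -> str:
    parts = ["G" * r]
    for _ in range(k - 1):
        loop_len = int(rng.integers(1, l + 1))
        loop = "".join(rng.choice(list("ACT"), size=loop_len))
        parts.append(loop + "G" * r)
    return "".join(parts)


def _scrub_g(seq_arr: np.ndarray, rng: np.random.Generator, start: int, end: int) -> None:
    """Replace Gs in [start, end) so no G-run can chain across."""
    for i in range(max(start, 0), min(end, len(seq_arr))):
        if seq_arr[i] == b"G":
            seq_arr[i] = np.frombuffer(b"ACT", dtype="S1")[rng.integers(0, 3)]


def plant_sequence_features(sequences: dict[str, str], genes: list[GeneModel],
                            truth: GroundTruth, config: SimConfig,
                            rng: Optional[np.random.Generator] = None
                            ) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant G4 motifs and repeat intervals in introns.

    G4 motifs are written into the sequence with non-G buffer zones so a
    scanner recovers them at exactly the recorded coordinates; repeats
    are annotation intervals (BED) at the configured bp fractions, with
    host flanking introns enriched by the configured fold. Nothing
    crosses an exon boundary.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 1)
    arrs = {c: np.frombuffer(s.encode("ascii"), dtype="S1").copy() for c, s in sequences.items()}
    repeat_rows = []
    clear = 8  # loop limit + 1: no foreign G-run can chain into a planted motif

    for gene in genes:
        host_rec = truth.host.get(gene.gene_id)
        introns = gene.introns
        flank_idx = set()
        if host_rec:
            flank_idx = {host_rec["acceptor_exon_index"] - 1, host_rec["donor_exon_index"]}
        for i, intron in enumerate(introns):
            is_flank = i in flank_idx
            region = "flank_intron" if is_flank else "intron"
            dens = config.g4_density_per_kb if is_flank else config.g4_background_per_kb
            n_motifs = int(round(dens * intron.length / 1000.0))
            if n_motifs > 0:
                motifs = [_make_g4(rng) for _ in range(n_motifs)]
                offsets = _place_nonoverlapping(rng, intron.length,
                                                [len(m) for m in motifs], clear)
                arr = arrs[intron.chrom]
                for m, off in zip(motifs, offsets):
                    s = intron.start + off
                    e = s + len(m)
                    arr[s:e] = np.frombuffer(m.encode("ascii"), dtype="S1")
                    _scrub_g(arr, rng, max(s - clear, intron.start), s)
                    _scrub_g(arr, rng, e, min(e + clear, intron.end))
                    truth.g4.append({"chrom": intron.chrom, "start": int(s), "end": int(e),
                                     "strand": "+", "gene_id": gene.gene_id,
                                     "region": region})
            for cls, base_frac in sorted(config.repeat_class_densities.items()):
                frac = base_frac * (config.repeat_flank_fold.get(cls, 1.0) if is_flank else 1.0)
                target_bp = int(round(frac * intron.length))
                if target_bp < 1:
                    continue
                # exact per-intron bp budget keeps the realized class
                # fraction unbiased even in short introns
                lengths = []
                remaining = target_bp
                while remaining > 0:
                    ln = int(min(remaining, rng.integers(100, 301)))
                    lengths.append(ln)
                    remaining -= ln
                offsets = _place_nonoverlapping(rng, intron.length, lengths, 1)
                for ln, off in zip(lengths, offsets):
                    s, e = intron.start + off, intron.start + off + ln
                    repeat_rows.append({"chrom": intron.chrom, "start": s, "end": e,
                                        "name": cls, "score": 0, "strand": "."})
                    truth.repeats.append({"chrom": intron.chrom, "start": int(s),
                                          "end": int(e), "class": cls,
                                          "gene_id": gene.gene_id, "region": region})

    out_seqs = {c: a.tobytes().decode("ascii") for c, a in arrs.items()}
    repeats = pd.DataFrame(repeat_rows,
                           columns=["chrom", "start", "end", "name", "score", "strand"])
    return out_seqs, repeats


# ---------------------------------------------------------------------------
# Coverage


def _truth_circ(gene: GeneModel, host_rec: dict) -> CircRNA:
    chrom, s, e, strand = host_rec["junction"]
    acc, don = host_rec["acceptor_exon_index"], host_rec["donor_exon_index"]
    return CircRNA(
        JunctionCall(chrom, s, e, strand, condition=host_rec["condition"]),
        host_rec["circ_class"], gene.gene_id, acc, don,
        list(gene.exons[acc + 1 : don]), list(gene.introns[acc:don]),
    )


def simulate_coverage(genes: list[GeneModel], truth: GroundTruth, config: SimConfig,
                      rng: Optional[np.random.Generator] = None,
                      chrom_lengths: Optional[dict[str, int]] = None
                      ) -> dict[str, CoverageTrack]:
    """Per-condition strand-resolved Poisson coverage.

    Per-base rate = depth x region multiplier; the region schema of each
    host gene's planted circRNA sets E1/A/I/D/dsE and flank multipliers,
    everything else in a gene body uses the 'body' multiplier, and bases
    outside genes are zero.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 2)
    if chrom_lengths is None:
        chrom_lengths = {}
        for g in genes:
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.span.end + 500)
    tracks: dict[str, CoverageTrack] = {}
    for condition in config.pause_multipliers:
        mults = config.pause_multipliers[condition]
        arrays = {(c, s): np.zeros(L) for c in chrom_lengths for s in "+-"
                  for L in [chrom_lengths[c]]}
        for gene in genes:
            span = gene.span
            rate = np.full(span.length, mults["body"], dtype=float)
            host_rec = truth.host.get(gene.gene_id)
            if host_rec:
                schema = define_regions(_truth_circ(gene, host_rec), gene)
                # flanks first, then cores with A last: for single-exon
                # circles (A and D share one exon) the acceptor wins
                ordered = [lab for lab in schema.regions if lab not in CORE_LABELS]
                ordered += [lab for lab in ("dsE", "I", "D", "E1", "A") if lab in schema.regions]
                effective = {}
                for label in ordered:
                    mult = mults[label] if label in CORE_LABELS else mults["flank"]
                    for iv in schema.regions[label]:
                        rate[iv.start - span.start : iv.end - span.start] = mult
                    if label in CORE_LABELS and schema.regions[label]:
                        effective[label] = mult
                if host_rec["circ_class"] == EXONIC_SINGLE:
                    effective["D"] = effective["A"]
                host_rec.setdefault("effective_multipliers", {})[condition] = effective
            counts = rng.poisson(config.coverage_depth * rate)
            arrays[(gene.chrom, gene.strand)][span.start:span.end] = counts
        track = CoverageTrack()
        for (chrom, strand), arr in arrays.items():
            track.set_array(chrom, strand, arr)
        tracks[condition] = track
    return tracks


# ---------------------------------------------------------------------------
# Probe counts


def simulate_counts(config: SimConfig, rng: Optional[np.random.Generator] = None,
                    gene_ids: Optional[list[str]] = None,
                    truth: Optional[GroundTruth] = None) -> ProbeCountMatrix:
    """Negative-binomial probe counts with planted condition effects.

    Counts ~ NB(mean = nb_mean * 2^effect, var = m + disp * m^2); with
    dispersion 0 the counts equal the (rounded) means exactly.
    Housekeeping probes never carry effects.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 3)
    if gene_ids is None:
        gene_ids = [f"nsg{i + 1:02d}" for i in range(config.n_probe_genes)]
    rows = []
    effects_used: dict = {}
    probes = [(g, t) for g in gene_ids for t in (CIRC, LINEAR)]
    probes += [(f"hk{i + 1}", HOUSEKEEPING) for i in range(config.n_housekeeping)]
    for gene, ptype in probes:
        row = {"probe_id": f"{gene}_{ptype}", "gene_id": gene, "probe_type": ptype}
        for cond in config.conditions:
            eff = 0.0
            if ptype != HOUSEKEEPING and cond != config.reference:
                eff = float(config.condition_logfc.get((gene, ptype, cond), 0.0))
                effects_used.setdefault(cond, {}).setdefault(gene, {})[ptype] = eff
            mean = config.nb_mean * 2.0**eff
            for rep in range(1, config.n_replicates + 1):
                if config.nb_dispersion == 0:
                    count = int(round(mean))
                else:
                    n_param = 1.0 / config.nb_dispersion
                    p_param = n_param / (n_param + mean)
                    count = int(rng.negative_binomial(n_param, p_param))
                row[f"{cond}_{rep}"] = count
        rows.append(row)
    if truth is not None:
        truth.probe_effects = effects_used
    return ProbeCountMatrix(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class SimBundle:
    genes: list[GeneModel]
    sequences: dict[str, str]
    junctions: list[JunctionCall]
    repeats: pd.DataFrame
    tracks: dict[str, CoverageTrack]
    counts: ProbeCountMatrix
    truth: GroundTruth
    paths: dict = field(default_factory=dict)


def simulate_bundle(config: SimConfig, outdir: Optional[str] = None) -> SimBundle:
    """Run the full generator; optionally write every file to ``outdir``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, sequences, truth, junctions = simulate_genome(config, rng)
    sequences, repeats = plant_sequence_features(sequences, genes, truth, config, rng)
    tracks = simulate_coverage(genes, truth, config, rng)
    probe_genes = [g.gene_id for g in genes[: config.n_probe_genes]
                   if g.gene_id in truth.host] or None
    counts = simulate_counts(config, rng, gene_ids=probe_genes, truth=truth)
    bundle = SimBundle(genes, sequences, junctions, repeats, tracks, counts, truth)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        p = bundle.paths
        p["gtf"] = os.path.join(outdir, "annotation.gtf")
        genomeio.write_gtf(genes, p["gtf"])
        p["fasta"] = os.path.join(outdir, "genome.fa")
        genomeio.write_fasta(sequences, p["fasta"])
        p["junctions"] = os.path.join(outdir, "junctions.tsv")
        genomeio.write_junctions(junctions, p["junctions"])
        p["repeats"] = os.path.join(outdir, "repeats.bed")
        genomeio.write_bed(repeats, p["repeats"])
        for cond, track in tracks.items():
            prefix = os.path.join(outdir, f"coverage_{cond}")
            plus, minus = genomeio.write_bedgraph_pair(track, prefix)
            p[f"coverage_{cond}"] = (plus, minus)
        p["counts"] = os.path.join(outdir, "probe_counts.tsv")
        counts.to_tsv(p["counts"])
        p["truth"] = os.path.join(outdir, "ground_truth.json")
        truth.to_json(p["truth"])
    return bundle
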