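"""End-to-end demo pipeline: simulate -> entropy -> overlap -> targets ->
nucleosomes -> differential occupancy -> spacing -> report.

Stages communicate through files in the output directory, so every stage is
also reachable from the CLI on externally supplied inputs. Reruns with the
same seed and config are byte-identical on all numeric tables; a resolved
config and a manifest with output hashes are written alongside the results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .entropy import TwoTierModel, entropy_by_cluster, two_tier_entropy
from .genomic_io import (
    GenomicInterval,
    GeneModel,
    Peak,
    read_bedgraph,
    read_counts,
    read_fasta,
    read_gene_models,
    read_narrowpeak,
    write_bedgraph,
    write_counts,
    write_fasta,
    write_gene_models,
    write_narrowpeak,
)
from .nucleosome import (
    call_nucleosomes,
    classify_peaks,
    differential_occupancy,
    metaprofile_point,
    metaprofile_scaled,
    shared_unique_signal,
)
from .peak_targets import (
    annotate_peaks_to_genes,
    assign_targets,
    marker_stats,
    motif_fraction_at_summits,
    permutation_overlap_test,
)
from .simulate import (
    SimulationDesign,
    genome_to_strings,
    make_genome,
    plant_peaks,
    simulate_chip_signal,
    simulate_counts,
    simulate_occupancy,
)
from .spacing import classify_spacing, localize_sites, pairwise_spacing, spacing_ks

log = logging.getLogger("chromfate")

STAGES = [
    "simulate",
    "entropy",
    "overlap",
    "targets",
    "nucleosome",
    "diffocc",
    "spacing",
    "report",
]


@dataclass
class RunConfig:
    """All pipeline thresholds and paths; defaults follow the study rules
    (25% expressing, log2FC 0.223, 3-kb annotation cutoff, 100-bp motif
    window at summits, 50-bp PWM localisation window)."""

    out_dir: str = "chromfate_run"
    seed: int = 0
    min_pct: float = 0.25
    min_log2fc: float = 0.223
    annotate_distance: int = 3000
    motif_window: int = 100
    site_window: int = 50
    motif_tail_prob: float = 0.001
    n_perm: int = 1000
    alpha: float = 0.01
    entropy_base: float | None = None
    smoothing_bandwidth: float = 30.0
    min_prominence: float = 5.0
    classify_window: int = 73
    diff_region_halfwidth: int = 150
    flank: int = 1000
    n_bins: int = 100
    n_occ_peaks: int = 100
    make_figures: bool = True
    design: SimulationDesign = field(default_factory=SimulationDesign)

    def __post_init__(self):
        if isinstance(self.design, dict):
            unknown = set(self.design) - {
                f.name for f in dataclasses.fields(SimulationDesign)
            }
            if unknown:
                raise ValueError(f"unknown design keys: {sorted(unknown)}")
            self.design = SimulationDesign(**self.design)
        self.design.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = self.as_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _table_header(cfg: RunConfig) -> str:
    return (
        f"# chromfate {__version__} config_hash={cfg.config_hash()} "
        f"seed={cfg.seed}\n"
    )


def write_table(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_table_header(cfg))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class Workspace:
    """Paths inside one pipeline run directory."""

    def __init__(self, out_dir):
        self.root = Path(out_dir)
        self.data = self.root / "data"
        self.tables = self.root / "tables"
        self.figures = self.root / "figures"
        for d in (self.data, self.tables, self.figures):
            d.mkdir(parents=True, exist_ok=True)


# ---------------------------------------------------------------------------
# stage outputs (relative to the run directory), used for --resume


def stage_outputs(cfg: RunConfig) -> dict[str, list[str]]:
    out = {
        "simulate": [
            "data/genome.fa",
            "data/peaks_A.narrowPeak",
            "data/peaks_B.narrowPeak",
            "data/occ_peaks.narrowPeak",
            "data/genes.gff3",
            "data/occupancy_mock.bedgraph",
            "data/occupancy_induced.bedgraph",
            "data/chip_A.bedgraph",
            "data/counts.mtx",
            "data/counts_genes.tsv",
            "data/counts_cells.tsv",
            "tables/truth_peaks.tsv",
            "tables/truth_nucleosomes.tsv",
            "tables/truth_occ_peaks.tsv",
            "tables/truth_clusters.tsv",
            "tables/truth_markers.tsv",
        ],
        "entropy": [
            "tables/entropy_cells.tsv",
            "tables/entropy_clusters.tsv",
            "tables/entropy_curves.tsv",
        ],
        "overlap": ["tables/overlap.json", "tables/motif_fraction.tsv"],
        "targets": ["tables/marker_stats.tsv", "tables/targets.tsv"],
        "nucleosome": [
            "tables/nucleosome_calls.tsv",
            "tables/occ_peak_labels.tsv",
            "tables/metaprofile_nucleosomal.tsv",
            "tables/metaprofile_genebody.tsv",
            "tables/shared_unique.json",
        ],
        "diffocc": ["tables/diffocc.tsv", "tables/diffocc_summary.json"],
        "spacing": ["tables/spacing.tsv", "tables/spacing.json"],
        "report": ["manifest.json", "config_resolved.yaml"],
    }
    return out


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, ws: Workspace) -> None:
    design = cfg.design
    rng = np.random.default_rng(design.seed)
    genome = make_genome(design, rng)
    peaks, truth_peaks = plant_peaks(design, genome, rng)
    write_fasta(genome_to_strings(genome), ws.data / "genome.fa")
    write_narrowpeak(peaks["A"], ws.data / "peaks_A.narrowPeak")
    write_narrowpeak(peaks["B"], ws.data / "peaks_B.narrowPeak")
    write_table(truth_peaks, ws.tables / "truth_peaks.tsv", cfg)

    # gene models downstream of A peaks: markers first, fillers after
    matrix, truth_counts = simulate_counts(design, rng)
    genes = []
    marker_ids = [m.gene_id for m in design.markers]
    filler = [g for g in matrix.gene_ids if g not in marker_ids]
    a_peaks = peaks["A"]
    for i, p in enumerate(a_peaks):
        gene_id = marker_ids[i] if i < len(marker_ids) else filler[i - len(marker_ids)]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval(p.chrom, p.summit + 100, p.summit + 400, "+"),
            )
        )
    write_gene_models(genes, ws.data / "genes.gff3")
    write_counts(
        matrix,
        ws.data / "counts.mtx",
        ws.data / "counts_genes.tsv",
        ws.data / "counts_cells.tsv",
    )
    write_table(truth_counts["clusters"], ws.tables / "truth_clusters.tsv", cfg)
    write_table(truth_counts["markers"], ws.tables / "truth_markers.tsv", cfg)

    mock, induced, truth_nuc = simulate_occupancy(design, rng)
    write_bedgraph(mock, ws.data / "occupancy_mock.bedgraph")
    write_bedgraph(induced, ws.data / "occupancy_induced.bedgraph")
    write_table(truth_nuc, ws.tables / "truth_nucleosomes.tsv", cfg)

    # planted occupancy peaks: half on nucleosome centers, half in the
    # nucleosome-free grid slots
    occ_peaks, occ_rows = [], []
    chrom = design.occ_chrom
    nuc_centers = truth_nuc.loc[truth_nuc["planted"], "center"].to_numpy()
    free_centers = truth_nuc.loc[~truth_nuc["planted"], "center"].to_numpy()
    half = cfg.n_occ_peaks // 2
    chosen_nuc = rng.choice(nuc_centers, size=half, replace=False)
    chosen_free = rng.choice(
        free_centers, size=cfg.n_occ_peaks - half, replace=False
    )
    for k in range(cfg.n_occ_peaks):
        on_nuc = k % 2 == 0
        pos = int(chosen_nuc[k // 2]) if on_nuc else int(chosen_free[k // 2])
        occ_peaks.append(
            Peak(
                GenomicInterval(chrom, pos - 100, pos + 100),
                100, 5.0, 10.0, name=f"occpeak{k:04d}",
            )
        )
        occ_rows.append(
            {
                "peak": f"occpeak{k:04d}",
                "summit": pos,
                "true_label": "nucleosomal" if on_nuc else "non-nucleosomal",
            }
        )
    write_narrowpeak(occ_peaks, ws.data / "occ_peaks.narrowPeak")
    write_table(pd.DataFrame(occ_rows), ws.tables / "truth_occ_peaks.tsv", cfg)

    chip = simulate_chip_signal(
        peaks["A"],
        peaks["B"],
        design.chrom_lengths,
        sigma=design.chip_sigma,
        amp_unique=design.chip_amp_unique,
        shared_boost=design.chip_shared_boost,
    )
    write_bedgraph(chip, ws.data / "chip_A.bedgraph")


def stage_entropy(cfg: RunConfig, ws: Workspace) -> None:
    matrix = read_counts(
        ws.data / "counts.mtx",
        ws.data / "counts_genes.tsv",
        ws.data / "counts_cells.tsv",
    )
    records, summary = entropy_by_cluster(matrix, base=cfg.entropy_base)
    write_table(records, ws.tables / "entropy_cells.tsv", cfg)
    write_table(summary, ws.tables / "entropy_clusters.tsv", cfg)

    rows = []
    for n in (100, 200, 500, 1000, 2000, 5000):
        for label, share in (("uniform", None), ("share_0.4", 0.4), ("share_0.5", 0.5)):
            model = TwoTierModel(n_genes=n, top_fraction=0.1,
                                 top_share=share if share is not None else 0.1)
            rows.append(
                {"n_genes": n, "curve": label, "entropy": two_tier_entropy(model)}
            )
    write_table(pd.DataFrame(rows), ws.tables / "entropy_curves.tsv", cfg)
    if cfg.make_figures:
        _fig_entropy(records, ws)


def stage_overlap(cfg: RunConfig, ws: Workspace) -> None:
    peaks_a = read_narrowpeak(ws.data / "peaks_A.narrowPeak")
    peaks_b = read_narrowpeak(ws.data / "peaks_B.narrowPeak")
    result = permutation_overlap_test(
        peaks_a, peaks_b, cfg.design.chrom_lengths, n_perm=cfg.n_perm, seed=cfg.seed
    )
    (ws.tables / "overlap.json").write_text(json.dumps(result.as_dict(), indent=2))
    genome = read_fasta(ws.data / "genome.fa")
    frac, table = motif_fraction_at_summits(
        peaks_a, cfg.design.pwm_a(), genome,
        window=cfg.motif_window, tail_prob=cfg.motif_tail_prob,
    )
    write_table(table, ws.tables / "motif_fraction.tsv", cfg)
    log.info("overlap: observed=%d p=%.4g; motif fraction=%.3f",
             result.observed_overlap, result.empirical_p, frac)


def stage_targets(cfg: RunConfig, ws: Workspace) -> None:
    matrix = read_counts(
        ws.data / "counts.mtx",
        ws.data / "counts_genes.tsv",
        ws.data / "counts_cells.tsv",
    )
    stats = marker_stats(matrix, cfg.design.factor_gene)
    write_table(stats, ws.tables / "marker_stats.tsv", cfg)
    peaks_a = read_narrowpeak(ws.data / "peaks_A.narrowPeak")
    genes = read_gene_models(ws.data / "genes.gff3")
    annotations = annotate_peaks_to_genes(peaks_a, genes, cfg.annotate_distance)
    targets = assign_targets(
        stats, annotations, factor=cfg.design.factor_gene,
        min_pct=cfg.min_pct, min_log2fc=cfg.min_log2fc,
    )
    write_table(targets, ws.tables / "targets.tsv", cfg)


def stage_nucleosome(cfg: RunConfig, ws: Workspace) -> None:
    design = cfg.design
    mock = read_bedgraph(
        ws.data / "occupancy_mock.bedgraph", design.occ_bin_size,
        design.occ_chrom_lengths,
    )
    calls = call_nucleosomes(
        mock, cfg.smoothing_bandwidth, cfg.min_prominence
    )
    call_df = pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "start": [c.interval.start for c in calls],
            "end": [c.interval.end for c in calls],
            "center": [c.center for c in calls],
            "occupancy_score": [c.occupancy_score for c in calls],
            "q_like_score": [c.q_like_score for c in calls],
        }
    )
    write_table(call_df, ws.tables / "nucleosome_calls.tsv", cfg)

    occ_peaks = read_narrowpeak(ws.data / "occ_peaks.narrowPeak")
    labels = classify_peaks(occ_peaks, calls, window=cfg.classify_window)
    write_table(labels, ws.tables / "occ_peak_labels.tsv", cfg)

    nuc_peaks = [
        p for p, lab in zip(occ_peaks, labels["label"]) if lab == "nucleosomal"
    ]
    prof = metaprofile_point(
        mock, [(p.chrom, p.summit) for p in nuc_peaks],
        flank=cfg.flank, n_bins=cfg.n_bins,
    )
    write_table(
        pd.DataFrame({"bin_center": prof.bin_centers, "mean": prof.mean}),
        ws.tables / "metaprofile_nucleosomal.tsv", cfg,
    )

    chip = read_bedgraph(
        ws.data / "chip_A.bedgraph", 10, design.chrom_lengths
    )
    genes = read_gene_models(ws.data / "genes.gff3")
    gb = metaprofile_scaled(chip, genes, body_bins=100, flank=cfg.flank, flank_bins=50)
    write_table(
        pd.DataFrame({"bin_center": gb.bin_centers, "mean": gb.mean}),
        ws.tables / "metaprofile_genebody.tsv", cfg,
    )

    peaks_a = read_narrowpeak(ws.data / "peaks_A.narrowPeak")
    peaks_b = read_narrowpeak(ws.data / "peaks_B.narrowPeak")
    su = shared_unique_signal(peaks_a, peaks_b, chip, cfg.flank, cfg.n_bins)
    (ws.tables / "shared_unique.json").write_text(
        json.dumps(
            {
                "n_shared": su["n_shared"],
                "n_unique": su["n_unique"],
                "shared_mean": su["shared_mean"],
                "unique_mean": su["unique_mean"],
                "shared_unique_ratio": su["shared_unique_ratio"],
            },
            indent=2,
        )
    )
    if cfg.make_figures:
        _fig_profiles(prof, su, ws)


def stage_diffocc(cfg: RunConfig, ws: Workspace) -> None:
    design = cfg.design
    mock = read_bedgraph(
        ws.data / "occupancy_mock.bedgraph", design.occ_bin_size,
        design.occ_chrom_lengths,
    )
    induced = read_bedgraph(
        ws.data / "occupancy_induced.bedgraph", design.occ_bin_size,
        design.occ_chrom_lengths,
    )
    truth = read_table(ws.tables / "truth_nucleosomes.tsv")
    truth = truth[truth["planted"]].reset_index(drop=True)
    h = cfg.diff_region_halfwidth
    regions = [
        GenomicInterval(r.chrom, int(r.center) - h, int(r.center) + h)
        for r in truth.itertuples(index=False)
    ]
    diff = differential_occupancy(induced, mock, regions)
    table = diff.table.copy()
    table["is_target"] = truth["is_target"].to_numpy()
    write_table(table, ws.tables / "diffocc.tsv", cfg)
    target_mean = float(table.loc[table["is_target"], "log2fc"].mean())
    other_mean = float(table.loc[~table["is_target"], "log2fc"].mean())
    (ws.tables / "diffocc_summary.json").write_text(
        json.dumps(
            {
                "size_factors": diff.size_factors,
                "target_mean_log2fc": target_mean,
                "nontarget_mean_log2fc": other_mean,
            },
            indent=2,
        )
    )
    log.info("diffocc: target mean log2FC=%.3f, non-target=%.3f",
             target_mean, other_mean)


def stage_spacing(cfg: RunConfig, ws: Workspace) -> None:
    design = cfg.design
    genome = read_fasta(ws.data / "genome.fa")
    peaks_a = read_narrowpeak(ws.data / "peaks_A.narrowPeak")
    peaks_b = read_narrowpeak(ws.data / "peaks_B.narrowPeak")
    sites_a = localize_sites(design.pwm_a(), genome, peaks_a, cfg.site_window)
    sites_b = localize_sites(design.pwm_b(), genome, peaks_b, cfg.site_window)
    dist = pairwise_spacing(
        peaks_a, sites_a, peaks_b, sites_b, window=cfg.site_window,
        factor_a="A", factor_b="B",
    )
    write_table(
        pd.DataFrame({"distance": dist.distances}), ws.tables / "spacing.tsv", cfg
    )
    ks_d, ks_p = spacing_ks(dist, null_window=cfg.site_window)
    cls = classify_spacing(dist, null_window=cfg.site_window, alpha=cfg.alpha)
    (ws.tables / "spacing.json").write_text(
        json.dumps(
            {
                "n_pairs": dist.n_pairs,
                "n_shared": dist.n_shared,
                "n_dropped": dist.n_dropped,
                "mean": float(dist.distances.mean()),
                "sd": float(dist.distances.std(ddof=1)),
                "ks_d_vs_null": ks_d,
                "ks_p_vs_null": ks_p,
                "classification": cls,
            },
            indent=2,
        )
    )
    if cfg.make_figures:
        _fig_spacing(dist, ws)


def stage_report(cfg: RunConfig, ws: Workspace) -> None:
    manifest = {"version": __version__, "seed": cfg.seed,
                "config_hash": cfg.config_hash(), "stages": {}}
    for stage, outputs in stage_outputs(cfg).items():
        if stage == "report":
            continue
        manifest["stages"][stage] = {
            rel: _sha256(ws.root / rel)
            for rel in outputs
            if (ws.root / rel).exists()
        }
    (ws.root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (ws.root / "config_resolved.yaml").write_text(
        yaml.safe_dump(cfg.as_dict(), sort_keys=True)
    )


# ---------------------------------------------------------------------------
# figures (optional)


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def _fig_entropy(records: pd.DataFrame, ws: Workspace) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    clusters = list(pd.unique(records["cluster"]))
    data = [records.loc[records["cluster"] == c, "entropy"] for c in clusters]
    ax.boxplot(data, tick_labels=clusters)
    ax.set_ylabel("entropy (nats)")
    fig.tight_layout()
    fig.savefig(ws.figures / "entropy_boxplot.png", dpi=100)
    plt.close(fig)


def _fig_profiles(prof, su, ws: Workspace) -> None:
    plt = _mpl()
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
    axes[0].plot(prof.bin_centers, prof.mean)
    axes[0].set_title("occupancy at nucleosomal peaks")
    axes[0].set_xlabel("bp from summit")
    for key, color in (("shared", "C0"), ("unique", "C1")):
        if su[key] is not None:
            axes[1].plot(su[key].bin_centers, su[key].mean, color, label=key)
    axes[1].legend()
    axes[1].set_title("shared vs unique peak signal")
    axes[1].set_xlabel("bp from summit")
    fig.tight_layout()
    fig.savefig(ws.figures / "metaprofiles.png", dpi=100)
    plt.close(fig)


def _fig_spacing(dist, ws: Workspace) -> None:
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(dist.distances, bins=40, density=True)
    ax.set_xlabel("site distance d = pos_B - pos_A (bp)")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(ws.figures / "spacing_density.png", dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# orchestration

_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "entropy": stage_entropy,
    "overlap": stage_overlap,
    "targets": stage_targets,
    "nucleosome": stage_nucleosome,
    "diffocc": stage_diffocc,
    "spacing": stage_spacing,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, resume: bool = False) -> list[str]:
    """Execute all stages in dependency order; returns the stages that ran.

    With ``resume=True`` a stage is skipped when all of its outputs already
    exist and no upstream stage was re-executed.
    """
    ws = Workspace(cfg.out_dir)
    outputs = stage_outputs(cfg)
    executed: list[str] = []
    upstream_ran = False
    for stage in STAGES:
        have_all = all((ws.root / rel).exists() for rel in outputs[stage])
        if resume and have_all and not upstream_ran:
            log.info("stage %-10s skipped (outputs present)", stage)
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](cfg, ws)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {stage!r} failed: {exc}"
            ) from exc
        elapsed = time.perf_counter() - t0
        hashes = ",".join(
            _sha256(ws.root / rel)[:8]
            for rel in outputs[stage]
            if (ws.root / rel).exists()
        )
        log.info("stage %-10s %6.2fs outputs=[%s]", stage, elapsed, hashes)
        executed.append(stage)
        upstream_ran = True
    return executed
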