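"""Synthetic fixtures with known ground truth.

Every generator is a pure function of (design, seed): reruns are
byte-identical, and each one emits a machine-readable truth table so that
downstream checks read ground truth from the data, never from constants
duplicated elsewhere. Generated files are valid inputs to the
:mod:`chromfate.genomic_io` readers.

What is emulated, and how:

* a random i.i.d. ACGT genome with ChIP peak sets whose summits carry
  planted PWM consensus motifs — including paired factors whose second
  motif sits at a constrained spacing Δ + Normal(0, σ) from the first, or
  uniformly within the scan window for the independence control;
* MNase-style nucleosome occupancy: Gaussian footprints (σ = fuzziness) on
  a low uniform background with per-bin Poisson noise, plus an induced
  condition in which designated target nucleosomes lose a fixed fraction of
  their amplitude;
* clustered scRNA-seq counts: per-cluster two-tier transcript
  concentration, multinomial sampling at fixed depth, and marker genes
  moment-matched so the factor-expressing cluster reaches declared
  detection rates and fold changes.

Background occurrences of either factor's consensus (and its reverse
complement) inside scanned peak windows are scrubbed before planting, so
site recovery measures scanner correctness rather than chance-hit noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .entropy import TwoTierModel, two_tier_entropy
from .genomic_io import ExpressionMatrix, GenomicInterval, Peak, SignalTrack
from .pwm import Pwm, pwm_from_consensus, reverse_complement

__all__ = [
    "ClusterSpec",
    "MarkerSpec",
    "SimulationDesign",
    "make_genome",
    "plant_peaks",
    "simulate_occupancy",
    "simulate_chip_signal",
    "simulate_counts",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ClusterSpec:
    name: str
    n_cells: int
    top_share: float


@dataclass(frozen=True)
class MarkerSpec:
    gene_id: str
    pct_expressing: float
    log2fc: float


@dataclass
class SimulationDesign:
    """Ground-truth parameters for the full synthetic study.

    Defaults describe the demo conditions: two ~100-kb chromosomes of peaks
    for a constrained bHLH/remodeler-like factor pair, a 200-kb occupancy
    chromosome of phased nucleosomes with 2-fold depletion at 10% of them
    after induction, and four epidermal-like clusters whose transcript
    concentration (top 10% of genes holding 30-50% of transcripts) rises
    with differentiation.
    """

    seed: int = 0
    # genome & peaks
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 150_000, "chr2": 110_000}
    )
    n_shared_peaks: int = 150
    n_a_only: int = 75
    n_b_only: int = 75
    peak_width: int = 200
    peak_gap: int = 200
    consensus_a: str = "CACGTG"  # G-box, the common bHLH motif
    consensus_b: str = "TTGACC"
    spacing_mode: str = "constrained"  # or "independent"
    delta: float = 10.0
    sigma: float = 2.0
    a_jitter: int = 10
    site_window: int = 50
    motif_prob_a: float = 1.0
    motif_prob_b: float = 1.0
    # nucleosome occupancy
    occ_chrom: str = "occ1"
    n_nucleosomes: int = 1000
    nuc_spacing: int = 200
    occ_bin_size: int = 10
    fuzziness: float = 20.0
    nuc_amplitude: float = 40.0
    background_rate: float = 0.1
    n_depleted_targets: int = 100
    depletion: float = 0.5
    occupancy_noise: bool = True
    nuc_skip_every: int = 10  # leave every k-th grid slot nucleosome-free
    # ChIP signal
    chip_sigma: float = 50.0
    chip_amp_unique: float = 1.0
    chip_shared_boost: float = 2.0
    # single-cell counts
    n_genes: int = 2000
    depth: int = 5000
    top_fraction: float = 0.1
    clusters: list[ClusterSpec] = field(
        default_factory=lambda: [
            ClusterSpec("meristemoid", 120, 0.30),
            ClusterSpec("GMC", 120, 0.40),
            ClusterSpec("GC", 120, 0.50),
            ClusterSpec("pavement", 120, 0.50),
        ]
    )
    factor_cluster: str = "GMC"
    factor_gene: str = "FACTOR"
    markers: list[MarkerSpec] = field(
        default_factory=lambda: [
            MarkerSpec("M_STRONG", 0.60, 1.00),
            MarkerSpec("M_MED", 0.40, 0.50),
            MarkerSpec("M_EDGE", 0.25, 0.223),
            MarkerSpec("M_RARE", 0.20, 1.00),
            MarkerSpec("M_FLAT", 0.80, 0.10),
        ]
    )

    def __post_init__(self):
        self.clusters = [
            c if isinstance(c, ClusterSpec) else ClusterSpec(**c) for c in self.clusters
        ]
        self.markers = [
            m if isinstance(m, MarkerSpec) else MarkerSpec(**m) for m in self.markers
        ]

    def as_dict(self) -> dict:
        return asdict(self)

    @property
    def occ_chrom_lengths(self) -> dict[str, int]:
        return {self.occ_chrom: (self.n_nucleosomes + 1) * self.nuc_spacing}

    def pwm_a(self) -> Pwm:
        return pwm_from_consensus(self.consensus_a, name="factor_A")

    def pwm_b(self) -> Pwm:
        return pwm_from_consensus(self.consensus_b, name="factor_B")


# ---------------------------------------------------------------------------
# genome


def make_genome(design: SimulationDesign, rng) -> dict[str, np.ndarray]:
    """I.i.d. uniform ACGT sequence per chromosome, as mutable char arrays."""
    for chrom, length in design.chrom_lengths.items():
        if length < 10_000:
            raise ValueError(f"{chrom}: chromosome shorter than 10 kb")
    return {
        chrom: rng.choice(_BASES, size=length)
        for chrom, length in design.chrom_lengths.items()
    }


def genome_to_strings(genome: dict[str, np.ndarray]) -> dict[str, str]:
    return {c: "".join(arr) for c, arr in genome.items()}


def _scrub_window(seq: np.ndarray, start: int, end: int, consensi, rng) -> None:
    """Mutate away chance occurrences of any consensus inside [start, end)."""
    start, end = max(start, 0), min(end, len(seq))
    for _ in range(20):
        text = "".join(seq[start:end])
        dirty = False
        for cons in consensi:
            pos = text.find(cons)
            while pos != -1:
                i = start + pos + len(cons) // 2
                current = seq[i]
                seq[i] = rng.choice([b for b in _BASES if b != current])
                dirty = True
                text = "".join(seq[start:end])
                pos = text.find(cons, pos + 1)
        if not dirty:
            return
    raise RuntimeError("could not scrub background motif occurrences")


def _plant(seq: np.ndarray, midpoint: int, consensus: str) -> tuple[int, int]:
    """Write a consensus with integer midpoint at ``midpoint``; returns span."""
    start = midpoint - len(consensus) // 2
    seq[start : start + len(consensus)] = list(consensus)
    return start, start + len(consensus)


def _compatible(span_a, cons_a, span_b, cons_b) -> bool:
    """True when two planted motifs can coexist: disjoint spans, or bases
    agreeing wherever the spans overlap (e.g. a shared recognition site)."""
    lo, hi = max(span_a[0], span_b[0]), min(span_a[1], span_b[1])
    if lo >= hi:
        return True
    return all(
        cons_a[i - span_a[0]] == cons_b[i - span_b[0]] for i in range(lo, hi)
    )


def _cleanup_junctions(
    seq: np.ndarray, start: int, end: int, patterns, protected, rng
) -> None:
    """Destroy pattern occurrences created by plant/background junctions.

    Occurrences lying entirely within a protected (planted) span are kept;
    any other occurrence gets one of its unprotected bases mutated.
    """
    start, end = max(start, 0), min(end, len(seq))
    protected_bp = set()
    for a, b in protected:
        protected_bp.update(range(a, b))
    for _ in range(20):
        text = "".join(seq[start:end])
        dirty = False
        for pat in patterns:
            pos = text.find(pat)
            while pos != -1:
                span = range(start + pos, start + pos + len(pat))
                free = [i for i in span if i not in protected_bp]
                if free:  # not a planted site: break it
                    i = rng.choice(free)
                    seq[i] = rng.choice([b for b in _BASES if b != seq[i]])
                    dirty = True
                pos = text.find(pat, pos + 1)
        if not dirty:
            return
    raise RuntimeError("could not clean junction motif occurrences")


def plant_peaks(
    design: SimulationDesign, genome: dict[str, np.ndarray], rng
) -> tuple[dict[str, list[Peak]], pd.DataFrame]:
    """Plant motif-bearing peak pairs into the genome.

    Returns peak lists per factor ("A", "B") and a truth table with one row
    per peak slot: the slot class, summit, planted site midpoints (absolute
    and as offsets from the summit), and the planted signed spacing d for
    shared slots. Shared slots share one interval in both factors' peak
    sets. A's site midpoint is uniform within ±a_jitter of the summit;
    in constrained mode B's midpoint is A's + round(Δ + Normal(0, σ)), in
    independent mode uniform within ±site_window of the summit.
    """
    n_slots = design.n_shared_peaks + design.n_a_only + design.n_b_only
    step = design.peak_width + design.peak_gap
    slots: list[tuple[str, int]] = []  # (chrom, peak start)
    for chrom, length in design.chrom_lengths.items():
        pos = design.peak_gap
        while pos + design.peak_width + design.peak_gap <= length:
            slots.append((chrom, pos))
            pos += step
    if len(slots) < n_slots:
        raise ValueError(
            f"genome holds {len(slots)} peak slots, design needs {n_slots}"
        )
    order = rng.permutation(len(slots))[:n_slots]
    classes = (
        ["shared"] * design.n_shared_peaks
        + ["a_only"] * design.n_a_only
        + ["b_only"] * design.n_b_only
    )
    cons_a, cons_b = design.consensus_a.upper(), design.consensus_b.upper()
    scrub_set = [
        cons_a, reverse_complement(cons_a), cons_b, reverse_complement(cons_b),
    ]
    max_len = max(len(cons_a), len(cons_b))
    peaks: dict[str, list[Peak]] = {"A": [], "B": []}
    rows = []
    for k, (slot_idx, cls) in enumerate(zip(order, classes)):
        chrom, start = slots[slot_idx]
        summit = start + design.peak_width // 2
        seq = genome[chrom]
        w = design.site_window + max_len + int(design.delta + 6 * design.sigma) + 1
        _scrub_window(seq, summit - w, summit + w, scrub_set, rng)
        interval = GenomicInterval(chrom, start, start + design.peak_width)
        name = f"peak{k:05d}"
        row = {
            "peak": name,
            "class": cls,
            "chrom": chrom,
            "summit": summit,
            "pos_a": np.nan,
            "pos_b": np.nan,
            "offset_a": np.nan,
            "offset_b": np.nan,
            "d": np.nan,
        }
        plant_a = cls in ("shared", "a_only") and rng.random() < design.motif_prob_a
        plant_b = cls in ("shared", "b_only") and rng.random() < design.motif_prob_b
        protected = []
        if plant_a and plant_b and cls == "shared":
            # joint placement so both motifs fit without steric collision
            for _ in range(100):
                if design.spacing_mode == "constrained":
                    pos_a = summit + int(
                        rng.integers(-design.a_jitter, design.a_jitter + 1)
                    )
                    pos_b = pos_a + int(round(design.delta + rng.normal(0, design.sigma)))
                else:  # independent: both uniform within the scan window
                    pos_a = summit + int(
                        rng.integers(-design.site_window, design.site_window + 1)
                    )
                    pos_b = summit + int(
                        rng.integers(-design.site_window, design.site_window + 1)
                    )
                sa = (pos_a - len(cons_a) // 2, pos_a - len(cons_a) // 2 + len(cons_a))
                sb = (pos_b - len(cons_b) // 2, pos_b - len(cons_b) // 2 + len(cons_b))
                if _compatible(sa, cons_a, sb, cons_b):
                    break
            else:
                raise RuntimeError("could not place motif pair without collision")
            protected.append(_plant(seq, pos_a, cons_a))
            protected.append(_plant(seq, pos_b, cons_b))
            row["pos_a"], row["offset_a"] = pos_a, pos_a - summit
            row["pos_b"], row["offset_b"] = pos_b, pos_b - summit
            row["d"] = pos_b - pos_a
        elif plant_a:
            pos_a = summit + int(rng.integers(-design.a_jitter, design.a_jitter + 1))
            protected.append(_plant(seq, pos_a, cons_a))
            row["pos_a"], row["offset_a"] = pos_a, pos_a - summit
        elif plant_b:
            pos_b = summit + int(rng.integers(-design.a_jitter, design.a_jitter + 1))
            protected.append(_plant(seq, pos_b, cons_b))
            row["pos_b"], row["offset_b"] = pos_b, pos_b - summit
        if protected:
            _cleanup_junctions(
                seq, summit - w, summit + w, scrub_set, protected, rng
            )
        if cls in ("shared", "a_only"):
            peaks["A"].append(
                Peak(interval, design.peak_width // 2, 10.0, 20.0, name=name)
            )
        if cls in ("shared", "b_only"):
            peaks["B"].append(
                Peak(interval, design.peak_width // 2, 10.0, 20.0, name=name)
            )
        rows.append(row)
    return peaks, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# occupancy tracks


def _stamp_gaussians(
    length: int, bin_size: int, centers, amplitudes, sigma: float
) -> np.ndarray:
    n_bins = -(-length // bin_size)
    x = (np.arange(n_bins) + 0.5) * bin_size
    out = np.zeros(n_bins)
    half_span = int(np.ceil(4 * sigma / bin_size))
    for c, a in zip(centers, amplitudes):
        i = int(c // bin_size)
        lo, hi = max(i - half_span, 0), min(i + half_span + 1, n_bins)
        out[lo:hi] += a * np.exp(-((x[lo:hi] - c) ** 2) / (2 * sigma**2))
    return out


def simulate_occupancy(
    design: SimulationDesign, rng
) -> tuple[SignalTrack, SignalTrack, pd.DataFrame]:
    """Mock and induced occupancy tracks plus the nucleosome truth table.

    Nucleosomes sit on a regular grid (``nuc_spacing`` apart, >= 167 bp),
    except that every ``nuc_skip_every``-th grid slot is left
    nucleosome-free (a planted open/linker region, marked ``planted=False``
    in the truth table). Each planted nucleosome contributes a Gaussian
    bump (σ = fuzziness) of ``nuc_amplitude`` on a uniform background; the
    induced track multiplies the bump amplitude by ``depletion`` at the
    designated target nucleosomes only. Per-bin Poisson noise uses one
    shared substream for both conditions, so a depletion factor of 1
    yields identical tracks.
    """
    if design.nuc_spacing < 167:
        raise ValueError("nucleosome spacing must be >= 167 bp")
    chrom = design.occ_chrom
    length = design.occ_chrom_lengths[chrom]
    centers = (np.arange(design.n_nucleosomes) + 1) * design.nuc_spacing
    planted = np.ones(design.n_nucleosomes, dtype=bool)
    if design.nuc_skip_every:
        planted[design.nuc_skip_every - 1 :: design.nuc_skip_every] = False
    targets = np.zeros(design.n_nucleosomes, dtype=bool)
    planted_idx = np.flatnonzero(planted)
    targets[
        rng.choice(planted_idx, size=design.n_depleted_targets, replace=False)
    ] = True
    amp_mock = np.where(planted, design.nuc_amplitude, 0.0)
    amp_ind = np.where(targets, design.depletion * amp_mock, amp_mock)
    mean_mock = design.background_rate + _stamp_gaussians(
        length, design.occ_bin_size, centers, amp_mock, design.fuzziness
    )
    mean_ind = design.background_rate + _stamp_gaussians(
        length, design.occ_bin_size, centers, amp_ind, design.fuzziness
    )
    if design.occupancy_noise:
        noise_seed = int(rng.integers(2**31))
        mock_vals = np.random.default_rng(noise_seed).poisson(mean_mock).astype(float)
        ind_vals = np.random.default_rng(noise_seed).poisson(mean_ind).astype(float)
    else:
        mock_vals, ind_vals = mean_mock, mean_ind
    lengths = {chrom: length}
    truth = pd.DataFrame(
        {"chrom": chrom, "center": centers, "planted": planted,
         "is_target": targets}
    )
    return (
        SignalTrack(design.occ_bin_size, dict(lengths), {chrom: mock_vals}),
        SignalTrack(design.occ_bin_size, dict(lengths), {chrom: ind_vals}),
        truth,
    )


def simulate_chip_signal(
    peaks: list[Peak],
    shared_with: list[Peak],
    chrom_lengths: dict[str, int],
    bin_size: int = 10,
    sigma: float = 100.0,
    amp_unique: float = 1.0,
    shared_boost: float = 2.0,
    background: float = 0.0,
) -> SignalTrack:
    """Noise-free ChIP enrichment with boosted amplitude at shared peaks.

    A Gaussian bump is stamped at every peak summit; peaks overlapping any
    peak in ``shared_with`` get ``shared_boost`` times the unique amplitude.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in shared_with:
        by_chrom.setdefault(p.chrom, []).append(p)
    track = SignalTrack(bin_size, dict(chrom_lengths))
    for chrom, length in chrom_lengths.items():
        mine = [p for p in peaks if p.chrom == chrom]
        amps = [
            amp_unique
            * (
                shared_boost
                if any(p.interval.overlaps(q.interval) for q in by_chrom.get(chrom, ()))
                else 1.0
            )
            for p in mine
        ]
        track.data[chrom] = background + _stamp_gaussians(
            length, bin_size, [p.summit for p in mine], amps, sigma
        )
    return track


# ---------------------------------------------------------------------------
# single-cell counts


def _detection_prob(pct: float, depth: int) -> float:
    """Per-transcript probability giving detection rate ``pct`` at ``depth``."""
    if not (0 <= pct < 1):
        raise ValueError(f"infeasible detection rate {pct}")
    return 1.0 - (1.0 - pct) ** (1.0 / depth)


def simulate_counts(
    design: SimulationDesign, rng
) -> tuple[ExpressionMatrix, dict[str, pd.DataFrame]]:
    """Clustered counts with two-tier structure and moment-matched markers.

    Per cluster, gene probabilities come from its two-tier model; the factor
    gene is expressed (detection ~1) only in ``factor_cluster``, and each
    marker's in/out probabilities are set so the declared detection rate and
    log2 fold change are met in expectation:
    p_in = 1 - (1 - pct)^(1/depth)  (detection moment match), and with
    m = 1e4 * p the expected counts-per-10k mean,
    m_out = (m_in + 1e-4) / 2^log2fc - 1e-4   (fold-change match).
    Remaining genes are renormalised. Truth tables carry the analytic
    two-tier entropy per cluster and the intended marker statistics.
    """
    reserved = [design.factor_gene] + [m.gene_id for m in design.markers]
    if len(reserved) >= design.n_genes:
        raise ValueError("n_genes too small for reserved factor/marker genes")
    gene_ids = reserved + [f"g{i:05d}" for i in range(design.n_genes - len(reserved))]
    n_res = len(reserved)

    blocks, labels, cell_ids = [], [], []
    cluster_rows = []
    p_factor_in = _detection_prob(0.9999, design.depth)
    for spec in design.clusters:
        model = TwoTierModel(
            n_genes=design.n_genes,
            top_fraction=design.top_fraction,
            top_share=spec.top_share,
        )
        base = model.probabilities()
        # shuffle tier membership of the non-reserved genes per cluster
        body = base[n_res:].copy()
        rng.shuffle(body)
        probs = np.concatenate([base[:n_res], body])
        in_factor = spec.name == design.factor_cluster
        probs[0] = p_factor_in if in_factor else 0.0
        for j, m in enumerate(design.markers, start=1):
            p_in = _detection_prob(m.pct_expressing, design.depth)
            m_in = 1e4 * p_in
            m_out = max((m_in + 1e-4) / 2**m.log2fc - 1e-4, 0.0) / 1e4
            probs[j] = p_in if in_factor else m_out
        # renormalise the unreserved genes around the pinned ones
        pinned = probs[:n_res].sum()
        probs[n_res:] *= (1.0 - pinned) / probs[n_res:].sum()
        counts = rng.multinomial(design.depth, probs, size=spec.n_cells)
        blocks.append(counts)
        labels.extend([spec.name] * spec.n_cells)
        cell_ids.extend(
            f"{spec.name}_c{i:04d}" for i in range(spec.n_cells)
        )
        cluster_rows.append(
            {
                "cluster": spec.name,
                "n_cells": spec.n_cells,
                "top_share": spec.top_share,
                "analytic_entropy": two_tier_entropy(model),
            }
        )
    matrix = ExpressionMatrix(
        np.vstack(blocks),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cluster_labels=labels,
        clusters=[c.name for c in design.clusters],
    )
    truth = {
        "clusters": pd.DataFrame(cluster_rows),
        "markers": pd.DataFrame(
            {
                "gene_id": [m.gene_id for m in design.markers],
                "pct_expressing": [m.pct_expressing for m in design.markers],
                "log2fc": [m.log2fc for m in design.markers],
            }
        ),
    }
    return matrix, truth
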