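"""Synthetic peak tables, genomes and promoter motif plants with ground truth.

The peak simulator emulates the statistical structure the classifier
assumes: four-condition normalized Pol II densities per gene, an input
baseline, SICER-like flags, and planted dependence classes whose ratios
clear every decision threshold by a multiplicative margin.  Because noise
is bounded below the margin, a classifier run recovers the planted labels
exactly — the recovery test is constructive, not statistical.

Default class counts reproduce the study-scale composition: 25,677 genes of
which 8,062 are active, 2,744 PARP-14-dependent (2,314 positive / 430
negative), 1,647 ART-independent, 756 PARP-14-only ART and 341 multi-PARP
ART, apportioned by largest remainder when n_genes differs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .motifs import Motif, PromoterWindow, reverse_complement
from .tables_io import Condition, GeneModel, GenePeakRecord, NON_INPUT_CONDITIONS

__all__ = [
    "SimulationConfig",
    "GeneTruth",
    "SyntheticTruth",
    "STUDY_SCALE_COUNTS",
    "default_class_proportions",
    "simulate_peak_table",
    "simulate_genome_with_motifs",
    "expected_assignment",
]

CLASS_LABELS = (
    "inactive",
    "no_change",
    "pool4_positive",
    "pool4_negative",
    "pool5_positive",
    "pool5_negative",
    "pool6_positive",
    "pool6_negative",
)

# Pool sizes of the reference Th2 ChIP-seq study this generator emulates.
STUDY_SCALE_COUNTS = {
    "total": 25_677,
    "pool1": 8_062,
    "pool2": 2_744,
    "positive": 2_314,
    "negative": 430,
    "pool3": 1_097,
    "pool4": 1_647,
    "pool5": 756,
    "pool6": 341,
}


def _largest_remainder(weights: Sequence[float], total: int) -> list[int]:
    """Integer apportionment of `total` proportional to `weights`."""
    raw = [w / sum(weights) * total for w in weights]
    base = [math.floor(x) for x in raw]
    short = total - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def default_class_proportions() -> dict[str, float]:
    """Per-class proportions derived from the printed pool sizes, with the
    positive/negative split apportioned within each of pools 4/5/6."""
    c = STUDY_SCALE_COUNTS
    inactive = c["total"] - c["pool1"]
    no_change = c["pool1"] - c["pool2"]
    pos_frac = c["positive"] / c["pool2"]
    props: dict[str, float] = {
        "inactive": inactive / c["total"],
        "no_change": no_change / c["total"],
    }
    for pool in ("pool4", "pool5", "pool6"):
        props[f"{pool}_positive"] = c[pool] * pos_frac / c["total"]
        props[f"{pool}_negative"] = c[pool] * (1 - pos_frac) / c["total"]
    return props


def _study_exact_counts(n: int) -> dict[str, int]:
    """Class counts for n genes; at the study scale they equal the printed
    pool sizes exactly (sign split by largest remainder within each pool)."""
    c = STUDY_SCALE_COUNTS
    scale = n / c["total"]
    pool_sizes = {p: c[p] * scale for p in ("pool4", "pool5", "pool6")}
    pos = _largest_remainder(list(pool_sizes.values()), round(c["positive"] * scale))
    counts: dict[str, int] = {}
    for (pool, size), npos in zip(pool_sizes.items(), pos):
        counts[f"{pool}_positive"] = npos
        counts[f"{pool}_negative"] = round(size) - npos
    counts["no_change"] = round((c["pool1"] - c["pool2"]) * scale)
    counts["inactive"] = n - sum(counts.values())
    return counts


@dataclass
class SimulationConfig:
    """Study conditions for the generators.

    ``effect_margin`` is the multiplicative factor by which every planted
    ratio clears its threshold; per-condition log-normal noise is truncated
    at 0.49·ln(margin) so two-condition ratios stay strictly inside their
    planted side (disable ``clip_noise`` to study threshold crossings).
    ``exact_counts`` plants deterministic class counts
    (shuffled by seed) instead of a multinomial draw.
    """

    n_genes: int = STUDY_SCALE_COUNTS["total"]
    class_proportions: dict[str, float] = field(default_factory=default_class_proportions)
    base_peak_log_mean: float = 0.4  # ln scale; exp(0.4) ~ 1.5 tag density
    base_peak_log_sd: float = 0.6
    effect_margin: float = 1.2
    input_level: float = 0.3
    noise_sd: float = 0.05
    motif_plant_rate_target: float = 0.4
    motif_plant_rate_background: float = 0.05
    planted_motif: Motif = field(
        default_factory=lambda: Motif("planted", "CACTGAGTGGAG", 2)
    )
    target_fraction: float = 1 / 3
    exact_counts: bool = True
    clip_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if set(self.class_proportions) - set(CLASS_LABELS):
            raise ValueError("unknown class label in proportions")
        if self.effect_margin <= 1:
            raise ValueError("effect_margin must be > 1")
        for rate in (self.motif_plant_rate_target, self.motif_plant_rate_background):
            if not 0 <= rate <= 1:
                raise ValueError("plant rates must be in [0, 1]")


@dataclass
class GeneTruth:
    gene_id: str
    label: str  # inactive | no_change | pool4 | pool5 | pool6
    sign: str  # none | positive | negative


@dataclass
class SyntheticTruth:
    """Planted per-gene labels and motif positions — the recovery oracle."""

    seed: int
    genes: list[GeneTruth] = field(default_factory=list)
    motif_plants: list[dict] = field(default_factory=list)
    target_genes: set[str] = field(default_factory=set)


def expected_assignment(truth: GeneTruth) -> dict[str, object]:
    """Pool flags and sign implied by a planted class label."""
    label, sign = truth.label, truth.sign
    return {
        "in_pool1": label != "inactive",
        "in_pool2": label in ("pool4", "pool5", "pool6"),
        "in_pool3": label in ("pool5", "pool6"),
        "in_pool4": label == "pool4",
        "in_pool5": label == "pool5",
        "in_pool6": label == "pool6",
        "regulation_sign": sign,
    }


def _assign_classes(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    labels = [l for l in CLASS_LABELS if config.class_proportions.get(l, 0) > 0]
    if config.exact_counts:
        uses_defaults = config.class_proportions == default_class_proportions()
        if uses_defaults:
            counts = _study_exact_counts(config.n_genes)
        else:
            counts = dict(
                zip(
                    labels,
                    _largest_remainder(
                        [config.class_proportions[l] for l in labels], config.n_genes
                    ),
                )
            )
        assigned = [l for l in labels for _ in range(counts.get(l, 0))]
        # pad (rounding shortfall is at most a gene or two)
        while len(assigned) < config.n_genes:
            assigned.append("no_change")
        rng.shuffle(assigned)
        return assigned[: config.n_genes]
    probs = [config.class_proportions[l] for l in labels]
    return list(rng.choice(labels, size=config.n_genes, p=probs))


def simulate_peak_table(
    config: SimulationConfig,
) -> tuple[list[GenePeakRecord], SyntheticTruth]:
    """Draw a peak table with planted dependence classes.

    Active genes get a log-normal baseline floored at 0.75 so the strongest
    condition stays strictly above the 0.500 activity threshold after
    noise; inactive genes sit below min(0.500, input)/margin² with all
    SICER flags cleared.
    """
    rng = np.random.default_rng(config.seed)
    m = config.effect_margin
    max_log_noise = 0.49 * math.log(m)
    labels = _assign_classes(config, rng)

    records: list[GenePeakRecord] = []
    truth = SyntheticTruth(seed=config.seed)
    for i, full_label in enumerate(labels):
        gene = f"g{i:05d}"
        if "_" in full_label and full_label not in ("no_change",):
            label, sign = full_label.rsplit("_", 1)
        else:
            label, sign = full_label, "none"

        noise = rng.normal(0.0, config.noise_sd, size=5)
        if config.clip_noise:
            noise = np.clip(noise, -max_log_noise, max_log_noise)
        input_peak = config.input_level * math.exp(noise[4])

        if label == "inactive":
            ceiling = min(0.5, config.input_level) / (m * m)
            raw = rng.uniform(0.02, ceiling, size=4)
            peaks = dict(zip(NON_INPUT_CONDITIONS, (float(x) for x in raw)))
            flags = {c: False for c in NON_INPUT_CONDITIONS}
        else:
            b = max(float(rng.lognormal(config.base_peak_log_mean, config.base_peak_log_sd)), 0.75)
            if sign == "positive":
                wt, ko = b, b / (1.4 * m)
            elif sign == "negative":
                wt, ko = b * 0.7 / m, b
            else:  # no_change: WT/KO ratio planted at 1
                wt, ko = b, b
            if label == "pool4" or label == "no_change":
                wt_pj = wt  # WT/WT+PJ34 planted inside the no-change band
            else:  # pool5/pool6: ART-dependent, ratio outside the band
                wt_pj = wt / (1.2 * m)
            if label == "pool6":
                ko_pj = ko / (1.2 * m)
            else:  # pool5 and everything else: KO arm unchanged
                ko_pj = ko
            base_vals = (wt, ko, wt_pj, ko_pj)
            peaks = {
                c: float(v * math.exp(e))
                for c, v, e in zip(NON_INPUT_CONDITIONS, base_vals, noise[:4])
            }
            flags = {c: True for c in NON_INPUT_CONDITIONS}

        peaks[Condition.INPUT] = float(input_peak)
        records.append(GenePeakRecord(gene, peaks, flags))
        truth.genes.append(GeneTruth(gene, label, sign))
    return records, truth


def simulate_genome_with_motifs(
    config: SimulationConfig,
    gene_length: int = 2_000,
    contig_length: int | None = None,
    flank: int = 10_000,
    plant_strand: str = "+",
    promoter_window: PromoterWindow | None = None,
) -> tuple[dict[str, str], list[GeneModel], SyntheticTruth]:
    """Uniform-ACGT contigs (one per gene) with motif copies planted in
    promoter windows of "target" genes at ``motif_plant_rate_target`` and of
    the remaining background genes at ``motif_plant_rate_background``.

    Each contig leaves room for the gene body plus ``flank`` on both sides
    so ±10 kb locus scans never clip.  ``plant_strand`` is "+", "-", or
    "random".  Planted positions and strands are recorded in the truth.
    """
    window = promoter_window or PromoterWindow()
    motif = config.planted_motif
    k = len(motif)
    min_len = gene_length + 2 * flank + 2 * window.upstream
    contig_length = contig_length or min_len
    if contig_length < min_len:
        raise ValueError(f"contig_length must be >= {min_len}")

    rng = np.random.default_rng(config.seed + 1)
    n_targets = int(round(config.n_genes * config.target_fraction))
    truth = SyntheticTruth(seed=config.seed)
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    bases = np.array(list("ACGT"))

    for i in range(config.n_genes):
        gene = f"g{i:05d}"
        chrom = f"contig_{gene}"
        is_target = i < n_targets
        if is_target:
            truth.target_genes.add(gene)
        seq = rng.choice(bases, size=contig_length)
        start = (contig_length - gene_length) // 2
        model = GeneModel(gene, chrom, start, start + gene_length, "+")
        models.append(model)

        rate = (
            config.motif_plant_rate_target
            if is_target
            else config.motif_plant_rate_background
        )
        if rng.random() < rate:
            # promoter-local offset such that the copy lies fully inside
            offset = int(rng.integers(0, window.length - k + 1))
            genomic = model.tss - window.upstream + offset
            strand = plant_strand if plant_strand in "+-" else ("+", "-")[rng.integers(2)]
            word = motif.sequence if strand == "+" else reverse_complement(motif.sequence)
            seq[genomic : genomic + k] = list(word)
            truth.motif_plants.append(
                {
                    "gene_id": gene,
                    "position": genomic,
                    "promoter_offset": offset,
                    "strand": strand,
                }
            )
        genome[chrom] = "".join(seq)
        truth.genes.append(GeneTruth(gene, "target" if is_target else "background", "none"))
    return genome, models, truth
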