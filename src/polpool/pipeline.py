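"""End-to-end orchestration: simulate/ingest -> filter -> classify ->
enrich -> discover/scan -> overlap, driven by a TOML config.

Every stage writes its artifact before the next starts and the whole run is
a pure function of (config, input files, seed); the JSON summary carries
the pool counts, sign split, artifact paths, seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .active import ActiveFilterConfig, build_pool1
from .classify import ClassifierConfig, assign_pools, assignments_to_frame
from .enrichment import enrichment_to_frame, gene_set_enrichment
from .motifs import LocusWindow, PromoterWindow, denovo_discover, extract_promoters, scan_locus
from .overlap import venn3
from .simulate import SimulationConfig, simulate_genome_with_motifs, simulate_peak_table
from . import tables_io

logger = logging.getLogger(__name__)

__all__ = ["RunSummary", "run_pipeline", "ConfigurationError"]


class ConfigurationError(ValueError):
    pass


@dataclass
class RunSummary:
    seed: int
    config_hash: str
    version: str
    counts: dict[str, int] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _classifier_config(section: dict) -> ClassifierConfig:
    kwargs = {}
    for key in (
        "up_ratio",
        "down_ratio",
        "band_min_peak",
        "pseudocount",
        "require_sicer_on_higher",
    ):
        if key in section:
            kwargs[key] = section[key]
    for key in ("band_up", "band_down", "no_change_band"):
        if key in section:
            kwargs[key] = tuple(section[key])
    return ClassifierConfig(**kwargs)


def run_pipeline(config_path: str | Path, outdir: str | Path | None = None) -> RunSummary:
    """Run the configured stages in fixed order; see the README for the
    config schema.  Requires either an [input] peak table or a [simulate]
    block."""
    config_path = Path(config_path)
    raw = config_path.read_bytes()
    cfg = tomllib.loads(raw.decode())
    out = Path(outdir or cfg.get("outdir", config_path.parent / "polpool_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    summary = RunSummary(
        seed=seed, config_hash=hashlib.sha256(raw).hexdigest()[:16], version=__version__
    )

    # --- stage: obtain the peak table -------------------------------------
    if "input" in cfg and "peak_table" in cfg["input"]:
        records = tables_io.read_gene_peak_table(cfg["input"]["peak_table"])
    elif "simulate" in cfg:
        sim_cfg = SimulationConfig(**{"seed": seed, **cfg["simulate"]})
        records, truth = simulate_peak_table(sim_cfg)
        tables_io.write_gene_peak_table(records, out / "peaks.tsv")
        with open(out / "truth.tsv", "w") as fh:
            fh.write("gene_id\tlabel\tsign\n")
            for g in truth.genes:
                fh.write(f"{g.gene_id}\t{g.label}\t{g.sign}\n")
        summary.artifacts["peak_table"] = str(out / "peaks.tsv")
        summary.artifacts["truth"] = str(out / "truth.tsv")
    else:
        raise ConfigurationError("config needs an [input] peak_table or a [simulate] block")
    logger.info("stage ingest: %d gene records", len(records))

    # --- stage: filter + classify -----------------------------------------
    fcfg = cfg.get("filter", {})
    active_cfg = ActiveFilterConfig(
        min_peak=fcfg.get("min_peak", 0.500),
        require_sicer=fcfg.get("require_sicer", True),
    )
    pool1 = build_pool1(records, active_cfg)
    tables_io.write_gene_list(pool1, out / "pool1.txt")
    summary.artifacts["pool1"] = str(out / "pool1.txt")
    logger.info("stage filter: %d of %d genes active", len(pool1), len(records))

    clf_cfg = _classifier_config(cfg.get("classify", {}))
    assignments, pool_summary = assign_pools(records, active_cfg, clf_cfg)
    frame = assignments_to_frame(assignments)
    frame.to_csv(out / "pools.tsv", sep="\t", index=False)
    summary.artifacts["pools"] = str(out / "pools.tsv")
    summary.counts = pool_summary.as_dict()
    logger.info("stage classify: %s", summary.counts)

    # --- optional stage: gene-set enrichment -------------------------------
    if "enrich" in cfg:
        e = cfg["enrich"]
        sets = tables_io.read_gene_sets(e["gene_sets"])
        target = {a.gene_id for a in assignments if a.in_pool2}
        background = {
            a.gene_id for a in assignments if a.in_pool1 and not a.in_pool2
        }
        results = gene_set_enrichment(target, background, sets, e.get("method", "hypergeometric"))
        enrichment_to_frame(results, sets).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        summary.artifacts["enrichment"] = str(out / "enrichment.tsv")
        logger.info("stage enrich: %d gene sets scored", len(results))

    # --- optional stage: motif discovery / locus scan ----------------------
    if "motifs" in cfg:
        msec = cfg["motifs"]
        sim_cfg = SimulationConfig(
            seed=seed,
            n_genes=msec.get("n_genes", 120),
            motif_plant_rate_target=msec.get("plant_rate_target", 0.4),
            motif_plant_rate_background=msec.get("plant_rate_background", 0.05),
        )
        genome, models, mtruth = simulate_genome_with_motifs(
            sim_cfg, gene_length=msec.get("gene_length", 1000)
        )
        promoters = extract_promoters(models, genome, PromoterWindow())
        targets = {g: promoters[g] for g in sorted(mtruth.target_genes)}
        background = {g: s for g, s in promoters.items() if g not in mtruth.target_genes}
        found = denovo_discover(
            targets,
            background,
            k=msec.get("k", 10),
            max_mm=msec.get("max_mm", 1),
            min_fold=msec.get("min_fold", 3.5),
        )
        tables_io.write_motif_file([m for m, _ in found], out / "motifs.txt")
        summary.artifacts["motifs"] = str(out / "motifs.txt")
        summary.counts["denovo_motifs"] = len(found)
        if found:
            hits_path = out / "hits.bed"
            with open(hits_path, "w") as fh:
                for model in models:
                    for h in scan_locus(model, genome, found[0][0], LocusWindow()):
                        fh.write(
                            f"{h.seq_id}\t{h.offset}\t{h.offset + len(found[0][0])}\t"
                            f"{found[0][0].motif_id}\t{h.mismatches}\t{h.strand}\n"
                        )
            summary.artifacts["hits"] = str(hits_path)
        logger.info("stage motifs: %d motifs discovered", len(found))

    # --- optional stage: three-set overlap ----------------------------------
    if "overlap" in cfg:
        o = cfg["overlap"]
        part = venn3(
            tables_io.read_gene_list(o["a"]),
            tables_io.read_gene_list(o["b"]),
            tables_io.read_gene_list(o["c"]),
        )
        with open(out / "venn.json", "w") as fh:
            json.dump(
                {"counts": part.region_counts, "members": part.region_members},
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        summary.artifacts["venn"] = str(out / "venn.json")
        logger.info("stage overlap: %s", part.region_counts)

    summary.to_json(out / "summary.json")
    summary.artifacts["summary"] = str(out / "summary.json")
    return summary
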