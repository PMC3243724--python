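"""End-to-end orchestration: configuration, validation, and report bundling."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import expression as expr_mod
from . import genome as genome_mod
from . import growth as growth_mod
from . import itc as itc_mod
from . import orthology as orth_mod

logger = logging.getLogger("pulscape")


@dataclass
class RunConfig:
    """All tunables of the pipeline with their study-derived defaults."""

    # inputs (any may be None to skip the stage)
    genome_a: str | None = None
    genome_b: str | None = None
    genome_format: str = "tsv"
    hits_ab: str | None = None
    hits_ba: str | None = None
    expression_matrix: str | None = None
    reference_condition: str = "MM-G"
    plate_csv: str | None = None
    layout_tsv: str | None = None
    itc_series: list[dict] = field(default_factory=list)  # {path, metadata, model}
    # tunables
    max_gap: int = 1
    merge_within: int = 5
    regulator_window: int = 3
    e_cutoff: float = 1e-10
    flank_window: int = 5
    similar_frac: float = 0.25
    min_syntenic: int = 3
    fold_cutoff: float = 10.0
    max_intergenic_bp: int = 150
    alpha: float = 0.01
    baseline_window_min: float = 500.0
    rise_fraction: float = 0.10
    no_growth_floor: float = 0.1
    temperature: float = 298.15
    seed: int = 0
    out_dir: str = "pulscape_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations (empty when the config is valid)."""
    v: list[str] = []
    if config.fold_cutoff <= 1:
        v.append("fold_cutoff must be > 1")
    if config.e_cutoff <= 0:
        v.append("e_cutoff must be > 0")
    if config.flank_window < 1:
        v.append("flank_window must be >= 1")
    if config.max_gap < 0 or config.merge_within < 0:
        v.append("max_gap and merge_within must be >= 0")
    if not (0 < config.alpha < 1):
        v.append("alpha must be in (0, 1)")
    if config.baseline_window_min <= 0:
        v.append("baseline_window_min must be > 0")
    if not (0 < config.rise_fraction < 1):
        v.append("rise_fraction must be in (0, 1)")
    if config.no_growth_floor < 0:
        v.append("no_growth_floor must be >= 0")
    if config.temperature <= 0:
        v.append("temperature must be > 0 K")
    if not (0 <= config.similar_frac <= 1):
        v.append("similar_frac must be in [0, 1]")
    for path_attr in ("genome_a", "genome_b", "hits_ab", "hits_ba",
                      "expression_matrix", "plate_csv", "layout_tsv"):
        p = getattr(config, path_attr)
        if p is not None and not Path(p).exists():
            v.append(f"{path_attr}: no such file {p!r}")
    return v


def run_full_comparison(config: RunConfig) -> dict:
    """Run every configured stage and write a report bundle.

    Stages with missing inputs are skipped and logged.  Returns the manifest
    (also written as ``manifest.json``), which records the package version,
    seed, config hash, and the outputs of each stage.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "pulscape_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": {},
    }
    try:
        ann_a = ann_b = None
        puls_a = puls_b = None
        if config.genome_a is not None:
            logger.info("stage detect: genome A")
            ann_a = genome_mod.read_gene_table(config.genome_a, format=config.genome_format)
            puls_a = genome_mod.detect_puls(ann_a, config.max_gap, config.merge_within)
            genome_mod.write_pul_report(puls_a, ann_a, out / "puls_a.tsv")
            manifest["stages"]["detect_a"] = {"n_puls": len(puls_a), "n_genes": len(ann_a)}
        if config.genome_b is not None:
            logger.info("stage detect: genome B")
            ann_b = genome_mod.read_gene_table(config.genome_b, format=config.genome_format)
            puls_b = genome_mod.detect_puls(ann_b, config.max_gap, config.merge_within)
            genome_mod.write_pul_report(puls_b, ann_b, out / "puls_b.tsv")
            manifest["stages"]["detect_b"] = {"n_puls": len(puls_b), "n_genes": len(ann_b)}

        if ann_a and ann_b and config.hits_ab and config.hits_ba:
            logger.info("stage compare: orthology classification")
            hits_ab = orth_mod.read_blast_table(config.hits_ab)
            hits_ba = orth_mod.read_blast_table(config.hits_ba)
            calls, summary = orth_mod.compare_genomes(
                ann_a, ann_b, puls_a, puls_b, hits_ab, hits_ba,
                e_cutoff=config.e_cutoff, window=config.flank_window,
                similar_frac=config.similar_frac, min_syntenic=config.min_syntenic,
            )
            orth_mod.calls_to_table(calls).to_csv(out / "orthology_calls.tsv", sep="\t", index=False)
            with open(out / "orthology_summary.json", "w") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True)
            manifest["stages"]["compare"] = summary["tiers_a"]
        else:
            logger.info("stage compare skipped (missing genomes or hit tables)")

        if config.expression_matrix is not None and ann_a is not None:
            logger.info("stage express: fold changes and operon induction")
            profile = expr_mod.read_expression_tsv(config.expression_matrix, config.reference_condition)
            fc = expr_mod.fold_changes(profile)
            operons = expr_mod.group_operons(ann_a, config.max_intergenic_bp)
            expr_mod.heatmap_matrix(fc[profile.conditions], operons, out / "operon_heatmap.tsv")
            summary = expr_mod.regulated_summary(
                fc[profile.conditions], puls_a or (), ann_a, cutoff=config.fold_cutoff
            )
            with open(out / "expression_summary.json", "w") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True)
            manifest["stages"]["express"] = {
                k: summary[k] for k in ("n_regulated", "n_up", "n_down", "pct_up", "pct_up_in_pul")
            }
        else:
            logger.info("stage express skipped (no expression matrix)")

        if config.plate_csv is not None:
            logger.info("stage growth: plate quantification")
            plate = growth_mod.read_plate_csv(config.plate_csv)
            layout = growth_mod.read_layout_tsv(config.layout_tsv) if config.layout_tsv else None
            metrics = growth_mod.analyze_plate(
                plate, layout,
                baseline_window_min=config.baseline_window_min,
                rise_fraction=config.rise_fraction,
                min_density=config.no_growth_floor,
            )
            metrics.to_csv(out / "growth_metrics.tsv", sep="\t", index=False)
            manifest["stages"]["growth"] = {
                "n_wells": int(len(metrics)), "n_grew": int(metrics["grew"].sum())
            }
        else:
            logger.info("stage growth skipped (no plate)")

        itc_results = []
        for spec_ in config.itc_series:
            logger.info("stage itc: fitting %s", spec_["path"])
            series = itc_mod.read_titration_tsv(spec_["path"], spec_["metadata"])
            fit = itc_mod.fit_isotherm(series, model=spec_.get("model", "one_site"),
                                       seed=config.seed)
            itc_results.append({"path": spec_["path"], **itc_mod.fit_to_dict(fit)})
        if itc_results:
            with open(out / "itc_fits.json", "w") as fh:
                json.dump(itc_results, fh, indent=1, sort_keys=True)
            manifest["stages"]["itc"] = {"n_series": len(itc_results)}
    except Exception as exc:  # re-raise with stage context preserved in the log
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
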