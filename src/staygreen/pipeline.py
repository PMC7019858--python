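"""Pipeline driver chaining simulate -> canopy -> BLUEs -> progress -> GWAS.

A :class:`PipelineConfig` (usually loaded from YAML) names the input files,
enables stages, and carries the stage parameter blocks. Each run writes its
outputs plus a JSON manifest (inputs, parameters, seed, package version) to
the output directory; deterministic stages are bit-identical on rerun.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association as assoc
from . import breeding_progress as bp
from . import canopy_traits as ct
from . import io as sgio
from . import mixed_model as mm
from . import synthetic_data as sd

log = logging.getLogger("staygreen")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    out_dir: str = "staygreen_out"
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "blues", "progress", "gwas"]
    )
    # file inputs (used when 'simulate' is disabled)
    phenotype_csv: str | None = None
    genotype_tsv: str | None = None
    marker_map_csv: str | None = None
    scoring_csv: str | None = None
    weather_csv: str | None = None
    # simulate block
    n_cultivars: int = 50
    release_span: tuple[int, int] = (1966, 2013)
    n_seasons: int = 3
    n_reps: int = 2
    trait_means: dict = field(default_factory=lambda: {"yield": 8.0, "gcd": 330.0})
    trait_slopes: dict = field(default_factory=lambda: {"yield": 0.04, "gcd": 2.0})
    var_components: dict = field(
        default_factory=lambda: {
            "yield": (0.3, 0.2, 0.02, 0.02, 0.6),
            "gcd": (500.0, 520.0, 30.0, 30.0, 1200.0),
        }
    )
    n_markers: int = 500
    n_groups: int = 5
    missing_rate: float = 0.02
    causal_region: tuple | None = ("6A", 400.0, 442.0, -15.0)
    causal_trait: str = "gcd"
    # analysis blocks
    window_size: int = 10
    ref_years: tuple[int, int] = (1970, 2010)
    segmented: bool = False
    qc_max_missing: float = 0.10
    qc_min_maf: float = 0.05
    alpha: float = 0.05
    fdr_rate: float = 0.10
    k_groups: int = 5
    gwas_trait: str = "gcd"

    def validate(self) -> None:
        order = ["simulate", "canopy", "blues", "progress", "gwas"]
        unknown = [s for s in self.stages if s not in order]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; valid: {order}")
        self.stages = [s for s in order if s in self.stages]
        if "simulate" not in self.stages:
            if ("blues" in self.stages or "progress" in self.stages) and not self.phenotype_csv:
                raise ValueError("phenotype_csv required when simulate is disabled")
            if "gwas" in self.stages and not (self.genotype_tsv and self.marker_map_csv):
                raise ValueError("genotype_tsv and marker_map_csv required for gwas")
        for p in (self.phenotype_csv, self.genotype_tsv, self.marker_map_csv,
                  self.scoring_csv, self.weather_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        if not (0 < self.alpha < 1) or not (0 < self.fdr_rate < 1):
            raise ValueError("alpha and fdr_rate must lie in (0, 1)")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**raw)
    for key in ("release_span", "ref_years", "causal_region"):
        val = getattr(cfg, key)
        if isinstance(val, list):
            setattr(cfg, key, tuple(val))
    cfg.var_components = {k: tuple(v) for k, v in cfg.var_components.items()}
    return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {k: v for k, v in asdict(config).items()},
        "outputs": {},
        "timings_s": {},
    }

    panel = None
    geno = None
    blues = None

    for stage in config.stages:
        t0 = time.perf_counter()
        log.info("stage %s: starting", stage)
        try:
            if stage == "simulate":
                pc = sd.PanelConfig(
                    n_cultivars=config.n_cultivars,
                    release_span=config.release_span,
                    n_seasons=config.n_seasons,
                    n_reps=config.n_reps,
                    trait_means=config.trait_means,
                    trait_slopes=config.trait_slopes,
                    var_components=config.var_components,
                    seed=config.seed,
                )
                panel = sd.simulate_panel(pc)
                gc = sd.GenoSimConfig(
                    n_markers=config.n_markers,
                    n_groups=config.n_groups,
                    missing_rate=config.missing_rate,
                    causal_region=config.causal_region,
                    seed=config.seed,
                )
                geno = sd.simulate_genotypes(gc, panel)
                if geno.causal_values is not None:
                    panel = sd.apply_causal_effect(panel, geno, config.causal_trait)
                sgio.write_phenotypes(panel, out / "phenotypes.csv")
                sgio.write_genotypes(geno, out / "genotypes")
                weather = sd.simulate_weather(seed=config.seed)
                weather.to_csv(out / "weather.csv", index=False)
                manifest["outputs"]["simulate"] = [
                    "phenotypes.csv", "genotypes.tsv", "genotypes_map.csv", "weather.csv",
                ]
                log.info("stage simulate: %d cultivars, %d markers",
                         config.n_cultivars, config.n_markers)

            elif stage == "canopy":
                scorings = sgio.read_scorings(config.scoring_csv)
                traits = ct.fit_plot_table(scorings)
                traits.to_csv(out / "canopy_traits.csv", index=False)
                manifest["outputs"]["canopy"] = ["canopy_traits.csv"]
                log.info("stage canopy: %d fits, %d converged",
                         len(traits), int(traits["converged"].sum()))

            elif stage == "blues":
                if panel is None:
                    panel = sgio.read_phenotypes(config.phenotype_csv)
                frames = []
                vc_rows = []
                for trait in sorted(panel["trait"].unique()):
                    fit = mm.fit_mixed_model(panel, mm.ModelSpec.blue_model(trait).restrict_to(panel.columns))
                    frames.append(mm.estimate_blues(fit))
                    rfit = mm.fit_mixed_model(panel, mm.ModelSpec.fully_random(trait).restrict_to(panel.columns))
                    n_env = panel["season"].nunique()
                    n_reps = panel["rep"].nunique()
                    vc_rows.append(
                        {
                            "trait": trait,
                            **rfit.vc.as_dict(),
                            "H2": mm.heritability(rfit.vc, n_env, n_reps),
                            "n_env": n_env,
                            "n_reps": n_reps,
                        }
                    )
                blues = pd.concat(frames, ignore_index=True)
                sgio.write_blues(blues, out / "blues.csv")
                pd.DataFrame(vc_rows).to_csv(out / "variance_components.csv", index=False)
                manifest["outputs"]["blues"] = ["blues.csv", "variance_components.csv"]

            elif stage == "progress":
                if blues is None:
                    blues = sgio.read_blues(out / "blues.csv")
                traits = sorted(blues["trait"].unique())
                rep = bp.progress_report(
                    blues, traits, window_size=config.window_size,
                    ref_years=config.ref_years, segmented=config.segmented,
                )
                rep.to_csv(out / "progress.csv", index=False)
                for trait in traits:
                    ws = bp.sliding_window(blues, trait, window_size=config.window_size)
                    ws.to_frame().to_csv(out / f"windows_{trait}.csv", index=False)
                manifest["outputs"]["progress"] = ["progress.csv"] + [
                    f"windows_{t}.csv" for t in traits
                ]

            elif stage == "gwas":
                if geno is None:
                    geno = sgio.read_genotypes(config.genotype_tsv, config.marker_map_csv)
                if blues is None:
                    blues = sgio.read_blues(out / "blues.csv")
                geno_qc, qc_report = assoc.marker_qc(
                    geno, max_missing=config.qc_max_missing, min_maf=config.qc_min_maf
                )
                K = assoc.kinship(geno_qc)
                structure = assoc.population_structure(
                    geno_qc, k=config.k_groups, seed=config.seed
                )
                scan = assoc.association_scan(
                    blues, geno_qc, K, structure, trait=config.gwas_trait
                )
                thresholds = assoc.significance_thresholds(
                    geno_qc.n_markers, alpha=config.alpha, fdr_rate=config.fdr_rate,
                    pvalues=scan["p_value"],
                )
                scan.to_csv(out / "association.csv", index=False)
                with open(out / "gwas_thresholds.json", "w") as fh:
                    json.dump(
                        {
                            "qc": asdict(qc_report),
                            "bonferroni_neglog10": thresholds.bonferroni_neglog10,
                            "bh_p_cutoff": thresholds.bh_p_cutoff,
                            "n_bh_rejected": thresholds.n_bh_rejected,
                            "delta": scan.attrs.get("delta"),
                        },
                        fh,
                        indent=2,
                    )
                manifest["outputs"]["gwas"] = ["association.csv", "gwas_thresholds.json"]
                log.info("stage gwas: %d markers post-QC, %d BH rejections",
                         geno_qc.n_markers, thresholds.n_bh_rejected)
        except Exception as exc:
            manifest["failed_stage"] = stage
            manifest["error"] = str(exc)
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, default=str)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
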