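"""End-to-end pipeline: simulate -> screen -> fit/select -> predict ->
vulnerability -> report, driven by a single validated config.

One global seed deterministically spawns per-stage substreams, so a
rerun with the same config reproduces bit-identical numerical outputs.
Artifacts land in a fixed directory layout (covariates/, screening/,
fits/, selection/, surfaces/, vulnerability/, logs/) with a manifest
recording the config hash, seed, package version and a checksum of
every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import derive_rugosity, screen_covariates, standardize
from .io import write_observations, write_stack, write_surface
from .matern import MaternParams
from .model import HurdleFit, InferenceConfig, ModelSpec, fit_conditional_lognormal, fit_occurrence
from .predict import delta_map, predict_surface
from .selection import forward_select
from .synthetic import (
    SCENARIO_DELTAS,
    ModelTruth,
    make_future_covariates,
    make_grid,
    simulate_covariates,
    simulate_observations,
)
from .vulnerability import (
    classify,
    class_area_change,
    kde_compare,
    max_standardize,
    overlap,
    quartile_thresholds,
)

_ALLOWED = {
    "seed": None,
    "grid": {"extent", "resolution", "coastline"},
    "covariates": {"spec"},
    "observations": {"n_sites", "records_per_site"},
    "truth": {"cover", "bleaching"},
    "screening": {"gvif_threshold", "corr_threshold", "exclude"},
    "selection": {"enabled", "candidates", "exhaustive", "include_spatial_step"},
    "inference": {
        "n_draws", "sigma_grid", "range_fractions", "nu",
        "sigma2_grid_size", "sigma2_grid_spread", "max_iter", "metric",
    },
    "scenarios": None,
    "vulnerability": {"thresholds", "standardize_future_by"},
}

_TRUTH_KEYS = {
    "alpha_occ", "alpha_cond", "beta_occ", "beta_cond", "sigma2_cond",
    "matern_occ", "matern_cond",
}


class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected by name)."""

    def __init__(self, raw: dict):
        unknown = sorted(set(raw) - set(_ALLOWED))
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        if "seed" not in raw:
            raise ValueError("config is missing required key 'seed'")
        for section, allowed in _ALLOWED.items():
            if allowed is None or section not in raw:
                continue
            sub = raw[section] or {}
            bad = sorted(set(sub) - allowed)
            if bad:
                raise ValueError(f"unknown key(s) in config section {section!r}: {bad}")
        for kind, spec in (raw.get("truth") or {}).items():
            bad = sorted(set(spec or {}) - _TRUTH_KEYS)
            if bad:
                raise ValueError(f"unknown key(s) in truth.{kind}: {bad}")
        self.raw = raw
        self.seed = int(raw["seed"])

    def section(self, name: str) -> dict:
        return dict(self.raw.get(name) or {})

    def hash(self) -> str:
        canonical = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _truth_from_config(spec: dict) -> ModelTruth:
    spec = dict(spec)
    for key in ("matern_occ", "matern_cond"):
        if spec.get(key) is not None:
            m = spec[key]
            spec[key] = MaternParams(m["sigma"], m["range"], m.get("nu", 1.0))
    return ModelTruth(**spec)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig | dict, out_dir) -> Path:
    """Run every stage; returns the run directory.

    A stage failure aborts with the stage name while keeping partial
    artifacts and the log on disk.
    """
    if isinstance(config, dict):
        config = PipelineConfig(config)
    out = Path(out_dir)
    for sub in ("covariates", "screening", "fits", "selection", "surfaces",
                "vulnerability", "logs"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    logger = logging.getLogger(f"reefvuln.pipeline.{id(config)}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(out / "logs" / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    warnings_record: list[str] = []

    seeds = _stage_seeds(config.seed)
    stage = "simulate"
    try:
        t0 = time.time()
        # ---------------------------------------------------- simulate
        gsec = config.section("grid")
        grid = make_grid(
            tuple(gsec.get("extent", (-4.0, -1.0, 40.0, 42.0))),
            resolution=float(gsec.get("resolution", 0.08)),
            coastline_profile=gsec.get("coastline"),
            seed=seeds[0],
        )
        stack = simulate_covariates(grid, seeds[1], spec=config.section("covariates").get("spec"))
        rug = np.full(grid.shape, np.nan)
        rug_full = derive_rugosity(stack["bathymetry"], cell_size=grid.resolution)
        rug[grid.mask] = rug_full[grid.mask]
        stack.add("rugosity", rug)
        write_stack(stack, out / "covariates" / "current.csv")

        obssec = config.section("observations")
        n_sites = int(obssec.get("n_sites", 150))
        rps = int(obssec.get("records_per_site", 1))
        truths = config.section("truth")
        truth_cover = _truth_from_config(truths.get("cover") or {})
        truth_bleach = _truth_from_config(truths.get("bleaching") or {})
        obs_cover = simulate_observations(
            grid, stack, truth_cover, n_sites, seeds[2], "cover", rps
        )
        obs_bleach = simulate_observations(
            grid, stack, truth_bleach, n_sites, seeds[3], "bleaching", rps
        )
        if obs_cover.n_capped or obs_bleach.n_capped:
            warnings_record.append(
                f"capped z draws: cover={obs_cover.n_capped}, bleaching={obs_bleach.n_capped}"
            )
        write_observations(obs_cover, out / "covariates" / "observations_cover.csv")
        write_observations(obs_bleach, out / "covariates" / "observations_bleaching.csv")
        logger.info("simulate: grid %s, %d sea cells, %d sites (%.1fs)",
                    grid.shape, grid.n_sea, n_sites, time.time() - t0)

        # ------------------------------------------------------ screen
        stage = "screen"
        t0 = time.time()
        ssec = config.section("screening")
        exclude = set(ssec.get("exclude") or [])
        names = [n for n in stack.names if n not in exclude]
        report = screen_covariates(
            stack, obs_cover, names=names,
            gvif_threshold=float(ssec.get("gvif_threshold", 3.0)),
            corr_threshold=float(ssec.get("corr_threshold", 0.70)),
        )
        report.correlation_matrix.to_csv(out / "screening" / "correlation_matrix.csv")
        report.gvif_table.to_csv(out / "screening" / "gvif_table.csv")
        (out / "screening" / "audit.txt").write_text(report.to_text() + "\n")
        logger.info("screen: retained %s (%.1fs)", report.retained, time.time() - t0)

        # -------------------------------------------------- fit/select
        stage = "fit"
        t0 = time.time()
        _, standardization = standardize(stack)
        isec = config.section("inference")
        inf = InferenceConfig(seed=seeds[4], **{k: v for k, v in isec.items()})
        selsec = config.section("selection")
        candidates = selsec.get("candidates") or report.retained
        candidates = [c for c in candidates if c in report.retained]

        fits = {}
        if selsec.get("enabled", True):
            stage = "select"
            for label, obs, kind in (
                ("occurrence", obs_cover, "occurrence"),
                ("cover", obs_cover, "cover"),
                ("bleaching", obs_bleach, "bleaching"),
            ):
                trace = forward_select(
                    obs, stack, candidates, config=inf, response_kind=kind,
                    standardization=standardization,
                    include_spatial_step=bool(selsec.get("include_spatial_step", True)),
                    exhaustive=bool(selsec.get("exhaustive", False)),
                )
                trace.to_csv(out / "selection" / f"trace_{label}.csv")
                fits[label] = trace.best_fit
                logger.info("select %s: best = %s", label, trace.best.label())
        else:
            spec_kw = dict(covariate_names=candidates, include_spatial=True)
            fits["occurrence"] = fit_occurrence(
                obs_cover, stack, ModelSpec("occurrence", **spec_kw), inf, standardization
            )
            fits["cover"] = fit_conditional_lognormal(
                obs_cover.presence_subset(), stack,
                ModelSpec("cover", **spec_kw), inf, standardization,
            )
            fits["bleaching"] = fit_conditional_lognormal(
                obs_bleach.presence_subset(), stack,
                ModelSpec("bleaching", **spec_kw), inf, standardization,
            )
        for label, fit in fits.items():
            fit.params.to_csv(out / "fits" / f"params_{label}.csv")
            if not all(fit.diagnostics.get("converged", [True])):
                warnings_record.append(f"fit {label}: some hyper-grid points not converged")
        logger.info("fit: %d models (%.1fs)", len(fits), time.time() - t0)

        # ----------------------------------------------------- predict
        stage = "predict"
        t0 = time.time()
        scen_cfg = config.raw.get("scenarios") or {
            k: dict(v) for k, v in SCENARIO_DELTAS.items()
        }
        stacks = {"current": stack}
        for scen in sorted(scen_cfg):
            stacks[scen] = make_future_covariates(stack, scen, deltas=scen_cfg[scen])

        hurdle_cover = HurdleFit(fits["occurrence"], fits["cover"])
        hurdle_bleach = HurdleFit(fits["occurrence"], fits["bleaching"])
        surfaces: dict[str, dict] = {}
        for scen, st in stacks.items():
            surfaces[scen] = {
                "occurrence": predict_surface(fits["occurrence"], st),
                "cover": predict_surface(hurdle_cover, st),
                "bleaching": predict_surface(hurdle_bleach, st),
            }
            for label, surf in surfaces[scen].items():
                write_surface(surf, out / "surfaces" / f"{label}_{scen}.csv")
                if surf.n_nearest_fallback:
                    warnings_record.append(
                        f"surface {label}/{scen}: {surf.n_nearest_fallback} cells used "
                        "nearest-site fallback outside the site hull"
                    )
        for scen in sorted(scen_cfg):
            for label in ("occurrence", "cover", "bleaching"):
                d = delta_map(surfaces[scen][label], surfaces["current"][label])
                _write_delta(d, out / "surfaces" / f"delta_{label}_{scen}.csv")
        logger.info("predict: %d scenario(s) (%.1fs)", len(stacks), time.time() - t0)

        # ----------------------------------------------- vulnerability
        stage = "vulnerability"
        t0 = time.time()
        vsec = config.section("vulnerability")
        by = vsec.get("standardize_future_by", "current")
        current_max = {
            label: float(np.nanmax(surfaces["current"][label].sea_values()))
            for label in ("occurrence", "cover", "bleaching")
        }
        vulns = {}
        for scen in stacks:
            parts = {}
            for label in ("occurrence", "cover", "bleaching"):
                mx = current_max[label] if by == "current" else None
                parts[label] = max_standardize(surfaces[scen][label], maximum=mx)
            vulns[scen] = overlap(
                parts["occurrence"], parts["cover"], parts["bleaching"],
                check_standardized=(scen == "current" or by != "current"),
            )

        thr_cfg = vsec.get("thresholds", "auto")
        override = None if thr_cfg in (None, "auto") else tuple(thr_cfg)
        thresholds = quartile_thresholds(vulns["current"], override=override)

        reports = {}
        for scen, v in vulns.items():
            classified, rep = classify(v, thresholds)
            reports[scen] = rep
            _write_vuln(classified, out / "vulnerability" / f"vulnerability_{scen}.csv")
        area_df = pd.concat([reports[s].to_frame() for s in sorted(reports)], ignore_index=True)
        area_df.to_csv(out / "vulnerability" / "area_report.csv", index=False)
        changes = []
        for scen in sorted(scen_cfg):
            ch = class_area_change(reports["current"], reports[scen])
            ch["scenario"] = scen
            changes.append(ch)
        pd.concat(changes, ignore_index=True).to_csv(
            out / "vulnerability" / "class_area_change.csv", index=False
        )
        kde = kde_compare(
            [vulns["current"]] + [vulns[s] for s in sorted(scen_cfg)],
            thresholds=thresholds,
        )
        kde.summary.to_csv(out / "vulnerability" / "kde_summary.csv", index=False)
        dens = pd.DataFrame({"value": kde.eval_grid, **kde.densities})
        dens.to_csv(out / "vulnerability" / "kde_densities.csv", index=False)
        logger.info("vulnerability: thresholds %s (%.1fs)", thresholds, time.time() - t0)

        # ---------------------------------------------------- manifest
        files = sorted(
            p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
            and p.suffix != ".log"
        )
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.hash(),
            "thresholds": list(thresholds),
            "warnings": warnings_record,
            "files": {str(p.relative_to(out)): _checksum(p) for p in files},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("pipeline complete")
        return out
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        handler.close()
        logger.removeHandler(handler)


def _write_delta(delta, path) -> None:
    grid = delta.grid
    centers = grid.sea_centers()
    pd.DataFrame(
        {
            "lat": centers[:, 0],
            "lon": centers[:, 1],
            "delta": delta.values[grid.mask],
        }
    ).to_csv(path, index=False)


def _write_vuln(v, path) -> None:
    grid = v.grid
    centers = grid.sea_centers()
    pd.DataFrame(
        {
            "lat": centers[:, 0],
            "lon": centers[:, 1],
            "value": v.values[grid.mask],
            "class": np.asarray(v.class_map)[grid.mask],
        }
    ).to_csv(path, index=False)
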