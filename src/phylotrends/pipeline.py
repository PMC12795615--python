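"""End-to-end orchestration: simulate/load → clean → bin → PD → trends.

One flat configuration drives every stage; a single root seed derives the
sub-seeds of each stochastic step, so rerunning the same config yields
byte-identical CSV outputs (the manifest's wall timestamps are the only
run-specific values, and they live outside the CSVs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg as sla
import yaml

from . import __version__
from ._util import derive_seed, pairwise_haversine
from .phylometrics import pd_table
from .records import (
    DEFAULT_REGION_BOXES,
    apply_filters,
    assign_regions,
    build_assemblages,
    join_covariates,
    read_occurrences,
)
from .synthetic import ScenarioConfig, generate_dataset, write_dataset
from .trends import (
    TrendDesign,
    aic_select,
    fit_lm,
    fit_spatial_mixed,
    marginal_effects,
    matern_corr,
    model_menu,
    morans_correlogram,
    prepare_trend_frame,
    run_regions,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "make_report", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run (YAML key: value file).

    Synthetic-scenario overrides use dotted keys (``scenario.n_species``).
    """

    mode: str = "synthetic"  # "synthetic" | "files"
    occurrences: Optional[str] = None
    tree: Optional[str] = None
    covariates: Optional[str] = None
    length_min: int = 600
    length_max: int = 700
    min_species: int = 10
    n_rand: int = 99
    rarefaction_m: int = 10
    include_root: bool = True
    null_pool: str = "tree"
    nu: float = 1.5
    fit_spatial: bool = True
    include_env: bool = False
    region_min_rows: int = 30
    bin_edges_km: List[float] = field(default_factory=lambda: [0, 500, 1000, 2000, 4000, 8000])
    n_perm: int = 199
    seed: int = 0
    scenario: Dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "files":
            for name in ("occurrences", "tree"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"files mode requires the {name!r} path")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name} file not found: {path}")
            if self.covariates is not None and not Path(self.covariates).exists():
                raise FileNotFoundError(f"covariates file not found: {self.covariates}")
        if self.nu not in (0.5, 1.5):
            raise ValueError("nu must be 0.5 or 1.5")
        if self.n_rand < 1 or self.rarefaction_m < 1:
            raise ValueError("n_rand and rarefaction_m must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        flat: Dict = {}
        scenario: Dict = {}
        for key, value in raw.items():
            if key.startswith("scenario."):
                scenario[key.split(".", 1)[1]] = value
            elif key == "scenario" and isinstance(value, dict):
                scenario.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat, scenario=scenario)


@dataclass
class RunManifest:
    """Provenance of one run: config hash, stage counts, warnings, timing."""

    config_hash: str
    version: str
    stage_counts: Dict[str, int] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    timestamps: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _load_covariates(path: Optional[str]) -> Optional[pd.DataFrame]:
    if path is None:
        return None
    cov = pd.read_csv(path)
    return cov


def _whitened_residuals(fit, design: TrendDesign) -> np.ndarray:
    """Decorrelate residuals by the fitted covariance (L⁻¹r for Σ = σ²LLᵀ)."""
    X, names, _ = design.matrix(fit.terms)
    keep = [j for j, nm in enumerate(names) if nm in fit.params.index]
    r = design.y - X[:, keep] @ fit.params.to_numpy()
    mp = fit.matern
    if mp is None or mp.sigma2_resid <= 0:
        return r
    n = len(r)
    V = np.eye(n)
    if mp.sigma2_spatial > 0 and np.isfinite(mp.range_rho):
        lat = design.frame["lat_2dp"].to_numpy(dtype=float)
        lon = design.frame["lon_2dp"].to_numpy(dtype=float)
        D = pairwise_haversine(lat, lon)
        V += (mp.sigma2_spatial / mp.sigma2_resid) * matern_corr(D, mp.range_rho, mp.smoothness_nu)
    if mp.sigma2_group > 0 and "decade_site" in design.frame:
        codes, _ = pd.factorize(design.frame["decade_site"], sort=True)
        G = np.zeros((n, codes.max() + 1))
        G[np.arange(n), codes] = 1.0
        V += (mp.sigma2_group / mp.sigma2_resid) * (G @ G.T)
    L = np.linalg.cholesky(V)
    return sla.solve_triangular(L, r, lower=True)


def _fit_to_dict(fit) -> dict:
    d = {
        "kind": fit.kind,
        "terms": list(fit.terms),
        "coefficients": {k: float(v) for k, v in fit.params.items()},
        "se": {k: float(v) for k, v in fit.bse.items()},
        "p": {k: float(v) for k, v in fit.pvalues.items()},
        "loglik": float(fit.loglik),
        "aic": float(fit.aic),
        "n_params": int(fit.n_params),
        "n_obs": int(fit.n_obs),
        "converged": bool(fit.converged),
    }
    if fit.matern is not None:
        d["matern"] = dataclasses.asdict(fit.matern)
    return d


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute every stage in order, writing all artifacts under ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), version=__version__)
    caught: List[str] = []

    def stage(name):
        manifest.timestamps[name] = time.time()

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        # ---- stage 1: inputs --------------------------------------------
        stage("inputs")
        try:
            if config.mode == "synthetic":
                scen_kwargs = dict(config.scenario)
                scen_kwargs.setdefault("seed", derive_seed(config.seed, "scenario"))
                scenario = ScenarioConfig.from_dict(scen_kwargs)
                dataset = generate_dataset(scenario)
                write_dataset(dataset, out)
                occurrences = dataset.occurrence_table
                tree = dataset.true_tree
                covariates = _load_covariates(config.covariates)
            else:
                occurrences = read_occurrences(config.occurrences)
                tree = dendropy.Tree.get(path=config.tree, schema="newick")
                covariates = _load_covariates(config.covariates)
        except Exception as exc:  # noqa: BLE001 — stage-named context
            raise StageError(f"inputs stage failed: {exc}") from exc
        manifest.stage_counts["input_records"] = int(len(occurrences))

        # ---- stage 2: filtering -----------------------------------------
        stage("filter")
        try:
            clean, report = apply_filters(
                occurrences, length_min=config.length_min, length_max=config.length_max
            )
        except Exception as exc:
            raise StageError(f"filter stage failed: {exc}") from exc
        report.to_json(out / "filter_report.json")
        clean.to_csv(out / "filtered.csv", index=False)
        manifest.stage_counts["filtered_records"] = int(len(clean))

        # ---- stage 3: assemblages ---------------------------------------
        stage("assemblages")
        try:
            assemblages, addendum = build_assemblages(clean, min_species=config.min_species)
            assemblages = assign_regions(assemblages, DEFAULT_REGION_BOXES)
            assemblages = join_covariates(assemblages, covariates)
        except Exception as exc:
            raise StageError(f"assemblage stage failed: {exc}") from exc
        report.extra = addendum
        report.to_json(out / "filter_report.json")
        flat = assemblages.copy()
        flat["species"] = [";".join(s) for s in flat["species"]]
        flat.to_csv(out / "assemblages.csv", index=False)
        manifest.stage_counts["assemblages"] = int(len(assemblages))
        manifest.stage_counts["duplicate_records_removed"] = addendum["duplicate_records_removed"]
        manifest.stage_counts["assemblages_dropped_small"] = addendum["assemblages_dropped_small"]

        # ---- stage 4: phylogenetic diversity ----------------------------
        stage("pd")
        try:
            pdres = pd_table(
                assemblages,
                tree,
                n_rand=config.n_rand,
                m=config.rarefaction_m,
                include_root=config.include_root,
                seed=derive_seed(config.seed, "pd"),
            )
        except Exception as exc:
            raise StageError(f"pd stage failed: {exc}") from exc
        meta_cols = ["lat_2dp", "lon_2dp", "year", "region", "has_covariates"] + [
            c for c in ("temperature", "precipitation", "elevation", "land_cover")
            if c in assemblages.columns
        ]
        pdres = pdres.merge(assemblages[meta_cols], on=["lat_2dp", "lon_2dp", "year"], how="left")
        pdres.to_csv(out / "pd_results.csv", index=False)
        manifest.stage_counts["degenerate_ses_mpd"] = int(pdres["degenerate"].sum())

        # ---- stage 5: trend models --------------------------------------
        stage("trends")
        try:
            frame, n_dropped = prepare_trend_frame(pdres)
            manifest.stage_counts["trend_rows"] = int(len(frame))
            manifest.stage_counts["trend_rows_dropped"] = int(n_dropped)
            design = TrendDesign(frame)
            use_env = bool(config.include_env) and bool(frame.get("has_covariates", pd.Series(dtype=bool)).all())
            menu = model_menu(include_env=use_env)
            menu = [[t for t in terms if _usable(design, t)] for terms in menu]
            fits = [fit_lm(design, terms) for terms in menu]
            aic_table, selected_ols = aic_select(fits)
            global_fits = {"menu_aic": aic_table.to_dict(orient="records"),
                           "selected_ols": _fit_to_dict(selected_ols)}

            corr_before = morans_correlogram(
                design.y - _fitted(selected_ols, design),
                frame[["lat_2dp", "lon_2dp"]].to_numpy(),
                config.bin_edges_km,
                n_perm=config.n_perm,
                seed=derive_seed(config.seed, "moran_before"),
            )
            corr_before.to_frame().to_csv(out / "correlogram_before.csv", index=False)

            final_fit = selected_ols
            if config.fit_spatial:
                final_fit = fit_spatial_mixed(design, selected_ols.terms, nu=config.nu)
                global_fits["selected_spatial"] = _fit_to_dict(final_fit)
                corr_after = morans_correlogram(
                    _whitened_residuals(final_fit, design),
                    frame[["lat_2dp", "lon_2dp"]].to_numpy(),
                    config.bin_edges_km,
                    n_perm=config.n_perm,
                    seed=derive_seed(config.seed, "moran_after"),
                )
                corr_after.to_frame().to_csv(out / "correlogram_after.csv", index=False)

            lat_grid = np.round(np.linspace(frame["abs_latitude"].min(), frame["abs_latitude"].max(), 5), 4)
            year_grid = np.round(np.linspace(frame["year"].min(), frame["year"].max(), 5), 0)
            me = marginal_effects(final_fit, lat_grid, year_grid)
            me.to_csv(out / "marginal_effects.csv", index=False)

            region_results, region_skipped = run_regions(
                frame,
                menu,
                fitter="matern" if config.fit_spatial else "ols",
                min_rows=config.region_min_rows,
                nu=config.nu,
            )
            global_fits["regions"] = {
                reg: {
                    "selected": _fit_to_dict(res["selected"]),
                    "menu_aic": res["table"].to_dict(orient="records"),
                }
                for reg, res in region_results.items()
            }
            global_fits["regions_skipped"] = region_skipped
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"trends stage failed: {exc}") from exc
        with open(out / "fits.json", "w", encoding="utf-8") as fh:
            json.dump(global_fits, fh, indent=2, sort_keys=True)

        caught = [str(w.message) for w in wlist]

    manifest.warnings = caught
    stage("done")
    manifest.write(out / "manifest.json")

    # ---- stage 6: report -------------------------------------------------
    report_text = make_report(out)
    (out / "report.md").write_text(report_text, encoding="utf-8")
    return manifest


def _fitted(fit, design: TrendDesign) -> np.ndarray:
    X, names, _ = design.matrix(fit.terms)
    keep = [j for j, nm in enumerate(names) if nm in fit.params.index]
    return X[:, keep] @ fit.params.to_numpy()


def _usable(design: TrendDesign, term: str) -> bool:
    from .trends import _term_available

    return _term_available(design, term)


def make_report(run_dir) -> str:
    """Regenerate the human-readable summary from saved stage outputs.

    Purely a function of the files on disk, so regeneration is identical.
    Missing stage outputs are listed explicitly instead of failing.
    """
    run = Path(run_dir)
    lines: List[str] = ["# Phylogenetic diversity trend report", ""]
    missing = [
        name
        for name in ("filter_report.json", "fits.json", "correlogram_before.csv")
        if not (run / name).exists()
    ]
    if missing:
        lines.append("**Missing stage outputs:** " + ", ".join(missing))
        return "\n".join(lines) + "\n"

    with open(run / "filter_report.json", encoding="utf-8") as fh:
        filt = json.load(fh)
    lines += [
        "## Record cleaning",
        "",
        f"- input records: {filt['input_count']}",
    ]
    for rule, count in filt["removed"].items():
        lines.append(f"- removed ({rule}): {count}")
    lines.append(f"- retained: {filt['output_count']}")
    if "assemblage_stage" in filt:
        a = filt["assemblage_stage"]
        lines += [
            f"- duplicate species records removed in binning: {a['duplicate_records_removed']}",
            f"- assemblages (>= min richness): {a['assemblages']}"
            f" (dropped small: {a['assemblages_dropped_small']})",
        ]
    lines.append("")

    with open(run / "fits.json", encoding="utf-8") as fh:
        fits = json.load(fh)

    def coef_table(fit: dict) -> List[str]:
        rows = ["| term | estimate | SE | p |", "|---|---|---|---|"]
        for name, est in fit["coefficients"].items():
            rows.append(
                f"| {name} | {est:.4f} | {fit['se'][name]:.4f} | {fit['p'][name]:.3g} |"
            )
        return rows

    key = "selected_spatial" if "selected_spatial" in fits else "selected_ols"
    best = fits[key]
    lines += [
        "## Global model",
        "",
        f"Selected terms: {' + '.join(best['terms']) or '(intercept only)'}"
        f"  (AIC {best['aic']:.2f}, {best['kind']}, converged={best['converged']})",
        "",
        *coef_table(best),
        "",
    ]
    corr = pd.read_csv(run / "correlogram_before.csv")
    lines += ["## Residual spatial autocorrelation (pre-correction)", ""]
    lines += ["| bin (km) | Moran's I | p | pairs |", "|---|---|---|---|"]
    for _, r in corr.iterrows():
        ival = "NA" if pd.isna(r["morans_i"]) else f"{r['morans_i']:.4f}"
        pval = "NA" if pd.isna(r["p_perm"]) else f"{r['p_perm']:.3f}"
        lines.append(f"| {r['bin_lo_km']:.0f}–{r['bin_hi_km']:.0f} | {ival} | {pval} | {int(r['n_pairs'])} |")
    lines.append("")
    if (run / "correlogram_after.csv").exists():
        corr2 = pd.read_csv(run / "correlogram_after.csv")
        lines += ["## Residual spatial autocorrelation (post-correction)", ""]
        lines += ["| bin (km) | Moran's I | p | pairs |", "|---|---|---|---|"]
        for _, r in corr2.iterrows():
            ival = "NA" if pd.isna(r["morans_i"]) else f"{r['morans_i']:.4f}"
            pval = "NA" if pd.isna(r["p_perm"]) else f"{r['p_perm']:.3f}"
            lines.append(f"| {r['bin_lo_km']:.0f}–{r['bin_hi_km']:.0f} | {ival} | {pval} | {int(r['n_pairs'])} |")
        lines.append("")

    lines += ["## Regional models", ""]
    for region, res in sorted(fits.get("regions", {}).items()):
        sel = res["selected"]
        lines += [
            f"### {region}",
            "",
            f"Selected terms: {' + '.join(sel['terms']) or '(intercept only)'}"
            f"  (AIC {sel['aic']:.2f}, n={sel['n_obs']})",
            "",
            *coef_table(sel),
            "",
        ]
    for region, reason in sorted(fits.get("regions_skipped", {}).items()):
        lines.append(f"- {region}: skipped — {reason}")
    return "\n".join(lines) + "\n"
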