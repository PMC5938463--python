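"""End-to-end analysis pipeline.

Stages: inputs (simulated or read from files) -> geometric morphometrics
(GPA, allometry correction, PCA/CVA, pairwise group distances) -> clonal
genetics (haplotype divergence, genotype collapsing, median-joining network)
-> mixed models (shape, size, smoothness, brood size with interactions) ->
report.  Every stage writes named CSV/JSON artifacts and the run manifest
records inputs, configuration, seeds, counts and exclusions; stages
communicate only through those artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import pydantic

from . import __version__
from .genetics import (collapse_mlg, encode_genotype_table,
                       locus_variability, read_genotype_csv)
from .landmarks import read_tps
from .mjnetwork import median_joining_network
from .mixed_models import (ModelSpec, build_design, fit_glmm, fit_lmm,
                           r2_nakagawa, reduce_model, wald_type2)
from .procrustes import export_aligned_csv, gpa, tangent_project
from .shape_stats import (allometric_regression, cva, pairwise_group_distances, pca)
from .synthetic import GeneratorConfig, generate_cohort
from .traditional import screen_collinear

log = logging.getLogger("snailmorph")

ENV_COLUMNS = ["temperature", "salinity", "conductivity", "ph", "nitrite",
               "nitrate", "flow", "coverage", "turbidity", "latitude",
               "longitude", "month"]
#: collinearity drops mirroring the survey protocol: salinity duplicates
#: conductivity, longitude duplicates latitude
DEFAULT_DROP_MAP = {"salinity": "conductivity", "longitude": "latitude"}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


DEFAULT_CONFIG = {
    "mode": "simulate",
    "generator": {},          # GeneratorConfig overrides
    "inputs": {},             # landmarks/specimens/sites/genotypes paths
    "n_permutations": 10000,
    "tangent_projection": True,
    "cs_family": "gaussian",
    "embryo_family": "poisson",
    "run_reduction": False,
    "interactions": {
        "pc1": ["flow", "nitrate", "coverage", "ph"],
        "cs": ["flow", "turbidity"],
    },
}


def run(out_dir, config: dict | None = None, seed: int = 0) -> dict:
    """Execute the full pipeline; returns the report dictionary.

    ``config`` overrides :data:`DEFAULT_CONFIG` keys; in "simulate" mode the
    generator writes its files under ``out_dir``/data and the analysis then
    consumes only those files (the same path as real inputs would take).
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package_version": __version__, "seed": seed,
                      "config": {k: v for k, v in cfg.items() if k != "generator"},
                      "stages": {}, "inputs": {}, "exclusions": {}}
    report: dict = {}

    def stage(name):
        t0 = time.time()
        log.info("stage %s", name)

        def done(**counts):
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **counts}
        return done

    # ------------------------------------------------------------------ inputs
    done = stage("inputs")
    if cfg["mode"] == "simulate":
        gen_cfg = GeneratorConfig(**{**cfg["generator"], "seed": seed})
        data_dir = out / "data"
        generate_cohort(gen_cfg, out_dir=data_dir)
        paths = {
            "landmarks": data_dir / "landmarks.tps",
            "specimens": data_dir / "specimens.csv",
            "sites": data_dir / "sites.csv",
            "genotypes": data_dir / "genotypes.csv",
        }
        manifest["generator_config"] = asdict(gen_cfg)
    else:
        paths = {k: Path(v) for k, v in cfg["inputs"].items()}
    for key, p in paths.items():
        manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}
    configs = read_tps(paths["landmarks"])
    specimens = pd.read_csv(paths["specimens"])
    sites = pd.read_csv(paths["sites"])
    genotype_calls = read_genotype_csv(paths["genotypes"])
    done(specimens=len(specimens), sites=len(sites), landmarks=len(configs))

    # ------------------------------------------------------- morphometrics
    done = stage("morphometrics")
    aligned = gpa(configs)
    if cfg["tangent_projection"]:
        aligned = tangent_project(aligned)
    export_aligned_csv(aligned, out / "aligned_coords.csv")
    allom = allometric_regression(aligned, n_perm=cfg["n_permutations"], seed=seed)
    residuals = allom.residuals_
    shape_space = pca(residuals)

    # orient PC1 so the dominant haplotype scores positive (slender morph)
    pc1 = shape_space.scores[:, 0].copy()
    spec_by_id = specimens.set_index("specimen_id")
    haps = spec_by_id.loc[aligned.specimen_ids, "haplotype"].to_numpy()
    dominant = pd.Series(haps).mode().iloc[0]
    pc1_flipped = False
    if pc1[haps == dominant].mean() < 0:
        pc1 = -pc1
        pc1_flipped = True
    manifest["stages"].setdefault("notes", {})
    manifest["pc1_flipped"] = pc1_flipped
    manifest["tangent_projection"] = cfg["tangent_projection"]

    site_labels = spec_by_id.loc[aligned.specimen_ids, "site_id"].to_numpy()
    cv_space = cva(residuals, site_labels)
    dist_table = pairwise_group_distances(residuals, site_labels,
                                          n_perm=cfg["n_permutations"], seed=seed)
    pd.DataFrame({"specimen_id": aligned.specimen_ids, "pc1": pc1,
                  **{f"pc{i + 2}": shape_space.scores[:, i + 1] for i in range(2)},
                  "cs": aligned.centroid_sizes}).to_csv(out / "pc_scores.csv", index=False)
    pd.DataFrame(cv_space.scores,
                 columns=[f"cv{i + 1}" for i in range(cv_space.scores.shape[1])]) \
        .assign(specimen_id=aligned.specimen_ids, site_id=site_labels) \
        .to_csv(out / "cv_scores.csv", index=False)
    pd.DataFrame({
        "axis": [f"pc{i + 1}" for i in range(len(shape_space.pct_variance))],
        "pct_variance": shape_space.pct_variance,
    }).to_csv(out / "variance_table.csv", index=False)
    dist_table.to_frame().to_csv(out / "group_distances.csv", index=False)
    report["morphometrics"] = {
        "n_specimens": aligned.n_specimens,
        "gpa_iterations": aligned.iterations_used,
        "allometry_r_squared": allom.r_squared_,
        "allometry_p": allom.permutation_p_,
        "pc_variance_pct": shape_space.pct_variance[:5].tolist(),
        "pc1_3_pct": float(shape_space.pct_variance[:3].sum()),
        "cv1_3_pct": float(cv_space.pct_variance[:3].sum()),
        "bonferroni_alpha": dist_table.bonferroni_alpha,
    }
    done(pairs=dist_table.n_pairs)

    # ------------------------------------------------------------ genetics
    done = stage("genetics")
    encoded = encode_genotype_table(genotype_calls)
    hap_by_spec = spec_by_id["haplotype"]
    genotypes = collapse_mlg(
        encoded.tolist(), specimen_ids=encoded.index.tolist(),
        haplotypes=hap_by_spec.loc[encoded.index].tolist(),
    )
    fixed, variable = locus_variability(genotypes)
    network = median_joining_network(genotypes)
    network.write_edge_csv(out / "network_edges.csv")
    network.write_graphml(out / "network.graphml")
    report["genetics"] = {
        "n_genotypes": len(genotypes),
        "genotype_counts": {g.genotype_id: g.count for g in genotypes},
        "n_variable_loci": len(variable), "n_fixed_loci": len(fixed),
        "network_nodes": network.graph.number_of_nodes(),
        "network_medians": len(network.median_nodes),
    }
    mlg_of = {}
    for g in genotypes:
        for m in g.members:
            mlg_of[m] = g.genotype_id
    done(genotypes=len(genotypes))

    # -------------------------------------------------------------- models
    done = stage("models")
    merged = specimens.merge(sites, on="site_id")
    merged = merged.set_index("specimen_id").loc[aligned.specimen_ids].reset_index()
    merged["pc1"] = pc1
    merged["cs"] = aligned.centroid_sizes
    merged["mlg"] = merged["specimen_id"].map(mlg_of)
    merged["ridged_int"] = merged["ridged"].astype(int)

    models_report, screen_info = fit_models(merged, cfg)
    manifest["collinearity_dropped"] = screen_info["dropped"]
    manifest["exclusions"].update(screen_info["exclusions"])
    report["models"] = models_report
    coef_rows = [
        {"model": m, "term": t, "coefficient": v,
         "se": models_report[m]["standard_errors"][t]}
        for m in models_report for t, v in models_report[m]["coefficients"].items()
    ]
    pd.DataFrame(coef_rows).to_csv(out / "coefficients.csv", index=False)
    done(models=len(models_report))

    # -------------------------------------------------------------- report
    (out / "model_report.json").write_text(json.dumps(report, indent=1, default=float))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    (out / "report.txt").write_text(render_report(report))
    return report


def fit_models(merged: pd.DataFrame, cfg: dict | None = None):
    """Fit the four mixed models on a merged specimen/site/shape table.

    ``merged`` needs specimen_id, haplotype, mlg, pc1, cs, ridged_int,
    embryo_count and the environment columns.  Returns the models-report
    dictionary and the collinearity-screen/exclusion bookkeeping.
    """
    cfg = {**DEFAULT_CONFIG, **(cfg or {})}
    retained, dropped_pairs = screen_collinear(
        merged[ENV_COLUMNS].apply(
            lambda c: c.map({"none": 0, "low": 1, "high": 2, "clear": 0, "unclear": 1})
            if c.dtype == object else c
        ),
        threshold_tau=0.38, drop_map=DEFAULT_DROP_MAP,
    )
    env_terms = [c for c in ENV_COLUMNS if c in retained]
    models_report: dict = {}
    exclusions: dict = {}

    def run_model(name, response, family, extra_fixed=(), interactions=()):
        spec = ModelSpec(response=response, family=family,
                         fixed=list(extra_fixed) + env_terms,
                         interactions=list(interactions),
                         random=("haplotype", "mlg"))
        design = build_design(merged, spec)
        exclusions[name] = design.n_excluded
        fit = fit_lmm(design) if family == "gaussian" else fit_glmm(design, family)
        r2m, r2c = r2_nakagawa(fit)
        wald = wald_type2(fit)
        models_report[name] = {
            "family": family,
            "coefficients": fit.coefficients.to_dict(),
            "standard_errors": fit.standard_errors.to_dict(),
            "variance_components": fit.variance_components,
            "boundary": fit.boundary,
            "log_likelihood": fit.log_likelihood,
            "r2_marginal": r2m, "r2_conditional": r2c,
            "wald": wald.to_dict(orient="records"),
            "effect_directions": fit.effect_directions().to_dict(orient="records"),
        }
        for key, flag in fit.boundary.items():
            if flag:
                log.warning("%s: variance component %s at boundary (0)", name, key)
        if cfg["run_reduction"] and family == "gaussian":
            final, trail = reduce_model(design, family=family)
            models_report[name]["reduction"] = {
                "retained_terms": [t for t in final.design.terms if t != "Intercept"],
                "dropped": [{"term": s.dropped, "p": s.p_value} for s in trail],
            }
        return fit

    run_model("shape_pc1", "pc1", "gaussian")
    run_model("size_cs", "cs", cfg["cs_family"])
    run_model("smoothness", "ridged_int", "binomial")
    inter = ([("pc1", e) for e in cfg["interactions"]["pc1"] if e in env_terms]
             + [("cs", e) for e in cfg["interactions"]["cs"] if e in env_terms])
    run_model("embryos", "embryo_count", cfg["embryo_family"],
              extra_fixed=["pc1", "cs"], interactions=inter)
    screen_info = {
        "dropped": [{"dropped": d, "kept": k, "tau": t} for d, k, t in dropped_pairs],
        "exclusions": exclusions,
    }
    return models_report, screen_info


def models_from_run(run_dir, config: dict | None = None) -> dict:
    """Re-fit the mixed models from a completed run's persisted artifacts
    (data/ tables plus pc_scores.csv), without re-running earlier stages."""
    run_dir = Path(run_dir)
    specimens = pd.read_csv(run_dir / "data" / "specimens.csv")
    sites = pd.read_csv(run_dir / "data" / "sites.csv")
    genotype_calls = read_genotype_csv(run_dir / "data" / "genotypes.csv")
    scores = pd.read_csv(run_dir / "pc_scores.csv")

    encoded = encode_genotype_table(genotype_calls)
    spec_by_id = specimens.set_index("specimen_id")
    genotypes = collapse_mlg(
        encoded.tolist(), specimen_ids=encoded.index.tolist(),
        haplotypes=spec_by_id["haplotype"].loc[encoded.index].tolist(),
    )
    mlg_of = {m: g.genotype_id for g in genotypes for m in g.members}

    merged = specimens.merge(sites, on="site_id").merge(
        scores[["specimen_id", "pc1", "cs"]], on="specimen_id")
    merged["mlg"] = merged["specimen_id"].map(mlg_of)
    merged["ridged_int"] = merged["ridged"].astype(int)
    models_report, _ = fit_models(merged, config)
    return models_report


class _MorphoSection(pydantic.BaseModel):
    n_specimens: int
    gpa_iterations: int
    allometry_r_squared: float
    allometry_p: float | None
    pc_variance_pct: list[float]
    pc1_3_pct: float
    cv1_3_pct: float
    bonferroni_alpha: float


class _GeneticsSection(pydantic.BaseModel):
    n_genotypes: int
    genotype_counts: dict[str, int]
    n_variable_loci: int
    n_fixed_loci: int
    network_nodes: int
    network_medians: int


class _ModelSection(pydantic.BaseModel):
    family: str
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    variance_components: dict[str, float]
    boundary: dict[str, bool]
    log_likelihood: float
    r2_marginal: float
    r2_conditional: float
    wald: list[dict]
    effect_directions: list[dict]
    reduction: dict | None = None


class ReportSchema(pydantic.BaseModel):
    """Schema of model_report.json; reports validate against this."""

    morphometrics: _MorphoSection | None = None
    genetics: _GeneticsSection | None = None
    models: dict[str, _ModelSection] = {}


def validate_report(report: dict) -> "ReportSchema":
    """Validate a report dictionary against :class:`ReportSchema`."""
    return ReportSchema.model_validate(report)


def render_report(report: dict) -> str:
    """Human-readable summary of a completed (or partial) run."""
    lines = ["snailmorph analysis report", "=" * 30]
    morpho = report.get("morphometrics")
    if morpho:
        lines += [
            f"specimens aligned: {morpho['n_specimens']}",
            f"allometry R^2: {morpho['allometry_r_squared']:.4f} "
            f"(p = {morpho['allometry_p']})",
            f"PC1-3 variance: {morpho['pc1_3_pct']:.2f}%   "
            f"CV1-3 variance: {morpho['cv1_3_pct']:.2f}%",
            f"Bonferroni-adjusted alpha for pairwise distances: "
            f"{morpho['bonferroni_alpha']:.2e}",
        ]
    gen = report.get("genetics")
    if gen:
        lines += [
            f"multilocus genotypes: {gen['n_genotypes']} "
            f"({gen['n_variable_loci']} variable loci)",
            f"network: {gen['network_nodes']} nodes "
            f"({gen['network_medians']} median vectors)",
        ]
    for name, model in report.get("models", {}).items():
        lines.append(f"--- model {name} [{model['family']}] ---")
        for comp, val in model["variance_components"].items():
            lines.append(f"  var({comp}) = {val:.4g}")
        lines.append(f"  R2 marginal = {model['r2_marginal']:.3f}, "
                     f"conditional = {model['r2_conditional']:.3f}")
        sig = [w for w in model["wald"] if w["p"] < 0.05]
        lines.append("  significant terms: "
                     + (", ".join(w["term"] for w in sig) if sig else "none"))
    return "\n".join(lines) + "\n"
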