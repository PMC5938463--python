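"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes: two mitochondrial
lineages at 92%/8% frequency carrying distinct mean shell shapes (slender vs
stout), clonal SNP genotypes nested in lineage with star-like divergence,
environmental effects on shape (weak) and on centroid size (strong, with no
lineage term by default — the headline contrast), allometry, isotropic
landmark noise, and brood counts driven by size, shape-by-flow and
size-by-environment interactions.  All outputs are reproducible bit-for-bit
under a fixed seed.

The generated haplotype sequences are synthetic stand-ins constructed to
show the published divergence pattern (six differing sites per marker);
they are not the deposited sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import (HaplotypeReference, MISSING, decode_genotype,
                       reference_genotypes, write_fasta)
from .landmarks import LandmarkConfiguration, centroid_size, write_tps


def shell_template(width_factor: float = 1.0) -> np.ndarray:
    """A 20-landmark shell outline: apex, six suture points, body-whorl
    extremes, four aperture extremes and seven auxiliary outline points.

    ``width_factor`` scales the x axis: 1.0 gives the slender morph, larger
    values progressively stouter shells.  The configuration is chiral
    (aperture offset to the right), so reflections are detectable.
    """
    pts = np.array([
        (0.00, 1.00),    # 1 apex
        (0.070, 0.85),   # 2 suture right
        (-0.065, 0.78),  # 3 suture left
        (0.115, 0.66),   # 4 suture right
        (-0.105, 0.58),  # 5 suture left
        (0.170, 0.44),   # 6 suture right
        (-0.155, 0.36),  # 7 suture left
        (0.225, 0.18),   # 8 body whorl right
        (-0.210, 0.20),  # 9 body whorl left
        (0.050, 0.245),  # 10 aperture top
        (0.180, 0.10),   # 11 aperture right
        (-0.080, 0.125), # 12 aperture left
        (0.040, 0.00),   # 13 aperture bottom
        (0.045, 0.925),  # 14 aux upper-right outline
        (-0.040, 0.895), # 15 aux upper-left outline
        (0.145, 0.55),   # 16 aux mid-right outline
        (-0.130, 0.47),  # 17 aux mid-left outline
        (0.205, 0.30),   # 18 aux lower-right outline
        (-0.185, 0.28),  # 19 aux lower-left outline
        (-0.060, 0.05),  # 20 aux basal outline
    ])
    pts = pts.copy()
    pts[:, 0] *= width_factor
    return pts


def _unit_shape(pts: np.ndarray) -> np.ndarray:
    centered = pts - pts.mean(axis=0)
    return centered / centroid_size(centered)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the surveyed system: 21 sites of up to 20 specimens
    (~425 snails), lineage frequencies 92%/8%, ten clonal genotypes (the
    published reference set) nested eight/two in the lineages, lineage-driven
    shape with weak environmental modulation, and environment-only control
    of centroid size.
    """

    n_sites: int = 21
    specimens_per_site: int = 20
    haplotype_freqs: dict = field(default_factory=lambda: {"t/22": 0.92, "z2/37": 0.08})
    # genotype frequencies within haplotype (reference genotype ids)
    genotype_freqs: dict = field(default_factory=lambda: {
        "t/22": {"1": 0.80, "2": 0.05, "3": 0.05, "4": 0.02, "5": 0.02,
                 "6": 0.02, "7": 0.01, "8": 0.03},
        "z2/37": {"9": 0.67, "10": 0.33},
    })
    stout_width_factor: float = 1.30       # z2/37 template vs slender t/22
    genotype_shape_sd: float = 0.007       # genotype offsets along the width axis
    genotype_shape_iso_sd: float = 0.002   # plus small isotropic genotype offsets
    # environmental effects on shape, expressed along the widening axis per
    # standardized covariate unit (negative = wider)
    shape_env_effects: dict = field(default_factory=lambda: {
        "temperature": -0.003, "latitude": 0.003, "nitrate": 0.003,
    })
    landmark_noise_sd: float = 0.005       # per coordinate, unit-CS scale
    # centroid size (mm): base + effects per standardized covariate + noise
    cs_base: float = 4.0
    cs_noise_sd: float = 0.20
    cs_env_effects: dict = field(default_factory=lambda: {
        "flow": 0.20, "latitude": 0.15, "turbidity": 0.15,
        "nitrate": -0.15, "coverage": -0.12,
    })
    cs_haplotype_effect: float = 0.0       # no lineage term on size by default
    allometry_strength: float = 0.005      # shape shift per CS sd, along width axis
    # embryo count model (log link): intercept at the observed median count
    embryo_intercept: float = float(np.log(23))
    embryo_cs_effect: float = 0.25
    embryo_env_effects: dict = field(default_factory=lambda: {
        "conductivity": 0.10, "month": 0.10, "latitude": -0.10,
        "flow": -0.15, "turbidity": -0.10, "ph": -0.08, "nitrite": -0.08,
    })
    # interactions: slender-axis score x flow positive (slender does better in
    # flow), size x flow and size x turbidity negative (weaker size benefit)
    embryo_shape_flow: float = 0.15
    embryo_cs_flow: float = -0.10
    embryo_cs_turbidity: float = -0.10
    embryo_family: str = "poisson"         # or "negative_binomial"
    embryo_nb_dispersion: float = 10.0
    ridged_rate_z2: float = 0.45
    ridged_rate_t: float = 0.01
    missing_locus_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if abs(sum(self.haplotype_freqs.values()) - 1) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark noise sd must be >= 0")
        if shell_template().shape != (20, 2):
            raise ValueError("templates must have 20 landmarks")


@dataclass
class SyntheticTruth:
    """Ground-truth record for recovery tests."""

    config: dict
    specimens: pd.DataFrame           # haplotype, genotype, site, true CS, components
    widen_axis: np.ndarray            # unit 40-vector: slender -> stout direction
    template_separation: float        # Procrustes distance between lineage templates

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "widen_axis": self.widen_axis.tolist(),
            "template_separation": self.template_separation,
            "specimens": self.specimens.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def generate_sites(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One row per site: physicochemistry, flow/turbidity classes, position.

    Salinity is generated as a near-deterministic function of conductivity
    (so the collinearity screen has something to find) and longitude is
    correlated with latitude.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_sites
    conductivity = rng.normal(600, 150, n).clip(100, None)
    salinity = conductivity * 5e-4 + rng.normal(0, 0.004, n)
    latitude = rng.normal(52.5, 1.5, n)
    longitude = 4.0 + 1.5 * (latitude - 52.5) + rng.normal(0, 1.6, n)
    df = pd.DataFrame({
        "site_id": [f"S{i + 1:02d}" for i in range(n)],
        "temperature": rng.normal(18, 3, n).round(1),
        "salinity": salinity.round(4),
        "conductivity": conductivity.round(0),
        "ph": rng.normal(7.8, 0.4, n).round(2),
        "nitrite": rng.exponential(0.05, n).round(3),
        "nitrate": rng.exponential(8.0, n).round(2),
        "flow": rng.choice(["none", "low", "high"], n, p=[0.5, 0.3, 0.2]),
        "coverage": rng.uniform(0, 100, n).round(0),
        "turbidity": rng.choice(["clear", "unclear"], n, p=[0.6, 0.4]),
        "latitude": latitude.round(4),
        "longitude": longitude.round(4),
        "month": rng.choice([6, 7, 8, 9], n),
    })
    return df


def synthetic_haplotype_references(rng: np.random.Generator):
    """Synthetic stand-in reference sequences for the two markers.

    16S-like pair (t, z2) of 481 sites and cyt-b-like pair (22, 37) of 497
    sites, each differing at exactly six sites (1.25% and 1.21%).
    """
    refs = {}
    for marker, names, length in (("16S", ("t", "z2"), 481), ("cytb", ("22", "37"), 497)):
        base = "".join(rng.choice(list("ACGT"), length))
        variant = list(base)
        sites = rng.choice(length, 6, replace=False)
        for s in sites:
            current = variant[s]
            variant[s] = rng.choice([b for b in "ACGT" if b != current])
        refs[marker] = [HaplotypeReference(names[0], base),
                        HaplotypeReference(names[1], "".join(variant))]
    return refs


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_cohort(config: GeneratorConfig, out_dir=None):
    """Generate a full synthetic cohort.

    Returns (landmark configs, specimens table, site table, genotype call
    table, haplotype references, SyntheticTruth); with ``out_dir`` set, also
    writes landmarks.tps, specimens.csv, sites.csv, genotypes.csv,
    haplotypes_16s.fasta, haplotypes_cytb.fasta and truth.json.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sites = generate_sites(config, rng)
    refs = synthetic_haplotype_references(rng)
    pool = {g.genotype_id: g for g in reference_genotypes()}

    slender = _unit_shape(shell_template(1.0)).ravel()
    stout = _unit_shape(shell_template(config.stout_width_factor)).ravel()
    widen = stout - slender
    separation = float(np.linalg.norm(widen))
    widen_axis = widen / separation
    templates = {"t/22": slender, "z2/37": stout}

    # per-genotype clonal shape offsets: mostly along the widening axis
    genotype_offsets = {}
    for hap, freqs in config.genotype_freqs.items():
        for gid in freqs:
            along = rng.normal(0, config.genotype_shape_sd)
            iso = rng.normal(0, config.genotype_shape_iso_sd, slender.size)
            genotype_offsets[gid] = along * widen_axis + iso

    # standardized site covariates (site-level, then broadcast to specimens)
    flow_score = sites["flow"].map({"none": 0, "low": 1, "high": 2}).to_numpy(float)
    turb_score = sites["turbidity"].map({"clear": 0, "unclear": 1}).to_numpy(float)
    site_cov = {
        "temperature": _standardize(sites["temperature"].to_numpy(float)),
        "latitude": _standardize(sites["latitude"].to_numpy(float)),
        "nitrate": _standardize(sites["nitrate"].to_numpy(float)),
        "nitrite": _standardize(sites["nitrite"].to_numpy(float)),
        "conductivity": _standardize(sites["conductivity"].to_numpy(float)),
        "ph": _standardize(sites["ph"].to_numpy(float)),
        "coverage": _standardize(sites["coverage"].to_numpy(float)),
        "month": _standardize(sites["month"].to_numpy(float)),
        "flow": _standardize(flow_score),
        "turbidity": _standardize(turb_score),
    }

    hap_names = list(config.haplotype_freqs)
    hap_p = np.array([config.haplotype_freqs[h] for h in hap_names])

    configs: list[LandmarkConfiguration] = []
    spec_rows = []
    geno_rows = []
    truth_rows = []
    loci = pool["1"].loci
    for si in range(config.n_sites):
        site = sites.iloc[si]
        for j in range(config.specimens_per_site):
            sid = f"{site.site_id}_{j + 1:02d}"
            hap = rng.choice(hap_names, p=hap_p)
            gf = config.genotype_freqs[hap]
            gids = list(gf)
            gid = rng.choice(gids, p=np.array([gf[g] for g in gids]) / sum(gf.values()))

            cs_env = sum(config.cs_env_effects[k] * site_cov[k][si]
                         for k in config.cs_env_effects)
            cs_hap = config.cs_haplotype_effect if hap == "z2/37" else 0.0
            cs = config.cs_base + cs_env + cs_hap + rng.normal(0, config.cs_noise_sd)
            cs = max(cs, 0.5)

            shape_env = sum(config.shape_env_effects[k] * site_cov[k][si]
                            for k in config.shape_env_effects) * widen_axis * -1.0
            # convention: positive shape_env_effects push toward slender,
            # i.e. against the widening axis
            allom = config.allometry_strength * ((cs - config.cs_base) / config.cs_noise_sd) \
                * widen_axis
            noise = rng.normal(0, config.landmark_noise_sd, slender.size)
            shape = templates[hap] + genotype_offsets[gid] + shape_env + allom + noise

            pts = shape.reshape(-1, 2)
            pts = pts - pts.mean(axis=0)
            pts = pts / centroid_size(pts) * cs
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
            placed = pts @ rot.T + rng.uniform(-5, 5, 2)
            configs.append(LandmarkConfiguration(specimen_id=sid, points=placed))

            # traditional measurements, from the unrotated scaled landmarks
            upright = pts
            height = float(upright[:, 1].max() - upright[:, 1].min())
            ap_h = float(np.linalg.norm(upright[9] - upright[12]))
            ap_w = float(np.linalg.norm(upright[10] - upright[11]))
            whorls = 4.5 + 0.8 * (height - 1.15 * config.cs_base / 4) + rng.normal(0, 0.125)
            whorls = float(np.clip(np.round(whorls * 8) / 8, 1, 10))

            slender_score = float(-(shape - slender) @ widen_axis)
            log_lam = (config.embryo_intercept
                       + config.embryo_cs_effect * (cs - config.cs_base) / config.cs_noise_sd
                       + sum(config.embryo_env_effects[k] * site_cov[k][si]
                             for k in config.embryo_env_effects)
                       + config.embryo_shape_flow * slender_score / 0.05 * site_cov["flow"][si]
                       + config.embryo_cs_flow * (cs - config.cs_base)
                       / config.cs_noise_sd * site_cov["flow"][si]
                       + config.embryo_cs_turbidity * (cs - config.cs_base)
                       / config.cs_noise_sd * site_cov["turbidity"][si])
            lam = float(np.exp(np.clip(log_lam, -5, 6)))
            if config.embryo_family == "negative_binomial":
                r = config.embryo_nb_dispersion
                embryos = int(rng.negative_binomial(r, r / (r + lam)))
            else:
                embryos = int(rng.poisson(lam))

            p_ridge = config.ridged_rate_z2 if hap == "z2/37" else config.ridged_rate_t
            if site.turbidity == "clear":
                p_ridge *= 1.5
            ridged = bool(rng.random() < min(p_ridge, 1.0))

            spec_rows.append({
                "specimen_id": sid, "site_id": site.site_id,
                "shell_height": round(height, 4),
                "aperture_height": round(ap_h, 4), "aperture_width": round(ap_w, 4),
                "whorls": whorls, "ridged": ridged, "embryo_count": embryos,
                "sex": "f", "infected": False, "haplotype": hap, "genotype": gid,
            })
            calls = decode_genotype(pool[gid].encoded)
            if config.missing_locus_rate > 0:
                calls = [MISSING if rng.random() < config.missing_locus_rate else c
                         for c in calls]
            geno_rows.append({"specimen_id": sid, "site_id": site.site_id,
                              **dict(zip(loci, calls))})
            truth_rows.append({
                "specimen_id": sid, "site_id": site.site_id, "haplotype": hap,
                "genotype": gid, "true_cs": cs, "cs_env_component": cs_env,
                "lineage_component": float((templates[hap] - slender) @ widen_axis),
                "genotype_component": float(genotype_offsets[gid] @ widen_axis),
                "env_shape_component": float(shape_env @ widen_axis),
                "allometry_component": float(allom @ widen_axis),
                "slender_score": slender_score, "lambda_embryos": lam,
            })

    specimens = pd.DataFrame(spec_rows)
    genotype_calls = pd.DataFrame(geno_rows)
    truth = SyntheticTruth(
        config=asdict(config), specimens=pd.DataFrame(truth_rows),
        widen_axis=widen_axis, template_separation=separation,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tps(configs, out / "landmarks.tps")
        specimens.to_csv(out / "specimens.csv", index=False)
        sites.to_csv(out / "sites.csv", index=False)
        genotype_calls.to_csv(out / "genotypes.csv", index=False)
        write_fasta(refs["16S"], out / "haplotypes_16s.fasta")
        write_fasta(refs["cytb"], out / "haplotypes_cytb.fasta")
        truth.to_json(out / "truth.json")

    return configs, specimens, sites, genotype_calls, refs, truth


def table2_fixture() -> list:
    """The published ten-genotype reference set (see
    :func:`snailmorph.genetics.reference_genotypes`)."""
    return reference_genotypes()
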