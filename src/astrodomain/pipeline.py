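"""Pipeline orchestration: simulate -> quantify -> domain -> stats.

A single YAML configuration drives every stage; each run writes tidy CSV
artifacts plus a manifest (inputs, parameter hash, seed, package version)
so that a rerun with an identical configuration reproduces identical
outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .domain_sholl import (
    DISTANCE_CLASSES,
    DomainGeometry,
    bin_densities_from_points,
    build_bin_layout,
    density_distribution,
    exclude_soma,
    extract_bin_densities,
)
from .fixtures import load_neuropath_traits, make_fixtures
from .image import read_scene, write_scene
from .imgproc import PreprocessParams
from .puncta_quant import QuantParams, quantify_field
from .scene_sim import (
    ChannelSpec,
    RadialProfile,
    SceneConfig,
    generate_domain_scene,
    generate_scene,
)
from .stats_suite import (
    anova_oneway_tukey,
    anova_twoway_levene,
    compare_groups,
    correlate_traits,
    games_howell,
    pairwise_holm_sidak,
    pairwise_table,
    rm_anova_omega,
)

__all__ = ["RunConfig", "run_pipeline", "make_fixtures"]

logger = logging.getLogger(__name__)

MODES = ("simulate", "quantify", "domain", "stats", "all")


class ConfigError(ValueError):
    """Invalid run configuration (raised before any computation)."""


@dataclass
class RunConfig:
    """Validated run configuration parsed from the pipeline YAML."""

    raw: dict
    seed: int
    out_dir: Path
    scene: dict
    preprocess: PreprocessParams
    quant: QuantParams
    cohorts: dict
    domain: dict
    stats: dict = field(default_factory=dict)
    qc: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None, out_dir: str | Path | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, seed=seed, out_dir=out_dir)

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None, out_dir: str | Path | None = None) -> "RunConfig":
        try:
            pp = PreprocessParams(**raw.get("preprocess", {}))
            quant_block = dict(raw.get("quant", {}))
            quant = QuantParams(**quant_block, preprocess=pp)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid preprocess/quant block: {exc}") from exc
        resolved_seed = int(seed if seed is not None else raw.get("seed", 0))
        out = Path(out_dir if out_dir is not None else raw.get("out_dir", "runs/out"))
        cfg = cls(
            raw=raw,
            seed=resolved_seed,
            out_dir=out,
            scene=raw.get("scene", {}),
            preprocess=pp,
            quant=quant,
            cohorts=raw.get("cohorts", {}),
            domain=raw.get("domain", {}),
            stats=raw.get("stats", {}),
        )
        cfg._validate()
        return cfg

    def _validate(self) -> None:
        dom = self.domain
        if dom:
            soma = dom.get("soma_radius_um", 7.5)
            if soma < 0:
                raise ConfigError(f"domain.soma_radius_um must be >= 0, got {soma}")
            for cohort, block in dom.get("cohorts", {}).items():
                prof = block.get("profile", {})
                try:
                    RadialProfile(tuple(prof.get("distances", (0.0,))), tuple(prof.get("multipliers", (1.0,))))
                except ValueError as exc:
                    raise ConfigError(f"domain.cohorts.{cohort}.profile: {exc}") from exc

    def scene_config(self, cohort_block: dict, seed: int) -> SceneConfig:
        sc = self.scene
        channels = tuple(
            ChannelSpec(name=name, **spec) for name, spec in sc.get("channels", {}).items()
        ) or SceneConfig().channel_specs
        return SceneConfig(
            field_size_um=sc.get("field_size_um", 50.0),
            pixel_size_um=sc.get("pixel_size_um", 0.1),
            channel_specs=channels,
            coloc_fraction=cohort_block.get("coloc_fraction", 0.33),
            coloc_jitter_um=sc.get("coloc_jitter_um", 0.1),
            background_level=sc.get("background_level", 500.0),
            noise_sd=sc.get("noise_sd", 50.0),
            blob_density_per_um2=sc.get("blob_density_per_um2", 5e-4),
            seed=seed,
        )


def _param_hash(raw: dict) -> str:
    return hashlib.sha256(json.dumps(raw, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _require_columns(df: pd.DataFrame, columns: list[str], path: Path) -> None:
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
        bad = df[df[col].isna()]
        if len(bad):
            raise ValueError(f"{path}: row {bad.index[0]}, column {col!r}: missing value")


def _qc_overlay(img, mask: np.ndarray, path: Path) -> None:
    """PNG of the raw channel with detected mask boundaries in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from skimage.segmentation import find_boundaries

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(img.values, cmap="gray")
    overlay = np.zeros((*mask.shape, 4))
    overlay[find_boundaries(mask)] = (1.0, 0.0, 0.0, 1.0)
    ax.imshow(overlay)
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def stage_simulate(cfg: RunConfig) -> list[Path]:
    """Generate field scenes per cohort and domain scenes per astrocyte cohort."""
    written: list[Path] = []
    fields_dir = cfg.out_dir / "fields"
    fields_dir.mkdir(parents=True, exist_ok=True)
    for c_idx, (cohort, block) in enumerate(sorted(cfg.cohorts.items())):
        for i in range(int(block.get("n_fields", 3))):
            seed = cfg.seed * 100003 + c_idx * 1009 + i
            scfg = cfg.scene_config(block, seed)
            images, truth = generate_scene(scfg)
            path = fields_dir / f"{cohort}_f{i:02d}.tif"
            write_scene(images, path)
            truth.to_csv(path.with_suffix(".truth.csv"))
            written.append(path)

    dom = cfg.domain
    if dom:
        dom_dir = cfg.out_dir / "domains"
        dom_dir.mkdir(parents=True, exist_ok=True)
        cores = []
        size = dom.get("field_size_um", 212.0)
        for c_idx, (cohort, block) in enumerate(sorted(dom.get("cohorts", {}).items())):
            prof_block = block.get("profile", {})
            profile = RadialProfile(
                tuple(prof_block.get("distances", (0.0,))),
                tuple(prof_block.get("multipliers", (1.0,))),
            )
            for i in range(int(dom.get("n_astrocytes", 4))):
                seed = cfg.seed * 90001 + c_idx * 757 + i
                scfg = SceneConfig(
                    field_size_um=size,
                    pixel_size_um=dom.get("pixel_size_um", 0.5),
                    channel_specs=(
                        ChannelSpec(
                            "post",
                            density_per_um2=dom.get("post_density_per_um2", 0.1),
                            punctum_radius_um=dom.get("punctum_radius_um", 0.3),
                            punctum_radius_sd_um=0.05,
                        ),
                        ChannelSpec("astro", density_per_um2=0.0, amplitude=6000.0),
                    ),
                    coloc_fraction=0.0,
                    background_level=cfg.scene.get("background_level", 500.0),
                    noise_sd=cfg.scene.get("noise_sd", 50.0),
                    blob_density_per_um2=cfg.scene.get("blob_density_per_um2", 5e-4),
                    seed=seed,
                )
                core = (size / 2.0, size / 2.0)
                images, _ = generate_domain_scene(
                    scfg, profile, core, core_radius_um=dom.get("soma_radius_um", 7.5)
                )
                astro_id = f"{cohort}_a{i:02d}"
                path = dom_dir / f"{astro_id}.tif"
                write_scene(images, path)
                written.append(path)
                cores.append(
                    {"astrocyte_id": astro_id, "cohort": cohort, "x_um": core[0], "y_um": core[1]}
                )
        cores_path = dom_dir / "cores.csv"
        pd.DataFrame(cores).to_csv(cores_path, index=False)
        written.append(cores_path)
    return written


def stage_quantify(cfg: RunConfig) -> list[Path]:
    """Quantify every simulated field: per-field densities + per-punctum table."""
    fields_dir = cfg.out_dir / "fields"
    tifs = sorted(fields_dir.glob("*.tif"))
    if not tifs:
        raise FileNotFoundError(f"no field TIFFs found under {fields_dir}")
    records, puncta_rows = [], []
    for n_done, path in enumerate(tifs):
        cohort = path.stem.rsplit("_f", 1)[0]
        images = read_scene(path)
        record, details = quantify_field(
            images, cfg.quant, field_id=path.stem, cohort=cohort, region="synthetic"
        )
        if cfg.qc and n_done == 0:
            qc_dir = cfg.out_dir / "qc"
            qc_dir.mkdir(exist_ok=True)
            for name, mask in details["masks"].items():
                _qc_overlay(images[name], mask, qc_dir / f"{path.stem}_{name}.png")
        records.append(record.__dict__)
        for name, pset in details["puncta"].items():
            for p in pset.puncta:
                puncta_rows.append(
                    {
                        "field_id": path.stem,
                        "channel": name,
                        "punctum_id": p.id,
                        "x_um": p.centroid_um[0],
                        "y_um": p.centroid_um[1],
                        "area_um2": p.area_um2,
                    }
                )
    out1 = cfg.out_dir / "synapse_densities.csv"
    pd.DataFrame(records).to_csv(out1, index=False)
    out2 = cfg.out_dir / "puncta.csv"
    pd.DataFrame(puncta_rows).to_csv(out2, index=False)
    return [out1, out2]


def stage_domain(cfg: RunConfig) -> list[Path]:
    """Run the Sholl-like domain analysis on every domain scene."""
    dom_dir = cfg.out_dir / "domains"
    cores_path = dom_dir / "cores.csv"
    if not cores_path.exists():
        raise FileNotFoundError(f"missing {cores_path}")
    cores = pd.read_csv(cores_path)
    _require_columns(cores, ["astrocyte_id", "cohort", "x_um", "y_um"], cores_path)
    soma_radius = cfg.domain.get("soma_radius_um", 7.5)
    logger.info("domain stage: soma exclusion radius %.2f um", soma_radius)

    long_rows, mean_rows = [], []
    for row in cores.itertuples():
        path = dom_dir / f"{row.astrocyte_id}.tif"
        images = read_scene(path)
        post = images[cfg.quant.post_channel]
        core = (float(row.x_um), float(row.y_um))
        post = exclude_soma(post, core, soma_radius)
        layout = build_bin_layout(core)
        bins = extract_bin_densities(post, layout, cfg.quant)
        dist = density_distribution(bins, astrocyte_id=row.astrocyte_id, cohort=row.cohort)
        for b in bins.itertuples():
            long_rows.append(
                {
                    "astrocyte_id": row.astrocyte_id,
                    "cohort": row.cohort,
                    "bin_index": b.bin_index,
                    "distance_class": b.distance_class,
                    "density": b.density,
                }
            )
        for cls in DISTANCE_CLASSES:
            mean_rows.append(
                {
                    "astrocyte_id": row.astrocyte_id,
                    "cohort": row.cohort,
                    "distance_class": cls,
                    "density": dist.class_means[cls],
                }
            )
    out1 = cfg.out_dir / "bin_densities.csv"
    pd.DataFrame(long_rows).to_csv(out1, index=False)
    out2 = cfg.out_dir / "class_means.csv"
    pd.DataFrame(mean_rows).to_csv(out2, index=False)
    return [out1, out2]


def stage_stats(cfg: RunConfig) -> list[Path]:
    """Run the statistical workflow on the quantification outputs."""
    written: list[Path] = []
    alpha = cfg.stats.get("alpha", 0.05)

    dens_path = cfg.out_dir / "synapse_densities.csv"
    if dens_path.exists():
        dens = pd.read_csv(dens_path)
        _require_columns(dens, ["cohort", "bipartite_density"], dens_path)
        groups = {c: g["bipartite_density"].to_numpy() for c, g in dens.groupby("cohort")}
        labels = sorted(groups)
        rows = []
        if len(labels) >= 2:
            raw_p, results = [], []
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    res = compare_groups(groups[labels[i]], groups[labels[j]])
                    res.groups = (labels[i], labels[j])
                    results.append(res)
                    raw_p.append(res.p_value)
            for res, ap in zip(results, pairwise_holm_sidak(raw_p)):
                res.adjusted_p = float(ap)
                rows.append(res.to_row())
            p = cfg.out_dir / "group_comparisons.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            written.append(p)
            if len(labels) >= 3:
                aov = anova_oneway_tukey([groups[l] for l in labels], labels, alpha=alpha)
                p = cfg.out_dir / "anova_tukey.csv"
                pd.DataFrame([r.to_row() for r in aov]).to_csv(p, index=False)
                written.append(p)

    bins_path = cfg.out_dir / "bin_densities.csv"
    if bins_path.exists():
        bins = pd.read_csv(bins_path).dropna(subset=["density"])
        _require_columns(bins, ["cohort", "distance_class", "density"], bins_path)
        try:
            two = anova_twoway_levene(bins)
        except ValueError as exc:
            logger.warning("two-way ANOVA skipped: %s", exc)
        else:
            p = cfg.out_dir / "twoway_anova.csv"
            pd.DataFrame([r.to_row() for r in two.values()]).to_csv(p, index=False)
            written.append(p)

        cohort_groups = {c: g["density"].to_numpy() for c, g in bins.groupby("cohort")}
        gh_labels = sorted(cohort_groups)
        gh = games_howell([cohort_groups[l] for l in gh_labels], gh_labels, alpha=alpha)
        p = cfg.out_dir / "games_howell.csv"
        pairwise_table(gh).to_csv(p, index=False)
        written.append(p)

        means_path = cfg.out_dir / "class_means.csv"
        if means_path.exists():
            means = pd.read_csv(means_path)
            rm_rows = []
            for cohort, g in means.groupby("cohort"):
                wide = g.pivot(
                    index="astrocyte_id", columns="distance_class", values="density"
                )
                # classes unmeasurable for any astrocyte (e.g. rings clipped by
                # the field) are dropped from the within-subject comparison
                wide = wide.dropna(axis=1, how="any")
                cols = [c for c in DISTANCE_CLASSES if c in wide.columns]
                if len(cols) < 2 or len(wide) < 2:
                    logger.warning("rm-anova skipped for cohort %s: too few complete cells", cohort)
                    continue
                long = (
                    wide[cols]
                    .reset_index()
                    .melt(id_vars="astrocyte_id", var_name="distance_class", value_name="density")
                )
                omnibus, posthoc = rm_anova_omega(long)
                rm_rows.append({"cohort": cohort, **omnibus.to_row()})
                for r in posthoc:
                    rm_rows.append({"cohort": cohort, **r.to_row()})
            p = cfg.out_dir / "rm_anova.csv"
            pd.DataFrame(rm_rows).to_csv(p, index=False)
            written.append(p)

    case_path = cfg.stats.get("case_densities")
    if case_path:
        case = pd.read_csv(case_path)
        _require_columns(case, ["case", "density"], Path(case_path))
        corr = correlate_traits(load_neuropath_traits(), case)
        p = cfg.out_dir / "trait_correlations.csv"
        corr.to_csv(p, index=False)
        written.append(p)
    return written


def run_pipeline(
    config: RunConfig | str | Path,
    mode: str = "all",
    seed: int | None = None,
    out_dir: str | Path | None = None,
    qc: bool = False,
) -> dict:
    """Run one or all pipeline stages; returns the artifact manifest."""
    if mode not in MODES:
        raise ConfigError(f"unknown mode {mode!r}; expected one of {MODES}")
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config, seed=seed, out_dir=out_dir)
    config.qc = config.qc or qc
    config.out_dir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "run_pipeline mode=%s seed=%d size_filter=[%g, %g] overlap_threshold=%g",
        mode,
        config.seed,
        config.quant.min_area_um2,
        config.quant.max_area_um2,
        config.quant.overlap_threshold,
    )

    artifacts: list[Path] = []
    stages = {
        "simulate": stage_simulate,
        "quantify": stage_quantify,
        "domain": stage_domain,
        "stats": stage_stats,
    }
    order = list(stages) if mode == "all" else [mode]
    for name in order:
        artifacts.extend(stages[name](config))

    manifest = {
        "mode": mode,
        "seed": config.seed,
        "parameter_hash": _param_hash(config.raw),
        "version": __version__,
        "quant": {
            "min_area_um2": config.quant.min_area_um2,
            "max_area_um2": config.quant.max_area_um2,
            "overlap_threshold": config.quant.overlap_threshold,
        },
        "artifacts": [str(p) for p in artifacts],
    }
    (config.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
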