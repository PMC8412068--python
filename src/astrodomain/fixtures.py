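"""Packaged fixtures: trait counts, worked-example masks, demo configuration.

The neuropathological trait table (total counts of tufted astrocytes /
astrocytic plaques, neurofibrillary tangles and pretangles, coiled bodies,
and the ordinal 0-5 neuropil-thread grade per case, counted over 10 visual
fields at 250x) ships with the package and feeds the trait-density
correlation stage. The worked-example masks pin the bipartite overlap rule:
a 100-pixel presynaptic punctum of which exactly 33 pixels are covered by
postsynaptic foreground sits exactly at the 0.33 calling threshold.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["load_neuropath_traits", "overlap_example_masks", "make_fixtures"]


def load_neuropath_traits() -> pd.DataFrame:
    """Per-case neuropathological trait counts (packaged CSV)."""
    with resources.files("astrodomain.data").joinpath("neuropath_traits.csv").open() as fh:
        return pd.read_csv(fh)


def overlap_example_masks(covered_px: int = 33) -> tuple[np.ndarray, np.ndarray]:
    """A 10x10 (100 px) presynaptic punctum with ``covered_px`` post pixels.

    Returns (pre_mask, post_mask) on a 20x20 grid; with the default 33
    covered pixels the overlap fraction is exactly 0.33.
    """
    if not 0 <= covered_px <= 100:
        raise ValueError("covered_px must be in [0, 100]")
    pre = np.zeros((20, 20), dtype=bool)
    pre[5:15, 5:15] = True
    post = np.zeros((20, 20), dtype=bool)
    rows, cols = np.nonzero(pre)
    post[rows[:covered_px], cols[:covered_px]] = True
    return pre, post


_DEMO_CONFIG: dict = {
    "seed": 0,
    "out_dir": "runs/demo",
    "scene": {
        "field_size_um": 25.0,
        "pixel_size_um": 0.1,
        "background_level": 500.0,
        "noise_sd": 50.0,
        "blob_density_per_um2": 0.0005,
        "coloc_jitter_um": 0.1,
        "channels": {
            "pre": {"density_per_um2": 0.4, "punctum_radius_um": 0.25,
                    "punctum_radius_sd_um": 0.05, "amplitude": 8000.0},
            "post": {"density_per_um2": 0.05, "punctum_radius_um": 0.25,
                     "punctum_radius_sd_um": 0.05, "amplitude": 8000.0},
        },
    },
    "preprocess": {
        "background_radius_px": 25,
        "bandpass_small_px": 2.0,
        "bandpass_large_px": 20.0,
        "despeckle_kernel_px": 3,
        "histogram_bins": 256,
    },
    "quant": {"min_area_um2": 0.1, "max_area_um2": 2.0, "overlap_threshold": 0.33},
    # field-level cohorts: colocalization fraction emulates bipartite density differences
    "cohorts": {
        "Ctrl": {"coloc_fraction": 0.6, "n_fields": 5},
        "PSP": {"coloc_fraction": 0.35, "n_fields": 5},
        "CBD": {"coloc_fraction": 0.55, "n_fields": 5},
    },
    # astrocyte-level cohorts: radial profiles emulate domain phenotypes
    "domain": {
        "field_size_um": 280.0,  # contains the full out ring (120 + 13.5 um)
        "pixel_size_um": 0.15,
        "post_density_per_um2": 0.1,
        "punctum_radius_um": 0.3,
        "soma_radius_um": 7.5,
        "n_astrocytes": 3,
        "cohorts": {
            "Ctrl": {"profile": {"distances": [0.0, 30.0, 60.0],
                                 "multipliers": [0.9, 1.1, 1.0]}},
            "PSP_TA": {"profile": {"distances": [0.0, 30.0, 60.0],
                                   "multipliers": [1.0, 0.6, 1.0]}},
            "CBD_AP": {"profile": {"distances": [0.0, 90.0, 105.0],
                                   "multipliers": [0.6, 0.6, 1.0]}},
        },
    },
    "stats": {"alpha": 0.05},
}


def make_fixtures(out_dir: str | Path) -> list[Path]:
    """Write every packaged fixture into ``out_dir`` (idempotent).

    Writes the trait-count CSV, the overlap worked-example masks (0/1 CSV
    grids), a demo pipeline configuration, and a clearly-labelled synthetic
    per-case density table for exercising the trait-correlation stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    traits_path = out / "neuropath_traits.csv"
    load_neuropath_traits().to_csv(traits_path, index=False)
    written.append(traits_path)

    pre, post = overlap_example_masks()
    for name, mask in (("overlap_example_pre.csv", pre), ("overlap_example_post.csv", post)):
        p = out / name
        np.savetxt(p, mask.astype(int), fmt="%d", delimiter=",")
        written.append(p)

    cfg_path = out / "demo_config.yaml"
    cfg_path.write_text(yaml.safe_dump(_DEMO_CONFIG, sort_keys=False))
    written.append(cfg_path)

    # synthetic stand-in for unpublished per-case densities (demo only)
    synth = pd.DataFrame(
        {
            "case": [102, 105, 107, 104, 108, 109],
            "density": [0.085, 0.110, 0.095, 0.078, 0.052, 0.129],
        }
    )
    synth_path = out / "synthetic_case_densities.csv"
    synth.to_csv(synth_path, index=False)
    written.append(synth_path)
    return written
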