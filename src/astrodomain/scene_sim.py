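"""Synthetic multi-channel fluorescence scene generator with known ground truth.

The generator emulates the two imaging situations the analysis pipeline is
built for:

* two-channel (pre-/postsynaptic) 50x50 um fields for general synapse
  counting, where a controllable fraction of presynaptic puncta carries a
  jittered postsynaptic partner (the true colocalization fraction), and
* three-channel 212x212 um astrocytic-domain scenes, where the postsynaptic
  channel follows an inhomogeneous Poisson process whose rate is modulated
  by a radial profile around an astrocyte core, and the astrocyte channel
  renders the core as a bright ring around an empty centre.

Puncta are isotropic 2D Gaussian spots (sigma = radius / 2, truncated at
3 sigma) on an additive background with Gaussian noise and sparse large
autofluorescence-like blobs. Everything downstream of a
:class:`SceneConfig` and a seed is deterministic, and the returned
:class:`GroundTruth` (true centroids, radii, matched pairs) never depends
on rendering, clipping or noise.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image import MAX_UINT16, Image, read_scene, write_scene

__all__ = [
    "ChannelSpec",
    "SceneConfig",
    "RadialProfile",
    "ChannelTruth",
    "GroundTruth",
    "generate_ground_truth",
    "generate_domain_ground_truth",
    "generate_scene",
    "generate_domain_scene",
    "render_scene",
    "write_scene",
    "read_scene",
]

logger = logging.getLogger(__name__)

# Autofluorescence blob appearance (sparse, much larger than puncta).
_BLOB_SIGMA_RANGE_UM = (1.0, 2.5)
_BLOB_AMPLITUDE_FRACTION = 0.4


@dataclass(frozen=True)
class ChannelSpec:
    """Puncta statistics for one fluorescence channel.

    ``density_per_um2`` is the homogeneous Poisson rate of puncta; for the
    postsynaptic channel of a pre/post scene it is the rate of *unmatched*
    puncta — matched partners are added on top, driven by
    ``SceneConfig.coloc_fraction``. Punctum radii are drawn from
    N(radius_mean, radius_sd) truncated at one pixel.
    """

    name: str
    density_per_um2: float = 0.4
    punctum_radius_um: float = 0.15
    punctum_radius_sd_um: float = 0.03
    amplitude: float = 8000.0

    def __post_init__(self) -> None:
        if self.density_per_um2 < 0:
            raise ValueError(f"channel {self.name}: density must be >= 0")
        if self.punctum_radius_um <= 0:
            raise ValueError(f"channel {self.name}: punctum radius must be > 0")
        if self.punctum_radius_sd_um < 0:
            raise ValueError(f"channel {self.name}: radius SD must be >= 0")


@dataclass(frozen=True)
class SceneConfig:
    """Full description of one synthetic field.

    The field is square, ``field_size_um`` on a side, sampled at
    ``pixel_size_um``; the two must combine to an integer pixel grid within
    0.5% rounding tolerance. ``coloc_fraction`` of presynaptic puncta
    receive a postsynaptic partner whose centroid is displaced by isotropic
    Gaussian jitter of SD ``coloc_jitter_um``.
    """

    field_size_um: float = 50.0
    pixel_size_um: float = 0.049
    channel_specs: tuple[ChannelSpec, ...] = (
        ChannelSpec("pre"),
        ChannelSpec("post", density_per_um2=0.0),
    )
    coloc_fraction: float = 0.33
    coloc_jitter_um: float = 0.1
    background_level: float = 500.0
    noise_sd: float = 50.0
    blob_density_per_um2: float = 5e-4
    seed: int = 0
    pre_channel: str = "pre"
    post_channel: str = "post"

    def __post_init__(self) -> None:
        if self.field_size_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("field_size_um and pixel_size_um must be > 0")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError(f"coloc_fraction must be in [0, 1], got {self.coloc_fraction}")
        if self.coloc_jitter_um < 0 or self.noise_sd < 0 or self.blob_density_per_um2 < 0:
            raise ValueError("coloc_jitter_um, noise_sd and blob_density_per_um2 must be >= 0")
        n = self.field_size_um / self.pixel_size_um
        if abs(n - round(n)) > 0.001 * n:  # grid must match the field within 0.1%
            raise ValueError(
                f"field_size_um / pixel_size_um = {n:.3f} is not an integer pixel "
                "dimension within rounding tolerance"
            )
        object.__setattr__(self, "channel_specs", tuple(self.channel_specs))

    @property
    def shape_px(self) -> tuple[int, int]:
        n = round(self.field_size_um / self.pixel_size_um)
        return (n, n)

    @property
    def area_um2(self) -> float:
        return self.field_size_um**2

    def channel(self, name: str) -> ChannelSpec:
        for spec in self.channel_specs:
            if spec.name == name:
                return spec
        raise KeyError(f"no channel named {name!r}")


@dataclass(frozen=True)
class RadialProfile:
    """Piecewise-linear density multiplier as a function of distance to a core.

    Knot distances must be strictly increasing and start at 0; between knots
    the multiplier is linearly interpolated, beyond the last knot it is
    constant at the last value. Multiplying a homogeneous Poisson rate by
    the profile yields the inhomogeneous rate of a domain scene.
    """

    knot_distances_um: tuple[float, ...]
    multipliers: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.knot_distances_um, dtype=float)
        m = np.asarray(self.multipliers, dtype=float)
        if d.size == 0 or d.size != m.size:
            raise ValueError("knot_distances_um and multipliers must be equal-length, non-empty")
        if d[0] != 0.0:
            raise ValueError("knot distances must start at 0")
        if np.any(np.diff(d) <= 0):
            raise ValueError("knot distances must be strictly increasing")
        if np.any(m < 0):
            raise ValueError("multipliers must be >= 0")
        object.__setattr__(self, "knot_distances_um", tuple(d))
        object.__setattr__(self, "multipliers", tuple(m))

    def __call__(self, distance_um: np.ndarray | float) -> np.ndarray:
        return np.interp(distance_um, self.knot_distances_um, self.multipliers)

    @property
    def max_multiplier(self) -> float:
        return max(self.multipliers)

    @classmethod
    def flat(cls, multiplier: float = 1.0) -> "RadialProfile":
        return cls((0.0,), (multiplier,))


@dataclass
class ChannelTruth:
    """True puncta of one channel: centroids in um (N, 2 = x, y) and radii."""

    centroids_um: np.ndarray
    radii_um: np.ndarray

    @property
    def count(self) -> int:
        return len(self.centroids_um)


@dataclass
class GroundTruth:
    """True scene content, independent of rendering.

    ``pairs`` lists matched (pre index, post index) tuples; matched post
    puncta occupy the first ``len(pairs)`` slots of the post channel.
    """

    channels: dict[str, ChannelTruth]
    pairs: list[tuple[int, int]] = field(default_factory=list)
    core_center_um: tuple[float, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: channel, x_um, y_um, radius_um, pair_id (-1 = unmatched)."""
        rows = []
        pre_pair = {p: i for i, (p, _) in enumerate(self.pairs)}
        post_pair = {q: i for i, (_, q) in enumerate(self.pairs)}
        for name, truth in self.channels.items():
            lookup = pre_pair if name == "pre" else post_pair if name == "post" else {}
            for j in range(truth.count):
                rows.append(
                    {
                        "channel": name,
                        "x_um": truth.centroids_um[j, 0],
                        "y_um": truth.centroids_um[j, 1],
                        "radius_um": truth.radii_um[j],
                        "pair_id": lookup.get(j, -1),
                    }
                )
        return pd.DataFrame(rows, columns=["channel", "x_um", "y_um", "radius_um", "pair_id"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _channel_rng(seed: int, name: str, purpose: str = "puncta") -> np.random.Generator:
    """Deterministic per-channel substream, stable under spec-list edits."""
    digest = hashlib.sha256(f"{purpose}:{name}".encode()).digest()
    key = int.from_bytes(digest[:8], "little") % (2**63)
    return np.random.default_rng(np.random.SeedSequence(entropy=[int(seed), key]))


def _draw_radii(rng: np.random.Generator, spec: ChannelSpec, n: int, pixel_size_um: float) -> np.ndarray:
    radii = rng.normal(spec.punctum_radius_um, spec.punctum_radius_sd_um, size=n)
    return np.maximum(radii, pixel_size_um)


def generate_ground_truth(config: SceneConfig) -> GroundTruth:
    """Sample true puncta for every channel of a homogeneous scene.

    Each channel is an independent homogeneous Poisson process of its spec
    density; then round(coloc_fraction x pre count) presynaptic puncta get a
    matched postsynaptic partner (centroid + isotropic Gaussian jitter,
    radius drawn independently), prepended to the post channel.
    """
    L = config.field_size_um
    channels: dict[str, ChannelTruth] = {}
    for spec in config.channel_specs:
        rng = _channel_rng(config.seed, spec.name)
        n = rng.poisson(spec.density_per_um2 * config.area_um2)
        centroids = rng.uniform(0.0, L, size=(n, 2))
        radii = _draw_radii(rng, spec, n, config.pixel_size_um)
        channels[spec.name] = ChannelTruth(centroids, radii)

    pairs: list[tuple[int, int]] = []
    if config.pre_channel in channels and config.post_channel in channels:
        pre = channels[config.pre_channel]
        post = channels[config.post_channel]
        post_spec = config.channel(config.post_channel)
        rng = _channel_rng(config.seed, config.post_channel, purpose="coloc")
        n_pairs = round(config.coloc_fraction * pre.count)
        matched_pre = rng.permutation(pre.count)[:n_pairs]
        jitter = rng.normal(0.0, config.coloc_jitter_um, size=(n_pairs, 2))
        matched_centroids = np.clip(pre.centroids_um[matched_pre] + jitter, 0.0, L)
        matched_radii = _draw_radii(rng, post_spec, n_pairs, config.pixel_size_um)
        channels[config.post_channel] = ChannelTruth(
            np.concatenate([matched_centroids, post.centroids_um]),
            np.concatenate([matched_radii, post.radii_um]),
        )
        pairs = [(int(p), i) for i, p in enumerate(matched_pre)]
    return GroundTruth(channels=channels, pairs=pairs)


def generate_domain_ground_truth(
    config: SceneConfig,
    profile: RadialProfile,
    core_center_um: tuple[float, float],
) -> GroundTruth:
    """Sample true puncta for an astrocytic-domain scene.

    The postsynaptic channel follows an inhomogeneous Poisson process with
    rate density x profile(distance to core), realised by thinning a
    homogeneous process at the profile's maximum; all other channels stay
    homogeneous. The core must lie inside the field.
    """
    cx, cy = core_center_um
    L = config.field_size_um
    if not (0.0 <= cx <= L and 0.0 <= cy <= L):
        raise ValueError(f"core centre {core_center_um} lies outside the {L} um field")

    gt = generate_ground_truth(config)
    post_name = config.post_channel
    if post_name not in gt.channels:
        raise ValueError(f"domain scene requires a {post_name!r} channel")

    spec = config.channel(post_name)
    mmax = profile.max_multiplier
    rng = _channel_rng(config.seed, post_name, purpose="domain")
    n = rng.poisson(spec.density_per_um2 * mmax * config.area_um2) if mmax > 0 else 0
    centroids = rng.uniform(0.0, L, size=(n, 2))
    dist = np.hypot(centroids[:, 0] - cx, centroids[:, 1] - cy)
    keep = rng.uniform(0.0, 1.0, size=n) < profile(dist) / mmax if mmax > 0 else np.zeros(0, bool)
    radii = _draw_radii(rng, spec, n, config.pixel_size_um)
    gt.channels[post_name] = ChannelTruth(centroids[keep], radii[keep])
    gt.pairs = []
    gt.core_center_um = (float(cx), float(cy))
    return gt


def _paint_spots(
    canvas: np.ndarray,
    centroids_um: np.ndarray,
    sigmas_um: np.ndarray,
    amplitudes: np.ndarray,
    pixel_size_um: float,
) -> None:
    """Add truncated (3 sigma) isotropic Gaussian spots onto ``canvas`` in place."""
    ny, nx = canvas.shape
    for (x_um, y_um), s_um, amp in zip(centroids_um, sigmas_um, amplitudes):
        s_px = s_um / pixel_size_um
        cx, cy = x_um / pixel_size_um, y_um / pixel_size_um
        r = int(np.ceil(3.0 * s_px))
        x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, nx)
        y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, ny)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        d2 = ys[:, None] ** 2 + xs[None, :] ** 2
        spot = amp * np.exp(-d2 / (2.0 * s_px**2))
        spot[d2 > (3.0 * s_px) ** 2] = 0.0
        canvas[y0:y1, x0:x1] += spot


def render_scene(
    config: SceneConfig,
    truth: GroundTruth,
    core_ring: bool = False,
    astro_channel: str = "astro",
    core_radius_um: float = 7.5,
) -> dict[str, Image]:
    """Render ground truth into noisy 16-bit-range channel images.

    Per channel: Gaussian spots for every true punctum, sparse large blobs,
    additive background, Gaussian noise, clipping to [0, 65535] (clipped
    fraction logged). With ``core_ring`` the astrocyte channel additionally
    gets a bright ring at ``core_radius_um`` around an empty core centre, the
    visual signature used to locate astrocyte cores.
    """
    shape = config.shape_px
    images: dict[str, Image] = {}
    for spec in config.channel_specs:
        ch = truth.channels.get(spec.name, ChannelTruth(np.zeros((0, 2)), np.zeros(0)))
        canvas = np.zeros(shape, dtype=np.float64)
        _paint_spots(
            canvas,
            ch.centroids_um,
            ch.radii_um / 2.0,  # sigma = radius / 2
            np.full(ch.count, spec.amplitude),
            config.pixel_size_um,
        )

        rng = _channel_rng(config.seed, spec.name, purpose="render")
        n_blobs = rng.poisson(config.blob_density_per_um2 * config.area_um2)
        if n_blobs:
            blob_xy = rng.uniform(0.0, config.field_size_um, size=(n_blobs, 2))
            blob_sigma = rng.uniform(*_BLOB_SIGMA_RANGE_UM, size=n_blobs)
            blob_amp = np.full(n_blobs, _BLOB_AMPLITUDE_FRACTION * spec.amplitude)
            _paint_spots(canvas, blob_xy, blob_sigma, blob_amp, config.pixel_size_um)

        if core_ring and spec.name == astro_channel and truth.core_center_um is not None:
            cx, cy = truth.core_center_um
            yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
            d_um = np.hypot(
                xx * config.pixel_size_um - cx, yy * config.pixel_size_um - cy
            )
            ring = spec.amplitude * np.exp(
                -((d_um - core_radius_um) ** 2) / (2.0 * (core_radius_um / 4.0) ** 2)
            )
            ring[d_um < 0.6 * core_radius_um] = 0.0  # empty centre
            canvas += ring

        canvas += config.background_level
        canvas += rng.normal(0.0, config.noise_sd, size=shape) if config.noise_sd else 0.0
        n_clipped = int((canvas < 0).sum() + (canvas > MAX_UINT16).sum())
        if n_clipped:
            logger.info(
                "render_scene[%s]: clipped %.5f%% of pixels",
                spec.name,
                100.0 * n_clipped / canvas.size,
            )
        images[spec.name] = Image(
            values=np.clip(canvas, 0.0, MAX_UINT16), pixel_size_um=config.pixel_size_um
        )
    return images


def generate_scene(config: SceneConfig) -> tuple[dict[str, Image], GroundTruth]:
    """Generate and render a homogeneous pre/post scene. Deterministic per seed."""
    truth = generate_ground_truth(config)
    return render_scene(config, truth), truth


def generate_domain_scene(
    config: SceneConfig,
    profile: RadialProfile,
    core_center_um: tuple[float, float],
    core_radius_um: float = 7.5,
) -> tuple[dict[str, Image], GroundTruth]:
    """Generate and render an astrocytic-domain scene. Deterministic per seed."""
    truth = generate_domain_ground_truth(config, profile, core_center_um)
    images = render_scene(config, truth, core_ring=True, core_radius_um=core_radius_um)
    return images, truth
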