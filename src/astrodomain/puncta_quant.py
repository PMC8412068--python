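"""Puncta detection, density computation and bipartite-synapse calling.

A punctum is an 8-connected foreground component of a binarized channel
whose area passes a physiological size filter. A bipartite synapse is a
presynaptic punctum whose pixel footprint overlaps postsynaptic foreground
by at least a fraction of its own area (default 0.33): the overlap fraction
is anchored on the presynaptic punctum, which makes the presynaptic count a
hard upper bound on the number of called synapses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure as skmeasure

from .image import Image
from .imgproc import PreprocessParams, preprocess

__all__ = [
    "Punctum",
    "PunctaSet",
    "BipartitePair",
    "SynapseDensityRecord",
    "QuantParams",
    "detect_puncta",
    "puncta_density",
    "pair_bipartite",
    "quantify_field",
]

logger = logging.getLogger(__name__)

OVERLAP_THRESHOLD_DEFAULT = 0.33


@dataclass(frozen=True)
class Punctum:
    id: int
    centroid_um: tuple[float, float]  # (x, y)
    area_um2: float
    pixel_count: int
    channel: str = ""


@dataclass
class PunctaSet:
    """Detected puncta of one channel of one field.

    ``labels`` keeps the punctum-id-labelled image (0 = background) so
    pixel-level overlap can be computed downstream; ``field_area_um2`` is
    the analyzed (non-excluded) area used as the density denominator.
    """

    puncta: list[Punctum]
    field_area_um2: float
    pixel_size_um: float
    source: str = ""
    channel: str = ""
    labels: np.ndarray | None = field(default=None, repr=False)

    @property
    def count(self) -> int:
        return len(self.puncta)

    def __post_init__(self) -> None:
        if self.field_area_um2 <= 0:
            raise ValueError("field_area_um2 must be > 0")
        ids = [p.id for p in self.puncta]
        if len(ids) != len(set(ids)):
            raise ValueError("punctum ids must be unique")


@dataclass(frozen=True)
class BipartitePair:
    pre_id: int
    post_id: int | None
    overlap_fraction: float


@dataclass(frozen=True)
class SynapseDensityRecord:
    """Per-field densities in puncta per um^2 (pre, post, bipartite)."""

    field_id: str
    cohort: str
    region: str
    pre_density: float
    post_density: float
    bipartite_density: float
    pre_count: int = 0
    post_count: int = 0
    bipartite_count: int = 0


@dataclass
class QuantParams:
    """Quantification settings; defaults must be logged with every run."""

    min_area_um2: float = 0.1
    max_area_um2: float = 2.0
    overlap_threshold: float = OVERLAP_THRESHOLD_DEFAULT
    pre_channel: str = "pre"
    post_channel: str = "post"
    restrict_to_post_puncta: bool = False
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)

    def __post_init__(self) -> None:
        if not 0 < self.min_area_um2 < self.max_area_um2:
            raise ValueError("require 0 < min_area_um2 < max_area_um2")
        if not 0.0 <= self.overlap_threshold <= 1.0:
            raise ValueError(
                f"overlap_threshold must be in [0, 1], got {self.overlap_threshold}"
            )


def detect_puncta(
    mask: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 0.1,
    max_area_um2: float = 2.0,
    channel: str = "",
    excluded_mask: np.ndarray | None = None,
    source: str = "",
) -> PunctaSet:
    """Detect puncta as size-filtered 8-connected components of a binary mask.

    Components with physical area outside ``[min_area_um2, max_area_um2]``
    are discarded; border-touching components are kept. Components whose
    centroid falls in ``excluded_mask`` are dropped and the excluded area is
    removed from the density denominator.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask must be binary, found values {uniq[:5]}")
        mask = mask.astype(bool)
    if not min_area_um2 < max_area_um2:
        raise ValueError("require min_area_um2 < max_area_um2")

    px_area = pixel_size_um**2
    cc = skmeasure.label(mask, connectivity=2)
    labels = np.zeros_like(cc)
    puncta: list[Punctum] = []
    next_id = 1
    for region in skmeasure.regionprops(cc):
        area_um2 = region.num_pixels * px_area
        if not min_area_um2 <= area_um2 <= max_area_um2:
            continue
        row, col = region.centroid
        if excluded_mask is not None and excluded_mask[int(round(row)), int(round(col))]:
            continue
        puncta.append(
            Punctum(
                id=next_id,
                centroid_um=(col * pixel_size_um, row * pixel_size_um),
                area_um2=area_um2,
                pixel_count=int(region.num_pixels),
                channel=channel,
            )
        )
        labels[cc == region.label] = next_id
        next_id += 1

    valid_px = mask.size if excluded_mask is None else int((~excluded_mask).sum())
    return PunctaSet(
        puncta=puncta,
        field_area_um2=valid_px * px_area,
        pixel_size_um=pixel_size_um,
        source=source,
        channel=channel,
        labels=labels,
    )


def puncta_density(pset: PunctaSet) -> float:
    """Puncta per um^2 of analyzed (non-excluded) field area."""
    return pset.count / pset.field_area_um2


def pair_bipartite(
    pre: PunctaSet,
    post_mask: np.ndarray,
    threshold: float = OVERLAP_THRESHOLD_DEFAULT,
    post_puncta: PunctaSet | None = None,
    restrict_to_post_puncta: bool = False,
) -> list[BipartitePair]:
    """Call bipartite synapses by presynaptic overlap with postsynaptic signal.

    For each presynaptic punctum the overlap fraction is the share of its
    own pixels that are postsynaptic foreground; a pair is emitted iff the
    fraction is >= ``threshold``, so each presynaptic punctum appears at
    most once. With ``post_puncta`` given, the pair records the id of the
    post punctum contributing the most overlapping pixels (ties -> lowest
    id); with ``restrict_to_post_puncta`` the overlap is counted against
    size-filtered post puncta instead of raw post foreground.
    """
    if pre.labels is None:
        raise ValueError("pre PunctaSet carries no label image")
    post_mask = np.asarray(post_mask).astype(bool)
    if post_mask.shape != pre.labels.shape:
        raise ValueError(
            f"geometry mismatch: pre labels {pre.labels.shape} vs post mask {post_mask.shape}"
        )
    if restrict_to_post_puncta:
        if post_puncta is None or post_puncta.labels is None:
            raise ValueError("restrict_to_post_puncta requires post_puncta with labels")
        post_fg = post_puncta.labels > 0
    else:
        post_fg = post_mask

    n = max((p.id for p in pre.puncta), default=0)
    overlap_px = np.bincount(pre.labels[post_fg].ravel(), minlength=n + 1)

    pairs: list[BipartitePair] = []
    for punctum in pre.puncta:
        fraction = overlap_px[punctum.id] / punctum.pixel_count
        if fraction < threshold:
            continue
        post_id = None
        if post_puncta is not None and post_puncta.labels is not None:
            in_pre = pre.labels == punctum.id
            post_labels_here = post_puncta.labels[in_pre & post_fg]
            post_labels_here = post_labels_here[post_labels_here > 0]
            if post_labels_here.size:
                counts = np.bincount(post_labels_here)
                post_id = int(np.flatnonzero(counts == counts.max())[0])
        pairs.append(BipartitePair(punctum.id, post_id, float(fraction)))
    return pairs


def quantify_field(
    images: dict[str, Image],
    params: QuantParams | None = None,
    field_id: str = "",
    cohort: str = "",
    region: str = "",
) -> tuple[SynapseDensityRecord, dict]:
    """Run the full per-field quantification: preprocess, detect, pair.

    Returns the density record plus a detail dict with the per-channel
    :class:`PunctaSet` objects and the bipartite pair list.
    """
    params = params or QuantParams()
    logger.info(
        "quantify_field %s: size filter [%g, %g] um^2, overlap threshold %g",
        field_id,
        params.min_area_um2,
        params.max_area_um2,
        params.overlap_threshold,
    )
    sets: dict[str, PunctaSet] = {}
    masks: dict[str, np.ndarray] = {}
    for name, img in images.items():
        mask = preprocess(img, params.preprocess)
        masks[name] = mask
        sets[name] = detect_puncta(
            mask,
            img.pixel_size_um,
            params.min_area_um2,
            params.max_area_um2,
            channel=name,
            excluded_mask=img.excluded_mask,
            source=field_id,
        )

    pre_set = sets[params.pre_channel]
    post_set = sets[params.post_channel]
    pairs = pair_bipartite(
        pre_set,
        masks[params.post_channel],
        params.overlap_threshold,
        post_puncta=post_set,
        restrict_to_post_puncta=params.restrict_to_post_puncta,
    )
    record = SynapseDensityRecord(
        field_id=field_id,
        cohort=cohort,
        region=region,
        pre_density=puncta_density(pre_set),
        post_density=puncta_density(post_set),
        bipartite_density=len(pairs) / pre_set.field_area_um2,
        pre_count=pre_set.count,
        post_count=post_set.count,
        bipartite_count=len(pairs),
    )
    return record, {"puncta": sets, "pairs": pairs, "masks": masks}
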