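"""MRE-derived mechanical property maps and their group averaging.

From complex shear modulus volumes ``G* = G' + iG''`` this module derives
the shear stiffness

    mu = 2 |G*|^2 / (G' + |G*|)

and the damping ratio ``xi = G'' / (2 G')``, averages derived per-subject
maps voxelwise with a majority (50%) vote mask, merges fine anatomical
labels to the six canonical regions, and summarises property distributions
(median + empirical CDF).

The stiffness definition uses ``|G*|`` in the denominator (the standard
elastography form, which reduces to ``mu = G'`` in the purely elastic
limit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .templates import GroupTemplate
from .volumes import LabelVolume, MaskVolume, Volume3D, require_same_grid

__all__ = [
    "ComplexModulusMap",
    "PropertySummary",
    "shear_stiffness",
    "damping_ratio",
    "majority_mask",
    "group_average_maps",
    "merge_regions",
    "summarize",
]


@dataclass
class ComplexModulusMap:
    """Storage/loss modulus volumes (Pa) at one actuation frequency."""

    frequency_hz: float
    storage: Volume3D
    loss: Volume3D
    valid: MaskVolume

    def __post_init__(self) -> None:
        require_same_grid(self.storage, self.loss, self.valid)
        if not self.frequency_hz > 0:
            raise ValueError("frequency must be positive")
        v = self.valid.data
        if np.any(self.storage.data[v] <= 0):
            raise ValueError("G' must be positive inside the valid mask")
        if np.any(self.loss.data[v] < 0):
            raise ValueError("G'' must be non-negative inside the valid mask")


@dataclass
class PropertySummary:
    """Median and empirical CDF of a property over masked voxels."""

    median: float
    cdf_values: np.ndarray
    cdf_fractions: np.ndarray
    n_voxels: int


def shear_stiffness(m: ComplexModulusMap) -> Volume3D:
    """Shear stiffness ``mu = 2|G*|^2 / (G' + |G*|)`` (Pa); NaN outside ``valid``."""
    v = m.valid.data
    if not v.any():
        raise ValueError("empty valid mask")
    gp = m.storage.data
    gpp = m.loss.data
    out = np.full(gp.shape, np.nan)
    mag2 = gp[v] ** 2 + gpp[v] ** 2
    out[v] = 2.0 * mag2 / (gp[v] + np.sqrt(mag2))
    return Volume3D(out, m.storage.spacing_mm, m.storage.origin_mm)


def damping_ratio(m: ComplexModulusMap) -> Volume3D:
    """Damping ratio ``xi = G'' / (2 G')`` (dimensionless); NaN outside ``valid``."""
    v = m.valid.data
    if not v.any():
        raise ValueError("empty valid mask")
    out = np.full(m.storage.shape, np.nan)
    out[v] = m.loss.data[v] / (2.0 * m.storage.data[v])
    return Volume3D(out, m.storage.spacing_mm, m.storage.origin_mm)


def majority_mask(counts: Volume3D, n_subjects: int) -> MaskVolume:
    """Majority (50%) vote: keep voxels with data in at least half the subjects.

    A voxel is removed iff its contribution count is strictly less than
    ``n_subjects / 2``.
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    if np.any(counts.data > n_subjects):
        raise ValueError("counts exceed n_subjects")
    return MaskVolume(counts.data >= n_subjects / 2.0, counts.spacing_mm, counts.origin_mm)


def group_average_maps(
    maps: Sequence[Volume3D],
    valids: Sequence[MaskVolume] | None = None,
) -> GroupTemplate:
    """Voxelwise mean/SD over subjects with valid data, majority-vote masked.

    ``valids`` defaults to the NaN pattern of each map (NaN = no data).  The
    returned template's mask applies :func:`majority_mask` to the count map;
    mean/SD are still reported wherever at least one subject contributed.
    """
    if len(maps) == 0:
        raise ValueError("empty map list")
    require_same_grid(*maps)
    n = len(maps)
    if valids is None:
        valids = [
            MaskVolume(np.isfinite(m.data), m.spacing_mm, m.origin_mm) for m in maps
        ]
    else:
        valids = [
            MaskVolume(v.data & np.isfinite(m.data), m.spacing_mm, m.origin_mm)
            for m, v in zip(maps, valids)
        ]
    require_same_grid(maps[0], *valids)
    from .templates import average_images  # shared implementation

    tpl = average_images(maps, masks=valids)
    tpl.mask = majority_mask(tpl.count, n)
    return tpl


def merge_regions(
    labels: LabelVolume,
    mapping: Mapping[int, int],
    region_names: Mapping[int, str] | None = None,
    passthrough: Sequence[int] = (),
) -> LabelVolume:
    """Merge fine anatomical labels into coarse regions.

    Every nonzero fine label must appear in ``mapping`` or ``passthrough``
    (kept unchanged); an unmapped label raises an error naming it.
    """
    present = [int(v) for v in np.unique(labels.data) if v != 0]
    keep = set(int(p) for p in passthrough)
    unmapped = [lab for lab in present if lab not in mapping and lab not in keep]
    if unmapped:
        raise KeyError(f"fine labels with no region mapping: {unmapped}")
    lut = np.arange(max(present, default=0) + 1, dtype=np.int32)
    for fine, region in mapping.items():
        if fine <= len(lut) - 1:
            lut[fine] = region
    merged = lut[labels.data]
    names: dict[int, str] = {}
    for lab in present:
        rid = int(mapping.get(lab, lab))
        if region_names and rid in region_names:
            names[rid] = region_names[rid]
        elif lab in keep:
            names[rid] = labels.label_names.get(lab, f"label_{lab}")
        else:
            names.setdefault(rid, f"region_{rid}")
    return LabelVolume(merged, labels.spacing_mm, names, labels.origin_mm)


def summarize(map_: Volume3D, mask: MaskVolume) -> PropertySummary:
    """Median (linear-interpolation percentile) and empirical CDF over a mask."""
    require_same_grid(map_, mask)
    vals = map_.data[mask.data]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty mask (or all-NaN values) in summarize")
    srt = np.sort(vals)
    fractions = np.arange(1, srt.size + 1) / srt.size
    return PropertySummary(
        median=float(np.percentile(vals, 50.0)),
        cdf_values=srt,
        cdf_fractions=fractions,
        n_voxels=int(vals.size),
    )
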