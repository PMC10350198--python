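"""Ordinal morphometry maps: the single-channel classifier input.

Tissue segmentations and the lesion mask are merged into one ordinal map
(background 0, CSF 1, GM 2, WM 3, lesion 4 -- lesion supersedes tissue),
downsampled by modal pooling, cropped to the cohort-common field of view and
linearly rescaled to [-1, 1].

The ordinal order CSF < GM < WM follows tissue density and is configurable
through ``code_table``.  Modal pooling is the block analog of nearest-neighbor
interpolation for label maps; ties are broken toward the HIGHEST code so a
lesion never disappears on a tie.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

from .errors import ArgumentError, ShapeError

DEFAULT_CODE_TABLE: dict[str, int] = {
    "background": 0, "csf": 1, "gm": 2, "wm": 3, "lesion": 4,
}


@dataclass
class OrdinalMorphometryMap:
    values: np.ndarray
    voxel_size_mm: float
    code_table: Mapping[str, int]
    scaled: bool = False

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return tuple(self.values.shape)

    def lesion_volume_voxels(self) -> int:
        code = max(self.code_table.values())
        target = 1.0 if self.scaled else code
        return int(np.count_nonzero(np.isclose(self.values, target)))


def compose_ordinal_map(
    tissue_masks: Mapping[str, np.ndarray],
    lesion_mask: np.ndarray,
    voxel_size_mm: float = 2.0,
    code_table: Mapping[str, int] = DEFAULT_CODE_TABLE,
) -> OrdinalMorphometryMap:
    """Merge binary tissue masks and the lesion into one ordinal volume.

    Every voxel receives exactly one code; the lesion code overrides any
    tissue code and background fills voxels no mask claims.
    """
    shape = lesion_mask.shape
    for name, mask in tissue_masks.items():
        if mask.shape != shape:
            raise ShapeError(f"mask '{name}' shape {mask.shape} != {shape}")
    values = np.full(shape, code_table["background"], dtype=np.int16)
    for name in ("csf", "gm", "wm"):
        values[np.asarray(tissue_masks[name], dtype=bool)] = code_table[name]
    values[np.asarray(lesion_mask, dtype=bool)] = code_table["lesion"]
    return OrdinalMorphometryMap(values, float(voxel_size_mm), dict(code_table))


def downsample_mode(omap: OrdinalMorphometryMap, factor: int) -> OrdinalMorphometryMap:
    """Modal (majority) pooling over ``factor**3`` blocks.

    Trailing partial blocks are pooled over the voxels they do contain.  Ties
    are broken toward the highest code.  The voxel size grows by ``factor``.
    """
    if factor < 1:
        raise ArgumentError("downsampling factor must be >= 1")
    if omap.scaled:
        raise ArgumentError("downsample before scaling, not after")
    if factor == 1:
        return replace(omap, values=omap.values.copy())
    v = omap.values
    pad = [(0, (-d) % factor) for d in v.shape]
    # Sentinel -1 marks padding; it is never a valid code so it cannot win.
    vp = np.pad(v, pad, constant_values=-1)
    blocks = vp.reshape(
        vp.shape[0] // factor, factor,
        vp.shape[1] // factor, factor,
        vp.shape[2] // factor, factor,
    ).transpose(0, 2, 4, 1, 3, 5).reshape(
        vp.shape[0] // factor, vp.shape[1] // factor, vp.shape[2] // factor, -1
    )
    codes = sorted(set(omap.code_table.values()))
    counts = np.stack([(blocks == c).sum(axis=-1) for c in codes], axis=-1)
    # argmax over reversed code axis returns the highest code among ties
    winner_rev = np.argmax(counts[..., ::-1], axis=-1)
    out = np.asarray(codes)[len(codes) - 1 - winner_rev].astype(np.int16)
    return OrdinalMorphometryMap(out, omap.voxel_size_mm * factor,
                                 dict(omap.code_table))


def crop_common_fov(
    maps: Sequence[OrdinalMorphometryMap],
) -> tuple[list[OrdinalMorphometryMap], tuple[slice, slice, slice]]:
    """Crop every map to the tightest box holding all nonzero voxels of all maps."""
    if not maps:
        raise ArgumentError("no maps to crop")
    shape = maps[0].grid_shape
    bg = maps[0].code_table["background"]
    union = np.zeros(shape, dtype=bool)
    for m in maps:
        if m.grid_shape != shape:
            raise ShapeError("maps do not share a grid")
        union |= m.values != bg
    if not union.any():
        raise ShapeError("all maps empty: no nonzero voxel to crop to")
    box = tuple(
        slice(int(idx.min()), int(idx.max()) + 1)
        for idx in np.nonzero(union)
    )
    cropped = [replace(m, values=m.values[box].copy()) for m in maps]
    return cropped, box


def scale_to_range(omap: OrdinalMorphometryMap) -> OrdinalMorphometryMap:
    """Linear rescale of codes to [-1, 1]: code c -> 2c/c_max - 1."""
    if omap.scaled:
        raise ArgumentError("map already scaled")
    c_max = max(omap.code_table.values())
    values = 2.0 * omap.values.astype(np.float64) / c_max - 1.0
    return OrdinalMorphometryMap(values, omap.voxel_size_mm,
                                 dict(omap.code_table), scaled=True)


def preprocess_cohort(
    tissue_masks_per_subject: Sequence[Mapping[str, np.ndarray]],
    lesion_masks: Sequence[np.ndarray],
    voxel_size_mm: float,
    factor: int,
) -> tuple[np.ndarray, tuple[slice, slice, slice], OrdinalMorphometryMap]:
    """compose -> downsample -> crop -> scale for a whole cohort.

    Returns the stacked scaled maps as an (n_subjects, *grid) float array,
    the common crop box (in downsampled coordinates), and one representative
    scaled map carrying the metadata.
    """
    coarse = [
        downsample_mode(compose_ordinal_map(tm, lm, voxel_size_mm), factor)
        for tm, lm in zip(tissue_masks_per_subject, lesion_masks)
    ]
    cropped, box = crop_common_fov(coarse)
    scaled = [scale_to_range(m) for m in cropped]
    X = np.stack([m.values for m in scaled]).astype(np.float32)
    return X, box, scaled[0]


# ---------------------------------------------------------------------------
# NIfTI I/O (RAS orientation, voxel size in the header)
# ---------------------------------------------------------------------------

def write_nifti(values: np.ndarray, voxel_size_mm: float, path) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(values), affine)
    img.header.set_zooms((voxel_size_mm,) * 3)
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj), float(zooms[0])


def write_map(omap: OrdinalMorphometryMap, path) -> None:
    write_nifti(omap.values, omap.voxel_size_mm, path)


def read_map(path, code_table: Mapping[str, int] = DEFAULT_CODE_TABLE,
             scaled: bool = False) -> OrdinalMorphometryMap:
    values, vox = read_nifti(path)
    return OrdinalMorphometryMap(values, vox, dict(code_table), scaled=scaled)
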