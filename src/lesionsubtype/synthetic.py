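"""Synthetic stroke cohorts with known ground truth.

Generates template-space tissue segmentations (CSF/GM/WM), left-hemisphere
lesion masks, planted multi-focal atrophy subtypes and WAB-AQ-like severity
scores.  The generator emulates the statistical structure the downstream
analysis assumes -- severity driven jointly by lesion size and extralesional
atrophy burden, subtype membership independent of lesion size, and a target
fraction of the cohort at or below the severe cutoff (WAB-AQ <= 50) -- while
remaining cheap enough to regenerate at test time.

All randomness flows from the single ``CohortSpec.seed`` through named
``numpy`` substreams, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import ArgumentError, ConfigurationError, ShapeError, SizingError

log = logging.getLogger(__name__)

#: WAB-AQ of an unimpaired speaker; near the top of the 0-100 scale.
DEFAULT_CEILING = 97.5

#: Largest lesion, as a fraction of left-hemisphere brain volume (MCA-scale).
MAX_LESION_FRACTION = 0.45


# ---------------------------------------------------------------------------
# Specs and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``lesion_effect`` is in severity points per unit lesion volume, where
    lesion volume is expressed as a fraction of the left-hemisphere brain
    volume; ``atrophy_effect`` is in severity points per unit atrophy burden
    (burden ~ U(*burden_range*)).  Both are rescaled by a common calibration
    factor so the realized severe fraction lands within +/-5 percentage
    points of ``severe_prevalence_target``.
    """

    n_subjects: int = 231
    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_size_mm: float = 2.0
    severe_prevalence_target: float = 0.35
    n_subtypes: int = 4
    #: Atrophy dominates severity (the phenomenon under study: integrity of
    #: tissue outside the lesion carries the predictive signal); the lesion
    #: contributes but is deliberately not the sole driver.
    atrophy_effect: float = 40.0
    #: Different subtypes (different brain systems) contribute differently
    #: to severity: subtype k's effect is atrophy_effect scaled linearly
    #: from (1 + spread) down to (1 - spread) across subtypes.  A predictor
    #: must therefore encode WHERE atrophy sits, not just how much there is.
    subtype_effect_spread: float = 0.5
    lesion_effect: float = 60.0
    noise_sd: float = 6.0
    ceiling: float = DEFAULT_CEILING
    #: burden ~ U(*burden_range*): even mildly affected subjects carry a
    #: spatially detectable share of their subtype's pattern.
    burden_range: tuple[float, float] = (0.5, 1.3)
    #: White matter in the pattern territory degenerates alongside the
    #: cortex, at this fraction of the grey-matter conversion rate.
    wm_atrophy_scale: float = 0.7
    #: Lesion size quantiles are drawn from this band: chronic left-MCA
    #: stroke cohorts concentrate at moderate volumes (tiny lacunes and
    #: hemisphere-wiping infarcts are both uncommon).
    lesion_quantile_range: tuple[float, float] = (0.2, 0.9)
    #: Gaussian focus width of subtype patterns as a fraction of the grid.
    pattern_sigma_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 12:
            raise ConfigurationError("n_subjects must be >= 12")
        if not (0.0 < self.severe_prevalence_target < 1.0):
            raise ConfigurationError("severe_prevalence_target must be in (0,1)")
        if self.n_subtypes < 1:
            raise ConfigurationError("n_subtypes must be >= 1")
        if len(self.grid_shape) != 3 or any(d % 2 for d in self.grid_shape):
            raise ConfigurationError("grid dimensions must be three even counts")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")


@dataclass
class AnatomyTemplate:
    """Mirror-symmetric ellipsoidal head: CSF shell, GM ribbon, WM core."""

    csf: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    brain: np.ndarray          # union of the three tissues
    left: np.ndarray           # left-hemisphere half of the brain mask
    right: np.ndarray
    voxel_size_mm: float
    lesion_seed_voxel: tuple[int, int, int]  # perisylvian-analog growth origin

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.brain.shape)


@dataclass
class SyntheticSubject:
    subject_id: str
    tissue_masks: dict[str, np.ndarray]   # keys: csf, gm, wm (bool grids)
    lesion_mask: np.ndarray
    true_subtype: int
    atrophy_burden: float
    wab_aq: float

    def validate(self) -> None:
        csf, gm, wm = (self.tissue_masks[k] for k in ("csf", "gm", "wm"))
        if (csf & gm).any() or (csf & wm).any() or (gm & wm).any():
            raise ShapeError(f"{self.subject_id}: tissue masks overlap")
        half = self.lesion_mask.shape[0] // 2
        if self.lesion_mask[half:].any():
            raise ShapeError(f"{self.subject_id}: lesion crosses midline")
        if not (0.0 <= self.wab_aq <= 100.0):
            raise ShapeError(f"{self.subject_id}: wab_aq outside [0,100]")


@dataclass
class Cohort:
    spec: CohortSpec
    template: AnatomyTemplate
    subjects: list[SyntheticSubject]
    subtype_patterns: np.ndarray          # (K, *grid) probability maps
    ground_truth: pd.DataFrame            # per-subject truth table
    calibration_scale: float = 1.0


# ---------------------------------------------------------------------------
# Template anatomy
# ---------------------------------------------------------------------------

def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Named substream of the cohort seed (keeps every draw reproducible)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


def build_anatomy_template(
    grid_shape: Sequence[int],
    voxel_size_mm: float = 2.0,
    seed: int = 0,
) -> AnatomyTemplate:
    """Deterministic mirror-symmetric brain phantom.

    Nested ellipsoids define WM core (rho < 0.55), a GM ribbon
    (0.55 <= rho < 0.85) and a CSF shell (0.85 <= rho <= 1), where rho is the
    normalized ellipsoidal radius.  The first axis is sagittal; the left
    hemisphere occupies indices below the midplane.  ``seed`` is accepted for
    interface uniformity; the template itself is deterministic.
    """
    grid_shape = tuple(int(d) for d in grid_shape)
    if len(grid_shape) != 3:
        raise SizingError("grid_shape must have three dimensions")
    if any(d < 16 for d in grid_shape):
        raise SizingError(
            f"grid {grid_shape} too small: every axis must be >= 16 to fit "
            "CSF shell, GM ribbon and WM core"
        )
    center = [(d - 1) / 2.0 for d in grid_shape]
    radii = [0.44 * d for d in grid_shape]
    coords = np.meshgrid(*(np.arange(d) for d in grid_shape), indexing="ij")
    rho = np.sqrt(sum(((c - m) / r) ** 2 for c, m, r in zip(coords, center, radii)))

    wm = rho < 0.55
    gm = (rho >= 0.55) & (rho < 0.85)
    csf = (rho >= 0.85) & (rho <= 1.0)
    brain = wm | gm | csf
    if not (wm.any() and gm.any() and csf.any()):
        raise SizingError("grid too small to contain all three tissue layers")

    half = grid_shape[0] // 2
    left = brain.copy()
    left[half:] = False
    right = brain & ~left

    # Perisylvian analog: lateral-left, mid-height, mid-depth, on the GM/WM rim.
    x0 = max(1, int(round(center[0] - 0.35 * radii[0])))
    seed_voxel = (x0, int(round(center[1])), int(round(center[2])))
    if not brain[seed_voxel]:  # pragma: no cover - defensive for odd grids
        idx = np.argwhere(left)
        d2 = ((idx - np.array(seed_voxel)) ** 2).sum(axis=1)
        seed_voxel = tuple(idx[np.argmin(d2)])

    return AnatomyTemplate(
        csf=csf, gm=gm, wm=wm, brain=brain, left=left, right=right,
        voxel_size_mm=float(voxel_size_mm), lesion_seed_voxel=seed_voxel,
    )


# ---------------------------------------------------------------------------
# Lesions
# ---------------------------------------------------------------------------

def _lesion_graph(template: AnatomyTemplate):
    """Edge structure of the 6-connected left-hemisphere graph (cached)."""
    cached = getattr(template, "_graph_cache", None)
    if cached is not None:
        return cached
    left_idx = np.flatnonzero(template.left.ravel())
    n = left_idx.size
    pos = -np.ones(template.left.size, dtype=np.int64)
    pos[left_idx] = np.arange(n)

    shape = template.grid_shape
    coords = np.array(np.unravel_index(left_idx, shape)).T
    rows, cols = [], []
    for axis in range(3):
        step = np.zeros(3, dtype=np.int64)
        step[axis] = 1
        nbr = coords + step
        ok = nbr[:, axis] < shape[axis]
        flat = np.ravel_multi_index(nbr[ok].T, shape)
        keep = pos[flat] >= 0
        rows.append(np.flatnonzero(ok)[keep])
        cols.append(pos[flat[keep]])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    src = pos[np.ravel_multi_index(template.lesion_seed_voxel, shape)]
    cached = (left_idx, rows, cols, int(src), n)
    template._graph_cache = cached
    return cached


def _growth_order(template: AnatomyTemplate, rng: np.random.Generator) -> np.ndarray:
    """Voxel ordering for lesion growth.

    Runs Dijkstra over the 6-connected left-hemisphere brain graph from the
    perisylvian seed with mildly randomized edge costs.  Sorting voxels by
    arrival distance yields orderings whose every prefix is connected, so a
    lesion of any size is a single blob and growth is monotone in size.
    """
    left_idx, rows, cols, src, n = _lesion_graph(template)
    # Cost of entering a voxel: 1 plus subject-specific jitter -> irregular blobs.
    jitter = rng.uniform(0.0, 1.5, size=n)
    w = 1.0 + 0.5 * (jitter[rows] + jitter[cols])
    graph = csr_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    )
    dist = dijkstra(graph, indices=src)
    order = np.argsort(dist, kind="stable")
    reachable = np.isfinite(dist[order])
    return left_idx[order[reachable]]


def sample_lesion_mask(
    template: AnatomyTemplate,
    size_quantile: float,
    seed: int = 0,
    _order: np.ndarray | None = None,
) -> np.ndarray:
    """Connected left-hemisphere lesion grown from the perisylvian seed.

    ``size_quantile`` in [0,1] maps linearly onto [1 voxel,
    ``MAX_LESION_FRACTION`` of the left-hemisphere volume]; for a fixed seed a
    larger quantile never yields a smaller lesion.
    """
    if not (0.0 <= size_quantile <= 1.0):
        raise ArgumentError("size_quantile must be in [0, 1]")
    order = _order if _order is not None else _growth_order(template, _rng(seed, 11))
    n_left = order.size
    target = max(1, int(round(size_quantile * MAX_LESION_FRACTION * n_left)))
    if target > n_left:  # pragma: no cover - cap never hit with fraction < 1
        log.warning("requested lesion volume exceeds left hemisphere; capping")
        target = n_left
    mask = np.zeros(template.brain.size, dtype=bool)
    mask[order[:target]] = True
    return mask.reshape(template.grid_shape)


# ---------------------------------------------------------------------------
# Atrophy subtypes
# ---------------------------------------------------------------------------

#: Octant assignment giving every subtype a unique primary focus, at least
#: one right-hemisphere (contralesional) focus, and disjoint anchor sets for
#: up to four subtypes.  Octant index bit pattern: 4*sx + 2*sy + sz with
#: sx=0 left; XOR with 4 mirrors the sagittal axis.
_ANCHOR_PERMUTATION = (1, 4, 3, 6, 0, 5, 2, 7)


def make_subtype_patterns(
    template: AnatomyTemplate,
    n_subtypes: int,
    seed: int = 0,
    sigma_fraction: float = 0.10,
) -> np.ndarray:
    """Probability maps (max 1) of K planted atrophy subtypes.

    Each subtype is a mixture of 2-4 Gaussian blobs.  The primary focus sits
    at a subtype-specific octant anchor on the GM ribbon; even-numbered
    subtypes add the sagittal mirror of their primary (bilateral patterns),
    odd-numbered subtypes add jittered satellites near the primary.  Lesions
    live in the left hemisphere only, so every subtype keeps at least one
    contralesional focus that a large stroke cannot erase.
    """
    if n_subtypes < 1:
        raise ArgumentError("n_subtypes must be >= 1")
    rng = _rng(seed, 23)
    shape = template.grid_shape
    center = np.array([(d - 1) / 2.0 for d in shape])
    radii = np.array([0.44 * d for d in shape])
    # Eight octant anchors on the GM ribbon (rho ~ 0.7).
    signs = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    anchors = center + 0.7 / np.sqrt(3.0) * signs * radii

    coords = np.stack(np.meshgrid(*(np.arange(d) for d in shape), indexing="ij"), axis=-1)
    sigma = sigma_fraction * np.array(shape)

    patterns = np.zeros((n_subtypes, *shape), dtype=np.float64)
    for k in range(n_subtypes):
        primary = anchors[_ANCHOR_PERMUTATION[k % 8]]
        foci = [primary]
        if k % 2 == 0:
            mirror = primary.copy()
            mirror[0] = 2 * center[0] - mirror[0]  # contralateral homologue
            foci.append(mirror)
        else:
            foci.append(primary + rng.normal(0.0, 3.0, size=3))
        for _ in range(int(rng.integers(0, 3))):  # 2-4 blobs total
            foci.append(foci[-1] + rng.normal(0.0, 3.0, size=3))
        pat = np.zeros(shape)
        for f in foci:
            d2 = (((coords - f) / sigma) ** 2).sum(axis=-1)
            pat = np.maximum(pat, np.exp(-0.5 * d2))
        patterns[k] = pat
    return patterns


def apply_subtype_atrophy(
    tissue_masks: dict[str, np.ndarray],
    subtype_pattern: np.ndarray,
    burden: float,
    seed: int = 0,
    tissue: str = "gm",
) -> tuple[dict[str, np.ndarray], int]:
    """Convert ``tissue`` voxels (GM by default) to CSF with probability
    ``burden * pattern``.

    Returns the modified masks (copies) and the number of converted voxels.
    The expected count is ``burden * pattern.sum over the tissue`` as long as
    the product stays <= 1 (probabilities are clipped above that).  The
    cohort generator applies the pattern to grey matter (cortical thinning)
    and, attenuated, to white matter (tract degeneration in the same
    territory).
    """
    if burden < 0:
        raise ArgumentError("burden must be nonnegative")
    if tissue not in ("gm", "wm"):
        raise ArgumentError("tissue must be 'gm' or 'wm'")
    target = tissue_masks[tissue]
    if subtype_pattern.shape != target.shape:
        raise ShapeError(
            f"pattern shape {subtype_pattern.shape} != grid {target.shape}"
        )
    out = {k: v.copy() for k, v in tissue_masks.items()}
    if burden == 0:
        return out, 0
    rng = _rng(seed, 37 if tissue == "gm" else 41)
    p = np.clip(burden * subtype_pattern, 0.0, 1.0)
    convert = target & (rng.random(target.shape) < p)
    n = int(convert.sum())
    out[tissue][convert] = False
    out["csf"][convert] = True
    return out, n


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _severity(ceiling, scale, lesion_effect, lesion_frac, atrophy_effect,
              burden, noise):
    raw = (ceiling
           - scale * (lesion_effect * lesion_frac + atrophy_effect * burden)
           + noise)
    return np.clip(raw, 0.0, 100.0)


def generate_cohort(spec: CohortSpec, calibrate: bool = True) -> Cohort:
    """Draw a full cohort under ``spec``.

    Severity follows a linear-with-Gaussian-noise model clipped to [0,100]:
    ``wab_aq = ceiling - lesion_effect*v - atrophy_effect*b + N(0, noise_sd)``
    with ``v`` the lesion volume as a fraction of the left hemisphere and
    ``b`` the planted atrophy burden.  Lesion size and subtype are drawn
    independently, so subtype is not predictable from lesion volume.  When
    both effects are nonzero a common multiplier is calibrated by bisection
    so the realized fraction with ``wab_aq <= 50`` falls within +/-5
    percentage points of the target.
    """
    template = build_anatomy_template(spec.grid_shape, spec.voxel_size_mm, spec.seed)
    patterns = make_subtype_patterns(template, spec.n_subtypes, spec.seed,
                                     sigma_fraction=spec.pattern_sigma_fraction)
    n = spec.n_subjects
    n_left = int(template.left.sum())

    draw = _rng(spec.seed, 1)
    quantiles = draw.uniform(*spec.lesion_quantile_range, size=n)
    subtypes = draw.integers(0, spec.n_subtypes, size=n)
    burdens = draw.uniform(*spec.burden_range, size=n)
    noise = (draw.normal(0.0, spec.noise_sd, size=n)
             if spec.noise_sd > 0 else np.zeros(n))

    subjects: list[SyntheticSubject] = []
    lesion_fracs = np.empty(n)
    lesion_vols = np.empty(n, dtype=int)
    for i in range(n):
        order = _growth_order(template, _rng(spec.seed, 2, i))
        lesion = sample_lesion_mask(template, quantiles[i], _order=order)
        masks = {"csf": template.csf.copy(), "gm": template.gm.copy(),
                 "wm": template.wm.copy()}
        masks, _ = apply_subtype_atrophy(
            masks, patterns[subtypes[i]], burdens[i], seed=_seed_for(spec.seed, 3, i))
        if spec.wm_atrophy_scale > 0:
            masks, _ = apply_subtype_atrophy(
                masks, patterns[subtypes[i]],
                spec.wm_atrophy_scale * burdens[i],
                seed=_seed_for(spec.seed, 4, i), tissue="wm")
        # Lesion supersedes tissue: carve it out of every tissue mask.
        for k in masks:
            masks[k] &= ~lesion
        lesion_vols[i] = int(lesion.sum())
        lesion_fracs[i] = lesion_vols[i] / n_left
        subjects.append(SyntheticSubject(
            subject_id=f"sub-{i + 1:04d}", tissue_masks=masks,
            lesion_mask=lesion, true_subtype=int(subtypes[i]),
            atrophy_burden=float(burdens[i]), wab_aq=np.nan,
        ))

    # per-subtype atrophy effects: linear spread, strongest for subtype 0
    if spec.n_subtypes > 1:
        spread = np.linspace(1.0 + spec.subtype_effect_spread,
                             1.0 - spec.subtype_effect_spread, spec.n_subtypes)
    else:
        spread = np.ones(1)
    subtype_effects = spec.atrophy_effect * spread
    effect_per_subject = subtype_effects[subtypes]

    # --- prevalence calibration (common multiplier on both effect sizes) ---
    def severe_fraction(scale: float) -> float:
        wab = _severity(spec.ceiling, scale, spec.lesion_effect, lesion_fracs,
                        effect_per_subject, burdens, noise)
        return float(np.mean(wab <= 50.0))

    scale = 1.0
    effects_zero = spec.lesion_effect == 0 and spec.atrophy_effect == 0
    if calibrate and not effects_zero:
        lo, hi = 0.0, 8.0
        f_lo, f_hi = severe_fraction(lo), severe_fraction(hi)
        target = spec.severe_prevalence_target
        if not (f_lo - 0.05 <= target <= f_hi + 0.05):
            raise ConfigurationError(
                "prevalence calibration failed: achievable severe fraction "
                f"range is [{f_lo:.3f}, {f_hi:.3f}] for target {target:.3f}"
            )
        for _ in range(60):
            scale = 0.5 * (lo + hi)
            f = severe_fraction(scale)
            if abs(f - target) <= 0.02:
                break
            if f < target:
                lo = scale
            else:
                hi = scale
        if abs(severe_fraction(scale) - target) > 0.05:
            raise ConfigurationError(
                "prevalence calibration failed to converge within +/-5 points"
            )

    wab = _severity(spec.ceiling, scale, spec.lesion_effect, lesion_fracs,
                    effect_per_subject, burdens, noise)
    for i, s in enumerate(subjects):
        s.wab_aq = float(wab[i])
        s.validate()

    truth = pd.DataFrame({
        "subject_id": [s.subject_id for s in subjects],
        "wab_aq": wab,
        "true_subtype": subtypes,
        "atrophy_burden": burdens,
        "lesion_volume_voxels": lesion_vols,
        "lesion_volume_fraction": lesion_fracs,
    })
    return Cohort(spec=spec, template=template, subjects=subjects,
                  subtype_patterns=patterns, ground_truth=truth,
                  calibration_scale=scale)


def _seed_for(seed: int, *stream: int) -> int:
    """Stable integer sub-seed (< 2**31) derived from a named substream."""
    return int(_rng(seed, *stream).integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# NIfTI export
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write per-subject NIfTI masks and ``cohort.csv`` under ``out_dir``."""
    import pathlib

    from .morphomap import write_nifti

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vox = cohort.spec.voxel_size_mm
    for s in cohort.subjects:
        for name, mask in {**s.tissue_masks, "lesion": s.lesion_mask}.items():
            write_nifti(mask.astype(np.uint8), vox,
                        out / f"{s.subject_id}_{name}.nii")
    cols = ["subject_id", "wab_aq", "true_subtype", "lesion_volume_voxels"]
    cohort.ground_truth[cols].to_csv(out / "cohort.csv", index=False)
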