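"""Preallocated repeated, stratified, nested cross-validation plans.

One plan is built up front and shared by every model (CNN, SVMs, fusion), so
paired comparisons across the repeats see byte-identical partitions.
Stratification uses the granular WAB-R severity categories (very severe,
severe, moderate, mild) rather than the binary target, which keeps the raw
score distributions of the folds similar.

Fold assignment shuffles subjects within each stratum and deals them
round-robin into folds, carrying the dealing pointer across strata; this
keeps every fold within one subject of the global stratum proportions and
overall fold sizes within one of each other.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, RangeError

log = logging.getLogger(__name__)

CATEGORIES = ("very_severe", "severe", "moderate", "mild")

#: Binary severe cutoff: WAB-AQ <= 50 (the "very severe" + "severe" categories).
SEVERE_CUTOFF = 50.0


def granular_category(wab_aq: float) -> tuple[str, int]:
    """WAB-R severity category and binary severe label for one score.

    Categories: very severe [0,25], severe (25,50], moderate (50,76),
    mild [76,100] -- the printed 75/76 gap is closed by assigning scores in
    (75,76) to moderate.  Binary label is 1 (severe) iff score <= 50.
    """
    if not (0.0 <= wab_aq <= 100.0):
        raise RangeError(f"wab_aq {wab_aq} outside [0, 100]")
    severe_binary = int(wab_aq <= SEVERE_CUTOFF)
    if wab_aq <= 25.0:
        return "very_severe", severe_binary
    if wab_aq <= 50.0:
        return "severe", severe_binary
    if wab_aq < 76.0:
        return "moderate", severe_binary
    return "mild", severe_binary


def categorize(scores) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ``granular_category``: (categories, binary labels)."""
    pairs = [granular_category(float(s)) for s in np.asarray(scores).ravel()]
    cats = np.array([p[0] for p in pairs])
    labels = np.array([p[1] for p in pairs], dtype=np.int64)
    return cats, labels


@dataclass
class CVPlan:
    """Repeated nested stratified partition indices.

    ``outer[r][f]`` is the test-index array of outer fold ``f`` in repeat
    ``r``; ``inner[r][f][g]`` is the validation-index array of inner fold
    ``g`` built on the corresponding outer-train set.
    """

    n_repeats: int
    n_outer: int
    n_inner: int
    strata: np.ndarray
    seed: int
    outer: list[list[np.ndarray]] = field(default_factory=list)
    inner: list[list[list[np.ndarray]]] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.strata)

    def outer_train(self, repeat: int, fold: int) -> np.ndarray:
        test = set(self.outer[repeat][fold].tolist())
        return np.array([i for i in range(self.n_subjects) if i not in test],
                        dtype=np.int64)

    # -- serialization (bit-exact round trip) --------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "n_repeats": self.n_repeats, "n_outer": self.n_outer,
            "n_inner": self.n_inner, "seed": self.seed,
            "strata": self.strata.tolist(),
            "outer": [[f.tolist() for f in rep] for rep in self.outer],
            "inner": [[[g.tolist() for g in fold] for fold in rep]
                      for rep in self.inner],
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "CVPlan":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(
            n_repeats=payload["n_repeats"], n_outer=payload["n_outer"],
            n_inner=payload["n_inner"], strata=np.array(payload["strata"]),
            seed=payload["seed"],
            outer=[[np.array(f, dtype=np.int64) for f in rep]
                   for rep in payload["outer"]],
            inner=[[[np.array(g, dtype=np.int64) for g in fold] for fold in rep]
                   for rep in payload["inner"]],
        )


def _ordered_strata(values) -> list:
    """Stratum labels in severity order; unknown labels appended sorted."""
    present = set(np.asarray(values).tolist())
    ordered = [c for c in CATEGORIES if c in present]
    ordered += sorted((v for v in present - set(CATEGORIES)), key=str)
    return ordered


def _merge_small_strata(strata: np.ndarray, min_size: int) -> np.ndarray:
    """Merge strata smaller than ``min_size`` into the adjacent severity category."""
    strata = strata.copy()
    order = _ordered_strata(strata)
    merged = True
    while merged and len(order) > 1:
        merged = False
        for c in list(order):
            n_c = int(np.sum(strata == c))
            if 0 < n_c < min_size:
                pos = order.index(c)
                neighbor = order[pos - 1] if pos > 0 else order[pos + 1]
                log.warning("merging stratum %r (%d subjects) into %r",
                            c, n_c, neighbor)
                strata[strata == c] = neighbor
                order.remove(c)
                merged = True
                break
    return strata


def _deal_folds(indices_by_stratum, n_folds, rng) -> list[list[int]]:
    """Shuffle within stratum, deal round-robin with a carried pointer."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    pointer = 0
    for members in indices_by_stratum:
        members = np.array(members)
        rng.shuffle(members)
        for idx in members:
            folds[pointer % n_folds].append(int(idx))
            pointer += 1
    return folds


def _stratified_partition(indices, strata, n_folds, rng):
    present = _ordered_strata([strata[i] for i in indices])
    by_stratum = [
        [i for i in indices if strata[i] == c] for c in present
    ]
    folds = _deal_folds(by_stratum, n_folds, rng)
    return [np.array(sorted(f), dtype=np.int64) for f in folds]


def build_cv_plan(
    strata,
    n_repeats: int = 20,
    n_outer: int = 6,
    n_inner: int = 8,
    seed: int = 0,
) -> CVPlan:
    """Repeated nested stratified fold assignment, deterministic given seed."""
    strata = np.asarray(strata)
    n = len(strata)
    if n_outer > n:
        raise ArgumentError(f"n_outer={n_outer} exceeds cohort size {n}")
    strata = _merge_small_strata(strata, min_size=n_outer)
    plan = CVPlan(n_repeats=n_repeats, n_outer=n_outer, n_inner=n_inner,
                  strata=strata, seed=seed)
    for r in range(n_repeats):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 101, r])
        outer = _stratified_partition(range(n), strata, n_outer, rng)
        plan.outer.append(outer)
        inner_per_fold = []
        for f in range(n_outer):
            train = plan.outer_train(r, f)
            rng_f = np.random.default_rng([seed & 0x7FFFFFFF, 102, r, f])
            inner_per_fold.append(
                _stratified_partition(train.tolist(), strata, n_inner, rng_f))
        plan.inner.append(inner_per_fold)
    return plan


def split_train_validation(
    outer_train_indices,
    strata,
    validation_fraction: float = 0.3,
    seed: int = 0,
):
    """Stratified 70/30-style split of an outer-train set.

    Validation size is ``round(fraction * n)`` exactly; per-stratum counts
    follow the largest-remainder method.  A stratum that would be emptied
    from the train side keeps one member there (with a warning).
    """
    if not (0.0 < validation_fraction < 1.0):
        raise ArgumentError("validation_fraction must be in (0, 1)")
    idx = np.asarray(outer_train_indices)
    strata = np.asarray(strata)
    n = len(idx)
    n_val = int(round(validation_fraction * n))
    n_val = min(max(n_val, 1), n - 1)

    cats = _ordered_strata(strata[idx])
    members = {c: idx[strata[idx] == c] for c in cats}
    ideal = {c: validation_fraction * len(members[c]) for c in cats}
    counts = {c: int(np.floor(ideal[c])) for c in cats}
    remainder = n_val - sum(counts.values())
    for c in sorted(cats, key=lambda c: ideal[c] - counts[c], reverse=True):
        if remainder <= 0:
            break
        counts[c] += 1
        remainder -= 1
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 103])
    val: list[int] = []
    for c in cats:
        m = members[c].copy()
        rng.shuffle(m)
        k = counts[c]
        if k >= len(m):
            log.warning("stratum %r would be emptied from train; keeping one", c)
            k = len(m) - 1 if len(m) > 1 else 0
        val.extend(m[:k].tolist())
    val_set = set(val)
    train = np.array([i for i in idx if i not in val_set], dtype=np.int64)
    validation = np.array(sorted(val), dtype=np.int64)
    return train, validation
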