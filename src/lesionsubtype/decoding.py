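"""Meta-analytic decoding of exemplar saliency maps.

A study corpus records, per study, which voxels reported activity and which
topics the study was associated with.  For each topic, a chi-square test at
every voxel contrasts activation rates between topic-associated and other
studies; the map value is the signed square root of the statistic (positive
where topic studies activate more often).  An exemplar saliency map is then
decoded by correlating it (outside the lesion) with every topic map and
retaining topics passing both a correlation and a Bonferroni-corrected
p-value threshold.

A synthetic corpus generator plants topic-activation associations inside
chosen regions so recovery can be tested end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ArgumentError, UndefinedSimilarityError

log = logging.getLogger(__name__)


@dataclass
class TopicStudyCorpus:
    activation: np.ndarray          # (n_studies, n_voxels) binary
    topic_membership: np.ndarray    # (n_studies, n_topics) binary
    grid_shape: tuple[int, ...]

    def __post_init__(self):
        on = self.topic_membership.sum(axis=0)
        n = len(self.topic_membership)
        if np.any(on == 0) or np.any(on == n):
            raise ArgumentError(
                "every topic needs at least one member and one non-member study")

    @property
    def n_topics(self) -> int:
        return self.topic_membership.shape[1]


def make_topic_corpus(
    grid_shape,
    n_studies: int = 400,
    n_topics: int = 200,
    baseline_rate: float = 0.05,
    membership_rate: float = 0.15,
    planted: dict[int, np.ndarray] | None = None,
    odds_ratio: float = 8.0,
    seed: int = 0,
) -> TopicStudyCorpus:
    """Synthetic study corpus with optionally planted topic-region links.

    ``planted`` maps topic index -> boolean region mask (on ``grid_shape``);
    studies associated with a planted topic activate voxels inside the region
    at the rate whose odds are ``odds_ratio`` times the baseline odds.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 91])
    n_vox = int(np.prod(grid_shape))
    membership = rng.random((n_studies, n_topics)) < membership_rate
    # guarantee the member/non-member invariant
    for t in range(n_topics):
        col = membership[:, t]
        if not col.any():
            membership[rng.integers(n_studies), t] = True
        if col.all():
            membership[rng.integers(n_studies), t] = False
    activation = rng.random((n_studies, n_vox)) < baseline_rate
    if planted:
        base_odds = baseline_rate / (1.0 - baseline_rate)
        odds = odds_ratio * base_odds
        boosted = odds / (1.0 + odds)
        for topic, region in planted.items():
            region_flat = np.asarray(region, dtype=bool).ravel()
            members = np.flatnonzero(membership[:, topic])
            block = rng.random((members.size, int(region_flat.sum()))) < boosted
            activation[np.ix_(members, np.flatnonzero(region_flat))] = block
    return TopicStudyCorpus(activation=activation.astype(np.uint8),
                            topic_membership=membership.astype(np.uint8),
                            grid_shape=tuple(grid_shape))


@dataclass
class TopicMetaMap:
    values: np.ndarray
    topic_id: int


def chi_square_meta_map(corpus: TopicStudyCorpus, topic: int) -> TopicMetaMap:
    """Signed-root chi-square association map for one topic.

    Per voxel the 2x2 table crosses activity (active / inactive) with topic
    membership; the statistic is Pearson's chi-square without continuity
    correction and the sign follows the direction of association (positive
    when active-and-member exceeds its expectation).  Voxels with a zero
    margin score 0.
    """
    member = corpus.topic_membership[:, topic].astype(bool)
    if member.all() or not member.any():
        raise ArgumentError("topic must have member and non-member studies")
    act = corpus.activation.astype(np.float64)
    n = act.shape[0]
    n1 = float(member.sum())
    n0 = n - n1
    a = act[member].sum(axis=0)        # active & member
    c = act[~member].sum(axis=0)       # active & non-member
    b = n1 - a                         # inactive & member
    d = n0 - c
    row1, row2 = a + c, b + d          # active, inactive margins
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / (row1 * row2 * n1 * n0)
    chi2 = np.where((row1 == 0) | (row2 == 0), 0.0, chi2)
    expected = row1 * n1 / n
    sign = np.sign(a - expected)
    values = (sign * np.sqrt(chi2)).reshape(corpus.grid_shape)
    return TopicMetaMap(values=values, topic_id=int(topic))


def decode_saliency(
    exemplar_map: np.ndarray,
    lesion_mask: np.ndarray,
    topic_maps: list[TopicMetaMap],
    brain_mask: np.ndarray | None = None,
    r_threshold: float = 0.2,
    corrected_p_threshold: float = 0.0001,
) -> dict:
    """Rank topics by Pearson correlation with an exemplar saliency map.

    Correlations use voxels outside the lesion (and inside the brain mask
    when given); the p-value of each correlation is Bonferroni-corrected by
    the number of topics (capped at 1).  Retained topics must pass BOTH
    ``r > r_threshold`` and ``corrected p < corrected_p_threshold``.
    """
    sal = np.asarray(exemplar_map, dtype=np.float64)
    mask = ~np.asarray(lesion_mask, dtype=bool)
    if brain_mask is not None:
        mask &= np.asarray(brain_mask, dtype=bool)
    if mask.sum() < 10:
        raise ArgumentError("fewer than 10 voxels outside the lesion")
    v = sal[mask]
    if np.allclose(v, v[0]):
        raise UndefinedSimilarityError("saliency constant outside the lesion")
    m = v.size
    n_topics = len(topic_maps)
    rows = []
    for tm in topic_maps:
        w = np.asarray(tm.values, dtype=np.float64)[mask]
        if np.allclose(w, w[0]):
            r, p_raw = 0.0, 1.0
        else:
            r, p_raw = stats.pearsonr(v, w)
        p_corr = min(1.0, p_raw * n_topics)
        rows.append({"topic_id": tm.topic_id, "r": float(r),
                     "p_raw": float(p_raw), "p_corrected": float(p_corr),
                     "retained": bool(r > r_threshold
                                      and p_corr < corrected_p_threshold)})
    rows.sort(key=lambda d: d["r"], reverse=True)
    return {"ranked": rows,
            "retained": [d for d in rows if d["retained"]],
            "n_voxels": int(m)}
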