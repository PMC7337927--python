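"""Signed 3'UTR change magnitude from vector projections.

A gene's per-group mean site-usage proportions form APA vectors ordered
proximal -> distal.  Both are projected onto a distance-weighted reference
vector w with w = 0 at the most proximal cleavage point and w = 1 at the
most distal, intermediate sites placed by their genomic distance ratio.
The score is the treated-minus-control projection difference rescaled by
the maximum attainable value, so it lives in [-1, 1]:

    score = (u_t - u_c) . w / (w_distal - w_proximal) = (u_t - u_c) . w

Negative scores mean usage moved toward proximal sites (3'UTR shortening),
positive toward distal sites (lengthening).  Because w grows with distance
from the proximal end, a full switch from the distal site to the most
proximal site scores larger in magnitude than the same mass moved to an
intermediate site — the score reflects both the amount of usage moved and
how far along the 3'UTR it moved, which a plain proximal/distal usage
ratio cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from apadiff.discovery import PolyASite
from apadiff.matrix import APAMatrix

DEFAULT_NOCHANGE_DELTA = 0.05

DIRECTIONS = ("Shortened", "Lengthened", "NoChange")


@dataclass(frozen=True)
class ProjectionScore:
    gene_id: str
    score: float
    direction: str
    proj_control: float
    proj_treated: float


def reference_weight_vector(sites: list[PolyASite]) -> np.ndarray:
    """Distance-ratio weights for sites ordered proximal -> distal.

    w_i = |cleavage_i - cleavage_proximal| / |cleavage_distal - cleavage_proximal|,
    hence w[0] = 0, w[-1] = 1 and w is strictly increasing.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    pos = np.array([s.cleavage_pos for s in sites], dtype=float)
    d = np.abs(pos - pos[0])
    if len(set(pos.tolist())) != len(sites):
        raise ValueError("duplicate cleavage points (merge upstream)")
    if not np.all(np.diff(d) > 0):
        raise ValueError("sites not ordered proximal -> distal")
    return d / d[-1]


def project(u: np.ndarray, v: np.ndarray) -> float:
    """Scalar projection of u on v: (u . v) / ||v||."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("dimension mismatch")
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("reference vector must be nonzero")
    return float(u @ v / norm)


def apa_score(
    matrix: APAMatrix, delta: float = DEFAULT_NOCHANGE_DELTA
) -> ProjectionScore | None:
    """Gene-level signed 3'UTR change score from group mean APA vectors.

    Group APA vectors are row means of the proportion columns; the score
    is their projection difference on the reference weight vector,
    normalized into [-1, 1].  Returns None when a group has no reads at
    the retained sites (no proportions to compare).
    """
    if matrix.proportions is None or len(matrix.retained_sites) < 2:
        raise ValueError(f"gene {matrix.gene_id}: not normalized or <2 sites")
    labels = np.array(matrix.group_labels)
    P = matrix.proportions
    vectors = {}
    for group in ("control", "treated"):
        cols = np.flatnonzero(labels == group)
        sub = P[:, cols]
        nonzero = sub.sum(axis=0) > 0
        if not nonzero.any():
            return None  # degenerate group: no usable replicate column
        vectors[group] = sub[:, nonzero].mean(axis=1)
    w = reference_weight_vector(matrix.retained_sites)
    proj_c = project(vectors["control"], w)
    proj_t = project(vectors["treated"], w)
    # (proj_t - proj_c) normalized by the largest attainable difference,
    # (max w - min w)/||w||; with w in [0, 1] this reduces to a dot product
    score = float((vectors["treated"] - vectors["control"]) @ w)
    if score < -delta:
        direction = "Shortened"
    elif score > delta:
        direction = "Lengthened"
    else:
        direction = "NoChange"
    return ProjectionScore(
        gene_id=matrix.gene_id, score=score, direction=direction,
        proj_control=proj_c, proj_treated=proj_t,
    )
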