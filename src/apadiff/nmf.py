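"""Iterative consensus non-negative matrix factorization (NMF).

A gene's normalized APA matrix V (m sites x n replicates) is factorized
as V ~ W H with W (m x k) and H (k x n), k = 2 clusters (control vs
treated), by minimizing the Frobenius cost ||V - W H||_F^2 with
hierarchical-alternating-least-squares coordinate descent.  Replicate j
is assigned to the cluster with the largest coefficient in column j of H.
Because a single NMF run depends on its random initialization, the
factorization is repeated ``ni`` times from different seeds and the runs
aggregated into an n x n consensus matrix CM of co-clustering
frequencies: CM[i, j] (i < j) is the fraction of runs in which replicates
i and j share a cluster, the diagonal is 1 and the lower triangle is kept
at 0 (upper-triangular storage).  A clustering stability score summarizes
how well the consensus agrees with the a priori group labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_NI = 100
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500

_EPS = 1e-12


@dataclass
class FactorizationResult:
    W: np.ndarray
    H: np.ndarray
    objective: float
    objective_history: np.ndarray
    labels: np.ndarray  # cluster index per replicate (argmax over H rows)
    n_iter: int


def nmf_factorize(
    V: np.ndarray,
    k: int = 2,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FactorizationResult:
    """One NMF run by HALS coordinate descent.

    Entries of W and H are updated block-wise with the closed-form
    non-negative least-squares solution, so the objective is
    non-increasing; convergence is declared when the relative objective
    change falls below ``tol``.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a matrix")
    if (V < 0).any():
        raise ValueError("V must be non-negative")
    if k < 2:
        raise ValueError("k must be >= 2")
    m, n = V.shape
    if n < k:
        raise ValueError("V must have at least k columns")
    if not V.any():
        raise ValueError("all-zero matrix cannot be factorized")

    rng = np.random.default_rng(seed)
    # random W scaled to V's mean magnitude; H starts at zero and is filled
    # by the first coordinate-descent pass, which makes the whole run
    # equivariant under replicate (column) permutations of V
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(0.0, 1.0, size=(m, k)) * scale + _EPS
    H = np.zeros((k, n))

    obj = float(np.linalg.norm(V - W @ H) ** 2)
    history = [obj]
    prev = obj
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # update H rows
        WtV = W.T @ V
        WtW = W.T @ W
        for j in range(k):
            denom = max(WtW[j, j], _EPS)
            H[j, :] = np.maximum(
                0.0, H[j, :] + (WtV[j, :] - WtW[j, :] @ H) / denom
            )
        # update W columns
        VHt = V @ H.T
        HHt = H @ H.T
        for j in range(k):
            denom = max(HHt[j, j], _EPS)
            W[:, j] = np.maximum(
                0.0, W[:, j] + (VHt[:, j] - W @ HHt[:, j]) / denom
            )
        obj = float(np.linalg.norm(V - W @ H) ** 2)
        history.append(obj)
        if prev - obj <= tol * max(prev, _EPS):
            break
        prev = obj

    labels = np.argmax(H, axis=0)
    return FactorizationResult(
        W=W, H=H, objective=history[-1],
        objective_history=np.array(history), labels=labels, n_iter=n_iter,
    )


def align_to_prior(labels: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """Resolve the 2-cluster label-permutation ambiguity against the
    a priori groups.

    ``prior`` holds 0/1 group codes (0 = control, 1 = treated).  Of the
    two possible label permutations the one maximizing agreement with the
    prior is returned; ties keep the identity permutation.
    """
    labels = np.asarray(labels)
    prior = np.asarray(prior)
    if labels.shape != prior.shape:
        raise ValueError("labels and prior must have the same length")
    flipped = 1 - labels
    if (flipped == prior).sum() > (labels == prior).sum():
        return flipped
    return labels.copy()


@dataclass
class ConsensusMatrix:
    """Upper-triangular co-clustering frequencies over ``ni`` NMF runs."""

    cm: np.ndarray
    ni: int
    group_labels: np.ndarray  # 0/1 prior codes per replicate

    @property
    def n(self) -> int:
        return self.cm.shape[0]

    def pair_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """(intra-group, inter-group) frequencies for genuine unordered
        pairs i < j; the diagonal and lower-triangle storage zeros are
        never data."""
        intra, inter = [], []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if self.group_labels[i] == self.group_labels[j]:
                    intra.append(self.cm[i, j])
                else:
                    inter.append(self.cm[i, j])
        return np.array(intra), np.array(inter)


def consensus_matrix(
    V: np.ndarray,
    prior: np.ndarray,
    ni: int = DEFAULT_NI,
    base_seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ConsensusMatrix:
    """Aggregate ``ni`` seeded NMF runs into a consensus matrix.

    Runs use seeds ``base_seed .. base_seed + ni - 1``, so the result is a
    pure function of (V, prior, ni, base_seed).
    """
    if ni < 1:
        raise ValueError("ni must be >= 1")
    prior = np.asarray(prior)
    n = V.shape[1]
    if prior.shape != (n,):
        raise ValueError("prior must give one group code per replicate")
    co = np.zeros((n, n))
    for r in range(ni):
        res = nmf_factorize(V, k=2, seed=base_seed + r, tol=tol, max_iter=max_iter)
        aligned = align_to_prior(res.labels, prior)
        same = aligned[:, None] == aligned[None, :]
        co += same
    cm = np.triu(co / ni, k=1)
    np.fill_diagonal(cm, 1.0)
    return ConsensusMatrix(cm=cm, ni=ni, group_labels=prior.copy())


def stability_score(cm: ConsensusMatrix) -> float:
    """Mean pairwise agreement between consensus and the a priori groups.

    Same-group pairs contribute their co-clustering frequency, cross-group
    pairs one minus it; 1.0 means every run reproduced the design exactly,
    0.5 is chance level.
    """
    intra, inter = cm.pair_frequencies()
    if intra.size == 0 or inter.size == 0:
        raise ValueError("need at least 2 replicates per group")
    return float(np.concatenate([intra, 1.0 - inter]).mean())
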