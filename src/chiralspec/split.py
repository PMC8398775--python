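"""Multi-platform training/test partitioning.

A Duplex split on a single spectral block cannot account for the sample
variability of the other platform, so the partition is made on the
row-concatenated PCA scores of all blocks: per-block PCA on mean-centered
data, the leading scores of each block concatenated column-wise, and
Snee's Duplex algorithm applied to the concatenated score matrix.

Duplex seeds the training set with the globally farthest sample pair, the
test set with the farthest remaining pair, then alternately assigns to
training and test the remaining sample farthest (maximin Euclidean
distance) from each growing set, stopping test assignments once the test
set is full; all leftovers go to training. Ties are broken by lowest row
index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["SplitResult", "pca_scores", "concat_scores", "duplex_split"]


@dataclass
class SplitResult:
    train_ids: list[str]
    test_ids: list[str]
    score_matrix_used: np.ndarray
    pca_components_per_block: int | None = None

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "train_ids": self.train_ids,
                "test_ids": self.test_ids,
                "pca_components_per_block": self.pca_components_per_block,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def pca_scores(matrix: np.ndarray, n_components: int) -> np.ndarray:
    """Scores on the top principal components of a (mean-centered) matrix.

    Computed by SVD of the column-centered matrix. Sign convention: the
    largest-magnitude loading coefficient of each component is positive,
    which makes scores deterministic across SVD implementations.
    """
    matrix = np.asarray(matrix, float)
    centered = matrix - matrix.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = max(centered.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if n_components > rank:
        raise ValueError(f"requested {n_components} components but rank is {rank}")
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components]
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            scores[:, k] = -scores[:, k]
    return scores


def concat_scores(*score_matrices: np.ndarray) -> np.ndarray:
    """Column-wise juxtaposition of per-block score matrices."""
    mats = [np.asarray(m, float) for m in score_matrices]
    n_rows = {m.shape[0] for m in mats}
    if len(n_rows) != 1:
        raise ValueError("score matrices must have equal row counts")
    return np.hstack(mats)


def _farthest_from(dist: np.ndarray, candidates: list[int], members: list[int]) -> int:
    """Maximin step: candidate maximizing its minimum distance to members,
    lowest index on ties."""
    best, best_d = candidates[0], -1.0
    for c in candidates:
        d = dist[c, members].min()
        if d > best_d:
            best, best_d = c, d
    return best


def duplex_split(t_conc: np.ndarray, n_test: int, sample_ids=None) -> SplitResult:
    """Snee's Duplex partition of samples on a score matrix.

    Parameters
    ----------
    t_conc : ndarray (n_samples, n_scores)
        Concatenated per-block PCA scores.
    n_test : int
        Requested test-set size, at most ``n_samples - 2``.
    sample_ids : sequence of str, optional
        Row labels; defaults to stringified row indices.
    """
    t_conc = np.asarray(t_conc, float)
    n = t_conc.shape[0]
    if not 0 <= n_test <= n - 2:
        raise ValueError(f"n_test must be in [0, {n - 2}]")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    sample_ids = list(sample_ids)

    diff = t_conc[:, None, :] - t_conc[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))

    # training seed: globally farthest pair (lowest indices on ties)
    masked = dist.copy()
    masked[np.tril_indices(n)] = -1.0
    i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
    train = [int(i), int(j)]
    remaining = [k for k in range(n) if k not in train]

    test: list[int] = []
    if n_test >= 2:
        sub = dist[np.ix_(remaining, remaining)]
        m = len(remaining)
        sub_masked = sub.copy()
        sub_masked[np.tril_indices(m)] = -1.0
        a, b = np.unravel_index(int(np.argmax(sub_masked)), sub_masked.shape)
        test = [remaining[int(a)], remaining[int(b)]]
        remaining = [k for k in remaining if k not in test]
    elif n_test == 1:
        pick = _farthest_from(dist, remaining, train)
        test = [pick]
        remaining.remove(pick)

    # alternate training, then test, until test is full; leftovers -> training
    turn = "train"
    while remaining:
        if turn == "train" or len(test) >= n_test:
            pick = _farthest_from(dist, remaining, train)
            train.append(pick)
        else:
            pick = _farthest_from(dist, remaining, test)
            test.append(pick)
        remaining.remove(pick)
        turn = "test" if turn == "train" else "train"

    return SplitResult(
        train_ids=[sample_ids[k] for k in sorted(train)],
        test_ids=[sample_ids[k] for k in sorted(test)],
        score_matrix_used=t_conc,
    )
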