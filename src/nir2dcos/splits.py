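"""Deterministic Kennard–Stone sample selection and stratified splits.

The Kennard–Stone algorithm picks a representative subset by (1) seeding
with the pair of points at maximal Euclidean distance and (2) repeatedly
adding the candidate whose minimum distance to the already-selected set
is largest.  It is fully deterministic, which avoids the
irreproducibility of random partitioning; ties are broken by lowest
index.

Two split schemes are provided, both stratified per class because the
study allocates percentages within each drying method / region:

* ``60-30-10`` (CNN images): per class, 60 % to train by Kennard–Stone,
  then 30 % of the class from the remainder to test, rest to external
  verification;
* ``70-30`` (PLS-DA spectra): 70 % train, remainder test.

Distances are computed on (possibly decimated) spectra for both schemes,
so the image and spectra splits share one geometry.  Per-class sizes use
round-half-up; the remainder absorbs rounding error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

__all__ = ["kennard_stone", "KennardStoneSplitter", "SplitAssignment",
           "split_images", "split_spectra"]


def kennard_stone(points: np.ndarray, k: int) -> list[int]:
    """Indices of ``k`` points chosen by the classic Kennard–Stone rule.

    Returned in selection order.  Deterministic; ties in the max / max-min
    searches resolve to the lowest index.
    """
    X = np.atleast_2d(np.asarray(points, float))
    n = X.shape[0]
    if n == 0:
        raise ValueError("no points to select from")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if n == 1:
        return [0]
    D = squareform(pdist(X))
    # seed pair: row-major argmax = lexicographically smallest (i, j)
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    i, j = min(i, j), max(i, j)
    if i == j:      # all pairwise distances zero (coincident points)
        i, j = 0, min(1, n - 1)
    selected = [int(i)] if k == 1 else [int(i), int(j)]
    remaining = [r for r in range(n) if r not in selected]
    min_dist = D[remaining][:, selected].min(axis=1) if remaining else None
    while len(selected) < k:
        pos = int(np.argmax(min_dist))
        chosen = remaining.pop(pos)
        selected.append(chosen)
        min_dist = np.delete(min_dist, pos)
        if remaining:
            min_dist = np.minimum(min_dist, D[remaining, chosen])
    return selected


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SplitAssignment:
    """Disjoint train/test/external sample-id lists plus per-class counts."""

    train_ids: list[str]
    test_ids: list[str]
    external_ids: list[str]
    scheme: str
    per_class_counts: pd.DataFrame

    def __post_init__(self) -> None:
        groups = [set(self.train_ids), set(self.test_ids),
                  set(self.external_ids)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("split groups are not pairwise disjoint")

    @property
    def all_ids(self) -> list[str]:
        return [*self.train_ids, *self.test_ids, *self.external_ids]

    def role_of(self) -> dict[str, str]:
        out = {s: "train" for s in self.train_ids}
        out.update({s: "test" for s in self.test_ids})
        out.update({s: "external" for s in self.external_ids})
        return out

    def to_frame(self) -> pd.DataFrame:
        role = self.role_of()
        return pd.DataFrame({"sample_id": list(role), "split": list(role.values())})


class KennardStoneSplitter:
    """Stratified Kennard–Stone splitter over sample feature vectors.

    ``fractions`` are per-class allocations for the successive partitions
    (the last partition takes the remainder): ``(0.6, 0.3)`` gives the
    train/test/external image scheme, ``(0.7,)`` the 70/30 spectra scheme.
    """

    def __init__(self, fractions: Sequence[float] = (0.6, 0.3),
                 scheme: str | None = None):
        if not fractions or sum(fractions) >= 1.0 + 1e-9:
            raise ValueError("fractions must be nonempty and sum to < 1")
        self.fractions = tuple(fractions)
        self.scheme = scheme or "-".join(
            str(int(round(100 * f))) for f in (*fractions,
                                               1 - sum(fractions)))

    def split(self, X: np.ndarray, y: Sequence,
              sample_ids: Sequence[str] | None = None) -> SplitAssignment:
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y)
        n = X.shape[0]
        if sample_ids is None:
            sample_ids = [str(i) for i in range(n)]
        ids = np.asarray([str(s) for s in sample_ids])
        min_size = len(self.fractions) + 1
        parts: list[list[str]] = [[] for _ in range(len(self.fractions) + 1)]
        counts = []
        for cls in sorted(pd.unique(y).tolist()):
            cls_idx = np.flatnonzero(y == cls)
            n_c = cls_idx.size
            if n_c < min_size:
                raise ValueError(
                    f"class {cls!r} has {n_c} samples; scheme "
                    f"{self.scheme} needs at least {min_size}")
            pool = cls_idx
            row = {"class": cls, "n": n_c}
            for part, frac in enumerate(self.fractions):
                k = min(_round_half_up(frac * n_c), pool.size)
                picked = kennard_stone(X[pool], k)
                chosen = pool[picked]
                parts[part].extend(ids[chosen])
                row[f"part{part}"] = k
                pool = np.array([i for i in pool if i not in set(chosen)],
                                dtype=int)
            parts[-1].extend(ids[pool])
            row[f"part{len(self.fractions)}"] = pool.size
            counts.append(row)
        names = (["train", "test", "external"] if len(parts) == 3
                 else ["train", "test"])
        counts_df = pd.DataFrame(counts).rename(
            columns={f"part{i}": name for i, name in enumerate(names)})
        if len(parts) == 2:
            parts = [parts[0], parts[1], []]
        return SplitAssignment(parts[0], parts[1], parts[2], self.scheme,
                               counts_df)


def split_images(features: np.ndarray, labels: Sequence,
                 sample_ids: Sequence[str] | None = None) -> SplitAssignment:
    """60/30/10 per-class Kennard–Stone split for the image pipeline.

    ``features`` are the samples' (decimated) spectra — selection geometry
    lives in spectral space, not pixel space.
    """
    return KennardStoneSplitter((0.6, 0.3)).split(features, labels, sample_ids)


def split_spectra(features: np.ndarray, labels: Sequence,
                  sample_ids: Sequence[str] | None = None) -> SplitAssignment:
    """70/30 per-class Kennard–Stone split for the PLS-DA baseline."""
    return KennardStoneSplitter((0.7,)).split(features, labels, sample_ids)
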