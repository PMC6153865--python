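"""Abundance transforms, Bray-Curtis similarity and rank machinery.

Similarities follow the community-ecology convention of a 0-100 scale:

    S_jk = 100 * (1 - sum_i |y_ij - y_ik| / sum_i (y_ij + y_ik))

which is 100 for identical composition and 0 when two samples share no
taxa. All downstream permutation tests (ANOSIM, SIMPROF, LINKTREE) consume
this matrix or mid-ranks of its complementary dissimilarities.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import TransformError, ValidationError
from .obsdata import CommunityMatrix

__all__ = [
    "ResemblanceMatrix",
    "RankMatrix",
    "transform_abundance",
    "bray_curtis",
    "rank_dissimilarities",
]

#: Absolute tolerance used to detect floating-point ties in dissimilarities.
TIE_TOLERANCE = 1e-9

TRANSFORMS = ("none", "sqrt")


@dataclasses.dataclass
class ResemblanceMatrix:
    """Symmetric similarity matrix on the 0-100 scale (diagonal 100)."""

    sample_ids: list[str]
    similarities: np.ndarray
    metric: str = "bray_curtis"
    transform: str = "none"

    def __post_init__(self) -> None:
        s = np.asarray(self.similarities, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1] or s.shape[0] != len(self.sample_ids):
            raise ValidationError("similarity matrix shape does not match sample ids")
        if not np.allclose(s, s.T):
            raise ValidationError("similarity matrix must be symmetric")
        if s.size and (np.nanmin(s) < -1e-9 or np.nanmax(s) > 100 + 1e-9):
            raise ValidationError("similarities must lie in [0, 100]")
        self.similarities = s

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def dissimilarities(self) -> np.ndarray:
        return 100.0 - self.similarities

    def condensed_dissimilarities(self) -> np.ndarray:
        """Off-diagonal dissimilarities in scipy condensed (row-major i<j) order."""
        n = self.n
        iu = np.triu_indices(n, k=1)
        return self.dissimilarities()[iu]

    def subset(self, sample_ids: Sequence[str]) -> "ResemblanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ResemblanceMatrix(
            list(sample_ids), self.similarities[np.ix_(idx, idx)], metric=self.metric, transform=self.transform
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.similarities, index=self.sample_ids, columns=self.sample_ids)

    def write_csv(self, path: str | Path) -> None:
        """Square CSV with sample ids as header row/column; metric in a JSON sidecar."""
        out = self.to_dataframe().copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, index=False)
        sidecar = Path(str(path) + ".json")
        sidecar.write_text(json.dumps({"metric": self.metric, "transform": self.transform}))

    @classmethod
    def read_csv(cls, path: str | Path) -> "ResemblanceMatrix":
        df = pd.read_csv(path)
        df["sample_id"] = df["sample_id"].astype(str)
        df = df.set_index("sample_id")
        meta = {"metric": "bray_curtis", "transform": "none"}
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            meta.update(json.loads(sidecar.read_text()))
        return cls(list(df.index), df.to_numpy(dtype=float), metric=meta["metric"], transform=meta["transform"])


@dataclasses.dataclass
class RankMatrix:
    """Mid-ranks of the n(n-1)/2 off-diagonal dissimilarities (ascending)."""

    sample_ids: list[str]
    ranks: np.ndarray  # condensed, aligned with ResemblanceMatrix.condensed_dissimilarities

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_pairs(self) -> int:
        return self.ranks.size

    def square(self) -> np.ndarray:
        n = self.n
        out = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        out[iu] = self.ranks
        out.T[iu] = self.ranks
        return out


def transform_abundance(m: CommunityMatrix, method: str = "sqrt") -> CommunityMatrix:
    """Element-wise abundance transform (``"none"`` or ``"sqrt"``).

    The square root is the conventional compromise for low-count lander
    data: it damps the dominant species without flattening the matrix to
    presence/absence. Raises :class:`TransformError` if *m* was already
    transformed.
    """
    if method not in TRANSFORMS:
        raise TransformError(f"unknown transform {method!r}; expected one of {TRANSFORMS}")
    if m.transform != "none":
        raise TransformError(f"matrix already carries transform {m.transform!r}")
    if method == "none":
        return CommunityMatrix(m.data.copy(), transform="none")
    return CommunityMatrix(np.sqrt(m.data), transform="sqrt")


def pairwise_bray_curtis(values: np.ndarray, zero_pairs: str = "error") -> np.ndarray:
    """Bray-Curtis similarity (0-100) between all rows of *values*.

    ``zero_pairs`` controls the undefined case of two all-zero rows:
    ``"error"`` raises, ``"zero"`` defines S = 0 (used inside permutation
    nulls, where column shuffles can empty a row).
    """
    x = np.asarray(values, dtype=float)
    totals = x.sum(axis=1)
    den = totals[:, None] + totals[None, :]
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = 100.0 * (1.0 - num / den)
    bad = den == 0
    if bad.any():
        if zero_pairs == "error":
            raise ValidationError(
                "similarity undefined for a pair of all-zero samples; "
                "pass zero_pairs='zero' to define it as 0"
            )
        s[bad] = 0.0
    np.fill_diagonal(s, 100.0)
    return np.clip(s, 0.0, 100.0)


def bray_curtis(m: CommunityMatrix, zero_pairs: str = "error") -> ResemblanceMatrix:
    """Bray-Curtis resemblance matrix of a community matrix (>= 2 samples)."""
    if len(m.sample_ids) < 2:
        raise ValidationError("bray_curtis requires at least 2 samples")
    s = pairwise_bray_curtis(m.values, zero_pairs=zero_pairs)
    return ResemblanceMatrix(m.sample_ids, s, metric="bray_curtis", transform=m.transform)


def midrank(values: np.ndarray, tol: float = TIE_TOLERANCE) -> np.ndarray:
    """Mid-ranks with ties detected at absolute tolerance *tol*."""
    v = np.asarray(values, dtype=float)
    # snap values within tol of each other onto a common representative
    order = np.argsort(v, kind="stable")
    snapped = v.copy()
    for k in range(1, v.size):
        a, b = order[k - 1], order[k]
        if snapped[b] - snapped[a] <= tol:
            snapped[b] = snapped[a]
    return rankdata(snapped, method="average")


def rank_dissimilarities(r: ResemblanceMatrix) -> RankMatrix:
    """Mid-ranked dissimilarities over all sample pairs (ascending).

    Ranks sum to M(M+1)/2 with M = n(n-1)/2; tied dissimilarities (within
    ``TIE_TOLERANCE``) share their mid-rank.
    """
    if r.n < 3:
        raise ValidationError("rank_dissimilarities requires at least 3 samples")
    return RankMatrix(list(r.sample_ids), midrank(r.condensed_dissimilarities()))
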