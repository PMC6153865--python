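"""Divisive linkage-tree analysis (LINKTREE).

A linkage tree explains assemblage structure by recursive binary splits,
each of which must be expressible as a threshold on a measured abiotic
variable (e.g. "depth < 1144.5 m" vs ">= 1144.5 m"). At every node the
candidate splits are all midpoints between consecutive ordered unique
values of each abiotic variable among the node's samples; the split
maximising the node-local ANOSIM R (computed on within-node mid-ranks) is
chosen, with ties broken by the larger B% separation and then by variable
name. Recursion stops when SIMPROF finds no significant structure in the
node, the node is too small, or no candidate split exists.

This is a reimplementation in the style of Clarke's linkage trees, not a
bit-match of any particular software: B% is the difference between mean
between-group and mean within-group global rank dissimilarities, rescaled
so the global ranks span 0-100, making separations comparable across the
tree.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .obsdata import AbioticTable, CommunityMatrix
from .resemblance import bray_curtis, midrank
from .community_tests import SimprofResult, simprof

__all__ = ["LinktreeNode", "linktree"]


@dataclasses.dataclass
class LinktreeNode:
    """One node of the linkage tree.

    Internal nodes carry the chosen split: ``variable``, the threshold
    (midpoint between ``below`` and ``above``, the two data values it
    separates), the node-local ANOSIM ``r_local`` and the global-rank
    separation ``b_pct``. Leaves have no children.
    """

    members: tuple[str, ...]
    simprof: Optional[SimprofResult] = None
    variable: Optional[str] = None
    threshold: Optional[float] = None
    below: Optional[float] = None
    above: Optional[float] = None
    r_local: Optional[float] = None
    b_pct: Optional[float] = None
    children: tuple["LinktreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["LinktreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def to_dict(self) -> dict:
        d = {
            "members": list(self.members),
            "variable": self.variable,
            "threshold": self.threshold,
            "r_local": self.r_local,
            "b_pct": self.b_pct,
            "simprof_p": None if self.simprof is None else self.simprof.p,
        }
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def splits_frame(self) -> pd.DataFrame:
        """Flat table of the tree's splits (one row per internal node)."""
        rows = []
        for node in self._walk():
            if not node.is_leaf:
                rows.append(
                    {
                        "members": ";".join(node.members),
                        "variable": node.variable,
                        "threshold": node.threshold,
                        "r_local": node.r_local,
                        "b_pct": node.b_pct,
                        "simprof_p": None if node.simprof is None else node.simprof.p,
                    }
                )
        return pd.DataFrame(rows)

    def _walk(self):
        yield self
        for c in self.children:
            yield from c._walk()


def _local_r(diss_sub: np.ndarray, left: np.ndarray) -> float:
    """ANOSIM R of a binary partition using within-node mid-ranks."""
    n = diss_sub.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = midrank(diss_sub[iu])
    m_pairs = ranks.size
    same = left[:, None] == left[None, :]
    within = same[iu]
    n_within = int(within.sum())
    if n_within == 0:  # both sides singletons: no within pairs
        return 0.0
    total = m_pairs * (m_pairs + 1) / 2.0
    sum_w = float(ranks[within].sum())
    mean_w = sum_w / n_within
    n_between = m_pairs - n_within
    mean_b = (total - sum_w) / n_between
    return float((mean_b - mean_w) / (m_pairs / 2.0))


def _b_pct(global_scaled: np.ndarray, idx: np.ndarray, left: np.ndarray) -> float:
    """Separation of a partition on the 0-100 global-rank scale."""
    sub = global_scaled[np.ix_(idx, idx)]
    n = idx.size
    iu = np.triu_indices(n, k=1)
    same = (left[:, None] == left[None, :])[iu]
    vals = sub[iu]
    between = vals[~same]
    within = vals[same]
    mean_w = float(within.mean()) if within.size else 0.0
    return float(np.clip(between.mean() - mean_w, 0.0, 100.0))


def linktree(
    m: CommunityMatrix,
    abiotic: AbioticTable,
    min_split_size: int = 3,
    simprof_kwargs: Optional[dict] = None,
    use_simprof: bool = True,
    alpha: float = 0.05,
    seed: int | None = None,
) -> LinktreeNode:
    """Grow a linkage tree for *m* constrained by *abiotic* thresholds.

    Parameters
    ----------
    m : transformed community matrix.
    abiotic : numeric variables covering all samples of *m*.
    min_split_size : nodes smaller than this are leaves (default 3, the
        smallest SIMPROF-testable set). Split-off singletons terminate
        immediately regardless.
    simprof_kwargs : permutation counts forwarded to :func:`simprof`.
    use_simprof : disable to grow the tree to exhaustion (with
        ``min_split_size=1`` this resolves to singleton leaves).
    seed : seeds the SIMPROF permutation streams deterministically.
    """
    missing = [s for s in m.sample_ids if s not in abiotic.sample_ids]
    if missing:
        raise ValidationError(f"abiotic table does not cover samples {missing}")
    a = abiotic.data.loc[m.sample_ids]
    variables = sorted(a.columns)
    if not variables:
        raise ValidationError("linktree requires at least one abiotic variable")
    sp_kwargs = {"n_perm_mean": 1000, "n_perm_test": 999} | (simprof_kwargs or {})

    if len(m.sample_ids) >= 2:
        r_global = bray_curtis(m, zero_pairs="zero")
        diss = r_global.dissimilarities()
        n = len(m.sample_ids)
        iu = np.triu_indices(n, k=1)
        ranks = midrank(diss[iu])
        scaled_cond = 100.0 * (ranks - 1.0) / (ranks.size - 1.0) if ranks.size > 1 else np.zeros_like(ranks)
        global_scaled = np.zeros((n, n))
        global_scaled[iu] = scaled_cond
        global_scaled.T[iu] = scaled_cond
    else:
        diss = np.zeros((1, 1))
        global_scaled = np.zeros((1, 1))

    sample_pos = {s: i for i, s in enumerate(m.sample_ids)}
    seed_seq = np.random.SeedSequence(seed)

    def grow(members: tuple[str, ...]) -> LinktreeNode:
        node = LinktreeNode(members=members)
        if len(members) < max(2, min_split_size):
            return node
        if use_simprof:
            child_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
            res = simprof(m.subset(list(members)), alpha=alpha, seed=child_seed, **sp_kwargs)
            node.simprof = res
            if not res.significant:
                return node
        idx = np.array([sample_pos[s] for s in members])
        sub_diss = diss[np.ix_(idx, idx)]
        best = None  # (r_local, b_pct, -var rank) maximised
        for var in variables:
            vals = a.loc[list(members), var].to_numpy(dtype=float)
            uniq = np.unique(vals)
            for lo, hi in zip(uniq[:-1], uniq[1:]):
                thr = (lo + hi) / 2.0
                left = vals < thr
                r_loc = _local_r(sub_diss, left)
                b = _b_pct(global_scaled, idx, left)
                # maximise R; ties by larger B%; further ties keep the
                # earlier candidate (variables are scanned in name order)
                if (
                    best is None
                    or r_loc > best[0] + 1e-12
                    or (abs(r_loc - best[0]) <= 1e-12 and b > best[1] + 1e-12)
                ):
                    best = (r_loc, b, var, thr, lo, hi, left)
        if best is None:
            return node  # all abiotic columns constant within the node
        r_loc, b, var, thr, lo, hi, left = best
        node.variable = var
        node.threshold = float(thr)
        node.below = float(lo)
        node.above = float(hi)
        node.r_local = float(r_loc)
        node.b_pct = float(b)
        left_members = tuple(s for s, flag in zip(members, left) if flag)
        right_members = tuple(s for s, flag in zip(members, left) if not flag)
        node.children = (grow(left_members), grow(right_members))
        return node

    return grow(tuple(m.sample_ids))
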