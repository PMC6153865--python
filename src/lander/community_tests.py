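"""Permutation-based assemblage analysis: CLUSTER, SIMPROF, ANOSIM, SIMPER.

The suite operates on a (transformed) community matrix and its Bray-Curtis
resemblance:

* :func:`cluster_group_average` — agglomerative group-average (UPGMA)
  clustering on the similarity scale;
* :func:`simprof` — similarity-profile permutation test for internal
  structure within a set of samples (null: each taxon column permuted
  independently across samples);
* :func:`simprof_cluster` — SIMPROF applied top-down the dendrogram to
  delimit the significant sample groups;
* :func:`anosim` — one-way analysis of similarities on mid-ranked
  dissimilarities, with exact enumeration of distinct label assignments
  when feasible;
* :func:`simper` — decomposition of within-group Bray-Curtis similarity
  into per-species contributions.

All permutation seeds are explicit; identical seeds give identical results.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .obsdata import CommunityMatrix
from .resemblance import (
    RankMatrix,
    ResemblanceMatrix,
    bray_curtis,
    midrank,
    pairwise_bray_curtis,
    rank_dissimilarities,
)

__all__ = [
    "DendroNode",
    "Dendrogram",
    "SimprofResult",
    "SimprofClustering",
    "AnosimResult",
    "SimperGroup",
    "SimperTable",
    "cluster_group_average",
    "simprof",
    "simprof_cluster",
    "anosim",
    "simper",
]


# ---------------------------------------------------------------------------
# SIMPROF


@dataclasses.dataclass
class SimprofResult:
    """Outcome of a similarity-profile permutation test.

    ``pi`` is the absolute deviation of the ordered observed similarity
    profile from its permutation mean; ``p`` the permutation p-value with
    the observed statistic counted in numerator and denominator. Nodes
    with fewer than 3 samples are *untestable* (``testable = False``), a
    distinct state from non-significant.
    """

    pi: float
    p: float | None
    n_perm_mean: int
    n_perm_test: int
    alpha: float
    testable: bool = True
    seed: int | None = None

    @property
    def significant(self) -> bool:
        return self.testable and self.p is not None and self.p <= self.alpha

    def to_dict(self) -> dict:
        return dataclasses.asdict(self) | {"significant": self.significant}


def _similarity_profile(values: np.ndarray) -> np.ndarray:
    s = pairwise_bray_curtis(values, zero_pairs="zero")
    iu = np.triu_indices(s.shape[0], k=1)
    return np.sort(s[iu])


def simprof(
    m: CommunityMatrix,
    n_perm_mean: int = 1000,
    n_perm_test: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimprofResult:
    """Similarity-profile test for internal structure among samples.

    The observed profile (ordered off-diagonal Bray-Curtis similarities) is
    compared with the mean profile under the null in which every taxon
    column is permuted independently across samples; ``pi`` sums the
    absolute profile deviations, and the p-value is the proportion of null
    ``pi`` at least as large as observed (observed included). Defaults
    follow common practice: 1000 permutations for the mean profile, 999
    for the null deviations, alpha = 0.05.
    """
    x = m.values
    n = x.shape[0]
    if n < 3:
        return SimprofResult(
            pi=float("nan"), p=None, n_perm_mean=n_perm_mean, n_perm_test=n_perm_test,
            alpha=alpha, testable=False, seed=seed,
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    obs = _similarity_profile(x)
    mean_prof = np.zeros_like(obs)
    for _ in range(n_perm_mean):
        mean_prof += _similarity_profile(rng.permuted(x, axis=0))
    mean_prof /= n_perm_mean
    pi_obs = float(np.abs(obs - mean_prof).sum())
    exceed = 0
    for _ in range(n_perm_test):
        pi_perm = float(np.abs(_similarity_profile(rng.permuted(x, axis=0)) - mean_prof).sum())
        if pi_perm >= pi_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_perm_test + 1)
    return SimprofResult(pi=pi_obs, p=p, n_perm_mean=n_perm_mean, n_perm_test=n_perm_test,
                         alpha=alpha, testable=True, seed=seed)


# ---------------------------------------------------------------------------
# Group-average clustering


@dataclasses.dataclass
class DendroNode:
    """Dendrogram node: a merge at ``height`` (fusion similarity, 0-100)."""

    members: tuple[str, ...]
    height: float  # fusion similarity; 100 at leaves
    children: tuple["DendroNode", ...] = ()
    simprof: SimprofResult | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterable["DendroNode"]:
        yield self
        for c in self.children:
            yield from c.walk()


@dataclasses.dataclass
class Dendrogram:
    root: DendroNode
    sample_ids: list[str]

    def nodes(self) -> list[DendroNode]:
        return list(self.root.walk())

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths on the
        dissimilarity scale (node height = (100 - fusion similarity) / 2)
        and fusion similarities as internal-node labels."""
        import dendropy

        taxon_ns = dendropy.TaxonNamespace(self.sample_ids)
        tree = dendropy.Tree(taxon_namespace=taxon_ns)

        def build(node: DendroNode, parent):
            h = (100.0 - node.height) / 2.0
            child = parent.new_child()
            child.h = h
            if node.is_leaf:
                child.taxon = taxon_ns.get_taxon(node.members[0])
            else:
                child.label = f"S{node.height:.6g}"
                for c in node.children:
                    build(c, child)
            return child

        tree.seed_node.h = (100.0 - self.root.height) / 2.0
        if self.root.is_leaf:
            tree.seed_node.taxon = taxon_ns.get_taxon(self.root.members[0])
        else:
            tree.seed_node.label = f"S{self.root.height:.6g}"
            for c in self.root.children:
                build(c, tree.seed_node)
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = nd.parent_node.h - nd.h
        return tree.as_string(schema="newick").strip()


def cluster_group_average(r: ResemblanceMatrix) -> Dendrogram:
    """Agglomerative group-average (UPGMA) clustering on similarities.

    At each step the pair of clusters with the highest average
    between-member similarity is fused at that similarity; ties are broken
    by the lowest-index pair in current cluster order (deterministic).
    Group-average linkage admits no inversions on the similarity scale, so
    fusion levels are non-increasing from leaves to root.
    """
    n = r.n
    if n < 2:
        raise ValidationError("clustering requires at least 2 samples")
    s = r.similarities
    clusters: list[list[int]] = [[i] for i in range(n)]
    nodes: list[DendroNode] = [DendroNode(members=(sid,), height=100.0) for sid in r.sample_ids]
    while len(clusters) > 1:
        best = (-math.inf, -1, -1)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                avg = s[np.ix_(clusters[i], clusters[j])].mean()
                if avg > best[0] + 1e-12:
                    best = (avg, i, j)
        avg, i, j = best
        merged = DendroNode(
            members=nodes[i].members + nodes[j].members,
            height=float(avg),
            children=(nodes[i], nodes[j]),
        )
        clusters[i] = clusters[i] + clusters[j]
        nodes[i] = merged
        del clusters[j], nodes[j]
    return Dendrogram(root=nodes[0], sample_ids=list(r.sample_ids))


@dataclasses.dataclass
class SimprofClustering:
    """Dendrogram annotated with SIMPROF tests plus the terminal groups."""

    dendrogram: Dendrogram
    groups: list[tuple[str, ...]]


def simprof_cluster(
    m: CommunityMatrix,
    n_perm_mean: int = 1000,
    n_perm_test: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> SimprofClustering:
    """Cluster samples and delimit significant groups by recursive SIMPROF.

    The dendrogram is tested top-down: a node is tested only if its parent
    was significant; recursion terminates at non-significant or untestable
    (< 3 samples) nodes, whose member sets become the terminal groups.
    Child seeds are spawned deterministically from *seed*.
    """
    r = bray_curtis(m)
    dendro = cluster_group_average(r)
    groups: list[tuple[str, ...]] = []
    seed_seq = np.random.SeedSequence(seed)

    def visit(node: DendroNode) -> None:
        sub = m.subset(list(node.members))
        child_seed = int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))
        res = simprof(sub, n_perm_mean=n_perm_mean, n_perm_test=n_perm_test, alpha=alpha, seed=child_seed)
        node.simprof = res
        if res.significant and not node.is_leaf:
            for c in node.children:
                visit(c)
        else:
            groups.append(node.members)

    visit(dendro.root)
    return SimprofClustering(dendrogram=dendro, groups=groups)


# ---------------------------------------------------------------------------
# ANOSIM


@dataclasses.dataclass
class AnosimResult:
    """One-way ANOSIM outcome: R in [-1, 1] and its permutation p-value."""

    R: float
    p: float
    n_permutations_used: int
    exact: bool
    seed: int | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _as_label_array(grouping, sample_ids: Sequence[str]) -> np.ndarray:
    if isinstance(grouping, Mapping):
        labels = [grouping[s] for s in sample_ids]
    else:
        labels = list(grouping)
        if len(labels) != len(sample_ids):
            raise ValidationError("grouping length does not match sample ids")
    return np.asarray(labels, dtype=object)


def _anosim_r(rank_sq: np.ndarray, labels: np.ndarray, m_pairs: int) -> float:
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    n_within = int(same.sum()) // 2
    sum_within = float(rank_sq[same].sum()) / 2.0
    total = m_pairs * (m_pairs + 1) / 2.0
    n_between = m_pairs - n_within
    mean_w = sum_within / n_within
    mean_b = (total - sum_within) / n_between
    return (mean_b - mean_w) / (m_pairs / 2.0)


def _n_distinct_assignments(counts: Sequence[int]) -> int:
    total = math.factorial(sum(counts))
    for c in counts:
        total //= math.factorial(c)
    return total


def anosim(
    r: ResemblanceMatrix,
    grouping,
    max_permutations: int = 100_000,
    n_monte_carlo: int = 9_999,
    seed: int | None = None,
) -> AnosimResult:
    """One-way analysis of similarities on mid-ranked dissimilarities.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairs; mid-ranks absorb ties (expected at the S = 0
    plateau of disjoint assemblages). When the number of distinct label
    assignments is at most *max_permutations* every assignment is
    enumerated and ``p = #(R_perm >= R_obs) / n_distinct`` (the observed
    assignment is among those enumerated); otherwise *n_monte_carlo* random
    relabelings are drawn and the observed statistic is added to numerator
    and denominator.
    """
    labels = _as_label_array(grouping, r.sample_ids)
    uniq, counts = np.unique(labels.astype(str), return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("anosim requires at least 2 groups")
    if counts.max() < 2:
        raise ValidationError("anosim requires at least one group with >= 2 samples")
    ranks = rank_dissimilarities(r)
    rank_sq = ranks.square()
    m_pairs = ranks.n_pairs
    r_obs = _anosim_r(rank_sq, labels, m_pairs)

    n_distinct = _n_distinct_assignments(counts.tolist())
    if n_distinct <= max_permutations:
        from sympy.utilities.iterables import multiset_permutations

        exceed = 0
        for perm in multiset_permutations(list(labels)):
            if _anosim_r(rank_sq, np.asarray(perm, dtype=object), m_pairs) >= r_obs - 1e-12:
                exceed += 1
        return AnosimResult(R=float(r_obs), p=exceed / n_distinct, n_permutations_used=n_distinct,
                            exact=True, seed=seed)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_monte_carlo):
        if _anosim_r(rank_sq, rng.permutation(labels), m_pairs) >= r_obs - 1e-12:
            exceed += 1
    return AnosimResult(R=float(r_obs), p=(exceed + 1) / (n_monte_carlo + 1),
                        n_permutations_used=n_monte_carlo, exact=False, seed=seed)


# ---------------------------------------------------------------------------
# SIMPER


@dataclasses.dataclass
class SimperGroup:
    """Within-group similarity decomposition for one group.

    ``table`` has one row per species, sorted by descending average
    similarity contribution, with columns ``species, avg_abundance,
    avg_similarity, pct_contribution, cum_pct``. Contributions sum to
    ``average_similarity``; percentages to 100.
    """

    label: str
    n_samples: int
    average_similarity: float
    table: pd.DataFrame


@dataclasses.dataclass
class SimperTable:
    groups: dict[str, SimperGroup]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for label, g in self.groups.items():
            t = g.table.copy()
            t.insert(0, "group", label)
            frames.append(t)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def pair_species_shares(y_j: np.ndarray, y_k: np.ndarray) -> np.ndarray:
    """Per-species share of the Bray-Curtis similarity of one sample pair:
    100 * 2*min(y_ij, y_ik) / sum_i (y_ij + y_ik). Shares sum to S_jk."""
    den = float(y_j.sum() + y_k.sum())
    if den == 0:
        raise ValidationError("similarity shares undefined for a pair of all-zero samples")
    return 100.0 * 2.0 * np.minimum(y_j, y_k) / den


def simper(m: CommunityMatrix, grouping) -> SimperTable:
    """Similarity-percentage decomposition within each group.

    For every within-group sample pair, each species' similarity share is
    computed and averaged over pairs; the per-species averages sum exactly
    to the group's average Bray-Curtis similarity. Average abundance is the
    group mean of the (transformed) matrix values, zeros included.
    Singleton groups are skipped with a warning.
    """
    labels = _as_label_array(grouping, m.sample_ids)
    x = m.values
    out: dict[str, SimperGroup] = {}
    for label in pd.unique(labels):
        idx = np.flatnonzero(labels == label)
        if idx.size < 2:
            warnings.warn(f"simper: group {label!r} has fewer than 2 samples; skipped")
            continue
        contribs = np.zeros(x.shape[1])
        n_pairs = 0
        for a in range(idx.size):
            for b in range(a + 1, idx.size):
                contribs += pair_species_shares(x[idx[a]], x[idx[b]])
                n_pairs += 1
        contribs /= n_pairs
        avg_sim = float(contribs.sum())
        avg_abund = x[idx].mean(axis=0)
        order = np.argsort(-contribs, kind="stable")
        pct = 100.0 * contribs / avg_sim if avg_sim > 0 else np.zeros_like(contribs)
        table = pd.DataFrame(
            {
                "species": [m.taxa[i] for i in order],
                "avg_abundance": avg_abund[order],
                "avg_similarity": contribs[order],
                "pct_contribution": pct[order],
            }
        )
        table["cum_pct"] = table["pct_contribution"].cumsum()
        out[str(label)] = SimperGroup(
            label=str(label), n_samples=int(idx.size), average_similarity=avg_sim, table=table
        )
    return SimperTable(groups=out)
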