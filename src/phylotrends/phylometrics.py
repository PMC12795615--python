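"""Assemblage-level phylogenetic diversity metrics.

Implements the standard community-phylogenetics toolkit on a rooted tree
with branch lengths:

* patristic (path-length) distance matrix between tips,
* MPD — mean pairwise patristic distance of an assemblage (presence-only,
  unweighted; assemblages are deduplicated species sets),
* ses.MPD — the standardized effect size of MPD under a tip-label
  randomization null: z = (MPD_obs − mean(MPD_null)) / sd(MPD_null).
  Positive z indicates phylogenetic overdispersion (members less related
  than a random assemblage of equal richness), negative z clustering,
* Faith's PD — total branch length of the minimal subtree spanning the
  assemblage, optionally extended to the root,
* exact rarefied Faith's PD — the expectation of Faith's PD over all
  size-m subsamples, computed in closed form from per-branch subtending
  counts rather than by resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from ._util import rng_for

__all__ = [
    "PhyloDistanceMatrix",
    "SesMpdResult",
    "RarefiedPD",
    "patristic_matrix",
    "mpd",
    "ses_mpd",
    "faith_pd",
    "rarefied_faith_pd",
    "pd_table",
]

# Relative tolerance below which a null SD is treated as exactly zero
# (degenerate null: every randomized assemblage has the same MPD).
_SD_DEGENERATE_RTOL = 1e-12


def _check_branch_lengths(tree: dendropy.Tree) -> None:
    """Every non-root edge must carry a branch length."""
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:  # root edge; length immaterial
            continue
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon is not None else f"internal node {id(head)}"
            raise ValueError(f"missing branch length on edge leading to {name!r}")


@dataclass(frozen=True)
class PhyloDistanceMatrix:
    """Labelled symmetric matrix of patristic distances between tree tips."""

    labels: tuple
    values: np.ndarray
    _index: Mapping[str, int] = field(repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(self.labels)})

    def indices(self, species: Iterable[str]) -> np.ndarray:
        missing = [s for s in species if s not in self._index]
        if missing:
            raise KeyError(f"species not in distance matrix: {sorted(missing)}")
        return np.array([self._index[s] for s in species], dtype=int)

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def __len__(self) -> int:
        return len(self.labels)


def patristic_matrix(tree: dendropy.Tree) -> PhyloDistanceMatrix:
    """Patristic distance matrix: d[i, j] = branch-length sum on the i–j path.

    Labels are sorted alphabetically so the matrix layout is independent of
    tree traversal order. Distances accumulate in a fixed postorder, so the
    result is bit-reproducible for a given newick string.
    """
    _check_branch_lengths(tree)
    labels = tuple(sorted(leaf.taxon.label for leaf in tree.leaf_node_iter()))
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n), dtype=float)
    # Per node: list of (tip index, distance from node), merged upward.
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = [(index[node.taxon.label], 0.0)]
            continue
        child_lists = []
        for child in node.child_nodes():
            bl = float(child.edge.length or 0.0)
            child_lists.append([(i, dist + bl) for i, dist in below.pop(child)])
        for a in range(len(child_lists)):
            for b in range(a + 1, len(child_lists)):
                for i, di in child_lists[a]:
                    for j, dj in child_lists[b]:
                        d[i, j] = d[j, i] = di + dj
        below[node] = [pair for lst in child_lists for pair in lst]
    return PhyloDistanceMatrix(labels=labels, values=d)


def mpd(species: Iterable[str], dmat: PhyloDistanceMatrix) -> float:
    """Mean patristic distance over all unordered distinct pairs."""
    # sorted indices: summation order (hence the float result) never depends
    # on set-iteration order
    idx = np.sort(dmat.indices(set(species)))
    r = len(idx)
    if r < 2:
        raise ValueError("MPD requires at least 2 species")
    sub = dmat.values[np.ix_(idx, idx)]
    return float(sub.sum() / (r * (r - 1)))


@dataclass(frozen=True)
class SesMpdResult:
    """ses.MPD of one assemblage against a label-randomization null."""

    obs_mpd: float
    null_mean: float
    null_sd: float
    z: Optional[float]  # None when the null is degenerate (sd == 0)
    p_rank: float
    n_rand: int
    degenerate: bool


def _null_mpds(
    dmat: PhyloDistanceMatrix,
    pool_idx: np.ndarray,
    r: int,
    n_rand: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """MPD of ``n_rand`` uniform size-r draws (without replacement) from the pool.

    Vectorized through 0/1 membership matrices: for membership row b,
    sum over unordered pairs of D equals (b D bᵀ) / 2 because diag(D) = 0.
    """
    L = len(pool_idx)
    keys = rng.random((n_rand, L))
    order = np.argpartition(keys, r - 1, axis=1)[:, :r]
    member = np.zeros((n_rand, L), dtype=float)
    np.put_along_axis(member, order, 1.0, axis=1)
    D = dmat.values[np.ix_(pool_idx, pool_idx)]
    pair_sums = np.einsum("ij,ij->i", member @ D, member) / 2.0
    return pair_sums / (r * (r - 1) / 2.0)


def ses_mpd(
    species: Iterable[str],
    dmat: PhyloDistanceMatrix,
    n_rand: int = 99,
    seed: int = 0,
    pool: Optional[Sequence[str]] = None,
) -> SesMpdResult:
    """Standardized effect size of MPD under a tip-label randomization null.

    Each null replicate draws ``len(species)`` labels uniformly without
    replacement from the null pool (default: every tip in the distance
    matrix) and recomputes MPD. The rank p-value uses the add-one formula
    p = (1 + #{null ≤ obs}) / (n_rand + 1), so p is always inside (0, 1).

    When every null draw yields the same MPD (e.g. the assemblage is the
    whole pool, or the tree is a star with equal branch lengths) the null SD
    is zero and z is undefined; the result is flagged ``degenerate`` and z
    is reported as ``None`` rather than ±inf.
    """
    species = set(species)
    if len(species) < 2:
        raise ValueError("ses.MPD requires at least 2 species")
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    pool_labels = tuple(pool) if pool is not None else dmat.labels
    pool_idx = dmat.indices(pool_labels)
    r = len(species)
    if r > len(pool_idx):
        raise ValueError(f"assemblage richness {r} exceeds null pool size {len(pool_idx)}")
    obs = mpd(species, dmat)
    rng = np.random.default_rng(seed)
    nulls = _null_mpds(dmat, pool_idx, r, n_rand, rng)
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1)) if n_rand > 1 else 0.0
    degenerate = null_sd <= _SD_DEGENERATE_RTOL * max(1.0, abs(null_mean))
    z = None if degenerate else (obs - null_mean) / null_sd
    p_rank = float((1 + np.sum(nulls <= obs)) / (n_rand + 1))
    return SesMpdResult(
        obs_mpd=obs,
        null_mean=null_mean,
        null_sd=0.0 if degenerate else null_sd,
        z=z,
        p_rank=p_rank,
        n_rand=n_rand,
        degenerate=bool(degenerate),
    )


def _edge_spans(tree: dendropy.Tree, species: set) -> list:
    """Per edge: (length, n_members_below). Root edge excluded."""
    _check_branch_lengths(tree)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = species - tips
    if unknown:
        raise KeyError(f"species not on tree: {sorted(unknown)}")
    counts = {}
    spans = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            c = 1 if node.taxon.label in species else 0
        else:
            c = sum(counts[ch] for ch in node.child_nodes())
        counts[node] = c
        if node.parent_node is not None:
            spans.append((float(node.edge.length), c))
    return spans


def faith_pd(species: Iterable[str], tree: dendropy.Tree, include_root: bool = True) -> float:
    """Faith's PD: branch-length sum of the minimal subtree spanning the set.

    With ``include_root=True`` (default) the subtree is extended along the
    path from the set's common ancestor to the root, so a single species has
    PD equal to its root-to-tip distance. With ``include_root=False`` only
    edges lying on paths *between* members count (edges whose descendant
    members number strictly between 0 and the full set size).
    """
    species = set(species)
    if not species:
        raise ValueError("faith_pd requires a non-empty species set")
    k = len(species)
    total = 0.0
    for length, c in _edge_spans(tree, species):
        if include_root:
            if c >= 1:
                total += length
        else:
            if 1 <= c <= k - 1:
                total += length
    return total


@dataclass(frozen=True)
class RarefiedPD:
    """Expected Faith's PD of an m-species subsample (exact expectation)."""

    m: int
    value: float


def _subset_miss_prob(n: int, m: int, n_b: int) -> float:
    """P(a uniform size-m subset of n species avoids all n_b marked ones).

    Equals C(n − n_b, m) / C(n, m), evaluated as a product of ratios so no
    large binomials are formed.
    """
    if n_b == 0:
        return 1.0
    if n - n_b < m:
        return 0.0
    p = 1.0
    for i in range(m):
        p *= (n - n_b - i) / (n - i)
    return p


def rarefied_faith_pd(
    species: Iterable[str],
    tree: dendropy.Tree,
    m: int = 10,
    include_root: bool = True,
) -> RarefiedPD:
    """Exact expected Faith's PD over all size-m subsets of the assemblage.

    For each branch b with n_b assemblage members below it, the probability
    that a uniform size-m subsample spans the branch is

    * include_root:  1 − C(n − n_b, m)/C(n, m)
      (the branch counts whenever at least one member survives below it);
    * tips-only:     1 − [C(n − n_b, m) + C(n_b, m)]/C(n, m)
      (the branch must separate surviving members on both sides).

    Summing branch length × span probability gives the exact rarefaction
    expectation, i.e. the m-point of the Faith's PD rarefaction curve.
    """
    species = set(species)
    n = len(species)
    if not 1 <= m <= n:
        raise ValueError(f"rarefaction size m={m} must be in [1, n={n}]")
    value = 0.0
    for length, n_b in _edge_spans(tree, species):
        if n_b == 0:
            continue
        p_miss = _subset_miss_prob(n, m, n_b)
        if include_root:
            p_span = 1.0 - p_miss
        else:
            p_span = 1.0 - p_miss - _subset_miss_prob(n, m, n - n_b)
        value += length * p_span
    return RarefiedPD(m=m, value=value)


def pd_table(
    assemblages: pd.DataFrame,
    tree: dendropy.Tree,
    n_rand: int = 99,
    m: int = 10,
    include_root: bool = True,
    seed: int = 0,
    pool: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-assemblage diversity table for a binned assemblage frame.

    ``assemblages`` needs columns lat_2dp, lon_2dp, year and species (an
    iterable of names per row). Rows are processed in sorted site-key order
    and each assemblage gets a sub-seed derived from its index in that
    order, so input row order never changes any result. Assemblages richer
    than the rarefaction size m get the exact rarefied PD; smaller ones get
    a missing value.
    """
    dmat = patristic_matrix(tree)
    work = assemblages.sort_values(["lat_2dp", "lon_2dp", "year"]).reset_index(drop=True)
    rows = []
    for i, rec in work.iterrows():
        sp = set(rec["species"])
        sub_seed = rng_for(seed, "ses_mpd", i).integers(2**31)
        res = ses_mpd(sp, dmat, n_rand=n_rand, seed=int(sub_seed), pool=pool)
        fpd = faith_pd(sp, tree, include_root=include_root)
        rpd = (
            rarefied_faith_pd(sp, tree, m=m, include_root=include_root).value
            if len(sp) >= m
            else np.nan
        )
        rows.append(
            {
                "lat_2dp": rec["lat_2dp"],
                "lon_2dp": rec["lon_2dp"],
                "year": rec["year"],
                "richness": len(sp),
                "obs_mpd": res.obs_mpd,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "z": np.nan if res.z is None else res.z,
                "p_rank": res.p_rank,
                "degenerate": res.degenerate,
                "faith_pd": fpd,
                f"rarefied_pd_m{m}": rpd,
            }
        )
    return pd.DataFrame(rows)
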