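"""Bray-Curtis community structure: clustering, SIMPROF, pair coupling.

Samples are compared with the Bray-Curtis dissimilarity
``d = sum|x_i - y_i| / sum(x_i + y_i)`` and agglomerated with
group-average (UPGMA) linkage, the PRIMER convention. Merge heights are
dissimilarities; a cut "at S% similarity" cuts at dissimilarity
``1 - S/100``.

SIMPROF (similarity profile test) asks whether a set of samples carries
multivariate structure beyond exchangeability: the observed ordered
dissimilarity profile is compared to the mean ordered profile under
permutations that shuffle each OTU's values independently across samples.
The test statistic ``pi`` is the mean absolute deviation from that mean
profile; its null distribution comes from further permutations. Applied
top-down along the dendrogram it flags which bifurcations separate
genuinely distinct groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import ks_2samp

from .io_tables import OtuTable, PairedLibraries
from .preprocess import RelAbundanceTable

__all__ = [
    "bray_curtis",
    "SimprofResult",
    "simprof_test",
    "ClusterResult",
    "cluster_samples",
    "pair_coupling",
    "season_agreement",
    "VennPartition",
    "venn_partition",
    "ks_compare_groups",
    "OverlapResult",
    "dataset_overlap",
    "percent_of_union",
]


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity between two abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


# ---------------------------------------------------------------------------
# SIMPROF
# ---------------------------------------------------------------------------


@dataclass
class SimprofResult:
    pi: float
    p: float
    alpha: float
    n_samples: int

    @property
    def significant(self) -> bool:
        return self.p <= self.alpha


def _sorted_profile(x: np.ndarray) -> np.ndarray:
    d = pdist(x, metric="braycurtis")
    return np.sort(d)


def simprof_test(
    counts,
    n_expected: int = 1000,
    n_test: int = 999,
    alpha: float = 0.05,
    seed=None,
) -> SimprofResult:
    """Similarity-profile permutation test on a samples x OTUs matrix.

    Permutations shuffle each OTU column independently across samples
    (Clarke-style), destroying sample structure while preserving each
    OTU's marginal distribution. ``pi`` is the mean absolute deviation of
    the observed ordered Bray-Curtis profile from the mean ordered
    profile of ``n_expected`` permutations; the p-value compares ``pi``
    with ``n_test`` further permutations, with add-one smoothing.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    if n_expected < 1 or n_test < 1:
        raise ValueError("permutation counts must be >= 1")
    rng = np.random.default_rng(seed)
    obs = _sorted_profile(x)
    m = obs.size
    perms = np.empty((n_expected + n_test, m))
    for i in range(n_expected + n_test):
        perms[i] = _sorted_profile(rng.permuted(x, axis=0))
    mean_profile = perms[:n_expected].mean(axis=0)
    pi_obs = float(np.abs(obs - mean_profile).mean())
    pi_null = np.abs(perms[n_expected:] - mean_profile).mean(axis=1)
    p = (1 + int((pi_null >= pi_obs - 1e-15).sum())) / (n_test + 1)
    if pi_obs == 0.0:
        p = 1.0
    return SimprofResult(pi=pi_obs, p=float(p), alpha=alpha, n_samples=x.shape[0])


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """UPGMA dendrogram over samples with per-node SIMPROF flags.

    ``linkage`` is a scipy linkage matrix whose heights are Bray-Curtis
    dissimilarities. ``simprof`` maps internal-node ids (scipy convention:
    node ``n + i`` is created by merge row ``i``) to test results; nodes
    below a non-significant ancestor are not tested.
    """

    linkage: np.ndarray
    sample_ids: list[str]
    dates: pd.Series | None = None
    molecule: pd.Series | None = None
    simprof: dict[int, SimprofResult] = field(default_factory=dict)

    def labels_at(self, similarity_pct: float) -> pd.Series:
        """Flat cluster labels from cutting at a similarity level (%)."""
        t = 1.0 - similarity_pct / 100.0
        labels = hierarchy.fcluster(self.linkage, t=t, criterion="distance")
        return pd.Series(labels, index=self.sample_ids, name="cluster")

    def n_clusters_at(self, similarity_pct: float) -> int:
        return int(self.labels_at(similarity_pct).nunique())

    def significant_nodes(self) -> set[int]:
        return {nid for nid, r in self.simprof.items() if r.significant}

    def homogeneous_groups(self) -> pd.Series:
        """Partition from the top-down SIMPROF stopping rule: descend while
        a node tests significant; every subtree whose root does not is one
        homogeneous group."""
        n = len(self.sample_ids)
        tree = hierarchy.to_tree(self.linkage)
        labels = np.zeros(n, dtype=int)
        counter = 0

        def assign(node) -> None:
            nonlocal counter
            res = self.simprof.get(node.id)
            if node.is_leaf() or res is None or not res.significant:
                counter += 1
                for leaf in node.pre_order(lambda x: x.id):
                    labels[leaf] = counter
                return
            assign(node.left)
            assign(node.right)

        assign(tree)
        return pd.Series(labels, index=self.sample_ids, name="simprof_group")

    def node_report(self) -> pd.DataFrame:
        rows = [
            {
                "node": nid,
                "n_samples": r.n_samples,
                "pi": r.pi,
                "p": r.p,
                "significant": r.significant,
            }
            for nid, r in sorted(self.simprof.items())
        ]
        return pd.DataFrame(rows)


def _table_matrix(table) -> tuple[np.ndarray, list[str], pd.Series | None, pd.Series | None]:
    if isinstance(table, OtuTable):
        return (
            table.counts.to_numpy(dtype=float),
            table.sample_ids,
            table.dates,
            table.molecule,
        )
    if isinstance(table, RelAbundanceTable):
        return (
            table.values.to_numpy(dtype=float),
            table.sample_ids,
            table.dates,
            table.molecule,
        )
    x = np.asarray(table, dtype=float)
    return x, [str(i) for i in range(x.shape[0])], None, None


def cluster_samples(
    table,
    linkage_method: str = "average",
    run_simprof: bool = True,
    n_expected: int = 1000,
    n_test: int = 999,
    alpha: float = 0.05,
    seed=None,
) -> ClusterResult:
    """UPGMA clustering of samples on the Bray-Curtis matrix with a
    top-down SIMPROF pass flagging significant bifurcations."""
    x, ids, dates, molecule = _table_matrix(table)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples to cluster")
    d = pdist(x, metric="braycurtis")
    z = hierarchy.linkage(d, method=linkage_method)
    result = ClusterResult(
        linkage=z, sample_ids=ids, dates=dates, molecule=molecule
    )
    if run_simprof:
        seq = np.random.SeedSequence(seed)
        tree = hierarchy.to_tree(z)

        def descend(node) -> None:
            if node.is_leaf() or node.get_count() < 2:
                return
            leaves = node.pre_order(lambda leaf: leaf.id)
            child_seed = seq.spawn(1)[0]
            res = simprof_test(
                x[leaves], n_expected=n_expected, n_test=n_test, alpha=alpha, seed=child_seed
            )
            result.simprof[node.id] = res
            if res.significant:
                descend(node.left)
                descend(node.right)

        descend(tree)
    return result


# ---------------------------------------------------------------------------
# pair coupling, season agreement
# ---------------------------------------------------------------------------


def _pair_list(pairs) -> list[tuple[str, str]]:
    if isinstance(pairs, PairedLibraries):
        return [(d, r) for _, d, r in pairs.pairs]
    return [(a, b) for a, b in pairs]


def pair_coupling(
    result: ClusterResult,
    pairs,
    similarity_pct: float = 40.0,
) -> tuple[int, int]:
    """Count (cherries, co-clustered pairs) for date-matched libraries.

    A pair is *adjacent* (side by side in the dendrogram) when its two
    leaves form a cherry: they merge with each other before either joins
    any other sample. Co-clustering is evaluated at the ``similarity_pct``
    cut (40% by default).
    """
    idx = {s: i for i, s in enumerate(result.sample_ids)}
    plist = _pair_list(pairs)
    leaf_merges = {
        frozenset((int(a), int(b)))
        for a, b, _, _ in result.linkage
        if a < len(result.sample_ids) and b < len(result.sample_ids)
    }
    n_adjacent = sum(
        1 for a, b in plist if frozenset((idx[a], idx[b])) in leaf_merges
    )
    labels = result.labels_at(similarity_pct)
    n_same = sum(1 for a, b in plist if labels[a] == labels[b])
    return n_adjacent, n_same


def season_agreement(labels: pd.Series, seasons: pd.Series) -> float:
    """Fraction of samples whose cluster's majority season matches their own.

    Each cluster is assigned the season held by the majority of its
    members; a sample agrees when its own season equals its cluster's
    majority season.
    """
    seasons = seasons.loc[labels.index]
    majority = (
        pd.DataFrame({"cluster": labels, "season": seasons})
        .groupby("cluster")["season"]
        .agg(lambda s: s.mode().iloc[0])
    )
    return float((seasons.values == majority.loc[labels].values).mean())


# ---------------------------------------------------------------------------
# Venn partition, KS, dataset overlap
# ---------------------------------------------------------------------------


def percent_of_union(n: int, n_union: int) -> int:
    """Share of the union, as a nearest-integer percentage."""
    if n_union <= 0:
        raise ValueError("empty union")
    return int(round(100.0 * n / n_union))


@dataclass
class VennPartition:
    """OTU membership regions for a set of clusters (3 -> 7 regions)."""

    membership: dict[object, set[str]]          # cluster -> OTUs present
    region_counts: dict[frozenset, int]         # cluster subset -> #OTUs
    n_union: int

    @property
    def center_count(self) -> int:
        all_clusters = frozenset(self.membership)
        return self.region_counts.get(all_clusters, 0)

    @property
    def center_pct(self) -> int:
        return percent_of_union(self.center_count, self.n_union)

    def report(self) -> pd.DataFrame:
        rows = [
            {
                "clusters": "&".join(str(c) for c in sorted(region, key=str)),
                "n_otus": n,
                "pct_of_union": percent_of_union(n, self.n_union),
            }
            for region, n in sorted(
                self.region_counts.items(), key=lambda kv: (len(kv[0]), str(sorted(kv[0], key=str)))
            )
        ]
        return pd.DataFrame(rows)


def venn_partition(labels: pd.Series, table: OtuTable, clusters=None) -> VennPartition:
    """Partition OTUs by which clusters they occur in (>= 1 read in >= 1
    sample of the cluster). ``clusters`` defaults to the labels present."""
    clusters = sorted(labels.unique(), key=str) if clusters is None else list(clusters)
    membership: dict[object, set[str]] = {}
    counts = table.counts
    for c in clusters:
        members = labels.index[labels == c]
        if len(members) == 0:
            raise ValueError(f"cluster {c!r} has no samples")
        present = counts.loc[members].sum(axis=0) > 0
        membership[c] = set(counts.columns[present])
    union: set[str] = set().union(*membership.values()) if membership else set()
    region_counts: dict[frozenset, int] = {}
    for otu in union:
        region = frozenset(c for c in clusters if otu in membership[c])
        region_counts[region] = region_counts.get(region, 0) + 1
    return VennPartition(
        membership=membership, region_counts=region_counts, n_union=len(union)
    )


def ks_compare_groups(values_a, values_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of per-group values
    (OTU counts or read proportions). Returns (D, asymptotic two-sided p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("need at least one value per side")
    res = ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class OverlapResult:
    n_union: int
    n_shared: int
    n_dna_only: int
    n_rna_only: int
    pct_shared: float


def dataset_overlap(dna_otus: Iterable[str], rna_otus: Iterable[str]) -> OverlapResult:
    """Set arithmetic between the OTU inventories of the two molecules."""
    dna = set(dna_otus)
    rna = set(rna_otus)
    shared = dna & rna
    union = dna | rna
    pct = 100.0 * len(shared) / len(union) if union else math.nan
    return OverlapResult(
        n_union=len(union),
        n_shared=len(shared),
        n_dna_only=len(dna - rna),
        n_rna_only=len(rna - dna),
        pct_shared=pct,
    )
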