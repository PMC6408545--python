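"""Rank-based transcriptional signatures and enrichment-score distances.

The method characterises each sample by the identities of its most
extreme fold changes.  Expression profiles are first divided by a
genewise reference (the average profile across the whole dataset), a
feature-selection t-test keeps genes that separate the configured group
contrasts, and each sample is then reduced to an ordered signature: the
``n1`` features with the highest fold changes (up-list) and the ``n2``
with the lowest (down-list).  Signatures are compared all-to-all with a
Kolmogorov–Smirnov-style enrichment score, yielding a distance matrix
in [0, 2], a percentile-thresholded similarity graph, and one consensus
signature per group ranked by how many subject signatures contain each
feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, SampleGroups


@dataclass
class FoldChangeMatrix:
    """Expression relative to the genewise reference profile.

    On the linear scale values are ratios; on the log2 scale they are
    differences from the genewise mean (the same quantity in log space).
    """

    data: pd.DataFrame
    scale: str  # "linear" | "log2"

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SubjectSignature:
    """Ordered up/down feature lists for one sample.

    ``up`` holds the ``n1`` features with the highest fold changes
    (highest first); ``down`` holds the ``n2`` lowest, ordered so the
    single most down-regulated feature comes last.  ``ranking`` is the
    full ordered feature list the signature was cut from, which the
    enrichment-score distance walks.
    """

    sample_id: str
    up: tuple[str, ...]
    down: tuple[str, ...]
    ranking: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError(f"up and down lists overlap for {self.sample_id!r}")


@dataclass
class ConsensusSignature:
    """Group-level signature ranked by feature popularity.

    Popularity of a feature is the number of subject signatures in the
    group whose up-list (resp. down-list) contains it.  ``up`` and
    ``down`` are the top ``n1``/``n2`` by popularity, most popular
    first; the full popularity tables are retained.
    """

    group: str
    up: tuple[str, ...]
    down: tuple[str, ...]
    up_popularity: dict[str, int]
    down_popularity: dict[str, int]


def fold_change_profiles(expr: ExpressionMatrix, scale: str = "log2") -> FoldChangeMatrix:
    """Divide each profile by the genewise average across the dataset.

    ``scale="linear"`` computes value / row-mean and requires strictly
    positive row means; ``scale="log2"`` computes value − row-mean,
    the equivalent operation for log-transformed intensities.
    """
    if scale not in {"linear", "log2"}:
        raise ValueError(f"scale must be 'linear' or 'log2', got {scale!r}")
    ref = expr.data.mean(axis=1)
    if scale == "linear":
        bad = ref[ref <= 0]
        if len(bad):
            raise ValueError(
                f"non-positive genewise mean for row {bad.index[0]!r}; "
                "linear fold changes require strictly positive references"
            )
        fc = expr.data.div(ref, axis=0)
    else:
        fc = expr.data.sub(ref, axis=0)
    return FoldChangeMatrix(fc, scale)


def select_features(
    fc: FoldChangeMatrix,
    groups: SampleGroups,
    contrasts: list[tuple[str, str]],
    alpha: float = 0.01,
) -> list[str]:
    """Two-sample pooled t-test per feature and contrast; union of hits.

    A feature is kept if any contrast gives p < ``alpha`` (two-sided,
    Student's t with pooled variance).  Features with zero pooled
    variance and equal group means carry no signal and are excluded;
    zero pooled variance with unequal means is treated as p = 0.
    Returned in the matrix's row order.
    """
    selected = np.zeros(len(fc.data.index), dtype=bool)
    for group_a, group_b in contrasts:
        sa = groups.samples_in(group_a)
        sb = groups.samples_in(group_b)
        if set(sa) & set(sb):
            raise ValueError(f"contrast groups {group_a!r}/{group_b!r} share samples")
        if len(sa) < 2 or len(sb) < 2:
            raise ValueError(f"contrast {group_a!r} vs {group_b!r} needs ≥2 samples per group")
        a = fc.data[sa].to_numpy()
        b = fc.data[sb].to_numpy()
        na, nb = a.shape[1], b.shape[1]
        mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
        ss_a = ((a - mean_a[:, None]) ** 2).sum(axis=1)
        ss_b = ((b - mean_b[:, None]) ** 2).sum(axis=1)
        dof = na + nb - 2
        pooled_var = (ss_a + ss_b) / dof
        diff = mean_a - mean_b
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
            p = 2.0 * stats.t.sf(np.abs(t), dof)
        degenerate = pooled_var == 0
        p[degenerate & (diff != 0)] = 0.0
        p[degenerate & (diff == 0)] = np.nan  # excluded: no signal at all
        selected |= p < alpha
    return [f for f, keep in zip(fc.data.index, selected) if keep]


def rank_features(values: pd.Series) -> tuple[str, ...]:
    """Order features by value descending, ties by feature id ascending."""
    ids = np.asarray(values.index, dtype=object)
    order = np.lexsort((ids, -values.to_numpy()))
    return tuple(ids[order])


def extract_signature(fc_profile: pd.Series, n1: int, n2: int, sample_id: str | None = None) -> SubjectSignature:
    """Cut a subject signature from one sample's fold-change vector.

    The vector is ranked by fold change (descending, ties by feature id);
    the up-list is the first ``n1`` entries and the down-list the last
    ``n2`` (most down-regulated last).
    """
    if n1 + n2 > len(fc_profile):
        raise ValueError(
            f"n1 + n2 = {n1 + n2} exceeds the {len(fc_profile)} available features"
        )
    ranking = rank_features(fc_profile)
    name = sample_id if sample_id is not None else str(fc_profile.name)
    return SubjectSignature(
        sample_id=name,
        up=ranking[:n1],
        down=ranking[len(ranking) - n2:],
        ranking=ranking,
    )


def extract_signatures(fc: FoldChangeMatrix, features: list[str], n1: int, n2: int) -> list[SubjectSignature]:
    """Per-sample signatures over the selected feature subset."""
    sub = fc.data.loc[features]
    return [extract_signature(sub[s], n1, n2, sample_id=s) for s in sub.columns]


# ---------------------------------------------------------------------------
# enrichment-score distance
# ---------------------------------------------------------------------------

def enrichment_score(members: tuple[str, ...] | set[str], ranking: tuple[str, ...]) -> float:
    """Signed extremum of the running enrichment sum.

    Walking ``ranking`` top to bottom, the sum gains 1/|S| at members of
    ``S`` and loses 1/(G−|S|) elsewhere.  The score is the deviation of
    largest magnitude reached (ties favour the positive extremum), so a
    set concentrated at the top scores +1 and one at the bottom −1.
    """
    members = set(members)
    size = len(members)
    total = len(ranking)
    if not 0 < size < total:
        raise ValueError("signature must be a proper non-empty subset of the ranking")
    hits = np.fromiter((f in members for f in ranking), dtype=bool, count=total)
    steps = np.where(hits, 1.0 / size, -1.0 / (total - size))
    running = np.cumsum(steps)
    hi, lo = running.max(), running.min()
    return float(hi if hi >= -lo else lo)


def signature_distance(sig_a: SubjectSignature, sig_b: SubjectSignature) -> float:
    """Enrichment-score distance between two subject signatures.

    Each signature's up- and down-lists are scored against the other
    sample's full ranking; similarity is the 4-term symmetrised average
    (up-scores positively, down-scores negatively) and distance is
    1 − similarity, so identical signatures give 0 and perfectly
    reversed ones 2.
    """
    if set(sig_a.ranking) != set(sig_b.ranking):
        raise ValueError(
            f"signatures {sig_a.sample_id!r} and {sig_b.sample_id!r} "
            "cover different feature universes"
        )
    similarity = (
        enrichment_score(sig_a.up, sig_b.ranking)
        - enrichment_score(sig_a.down, sig_b.ranking)
        + enrichment_score(sig_b.up, sig_a.ranking)
        - enrichment_score(sig_b.down, sig_a.ranking)
    ) / 4.0
    return 1.0 - similarity


def distance_matrix(signatures: list[SubjectSignature]) -> pd.DataFrame:
    """Symmetric all-to-all signature distance matrix with zero diagonal."""
    if len(signatures) < 2:
        raise ValueError("need at least 2 signatures")
    ids = [s.sample_id for s in signatures]
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = signature_distance(signatures[i], signatures[j])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


def similarity_graph(distances: pd.DataFrame, k: float = 10.0):
    """Graph connecting samples whose distance falls in the bottom ``k`` %.

    The threshold is the ``k``-th percentile (linear interpolation) of
    the strictly-upper-triangle distances; an edge joins every pair at
    or below it.  Edge attribute ``distance`` carries the value.
    """
    import networkx as nx

    if not 0 < k <= 100:
        raise ValueError("percentile k must be in (0, 100]")
    n = distances.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to build a graph")
    iu = np.triu_indices(n, 1)
    upper = distances.to_numpy()[iu]
    threshold = float(np.percentile(upper, k))
    graph = nx.Graph(threshold=threshold)
    graph.add_nodes_from(distances.index)
    for i, j in zip(*iu):
        d = distances.iat[i, j]
        if d <= threshold:
            graph.add_edge(distances.index[i], distances.columns[j], distance=float(d))
    return graph


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _popularity_order(lists: list[tuple[str, ...]], from_end: bool) -> tuple[list[str], dict[str, int]]:
    """Features sorted by (count desc, mean within-list rank asc, id asc).

    ``from_end=True`` measures the rank from the extreme (last) end of
    each list, matching the down-list convention of most-extreme-last.
    """
    counts: dict[str, int] = {}
    rank_sums: dict[str, float] = {}
    for lst in lists:
        size = len(lst)
        for pos, feat in enumerate(lst):
            rank = size - pos if from_end else pos + 1
            counts[feat] = counts.get(feat, 0) + 1
            rank_sums[feat] = rank_sums.get(feat, 0.0) + rank
    order = sorted(counts, key=lambda f: (-counts[f], rank_sums[f] / counts[f], f))
    return order, counts


def consensus_signature(
    signatures: list[SubjectSignature], n1: int, n2: int, group: str = ""
) -> ConsensusSignature:
    """Group consensus: the ``n1``/``n2`` most popular up/down features.

    Popularity counts how many subject signatures include a feature in
    the corresponding list; ties break by better (more extreme) mean
    within-list rank, then feature id.
    """
    if not signatures:
        raise ValueError("need at least 1 signature for a consensus")
    up_order, up_counts = _popularity_order([s.up for s in signatures], from_end=False)
    down_order, down_counts = _popularity_order([s.down for s in signatures], from_end=True)
    if len(up_order) < n1:
        raise ValueError(
            f"only {len(up_order)} distinct up features across the group; need n1={n1}"
        )
    if len(down_order) < n2:
        raise ValueError(
            f"only {len(down_order)} distinct down features across the group; need n2={n2}"
        )
    return ConsensusSignature(
        group=group,
        up=tuple(up_order[:n1]),
        down=tuple(down_order[:n2]),
        up_popularity=up_counts,
        down_popularity=down_counts,
    )
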