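"""Synthetic datasets with the statistical structure the pipeline assumes.

Every generator is a pure function of its parameters and seed, and each
returns a ground-truth record alongside the data so recovery can be
scored.  Expression noise is normal on the log2 scale and qPCR noise
normal on the Ct scale, matching the multiplicative error model implied
by fold-change and 2^−ΔΔCt analyses.  The default expression design
mirrors a four-group case/control study of two crossed phenotypes with
the cohort sizes 20/12/6/19.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import (
    CtTable,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    InteractionRecord,
    SampleGroups,
)

#: Default 4-group design (label → number of samples).
DEFAULT_GROUP_SIZES = {
    "t2dm_ctrl": 20,
    "ctrl": 12,
    "t2dm_ad": 6,
    "ad": 19,
}


@dataclass
class SyntheticTruth:
    """Ground truth serialised alongside every generated dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    planted_up: dict[str, list[str]] = field(default_factory=dict)    # group → features
    planted_down: dict[str, list[str]] = field(default_factory=dict)
    planted_set_name: str | None = None
    planted_module: list[str] = field(default_factory=list)
    planted_fold_changes: dict[str, float] = field(default_factory=dict)  # qPCR gene → fold

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        return cls(**json.loads(text))


def generate_expression_dataset(
    n_features: int = 20000,
    group_sizes: dict[str, int] | None = None,
    planted_per_group: int = 10,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    baseline: float = 8.0,
    scale: str = "log2",
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleGroups, SyntheticTruth]:
    """Four-group expression matrix with planted group-specific genes.

    Background values are Normal(``baseline``, ``noise_sd``) on the log2
    scale.  Each group receives ``planted_per_group`` up-regulated and
    as many down-regulated features, disjoint across groups, shifted by
    ±``effect_size``·``noise_sd`` in that group's samples only.
    ``scale="linear"`` exponentiates, guaranteeing positive intensities.
    """
    if scale not in {"linear", "log2"}:
        raise ValueError(f"scale must be 'linear' or 'log2', got {scale!r}")
    sizes = dict(group_sizes) if group_sizes else dict(DEFAULT_GROUP_SIZES)
    n_planted_total = 2 * planted_per_group * len(sizes)
    if n_planted_total > n_features:
        raise ValueError(
            f"cannot plant {n_planted_total} features into {n_features}"
        )
    rng = np.random.default_rng(seed)
    width = len(str(n_features))
    features = [f"P{i + 1:0{width}d}" for i in range(n_features)]
    samples, labels = [], {}
    for g, n in sizes.items():
        for i in range(n):
            s = f"{g}_{i + 1:02d}"
            samples.append(s)
            labels[s] = g

    values = rng.normal(baseline, noise_sd, size=(n_features, len(samples)))
    chosen = rng.choice(n_features, size=n_planted_total, replace=False)
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_features": n_features,
            "group_sizes": sizes,
            "planted_per_group": planted_per_group,
            "effect_size": effect_size,
            "noise_sd": noise_sd,
            "baseline": baseline,
            "scale": scale,
        },
    )
    shift = effect_size * noise_sd
    cursor = 0
    for g in sizes:
        cols = [i for i, s in enumerate(samples) if labels[s] == g]
        up_idx = chosen[cursor:cursor + planted_per_group]
        down_idx = chosen[cursor + planted_per_group:cursor + 2 * planted_per_group]
        cursor += 2 * planted_per_group
        values[np.ix_(up_idx, cols)] += shift
        values[np.ix_(down_idx, cols)] -= shift
        truth.planted_up[g] = sorted(features[i] for i in up_idx)
        truth.planted_down[g] = sorted(features[i] for i in down_idx)

    if scale == "linear":
        values = np.exp2(values)
    expr = ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples))
    return expr, SampleGroups(labels), truth


def _decode_pair_index(t: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    # unordered pair (i, j), i < j, from a flat index over the upper triangle
    counts = np.arange(n - 1, 0, -1)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    i = np.searchsorted(offsets, t, side="right") - 1
    j = t - offsets[i] + i + 1
    return i, j


def generate_interactome(
    symbols: list[str],
    n_edges: int,
    planted_module: list[str] | None = None,
    seed: int = 0,
) -> tuple[list[InteractionRecord], SyntheticTruth]:
    """Random sparse undirected interactome, all physical human pairs.

    Draws ``n_edges`` distinct unordered pairs uniformly; a planted
    module, if given, is wired as a connected path among its members and
    merged in (duplicates collapse).
    """
    n = len(symbols)
    max_edges = n * (n - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges={n_edges} exceeds the {max_edges} possible pairs")
    rng = np.random.default_rng(seed)
    module = [s.upper() for s in (planted_module or [])]
    unknown = set(module) - {s.upper() for s in symbols}
    if unknown:
        raise ValueError(f"planted module symbols not in the universe: {sorted(unknown)}")
    edges: set[tuple[str, str]] = set()
    for a, b in zip(module, module[1:]):
        edges.add((a, b) if a <= b else (b, a))
    if n_edges:
        idx = rng.choice(max_edges, size=n_edges, replace=False)
        ii, jj = _decode_pair_index(np.sort(idx), n)
        for i, j in zip(ii, jj):
            a, b = symbols[i].upper(), symbols[j].upper()
            edges.add((a, b) if a <= b else (b, a))
    records = [
        InteractionRecord(a, b, 9606, 9606, "physical") for a, b in sorted(edges)
    ]
    truth = SyntheticTruth(
        seed=seed,
        params={"n_symbols": n, "n_edges": n_edges},
        planted_module=module,
    )
    return records, truth


def generate_gene_sets(
    universe: list[str],
    n_sets: int = 50,
    set_size: int = 20,
    planted_query: list[str] | None = None,
    planted_overlap: int = 0,
    seed: int = 0,
) -> tuple[GeneSetCollection, SyntheticTruth]:
    """Decoy gene sets plus one set enriched for a planted query.

    ``n_sets − 1`` decoys are drawn uniformly from the universe; the
    planted set contains exactly ``planted_overlap`` members of
    ``planted_query`` and random fill from outside it.
    """
    universe = [u.upper() for u in universe]
    query = [q.upper() for q in (planted_query or [])]
    if planted_overlap > min(set_size, len(query) if query else set_size):
        raise ValueError("planted_overlap exceeds set size or query size")
    if set_size > len(universe):
        raise ValueError("set_size exceeds the universe")
    rng = np.random.default_rng(seed)
    coll = GeneSetCollection()
    truth = SyntheticTruth(
        seed=seed,
        params={"n_sets": n_sets, "set_size": set_size, "planted_overlap": planted_overlap},
    )
    n_decoys = n_sets - 1 if query else n_sets
    for d in range(n_decoys):
        members = rng.choice(len(universe), size=set_size, replace=False)
        coll.add(
            GeneSet(
                f"DECOY_{d + 1:03d}",
                "random decoy set",
                tuple(universe[i] for i in members),
            )
        )
    if query:
        hit_idx = rng.choice(len(query), size=planted_overlap, replace=False)
        hits = [query[i] for i in hit_idx]
        pool = [u for u in universe if u not in set(query)]
        n_fill = set_size - planted_overlap
        if n_fill > len(pool):
            raise ValueError("universe too small to fill the planted set")
        fill_idx = rng.choice(len(pool), size=n_fill, replace=False)
        members = tuple(hits + [pool[i] for i in fill_idx])
        coll.add(GeneSet("PLANTED_SET", "set enriched for the planted query", members))
        truth.planted_set_name = "PLANTED_SET"
    return coll, truth


def generate_ct_table(
    n_genes: int = 80,
    groups: dict[str, int] | None = None,
    n_reference_genes: int = 3,
    planted: dict[str, float] | None = None,
    ct_noise_sd: float = 0.25,
    control_group: str | None = None,
    seed: int = 0,
) -> tuple[CtTable, SyntheticTruth]:
    """qPCR Ct panel with stable references and planted fold changes.

    Reference genes centre at Ct 20 and targets at Ct 25 with normal
    noise of ``ct_noise_sd`` cycles.  A planted fold change ``f`` on a
    target gene shifts its Ct by −log2(f) in every non-control animal.
    Target genes are named ``G001``…; planted keys may use those names.
    """
    sizes = dict(groups) if groups else {"control": 6, "treated": 6}
    control = control_group if control_group is not None else next(iter(sizes))
    if control not in sizes:
        raise ValueError(f"control group {control!r} not among groups")
    planted = dict(planted or {})
    width = len(str(n_genes))
    targets = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    refs = [f"REF{i + 1}" for i in range(n_reference_genes)]
    bad = set(planted) - set(targets)
    if bad:
        raise ValueError(f"planted genes are not target genes: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    animals, labels = [], {}
    for g, n in sizes.items():
        for i in range(n):
            a = f"{g}_{i + 1:02d}"
            animals.append(a)
            labels[a] = g
    data = pd.DataFrame(
        np.concatenate(
            [
                rng.normal(20.0, ct_noise_sd, size=(len(refs), len(animals))),
                rng.normal(25.0, ct_noise_sd, size=(len(targets), len(animals))),
            ]
        ),
        index=refs + targets,
        columns=animals,
    )
    treated_cols = [a for a in animals if labels[a] != control]
    for gene, fold in planted.items():
        data.loc[gene, treated_cols] -= np.log2(fold)
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "groups": sizes,
            "n_reference_genes": n_reference_genes,
            "ct_noise_sd": ct_noise_sd,
            "control_group": control,
        },
        planted_fold_changes={g: float(f) for g, f in planted.items()},
    )
    return CtTable(data, labels, refs), truth
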