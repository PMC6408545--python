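"""Relative qPCR quantification (ΔΔCt) and rank-product differential expression.

Ct values are normalised per animal to the arithmetic mean Ct of the
reference genes — equivalent to the geometric average of their 2^−Ct
expression levels — then referenced to the control-group mean ΔCt and
converted to relative expression ratios 2^(−ΔΔCt).

Differential expression between two groups uses the rank product: every
between-group pair of animals forms one ratio comparison, genes are
ranked within each comparison (ties get average ranks), and the
statistic is the geometric mean of a gene's ranks across comparisons.
Significance comes from a permutation null in which each comparison's
ranks are reassigned uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CtTable


@dataclass
class RelativeExpressionTable:
    """Gene × animal matrix of 2^(−ΔΔCt) ratios; reference genes excluded."""

    data: pd.DataFrame
    groups: dict[str, str]

    def samples_in(self, group: str) -> list[str]:
        members = [a for a in self.data.columns if self.groups[a] == group]
        if not members:
            raise KeyError(f"unknown or empty group: {group!r}")
        return members


@dataclass
class RankProductResult:
    """Per-gene rank-product statistics in both directions.

    ``table`` columns: rp_up, p_up, pfp_up, rp_down, p_down, pfp_down,
    mean_ratio_a, mean_ratio_b.  RP is the geometric mean of ranks, so
    1 ≤ RP ≤ n_genes; p-values carry +1 smoothing:
    p = (1 + #{null RP ≤ observed}) / (n_perm + 1).  pfp is the
    expected false-positive proportion n_genes·p / rank(RP).
    """

    table: pd.DataFrame
    n_comparisons: int
    n_perm: int
    group_a: str
    group_b: str


def ddct_relative_expression(ct: CtTable, control_group: str) -> RelativeExpressionTable:
    """ΔΔCt relative quantification against the control-group mean.

    Per animal: ΔCt = Ct − mean(reference Ct); per gene:
    ΔΔCt = ΔCt − mean ΔCt over control animals; ratio = 2^(−ΔΔCt).
    """
    if not ct.reference_genes:
        raise ValueError("at least one reference gene is required")
    controls = [a for a, g in ct.groups.items() if g == control_group]
    if not controls:
        raise ValueError(f"control group {control_group!r} has no animals")
    refs = ct.data.loc[ct.reference_genes]
    for gene in ct.reference_genes:
        bad = refs.loc[gene][~np.isfinite(refs.loc[gene])]
        if len(bad):
            raise ValueError(
                f"reference gene {gene!r} lacks a Ct for animal {bad.index[0]!r}"
            )
    ref_mean = refs.mean(axis=0)
    dct = ct.data.loc[ct.target_genes].sub(ref_mean, axis=1)
    ddct = dct.sub(dct[controls].mean(axis=1), axis=0)
    return RelativeExpressionTable(np.exp2(-ddct), dict(ct.groups))


def _rank_product(ranks: np.ndarray) -> np.ndarray:
    # geometric mean over the comparison axis; log-space for stability
    return np.exp(np.log(ranks).mean(axis=1))


def rank_product_test(
    expr: RelativeExpressionTable,
    group_a: str,
    group_b: str,
    n_perm: int = 10000,
    seed: int = 0,
) -> RankProductResult:
    """Two-class unpaired rank product over all between-group comparisons.

    For each of the |A|·|B| animal pairs the per-gene log ratio
    (animal_a / animal_b) is ranked ascending — rank 1 marks the gene
    most down-regulated in ``group_a`` — and descending for the up
    direction.  The permutation null redraws each comparison's ranks as
    an independent random permutation; under such an assignment any
    fixed gene's rank is uniform on 1..n_genes independently per
    comparison, so each null draw samples one uniform rank per
    comparison.  One shared null sample serves every gene and both
    directions (their marginal null distributions are identical), which
    makes the p-values exactly invariant to gene relabelling.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    animals_a = expr.samples_in(group_a)
    animals_b = expr.samples_in(group_b)
    genes = list(expr.data.index)
    n_genes = len(genes)
    log_expr = np.log2(expr.data.to_numpy())
    ia = [expr.data.columns.get_loc(a) for a in animals_a]
    ib = [expr.data.columns.get_loc(b) for b in animals_b]
    # genes × (|A|·|B|) log-ratio comparisons
    ratios = np.stack(
        [log_expr[:, i] - log_expr[:, j] for i in ia for j in ib], axis=1
    )
    n_comp = ratios.shape[1]
    ranks_down = np.apply_along_axis(stats.rankdata, 0, ratios)
    ranks_up = np.apply_along_axis(stats.rankdata, 0, -ratios)
    rp_down = _rank_product(ranks_down)
    rp_up = _rank_product(ranks_up)

    rng = np.random.default_rng(seed)
    null_ranks = rng.integers(1, n_genes + 1, size=(n_perm, n_comp))
    null_rp = np.sort(np.exp(np.log(null_ranks).mean(axis=1)))
    count_up = np.searchsorted(null_rp, rp_up * (1 + 1e-12), side="right")
    count_down = np.searchsorted(null_rp, rp_down * (1 + 1e-12), side="right")
    p_up = (1.0 + count_up) / (n_perm + 1.0)
    p_down = (1.0 + count_down) / (n_perm + 1.0)
    pfp_up = p_up * n_genes / stats.rankdata(rp_up)
    pfp_down = p_down * n_genes / stats.rankdata(rp_down)

    lin = expr.data
    table = pd.DataFrame(
        {
            "rp_up": rp_up,
            "p_up": p_up,
            "pfp_up": pfp_up,
            "rp_down": rp_down,
            "p_down": p_down,
            "pfp_down": pfp_down,
            "mean_ratio_a": lin[animals_a].mean(axis=1).to_numpy(),
            "mean_ratio_b": lin[animals_b].mean(axis=1).to_numpy(),
        },
        index=pd.Index(genes, name="gene"),
    )
    return RankProductResult(table, n_comp, n_perm, group_a, group_b)
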