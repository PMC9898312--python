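"""Gene-group score comparisons and the pooled two-proportion z statistic.

Key candidates, remaining candidates, recruited intermediates and the rest of
the genome are compared on their gene-wise scores with a one-sided
permutation test of the mean difference (Welch's t as the asymptotic
cross-check), and a per-gene pooled two-proportion z-score summarises how
often a gene clears the single-gene significance line across conditions
relative to the genome background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import logger, normalize_gene_id
from .gene_scores import GeneScoreTable
from .sampling import sample_index_subsets

METHODS = ("permutation_mean_diff", "welch_t")


@dataclass
class GroupComparisonResult:
    group_a: str
    group_b: str
    condition_label: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    method: str


def compare_group_means(scores_a, scores_b, method: str = "permutation_mean_diff",
                        n_resamples: int = 10_000, seed: int = 0,
                        labels: tuple[str, str] = ("a", "b"),
                        condition_label: str = "",
                        genes_a=None, genes_b=None) -> GroupComparisonResult:
    """One-sided test of mean(a) > mean(b).

    The permutation method shuffles group labels ``n_resamples`` times and
    reports the add-one p-value; Welch's t is the asymptotic alternative.
    Groups must be disjoint gene sets; pass ``genes_a``/``genes_b`` to have
    this checked.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 values")
    if genes_a is not None and genes_b is not None:
        overlap = {normalize_gene_id(g) for g in genes_a} & \
                  {normalize_gene_id(g) for g in genes_b}
        if overlap:
            raise ValueError(f"overlapping groups: {sorted(overlap)[:5]}")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    obs = mean_a - mean_b
    if a.std() == 0 and b.std() == 0 and obs == 0:
        return GroupComparisonResult(labels[0], labels[1], condition_label,
                                     mean_a, mean_b, a.size, b.size, 0.0, 1.0,
                                     method)
    if method == "welch_t":
        t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        return GroupComparisonResult(labels[0], labels[1], condition_label,
                                     mean_a, mean_b, a.size, b.size,
                                     float(t), float(p), method)
    pool = np.concatenate([a, b])
    total = pool.sum()
    rng = np.random.default_rng(seed)
    idx = sample_index_subsets(rng, pool.size, a.size, n_resamples)
    sums_a = pool[idx].sum(axis=1)
    perm = sums_a / a.size - (total - sums_a) / b.size
    p = float((1 + np.count_nonzero(perm >= obs)) / (n_resamples + 1))
    return GroupComparisonResult(labels[0], labels[1], condition_label,
                                 mean_a, mean_b, a.size, b.size, obs, p,
                                 method)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> float:
    """Pooled two-proportion z statistic.

    ``z = (p1 - p2) / sqrt(p (1 - p) (1/n1 + 1/n2))`` with pooled
    ``p = (x1 + x2) / (n1 + n2)``.  Returns 0 when the pooled proportion is
    degenerate (0 or 1), with a logged note.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not (0 <= x <= n):
            raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        logger.info("two_proportion_z: degenerate pooled proportion %g",
                    pooled)
        return 0.0
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    return (x1 / n1 - x2 / n2) / se


def stratify_genes(table: GeneScoreTable, key_genes, candidates,
                   intermediates) -> dict[str, list[str]]:
    """Partition the score universe into four disjoint groups.

    Groups: ``key`` (key candidates), ``candidate`` (non-key candidates),
    ``intermediate`` (recruited connectors), ``remaining``.  Candidate status
    takes precedence over intermediate; key genes must be candidates.
    """
    key = {normalize_gene_id(g) for g in key_genes}
    cand = {normalize_gene_id(g) for g in candidates}
    inter = {normalize_gene_id(g) for g in intermediates}
    if not key <= cand:
        raise ValueError(f"key genes outside candidate list: "
                         f"{sorted(key - cand)[:5]}")
    both = cand & inter
    if both:
        logger.warning("%d genes both candidate and intermediate; candidate "
                       "label wins", len(both))
        inter -= both
    universe = table.universe
    groups = {
        "key": sorted(key & universe),
        "candidate": sorted((cand - key) & universe),
        "intermediate": sorted(inter & universe),
    }
    taken = set().union(*[set(v) for v in groups.values()])
    groups["remaining"] = sorted(universe - taken)
    logger.info("group sizes: %s",
                {k: len(v) for k, v in groups.items()})
    return groups
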