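"""Competitive and self-contained pathway enrichment.

Two families of tests over a prioritised candidate list and per-gene scores:

* **Competitive** (hypergeometric over-representation): is the candidate list
  over-represented among a pathway's members, relative to the measured
  universe?  With L measured genes, M candidates, S pathway members and g
  overlapping genes, the p-value is the upper hypergeometric tail
  ``sum_{x>=g} C(S,x) C(L-S,M-x) / C(L,M)``.

* **Self-contained** (SUMSTAT / SUMSQ): does the pathway's member-score sum
  (or sum of squares) exceed what size-matched random gene sets achieve?
  The null is built by drawing B random subsets of the same size from the
  score universe; the empirical p-value uses the add-one estimator
  ``(1 + #{null >= observed}) / (B + 1)`` and the normalised enrichment score
  is ``z = (ES - mean(null)) / sd(null)`` with a standard-normal upper-tail
  p as the asymptotic alternative.

Both are exposed statsmodels-style: a model object built from the data whose
``fit()`` returns an :class:`EnrichmentResults` carrying the per-pathway
table, adjusted p-values and a ``summary()``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import logger
from .annotations import CandidateGeneList, PathwayCollection
from .gene_scores import GeneScoreTable
from .sampling import sample_index_subsets

STATISTICS = ("sumstat", "sumsq")
METHODS = ("hypergeometric", "sumstat", "sumsq")

#: default genome-wide significance threshold on the raw calling p-value
SIGNIFICANCE_THRESHOLD = 1e-4

#: empirical p-values with fewer exceedances than this are considered below
#: the permutation test's resolution and are replaced, for significance
#: calls only, by the asymptotic normal-tail p of the normalised ES
MIN_EXCEEDANCES = 10

RESULT_COLUMNS = [
    "pathway_id", "name", "condition", "method", "N_G", "N_FT",
    "ES", "normalized_ES", "p_empirical", "p_asymptotic", "p_value",
    "p_bh", "p_bonferroni", "significant",
]


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def hypergeometric_pvalue(L: int, M: int, S: int, g: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= g).

    L: universe size, M: candidate-list size, S: pathway size, g: overlap.
    """
    L, M, S, g = int(L), int(M), int(S), int(g)
    if L < 1 or M < 0 or S < 0 or g < 0:
        raise ValueError("counts must be non-negative (L >= 1)")
    if S > L or M > L:
        raise ValueError(f"infeasible counts: S={S}, M={M} exceed L={L}")
    if g > min(S, M):
        raise ValueError(f"infeasible overlap g={g} > min(S={S}, M={M})")
    if g == 0:
        return 1.0
    p = float(stats.hypergeom.sf(g - 1, L, S, M))
    # guard against underflow to exactly 0 in extreme tails
    return max(p, 5e-324)


def enrichment_score(member_scores, statistic: str = "sumstat") -> float:
    """Sum (sumstat) or sum of squares (sumsq) of member gene scores."""
    x = np.asarray(member_scores, dtype=float)
    if x.size == 0:
        raise ValueError("empty membership")
    if statistic == "sumstat":
        return float(x.sum())
    if statistic == "sumsq":
        return float((x ** 2).sum())
    raise ValueError(f"unknown statistic {statistic!r}")


def empirical_pvalue(observed_es: float, null_es) -> float:
    """Add-one one-sided empirical p-value (1 + #{null >= obs}) / (B + 1)."""
    null = np.asarray(null_es, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    # tolerance so exact ties survive summation-order rounding
    cutoff = observed_es - 1e-9 * max(1.0, abs(float(observed_es)))
    return float((1 + np.count_nonzero(null >= cutoff)) / (null.size + 1))


def normalize_es(observed_es: float, null_es) -> tuple[float, float]:
    """Normalise the ES against its permutation null.

    Returns ``(z, p_asymptotic)`` with ``z = (obs - mean) / sd`` (sample sd)
    and the standard-normal upper-tail probability of z.
    """
    null = np.asarray(null_es, dtype=float)
    if null.size < 2:
        raise ValueError("need >= 2 null values")
    sd = float(np.std(null, ddof=1))
    mean = float(np.mean(null))
    # a sd at rounding-noise level counts as zero (e.g. constant null)
    if sd <= 1e-12 * max(1.0, abs(mean), abs(float(observed_es))):
        raise ValueError("zero null variance: normalised ES undefined")
    z = (float(observed_es) - mean) / sd
    return z, float(stats.norm.sf(z))


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = _checked_p(p_values)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def adjust_bonferroni(p_values) -> np.ndarray:
    """Bonferroni-adjusted p-values min(1, p * m), in input order."""
    p = _checked_p(p_values)
    if p.size == 0:
        return p
    return multipletests(p, method="bonferroni")[1]


def _checked_p(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

@dataclass
class PermutationConfig:
    """Permutation-null settings.

    B replicate gene-label subsets are drawn per pathway size; streams are
    derived deterministically from the single ``seed`` and the (condition,
    set size) pair, so results do not depend on pathway iteration order.
    """

    B: int = 10_000
    seed: int = 0
    scheme: str = "gene_label_shuffle"

    def __post_init__(self):
        if self.B < 100:
            raise ValueError("B must be >= 100")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.scheme != "gene_label_shuffle":
            raise ValueError(f"unknown permutation scheme {self.scheme!r}")


class PermutationNullCache:
    """Per-(set size) cached null ES distributions for one score table.

    Both statistics are computed from the same index draws, so a shared cache
    serves SUMSTAT and SUMSQ at no extra sampling cost.
    """

    def __init__(self, table: GeneScoreTable, config: PermutationConfig):
        self.config = config
        self._scores = table.scores.astype(float)
        self._sq = self._scores ** 2
        self._cond_key = zlib.crc32(table.condition_label.encode())
        self._cache: dict[int, dict[str, np.ndarray]] = {}

    @property
    def universe_size(self) -> int:
        return self._scores.size

    def null(self, set_size: int, statistic: str) -> np.ndarray:
        if statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {statistic!r}")
        if not (1 <= set_size <= self.universe_size):
            raise ValueError(
                f"set_size {set_size} outside universe of {self.universe_size}")
        if set_size not in self._cache:
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=self.config.seed,
                spawn_key=(self._cond_key, set_size)))
            idx = sample_index_subsets(rng, self.universe_size, set_size,
                                       self.config.B)
            self._cache[set_size] = {
                "sumstat": self._scores[idx].sum(axis=1),
                "sumsq": self._sq[idx].sum(axis=1),
            }
        return self._cache[set_size][statistic]


def permutation_null(table: GeneScoreTable, set_size: int, statistic: str,
                     config: PermutationConfig) -> np.ndarray:
    """B replicate null ES values for random size-matched gene sets."""
    return PermutationNullCache(table, config).null(set_size, statistic)


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

class EnrichmentResults:
    """Per-pathway enrichment statistics for one method and condition.

    Attributes
    ----------
    frame : pandas.DataFrame
        One row per pathway with the columns in :data:`RESULT_COLUMNS`.
        ``p_value`` is the calling p-value used for significance: for the
        hypergeometric test the exact tail probability; for the permutation
        tests the empirical p-value, replaced by the asymptotic normal-tail
        p when fewer than :data:`MIN_EXCEEDANCES` permutations reach the
        observed ES (finite resampling cannot resolve such values reliably).
    """

    def __init__(self, frame: pd.DataFrame, method: str, condition: str,
                 universe_size: int, n_candidates: int,
                 threshold: float = SIGNIFICANCE_THRESHOLD,
                 fdr_level: float = 0.05,
                 config: PermutationConfig | None = None):
        self.method = method
        self.condition = condition
        self.universe_size = universe_size
        self.n_candidates = n_candidates
        self.threshold = threshold
        self.fdr_level = fdr_level
        self.config = config
        frame = frame.copy()
        frame["p_bh"] = adjust_bh(frame["p_value"].to_numpy())
        frame["p_bonferroni"] = adjust_bonferroni(frame["p_value"].to_numpy())
        frame["significant"] = frame["p_value"] < threshold
        self.frame = frame[RESULT_COLUMNS].reset_index(drop=True)

    def ranked(self) -> pd.DataFrame:
        """Rows sorted by calling p-value (ties broken by normalised ES)."""
        key = self.frame.assign(_nes=-self.frame["normalized_ES"].fillna(0.0))
        out = key.sort_values(["p_value", "_nes", "pathway_id"],
                              kind="mergesort").drop(columns="_nes")
        return out.reset_index(drop=True)

    def significant_ids(self) -> list[str]:
        sig = self.frame.loc[self.frame["significant"], "pathway_id"]
        return sorted(sig)

    def to_tsv(self, path) -> None:
        self.ranked().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self, top: int = 10) -> str:
        head = self.ranked().head(top)
        lines = [
            f"{self.method} enrichment, condition {self.condition}",
            f"universe L={self.universe_size}, candidates M={self.n_candidates},"
            f" pathways tested={len(self.frame)}",
            f"significant at p < {self.threshold:g}:"
            f" {int(self.frame['significant'].sum())}",
            "",
            head.to_string(index=False,
                           float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<EnrichmentResults {self.method}/{self.condition}: "
                f"{len(self.frame)} pathways>")


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class CompetitiveEnrichment:
    """Hypergeometric over-representation of candidates within pathways.

    The background is L = genes in the score table; M = candidates present in
    that universe.  The collection should already be restricted to the
    universe (`annotations.restrict_to_universe`).
    """

    def __init__(self, table: GeneScoreTable, collection: PathwayCollection,
                 candidates: CandidateGeneList,
                 significance_threshold: float = SIGNIFICANCE_THRESHOLD):
        self.table = table
        self.collection = collection
        self.candidates = candidates
        self.threshold = significance_threshold

    def fit(self) -> EnrichmentResults:
        universe = self.table.universe
        cand = self.candidates.gene_ids & universe
        L, M = len(universe), len(cand)
        logger.info("competitive background for %s: L=%d, M=%d",
                    self.table.condition_label, L, M)
        rows = []
        for p in self.collection:
            genes = p.genes & universe
            S, g = len(genes), len(genes & cand)
            pval = hypergeometric_pvalue(L, M, S, g) if S else 1.0
            rows.append((p.pathway_id, p.name, self.table.condition_label,
                         "hypergeometric", S, g, np.nan, np.nan, np.nan,
                         np.nan, pval))
        frame = pd.DataFrame(rows, columns=RESULT_COLUMNS[:11])
        return EnrichmentResults(frame, "hypergeometric",
                                 self.table.condition_label, L, M,
                                 threshold=self.threshold)


class SelfContainedEnrichment:
    """Permutation test of member-score sums against size-matched null sets.

    Genes outside a pathway enter only through the permutation universe; the
    candidate list is used for reporting the overlap count N_FT, not for the
    statistic.
    """

    def __init__(self, table: GeneScoreTable, collection: PathwayCollection,
                 statistic: str = "sumstat",
                 config: PermutationConfig | None = None,
                 candidates: CandidateGeneList | None = None,
                 significance_threshold: float = SIGNIFICANCE_THRESHOLD,
                 null_cache: PermutationNullCache | None = None):
        if statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {statistic!r}")
        self.table = table
        self.collection = collection
        self.statistic = statistic
        self.config = config or PermutationConfig()
        self.candidates = candidates
        self.threshold = significance_threshold
        if null_cache is not None and null_cache.config is not self.config:
            raise ValueError("null_cache must share the model's config")
        self._cache = null_cache or PermutationNullCache(table, self.config)

    def fit(self) -> EnrichmentResults:
        universe = self.table.universe
        cand = (self.candidates.gene_ids & universe
                if self.candidates is not None else frozenset())
        gene_pos = {g: i for i, g in enumerate(self.table.gene_ids)}
        scores = self.table.scores
        # below ~10 exceedances the empirical estimate's relative error
        # exceeds ~30%; the normal-tail p of the normalised ES takes over
        resolution = (1.0 + MIN_EXCEEDANCES) / (self.config.B + 1)
        rows = []
        for p in self.collection:
            genes = p.genes & universe
            if not genes:
                continue
            # sorted so the summation order (hence the float result) does
            # not depend on set iteration order across processes
            idx = np.sort(np.fromiter((gene_pos[g] for g in genes),
                                      dtype=np.int64, count=len(genes)))
            es = enrichment_score(scores[idx], self.statistic)
            null = self._cache.null(len(genes), self.statistic)
            p_emp = empirical_pvalue(es, null)
            try:
                z, p_asym = normalize_es(es, null)
            except ValueError:
                # degenerate null (e.g. pathway == universe): no z available
                z, p_asym = np.nan, np.nan
            p_call = p_emp
            if p_emp < resolution and np.isfinite(p_asym):
                p_call = min(p_emp, p_asym)
            rows.append((p.pathway_id, p.name, self.table.condition_label,
                         self.statistic, len(genes), len(genes & cand),
                         es, z, p_emp, p_asym, p_call))
        frame = pd.DataFrame(rows, columns=RESULT_COLUMNS[:11])
        return EnrichmentResults(frame, self.statistic,
                                 self.table.condition_label,
                                 len(universe), len(cand),
                                 threshold=self.threshold, config=self.config)


def test_competitive(table, collection, candidates,
                     significance_threshold=SIGNIFICANCE_THRESHOLD):
    """Functional wrapper around :class:`CompetitiveEnrichment`."""
    return CompetitiveEnrichment(table, collection, candidates,
                                 significance_threshold).fit()


def test_selfcontained(table, collection, statistic="sumstat", config=None,
                       candidates=None,
                       significance_threshold=SIGNIFICANCE_THRESHOLD,
                       null_cache=None):
    """Functional wrapper around :class:`SelfContainedEnrichment`."""
    return SelfContainedEnrichment(
        table, collection, statistic, config, candidates,
        significance_threshold, null_cache).fit()


# ---------------------------------------------------------------------------
# cross-condition consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Pathways significant per method across conditions, plus intersections."""

    per_method: dict[str, list[str]] = field(default_factory=dict)
    intersections: dict[str, list[str]] = field(default_factory=dict)
    threshold: float = SIGNIFICANCE_THRESHOLD
    require_all_conditions: bool = True

    def to_frame(self) -> pd.DataFrame:
        rows = [("method", m, pid)
                for m, ids in sorted(self.per_method.items()) for pid in ids]
        rows += [("intersection", key, pid)
                 for key, ids in sorted(self.intersections.items())
                 for pid in ids]
        return pd.DataFrame(rows, columns=["kind", "set_label", "pathway_id"])


def consensus_pathways(results: list[EnrichmentResults],
                       threshold: float = SIGNIFICANCE_THRESHOLD,
                       require_all_conditions: bool = True) -> ConsensusResult:
    """Per-method consensus over conditions and pairwise method intersections.

    A pathway enters a method's consensus when its calling p-value is below
    ``threshold`` in every condition tested (``require_all_conditions``) or
    in at least one.
    """
    if not results:
        raise ValueError("no enrichment results given")
    frames = pd.concat([r.frame for r in results], ignore_index=True)
    per_method: dict[str, list[str]] = {}
    for method, grp in frames.groupby("method"):
        n_cond = grp["condition"].nunique()
        hit = grp[grp["p_value"] < threshold]
        counts = hit.groupby("pathway_id")["condition"].nunique()
        if require_all_conditions:
            ids = counts[counts == n_cond].index
        else:
            ids = counts[counts >= 1].index
        per_method[method] = sorted(ids)
    methods = sorted(per_method)
    inter: dict[str, list[str]] = {}
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            inter[f"{a}&{b}"] = sorted(
                set(per_method[a]) & set(per_method[b]))
    if len(methods) > 2:
        inter["&".join(methods)] = sorted(
            set.intersection(*(set(per_method[m]) for m in methods)))
    return ConsensusResult(per_method, inter, threshold,
                           require_all_conditions)
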