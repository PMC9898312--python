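"""Per-gene score tables: -log10 p-value transform and distribution shape.

The gene-wise statistic is t_i = -log10(p_i), where p_i is a gene's
differential-expression p-value for one condition (time point).  Larger t_i
means stronger expression change; the distribution of t_i over the genome is
strongly right-skewed, which is what the enrichment statistics exploit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._util import logger, normalize_gene_id

#: p-values of exactly zero are clamped here before taking logarithms.
P_FLOOR_DEFAULT = 1e-300


class GeneScoreTable:
    """Per-gene p-values and derived -log10 scores for one condition.

    Parameters
    ----------
    condition_label : str
        e.g. ``"3h"``.
    gene_ids, p_values : sequences
        Parallel arrays; gene ids must be unique after normalisation and
        p-values must lie in (0, 1] (exact zeros are clamped to ``p_floor``
        with a logged warning).
    """

    def __init__(self, condition_label: str, gene_ids, p_values,
                 p_floor: float = P_FLOOR_DEFAULT):
        self.condition_label = str(condition_label)
        ids = [normalize_gene_id(g) for g in gene_ids]
        if len(ids) != len(set(ids)):
            counts = pd.Series(ids).value_counts()
            dup = counts[counts > 1].index.tolist()
            raise ValueError(f"duplicate gene ids in score table: {dup[:5]}")
        p = np.asarray(p_values, dtype=float)
        if p.shape != (len(ids),):
            raise ValueError("gene_ids and p_values must be parallel 1-d arrays")
        if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
            bad = np.flatnonzero(~((p > 0) & (p <= 1)) | ~np.isfinite(p))
            raise ValueError(
                f"p-values outside (0, 1] at rows {bad[:5].tolist()}")
        n_zero = int(np.sum(p == 0))
        if n_zero:
            logger.warning(
                "%s: clamped %d zero p-values to floor %.3g",
                self.condition_label, n_zero, p_floor)
            p = np.where(p == 0, p_floor, p)
        self.frame = pd.DataFrame(
            {"p_value": p, "score": -np.log10(p)},
            index=pd.Index(ids, name="gene_id"),
        )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_tsv(cls, path, condition_label: str | None = None,
                 gene_col: str = "gene_id", p_col: str = "p_value",
                 p_floor: float = P_FLOOR_DEFAULT) -> "GeneScoreTable":
        frame = pd.read_csv(path, sep="\t")
        for col in (gene_col, p_col):
            if col not in frame.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        try:
            p = frame[p_col].astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric p-values: {exc}") from exc
        label = condition_label if condition_label is not None else str(path)
        return cls(label, frame[gene_col].astype(str), p, p_floor=p_floor)

    # -- access -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def gene_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.frame.index)

    @property
    def scores(self) -> np.ndarray:
        return self.frame["score"].to_numpy()

    def scores_for(self, genes) -> np.ndarray:
        """Scores of the given genes (all must be in the table)."""
        genes = [normalize_gene_id(g) for g in genes]
        missing = [g for g in genes if g not in self.frame.index]
        if missing:
            raise KeyError(f"genes not in score table: {missing[:5]}")
        return self.frame.loc[genes, "score"].to_numpy()

    def to_tsv(self, path, significance_threshold: float | None = None) -> None:
        out = self.frame.reset_index()
        if significance_threshold is not None:
            flags = flag_single_gene_significance(self, significance_threshold)
            out["significant"] = [flags[g] for g in out["gene_id"]]
        out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_score_table(path, condition_label: str | None = None,
                     **kwargs) -> GeneScoreTable:
    """Read a per-gene p-value TSV (columns gene_id, p_value)."""
    return GeneScoreTable.from_tsv(path, condition_label=condition_label,
                                   **kwargs)


def transform_pvalues(table: GeneScoreTable) -> GeneScoreTable:
    """Recompute score = -log10(p) for every row (idempotent)."""
    table.frame["score"] = -np.log10(table.frame["p_value"].to_numpy())
    return table


def sample_skewness(values) -> float:
    """Moment-coefficient skewness g1 = m3 / m2^(3/2).

    Central moments are taken over the full vector with no small-sample bias
    correction; a constant vector has undefined skewness and raises.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("skewness needs a 1-d vector of >= 3 values")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("undefined skewness: constant vector")
    return float(stats.skew(x, bias=True))


def flag_single_gene_significance(table: GeneScoreTable,
                                  threshold: float = 3.0) -> dict[str, bool]:
    """Flag genes whose score strictly exceeds the threshold.

    The default of 3 corresponds to p < 10^-3; genes sitting exactly on the
    line are not flagged.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    scores = table.frame["score"]
    return {g: bool(s > threshold) for g, s in scores.items()}
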