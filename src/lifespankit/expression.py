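"""Inter-individual expression-variability (CV) analysis.

The pipeline mirrors a liver RNA-seq heterogeneity analysis: counts are
depth-normalised to fragments per million (FPM, no gene-length term),
genes with overall mean expression below 1 FPM are removed, the per-gene
coefficient of variation (sample SD over mean, within a sample group) is
computed for two groups and compared — an OLS regression line summarises
the global shift, and genes whose CV in one group is more than twice the
CV of the same gene in the other group form the "highly variable" sets.
Those sets are then tested for over-representation against user-supplied
gene collections (GMT) with a one-sided hypergeometric test and
Benjamini-Hochberg FDR.

A simple per-gene differential test on log FPM is provided as a pluggable
stand-in for a dedicated count-model engine; its output records the
method used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .survival import ttest_unpaired

__all__ = [
    "ExpressionMatrix",
    "CVComparison",
    "EnrichmentResult",
    "DifferentialResult",
    "fpm_normalize",
    "filter_by_mean",
    "genewise_cv",
    "compare_cv",
    "overrepresentation",
    "differential_count",
    "read_gmt",
    "read_expression",
]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with a group label per sample.

    ``values`` is a genes x samples frame of non-negative reals (FPM);
    ``sample_groups`` maps every sample id to its group label.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("gene_ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]


@dataclass
class CVComparison:
    """Per-gene CVs of two groups and the ratio-based selections.

    ``table`` has one row per gene with columns ``cv_<group1>`` and
    ``cv_<group2>``; ``highvar_in_1`` are the genes whose CV in group 1
    exceeds ``ratio_threshold`` times the CV in group 2, and vice versa.
    The OLS line regresses group-2 CV on group-1 CV (with intercept).
    Genes with an undefined CV in either group are excluded from the
    selections and counted in ``n_dropped``.
    """

    group1: str
    group2: str
    table: pd.DataFrame
    regression_slope: float
    regression_intercept: float
    highvar_in_1: set[str]
    highvar_in_2: set[str]
    ratio_threshold: float
    n_dropped: int


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene-set term's over-representation outcome."""

    term_id: str
    term_size: int
    query_size: int
    universe_size: int
    overlap: int
    p_hypergeometric: float
    fdr_bh: float = math.nan

    def to_dict(self) -> dict:
        return {
            "term_id": self.term_id,
            "term_size": self.term_size,
            "query_size": self.query_size,
            "universe_size": self.universe_size,
            "overlap": self.overlap,
            "p_hypergeometric": self.p_hypergeometric,
            "fdr_bh": self.fdr_bh,
        }


@dataclass
class DifferentialResult:
    """Per-gene differential expression summary from the stand-in test."""

    table: pd.DataFrame  # columns: delta_log2, p_value, fdr_bh, direction
    n_up: int
    n_down: int
    fdr_threshold: float
    method: str = "student_ttest_on_log2_fpm"
    extra: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return self.n_up + self.n_down


# ---------------------------------------------------------------------------
# Normalisation and filtering


def fpm_normalize(counts: pd.DataFrame, library_sizes, sample_groups) -> ExpressionMatrix:
    """Depth-only normalisation: 1e6 * count / library_size per sample.

    ``library_sizes`` is a mapping/Series per sample (often the column
    totals, in which case each FPM column sums to 1e6). No gene-length
    term enters: the unit is fragments per million.
    """
    libs = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    if libs.isna().any():
        raise ValidationError(
            f"library sizes missing for samples: {list(libs.index[libs.isna()])}"
        )
    if (libs <= 0).any():
        raise ValidationError("library sizes must be positive")
    values = counts.astype(float).div(libs, axis=1) * 1e6
    return ExpressionMatrix(values=values, sample_groups=dict(sample_groups))


def filter_by_mean(matrix: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Keep genes whose overall mean is at or above ``threshold`` FPM.

    The boundary gene (mean exactly at the threshold) is retained: only
    genes *below* the threshold are excluded. Idempotent.
    """
    keep = matrix.values.mean(axis=1) >= threshold
    return ExpressionMatrix(
        values=matrix.values.loc[keep], sample_groups=dict(matrix.sample_groups)
    )


# ---------------------------------------------------------------------------
# Coefficient of variation


def genewise_cv(matrix: ExpressionMatrix, group: str) -> pd.Series:
    """Per-gene CV (sample SD with n-1 over mean) within one group.

    Genes with zero mean in the group get NaN (CV undefined).
    """
    samples = matrix.group_samples(group)
    if len(samples) < 2:
        raise ValidationError(f"group {group!r} needs >= 2 samples")
    sub = matrix.values[samples]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.nan
    cv.name = f"cv_{group}"
    return cv


def compare_cv(
    matrix: ExpressionMatrix,
    group1: str,
    group2: str,
    ratio_threshold: float = 2.0,
) -> CVComparison:
    """Compare per-gene CVs between two groups.

    Fits the OLS line cv2 = slope * cv1 + intercept and selects the genes
    whose CV in one group exceeds ``ratio_threshold`` times the CV of the
    same gene in the other group. The two selections are disjoint for any
    threshold >= 1.
    """
    cv1 = genewise_cv(matrix, group1)
    cv2 = genewise_cv(matrix, group2)
    table = pd.DataFrame({f"cv_{group1}": cv1, f"cv_{group2}": cv2})
    ok = table.notna().all(axis=1)
    n_dropped = int((~ok).sum())
    t = table.loc[ok]

    x = t.iloc[:, 0].to_numpy()
    y = t.iloc[:, 1].to_numpy()
    if len(t) >= 2 and np.ptp(x) > 0:
        slope, intercept = np.polyfit(x, y, 1)
    else:
        slope, intercept = math.nan, math.nan

    hv1 = set(t.index[x > ratio_threshold * y])
    hv2 = set(t.index[y > ratio_threshold * x])
    return CVComparison(
        group1=group1,
        group2=group2,
        table=table,
        regression_slope=float(slope),
        regression_intercept=float(intercept),
        highvar_in_1=hv1,
        highvar_in_2=hv2,
        ratio_threshold=ratio_threshold,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Over-representation


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read a GMT file: term, description, then tab-separated gene ids."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def overrepresentation(
    query: set[str],
    universe: set[str],
    gene_sets: dict[str, set[str]],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation with BH-FDR.

    For each term the upper-tail probability of drawing at least the
    observed overlap when sampling ``len(query)`` genes from the universe
    is computed; terms with no gene in the universe are skipped. BH-FDR is
    applied across the tested terms. Results are sorted by p-value.
    """
    query = set(query)
    universe = set(universe)
    stray = query - universe
    if stray:
        raise ValidationError(
            f"query genes outside the universe: {sorted(stray)[:10]}"
        )
    n_universe = len(universe)
    n_query = len(query)
    results = []
    for term, genes in gene_sets.items():
        in_universe = genes & universe
        if not in_universe:
            continue
        k = len(in_universe & query)
        # P(X >= k), X ~ Hypergeom(N=universe, K=term, n=query)
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(in_universe), n_query))
        results.append(
            EnrichmentResult(
                term_id=term,
                term_size=len(in_universe),
                query_size=n_query,
                universe_size=n_universe,
                overlap=k,
                p_hypergeometric=min(1.0, p),
            )
        )
    if results:
        fdr = multipletests([r.p_hypergeometric for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(
                term_id=r.term_id,
                term_size=r.term_size,
                query_size=r.query_size,
                universe_size=r.universe_size,
                overlap=r.overlap,
                p_hypergeometric=r.p_hypergeometric,
                fdr_bh=float(q),
            )
            for r, q in zip(results, fdr)
        ]
    return sorted(results, key=lambda r: (r.p_hypergeometric, r.term_id))


# ---------------------------------------------------------------------------
# Differential stand-in


def differential_count(
    matrix: ExpressionMatrix,
    group1: str,
    group2: str,
    fdr_threshold: float = 0.01,
    pseudocount: float = 1.0,
) -> DifferentialResult:
    """Per-gene two-group Student t-test on log2(FPM + pseudocount).

    A deliberately simple differential-expression stand-in (the method is
    recorded in the result): per-gene pooled-variance t-test on the log
    scale, BH correction across genes, and up/down counts at the FDR
    threshold with the sign taken from the group-2 minus group-1 mean
    difference. Degenerate (zero-variance) genes follow the t-test's
    conventions.
    """
    s1 = matrix.group_samples(group1)
    s2 = matrix.group_samples(group2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValidationError("each group needs >= 2 samples")
    log1 = np.log2(matrix.values[s1].to_numpy() + pseudocount)
    log2_ = np.log2(matrix.values[s2].to_numpy() + pseudocount)
    pvals = np.empty(len(matrix.values))
    delta = log2_.mean(axis=1) - log1.mean(axis=1)
    for i in range(len(pvals)):
        pvals[i] = ttest_unpaired(log1[i], log2_[i]).p_value
    fdr = multipletests(pvals, method="fdr_bh")[1]
    direction = np.where(delta > 0, "up", np.where(delta < 0, "down", "none"))
    table = pd.DataFrame(
        {
            "delta_log2": delta,
            "p_value": pvals,
            "fdr_bh": fdr,
            "direction": direction,
        },
        index=matrix.values.index,
    )
    sig = table["fdr_bh"] < fdr_threshold
    n_up = int((sig & (table["direction"] == "up")).sum())
    n_down = int((sig & (table["direction"] == "down")).sum())
    return DifferentialResult(
        table=table,
        n_up=n_up,
        n_down=n_down,
        fdr_threshold=fdr_threshold,
        extra={"group1": group1, "group2": group2, "pseudocount": pseudocount},
    )


# ---------------------------------------------------------------------------
# IO


def read_expression(
    expression_tsv: str,
    metadata_tsv: str,
    library_sizes_tsv: str | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV (gene rows x sample columns) plus metadata.

    The metadata TSV needs columns ``sample_id`` and ``group``. When a
    library-size TSV (columns ``sample_id``, ``library_size``) is given,
    the matrix is treated as raw counts and FPM-normalised; otherwise the
    values are taken as already normalised.
    """
    values = pd.read_csv(expression_tsv, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_tsv, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ValidationError(f"{metadata_tsv}: missing column {col!r}")
    groups = dict(zip(meta["sample_id"], meta["group"]))
    if library_sizes_tsv is not None:
        libs = pd.read_csv(library_sizes_tsv, sep="\t")
        libs = pd.Series(
            libs["library_size"].to_numpy(), index=libs["sample_id"].astype(str)
        )
        return fpm_normalize(values, libs, groups)
    return ExpressionMatrix(values=values, sample_groups=groups)
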