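"""Count-matrix preparation, diversity measures and correlation analyses.

The cohort-analysis workflow on features × samples count matrices: collapse
repeated visits to one median value per individual, drop features without
sufficient support across individuals (at least 20 reads — or 10 spectra —
in 25% of individuals), then richness and Simpson's index of diversity,
Bray–Curtis dissimilarity, Mann–Whitney U group comparisons, and Spearman
correlation screens with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .formats import SampleMeta


@dataclass
class CountMatrix:
    """Non-negative features × samples counts of one kind (reads or spectra)."""

    data: pd.DataFrame  # index = features, columns = samples
    kind: str = "reads"  # "reads" | "spectra"

    def __post_init__(self) -> None:
        if self.kind not in ("reads", "spectra"):
            raise ValueError("kind must be 'reads' or 'spectra'")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.data.index.duplicated().any() or self.data.columns.duplicated().any():
            raise ValueError("feature and sample ids must be unique")

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns divided by their totals)."""
        totals = self.data.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.data / totals
        return rel


@dataclass(frozen=True, slots=True)
class FilterParams:
    """Prevalence filter: keep features with value >= min_count in at least
    min_fraction of individuals (reads: 20, spectra: 10; fraction 0.25)."""

    min_count: float = 20.0
    min_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.min_count <= 0:
            raise ValueError("min_count must be > 0")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")

    @classmethod
    def for_kind(cls, kind: str) -> "FilterParams":
        return cls(min_count=10.0 if kind == "spectra" else 20.0, min_fraction=0.25)


@dataclass(frozen=True, slots=True)
class CorrelationEdge:
    """One retained feature-pair correlation."""

    feature_a: str
    feature_b: str
    rho: float
    p_raw: float
    p_adjusted: float


class GroupCompareResult(NamedTuple):
    U: float
    p: float
    testable: bool


def prepare_feature_matrix(
    raw: CountMatrix,
    metadata: Sequence[SampleMeta] | Mapping[str, str],
    params: FilterParams | None = None,
) -> CountMatrix:
    """Collapse visits to per-individual medians and apply the prevalence
    filter.

    ``metadata`` maps sample columns to individuals (a sequence of
    :class:`SampleMeta` or a plain mapping).  The median over the available
    visits is taken per individual (mean of the two central values for an
    even number of visits); features with value >= ``min_count`` in fewer
    than ``min_fraction`` of all individuals are dropped.
    """
    params = params or FilterParams.for_kind(raw.kind)
    if isinstance(metadata, Mapping):
        sample_to_ind = dict(metadata)
    else:
        sample_to_ind = {s.sample_id: s.individual for s in metadata}
    missing = [c for c in raw.samples if c not in sample_to_ind]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    groups: dict[str, list[str]] = {}
    for col in raw.samples:
        groups.setdefault(sample_to_ind[col], []).append(col)
    for ind, cols in groups.items():
        if not cols:
            raise ValueError(f"individual {ind} has no visits")
    medians = pd.DataFrame(
        {ind: raw.data[cols].median(axis=1) for ind, cols in groups.items()}
    )
    n_ind = medians.shape[1]
    prevalence = (medians >= params.min_count).sum(axis=1) / n_ind
    kept = medians.loc[prevalence >= params.min_fraction]
    return CountMatrix(data=kept, kind=raw.kind)


def alpha_diversity(rel_abundance: pd.DataFrame, atol: float = 1e-8) -> pd.DataFrame:
    """Richness and Simpson's index of diversity per sample.

    Expects per-sample relative abundances (columns summing to 1).  Richness
    is the number of features with positive abundance; Simpson's index of
    diversity is D = 1 − Σ pᵢ².  All-zero samples are flagged undefined.
    """
    arr = rel_abundance.to_numpy(dtype=float)
    totals = arr.sum(axis=0)
    defined = totals > 0
    if np.any(np.abs(totals[defined] - 1.0) > atol):
        raise ValueError("abundances must be normalised to sum 1 per sample")
    richness = (arr > 0).sum(axis=0)
    simpson = 1.0 - (arr**2).sum(axis=0)
    return pd.DataFrame(
        {
            "richness": np.where(defined, richness, 0).astype(int),
            "simpson": np.where(defined, simpson, np.nan),
            "defined": defined,
        },
        index=rel_abundance.columns,
    )


def bray_curtis(matrix: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Sample × sample Bray–Curtis dissimilarity.

    d(u, v) = 1 − 2 Σ min(uᵢ, vᵢ) / (Σuᵢ + Σvᵢ).  Pairs of all-zero samples
    are undefined and reported as NaN; the diagonal is zero.
    """
    data = matrix.data if isinstance(matrix, CountMatrix) else matrix
    arr = data.to_numpy(dtype=float).T  # samples × features
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dm = squareform(pdist(arr, metric="braycurtis"))
    np.fill_diagonal(dm, 0.0)
    return pd.DataFrame(dm, index=data.columns, columns=data.columns)


def group_compare(values_a: Sequence[float], values_b: Sequence[float]) -> GroupCompareResult:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when both groups have at most 8
    observations, the tie-corrected normal approximation otherwise.  Groups
    with fewer than two observations are flagged not testable.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        return GroupCompareResult(U=float("nan"), p=float("nan"), testable=False)
    method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupCompareResult(U=float(res.statistic), p=float(res.pvalue), testable=True)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def spearman_bh(
    matrix_x: pd.DataFrame,
    matrix_y: pd.DataFrame,
    rho_min: float = 0.7,
    alpha: float = 0.001,
) -> tuple[list[CorrelationEdge], list[tuple[str, str, str]]]:
    """Spearman correlation screen between two feature sets with BH control.

    Correlates every feature of ``matrix_x`` with every feature of
    ``matrix_y`` over their shared sample columns (at least 4 required),
    adjusts the two-sided p-values over all tested pairs with
    Benjamini–Hochberg, and returns the edges with |rho| >= ``rho_min`` and
    adjusted p < ``alpha``.  Pairs involving a constant feature are excluded
    and reported in the second return value.
    """
    shared = [c for c in matrix_x.columns if c in set(matrix_y.columns)]
    if len(shared) < 4:
        raise ValueError("at least 4 shared samples are required")
    x = matrix_x[shared]
    y = matrix_y[shared]
    excluded: list[tuple[str, str, str]] = []
    tested: list[tuple[str, str, float, float]] = []
    const_x = {f for f in x.index if x.loc[f].nunique() <= 1}
    const_y = {f for f in y.index if y.loc[f].nunique() <= 1}
    for fa in x.index:
        for fb in y.index:
            if fa in const_x or fb in const_y:
                excluded.append((fa, fb, "constant feature"))
                continue
            rho, p = sps.spearmanr(x.loc[fa], y.loc[fb])
            tested.append((fa, fb, float(rho), float(p)))
    if not tested:
        return [], excluded
    adjusted = benjamini_hochberg([t[3] for t in tested])
    edges = [
        CorrelationEdge(feature_a=fa, feature_b=fb, rho=rho, p_raw=p, p_adjusted=float(padj))
        for (fa, fb, rho, p), padj in zip(tested, adjusted)
        if abs(rho) >= rho_min and padj < alpha
    ]
    return edges, excluded
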