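"""Co-expression grouping of candidate interactors across tissues.

Homologs of the co-precipitated proteins are compared on a tissue
expression compendium: Spearman rank correlation for every gene pair,
t-approximation significance tests, agglomerative clustering on the
correlation distance ``1 - rho`` (average linkage) cut into two groups,
and a reference-set vote that labels each candidate as co-expressed
with the secondary-cell-wall cellulose synthases, with the callose
synthase, with both, or with neither.

The t-approximation is adequate at the compendium's 64 tissues; a
seeded permutation p-value is provided for small panels.
"""

from __future__ import annotations

import dataclasses
import enum
import math
import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_model import ExpressionMatrix

__all__ = [
    "Significance",
    "CorrelationResult",
    "AssociationLabel",
    "spearman_rho",
    "correlation_pvalue",
    "permutation_pvalue",
    "correlate_pairs",
    "cluster_expression",
    "associate",
]


class Significance(str, enum.Enum):
    P01 = "p01"
    P05 = "p05"
    NONE = "none"


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    gene_a: str
    gene_b: str
    rho: Optional[float]  # None when either profile is constant
    p_value: Optional[float]
    significant_at: Significance


@dataclasses.dataclass(frozen=True)
class AssociationLabel:
    gene_id: str
    label: str  # cesa_associated | cals_associated | both | none
    supporting: tuple[tuple[str, float, float], ...]  # (reference gene, rho, p)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Spearman's rank correlation with average ranks for ties.

    Returns ``None`` when either vector is constant (the statistic is
    undefined); requires at least 3 paired observations.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return None
    return float(stats.spearmanr(xa, ya).statistic)


def correlation_pvalue(rho: float, n: int) -> float:
    """Two-sided p for a correlation via the t-transform on n-2 df."""
    if n < 4:
        raise ValueError("need n >= 4 tissues for the t-approximation")
    if abs(rho) > 1:
        raise ValueError("|rho| cannot exceed 1")
    if abs(rho) == 1:
        warnings.warn(
            "perfect correlation: p-value reported as 0 by convention",
            stacklevel=2,
        )
        return 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return 2 * float(stats.t.sf(abs(t), n - 2))


def permutation_pvalue(
    x: Sequence[float], y: Sequence[float], n_permutations: int = 999, seed: int = 0
) -> float:
    """Seeded two-sided permutation p-value for Spearman's rho.

    Uses the add-one estimator (observed arrangement counted once), for
    small tissue panels where the t-approximation is doubtful.
    """
    rho_obs = spearman_rho(x, y)
    if rho_obs is None:
        raise ValueError("rho undefined for constant input")
    rng = np.random.default_rng(seed)
    ya = np.asarray(y, dtype=float)
    hits = 0
    for _ in range(n_permutations):
        rho_perm = spearman_rho(x, rng.permutation(ya))
        if rho_perm is not None and abs(rho_perm) >= abs(rho_obs) - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def _significance(p: Optional[float]) -> Significance:
    if p is None:
        return Significance.NONE
    if p < 0.01:
        return Significance.P01
    if p < 0.05:
        return Significance.P05
    return Significance.NONE


def correlate_pairs(matrix: ExpressionMatrix) -> list[CorrelationResult]:
    """All unordered gene pairs with rho, p, and significance flags."""
    if matrix.n_tissues < 3:
        raise ValueError("need at least 3 tissues")
    results = []
    genes = sorted(matrix.gene_ids)
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            rho = spearman_rho(matrix.row(ga), matrix.row(gb))
            if rho is None:
                p = None
            else:
                p = correlation_pvalue(rho, matrix.n_tissues)
            results.append(CorrelationResult(ga, gb, rho, p, _significance(p)))
    return results


def cluster_expression(matrix: ExpressionMatrix, k: int = 2) -> dict[str, int]:
    """Cut an average-linkage tree on 1 - Spearman rho into ``k`` clusters.

    Genes are processed in lexicographic order so the result is
    deterministic for a given matrix regardless of row order; cluster
    labels are renumbered 1..k by first appearance in that order.
    """
    genes = sorted(matrix.gene_ids)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(genes):
        raise ValueError(f"k={k} exceeds the {len(genes)} genes available")
    data = np.vstack([matrix.row(g) for g in genes])
    for g, row in zip(genes, data):
        if np.ptp(row) == 0:
            raise ValueError(f"gene {g!r} is constant across tissues; rho undefined")
    if k == len(genes):
        return {g: i + 1 for i, g in enumerate(genes)}
    if len(genes) == 2:
        corr = np.array([[1.0, float(stats.spearmanr(data[0], data[1]).statistic)], [0.0, 1.0]])
        corr[1, 0] = corr[0, 1]
    else:
        corr = stats.spearmanr(data.T).statistic
    dist = 1.0 - np.asarray(corr)
    np.fill_diagonal(dist, 0.0)
    # tiny negative entries from float round-off
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for g, lab in zip(genes, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        out[g] = relabel[lab]
    return out


def associate(
    candidates: Iterable[str],
    cesa_refs: Iterable[str],
    cals_refs: Iterable[str],
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
) -> dict[str, AssociationLabel]:
    """Label candidates by significant positive correlation with reference sets.

    A candidate is ``cesa_associated`` when it shows rho > 0 with
    p < ``alpha`` against a majority of the cellulose-synthase reference
    genes, ``cals_associated`` likewise against the callose-synthase
    references, ``both``/``none`` accordingly.  A candidate appearing in
    a reference set does not vote for itself.
    """
    cesa_refs = sorted(set(cesa_refs))
    cals_refs = sorted(set(cals_refs))
    if not cesa_refs or not cals_refs:
        raise ValueError("reference sets must be non-empty")
    for ref in (*cesa_refs, *cals_refs):
        if ref not in matrix.gene_ids:
            raise KeyError(f"reference gene {ref!r} not in matrix")
    n = matrix.n_tissues
    out: dict[str, AssociationLabel] = {}
    for cand in sorted(set(candidates)):
        profile = matrix.row(cand)
        supporting: list[tuple[str, float, float]] = []

        def _votes(refs: list[str]) -> bool:
            used = [r for r in refs if r != cand]
            if not used:
                return False
            hits = 0
            for ref in used:
                rho = spearman_rho(profile, matrix.row(ref))
                if rho is None:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = correlation_pvalue(rho, n)
                if rho > 0 and p < alpha:
                    hits += 1
                    supporting.append((ref, rho, p))
            return hits > len(used) / 2

        cesa_hit = _votes(cesa_refs)
        cals_hit = _votes(cals_refs)
        if cesa_hit and cals_hit:
            label = "both"
        elif cesa_hit:
            label = "cesa_associated"
        elif cals_hit:
            label = "cals_associated"
        else:
            label = "none"
        out[cand] = AssociationLabel(cand, label, tuple(supporting))
    return out
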