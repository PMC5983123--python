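"""Positively co-expressed gene-pair screening.

Elevated expression of one ceRNA de-represses its partner by soaking up their
shared miRNAs, so genuine ceRNA pairs are positively co-expressed. The screen
therefore keeps pairs with Spearman rho > 0 whose Benjamini-Hochberg adjusted
p-value clears a threshold (default q <= 0.001). Spearman is used rather than
Pearson because tumor expression profiles are heavy-tailed and not normal.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterator, Literal

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .types import CorrelatedPair, ExpressionMatrix

__all__ = ["spearman", "bh_fdr", "candidate_pairs"]

_EXACT_MAX_N = 10


def spearman(
    x: np.ndarray,
    y: np.ndarray,
    method: Literal["t", "exact"] = "t",
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average (mid-)ranks. With ``method="t"`` the p-value is the
    usual t-approximation, t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of
    freedom; |rho| = 1 gives p = 0. With ``method="exact"`` the p-value is
    computed by full enumeration of the n! rank permutations (only permitted
    for n <= 10) as the fraction with |rho_perm| >= |rho_observed|.

    A constant input vector makes the correlation undefined; ``(nan, nan)``
    is returned so that batch callers can drop the pair rather than abort.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    if method == "t":
        res = stats.spearmanr(x, y)
        rho = float(res.statistic)
        if abs(rho) >= 1.0:
            return (math.copysign(1.0, rho), 0.0)
        return (rho, float(res.pvalue))
    if method == "exact":
        if n > _EXACT_MAX_N:
            raise ValueError(f"exact permutation p only supported for n <= {_EXACT_MAX_N}")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rho_obs = float(np.corrcoef(rx, ry)[0, 1])
        # Pearson correlation of ranks over every permutation of one margin
        rx_c = rx - rx.mean()
        count = 0
        total = 0
        denom_x = math.sqrt(float(rx_c @ rx_c))
        for perm in itertools.permutations(ry):
            ry_p = np.asarray(perm) - ry.mean()
            rho_p = float(rx_c @ ry_p) / (denom_x * math.sqrt(float(ry_p @ ry_p)))
            if abs(rho_p) >= abs(rho_obs) - 1e-12:
                count += 1
            total += 1
        return (rho_obs, count / total)
    raise ValueError(f"unknown method {method!r}")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Returns adjusted values in the same order as the input; each q is the
    minimum over j >= i (in sorted order) of p_(j)*m/j, clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return np.array([])
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _eligible_rows(genes: ExpressionMatrix) -> np.ndarray:
    """Boolean mask of genes that can enter the screen: expressed (at least
    one nonzero value) and non-constant across samples (constant rows make
    rank correlation undefined)."""
    v = genes.values
    nonzero = (v != 0).any(axis=1)
    nonconstant = np.ptp(v, axis=1) > 0
    return nonzero & nonconstant


def _pairwise_spearman(
    values: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided t-approximation p for the rows of
    ``values``. Returns (rho_matrix, p_matrix)."""
    ranks = stats.rankdata(values, axis=1)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    n = values.shape[1]
    r = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return rho, p


def _iter_candidate_index_pairs(
    n: int, goi_idx: int | None
) -> Iterator[tuple[int, int]]:
    if goi_idx is None:
        yield from itertools.combinations(range(n), 2)
    else:
        for j in range(n):
            if j != goi_idx:
                yield (min(goi_idx, j), max(goi_idx, j))


def candidate_pairs(
    genes: ExpressionMatrix,
    q_threshold: float = 0.001,
    goi: str | None = None,
) -> list[CorrelatedPair]:
    """Screen for probable ceRNA pairs: positively correlated genes surviving
    FDR control.

    The FDR family is the set of positively correlated pairs only
    (rho > 0); negatively correlated pairs are discarded before correction
    since the ceRNA mechanism predicts positive co-expression. With ``goi``
    set, only pairs containing that gene are computed and the correction
    family is that gene's positive pairs (per-GOI mode); otherwise every
    gene pair enters (genome-wide mode).

    Emitted pairs satisfy rho > 0 and q <= ``q_threshold``, are oriented
    canonically (``gene_a < gene_b``), and are sorted by (gene_a, gene_b).
    Genes that are unexpressed or constant across samples are excluded.
    """
    if genes.n_samples < 3:
        raise DataError(f"need at least 3 samples for correlation, got {genes.n_samples}")
    if len(genes) < 2:
        raise DataError("need at least 2 genes")
    if not (0 < q_threshold <= 1):
        raise ValueError(f"q_threshold must be in (0, 1], got {q_threshold}")

    ids = np.asarray(genes.entity_ids)
    mask = _eligible_rows(genes)
    if goi is not None:
        if goi not in genes:
            raise DataError(f"gene of interest {goi!r} not in the gene expression matrix")
        if not mask[list(ids).index(goi)]:
            raise DataError(
                f"gene of interest {goi!r} is constant or unexpressed across samples"
            )
    values = genes.values[mask]
    kept_ids = ids[mask]
    if values.shape[0] < 2:
        return []
    goi_idx = list(kept_ids).index(goi) if goi is not None else None

    rho_mat, p_mat = _pairwise_spearman(values)

    pos: list[tuple[int, int, float, float]] = []
    for i, j in _iter_candidate_index_pairs(values.shape[0], goi_idx):
        rho = rho_mat[i, j]
        if np.isnan(rho) or rho <= 0:
            continue
        pos.append((i, j, float(rho), float(p_mat[i, j])))
    if not pos:
        return []

    q = bh_fdr([p for _i, _j, _rho, p in pos])
    out = []
    for (i, j, rho, p), qv in zip(pos, q):
        if qv <= q_threshold:
            a, b = sorted((str(kept_ids[i]), str(kept_ids[j])))
            out.append(CorrelatedPair(gene_a=a, gene_b=b, rho=rho, p_value=p, q_value=float(qv)))
    out.sort(key=lambda pr: (pr.gene_a, pr.gene_b))
    return out
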