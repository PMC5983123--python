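"""Seeded synthetic fixtures with known ground-truth structure.

The generator emulates the statistical shape of the three inputs the scorer
consumes: a gene expression matrix with planted blocks of rank-correlated
genes (Gaussian copula over lognormal marginals), an independent lognormal
miRNA matrix, and a miRanda/mirSVR-style MRE table with negative free
energies, bounded conservation, miRanda-scale alignment scores and
categorical seed types. It does not simulate read counts, library-size
normalization or tumor heterogeneity.

Rank correlation inside a planted block is controlled exactly: a target
Spearman rho_s is converted to the latent Pearson correlation
r = 2*sin(pi*rho_s/6), and the block's latent normals are built by the
equicorrelation construction sqrt(r)*shared + sqrt(1-r)*idiosyncratic,
which degenerates cleanly to co-monotone rows at rho_s = 1. The monotone
lognormal marginal transform preserves ranks, so the copula's rank
correlation carries through unchanged.

All randomness flows from ``SimulationConfig.seed`` through
``numpy.random.default_rng``; expression and target-site generation use the
child streams ``SeedSequence([seed, 0])`` and ``SeedSequence([seed, 1])`` so
the two can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .types import (
    ExpressionMatrix,
    SeedType,
    SeedWeightConfig,
    TargetSite,
    SEED_ORDER,
)

__all__ = [
    "SimulationConfig",
    "simulate_expression",
    "simulate_target_sites",
    "ground_truth_scores",
]

_ORACLE_MAX = 10


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic instance.

    ``planted_blocks`` lists (gene index set, target Spearman rho in (0, 1])
    pairs; genes outside any block are independent. ``expression_scale`` is
    the (mu, sigma) of the lognormal marginal in natural-log space — the
    defaults put the median around 4.5 with a heavy right tail, the shape of
    RPKM/RSEM abundance distributions. ``mre_rate`` is the expected number
    of background MREs per (gene, miRNA) combination (Poisson).
    ``energy_range`` (kcal/mol-like, nonpositive), ``conservation_range``
    and ``alignment_range`` bound the uniform feature draws;
    ``seed_type_probs`` orders as (8mer, 7mer-m8, 7mer-A1, 6mer), weaker
    seed matches being the more frequent as in genome-wide site scans.
    """

    n_genes: int = 20
    n_mirnas: int = 10
    n_samples: int = 100
    planted_blocks: tuple[tuple[tuple[int, ...], float], ...] = ()
    mre_rate: float = 0.5
    seed: int = 0
    expression_scale: tuple[float, float] = (1.5, 1.0)
    energy_range: tuple[float, float] = (-30.0, -5.0)
    conservation_range: tuple[float, float] = (0.0, 1.0)
    alignment_range: tuple[float, float] = (120.0, 200.0)
    seed_type_probs: tuple[float, float, float, float] = (0.15, 0.25, 0.25, 0.35)

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_mirnas < 1 or self.n_samples < 3:
            raise ValueError("need n_genes >= 2, n_mirnas >= 1, n_samples >= 3")
        if self.mre_rate < 0:
            raise ValueError("mre_rate must be >= 0")
        if abs(sum(self.seed_type_probs) - 1.0) > 1e-12:
            raise ValueError("seed_type_probs must sum to 1")
        lo, hi = self.energy_range
        if not (lo <= hi <= 0):
            raise ValueError("energy_range must satisfy lo <= hi <= 0")
        for name in ("conservation_range", "alignment_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi")
        for genes, rho in self.planted_blocks:
            if not (0 < rho <= 1):
                raise ValueError(f"block rho must be in (0, 1], got {rho}")
            if len(genes) < 2:
                raise ValueError("a planted block needs at least 2 genes")
            if any(g < 0 or g >= self.n_genes for g in genes):
                raise ValueError(f"block gene index out of range: {genes}")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def mirna_ids(self) -> list[str]:
        return [f"miR-{i + 1}" for i in range(self.n_mirnas)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]


def _spearman_to_latent_pearson(rho_s: float) -> float:
    """Latent-normal Pearson correlation that yields Spearman rho_s after
    any monotone marginal transform."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Draw the gene and miRNA expression matrices.

    Gene rows inside a planted block have pairwise Spearman correlation at
    the block's target rho; all other rows (and all miRNA rows) are
    independent. Marginals are lognormal, so every value is positive and
    RPKM-like in shape. Deterministic under a fixed config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    mu, sigma = config.expression_scale

    latent = rng.standard_normal((config.n_genes, config.n_samples))
    for genes, rho_s in config.planted_blocks:
        r = _spearman_to_latent_pearson(rho_s)
        shared = rng.standard_normal(config.n_samples)
        for g in genes:
            own = rng.standard_normal(config.n_samples)
            latent[g] = math.sqrt(r) * shared + math.sqrt(1.0 - r) * own
    gene_values = np.exp(mu + sigma * latent)

    mirna_values = np.exp(
        mu + sigma * rng.standard_normal((config.n_mirnas, config.n_samples))
    )

    genes = ExpressionMatrix(
        pd.DataFrame(gene_values, index=config.gene_ids, columns=config.sample_ids)
    )
    mirnas = ExpressionMatrix(
        pd.DataFrame(mirna_values, index=config.mirna_ids, columns=config.sample_ids)
    )
    return genes, mirnas


def _draw_site(rng: np.random.Generator, config: SimulationConfig, gene: str, mirna: str) -> TargetSite:
    c_lo, c_hi = config.conservation_range
    e_lo, e_hi = config.energy_range
    a_lo, a_hi = config.alignment_range
    seed_type = SEED_ORDER[rng.choice(4, p=np.asarray(config.seed_type_probs))]
    return TargetSite(
        mirna_id=mirna,
        gene_id=gene,
        conservation=float(rng.uniform(c_lo, c_hi)),
        energy=float(rng.uniform(e_lo, e_hi)),
        alignment_score=float(rng.uniform(a_lo, a_hi)),
        seed_type=seed_type,
    )


def simulate_target_sites(
    config: SimulationConfig,
    shared_pairs: Sequence[tuple[str, str, Iterable[str]]] = (),
) -> list[TargetSite]:
    """Draw an MRE table.

    Background sites are Poisson(``mre_rate``) per (gene, miRNA)
    combination. Each entry of ``shared_pairs`` — (gene_a, gene_b, miRNAs) —
    guarantees at least one MRE for every listed miRNA on *both* genes, so
    tests can plant pairs with a known shared pool. Deterministic under a
    fixed config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gene_ids = config.gene_ids
    mirna_ids = config.mirna_ids
    sites: list[TargetSite] = []
    if config.mre_rate > 0:
        counts = rng.poisson(config.mre_rate, size=(len(gene_ids), len(mirna_ids)))
        for gi, gene in enumerate(gene_ids):
            for mi, mirna in enumerate(mirna_ids):
                for _ in range(counts[gi, mi]):
                    sites.append(_draw_site(rng, config, gene, mirna))
    covered = {(s.gene_id, s.mirna_id) for s in sites}
    for gene_a, gene_b, mirnas in shared_pairs:
        for mirna in mirnas:
            for gene in (gene_a, gene_b):
                if (gene, mirna) not in covered:
                    sites.append(_draw_site(rng, config, gene, mirna))
                    covered.add((gene, mirna))
    return sites


def ground_truth_scores(
    genes: ExpressionMatrix,
    mirnas: ExpressionMatrix,
    sites: Sequence[TargetSite],
    weights: SeedWeightConfig | None = None,
) -> dict[tuple[str, str], float]:
    """Brute-force reference for the non-normalized tug-of-war score.

    Evaluates the score for every ordered gene pair by literal nested loops
    over miRNAs and MREs, with no shared code or data structures with the
    scoring module. Deliberately naive and restricted to tiny instances
    (<= 10 genes, <= 10 miRNAs) — it exists to check the scorer, not to be
    fast.
    """
    if len(genes) > _ORACLE_MAX or len(mirnas) > _ORACLE_MAX:
        raise DataError(
            f"oracle limited to <= {_ORACLE_MAX} genes and miRNAs; "
            f"got {len(genes)} genes, {len(mirnas)} miRNAs"
        )
    weights = weights or SeedWeightConfig()
    gene_ids = genes.entity_ids
    mirna_ids = mirnas.entity_ids
    e_gene = {g: float(np.mean(genes.data.loc[g].to_numpy())) for g in gene_ids}
    e_mirna = {m: float(np.mean(mirnas.data.loc[m].to_numpy())) for m in mirna_ids}

    scores: dict[tuple[str, str], float] = {}
    for goi in gene_ids:
        for pcc in gene_ids:
            if goi == pcc:
                continue
            total = 0.0
            for mirna in mirna_ids:
                sum_b_goi = 0.0
                sum_b_pcc = 0.0
                n_mre_goi = 0
                n_mre_pcc = 0
                for site in sites:
                    if site.mirna_id != mirna:
                        continue
                    b = (
                        site.conservation
                        * abs(site.energy)
                        * site.alignment_score
                        * weights.weight(site.seed_type)
                    )
                    if site.gene_id == goi:
                        sum_b_goi += b
                        n_mre_goi += 1
                    elif site.gene_id == pcc:
                        sum_b_pcc += b
                        n_mre_pcc += 1
                if n_mre_goi == 0 or n_mre_pcc == 0:
                    continue  # not a shared miRNA of this pair
                numer = e_gene[pcc] * sum_b_pcc - e_gene[goi] * sum_b_goi
                denom = e_gene[pcc] * sum_b_pcc + e_gene[goi] * sum_b_goi
                if denom > 0:
                    total += e_mirna[mirna] * numer / denom
            scores[(goi, pcc)] = total
    return scores
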