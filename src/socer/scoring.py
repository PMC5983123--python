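"""The miRNA-mediated tug-of-war score.

Two genes sharing a miRNA pool compete for it: each MRE pulls free miRNA
toward its transcript with a binding affinity

    b = c * |e| * a * s

(conservation, binding free energy magnitude, alignment score, seed-type
weight — a multiplicative combination so proportional changes in any feature
change the affinity proportionally). For one shared miRNA the pull of a gene
is its binding mass M = E_gene * sum of its per-MRE affinities for that
miRNA, where E_gene is the gene's mean abundance across samples. At the
steady state the miRNA pool E_miRNA splits between the pair in proportion to
the masses, and the signed excess captured by the candidate is

    term(miRNA) = E_miRNA * (M_pcc - M_goi) / (M_pcc + M_goi).

The non-normalized score is the sum of these terms over the pair's shared
miRNAs; it is antisymmetric under swapping the two genes and exactly zero
for a pair with no shared pool. Per gene of interest, scores are normalized
by the largest absolute raw score so the reported score lies in [-1, +1]:
-1/+1 means the GOI/candidate dominates the tug-of-war, values near zero
mean the pair pulls with similar strength (ceRNA dependency).

Relative and total binding affinities (``relative_binding_affinity``,
``total_binding_affinity``) are exposed as standalone diagnostics of the
per-MRE competition; the score itself is the mass-ratio form above.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from typing import Iterable, Literal, Mapping

from .errors import DataError
from .types import ScorePair, SeedWeightConfig, TargetSite, Dominance

_log = logging.getLogger(__name__)

__all__ = [
    "binding_affinity",
    "relative_binding_affinity",
    "total_binding_affinity",
    "per_mirna_term",
    "AffinityTable",
    "socer_raw",
    "normalize_scores",
    "classify_dominance",
    "apply_socer_band",
    "rank_pccs",
    "score_goi",
    "DEFAULT_BAND",
]

#: Recommended |score| acceptance band, derived from the span of validated
#: ceRNA pairs; pairs outside it are unlikely to be biologically meaningful.
DEFAULT_BAND: tuple[float, float] = (0.00403, 0.88367)


def binding_affinity(site: TargetSite, weights: SeedWeightConfig | None = None) -> float:
    """Binding affinity b = c * |e| * a * s of a single MRE.

    The free energy enters by magnitude: a more negative duplex energy is a
    stronger bond and must raise, not lower, the affinity. The result is
    nonnegative and zero iff any factor is zero.
    """
    weights = weights or SeedWeightConfig()
    return site.conservation * abs(site.energy) * site.alignment_score * weights.weight(site.seed_type)


def relative_binding_affinity(b_pcc: float, b_goi: float, z: float = 2.0) -> float:
    """Relative binding affinity of a candidate's MRE against the GOI's:
    b_pcc * z / (b_goi + b_pcc).

    The coefficient z = 2 is fixed by self-consistency: a gene pitted against
    itself must have relative affinity exactly 1. Rescaling to a relative
    quantity removes the bias of the raw features' different scales.
    """
    if b_pcc < 0 or b_goi < 0:
        raise ValueError("binding affinities must be nonnegative")
    denom = b_goi + b_pcc
    if denom == 0:
        raise DataError("relative binding affinity undefined: both affinities are zero")
    return b_pcc * z / denom


def total_binding_affinity(
    pcc_sites: Iterable[TargetSite],
    goi_aggregate_b: Mapping[str, float],
    e_pcc: float,
    weights: SeedWeightConfig | None = None,
    z: float = 2.0,
) -> float:
    """Total binding affinity (TBA) of a candidate with respect to a GOI.

    Sum over the candidate's MREs of E_pcc times the MRE's relative binding
    affinity against the GOI's aggregate affinity for the same miRNA
    (``goi_aggregate_b``, the GOI's per-MRE affinities summed per miRNA —
    per-MRE pairing between the two genes is not defined). MREs whose miRNA
    the GOI does not bind at all get b_goi = 0; an MRE where both sides are
    zero is skipped.
    """
    if e_pcc < 0:
        raise ValueError("expression must be nonnegative")
    weights = weights or SeedWeightConfig()
    total = 0.0
    for site in pcc_sites:
        b = binding_affinity(site, weights)
        b_goi = goi_aggregate_b.get(site.mirna_id, 0.0)
        if b + b_goi == 0:
            continue
        total += e_pcc * relative_binding_affinity(b, b_goi, z)
    return total


def per_mirna_term(m_pcc: float, m_goi: float, e_mirna: float) -> float:
    """Signed share of one miRNA's pool captured by the candidate:
    E_miRNA * (M_pcc - M_goi) / (M_pcc + M_goi).

    M is a gene's binding mass for the miRNA (mean expression times summed
    MRE affinity). If neither gene has any mass the miRNA pulls on nothing
    and the term is 0.
    """
    if m_pcc < 0 or m_goi < 0 or e_mirna < 0:
        raise ValueError("masses and expression must be nonnegative")
    denom = m_pcc + m_goi
    if denom == 0:
        return 0.0
    return e_mirna * (m_pcc - m_goi) / denom


class AffinityTable:
    """Aggregated per-(gene, miRNA) binding affinities and masses.

    Built once from the MRE list, the seed weights and the genes' mean
    expressions; queried by the scorer for every pair.
    """

    def __init__(
        self,
        aggregate_b: Mapping[tuple[str, str], float],
        per_mre_b: Mapping[tuple[str, str], list[float]],
        gene_expr: Mapping[str, float],
    ):
        self._aggregate_b = dict(aggregate_b)
        self._per_mre_b = {k: list(v) for k, v in per_mre_b.items()}
        self._gene_expr = dict(gene_expr)
        self._mirnas_of: dict[str, set[str]] = defaultdict(set)
        for gene, mirna in self._aggregate_b:
            self._mirnas_of[gene].add(mirna)

    @classmethod
    def from_sites(
        cls,
        sites: Iterable[TargetSite],
        gene_expr: Mapping[str, float],
        weights: SeedWeightConfig | None = None,
    ) -> "AffinityTable":
        """Aggregate a flat MRE list: b summed per (gene, miRNA), masses
        weighted by each gene's mean expression. Genes in the site table but
        absent from ``gene_expr`` get expression 0 (present but silent)."""
        weights = weights or SeedWeightConfig()
        aggregate: dict[tuple[str, str], float] = defaultdict(float)
        per_mre: dict[tuple[str, str], list[float]] = defaultdict(list)
        for site in sites:
            b = binding_affinity(site, weights)
            key = (site.gene_id, site.mirna_id)
            aggregate[key] += b
            per_mre[key].append(b)
        return cls(aggregate, per_mre, gene_expr)

    @property
    def genes(self) -> set[str]:
        return set(self._mirnas_of)

    def __contains__(self, gene: str) -> bool:
        return gene in self._mirnas_of

    def mirnas_of(self, gene: str) -> set[str]:
        """miRNAs with at least one MRE on ``gene``."""
        return set(self._mirnas_of.get(gene, set()))

    def aggregate_b(self, gene: str, mirna: str) -> float:
        """Summed per-MRE affinity of ``gene`` for ``mirna`` (0 if no MRE)."""
        return self._aggregate_b.get((gene, mirna), 0.0)

    def per_mre_b(self, gene: str, mirna: str) -> list[float]:
        return list(self._per_mre_b.get((gene, mirna), []))

    def expression(self, gene: str) -> float:
        return self._gene_expr.get(gene, 0.0)

    def mass(self, gene: str, mirna: str) -> float:
        """Binding mass M = E_gene * aggregate b; 0 iff either factor is 0."""
        return self.expression(gene) * self.aggregate_b(gene, mirna)


def socer_raw(
    goi: str,
    pcc: str,
    affinities: AffinityTable,
    mirna_expr: Mapping[str, float],
    pool: Literal["shared", "union"] = "shared",
) -> ScorePair:
    """Non-normalized tug-of-war score of a (GOI, candidate) pair.

    The competed pool is the set of miRNAs with at least one MRE on *both*
    genes (``pool="shared"``, the default: a miRNA binding only one gene is
    not competed for) intersected with the miRNAs present in the expression
    map; ``pool="union"`` instead includes miRNAs binding either gene, in
    which case a one-sided miRNA contributes its full expression to the side
    that binds it. miRNAs absent from ``mirna_expr`` are skipped.

    Raises ``DataError`` if either gene has no MRE at all in the table — a
    gene missing from the target-site data cannot be scored, as opposed to
    scoring zero.
    """
    for gene in (goi, pcc):
        if gene not in affinities:
            raise DataError(f"gene {gene!r} has no target sites in the MRE table")
    mi_goi = affinities.mirnas_of(goi)
    mi_pcc = affinities.mirnas_of(pcc)
    if pool == "shared":
        competed = mi_goi & mi_pcc
    elif pool == "union":
        competed = mi_goi | mi_pcc
    else:
        raise ValueError(f"pool must be 'shared' or 'union', got {pool!r}")
    unmeasured = competed - set(mirna_expr)
    if unmeasured:
        _log.warning(
            "pair (%s, %s): %d competed miRNA(s) absent from the miRNA "
            "expression matrix and skipped: %s",
            goi, pcc, len(unmeasured), ", ".join(sorted(unmeasured)[:5]),
        )
    competed -= unmeasured

    terms: dict[str, float] = {}
    for mirna in sorted(competed):
        m_goi = affinities.mass(goi, mirna)
        m_pcc = affinities.mass(pcc, mirna)
        terms[mirna] = per_mirna_term(m_pcc, m_goi, float(mirna_expr[mirna]))
    return ScorePair(
        goi=goi,
        pcc=pcc,
        shared_mirnas=tuple(sorted(competed)),
        per_mirna_terms=terms,
        raw_score=math.fsum(terms.values()),
    )


def normalize_scores(pairs: list[ScorePair]) -> list[ScorePair]:
    """Normalize one GOI's raw scores into [-1, +1] by the largest absolute
    raw score among its candidates; if every raw score is zero, all
    normalized scores are zero. The pairs must share a GOI."""
    if not pairs:
        raise ValueError("cannot normalize an empty score list")
    gois = {p.goi for p in pairs}
    if len(gois) > 1:
        raise ValueError(f"normalization is per-GOI; got multiple GOIs {sorted(gois)}")
    scale = max(abs(p.raw_score) for p in pairs)
    for p in pairs:
        p.norm_score = p.raw_score / scale if scale > 0 else 0.0
    return pairs


def classify_dominance(norm_score: float, dominance_cutoff: float = 0.5) -> Dominance:
    """Read a normalized score's magnitude: |s| >= cutoff → one gene
    dominates the pool; 0 < |s| < cutoff → dependent (comparable pulls);
    exactly 0 → no ceRNA activity."""
    if abs(norm_score) > 1 + 1e-12:
        raise ValueError(f"|norm_score| must be <= 1, got {norm_score}")
    if not (0 < dominance_cutoff <= 1):
        raise ValueError(f"dominance_cutoff must be in (0, 1], got {dominance_cutoff}")
    if norm_score == 0:
        return Dominance.NONE
    if abs(norm_score) >= dominance_cutoff:
        return Dominance.DOMINANT
    return Dominance.DEPENDENT


def apply_socer_band(
    pairs: list[ScorePair],
    lo: float = DEFAULT_BAND[0],
    hi: float = DEFAULT_BAND[1],
) -> list[ScorePair]:
    """Keep pairs whose |normalized score| lies within [lo, hi].

    The default band spans the absolute scores of experimentally validated
    ceRNA pairs; scores below it indicate negligible competition and scores
    above it exceed anything validated.
    """
    if lo > hi:
        raise ValueError(f"band lower bound {lo} exceeds upper bound {hi}")
    for p in pairs:
        if p.norm_score is None:
            raise ValueError("normalize_scores must run before the band filter")
    return [p for p in pairs if lo <= abs(p.norm_score) <= hi]


def rank_pccs(
    pairs: list[ScorePair],
    direction: Literal["ascending", "descending"] = "descending",
) -> list[ScorePair]:
    """Order one GOI's candidates by normalized score.

    Ties break by shared-miRNA count (more first), then candidate name.
    Descending order puts the strongest competitors of the GOI first;
    ascending puts the genes the GOI dominates first.
    """
    if direction not in ("ascending", "descending"):
        raise ValueError(f"direction must be 'ascending' or 'descending', got {direction!r}")
    gois = {p.goi for p in pairs}
    if len(gois) > 1:
        raise ValueError(f"ranking is per-GOI; got multiple GOIs {sorted(gois)}")
    for p in pairs:
        if p.norm_score is None:
            raise ValueError("normalize_scores must run before ranking")
    sign = 1.0 if direction == "ascending" else -1.0
    return sorted(pairs, key=lambda p: (sign * p.norm_score, -p.n_shared_mirna, p.pcc))


def score_goi(
    goi: str,
    pccs: Iterable[str],
    affinities: AffinityTable,
    mirna_expr: Mapping[str, float],
    pool: Literal["shared", "union"] = "shared",
) -> list[ScorePair]:
    """Score and normalize every candidate of one GOI in a single call."""
    pairs = [socer_raw(goi, p, affinities, mirna_expr, pool=pool) for p in pccs]
    if not pairs:
        return []
    return normalize_scores(pairs)
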