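"""Shared domain types.

The vocabulary follows the ceRNA literature: a *GOI* (gene of interest) is the
query gene, a *PCC* (probable ceRNA candidate) is a gene positively
co-expressed with it, and an *MRE* (miRNA response element) is a single miRNA
binding site on a transcript.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "SeedType",
    "Dominance",
    "SeedWeightConfig",
    "TargetSite",
    "ExpressionMatrix",
    "CorrelatedPair",
    "ScorePair",
    "SoCeRRecord",
]


class SeedType(str, enum.Enum):
    """Category of miRNA 5'-seed pairing, ordered by repression efficacy."""

    MER8 = "8mer"
    MER7_M8 = "7mer-m8"
    MER7_A1 = "7mer-A1"
    MER6 = "6mer"

    @classmethod
    def parse(cls, label: str) -> "SeedType":
        try:
            return cls(label)
        except ValueError:
            valid = ", ".join(s.value for s in cls)
            raise FormatError(
                f"unknown seed type {label!r}; expected one of: {valid}"
            ) from None


#: Seed types from strongest to weakest repression.
SEED_ORDER: tuple[SeedType, ...] = (
    SeedType.MER8,
    SeedType.MER7_M8,
    SeedType.MER7_A1,
    SeedType.MER6,
)


class Dominance(str, enum.Enum):
    """Qualitative reading of a normalized score's magnitude.

    ``dominant``: one gene of the pair clearly out-sequesters the other
    (|score| near unity). ``dependent``: the two genes pull with comparable
    strength (|score| near zero but nonzero). ``none``: no ceRNA activity
    (score exactly zero, e.g. no shared miRNA pool).
    """

    DOMINANT = "dominant"
    DEPENDENT = "dependent"
    NONE = "none"


@dataclass(frozen=True)
class SeedWeightConfig:
    """Weights ``s`` assigned to each seed-match category in the binding
    affinity product b = c * |e| * a * s.

    Site-level repression efficacy decreases 8mer > 7mer-m8 > 7mer-A1 > 6mer;
    the weights must respect that ordering. The defaults are an evenly spaced
    convention of this package — the weights are a free parameter of the
    model and can be overridden wholesale.
    """

    weight_8mer: float = 1.0
    weight_7mer_m8: float = 0.75
    weight_7mer_a1: float = 0.5
    weight_6mer: float = 0.25

    def __post_init__(self) -> None:
        w = (self.weight_8mer, self.weight_7mer_m8, self.weight_7mer_a1, self.weight_6mer)
        if any(not (x > 0 and math.isfinite(x)) for x in w):
            raise ValueError(f"seed weights must be finite and > 0, got {w}")
        if not (w[0] >= w[1] >= w[2] >= w[3]):
            raise ValueError(
                "seed weights must satisfy 8mer >= 7mer-m8 >= 7mer-A1 >= 6mer, "
                f"got {w}"
            )

    def weight(self, seed_type: SeedType) -> float:
        return {
            SeedType.MER8: self.weight_8mer,
            SeedType.MER7_M8: self.weight_7mer_m8,
            SeedType.MER7_A1: self.weight_7mer_a1,
            SeedType.MER6: self.weight_6mer,
        }[SeedType(seed_type)]

    def as_dict(self) -> dict[str, float]:
        return {s.value: self.weight(s) for s in SEED_ORDER}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "SeedWeightConfig":
        return cls(
            weight_8mer=float(d["8mer"]),
            weight_7mer_m8=float(d["7mer-m8"]),
            weight_7mer_a1=float(d["7mer-A1"]),
            weight_6mer=float(d["6mer"]),
        )


@dataclass(frozen=True)
class TargetSite:
    """One miRNA response element: a single predicted binding site of a
    mature miRNA on a gene's transcript, with the duplex features that enter
    the binding-affinity product.

    ``energy`` is a hybridization free energy in the miRanda/mirSVR
    convention: nonpositive, more negative = stronger duplex.
    """

    mirna_id: str
    gene_id: str
    conservation: float
    energy: float
    alignment_score: float
    seed_type: SeedType

    def __post_init__(self) -> None:
        object.__setattr__(self, "seed_type", SeedType(self.seed_type))
        if not (self.conservation >= 0):
            raise FormatError(
                f"conservation must be >= 0, got {self.conservation} "
                f"({self.mirna_id}/{self.gene_id})"
            )
        if not (self.energy <= 0):
            raise FormatError(
                f"binding energy must be <= 0 (free-energy convention), got "
                f"{self.energy} ({self.mirna_id}/{self.gene_id})"
            )
        if not (self.alignment_score >= 0):
            raise FormatError(
                f"alignment score must be >= 0, got {self.alignment_score} "
                f"({self.mirna_id}/{self.gene_id})"
            )


class ExpressionMatrix:
    """Entity-by-sample nonnegative abundance table (RPKM/RSEM-like scale).

    Thin wrapper over a :class:`pandas.DataFrame` (rows = genes or mature
    miRNAs, columns = samples) that enforces the loader invariants once so
    downstream code can rely on them: no missing cells, no negative values,
    unique entity and sample identifiers, at least one entity and sample.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] == 0 or data.shape[1] == 0:
            raise FormatError("expression matrix is empty")
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate entity IDs: {dupes[:5]}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dupes[:5]}")
        values = data.to_numpy(dtype=float, copy=False)
        if np.isnan(values).any():
            raise FormatError("expression matrix contains missing values")
        if not np.isfinite(values).all():
            raise FormatError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise FormatError("expression values must be nonnegative")
        self._data = data.astype(float)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def entity_ids(self) -> list[str]:
        return [str(i) for i in self._data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self._data.columns]

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self._data.shape[1]

    def row_means(self) -> pd.Series:
        """Mean abundance of each entity across all samples (the E_gene /
        E_miRNA of the steady-state model)."""
        return self._data.mean(axis=1)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._data.index

    def __len__(self) -> int:
        return self._data.shape[0]

    def __repr__(self) -> str:
        return f"ExpressionMatrix({len(self)} entities x {self.n_samples} samples)"


@dataclass(frozen=True)
class CorrelatedPair:
    """A candidate co-expressed gene pair surviving the positivity and FDR
    filters. Canonical orientation: ``gene_a < gene_b`` lexicographically."""

    gene_a: str
    gene_b: str
    rho: float
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError(
                f"pair not in canonical order: {self.gene_a!r} >= {self.gene_b!r}"
            )


@dataclass
class ScorePair:
    """A directed (GOI, PCC) pair with its tug-of-war score.

    ``raw_score`` is the non-normalized score: the signed, miRNA-expression
    weighted imbalance of binding mass summed over the pair's shared miRNA
    pool. Positive means the PCC sequesters more of the pool; negative means
    the GOI does. ``norm_score`` is filled in by per-GOI normalization.
    """

    goi: str
    pcc: str
    shared_mirnas: tuple[str, ...]
    per_mirna_terms: dict[str, float]
    raw_score: float
    norm_score: float | None = None

    @property
    def n_shared_mirna(self) -> int:
        return len(self.shared_mirnas)


@dataclass
class SoCeRRecord:
    """One output row: the fully scored, normalized and classified pair."""

    goi: str
    pcc: str
    n_shared_mirna: int
    rho: float
    q_value: float
    raw_score: float
    norm_score: float
    dominance_class: Dominance
    per_mirna_terms: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dominance_class = Dominance(self.dominance_class)
        if abs(self.norm_score) > 1 + 1e-12:
            raise ValueError(f"|norm_score| > 1: {self.norm_score}")
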