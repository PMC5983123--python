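"""TSV readers and writers for the three inputs and the scored output.

Dialect: tab-separated, UTF-8, ``.`` decimal separator, no quoting. Gene and
miRNA identifiers are opaque strings — no miRBase parsing is attempted.
"""

from __future__ import annotations

import os
from typing import Iterable, Literal

import pandas as pd

from .errors import FormatError
from .types import (
    CorrelatedPair,
    Dominance,
    ExpressionMatrix,
    SeedType,
    SoCeRRecord,
    TargetSite,
)

__all__ = [
    "read_expression",
    "read_target_sites",
    "write_target_sites",
    "write_expression",
    "write_records",
    "read_records",
    "write_correlated_pairs",
    "read_correlated_pairs",
]

TARGET_SITE_COLUMNS = ("mirna", "gene", "conservation", "energy", "alignment_score", "seed_type")

RECORD_COLUMNS = (
    "goi",
    "pcc",
    "n_shared_mirna",
    "rho",
    "q_value",
    "raw_score",
    "norm_score",
    "dominance_class",
)

PAIR_COLUMNS = ("gene_a", "gene_b", "rho", "p_value", "q_value")

TERM_COLUMNS = ("goi", "pcc", "mirna", "term")


def _read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from None


def read_expression(
    path: str | os.PathLike, kind: Literal["gene", "mirna"] = "gene"
) -> ExpressionMatrix:
    """Load an entity-by-sample expression matrix from TSV.

    Expected layout: a header row of sample IDs, first column entity IDs
    (genes or mature miRNAs), remaining cells nonnegative normalized
    abundances (RPKM/RSEM scale). Duplicate entity rows, duplicate sample
    columns, missing cells and negative values are all rejected — never
    silently collapsed or imputed.

    Parameters
    ----------
    path : path to the TSV file
    kind : ``"gene"`` or ``"mirna"`` — only used for error messages
    """
    if kind not in ("gene", "mirna"):
        raise ValueError(f"kind must be 'gene' or 'mirna', got {kind!r}")
    # pandas silently mangles duplicate header names, so check the raw header
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate sample IDs in {kind} matrix header")
    df = _read_tsv(path, index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: {kind} matrix has no sample columns")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return ExpressionMatrix(df)
    except FormatError as exc:
        raise FormatError(f"{path} ({kind} matrix): {exc}") from None


def read_target_sites(path: str | os.PathLike) -> list[TargetSite]:
    """Load a miRanda/mirSVR-style target-site table.

    One row per MRE with columns ``mirna``, ``gene``, ``conservation``,
    ``energy`` (nonpositive free energy), ``alignment_score``, ``seed_type``
    (one of 8mer, 7mer-m8, 7mer-A1, 6mer). Multiple rows per (miRNA, gene)
    pair are expected — a transcript typically carries several MREs.
    """
    df = _read_tsv(path, dtype={"mirna": str, "gene": str, "seed_type": str})
    missing = set(TARGET_SITE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    sites: list[TargetSite] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            sites.append(
                TargetSite(
                    mirna_id=str(row.mirna),
                    gene_id=str(row.gene),
                    conservation=float(row.conservation),
                    energy=float(row.energy),
                    alignment_score=float(row.alignment_score),
                    seed_type=SeedType.parse(str(row.seed_type)),
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}, line {row_no}: {exc}") from None
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}, line {row_no}: {exc}") from None
    return sites


def write_target_sites(sites: Iterable[TargetSite], path: str | os.PathLike) -> None:
    """Write a target-site table in the same layout ``read_target_sites`` reads."""
    df = pd.DataFrame(
        [
            (s.mirna_id, s.gene_id, s.conservation, s.energy, s.alignment_score, s.seed_type.value)
            for s in sites
        ],
        columns=list(TARGET_SITE_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def write_expression(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write an expression matrix in the layout ``read_expression`` reads."""
    matrix.data.to_csv(path, sep="\t", index=True, index_label="id")


def write_records(
    records: Iterable[SoCeRRecord],
    path: str | os.PathLike,
    terms_path: str | os.PathLike | None = None,
) -> None:
    """Write scored pairs as TSV; optionally a companion per-miRNA term table.

    The companion table has one row per (GOI, PCC, shared miRNA) with the
    miRNA's signed contribution to the raw score, mirroring the per-miRNA
    breakdowns the method reports for individual pairs.

    Float columns use ``repr`` round-tripping, so a write → read cycle
    preserves every numeric field exactly.
    """
    records = list(records)
    df = pd.DataFrame(
        [
            (
                r.goi,
                r.pcc,
                r.n_shared_mirna,
                r.rho,
                r.q_value,
                r.raw_score,
                r.norm_score,
                r.dominance_class.value,
            )
            for r in records
        ],
        columns=list(RECORD_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)
    if terms_path is not None:
        terms = pd.DataFrame(
            [
                (r.goi, r.pcc, mirna, term)
                for r in records
                for mirna, term in sorted(r.per_mirna_terms.items())
            ],
            columns=list(TERM_COLUMNS),
        )
        terms.to_csv(terms_path, sep="\t", index=False)


def read_records(
    path: str | os.PathLike, terms_path: str | os.PathLike | None = None
) -> list[SoCeRRecord]:
    """Parse a scored-pair TSV written by ``write_records``."""
    df = _read_tsv(path, dtype={"goi": str, "pcc": str, "dominance_class": str})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    terms_by_pair: dict[tuple[str, str], dict[str, float]] = {}
    if terms_path is not None:
        tdf = _read_tsv(terms_path, dtype={"goi": str, "pcc": str, "mirna": str})
        for row in tdf.itertuples(index=False):
            terms_by_pair.setdefault((row.goi, row.pcc), {})[row.mirna] = float(row.term)
    out = []
    for row in df.itertuples(index=False):
        try:
            out.append(
                SoCeRRecord(
                    goi=row.goi,
                    pcc=row.pcc,
                    n_shared_mirna=int(row.n_shared_mirna),
                    rho=float(row.rho),
                    q_value=float(row.q_value),
                    raw_score=float(row.raw_score),
                    norm_score=float(row.norm_score),
                    dominance_class=Dominance(row.dominance_class),
                    per_mirna_terms=terms_by_pair.get((row.goi, row.pcc), {}),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from None
    return out


def write_correlated_pairs(pairs: Iterable[CorrelatedPair], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(p.gene_a, p.gene_b, p.rho, p.p_value, p.q_value) for p in pairs],
        columns=list(PAIR_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def read_correlated_pairs(path: str | os.PathLike) -> list[CorrelatedPair]:
    df = _read_tsv(path, dtype={"gene_a": str, "gene_b": str})
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        CorrelatedPair(
            gene_a=row.gene_a,
            gene_b=row.gene_b,
            rho=float(row.rho),
            p_value=float(row.p_value),
            q_value=float(row.q_value),
        )
        for row in df.itertuples(index=False)
    ]
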