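"""End-to-end orchestration: read → correlate → score → rank/filter → write.

Outputs are written atomically: all result files are produced in a temporary
directory next to the output directory and moved into place only once every
stage has succeeded, so a failed run never leaves partial results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml

from . import __version__
from .correlation import candidate_pairs
from .errors import DataError, SocerError
from .io import (
    read_expression,
    read_target_sites,
    write_correlated_pairs,
    write_records,
)
from .scoring import (
    DEFAULT_BAND,
    AffinityTable,
    apply_socer_band,
    classify_dominance,
    normalize_scores,
    rank_pccs,
    socer_raw,
)
from .types import Dominance, SeedWeightConfig, SoCeRRecord

_log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    ``fdr_mode``: ``genome_wide`` corrects the positive-pair p-values over
    all gene pairs; ``per_goi`` (requires ``goi``) restricts computation and
    the correction family to the GOI's pairs. ``mirna_pool_mode``: which
    miRNAs a pair competes for — ``shared`` (MREs on both genes) or
    ``union`` (MREs on either). ``socer_band`` filters scored pairs by
    |normalized score| when set.
    """

    gene_expression: str
    mirna_expression: str
    target_sites: str
    output_dir: str
    goi: str | None = None
    q_threshold: float = 0.001
    seed_weights: SeedWeightConfig = field(default_factory=SeedWeightConfig)
    z: float = 2.0
    socer_band: tuple[float, float] | None = None
    dominance_cutoff: float = 0.5
    fdr_mode: Literal["genome_wide", "per_goi"] = "genome_wide"
    mirna_pool_mode: Literal["shared", "union"] = "shared"
    rank_direction: Literal["ascending", "descending"] = "descending"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.q_threshold <= 1):
            raise ValueError(f"q_threshold must be in (0, 1], got {self.q_threshold}")
        if not (0 < self.dominance_cutoff <= 1):
            raise ValueError(f"dominance_cutoff must be in (0, 1], got {self.dominance_cutoff}")
        if self.fdr_mode not in ("genome_wide", "per_goi"):
            raise ValueError(f"invalid fdr_mode {self.fdr_mode!r}")
        if self.mirna_pool_mode not in ("shared", "union"):
            raise ValueError(f"invalid mirna_pool_mode {self.mirna_pool_mode!r}")
        if self.fdr_mode == "per_goi" and self.goi is None:
            raise ValueError("fdr_mode='per_goi' requires a goi")
        if self.socer_band is not None:
            lo, hi = self.socer_band
            if lo > hi:
                raise ValueError(f"socer_band lower bound {lo} exceeds upper bound {hi}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seed_weights"] = self.seed_weights.as_dict()
        d["socer_band"] = list(self.socer_band) if self.socer_band else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("seed_weights"), dict):
            d["seed_weights"] = SeedWeightConfig.from_dict(d["seed_weights"])
        if d.get("socer_band") is not None:
            d["socer_band"] = tuple(d["socer_band"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _score_pairs(config: RunConfig, pairs, affinities, mirna_means) -> list[SoCeRRecord]:
    """Score candidate pairs grouped per GOI and normalize within each group.

    With a GOI set, that gene anchors every pair. Otherwise each gene in turn
    is treated as the GOI of all its candidate pairs (both orientations are
    reported, since normalization — and hence the score — is GOI-relative).
    """
    pair_stats = {}
    partners: dict[str, list[str]] = {}
    for p in pairs:
        pair_stats[(p.gene_a, p.gene_b)] = (p.rho, p.q_value)
        pair_stats[(p.gene_b, p.gene_a)] = (p.rho, p.q_value)
        partners.setdefault(p.gene_a, []).append(p.gene_b)
        partners.setdefault(p.gene_b, []).append(p.gene_a)

    gois = [config.goi] if config.goi is not None else sorted(partners)
    records: list[SoCeRRecord] = []
    n_skipped = 0
    for goi in gois:
        if goi not in affinities:
            if config.goi is not None:
                raise DataError(
                    f"gene of interest {goi!r} has no entries in the target-site table"
                )
            n_skipped += 1
            continue
        scorable = [p for p in partners.get(goi, []) if p in affinities]
        n_skipped += len(partners.get(goi, [])) - len(scorable)
        if not scorable:
            continue
        scored = [
            socer_raw(goi, pcc, affinities, mirna_means, pool=config.mirna_pool_mode)
            for pcc in scorable
        ]
        scored = normalize_scores(scored)
        if config.socer_band is not None:
            scored = apply_socer_band(scored, *config.socer_band)
        scored = rank_pccs(scored, direction=config.rank_direction) if scored else []
        for sp in scored:
            rho, q = pair_stats[(sp.goi, sp.pcc)]
            records.append(
                SoCeRRecord(
                    goi=sp.goi,
                    pcc=sp.pcc,
                    n_shared_mirna=sp.n_shared_mirna,
                    rho=rho,
                    q_value=q,
                    raw_score=sp.raw_score,
                    norm_score=sp.norm_score,
                    dominance_class=classify_dominance(sp.norm_score, config.dominance_cutoff),
                    per_mirna_terms=sp.per_mirna_terms,
                )
            )
    if n_skipped:
        _log.warning("%d candidate pair(s) skipped: gene absent from the MRE table", n_skipped)
    return records


def run_pipeline(config: RunConfig) -> dict:
    """Run the full screen and write results under ``config.output_dir``.

    Files written: ``pairs.tsv`` (surviving co-expressed pairs),
    ``scores.tsv`` (scored, normalized, classified pairs — the GOI's ranked
    candidate list when a GOI is set), ``per_mirna_terms.tsv`` (per-miRNA
    score breakdown) and ``manifest.yaml`` (config echo, package version,
    stage counts). Returns the manifest as a dict.

    A run with zero surviving candidate pairs succeeds with header-only
    outputs and a warning.
    """
    genes = read_expression(config.gene_expression, kind="gene")
    mirnas = read_expression(config.mirna_expression, kind="mirna")
    sites = read_target_sites(config.target_sites)
    if config.goi is not None and config.goi not in genes:
        raise DataError(
            f"gene of interest {config.goi!r} not in the gene expression matrix"
        )
    _log.info(
        "loaded %d genes, %d miRNAs, %d samples, %d MREs",
        len(genes), len(mirnas), genes.n_samples, len(sites),
    )

    goi_for_corr = config.goi if config.fdr_mode == "per_goi" else None
    pairs = candidate_pairs(genes, q_threshold=config.q_threshold, goi=goi_for_corr)
    if config.goi is not None and config.fdr_mode == "genome_wide":
        pairs = [p for p in pairs if config.goi in (p.gene_a, p.gene_b)]
    _log.info("%d candidate pair(s) at q <= %g", len(pairs), config.q_threshold)
    if not pairs:
        _log.warning("no candidate pairs survived the correlation screen")

    affinities = AffinityTable.from_sites(
        sites, gene_expr=genes.row_means().to_dict(), weights=config.seed_weights
    )
    mirna_means = mirnas.row_means().to_dict()
    records = _score_pairs(config, pairs, affinities, mirna_means)
    _log.info("%d scored pair record(s)", len(records))

    out_dir = Path(config.output_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    tmp_dir = Path(tempfile.mkdtemp(prefix=".socer-run-", dir=out_dir.parent))
    try:
        write_correlated_pairs(pairs, tmp_dir / "pairs.tsv")
        write_records(records, tmp_dir / "scores.tsv", tmp_dir / "per_mirna_terms.tsv")
        manifest = {
            "package": "socer",
            "version": __version__,
            "config": config.to_dict(),
            "counts": {
                "genes": len(genes),
                "mirnas": len(mirnas),
                "samples": genes.n_samples,
                "target_sites": len(sites),
                "candidate_pairs": len(pairs),
                "scored_records": len(records),
                "dominant": sum(r.dominance_class is Dominance.DOMINANT for r in records),
                "dependent": sum(r.dominance_class is Dominance.DEPENDENT for r in records),
            },
        }
        with open(tmp_dir / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("pairs.tsv", "scores.tsv", "per_mirna_terms.tsv", "manifest.yaml"):
            os.replace(tmp_dir / name, out_dir / name)
    finally:
        shutil.rmtree(tmp_dir, ignore_errors=True)
    return manifest
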