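"""End-to-end pipeline: read → filter → signatures → partition → score.

The whole analysis is deterministic given its inputs; re-running with an
identical config produces byte-identical output tables.  Every stage
logs its input/output dimensions because the procedure silently drops
data in several places (time filter, category slices, genes without
activator data, unscorable chemicals) and those drops must be auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .io import (
    read_activator_config,
    read_fold_change_table,
    read_gene_catalog,
    write_signature_tables,
)
from .model import (
    PATHWAYS,
    ActivatorConfig,
    CategoryKey,
    ConfigError,
    FoldChangeMatrix,
    GeneTargetCatalog,
    Pathway,
)
from .scoring import (
    COS_CUTOFF,
    MODULE_CUTOFF,
    ClassificationResult,
    classify_chemicals,
    export_scatter_data,
    score_chemicals,
)
from .selection import SelectionReport, filter_by_max_time, select_category
from .signatures import (
    OverlapPartition,
    SignatureSet,
    build_signature_set,
    partition_overlaps,
)

__all__ = ["PipelineConfig", "RunSummary", "AnalysisResult", "analyze", "run_pipeline", "venn_summary"]

logger = logging.getLogger("toxsig")

#: The standard analysis choices: conditions up to 24 h, a 2σ rule, human
#: liver in vitro as the scoring category, cut-offs 1/√3 and 0.5.
PAPER_DEFAULTS = dict(
    max_hours=24.0,
    sigma_mult=2.0,
    scoring_category=CategoryKey(species="human", tissue="liver", setting="in_vitro"),
    cos_cutoff=COS_CUTOFF,
    module_cutoff=MODULE_CUTOFF,
)


@dataclass
class PipelineConfig:
    """File-level configuration of one pipeline run."""

    data: Union[str, Path]
    activators: Union[str, Path]
    catalog: Optional[Union[str, Path]] = None
    out_dir: Union[str, Path] = "toxsig_out"
    max_hours: float = 24.0
    sigma_mult: float = 2.0
    signature_category: Optional[CategoryKey] = None
    scoring_category: Optional[CategoryKey] = CategoryKey(
        species="human", tissue="liver", setting="in_vitro"
    )
    cos_cutoff: float = COS_CUTOFF
    module_cutoff: float = MODULE_CUTOFF
    ddof: int = 0
    require_all_activators: bool = False

    def validate(self) -> None:
        for name in ("data", "activators"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ConfigError(f"{name} path does not exist: {path}")
        if self.catalog is not None and not Path(self.catalog).exists():
            raise ConfigError(f"catalog path does not exist: {self.catalog}")
        if not self.max_hours > 0:
            raise ConfigError("max_hours must be > 0")
        if not self.sigma_mult > 0:
            raise ConfigError("sigma_mult must be > 0")

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "max_hours": self.max_hours,
                "sigma_mult": self.sigma_mult,
                "signature_category": self.signature_category.label()
                if self.signature_category
                else None,
                "scoring_category": self.scoring_category.label()
                if self.scoring_category
                else None,
                "cos_cutoff": self.cos_cutoff,
                "module_cutoff": self.module_cutoff,
                "ddof": self.ddof,
                "require_all_activators": self.require_all_activators,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AnalysisResult:
    """In-memory results of one analysis (the library-level return value)."""

    selection: SelectionReport
    signature_set: SignatureSet
    partition: OverlapPartition
    scores: list
    classification: ClassificationResult
    filtered_matrix: FoldChangeMatrix
    scoring_matrix: FoldChangeMatrix


@dataclass
class RunSummary:
    """Everything a reader needs to audit one run, JSON-serializable."""

    selection: dict
    profiles: dict
    zone_sizes: dict
    pass_counts: dict
    top_chemicals: dict
    not_scorable: list
    n_chemicals_scored: int
    version: str = ""
    config_hash: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def analyze(
    matrix: FoldChangeMatrix,
    activators: ActivatorConfig,
    *,
    max_hours: float = 24.0,
    sigma_mult: float = 2.0,
    signature_category: Optional[CategoryKey] = None,
    scoring_category: Optional[CategoryKey] = None,
    cos_cutoff: float = COS_CUTOFF,
    module_cutoff: float = MODULE_CUTOFF,
    ddof: int = 0,
    require_all_activators: bool = False,
) -> AnalysisResult:
    """Run the full analysis on an in-memory matrix.

    Stages: time filter (≤ *max_hours*) → per-pathway activation profiles
    and μ ± m·σ signatures (on *signature_category* if given, else all
    retained data) → seven-zone Venn partition → CAC scoring and
    classification of every chemical in *scoring_category* (default: the
    signature data itself).
    """
    filtered, report = filter_by_max_time(matrix, max_hours)
    logger.info(
        "time filter: %d -> %d conditions, %d -> %d values",
        report.n_conditions_before,
        report.n_conditions_after,
        report.n_values_before,
        report.n_values_after,
    )
    sigset = build_signature_set(
        filtered,
        activators,
        category=signature_category,
        sigma_mult=sigma_mult,
        require_all_activators=require_all_activators,
        ddof=ddof,
        strict=False,
    )
    for p in PATHWAYS:
        prof = sigset.profiles[p]
        if prof is not None:
            logger.info(
                "profile %s: %d genes, mu=%.4g sigma=%.4g, %d excluded",
                p.value,
                prof.n_genes,
                prof.mu,
                prof.sigma,
                len(prof.excluded_genes),
            )
    partition = partition_overlaps(sigset)
    logger.info("venn zones: %s", partition.zone_sizes())

    scoring_matrix = (
        select_category(filtered, scoring_category)
        if scoring_category is not None
        else filtered
    )
    scores = score_chemicals(
        scoring_matrix,
        partition,
        cos_cutoff=cos_cutoff,
        module_cutoff=module_cutoff,
    )
    classification = classify_chemicals(scores, cos_cutoff, module_cutoff)
    logger.info("classified: %s", classification.pass_counts())
    return AnalysisResult(
        selection=report,
        signature_set=sigset,
        partition=partition,
        scores=scores,
        classification=classification,
        filtered_matrix=filtered,
        scoring_matrix=scoring_matrix,
    )


def venn_summary(partition: OverlapPartition) -> dict:
    """Seven labeled zone counts plus the sorted gene list of each zone."""
    sizes = partition.zone_sizes()
    genes = {}
    for p in PATHWAYS:
        genes[p.value] = sorted(partition.exclusive[p])
    pairs = (
        (PATHWAYS[0], PATHWAYS[1]),
        (PATHWAYS[1], PATHWAYS[2]),
        (PATHWAYS[0], PATHWAYS[2]),
    )
    for a, b in pairs:
        genes[f"{a.value}+{b.value}"] = sorted(partition.pairwise[frozenset({a, b})])
    genes["+".join(p.value for p in PATHWAYS)] = sorted(partition.triple)
    return {"counts": sizes, "genes": genes}


def _summarize(result: AnalysisResult, config_hash: str = "") -> RunSummary:
    profiles = {}
    for p in PATHWAYS:
        prof = result.signature_set.profiles[p]
        profiles[p.value] = (
            None
            if prof is None
            else {
                "mu": prof.mu,
                "sigma": prof.sigma,
                "n_genes": prof.n_genes,
                "n_excluded": len(prof.excluded_genes),
            }
        )
    classification = result.classification
    return RunSummary(
        selection=dict(result.selection.__dict__),
        profiles=profiles,
        zone_sizes=result.partition.zone_sizes(),
        pass_counts=classification.pass_counts(),
        top_chemicals={
            p.value: classification.top(p) for p in PATHWAYS
        },
        not_scorable=list(classification.not_scorable),
        n_chemicals_scored=sum(1 for s in result.scores if s.scorable),
        version=__version__,
        config_hash=config_hash,
    )


def _write_scores(result: AnalysisResult, out_dir: Path) -> None:
    rows = []
    for s in result.scores:
        row = {"chemical": s.chemical, "n_conditions": s.n_conditions}
        for i, p in enumerate(PATHWAYS):
            row[f"cac_{p.value}"] = s.cac[i]
            row[f"cos_{p.value}"] = s.cos_alpha[p]
            row[f"score_{p.value}"] = s.score[p]
            row[f"passes_{p.value}"] = s.passes[p]
        row["module"] = s.module
        row["scorable"] = s.scorable
        rows.append(row)
    pd.DataFrame(rows).sort_values("chemical", kind="mergesort").to_csv(
        out_dir / "chemical_scores.tsv", sep="\t", index=False, float_format="%.6g"
    )
    scatter = export_scatter_data(
        result.scores, result.classification.cos_cutoff, result.classification.module_cutoff
    )
    for p in PATHWAYS:
        scatter[scatter["pathway"] == p.value].to_csv(
            out_dir / f"scatter_{p.value}.tsv", sep="\t", index=False, float_format="%.6g"
        )
    for p in PATHWAYS:
        ranked = result.classification.per_pathway[p]
        pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "chemical": s.chemical,
                    "score": s.score[p],
                    "cos_alpha": s.cos_alpha[p],
                    "module": s.module,
                    "cac": s.cac_of(p),
                }
                for i, s in enumerate(ranked)
            ],
            columns=["rank", "chemical", "score", "cos_alpha", "module", "cac"],
        ).to_csv(out_dir / f"ranked_{p.value}.tsv", sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """File-to-file pipeline run; halts on the first stage error.

    Writes to ``config.out_dir``: the seven signature-zone tables, a Venn
    summary (JSON), per-chemical scores, per-pathway ranked lists and
    scatter coordinates, and ``run_summary.json``.
    """
    config.validate()
    stage = "read"
    try:
        matrix = read_fold_change_table(config.data)
        activators = read_activator_config(config.activators)
        catalog: Optional[GeneTargetCatalog] = (
            read_gene_catalog(config.catalog) if config.catalog is not None else None
        )
        logger.info(
            "read: %d conditions, %d genes, %d values",
            matrix.n_conditions,
            len(matrix.genes),
            matrix.n_values,
        )
        stage = "analyze"
        result = analyze(
            matrix,
            activators,
            max_hours=config.max_hours,
            sigma_mult=config.sigma_mult,
            signature_category=config.signature_category,
            scoring_category=config.scoring_category,
            cos_cutoff=config.cos_cutoff,
            module_cutoff=config.module_cutoff,
            ddof=config.ddof,
            require_all_activators=config.require_all_activators,
        )
        stage = "write"
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_signature_tables(result.signature_set, result.partition, out_dir, catalog)
        (out_dir / "venn_summary.json").write_text(
            json.dumps(venn_summary(result.partition), indent=2, sort_keys=True) + "\n"
        )
        _write_scores(result, out_dir)
        summary = _summarize(result, config.content_hash())
        (out_dir / "run_summary.json").write_text(summary.to_json() + "\n")
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
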