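"""Readers and writers for the package's delimited-text interchange formats.

All tables are UTF-8 delimited text with a header row and '.' decimals.
The canonical fold-change layout is long (tidy): one row per measured
condition x gene value, metadata repeated per row and de-duplicated on
read.  Long format is canonical because source toxicogenomic projects
ship incompatible wide layouts; a wide import is a convenience conversion.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .model import (
    CONDITION_COLUMNS,
    PATHWAYS,
    ActivatorConfig,
    CategoryKey,
    ConfigError,
    FoldChangeMatrix,
    GeneTargetCatalog,
    IntegrityError,
    Pathway,
    SchemaError,
)

__all__ = [
    "read_fold_change_table",
    "write_fold_change_table",
    "read_gene_catalog",
    "write_gene_catalog",
    "read_activator_config",
    "write_activator_config",
    "write_signature_tables",
    "read_signature_table",
]

PathLike = Union[str, Path]

_SEPS = {"long_tsv": "\t", "long_csv": ","}


def _sep_for(path: PathLike, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in _SEPS:
            raise ConfigError(f"unknown dialect {dialect!r}; expected long_tsv or long_csv")
        return _SEPS[dialect]
    return "," if str(path).endswith(".csv") else "\t"


def read_fold_change_table(path: PathLike, dialect: Optional[str] = None) -> FoldChangeMatrix:
    """Read a long-format fold-change table.

    Required columns: ``condition_id, chemical, species, tissue, setting,
    dosing, time_h, dose_label, project, gene, log2fc``.  Rows with a blank
    ``log2fc`` are recorded as missing measurements (never as zero).
    Condition metadata is de-duplicated per ``condition_id``; conflicting
    metadata for one id raises :class:`IntegrityError`.
    """
    sep = _sep_for(path, dialect)
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = list(CONDITION_COLUMNS) + ["gene", "log2fc"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"fold-change table missing column(s): {', '.join(missing)}")

    meta = table[list(CONDITION_COLUMNS)].drop_duplicates()
    clash = meta["condition_id"].duplicated()
    if clash.any():
        bad = sorted(meta.loc[clash, "condition_id"].unique())
        raise IntegrityError(f"conflicting metadata for condition_id(s): {bad}")
    meta = meta.set_index("condition_id")

    rows = table[["condition_id", "gene", "log2fc"]]
    measured = rows[rows["log2fc"].str.strip() != ""].copy()
    try:
        measured["log2fc"] = pd.to_numeric(measured["log2fc"], errors="raise")
    except (ValueError, TypeError):
        numeric = pd.to_numeric(measured["log2fc"], errors="coerce")
        bad_rows = measured.index[numeric.isna()] + 2  # 1-based + header
        raise SchemaError(f"non-numeric log2fc at file row(s): {list(bad_rows)}") from None
    return FoldChangeMatrix(meta, measured)


def write_fold_change_table(matrix: FoldChangeMatrix, path: PathLike) -> None:
    """Write the long-format counterpart of :func:`read_fold_change_table`.

    Only measured values are emitted; missing cells simply have no row.
    Deterministic row order: (condition_id, gene).
    """
    sep = _sep_for(path, None)
    long = matrix.values.merge(
        matrix.conditions.reset_index(), on="condition_id", how="left"
    )
    long = long[list(CONDITION_COLUMNS) + ["gene", "log2fc"]]
    long = long.sort_values(["condition_id", "gene"], kind="mergesort")
    long.to_csv(path, sep=sep, index=False)


def read_gene_catalog(path: PathLike, dialect: Optional[str] = None) -> GeneTargetCatalog:
    """Read a gene catalog with columns ``gene, pathway``.

    A gene listed under several pathways receives the union of its
    memberships.  Unknown pathway labels raise :class:`SchemaError`.
    """
    sep = _sep_for(path, dialect)
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("gene", "pathway"):
        if col not in table.columns:
            raise SchemaError(f"gene catalog missing column: {col}")
    memberships: dict[str, set[Pathway]] = {}
    for gene, label in table[["gene", "pathway"]].itertuples(index=False):
        gene = gene.strip()
        if not gene:
            raise SchemaError("gene catalog contains an empty gene symbol")
        memberships.setdefault(gene, set()).add(Pathway.parse(label))
    return GeneTargetCatalog({g: frozenset(ps) for g, ps in memberships.items()})


def write_gene_catalog(catalog: GeneTargetCatalog, path: PathLike) -> None:
    sep = _sep_for(path, None)
    rows = [
        {"gene": gene, "pathway": p.value}
        for gene in catalog.genes
        for p in PATHWAYS
        if p in catalog.pathways_of(gene)
    ]
    pd.DataFrame(rows, columns=["gene", "pathway"]).to_csv(path, sep=sep, index=False)


def _category_to_obj(key: CategoryKey) -> dict:
    return {
        name: getattr(key, name)
        for name in ("species", "tissue", "setting", "dosing")
        if getattr(key, name) is not None
    }


def _category_from_obj(obj: dict) -> CategoryKey:
    extra = set(obj) - {"species", "tissue", "setting", "dosing"}
    if extra:
        raise ConfigError(f"unknown category field(s): {sorted(extra)}")
    return CategoryKey(**obj)


def read_activator_config(path: PathLike) -> ActivatorConfig:
    """Read a pathway -> activator-chemicals config (JSON or YAML).

    Schema::

        activators:
          AhR: [Benzo(a)pyrene, Omeprazole]
          Nrf2: [Potassium Bromate, Phorone]
          ATF4: [Tunicamycin]
        scopes:            # optional, per-activator applicable category
          Phorone: {tissue: liver}

    A bare top-level mapping of pathway -> list is also accepted.
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("activator config must be a mapping")
    raw = data.get("activators", data)
    scopes_raw = data.get("scopes", {}) if "activators" in data else {}
    activators: dict[Pathway, list[str]] = {}
    for label, chems in raw.items():
        pathway = Pathway.parse(label)
        if chems is None or not isinstance(chems, list) or not chems:
            raise ConfigError(f"pathway {pathway.value} must map to a non-empty chemical list")
        activators[pathway] = [str(c) for c in chems]
    scopes = {str(chem): _category_from_obj(obj) for chem, obj in (scopes_raw or {}).items()}
    return ActivatorConfig(activators=activators, scopes=scopes)


def write_activator_config(config: ActivatorConfig, path: PathLike) -> None:
    data: dict = {
        "activators": {p.value: list(config.activators[p]) for p in PATHWAYS},
    }
    if config.scopes:
        data["scopes"] = {c: _category_to_obj(k) for c, k in config.scopes.items()}
    path = Path(path)
    if str(path).endswith(".json"):
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Signature / partition tables

_ZONE_FILES = {
    "AhR": "signature_AhR_exclusive.tsv",
    "Nrf2": "signature_Nrf2_exclusive.tsv",
    "ATF4": "signature_ATF4_exclusive.tsv",
    "AhR+Nrf2": "signature_overlap_AhR_Nrf2.tsv",
    "Nrf2+ATF4": "signature_overlap_Nrf2_ATF4.tsv",
    "AhR+ATF4": "signature_overlap_AhR_ATF4.tsv",
    "AhR+Nrf2+ATF4": "signature_overlap_triple.tsv",
}


def write_signature_tables(signatures, partition, out_dir: PathLike, catalog=None) -> list[Path]:
    """Write one delimited table per Venn zone (3 exclusive + 4 overlap).

    Each table lists the zone's genes with their per-pathway average
    activation value(s), a section label (``activated``/``inhibited`` by
    the sign of the leading pathway's average), sorted by decreasing
    absolute average; ties broken alphabetically.  Returns written paths.
    """
    from .signatures import OverlapPartition, SignatureSet  # local: avoid cycle

    assert isinstance(signatures, SignatureSet)
    assert isinstance(partition, OverlapPartition)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for zone_label, fname in _ZONE_FILES.items():
        zone_pathways = [p for p in PATHWAYS if p.value in zone_label.split("+")]
        genes = partition.zone(frozenset(zone_pathways))
        rows = []
        for gene in genes:
            values = {p: partition.values[p].get(gene) for p in zone_pathways}
            lead = values[zone_pathways[0]]
            rows.append(
                {
                    "gene": gene,
                    **{f"avg_{p.value}": values[p] for p in zone_pathways},
                    "section": "activated" if lead is not None and lead > 0 else "inhibited",
                    "abs_avg": abs(lead) if lead is not None else 0.0,
                    "a_priori": catalog.apriori_label(gene) if catalog is not None else "",
                }
            )
        cols = (
            ["gene"]
            + [f"avg_{p.value}" for p in zone_pathways]
            + ["section", "abs_avg", "a_priori"]
        )
        table = pd.DataFrame(rows, columns=cols)
        if len(table):
            table = table.sort_values(
                ["abs_avg", "gene"], ascending=[False, True], kind="mergesort"
            )
        path = out_dir / fname
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)
    return written


def read_signature_table(path: PathLike) -> pd.DataFrame:
    """Re-read a zone table written by :func:`write_signature_tables`."""
    return pd.read_csv(path, sep="\t")
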