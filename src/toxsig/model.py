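"""Core data types for pathway-signature analysis of fold-change data.

The analysis substrate is a sparse condition x gene table of log2 fold
changes over time-matched controls, with per-condition experimental
metadata (chemical, species, tissue, in vitro/in vivo, dosing mode,
exposure time, dose label).  Three stress-response pathways are modelled:
AhR (xenobiotic response), Nrf2 (oxidative stress) and ATF4 (ER stress /
integrated stress response).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pathway",
    "PATHWAYS",
    "SPECIES",
    "TISSUES",
    "SETTINGS",
    "DOSINGS",
    "CONDITION_COLUMNS",
    "CategoryKey",
    "FoldChangeMatrix",
    "GeneTargetCatalog",
    "ActivatorConfig",
    "SchemaError",
    "IntegrityError",
    "ConfigError",
    "normalize_chemical",
]


class Pathway(str, enum.Enum):
    """The three stress-response transcription-factor pathways."""

    AHR = "AhR"
    NRF2 = "Nrf2"
    ATF4 = "ATF4"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def parse(cls, label: str) -> "Pathway":
        for p in cls:
            if p.value.lower() == str(label).strip().lower():
                return p
        raise SchemaError(
            f"unknown pathway label {label!r}; expected one of "
            + ", ".join(p.value for p in cls)
        )


#: Canonical pathway order used for 3-vectors (CAC coordinates).
PATHWAYS: tuple[Pathway, Pathway, Pathway] = (Pathway.AHR, Pathway.NRF2, Pathway.ATF4)

SPECIES = ("human", "rat")
TISSUES = ("liver", "kidney")
SETTINGS = ("in_vitro", "in_vivo")
DOSINGS = ("bolus", "repeated")

#: Required metadata columns of a long-format fold-change table, in
#: canonical order; 'gene' and 'log2fc' complete the schema.
CONDITION_COLUMNS = (
    "condition_id",
    "chemical",
    "species",
    "tissue",
    "setting",
    "dosing",
    "time_h",
    "dose_label",
    "project",
)


class SchemaError(ValueError):
    """An input file or config violates the documented schema."""


class IntegrityError(ValueError):
    """Structurally valid input contradicts itself (e.g. duplicate keys)."""


class ConfigError(ValueError):
    """A configuration value is invalid or infeasible."""


def normalize_chemical(name: str) -> str:
    """Canonical form for chemical-name matching: trimmed, case-folded.

    Names are matched case-insensitively after whitespace trimming; no
    fuzzy matching is attempted (silently merging distinct chemicals is
    worse than a reported miss).
    """
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True)
class CategoryKey:
    """Selector over experimental categories; ``None`` fields are wildcards.

    A fully wildcarded key selects every condition.  Used both to
    stratify signature construction (e.g. rat liver in vitro) and to
    choose the scoring category (human liver in vitro).
    """

    species: Optional[str] = None
    tissue: Optional[str] = None
    setting: Optional[str] = None
    dosing: Optional[str] = None

    def __post_init__(self) -> None:
        for name, allowed in (
            ("species", SPECIES),
            ("tissue", TISSUES),
            ("setting", SETTINGS),
            ("dosing", DOSINGS),
        ):
            value = getattr(self, name)
            if value is not None and value not in allowed:
                raise ConfigError(
                    f"invalid {name}={value!r}; expected one of {allowed} or wildcard"
                )

    def matches(self, row: Mapping[str, object]) -> bool:
        for name in ("species", "tissue", "setting", "dosing"):
            want = getattr(self, name)
            if want is not None and row[name] != want:
                return False
        return True

    def label(self) -> str:
        parts = [
            str(getattr(self, name)) if getattr(self, name) is not None else "*"
            for name in ("species", "tissue", "setting", "dosing")
        ]
        return "/".join(parts)


class FoldChangeMatrix:
    """Sparse condition x gene log2 fold-change table with condition metadata.

    Parameters
    ----------
    conditions:
        One row per experimental condition, indexed by ``condition_id``,
        with columns ``chemical, species, tissue, setting, dosing,
        time_h, dose_label, project``.
    values:
        Long table with columns ``condition_id, gene, log2fc``.  Absent
        (condition, gene) pairs mean "not measured" — never zero; per-gene
        averages skip them.
    genes:
        Optional explicit gene universe.  Defaults to the genes present in
        ``values``.  Genes in the universe without any stored value are
        carried as "covered by the dataset but unmeasured here".
    """

    def __init__(
        self,
        conditions: pd.DataFrame,
        values: pd.DataFrame,
        genes: Optional[Sequence[str]] = None,
    ) -> None:
        conditions = conditions.copy()
        if conditions.index.name != "condition_id":
            if "condition_id" in conditions.columns:
                conditions = conditions.set_index("condition_id")
            else:
                raise SchemaError("conditions table lacks a condition_id column/index")
        missing = [c for c in CONDITION_COLUMNS[1:] if c not in conditions.columns]
        if missing:
            raise SchemaError(f"conditions table missing column(s): {', '.join(missing)}")
        if conditions.index.duplicated().any():
            dupes = conditions.index[conditions.index.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate condition_id(s): {dupes}")

        values = values.loc[:, ["condition_id", "gene", "log2fc"]].copy()
        values["log2fc"] = pd.to_numeric(values["log2fc"], errors="raise")
        if not np.isfinite(values["log2fc"].to_numpy()).all():
            raise IntegrityError("log2fc values must be finite (blank cells mean missing)")
        if values.duplicated(subset=["condition_id", "gene"]).any():
            pairs = (
                values.loc[
                    values.duplicated(subset=["condition_id", "gene"]), ["condition_id", "gene"]
                ]
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            raise IntegrityError(f"duplicate (condition, gene) pair(s): {sorted(pairs)}")
        unknown = set(values["condition_id"]) - set(conditions.index)
        if unknown:
            raise IntegrityError(f"values reference unknown condition_id(s): {sorted(unknown)}")

        for col, allowed in (("species", SPECIES), ("tissue", TISSUES), ("setting", SETTINGS), ("dosing", DOSINGS)):
            bad = set(conditions[col].unique()) - set(allowed)
            if bad:
                raise SchemaError(f"invalid {col} value(s) {sorted(bad)}; expected {allowed}")
        time_h = pd.to_numeric(conditions["time_h"], errors="raise")
        if (time_h <= 0).any():
            raise IntegrityError("time_h must be > 0 for every condition")
        conditions["time_h"] = time_h.astype(float)

        value_genes = set(values["gene"])
        if genes is None:
            gene_list = sorted(value_genes)
        else:
            gene_list = list(dict.fromkeys(genes))
            extra = value_genes - set(gene_list)
            if extra:
                raise IntegrityError(f"values reference gene(s) outside the universe: {sorted(extra)}")

        self.conditions = conditions
        self.values = values.reset_index(drop=True)
        self.genes = gene_list

    # -- basic accessors -------------------------------------------------
    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_values(self) -> int:
        return len(self.values)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.conditions.index)

    def chemicals(self) -> list[str]:
        """Distinct chemical names, dataset spelling, sorted."""
        return sorted(self.conditions["chemical"].unique())

    def conditions_of_chemical(self, chemical: str) -> list[str]:
        key = normalize_chemical(chemical)
        mask = self.conditions["chemical"].map(normalize_chemical) == key
        return list(self.conditions.index[mask])

    def subset_conditions(self, condition_ids: Iterable[str]) -> "FoldChangeMatrix":
        """Restrict to the given conditions; values follow, gene universe kept."""
        keep = [c for c in self.conditions.index if c in set(condition_ids)]
        conditions = self.conditions.loc[keep]
        values = self.values[self.values["condition_id"].isin(keep)]
        return FoldChangeMatrix(conditions, values, genes=self.genes)

    def equals(self, other: "FoldChangeMatrix") -> bool:
        """Field-for-field equality (order-insensitive on values)."""
        if set(self.genes) != set(other.genes):
            return False
        a = self.conditions.sort_index()
        b = other.conditions.sort_index()
        if not a.index.equals(b.index):
            return False
        if not a[list(CONDITION_COLUMNS[1:])].equals(b[list(CONDITION_COLUMNS[1:])]):
            return False
        key = ["condition_id", "gene"]
        va = self.values.sort_values(key).reset_index(drop=True)
        vb = other.values.sort_values(key).reset_index(drop=True)
        if len(va) != len(vb):
            return False
        return bool(
            (va[key] == vb[key]).all().all()
            and np.allclose(va["log2fc"], vb["log2fc"], rtol=0, atol=1e-12)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FoldChangeMatrix({self.n_conditions} conditions, "
            f"{len(self.genes)} genes, {self.n_values} values)"
        )


@dataclass
class GeneTargetCatalog:
    """A-priori gene -> pathway membership catalog.

    Each gene carries the (non-empty) set of pathways under which it was
    curated.  Membership is reporting metadata for the derived signatures;
    it does not constrain which pathway a gene may end up in.
    """

    memberships: dict[str, frozenset[Pathway]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, pathways in self.memberships.items():
            if not pathways:
                raise IntegrityError(f"gene {gene!r} has no a-priori pathway")
            self.memberships[gene] = frozenset(pathways)

    @property
    def genes(self) -> list[str]:
        return sorted(self.memberships)

    def __len__(self) -> int:
        return len(self.memberships)

    def __contains__(self, gene: str) -> bool:
        return gene in self.memberships

    def pathways_of(self, gene: str) -> frozenset[Pathway]:
        return self.memberships.get(gene, frozenset())

    def apriori_label(self, gene: str) -> str:
        """Slash-joined label in canonical pathway order, '' if uncatalogued."""
        member = self.memberships.get(gene, frozenset())
        return "/".join(p.value for p in PATHWAYS if p in member)


@dataclass
class ActivatorConfig:
    """Pathway -> reference activator chemicals, with optional category scopes.

    An activator is a chemical whose known mode of action activates one
    pathway without directly activating the other two (e.g. tunicamycin
    for ATF4).  A configured activator absent from a given dataset is
    legal at parse time and reported as "uncovered" when profiles are
    computed.
    """

    activators: dict[Pathway, list[str]] = field(default_factory=dict)
    scopes: dict[str, CategoryKey] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pathway in PATHWAYS:
            chems = self.activators.get(pathway)
            if not chems:
                raise ConfigError(f"pathway {pathway.value} has no activator chemicals")
            seen: dict[str, str] = {}
            for chem in chems:
                key = normalize_chemical(chem)
                if key in seen:
                    raise ConfigError(
                        f"duplicate activator {chem!r} for pathway {pathway.value}"
                    )
                seen[key] = chem

    def for_pathway(self, pathway: Pathway) -> list[str]:
        return list(self.activators[pathway])

    def all_chemicals(self) -> list[str]:
        out: list[str] = []
        for pathway in PATHWAYS:
            out.extend(self.activators[pathway])
        return out

    def uncovered(self, matrix: FoldChangeMatrix) -> list[str]:
        """Configured activators with no condition in *matrix*."""
        present = {normalize_chemical(c) for c in matrix.conditions["chemical"]}
        return [c for c in self.all_chemicals() if normalize_chemical(c) not in present]
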