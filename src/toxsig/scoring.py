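"""Chemical activation capacity (CAC) scoring and geometric classification.

Each chemical K gets a 3-vector of CAC coordinates, one per pathway: the
mean log2FC of that pathway's EXCLUSIVE signature genes over the
chemical's retained conditions (overlap-zone genes are left out so a
coordinate speaks for one pathway only).  In the 3D space whose axes are
the pathways, specificity for a pathway is |cos α| between the vector OK
and that axis, and potency is the Euclidean norm ‖OK‖.  A point nearer
one axis than the other two has |cos α| > 1/√3 ≈ 0.57735 with it, hence
the specificity cut-off; the potency cut-off is ‖OK‖ > 0.5.  Chemicals
passing both are ranked by the product |cos α|·‖OK‖, which
algebraically equals |CAC| on that axis.

The converse fails: two cosines can exceed 1/√3 at once (e.g. (0, 1, 1)
has |cos α| = 1/√2 on two axes), so the cut-off alone would not make
pathway lists mutually exclusive.  The geometric intent — the point is
*nearer this axis than the other two* — does.  Classification therefore
also requires the pathway to be the chemical's strictly nearest axis
(largest |cos α|; an exact tie means equidistant, specific to neither).
Whenever only one cosine clears the cut-off — the generic case — this
coincides with the plain cut-off rule.

CAC coordinates can be negative (chemicals inhibiting most genes of a
pathway); |cos α| therefore also flags specific *inhibitors*, so the
signed coordinate is reported alongside every score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import PATHWAYS, ConfigError, FoldChangeMatrix, Pathway, normalize_chemical
from .signatures import OverlapPartition

__all__ = [
    "COS_CUTOFF",
    "MODULE_CUTOFF",
    "ChemicalScore",
    "ClassificationResult",
    "exclusive_genes",
    "chemical_cac",
    "axis_cosine",
    "vector_module",
    "score_chemicals",
    "classify_chemicals",
    "export_scatter_data",
]

#: A point is closer to one of three orthogonal axes than to the other two
#: iff its |cos α| with that axis exceeds 1/√3.
COS_CUTOFF: float = 1.0 / math.sqrt(3.0)
MODULE_CUTOFF: float = 0.5

_AXIS_INDEX = {p: i for i, p in enumerate(PATHWAYS)}


def exclusive_genes(partition: OverlapPartition, pathway: Pathway) -> frozenset[str]:
    """A pathway's exclusive Venn zone: signature genes in no overlap zone.

    Both activated and inhibited genes are included.
    """
    return partition.exclusive[pathway]


def chemical_cac(
    matrix: FoldChangeMatrix, chemical: str, genes: Iterable[str]
) -> Optional[float]:
    """Mean log2FC over (chemical's conditions × genes); None if no data.

    Missing cells are skipped.  ``None`` (a flagged null) is returned when
    the chemical is absent from the matrix or has no measurement for any
    of the genes — it is never silently coerced to 0, which would
    fabricate a "no effect" coordinate.
    """
    gene_set = set(genes)
    if not gene_set:
        raise ConfigError("gene set must be non-empty")
    cond_ids = matrix.conditions_of_chemical(chemical)
    if not cond_ids:
        warnings.warn(f"chemical {chemical!r} absent from the dataset", stacklevel=2)
        return None
    sub = matrix.values[
        matrix.values["condition_id"].isin(cond_ids) & matrix.values["gene"].isin(gene_set)
    ]
    if sub.empty:
        return None
    return float(sub["log2fc"].mean())


def axis_cosine(v: Sequence[float], axis: Pathway) -> float:
    """|cos α| between 3-vector *v* and a pathway axis: |v_axis| / ‖v‖.

    Undefined for the zero vector; callers map that case to a 0 sentinel
    ("specific to nothing").
    """
    arr = np.asarray(v, dtype=float)
    norm = float(np.linalg.norm(arr))
    if norm == 0.0:
        raise ZeroDivisionError("axis cosine undefined for the zero vector")
    return abs(float(arr[_AXIS_INDEX[axis]])) / norm


def vector_module(v: Sequence[float]) -> float:
    """Euclidean norm ‖v‖ (the chemical's overall activation potency)."""
    return float(np.linalg.norm(np.asarray(v, dtype=float)))


@dataclass
class ChemicalScore:
    """One chemical's CAC vector with its geometric decomposition.

    ``cac`` components follow the canonical pathway order (AhR, Nrf2,
    ATF4); a ``None`` component means the chemical had no data on that
    pathway's exclusive genes, which makes the chemical unscorable.
    """

    chemical: str
    cac: tuple[Optional[float], Optional[float], Optional[float]]
    n_conditions: int
    n_genes_used: dict[Pathway, int]
    cos_alpha: dict[Pathway, float]
    module: float
    score: dict[Pathway, float]
    passes: dict[Pathway, bool]

    @property
    def scorable(self) -> bool:
        return all(c is not None for c in self.cac)

    def cac_of(self, pathway: Pathway) -> Optional[float]:
        return self.cac[_AXIS_INDEX[pathway]]


def _geometry(cac: Sequence[float]) -> tuple[dict[Pathway, float], float, dict[Pathway, float]]:
    module = vector_module(cac)
    if module == 0.0:
        cos = {p: 0.0 for p in PATHWAYS}  # zero vector: specific to nothing
    else:
        cos = {p: axis_cosine(cac, p) for p in PATHWAYS}
    score = {p: cos[p] * module for p in PATHWAYS}
    return cos, module, score


def _passes(
    cos: Mapping[Pathway, float],
    module: float,
    pathway: Pathway,
    cos_cutoff: float,
    module_cutoff: float,
) -> bool:
    """Both cut-offs exceeded AND *pathway* is the strictly nearest axis."""
    return (
        cos[pathway] > cos_cutoff
        and module > module_cutoff
        and all(cos[pathway] > cos[q] for q in PATHWAYS if q is not pathway)
    )


def score_chemicals(
    matrix: FoldChangeMatrix,
    partition: OverlapPartition,
    chemicals: Optional[Sequence[str]] = None,
    *,
    cos_cutoff: float = COS_CUTOFF,
    module_cutoff: float = MODULE_CUTOFF,
) -> list[ChemicalScore]:
    """Compute a ChemicalScore per chemical on the partition's exclusive zones.

    *chemicals* defaults to every chemical in *matrix*.  Chemicals missing
    a coordinate get ``cos_alpha``/``score`` of 0, ``passes`` all False
    and ``scorable=False``; they surface in the "not scorable" report of
    :func:`classify_chemicals` rather than being classified (treating a
    null as 0 would fabricate specificity for the covered axes).
    """
    if chemicals is None:
        chemicals = matrix.chemicals()
    zones = {p: exclusive_genes(partition, p) for p in PATHWAYS}
    empty_zones = [p.value for p in PATHWAYS if not zones[p]]
    if empty_zones:
        warnings.warn(
            "empty exclusive signature for pathway(s): " + ", ".join(empty_zones),
            stacklevel=2,
        )
    # one aggregation pass instead of a per-chemical scan
    chem_of_cond = matrix.conditions["chemical"].map(normalize_chemical)
    vals = matrix.values
    vals = vals.assign(_chem=vals["condition_id"].map(chem_of_cond))
    agg: dict[Pathway, pd.DataFrame] = {}
    for p in PATHWAYS:
        sub = vals[vals["gene"].isin(zones[p])]
        agg[p] = sub.groupby("_chem").agg(
            mean=("log2fc", "mean"), n_genes=("gene", "nunique")
        )
    n_cond_per_chem = chem_of_cond.value_counts()

    out: list[ChemicalScore] = []
    for chem in chemicals:
        key = normalize_chemical(chem)
        if key not in n_cond_per_chem.index:
            warnings.warn(f"chemical {chem!r} absent from the dataset", stacklevel=2)
        cac: list[Optional[float]] = []
        n_genes: dict[Pathway, int] = {}
        for p in PATHWAYS:
            if zones[p] and key in agg[p].index:
                cac.append(float(agg[p].loc[key, "mean"]))
                n_genes[p] = int(agg[p].loc[key, "n_genes"])
            else:
                cac.append(None)
                n_genes[p] = 0
        if all(c is not None for c in cac):
            cos, module, score = _geometry([float(c) for c in cac])
            passes = {
                p: _passes(cos, module, p, cos_cutoff, module_cutoff) for p in PATHWAYS
            }
        else:
            cos = {p: 0.0 for p in PATHWAYS}
            module = 0.0
            score = {p: 0.0 for p in PATHWAYS}
            passes = {p: False for p in PATHWAYS}
        out.append(
            ChemicalScore(
                chemical=chem,
                cac=(cac[0], cac[1], cac[2]),
                n_conditions=int(n_cond_per_chem.get(key, 0)),
                n_genes_used=n_genes,
                cos_alpha=cos,
                module=module,
                score=score,
                passes=passes,
            )
        )
    return out


@dataclass
class ClassificationResult:
    """Per-pathway ranked lists of chemicals passing both cut-offs."""

    per_pathway: dict[Pathway, list[ChemicalScore]]
    not_scorable: list[str]
    cos_cutoff: float
    module_cutoff: float

    def pass_counts(self) -> dict[str, int]:
        return {p.value: len(self.per_pathway[p]) for p in PATHWAYS}

    def top(self, pathway: Pathway) -> Optional[str]:
        ranked = self.per_pathway[pathway]
        return ranked[0].chemical if ranked else None


def classify_chemicals(
    scores: Sequence[ChemicalScore],
    cos_cutoff: float = COS_CUTOFF,
    module_cutoff: float = MODULE_CUTOFF,
) -> ClassificationResult:
    """Select and rank chemicals per pathway by the axis-proximity geometry.

    A chemical is listed for a pathway when |cos α| > *cos_cutoff*,
    ‖OK‖ > *module_cutoff* (both strict) and the pathway is its strictly
    nearest axis; lists are ranked by decreasing |cos α|·‖OK‖, ties
    broken alphabetically.  The nearest-axis condition makes the
    per-pathway lists mutually exclusive by construction (see module
    docstring).
    """
    if not (0.0 < cos_cutoff <= 1.0):
        raise ConfigError(f"cos_cutoff must be in (0, 1], got {cos_cutoff}")
    if not module_cutoff > 0:
        raise ConfigError(f"module_cutoff must be > 0, got {module_cutoff}")
    per_pathway: dict[Pathway, list[ChemicalScore]] = {}
    for p in PATHWAYS:
        hits = [
            s
            for s in scores
            if s.scorable and _passes(s.cos_alpha, s.module, p, cos_cutoff, module_cutoff)
        ]
        hits.sort(key=lambda s: (-s.score[p], normalize_chemical(s.chemical)))
        per_pathway[p] = hits
    not_scorable = sorted(
        (s.chemical for s in scores if not s.scorable), key=normalize_chemical
    )
    return ClassificationResult(per_pathway, not_scorable, cos_cutoff, module_cutoff)


def export_scatter_data(
    scores: Sequence[ChemicalScore],
    cos_cutoff: float = COS_CUTOFF,
    module_cutoff: float = MODULE_CUTOFF,
) -> pd.DataFrame:
    """Coordinates of the potency-vs-specificity scatter, one row per
    chemical × pathway.

    Columns: ``rank`` (the chemical's 1-based index in the alphabetically
    ordered list, stable across pathways), ``chemical``, ``pathway``,
    ``cos_alpha``, ``module``, ``cac`` (signed), ``passes``.
    """
    ordered = sorted({s.chemical for s in scores}, key=normalize_chemical)
    rank = {chem: i + 1 for i, chem in enumerate(ordered)}
    rows = []
    for s in scores:
        for p in PATHWAYS:
            rows.append(
                {
                    "rank": rank[s.chemical],
                    "chemical": s.chemical,
                    "pathway": p.value,
                    "cos_alpha": s.cos_alpha[p],
                    "module": s.module,
                    "cac": s.cac_of(p),
                    "passes": bool(
                        s.scorable and _passes(s.cos_alpha, s.module, p, cos_cutoff, module_cutoff)
                    ),
                }
            )
    return pd.DataFrame(
        rows, columns=["rank", "chemical", "pathway", "cos_alpha", "module", "cac", "passes"]
    ).sort_values(["rank", "pathway"], kind="mergesort").reset_index(drop=True)
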