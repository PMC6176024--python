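"""Pathway signature derivation by the mean ± 2·SD rule.

For each pathway, conditions of its reference activator chemicals are
pooled; every gene's log2 fold changes are averaged per activator, and
the per-activator means are averaged again (a mean of means, NOT a
pooled-condition mean — activators with more conditions must not
dominate).  Over the resulting per-gene "average activation values" the
mean μ and standard deviation σ are computed, and the signature keeps
genes with value > μ + m·σ (activated, positive values only) or
value < μ − m·σ (inhibited, negative values only), with multiplier
m = 2 by default.  Genes in more than one pathway's signature are set
apart into overlapping zones, yielding a seven-zone Venn partition:
three exclusive signatures, three pairwise overlaps, one triple overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    PATHWAYS,
    ActivatorConfig,
    CategoryKey,
    ConfigError,
    FoldChangeMatrix,
    Pathway,
    normalize_chemical,
)
from .selection import select_category, select_chemical_conditions

__all__ = [
    "ActivationProfile",
    "PathwaySignature",
    "SignatureSet",
    "OverlapPartition",
    "per_activator_gene_means",
    "combine_activator_means",
    "compute_profile",
    "threshold_signature",
    "build_signature_set",
    "partition_overlaps",
    "stratified_signatures",
]


def per_activator_gene_means(matrix: FoldChangeMatrix, activator: str) -> pd.Series:
    """Per-gene mean log2FC over all conditions of *activator*.

    Genes with no measurement under any of the activator's conditions are
    omitted (missing cells are skipped, never treated as zero).
    """
    cond_ids = matrix.conditions_of_chemical(activator)
    if not cond_ids:
        warnings.warn(f"activator {activator!r} has no conditions in the dataset", stacklevel=2)
        return pd.Series(dtype=float)
    sub = matrix.values[matrix.values["condition_id"].isin(cond_ids)]
    return sub.groupby("gene")["log2fc"].mean().sort_index()


def combine_activator_means(means: Sequence[Mapping[str, float]]) -> pd.Series:
    """Average activation value per gene: unweighted mean of per-activator means.

    A gene covered by only a subset of activators is averaged over the
    activators where it has data; single-activator pathways pass through.
    """
    if not means:
        raise ConfigError("need at least one per-activator mean mapping")
    series = [m if isinstance(m, pd.Series) else pd.Series(dict(m), dtype=float) for m in means]
    if all(s.empty for s in series):
        warnings.warn("all per-activator mean mappings are empty", stacklevel=2)
        return pd.Series(dtype=float)
    frame = pd.concat(series, axis=1)
    return frame.mean(axis=1, skipna=True).sort_index()


@dataclass
class ActivationProfile:
    """Per-pathway average activation values with their μ and σ.

    ``combined_values`` maps each gene with data under ≥1 activator to its
    average activation value; ``excluded_genes`` are the dataset genes
    with no data under any configured activator for this pathway.  μ and
    σ are computed over exactly the combined-value genes (σ uses the
    divisor-N population estimator by default; see ``ddof``).
    """

    pathway: Pathway
    per_activator_means: dict[str, pd.Series]
    combined_values: pd.Series
    mu: float
    sigma: float
    excluded_genes: frozenset[str]
    ddof: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.combined_values)


def compute_profile(
    matrix: FoldChangeMatrix,
    pathway: Pathway,
    config: ActivatorConfig,
    *,
    require_all_activators: bool = False,
    ddof: int = 0,
    category: Optional[CategoryKey] = None,
) -> ActivationProfile:
    """Build the activation profile of *pathway* from its configured activators.

    Raises :class:`ConfigError` when no activator of the pathway has any
    condition in *matrix* (e.g. no Nrf2 activator exists for rat kidney
    in vivo), naming the pathway and category.
    """
    per_activator: dict[str, pd.Series] = {}
    for chem in config.for_pathway(pathway):
        scope = config.scopes.get(chem)
        scoped = select_category(matrix, scope) if scope is not None else matrix
        cond_ids = scoped.conditions_of_chemical(chem)
        if cond_ids:
            per_activator[chem] = per_activator_gene_means(scoped, chem)
    if not per_activator:
        where = category.label() if category is not None else "the selected data"
        raise ConfigError(
            f"no activator condition for pathway {pathway.value} in {where}: "
            + ", ".join(config.for_pathway(pathway))
        )

    combined = combine_activator_means(list(per_activator.values()))
    if require_all_activators:
        counts = pd.concat(per_activator.values(), axis=1).notna().sum(axis=1)
        combined = combined[counts == len(per_activator)]

    values = combined.to_numpy(dtype=float)
    mu = float(np.mean(values)) if len(values) else float("nan")
    sigma = float(np.std(values, ddof=ddof)) if len(values) > ddof else float("nan")
    # identical values must give sigma exactly 0, not rounding dust
    if sigma == sigma and sigma <= 1e-12 * max(1.0, float(np.max(np.abs(values), initial=0.0))):
        sigma = 0.0
    excluded = frozenset(matrix.genes) - frozenset(combined.index)
    return ActivationProfile(
        pathway=pathway,
        per_activator_means=per_activator,
        combined_values=combined,
        mu=mu,
        sigma=sigma,
        excluded_genes=excluded,
        ddof=ddof,
    )


@dataclass
class PathwaySignature:
    """Genes in the extreme tails of a pathway's activation profile.

    ``activated``: value > μ + m·σ and value > 0; ``inhibited``:
    value < μ − m·σ and value < 0.  Both lists are sorted by decreasing
    |value| (ties alphabetical).  The positivity/negativity guards matter
    when μ is far from zero: a value above μ + m·σ but still ≤ 0 is not an
    activation.
    """

    pathway: Pathway
    activated: list[tuple[str, float]]
    inhibited: list[tuple[str, float]]
    sigma_mult: float = 2.0

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.activated) | frozenset(g for g, _ in self.inhibited)

    def value_of(self, gene: str) -> float:
        for g, v in self.activated + self.inhibited:
            if g == gene:
                return v
        raise KeyError(gene)

    def __len__(self) -> int:
        return len(self.activated) + len(self.inhibited)


def _sorted_tail(values: pd.Series) -> list[tuple[str, float]]:
    items = sorted(values.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    return [(g, float(v)) for g, v in items]


def threshold_signature(profile: ActivationProfile, sigma_mult: float = 2.0) -> PathwaySignature:
    """Apply the μ ± m·σ rule (strict inequalities) to a profile.

    With σ = 0 no gene can strictly exceed the bounds: the signature is
    empty and a warning is emitted.
    """
    if sigma_mult <= 0:
        raise ConfigError(f"sigma_mult must be > 0, got {sigma_mult}")
    v = profile.combined_values
    if len(v) == 0:
        warnings.warn(f"empty activation profile for {profile.pathway.value}", stacklevel=2)
        return PathwaySignature(profile.pathway, [], [], sigma_mult)
    if profile.sigma <= 1e-12 * max(1.0, float(np.max(np.abs(v.to_numpy()), initial=0.0))):
        warnings.warn(
            f"sigma = 0 for pathway {profile.pathway.value}; signature is empty",
            stacklevel=2,
        )
        return PathwaySignature(profile.pathway, [], [], sigma_mult)
    upper = profile.mu + sigma_mult * profile.sigma
    lower = profile.mu - sigma_mult * profile.sigma
    activated = v[(v > upper) & (v > 0)]
    inhibited = v[(v < lower) & (v < 0)]
    return PathwaySignature(
        profile.pathway, _sorted_tail(activated), _sorted_tail(inhibited), sigma_mult
    )


@dataclass
class SignatureSet:
    """One signature per pathway plus their source profiles and category."""

    signatures: dict[Pathway, PathwaySignature]
    profiles: dict[Pathway, Optional[ActivationProfile]]
    category: Optional[CategoryKey] = None
    #: pathways whose profile could not be computed in this category
    missing_pathways: frozenset[Pathway] = frozenset()

    def __post_init__(self) -> None:
        assert set(self.signatures) == set(PATHWAYS), "all three pathways must be present"

    def union_genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for sig in self.signatures.values():
            out |= sig.genes
        return out


def build_signature_set(
    matrix: FoldChangeMatrix,
    config: ActivatorConfig,
    *,
    category: Optional[CategoryKey] = None,
    sigma_mult: float = 2.0,
    require_all_activators: bool = False,
    ddof: int = 0,
    strict: bool = True,
) -> SignatureSet:
    """Derive all three pathway signatures on (a category slice of) *matrix*.

    With ``strict=False`` a pathway whose activators are absent from the
    slice yields an empty signature and is recorded in
    ``missing_pathways`` instead of raising — the behaviour stratified
    runs need (e.g. kidney categories lack an ATF4 activator).
    """
    sliced = select_category(matrix, category) if category is not None else matrix
    signatures: dict[Pathway, PathwaySignature] = {}
    profiles: dict[Pathway, Optional[ActivationProfile]] = {}
    missing: set[Pathway] = set()
    for pathway in PATHWAYS:
        try:
            profile = compute_profile(
                sliced,
                pathway,
                config,
                require_all_activators=require_all_activators,
                ddof=ddof,
                category=category,
            )
        except ConfigError:
            if strict:
                raise
            missing.add(pathway)
            profiles[pathway] = None
            signatures[pathway] = PathwaySignature(pathway, [], [], sigma_mult)
            warnings.warn(
                f"no activator coverage for {pathway.value}"
                + (f" in {category.label()}" if category else ""),
                stacklevel=2,
            )
            continue
        profiles[pathway] = profile
        signatures[pathway] = threshold_signature(profile, sigma_mult)
    return SignatureSet(signatures, profiles, category, frozenset(missing))


@dataclass
class OverlapPartition:
    """The seven-zone Venn partition of the three thresholded signatures.

    Zones are keyed by the frozenset of member pathways; ``values`` keeps
    each pathway's average activation value for every gene in its
    signature, for reporting.  Zone disjointness and coverage of the
    signature union are asserted at construction.
    """

    exclusive: dict[Pathway, frozenset[str]]
    pairwise: dict[frozenset[Pathway], frozenset[str]]
    triple: frozenset[str]
    values: dict[Pathway, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        zones = list(self.exclusive.values()) + list(self.pairwise.values()) + [self.triple]
        total = sum(len(z) for z in zones)
        union: set[str] = set()
        for z in zones:
            union |= z
        assert total == len(union), "Venn zones must be mutually disjoint"

    def zone(self, pathways: frozenset[Pathway]) -> frozenset[str]:
        if len(pathways) == 1:
            (p,) = pathways
            return self.exclusive[p]
        if len(pathways) == 2:
            return self.pairwise[frozenset(pathways)]
        if len(pathways) == 3:
            return self.triple
        raise KeyError(pathways)

    def zone_sizes(self) -> dict[str, int]:
        """The 7 labeled zone sizes in canonical order."""
        out = {p.value: len(self.exclusive[p]) for p in PATHWAYS}
        for a, b in ((PATHWAYS[0], PATHWAYS[1]), (PATHWAYS[1], PATHWAYS[2]), (PATHWAYS[0], PATHWAYS[2])):
            out[f"{a.value}+{b.value}"] = len(self.pairwise[frozenset({a, b})])
        out["+".join(p.value for p in PATHWAYS)] = len(self.triple)
        return out

    def all_genes(self) -> frozenset[str]:
        out = set(self.triple)
        for z in self.exclusive.values():
            out |= z
        for z in self.pairwise.values():
            out |= z
        return frozenset(out)


def partition_overlaps(sigset: SignatureSet) -> OverlapPartition:
    """Classify every signature gene by its membership vector across pathways."""
    membership: dict[str, set[Pathway]] = {}
    for pathway, sig in sigset.signatures.items():
        for gene in sig.genes:
            membership.setdefault(gene, set()).add(pathway)

    exclusive = {p: frozenset(g for g, m in membership.items() if m == {p}) for p in PATHWAYS}
    pairwise = {
        frozenset(pair): frozenset(g for g, m in membership.items() if m == set(pair))
        for pair in (
            (PATHWAYS[0], PATHWAYS[1]),
            (PATHWAYS[1], PATHWAYS[2]),
            (PATHWAYS[0], PATHWAYS[2]),
        )
    }
    triple = frozenset(g for g, m in membership.items() if len(m) == 3)
    values = {
        p: {g: v for g, v in sig.activated + sig.inhibited}
        for p, sig in sigset.signatures.items()
    }
    return OverlapPartition(exclusive=exclusive, pairwise=pairwise, triple=triple, values=values)


def stratified_signatures(
    matrix: FoldChangeMatrix,
    config: ActivatorConfig,
    keys: Sequence[CategoryKey],
    *,
    sigma_mult: float = 2.0,
    require_all_activators: bool = False,
    ddof: int = 0,
) -> list[SignatureSet]:
    """One SignatureSet per category key, tolerating activator gaps.

    Categories lacking any activator for a pathway yield that pathway as a
    recorded absence (empty signature + ``missing_pathways``), not a crash.
    """
    if not keys:
        raise ConfigError("need at least one category key")
    return [
        build_signature_set(
            matrix,
            config,
            category=key,
            sigma_mult=sigma_mult,
            require_all_activators=require_all_activators,
            ddof=ddof,
            strict=False,
        )
        for key in keys
    ]
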