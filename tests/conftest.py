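import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from toxsig import FoldChangeMatrix

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_matrix(rows, genes=None):
    """Build a FoldChangeMatrix from (condition_meta, gene, log2fc) triples.

    ``rows`` is a list of dicts with the long-table columns; metadata for a
    condition_id may be repeated and must agree.
    """
    frame = pd.DataFrame(rows)
    meta_cols = [
        "condition_id",
        "chemical",
        "species",
        "tissue",
        "setting",
        "dosing",
        "time_h",
        "dose_label",
        "project",
    ]
    meta = frame[meta_cols].drop_duplicates().set_index("condition_id")
    values = frame[["condition_id", "gene", "log2fc"]].dropna(subset=["log2fc"])
    return FoldChangeMatrix(meta, values, genes=genes)


def cond(condition_id, chemical, time_h=6.0, species="human", tissue="liver",
         setting="in_vitro", dosing="bolus", dose_label="mid", project="test"):
    return dict(
        condition_id=condition_id,
        chemical=chemical,
        species=species,
        tissue=tissue,
        setting=setting,
        dosing=dosing,
        time_h=time_h,
        dose_label=dose_label,
        project=project,
    )


@pytest.fixture
def tiny_matrix():
    """4 conditions (3 chemicals, mixed categories/times), 4 genes, 1 missing."""
    rows = [
        {**cond("c1", "ChemA", time_h=6.0), "gene": "g1", "log2fc": 1.0},
        {**cond("c1", "ChemA", time_h=6.0), "gene": "g2", "log2fc": -0.5},
        {**cond("c2", "ChemA", time_h=24.0), "gene": "g1", "log2fc": 3.0},
        {**cond("c2", "ChemA", time_h=24.0), "gene": "g3", "log2fc": 0.25},
        {**cond("c3", "ChemB", time_h=72.0, species="rat", setting="in_vivo",
                dosing="repeated"), "gene": "g1", "log2fc": 0.1},
        {**cond("c3", "ChemB", time_h=72.0, species="rat", setting="in_vivo",
                dosing="repeated"), "gene": "g4", "log2fc": -2.0},
        {**cond("c4", "ChemC", time_h=6.0, tissue="kidney"), "gene": "g2", "log2fc": 0.8},
    ]
    return make_matrix(rows, genes=["g1", "g2", "g3", "g4", "g5"])


def random_matrix(rng, n_genes=50, n_conditions=30, n_chemicals=6, missing=0.2):
    """Dense-ish random matrix for brute-force oracle comparisons."""
    genes = [f"g{i:03d}" for i in range(n_genes)]
    chems = [f"chem{i}" for i in range(n_chemicals)]
    rows = []
    for c in range(n_conditions):
        meta = cond(
            f"c{c:03d}",
            chems[int(rng.integers(n_chemicals))],
            time_h=float(rng.choice([2.0, 8.0, 24.0, 72.0])),
            species=str(rng.choice(["human", "rat"])),
            tissue=str(rng.choice(["liver", "kidney"])),
            setting=str(rng.choice(["in_vitro", "in_vivo"])),
            dosing=str(rng.choice(["bolus", "repeated"])),
        )
        for g in genes:
            if rng.random() >= missing:
                rows.append({**meta, "gene": g, "log2fc": float(rng.normal())})
    return make_matrix(rows, genes=genes)
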