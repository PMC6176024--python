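import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import toxsig as ts
from toxsig.signatures import ActivationProfile

from conftest import cond, make_matrix, random_matrix


def brute_force_means(matrix, chemical):
    """Independent per-gene mean over a chemical's conditions (plain loops)."""
    conds = set(matrix.conditions_of_chemical(chemical))
    acc = {}
    for row in matrix.values.itertuples(index=False):
        if row.condition_id in conds:
            acc.setdefault(row.gene, []).append(row.log2fc)
    return {g: sum(v) / len(v) for g, v in acc.items()}


def profile_of(values: dict, pathway=ts.Pathway.AHR, ddof=0):
    s = pd.Series(values, dtype=float)
    arr = s.to_numpy()
    return ActivationProfile(
        pathway=pathway,
        per_activator_means={"x": s},
        combined_values=s,
        mu=float(np.mean(arr)),
        sigma=float(np.std(arr, ddof=ddof)),
        excluded_genes=frozenset(),
        ddof=ddof,
    )


class TestActivatorMeans:
    def test_arithmetic_mean_over_conditions(self, tiny_matrix):
        means = ts.per_activator_gene_means(tiny_matrix, "ChemA")
        assert means["g1"] == pytest.approx(2.0)  # (1.0 + 3.0)/2

    def test_gene_without_data_omitted(self, tiny_matrix):
        means = ts.per_activator_gene_means(tiny_matrix, "ChemA")
        assert "g4" not in means and "g5" not in means

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_loop(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, n_genes=50, n_conditions=30)
        for chem in m.chemicals():
            got = ts.per_activator_gene_means(m, chem).to_dict()
            assert got == pytest.approx(brute_force_means(m, chem))


class TestCombineMeans:
    def test_mean_of_means(self):
        combined = ts.combine_activator_means([{"g": 1.0}, {"g": 0.0}])
        assert combined["g"] == pytest.approx(0.5)

    def test_gene_under_one_activator_passes_through(self):
        combined = ts.combine_activator_means([{"g": 0.8}, {"h": 1.0}])
        assert combined["g"] == pytest.approx(0.8)
        assert combined["h"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_mean_of_means_not_pooled_mean(self, seed):
        # two activators with unequal condition counts: the combined value
        # must match the mean-of-means oracle, not the pooled-condition mean
        rng = np.random.default_rng(1000 + seed)
        rows = []
        na, nb = 2, 5
        for i in range(na):
            rows.append({**cond(f"a{i}", "ActA"), "gene": "g", "log2fc": float(rng.normal())})
        for i in range(nb):
            rows.append({**cond(f"b{i}", "ActB"), "gene": "g", "log2fc": float(rng.normal())})
        m = make_matrix(rows)
        ma = brute_force_means(m, "ActA")["g"]
        mb = brute_force_means(m, "ActB")["g"]
        pooled = m.values["log2fc"].mean()
        combined = ts.combine_activator_means(
            [ts.per_activator_gene_means(m, "ActA"), ts.per_activator_gene_means(m, "ActB")]
        )["g"]
        assert combined == pytest.approx((ma + mb) / 2)
        assert combined != pytest.approx(pooled, abs=1e-12) or math.isclose(
            (ma + mb) / 2, pooled
        )

    def test_all_empty_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = ts.combine_activator_means([pd.Series(dtype=float)])
        assert len(out) == 0


class TestComputeProfile:
    @staticmethod
    def _config():
        return ts.ActivatorConfig(
            activators={
                ts.Pathway.AHR: ["ChemA"],
                ts.Pathway.NRF2: ["ChemB"],
                ts.Pathway.ATF4: ["ChemC"],
            }
        )

    def test_identical_values_give_sigma_zero(self):
        rows = [
            {**cond("c1", "ChemA"), "gene": g, "log2fc": 0.4} for g in ("g1", "g2", "g3")
        ]
        m = make_matrix(rows)
        prof = ts.compute_profile(m, ts.Pathway.AHR, self._config())
        assert prof.sigma == 0.0 and prof.mu == pytest.approx(0.4)

    def test_mu_sigma_closed_form(self):
        # values {0,0,0,10}: mu = 2.5, population sigma = sqrt(75/4)
        rows = [
            {**cond("c1", "ChemA"), "gene": f"g{i}", "log2fc": v}
            for i, v in enumerate([0.0, 0.0, 0.0, 10.0])
        ]
        prof = ts.compute_profile(make_matrix(rows), ts.Pathway.AHR, self._config())
        assert prof.mu == pytest.approx(2.5)
        assert prof.sigma == pytest.approx(math.sqrt(75.0 / 4.0))
        # sample-SD alternative stays available and differs
        prof1 = ts.compute_profile(
            make_matrix(rows), ts.Pathway.AHR, self._config(), ddof=1
        )
        assert prof1.sigma == pytest.approx(5.0)

    def test_excluded_genes_have_no_activator_data(self, tiny_matrix):
        prof = ts.compute_profile(tiny_matrix, ts.Pathway.AHR, self._config())
        # g4 measured only under ChemB, g5 never measured
        assert prof.excluded_genes == {"g4", "g5"}
        assert set(prof.combined_values.index).isdisjoint(prof.excluded_genes)

    def test_missing_activator_errors_with_pathway_and_category(self, tiny_matrix):
        key = ts.CategoryKey(species="rat", tissue="kidney", setting="in_vivo")
        with pytest.raises(ts.ConfigError, match="Nrf2.*rat/kidney/in_vivo"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ts.compute_profile(
                    ts.select_category(tiny_matrix, key),
                    ts.Pathway.NRF2,
                    self._config(),
                    category=key,
                )

    @pytest.mark.parametrize("seed", range(20))
    def test_mu_sigma_match_brute_force(self, seed):
        rng = np.random.default_rng(2000 + seed)
        m = random_matrix(rng, n_genes=50, n_conditions=30)
        config = ts.ActivatorConfig(
            activators={
                ts.Pathway.AHR: ["chem0", "chem1"],
                ts.Pathway.NRF2: ["chem2"],
                ts.Pathway.ATF4: ["chem3"],
            }
        )
        prof = ts.compute_profile(m, ts.Pathway.AHR, config)
        m0, m1 = brute_force_means(m, "chem0"), brute_force_means(m, "chem1")
        expected = {}
        for g in set(m0) | set(m1):
            vals = [d[g] for d in (m0, m1) if g in d]
            expected[g] = sum(vals) / len(vals)
        assert prof.combined_values.to_dict() == pytest.approx(expected)
        arr = np.array(list(expected.values()))
        assert prof.mu == pytest.approx(arr.mean())
        assert prof.sigma == pytest.approx(arr.std(ddof=0))


class TestThresholdSignature:
    def test_two_outliers_among_flat_background(self):
        values = {f"b{i:02d}": 0.1 for i in range(98)}
        values.update({"up": 5.0, "down": -5.0})
        prof = profile_of(values)
        arr = np.array(list(values.values()))
        mu, sd = arr.mean(), arr.std()
        assert 5.0 > mu + 2 * sd and -5.0 < mu - 2 * sd  # oracle bounds
        sig = ts.threshold_signature(prof)
        assert [g for g, _ in sig.activated] == ["up"]
        assert [g for g, _ in sig.inhibited] == ["down"]

    def test_all_equal_values_give_empty_signature(self):
        prof = profile_of({f"g{i}": 1.3 for i in range(10)})
        with pytest.warns(UserWarning, match="sigma = 0"):
            sig = ts.threshold_signature(prof)
        assert len(sig) == 0

    def test_positive_guard_on_activated_genes(self):
        # mu is very negative: a value above mu+2sigma but <= 0 is NOT activated
        values = {f"g{i}": -10.0 for i in range(40)}
        values["zero"] = 0.0
        values["neg"] = -0.5
        prof = profile_of(values)
        assert prof.mu + 2 * prof.sigma < -0.5  # both exceed the upper bound...
        sig = ts.threshold_signature(prof)
        assert [g for g, _ in sig.activated] == []  # ...but neither is positive
        assert [g for g, _ in sig.inhibited] == []

    def test_strict_inequality_excludes_boundary(self):
        # crafted so one value sits exactly at mu + 2 sigma
        values = {"a": 1.0, "b": -1.0, "c": 2.0, "d": -2.0}
        prof = profile_of(values)
        boundary = prof.mu + 2 * prof.sigma
        values["e"] = boundary
        # recompute profile including the boundary gene, then pin the bound
        prof2 = profile_of(values)
        upper = prof2.mu + 2 * prof2.sigma
        sig = ts.threshold_signature(prof2)
        assert all(v > upper for _, v in sig.activated)

    def test_ordering_decreasing_absolute_value_ties_alphabetical(self):
        values = {f"b{i:02d}": 0.0 for i in range(60)}
        values.update({"x": 3.0, "y": -4.0, "z": 3.0})
        sig = ts.threshold_signature(profile_of(values))
        assert [g for g, _ in sig.activated] == ["x", "z"]
        assert [g for g, _ in sig.inhibited] == ["y"]

    def test_scaling_invariance_of_membership(self):
        rng = np.random.default_rng(5)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=200))}
        values["hot"] = 10.0
        sig1 = ts.threshold_signature(profile_of(values))
        c = 3.7
        scaled = profile_of({g: c * v for g, v in values.items()})
        sig2 = ts.threshold_signature(scaled)
        assert sig1.genes == sig2.genes
        for g, v in sig1.activated:
            assert scaled.combined_values[g] == pytest.approx(c * v)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=100))}
        items = list(values.items())
        rng.shuffle(items)
        sig1 = ts.threshold_signature(profile_of(values))
        sig2 = ts.threshold_signature(profile_of(dict(items)))
        assert sig1.activated == sig2.activated and sig1.inhibited == sig2.inhibited


class TestPartition:
    @staticmethod
    def _sigset(a, n, t):
        sigs = {}
        for p, genes in zip(ts.PATHWAYS, (a, n, t)):
            sigs[p] = ts.PathwaySignature(p, [(g, 1.0) for g in sorted(genes)], [])
        return ts.SignatureSet(sigs, {p: None for p in ts.PATHWAYS})

    def test_worked_example(self):
        part = ts.partition_overlaps(self._sigset({"a", "b"}, {"b", "c"}, {"c"}))
        assert part.exclusive[ts.Pathway.AHR] == {"a"}
        assert part.exclusive[ts.Pathway.NRF2] == set()
        assert part.exclusive[ts.Pathway.ATF4] == set()
        assert part.pairwise[frozenset({ts.Pathway.AHR, ts.Pathway.NRF2})] == {"b"}
        assert part.pairwise[frozenset({ts.Pathway.NRF2, ts.Pathway.ATF4})] == {"c"}
        assert part.pairwise[frozenset({ts.Pathway.AHR, ts.Pathway.ATF4})] == set()
        assert part.triple == set()

    def test_identical_signatures_all_triple(self):
        part = ts.partition_overlaps(self._sigset({"x", "y"}, {"x", "y"}, {"x", "y"}))
        assert part.triple == {"x", "y"}
        assert all(not z for z in part.exclusive.values())

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_zones_match_membership_vector_oracle(self, data):
        genes = [f"g{i}" for i in range(12)]
        sets = [
            set(data.draw(st.sets(st.sampled_from(genes)), label=p.value))
            for p in ts.PATHWAYS
        ]
        part = ts.partition_overlaps(self._sigset(*sets))
        # brute force: classify each gene by its 3-bit membership vector
        for g in set().union(*sets):
            vec = tuple(g in s for s in sets)
            members = frozenset(p for p, b in zip(ts.PATHWAYS, vec) if b)
            assert g in part.zone(members)
        # disjointness + coverage
        assert part.all_genes() == set().union(*sets)
        sizes = sum(part.zone_sizes().values())
        assert sizes == len(part.all_genes())


class TestStratified:
    def test_one_signature_set_per_category_key(self):
        cfg = ts.default_study_mimic(11)
        matrix, _, activators, _ = ts.generate(cfg)
        keys = [
            ts.CategoryKey(tissue="liver"),
            ts.CategoryKey(species="human", tissue="liver", setting="in_vitro"),
        ]
        sets_ = ts.stratified_signatures(matrix, activators, keys)
        assert len(sets_) == 2
        assert all(set(s.signatures) == set(ts.PATHWAYS) for s in sets_)

    def test_key_selecting_nothing_yields_empty_signatures(self, tiny_matrix):
        config = ts.ActivatorConfig(
            activators={
                ts.Pathway.AHR: ["ChemA"],
                ts.Pathway.NRF2: ["ChemB"],
                ts.Pathway.ATF4: ["ChemC"],
            }
        )
        key = ts.CategoryKey(species="rat", tissue="kidney")
        with pytest.warns(UserWarning):
            (sigset,) = ts.stratified_signatures(tiny_matrix, config, [key])
        assert sigset.missing_pathways == set(ts.PATHWAYS)
        assert all(len(s) == 0 for s in sigset.signatures.values())
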