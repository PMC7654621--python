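import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from temporadt.data_model import ValidationError
from temporadt.enrichment import (
    classify_temporal_type,
    correspondence_analysis,
    count_classifications,
    enrich,
    flag_recovery_specific,
    pcoa,
)


def _hypergeom_tail_oracle(N, K, n, x):
    return sum(
        math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
        for k in range(x, min(K, n) + 1)
    )


class TestEnrich:
    def _maps(self, N=100, K=10):
        population = {f"g{i}" for i in range(N)}
        annotated = {f"g{i}" for i in range(K)}
        gene2go = {g: frozenset({"GO:1"}) for g in annotated}
        return population, gene2go

    def test_matches_exact_tail_oracle(self):
        population, gene2go = self._maps()
        study = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        res = enrich(study, population, gene2go).set_index("term")
        expected = _hypergeom_tail_oracle(100, 10, 10, 5)
        assert res.loc["GO:1", "p"] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(6.53e-4, rel=0.05)

    def test_study_equals_population_p_one(self):
        population, gene2go = self._maps()
        res = enrich(set(population), population, gene2go)
        assert np.allclose(res["p"].to_numpy(), 1.0, atol=1e-9)

    def test_zero_hits_p_one(self):
        population, gene2go = self._maps()
        study = {f"g{i}" for i in range(50, 60)}
        res = enrich(study, population, gene2go).set_index("term")
        assert res.loc["GO:1", "study_count"] == 0
        assert res.loc["GO:1", "p"] == pytest.approx(1.0)

    def test_empty_study_empty_result(self):
        population, gene2go = self._maps()
        assert len(enrich(set(), population, gene2go)) == 0

    def test_study_must_be_subset(self):
        population, gene2go = self._maps()
        with pytest.raises(ValidationError):
            enrich({"not_there"}, population, gene2go)

    def test_pvalues_conservative_under_permutation(self):
        # permuted study sets should not over-reject
        rng = np.random.default_rng(0)
        population = [f"g{i}" for i in range(200)]
        gene2go = {g: frozenset({"GO:1"}) for g in population[:20]}
        hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            study = set(rng.choice(population, size=20, replace=False))
            res = enrich(study, set(population), gene2go)
            hits += int((res["p"] < 0.05).any())
        assert hits / n_perm <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_perm)


class TestTemporalTyping:
    @pytest.mark.parametrize(
        "t,s,expected",
        [
            ((1, 1, 1, 1, 1), (0, 0, 0, 0, 0), "II"),
            ((0, 0, 0, 0, 0), (0, 1, 1, 1, 0), "III"),
            ((1, 1, 0, 1, 0), (1, 1, 0, 1, 0), "I"),
            ((1, 1, 1, 0, 0), (0, 0, 1, 1, 0), "IV"),  # earlier and longer
            ((0, 0, 1, 1, 0), (1, 1, 1, 0, 0), "V"),
            ((1, 1, 0, 0, 0), (0, 1, 1, 1, 0), "VI"),  # earlier vs longer conflict
            ((1, 0, 0, 0, 0), (0, 1, 0, 0, 0), "IV"),  # earlier, same duration
        ],
    )
    def test_type_assignment(self, t, s, expected):
        assert classify_temporal_type(t, s) == expected

    def test_never_enriched_rejected(self):
        with pytest.raises(ValidationError):
            classify_temporal_type((0,) * 5, (0,) * 5)

    @given(
        st.lists(st.booleans(), min_size=5, max_size=5),
        st.lists(st.booleans(), min_size=5, max_size=5),
    )
    @settings(max_examples=300, deadline=None)
    def test_mirror_symmetry(self, t, s):
        if not (any(t) or any(s)):
            return
        mapping = {"II": "III", "III": "II", "IV": "V", "V": "IV", "I": "I", "VI": "VI"}
        assert classify_temporal_type(s, t) == mapping[classify_temporal_type(t, s)]

    def test_types_partition_default_run(self, default_run):
        tl = default_run.term_timelines
        drought_cols = [c for c in tl.columns if c.startswith(("T_", "S_"))]
        enriched_in_drought = tl[drought_cols].any(axis=1)
        assert tl.loc[enriched_in_drought, "type"].isin(
            ["I", "II", "III", "IV", "V", "VI"]
        ).all()
        assert tl.loc[~enriched_in_drought, "type"].isna().all()

    def test_recovery_specific_flag(self):
        assert flag_recovery_specific([0] * 5, [0] * 5, True, False)
        assert not flag_recovery_specific([0, 1, 0, 0, 0], [0] * 5, True, True)
        assert not flag_recovery_specific([0] * 5, [0] * 5, False, False)


class TestClassificationCounter:
    def test_conservation_and_multicount(self):
        cells = {"tolerant:T1": {"GO:1", "GO:2", "GO:3"}}
        go2class = {
            "GO:1": frozenset({"metabolism"}),
            "GO:2": frozenset({"metabolism", "transport"}),  # counted twice
        }
        table = count_classifications(cells, go2class)
        assert table["tolerant:T1"].sum() == 4  # 1 + 2 + 1 unclassified
        assert table.loc["metabolism", "tolerant:T1"] == 2
        assert table.loc["unclassified", "tolerant:T1"] == 1

    def test_empty_enrichment_zero_table(self):
        table = count_classifications({"c": set()}, {})
        assert table.size == 0 or (table.to_numpy() == 0).all()


class TestPcoa:
    def test_identical_objects_coincide(self):
        data = pd.DataFrame([[1, 0, 1], [1, 0, 1], [0, 1, 0], [1, 1, 1]],
                            index=list("abcd")).astype(bool)
        coords, eigvals = pcoa(data, distance="jaccard")
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-9)
        assert all(x >= y - 1e-12 for x, y in zip(eigvals, eigvals[1:]))

    def test_euclidean_coordinates_reproduce_distances(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.normal(0, 1, (4, 6)), index=list("abcd"))
        coords, eigvals = pcoa(data, distance="euclidean")
        original = squareform(pdist(data.to_numpy()))
        embedded = squareform(pdist(coords.to_numpy()))
        assert np.allclose(original, embedded, atol=1e-8)

    def test_matches_skbio_oracle(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        from skbio import DistanceMatrix

        rng = np.random.default_rng(9)
        data = pd.DataFrame(rng.normal(0, 1, (6, 4)),
                            index=[f"o{i}" for i in range(6)])
        coords, eigvals = pcoa(data, distance="euclidean")
        dm = DistanceMatrix(squareform(pdist(data.to_numpy())), ids=list(data.index))
        ref = skbio_ord.pcoa(dm)
        n_pos = coords.shape[1]
        assert np.allclose(
            np.sort(eigvals[:n_pos]), np.sort(ref.eigvals.to_numpy()[:n_pos]),
            atol=1e-8,
        )

    def test_needs_three_objects(self):
        with pytest.raises(ValidationError):
            pcoa(pd.DataFrame([[1, 0], [0, 1]]))


class TestCorrespondenceAnalysis:
    def test_independent_table_zero_inertia(self):
        r = np.array([0.2, 0.3, 0.5])
        c = np.array([0.4, 0.6])
        table = pd.DataFrame(np.outer(r, c) * 1000)
        _, _, inertia, sv = correspondence_analysis(table)
        assert inertia == pytest.approx(0.0, abs=1e-12)

    def test_inertia_equals_chi2_over_n(self):
        table = pd.DataFrame([[20, 5, 10], [3, 30, 8], [9, 7, 40]])
        _, _, inertia, sv = correspondence_analysis(table)
        chi2 = stats.chi2_contingency(table.to_numpy(), correction=False)[0]
        assert inertia == pytest.approx(chi2 / table.to_numpy().sum(), abs=1e-10)
        assert (sv**2).sum() == pytest.approx(inertia, abs=1e-12)

    def test_rejects_negative_entries(self):
        with pytest.raises(ValidationError):
            correspondence_analysis(pd.DataFrame([[1, -2], [3, 4]]))
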