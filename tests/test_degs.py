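import numpy as np
import pandas as pd
import pytest
from scipy import stats

from temporadt import generate
from temporadt.data_model import ExperimentSet, ValidationError
from temporadt.degs import (
    call_degs,
    compute_log2fc,
    final_deg_calls,
    flag_development_dependent,
    frequency_filter,
    label_drg_rrg,
    summarize_genotypes,
)


class TestLog2Fc:
    def test_near_doubling(self):
        assert compute_log2fc(10, 20, 0.01) == pytest.approx(0.9993, abs=1e-4)

    def test_identity_and_both_zero(self):
        assert compute_log2fc(7.3, 7.3) == 0.0
        assert compute_log2fc(0.0, 0.0, 0.01) == 0.0

    def test_rejects_negative(self):
        with pytest.raises(ValidationError):
            compute_log2fc(-1.0, 2.0)


class TestCallDegs:
    def test_threshold_conjunction(self, tiny_experiment):
        # both the FDR and the |log2FC| >= 1 condition must hold
        calls = call_degs(tiny_experiment, "G1", "T1").set_index("gene")
        assert calls.loc["geneA", "is_deg"]           # 2-fold, tight reps
        assert calls.loc["geneD", "is_deg"]           # 4-fold
        assert not calls.loc["geneB", "is_deg"]       # flat
        assert not calls.loc["geneC", "is_deg"]       # below expression floor
        assert np.isnan(calls.loc["geneC", "p"])

    def test_identical_conditions_no_degs(self, tiny_experiment):
        calls = call_degs(tiny_experiment, "G1", "T2").set_index("gene")
        assert not calls.loc["geneA", "is_deg"]
        assert calls.loc["geneD", "is_deg"]

    def test_welch_oracle_on_planted_gene(self):
        rng = np.random.default_rng(11)
        w = 2.0 ** rng.normal(3, 0.2, 3)
        d = 2.0 ** rng.normal(6, 0.2, 3)
        _, p = stats.ttest_ind(np.log2(d + 0.01), np.log2(w + 0.01), equal_var=False)
        assert p < 1e-3

    def test_single_library_mode(self):
        # one library per condition: z-test against adjacent-W spread
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        base = rng.uniform(2, 6, 200)
        cols, meta = {}, []
        for tp in ("T1", "T2", "T3", "T4", "T5"):
            for cond in ("W", "D"):
                shift = np.zeros(200)
                if cond == "D":
                    shift[0] = 3.0  # strong planted response on g0
                sid = f"G1_{cond}_{tp}"
                cols[sid] = 2.0 ** (base + shift + rng.normal(0, 0.1, 200))
                meta.append(dict(sample_id=sid, genotype="G1", condition=cond,
                                 timepoint=tp, replicate=1))
        es = ExperimentSet(
            expression=pd.DataFrame(cols, index=genes),
            samples=pd.DataFrame(meta).set_index("sample_id"),
        )
        calls = call_degs(es, "G1", "T3").set_index("gene")
        assert calls.loc["g0", "is_deg"]
        assert calls["is_deg"].sum() <= 5  # essentially only the planted gene


class TestDevelopmentFilter:
    def _series_experiment(self, w_profile):
        """One genotype, 5 W timepoints x 3 reps (plus D mirrors of W)."""
        rng = np.random.default_rng(2)
        cols, meta = {}, []
        for ti, tp in enumerate(("T1", "T2", "T3", "T4", "T5")):
            for cond in ("W", "D"):
                for rep in (1, 2, 3):
                    sid = f"G1_{cond}_{tp}_r{rep}"
                    cols[sid] = 2.0 ** (
                        np.array([4.0 + w_profile[ti], 4.0]) + rng.normal(0, 0.05, 2)
                    )
                    meta.append(dict(sample_id=sid, genotype="G1", condition=cond,
                                     timepoint=tp, replicate=rep))
        return ExperimentSet(
            expression=pd.DataFrame(cols, index=["dev", "flat"]),
            samples=pd.DataFrame(meta).set_index("sample_id"),
        )

    def test_adjacent_step_flagged(self):
        es = self._series_experiment([0, 0, 1.2, 1.2, 1.2])  # W2->W3 jump
        assert "dev" in flag_development_dependent(es, "G1")

    def test_constant_not_flagged(self):
        es = self._series_experiment([0, 0, 0, 0, 0])
        assert flag_development_dependent(es, "G1") == frozenset()

    def test_gradual_nonadjacent_change_not_flagged(self):
        # significant only between distant timepoints, never adjacent ones
        es = self._series_experiment([0, 0.4, 0.8, 1.2, 1.6])
        assert "dev" not in flag_development_dependent(es, "G1")
        # exhaustive adjacent-pair oracle: every adjacent |step| < threshold
        assert max(abs(np.diff([0, 0.4, 0.8, 1.2, 1.6]))) < 1.0

    def test_planted_dev_genes_never_survive(self, default_run):
        truth = default_run.truth
        dev = set(truth.genes.index[truth.genes["class"] == "dev_dependent"])
        final = default_run.calls
        survivors = set(final.loc[final["is_deg"], "gene"]) & dev
        assert not survivors


def _toy_calls():
    rows = []
    for genotype, genes in (("A", ["g1", "g2"]), ("B", ["g1"]), ("C", ["g3"])):
        for gene in genes:
            rows.append(dict(gene=gene, genotype=genotype, timepoint="T3",
                             log2fc=2.0, p=1e-4, fdr=1e-3, direction="up",
                             is_deg=True, dev_dependent=False))
    rows.append(dict(gene="g9", genotype="A", timepoint="R", log2fc=1.5,
                     p=1e-3, fdr=1e-2, direction="up", is_deg=True,
                     dev_dependent=False))
    rows.append(dict(gene="g9", genotype="B", timepoint="R", log2fc=1.4,
                     p=1e-3, fdr=1e-2, direction="up", is_deg=True,
                     dev_dependent=False))
    return pd.DataFrame(rows)


class TestFrequencyFilterAndLabels:
    def test_singleton_removed_pair_retained(self):
        out = frequency_filter(_toy_calls())
        kept = out[out["is_deg"]]
        assert set(kept["gene"]) == {"g1", "g9"}
        assert (kept.loc[kept["gene"] == "g1", "freq"] == 2).all()

    def test_idempotent(self):
        once = frequency_filter(_toy_calls())
        twice = frequency_filter(once)
        assert (once["is_deg"] == twice["is_deg"]).all()
        kept = once["is_deg"]
        pd.testing.assert_frame_equal(once[kept], twice[kept])

    def test_empty_input(self):
        empty = _toy_calls().iloc[0:0]
        assert len(frequency_filter(empty)) == 0

    def test_min_freq_validation(self):
        with pytest.raises(ValidationError):
            frequency_filter(_toy_calls(), min_freq=0)

    def test_drg_rrg_labels(self):
        out = label_drg_rrg(frequency_filter(_toy_calls()))
        g1 = out[(out["gene"] == "g1") & out["is_deg"]]
        assert g1["is_drg"].all() and not g1["is_rrg"].any()
        g9 = out[(out["gene"] == "g9") & out["is_deg"]]
        assert g9["is_rrg"].all() and not g9["is_drg"].any()

    def test_unknown_timepoint_rejected(self):
        calls = _toy_calls()
        calls.loc[0, "timepoint"] = "D7"
        with pytest.raises(ValidationError):
            label_drg_rrg(calls)

    def test_filters_only_remove(self, default_run):
        # final DEG set is a subset of the raw DEG set
        final = default_run.calls
        key = ["gene", "genotype", "timepoint"]
        raw_like = final[final["freq"] >= 1]  # freq>=1 means raw DEG eligible
        final_set = set(map(tuple, final.loc[final["is_deg"], key].to_numpy()))
        raw_set = set(map(tuple, raw_like[key].to_numpy()))
        assert final_set <= raw_set


class TestGenotypeSummary:
    def test_jaccard_arithmetic(self):
        calls = label_drg_rrg(frequency_filter(_toy_calls(), min_freq=1))
        summary, shared, presence, linkage = summarize_genotypes(calls)
        # A={g1,g2}, B={g1}: |A&B|/|A|B|| = 1/2
        assert shared.loc["A", "B"] == pytest.approx(0.5)
        assert shared.loc["A", "C"] == 0.0
        assert np.allclose(np.diag(shared), 1.0)
        assert np.allclose(shared, shared.T)

    def test_direction_partition(self, default_run):
        calls = default_run.calls
        drg = calls[calls["is_drg"]]
        n_up = (drg["direction"] == "up").sum()
        n_down = (drg["direction"] == "down").sum()
        assert n_up + n_down == len(drg)
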