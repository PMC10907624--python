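"""Efficacy/toxicity profiling, top-5% selection, pair labeling, proportion test."""

import math

import numpy as np
import pandas as pd
import pytest

from combnet.network import ClusterAssignment
from combnet.response import ResponseMatrix
from combnet.selection import (
    DrugProfile,
    all_pairs,
    label_combinations,
    profile_drugs,
    proportion_test,
    select_candidates,
)


def _matrix(a, n_patient):
    a = np.asarray(a, dtype=float)
    n_s, n_d = a.shape
    return ResponseMatrix(
        a=a,
        sample_ids=[f"s{i}" for i in range(n_s)],
        drug_ids=[f"d{j}" for j in range(n_d)],
        sample_class=["patient"] * n_patient + ["healthy"] * (n_s - n_patient),
    )


class TestProfiles:
    def test_one_of_each_class(self):
        m = _matrix([[0.8, 0.2], [0.1, 0.4]], n_patient=1)
        profs = profile_drugs(m)
        assert profs[0].efficacy == 0.8 and profs[0].toxicity == 0.1
        assert profs[1].efficacy == 0.2 and profs[1].toxicity == 0.4

    def test_matches_groupby_mean_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.random((10, 4))
        m = _matrix(a, n_patient=7)
        profs = profile_drugs(m)
        for j, p in enumerate(profs):
            assert p.efficacy == pytest.approx(a[:7, j].mean(), abs=1e-12)
            assert p.toxicity == pytest.approx(a[7:, j].mean(), abs=1e-12)

    def test_missing_class_rejected(self):
        m = _matrix([[0.5], [0.5]], n_patient=2)
        with pytest.raises(ValueError, match="healthy"):
            profile_drugs(m)


class TestSelection:
    def test_identical_drugs_select_nothing(self):
        profs = [DrugProfile(f"d{i}", 0.5, 0.2, 1) for i in range(10)]
        assert select_candidates(profs) == []

    def test_dominant_drug_selected_first(self):
        profs = [DrugProfile("best", 0.9, 0.05, 1)] + [
            DrugProfile(f"d{i}", 0.3, 0.3, 1 + i % 2) for i in range(9)
        ]
        sel = select_candidates(profs)
        assert sel and sel[0].drug_id == "best"

    def test_filter_soundness_on_synthetic_screen(self, default_screen):
        from combnet.response import extract_complete_submatrix, normalize_inhibition

        m = normalize_inhibition(extract_complete_submatrix(default_screen.screen))
        cl = ClusterAssignment(
            labels={d: default_screen.planted_cluster[d] for d in m.drug_ids},
            modularity=0,
        )
        profs = profile_drugs(m, cl)
        mean_eff = np.mean([p.efficacy for p in profs])
        mean_tox = np.mean([p.toxicity for p in profs])
        for p in select_candidates(profs, fraction=0.25):
            assert p.efficacy > mean_eff
            assert p.toxicity < mean_tox

    def test_per_cluster_cap(self):
        profs = [DrugProfile(f"d{i:02d}", 0.9 - i * 0.01, 0.05, 1) for i in range(10)]
        profs += [DrugProfile(f"e{i:02d}", 0.3, 0.4, 2) for i in range(10)]
        sel = select_candidates(profs, fraction=0.5, per_cluster=4)
        assert len(sel) == 4  # cluster-2 drugs never pass the mean filters

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(1)
        profs = [
            DrugProfile(f"d{i}", float(rng.random()), float(rng.random()), 1 + i % 2)
            for i in range(30)
        ]
        a = select_candidates(profs, fraction=0.3)
        shuffled = list(profs)
        rng.shuffle(shuffled)
        b = select_candidates(shuffled, fraction=0.3)
        assert [p.drug_id for p in a] == [p.drug_id for p in b]


class TestLabeling:
    def test_four_per_cluster_gives_16_inter_12_intra(self):
        labels = {f"c1_{i}": 1 for i in range(4)} | {f"c2_{i}": 2 for i in range(4)}
        cl = ClusterAssignment(labels=labels, modularity=0)
        pairs = all_pairs(sorted(labels))
        df = label_combinations(pairs, cl)
        counts = df["group"].value_counts()
        assert counts["inter"] == 16
        assert counts["intra_1"] == 6 and counts["intra_2"] == 6

    def test_self_pair_rejected(self):
        cl = ClusterAssignment(labels={"a": 1}, modularity=0)
        with pytest.raises(ValueError, match="self"):
            label_combinations([("a", "a")], cl)

    def test_unclustered_drug_rejected(self):
        cl = ClusterAssignment(labels={"a": 1}, modularity=0)
        with pytest.raises(ValueError, match="cluster"):
            label_combinations([("a", "zzz")], cl)


def _binom_tail_oracle(k, n, p0):
    return sum(
        math.comb(n, i) * p0**i * (1.0 - p0) ** (n - i) for i in range(k, n + 1)
    )


class TestProportionTest:
    def _records(self, eff_inter, tox_inter, eff_intra, tox_intra):
        rows = [
            {"group": "inter", "efficacy": e, "toxicity": t}
            for e, t in zip(eff_inter, tox_inter)
        ] + [
            {"group": "intra_1", "efficacy": e, "toxicity": t}
            for e, t in zip(eff_intra, tox_intra)
        ]
        return pd.DataFrame(rows)

    def test_exact_mode_matches_enumeration_oracle(self):
        """Exact binomial tail equals Σ C(n,i) p^i (1-p)^(n-i) for all n<=25."""
        from scipy.stats import binomtest

        for n in range(1, 26):
            for k in range(0, n + 1):
                ours = binomtest(k, n, 0.33, alternative="greater").pvalue
                assert ours == pytest.approx(_binom_tail_oracle(k, n, 0.33), abs=1e-12)

    def test_all_successes(self):
        # 16 inter records in the good corner of pooled Q3/Q1 thresholds
        rec = self._records(
            eff_inter=np.linspace(0.9, 1.0, 16),
            tox_inter=np.linspace(0.0, 0.05, 16),
            eff_intra=np.linspace(0.1, 0.3, 12),
            tox_intra=np.linspace(0.5, 0.9, 12),
        )
        res = proportion_test(rec)
        # Q3 over 28 pooled efficacies lies inside the inter block, so not
        # every inter record can clear it — successes = #\{eff > Q3, tox < Q1\}
        q3 = np.quantile(rec["efficacy"], 0.75)
        q1 = np.quantile(rec["toxicity"], 0.25)
        expected_k = int(
            (
                (rec["group"] == "inter")
                & (rec["efficacy"] > q3)
                & (rec["toxicity"] < q1)
            ).sum()
        )
        assert res.successes == expected_k
        assert res.trials == 16
        assert res.p_value == pytest.approx(
            _binom_tail_oracle(expected_k, 16, 0.33), abs=1e-12
        )

    def test_zero_successes_gives_p_one(self):
        rec = self._records(
            eff_inter=np.full(16, 0.2),
            tox_inter=np.full(16, 0.8),
            eff_intra=np.linspace(0.5, 1.0, 12),
            tox_intra=np.linspace(0.0, 0.2, 12),
        )
        res = proportion_test(rec)
        assert res.successes == 0
        assert res.p_value == 1.0

    def test_duality_swap_metrics(self):
        """Swapping the metric columns and negating values yields the same
        success set (efficacy-high/toxicity-low corner is self-dual)."""
        rng = np.random.default_rng(2)
        rec = self._records(
            eff_inter=rng.random(16),
            tox_inter=rng.random(16),
            eff_intra=rng.random(12),
            tox_intra=rng.random(12),
        )
        res = proportion_test(rec, metric_pair=("efficacy", "toxicity"))
        mirrored = rec.copy()
        mirrored["efficacy"], mirrored["toxicity"] = -rec["toxicity"], -rec["efficacy"]
        res2 = proportion_test(mirrored, metric_pair=("efficacy", "toxicity"))
        assert res.successes == res2.successes

    def test_normal_approx_direction(self):
        rec = self._records(
            eff_inter=np.linspace(0.9, 1.0, 16),
            tox_inter=np.linspace(0.0, 0.05, 16),
            eff_intra=np.linspace(0.1, 0.3, 12),
            tox_intra=np.linspace(0.5, 0.9, 12),
        )
        exact = proportion_test(rec, mode="exact_binomial")
        approx = proportion_test(rec, mode="normal_approx")
        assert approx.successes == exact.successes
        assert 0.0 <= approx.p_value <= 1.0

    def test_no_inter_records_rejected(self):
        rec = pd.DataFrame([{"group": "intra_1", "efficacy": 0.5, "toxicity": 0.5}])
        with pytest.raises(ValueError):
            proportion_test(rec)
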