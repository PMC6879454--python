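import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import txoverlap as tx
from txoverlap.datatypes import ConfigError


def welch_oracle(x, y):
    """Closed-form Welch statistic with Satterthwaite df, evaluated directly."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def bh_oracle(p):
    """Step-up definition: q_(i) = min_{j>=i} p_(j) * m / j, clipped to 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestWelch:
    def test_identical_groups_t0_p1(self):
        t, df, p = tx.welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1

    def test_matches_closed_form_oracle(self):
        x, y = [1, 2, 3, 4], [2, 4, 6, 8]
        t, df, p = tx.welch_t_test(x, y)
        t0, df0, p0 = welch_oracle(x, y)
        assert t == pytest.approx(t0, rel=1e-12)
        assert df == pytest.approx(df0, rel=1e-12)
        assert p == pytest.approx(p0, rel=1e-12)

    def test_permutation_within_groups_invariant(self):
        x, y = [3.0, 1.0, 2.5, 0.5], [2.0, 4.5, 1.5]
        _, _, p1 = tx.welch_t_test(x, y)
        _, _, p2 = tx.welch_t_test(x[::-1], sorted(y))
        assert p1 == pytest.approx(p2, rel=1e-14)

    def test_small_group_rejected(self):
        with pytest.raises(ConfigError, match=">= 2"):
            tx.welch_t_test([1.0], [1.0, 2.0])

    def test_zero_variance_unequal_means(self):
        t, _, p = tx.welch_t_test([2, 2, 2], [1, 1, 1])
        assert t == np.inf and p == 0

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        st.lists(st.floats(-50, 50), min_size=2, max_size=8),
    )
    def test_oracle_equivalence_property(self, x, y):
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
            return
        t, df, p = tx.welch_t_test(x, y)
        t0, df0, p0 = welch_oracle(x, y)
        assert t == pytest.approx(t0, rel=1e-9, abs=1e-12)
        assert p == pytest.approx(p0, rel=1e-9, abs=1e-12)


class TestBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_known_values(self, p, expected):
        assert tx.bh_adjust(p) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ConfigError):
            tx.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_step_up_oracle(self, p):
        q = tx.bh_adjust(p)
        assert q == pytest.approx(bh_oracle(p), rel=1e-12, abs=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-15)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_monotone_in_sorted_order_and_permutation_invariant(self, p):
        q = tx.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        perm = np.roll(np.arange(len(p)), 1)
        q_perm = tx.bh_adjust(np.asarray(p)[perm])
        assert q_perm == pytest.approx(q[perm], rel=1e-12, abs=1e-15)


class TestFoldChange:
    def test_equal_medians_unity(self):
        log2fc, fc = tx.fold_change_vs_control_median([3, 4, 5], [4, 4, 4])
        assert log2fc == 0 and fc == 1

    def test_one_log2_unit_doubles(self):
        log2fc, fc = tx.fold_change_vs_control_median([4, 4], [3, 3])
        assert log2fc == 1 and fc == 2

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=6))
    def test_even_length_median_matches_order_statistic_oracle(self, case):
        control = [0.0, 1.0]
        log2fc, fc = tx.fold_change_vs_control_median(case, control)
        s = sorted(case)
        n = len(s)
        med = (s[n // 2 - 1] + s[n // 2]) / 2 if n % 2 == 0 else s[n // 2]
        assert log2fc == pytest.approx(med - 0.5, abs=1e-12)
        assert fc == pytest.approx(2.0**log2fc)

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigError):
            tx.fold_change_vs_control_median([], [1.0])


class TestDifferentialExpression:
    def test_null_study_calibrated_and_constant_probe_handled(self):
        config = tx.StudyConfig(
            n_genes=2000, n_case=10, n_control=10, n_de=0, effect_size=0.0, seed=2
        )
        ds = tx.simulate_dataset(config)
        # splice in an all-constant probe to exercise the defined t=0 limit
        values = ds.matrix.values.copy()
        values.iloc[0, :] = 5.0
        records = tx.differential_expression(
            tx.ExpressionMatrix(values), ds.design, ds.annotation
        )
        const = records[records["probe_id"] == values.index[0]].iloc[0]
        assert const["t_stat"] == 0 and const["p_value"] == 1
        frac = (records["p_value"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * math.sqrt(0.05 * 0.95 / len(records))

    def test_null_pvalues_uniform_ks(self):
        config = tx.StudyConfig(
            n_genes=10_000, n_case=8, n_control=8, n_de=0, effect_size=0.0, seed=5
        )
        ds = tx.simulate_dataset(config)
        records = tx.differential_expression(ds.matrix, ds.design)
        ks = stats.kstest(records["p_value"], "uniform")
        assert ks.pvalue > 1e-3

    def test_planted_probe_detected_with_direction(self, strong_study):
        records = tx.differential_expression(
            strong_study.matrix, strong_study.design, strong_study.annotation
        )
        planted = strong_study.de_directions
        called = records[records["q_value"] <= 0.05]
        for gene, direction in planted.items():
            row = called[called["gene"] == gene]
            assert len(row) == 1
            assert row.iloc[0]["direction"] == ("up" if direction == 1 else "down")

    def test_ordering_deterministic_by_probe_id(self, strong_study):
        records = tx.differential_expression(strong_study.matrix, strong_study.design)
        assert list(records["probe_id"]) == sorted(records["probe_id"])

    def test_q_never_below_p(self, strong_study):
        records = tx.differential_expression(strong_study.matrix, strong_study.design)
        assert (records["q_value"] >= records["p_value"] - 1e-15).all()


class TestSelectSignature:
    def _records(self, rows):
        df = pd.DataFrame(
            rows,
            columns=["probe_id", "gene", "fold_change", "p_value", "q_value", "direction"],
        )
        return df

    def _annotation(self, mapping):
        return tx.ProbeAnnotation(pd.Series(mapping, dtype=object), taxon="9606")

    def test_conflicting_probes_resolved_by_min_p(self):
        records = self._records(
            [
                ("P1", "FLG", 4.0, 0.001, 0.01, "up"),
                ("P2", "FLG", 0.25, 0.0001, 0.001, "down"),
            ]
        )
        ann = self._annotation({"P1": "FLG", "P2": "FLG"})
        sig = tx.select_signature(records, ann, tx.SelectionConfig(), "d")
        assert sig.directions == {"FLG": -1}
        assert sig.pvalues["FLG"] == 0.0001

    def test_fc_cutoff_one_reduces_to_significance_filter(self):
        records = self._records(
            [
                ("P1", "A", 1.1, 0.01, 0.01, "up"),
                ("P2", "B", 1.0, 0.5, 0.5, "down"),
            ]
        )
        ann = self._annotation({"P1": "A", "P2": "B"})
        sig = tx.select_signature(
            records, ann, tx.SelectionConfig(fc_cutoff=1.0), "d"
        )
        assert sig.genes == {"A"}

    def test_unannotated_probes_dropped_and_empty_allowed(self, caplog):
        records = self._records([("P1", "", 4.0, 0.001, 0.001, "up")])
        ann = self._annotation({"P1": ""})
        sig = tx.select_signature(records, ann, tx.SelectionConfig(), "d")
        assert len(sig) == 0

    def test_raw_p_mode(self):
        records = self._records([("P1", "A", 4.0, 0.03, 0.2, "up")])
        ann = self._annotation({"P1": "A"})
        with_fdr = tx.select_signature(records, ann, tx.SelectionConfig(), "d")
        without = tx.select_signature(
            records, ann, tx.SelectionConfig(use_fdr=False), "d"
        )
        assert len(with_fdr) == 0 and without.genes == {"A"}


class TestEqualize:
    def _sig(self, label, n, p_start=0.001):
        genes = {f"G{i:03d}": (1, p_start + i * 1e-4) for i in range(n)}
        return tx.DiseaseSignature(
            label=label,
            taxon="9606",
            directions={g: d for g, (d, _) in genes.items()},
            pvalues={g: p for g, (_, p) in genes.items()},
        )

    def test_truncates_to_smallest_by_default(self):
        sigs = [self._sig("a", 30), self._sig("b", 25), self._sig("c", 40)]
        out = tx.equalize_signatures(sigs)
        assert [len(s) for s in out] == [25, 25, 25]
        assert [len(s) for s in sigs] == [30, 25, 40]  # inputs untouched

    def test_keeps_smallest_p(self):
        sig = self._sig("a", 10)
        out = tx.equalize_signatures([sig, self._sig("b", 5)])
        kept = out[0].genes
        assert kept == {f"G{i:03d}" for i in range(5)}

    def test_ties_broken_lexicographically_and_deterministic(self):
        directions = {g: 1 for g in ["GB", "GA", "GC"]}
        pvalues = {g: 0.01 for g in directions}
        sig = tx.DiseaseSignature("a", "9606", directions, pvalues)
        runs = {
            frozenset(tx.equalize_signatures([sig, self._sig("b", 2)])[0].genes)
            for _ in range(5)
        }
        assert runs == {frozenset({"GA", "GB"})}

    def test_target_larger_than_signature_rejected(self):
        with pytest.raises(ConfigError, match="target_size"):
            tx.equalize_signatures([self._sig("a", 5), self._sig("b", 8)], target_size=6)
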