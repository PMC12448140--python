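import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from looptrax.cohort_io import Cohort, PhenotypeRecord, VariableSchema, CohortSchema
from looptrax.stats import (
    ContingencyTable,
    bh_adjust,
    chi_square_gof,
    fisher_exact,
    pairwise_scan,
    sankey_flows,
)


def table(counts):
    counts = np.asarray(counts)
    return ContingencyTable(
        counts=counts,
        row_labels=tuple(f"r{i}" for i in range(counts.shape[0])),
        col_labels=tuple(f"c{j}" for j in range(counts.shape[1])),
    )


# independent oracle: exact-Fraction enumeration over fixed-margin tables
from _oracles import fisher_p_enumeration as oracle_fisher_p


class TestFisherExact:
    def test_diagonal_5_table(self):
        # margins (5,5)/(5,5): only 6 tables; the two extreme ones carry 1/252 each
        res = fisher_exact(table([[5, 0], [0, 5]]))
        assert res.p_value == pytest.approx(2 / 252, abs=1e-12)
        assert res.method == "exact-2x2"

    def test_identical_rows_give_p_one(self):
        assert fisher_exact(table([[3, 3], [3, 3]])).p_value == pytest.approx(1.0)

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = fisher_exact(table([[0, 0], [3, 4]]))
        assert res.p_value == 1.0

    @settings(derandomize=True, max_examples=80)
    @given(
        a=st.integers(0, 10), b=st.integers(0, 10),
        c=st.integers(0, 10), d=st.integers(0, 10),
    )
    def test_2x2_matches_scipy(self, a, b, c, d):
        counts = [[a, b], [c, d]]
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        ours = fisher_exact(table(counts)).p_value
        theirs = scipy_fisher(np.array(counts), alternative="two-sided")[1]
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_rxc_exact_matches_fraction_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            r, c = rng.integers(2, 4, size=2)
            counts = rng.integers(0, 5, size=(r, c))
            if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
                continue
            res = fisher_exact(table(counts))
            assert res.method == ("exact-2x2" if counts.shape == (2, 2) else "exact-enumeration")
            assert res.p_value == pytest.approx(float(oracle_fisher_p(counts)), abs=1e-12)

    def test_monte_carlo_agrees_with_exact(self):
        counts = [[8, 2, 1], [2, 7, 3], [1, 2, 9]]
        exact = fisher_exact(table(counts)).p_value
        mc = fisher_exact(table(counts), enumeration_budget=1, mc_replicates=40_000, seed=3)
        assert mc.method == "monte-carlo"
        assert mc.mc_standard_error is not None
        assert abs(mc.p_value - exact) < 4 * mc.mc_standard_error + 1e-3

    def test_exact_p_is_conservative_under_independence(self):
        """Fisher p under a true null is stochastically >= uniform."""
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(300):
            x = rng.integers(0, 2, size=30)
            y = rng.integers(0, 2, size=30)
            counts = np.zeros((2, 2), int)
            np.add.at(counts, (x, y), 1)
            if min(counts.sum(0).min(), counts.sum(1).min()) == 0:
                continue
            ps.append(fisher_exact(table(counts)).p_value)
        ps = np.asarray(ps)
        for alpha in (0.05, 0.1, 0.25):
            assert (ps <= alpha).mean() <= alpha + 0.03


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.03, 0.04]) == pytest.approx([0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.07, 0.07, 0.07]) == pytest.approx([0.07, 0.07, 0.07])

    def test_adjusted_at_least_raw_and_capped(self):
        raw = [0.001, 0.2, 0.9, 0.04, 1.0]
        adj = bh_adjust(raw)
        assert np.all(adj >= raw) and np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])

    @settings(derandomize=True, max_examples=40)
    @given(data=st.data())
    def test_monotone_in_every_coordinate(self, data):
        ps = data.draw(
            st.lists(st.floats(1e-6, 1.0, exclude_min=False), min_size=2, max_size=8)
        )
        idx = data.draw(st.integers(0, len(ps) - 1))
        bumped = list(ps)
        bumped[idx] = min(1.0, bumped[idx] * 1.5 + 1e-6)
        assert np.all(bh_adjust(bumped) >= bh_adjust(ps) - 1e-12)


class TestChiSquareGof:
    def test_exact_match_gives_zero(self):
        stat, p = chi_square_gof([10, 10, 10, 10], [0.25] * 4)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        stat, _ = chi_square_gof([20, 10, 5, 5], [0.25] * 4)
        assert stat == pytest.approx(15.0)

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError, match="zero expected"):
            chi_square_gof([5, 5], [1.0, 0.0])


class TestSankeyFlows:
    def test_zero_cells_omitted_and_counts_conserved(self):
        t = table([[5, 0], [2, 3]])
        flows = sankey_flows(t)
        assert len(flows) == 3
        assert sum(f["count"] for f in flows) == t.n

    def test_flows_regroup_to_row_margins(self):
        t = table([[4, 1, 2], [0, 3, 5]])
        flows = sankey_flows(t)
        by_source = {}
        for f in flows:
            by_source[f["source"]] = by_source.get(f["source"], 0) + f["count"]
        assert by_source == {"r0": 7, "r1": 8}


def _two_level_schema(names):
    variables = [
        VariableSchema(name="focal", role="E9.5", levels=("a", "b"), missing_codes=("unknown",))
    ] + [
        VariableSchema(name=n, role="E18.5", levels=("x", "y"), missing_codes=("unknown",))
        for n in names
    ]
    return CohortSchema(variables=tuple(variables))


class TestPairwiseScan:
    def _cohort(self, n=80, planted="f0", n_features=6, seed=0):
        rng = np.random.default_rng(seed)
        names = [f"f{i}" for i in range(n_features)]
        schema = _two_level_schema(names)
        records = []
        for i in range(n):
            focal = "a" if rng.random() < 0.5 else "b"
            feats = {"focal": focal}
            for nme in names:
                if nme == planted:
                    # strong association: follows the focal level 90% of the time
                    feats[nme] = ("x" if focal == "a" else "y") if rng.random() < 0.9 else (
                        "y" if focal == "a" else "x"
                    )
                else:
                    feats[nme] = "x" if rng.random() < 0.5 else "y"
            records.append(PhenotypeRecord(subject_id=f"S{i}", looping_class="unknown", features=feats))
        return Cohort(records=tuple(records), schema=schema), names

    def test_planted_association_ranks_first(self):
        cohort, names = self._cohort(seed=3)
        res = pairwise_scan(cohort, "focal", names)
        assert res[0].feature == "f0"
        assert res[0].p_adjusted < 0.01
        assert [r.p_raw for r in res] == sorted(r.p_raw for r in res)

    def test_empty_feature_list(self):
        cohort, _ = self._cohort()
        assert pairwise_scan(cohort, "focal", []) == []

    def test_single_level_feature_skipped_with_warning(self):
        cohort, names = self._cohort(seed=3)
        # overwrite one feature to a constant
        records = tuple(
            PhenotypeRecord(
                subject_id=r.subject_id, looping_class=r.looping_class,
                features={**r.features, "f1": "x"},
            )
            for r in cohort.records
        )
        const = Cohort(records=records, schema=cohort.schema)
        with pytest.warns(UserWarning, match="f1"):
            res = pairwise_scan(const, "focal", names)
        assert "f1" not in {r.feature for r in res}

    def test_false_discovery_rate_controlled_under_null(self):
        """With independent features, scans with any BH-significant hit at
        q=0.05 occur in at most ~5% of simulated scans."""
        hits = 0
        n_scans = 150
        for seed in range(n_scans):
            cohort, names = self._cohort(n=40, planted="none", n_features=8, seed=seed + 100)
            res = pairwise_scan(cohort, "focal", names)
            if res and min(r.p_adjusted for r in res) < 0.05:
                hits += 1
        assert hits / n_scans <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_scans)
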