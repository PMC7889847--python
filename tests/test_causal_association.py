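from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from lymphosig.causal_association import (
    associate_variants,
    causal_contribution,
    causal_contribution_table,
    derive_causal_peaks,
    fisher_exact,
    wilcoxon_rank_sum,
)
from lymphosig.channels import CHANNEL_LABELS, channel_from_label
from lymphosig.io_formats import SignatureMatrix


# --- independent oracles -----------------------------------------------------


def rank_sum_permutation_p(x, y):
    """Two-sided exact p by enumerating every assignment of pooled ranks to x."""
    pooled = sorted(x + y)
    nx = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # tie-free inputs only
    obs = sum(ranks[v] for v in x)
    mu = nx * (len(pooled) + 1) / 2
    total = extreme = 0
    for combo in combinations(range(1, len(pooled) + 1), nx):
        total += 1
        if abs(sum(combo) - mu) >= abs(obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


def fisher_enumeration_p(table):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = scipy.stats.hypergeom.pmf(a, n, col1, row1)
    p = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = scipy.stats.hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-9):
            p += pk
    return p


# --- causal peaks ------------------------------------------------------------


class TestCausalPeaks:
    def test_single_signature_claims_all_its_channels(self, signatures):
        one = signatures.restrict(["Signature 7"])
        peaks = derive_causal_peaks(one)
        expected = {i for i in range(96) if one.probabilities[0, i] > 0}
        assert set(peaks.assignments) == expected
        assert all(s == "Signature 7" for s in peaks.assignments.values())

    def test_identical_signatures_yield_no_peaks(self, signatures):
        p = signatures.profile("Signature 7")
        twins = SignatureMatrix(["A", "B"], np.vstack([p, p]))
        assert derive_causal_peaks(twins).assignments == {}

    def test_tcc_context_is_a_uv_peak(self, signatures):
        """With the aging and UV signatures retained, T[C>T]C belongs to UV."""
        peaks = derive_causal_peaks(
            signatures.restrict(["Signature 1", "Signature 7"])
        )
        idx = channel_from_label("T[C>T]C").index
        assert peaks.assignments[idx] == "Signature 7"
        assert peaks.dominance[idx] >= 0.75
        # and the aging signature keeps its NCG deamination peaks
        assert peaks.assignments[channel_from_label("A[C>T]G").index] == "Signature 1"

    def test_no_channel_double_assigned(self, signatures):
        peaks = derive_causal_peaks(signatures)
        per_sig = [set(peaks.channels_of(s)) for s in signatures.signature_ids]
        counted = sum(len(s) for s in per_sig)
        assert counted == len(peaks.assignments)


class TestCausalContribution:
    def test_complete_and_partial_assignment_arithmetic(self, signatures):
        peaks = derive_causal_peaks(
            signatures.restrict(["Signature 1", "Signature 7"])
        )
        uv_channels = peaks.channels_of("Signature 7")
        v = np.zeros(96)
        v[uv_channels[0]] = 50
        assert causal_contribution(v, peaks) == {"Signature 7": 100.0}

        unassigned = [i for i in range(96) if i not in peaks.assignments]
        v2 = np.zeros(96)
        v2[uv_channels[0]] = 30
        v2[unassigned[0]] = 30
        assert causal_contribution(v2, peaks)["Signature 7"] == pytest.approx(50.0)

    def test_scale_invariance(self, signatures, rng):
        peaks = derive_causal_peaks(signatures)
        v = rng.integers(0, 20, size=96).astype(float) + 1
        a = causal_contribution(v, peaks)
        b = causal_contribution(9 * v, peaks)
        assert a.keys() == b.keys()
        for k in a:
            assert a[k] == pytest.approx(b[k])

    def test_twenty_snv_gate_is_strict(self, signatures):
        peaks = derive_causal_peaks(signatures)
        cat = pd.DataFrame(
            [np.r_[np.full(20, 1.0), np.zeros(76)],
             np.r_[np.full(21, 1.0), np.zeros(75)]],
            index=["at_gate", "above_gate"], columns=list(CHANNEL_LABELS),
        )
        table = causal_contribution_table(cat, peaks)
        assert list(table.index) == ["above_gate"]
        assert table.attrs["excluded"] == ["at_gate"]


# --- rank-sum and Fisher tests ----------------------------------------------


class TestWilcoxon:
    def test_textbook_separation_example(self):
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_full_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 5), rng.integers(2, 5)
        pooled = rng.choice(1000, size=nx + ny, replace=False).astype(float)
        x, y = list(pooled[:nx]), list(pooled[nx:])
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(rank_sum_permutation_p(x, y), abs=1e-12)

    def test_exact_and_normal_paths_agree_for_6_plus_6(self, rng):
        # the continuity-corrected normal differs from the exact null by at
        # most ~0.015 over all 6+6 tie-free splits (worst at mid-range p)
        for _ in range(10):
            pooled = rng.choice(10_000, size=12, replace=False).astype(float)
            x, y = list(pooled[:6]), list(pooled[6:])
            _, p_exact = wilcoxon_rank_sum(x, y)
            res = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            )
            assert abs(p_exact - res.pvalue) < 0.016

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestFisher:
    def test_diagonal_table_enumeration_value(self):
        _, p, _ = fisher_exact([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252)

    def test_identical_rows_p_one(self):
        odds, p, corrected = fisher_exact([[7, 3], [7, 3]])
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)
        assert not corrected

    def test_atll_aggressive_vs_indolent_not_significant(self):
        """1/13 indolent vs 9/32 aggressive tumours showing the signature."""
        odds, p, _ = fisher_exact([[1, 12], [9, 23]])
        assert p > 0.05

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 10, size=(2, 2))
        _, p, _ = fisher_exact(table)
        assert p == pytest.approx(fisher_enumeration_p(table), rel=1e-9)

    def test_zero_cell_triggers_haldane_flag(self):
        odds, _, corrected = fisher_exact([[5, 0], [2, 5]])
        assert corrected
        assert odds == pytest.approx((5.5 * 5.5) / (0.5 * 2.5))

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            fisher_exact([[0, 5], [0, 5]])


# --- associate_variants ------------------------------------------------------


def _contributions(values_by_sample):
    return pd.DataFrame(
        {"Signature 17": pd.Series(values_by_sample)}
    ).rename_axis("sample_id")


def _recurrent(carriers):
    return pd.DataFrame(
        [{"gene": "IRF4", "protein_change": "K59R", "n_carriers": len(carriers),
          "carriers": list(carriers), "substitution_breakdown": {},
          "carriers_by_subtype": {}}]
    )


class TestAssociateVariants:
    def test_shifted_carriers_detected(self):
        contrib = _contributions(
            {f"hi{i}": 45.0 + i for i in range(10)}
            | {f"lo{i}": 10.0 + 0.1 * i for i in range(40)}
        )
        results = associate_variants(
            _recurrent([f"hi{i}" for i in range(10)]), contrib
        )
        assert len(results) == 1
        assert results[0].significant and results[0].p_value < 0.00029

    def test_too_few_eligible_carriers_skipped(self):
        contrib = _contributions({f"s{i}": float(i) for i in range(20)})
        results = associate_variants(_recurrent(["s0", "s1", "s2", "s3"]), contrib)
        assert results == []

    def test_carriers_not_in_contribution_table_are_ineligible(self):
        contrib = _contributions({f"s{i}": float(i) for i in range(10)})
        carriers = ["s0", "s1", "s2", "gated_out_1", "gated_out_2"]
        assert associate_variants(_recurrent(carriers), contrib) == []

    def test_empty_wild_type_group_skipped(self):
        contrib = _contributions({f"s{i}": float(i) for i in range(6)})
        assert associate_variants(_recurrent([f"s{i}" for i in range(6)]), contrib) == []

    def test_permuted_labels_are_calibrated(self, rng):
        """With carriers drawn at random, p < 0.05 should be rare."""
        values = {f"s{i}": float(v) for i, v in enumerate(rng.normal(20, 5, 50))}
        contrib = _contributions(values)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            carriers = list(rng.choice(list(values), size=10, replace=False))
            res = associate_variants(_recurrent(carriers), contrib)
            hits += res[0].p_value < 0.05
        assert hits / n_rep <= 0.08  # 0.05 plus binomial noise at n=200
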