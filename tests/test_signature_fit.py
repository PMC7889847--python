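import numpy as np
import pytest

from lymphosig.io_formats import SignatureMatrix, TrinucleotideFrequencyTable
from lymphosig.channels import CHANNELS, PYR_TRINUCLEOTIDES
from lymphosig.signature_fit import (
    FitConfig,
    cosine_similarity,
    fit_cohort,
    fit_sample,
    nnls_fit,
    renormalize_signatures,
    sparsify_fit,
)
from lymphosig.synthetic_data import sample_catalogue


def random_signatures(rng, k=3, concentration=0.5):
    probs = rng.dirichlet(np.full(96, concentration), size=k)
    return SignatureMatrix([f"R{i}" for i in range(k)], probs)


def grid_search_exposures(v, signatures, step=0.005):
    """Exhaustive search over the share simplex with the optimal scale per point.

    For each share vector s on the grid the mixture profile is m = s @ P and
    the best scale is t* = <v, m> / <m, m>, so the candidate exposures are
    t* s; the candidate with the smallest residual wins.  Independent of the
    active-set path used by the fit.
    """
    P = signatures.probabilities
    n = int(round(1 / step))
    pts = [
        (i, j, n - i - j)
        for i in range(n + 1)
        for j in range(n + 1 - i)
    ]
    G = np.array(pts, dtype=float) / n
    M = G @ P  # grid x 96
    numer = M @ v
    denom = np.einsum("ij,ij->i", M, M)
    t = np.where(denom > 0, np.maximum(numer, 0) / np.where(denom > 0, denom, 1), 0.0)
    resid2 = v @ v - 2 * t * numer + t**2 * denom
    best = int(np.argmin(resid2))
    return t[best] * G[best]


class TestCosine:
    def test_identity_orthogonality_scale(self):
        a = np.arange(1.0, 97.0)
        assert cosine_similarity(a, a) == pytest.approx(1.0)
        assert cosine_similarity(a, 2 * a) == pytest.approx(1.0)
        x = np.zeros(96); x[0] = 1
        y = np.zeros(96); y[1] = 1
        assert cosine_similarity(x, y) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            cosine_similarity(a, np.zeros(96))


class TestRenormalize:
    def uniform_table(self):
        return TrinucleotideFrequencyTable(
            {t: 1.0 for t in PYR_TRINUCLEOTIDES}, "genome"
        )

    def test_identity_ratio(self, signatures):
        t = self.uniform_table()
        out = renormalize_signatures(signatures, t, t)
        np.testing.assert_allclose(out.probabilities, signatures.probabilities)

    def test_doubling_one_trinucleotide_on_uniform_signature(self):
        uniform = SignatureMatrix(["U"], np.full((1, 96), 1 / 96))
        t_from = self.uniform_table()
        doubled = {t: (2.0 if t == "ACA" else 1.0) for t in PYR_TRINUCLEOTIDES}
        t_to = TrinucleotideFrequencyTable(doubled, "exome")
        out = renormalize_signatures(uniform, t_from, t_to)
        # ACA hosts 3 channels (C>A, C>G, C>T with A flanks); each gains 2x
        # before renormalisation: new mass 2/99 there, 1/99 elsewhere.
        for ch in CHANNELS:
            expected = 2 / 99 if ch.context == "ACA" else 1 / 99
            assert out.probabilities[0, ch.index] == pytest.approx(expected)
        assert out.probabilities.sum() == pytest.approx(1.0)

    def test_genome_exome_round_trip(self, signatures, rng):
        g = TrinucleotideFrequencyTable(
            {t: float(v) for t, v in zip(PYR_TRINUCLEOTIDES, rng.uniform(0.5, 2, 32))},
            "genome",
        )
        e = TrinucleotideFrequencyTable(
            {t: float(v) for t, v in zip(PYR_TRINUCLEOTIDES, rng.uniform(0.5, 2, 32))},
            "exome",
        )
        there = renormalize_signatures(signatures, g, e)
        back = renormalize_signatures(there, e, g)
        np.testing.assert_allclose(back.probabilities, signatures.probabilities,
                                   atol=1e-10)

    def test_zero_from_frequency_rejected(self):
        with pytest.raises(ValueError):
            TrinucleotideFrequencyTable(
                {t: (0.0 if t == "ACA" else 1.0) for t in PYR_TRINUCLEOTIDES}, "genome"
            )


class TestNnls:
    def test_exact_single_signature(self, signatures):
        sub = signatures.restrict(["Signature 1", "Signature 7"])
        v = 100 * signatures.profile("Signature 1")
        e = nnls_fit(v, sub)
        assert e["Signature 1"] == pytest.approx(100, abs=1e-8)
        assert e["Signature 7"] == pytest.approx(0, abs=1e-8)

    def test_exact_two_signature_combination(self, signatures):
        sub = signatures.restrict(["Signature 1", "Signature 7"])
        v = 60 * signatures.profile("Signature 1") + 40 * signatures.profile("Signature 7")
        e = nnls_fit(v, sub)
        assert e["Signature 1"] == pytest.approx(60, abs=1e-8)
        assert e["Signature 7"] == pytest.approx(40, abs=1e-8)

    def test_matches_grid_search_oracle(self, rng):
        total = 2000
        for _ in range(5):
            sigs = random_signatures(rng)
            shares = rng.dirichlet([1, 1, 1])
            p = shares @ sigs.probabilities
            v = rng.multinomial(total, p).astype(float)
            fitted = nnls_fit(v, sigs).to_numpy()
            oracle = grid_search_exposures(v, sigs)
            assert np.max(np.abs(fitted - oracle)) < 0.01 * total

    def test_no_unit_perturbation_improves_residual(self, rng):
        sigs = random_signatures(rng, k=4)
        v = rng.multinomial(1000, np.full(96, 1 / 96)).astype(float)
        e = nnls_fit(v, sigs).to_numpy()
        P = sigs.probabilities
        base = np.linalg.norm(v - e @ P)
        for i in range(4):
            for d in (+1.0, -1.0):
                trial = e.copy()
                trial[i] += d
                if (trial < 0).any():
                    continue
                assert np.linalg.norm(v - trial @ P) >= base - 1e-9

    def test_zero_catalogue_rejected(self, signatures):
        with pytest.raises(ValueError):
            nnls_fit(np.zeros(96), signatures)


class TestSparsify:
    def test_pure_catalogue_retains_only_generator(self, signatures):
        v = 500 * signatures.profile("Signature 1")
        res = sparsify_fit(v, signatures)
        assert res.retained_ids == ["Signature 1"]
        assert res.cosine == pytest.approx(1.0, abs=1e-9)

    def test_zero_budget_keeps_both_needed_signatures(self, signatures):
        v = 300 * signatures.profile("Signature 1") + 200 * signatures.profile("Signature 7")
        res = sparsify_fit(v, signatures, FitConfig(max_cosine_drop=0.0))
        assert set(res.retained_ids) >= {"Signature 1", "Signature 7"}

    def test_admissibility_and_monotone_trace(self, signatures, rng):
        for _ in range(20):
            shares = rng.dirichlet(np.ones(5))
            p = shares @ signatures.probabilities
            v = rng.multinomial(1000, p).astype(float)
            full = nnls_fit(v, signatures).to_numpy()
            c_full = cosine_similarity(v, full @ signatures.probabilities)
            res = sparsify_fit(v, signatures)
            assert res.cosine >= c_full - 0.05 - 1e-12
            last = c_full
            for _sid, c in res.removal_trace:
                assert c <= last + 1e-12
                last = c

    def test_greedy_within_budget_against_exhaustive_subsets(self, signatures, rng):
        """Exhaustive subset search confirms the greedy pick is admissible."""
        from itertools import combinations

        sub = signatures.restrict(["Signature 1", "Signature 2", "Signature 7"])
        expected = (
            0.9 * signatures.profile("Signature 1")
            + 0.1 * signatures.profile("Signature 2")
        )
        v = np.round(5000 * expected)
        res = sparsify_fit(v, sub)
        full = nnls_fit(v, sub).to_numpy()
        c_full = cosine_similarity(v, full @ sub.probabilities)
        assert set(res.retained_ids) <= {"Signature 1", "Signature 2"}
        assert res.cosine >= c_full - 0.05
        # the greedy result must be one of the admissible subsets
        admissible = []
        for r in (1, 2, 3):
            for ids in combinations(sub.signature_ids, r):
                e = nnls_fit(v, sub.restrict(list(ids))).to_numpy()
                recon = e @ sub.restrict(list(ids)).probabilities
                if recon.any() and cosine_similarity(v, recon) >= c_full - 0.05:
                    admissible.append(set(ids))
        assert set(res.retained_ids) in admissible

    def test_scale_equivariance(self, signatures, rng):
        shares = rng.dirichlet(np.ones(5))
        v = rng.multinomial(2000, shares @ signatures.probabilities).astype(float)
        a = sparsify_fit(v, signatures)
        b = sparsify_fit(7 * v, signatures)
        assert a.retained_ids == b.retained_ids
        assert b.cosine == pytest.approx(a.cosine, abs=1e-9)
        np.testing.assert_allclose(
            b.exposures.to_numpy(), 7 * a.exposures.to_numpy(), rtol=1e-6, atol=1e-6
        )

    def test_per_step_budget_flag(self, signatures):
        v = 500 * signatures.profile("Signature 7")
        res = sparsify_fit(v, signatures, FitConfig(per_step_budget=True))
        assert res.retained_ids == ["Signature 7"]


class TestSampleGates:
    def test_too_few_snvs(self, signatures):
        v = 15 * signatures.profile("Signature 7")
        res = fit_sample(v, signatures.restrict(["Signature 7"]))
        assert res.gate == "rejected_too_few_snvs" and res.retained_ids == []

    def test_exactly_twenty_snvs_rejected_under_strict_rule(self, signatures):
        v = np.zeros(96)
        v[:20] = 1
        res = fit_sample(v, signatures.restrict(["Signature 7"]))
        assert res.gate == "rejected_too_few_snvs"

    def test_small_exposure_dropped_with_refit(self, signatures):
        allowed = signatures.restrict(["Signature 1", "Signature 7"])
        v = 30 * signatures.profile("Signature 7") + 10 * signatures.profile("Signature 1")
        res = fit_sample(v, allowed)
        assert res.gate == "ok"
        assert res.retained_ids == ["Signature 7"]
        assert res.exposures["Signature 1"] == 0.0

    def test_low_cosine_voids_assignment(self, signatures):
        # all mass on T>A channels, orthogonal-ish to the C>T-heavy UV signature
        v = np.zeros(96)
        v[48:64] = 10  # the T>A block
        res = fit_sample(v, signatures.restrict(["Signature 7"]))
        assert res.gate == "rejected_low_cosine"
        assert res.retained_ids == []
        assert (res.exposures == 0).all()


class TestFitCohort:
    def test_parameter_recovery_60_40(self, genome, signatures):
        from lymphosig.catalogue import build_catalogue
        from lymphosig.synthetic_data import (
            SubtypeSpec, SyntheticCohortSpec, synthesize_cohort,
        )

        spec = SyntheticCohortSpec(
            [SubtypeSpec("MF", 50, {"Signature 1": 0.6, "Signature 7": 0.4},
                         burden_median=200, burden_sigma_log10=0.0)],
            seed=21,
        )
        cohort = synthesize_cohort(spec, genome, signatures)
        cat, _ = build_catalogue(cohort.records, genome.contigs, "subtype")
        _, pct = fit_cohort(cat, signatures)
        by_sig = dict(zip(pct["signature"], pct["percent"]))
        assert by_sig["Signature 1"] == pytest.approx(60, abs=5)
        assert by_sig["Signature 7"] == pytest.approx(40, abs=5)

    def test_single_row_cohort_equals_sparsify(self, signatures):
        import pandas as pd

        v = np.round(400 * signatures.profile("Signature 17"))
        cat = pd.DataFrame([v], index=["one"], columns=list(
            __import__("lymphosig.channels", fromlist=["CHANNEL_LABELS"]).CHANNEL_LABELS
        ))
        results, pct = fit_cohort(cat, signatures)
        direct = sparsify_fit(v, signatures)
        assert results["one"].retained_ids == direct.retained_ids
        assert results["one"].cosine == pytest.approx(direct.cosine)

    def test_parameter_recovery_mean_error_and_false_positives(self, signatures, rng):
        """NNLS shares track generating shares; sparsification keeps no extras.

        Active signatures are drawn from the four distinctive profiles
        (shares >= 0.15 each); the flat signature stays in the fitting pool
        as a false-positive trap.  Accuracy is measured on the NNLS fit;
        specificity on the sparsified retained set — the sparsifier itself
        deliberately trades sensitivity for specificity, so a barely
        identifiable low-share signature may be pruned within its cosine
        budget.
        """
        n_samples, n_mut = 60, 2000
        distinctive = ["Signature 1", "Signature 2", "Signature 7", "Signature 17"]
        errs, false_pos = [], 0
        for _ in range(n_samples):
            active = rng.choice(4, size=3, replace=False)
            shares = rng.dirichlet(np.ones(3))
            while shares.min() < 0.15:
                shares = rng.dirichlet(np.ones(3))
            share_map = {distinctive[a]: s for a, s in zip(active, shares)}
            v = sample_catalogue(share_map, n_mut, signatures, rng).astype(float)
            e = nnls_fit(v, signatures)
            fitted = e / e.sum()
            errs.extend(abs(fitted[k] - share_map[k]) for k in share_map)
            res = sparsify_fit(v, signatures)
            false_pos += any(
                sid in res.retained_ids
                for sid in signatures.signature_ids
                if sid not in share_map
            )
        assert np.mean(errs) < 0.03
        assert false_pos / n_samples <= 0.10
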