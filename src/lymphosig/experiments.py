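"""Seeded end-to-end verification experiments.

Each function runs one self-contained experiment on synthetic data —
NNLS-versus-grid-search agreement, sparsification admissibility, cohort
share recovery, driver-association power and calibration, UV strand
diagnostics, and the generator round trip — and returns the measured
quantities.  They are called both by the acceptance checks in the test
suite and by ``scripts/acceptance.py``; all randomness flows from the seed
argument.
"""

from __future__ import annotations

import numpy as np

from . import catalogue as cat
from . import causal_association as ca
from . import signature_fit as sf
from . import strand_genome as sg
from .channels import channel_from_label
from .io_formats import SignatureMatrix
from .synthetic_data import (
    SubtypeSpec,
    SyntheticCohortSpec,
    demo_signatures,
    generate_reference,
    generate_strand_cohort,
    inject_recurrent_variant,
    synthesize_cohort,
)


def grid_search_exposures(
    v: np.ndarray, signatures: SignatureMatrix, step: float = 0.005
) -> np.ndarray:
    """Exhaustive 3-signature exposure search: share simplex grid x best scale.

    For each share vector s on the simplex grid the mixture profile is
    m = s @ P and the optimal non-negative scale is t* = <v,m>/<m,m>, so the
    candidate exposures are t* s; the candidate with the smallest residual
    wins.  Brute force — no active sets, no pivoting — so it serves as an
    independent check on the NNLS solver.
    """
    P = signatures.probabilities
    if P.shape[0] != 3:
        raise ValueError("grid oracle is written for exactly 3 signatures")
    n = int(round(1 / step))
    pts = [(i, j, n - i - j) for i in range(n + 1) for j in range(n + 1 - i)]
    G = np.array(pts, dtype=float) / n
    M = G @ P
    numer = M @ v
    denom = np.einsum("ij,ij->i", M, M)
    t = np.where(denom > 0, np.maximum(numer, 0) / np.where(denom > 0, denom, 1), 0.0)
    resid2 = v @ v - 2 * t * numer + t**2 * denom
    best = int(np.argmin(resid2))
    return t[best] * G[best]


def nnls_grid_agreement(seed: int, n_instances: int = 50, total: int = 2000) -> dict:
    """Max |NNLS - grid search| over random 3-signature instances.

    Returns the worst-case disagreement as a percentage of the catalogue
    total (the spec of the solver is that this stays below 1%).
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        probs = rng.dirichlet(np.full(96, 0.5), size=3)
        sigs = SignatureMatrix(["A", "B", "C"], probs)
        shares = rng.dirichlet([1.0, 1.0, 1.0])
        v = rng.multinomial(total, shares @ probs).astype(float)
        fitted = sf.nnls_fit(v, sigs).to_numpy()
        oracle = grid_search_exposures(v, sigs)
        worst = max(worst, float(np.max(np.abs(fitted - oracle))))
    return {"max_error_pct_of_total": 100.0 * worst / total, "n": n_instances}


def sparsification_admissibility(seed: int, n_instances: int = 200) -> dict:
    """Cosine-budget admissibility on random mixtures; exact recovery on pure ones.

    Half the instances are random Dirichlet mixtures of the demo signatures
    (checked against the cumulative 0.05 budget), half are pure
    single-signature catalogues (checked for exact retained-set recovery).
    """
    rng = np.random.default_rng(seed)
    sigs = demo_signatures()
    ids = sigs.signature_ids
    n_mixture = n_instances // 2
    admissible = 0
    for _ in range(n_mixture):
        shares = rng.dirichlet(np.ones(len(ids)))
        v = rng.multinomial(1000, shares @ sigs.probabilities).astype(float)
        full = sf.nnls_fit(v, sigs).to_numpy()
        c_full = sf.cosine_similarity(v, full @ sigs.probabilities)
        res = sf.sparsify_fit(v, sigs)
        admissible += res.cosine >= c_full - 0.05 - 1e-12
    pure_exact = 0
    n_pure = n_instances - n_mixture
    for k in range(n_pure):
        sid = ids[k % len(ids)]
        v = np.round(500 * sigs.profile(sid))
        res = sf.sparsify_fit(v, sigs)
        pure_exact += res.retained_ids == [sid]
    return {
        "admissible_fraction": admissible / n_mixture,
        "pure_exact_recovery_fraction": pure_exact / n_pure,
        "n": n_instances,
    }


def cohort_share_recovery(seed: int, n_samples: int = 50, burden: int = 200) -> dict:
    """Fit a synthetic subtype generated at 60% aging / 40% UV shares."""
    sigs = demo_signatures()
    genome = generate_reference(100_000, seed=seed)
    spec = SyntheticCohortSpec(
        [SubtypeSpec("MF", n_samples, {"Signature 1": 0.6, "Signature 7": 0.4},
                     burden_median=burden, burden_sigma_log10=0.0)],
        seed=seed + 1,
    )
    cohort = synthesize_cohort(spec, genome, sigs)
    catalogue, _ = cat.build_catalogue(cohort.records, genome.contigs, "subtype")
    _, pct = sf.fit_cohort(catalogue, sigs)
    by_sig = dict(zip(pct["signature"], pct["percent"]))
    return {
        "signature1_percent": by_sig.get("Signature 1", 0.0),
        "signature7_percent": by_sig.get("Signature 7", 0.0),
        "n": n_samples,
    }


def _association_p_value(genome, sigs, seed: int, mode: str) -> float:
    """One association replicate: 10 high-share carriers vs 40 low-share WT."""
    spec = SyntheticCohortSpec(
        [
            SubtypeSpec("ATLL", 10,
                        {"Signature 1": 0.2, "Signature 5": 0.2, "Signature 17": 0.6},
                        sample_prefix="hi"),
            SubtypeSpec("ATLL", 40,
                        {"Signature 1": 0.45, "Signature 5": 0.45, "Signature 17": 0.1},
                        sample_prefix="lo"),
        ],
        seed=seed,
    )
    cohort = synthesize_cohort(spec, genome, sigs)
    inject_recurrent_variant(
        cohort, genome, "IRF4", "K59R", channel_from_label("C[T>G]T"),
        k=10, mode=mode, signature_id="Signature 17", seed=seed + 1,
    )
    catalogue, _ = cat.build_catalogue(cohort.records, genome.contigs, "sample")
    cfg = ca.AssociationConfig()
    peaks = ca.derive_causal_peaks(
        sigs.restrict(["Signature 1", "Signature 5", "Signature 17"]), cfg
    )
    contributions = ca.causal_contribution_table(catalogue, peaks, cfg)
    recurrent = cat.find_recurrent_variants(cohort.records, min_carriers=3)
    results = ca.associate_variants(recurrent, contributions, cfg)
    for r in results:
        if r.signature_id == "Signature 17":
            return r.p_value
    return 1.0


def association_power_and_calibration(seed: int, n_seeds: int = 100) -> dict:
    """Power of detecting a signature-linked driver, and null calibration.

    Power: carriers are the 10 samples with the highest generating
    signature-17 share (a causal-contribution shift of roughly 35 points
    over the 40 wild-type samples); detection means p < 0.00029 (the
    Bonferroni threshold).  Calibration: carriers drawn at random; flagged
    means p < 0.05 uncorrected.
    """
    sigs = demo_signatures()
    genome = generate_reference(100_000, seed=seed)
    detected = flagged = 0
    for k in range(n_seeds):
        p = _association_p_value(genome, sigs, seed + 1000 + 7 * k, "top_by_share")
        detected += p < 0.00029
        p0 = _association_p_value(genome, sigs, seed + 90_000 + 7 * k, "random")
        flagged += p0 < 0.05
    return {
        "power_at_bonferroni": detected / n_seeds,
        "null_flag_rate_at_0.05": flagged / n_seeds,
        "n": n_seeds,
    }


def strand_diagnostics(seed: int, n_ct: int = 400) -> dict:
    """C>T strand-bias p in UV mode (2:1 untranscribed) and in the null mode."""
    genome = generate_reference(100_000, seed=seed)
    out = {}
    for name, fraction, pairs in (("uv", 2 / 3, 20), ("null", 0.5, 0)):
        records = generate_strand_cohort(
            genome, n_ct=n_ct, untranscribed_fraction=fraction,
            n_cc_tt_pairs=pairs, seed=seed + (1 if name == "uv" else 2),
            sample_id=name,
        )
        labels = sg.annotate_strand(records, genome.genes)
        counts = sg.strand_counts(records, labels)
        res = sg.strand_bias_test(
            int(counts.loc["C>T", "n_transcribed"]),
            int(counts.loc["C>T", "n_untranscribed"]),
        )
        out[f"{name}_p"] = res.two_sided_p
        out[f"{name}_direction"] = res.direction
        if name == "uv":
            dnvs, _ = cat.detect_dinucleotides(records)
            out["uv_cc_tt_doublets"] = sum(d.is_cc_to_tt for d in dnvs)
    out["n"] = n_ct
    return out


def generator_round_trip(seed: int, n_samples: int = 10) -> dict:
    """sense_check mismatches and catalogue discrepancies on a fresh cohort."""
    sigs = demo_signatures()
    genome = generate_reference(100_000, seed=seed)
    spec = SyntheticCohortSpec(
        [SubtypeSpec("SS", n_samples, {"Signature 1": 0.5, "Signature 7": 0.5})],
        seed=seed + 1,
    )
    cohort = synthesize_cohort(spec, genome, sigs)
    _, report = cat.sense_check(cohort.records, genome.contigs)
    catalogue, n_boundary = cat.build_catalogue(cohort.records, genome.contigs, "sample")
    mismatched_cells = sum(
        int(np.sum(catalogue.loc[s].to_numpy() != drawn))
        for s, drawn in cohort.catalogues.items()
    )
    return {
        "sense_check_mismatches": report.n_mismatches,
        "catalogue_cell_mismatches": mismatched_cells,
        "boundary_exclusions": n_boundary,
        "n": n_samples,
    }
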