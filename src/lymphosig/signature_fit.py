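"""Signature refitting by non-negative least squares.

A 96-channel catalogue ``v`` is modelled as a non-negative combination of
reference signature profiles ``P`` (rows summing to 1):

    e* = argmin_{e >= 0} || v - P^T e ||_2

Exposures are in mutation-count units.  Fit quality is the cosine similarity
between the catalogue and its reconstruction.  Because the NNLS solution is
stationary on its active cone, the reconstruction ``r`` satisfies
``r . (v - r) = 0``, so the cosine equals ``|r| / |v|`` and is monotone in
the residual — removing signatures can never raise it.

Cohort-level fits are sparsified by greedy backward elimination: refit
without each retained signature in turn, accept the removal that costs the
least cosine, and stop once any further removal would push the cosine more
than a fixed budget (default 0.05) below the full-model cosine.  Per-sample
fits are restricted to the cohort-retained set and gated: samples need more
than 20 SNVs, signatures assigned fewer than 20 mutations are dropped (with
refitting, iterated to a fixed point), and a final cosine below 0.6 voids
the assignment entirely.

Signatures derived from whole genomes are refit to exome catalogues after
rescaling each channel by the exome/genome frequency ratio of its
trinucleotide context (and renormalising), the standard exome adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .channels import CHANNELS
from .io_formats import SignatureMatrix, TrinucleotideFrequencyTable

logger = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Thresholds of the fitting and gating procedure.

    max_cosine_drop
        Cosine-similarity budget for sparsification (against the full-model
        cosine by default; per-step when ``per_step_budget``).
    min_mutations_per_signature
        Per-sample: signatures assigned fewer mutations than this are dropped.
    min_sample_cosine
        Per-sample: below this reconstruction cosine no signatures are assigned.
    min_sample_snvs
        Samples need strictly more than this many SNVs to be fit.
    """

    max_cosine_drop: float = 0.05
    min_mutations_per_signature: int = 20
    min_sample_cosine: float = 0.6
    min_sample_snvs: int = 20
    territory: str = "exome"
    per_step_budget: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.max_cosine_drop <= 1:
            raise ValueError("max_cosine_drop must be in [0, 1]")
        if min(self.min_mutations_per_signature, self.min_sample_snvs) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class FitResult:
    """Outcome of a (sparsified or gated) signature fit."""

    exposures: pd.Series  # signature id -> mutation count, full id set
    retained_ids: list[str]
    cosine: float
    gate: str = "ok"  # ok | rejected_low_cosine | rejected_too_few_snvs
    removal_trace: list[tuple[str, float]] = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(self.exposures.sum())

    def percentages(self, catalogue_total: float) -> pd.Series:
        return 100.0 * self.exposures / catalogue_total


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """dot(a, b) / (|a| |b|); scale invariant; zero vectors are an error."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity of a zero vector is undefined")
    return float(np.dot(a, b) / (na * nb))


def renormalize_signatures(
    signatures: SignatureMatrix,
    from_freq: TrinucleotideFrequencyTable,
    to_freq: TrinucleotideFrequencyTable,
) -> SignatureMatrix:
    """Rescale signatures from one trinucleotide territory to another.

    Each channel probability is multiplied by
    ``to_freq(context) / from_freq(context)`` for its pyrimidine-centred
    context, then each signature is renormalised to sum to 1.  Applying
    genome->exome then exome->genome recovers the input.
    """
    ratio = np.array(
        [to_freq[ch.context] / from_freq[ch.context] for ch in CHANNELS]
    )
    mat = signatures.probabilities * ratio[None, :]
    mat = mat / mat.sum(axis=1, keepdims=True)
    return SignatureMatrix(signatures.signature_ids, mat)


def nnls_fit(catalogue_vector: np.ndarray, signatures: SignatureMatrix) -> pd.Series:
    """Non-negative least-squares exposures (mutation counts) for one catalogue.

    Solved by the Lawson–Hanson active-set method; no sum constraint is
    imposed, so the exposure total tracks but need not equal the catalogue
    total.
    """
    v = np.asarray(catalogue_vector, dtype=float)
    if v.sum() <= 0:
        raise ValueError("catalogue vector must have positive total count")
    A = signatures.probabilities.T  # 96 x k
    e, _ = scipy.optimize.nnls(A, v)
    return pd.Series(e, index=signatures.signature_ids)


def _fit_cosine(v: np.ndarray, ids: list[str], signatures: SignatureMatrix):
    """NNLS over a signature subset; returns (exposures over subset, cosine)."""
    sub = signatures.restrict(ids)
    e = nnls_fit(v, sub)
    recon = e.to_numpy() @ sub.probabilities
    if not recon.any():
        return e, 0.0
    return e, cosine_similarity(v, recon)


def sparsify_fit(
    catalogue_vector: np.ndarray,
    signatures: SignatureMatrix,
    config: FitConfig | None = None,
) -> FitResult:
    """Greedy backward elimination of signatures under a cosine budget.

    Starts from the full NNLS fit (cosine ``c_full``).  Zero-exposure
    signatures are removed first (no cosine change).  Then, repeatedly, the
    retained signature whose removal costs the least cosine is dropped — but
    only while the refitted cosine stays within ``max_cosine_drop`` of
    ``c_full`` (or of the current cosine in per-step mode).  Ties are broken
    by smaller exposure, then lexicographic id.  The last signature is never
    removed.
    """
    config = config or FitConfig()
    v = np.asarray(catalogue_vector, dtype=float)
    full_ids = list(signatures.signature_ids)
    exposures, c_full = _fit_cosine(v, full_ids, signatures)
    retained = list(full_ids)
    trace: list[tuple[str, float]] = []
    current_c = c_full

    # zero-exposure signatures: free removals, lexicographic order
    for sid in sorted(s for s in retained if exposures[s] == 0.0):
        if len(retained) == 1:
            break
        retained.remove(sid)
        trace.append((sid, current_c))
    if len(retained) < len(full_ids):
        exposures, current_c = _fit_cosine(v, retained, signatures)

    while len(retained) > 1:
        candidates = []
        for sid in retained:
            ids = [s for s in retained if s != sid]
            e_new, c_new = _fit_cosine(v, ids, signatures)
            candidates.append((-c_new, float(exposures[sid]), sid, e_new))
        candidates.sort(key=lambda t: (t[0], t[1], t[2]))
        neg_c, _, sid, e_new = candidates[0]
        c_new = -neg_c
        floor = (current_c if config.per_step_budget else c_full) - config.max_cosine_drop
        if c_new < floor:
            break
        retained = [s for s in retained if s != sid]
        exposures = e_new
        current_c = c_new
        trace.append((sid, current_c))

    full_exposures = pd.Series(0.0, index=full_ids)
    full_exposures[list(exposures.index)] = exposures
    return FitResult(
        exposures=full_exposures,
        retained_ids=retained,
        cosine=current_c,
        removal_trace=trace,
    )


def fit_cohort(
    catalogue: pd.DataFrame,
    signatures: SignatureMatrix,
    config: FitConfig | None = None,
) -> tuple[dict[str, FitResult], pd.DataFrame]:
    """Sparsified fit per catalogue row (one row per cohort/subtype).

    Returns the per-row fit results and a long-format percentage table
    (row_id, signature, exposure, percent, cosine) restricted to retained
    signatures; percent = exposure / row total x 100.
    """
    config = config or FitConfig()
    results: dict[str, FitResult] = {}
    rows = []
    for row_id, row in catalogue.iterrows():
        v = row.to_numpy(dtype=float)
        total = v.sum()
        if total <= 0:
            logger.warning("fit_cohort: %s has zero SNVs; skipped", row_id)
            continue
        res = sparsify_fit(v, signatures, config)
        results[str(row_id)] = res
        for sid in res.retained_ids:
            rows.append(
                {
                    "row_id": row_id,
                    "signature": sid,
                    "exposure": float(res.exposures[sid]),
                    "percent": 100.0 * float(res.exposures[sid]) / total,
                    "cosine": res.cosine,
                }
            )
    return results, pd.DataFrame(
        rows, columns=["row_id", "signature", "exposure", "percent", "cosine"]
    )


def fit_sample(
    sample_vector: np.ndarray,
    allowed_signatures: SignatureMatrix,
    config: FitConfig | None = None,
) -> FitResult:
    """Gated per-sample fit restricted to the cohort-retained signatures.

    Samples with no more than ``min_sample_snvs`` SNVs are rejected before
    fitting.  After the restricted NNLS, signatures assigned fewer than
    ``min_mutations_per_signature`` mutations are dropped and the fit re-run
    on the survivors, iterating to a fixed point (dropped mass must be
    reassigned).  If the final reconstruction cosine falls below
    ``min_sample_cosine`` — including the degenerate case where every
    signature was dropped — the gate closes and no signatures are assigned.
    """
    config = config or FitConfig()
    if len(allowed_signatures) == 0:
        raise ValueError("allowed_signatures must be non-empty")
    v = np.asarray(sample_vector, dtype=float)
    ids = list(allowed_signatures.signature_ids)
    zeros = pd.Series(0.0, index=ids)
    total = v.sum()
    if total <= config.min_sample_snvs:
        return FitResult(zeros, [], 0.0, gate="rejected_too_few_snvs")

    retained = list(ids)
    exposures, cos = _fit_cosine(v, retained, allowed_signatures)
    while True:
        keep = [s for s in retained if exposures[s] >= config.min_mutations_per_signature]
        if len(keep) == len(retained):
            break
        if not keep:
            retained, cos = [], 0.0
            break
        retained = keep
        exposures, cos = _fit_cosine(v, retained, allowed_signatures)

    if cos < config.min_sample_cosine:
        return FitResult(zeros, [], cos, gate="rejected_low_cosine")
    full = zeros.copy()
    full[list(exposures.index)] = exposures
    return FitResult(full, retained, cos, gate="ok")


def fit_samples(
    catalogue: pd.DataFrame,
    cohort_retained: dict[str, list[str]] | list[str],
    sample_subtypes: dict[str, str] | None,
    signatures: SignatureMatrix,
    config: FitConfig | None = None,
) -> tuple[dict[str, FitResult], pd.DataFrame]:
    """Per-sample gated fits for every row of a per-sample catalogue.

    ``cohort_retained`` is either one retained-id list applied to all
    samples, or a subtype -> retained-ids map combined with
    ``sample_subtypes``.  Returns fit results and a long-format table with a
    gate column.
    """
    config = config or FitConfig()
    results: dict[str, FitResult] = {}
    rows = []
    for sample_id, row in catalogue.iterrows():
        sample_id = str(sample_id)
        if isinstance(cohort_retained, dict):
            subtype = (sample_subtypes or {}).get(sample_id, "")
            allowed_ids = cohort_retained.get(subtype, [])
        else:
            allowed_ids = list(cohort_retained)
        v = row.to_numpy(dtype=float)
        total = v.sum()
        if not allowed_ids:
            res = FitResult(
                pd.Series(dtype=float), [], 0.0, gate="rejected_low_cosine"
            )
        else:
            res = fit_sample(v, signatures.restrict(allowed_ids), config)
        results[sample_id] = res
        if res.gate == "ok":
            for sid in res.retained_ids:
                rows.append(
                    {
                        "sample_id": sample_id,
                        "signature": sid,
                        "exposure": float(res.exposures[sid]),
                        "percent": 100.0 * float(res.exposures[sid]) / total,
                        "cosine": res.cosine,
                        "gate": res.gate,
                    }
                )
        else:
            rows.append(
                {
                    "sample_id": sample_id,
                    "signature": "",
                    "exposure": 0.0,
                    "percent": 0.0,
                    "cosine": res.cosine,
                    "gate": res.gate,
                }
            )
    return results, pd.DataFrame(
        rows, columns=["sample_id", "signature", "exposure", "percent", "cosine", "gate"]
    )
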