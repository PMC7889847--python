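"""Driver-variant / signature association via causal peaks.

Attributing individual mutations to signatures is only reliable in contexts
where one signature dominates the probability mass.  A channel is a *causal
peak* of a retained signature when that signature holds at least a fixed
fraction (default 0.75) of the summed channel probability over all retained
signatures.  Summing a sample's mutations over a signature's causal peaks
and dividing by its total SNV count gives a per-patient percentage
contribution, computed for every patient with more than 20 SNVs.  For each
recurrent driver variant (carried by at least five eligible patients) and
each signature, carriers and non-carriers are compared by a two-sided
Wilcoxon rank-sum test against a Bonferroni-corrected threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .channels import CHANNEL_LABELS
from .io_formats import SignatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class AssociationConfig:
    min_carriers: int = 5
    bonferroni_alpha: float = 0.00029
    dominance_fraction: float = 0.75
    min_sample_snvs: int = 20
    report_min_carriers: int = 3

    def __post_init__(self) -> None:
        if self.min_carriers < 2:
            raise ValueError("min_carriers must be >= 2")
        if not 0 < self.bonferroni_alpha < 1:
            raise ValueError("bonferroni_alpha must be in (0, 1)")
        if not 0.5 < self.dominance_fraction <= 1:
            raise ValueError("dominance_fraction must be in (0.5, 1]")


@dataclass
class CausalPeakMap:
    """Partial map from channel index to the signature dominating it."""

    assignments: dict[int, str]
    dominance: dict[int, float] = field(default_factory=dict)

    def channels_of(self, signature_id: str) -> list[int]:
        return [c for c, s in self.assignments.items() if s == signature_id]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "channel": CHANNEL_LABELS[c],
                "signature": s,
                "dominance": self.dominance.get(c, float("nan")),
            }
            for c, s in sorted(self.assignments.items())
        ]
        return pd.DataFrame(rows, columns=["channel", "signature", "dominance"])


@dataclass
class AssociationResult:
    gene: str
    protein_change: str
    signature_id: str
    carrier_contributions: list[float]
    noncarrier_contributions: list[float]
    statistic: float
    p_value: float
    significant: bool


def derive_causal_peaks(
    fitted_signatures: SignatureMatrix, config: AssociationConfig | None = None
) -> CausalPeakMap:
    """Assign each channel to the retained signature that dominates it.

    Channel ``c`` is assigned to signature ``s`` iff
    ``p_s(c) / sum_r p_r(c) >= dominance_fraction`` over the retained set
    and ``p_s(c) > 0``; channels where no signature dominates stay
    unassigned.  With a single retained signature every channel it touches
    is assigned to it; two identical retained signatures yield no peaks.
    """
    config = config or AssociationConfig()
    if len(fitted_signatures) == 0:
        raise ValueError("need at least one retained signature")
    P = fitted_signatures.probabilities  # k x 96
    totals = P.sum(axis=0)
    assignments: dict[int, str] = {}
    dominance: dict[int, float] = {}
    for c in range(96):
        if totals[c] <= 0:
            continue
        shares = P[:, c] / totals[c]
        k = int(np.argmax(shares))
        if shares[k] >= config.dominance_fraction and P[k, c] > 0:
            assignments[c] = fitted_signatures.signature_ids[k]
            dominance[c] = float(shares[k])
    return CausalPeakMap(assignments, dominance)


def causal_contribution(
    sample_vector: np.ndarray, peaks: CausalPeakMap
) -> dict[str, float]:
    """Percent of a sample's SNVs falling in each signature's causal peaks.

    Unassigned channels contribute to no signature, so the percentages sum
    to at most 100.  The result is invariant to scaling the sample vector.
    """
    v = np.asarray(sample_vector, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("sample vector has no mutations")
    out: dict[str, float] = {}
    for c, s in peaks.assignments.items():
        if v[c] > 0:
            out[s] = out.get(s, 0.0) + v[c]
    return {s: 100.0 * x / total for s, x in out.items()}


def causal_contribution_table(
    sample_catalogue: pd.DataFrame,
    peaks: CausalPeakMap,
    config: AssociationConfig | None = None,
) -> pd.DataFrame:
    """Per-sample causal contributions for samples above the SNV gate.

    Samples with no more than ``min_sample_snvs`` SNVs are excluded (the
    strict > rule); excluded sample ids are listed in
    ``df.attrs["excluded"]``.
    """
    config = config or AssociationConfig()
    sig_ids = sorted(set(peaks.assignments.values()))
    rows, excluded = [], []
    for sample_id, row in sample_catalogue.iterrows():
        v = row.to_numpy(dtype=float)
        if v.sum() <= config.min_sample_snvs:
            excluded.append(str(sample_id))
            continue
        contrib = causal_contribution(v, peaks)
        rows.append({"sample_id": str(sample_id), **{s: contrib.get(s, 0.0) for s in sig_ids}})
    df = pd.DataFrame(rows, columns=["sample_id", *sig_ids]).set_index("sample_id")
    df.attrs["excluded"] = excluded
    return df


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact null distribution when the pooled size is <= 12 with no ties;
    otherwise the normal approximation with midranks, tie correction and
    continuity correction.  Returns (U statistic of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and tie_free) else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> tuple[float, float, bool]:
    """Two-sided Fisher's exact test on a 2x2 table.

    p sums hypergeometric probabilities no larger than the observed table's.
    The sample odds ratio (ad/bc) is reported; when a zero cell exists, 0.5
    is added to every cell for the odds ratio only and the third return
    value flags the correction.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        raise ValueError("a zero margin makes the test degenerate")
    _, p = scipy.stats.fisher_exact(t, alternative="two-sided")
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    odds_ratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(odds_ratio), float(p), corrected


def associate_variants(
    recurrent: pd.DataFrame,
    contributions: pd.DataFrame,
    config: AssociationConfig | None = None,
    signature_ids: list[str] | None = None,
) -> list[AssociationResult]:
    """Test every (recurrent variant, signature) pair for a contribution shift.

    ``recurrent`` is the table from
    :func:`lymphosig.catalogue.find_recurrent_variants`; ``contributions``
    the per-sample causal-percent table (already gated to > 20 SNVs).
    Variants with fewer than ``min_carriers`` eligible carriers — or with an
    empty wild-type group — are skipped with a log message.  Results are
    sorted by p-value; significance is ``p < bonferroni_alpha``.
    """
    config = config or AssociationConfig()
    sig_ids = signature_ids or [c for c in contributions.columns]
    eligible = set(contributions.index)
    results: list[AssociationResult] = []
    for _, var in recurrent.iterrows():
        carriers = [s for s in var["carriers"] if s in eligible]
        if len(carriers) < config.min_carriers:
            logger.info(
                "associate_variants: %s %s has %d eligible carriers (< %d); skipped",
                var["gene"], var["protein_change"], len(carriers), config.min_carriers,
            )
            continue
        wt = sorted(eligible - set(carriers))
        if not wt:
            logger.info(
                "associate_variants: %s %s leaves an empty wild-type group; skipped",
                var["gene"], var["protein_change"],
            )
            continue
        for sid in sig_ids:
            xs = contributions.loc[carriers, sid].tolist()
            ys = contributions.loc[wt, sid].tolist()
            stat, p = wilcoxon_rank_sum(xs, ys)
            results.append(
                AssociationResult(
                    gene=var["gene"],
                    protein_change=var["protein_change"],
                    signature_id=sid,
                    carrier_contributions=xs,
                    noncarrier_contributions=ys,
                    statistic=stat,
                    p_value=p,
                    significant=p < config.bonferroni_alpha,
                )
            )
    results.sort(key=lambda r: (r.p_value, r.gene, r.protein_change, r.signature_id))
    return results


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    rows = [
        {
            "gene": r.gene,
            "protein_change": r.protein_change,
            "signature": r.signature_id,
            "n_mut": len(r.carrier_contributions),
            "n_wt": len(r.noncarrier_contributions),
            "median_mut": float(np.median(r.carrier_contributions)),
            "median_wt": float(np.median(r.noncarrier_contributions)),
            "statistic": r.statistic,
            "p_value": r.p_value,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["gene", "protein_change", "signature", "n_mut", "n_wt",
                 "median_mut", "median_wt", "statistic", "p_value", "significant"],
    )
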