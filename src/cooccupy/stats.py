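"""Enrichment and expression statistics.

Hypergeometric over-representation (upper tail, P(X >= k)) computed by
log-space summation; Benjamini-Hochberg FDR; fold-change threshold
classification with the knockdown dependence window; and relative qPCR
quantification by 2^-ddCt. All thresholds are applied inclusively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "HypergeomParams",
    "FoldChangeRecord",
    "hypergeom_tail",
    "bh_fdr",
    "classify_fold_changes",
    "melanocyte_panel_enrichment",
    "ddct",
]


@dataclass(frozen=True)
class HypergeomParams:
    """N: population, K: population successes, n: draws, k: observed successes."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self):
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValidationError("need 0 <= K <= N and 0 <= n <= N")
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValidationError("need 0 <= k <= min(n, K)")


def _log_comb(n, r):
    return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)


def hypergeom_tail(p: HypergeomParams) -> float:
    """Upper-tail P(X >= k) by summation of log-probabilities.

    Exact (to float precision) and stable for populations up to ~1e6:
    each term is a ratio of binomial coefficients evaluated through
    log-gamma, accumulated with logsumexp.
    """
    N, K, n, k = p.N, p.K, p.n, p.k
    if k == 0:
        return 1.0
    upper = min(n, K)
    i = np.arange(k, upper + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(np.exp(logsumexp(log_terms)))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class FoldChangeRecord:
    gene_id: str
    fc: float | None  # None when control expression is not positive
    cls: str  # decreased | increased | unchanged | undefined
    dependent: bool


def classify_fold_changes(
    expr_condition: dict[str, float],
    expr_control: dict[str, float],
    down_thr: float = 0.7,
    up_thr: float = 1.25,
    dep_lo: float = 0.2,
    dep_hi: float = 0.55,
) -> list[FoldChangeRecord]:
    """Classify per-gene condition/control ratios against inclusive thresholds.

    decreased: fc <= down_thr; increased: fc >= up_thr; dependent:
    dep_lo <= fc <= dep_hi (the knockdown dependence window). Genes with
    non-positive control expression get an undefined, flagged record.
    """
    if set(expr_condition) != set(expr_control):
        raise ValidationError("condition and control gene ids do not match")
    records = []
    for gid in expr_control:  # dict order = input order
        ctrl = expr_control[gid]
        if ctrl <= 0:
            records.append(FoldChangeRecord(gid, None, "undefined", False))
            continue
        fc = expr_condition[gid] / ctrl
        cls = "decreased" if fc <= down_thr else "increased" if fc >= up_thr else "unchanged"
        records.append(FoldChangeRecord(gid, fc, cls, dep_lo <= fc <= dep_hi))
    return records


def melanocyte_panel_enrichment(
    panel: set[str],
    dependent: set[str],
    decreased_universe_size: int,
    universe_size: int,
) -> float:
    """Upper-tail probability that >= |panel ∩ dependent| of a panel of genes
    would fall among the decreased transcripts by chance."""
    k = len(panel & dependent)
    return hypergeom_tail(
        HypergeomParams(N=universe_size, K=decreased_universe_size, n=len(panel), k=k)
    )


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_cal: float,
    ct_ref_cal: float,
) -> float:
    """Relative expression by 2^-ddCt against a reference gene and calibrator."""
    for v in (ct_target_sample, ct_ref_sample, ct_target_cal, ct_ref_cal):
        if not np.isfinite(v):
            raise ValidationError("Ct values must be finite")
    ddct_value = (ct_target_sample - ct_ref_sample) - (ct_target_cal - ct_ref_cal)
    return float(2.0 ** (-ddct_value))
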