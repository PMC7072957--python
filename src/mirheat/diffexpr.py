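"""Per-stage differential-expression screening between two genotypes.

The design has one library per (genotype, condition, stage) cell, so the
default test is the replicate-free exact conditional test: conditioning on a
miRNA's combined count across the two libraries, its count in library A is
hypergeometric under the null of equal proportions, and the two-sided p-value
sums the probabilities of all tables at most as probable as the observed one
(Fisher's exact-test ordering). Small tables are evaluated in exact integer
arithmetic; large ones with vectorized log-pmf.

A miRNA is called when p <= alpha AND its tolerant/sensitive fold change on
pseudocounted TPM is >= fc_high or <= fc_low (all inequalities inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control, ttest_ind

from .abundance import ExpressionMatrix
from .io import CountMatrix, DesignError, SampleDesign

# Totals at or below this use exact integer enumeration; above it, log-space
# floats with a 1e-7 relative tie tolerance (the scipy fisher_exact convention).
_EXACT_INT_TOTAL = 4000
_LOG_TIE_TOL = 1e-7


def test_unreplicated(
    count_a: int, total_a: int, count_b: int, total_b: int
) -> float:
    """Two-sided exact conditional p-value for equal count proportions.

    Tests count_a/total_a against count_b/total_b for two unreplicated
    libraries. Symmetric in the two sides; returns 1.0 for identical zero
    observations.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    if not (0 <= count_a <= total_a and 0 <= count_b <= total_b):
        raise ValueError("counts must lie in [0, total]")
    n = count_a + count_b
    if n == 0:
        return 1.0
    lo = max(0, n - total_b)
    hi = min(n, total_a)
    if lo == hi:  # degenerate support
        return 1.0
    if total_a + total_b <= _EXACT_INT_TOTAL:
        weights = [comb(total_a, k) * comb(total_b, n - k) for k in range(lo, hi + 1)]
        w_obs = weights[count_a - lo]
        num = sum(w for w in weights if w <= w_obs)
        return num / comb(total_a + total_b, n)
    k = np.arange(lo, hi + 1)
    logw = (
        gammaln(total_a + 1)
        - gammaln(k + 1)
        - gammaln(total_a - k + 1)
        + gammaln(total_b + 1)
        - gammaln(n - k + 1)
        - gammaln(total_b - n + k + 1)
    )
    log_denom = (
        gammaln(total_a + total_b + 1) - gammaln(n + 1) - gammaln(total_a + total_b - n + 1)
    )
    logp = logw - log_denom
    keep = logp <= logp[count_a - lo] + _LOG_TIE_TOL
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


# the leading "test_" names describe what the functions do; tell pytest they
# are not test cases when imported into a test module
test_unreplicated.__test__ = False  # type: ignore[attr-defined]


def test_replicated(tpm_a, tpm_b, pseudocount: float = 1.0) -> float:
    """Two-sided Welch t-test on log2(TPM + pseudocount) between replicate groups."""
    a = np.asarray(tpm_a, dtype=float)
    b = np.asarray(tpm_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            "replicated test needs >= 2 values per side; use test_unreplicated"
        )
    la, lb = np.log2(a + pseudocount), np.log2(b + pseudocount)
    if np.allclose(la, la[0]) and np.allclose(lb, lb[0]) and np.isclose(la[0], lb[0]):
        return 1.0
    p = ttest_ind(la, lb, equal_var=False).pvalue
    return 1.0 if np.isnan(p) else float(p)


test_replicated.__test__ = False  # type: ignore[attr-defined]


@dataclass(frozen=True)
class Contrast:
    """One genotype comparison at a fixed stage and condition.

    The numerator is the tolerant (H) line: "up" means higher in the
    tolerant line.
    """

    stage: str
    condition: str
    numerator_libraries: tuple[str, ...]
    denominator_libraries: tuple[str, ...]
    numerator_genotype: str = "tolerant"
    denominator_genotype: str = "sensitive"

    def __post_init__(self) -> None:
        if not self.numerator_libraries or not self.denominator_libraries:
            raise DesignError(
                f"contrast {self.stage}/{self.condition}: both sides need >= 1 library"
            )

    @property
    def label(self) -> str:
        return f"{self.stage}.{self.condition}"


def make_contrast(design: SampleDesign, stage: str, condition: str) -> Contrast:
    num = design.libraries(genotype="tolerant", condition=condition, stage=stage)
    den = design.libraries(genotype="sensitive", condition=condition, stage=stage)
    return Contrast(stage, condition, tuple(num), tuple(den))


def screen(
    expr: ExpressionMatrix,
    counts: CountMatrix,
    contrast: Contrast,
    alpha: float = 0.05,
    fc_high: float = 2.0,
    fc_low: float = 0.5,
    pseudocount: float = 1.0,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Screen every miRNA in ``expr`` for differential expression in a contrast.

    Returns one row per tested miRNA (not only the significant ones) with
    mean TPM per side, pseudocounted fold change, log2FC, p-value and call.
    With one library per side the exact conditional test runs on raw counts;
    with replicates on both sides the log-TPM location test is used (mixed
    designs pool counts within a side). ``adjust='bh'`` applies
    Benjamini-Hochberg before calling.
    """
    num, den = list(contrast.numerator_libraries), list(contrast.denominator_libraries)
    missing = [l for l in num + den if l not in expr.tpm.columns]
    if missing:
        raise DesignError(f"contrast libraries absent from expression matrix: {missing}")
    mean_num = expr.tpm[num].mean(axis=1)
    mean_den = expr.tpm[den].mean(axis=1)
    fc = (mean_num + pseudocount) / (mean_den + pseudocount)

    replicated = len(num) >= 2 and len(den) >= 2
    if replicated:
        pvals = np.array(
            [
                test_replicated(expr.tpm.loc[m, num], expr.tpm.loc[m, den], pseudocount)
                for m in expr.mirna_ids
            ]
        )
    else:
        ca = counts.counts[num].sum(axis=1)
        cb = counts.counts[den].sum(axis=1)
        ta = int(counts.library_sizes[num].sum())
        tb = int(counts.library_sizes[den].sum())
        pvals = np.array(
            [
                test_unreplicated(int(ca[m]), ta, int(cb[m]), tb)
                for m in expr.mirna_ids
            ]
        )

    if adjust == "bh":
        p_eff = false_discovery_control(pvals, method="bh")
    elif adjust in (None, "none"):
        p_eff = pvals
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    call = np.where(
        (p_eff <= alpha) & (fc >= fc_high),
        "up",
        np.where((p_eff <= alpha) & (fc <= fc_low), "down", "not_de"),
    )
    out = pd.DataFrame(
        {
            "mirna_id": expr.mirna_ids,
            "stage": contrast.stage,
            "condition": contrast.condition,
            "mean_tpm_num": mean_num.to_numpy(),
            "mean_tpm_den": mean_den.to_numpy(),
            "fold_change": fc.to_numpy(),
            "log2fc": np.log2(fc.to_numpy()),
            "p_value": pvals,
            "p_adjusted": p_eff,
            "call": call,
        }
    )
    out.attrs["test"] = "replicated_log_t" if replicated else "exact_conditional"
    out.attrs["alpha"] = alpha
    return out


def called(results: pd.DataFrame) -> pd.DataFrame:
    """Rows of a screen result that received an up/down call."""
    return results[results["call"] != "not_de"]


def unique_de_union(per_stage_results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Deduplicate called miRNAs across stages, keeping per-stage provenance.

    Returns one row per unique called miRNA with every (stage, direction)
    where it was called; a miRNA called in opposite directions at different
    stages keeps both annotations.
    """
    if not per_stage_results:
        raise ValueError("need results from at least one stage")
    calls: dict[str, list[tuple[str, str]]] = {}
    for stage, res in per_stage_results.items():
        for row in called(res).itertuples(index=False):
            calls.setdefault(row.mirna_id, []).append((stage, row.call))
    rows = []
    for mirna in sorted(calls):
        entries = calls[mirna]
        dirs = {d for _, d in entries}
        rows.append(
            {
                "mirna_id": mirna,
                "n_stage_calls": len(entries),
                "stage_directions": ";".join(f"{s}:{d}" for s, d in entries),
                "opposing_across_stages": len(dirs) > 1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "n_stage_calls", "stage_directions", "opposing_across_stages"],
    )
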