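"""Protein-level target calling from peptide-level shift statistics.

Peptide p-values from one protein are merged with Fisher's combined
probability test: chi2 = -2 * sum(ln p_i) follows a chi-square distribution
with 2k degrees of freedom under the joint null, k being the number of
peptides combined.  The protein-level ΔCoG is the median of its peptides'
shifts.  Multiple testing across proteins is controlled with a Bonferroni
correction over the number of proteins tested.

Only peptides unique to one protein group feed the combination by default:
shared peptides would both violate the independence assumption and smear
evidence across groups.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Floor applied to p-values of exactly zero before taking logarithms.
P_FLOOR = 1e-300


def fisher_combine(
    p_values: Sequence[float], floor: float = P_FLOOR
) -> tuple[float, float]:
    """Fisher's combined probability test.

    Returns ``(chi2, combined_p)`` where ``chi2 = -2 * sum(ln p_i)`` and
    ``combined_p`` is the upper tail of the chi-square distribution with
    ``2k`` degrees of freedom.  Zero p-values are floored at ``floor`` with a
    warning; p-values above 1 are rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value to combine")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(p == 0):
        logger.warning("flooring %d zero p-value(s) at %g", int((p == 0).sum()), floor)
        p = np.maximum(p, floor)
    chi2 = float(-2.0 * np.log(p).sum())
    combined = float(stats.chi2.sf(chi2, df=2 * p.size))
    return chi2, combined


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-corrected p-value: ``min(1, p * n_tests)``."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def aggregate_proteins(
    peptides: pd.DataFrame,
    unique_only: bool = True,
) -> pd.DataFrame:
    """Aggregate a peptide shift table to protein-level target calls.

    Parameters
    ----------
    peptides
        Peptide table with columns ``proteins``, ``is_unique``, ``tested``,
        ``p_value``, ``delta_cog``, ``significant`` (as produced by
        :func:`afdip.timecourse.shift_table`).
    unique_only
        Restrict the combination to peptides unique to one protein group.

    Returns
    -------
    DataFrame with one row per protein: k (peptides combined), chi2,
    combined_p, bonferroni_p (over the number of proteins tested),
    median_delta_cog, n_significant_peptides; sorted by combined_p.
    """
    pool = peptides[peptides["tested"] & peptides["p_value"].notna()]
    if unique_only:
        pool = pool[pool["is_unique"]]
    groups = pool.groupby("proteins", sort=False)
    rows = []
    for protein, g in groups:
        chi2, combined = fisher_combine(g["p_value"].to_numpy())
        rows.append(
            {
                "protein": protein,
                "k": len(g),
                "chi2": chi2,
                "combined_p": combined,
                "median_delta_cog": float(np.median(g["delta_cog"])),
                "n_significant_peptides": int(g["significant"].sum()),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "protein", "k", "chi2", "combined_p",
            "median_delta_cog", "n_significant_peptides",
        ],
    )
    n_proteins = len(out)
    if n_proteins:
        out["bonferroni_p"] = np.minimum(1.0, out["combined_p"] * n_proteins)
    else:
        out["bonferroni_p"] = pd.Series(dtype=float)
    out.sort_values("combined_p", kind="mergesort", inplace=True)
    out.reset_index(drop=True, inplace=True)
    return out


def rank_peptides(
    peptides: pd.DataFrame,
    dcog_col: str = "delta_cog",
    p_col: str = "p_value",
) -> pd.DataFrame:
    """Prioritize peptides by the sum of their |shift| and p-value ranks.

    ``rank_dcog`` ranks the absolute shift descending (largest = 1) and
    ``rank_p`` ranks the p-value ascending (smallest = 1); ties receive
    average ranks.  Ranking on p is monotone-equivalent to ranking on
    log10(p), so the logarithm is never taken.  The output is sorted by
    ``rank_sum`` ascending, ties broken by p-value then sequence.
    """
    pool = peptides.dropna(subset=[dcog_col, p_col]).copy()
    pool["rank_dcog"] = stats.rankdata(-pool[dcog_col].abs(), method="average")
    pool["rank_p"] = stats.rankdata(pool[p_col], method="average")
    pool["rank_sum"] = pool["rank_dcog"] + pool["rank_p"]
    by = ["rank_sum", p_col] + (["sequence"] if "sequence" in pool.columns else [])
    pool.sort_values(by, kind="mergesort", inplace=True)
    pool.reset_index(drop=True, inplace=True)
    return pool


# ---------------------------------------------------------------------------
# Method-combination arithmetic
# ---------------------------------------------------------------------------

def detection_probability(success_rate: float, n_methods: int) -> float:
    """Probability that at least one of n independent methods detects a target.

    With per-method success rate s, the combined detection probability is
    1 - (1 - s)^n; three orthogonal methods at a 65% success rate already
    clear 95%.
    """
    if not 0 <= success_rate <= 1:
        raise ValueError("success_rate must lie in [0, 1]")
    return 1.0 - (1.0 - success_rate) ** n_methods


def methods_needed(success_rate: float, target: float = 0.95) -> int:
    """Smallest number of independent methods whose combined detection
    probability reaches ``target``."""
    n = 1
    while detection_probability(success_rate, n) < target:
        n += 1
        if n > 1000:
            raise ValueError("target unreachable at this success rate")
    return n
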