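"""Concentration-mode analysis: fold change across a drug dilution series.

At a fixed digestion time, ligand occupancy modulates the yield of peptides
near the binding site, so the relative abundance of a true-target peptide
changes monotonically (sigmoidally in log concentration) along the series.
The screen statistic is the fold change between the mean relative abundance
at the two lowest and the two highest treatment concentrations, paired with
a two-sample t-test between the same groups, and a rank-sum prioritization
over |log2 fold change| and p.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DesignError
from .io_quant import PeptideRecord, SampleDesign, intensity_frame
from .protein_stats import rank_peptides

logger = logging.getLogger(__name__)

#: Number of concentrations pooled at each end of the series.
N_EDGE = 2
#: Default abundance filter: keep the most abundant peptides only.
TOP_N_ABUNDANCE = 30000


def _edge_groups(
    concentrations: Sequence[float], include_vehicle: bool = False
) -> tuple[list[float], list[float]]:
    """The two lowest and two highest treatment concentrations of a series.

    The 0 nM vehicle is not a treatment concentration and is excluded unless
    ``include_vehicle`` is set.
    """
    concs = sorted(set(float(c) for c in concentrations))
    if not include_vehicle:
        concs = [c for c in concs if c > 0]
    if len(concs) < 2 * N_EDGE:
        raise DesignError(
            f"need at least {2 * N_EDGE} treatment concentrations, got {len(concs)}"
        )
    return concs[:N_EDGE], concs[-N_EDGE:]


def fold_change(
    low_values: Sequence[float], high_values: Sequence[float]
) -> tuple[float, float]:
    """Fold change low/high and its log2.

    ``low_values`` / ``high_values`` are the (replicate-pooled) abundances at
    the two lowest / two highest treatment concentrations.  A zero or
    non-finite denominator yields NaN, flagging the peptide out of ranking.
    """
    lo = np.nanmean(np.asarray(low_values, dtype=float))
    hi = np.nanmean(np.asarray(high_values, dtype=float))
    if not np.isfinite(hi) or hi == 0 or not np.isfinite(lo):
        return float("nan"), float("nan")
    fc = float(lo / hi)
    return fc, float(np.log2(fc)) if fc > 0 else float("nan")


def conc_test(low_values: Sequence[float], high_values: Sequence[float]) -> float:
    """Two-sided equal-variance t-test between low- and high-concentration
    abundances; NaN when untestable (single observations or zero variance)."""
    lo = np.asarray(low_values, dtype=float)
    hi = np.asarray(high_values, dtype=float)
    lo, hi = lo[~np.isnan(lo)], hi[~np.isnan(hi)]
    if lo.size < 2 or hi.size < 2:
        return float("nan")
    if np.ptp(lo) == 0 and np.ptp(hi) == 0:
        return float("nan") if lo.mean() != hi.mean() else 1.0
    res = stats.ttest_ind(lo, hi, equal_var=True)
    return float(res.pvalue)


def abundance_filter(results: pd.DataFrame, top_n: int = TOP_N_ABUNDANCE) -> pd.DataFrame:
    """Keep the ``top_n`` peptides with highest mean abundance.

    Ties at the boundary are kept inclusively, so slightly more than
    ``top_n`` rows can survive.
    """
    if len(results) <= top_n:
        return results
    threshold = results["mean_abundance"].nlargest(top_n).iloc[-1]
    return results[results["mean_abundance"] >= threshold]


def conc_rank(results: pd.DataFrame) -> pd.DataFrame:
    """Rank-sum prioritization: |log2 fold change| descending plus p ascending."""
    return rank_peptides(results, dcog_col="log2_fc", p_col="p_value")


def conc_table(
    records: Sequence[PeptideRecord],
    design: SampleDesign,
    include_vehicle: bool = False,
    top_n: int | None = TOP_N_ABUNDANCE,
) -> pd.DataFrame:
    """Per-peptide fold-change statistics for a concentration-series design.

    Relative abundance is each channel divided by the peptide's maximum
    across the whole series (the ratio statistic is normalization-invariant,
    but exported values are relative).  Returns one row per peptide with
    mean_abundance, fc, log2_fc, p_value, tested; when ``top_n`` is given the
    abundance filter is applied before ranking and a ``kept`` column records
    survival.
    """
    frame = intensity_frame(records, design)
    lows, highs = _edge_groups(
        [e.axis_value for e in design.entries], include_vehicle=include_vehicle
    )
    low_cols = [e.channel for e in design.entries if e.axis_value in lows]
    high_cols = [e.channel for e in design.entries if e.axis_value in highs]

    raw = frame.to_numpy()
    mean_abundance = np.nanmean(raw, axis=1)
    with np.errstate(invalid="ignore"):
        rel = raw / np.nanmax(raw, axis=1, keepdims=True)
    rel_frame = pd.DataFrame(rel, index=frame.index, columns=frame.columns)

    rows = []
    for i in range(len(frame)):
        lo = rel_frame.iloc[i][low_cols].to_numpy(dtype=float)
        hi = rel_frame.iloc[i][high_cols].to_numpy(dtype=float)
        fc, lfc = fold_change(lo, hi)
        p = conc_test(lo, hi)
        rows.append((fc, lfc, p))
    out = pd.DataFrame(
        {
            "sequence": frame.index.get_level_values("sequence"),
            "proteins": frame.index.get_level_values("proteins"),
            "is_unique": [r.is_unique for r in records],
            "mean_abundance": mean_abundance,
            "fc": [r[0] for r in rows],
            "log2_fc": [r[1] for r in rows],
            "p_value": [r[2] for r in rows],
        }
    )
    out["tested"] = out["log2_fc"].notna() & out["p_value"].notna()
    if top_n is not None:
        kept = abundance_filter(out, top_n)
        out["kept"] = out.index.isin(kept.index)
    else:
        out["kept"] = True
    return out
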