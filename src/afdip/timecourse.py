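"""Per-peptide digestion-kinetics statistics.

The read-out of an above-filter digestion experiment is, for every peptide,
the hourly filtrate yield over the digestion time course.  Ligand binding
that locally protects (or flexibilizes) the protein backbone slows (or
speeds) the release of nearby peptides, shifting mass of the yield curve to
later (earlier) time points.  The summary statistic is the center of
gravity

    CoG = sum_i t_i * a_i / sum_i a_i

the abundance-weighted mean time point, with a_i the relative abundance at
time t_i.  The shift ΔCoG = mean CoG(treated) − mean CoG(control) is tested
with a two-sided unpaired Student's t test on the per-replicate centroids.

CoG is invariant to rescaling the abundances, so normalization (each
profile divided by its own maximum) affects only exported curves, never the
statistic itself.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateProfileError, DesignError
from .io_quant import PeptideRecord, SampleDesign, intensity_frame

#: Volcano-plot significance cutoffs: raw p-value and |ΔCoG| in hours.
P_CUTOFF = 0.05
DCOG_CUTOFF = 0.5


def normalize_profile(abundances: Sequence[float]) -> np.ndarray:
    """Scale a profile to its own maximum; missing (NaN) values stay missing.

    Raises
    ------
    DegenerateProfileError
        If the profile has no positive abundance to scale by.
    """
    a = np.asarray(abundances, dtype=float)
    if a.size == 0 or not np.any(np.nan_to_num(a) > 0):
        raise DegenerateProfileError("profile has no positive abundance")
    return a / np.nanmax(a)


def center_of_gravity(times: Sequence[float], abundances: Sequence[float]) -> float:
    """Abundance-weighted mean time point of a profile.

    NaN abundances are ignored (their time points carry no weight).
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(abundances, dtype=float)
    if t.shape != a.shape:
        raise ValueError("times and abundances must have equal length")
    mask = ~np.isnan(a)
    total = a[mask].sum()
    if total <= 0:
        raise DegenerateProfileError("profile abundances sum to zero")
    return float((t[mask] * a[mask]).sum() / total)


def delta_cog(
    cog_treated: Sequence[float], cog_control: Sequence[float]
) -> tuple[float, float]:
    """Centroid shift and its two-sided pooled (equal-variance) t-test p-value.

    Returns ``(delta, p)`` with ``delta = mean(treated) - mean(control)``.
    When the pooled variance is zero the test is undefined and ``p`` is NaN —
    the caller must flag the peptide rather than report a spurious p of 0.
    """
    ct = np.asarray(cog_treated, dtype=float)
    cc = np.asarray(cog_control, dtype=float)
    if ct.size < 2 or cc.size < 2:
        raise ValueError("need at least 2 centroids per condition")
    delta = float(ct.mean() - cc.mean())
    n1, n2 = ct.size, cc.size
    ss = float(((ct - ct.mean()) ** 2).sum() + ((cc - cc.mean()) ** 2).sum())
    df = n1 + n2 - 2
    if ss == 0.0:
        return delta, float("nan")
    se = np.sqrt(ss / df * (1.0 / n1 + 1.0 / n2))
    tval = delta / se
    p = float(2.0 * stats.t.sf(abs(tval), df))
    return delta, p


def fit_poly4(times: Sequence[float], abundances: Sequence[float]) -> np.ndarray:
    """Least-squares degree-4 polynomial coefficients (ascending order).

    Used only for smoothed curve export; CoG and p-values are always computed
    from the raw normalized points.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(abundances, dtype=float)
    mask = ~np.isnan(a)
    t, a = t[mask], a[mask]
    if np.unique(t).size < 5:
        raise ValueError("degree-4 fit needs at least 5 distinct time points")
    return np.polynomial.polynomial.polyfit(t, a, 4)


def classify_significant(
    delta: float,
    p: float,
    p_cutoff: float = P_CUTOFF,
    dcog_cutoff: float = DCOG_CUTOFF,
) -> bool:
    """Volcano call: significant iff p < p_cutoff and |ΔCoG| > dcog_cutoff.

    Comparisons are strict, so a peptide sitting exactly on a cutoff is not
    called.
    """
    if np.isnan(p) or np.isnan(delta):
        return False
    return bool(p < p_cutoff and abs(delta) > dcog_cutoff)


# ---------------------------------------------------------------------------
# Vectorized peptide-level analysis
# ---------------------------------------------------------------------------

def _profile_tensor(
    frame: pd.DataFrame, design: SampleDesign, condition: str
) -> tuple[np.ndarray, np.ndarray]:
    """Stack one condition's profiles into (n_peptides, n_replicates, n_times).

    Requires every replicate of the condition to share the same time grid.
    """
    reps = design.replicates(condition)
    grid = design.axis_values(condition)
    mats = []
    for rep in reps:
        chans = design.channels_for(condition, rep)
        if [e.axis_value for e in chans] != grid:
            raise DesignError(
                f"replicate {rep} of condition {condition!r} does not cover the "
                "condition's full axis grid"
            )
        mats.append(frame[[e.channel for e in chans]].to_numpy())
    return np.stack(mats, axis=1), np.asarray(grid, dtype=float)


def shift_table(
    records: Sequence[PeptideRecord],
    design: SampleDesign,
    p_cutoff: float = P_CUTOFF,
    dcog_cutoff: float = DCOG_CUTOFF,
    min_points: int | None = None,
) -> pd.DataFrame:
    """Compute per-peptide CoG shifts for a whole quantification table.

    Parameters
    ----------
    records, design
        Quantified peptides and the channel design (time mode: conditions
        ``control`` and ``treated``).
    p_cutoff, dcog_cutoff
        Volcano significance cutoffs.
    min_points
        Minimum observed points per profile for a peptide to be tested;
        default requires the full time grid in every profile of both
        conditions (centroids on differing supports are biased).

    Returns
    -------
    DataFrame indexed like the input with columns: sequence, proteins,
    is_unique, per-replicate centroids, cog_control_mean, cog_treated_mean,
    delta_cog, p_value, significant, tested, and a ``reason`` for untested
    peptides (``incomplete`` or ``zero_variance`` or ``degenerate``).
    """
    if "control" not in design.conditions or "treated" not in design.conditions:
        raise DesignError("time-mode analysis needs both control and treated channels")
    frame = intensity_frame(records, design)

    Xc, grid_c = _profile_tensor(frame, design, "control")
    Xt, grid_t = _profile_tensor(frame, design, "treated")

    def cogs(X: np.ndarray, grid: np.ndarray, need: int) -> tuple[np.ndarray, np.ndarray]:
        observed = ~np.isnan(X)
        complete = observed.sum(axis=2) >= need
        w = np.where(observed, X, 0.0)
        total = w.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            cog = (w * grid).sum(axis=2) / total
        cog[total <= 0] = np.nan
        return cog, complete

    need_c = len(grid_c) if min_points is None else min_points
    need_t = len(grid_t) if min_points is None else min_points
    cog_c, complete_c = cogs(Xc, grid_c, need_c)
    cog_t, complete_t = cogs(Xt, grid_t, need_t)

    complete = complete_c.all(axis=1) & complete_t.all(axis=1)
    finite = ~np.isnan(cog_c).any(axis=1) & ~np.isnan(cog_t).any(axis=1)

    n1, n2 = cog_t.shape[1], cog_c.shape[1]
    mt, mc = cog_t.mean(axis=1), cog_c.mean(axis=1)
    delta = mt - mc
    ss = ((cog_t - mt[:, None]) ** 2).sum(axis=1) + ((cog_c - mc[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(ss / df * (1.0 / n1 + 1.0 / n2))
        tval = delta / se
    p = 2.0 * stats.t.sf(np.abs(tval), df)
    zero_var = ss == 0.0
    p = np.where(zero_var, np.nan, p)

    tested = complete & finite & ~zero_var
    significant = tested & (p < p_cutoff) & (np.abs(delta) > dcog_cutoff)

    reason = np.full(len(frame), "", dtype=object)
    reason[~complete] = "incomplete"
    reason[complete & ~finite] = "degenerate"
    reason[complete & finite & zero_var] = "zero_variance"

    out = pd.DataFrame(
        {
            "sequence": frame.index.get_level_values("sequence"),
            "proteins": frame.index.get_level_values("proteins"),
            "is_unique": [r.is_unique for r in records],
            "cog_control_mean": mc,
            "cog_treated_mean": mt,
            "delta_cog": delta,
            "p_value": p,
            "significant": significant,
            "tested": tested,
            "reason": reason,
        }
    )
    for j in range(n2):
        out[f"cog_control_r{j + 1}"] = cog_c[:, j]
    for j in range(n1):
        out[f"cog_treated_r{j + 1}"] = cog_t[:, j]
    # untested peptides report no shift statistics (zero-variance keeps its
    # well-defined delta, with p = NaN as the flag)
    blank = ~tested & (out["reason"] != "zero_variance")
    out.loc[blank, ["delta_cog", "p_value", "cog_control_mean", "cog_treated_mean"]] = np.nan
    out.reset_index(drop=True, inplace=True)
    return out
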