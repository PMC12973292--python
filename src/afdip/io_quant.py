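"""Reading and writing peptide quantification tables and sample designs.

The quantification dialect is the MaxQuant ``peptides.txt`` family: a
tab-separated table with a peptide-sequence column, one or more protein
columns, and one reporter-intensity column per TMT channel.  The sample
design table is authoritative for what each channel means: it maps every
channel label to a condition (``control`` or ``treated``), an axis value
(hours of digestion in time mode, nM of compound in concentration mode)
and a replicate index.

Zero reporter intensities are treated as missing (non-detection), matching
the MaxQuant convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DesignError, FormatError

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "treated")

#: Column names recognised as the peptide sequence column, in priority order.
SEQUENCE_COLUMNS = ("Sequence", "sequence", "Peptide", "peptide")
#: Column names recognised as the protein-accession column, in priority order.
PROTEIN_COLUMNS = ("Proteins", "Protein IDs", "proteins", "protein", "Leading razor protein")


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelAssignment:
    """One TMT channel's role in the experiment."""

    channel: str
    condition: str
    axis_value: float
    replicate: int

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise DesignError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.replicate < 1:
            raise DesignError("replicate indices are 1-based positive integers")


@dataclass
class SampleDesign:
    """Maps TMT channel labels to (condition, axis value, replicate).

    ``axis_value`` is hours in time mode and nM in concentration mode; the
    design itself is agnostic, downstream analyses give it meaning.
    """

    entries: list[ChannelAssignment] = field(default_factory=list)

    def __post_init__(self):
        channels = [e.channel for e in self.entries]
        if len(set(channels)) != len(channels):
            raise DesignError("channel labels must be unique")
        keys = [(e.condition, e.axis_value, e.replicate) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise DesignError(
                "each (condition, axis_value, replicate) may appear at most once"
            )
        for cond in self.conditions:
            values = {e.axis_value for e in self.entries if e.condition == cond}
            if len(values) < 2:
                raise DesignError(
                    f"condition {cond!r} needs at least 2 distinct axis values"
                )

    # -- accessors ----------------------------------------------------------

    @property
    def channels(self) -> list[str]:
        return [e.channel for e in self.entries]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.condition not in seen:
                seen.append(e.condition)
        return seen

    def axis_values(self, condition: str) -> list[float]:
        return sorted({e.axis_value for e in self.entries if e.condition == condition})

    def replicates(self, condition: str) -> list[int]:
        return sorted({e.replicate for e in self.entries if e.condition == condition})

    def channels_for(self, condition: str, replicate: int) -> list[ChannelAssignment]:
        """Channels of one profile, ordered by axis value."""
        sub = [
            e for e in self.entries
            if e.condition == condition and e.replicate == replicate
        ]
        return sorted(sub, key=lambda e: e.axis_value)

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_table(cls, path: str | Path) -> "SampleDesign":
        """Read a design TSV with columns channel, condition, value, replicate."""
        df = pd.read_csv(path, sep="\t", dtype={"channel": str})
        required = {"channel", "condition", "value", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(
                f"design table {path} lacks column(s): {', '.join(sorted(missing))}"
            )
        entries = [
            ChannelAssignment(
                channel=str(r.channel),
                condition=str(r.condition),
                axis_value=float(r.value),
                replicate=int(r.replicate),
            )
            for r in df.itertuples()
        ]
        return cls(entries)

    def to_table(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "channel": [e.channel for e in self.entries],
                "condition": [e.condition for e in self.entries],
                "value": [e.axis_value for e in self.entries],
                "replicate": [e.replicate for e in self.entries],
            }
        )
        df.to_csv(path, sep="\t", index=False)


def time_course_design(
    time_grid: Sequence[float],
    n_replicates: int,
    conditions: Sequence[str] = CONDITIONS,
    label: str = "{condition}_{value:g}h_r{replicate}",
) -> SampleDesign:
    """Build the standard time-mode design: conditions x time points x replicates."""
    entries = [
        ChannelAssignment(
            channel=label.format(condition=cond, value=t, replicate=rep),
            condition=cond,
            axis_value=float(t),
            replicate=rep,
        )
        for rep in range(1, n_replicates + 1)
        for cond in conditions
        for t in time_grid
    ]
    return SampleDesign(entries)


def concentration_design(
    conc_grid: Sequence[float],
    n_replicates: int,
    label: str = "conc_{value:g}nM_r{replicate}",
) -> SampleDesign:
    """Build the concentration-mode design: one 'treated' series over the grid."""
    entries = [
        ChannelAssignment(
            channel=label.format(value=c, replicate=rep),
            condition="treated",
            axis_value=float(c),
            replicate=rep,
        )
        for rep in range(1, n_replicates + 1)
        for c in conc_grid
    ]
    return SampleDesign(entries)


# ---------------------------------------------------------------------------
# Peptide records
# ---------------------------------------------------------------------------

@dataclass
class PeptideRecord:
    """One quantified peptide row.

    ``intensities`` maps channel label to a positive intensity; channels with
    missing (or zero) reporter signal are simply absent from the mapping.
    """

    sequence: str
    protein_ids: tuple[str, ...]
    intensities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sequence or self.sequence != self.sequence.upper():
            raise FormatError(f"peptide sequence must be nonempty uppercase: {self.sequence!r}")
        self.protein_ids = tuple(self.protein_ids)

    @property
    def is_unique(self) -> bool:
        """True when the peptide maps to exactly one protein group."""
        return len(self.protein_ids) == 1

    @property
    def protein_key(self) -> str:
        return ";".join(self.protein_ids)


def _pick_column(columns: Iterable[str], candidates: Sequence[str], what: str) -> str:
    cols = list(columns)
    for cand in candidates:
        if cand in cols:
            return cand
    raise FormatError(
        f"no {what} column found; expected one of {', '.join(candidates)}"
    )


def read_peptide_table(path: str | Path, design: SampleDesign) -> list[PeptideRecord]:
    """Read a MaxQuant-style peptide quantification TSV.

    Unparseable or zero intensity cells become missing values.  Duplicate
    (sequence, protein) rows — e.g. modified-sequence variants — are merged by
    summing their intensities, with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    seq_col = _pick_column(df.columns, SEQUENCE_COLUMNS, "peptide sequence")
    prot_col = _pick_column(df.columns, PROTEIN_COLUMNS, "protein")
    missing_channels = [c for c in design.channels if c not in df.columns]
    if missing_channels:
        raise FormatError(
            "quant table lacks reporter intensity column(s): "
            + ", ".join(missing_channels)
        )

    inten = df[design.channels].apply(pd.to_numeric, errors="coerce")
    inten = inten.where(inten > 0)  # zero intensity = non-detection

    merged: dict[tuple[str, str], PeptideRecord] = {}
    n_dup = 0
    for i in range(len(df)):
        seq = str(df.iloc[i][seq_col]).strip().upper()
        prot_raw = df.iloc[i][prot_col]
        proteins = tuple(
            p.strip() for p in str(prot_raw).split(";") if p.strip()
        ) if pd.notna(prot_raw) else ()
        row = inten.iloc[i]
        intensities = {c: float(v) for c, v in row.items() if pd.notna(v)}
        key = (seq, ";".join(proteins))
        if key in merged:
            n_dup += 1
            rec = merged[key]
            for c, v in intensities.items():
                rec.intensities[c] = rec.intensities.get(c, 0.0) + v
        else:
            merged[key] = PeptideRecord(seq, proteins, intensities)
    if n_dup:
        logger.warning(
            "merged %d duplicate (sequence, protein) rows by summing intensities", n_dup
        )
    return list(merged.values())


def write_peptide_table(
    records: Sequence[PeptideRecord], design: SampleDesign, path: str | Path
) -> None:
    """Write records back to the quantification dialect ``read_peptide_table`` reads."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "Sequence": rec.sequence,
            "Proteins": rec.protein_key,
        }
        for c in design.channels:
            row[c] = rec.intensities.get(c, "")
        rows.append(row)
    pd.DataFrame(rows, columns=["Sequence", "Proteins", *design.channels]).to_csv(
        path, sep="\t", index=False
    )


def intensity_frame(
    records: Sequence[PeptideRecord], design: SampleDesign
) -> pd.DataFrame:
    """Records as a wide DataFrame: one row per peptide, one column per channel.

    The index is a MultiIndex of (sequence, protein group); missing channels
    are NaN.
    """
    data = np.full((len(records), len(design.channels)), np.nan)
    col_index = {c: j for j, c in enumerate(design.channels)}
    for i, rec in enumerate(records):
        for c, v in rec.intensities.items():
            j = col_index.get(c)
            if j is not None:
                data[i, j] = v
    index = pd.MultiIndex.from_tuples(
        [(r.sequence, r.protein_key) for r in records], names=["sequence", "proteins"]
    )
    return pd.DataFrame(data, index=index, columns=design.channels)


# ---------------------------------------------------------------------------
# Time courses
# ---------------------------------------------------------------------------

@dataclass
class PeptideTimeCourse:
    """One peptide's ordered (axis value, abundance) profile for one
    condition and replicate.  ``complete`` is False when the profile has
    fewer observed points than the analysis requires."""

    sequence: str
    protein_ids: tuple[str, ...]
    condition: str
    replicate: int
    points: list[tuple[float, float]]
    complete: bool = True

    def __post_init__(self):
        values = [v for v, _ in self.points]
        if values != sorted(values):
            raise FormatError("time-course axis values must be increasing")
        if any(a < 0 for _, a in self.points):
            raise FormatError("abundances must be nonnegative")


def assemble_timecourses(
    records: Sequence[PeptideRecord],
    design: SampleDesign,
    min_points: int | None = None,
) -> list[PeptideTimeCourse]:
    """Assemble one time course per (peptide, condition, replicate).

    Profiles observed at fewer than ``min_points`` axis values (default: the
    full grid of the design) are flagged ``complete=False`` rather than
    dropped — no points are ever invented or silently discarded.
    """
    courses: list[PeptideTimeCourse] = []
    for rec in records:
        for cond in design.conditions:
            for rep in design.replicates(cond):
                chans = design.channels_for(cond, rep)
                need = len(chans) if min_points is None else min_points
                points = [
                    (e.axis_value, rec.intensities[e.channel])
                    for e in chans
                    if e.channel in rec.intensities
                ]
                courses.append(
                    PeptideTimeCourse(
                        sequence=rec.sequence,
                        protein_ids=rec.protein_ids,
                        condition=cond,
                        replicate=rep,
                        points=points,
                        complete=len(points) >= need,
                    )
                )
    return courses
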