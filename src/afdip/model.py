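"""Model/Results interface over the digestion-shift analyses.

Mirrors the statsmodels idiom: a model object is built from data (records
plus a channel design, or directly from tables on disk), ``fit()`` runs the
analysis and returns a results object carrying the peptide- and
protein-level tables, filter diagnostics, and a ``summary()``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import dose_response, protein_stats, structure, timecourse
from .io_quant import PeptideRecord, SampleDesign, read_peptide_table
from .simulate import SimConfig, simulate_conc_mode, simulate_time_mode


class _BaseModel:
    def __init__(self, records: Sequence[PeptideRecord], design: SampleDesign):
        self.records = list(records)
        self.design = design

    @classmethod
    def from_tables(cls, peptides_path, design_path, **kwargs):
        """Build the model from a quantification TSV and a design TSV."""
        design = SampleDesign.from_table(design_path)
        records = read_peptide_table(peptides_path, design)
        return cls(records, design, **kwargs)


@dataclass
class FilterCounts:
    """Row bookkeeping across the analysis: input = tested + dropped."""

    n_input: int
    n_tested: int
    dropped: dict[str, int] = field(default_factory=dict)

    def check(self) -> bool:
        return self.n_input == self.n_tested + sum(self.dropped.values())


class TimeCourseAFDIP(_BaseModel):
    """Time-mode digestion-shift model.

    Parameters
    ----------
    records, design
        Quantified peptides and channel design with ``control`` and
        ``treated`` conditions over a shared time grid.
    p_cutoff, dcog_cutoff
        Volcano significance cutoffs (raw peptide p and |ΔCoG| hours).
    min_points
        Minimum observed points per profile for testing (default: full grid).
    """

    def __init__(
        self,
        records: Sequence[PeptideRecord],
        design: SampleDesign,
        p_cutoff: float = timecourse.P_CUTOFF,
        dcog_cutoff: float = timecourse.DCOG_CUTOFF,
        min_points: int | None = None,
        unique_only: bool = True,
    ):
        super().__init__(records, design)
        self.p_cutoff = p_cutoff
        self.dcog_cutoff = dcog_cutoff
        self.min_points = min_points
        self.unique_only = unique_only

    @classmethod
    def from_simulation(cls, config: SimConfig, **kwargs):
        """Simulate a time-mode experiment and wrap it in a model.

        Returns ``(model, ground_truth)``.
        """
        records, design, truth = simulate_time_mode(config)
        return cls(records, design, **kwargs), truth

    def fit(self) -> "TimeCourseResults":
        peptides = timecourse.shift_table(
            self.records,
            self.design,
            p_cutoff=self.p_cutoff,
            dcog_cutoff=self.dcog_cutoff,
            min_points=self.min_points,
        )
        proteins = protein_stats.aggregate_proteins(
            peptides, unique_only=self.unique_only
        )
        dropped = {
            reason: int((peptides["reason"] == reason).sum())
            for reason in ("incomplete", "degenerate", "zero_variance")
            if (peptides["reason"] == reason).any()
        }
        counts = FilterCounts(
            n_input=len(peptides),
            n_tested=int(peptides["tested"].sum()),
            dropped=dropped,
        )
        return TimeCourseResults(self, peptides, proteins, counts)


class TimeCourseResults:
    """Fitted time-mode results: peptide and protein tables plus diagnostics."""

    def __init__(
        self,
        model: TimeCourseAFDIP,
        peptides: pd.DataFrame,
        proteins: pd.DataFrame,
        counts: FilterCounts,
    ):
        self.model = model
        self.peptides = peptides
        self.proteins = proteins
        self.counts = counts

    # -- views --------------------------------------------------------------

    @property
    def significant_peptides(self) -> pd.DataFrame:
        return self.peptides[self.peptides["significant"]]

    def ranked_peptides(self) -> pd.DataFrame:
        """Peptides prioritized by the |ΔCoG| + p rank sum."""
        return protein_stats.rank_peptides(self.peptides[self.peptides["tested"]])

    def volcano(self, level: str = "peptide") -> pd.DataFrame:
        """Volcano-plot coordinates: shift on x, -log10 p on y."""
        if level == "peptide":
            df = self.peptides[self.peptides["tested"]]
            return pd.DataFrame(
                {
                    "sequence": df["sequence"],
                    "proteins": df["proteins"],
                    "x_delta_cog": df["delta_cog"],
                    "y_neg_log10_p": -np.log10(df["p_value"]),
                    "significant": df["significant"],
                }
            )
        if level == "protein":
            df = self.proteins
            return pd.DataFrame(
                {
                    "protein": df["protein"],
                    "x_median_delta_cog": df["median_delta_cog"],
                    "y_neg_log10_p": -np.log10(df["combined_p"]),
                }
            )
        raise ValueError("level must be 'peptide' or 'protein'")

    def localize_binding_site(
        self,
        structure_source,
        ligand_resname: str,
        protein: str | None = None,
        top_k: int = structure.DEFAULT_TOP_K,
        cutoff: float = structure.DEFAULT_CUTOFF,
    ) -> structure.BindingSiteReport:
        """Map the top-shifting peptides (optionally of one protein) onto a
        PDB structure and measure ΔCoM against the ligand's 5 Å shell."""
        atoms = structure.parse_structure(structure_source)
        pool = self.peptides[self.peptides["tested"]]
        if protein is not None:
            pool = pool[pool["proteins"].str.contains(protein, regex=False)]
        return structure.localize_binding_site(
            pool, atoms, ligand_resname, top_k=top_k, cutoff=cutoff
        )

    # -- output -------------------------------------------------------------

    def summary(self, top: int = 10) -> str:
        """Human-readable analysis summary with the top protein calls."""
        buf = io.StringIO()
        c = self.counts
        buf.write("Time-mode digestion-shift analysis\n")
        buf.write("==================================\n")
        buf.write(f"Peptides quantified: {c.n_input}\n")
        buf.write(f"Peptides tested:     {c.n_tested}\n")
        for reason, n in c.dropped.items():
            buf.write(f"  dropped ({reason}): {n}\n")
        buf.write(f"Significant peptides (p < {self.model.p_cutoff:g}, "
                  f"|dCoG| > {self.model.dcog_cutoff:g} h): "
                  f"{int(self.peptides['significant'].sum())}\n")
        buf.write(f"Proteins tested:     {len(self.proteins)}\n")
        hits = self.proteins[self.proteins["bonferroni_p"] < self.model.p_cutoff]
        buf.write(f"Bonferroni protein hits (p* < {self.model.p_cutoff:g}): {len(hits)}\n\n")
        cols = ["protein", "k", "combined_p", "bonferroni_p", "median_delta_cog"]
        buf.write("Top proteins by combined p-value:\n")
        buf.write(self.proteins[cols].head(top).to_string(index=False,
                  float_format=lambda v: f"{v:.3g}"))
        buf.write("\n")
        return buf.getvalue()

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write peptide, protein, and volcano TSVs to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peptides": outdir / "peptide_results.tsv",
            "proteins": outdir / "protein_results.tsv",
            "volcano_peptide": outdir / "volcano_peptides.tsv",
            "volcano_protein": outdir / "volcano_proteins.tsv",
        }
        self.peptides.to_csv(paths["peptides"], sep="\t", index=False)
        self.proteins.to_csv(paths["proteins"], sep="\t", index=False)
        self.volcano("peptide").to_csv(paths["volcano_peptide"], sep="\t", index=False)
        self.volcano("protein").to_csv(paths["volcano_protein"], sep="\t", index=False)
        return paths


class DoseResponseAFDIP(_BaseModel):
    """Concentration-mode fold-change model at a fixed digestion time."""

    def __init__(
        self,
        records: Sequence[PeptideRecord],
        design: SampleDesign,
        top_n: int | None = dose_response.TOP_N_ABUNDANCE,
        include_vehicle: bool = False,
    ):
        super().__init__(records, design)
        self.top_n = top_n
        self.include_vehicle = include_vehicle

    @classmethod
    def from_simulation(cls, config: SimConfig, **kwargs):
        records, design, truth = simulate_conc_mode(config)
        return cls(records, design, **kwargs), truth

    def fit(self) -> "DoseResponseResults":
        table = dose_response.conc_table(
            self.records,
            self.design,
            include_vehicle=self.include_vehicle,
            top_n=self.top_n,
        )
        counts = FilterCounts(
            n_input=len(table),
            n_tested=int((table["tested"] & table["kept"]).sum()),
            dropped={
                "abundance_filter": int((~table["kept"]).sum()),
                "untestable": int((table["kept"] & ~table["tested"]).sum()),
            },
        )
        return DoseResponseResults(self, table, counts)


class DoseResponseResults:
    """Fitted concentration-mode results."""

    def __init__(self, model: DoseResponseAFDIP, peptides: pd.DataFrame,
                 counts: FilterCounts):
        self.model = model
        self.peptides = peptides
        self.counts = counts

    def ranked_peptides(self) -> pd.DataFrame:
        """Abundance-filtered peptides ranked by |log2 FC| + p rank sum."""
        pool = self.peptides[self.peptides["tested"] & self.peptides["kept"]]
        ranked = dose_response.conc_rank(pool)
        ranked["rank"] = np.arange(1, len(ranked) + 1)
        return ranked

    def volcano(self) -> pd.DataFrame:
        df = self.peptides[self.peptides["tested"]]
        return pd.DataFrame(
            {
                "sequence": df["sequence"],
                "proteins": df["proteins"],
                "x_log2_fc": df["log2_fc"],
                "y_neg_log10_p": -np.log10(df["p_value"]),
            }
        )

    def summary(self, top: int = 10) -> str:
        buf = io.StringIO()
        c = self.counts
        buf.write("Concentration-mode fold-change analysis\n")
        buf.write("=======================================\n")
        buf.write(f"Peptides quantified: {c.n_input}\n")
        buf.write(f"Peptides ranked:     {c.n_tested}\n")
        for reason, n in c.dropped.items():
            buf.write(f"  dropped ({reason}): {n}\n")
        buf.write("\nTop peptides by rank sum:\n")
        cols = ["sequence", "proteins", "log2_fc", "p_value", "rank_sum"]
        buf.write(self.ranked_peptides()[cols].head(top).to_string(
            index=False, float_format=lambda v: f"{v:.3g}"))
        buf.write("\n")
        return buf.getvalue()

    def save(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peptides": outdir / "conc_results.tsv",
            "ranked": outdir / "conc_ranked.tsv",
            "volcano": outdir / "volcano_conc.tsv",
        }
        self.peptides.to_csv(paths["peptides"], sep="\t", index=False)
        self.ranked_peptides().to_csv(paths["ranked"], sep="\t", index=False)
        self.volcano().to_csv(paths["volcano"], sep="\t", index=False)
        return paths
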