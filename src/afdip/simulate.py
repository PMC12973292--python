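"""Ground-truth generator for digestion-kinetics experiments.

The simulator emulates the filtrate read-out of an above-filter digestion:
each peptide is released from its (retained, undigested) parent protein by
first-order kinetics with rate k, and the buffer above the filter is
replaced after every sampling interval, so the interval yields are
independent increments

    y_j = A * (exp(-k * t_{j-1}) - exp(-k * t_j)),   t_0 = 0.

Ligand binding multiplies the rate of affected peptides of target proteins:
protected peptides digest slower (rate rho * k with rho < 1, shifting the
yield curve later, ΔCoG > 0) and flexibilized peptides digest faster (rate
k / rho, ΔCoG < 0).  Reporter noise is multiplicative log-normal per
channel, and channels drop to missing with a configurable probability.

In concentration mode a fixed digestion time T is used and occupancy
follows a one-site binding isotherm theta(c) = c / (c + K_d); the effective
rate is k_eff = k * (1 - theta * (1 - rho)), giving true-target peptides a
sigmoid abundance dependence on concentration.

Default parameter values describe the emulated study conditions: an 8 h
hourly time course, 3 replicates, rates log-normal around a ~1.4 h release
half-life (so the sampling window is informative), protection factor 0.5,
10% multiplicative reporter noise.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_quant import (
    PeptideRecord,
    SampleDesign,
    concentration_design,
    time_course_design,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic proteome.

    Rates are h^-1, times hours, concentrations nM, abundances arbitrary
    reporter-intensity units.
    """

    n_proteins: int = 200
    peptides_per_protein: int | tuple[int, int] = 10
    #: log-normal release-rate law: ln k ~ Normal(rate_log_mean, rate_log_sigma^2)
    rate_log_mean: float = math.log(0.5)
    rate_log_sigma: float = 0.5
    target_fraction: float = 0.01
    #: rate multiplier for protected peptides (< 1 slows digestion);
    #: flexibilized peptides use the reciprocal.
    protection_factor: float = 0.5
    protected_per_target: int = 3
    flexibilized_per_target: int = 1
    #: protein abundance scale A ~ log-normal (exercises the abundance filter)
    abundance_log_mean: float = math.log(1e6)
    abundance_log_sigma: float = 1.0
    noise_sigma: float = 0.1
    n_replicates: int = 3
    time_grid: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    conc_grid: tuple[float, ...] = (0.0, 0.1, 1.0, 10.0, 100.0, 1000.0)
    k_d: float = 10.0
    digestion_time_conc_mode: float = 2.0
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.protection_factor <= 0:
            raise ValueError("protection_factor must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ValueError("counts must be positive")


@dataclass
class GroundTruth:
    """Per-peptide rates and labels, per-protein target flags."""

    peptides: pd.DataFrame  # sequence, protein, k_control, k_treated, label
    proteins: pd.DataFrame  # protein, is_target

    def label_of(self) -> dict[str, str]:
        return dict(zip(self.peptides["sequence"], self.peptides["label"]))


def interval_yields(
    k: float, times: Sequence[float], amplitude: float = 1.0
) -> np.ndarray:
    """Noiseless filtrate yields of the sampling intervals ending at ``times``.

    With ideal buffer replacement the increments are independent, and their
    sum over the full course is A * (1 - exp(-k * t_n)).
    """
    t = np.concatenate([[0.0], np.asarray(times, dtype=float)])
    return amplitude * (np.exp(-k * t[:-1]) - np.exp(-k * t[1:]))


def expected_cog(k: float, times: Sequence[float]) -> float:
    """Noiseless center of gravity of the first-order yield curve."""
    y = interval_yields(k, times)
    t = np.asarray(times, dtype=float)
    return float((t * y).sum() / y.sum())


def occupancy(c: float | np.ndarray, k_d: float) -> float | np.ndarray:
    """One-site binding isotherm theta(c) = c / (c + K_d)."""
    c = np.asarray(c, dtype=float)
    theta = c / (c + k_d)
    return float(theta) if theta.ndim == 0 else theta


def conc_mode_abundance(
    k: float, rho: float, c: float | np.ndarray, k_d: float, t_digest: float
) -> float | np.ndarray:
    """Noiseless filtrate abundance after ``t_digest`` hours at concentration c."""
    theta = occupancy(c, k_d)
    k_eff = k * (1.0 - theta * (1.0 - rho))
    return 1.0 - np.exp(-k_eff * t_digest)


# ---------------------------------------------------------------------------
# Proteome construction
# ---------------------------------------------------------------------------

def _random_peptide(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        length = int(rng.integers(8, 21))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        if seq not in taken:
            taken.add(seq)
            return seq


def _draw_proteome(config: SimConfig, rng: np.random.Generator) -> GroundTruth:
    n_targets = int(round(config.target_fraction * config.n_proteins))
    if config.target_fraction > 0:
        n_targets = max(1, n_targets)
    target_idx = set(
        rng.choice(config.n_proteins, size=n_targets, replace=False).tolist()
    ) if n_targets else set()

    taken: set[str] = set()
    pep_rows = []
    prot_rows = []
    for i in range(config.n_proteins):
        protein = f"P{i + 1:05d}"
        is_target = i in target_idx
        prot_rows.append({"protein": protein, "is_target": is_target})
        if isinstance(config.peptides_per_protein, tuple):
            lo, hi = config.peptides_per_protein
            n_pep = int(rng.integers(lo, hi + 1))
        else:
            n_pep = int(config.peptides_per_protein)
        amplitude = float(
            np.exp(rng.normal(config.abundance_log_mean, config.abundance_log_sigma))
        )
        labels = ["null"] * n_pep
        if is_target:
            n_prot = min(config.protected_per_target, n_pep)
            n_flex = min(config.flexibilized_per_target, n_pep - n_prot)
            affected = rng.choice(n_pep, size=n_prot + n_flex, replace=False)
            for j in affected[:n_prot]:
                labels[j] = "protected"
            for j in affected[n_prot:]:
                labels[j] = "flexibilized"
        for label in labels:
            k = float(np.exp(rng.normal(config.rate_log_mean, config.rate_log_sigma)))
            if label == "protected":
                k_treated = k * config.protection_factor
            elif label == "flexibilized":
                k_treated = k / config.protection_factor
            else:
                k_treated = k
            pep_rows.append(
                {
                    "sequence": _random_peptide(rng, taken),
                    "protein": protein,
                    "k_control": k,
                    "k_treated": k_treated,
                    "label": label,
                    "amplitude": amplitude,
                }
            )
    return GroundTruth(pd.DataFrame(pep_rows), pd.DataFrame(prot_rows))


def _noisy(
    values: np.ndarray, rng: np.random.Generator, sigma: float, missing_rate: float
) -> np.ndarray:
    out = values * np.exp(rng.normal(0.0, sigma, size=values.shape))
    if missing_rate > 0:
        out = np.where(rng.random(values.shape) < missing_rate, np.nan, out)
    return out


# ---------------------------------------------------------------------------
# Simulation entry points
# ---------------------------------------------------------------------------

def simulate_time_mode(
    config: SimConfig,
) -> tuple[list[PeptideRecord], SampleDesign, GroundTruth]:
    """Synthesize a full time-mode experiment.

    Returns quantified peptide records (identical peptide sets in every
    condition and replicate, bar missing values), the channel design, and the
    ground truth.
    """
    rng = np.random.default_rng(config.seed)
    truth = _draw_proteome(config, rng)
    design = time_course_design(config.time_grid, config.n_replicates)

    records = []
    for row in truth.peptides.itertuples():
        intensities: dict[str, float] = {}
        for cond, k in (("control", row.k_control), ("treated", row.k_treated)):
            y = interval_yields(k, config.time_grid, amplitude=row.amplitude)
            for rep in range(1, config.n_replicates + 1):
                noisy = _noisy(y, rng, config.noise_sigma, config.missing_rate)
                for e, v in zip(design.channels_for(cond, rep), noisy):
                    if not np.isnan(v):
                        intensities[e.channel] = float(v)
        records.append(PeptideRecord(row.sequence, (row.protein,), intensities))
    return records, design, truth


def simulate_conc_mode(
    config: SimConfig,
) -> tuple[list[PeptideRecord], SampleDesign, GroundTruth]:
    """Synthesize a concentration-mode experiment at a fixed digestion time."""
    rng = np.random.default_rng(config.seed)
    truth = _draw_proteome(config, rng)
    design = concentration_design(config.conc_grid, config.n_replicates)
    concs = np.asarray(config.conc_grid, dtype=float)

    records = []
    for row in truth.peptides.itertuples():
        rho = row.k_treated / row.k_control
        base = row.amplitude * conc_mode_abundance(
            row.k_control, rho, concs, config.k_d, config.digestion_time_conc_mode
        )
        intensities: dict[str, float] = {}
        for rep in range(1, config.n_replicates + 1):
            noisy = _noisy(base, rng, config.noise_sigma, config.missing_rate)
            for e, v in zip(design.channels_for("treated", rep), noisy):
                if not np.isnan(v):
                    intensities[e.channel] = float(v)
        records.append(PeptideRecord(row.sequence, (row.protein,), intensities))
    return records, design, truth


def export_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write the peptide-level truth table (TSV) consumed by evaluations."""
    truth.peptides.to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    # keep_default_na so the 'null' peptide label survives as a string
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def write_config(config: SimConfig, path: str | Path) -> None:
    """Write a config as a plain ``key = value`` file."""
    with open(path, "w") as fh:
        for key, value in asdict(config).items():
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            fh.write(f"{key} = {value}\n")


def read_config(path: str | Path) -> SimConfig:
    """Read a plain ``key = value`` config file written by :func:`write_config`."""
    kwargs: dict[str, object] = {}
    fields = {f.name: f for f in SimConfig.__dataclass_fields__.values()}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in fields:
            raise ValueError(f"unknown simulator parameter {key!r}")
        if key in ("time_grid", "conc_grid"):
            kwargs[key] = tuple(float(v) for v in raw.split(","))
        elif key in ("n_proteins", "protected_per_target", "flexibilized_per_target",
                     "n_replicates", "seed"):
            kwargs[key] = int(raw)
        elif key == "peptides_per_protein":
            parts = raw.split(",")
            kwargs[key] = int(parts[0]) if len(parts) == 1 else (int(parts[0]), int(parts[1]))
        else:
            kwargs[key] = float(raw)
    return SimConfig(**kwargs)


def null_config(**overrides) -> SimConfig:
    """A no-effect configuration (every peptide null) for calibration checks."""
    cfg = SimConfig(target_fraction=0.0, **overrides)
    return cfg


# ---------------------------------------------------------------------------
# Synthetic toy structure
# ---------------------------------------------------------------------------

#: 40-residue synthetic chain; chosen so every >=4-mer occurs exactly once.
TOY_SEQUENCE = "ACDEFGHIKLMNPQRSTVWYAYCWDVETGSHFIMKNLPQR"

#: Peptides tiling the synthetic chain (1-based residue spans).
TOY_PEPTIDES = {
    "ACDEFGHI": (1, 8),
    "IKLMNPQR": (8, 15),
    "RSTVWYAY": (15, 22),
    "YCWDVETG": (22, 29),
    "GSHFIMKN": (29, 36),
    "KNLPQR": (35, 40),
}


def toy_structure() -> str:
    """Synthetic CA-only PDB text: a 40-residue chain laid along x with a
    4-atom ligand (residue name LIG) sitting next to residues 10–12.

    Purely synthetic geometry for testing binding-site localization; peptides
    from :data:`TOY_PEPTIDES` map exactly onto the chain.
    """
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
        "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    }
    lines = []
    serial = 1
    for i, aa in enumerate(TOY_SEQUENCE, start=1):
        x = 3.8 * i
        y = 1.0 if i % 2 else -1.0  # mild zig-zag
        lines.append(
            f"ATOM  {serial:>5}  CA  {three[aa]} A{i:>4}    "
            f"{x:8.3f}{y:8.3f}{0.0:8.3f}{1.00:6.2f}{0.00:6.2f}           C"
        )
        serial += 1
    # ligand next to residues 9-11 (x = 34.2 .. 41.8), ~4 Å off the chain
    # axis; offsets keep every contact distance away from the 5 Å boundary
    for j, (lx, ly, lz) in enumerate(
        [(38.0, 3.9, 0.0), (40.5, 4.4, 0.5), (43.0, 3.9, -0.5), (45.5, 4.4, 0.0)]
    ):
        lines.append(
            f"HETATM{serial:>5}  C{j + 1:<2} LIG A{99:>4}    "
            f"{lx:8.3f}{ly:8.3f}{lz:8.3f}{1.00:6.2f}{0.00:6.2f}           C"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
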