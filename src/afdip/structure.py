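"""Binding-site localization on PDB structures.

The structural read-out of a digestion-kinetics screen is geometric: map
the top-shifting peptides of the target protein onto a crystal structure,
take the center of mass (CoM) of all their atoms, and compare it with the
CoM of the crystallographic binding site — every residue with any atom
within 5 Å of the ligand.  The Euclidean distance between the two centers
(ΔCoM, in Å) measures how well the kinetic shifts localize the site.

Parsing is backed by gemmi; author residue numbering is preserved, waters
are dropped, and for alternate locations the highest-occupancy conformer is
kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import LigandNotFoundError, StructureParseError

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 5.0  # Å, atom–atom, inclusive
DEFAULT_TOP_K = 3


@dataclass(frozen=True)
class AtomRecord:
    """One non-water atom of a structure, with element mass in Da."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    xyz: tuple[float, float, float]
    occupancy: float
    is_hetero: bool
    mass: float

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class PeptideSpan:
    """One exact placement of a peptide sequence on a chain."""

    sequence: str
    chain_id: str
    start_residue: int
    end_residue: int
    residue_keys: list[tuple[str, int, str]]
    ambiguous: bool = False


@dataclass
class BindingSiteReport:
    """Result of localizing a binding site from shifting peptides."""

    ligand_resname: str
    site_residues: list[tuple[str, int, str]]  # (chain, residue number, residue name)
    site_com: tuple[float, float, float]
    peptide_com: tuple[float, float, float]
    delta_com: float
    peptides_used: list[str]
    peptides_unmapped: list[str] = field(default_factory=list)
    peptides_ambiguous: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.site_residues, columns=["chain", "residue_number", "residue_name"]
        )

    def pymol_selections(self) -> dict[str, str]:
        """Selection strings loadable in PyMOL for visual inspection."""
        site = " or ".join(
            f"(chain {c} and resi {n})" for c, n, _ in self.site_residues
        )
        return {
            "ligand": f"resn {self.ligand_resname}",
            "site": site or "none",
        }


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _validate_pdb_text(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line[:6].strip() in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise StructureParseError("truncated ATOM/HETATM record", lineno)
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise StructureParseError("unparseable coordinates", lineno) from None


def parse_structure(source: str | Path) -> list[AtomRecord]:
    """Parse a PDB file (or literal PDB text) into atom records.

    Waters are excluded; for alternate locations only the highest-occupancy
    conformer of each atom is kept (ties resolved to the first conformer).
    """
    if isinstance(source, Path) or "\n" not in str(source):
        text = Path(source).read_text()
    else:
        text = str(source)
    _validate_pdb_text(text)
    st = gemmi.read_pdb_string(text)
    st.setup_entities()

    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            if residue.name == "HOH":
                continue
            # highest-occupancy conformer per atom name
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif atom.occ > prev.occ:
                    best[atom.name] = atom
            for name in order:
                atom = best[name]
                atoms.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=atom.element.name,
                        residue_name=residue.name,
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or " ").strip(),
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=atom.occ,
                        is_hetero=residue.het_flag == "H",
                        mass=atom.element.weight,
                    )
                )
    return atoms


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _coords(atoms: Sequence[AtomRecord]) -> np.ndarray:
    return np.array([a.xyz for a in atoms], dtype=float)


def center_of_mass(
    atoms: Sequence[AtomRecord], mass_weighted: bool = True
) -> np.ndarray:
    """Center of mass of a selection: sum(m_i x_i)/sum(m_i), or the plain
    coordinate mean when ``mass_weighted`` is False."""
    if not atoms:
        raise ValueError("empty atom selection has no center of mass")
    xyz = _coords(atoms)
    if not mass_weighted:
        return xyz.mean(axis=0)
    m = np.array([a.mass for a in atoms], dtype=float)
    return (xyz * m[:, None]).sum(axis=0) / m.sum()


def ligand_atoms(
    atoms: Sequence[AtomRecord], ligand_resname: str, chain: str | None = None
) -> list[AtomRecord]:
    sel = [
        a for a in atoms
        if a.is_hetero and a.residue_name == ligand_resname
        and (chain is None or a.chain_id == chain)
    ]
    if not sel:
        available = sorted({a.residue_name for a in atoms if a.is_hetero})
        raise LigandNotFoundError(
            f"no hetero atoms named {ligand_resname!r}; available hetero residues: "
            + (", ".join(available) or "none")
        )
    return sel


def binding_site_residues(
    atoms: Sequence[AtomRecord],
    ligand_resname: str,
    cutoff: float = DEFAULT_CUTOFF,
    ligand_chain: str | None = None,
) -> list[tuple[str, int, str]]:
    """Protein residues with any atom within ``cutoff`` Å (inclusive) of any
    ligand atom, as (chain, residue number, residue name) tuples."""
    lig = ligand_atoms(atoms, ligand_resname, chain=ligand_chain)
    protein = [a for a in atoms if not a.is_hetero]
    if not protein:
        return []
    tree = cKDTree(_coords(lig))
    dist, _ = tree.query(_coords(protein))
    seen: dict[tuple[str, int, str], tuple[str, int, str]] = {}
    for atom, d in zip(protein, dist):
        if d <= cutoff and atom.residue_key not in seen:
            seen[atom.residue_key] = (
                atom.chain_id, atom.residue_number, atom.residue_name
            )
    if not seen:
        logger.warning(
            "no protein residues within %.1f Å of ligand %s", cutoff, ligand_resname
        )
    return list(seen.values())


# ---------------------------------------------------------------------------
# Sequence mapping
# ---------------------------------------------------------------------------

def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def chain_sequences(
    atoms: Sequence[AtomRecord],
) -> dict[str, tuple[str, list[tuple[str, int, str]]]]:
    """One-letter sequence per chain, built from protein residues in file
    (author-number) order, with the parallel list of residue keys.
    Nonstandard residues become 'X' and thus break exact peptide matches."""
    chains: dict[str, tuple[list[str], list[tuple[str, int, str]]]] = {}
    seen: set[tuple[str, int, str]] = set()
    for a in atoms:
        if a.is_hetero:
            continue
        key = a.residue_key
        if key in seen:
            continue
        seen.add(key)
        letters, keys = chains.setdefault(a.chain_id, ([], []))
        letters.append(_one_letter(a.residue_name))
        keys.append(key)
    return {c: ("".join(ls), ks) for c, (ls, ks) in chains.items()}


def map_peptide_to_structure(
    sequence: str, atoms: Sequence[AtomRecord]
) -> list[PeptideSpan]:
    """Exact substring placement of a peptide on every chain.

    Returns all matches; more than one match sets the ambiguity flag on each
    span.  An empty list means the peptide is unmapped.
    """
    spans: list[PeptideSpan] = []
    for chain_id, (seq, keys) in chain_sequences(atoms).items():
        start = 0
        while True:
            idx = seq.find(sequence, start)
            if idx < 0:
                break
            span_keys = keys[idx : idx + len(sequence)]
            spans.append(
                PeptideSpan(
                    sequence=sequence,
                    chain_id=chain_id,
                    start_residue=span_keys[0][1],
                    end_residue=span_keys[-1][1],
                    residue_keys=list(span_keys),
                )
            )
            start = idx + 1
    if len(spans) > 1:
        for s in spans:
            s.ambiguous = True
    return spans


def _atoms_of_residues(
    atoms: Sequence[AtomRecord], keys: Sequence[tuple[str, int, str]]
) -> list[AtomRecord]:
    keyset = set(keys)
    return [a for a in atoms if a.residue_key in keyset]


def localize_binding_site(
    shift_results: pd.DataFrame,
    atoms: Sequence[AtomRecord],
    ligand_resname: str,
    top_k: int = DEFAULT_TOP_K,
    cutoff: float = DEFAULT_CUTOFF,
    mass_weighted: bool = True,
    p_col: str = "p_value",
    seq_col: str = "sequence",
) -> BindingSiteReport:
    """Localize the binding site from the most significantly shifting peptides.

    The ``top_k`` peptides with the smallest p-values that map onto the
    structure contribute all their atoms to the peptide CoM; the reference is
    the CoM of the ligand's ``cutoff``-Å residue shell.  Ambiguous multi-chain
    matches resolve to the chain whose atoms come closest to the ligand;
    unmapped peptides are reported and skipped (more candidates are consumed
    until ``top_k`` mapped peptides are found, or the list is exhausted).
    """
    lig = ligand_atoms(atoms, ligand_resname)
    lig_tree = cKDTree(_coords(lig))

    ranked = shift_results.dropna(subset=[p_col]).sort_values(
        [p_col, seq_col], kind="mergesort"
    )
    used: list[str] = []
    unmapped: list[str] = []
    ambiguous: list[str] = []
    peptide_atoms: list[AtomRecord] = []
    for seq in ranked[seq_col]:
        if len(used) >= top_k:
            break
        spans = map_peptide_to_structure(seq, atoms)
        if not spans:
            unmapped.append(seq)
            continue
        if len(spans) > 1:
            ambiguous.append(seq)
            # deterministic tie-break: span nearest to the ligand
            def span_distance(span: PeptideSpan) -> float:
                sel = _atoms_of_residues(atoms, span.residue_keys)
                return float(lig_tree.query(_coords(sel))[0].min())
            spans = [min(spans, key=span_distance)]
        sel = _atoms_of_residues(atoms, spans[0].residue_keys)
        peptide_atoms.extend(sel)
        used.append(seq)
    if len(used) < top_k:
        logger.warning(
            "only %d of the requested %d peptides could be mapped", len(used), top_k
        )
    if not peptide_atoms:
        raise ValueError("no peptides could be mapped onto the structure")

    site = binding_site_residues(atoms, ligand_resname, cutoff=cutoff)
    site_atoms = [
        a for a in atoms
        if not a.is_hetero and (a.chain_id, a.residue_number) in
        {(c, n) for c, n, _ in site}
    ]
    if not site_atoms:
        raise ValueError(f"binding-site shell of {ligand_resname!r} is empty")

    site_com = center_of_mass(site_atoms, mass_weighted=mass_weighted)
    pep_com = center_of_mass(peptide_atoms, mass_weighted=mass_weighted)
    delta = float(np.linalg.norm(site_com - pep_com))
    return BindingSiteReport(
        ligand_resname=ligand_resname,
        site_residues=site,
        site_com=tuple(site_com),
        peptide_com=tuple(pep_com),
        delta_com=delta,
        peptides_used=used,
        peptides_unmapped=unmapped,
        peptides_ambiguous=ambiguous,
    )
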