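"""Molecular graph data model, SMILES/SDF I/O, and heteroatom perturbation.

The :class:`MolecularGraph` is a thin, hydrogen-implicit wrapper around an
RDKit molecule. It is the substrate for Mol2D featurization and for the
heteroatom→carbon perturbation used by atomic sensitivity analysis: a
heteroatom is swapped for a neutral carbon, the valence is completed with
implicit hydrogens, and any aromatic ring broken by the swap is kekulized
and re-perceived rather than rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

# RDKit's C++-level warnings (e.g. kekulization notes on intentionally
# perturbed rings) would flood stderr during ASA scans.
RDLogger.DisableLog("rdApp.warning")
RDLogger.DisableLog("rdApp.error")


class SmilesParseError(ValueError):
    """Raised when a SMILES/molblock cannot be parsed or sanitized."""


class NotHeteroatomError(ValueError):
    """Raised when a perturbation targets a carbon or hydrogen atom."""


class UnperturbableAtomError(ValueError):
    """Raised when no valid carbon valence completion exists for an atom.

    Callers (ASA) catch this specifically and mark the atom as skipped.
    """


_BOND_ORDER_NAMES = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}

_HYBRID_TAGS = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


@dataclass(frozen=True)
class AtomInfo:
    element: str
    formal_charge: int
    n_implicit_h: int
    aromatic: bool
    hybridization: str  # one of {"sp", "sp2", "sp3", "other"}


@dataclass(frozen=True)
class BondInfo:
    i: int
    j: int
    order: str  # one of {"single", "double", "triple", "aromatic"}


class MolecularGraph:
    """Attributed molecular graph with implicit hydrogens.

    Atom indices are 0-based, contiguous and stable: featurization,
    perturbation and site annotations all refer to the same numbering.
    """

    __slots__ = ("_mol", "name")

    def __init__(self, mol: Chem.Mol, name: str = ""):
        if mol is None:
            raise SmilesParseError("cannot build a graph from a null molecule")
        self._mol = mol
        self.name = name

    # -- construction -------------------------------------------------

    @classmethod
    def from_smiles(
        cls, smiles: str, name: str = "", largest_fragment: bool = True
    ) -> "MolecularGraph":
        if not smiles or not smiles.strip():
            raise SmilesParseError("empty SMILES string")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise SmilesParseError(f"could not parse SMILES {smiles!r}")
        mol = Chem.RemoveHs(mol)  # fold explicit H into implicit counts
        if largest_fragment and len(Chem.GetMolFrags(mol)) > 1:
            frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
            mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        return cls(mol, name=name)

    @classmethod
    def from_molblock(cls, block: str, name: str = "") -> "MolecularGraph":
        mol = Chem.MolFromMolBlock(block)
        if mol is None:
            raise SmilesParseError("could not parse MOL block")
        mol = Chem.RemoveHs(mol)
        return cls(mol, name=name or mol.GetProp("_Name") if mol.HasProp("_Name") else name)

    # -- views ---------------------------------------------------------

    @property
    def rdkit_mol(self) -> Chem.Mol:
        return self._mol

    @property
    def n_heavy_atoms(self) -> int:
        return self._mol.GetNumHeavyAtoms()

    @property
    def n_bonds(self) -> int:
        return self._mol.GetNumBonds()

    @property
    def atoms(self) -> list[AtomInfo]:
        out = []
        for a in self._mol.GetAtoms():
            out.append(
                AtomInfo(
                    element=a.GetSymbol(),
                    formal_charge=a.GetFormalCharge(),
                    n_implicit_h=a.GetTotalNumHs(),
                    aromatic=a.GetIsAromatic(),
                    hybridization=_HYBRID_TAGS.get(a.GetHybridization(), "other"),
                )
            )
        return out

    @property
    def bonds(self) -> list[BondInfo]:
        return [
            BondInfo(
                i=b.GetBeginAtomIdx(),
                j=b.GetEndAtomIdx(),
                order=_BOND_ORDER_NAMES.get(b.GetBondType(), "single"),
            )
            for b in self._mol.GetBonds()
        ]

    def heteroatom_indices(self) -> list[int]:
        """Indices of non-carbon, non-hydrogen heavy atoms (halogens included)."""
        return [
            a.GetIdx()
            for a in self._mol.GetAtoms()
            if a.GetAtomicNum() not in (1, 6)
        ]

    # -- canonical forms ----------------------------------------------

    @property
    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self._mol)

    def to_smiles(self) -> str:
        return self.canonical_smiles

    def to_molblock(self) -> str:
        mol = Chem.Mol(self._mol)
        mol.SetProp("_Name", self.name)
        return Chem.MolToMolBlock(mol)

    def is_isomorphic(self, other: "MolecularGraph") -> bool:
        return self.canonical_smiles == other.canonical_smiles

    def matches(self, smarts: str) -> bool:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS pattern {smarts!r}")
        return self._mol.HasSubstructMatch(patt)

    def substruct_matches(self, smarts: str) -> list[tuple[int, ...]]:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS pattern {smarts!r}")
        return [tuple(m) for m in self._mol.GetSubstructMatches(patt)]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MolecularGraph({self.canonical_smiles!r}, name={self.name!r})"


def parse_smiles(smiles: str, name: str = "") -> MolecularGraph:
    """Parse a SMILES string into a valence-consistent :class:`MolecularGraph`.

    Multi-fragment inputs (salts) keep only the largest fragment. Raises
    :class:`SmilesParseError` on malformed input.
    """
    return MolecularGraph.from_smiles(smiles, name=name)


def replace_heteroatom_with_carbon(mol: MolecularGraph, atom_index: int) -> MolecularGraph:
    """Return a new graph with the heteroatom at ``atom_index`` replaced by carbon.

    The replacement carbon is neutral (formal charge reset to 0) with the
    valence completed by implicit hydrogens; incident heavy-atom bonds are
    preserved. Aromatic rings broken by the swap are kekulized and
    re-perceived. The parent graph is never modified.

    Raises
    ------
    IndexError
        ``atom_index`` out of range.
    NotHeteroatomError
        The target atom is carbon or hydrogen.
    UnperturbableAtomError
        No chemically valid carbon completion exists (e.g. hexavalent
        sulfone sulfur); callers should skip the atom.
    """
    parent = mol.rdkit_mol
    if not 0 <= atom_index < parent.GetNumAtoms():
        raise IndexError(f"atom index {atom_index} out of range")
    if parent.GetAtomWithIdx(atom_index).GetAtomicNum() in (1, 6):
        raise NotHeteroatomError(f"atom {atom_index} is not a heteroatom")

    rw = Chem.RWMol(Chem.Mol(parent))
    try:
        Chem.Kekulize(rw, clearAromaticFlags=True)
    except Chem.KekulizeException as exc:  # pragma: no cover - parent is sanitized
        raise UnperturbableAtomError(str(exc)) from exc
    atom = rw.GetAtomWithIdx(atom_index)
    atom.SetAtomicNum(6)
    atom.SetFormalCharge(0)
    atom.SetNumExplicitHs(0)
    atom.SetNoImplicit(False)
    atom.SetIsAromatic(False)
    try:
        Chem.SanitizeMol(rw)
    except Exception as exc:
        raise UnperturbableAtomError(
            f"no valid carbon valence completion for atom {atom_index}: {exc}"
        ) from exc
    return MolecularGraph(rw.GetMol(), name=f"{mol.name}[{atom_index}->C]")


@dataclass
class DatasetRecord:
    graph: MolecularGraph
    pka: float
    task: str  # "acid" or "base"


def load_dataset(
    path: str | Path, format: str | None = None
) -> tuple[list[DatasetRecord], int]:
    """Load labeled molecules from a delimited table or an SDF.

    Tables need columns ``smiles``, ``pka``, ``task`` (separator inferred
    from the extension: .tsv → tab, otherwise comma). SDF records need
    ``pka`` and ``task`` properties. Unparseable rows are skipped with a
    logged warning.

    Returns ``(records, n_skipped)`` with records in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "smiles-table"

    records: list[DatasetRecord] = []
    skipped = 0
    if format == "smiles-table":
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        try:
            df = pd.read_csv(path, sep=sep)
        except pd.errors.EmptyDataError:
            raise ValueError(f"no records in {path}") from None
        missing = {"smiles", "pka", "task"} - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        for row in df.itertuples(index=False):
            try:
                name = str(getattr(row, "name", "")) if hasattr(row, "name") else ""
                graph = parse_smiles(str(row.smiles), name=name)
                records.append(DatasetRecord(graph, float(row.pka), str(row.task)))
            except (SmilesParseError, ValueError) as exc:
                logger.warning("skipping row (%s): %s", row.smiles, exc)
                skipped += 1
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for i, rdmol in enumerate(supplier):
            if rdmol is None or not (rdmol.HasProp("pka") and rdmol.HasProp("task")):
                logger.warning("skipping SDF record %d", i)
                skipped += 1
                continue
            name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
            records.append(
                DatasetRecord(
                    MolecularGraph(Chem.RemoveHs(rdmol), name=name),
                    float(rdmol.GetProp("pka")),
                    rdmol.GetProp("task"),
                )
            )
    else:
        raise ValueError(f"unknown format {format!r}")

    if not records and skipped == 0:
        raise ValueError(f"no records in {path}")
    return records, skipped


def write_sdf(
    graphs: Iterable[MolecularGraph],
    path: str | Path,
    properties: Sequence[dict] | None = None,
) -> None:
    """Write graphs to an SDF (V2000), optionally with per-molecule properties."""
    writer = Chem.SDWriter(str(path))
    try:
        for k, g in enumerate(graphs):
            mol = Chem.Mol(g.rdkit_mol)
            mol.SetProp("_Name", g.name)
            if properties is not None:
                for key, value in properties[k].items():
                    mol.SetProp(str(key), str(value))
            writer.write(mol)
    finally:
        writer.close()
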