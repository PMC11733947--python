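"""Mol2D atomic-environment count descriptors.

Each heavy atom contributes one *atomic environment* (AE): the atom itself
(element, formal charge, aromaticity, implicit-hydrogen count), its
incident bonds, and its neighbors one bond away (element and aromaticity).
A molecule's Mol2D vector counts the occurrences of each distinct AE over
a fixed vocabulary; AEs absent from the vocabulary accrue to a single
``unknown`` position so the counts always sum to the heavy-atom total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .chemgraph import MolecularGraph

_BOND_GLYPH = {"single": "-", "double": "=", "triple": "#", "aromatic": ":"}


@dataclass(frozen=True, order=True)
class AtomicEnvironmentKey:
    """Canonical key for one atom's 1-bond neighborhood.

    ``center`` is ``(element, formal_charge, aromatic, n_implicit_h)``;
    ``shell`` is the sorted multiset of ``(bond_glyph, element, aromatic)``
    over the neighbors. Two atoms with equal center tuples and equal shell
    multisets produce byte-identical keys regardless of atom numbering.
    """

    center: tuple[str, int, bool, int]
    shell: tuple[tuple[str, str, bool], ...]

    @property
    def text(self) -> str:
        el, q, ar, h = self.center
        head = f"{el}{'a' if ar else ''}H{h}{q:+d}"
        body = ",".join(f"{g}{nel}{'a' if nar else ''}" for g, nel, nar in self.shell)
        return f"{head}({body})"

    def __str__(self) -> str:
        return self.text


def atom_environment(mol: MolecularGraph, atom_index: int) -> AtomicEnvironmentKey:
    """Canonical AE key of the atom at ``atom_index``."""
    rdmol = mol.rdkit_mol
    if not 0 <= atom_index < rdmol.GetNumAtoms():
        raise IndexError(f"atom index {atom_index} out of range")
    atom = rdmol.GetAtomWithIdx(atom_index)
    center = (
        atom.GetSymbol(),
        atom.GetFormalCharge(),
        atom.GetIsAromatic(),
        atom.GetTotalNumHs(),
    )
    shell = []
    for bond in atom.GetBonds():
        nbr = bond.GetOtherAtom(atom)
        glyph = _BOND_GLYPH.get(bond.GetBondType().name.lower(), "-")
        shell.append((glyph, nbr.GetSymbol(), nbr.GetIsAromatic()))
    return AtomicEnvironmentKey(center=center, shell=tuple(sorted(shell)))


def molecule_environments(mol: MolecularGraph) -> list[AtomicEnvironmentKey]:
    """AE keys for every heavy atom, in atom-index order."""
    return [atom_environment(mol, i) for i in range(mol.n_heavy_atoms)]


class Mol2DVocabulary:
    """Ordered, deduplicated set of AE keys defining descriptor positions."""

    def __init__(self, keys: Sequence[AtomicEnvironmentKey], provenance: str = ""):
        uniq = sorted(set(keys), key=lambda k: k.text)
        self._keys: tuple[AtomicEnvironmentKey, ...] = tuple(uniq)
        self._index = {k: i for i, k in enumerate(self._keys)}
        self.provenance = provenance

    @classmethod
    def from_molecules(
        cls, mols: Iterable[MolecularGraph], provenance: str = ""
    ) -> "Mol2DVocabulary":
        mols = list(mols)
        if not mols:
            raise ValueError("cannot build a vocabulary from an empty molecule list")
        keys: set[AtomicEnvironmentKey] = set()
        for m in mols:
            keys.update(molecule_environments(m))
        return cls(sorted(keys, key=lambda k: k.text), provenance=provenance)

    def __len__(self) -> int:
        return len(self._keys)

    def __iter__(self):
        return iter(self._keys)

    def __getitem__(self, i: int) -> AtomicEnvironmentKey:
        return self._keys[i]

    def __contains__(self, key: AtomicEnvironmentKey) -> bool:
        return key in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, Mol2DVocabulary) and self._keys == other._keys

    def index_of(self, key: AtomicEnvironmentKey) -> int | None:
        return self._index.get(key)

    @property
    def key_texts(self) -> list[str]:
        return [k.text for k in self._keys]

    # -- serialization (text/JSON) ------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {"provenance": self.provenance, "keys": self.key_texts}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Mol2DVocabulary":
        payload = json.loads(Path(path).read_text())
        keys = [_parse_key_text(t) for t in payload["keys"]]
        return cls(keys, provenance=payload.get("provenance", ""))


def _parse_key_text(text: str) -> AtomicEnvironmentKey:
    head, _, body = text.partition("(")
    body = body.rstrip(")")
    hpos = head.index("H")
    el_ar = head[:hpos]
    aromatic = el_ar.endswith("a")
    element = el_ar[:-1] if aromatic else el_ar
    rest = head[hpos + 1 :]
    sign = rest.index("+") if "+" in rest else rest.index("-")
    n_h, charge = int(rest[:sign]), int(rest[sign:])
    shell = []
    if body:
        for item in body.split(","):
            glyph, tail = item[0], item[1:]
            nar = tail.endswith("a")
            shell.append((glyph, tail[:-1] if nar else tail, nar))
    return AtomicEnvironmentKey(
        center=(element, charge, aromatic, n_h), shell=tuple(sorted(shell))
    )


@dataclass
class Mol2DVector:
    """Integer AE counts aligned to a vocabulary, plus an unknown-AE count.

    Invariant: ``counts.sum() + unknown_count`` equals the molecule's
    heavy-atom count.
    """

    counts: np.ndarray  # shape (len(vocab),), non-negative ints
    unknown_count: int

    @property
    def with_unknown(self) -> np.ndarray:
        """Counts with the unknown tally appended as one extra position."""
        return np.concatenate([self.counts, [self.unknown_count]])


def build_vocabulary(
    mols: Iterable[MolecularGraph], provenance: str = ""
) -> Mol2DVocabulary:
    """Union of AE keys over ``mols``, ordered by canonical key text."""
    return Mol2DVocabulary.from_molecules(mols, provenance=provenance)


def featurize(mol: MolecularGraph, vocab: Mol2DVocabulary) -> Mol2DVector:
    """Count ``mol``'s atomic environments over ``vocab``."""
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    counts = np.zeros(len(vocab), dtype=np.int64)
    unknown = 0
    for key in molecule_environments(mol):
        idx = vocab.index_of(key)
        if idx is None:
            unknown += 1
        else:
            counts[idx] += 1
    return Mol2DVector(counts=counts, unknown_count=unknown)


class Mol2DFeaturizer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: molecules → Mol2D count matrix.

    ``fit`` builds the AE vocabulary from the training molecules;
    ``transform`` returns an ``(n_molecules, n_keys + 1)`` integer matrix
    whose last column is the unknown-AE count (a "novel chemistry" signal
    for molecules outside the training chemistry).
    """

    def __init__(self, include_unknown: bool = True):
        self.include_unknown = include_unknown

    def fit(self, X: Sequence[MolecularGraph], y=None) -> "Mol2DFeaturizer":
        self.vocabulary_ = Mol2DVocabulary.from_molecules(X)
        self.n_features_out_ = len(self.vocabulary_) + int(self.include_unknown)
        return self

    def transform(self, X: Sequence[MolecularGraph]) -> np.ndarray:
        if not hasattr(self, "vocabulary_"):
            raise ValueError("Mol2DFeaturizer is not fitted")
        rows = []
        for mol in X:
            vec = featurize(mol, self.vocabulary_)
            rows.append(vec.with_unknown if self.include_unknown else vec.counts)
        return np.asarray(rows, dtype=np.float64)

    def transform_one(self, mol: MolecularGraph) -> np.ndarray:
        return self.transform([mol])[0]
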