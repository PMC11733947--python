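"""Atomic Sensitivity Analysis (ASA).

A trained pKa model is probed atom by atom: each heteroatom of the parent
molecule is replaced, independently, with a correctly hybridized neutral
carbon, the perturbed molecule is rescored, and the shift between parent
and perturbed output distributions is measured by KL divergence
D(P'||P). A denoising transform — zero below a floor threshold, then
``coeff · (e^D − 1)`` — converts divergences to ASA scores; the atom with
the maximal score (if it clears a cutoff) is reported as the ionization
site. ASA never retrains or modifies the model, and reports magnitude
only, not the direction of the pKa change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chemgraph import (
    MolecularGraph,
    NotHeteroatomError,
    UnperturbableAtomError,
    replace_heteroatom_with_carbon,
)
from .pka_mtc import PkaPredictor

DEFAULT_COEFF = 5.0
DEFAULT_TAU = 0.05  # nats; floor threshold of the denoising transform
DEFAULT_CUTOFF = 1.5  # site-selection threshold on the ASA score

STATUS_SCORED = "scored"
STATUS_SKIPPED = "skipped-unperturbable"
STATUS_NOT_HETEROATOM = "not-heteroatom"


def kl_divergence(p_prime: np.ndarray, p: np.ndarray, eps: float = 1e-9) -> float:
    """D(P'||P) = Σ_j p'_j ln(p'_j / p_j) in nats, with epsilon smoothing.

    Bins below ``eps`` are clipped up to ``eps`` and the distributions
    renormalized before the sum, keeping the divergence finite when
    softmax outputs underflow to zero while leaving strictly positive
    distributions untouched. Zero iff the distributions are identical
    after smoothing.
    """
    p_prime = np.asarray(p_prime, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if p_prime.shape != p.shape:
        raise ValueError(f"length mismatch: {p_prime.shape} vs {p.shape}")
    q1 = np.clip(p_prime, eps, None)
    q0 = np.clip(p, eps, None)
    q1, q0 = q1 / q1.sum(), q0 / q0.sum()
    return float(np.sum(q1 * np.log(q1 / q0)))


def asa_transform(
    d_kl: float, coeff: float = DEFAULT_COEFF, tau: float = DEFAULT_TAU
) -> float:
    """Denoised ASA score: 0 below the floor ``tau``, else ``coeff·(e^D − 1)``.

    The floor zeroes out perturbations that only marginally modify the
    output distribution; exponentiation widens the separation between true
    and false positives; subtracting 1 anchors D=0 at score 0.
    """
    if d_kl < 0:
        raise ValueError(f"KL divergence must be non-negative, got {d_kl}")
    if d_kl < tau:
        return 0.0
    return coeff * (math.exp(d_kl) - 1.0)


@dataclass(frozen=True)
class AtomScore:
    atom_index: int
    element: str
    d_kl: float  # nan unless scored
    asa_score: float  # nan unless scored
    status: str  # scored | skipped-unperturbable | not-heteroatom


@dataclass
class AsaProfile:
    """Per-atom ASA results for one molecule under one trained model."""

    name: str
    entries: list[AtomScore] = field(default_factory=list)

    def scored(self) -> list[AtomScore]:
        return [e for e in self.entries if e.status == STATUS_SCORED]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": self.name,
                    "atom_index": e.atom_index,
                    "element": e.element,
                    "d_kl": e.d_kl,
                    "asa_score": e.asa_score,
                    "status": e.status,
                }
                for e in self.entries
            ]
        )


def asa_profile(
    model: PkaPredictor,
    mol: MolecularGraph,
    coeff: float = DEFAULT_COEFF,
    tau: float = DEFAULT_TAU,
) -> AsaProfile:
    """Score every heteroatom of ``mol`` under ``model``.

    The parent is scored once; each heteroatom is perturbed independently
    from the parent (perturbations never compound). Atoms with no valid
    carbon completion are reported with status ``skipped-unperturbable``;
    carbons/hydrogens with ``not-heteroatom``. When a perturbed molecule
    featurizes identically to the parent (symmetry masking), the KL
    divergence and hence the ASA score are exactly 0.
    """
    parent_dist = model.predict_distribution(mol)
    profile = AsaProfile(name=mol.name)
    heteroatoms = set(mol.heteroatom_indices())
    for idx, atom in enumerate(mol.atoms):
        if idx not in heteroatoms:
            profile.entries.append(
                AtomScore(idx, atom.element, float("nan"), float("nan"), STATUS_NOT_HETEROATOM)
            )
            continue
        try:
            perturbed = replace_heteroatom_with_carbon(mol, idx)
        except UnperturbableAtomError:
            profile.entries.append(
                AtomScore(idx, atom.element, float("nan"), float("nan"), STATUS_SKIPPED)
            )
            continue
        d = kl_divergence(model.predict_distribution(perturbed), parent_dist)
        profile.entries.append(
            AtomScore(idx, atom.element, d, asa_transform(d, coeff=coeff, tau=tau), STATUS_SCORED)
        )
    return profile


def select_ionization_site(
    profile: AsaProfile, cutoff: float = DEFAULT_CUTOFF
) -> int | None:
    """Atom index of the maximal ASA score if it clears ``cutoff``, else None.

    Ties are broken by the lowest atom index.
    """
    best: AtomScore | None = None
    for entry in profile.scored():
        if (
            best is None
            or entry.asa_score > best.asa_score
            or (entry.asa_score == best.asa_score and entry.atom_index < best.atom_index)
        ):
            best = entry
    if best is None or best.asa_score < cutoff:
        return None
    return best.atom_index


def profiles_to_frame(profiles: Sequence[AsaProfile]) -> pd.DataFrame:
    """Concatenate per-atom rows of several profiles (CSV-ready)."""
    if not profiles:
        return pd.DataFrame(
            columns=["name", "atom_index", "element", "d_kl", "asa_score", "status"]
        )
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
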