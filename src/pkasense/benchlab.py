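"""Synthetic training-regime generator and evaluation machinery.

The generator emulates the monoprotic druglike training regime: small
scaffolds (alkyl chains and single rings, 3–12 heavy atoms) decorated
with exactly one ionizable functional group whose pKa is drawn from a
textbook group distribution, plus nonionizable hydrocarbon/ether
"negative" molecules carrying sentinel labels (acid task: 50, base
task: −5). Every positive record is annotated with the heteroatoms of
its ionizable group so that site-identification metrics can be scored.

Evaluation covers MAE and Brier score against independent oracles,
pathological-confidence detection (high confidence, high error),
leave-class-out split construction, matched-pair direction accuracy, and
atom-level ASA site metrics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .asa import AsaProfile, select_ionization_site
from .chemgraph import MolecularGraph, SmilesParseError, parse_smiles
from .pka_mtc import (
    BinScheme,
    PkaPredictor,
    TrainingConfig,
    distribution_std,
    encode_label,
    expected_pka,
)

logger = logging.getLogger(__name__)

ACID_SENTINEL = 50.0
BASE_SENTINEL = -5.0


@dataclass(frozen=True)
class FunctionalGroupRule:
    """One ionizable functional group the generator can install.

    ``fragment`` is a SMILES suffix appended to a scaffold whose last atom
    is the attachment carbon; ``smarts`` locates the installed group and
    ``site_position`` indexes the principal ionizable atom within the
    SMARTS match.
    """

    name: str
    smarts: str
    fragment: str
    pka_mean: float
    pka_sd: float
    task: str  # "acid" or "base"
    site_position: int
    exemplar: str  # canonical exemplar SMILES; must match its own smarts

    def __post_init__(self):
        if self.pka_sd < 0:
            raise ValueError("pKa sd must be non-negative")


# Textbook group pKa values; generator parameters, not claims about data.
DEFAULT_ACID_RULES = (
    FunctionalGroupRule("carboxylic_acid", "[CX3](=[OX1])[OX2H1]", "C(=O)O", 4.0, 0.5, "acid", 2, "CC(=O)O"),
    FunctionalGroupRule("phenol", "[OX2H1][c]", "c1ccc(O)cc1", 9.9, 0.7, "acid", 0, "Oc1ccccc1"),
    FunctionalGroupRule("thiol", "[SX2H1]", "S", 10.5, 0.5, "acid", 0, "CS"),
    FunctionalGroupRule("sulfonamide", "[SX4](=[OX1])(=[OX1])[NX3H2]", "S(N)(=O)=O", 10.0, 0.5, "acid", 3, "CS(N)(=O)=O"),
)

DEFAULT_BASE_RULES = (
    FunctionalGroupRule("amine_primary", "[NX3H2][CX4]", "N", 10.6, 0.6, "base", 0, "CN"),
    FunctionalGroupRule("pyridine", "[nX2]1ccccc1", "c1ccncc1", 5.2, 0.5, "base", 0, "c1ccncc1"),
    FunctionalGroupRule("imidazole", "c1c[nX2]c[nX3H1]1", "c1cnc[nH]1", 7.0, 0.4, "base", 2, "c1c[nH]cn1"),
    FunctionalGroupRule("aniline", "[NX3H2][c]", "c1ccc(N)cc1", 4.6, 0.5, "base", 0, "Nc1ccccc1"),
)

DEFAULT_RULES = DEFAULT_ACID_RULES + DEFAULT_BASE_RULES

# Default leave-class-out pattern list: the generator groups plus common
# variants (secondary amine, aromatic N heterocycles, alcohols).
DEFAULT_LCO_PATTERNS = [r.smarts for r in DEFAULT_RULES] + [
    "[NX3H1]([CX4])[CX4]",
    "[nX2]",
    "[OX2H1][CX4]",
]


@dataclass
class SynRecord:
    """One generated molecule with its label and site annotation."""

    graph: MolecularGraph
    pka: float
    task: str
    group: str  # rule name, or "negative"
    site_atoms: tuple[int, ...]  # heteroatoms of the installed group (empty for negatives)
    site_atom: int | None  # principal ionizable atom


def _chain_scaffold(
    rng: np.random.Generator,
    length: int,
    budget: int,
    ether_p: float,
    fluoro_p: float,
    branch_p: float = 0.3,
) -> str:
    """Linear alkyl scaffold SMILES whose last atom is the attachment carbon.

    ``budget`` caps the scaffold's total heavy atoms including the methyl
    branch and fluorine decorations.
    """
    atoms = ["C"] * length
    used = length
    if length >= 3 and rng.random() < ether_p:
        atoms[int(rng.integers(1, length - 1))] = "O"
    parts = list(atoms)
    if length >= 3 and used + 1 <= budget and rng.random() < branch_p:
        pos = int(rng.integers(1, length - 1))
        if parts[pos] == "C":
            parts[pos] = "C(C)"
            used += 1
    if used + 1 <= budget and rng.random() < fluoro_p and parts[0] == "C":
        parts[0] = "C(F)"
    return "".join(parts)


def _ring_scaffold(rng: np.random.Generator) -> str:
    return str(rng.choice(["C1CCCCC1", "C1CCCC1", "CC1CCCCC1"]))


def _scaffold(rng: np.random.Generator, min_len: int, max_len: int, ether_p: float, fluoro_p: float) -> str:
    if max_len >= 7 and rng.random() < 0.25:
        return _ring_scaffold(rng)  # 5-7 heavy atoms
    length = int(rng.integers(min_len, max_len + 1))
    return _chain_scaffold(rng, length, max_len, ether_p, fluoro_p)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Group pKa draw, truncated to mean±2sd and the 0–12 axis interior."""
    lo = max(mean - 2 * sd, 0.05)
    hi = min(mean + 2 * sd, 11.95)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_synthetic_set(
    rules: Sequence[FunctionalGroupRule] = DEFAULT_ACID_RULES,
    n: int = 100,
    negative_fraction: float = 0.2,
    seed: int = 0,
    scaffold_ether_p: float = 0.35,
    scaffold_fluoro_p: float = 0.15,
) -> list[SynRecord]:
    """Generate ``n`` labeled monoprotic molecules, reproducibly per seed.

    Positives carry exactly one functional group from ``rules`` with a
    truncated-normal pKa label and the group's heteroatoms annotated;
    negatives are hydrocarbon/ether scaffolds labeled with the task
    sentinel. Output order is positives then negatives.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not rules:
        raise ValueError("rules must be non-empty")
    if not 0 <= negative_fraction < 1:
        raise ValueError("negative_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_neg = int(round(n * negative_fraction))
    n_pos = n - n_neg
    records: list[SynRecord] = []

    for i in range(n_pos):
        rule = rules[int(rng.integers(len(rules)))]
        group_size = parse_smiles(rule.fragment).n_heavy_atoms
        min_len = max(1, 3 - group_size)
        max_len = max(min_len, min(6, 12 - group_size))
        for _attempt in range(50):
            scaffold = _scaffold(rng, min_len, max_len, scaffold_ether_p, scaffold_fluoro_p)
            smiles = scaffold + rule.fragment
            try:
                graph = parse_smiles(smiles, name=f"{rule.name}-{i:04d}")
            except SmilesParseError:
                continue
            matches = graph.substruct_matches(rule.smarts)
            if len(matches) != 1:
                continue
            if any(graph.substruct_matches(r.smarts) for r in rules if r.name != rule.name):
                continue
            match = matches[0]
            hetero = set(graph.heteroatom_indices())
            site_atoms = tuple(a for a in match if a in hetero)
            site_atom = match[rule.site_position]
            records.append(
                SynRecord(
                    graph=graph,
                    pka=_truncated_normal(rng, rule.pka_mean, rule.pka_sd),
                    task=rule.task,
                    group=rule.name,
                    site_atoms=site_atoms,
                    site_atom=site_atom,
                )
            )
            break
        else:  # pragma: no cover - templates are self-consistent
            raise RuntimeError(f"could not build a molecule for rule {rule.name}")

    tasks = sorted({r.task for r in rules})
    for i in range(n_neg):
        task = tasks[int(rng.integers(len(tasks)))]
        for _attempt in range(50):
            length = int(rng.integers(3, 11))
            smiles = _chain_scaffold(rng, length, budget=12, ether_p=0.5, fluoro_p=0.0)
            if rng.random() < 0.2:
                smiles = _ring_scaffold(rng)
            try:
                graph = parse_smiles(smiles, name=f"neg-{i:04d}")
            except SmilesParseError:  # pragma: no cover
                continue
            if any(graph.substruct_matches(r.smarts) for r in rules):
                continue  # pragma: no cover - hydrocarbons/ethers match no rule
            records.append(
                SynRecord(
                    graph=graph,
                    pka=ACID_SENTINEL if task == "acid" else BASE_SENTINEL,
                    task=task,
                    group="negative",
                    site_atoms=(),
                    site_atom=None,
                )
            )
            break
    return records


def records_to_frame(records: Sequence[SynRecord]) -> pd.DataFrame:
    """SMILES table with label, task and site annotation columns."""
    return pd.DataFrame(
        {
            "smiles": [r.graph.canonical_smiles for r in records],
            "pka": [r.pka for r in records],
            "task": [r.task for r in records],
            "ionizable_atom_index": [
                -1 if r.site_atom is None else r.site_atom for r in records
            ],
            "group_name": [r.group for r in records],
            "name": [r.graph.name for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def mae(
    records: Sequence[tuple[np.ndarray, float]], scheme: BinScheme
) -> float:
    """Mean absolute error between expected-value pKa and the true pKa."""
    if not records:
        raise ValueError("empty record list")
    errs = [abs(expected_pka(dist, scheme) - true) for dist, true in records]
    return float(np.mean(errs))


def brier(records: Sequence[tuple[np.ndarray, np.ndarray]]) -> float:
    """Per-molecule mean of Σ_j (p_ij − r_ij)² over predicted distributions
    and one-hot result labels. 0 for perfect one-hot predictions; 2 for a
    maximally wrong one-hot prediction."""
    if not records:
        raise ValueError("empty record list")
    total = 0.0
    for dist, label in records:
        dist = np.asarray(dist, dtype=np.float64)
        label = np.asarray(label, dtype=np.float64)
        if dist.shape != label.shape:
            raise ValueError("distribution/label length mismatch")
        total += float(np.sum((dist - label) ** 2))
    return total / len(records)


def pathological_confidence(
    records: Sequence[tuple[np.ndarray, float]],
    scheme: BinScheme,
    sigma_max: float = 1.0,
    err_min: float = 1.0,
) -> list[int]:
    """Indices of records with high confidence (σ ≤ ``sigma_max``) *and*
    high error (|E[P] − pKa| > ``err_min``)."""
    if not records:
        raise ValueError("empty record list")
    flagged = []
    for i, (dist, true) in enumerate(records):
        sigma = distribution_std(dist, scheme)
        err = abs(expected_pka(dist, scheme) - true)
        if sigma <= sigma_max and err > err_min:
            flagged.append(i)
    return flagged


@dataclass
class LcoFold:
    """One leave-class-out fold: records matching the pattern are held out."""

    pattern: str
    held_out: list
    training: list


def lco_split(records: Sequence, class_patterns: Sequence[str]) -> list[LcoFold]:
    """Leave-class-out folds, one per substructure pattern, in input order.

    ``records`` must expose a ``.graph`` attribute. A record matching
    several patterns is held out of every corresponding fold; a pattern
    matching nothing yields an empty held-out fold with a logged warning.
    """
    if not class_patterns:
        raise ValueError("class_patterns must be non-empty")
    folds = []
    for pattern in class_patterns:
        held, train = [], []
        for rec in records:
            (held if rec.graph.matches(pattern) else train).append(rec)
        if not held:
            logger.warning("LCO pattern %r matches no record", pattern)
        folds.append(LcoFold(pattern=pattern, held_out=held, training=train))
    return folds


def pair_direction_accuracy(
    model: PkaPredictor | Callable[[MolecularGraph], float],
    pairs: Sequence[tuple[MolecularGraph, MolecularGraph, float, float]],
) -> float:
    """Fraction of matched pairs whose predicted pKa difference has the
    same sign as the true difference; predicted ties count as incorrect."""
    if not pairs:
        raise ValueError("empty pair list")
    predict = model if callable(model) else model.predict_pka
    hits = 0
    for mol_a, mol_b, true_a, true_b in pairs:
        if true_a == true_b:
            raise ValueError("matched pair with equal true pKa values")
        delta = predict(mol_a) - predict(mol_b)
        if delta != 0 and np.sign(delta) == np.sign(true_a - true_b):
            hits += 1
    return hits / len(pairs)


@dataclass
class SiteMetrics:
    sensitivity: float
    specificity: float
    npv: float
    top1_accuracy: float
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0


def asa_site_metrics(
    profiles: Sequence[tuple[AsaProfile, Iterable[int]]],
    cutoff: float = 1.5,
) -> SiteMetrics:
    """Atom-level confusion metrics for ASA site identification.

    Each entry pairs a profile with the atom indices of the molecule's
    true ionizable group (empty for molecules with none). An atom is
    called positive when its ASA score clears ``cutoff``. ``top1`` is the
    fraction of site-bearing molecules whose maximal-ASA atom lies in the
    true group.
    """
    tp = fp = tn = fn = 0
    top1_hits = 0
    top1_total = 0
    for profile, truth in profiles:
        if truth is None:
            raise ValueError(f"profile {profile.name!r} has no site annotation")
        truth = set(truth)
        scored = profile.scored()
        for entry in scored:
            called = entry.asa_score >= cutoff
            is_site = entry.atom_index in truth
            if called and is_site:
                tp += 1
            elif called:
                fp += 1
            elif is_site:
                fn += 1
            else:
                tn += 1
        if truth:
            top1_total += 1
            if scored:
                best = max(scored, key=lambda e: (e.asa_score, -e.atom_index))
                # an all-zero profile identifies nothing
                if best.asa_score > 0 and best.atom_index in truth:
                    top1_hits += 1

    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return SiteMetrics(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        npv=_ratio(tn, tn + fn),
        top1_accuracy=_ratio(top1_hits, top1_total),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


# ---------------------------------------------------------------------------
# End-to-end evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    n: int
    mae: float
    brier: float
    records: pd.DataFrame  # per-record expected pKa, sigma, abs error
    pathological: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n": self.n,
                    "mae": self.mae,
                    "brier": self.brier,
                    "n_pathological": len(self.pathological),
                    "pathological_indices": self.pathological,
                },
                indent=1,
            )
        )


def evaluate(
    predictor: PkaPredictor,
    mols: Sequence[MolecularGraph],
    pkas: Sequence[float],
) -> EvaluationReport:
    """Score molecules and report MAE, Brier score, per-record errors and
    pathological-confidence flags."""
    if len(mols) == 0:
        raise ValueError("no molecules to evaluate")
    scheme = predictor.scheme
    X = predictor.featurizer.transform(mols)
    probs = predictor.classifier.predict_proba(X)
    dist_records = [(probs[i], float(pkas[i])) for i in range(len(mols))]
    label_records = [
        (probs[i], encode_label(float(pkas[i]), scheme)) for i in range(len(mols))
    ]
    mu = probs @ scheme.medians
    sigma = np.sqrt(np.clip(probs @ scheme.medians**2 - mu**2, 0.0, None))
    frame = pd.DataFrame(
        {
            "name": [m.name for m in mols],
            "true_pka": np.asarray(pkas, dtype=float),
            "expected_pka": mu,
            "sigma": sigma,
            "abs_error": np.abs(mu - np.asarray(pkas, dtype=float)),
        }
    )
    return EvaluationReport(
        n=len(mols),
        mae=mae(dist_records, scheme),
        brier=brier(label_records),
        records=frame,
        pathological=pathological_confidence(dist_records, scheme),
    )


def bin_width_sweep(
    train_records: Sequence[SynRecord],
    test_records: Sequence[SynRecord],
    widths: Sequence[float] = (0.5, 1.0, 2.0, 3.0),
    base_config: TrainingConfig | None = None,
) -> dict[float, float]:
    """Train/evaluate once per bin width; returns width → held-out MAE.

    The ordering of MAEs across widths is data-dependent; this harness
    only guarantees the sweep runs under each width.
    """
    base = base_config or TrainingConfig()
    out: dict[float, float] = {}
    test_mols = [r.graph for r in test_records]
    test_pkas = [r.pka for r in test_records]
    for w in widths:
        cfg = TrainingConfig(**{**base.to_dict(), "bin_width": w})
        predictor = PkaPredictor.train(
            [r.graph for r in train_records], [r.pka for r in train_records], cfg
        )
        out[w] = evaluate(predictor, test_mols, test_pkas).mae
    return out
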