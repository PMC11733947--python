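"""Multitask-classification pKa model.

Instead of regressing a continuous pKa, the model classifies a molecule's
pKa into ordinal bins on the 0–12 axis: ``12/w`` half-open interior bins
of width ``w`` plus two open catch-all bins (pKa < 0 and pKa ≥ 12) that
also absorb the negative-data sentinels (acid task 50, base task −5).
The classifier outputs a discrete probability distribution over bins
(per-bin local positive predictive values); the point prediction is the
median-weighted expected value and the model's confidence is the standard
deviation of that distribution. At width 1 the attainable output range is
exactly [−0.5, 12.5].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .chemgraph import MolecularGraph
from .mol2d import Mol2DFeaturizer, Mol2DVocabulary

PKA_AXIS_LOW = 0.0
PKA_AXIS_HIGH = 12.0


@dataclass(frozen=True)
class BinScheme:
    """Discretization of the pKa axis.

    Interior bin *i* (1-based) covers ``[w·(i−1), w·i)`` — half-open,
    lower-inclusive. The first and last bins are open catch-alls for
    pKa < 0 and pKa ≥ 12 with representative medians ``−w/2`` and
    ``12 + w/2``; interior medians are bin midpoints.
    """

    width: float = 1.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"bin width must be positive, got {self.width}")
        n = (PKA_AXIS_HIGH - PKA_AXIS_LOW) / self.width
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"bin width {self.width} must evenly divide the 0-12 axis")

    @property
    def n_interior(self) -> int:
        return int(round((PKA_AXIS_HIGH - PKA_AXIS_LOW) / self.width))

    @property
    def n_bins(self) -> int:
        return self.n_interior + 2

    @property
    def medians(self) -> np.ndarray:
        w = self.width
        interior = PKA_AXIS_LOW + w * (np.arange(self.n_interior) + 0.5)
        return np.concatenate([[PKA_AXIS_LOW - w / 2], interior, [PKA_AXIS_HIGH + w / 2]])

    def bin_index(self, pka: float) -> int:
        """Index of the unique bin covering ``pka`` (sentinels allowed)."""
        if not np.isfinite(pka):
            raise ValueError(f"pKa label must be finite, got {pka}")
        if pka < PKA_AXIS_LOW:
            return 0
        if pka >= PKA_AXIS_HIGH:
            return self.n_bins - 1
        return 1 + int(np.floor((pka - PKA_AXIS_LOW) / self.width))

    def bin_labels(self) -> list[str]:
        w = self.width
        labels = [f"pKa<{PKA_AXIS_LOW:g}"]
        for i in range(self.n_interior):
            labels.append(f"[{PKA_AXIS_LOW + i * w:g},{PKA_AXIS_LOW + (i + 1) * w:g})")
        labels.append(f"pKa>={PKA_AXIS_HIGH:g}")
        return labels


def encode_label(pka: float, scheme: BinScheme) -> np.ndarray:
    """One-hot result label over the scheme's bins."""
    vec = np.zeros(scheme.n_bins)
    vec[scheme.bin_index(pka)] = 1.0
    return vec


def validate_distribution(dist: np.ndarray, scheme: BinScheme | None = None) -> np.ndarray:
    dist = np.asarray(dist, dtype=np.float64)
    if scheme is not None and dist.shape != (scheme.n_bins,):
        raise ValueError(f"distribution length {dist.shape} != {scheme.n_bins} bins")
    if np.any(dist < -1e-12) or abs(dist.sum() - 1.0) > 1e-9:
        raise ValueError("not a probability distribution")
    return dist


def expected_pka(dist: np.ndarray, scheme: BinScheme) -> float:
    """Median-weighted expected value E[P] = Σ_j median_j · p_j."""
    dist = validate_distribution(dist, scheme)
    return float(dist @ scheme.medians)


def distribution_std(dist: np.ndarray, scheme: BinScheme) -> float:
    """Standard deviation of the bin-median random variable — the model's
    per-prediction confidence (0 iff the distribution is one-hot)."""
    dist = validate_distribution(dist, scheme)
    mu = dist @ scheme.medians
    var = dist @ (scheme.medians - mu) ** 2
    return float(np.sqrt(max(var, 0.0)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class PkaBinClassifier(BaseEstimator):
    """MLP multitask classifier over pKa bins (numeric-feature interface).

    One hidden ReLU layer with inverted dropout, softmax output trained by
    cross-entropy with Adam for a fixed epoch count and no early stopping.
    Training is bit-reproducible for a given ``(random_state, params)``;
    dropout is active only during training, so prediction is deterministic.

    ``fit`` takes a feature matrix and *continuous* pKa labels (sentinels
    allowed); labels are binned internally by the :class:`BinScheme`.
    """

    def __init__(
        self,
        bin_width: float = 1.0,
        hidden_units: int = 256,
        dropout: float = 0.25,
        epochs: int = 250,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        random_state: int = 0,
    ):
        self.bin_width = bin_width
        self.hidden_units = hidden_units
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # -- training ------------------------------------------------------

    def fit(self, X: np.ndarray, y: Sequence[float]) -> "PkaBinClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-D feature matrix")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        scheme = BinScheme(self.bin_width)
        bins = np.array([scheme.bin_index(v) for v in y])
        if len(np.unique(bins)) < 2:
            raise ValueError("training labels fall in a single bin; need >= 2 classes")

        n, d = X.shape
        k = scheme.n_bins
        h = self.hidden_units
        rng = np.random.default_rng(self.random_state)

        # He initialization for the ReLU layer, Glorot for the head
        W1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h))
        b1 = np.zeros(h)
        W2 = rng.normal(0.0, np.sqrt(1.0 / h), size=(h, k))
        b2 = np.zeros(k)

        Y = np.zeros((n, k))
        Y[np.arange(n), bins] = 1.0

        # Adam state
        params = [W1, b1, W2, b2]
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = self.learning_rate
        keep = 1.0 - self.dropout
        step = 0
        loss_curve = []

        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], Y[idx]
                z1 = xb @ W1 + b1
                a1 = np.maximum(z1, 0.0)
                if self.dropout > 0.0:
                    mask = (rng.random(a1.shape) < keep) / keep
                    a1 = a1 * mask
                probs = _softmax(a1 @ W2 + b2)
                epoch_loss += -np.sum(
                    yb * np.log(np.clip(probs, 1e-12, None))
                )

                gz2 = (probs - yb) / len(idx)
                gW2 = a1.T @ gz2
                gb2 = gz2.sum(axis=0)
                ga1 = gz2 @ W2.T
                if self.dropout > 0.0:
                    ga1 = ga1 * mask
                gz1 = ga1 * (z1 > 0.0)
                gW1 = xb.T @ gz1
                gb1 = gz1.sum(axis=0)

                step += 1
                for p, g, m_, v_ in zip(params, [gW1, gb1, gW2, gb2], m_t, v_t):
                    m_ += (1 - beta1) * (g - m_)
                    v_ += (1 - beta2) * (g * g - v_)
                    m_hat = m_ / (1 - beta1**step)
                    v_hat = v_ / (1 - beta2**step)
                    p -= lr * m_hat / (np.sqrt(v_hat) + eps)
            loss_curve.append(epoch_loss / n)

        self.scheme_ = scheme
        self.coefs_ = [W1, W2]
        self.intercepts_ = [b1, b2]
        self.loss_curve_ = loss_curve
        self.n_features_in_ = d
        return self

    # -- inference -----------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "coefs_"):
            raise ValueError("PkaBinClassifier is not fitted")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-bin probability distributions (rows sum to 1)."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} != fitted {self.n_features_in_}"
            )
        a1 = np.maximum(X @ self.coefs_[0] + self.intercepts_[0], 0.0)
        return _softmax(a1 @ self.coefs_[1] + self.intercepts_[1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Expected-value pKa per row."""
        return self.predict_proba(X) @ self.scheme_.medians

    def predict_std(self, X: np.ndarray) -> np.ndarray:
        """Distribution standard deviation (confidence) per row."""
        probs = self.predict_proba(X)
        mu = probs @ self.scheme_.medians
        var = probs @ self.scheme_.medians**2 - mu**2
        return np.sqrt(np.clip(var, 0.0, None))


@dataclass
class TrainingConfig:
    """Hyperparameters of one model-training run; every field has a default."""

    task: str = "acid"
    bin_width: float = 1.0
    hidden_units: int = 256
    dropout: float = 0.25
    epochs: int = 250
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class PkaPredictor:
    """End-to-end predictor: molecules → Mol2D features → bin distribution.

    Bundles a fitted :class:`Mol2DFeaturizer` and :class:`PkaBinClassifier`
    for one task (acid or base). Acid and base are fully independent models
    sharing this code.
    """

    def __init__(
        self,
        featurizer: Mol2DFeaturizer,
        classifier: PkaBinClassifier,
        task: str = "acid",
        config: TrainingConfig | None = None,
    ):
        self.featurizer = featurizer
        self.classifier = classifier
        self.task = task
        self.config = config or TrainingConfig(task=task)

    @property
    def scheme(self) -> BinScheme:
        return self.classifier.scheme_

    @property
    def vocabulary(self) -> Mol2DVocabulary:
        return self.featurizer.vocabulary_

    @classmethod
    def train(
        cls,
        mols: Sequence[MolecularGraph],
        pkas: Sequence[float],
        config: TrainingConfig | None = None,
    ) -> "PkaPredictor":
        """Fit featurizer vocabulary and classifier on labeled molecules."""
        config = config or TrainingConfig()
        if len(mols) != len(pkas):
            raise ValueError("molecule and label counts differ")
        featurizer = Mol2DFeaturizer().fit(mols)
        X = featurizer.transform(mols)
        clf = PkaBinClassifier(
            bin_width=config.bin_width,
            hidden_units=config.hidden_units,
            dropout=config.dropout,
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            random_state=config.seed,
        ).fit(X, pkas)
        return cls(featurizer, clf, task=config.task, config=config)

    def predict_distribution(self, mol: MolecularGraph) -> np.ndarray:
        return self.classifier.predict_proba(self.featurizer.transform([mol]))[0]

    def predict_pka(self, mol: MolecularGraph) -> float:
        return float(expected_pka(self.predict_distribution(mol), self.scheme))

    def predict_table(self, mols: Sequence[MolecularGraph]):
        """DataFrame with name, expected pKa, sigma and per-bin localPPVs."""
        import pandas as pd

        X = self.featurizer.transform(mols)
        probs = self.classifier.predict_proba(X)
        mu = probs @ self.scheme.medians
        sigma = np.sqrt(
            np.clip(probs @ self.scheme.medians**2 - mu**2, 0.0, None)
        )
        df = pd.DataFrame(
            {"name": [m.name for m in mols], "expected_pka": mu, "sigma": sigma}
        )
        for j, label in enumerate(self.scheme.bin_labels()):
            df[f"ppv_{label}"] = probs[:, j]
        return df

    # -- serialization: JSON metadata + npz weight blob ----------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "task": self.task,
            "config": self.config.to_dict(),
            "vocabulary": self.vocabulary.key_texts,
            "vocabulary_provenance": self.vocabulary.provenance,
            "bin_width": self.scheme.width,
            "n_features": self.classifier.n_features_in_,
        }
        path.write_text(json.dumps(meta, indent=1))
        np.savez(
            path.with_suffix(".weights.npz"),
            W1=self.classifier.coefs_[0],
            b1=self.classifier.intercepts_[0],
            W2=self.classifier.coefs_[1],
            b2=self.classifier.intercepts_[1],
        )

    @classmethod
    def load(cls, path: str | Path) -> "PkaPredictor":
        path = Path(path)
        meta = json.loads(path.read_text())
        from .mol2d import _parse_key_text

        vocab = Mol2DVocabulary(
            [_parse_key_text(t) for t in meta["vocabulary"]],
            provenance=meta.get("vocabulary_provenance", ""),
        )
        featurizer = Mol2DFeaturizer()
        featurizer.vocabulary_ = vocab
        featurizer.n_features_out_ = len(vocab) + 1
        config = TrainingConfig(**meta["config"])
        clf = PkaBinClassifier(
            bin_width=meta["bin_width"],
            hidden_units=config.hidden_units,
            dropout=config.dropout,
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            random_state=config.seed,
        )
        blob = np.load(path.with_suffix(".weights.npz"))
        clf.coefs_ = [blob["W1"], blob["W2"]]
        clf.intercepts_ = [blob["b1"], blob["b2"]]
        clf.scheme_ = BinScheme(meta["bin_width"])
        clf.n_features_in_ = int(meta["n_features"])
        if clf.coefs_[0].shape[0] != len(vocab) + 1:
            raise ValueError("weight blob does not match vocabulary dimension")
        if clf.coefs_[1].shape[1] != clf.scheme_.n_bins:
            raise ValueError("weight blob does not match bin scheme")
        return cls(featurizer, clf, task=meta["task"], config=config)
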