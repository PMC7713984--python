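"""One-vs-one linear SVM identity classification over embeddings, and the
embedding-distance verification mode.

For K identities the classifier trains K(K-1)/2 binary linear SVMs, one per
unordered label pair, and predicts by majority vote.  Ties break toward the
label seen earlier in training order and are flagged.  The catalogue is
closed: every query is assigned one of the trained identities.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.base import BaseEstimator
from sklearn.svm import LinearSVC

from .annotations import AnnotationError
from .embedding import MetricEmbedder, PairLossSpec


@dataclass
class ClassificationResult:
    label: str
    vote_counts: dict[str, int]
    tie: bool


class IdentityClassifier(BaseEstimator):
    """One-vs-one soft-margin linear SVM voter.

    Labels with a single training embedding are accepted (field catalogues
    contain singleton individuals).
    """

    def __init__(self, C: float = 1.0, tol: float = 1e-4, seed: int = 0) -> None:
        self.C = C
        self.tol = tol
        self.seed = seed

    def fit(self, X: np.ndarray, y: list[str]) -> "IdentityClassifier":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise AnnotationError("X must be (n, d) aligned with labels")
        self.labels_ = list(dict.fromkeys(y))  # session label order
        if len(self.labels_) < 2:
            raise AnnotationError("classifier requires >=2 identities")
        y = np.asarray(y)
        self.dim_ = X.shape[1]
        self.pair_models_: dict[tuple[str, str], LinearSVC] = {}
        for a_i in range(len(self.labels_)):
            for b_i in range(a_i + 1, len(self.labels_)):
                a, b = self.labels_[a_i], self.labels_[b_i]
                mask = (y == a) | (y == b)
                clf = LinearSVC(C=self.C, tol=self.tol, random_state=self.seed, max_iter=20000)
                clf.fit(X[mask], (y[mask] == b).astype(int))
                self.pair_models_[(a, b)] = clf
        return self

    def _check_dim(self, e: np.ndarray) -> np.ndarray:
        e = np.asarray(e, dtype=float).ravel()
        if e.shape[0] != self.dim_:
            raise AnnotationError(f"embedding has dimension {e.shape[0]}, model expects {self.dim_}")
        return e

    def classify(self, e: np.ndarray) -> ClassificationResult:
        """Majority vote over all pairwise classifiers."""
        e = self._check_dim(e)
        votes = {lab: 0 for lab in self.labels_}
        for (a, b), clf in self.pair_models_.items():
            winner = b if clf.predict(e[None])[0] == 1 else a
            votes[winner] += 1
        best = max(votes.values())
        winners = [lab for lab in self.labels_ if votes[lab] == best]
        return ClassificationResult(label=winners[0], vote_counts=votes, tie=len(winners) > 1)

    def predict(self, X: np.ndarray) -> list[str]:
        return [self.classify(e).label for e in np.atleast_2d(np.asarray(X, dtype=float))]

    # -- persistence -----------------------------------------------------------

    def save(self, path: str) -> None:
        joblib.dump(
            {
                "format": "wildface-svm-v1",
                "params": self.get_params(),
                "labels": self.labels_,
                "dim": self.dim_,
                "pair_models": self.pair_models_,
            },
            path,
        )

    @classmethod
    def load(cls, path: str) -> "IdentityClassifier":
        blob = joblib.load(path)
        if blob.get("format") != "wildface-svm-v1":
            raise AnnotationError(f"{path} is not a classifier model file")
        model = cls(**blob["params"])
        model.labels_ = blob["labels"]
        model.dim_ = blob["dim"]
        model.pair_models_ = blob["pair_models"]
        return model


def train_identity_classifier(embeddings: np.ndarray, labels: list[str], cfg: dict | None = None) -> IdentityClassifier:
    return IdentityClassifier(**(cfg or {})).fit(embeddings, labels)


def classify_embedding(model: IdentityClassifier, e: np.ndarray) -> ClassificationResult:
    return model.classify(e)


def verify_pair(
    embed_model: MetricEmbedder,
    chip_a,
    chip_b,
    spec: PairLossSpec = PairLossSpec(),
) -> dict:
    """Same-individual verification by embedding distance.

    Match iff the Euclidean distance is strictly below the threshold.
    """
    ea, eb = embed_model.embed(chip_a), embed_model.embed(chip_b)
    distance = float(np.linalg.norm(ea - eb))
    return {"match": distance < spec.distance_threshold, "distance": distance}
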