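"""Subcellular localization by k-nearest neighbors on amino-acid composition.

A protein is represented by its 20 amino-acid frequencies plus a
(down-weighted) log-length term, and classified by the labels of its
``k`` nearest labelled reference proteins (Euclidean distance, k = 32 by
default). The neighbor tally ``N(c_i)`` per compartment ``c_i`` converts
to a probability model ``P(c_i) = N(c_i) / k``. Predictions are made
twice — against a plant-lineage and an animal-lineage reference set —
and consolidated: a protein is binned to a single compartment when more
than 50% of its neighbors share it, and the two lineages are merged by
keeping the higher-confidence prediction when both clear an 85% cutoff.

The classifier itself is exposed as the scikit-learn style estimator
:class:`CompartmentKNN`; :func:`knn_predict` is a thin record-level
wrapper around it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Literal, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin

from .records import SequenceRecord

COMPARTMENTS: Tuple[str, ...] = (
    "chlo",  # chloroplast
    "cyto",  # cytosol
    "cysk",  # cytoskeleton
    "er",  # endoplasmic reticulum
    "extr",  # extracellular
    "mito",  # mitochondrion
    "nucl",  # nucleus
    "pero",  # peroxisome
    "plas",  # plasma membrane
    "vacu",  # vacuolar membrane
)
OTHER = "other"

Lineage = Literal["plant", "animal"]

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
# log-length enters the feature vector scaled down so that composition,
# not size, dominates the Euclidean metric
_LENGTH_WEIGHT = 0.1


def composition_features(protein: SequenceRecord) -> np.ndarray:
    """20 amino-acid frequencies (summing to 1) plus a scaled log10-length.

    ``X`` residues are ignored in the frequency tally. Deterministic and
    invariant to residue order for the composition part.
    """
    if protein.alphabet != "protein":
        raise ValueError(f"{protein.id}: composition features need a protein record")
    counts = np.zeros(20)
    for ch in protein.residues:
        idx = _AA_ORDER.find(ch)
        if idx >= 0:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError(f"{protein.id}: sequence has no standard residues")
    freqs = counts / total
    return np.concatenate([freqs, [_LENGTH_WEIGHT * math.log10(len(protein))]])


@dataclass(frozen=True)
class LocalizationPrediction:
    """Neighbor counts and the derived probability model for one protein."""

    orf_id: str
    lineage: Lineage
    neighbor_counts: Mapping[str, float]
    k: int
    probabilities: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if abs(sum(self.neighbor_counts.values()) - self.k) > 1e-9:
            raise ValueError("neighbor counts must sum to k")
        if abs(sum(self.probabilities.values()) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        for label in self.neighbor_counts:
            if label not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {label!r}")

    @property
    def top(self) -> Tuple[str, float]:
        """(compartment, probability) of the modal compartment; ties break
        alphabetically."""
        best = min(self.probabilities.items(), key=lambda kv: (-kv[1], kv[0]))
        return best


@dataclass(frozen=True)
class ConsolidatedLocalization:
    orf_id: str
    assignment: str  # a compartment label or OTHER
    confidence: float
    lineage_used: Literal["plant", "animal", "none"]

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")


class CompartmentKNN(BaseEstimator, ClassifierMixin):
    """k-nearest-neighbor compartment classifier with a neighbor-count output.

    Parameters
    ----------
    k : int, default 32
        Number of nearest references tallied per query.
    weighting : {"uniform", "inverse_distance"}
        ``uniform`` counts each neighbor once; ``inverse_distance``
        weights neighbors by 1/distance, renormalized so the weighted
        counts still sum to ``k``.

    Distance ties at the k-th neighbor break by reference id, so
    predictions are deterministic for any input order.
    """

    def __init__(self, k: int = 32, weighting: str = "uniform"):
        self.k = k
        self.weighting = weighting

    def fit(self, X, y, reference_ids: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if len(X) < self.k:
            raise ValueError(f"reference set of {len(X)} is smaller than k={self.k}")
        for label in y:
            if label not in COMPARTMENTS:
                raise ValueError(f"unknown compartment label {label!r}")
        if self.weighting not in ("uniform", "inverse_distance"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if reference_ids is None:
            reference_ids = [f"ref{i:06d}" for i in range(len(X))]
        if len(set(reference_ids)) != len(X):
            raise ValueError("reference ids must be unique")
        order = np.lexsort((np.asarray(reference_ids, dtype=object),))
        self.X_ = X[order]
        self.y_ = y[order]
        self.reference_ids_ = np.asarray(reference_ids, dtype=object)[order]
        self.classes_ = np.array(sorted(set(y)), dtype=object)
        return self

    def _neighbor_matrix(self, X) -> Tuple[np.ndarray, np.ndarray]:
        """Indices (n_queries, k) of the k nearest references and distances."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = cdist(X, self.X_)
        # stable sort on distance; references were pre-sorted by id, so
        # equal distances resolve to the smaller reference id
        idx = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        return idx, np.take_along_axis(d, idx, axis=1)

    def neighbor_counts(self, X) -> List[Dict[str, float]]:
        """Per query, the (possibly weighted) neighbor tally per compartment."""
        idx, dist = self._neighbor_matrix(X)
        out = []
        for row_idx, row_dist in zip(idx, dist):
            labels = self.y_[row_idx]
            if self.weighting == "uniform":
                weights = np.ones(self.k)
            else:
                weights = 1.0 / (row_dist + 1e-12)
                weights *= self.k / weights.sum()
            counts: Dict[str, float] = {}
            for label, w in zip(labels, weights):
                counts[label] = counts.get(label, 0.0) + float(w)
            out.append(counts)
        return out

    def predict_proba(self, X) -> np.ndarray:
        counts = self.neighbor_counts(X)
        proba = np.zeros((len(counts), len(self.classes_)))
        for i, c in enumerate(counts):
            for j, label in enumerate(self.classes_):
                proba[i, j] = c.get(label, 0.0) / self.k
        return proba

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # argmax with alphabetical tie-break (classes_ is sorted)
        return self.classes_[np.argmax(proba, axis=1)]


def knn_predict(
    protein: SequenceRecord,
    reference_set: Sequence[Tuple[SequenceRecord, str]],
    k: int = 32,
    weighting: str = "uniform",
    lineage: Lineage = "plant",
) -> LocalizationPrediction:
    """Predict one protein's compartment neighbor counts and probabilities."""
    model = fit_reference_knn(reference_set, k=k, weighting=weighting)
    return predict_record(model, protein, lineage)


def fit_reference_knn(
    reference_set: Sequence[Tuple[SequenceRecord, str]],
    k: int = 32,
    weighting: str = "uniform",
) -> CompartmentKNN:
    """Fit a :class:`CompartmentKNN` on labelled reference records."""
    ids = [rec.id for rec, _ in reference_set]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate reference protein ids (dual labels disallowed)")
    X = np.array([composition_features(rec) for rec, _ in reference_set])
    y = [label for _, label in reference_set]
    return CompartmentKNN(k=k, weighting=weighting).fit(X, y, reference_ids=ids)


def predict_record(
    model: CompartmentKNN, protein: SequenceRecord, lineage: Lineage
) -> LocalizationPrediction:
    counts = model.neighbor_counts([composition_features(protein)])[0]
    probabilities = {label: c / model.k for label, c in counts.items()}
    return LocalizationPrediction(
        orf_id=protein.id,
        lineage=lineage,
        neighbor_counts=counts,
        k=model.k,
        probabilities=probabilities,
    )


def bin_primary(pred: LocalizationPrediction, threshold: float = 0.5) -> str:
    """The single compartment holding strictly more than ``threshold`` of the
    probability mass, else OTHER (multiple/ambiguous compartments)."""
    label, p = pred.top
    return label if p > threshold else OTHER


def consolidate(
    plant: LocalizationPrediction,
    animal: LocalizationPrediction,
    cutoff: float = 0.85,
) -> ConsolidatedLocalization:
    """Merge the two lineage predictions for one protein.

    If both lineages' top compartments reach the cutoff, the higher
    probability wins (ties go to plant, the phylogenetically closer
    lineage); if exactly one reaches it, that lineage is used; if
    neither, the protein stays OTHER.
    """
    if plant.orf_id != animal.orf_id:
        raise ValueError("predictions belong to different proteins")
    p_label, p_conf = plant.top
    a_label, a_conf = animal.top
    p_ok = p_conf >= cutoff
    a_ok = a_conf >= cutoff
    if p_ok and (not a_ok or p_conf >= a_conf):
        return ConsolidatedLocalization(plant.orf_id, p_label, p_conf, "plant")
    if a_ok:
        return ConsolidatedLocalization(plant.orf_id, a_label, a_conf, "animal")
    return ConsolidatedLocalization(plant.orf_id, OTHER, max(p_conf, a_conf), "none")


def predictions_table(preds: Sequence[LocalizationPrediction]) -> pd.DataFrame:
    """Per-lineage neighbor-count table (one row per protein)."""
    rows = []
    for p in sorted(preds, key=lambda p: (p.orf_id, p.lineage)):
        row = {"orf_id": p.orf_id, "lineage": p.lineage, "k": p.k}
        for c in COMPARTMENTS:
            row[f"n_{c}"] = p.neighbor_counts.get(c, 0.0)
        row["primary"] = bin_primary(p)
        rows.append(row)
    return pd.DataFrame(rows)


def consolidated_table(items: Sequence[ConsolidatedLocalization]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "orf_id": c.orf_id,
                "assignment": c.assignment,
                "confidence": round(c.confidence, 6),
                "lineage_used": c.lineage_used,
            }
            for c in sorted(items, key=lambda c: c.orf_id)
        ],
        columns=["orf_id", "assignment", "confidence", "lineage_used"],
    )


def compartment_frequencies(preds: Sequence[LocalizationPrediction]) -> pd.DataFrame:
    """Histogram of primary-bin assignments (compartments plus OTHER)."""
    counts = {c: 0 for c in COMPARTMENTS}
    counts[OTHER] = 0
    for p in preds:
        counts[bin_primary(p)] += 1
    return pd.DataFrame(
        [{"compartment": c, "n": n} for c, n in counts.items()],
        columns=["compartment", "n"],
    )
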