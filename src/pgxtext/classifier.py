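"""Supervised relation classification for candidate chemical/variant pairs.

Two independent logistic-regression models are trained, one per candidate
group (group 1: rs ids and star alleles; group 2: DNA/protein changes),
over sparse count features of the sentence and the entity pair.  Features
follow the classic lexical/path family used in relation extraction: bag of
lemma-like tokens over the sentence, tokens between the two entities (the
linear-order analogue of a shortest path), the entity kinds, the
between-span length, and ±2-token windows around each entity.  The
probability output is thresholded (default 0.75) to favour precision over
recall, and an annotation-policy detail matters for training data:
explicitly negative findings ("does not affect") count as pharmacogenomic
associations, because curators want them.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .candidates import CandidateRelation

DEFAULT_THRESHOLD = 0.75
DEFAULT_L2_C = 1.0

_TOKEN = re.compile(r"\w+|[^\w\s]")


@dataclass
class LabeledCandidate:
    candidate: CandidateRelation
    label: bool


def _lemma(token: str) -> str:
    """Crude lemmatizer: lowercase plus plural/inflection stripping."""
    t = token.lower()
    if t.endswith("'s"):
        t = t[:-2]
    if len(t) > 4 and t.endswith("ies"):
        return t[:-3] + "y"
    if len(t) > 3 and t.endswith("s") and not t.endswith("ss"):
        return t[:-1]
    return t


def _tokenize(text: str) -> list[tuple[str, int, int]]:
    return [(m.group(), m.start(), m.end()) for m in _TOKEN.finditer(text)]


def featurize(candidate: CandidateRelation) -> dict[str, float]:
    """Sparse count features for one candidate pair.

    All features are counts; entity tokens themselves are replaced by
    placeholder lemmas inside the between/window features so the model
    learns contexts, not memorized entity names.
    """
    sent = candidate.sentence
    c_start, c_end = sent.relative_span(candidate.chemical)
    v_start, v_end = sent.relative_span(candidate.variant.base)
    tokens = _tokenize(sent.text)

    def covered(ts, te, a, b):
        return a <= ts and te <= b

    feats: dict[str, float] = {}

    def bump(name: str) -> None:
        feats[name] = feats.get(name, 0.0) + 1.0

    lo, hi = sorted([(c_start, c_end), (v_start, v_end)])
    for tok, ts, te in tokens:
        lem = _lemma(tok)
        bump(f"bow:{lem}")
        if lo[1] <= ts and te <= hi[0]:
            bump(f"between:{lem}")
    n_between = sum(1 for _, ts, te in tokens if lo[1] <= ts and te <= hi[0])
    bump(f"between_len:{min(n_between, 10)}")
    bump(f"pair:{candidate.chemical.entity_class}~{candidate.variant.variant_kind}")

    for label, (a, b) in (("chem", (c_start, c_end)), ("var", (v_start, v_end))):
        idx = [i for i, (_, ts, te) in enumerate(tokens) if te <= a or ts >= b]
        before = [i for i in idx if tokens[i][2] <= a][-2:]
        after = [i for i in idx if tokens[i][1] >= b][:2]
        for i in before:
            bump(f"{label}win_before:{_lemma(tokens[i][0])}")
        for i in after:
            bump(f"{label}win_after:{_lemma(tokens[i][0])}")
    return feats


@dataclass
class TrainedModel:
    """Serializable logistic-regression model for one candidate group."""

    group: str
    weights: dict[str, float]
    intercept: float
    metadata: dict = field(default_factory=dict)

    @property
    def vocabulary(self) -> set[str]:
        return set(self.weights)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "group": self.group,
                    "intercept": self.intercept,
                    "weights": self.weights,
                    "metadata": self.metadata,
                },
                indent=1,
                sort_keys=True,
            ),
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            group=data["group"],
            weights=data["weights"],
            intercept=data["intercept"],
            metadata=data.get("metadata", {}),
        )


def train(
    labeled: Sequence[LabeledCandidate],
    group: str,
    seed: int,
    C: float = DEFAULT_L2_C,
    balanced: bool = False,
) -> TrainedModel:
    """Fit an L2-regularized logistic regression on featurized candidates.

    Deterministic given ``seed`` (which controls the data shuffle); the
    model stores its feature vocabulary so unseen features are ignored at
    scoring time.  Raises on single-class input, naming the missing class.
    """
    if not labeled:
        raise ValueError("no labeled candidates provided")
    labels = {lc.label for lc in labeled}
    if labels == {True}:
        raise ValueError("training data contains no negative examples")
    if labels == {False}:
        raise ValueError("training data contains no positive examples")

    rng = np.random.RandomState(seed)
    order = rng.permutation(len(labeled))
    shuffled = [labeled[i] for i in order]

    vocab: dict[str, int] = {}
    rows = []
    for lc in shuffled:
        f = featurize(lc.candidate)
        for name in f:
            vocab.setdefault(name, len(vocab))
        rows.append(f)
    X = np.zeros((len(rows), len(vocab)))
    for i, f in enumerate(rows):
        for name, val in f.items():
            X[i, vocab[name]] = val
    y = np.array([lc.label for lc in shuffled], dtype=int)

    clf = LogisticRegression(  # liblinear defaults to an L2 penalty
        C=C,
        solver="liblinear",
        random_state=seed,
        class_weight="balanced" if balanced else None,
        max_iter=1000,
    )
    clf.fit(X, y)
    inv = {i: name for name, i in vocab.items()}
    weights = {inv[i]: float(w) for i, w in enumerate(clf.coef_[0])}
    return TrainedModel(
        group=group,
        weights=weights,
        intercept=float(clf.intercept_[0]),
        metadata={
            "n": len(labeled),
            "n_positive": int(y.sum()),
            "seed": seed,
            "C": C,
            "balanced": balanced,
            "date": _dt.date.today().isoformat(),
        },
    )


def score(model: TrainedModel, candidate: CandidateRelation) -> float:
    """Probability that the candidate expresses a pharmacogenomic association.

    Computed directly from the stored weights (sigmoid of the linear
    score); features outside the model vocabulary are ignored.  Raises if
    the candidate's group differs from the model's.
    """
    if candidate.group != model.group:
        raise ValueError(
            f"candidate group {candidate.group!r} does not match model group {model.group!r}"
        )
    z = model.intercept
    for name, val in featurize(candidate).items():
        w = model.weights.get(name)
        if w is not None:
            z += w * val
    return 1.0 / (1.0 + math.exp(-z))


def score_candidates(
    models: dict[str, TrainedModel], candidates: Iterable[CandidateRelation]
) -> list[CandidateRelation]:
    """Score each candidate in place with its group's model."""
    out = []
    for cand in candidates:
        cand.score = score(models[cand.group], cand)
        out.append(cand)
    return out


def apply_threshold(
    candidates: Iterable[CandidateRelation], threshold: float = DEFAULT_THRESHOLD
) -> list[CandidateRelation]:
    """Keep candidates with score >= threshold (inclusive boundary)."""
    kept = []
    for cand in candidates:
        if cand.score is None:
            raise ValueError("candidate has no score; run score_candidates first")
        if cand.score >= threshold:
            kept.append(cand)
    return kept


def filter_cancer_chemicals(
    accepted: Iterable[CandidateRelation], cancer_chemical_ids: set[str]
) -> list[CandidateRelation]:
    """Drop cancer-drug candidates whose variant is a DNA/protein change.

    Such pairs are overwhelmingly somatic tumour events rather than
    germline pharmacogenomics.  Group-1 candidates (rs ids, star alleles)
    are never removed by this rule.
    """
    return [
        c
        for c in accepted
        if not (
            c.chemical.normalized_id in cancer_chemical_ids
            and c.variant.variant_kind in ("dna_sub", "protein_sub")
        )
    ]


@dataclass
class EvaluationPoint:
    threshold: float
    precision: Optional[float]  # None when nothing is predicted positive
    recall: float


def evaluate(
    model: TrainedModel, held_out: Sequence[LabeledCandidate]
) -> list[EvaluationPoint]:
    """Precision/recall at every achievable threshold on a held-out set.

    Thresholds are the sorted unique scores (plus 0.0); at thresholds with
    zero positive predictions precision is reported as absent, never 0.
    Raises when the held-out set has no positive labels (recall undefined).
    """
    if not any(lc.label for lc in held_out):
        raise ValueError("held-out set contains no positive examples; recall undefined")
    scored = [(score(model, lc.candidate), lc.label) for lc in held_out]
    n_pos = sum(1 for _, lab in scored if lab)
    thresholds = sorted({0.0} | {s for s, _ in scored})
    points = []
    for t in thresholds:
        tp = sum(1 for s, lab in scored if s >= t and lab)
        fp = sum(1 for s, lab in scored if s >= t and not lab)
        precision = tp / (tp + fp) if (tp + fp) else None
        points.append(EvaluationPoint(threshold=t, precision=precision, recall=tp / n_pos))
    return points


def precision_recall_at(
    points: Sequence[EvaluationPoint], threshold: float
) -> tuple[Optional[float], float]:
    """Precision/recall at an operating threshold, from an evaluate() curve."""
    # predictions at t are exactly those at the smallest achievable score >= t
    eligible = [p for p in points if p.threshold >= threshold]
    if not eligible:
        return None, 0.0
    best = min(eligible, key=lambda p: p.threshold)
    return best.precision, best.recall


def train_test_split_stratified(
    labeled: Sequence[LabeledCandidate], test_fraction: float, seed: int
) -> tuple[list[LabeledCandidate], list[LabeledCandidate]]:
    """Deterministic stratified-by-label split (default use: 80/20)."""
    rng = np.random.RandomState(seed)
    train_set: list[LabeledCandidate] = []
    test_set: list[LabeledCandidate] = []
    for label in (False, True):
        idx = [i for i, lc in enumerate(labeled) if lc.label == label]
        idx = [idx[i] for i in rng.permutation(len(idx))]
        n_test = int(round(len(idx) * test_fraction))
        test_set.extend(labeled[i] for i in idx[:n_test])
        train_set.extend(labeled[i] for i in idx[n_test:])
    return train_set, test_set
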