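"""Binary increase/decrease sentence classifier used as a ranking factor.

The polarity of a causal assertion ("TNF *induces* CREB1" vs "RSK2
*represses* HSF1") is predicted from lexical features of the sentence:

``uni:``   lowercase unigram counts, stopwords and entity spans excluded;
``bi:``    bigram counts over the stopword-filtered token stream, with
           each entity span collapsed to an ``ENTITY`` placeholder;
``ent:``   one indicator per matched entity surface;
``pos:``   position-indexed part-of-speech tags of the tokens strictly
           between the first and last entity span.

Three model families are supported (naive Bayes, random forest, linear
SVM) behind a sklearn-compatible estimator, plus stratified k-fold cross
validation producing the model x feature-set macro-F grid.

POS tagging is a pluggable ``token -> tag`` callable; the default is a
lightweight closed-class-lexicon + suffix tagger whose coarse tags are
sufficient for the ``pos:`` feature family.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction import DictVectorizer
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LabeledSentence",
    "default_pos_tagger",
    "DEFAULT_STOPWORDS",
    "featurize_sentence",
    "RelationClassifier",
    "train_classifier",
    "predict_polarity",
    "cross_validate",
    "MODEL_KINDS",
    "FEATURE_SETS",
]

LABELS = ("increase", "decrease")
MODEL_KINDS = ("naive_bayes", "random_forest", "svm")
#: Cumulative feature sets, mirrored by the cross-validation grid.
FEATURE_SETS = (("uni",), ("uni", "pos"), ("uni", "pos", "bi"))

ENTITY_PLACEHOLDER = "ENTITY"

#: Built-in English stopword list (function words only; overridable).
DEFAULT_STOPWORDS = frozenset("""
a an and are as at be been but by for from had has have if in into is it its
of on or such that the their then there these this to was were which will
with we our they he she you i not no nor do does did than
""".split())


@dataclass(frozen=True)
class LabeledSentence:
    """A sentence, the character spans of the statement entities found in
    it, and its polarity label."""

    text: str
    entity_spans: tuple[tuple[int, int], ...]
    label: str

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        prev_end = -1
        for start, end in sorted(self.entity_spans):
            if start < 0 or end > len(self.text) or start >= end:
                raise ValueError(f"entity span ({start},{end}) out of bounds")
            if start < prev_end:
                raise ValueError("entity spans overlap")
            prev_end = end


# ---------------------------------------------------------------------------
# Default POS tagger

_CLOSED_CLASS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT",
    "of": "IN", "in": "IN", "on": "IN", "at": "IN", "by": "IN", "for": "IN",
    "with": "IN", "from": "IN", "to": "TO", "into": "IN", "between": "IN",
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "has": "VBZ", "have": "VBP", "had": "VBD",
    "can": "MD", "may": "MD", "will": "MD", "would": "MD", "should": "MD",
    "not": "RB", "no": "DT",
    "it": "PRP", "we": "PRP", "they": "PRP",
}

_SUFFIX_RULES = (
    ("ly", "RB"), ("ing", "VBG"), ("ed", "VBD"), ("es", "VBZ"),
    ("tion", "NN"), ("sion", "NN"), ("ment", "NN"), ("ness", "NN"),
    ("ous", "JJ"), ("ive", "JJ"), ("ic", "JJ"), ("al", "JJ"),
)


def default_pos_tagger(token: str) -> str:
    """Coarse POS tag from a closed-class lexicon and suffix heuristics."""
    low = token.lower()
    if low in _CLOSED_CLASS:
        return _CLOSED_CLASS[low]
    if token.isdigit():
        return "CD"
    if token[:1].isupper():
        return "NNP"
    for suffix, tag in _SUFFIX_RULES:
        if len(low) > len(suffix) + 1 and low.endswith(suffix):
            return tag
    return "NN"


# ---------------------------------------------------------------------------
# Feature extraction

_WORD_RE = re.compile(r"\w+", re.UNICODE)


def _tokens_with_entities(text, entity_spans):
    """Token stream with each entity span collapsed to one placeholder.

    Returns (stream, n_entities_matched): stream items are
    (surface, is_entity) in document order.
    """
    spans = sorted(entity_spans)
    stream: list[tuple[str, bool]] = []
    emitted: set[int] = set()  # one placeholder per span, not per token
    for m in _WORD_RE.finditer(text):
        inside = None
        for k, (s, e) in enumerate(spans):
            if m.start() < e and m.end() > s:
                inside = k
                break
        if inside is None:
            stream.append((m.group(0), False))
        elif inside not in emitted:
            emitted.add(inside)
            stream.append((ENTITY_PLACEHOLDER, True))
    return stream


def featurize_sentence(
    sentence: LabeledSentence | tuple,
    stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
    tagger=default_pos_tagger,
) -> dict[str, float]:
    """Sparse feature mapping for one sentence (no zero-valued entries).

    Feature names carry a namespace prefix: ``uni:``, ``bi:``, ``ent:``,
    ``pos:``.  The ``pos:`` family covers tokens strictly between the
    first and last entity span and is empty for sentences with fewer than
    two entity spans.
    """
    if isinstance(sentence, LabeledSentence):
        text, spans = sentence.text, sentence.entity_spans
    else:
        text, spans = sentence

    feats: dict[str, float] = {}

    def bump(name: str, by: float = 1.0) -> None:
        feats[name] = feats.get(name, 0.0) + by

    stream = _tokens_with_entities(text, spans)

    # ent: indicators for the matched entity surfaces
    for s, e in sorted(spans):
        bump(f"ent:{text[s:e].lower()}")

    # filtered stream: drop stopwords, keep entity placeholders
    filtered = [
        (surface, is_ent)
        for surface, is_ent in stream
        if is_ent or surface.lower() not in stopwords
    ]
    for surface, is_ent in filtered:
        if not is_ent:
            bump(f"uni:{surface.lower()}")
    for (s1, e1), (s2, e2) in zip(filtered, filtered[1:]):
        w1 = ENTITY_PLACEHOLDER if e1 else s1.lower()
        w2 = ENTITY_PLACEHOLDER if e2 else s2.lower()
        bump(f"bi:{w1}_{w2}")

    # pos: tags of tokens strictly between the first and last entity span
    if len(spans) >= 2:
        ordered = sorted(spans)
        lo, hi = ordered[0][1], ordered[-1][0]
        between = [
            m.group(0)
            for m in _WORD_RE.finditer(text)
            if m.start() >= lo and m.end() <= hi
        ]
        for offset, token in enumerate(between):
            bump(f"pos:{offset}:{tagger(token)}")

    return feats


# ---------------------------------------------------------------------------
# Estimator

def _csr32(mat):
    # LinearSVC only accepts 32-bit sparse indices
    mat = mat.tocsr()
    mat.indices = mat.indices.astype(np.int32)
    mat.indptr = mat.indptr.astype(np.int32)
    return mat


def _make_model(kind: str, random_state: int):
    if kind == "naive_bayes":
        return MultinomialNB()
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=random_state)
    if kind == "svm":
        return LinearSVC(random_state=random_state)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


class RelationClassifier(BaseEstimator, ClassifierMixin):
    """Increase/decrease polarity classifier over lexical sentence features.

    Parameters
    ----------
    model : {"naive_bayes", "random_forest", "svm"}
    feature_set : tuple of {"uni", "pos", "bi"}
        Feature families to keep ("ent" indicators ride with "uni").
    stopwords, tagger :
        Overridable stopword set and token->POS callable.
    min_feature_df : int
        Drop features occurring in fewer training sentences than this;
        hapax n-grams carry no generalizable signal and dilute the
        class-conditional likelihoods.
    random_state : int
        Seed for the stochastic models.
    """

    def __init__(
        self,
        model: str = "naive_bayes",
        feature_set: tuple[str, ...] = ("uni", "pos", "bi"),
        stopwords=DEFAULT_STOPWORDS,
        tagger=default_pos_tagger,
        min_feature_df: int = 2,
        random_state: int = 0,
    ):
        self.model = model
        self.feature_set = feature_set
        self.stopwords = stopwords
        self.tagger = tagger
        self.min_feature_df = min_feature_df
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    def _features(self, sentence) -> dict[str, float]:
        feats = featurize_sentence(sentence, self.stopwords, self.tagger)
        keep = set(self.feature_set) | ({"ent"} if "uni" in self.feature_set else set())
        return {
            name: value
            for name, value in feats.items()
            if name.split(":", 1)[0] in keep
        }

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y=None):
        """Fit on labeled sentences.

        ``X`` is a sequence of :class:`LabeledSentence` (then ``y`` is
        optional) or of ``(text, entity_spans)`` pairs with ``y`` the
        label sequence.
        """
        if y is None:
            if not all(isinstance(s, LabeledSentence) for s in X):
                raise ValueError("y required unless X holds LabeledSentence items")
            y = [s.label for s in X]
        X = list(X)
        y = list(y)
        if not X:
            raise ValueError("training data is empty")
        classes = sorted(set(y))
        if len(classes) < 2:
            raise ValueError(f"training data has a single class {classes}")
        self.vectorizer_ = DictVectorizer(sparse=True)
        feats = [self._features(s) for s in X]
        if self.min_feature_df > 1:
            df: dict[str, int] = {}
            for f in feats:
                for name in f:
                    df[name] = df.get(name, 0) + 1
            feats = [
                {k: v for k, v in f.items() if df[k] >= self.min_feature_df}
                for f in feats
            ]
        mat = _csr32(self.vectorizer_.fit_transform(feats))
        self.estimator_ = _make_model(self.model, self.random_state)
        self.estimator_.fit(mat, y)
        self.classes_ = np.asarray(self.estimator_.classes_)
        counts = pd.Series(y).value_counts()
        self.class_priors_ = (counts / counts.sum()).to_dict()
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        mat = _csr32(self.vectorizer_.transform([self._features(s) for s in X]))
        return self.estimator_.predict(mat)

    def predict_with_confidence(self, sentence) -> tuple[str, float]:
        """Polarity and a confidence in [0, 1] for one sentence."""
        check_is_fitted(self, "estimator_")
        mat = _csr32(self.vectorizer_.transform([self._features(sentence)]))
        if hasattr(self.estimator_, "predict_proba"):
            proba = self.estimator_.predict_proba(mat)[0]
            k = int(np.argmax(proba))
            return str(self.classes_[k]), float(proba[k])
        # margin-based models: squash the decision value through a logistic
        margin = float(np.ravel(self.estimator_.decision_function(mat))[0])
        conf = 1.0 / (1.0 + np.exp(-abs(margin)))
        label = str(self.estimator_.predict(mat)[0])
        return label, conf


def train_classifier(data, model: str = "naive_bayes", random_state: int = 0,
                     feature_set: tuple[str, ...] = ("uni", "pos", "bi"),
                     stopwords=DEFAULT_STOPWORDS, tagger=default_pos_tagger):
    """Fit a :class:`RelationClassifier` on labeled sentences."""
    clf = RelationClassifier(
        model=model, feature_set=feature_set, stopwords=stopwords,
        tagger=tagger, random_state=random_state,
    )
    return clf.fit(list(data))


def predict_polarity(clf: RelationClassifier, sentence) -> tuple[str, float]:
    """Predict (polarity, confidence) for a sentence or (text, spans) pair."""
    return clf.predict_with_confidence(sentence)


def cross_validate(
    data,
    folds: int = 10,
    models=MODEL_KINDS,
    feature_sets=FEATURE_SETS,
    random_state: int = 0,
) -> pd.DataFrame:
    """Stratified k-fold macro F-measure per (model, feature set).

    Returns a DataFrame indexed by model with one column per cumulative
    feature set ("uni", "uni+pos", "uni+pos+bi" under the defaults); the
    fixed seed makes the table bit-reproducible.
    """
    data = list(data)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = [s.label for s in data]
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValueError("cross-validation needs both classes present")
    if folds > counts.min():
        raise ValueError(
            f"folds={folds} exceeds the minority class count {counts.min()}"
        )
    y = np.asarray(labels)
    table = pd.DataFrame(
        index=list(models),
        columns=["+".join(fs) for fs in feature_sets],
        dtype=float,
    )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
    for model in models:
        for fs in feature_sets:
            scores = []
            for train_idx, test_idx in skf.split(np.zeros(len(data)), y):
                clf = RelationClassifier(
                    model=model, feature_set=tuple(fs), random_state=random_state
                )
                clf.fit([data[i] for i in train_idx])
                pred = clf.predict([data[i] for i in test_idx])
                scores.append(f1_score(y[test_idx], pred, average="macro"))
            table.loc[model, "+".join(fs)] = float(np.mean(scores))
    return table
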