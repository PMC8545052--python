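"""Six-class emotion profiles: pluggable classifier, dominant label, summaries.

Each tweet carries a probability vector over Ekman's six basic emotions
(anger, disgust, fear, joy, sadness, surprise). Profiles come either from a
precomputed CSV (e.g. the output of an external neural classifier) or from
the packaged deterministic keyword-lexicon stub, which exists so the
aggregation pipeline can be exercised and tested without trained weights —
it is a transparent toy, not a real emotion model. Corpus-level summaries
are the per-class mean probabilities and quantiles, and the proportion of
tweets whose *dominant* (argmax) emotion falls in each class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topics import tokenize

__all__ = [
    "EMOTIONS",
    "EmotionProfile",
    "EmotionSummary",
    "LexiconEmotionClassifier",
    "classify_emotions",
    "make_profile",
    "load_emotion_csv",
    "dominant_emotion",
    "emotion_summary",
]

#: Fixed class order; also the tie-break order for dominant_emotion.
EMOTIONS = ("anger", "disgust", "fear", "joy", "sadness", "surprise")

_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass(frozen=True)
class EmotionProfile:
    """A probability vector over the six Ekman emotions (sums to 1)."""

    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (6,):
            raise ValueError("expected 6 probabilities")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"probabilities sum to {p.sum():.8f}, not 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probabilities, dtype=float)

    def __getitem__(self, emotion: str) -> float:
        return self.probabilities[EMOTIONS.index(emotion)]


@dataclass(frozen=True)
class EmotionSummary:
    n: int
    mean: dict[str, float]
    quantiles: dict[str, dict[float, float]]
    dominant_proportion: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in EMOTIONS:
            row = {"emotion": e, "mean": self.mean[e],
                   "dominant_proportion": self.dominant_proportion[e]}
            for q in _QUANTILES:
                row[f"q{int(q * 100):02d}"] = self.quantiles[e][q]
            rows.append(row)
        return pd.DataFrame(rows).set_index("emotion")


# -- classifiers -----------------------------------------------------------

_LEXICON: dict[str, tuple[str, ...]] = {
    "anger": ("angry", "anger", "mad", "furious", "outrage", "outraged", "hate",
              "rage", "annoyed", "disgrace", "fedup"),
    "disgust": ("disgust", "disgusting", "gross", "vile", "nasty", "revolting",
                "yuck", "ew", "filthy"),
    "fear": ("fear", "afraid", "scared", "scary", "terrified", "terrifying",
             "panic", "worried", "worry", "anxious", "dread", "frightened",
             "alarming", "danger", "dangerous"),
    "joy": ("happy", "joy", "lol", "haha", "funny", "hilarious", "love",
            "great", "awesome", "glad", "relieved", "wonderful"),
    "sadness": ("sad", "sadness", "cry", "crying", "grief", "mourning",
                "heartbroken", "depressed", "tragic", "loss"),
    "surprise": ("surprised", "surprising", "shocked", "shocking", "unbelievable",
                 "incredible", "astonishing", "whoa", "unexpected"),
}


class LexiconEmotionClassifier:
    """Deterministic keyword-count stub with a uniform fallback.

    Scores each emotion by the number of its lexicon words among the
    tweet's tokens, adds a symmetric smoothing pseudo-count, and
    normalises. A text with no lexicon hits (or an empty text) gets the
    uniform profile. sklearn-style ``predict_proba`` over a list of texts.
    """

    def __init__(self, smoothing: float = 0.5):
        if smoothing <= 0:
            raise ValueError("smoothing must be > 0")
        self.smoothing = smoothing

    def get_params(self, deep: bool = True) -> dict:
        return {"smoothing": self.smoothing}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def predict_proba(self, texts) -> np.ndarray:
        out = np.empty((len(texts), 6))
        for i, text in enumerate(texts):
            toks = tokenize(text or "")
            counts = np.array(
                [sum(t in _LEXICON[e] for t in toks) for e in EMOTIONS], dtype=float
            )
            if counts.sum() == 0:
                out[i] = 1.0 / 6.0
            else:
                counts += self.smoothing
                out[i] = counts / counts.sum()
        return out


def classify_emotions(text: str, classifier=None) -> EmotionProfile:
    """Run a classifier on one text and validate/normalise its output.

    ``classifier`` may expose ``predict_proba([text])`` or be a plain
    callable text -> 6 numbers; default is the lexicon stub. A vector whose
    sum is within [0.99, 1.01] is renormalised; anything further off is an
    error.
    """
    if classifier is None:
        classifier = LexiconEmotionClassifier()
    if hasattr(classifier, "predict_proba"):
        raw = np.asarray(classifier.predict_proba([text]))[0]
    else:
        raw = np.asarray(classifier(text), dtype=float)
    if raw.shape != (6,):
        raise ValueError("classifier must return 6 probabilities")
    s = float(raw.sum())
    if not 0.99 <= s <= 1.01:
        raise ValueError(f"classifier output sums to {s:.4f}, outside [0.99, 1.01]")
    return EmotionProfile(probabilities=tuple(raw / s))


def make_profile(values) -> EmotionProfile:
    """Build a profile from six numbers, renormalising sums in [0.99, 1.01].

    Published probability tables are often rounded so rows sum to 0.999 or
    1.001; anything further from 1 is rejected.
    """
    p = np.asarray(values, dtype=float)
    if p.shape != (6,):
        raise ValueError("expected 6 probabilities")
    s = float(p.sum())
    if not 0.99 <= s <= 1.01:
        raise ValueError(f"probabilities sum to {s:.4f}, outside [0.99, 1.01]")
    return EmotionProfile(probabilities=tuple(p / s))


def load_emotion_csv(path) -> dict[str, EmotionProfile]:
    """Load precomputed profiles from CSV columns tweet_id, anger..surprise."""
    df = pd.read_csv(path)
    missing = ({"tweet_id", *EMOTIONS}) - set(df.columns)
    if missing:
        raise ValueError(f"emotion CSV missing columns: {sorted(missing)}")
    return {
        str(row["tweet_id"]): make_profile([float(row[e]) for e in EMOTIONS])
        for _, row in df.iterrows()
    }


def dominant_emotion(profile: EmotionProfile | np.ndarray) -> str:
    """The argmax emotion; ties go to the first class in EMOTIONS order."""
    p = profile.as_array() if isinstance(profile, EmotionProfile) else np.asarray(profile)
    return EMOTIONS[int(np.argmax(p))]


def emotion_summary(profiles) -> EmotionSummary:
    """Corpus-level means, quantiles and dominant-emotion proportions."""
    mats = [
        p.as_array() if isinstance(p, EmotionProfile) else np.asarray(p, dtype=float)
        for p in profiles
    ]
    if not mats:
        raise ValueError("need at least one profile")
    mat = np.vstack(mats)
    mean = {e: float(mat[:, j].mean()) for j, e in enumerate(EMOTIONS)}
    quantiles = {
        e: {q: float(np.quantile(mat[:, j], q)) for q in _QUANTILES}
        for j, e in enumerate(EMOTIONS)
    }
    dom_idx = np.argmax(mat, axis=1)
    dominant = {
        e: float(np.mean(dom_idx == j)) for j, e in enumerate(EMOTIONS)
    }
    return EmotionSummary(
        n=mat.shape[0], mean=mean, quantiles=quantiles, dominant_proportion=dominant
    )
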