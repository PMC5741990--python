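"""Activation detection and yes/no answer decoding.

Each channel's oxyhemoglobin time course is summarized by two features —
the contrast-to-noise ratio (task-rest mean difference over the rest-period
standard deviation) and the Pearson correlation with the theoretical
activation model (boxcar convolved with the HRF).  A support-vector
classifier trained on the simulated corpus calls each channel activated or
not; a question is answered "yes" when at least one channel over the motor
planning regions is activated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .hrf import HRFModel, build_regressor
from .paradigm import BlockDesign, Timeline, build_timeline
from .preprocess import FilterSpec, MaraSpec, preprocess_series

__all__ = [
    "FeatureVector",
    "ChannelDecision",
    "Answer",
    "compute_cnr",
    "compute_model_correlation",
    "extract_features",
    "train_classifier",
    "TrainedClassifier",
    "classify_channel",
    "decide_answer",
    "cycle_average_report",
]


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureVector:
    cnr: float
    r: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.cnr):
            raise ClassifierError("CNR must be finite")
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ClassifierError(f"correlation {self.r} outside [-1, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.cnr, self.r])


@dataclass(frozen=True)
class ChannelDecision:
    channel: str
    activated: bool
    features: FeatureVector


@dataclass(frozen=True)
class Answer:
    """Decoded response to one question.

    ``mean_cnr``/``mean_r`` average over the activated channels for a "yes"
    and over all channels for a "no", mirroring how per-question summaries
    are reported.
    """

    question: str
    response: str  # "yes" | "no"
    n_activated: int
    decisions: tuple[ChannelDecision, ...]
    mean_cnr: float
    mean_r: float


def compute_cnr(series: np.ndarray, timeline: Timeline) -> float:
    """Contrast-to-noise ratio: (mean task - mean rest) / SD of rest."""
    x = np.asarray(series, dtype=float)
    if x.size != timeline.n_frames:
        raise ClassifierError("series length does not match timeline")
    task = x[timeline.task_mask]
    rest = x[timeline.rest_mask]
    if task.size == 0 or rest.size == 0:
        raise ClassifierError("both task and rest frames required")
    sd = rest.std()
    if sd == 0:
        raise ClassifierError("zero rest-period standard deviation: CNR undefined")
    return float((task.mean() - rest.mean()) / sd)


def compute_model_correlation(
    series: np.ndarray, design: BlockDesign, hrf: HRFModel | None = None
) -> float:
    """Pearson correlation between the series and the theoretical model."""
    x = np.asarray(series, dtype=float)
    reg = build_regressor(design, hrf)
    if x.size != reg.size:
        raise ClassifierError("series length does not match design timeline")
    if x.std() == 0 or reg.std() == 0:
        raise ClassifierError("zero-variance input: correlation undefined")
    return float(np.corrcoef(x, reg)[0, 1])


def extract_features(
    series: np.ndarray, design: BlockDesign, hrf: HRFModel | None = None
) -> FeatureVector:
    timeline = build_timeline(design)
    return FeatureVector(cnr=compute_cnr(series, timeline),
                         r=compute_model_correlation(series, design, hrf))


@dataclass(frozen=True)
class TrainedClassifier:
    """Support-vector activation detector over (CNR, r) features."""

    pipeline: Pipeline
    design: BlockDesign
    hrf: HRFModel
    training_report: dict = field(default_factory=dict)

    def predict(self, features: FeatureVector) -> bool:
        return bool(self.pipeline.predict(features.as_array()[None, :])[0])


def _corpus_features(
    corpus: pd.DataFrame,
    design: BlockDesign,
    hrf: HRFModel,
    filt: FilterSpec | None,
    mara: MaraSpec | None,
) -> np.ndarray:
    feats = np.empty((len(corpus), 2))
    for i, series in enumerate(corpus["series"]):
        x = preprocess_series(series, design.frame_interval_s, mara, filt)
        fv = extract_features(x, design, hrf)
        feats[i] = (fv.cnr, fv.r)
    return feats


def train_classifier(
    corpus: pd.DataFrame,
    design: BlockDesign | None = None,
    hrf: HRFModel | None = None,
    C: float = 1.0,
    gamma: str | float = "scale",
    kernel: str = "rbf",
    seed: int = 0,
    filt: FilterSpec | None = None,
    mara: MaraSpec | None = None,
    cross_validate: bool = True,
) -> TrainedClassifier:
    """Train the support-vector activation detector on a simulated corpus.

    The corpus series are passed through the same conditioning chain used
    at decoding time before features are computed, so training and
    application see identically distributed inputs.
    """
    design = design or BlockDesign()
    hrf = hrf or HRFModel()
    labels = corpus["label"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ClassifierError("corpus must contain both classes")
    X = _corpus_features(corpus, design, hrf, filt, mara)
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(C=C, gamma=gamma, kernel=kernel, random_state=seed)),
    ])
    pipe.fit(X, labels)
    report = {
        "n_train": int(len(labels)),
        "train_accuracy": float(pipe.score(X, labels)),
        "kernel": kernel, "C": C, "gamma": gamma, "seed": seed,
        "n_support": [int(n) for n in pipe["svc"].n_support_],
    }
    if cross_validate and len(labels) >= 10:
        cv = cross_val_score(pipe, X, labels, cv=5)
        report["cv_accuracy"] = float(cv.mean())
    return TrainedClassifier(pipeline=pipe, design=design, hrf=hrf,
                             training_report=report)


def classify_channel(
    series: np.ndarray,
    model: TrainedClassifier,
    channel: str = "ch1",
    preprocessed: bool = True,
) -> ChannelDecision:
    """Apply the detector to one (preprocessed) oxyhemoglobin series.

    A channel is called activated only when the classifier votes for the
    activation class AND the CNR is positive — the target response is an
    oxyhemoglobin *increase*, so deactivation patterns must not drive a yes.
    """
    x = np.asarray(series, dtype=float)
    if not preprocessed:
        x = preprocess_series(x, model.design.frame_interval_s)
    fv = extract_features(x, model.design, model.hrf)
    activated = model.predict(fv) and fv.cnr > 0
    return ChannelDecision(channel=channel, activated=activated, features=fv)


def decide_answer(
    decisions: list[ChannelDecision] | tuple[ChannelDecision, ...],
    question: str = "q1",
) -> Answer:
    """Aggregate channel decisions into a yes/no answer.

    "Yes" iff at least one channel is activated.
    """
    if not decisions:
        raise ClassifierError("at least one channel decision required")
    activated = [d for d in decisions if d.activated]
    pool = activated if activated else list(decisions)
    return Answer(
        question=question,
        response="yes" if activated else "no",
        n_activated=len(activated),
        decisions=tuple(decisions),
        mean_cnr=float(np.mean([d.features.cnr for d in pool])),
        mean_r=float(np.mean([d.features.r for d in pool])),
    )


def cycle_average_report(
    series: np.ndarray,
    design: BlockDesign,
    include_lead_in: bool = False,
) -> pd.DataFrame:
    """Fold a series over the task+rest cycle and average across cycles.

    Returns a DataFrame with columns ``time_s`` (time within the cycle,
    task onset at 0), ``mean``, ``sem`` and ``n_cycles``.  With
    ``include_lead_in`` the lead-in rest is folded in as an extra
    (incomplete) pseudo-cycle where it fits; by default it is dropped.
    Trailing incomplete cycles are always dropped.
    """
    x = np.asarray(series, dtype=float)
    cyc = design.frames(design.cycle_s)
    start = 0 if include_lead_in else design.frames(design.lead_in_rest_s)
    usable = x[start:]
    n_cycles = usable.size // cyc
    if n_cycles < 1:
        raise ClassifierError("no complete cycle in series")
    folded = usable[: n_cycles * cyc].reshape(n_cycles, cyc)
    mean = folded.mean(axis=0)
    sem = (folded.std(axis=0, ddof=1) / np.sqrt(n_cycles)
           if n_cycles > 1 else np.zeros(cyc))
    return pd.DataFrame({
        "time_s": np.arange(cyc) * design.frame_interval_s,
        "mean": mean,
        "sem": sem,
        "n_cycles": n_cycles,
    })
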