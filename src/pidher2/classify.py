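"""Cut-point classification of PID values into IHC categories.

The tentative PID IHC score thresholds a core's PID value at cut points
equal to the per-DAB-class PID-value minima of a reference cohort: the cut
for class k is the smallest PID value among cores the pathologists called
k. Because cut points are class minima, class intervals are closed below
(a value exactly at a cut belongs to that class). DAB-0 cores whose PID
value exceeds the negative-control mean carry detectable HER2 signal and
are flagged as candidate "ultra-low".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .io import DAB_CLASSES, CoreRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CutPoints:
    """Ascending PID-value thresholds for classes 1+, 2+, 3+ (arbitrary units)."""

    c1: float
    c2: float
    c3: float

    def __post_init__(self) -> None:
        if not (0 < self.c1 < self.c2 < self.c3):
            raise ValueError(
                f"cut points must satisfy 0 < c1 < c2 < c3, got ({self.c1}, {self.c2}, {self.c3})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3], dtype=float)


@dataclass(frozen=True)
class NegativeControlStats:
    """Mean PID value of the negative-control cores — the detection floor."""

    mean_value: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("negative-control statistics need at least one core")
        if self.mean_value < 0:
            raise ValueError(f"negative-control mean must be nonnegative, got {self.mean_value}")


class MissingClassError(ValueError):
    """A DAB class required for cut-point derivation has no cores."""


class CutPointClassifier(ClassifierMixin, BaseEstimator):
    """Classify PID values into IHC categories at per-class minima cut points.

    ``fit(X, y)`` takes PID values (one feature) and DAB category labels
    and sets each cut point to the minimum PID value of the corresponding
    class; ``predict`` assigns the category whose half-open interval
    [c_k, c_{k+1}) contains the value. Passing ``cut_points`` at
    construction fixes the thresholds (e.g. published values) instead of
    deriving them, in which case ``fit`` only validates.

    Attributes
    ----------
    cut_points_ : CutPoints
        Thresholds for classes 1+, 2+, 3+ after fitting.
    classes_ : ndarray
        The four category labels in ascending order.
    """

    def __init__(self, cut_points: CutPoints | None = None):
        self.cut_points = cut_points

    def fit(self, X, y=None):
        X = self._validate_values(X)
        if self.cut_points is not None:
            self.cut_points_ = self.cut_points
        else:
            if y is None:
                raise ValueError("y (DAB categories) is required when cut_points is not fixed")
            y = np.asarray(y, dtype=object)
            if len(y) != len(X):
                raise ValueError(f"X and y length mismatch: {len(X)} vs {len(y)}")
            minima = {}
            for cls in ("1+", "2+", "3+"):
                vals = X[y == cls]
                if vals.size == 0:
                    raise MissingClassError(f"cannot derive a cut point: no cores with DAB class {cls}")
                minima[cls] = float(vals.min())
            if not (minima["1+"] < minima["2+"] < minima["3+"]):
                raise ValueError(
                    "per-class PID minima are not strictly increasing: "
                    f"1+={minima['1+']}, 2+={minima['2+']}, 3+={minima['3+']}"
                )
            self.cut_points_ = CutPoints(minima["1+"], minima["2+"], minima["3+"])
        self.classes_ = np.asarray(DAB_CLASSES, dtype=object)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "cut_points_")
        X = self._validate_values(X)
        idx = np.searchsorted(self.cut_points_.as_array(), X, side="right")
        return self.classes_[idx]

    @staticmethod
    def _validate_values(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError(f"expected PID values as a 1-D array or (n, 1) column, got shape {X.shape}")
        if np.any(~np.isfinite(X)) or np.any(X < 0):
            raise ValueError("PID values must be finite and nonnegative")
        return X


def consensus_dab(p1: str | None, p2: str | None, policy: str = "higher", core_id: str = "") -> str | None:
    """Adjudicate two pathologists' DAB scores.

    Policies: ``higher`` (default — keep the higher category and log the
    discordance), ``lower``, ``p1``. Missing readings fall back to the
    other reader.
    """
    if p1 is None:
        return p2
    if p2 is None:
        return p1
    if p1 == p2:
        return p1
    logger.info("core %s: discordant DAB scores %s vs %s (policy=%s)", core_id or "?", p1, p2, policy)
    i1, i2 = DAB_CLASSES.index(p1), DAB_CLASSES.index(p2)
    if policy == "higher":
        return DAB_CLASSES[max(i1, i2)]
    if policy == "lower":
        return DAB_CLASSES[min(i1, i2)]
    if policy == "p1":
        return p1
    raise ValueError(f"unknown consensus policy {policy!r}")


def _reference_records(records: list[CoreRecord]) -> list[CoreRecord]:
    return [
        r
        for r in records
        if r.exclusion_reason == "none"
        and not r.is_negative_control
        and r.pid_value is not None
        and r.dab_consensus is not None
    ]


def derive_cut_points(records: list[CoreRecord]) -> CutPoints:
    """Cut points = per-class PID minima over analyzable, non-control cores."""
    ref = _reference_records(records)
    clf = CutPointClassifier().fit(
        np.array([r.pid_value for r in ref]), np.array([r.dab_consensus for r in ref], dtype=object)
    )
    return clf.cut_points_


def classify_pid(pid_value: float, cuts: CutPoints) -> str:
    """Assign the tentative PID IHC score of one PID value."""
    clf = CutPointClassifier(cut_points=cuts).fit(np.array([0.0]))
    return str(clf.predict(np.array([pid_value]))[0])


def negative_control_mean(records: list[CoreRecord]) -> NegativeControlStats:
    """Arithmetic mean PID value over the negative-control cores."""
    vals = [r.pid_value for r in records if r.is_negative_control and r.pid_value is not None]
    if not vals:
        raise ValueError("no negative-control cores with a PID value")
    return NegativeControlStats(mean_value=float(np.mean(vals)), n=len(vals))


def flag_ultra_low(
    records: list[CoreRecord], cuts: CutPoints, ncs: NegativeControlStats
) -> tuple[list[CoreRecord], dict[str, int]]:
    """Flag DAB-0 cores whose PID value strictly exceeds the control floor.

    Returns the records (flags set in place on DAB-0 cores with a PID
    value) and counts of flagged vs unflagged DAB-0 cores.
    """
    flagged = unflagged = 0
    for r in records:
        if r.dab_consensus == "0" and r.pid_value is not None and not r.is_negative_control:
            r.ultra_low_flag = r.pid_value > ncs.mean_value
            if r.ultra_low_flag:
                flagged += 1
            else:
                unflagged += 1
        # other classes: flag stays unset
    return records, {"flagged": flagged, "unflagged": unflagged}


def assign_pid_scores(records: list[CoreRecord], cuts: CutPoints) -> list[CoreRecord]:
    """Set ``pid_score`` on every analyzable record that has a PID value."""
    clf = CutPointClassifier(cut_points=cuts).fit(np.array([0.0]))
    for r in records:
        if r.pid_value is not None and r.exclusion_reason == "none":
            r.pid_score = str(clf.predict(np.array([r.pid_value]))[0])
    return records
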