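"""Inference layer: PCA motion separation, multicoil regression, MIMO stacking.

Multicoil navigator magnitudes are averaged per image frame, compressed by
PCA for motion-type visualization/classification, and regressed against
reference traces (displacement ballistocardiogram, registration-derived
rigid-motion PCs) with the Pearson correlation of fit as the headline
statistic.  Channels from multiple transmit antennas are concatenated for
MIMO operation; a nested-model guarantee makes the in-sample correlation of
the stacked regression at least that of either antenna alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .kspace import BptSeries

__all__ = [
    "PCModel",
    "RegressionFit",
    "LabeledFrameSet",
    "frame_average",
    "pca_fit",
    "pca_project",
    "regress_multicoil",
    "separability_plane",
    "SeparabilityResult",
    "mimo_stack",
]


@dataclass
class PCModel:
    """Mean-centered principal-component basis over navigator channels."""

    channel_means: np.ndarray                  # [channels]
    components: np.ndarray                     # [n_pc, channels], orthonormal rows
    explained_variance_fraction: np.ndarray    # [n_pc], non-increasing

    def __post_init__(self) -> None:
        self.channel_means = np.asarray(self.channel_means, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.explained_variance_fraction = np.asarray(
            self.explained_variance_fraction, dtype=float)
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.components.shape[0]), atol=1e-9):
            raise ValueError("components must be orthonormal")

    @property
    def n_pc(self) -> int:
        return self.components.shape[0]

    def to_json(self) -> str:
        return json.dumps({
            "channel_means": self.channel_means.tolist(),
            "components": self.components.tolist(),
            "explained_variance_fraction":
                self.explained_variance_fraction.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "PCModel":
        d = json.loads(text)
        return cls(np.array(d["channel_means"]), np.array(d["components"]),
                   np.array(d["explained_variance_fraction"]))


@dataclass
class RegressionFit:
    """Multicoil OLS fit against a reference trace."""

    weights: np.ndarray     # per channel, on de-meaned design
    intercept: float
    fitted: np.ndarray
    pearson_r: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("|pearson_r| must be <= 1")

    def to_json(self) -> str:
        return json.dumps({
            "weights": np.asarray(self.weights).tolist(),
            "intercept": float(self.intercept),
            "pearson_r": float(self.pearson_r),
        })


@dataclass
class LabeledFrameSet:
    """Frame-averaged channel matrix with per-frame labels and antenna bookkeeping."""

    matrix: np.ndarray                  # [frames, channels]
    frame_times: np.ndarray             # [frames]
    labels: np.ndarray | None = None    # per-frame label
    antenna_id: np.ndarray | None = None  # per-channel antenna tag

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.frame_times.size:
            raise ValueError("matrix must be [frames, channels] matching frame_times")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.size != self.matrix.shape[0]:
                raise ValueError("one label per frame required")
        if self.antenna_id is not None:
            self.antenna_id = np.asarray(self.antenna_id)
            if self.antenna_id.size != self.matrix.shape[1]:
                raise ValueError("one antenna_id per channel required")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]

    def select_antenna(self, antenna) -> "LabeledFrameSet":
        if self.antenna_id is None:
            raise ValueError("frame set has no antenna bookkeeping")
        mask = self.antenna_id == antenna
        return LabeledFrameSet(self.matrix[:, mask], self.frame_times,
                               self.labels, self.antenna_id[mask])


def frame_average(series: BptSeries, frame_boundaries: Sequence[tuple[float, float]]
                  ) -> LabeledFrameSet:
    """Average navigator magnitudes over image frames.

    ``frame_boundaries`` are non-overlapping, increasing (start, end) times;
    each frame's value per channel is the mean of |values| over the lines
    whose times fall in [start, end).
    """
    bounds = list(frame_boundaries)
    for (s0, e0), (s1, _) in zip(bounds, bounds[1:]):
        if e0 > s1 or s0 >= e0:
            raise ValueError("frame boundaries must be increasing and non-overlapping")
    if bounds and bounds[-1][0] >= bounds[-1][1]:
        raise ValueError("frame boundaries must be increasing and non-overlapping")
    mags = np.abs(series.values)
    rows, times = [], []
    for start, end in bounds:
        mask = (series.line_times >= start) & (series.line_times < end)
        if not mask.any():
            raise ValueError(f"frame [{start}, {end}) contains no lines")
        rows.append(mags[mask].mean(axis=0))
        times.append(0.5 * (start + end))
    return LabeledFrameSet(np.array(rows), np.array(times))


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    out = components.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def pca_fit(frames: np.ndarray | LabeledFrameSet, n_pc: int) -> PCModel:
    """Mean-centered PCA of frame-averaged channel data."""
    X = frames.matrix if isinstance(frames, LabeledFrameSet) else np.asarray(
        frames, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 frames")
    if n_pc > min(n - 1, p):
        raise ValueError(f"n_pc={n_pc} exceeds min(frames-1, channels)={min(n - 1, p)}")
    pca = PCA(n_components=n_pc, svd_solver="full")
    pca.fit(X)
    return PCModel(pca.mean_, _fix_signs(pca.components_),
                   pca.explained_variance_ratio_)


def pca_project(model: PCModel, new_frames: np.ndarray | LabeledFrameSet
                ) -> np.ndarray:
    """Scores of new frames in a learned PC basis: ``(X - means) @ components.T``."""
    X = new_frames.matrix if isinstance(new_frames, LabeledFrameSet) else np.asarray(
        new_frames, dtype=float)
    if X.shape[1] != model.channel_means.size:
        raise ValueError(
            f"channel count {X.shape[1]} does not match model "
            f"({model.channel_means.size})")
    return (X - model.channel_means) @ model.components.T


def regress_multicoil(frames: np.ndarray | LabeledFrameSet, target: np.ndarray,
                      *, ridge: float = 0.0) -> RegressionFit:
    """OLS fit of a reference trace from de-meaned multichannel data.

    All signals are de-meaned before the fit; the Pearson correlation
    between the fitted and target traces is reported.  ``ridge`` adds
    optional Tikhonov regularization for ill-conditioned channel sets.
    """
    X = frames.matrix if isinstance(frames, LabeledFrameSet) else np.asarray(
        frames, dtype=float)
    y = np.asarray(target, dtype=float)
    if y.ndim != 1 or y.size != X.shape[0]:
        raise ValueError("target length must equal the number of frames")
    if np.std(y) == 0:
        raise ValueError("target has zero variance")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    if ridge > 0:
        A = Xc.T @ Xc + ridge * np.eye(X.shape[1])
        w = np.linalg.solve(A, Xc.T @ yc)
    else:
        w, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    fitted = Xc @ w + y.mean()
    if np.std(fitted) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(fitted, y)[0, 1])
    return RegressionFit(weights=w, intercept=float(y.mean()), fitted=fitted,
                         pearson_r=r)


@dataclass
class SeparabilityResult:
    """Linear separator between two motion classes in PC space."""

    normal: np.ndarray
    offset: float
    margin: float
    loo_accuracy: float
    separable: bool


def _loo_accuracy(scores: np.ndarray, y: np.ndarray, fit_predict) -> float:
    hits = 0
    n = len(y)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            continue
        hits += int(fit_predict(scores[mask], y[mask], scores[i]) == y[i])
    return hits / n


def _linearly_separable(X: np.ndarray, y_pm: np.ndarray) -> bool:
    """Feasibility LP: does some (w, b) satisfy y_i (w.x_i + b) >= 1?"""
    from scipy.optimize import linprog
    n, d = X.shape
    # variables [w (d), b]; constraints -y_i (x_i.w + b) <= -1
    A = -y_pm[:, None] * np.column_stack([X, np.ones(n)])
    res = linprog(c=np.zeros(d + 1), A_ub=A, b_ub=-np.ones(n),
                  bounds=[(None, None)] * (d + 1), method="highs")
    return bool(res.success)


def _lsq_discriminant(X: np.ndarray, y_pm: np.ndarray) -> tuple[np.ndarray, float]:
    A = np.column_stack([X, np.ones(len(y_pm))])
    coef, *_ = np.linalg.lstsq(A, y_pm, rcond=None)
    return coef[:-1], float(coef[-1])


def separability_plane(scores: np.ndarray, labels: np.ndarray
                       ) -> SeparabilityResult:
    """Maximum-margin plane between two labeled point clouds in score space.

    A reproducible surrogate for drawing a separating plane by eye: if the
    classes are linearly separable a hard-margin separator is returned
    (margin = distance from the plane to the closest point); otherwise a
    least-squares discriminant with margin 0.  Leave-one-out accuracy is
    the reported separability score.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"exactly 2 label classes required, got {classes.size}")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 points per class")
    y_pm = np.where(y == classes[1], 1.0, -1.0)

    separable = _linearly_separable(X, y_pm)
    if separable:
        # hard-margin SVM is safe (and fast) once separability is certain
        svc = SVC(kernel="linear", C=1e9)
        svc.fit(X, y_pm)
        w = svc.coef_[0]
        b = float(svc.intercept_[0])
        margin = 1.0 / float(np.linalg.norm(w))

        def fit_predict(Xt, yt, xq):
            m = SVC(kernel="linear", C=1e9)
            m.fit(Xt, yt)
            return m.predict(xq[None, :])[0]

        loo = _loo_accuracy(X, y_pm, fit_predict)
    else:
        w, b = _lsq_discriminant(X, y_pm)
        margin = 0.0

        def fit_predict(Xt, yt, xq):
            wt, bt = _lsq_discriminant(Xt, yt)
            return np.sign(xq @ wt + bt) or 1.0

        loo = _loo_accuracy(X, y_pm, fit_predict)
    nrm = np.linalg.norm(w)
    if nrm > 0:
        b = b / nrm
        w = w / nrm
    return SeparabilityResult(normal=w, offset=float(b), margin=margin,
                              loo_accuracy=loo, separable=separable)


def mimo_stack(per_antenna_framesets: Sequence[LabeledFrameSet]
               ) -> LabeledFrameSet:
    """Concatenate per-antenna channel blocks into one MIMO frame set.

    Frame axes must match exactly; per-antenna blocks remain recoverable
    via ``select_antenna``.  E.g. two 22-coil antennas over 115 frames
    stack to a [115 x 44] matrix.
    """
    fsets = list(per_antenna_framesets)
    if not fsets:
        raise ValueError("no frame sets to stack")
    t0 = fsets[0].frame_times
    for fs in fsets[1:]:
        if fs.frame_times.shape != t0.shape or not np.allclose(fs.frame_times, t0):
            raise ValueError("frame axes do not match across antennas")
    mats = [fs.matrix for fs in fsets]
    ant = np.concatenate([
        fs.antenna_id if fs.antenna_id is not None
        else np.full(fs.n_channels, i)
        for i, fs in enumerate(fsets)
    ])
    labels = fsets[0].labels
    return LabeledFrameSet(np.concatenate(mats, axis=1), t0, labels, ant)
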