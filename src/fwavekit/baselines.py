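"""Template-based reference extractors: average beat subtraction and beat PCA.

Average beat subtraction (ABS) cancels ventricular activity by subtracting a
beat-averaged QRST template at each annotated R peak; it is the most common
single-lead F-wave extractor but leaves a large residue wherever a beat
deviates from the template (ectopic beats in particular).  Beat-stacking PCA
generalizes the template to a low-rank subspace: each beat window is
reconstructed from the leading principal components of the beat matrix and
the reconstruction subtracted.

Both methods consume explicit R-peak annotations (the simulator's ground
truth in benchmarks, isolating extractor quality from detector quality); a
simple amplitude-threshold detector is provided for external records.
Outside beat windows the signal passes through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from sklearn.base import BaseEstimator

__all__ = [
    "BeatMatrix",
    "stack_beats",
    "abs_extract",
    "pca_extract",
    "detect_r_peaks",
    "AverageBeatSubtraction",
    "BeatPCA",
]

#: Default beat window: 0.12 s before to 0.48 s after the R peak (covers QRST
#: at normal rates).
DEFAULT_WINDOW = (0.12, 0.48)


@dataclass
class BeatMatrix:
    """Beats stacked row-wise over a fixed window around each R peak."""

    beats: np.ndarray                 # (n_beats, window_samples)
    annotations: list[tuple[int, str]]  # in-bounds (R sample, beat type)
    pre_samples: int
    post_samples: int
    n_dropped: int                    # edge beats excluded


def _as_signal_and_annotations(record, annotations):
    x = np.asarray(getattr(record, "x", record), dtype=float)
    if annotations is None:
        annotations = getattr(record, "beat_annotations", None)
    if annotations is None:
        raise ValueError("no beat annotations given and record carries none")
    return x, list(annotations)


def stack_beats(
    record,
    annotations=None,
    window_pre_s: float = DEFAULT_WINDOW[0],
    window_post_s: float = DEFAULT_WINDOW[1],
    fs: float | None = None,
) -> BeatMatrix:
    """Extract fixed windows around each in-bounds R peak.

    ``record`` may be an ``AfRecord`` (annotations and ``fs`` taken from it)
    or a plain array with explicit ``annotations`` and ``fs``.
    """
    x, anns = _as_signal_and_annotations(record, annotations)
    fs = fs if fs is not None else getattr(record, "fs", None)
    if fs is None:
        raise ValueError("sampling rate unknown; pass fs")
    pre = int(round(window_pre_s * fs))
    post = int(round(window_post_s * fs))
    rows, kept = [], []
    dropped = 0
    for idx, btype in anns:
        if idx - pre < 0 or idx + post > len(x):
            dropped += 1
            continue
        rows.append(x[idx - pre : idx + post])
        kept.append((idx, btype))
    if len(rows) < 2:
        raise ValueError(f"need at least 2 usable beats, got {len(rows)}")
    return BeatMatrix(
        beats=np.vstack(rows),
        annotations=kept,
        pre_samples=pre,
        post_samples=post,
        n_dropped=dropped,
    )


def _subtract_reconstructions(x, bm: BeatMatrix, recon: np.ndarray) -> np.ndarray:
    est = x.copy()
    for (idx, _), row in zip(bm.annotations, recon):
        est[idx - bm.pre_samples : idx + bm.post_samples] -= row
    return est


def abs_extract(
    record,
    annotations=None,
    window_pre_s: float = DEFAULT_WINDOW[0],
    window_post_s: float = DEFAULT_WINDOW[1],
    fs: float | None = None,
    per_type_templates: bool = True,
    ls_scale: bool = True,
) -> np.ndarray:
    """F-wave estimate by average beat subtraction.

    A mean QRST template (per beat type unless ``per_type_templates`` is
    False, which reproduces the classic single-template failure mode on
    ectopic beats) is subtracted within each beat window, amplitude-matched
    per beat by least squares when ``ls_scale``.
    """
    x, anns = _as_signal_and_annotations(record, annotations)
    bm = stack_beats(record, anns, window_pre_s, window_post_s, fs)
    types = {t for _, t in bm.annotations} if per_type_templates else {None}
    recon = np.zeros_like(bm.beats)
    for btype in types:
        rows = (
            np.array([t == btype for _, t in bm.annotations])
            if btype is not None
            else np.ones(len(bm.beats), dtype=bool)
        )
        template = bm.beats[rows].mean(axis=0)
        denom = float(template @ template)
        for i in np.flatnonzero(rows):
            scale = float(bm.beats[i] @ template) / denom if (ls_scale and denom > 0) else 1.0
            recon[i] = scale * template
    return _subtract_reconstructions(x, bm, recon)


def pca_extract(
    record,
    annotations=None,
    window_pre_s: float = DEFAULT_WINDOW[0],
    window_post_s: float = DEFAULT_WINDOW[1],
    fs: float | None = None,
    n_components: int = 2,
) -> np.ndarray:
    """F-wave estimate by beat-stacking PCA QRST cancellation.

    Each beat is reconstructed as the beat-matrix mean plus its projection
    onto the ``n_components`` leading principal directions, and the
    reconstruction is subtracted within the beat window.
    """
    x, anns = _as_signal_and_annotations(record, annotations)
    bm = stack_beats(record, anns, window_pre_s, window_post_s, fs)
    if len(bm.beats) < n_components + 1:
        raise ValueError(
            f"need at least n_components+1={n_components + 1} beats, got {len(bm.beats)}"
        )
    mean = bm.beats.mean(axis=0)
    centered = bm.beats - mean
    # principal directions via SVD of the centered beat matrix
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    basis = vt[:n_components]
    recon = mean + (centered @ basis.T) @ basis
    return _subtract_reconstructions(x, bm, recon)


def detect_r_peaks(
    x: np.ndarray, fs: float, min_rr_s: float = 0.3, rel_height: float = 0.5
) -> list[tuple[int, str]]:
    """Simple amplitude-threshold R detector for externally supplied records.

    Peaks of ``|x - median|`` above ``rel_height`` times its maximum,
    separated by at least ``min_rr_s``.  All beats are labelled 'normal'.
    """
    x = np.asarray(x, dtype=float)
    mag = np.abs(x - np.median(x))
    peaks, _ = _signal.find_peaks(
        mag, height=rel_height * mag.max(), distance=int(min_rr_s * fs)
    )
    return [(int(p), "normal") for p in peaks]


class AverageBeatSubtraction(BaseEstimator):
    """Estimator wrapper around :func:`abs_extract` (stateless; fit is a no-op)."""

    def __init__(
        self,
        window_pre_s: float = DEFAULT_WINDOW[0],
        window_post_s: float = DEFAULT_WINDOW[1],
        per_type_templates: bool = True,
        ls_scale: bool = True,
    ):
        self.window_pre_s = window_pre_s
        self.window_post_s = window_post_s
        self.per_type_templates = per_type_templates
        self.ls_scale = ls_scale

    def fit(self, X=None, y=None):
        return self

    def extract(self, record, annotations=None, fs=None) -> np.ndarray:
        return abs_extract(
            record,
            annotations,
            self.window_pre_s,
            self.window_post_s,
            fs,
            self.per_type_templates,
            self.ls_scale,
        )


class BeatPCA(BaseEstimator):
    """Estimator wrapper around :func:`pca_extract` (stateless; fit is a no-op)."""

    def __init__(
        self,
        window_pre_s: float = DEFAULT_WINDOW[0],
        window_post_s: float = DEFAULT_WINDOW[1],
        n_components: int = 2,
    ):
        self.window_pre_s = window_pre_s
        self.window_post_s = window_post_s
        self.n_components = n_components

    def fit(self, X=None, y=None):
        return self

    def extract(self, record, annotations=None, fs=None) -> np.ndarray:
        return pca_extract(
            record,
            annotations,
            self.window_pre_s,
            self.window_post_s,
            fs,
            self.n_components,
        )
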