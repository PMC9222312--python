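"""Resonance-based signal decomposition (dual-Q morphological component analysis).

An ECG trace ``x`` is modelled as the sum of an oscillatory component that is
sparse in a high-Q TQWT dictionary (the sustained fibrillatory F-wave) and a
transient component sparse in a low-Q dictionary (the pulse-like QRST
complexes), by minimizing

    J(W1, W2) = ||x - S1 W1 - S2 W2||_2^2 + lambda1 ||W1||_1 + lambda2 ||W2||_1

where ``S_i`` are the synthesis (inverse-TQWT) operators.  The minimizer is
found with SALSA, an ADMM-type splitting in which the ℓ1 proximal step is
elementwise soft-thresholding and the data-consistency step is solved exactly
using the Parseval-frame identity ``S_i S_iᵀ = I``.

Two refinements make the split effective on AF ECG:

* per-subband thresholds are scaled by the synthesis-wavelet norms, so the
  ℓ1 penalty is uniform in signal units across scales;
* the oscillatory dictionary is restricted to subbands whose center
  frequency lies in a fibrillatory band (default 3-30 Hz: the 3-12 Hz
  F-wave band plus harmonic headroom).  Out-of-band oscillatory subbands
  carry infinite penalty (coefficients pinned at zero) and the oscillatory
  depth is capped at the band's lower edge, since by definition no
  fibrillatory oscillation lives below it.  Without this restriction the
  deep, weakly-penalized high-Q subbands absorb T waves and baseline
  content.  Set ``osc_band_hz=None`` for the unrestricted objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .tqwt import (
    TqwtParams,
    TqwtCoeffs,
    max_levels,
    subband_wavelet_norms,
    tqwt_forward,
    tqwt_inverse,
)

__all__ = [
    "DualQConfig",
    "DecompositionResult",
    "DictionarySpec",
    "soft_threshold",
    "objective",
    "decompose",
    "mca_salsa",
    "calibrate_regularization",
    "default_lambda_grid",
    "ResonanceDecomposer",
    "DEFAULT_Q_HIGH",
    "DEFAULT_Q_LOW",
]

#: Genetic-algorithm-optimized reference Q-factor pair (high-Q oscillatory
#: dictionary for the F-wave, low-Q transient dictionary for QRST).
DEFAULT_Q_HIGH = 6.42
DEFAULT_Q_LOW = 1.35


def level_center_frequencies(params: TqwtParams, fs: float) -> np.ndarray:
    """Approximate center frequency (Hz) of each subband's wavelet.

    Level-j high-pass wavelets are centered near ``alpha^(j-1) (2-beta) fs/4``;
    the final low-pass band is reported as 0 Hz.
    """
    a, b = params.alpha, params.beta
    f1 = (2.0 - b) * fs / 4.0
    fcs = f1 * a ** np.arange(params.J)
    return np.concatenate([fcs, [0.0]])


@dataclass
class DualQConfig:
    """Configuration of the dual-dictionary decomposition.

    ``lambda_osc``/``lambda_trn`` are in signal-amplitude units; ``j_high``/
    ``j_low`` default to the maximum usable depth (the oscillatory depth is
    additionally capped at the lower edge of ``osc_band_hz``).
    """

    q_high: float = DEFAULT_Q_HIGH
    q_low: float = DEFAULT_Q_LOW
    r: float = 3.0
    j_high: int | None = None
    j_low: int | None = None
    lambda_osc: float = 2.0
    lambda_trn: float = 1.5
    mu: float = 0.05
    n_iter: int = 250
    tol: float = 1e-6
    fs: float = 500.0
    osc_band_hz: tuple[float, float] | None = (3.0, 30.0)

    def __post_init__(self) -> None:
        if not (self.q_high > self.q_low >= 1.0):
            raise ValueError(
                f"need q_high > q_low >= 1, got ({self.q_high}, {self.q_low})"
            )
        if self.lambda_osc < 0 or self.lambda_trn < 0:
            raise ValueError("regularization weights must be >= 0")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    def params_for(self, N: int) -> tuple[TqwtParams, TqwtParams]:
        """Concrete TQWT parameter pair for a length-``N`` signal."""
        mh = max_levels(N, self.q_high, self.r)
        ml = max_levels(N, self.q_low, self.r)
        jh = mh if self.j_high is None else min(self.j_high, mh)
        jl = ml if self.j_low is None else min(self.j_low, ml)
        if self.j_high is None and self.osc_band_hz is not None:
            # one level past the band edge; deeper levels would be masked anyway
            p = TqwtParams(Q=self.q_high, r=self.r, J=mh)
            fcs = level_center_frequencies(p, self.fs)[:-1]
            jh = min(jh, max(1, int(np.sum(fcs >= self.osc_band_hz[0])) + 1))
        return (
            TqwtParams(Q=self.q_high, r=self.r, J=jh),
            TqwtParams(Q=self.q_low, r=self.r, J=jl),
        )


@dataclass(frozen=True)
class DictionarySpec:
    """One dictionary of the symmetric MCA core: TQWT bank + penalty.

    ``thresholds`` holds the per-subband SALSA shrinkage thresholds
    (``lambda * wavelet_norm / (2 mu)``); a non-finite threshold pins the
    subband's coefficients at zero (infinite penalty).
    """

    params: TqwtParams
    lam: float
    thresholds: tuple[float, ...]
    norms: tuple[float, ...]


def _make_spec(
    params: TqwtParams,
    lam: float,
    N: int,
    mu: float,
    fs: float,
    band: tuple[float, float] | None,
) -> DictionarySpec:
    norms = subband_wavelet_norms(params, N)
    thr = lam * norms / (2.0 * mu)
    if band is not None:
        fcs = level_center_frequencies(params, fs)
        thr = np.where((fcs < band[0]) | (fcs > band[1]), np.inf, thr)
    return DictionarySpec(
        params=params, lam=lam, thresholds=tuple(thr), norms=tuple(norms)
    )


@dataclass
class DecompositionResult:
    """Outcome of one dual-Q decomposition.

    ``x_osc + x_trn + residual`` reconstructs the input exactly by
    construction; ``objective_trace`` holds the per-iteration objective.
    """

    x_osc: np.ndarray
    x_trn: np.ndarray
    residual: np.ndarray
    objective_trace: np.ndarray
    coeffs_osc: TqwtCoeffs
    coeffs_trn: TqwtCoeffs
    config: DualQConfig | None = field(repr=False, default=None)


def soft_threshold(w, t):
    """Elementwise soft-thresholding ``sign(w) * max(|w| - t, 0)``.

    ``t`` may be a scalar or broadcastable array of non-negative thresholds;
    an infinite threshold maps everything to zero.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("threshold must be non-negative")
    w = np.asarray(w, dtype=float)
    # |w| - inf = -inf, so an infinite threshold yields 0 without special-casing
    return np.sign(w) * np.maximum(np.abs(w) - t, 0.0)


def _l1_weighted(coeffs: TqwtCoeffs, lam: float, norms) -> float:
    return float(
        sum(lam * nj * np.sum(np.abs(b)) for b, nj in zip(coeffs.subbands, norms))
    )


def objective(
    x: np.ndarray,
    coeffs_osc: TqwtCoeffs,
    coeffs_trn: TqwtCoeffs,
    cfg: DualQConfig,
    norms_osc=None,
    norms_trn=None,
) -> float:
    """Evaluate the MCA objective for a candidate coefficient pair."""
    x = np.asarray(x, dtype=float)
    if coeffs_osc.original_length != len(x) or coeffs_trn.original_length != len(x):
        raise ValueError("coefficient sets inconsistent with signal length")
    if norms_osc is None:
        norms_osc = subband_wavelet_norms(coeffs_osc.params, len(x))
    if norms_trn is None:
        norms_trn = subband_wavelet_norms(coeffs_trn.params, len(x))
    resid = x - tqwt_inverse(coeffs_osc) - tqwt_inverse(coeffs_trn)
    return (
        float(np.sum(resid * resid))
        + _l1_weighted(coeffs_osc, cfg.lambda_osc, norms_osc)
        + _l1_weighted(coeffs_trn, cfg.lambda_trn, norms_trn)
    )


def _clone(c: TqwtCoeffs, subbands) -> TqwtCoeffs:
    return TqwtCoeffs(
        subbands=list(subbands),
        params=c.params,
        original_length=c.original_length,
        padded=c.padded,
    )


def _shrink(wb: np.ndarray, db: np.ndarray, t: float) -> np.ndarray:
    if not np.isfinite(t):
        return -db
    return np.sign(wb + db) * np.maximum(np.abs(wb + db) - t, 0.0) - db


def mca_salsa(
    x: np.ndarray,
    spec_a: DictionarySpec,
    spec_b: DictionarySpec,
    mu: float,
    n_iter: int,
    tol: float = 0.0,
) -> tuple[TqwtCoeffs, TqwtCoeffs, np.ndarray]:
    """Symmetric SALSA core: minimize the two-dictionary MCA objective.

    Returns the two coefficient sets and the per-iteration objective trace.
    Swapping ``spec_a`` and ``spec_b`` swaps the roles of the outputs.
    """
    x = np.asarray(x, dtype=float)
    w1 = tqwt_forward(x, spec_a.params)
    w2 = tqwt_forward(x, spec_b.params)
    d1 = [np.zeros_like(b) for b in w1.subbands]
    d2 = [np.zeros_like(b) for b in w2.subbands]

    fin_a = [t if np.isfinite(t) else 0.0 for t in spec_a.thresholds]
    fin_b = [t if np.isfinite(t) else 0.0 for t in spec_b.thresholds]

    def _obj(c1: TqwtCoeffs, c2: TqwtCoeffs) -> float:
        resid = x - tqwt_inverse(c1) - tqwt_inverse(c2)
        # masked subbands hold zeros, so their (infinite-weight) penalty is 0
        pen = sum(
            2.0 * mu * t * np.sum(np.abs(b))
            for b, t in zip(c1.subbands, fin_a)
        ) + sum(
            2.0 * mu * t * np.sum(np.abs(b))
            for b, t in zip(c2.subbands, fin_b)
        )
        return float(np.sum(resid * resid) + pen)

    trace = []
    prev = np.inf
    for _ in range(n_iter):
        u1 = [_shrink(wb, db, t) for wb, db, t in zip(w1.subbands, d1, spec_a.thresholds)]
        u2 = [_shrink(wb, db, t) for wb, db, t in zip(w2.subbands, d2, spec_b.thresholds)]
        c = x - tqwt_inverse(_clone(w1, u1)) - tqwt_inverse(_clone(w2, u2))
        c /= mu + 2.0
        d1 = tqwt_forward(c, spec_a.params).subbands
        d2 = tqwt_forward(c, spec_b.params).subbands
        w1 = _clone(w1, [db + ub for db, ub in zip(d1, u1)])
        w2 = _clone(w2, [db + ub for db, ub in zip(d2, u2)])
        obj = _obj(w1, w2)
        trace.append(obj)
        if prev < np.inf and abs(prev - obj) <= tol * max(abs(prev), 1e-30):
            break
        prev = obj
    return w1, w2, np.asarray(trace)


def decompose(x: np.ndarray, cfg: DualQConfig | None = None) -> DecompositionResult:
    """Split ``x`` into oscillatory (F-wave) and transient (QRST) components.

    Runs SALSA for ``cfg.n_iter`` iterations or until the relative objective
    change drops below ``cfg.tol``.  Non-convergence is not an error; inspect
    ``objective_trace``.
    """
    if cfg is None:
        cfg = DualQConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 64:
        raise ValueError("x must be a 1-D signal with at least 64 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite samples")

    p_osc, p_trn = cfg.params_for(len(x))
    spec_osc = _make_spec(p_osc, cfg.lambda_osc, len(x), cfg.mu, cfg.fs, cfg.osc_band_hz)
    spec_trn = _make_spec(p_trn, cfg.lambda_trn, len(x), cfg.mu, cfg.fs, None)
    w1, w2, trace = mca_salsa(x, spec_osc, spec_trn, cfg.mu, cfg.n_iter, cfg.tol)

    x_osc = tqwt_inverse(w1)
    x_trn = tqwt_inverse(w2)
    return DecompositionResult(
        x_osc=x_osc,
        x_trn=x_trn,
        residual=x - x_osc - x_trn,
        objective_trace=trace,
        coeffs_osc=w1,
        coeffs_trn=w2,
        config=cfg,
    )


def default_lambda_grid(signal_rms: float, n: int = 4) -> list[tuple[float, float]]:
    """Logarithmic (lambda_osc, lambda_trn) ladder spanning 0.01-1 x RMS."""
    ladder = signal_rms * np.logspace(-2, 0, n)
    return [(float(lo), float(lt)) for lo in ladder for lt in ladder]


def calibrate_regularization(
    records: Sequence,
    grid: Sequence[tuple[float, float]],
    cfg_base: DualQConfig,
) -> tuple[float, float]:
    """Pick the (lambda_osc, lambda_trn) grid pair minimizing mean NMSE.

    ``records`` must carry ground truth (``AfRecord`` with ``fwave_truth``);
    the experimental grid search mirrors how the regularization weights are
    chosen in practice when simulated truth is available.  Deterministic
    given inputs (ties break toward the earlier grid entry).
    """
    from .metrics import nmse

    if len(grid) == 0:
        raise ValueError("empty regularization grid")
    if len(records) == 0:
        raise ValueError("no calibration records")
    best, best_score = None, np.inf
    for lo, lt in grid:
        cfg = replace(cfg_base, lambda_osc=lo, lambda_trn=lt)
        score = float(
            np.mean(
                [nmse(rec.fwave_truth, decompose(rec.x, cfg).x_osc) for rec in records]
            )
        )
        if score < best_score:
            best, best_score = (lo, lt), score
    return best


class ResonanceDecomposer(BaseEstimator, TransformerMixin):
    """Scikit-learn style F-wave extractor.

    ``transform(X)`` maps each row of ``X`` (one trace per row, equal
    lengths) to its oscillatory-component estimate, i.e. the extracted
    F-wave.  Use :meth:`decompose` for the full result on a single trace.

    Parameters mirror :class:`DualQConfig`.

    Attributes
    ----------
    j_high_, j_low_ : int
        Dictionary depths resolved for the fitted signal length.
    n_samples_ : int
        Signal length seen during :meth:`fit`.
    """

    def __init__(
        self,
        q_high: float = DEFAULT_Q_HIGH,
        q_low: float = DEFAULT_Q_LOW,
        r: float = 3.0,
        j_high: int | None = None,
        j_low: int | None = None,
        lambda_osc: float = 2.0,
        lambda_trn: float = 1.5,
        mu: float = 0.05,
        n_iter: int = 250,
        tol: float = 1e-6,
        fs: float = 500.0,
        osc_band_hz: tuple[float, float] | None = (3.0, 30.0),
    ):
        self.q_high = q_high
        self.q_low = q_low
        self.r = r
        self.j_high = j_high
        self.j_low = j_low
        self.lambda_osc = lambda_osc
        self.lambda_trn = lambda_trn
        self.mu = mu
        self.n_iter = n_iter
        self.tol = tol
        self.fs = fs
        self.osc_band_hz = osc_band_hz

    def _config(self) -> DualQConfig:
        return DualQConfig(
            q_high=self.q_high,
            q_low=self.q_low,
            r=self.r,
            j_high=self.j_high,
            j_low=self.j_low,
            lambda_osc=self.lambda_osc,
            lambda_trn=self.lambda_trn,
            mu=self.mu,
            n_iter=self.n_iter,
            tol=self.tol,
            fs=self.fs,
            osc_band_hz=self.osc_band_hz,
        )

    def fit(self, X, y=None):
        X = self._validate(X)
        cfg = self._config()
        p_osc, p_trn = cfg.params_for(X.shape[1])
        self.j_high_ = p_osc.J
        self.j_low_ = p_trn.J
        self.n_samples_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Extracted F-wave (oscillatory component) per row of ``X``."""
        X = self._validate(X)
        cfg = self._config()
        return np.vstack([decompose(row, cfg).x_osc for row in X])

    def decompose(self, x) -> DecompositionResult:
        """Full decomposition of a single 1-D trace."""
        return decompose(np.asarray(x, dtype=float), self._config())

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2:
            raise ValueError("X must be a 1-D trace or a 2-D (n_traces, n_samples) array")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite samples")
        return X
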