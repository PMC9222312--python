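"""Simulated atrial-fibrillation ECG with ground truth.

Atrial activity follows the harmonic sawtooth F-wave model: a fundamental at
``f0`` with ``M-1`` harmonics, slow sinusoidal frequency modulation
(deviation ``delta_f`` at rate ``ff``) and sinusoidal amplitude modulation of
the common envelope,

    x_f(n) = sum_{m=1..M} a_m(n) sin(m w0 n + (delta_f/ff) sin(wf n)),
    a_m(n) = (2/(m pi)) (a + delta_a sin(wa n)),

with all angular frequencies per sample (w = 2 pi f / fs).  Three standard
parameter sets (types A, B, C; fundamental 4, 8, 12 Hz) with per-lead
amplitudes for leads II, V1, V5 are provided.

Ventricular activity is a *synthetic* surrogate built from Gaussian
sub-waves (Q, R, S, T; no P wave, as in AF): R peaks are placed at irregular
RR intervals and each beat contributes a QRST template, with ventricular
premature beats (PVCs) drawn as wide, large-amplitude biphasic complexes
without a T wave.  It stands in for clinical sinus-rhythm recordings, which
are not distributable; see docs/methods.md for what this surrogate does and
does not emulate.

The composite record keeps every part (F-wave truth, ventricular, noise)
so extraction error can be measured exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "FwaveModelParams",
    "VentricularConfig",
    "AfRecord",
    "FWAVE_TYPES",
    "LEADS",
    "make_fwave_params",
    "gen_fwave",
    "gen_ventricular",
    "add_noise",
    "compose_record",
]

LEADS = ("II", "V1", "V5")


@dataclass(frozen=True)
class FwaveModelParams:
    """Sawtooth F-wave model parameters (amplitudes in µV)."""

    f0: float            # fundamental frequency, Hz
    delta_f: float       # frequency deviation, Hz
    ff: float            # frequency-modulation frequency, Hz
    M: int               # number of harmonics (fundamental included)
    a: float             # base amplitude, µV
    delta_a: float       # amplitude-modulation depth, µV
    fa: float            # amplitude-modulation frequency, Hz
    fs: float = 500.0    # sampling rate, Hz
    polarity: int = 1    # +1 per the positive-sum convention; -1 flips

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.M < 1 or self.a <= 0 or self.delta_a < 0:
            raise ValueError("invalid F-wave parameters")
        if self.M * self.f0 >= self.fs / 2:
            raise ValueError(
                f"aliasing: M*f0 = {self.M * self.f0} Hz >= Nyquist {self.fs / 2} Hz"
            )


# Per-type model constants; amplitude triplets are per lead (II, V1, V5).
# ff is not part of the published parameter table; 0.1 Hz is the sawtooth-
# model convention and is configurable via make_fwave_params.
_TYPE_TABLE = {
    "A": dict(f0=4.0, delta_f=0.2, M=3, a=(60.0, 50.0, 40.0), delta_a=(50.0, 25.0, 15.0), fa=0.08),
    "B": dict(f0=8.0, delta_f=0.3, M=5, a=(60.0, 50.0, 40.0), delta_a=(18.0, 15.0, 12.0), fa=0.5),
    "C": dict(f0=12.0, delta_f=0.3, M=5, a=(60.0, 50.0, 40.0), delta_a=(25.0, 15.0, 10.0), fa=0.5),
}
FWAVE_TYPES = tuple(_TYPE_TABLE)


def make_fwave_params(
    ftype: str, lead: str = "II", fs: float = 500.0, ff: float = 0.1
) -> FwaveModelParams:
    """F-wave parameters for a named type ('A'|'B'|'C') and lead."""
    if ftype not in _TYPE_TABLE:
        raise ValueError(f"unknown F-wave type {ftype!r}; choose from {FWAVE_TYPES}")
    if lead not in LEADS:
        raise ValueError(f"unknown lead {lead!r}; choose from {LEADS}")
    t = _TYPE_TABLE[ftype]
    i = LEADS.index(lead)
    return FwaveModelParams(
        f0=t["f0"], delta_f=t["delta_f"], ff=ff, M=t["M"],
        a=t["a"][i], delta_a=t["delta_a"][i], fa=t["fa"], fs=fs,
    )


def gen_fwave(params: FwaveModelParams, n_samples: int) -> np.ndarray:
    """Deterministic sawtooth-model F-wave, length ``n_samples``, in µV."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n = np.arange(n_samples)
    fs = params.fs
    w0 = 2.0 * np.pi * params.f0 / fs
    wf = 2.0 * np.pi * params.ff / fs
    wa = 2.0 * np.pi * params.fa / fs
    fm = (params.delta_f / params.ff) * np.sin(wf * n)
    env = params.a + params.delta_a * np.sin(wa * n)
    x = np.zeros(n_samples)
    for m in range(1, params.M + 1):
        x += (2.0 / (m * np.pi)) * env * np.sin(m * w0 * n + fm)
    return params.polarity * x


@dataclass(frozen=True)
class VentricularConfig:
    """Synthetic ventricular-activity generator settings (amplitudes in µV)."""

    fs: float = 500.0
    mean_rr_s: float = 0.75      # mean RR interval; AF is irregular
    rr_jitter_s: float = 0.08    # SD of independent RR jitter
    pvc_prob: float = 0.0        # per-beat probability of a PVC
    r_amp: float = 1000.0        # nominal R-wave amplitude
    amp_jitter: float = 0.03     # relative per-beat amplitude variability

    def __post_init__(self) -> None:
        if self.mean_rr_s <= 0 or self.rr_jitter_s < 0:
            raise ValueError("invalid RR parameters")
        if not 0.0 <= self.pvc_prob <= 1.0:
            raise ValueError("pvc_prob must be in [0, 1]")


# Gaussian sub-waves (relative amplitude, center offset s, width s) for a
# normal QRST (no P wave in AF) and a wide biphasic PVC without a T wave.
_NORMAL_WAVES = (
    (-0.12, -0.035, 0.012),   # Q
    (1.00, 0.000, 0.011),     # R
    (-0.25, 0.035, 0.013),    # S
    (0.25, 0.300, 0.070),     # T
)
_PVC_WAVES = (
    (1.30, 0.000, 0.030),
    (-0.70, 0.060, 0.035),
)


def gen_ventricular(
    duration_s: float,
    fs: float = 500.0,
    mean_rr_s: float = 0.75,
    rr_jitter_s: float = 0.08,
    pvc_prob: float = 0.0,
    seed: int | None = None,
    r_amp: float = 1000.0,
    amp_jitter: float = 0.03,
) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Synthetic ventricular signal plus (R-sample, beat-type) annotations."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    cfg = VentricularConfig(
        fs=fs, mean_rr_s=mean_rr_s, rr_jitter_s=rr_jitter_s,
        pvc_prob=pvc_prob, r_amp=r_amp, amp_jitter=amp_jitter,
    )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    annotations: list[tuple[int, str]] = []

    # R times: walk forward with independent jitter per interval
    r_time = 0.4 + rng.normal(0.0, rr_jitter_s)
    while r_time < duration_s - 0.05:
        is_pvc = rng.random() < pvc_prob
        scale = cfg.r_amp * (1.0 + cfg.amp_jitter * rng.standard_normal())
        waves = _PVC_WAVES if is_pvc else _NORMAL_WAVES
        for rel_amp, center, width in waves:
            x += rel_amp * scale * np.exp(-0.5 * ((t - (r_time + center)) / width) ** 2)
        idx = int(round(r_time * fs))
        if 0 <= idx < n:
            annotations.append((idx, "pvc" if is_pvc else "normal"))
        rr = cfg.mean_rr_s + rng.normal(0.0, cfg.rr_jitter_s)
        r_time += max(rr, 0.3)  # refractory floor
    return x, annotations


def add_noise(
    n_samples: int, mean_abs_amplitude: float, seed: int | None = None
) -> np.ndarray:
    """Zero-mean Gaussian noise with E|noise| = ``mean_abs_amplitude`` (µV).

    The mean absolute amplitude convention maps to sigma via
    ``sigma = mean_abs * sqrt(pi/2)`` (half-normal mean identity).
    """
    if mean_abs_amplitude < 0:
        raise ValueError("mean_abs_amplitude must be >= 0")
    if mean_abs_amplitude == 0:
        return np.zeros(n_samples)
    sigma = mean_abs_amplitude * math.sqrt(math.pi / 2.0)
    return np.random.default_rng(seed).normal(0.0, sigma, n_samples)


@dataclass
class AfRecord:
    """Composite simulated AF-ECG with ground-truth parts (all µV)."""

    x: np.ndarray
    fwave_truth: np.ndarray
    ventricular: np.ndarray
    noise: np.ndarray
    fs: float
    beat_annotations: list[tuple[int, str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return len(self.x) / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.x)) / self.fs


def compose_record(
    fparams: FwaveModelParams,
    vent_cfg: VentricularConfig | None = None,
    noise_level: float = 0.0,
    duration_s: float = 10.0,
    seed: int | None = None,
) -> AfRecord:
    """Simulate one AF-ECG record: F-wave + ventricular + noise.

    ``noise_level`` is the mean absolute noise amplitude in µV.  All
    randomness derives from ``seed`` (sub-streams for beats and noise), so a
    fixed seed reproduces the record exactly.
    """
    if vent_cfg is None:
        vent_cfg = VentricularConfig(fs=fparams.fs)
    if vent_cfg.fs != fparams.fs:
        raise ValueError(
            f"sampling-rate mismatch: F-wave fs={fparams.fs}, ventricular fs={vent_cfg.fs}"
        )
    n = int(round(duration_s * fparams.fs))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_vent, seed_noise = ss.spawn(2)
    fwave = gen_fwave(fparams, n)
    vent, annotations = gen_ventricular(
        duration_s,
        fs=vent_cfg.fs,
        mean_rr_s=vent_cfg.mean_rr_s,
        rr_jitter_s=vent_cfg.rr_jitter_s,
        pvc_prob=vent_cfg.pvc_prob,
        seed=seed_vent,
        r_amp=vent_cfg.r_amp,
        amp_jitter=vent_cfg.amp_jitter,
    )
    noise = add_noise(n, noise_level, seed=seed_noise)
    return AfRecord(
        x=fwave + vent + noise,
        fwave_truth=fwave,
        ventricular=vent,
        noise=noise,
        fs=fparams.fs,
        beat_annotations=annotations,
        provenance={
            "fwave": asdict(fparams),
            "ventricular": asdict(vent_cfg),
            "noise_level": noise_level,
            "duration_s": duration_s,
            "seed": seed if isinstance(seed, (int, type(None))) else repr(seed),
        },
    )
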