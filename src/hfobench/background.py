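"""Channel-specific autoregressive background models.

SEEG background activity is modeled per channel as a stable all-pole (AR)
filter driven by Gaussian white noise.  Models are fitted on marked baseline
segments with the autocorrelation (Levinson-Durbin / LPC) method, averaged
over segments of the same channel, and then used to synthesize arbitrarily
many statistically identical background realizations.

Coefficient convention: the prediction-error filter
A(z) = 1 + a[0] z^-1 + ... + a[p-1] z^-p, so synthesis is 1/A(z) applied to
white noise of SD ``gain``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from statsmodels.regression.linear_model import yule_walker

__all__ = [
    "BaselineSegment",
    "ARBackgroundModel",
    "estimate_ar",
    "average_ar",
    "synthesize_background",
    "ar_psd",
    "pole_model",
    "low_hf_model",
    "high_hf_model",
]

DEFAULT_AR_ORDER = 30  # at fs = 2048 Hz: spectral slope plus rhythms up to ~500 Hz
POLE_SHRINK_RADIUS = 0.98


@dataclass
class BaselineSegment:
    """A marked stretch of event-free background from one channel."""

    channel_id: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"segment {self.channel_id!r} contains NaN/Inf")
        if self.samples.size < 2 * self.fs:
            raise ValueError(
                f"segment {self.channel_id!r} shorter than 2 s "
                f"({self.samples.size / self.fs:.2f} s); AR fit would be unstable"
            )


@dataclass
class ARBackgroundModel:
    """AR coefficients + innovation gain: the statistical identity of a channel."""

    channel_id: str
    order: int
    coeffs: np.ndarray  # a[1..p] of A(z), leading 1 implicit
    gain: float  # innovation SD, signal units
    fs: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.size != self.order:
            raise ValueError("coefficient count must equal the model order")
        if self.gain <= 0:
            raise ValueError("innovation gain must be positive")

    @property
    def a_full(self) -> np.ndarray:
        """Denominator polynomial [1, a1, ..., ap]."""
        return np.concatenate(([1.0], self.coeffs))

    def poles(self) -> np.ndarray:
        if self.order == 0:
            return np.empty(0, dtype=complex)
        return np.roots(self.a_full)

    def is_stable(self, tol: float = 0.0) -> bool:
        p = self.poles()
        return bool(p.size == 0 or np.max(np.abs(p)) < 1.0 - tol)

    def to_dict(self) -> dict:
        return {
            "channel_id": self.channel_id,
            "order": int(self.order),
            "coeffs": self.coeffs.tolist(),
            "gain": float(self.gain),
            "fs": float(self.fs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ARBackgroundModel":
        return cls(
            channel_id=d["channel_id"],
            order=int(d["order"]),
            coeffs=np.asarray(d["coeffs"], dtype=float),
            gain=float(d["gain"]),
            fs=float(d["fs"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ARBackgroundModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def estimate_ar(segment: BaselineSegment, order: int = DEFAULT_AR_ORDER) -> ARBackgroundModel:
    """Fit an AR model to a baseline segment by the autocorrelation method.

    The segment mean is removed before fitting.  Levinson-Durbin on the
    biased autocorrelation (the LPC convention) yields the prediction
    coefficients and the innovation variance, so the model's integrated PSD
    matches the segment variance by construction.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    x = segment.samples
    if x.size <= 10 * order:
        raise ValueError(
            f"segment {segment.channel_id!r} too short for order {order}: "
            f"{x.size} samples <= 10 x order"
        )
    x = x - x.mean()
    if np.allclose(x, 0.0):
        raise ValueError(f"segment {segment.channel_id!r} has zero variance")
    try:
        # method="mle" = biased autocorrelation, i.e. the Levinson-Durbin/LPC route
        rho, sigma = yule_walker(x, order=order, method="mle")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - hard to trigger
        raise ValueError(
            f"autocorrelation matrix singular for segment {segment.channel_id!r}"
        ) from exc
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError(f"degenerate innovation variance for {segment.channel_id!r}")
    # yule_walker convention: x[n] = sum rho_i x[n-i] + e  ->  a_i = -rho_i
    return ARBackgroundModel(
        channel_id=segment.channel_id,
        order=order,
        coeffs=-rho,
        gain=float(sigma),
        fs=segment.fs,
    )


def _stabilize(a_full: np.ndarray, radius: float = POLE_SHRINK_RADIUS) -> np.ndarray:
    """Radially shrink poles with modulus >= 1 to the given radius."""
    poles = np.roots(a_full)
    mods = np.abs(poles)
    if poles.size == 0 or np.max(mods) < 1.0:
        return a_full
    poles = np.where(mods >= 1.0, poles / mods * radius, poles)
    return np.real(np.poly(poles))


def average_ar(models: list[ARBackgroundModel]) -> ARBackgroundModel:
    """Average per-segment AR fits of one channel into a single model.

    Coefficients and gains are averaged element-wise.  Averaging is not
    stability-preserving, so the result is re-checked and, if needed, poles
    at or beyond the unit circle are radially shrunk to modulus 0.98 (with a
    warning).
    """
    if not models:
        raise ValueError("cannot average an empty model list")
    first = models[0]
    for m in models[1:]:
        if m.order != first.order or m.fs != first.fs:
            raise ValueError("all models must share order and sampling rate")
        if m.channel_id != first.channel_id:
            raise ValueError("all models must belong to the same channel")
    coeffs = np.mean([m.coeffs for m in models], axis=0)
    gain = float(np.mean([m.gain for m in models]))
    avg = ARBackgroundModel(first.channel_id, first.order, coeffs, gain, first.fs)
    if not avg.is_stable():
        warnings.warn(
            f"averaged AR model for channel {first.channel_id!r} unstable; "
            f"shrinking poles to radius {POLE_SHRINK_RADIUS}",
            stacklevel=2,
        )
        a_full = _stabilize(avg.a_full)
        avg = ARBackgroundModel(first.channel_id, first.order, a_full[1:], gain, first.fs)
    return avg


def synthesize_background(
    model: ARBackgroundModel, duration_s: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Generate one stationary realization of the model's background process.

    Gaussian white noise of SD ``gain`` is filtered by 1/A(z); a burn-in of
    10 x order samples is generated and discarded so the output carries no
    start-up transient.  Identical (model, seed) pairs give identical output.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not model.is_stable():
        raise ValueError(f"model for channel {model.channel_id!r} is unstable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * model.fs))
    burn = 10 * model.order
    e = rng.normal(0.0, model.gain, size=n + burn)
    if model.order == 0:
        return e[burn:]
    y = sp_signal.lfilter([1.0], model.a_full, e)
    return y[burn:]


def ar_psd(model: ARBackgroundModel, freqs_hz) -> np.ndarray:
    """Theoretical power spectrum gain^2 / |A(e^{j 2 pi f / fs})|^2."""
    f = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if np.any(f < 0) or np.any(f >= model.fs / 2):
        raise ValueError("frequencies must lie in [0, fs/2)")
    w = 2.0 * np.pi * f / model.fs
    # A(e^{jw}) = 1 + sum a_k e^{-jkw}
    k = np.arange(1, model.order + 1)
    a_resp = 1.0 + (model.coeffs[None, :] * np.exp(-1j * np.outer(w, k))).sum(axis=1)
    return model.gain**2 / np.abs(a_resp) ** 2


# ---------------------------------------------------------------------------
# Synthetic channel models by pole placement
# ---------------------------------------------------------------------------


def ar_from_psd(
    psd: np.ndarray, channel_id: str, order: int = DEFAULT_AR_ORDER, fs: float = 2048.0
) -> ARBackgroundModel:
    """Fit an AR model to a target power spectrum (Yule-Walker on its exact
    autocorrelation).

    ``psd`` is sampled on ``np.fft.rfftfreq(n, 1/fs)`` in the per-sample
    variance convention (a flat value c means white noise of variance c).
    Used to build synthetic channels whose spectrum combines shaped (pole)
    components with a flat measurement-noise floor, the way an AR fit to a
    real recording would.
    """
    from scipy.linalg import solve_toeplitz

    psd = np.asarray(psd, dtype=float)
    n = 2 * (psd.size - 1)
    r = np.fft.irfft(psd, n)[: order + 1]
    rho = solve_toeplitz(r[:order], r[1 : order + 1])
    gain_sq = r[0] - rho @ r[1 : order + 1]
    if gain_sq <= 0:
        raise ValueError("target spectrum yields a non-positive innovation variance")
    model = ARBackgroundModel(channel_id, order, -rho, float(np.sqrt(gain_sq)), fs)
    if not model.is_stable():  # pragma: no cover - YW on a valid PSD is stable
        raise ValueError("AR fit to target spectrum is unstable")
    return model


def pole_model(
    channel_id: str,
    pole_freqs_hz: list[float],
    pole_moduli: list[float],
    gain: float = 1.0,
    fs: float = 2048.0,
) -> ARBackgroundModel:
    """Build an AR model from conjugate pole pairs (real pole if freq is 0).

    The workhorse for constructing fully synthetic channels with a chosen
    spectral profile: poles near DC shape the 1/f-like slope, a resonant
    pair inside 80-500 Hz creates semi-continuous high-frequency activity.
    """
    poles: list[complex] = []
    for f0, r in zip(pole_freqs_hz, pole_moduli, strict=True):
        if not 0 <= r < 1:
            raise ValueError("pole modulus must be in [0, 1)")
        if f0 == 0:
            poles.append(complex(r))
        else:
            w = 2.0 * np.pi * f0 / fs
            poles.extend([r * np.exp(1j * w), r * np.exp(-1j * w)])
    a_full = np.real(np.poly(poles))
    return ARBackgroundModel(channel_id, a_full.size - 1, a_full[1:], gain, fs)


def _shaped_plus_floor(
    shaped: ARBackgroundModel, channel_id: str, floor_at_hz: float, fs: float
) -> ARBackgroundModel:
    """AR(30) whose spectrum is the shaped model's plus a flat noise floor
    pinned at the shaped spectrum's level at ``floor_at_hz``."""
    n = 8192
    f = np.fft.rfftfreq(n, 1.0 / fs)
    f = np.minimum(f, fs / 2 - 1e-9)
    target = ar_psd(shaped, f) + ar_psd(shaped, [floor_at_hz])[0]
    return ar_from_psd(target, channel_id, fs=fs)


def low_hf_model(channel_id: str = "lowHF", fs: float = 2048.0) -> ARBackgroundModel:
    """1/f-like background with modest power in the 80-500 Hz band.

    Two real poles near DC give a 1/f-like spectrum with log-log slope about
    -3 over 10-500 Hz (typical of bipolar SEEG) and a weak broad resonance
    keeps the HFO band alive; a flat measurement-noise floor takes over
    above ~500 Hz, as it would in any real recording.
    """
    shaped = pole_model(channel_id, [0.0, 0.0, 120.0], [0.98, 0.50, 0.35], fs=fs)
    return _shaped_plus_floor(shaped, channel_id, 500.0, fs)


def high_hf_model(channel_id: str = "highHF", fs: float = 2048.0) -> ARBackgroundModel:
    """Background with strong semi-continuous high-frequency activity.

    A sharp resonance inside the ripple band (decay time ~20 ms, i.e.
    sustained visible rhythmicity) plus a secondary fast-ripple-band
    resonance elevate the whole 80-500 Hz range, mimicking mesial-temporal
    channels whose semi-continuous activity defeats baseline-hunting
    detector stages; the same measurement-noise floor applies above the
    band.
    """
    shaped = pole_model(
        channel_id, [0.0, 0.0, 140.0, 320.0], [0.98, 0.50, 0.975, 0.965], fs=fs
    )
    return _shaped_plus_floor(shaped, channel_id, 450.0, fs)
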