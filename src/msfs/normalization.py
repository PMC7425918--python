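"""Stage 1 normalization bank: ten amplitude normalizations plus the FFT.

Five conventional methods act on each record in isolation (Decimal Scaling,
Z-score, Linear Scaling, Min-Max) or with dataset-global statistics
(Mean & Standard Deviation).  Five "relative voltage" methods compare each
record against a reference signal computed from tumor-free records; they exist
to cancel the slow additive baseline drift that contaminates raw acquisitions.
All ten are element-wise and dimension-preserving.

Formulas for the relative family (this package's definitions, chosen to be
element-wise, reference-based and drift/scale-correcting):

- RV    : v - v_ref
- FVC   : (v - v_ref) / (|v_ref| + eps)
- RLV   : log10((|v| + eps) / (|v_ref| + eps))
- RSSV  : (v - v_ref)*|v - v_ref| / sum(v_ref**2)   (sign-preserving)
- RLSSV : log10(((v - v_ref)**2 + eps) / sum(v_ref**2))
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .phantom import SignalSet

NORMALIZATION_METHODS = ("DS", "ZS", "LS", "MM", "MSD", "RLSSV", "RLV", "RV", "FVC", "RSSV")
#: Methods that require a tumor-free reference signal.
REFERENCE_METHODS = frozenset({"RLSSV", "RLV", "RV", "FVC", "RSSV"})

EPS_GUARD = 1e-12


@dataclass
class ReferenceSignal:
    """Element-wise mean of tumor-free amplitude vectors."""

    amplitude: np.ndarray


@dataclass
class NormalizedSet:
    """One normalized dataset: method name, record matrix and class labels."""

    method_name: str
    matrix: np.ndarray
    labels: np.ndarray
    reference_used: bool


def to_frequency(signal: np.ndarray) -> np.ndarray:
    """One-sided magnitude spectrum (|rFFT|, length n//2 + 1) of the last axis."""
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] == 0:
        raise ValueError("cannot transform an empty signal")
    return np.abs(np.fft.rfft(signal, axis=-1))


def compute_reference(signal_set: SignalSet) -> ReferenceSignal:
    """Mean tumor-free signal, the baseline for the relative methods."""
    rows = [r.amplitude for r in signal_set.records if r.size_mm == 0]
    if not rows:
        raise ValueError("reference requires at least one tumor-free record")
    return ReferenceSignal(amplitude=np.mean(rows, axis=0))


def _degenerate(v: np.ndarray, policy: str, what: str) -> np.ndarray:
    if policy == "zeros":
        warnings.warn(f"{what}: degenerate input, returning zeros", RuntimeWarning)
        return np.zeros_like(v)
    raise ValueError(f"{what}: degenerate input (constant signal)")


def normalize(
    signal: np.ndarray,
    method: str,
    reference: Optional[ReferenceSignal] = None,
    global_stats: Optional[Tuple[float, float]] = None,
    eps_guard: float = EPS_GUARD,
    degenerate_policy: str = "zeros",
) -> np.ndarray:
    """Apply one normalization method to a signal (1-D) or record matrix (2-D).

    Parameters
    ----------
    signal
        Amplitude vector, or matrix with one record per row.
    method
        One of :data:`NORMALIZATION_METHODS`.
    reference
        Tumor-free reference; required for the relative methods.
    global_stats
        ``(mean, sd)`` over the whole dataset; required for MSD.
    eps_guard
        Additive guard on divisions and logarithms.
    degenerate_policy
        ``"zeros"`` (warn and return zeros) or ``"error"`` for constant
        signals under ZS/MM.
    """
    v = np.asarray(signal, dtype=float)
    if method not in NORMALIZATION_METHODS:
        raise ValueError(f"unknown normalization method {method!r}")
    if method in REFERENCE_METHODS:
        if reference is None:
            raise ValueError(f"method {method} requires a reference signal")
        ref = np.asarray(reference.amplitude, dtype=float)

    if method == "DS":
        peak = np.max(np.abs(v), axis=-1, keepdims=True)
        # smallest j >= 0 with max|v| / 10^j <= 1
        with np.errstate(divide="ignore"):
            j = np.ceil(np.log10(np.maximum(peak, eps_guard)))
        j = np.maximum(j, 0.0)
        return v / 10.0**j
    if method == "ZS":
        mu = np.mean(v, axis=-1, keepdims=True)
        sd = np.std(v, axis=-1, keepdims=True)  # population (1/N)
        out = np.where(sd > 0, (v - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        if np.any(sd == 0):
            bad = _degenerate(v, degenerate_policy, "ZS")
            out = np.where(sd > 0, out, bad)
        return out
    if method == "LS":
        peak = np.max(np.abs(v), axis=-1, keepdims=True)
        return np.where(peak > 0, v / np.where(peak > 0, peak, 1.0), 0.0)
    if method == "MM":
        lo = np.min(v, axis=-1, keepdims=True)
        rng = np.max(v, axis=-1, keepdims=True) - lo
        out = np.where(rng > 0, (v - lo) / np.where(rng > 0, rng, 1.0), 0.0)
        if np.any(rng == 0):
            bad = _degenerate(v, degenerate_policy, "MM")
            out = np.where(rng > 0, out, bad)
        return out
    if method == "MSD":
        if global_stats is None:
            raise ValueError("MSD requires dataset-global (mean, sd)")
        g_mu, g_sd = global_stats
        if g_sd <= 0:
            raise ValueError("MSD requires positive global sd")
        return (v - g_mu) / g_sd
    if method == "RV":
        return v - ref
    if method == "FVC":
        return (v - ref) / (np.abs(ref) + eps_guard)
    if method == "RLV":
        return np.log10((np.abs(v) + eps_guard) / (np.abs(ref) + eps_guard))
    ref_energy = float(np.sum(ref**2))
    if ref_energy <= 0:
        raise ValueError(f"{method} requires a non-zero reference signal")
    if method == "RSSV":
        d = v - ref
        return d * np.abs(d) / ref_energy
    # RLSSV
    return np.log10(((v - ref) ** 2 + eps_guard) / ref_energy)


def global_amplitude_stats(signal_set: SignalSet) -> Tuple[float, float]:
    """Pooled mean and population sd over every sample of every record."""
    x = signal_set.amplitude_matrix()
    return float(np.mean(x)), float(np.std(x))


def normalize_set(
    signal_set: SignalSet,
    method: str,
    reference: Optional[ReferenceSignal] = None,
    global_stats: Optional[Tuple[float, float]] = None,
    eps_guard: float = EPS_GUARD,
    degenerate_policy: str = "zeros",
) -> NormalizedSet:
    """Normalize every record of a signal set with one method."""
    if method in REFERENCE_METHODS and reference is None:
        reference = compute_reference(signal_set)
    if method == "MSD" and global_stats is None:
        global_stats = global_amplitude_stats(signal_set)
    matrix = normalize(
        signal_set.amplitude_matrix(),
        method,
        reference=reference,
        global_stats=global_stats,
        eps_guard=eps_guard,
        degenerate_policy=degenerate_policy,
    )
    return NormalizedSet(
        method_name=method,
        matrix=matrix,
        labels=signal_set.labels(),
        reference_used=method in REFERENCE_METHODS,
    )
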