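"""Stage 2 feature extractors: ten scalars per record.

Statistical moments (mean, standard deviation, variance, skewness), Shannon
entropy of the energy distribution, SURE entropy with a Stein-selected
threshold, the first FastICA component, and three frequency-domain features
(mean Welch PSD, max and min of the magnitude spectrum).  Moments use the
population (1/N) convention.

Row-wise features are computed on each record's retained PCA-score vector;
the frequency-domain features (PSD, MAX, MIN) are computed on the record's
full-length normalized signal, since spectra of PC scores carry no frequency
meaning.  ICA is estimated once per dataset (seeded) and contributes the
first independent component's value per record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .normalization import to_frequency

FEATURE_NAMES = ("SD", "M", "V", "S", "SE", "ICA", "SU", "PSD", "MAX", "MIN")


@dataclass
class FeatureParams:
    """Extractor settings: Welch segmentation, SURE mode, ICA seeding."""

    welch_window_length: int = 256
    welch_overlap: int = 128
    hamming: bool = True
    sure_threshold_mode: str = "rigorous"  # exhaustive SURE scan over |v|
    ica_seed: int = 0
    ica_max_iter: int = 500
    ica_tol: float = 1e-4


@dataclass
class FeatureMatrix:
    """Records x 10 named features, with class labels and provenance."""

    values: np.ndarray
    labels: np.ndarray
    feature_names: tuple = FEATURE_NAMES
    source_method: Optional[str] = None
    excluded_rows: Optional[np.ndarray] = None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "label", self.labels)
        if self.source_method:
            df.insert(0, "method", self.source_method)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _as_rows(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return v


def feat_mean(v: np.ndarray) -> np.ndarray:
    return _as_rows(v).mean(axis=-1)


def feat_var(v: np.ndarray) -> np.ndarray:
    v = _as_rows(v)
    if v.shape[-1] < 2:
        raise ValueError("variance requires length >= 2")
    return v.var(axis=-1)


def feat_sd(v: np.ndarray) -> np.ndarray:
    return np.sqrt(feat_var(v))


def feat_skew(v: np.ndarray) -> np.ndarray:
    """Population skewness m3 / m2**1.5; zero-variance input yields 0."""
    v = _as_rows(v)
    if v.shape[-1] < 2:
        raise ValueError("skewness requires length >= 2")
    mu = v.mean(axis=-1, keepdims=True)
    d = v - mu
    m2 = (d**2).mean(axis=-1)
    m3 = (d**3).mean(axis=-1)
    zero = m2 == 0
    if np.any(zero):
        warnings.warn("feat_skew: zero-variance input, returning 0", RuntimeWarning)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero, 0.0, m3 / np.where(zero, 1.0, m2) ** 1.5)
    return out


def feat_psd(v: np.ndarray, params: FeatureParams = FeatureParams()) -> np.ndarray:
    """Mean of the Welch PSD estimate over all frequency bins.

    Hamming-windowed segments of ``welch_window_length`` samples with
    ``welch_overlap`` overlap (fs = 1, density scaling, no detrending).
    """
    v = _as_rows(v)
    nperseg = params.welch_window_length
    if nperseg > v.shape[-1]:
        raise ValueError(
            f"welch_window_length {nperseg} exceeds signal length {v.shape[-1]}"
        )
    if params.welch_overlap >= nperseg:
        raise ValueError("welch_overlap must be smaller than the window length")
    window = "hamming" if params.hamming else "boxcar"
    _, pxx = sps.welch(
        v,
        window=window,
        nperseg=nperseg,
        noverlap=params.welch_overlap,
        detrend=False,
        axis=-1,
    )
    return pxx.mean(axis=-1)


def feat_maxfft(v: np.ndarray) -> np.ndarray:
    return to_frequency(_as_rows(v)).max(axis=-1)


def feat_minfft(v: np.ndarray) -> np.ndarray:
    return to_frequency(_as_rows(v)).min(axis=-1)


def feat_shannon(v: np.ndarray) -> np.ndarray:
    """Shannon entropy of the energy distribution p_i = v_i^2 / sum v^2 (nats)."""
    v = _as_rows(v)
    one_d = v.ndim == 1
    V = np.atleast_2d(v)
    energy = (V**2).sum(axis=-1, keepdims=True)
    zero = energy[:, 0] == 0
    if np.any(zero):
        warnings.warn("feat_shannon: all-zero input, returning 0", RuntimeWarning)
    p = V**2 / np.where(energy > 0, energy, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    out = -terms.sum(axis=-1)
    out[zero] = 0.0
    return out[0] if one_d else out


def sure_threshold(v: np.ndarray, params: FeatureParams = FeatureParams()) -> float:
    """Threshold epsilon minimizing Stein's unbiased risk of soft thresholding.

    Noise scale sigma is estimated by MAD/0.6745; the SURE risk
    ``n - 2*#{|y| <= t} + sum(min(y^2, t^2))`` is minimized exactly over the
    candidate set {0} U {|y_(i)|} of the sigma-scaled data y = v/sigma.
    """
    v = np.asarray(v, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    sigma = float(np.median(np.abs(v - np.median(v)))) / 0.6745
    if sigma == 0:
        sigma = float(np.std(v))
    if sigma == 0:
        return 0.0
    y = v / sigma
    s = np.sort(y**2)
    n = s.size
    csum = np.cumsum(s)
    # candidate t = |y|_(k) (k = 1..n): #{<= t} = k, sum min = csum[k-1] + (n-k)*s[k-1]
    ks = np.arange(1, n + 1)
    risks = n - 2.0 * ks + csum + (n - ks) * s
    risk0 = float(n - 2.0 * np.count_nonzero(y == 0))  # t = 0
    best = int(np.argmin(risks))
    if risk0 < risks[best]:
        return 0.0
    return float(np.sqrt(s[best]) * sigma)


def feat_sure(v: np.ndarray, params: FeatureParams = FeatureParams()) -> np.ndarray:
    """SURE entropy: sum_i min(v_i^2, eps^2) with a SURE-selected eps."""
    v = _as_rows(v)
    if v.ndim == 1:
        eps = sure_threshold(v, params)
        return np.minimum(v**2, eps**2).sum()
    return np.array([feat_sure(row, params) for row in v])


def feat_ica(matrix: np.ndarray, params: FeatureParams = FeatureParams()) -> np.ndarray:
    """Leading independent component per record, FastICA on the whole matrix.

    Seeded and iteration-capped for determinism.  FastICA returns components
    in arbitrary order, so "leading" is made well-defined by picking the most
    non-Gaussian source (largest |excess kurtosis|); its sign is fixed by the
    positive-skew convention.  If FastICA fails to converge the first
    principal component is returned instead (with a warning).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("feat_ica requires >= 2 records and >= 2 columns")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ica = FastICA(
            random_state=params.ica_seed,
            max_iter=params.ica_max_iter,
            tol=params.ica_tol,
            whiten="unit-variance",
        )
        sources = ica.fit_transform(X)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        warnings.warn(
            "feat_ica: FastICA did not converge, falling back to the first "
            "principal component",
            RuntimeWarning,
        )
        from .reduction import fit_pca

        sources = fit_pca(X, n_components=1).transform(X)
    z = (sources - sources.mean(axis=0)) / np.where(sources.std(axis=0) > 0, sources.std(axis=0), 1.0)
    kurt = np.abs((z**4).mean(axis=0) - 3.0)
    component = sources[:, int(np.argmax(kurt))]
    if feat_skew(component) < 0:
        component = -component
    return component


def build_feature_matrix(
    scores: np.ndarray,
    labels: np.ndarray,
    params: FeatureParams = FeatureParams(),
    signals: Optional[np.ndarray] = None,
    source_method: Optional[str] = None,
) -> FeatureMatrix:
    """Assemble the records x 10 feature matrix in the fixed column order.

    ``scores`` carries each record's retained PCA-score vector (row-wise
    features and ICA); ``signals`` carries the full-length normalized signals
    for the frequency-domain features and defaults to ``scores`` when omitted.
    Rows with any non-finite feature are excluded (indices recorded on the
    result, warning emitted).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores rows and labels must align")
    freq_input = scores if signals is None else np.atleast_2d(np.asarray(signals, dtype=float))
    if freq_input.shape[0] != scores.shape[0]:
        raise ValueError("signals rows and scores rows must align")
    # rows with non-finite inputs cannot be extracted (ICA/FFT reject them)
    input_finite = np.isfinite(scores).all(axis=1) & np.isfinite(freq_input).all(axis=1)
    if not input_finite.all():
        keep_idx = np.flatnonzero(input_finite)
        sub = build_feature_matrix(
            scores[input_finite],
            labels[input_finite],
            params=params,
            signals=None if signals is None else freq_input[input_finite],
            source_method=source_method,
        )
        excluded = np.flatnonzero(~input_finite)
        if sub.excluded_rows is not None:
            excluded = np.sort(np.concatenate([excluded, keep_idx[sub.excluded_rows]]))
        warnings.warn(
            f"build_feature_matrix: excluding {excluded.size} row(s) with "
            "non-finite features",
            RuntimeWarning,
        )
        return FeatureMatrix(
            values=sub.values,
            labels=sub.labels,
            source_method=source_method,
            excluded_rows=excluded,
        )
    wl = min(params.welch_window_length, freq_input.shape[1])
    psd_params = FeatureParams(
        welch_window_length=wl,
        welch_overlap=min(params.welch_overlap, wl - 1) if wl > 1 else 0,
        hamming=params.hamming,
        sure_threshold_mode=params.sure_threshold_mode,
        ica_seed=params.ica_seed,
        ica_max_iter=params.ica_max_iter,
        ica_tol=params.ica_tol,
    )
    if scores.shape[1] >= 2 and scores.shape[0] >= 2:
        ica_col = feat_ica(scores, params)
    else:
        ica_col = scores[:, 0]
    columns = {
        "SD": feat_sd(scores),
        "M": feat_mean(scores),
        "V": feat_var(scores),
        "S": feat_skew(scores),
        "SE": feat_shannon(scores),
        "ICA": ica_col,
        "SU": feat_sure(scores, params),
        "PSD": feat_psd(freq_input, psd_params),
        "MAX": feat_maxfft(freq_input),
        "MIN": feat_minfft(freq_input),
    }
    values = np.column_stack([np.atleast_1d(columns[name]) for name in FEATURE_NAMES])
    finite = np.isfinite(values).all(axis=1)
    excluded = np.flatnonzero(~finite)
    if excluded.size:
        warnings.warn(
            f"build_feature_matrix: excluding {excluded.size} row(s) with "
            "non-finite features",
            RuntimeWarning,
        )
    return FeatureMatrix(
        values=values[finite],
        labels=labels[finite],
        source_method=source_method,
        excluded_rows=excluded if excluded.size else None,
    )
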