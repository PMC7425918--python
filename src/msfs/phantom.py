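"""Synthetic UWB phantom-signal simulator.

Emulates the acquisition protocol of a forward-scatter breast-phantom
measurement: a Gaussian-modulated pulse centered at 4.3 GHz is transmitted
through the phantom, and the receiver on the opposite side records 1632
time-domain samples per acquisition.  A tumor inserted at a known (x, y, z)
location adds a delayed echo whose amplitude grows with tumor size
(cross-section-like ``size_mm**2`` scaling) and whose extra delay follows the
Euclidean detour transmitter -> tumor -> receiver.  Additive Gaussian noise
and a slow deterministic baseline-drift sinusoid contaminate every record, so
the reference-based normalizations downstream have something to correct.

This is a statistical stand-in for the measurement, not an electromagnetic
solver: amplitudes, gains and the propagation speed are configurable
conventions chosen to reproduce the protocol's structure (record counts,
spectral content, size/location dependence), not Maxwellian field values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

Location = Tuple[float, float, float]

#: Propagation speed inside the phantom medium, cm/ns (~c/3, eps_r ~ 9).
SPEED_CM_PER_NS = 10.0


def _default_locations() -> tuple:
    """3 x 3 x 3 subgrid of the printed coordinate values: 27 locations."""
    xs = (0.25, 3.25, 6.25)
    ys = (0.25, 3.25, 6.25)
    zs = (3.0, 4.0, 5.0)
    return tuple((x, y, z) for x in xs for y in ys for z in zs)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition protocol and signal-model parameters.

    Defaults reproduce the measurement protocol: 1632 samples over a 16.32 ns
    window (100 GS/s), pulse content centered at 4.3 GHz, five tumor sizes
    (2-6 mm) at 27 phantom locations with 50 repetitions each, plus 750
    tumor-free records.
    """

    n_points: int = 1632
    window_ns: float = 16.32
    center_freq_ghz: float = 4.3
    pulse_sigma_ns: float = 0.25
    pulse_center_ns: float = 3.0
    tumor_sizes_mm: Tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0)
    locations_cm: Tuple[Location, ...] = field(default_factory=_default_locations)
    reps_per_point: int = 50
    n_tumor_free: int = 750
    noise_sd: float = 0.01
    drift_amplitude: float = 0.05
    echo_gain: float = 0.01
    direct_gain: float = 0.5
    tx_cm: Location = (3.25, 3.25, 0.0)
    rx_cm: Location = (3.25, 3.25, 10.0)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_points < 8:
            raise ValueError(f"n_points must be >= 8, got {self.n_points}")
        if self.window_ns <= 0:
            raise ValueError(f"window_ns must be positive, got {self.window_ns}")
        if self.reps_per_point < 1:
            raise ValueError("reps_per_point must be >= 1")
        if self.n_tumor_free < 0:
            raise ValueError("n_tumor_free must be >= 0")
        if any(s <= 0 for s in self.tumor_sizes_mm):
            raise ValueError("all tumor sizes must be positive")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise_sd and drift_amplitude must be >= 0")
        if not self.locations_cm:
            raise ValueError("at least one tumor location is required")

    @property
    def sample_times_ns(self) -> np.ndarray:
        return np.arange(self.n_points) * (self.window_ns / self.n_points)

    @property
    def n_tumor_records(self) -> int:
        return len(self.tumor_sizes_mm) * len(self.locations_cm) * self.reps_per_point

    @property
    def n_records(self) -> int:
        return self.n_tumor_records + self.n_tumor_free

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["locations_cm"] = [list(loc) for loc in self.locations_cm]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        d = dict(d)
        if "locations_cm" in d:
            d["locations_cm"] = tuple(tuple(loc) for loc in d["locations_cm"])
        if "tumor_sizes_mm" in d:
            d["tumor_sizes_mm"] = tuple(d["tumor_sizes_mm"])
        for key in ("tx_cm", "rx_cm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SignalRecord:
    """One acquisition: amplitude trace plus tumor-size/location metadata.

    ``size_mm == 0`` encodes a tumor-free record; its ``location_cm`` is None.
    """

    amplitude: np.ndarray
    size_mm: float
    location_cm: Optional[Location]
    rep: int


@dataclass
class SignalSet:
    """Ordered collection of records with the acquisition config that made it."""

    records: list
    config: AcquisitionConfig

    def __len__(self) -> int:
        return len(self.records)

    def amplitude_matrix(self) -> np.ndarray:
        return np.vstack([r.amplitude for r in self.records])

    def labels(self) -> np.ndarray:
        """Tumor-size class per record (0.0 = tumor-free)."""
        return np.array([r.size_mm for r in self.records])

    def tumor_mask(self) -> np.ndarray:
        return self.labels() > 0


def _pulse_waveform(config: AcquisitionConfig, delay_ns: float = 0.0) -> np.ndarray:
    """Analytic Gaussian-modulated sinusoid, optionally delayed by ``delay_ns``."""
    t = config.sample_times_ns - config.pulse_center_ns - delay_ns
    envelope = np.exp(-(t**2) / (2.0 * config.pulse_sigma_ns**2))
    return envelope * np.cos(2.0 * np.pi * config.center_freq_ghz * t)


def _drift(config: AcquisitionConfig) -> np.ndarray:
    # 0.1 of a sinusoid period across the window: a slow, near-monotone bow.
    t = config.sample_times_ns
    return config.drift_amplitude * np.sin(2.0 * np.pi * 0.1 * t / config.window_ns)


def _path_delay_ns(a: Location, b: Location) -> float:
    return float(np.linalg.norm(np.subtract(a, b))) / SPEED_CM_PER_NS


def generate_pulse(config: AcquisitionConfig) -> np.ndarray:
    """Transmitted pulse: Gaussian-modulated sinusoid at ``center_freq_ghz``.

    Deterministic for a given config; the magnitude-spectrum peak falls within
    one FFT bin of the configured center frequency.
    """
    config.validate()
    return _pulse_waveform(config)


def clean_received(
    config: AcquisitionConfig, size_mm: float, location_cm: Optional[Location]
) -> np.ndarray:
    """Noise- and drift-free received signal: direct path plus tumor echo."""
    config.validate()
    direct_delay = _path_delay_ns(config.tx_cm, config.rx_cm)
    out = config.direct_gain * _pulse_waveform(config, direct_delay)
    if size_mm > 0:
        if location_cm is None:
            raise ValueError("tumor records require a location")
        echo_delay = _path_delay_ns(config.tx_cm, location_cm) + _path_delay_ns(
            location_cm, config.rx_cm
        )
        echo_amp = config.echo_gain * size_mm**2
        out = out + echo_amp * _pulse_waveform(config, echo_delay)
    return out


def generate_received(
    config: AcquisitionConfig,
    size_mm: float,
    location_cm: Optional[Location],
    rng: np.random.Generator,
    rep: int = 0,
) -> SignalRecord:
    """One received record: clean signal + baseline drift + Gaussian noise.

    The echo amplitude is strictly increasing in ``size_mm`` (prop. to
    ``size_mm**2``) and its delay is monotone in the tx->tumor->rx path
    length.  ``size_mm = 0`` yields no echo term.
    """
    allowed = {0.0} | {float(s) for s in config.tumor_sizes_mm}
    if float(size_mm) not in allowed:
        raise ValueError(f"unknown tumor size {size_mm}; allowed {sorted(allowed)}")
    amp = clean_received(config, size_mm, location_cm) + _drift(config)
    if config.noise_sd > 0:
        amp = amp + rng.normal(0.0, config.noise_sd, config.n_points)
    return SignalRecord(
        amplitude=amp,
        size_mm=float(size_mm),
        location_cm=None if size_mm == 0 else tuple(location_cm),
        rep=rep,
    )


def generate_dataset(config: AcquisitionConfig) -> SignalSet:
    """Full protocol sweep: sizes x locations x repetitions, then tumor-free.

    Ordering is size-major, then location, then repetition; the
    ``n_tumor_free`` tumor-free records are appended last.  Fully reproducible
    from ``config.rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    records = []
    for size in config.tumor_sizes_mm:
        for loc in config.locations_cm:
            for rep in range(config.reps_per_point):
                records.append(generate_received(config, size, loc, rng, rep=rep))
    for rep in range(config.n_tumor_free):
        records.append(generate_received(config, 0.0, None, rng, rep=rep))
    return SignalSet(records=records, config=config)


# ---------------------------------------------------------------------------
# I/O: wide CSV (text) and HDF5 (binary) containers.

def write_signalset_csv(signal_set: SignalSet, path) -> None:
    """Wide CSV: metadata columns then one amplitude column per sample."""
    n = signal_set.config.n_points
    meta = pd.DataFrame(
        {
            "size_mm": [r.size_mm for r in signal_set.records],
            "x_cm": [r.location_cm[0] if r.location_cm else np.nan for r in signal_set.records],
            "y_cm": [r.location_cm[1] if r.location_cm else np.nan for r in signal_set.records],
            "z_cm": [r.location_cm[2] if r.location_cm else np.nan for r in signal_set.records],
            "rep": [r.rep for r in signal_set.records],
        }
    )
    amp = pd.DataFrame(
        signal_set.amplitude_matrix(), columns=[f"a{i:04d}" for i in range(n)]
    )
    pd.concat([meta, amp], axis=1).to_csv(path, index=False, float_format="%.17g")


def read_signalset_csv(path, config: AcquisitionConfig) -> SignalSet:
    df = pd.read_csv(path)
    amp_cols = [c for c in df.columns if c.startswith("a") and c[1:].isdigit()]
    records = []
    for _, row in df.iterrows():
        loc = (
            None
            if row["size_mm"] == 0 or np.isnan(row["x_cm"])
            else (row["x_cm"], row["y_cm"], row["z_cm"])
        )
        records.append(
            SignalRecord(
                amplitude=row[amp_cols].to_numpy(dtype=float),
                size_mm=float(row["size_mm"]),
                location_cm=loc,
                rep=int(row["rep"]),
            )
        )
    return SignalSet(records=records, config=config)


def write_signalset_h5(signal_set: SignalSet, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("amplitude", data=signal_set.amplitude_matrix())
        f.create_dataset("size_mm", data=signal_set.labels())
        loc = np.full((len(signal_set), 3), np.nan)
        for i, r in enumerate(signal_set.records):
            if r.location_cm is not None:
                loc[i] = r.location_cm
        f.create_dataset("location_cm", data=loc)
        f.create_dataset("rep", data=np.array([r.rep for r in signal_set.records]))
        f.attrs["config"] = json.dumps(signal_set.config.to_dict())


def read_signalset_h5(path) -> SignalSet:
    import h5py

    with h5py.File(path, "r") as f:
        config = AcquisitionConfig.from_dict(json.loads(f.attrs["config"]))
        amp = f["amplitude"][...]
        sizes = f["size_mm"][...]
        locs = f["location_cm"][...]
        reps = f["rep"][...]
    records = [
        SignalRecord(
            amplitude=amp[i],
            size_mm=float(sizes[i]),
            location_cm=None if np.isnan(locs[i]).any() else tuple(locs[i]),
            rep=int(reps[i]),
        )
        for i in range(len(sizes))
    ]
    return SignalSet(records=records, config=config)
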