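"""The 70-entry feature vector consumed by the linear classifiers.

Layout (fixed order, serialized with every trained model):

* 23 time features — means of consecutive 100-sample (4 µs) bins of the
  rectified signal over [15, 107] µs after t0;
* 11 time features — means of consecutive 200-sample (8 µs) bins over the
  first 2200 samples of the same window;
* 16 frequency features — means of consecutive 10-sample (62.5 kHz) bins
  of the zero-padded magnitude spectrum over [0, 1 MHz);
* 8 frequency features — means of consecutive 20-sample (125 kHz) bins
  over the same range;
* 1 frequency feature — the spectrum value at 0 Hz (an average of the full
  windowed signal);
* 11 demographic/physical-metric features — sex (M=0, F=1), age, height,
  weight, BMI, three abdominal circumferences, three body lengths.

All entries are scaled into [0, 1] by per-group divisors and clipped.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ContractError, DataError
from .preprocess import AlignedTrace, Spectrum, TIME_WINDOW, window_time
from .sim import Participant

N_T4, N_T8 = 23, 11
N_F62, N_F125 = 16, 8
N_TIME, N_FREQ, N_DEMO = 34, 25, 11
N_FEATURES = 70

DEMO_NAMES = (
    "sex", "age", "height", "weight", "bmi",
    "circ_waist", "circ_navel", "circ_sternum",
    "len_navel_sternum", "len_navel_chin", "len_hip_armpit",
)

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"t4_{i:02d}" for i in range(1, N_T4 + 1))
    + tuple(f"t8_{i:02d}" for i in range(1, N_T8 + 1))
    + tuple(f"f62_{i:02d}" for i in range(1, N_F62 + 1))
    + tuple(f"f125_{i:02d}" for i in range(1, N_F125 + 1))
    + ("f_dc",)
    + DEMO_NAMES
)
assert len(FEATURE_NAMES) == N_FEATURES

SCHEMA_HASH = hashlib.sha256(",".join(FEATURE_NAMES).encode()).hexdigest()[:16]


def _default_demo_divisors() -> dict[str, float]:
    # Within the documented 40-200 scaling range except sex, which is
    # already binary in [0, 1].
    return {
        "sex": 1.0, "age": 100.0, "height": 200.0, "weight": 150.0,
        "bmi": 50.0, "circ_waist": 150.0, "circ_navel": 150.0,
        "circ_sternum": 150.0, "len_navel_sternum": 100.0,
        "len_navel_chin": 100.0, "len_hip_armpit": 100.0,
    }


#: Divisors of the original device protocol (acquisition units unknown);
#: kept for loading models trained against that convention.
STUDY_TIME_DIVISOR = 1e4
STUDY_FREQ_DIVISOR = 1e6


@dataclass(frozen=True)
class ScalingTable:
    """Divisors mapping raw features into [0, 1] (values clipped after).

    The defaults are calibrated to the simulator's volt-scale traces:
    rectified 4 µs bin means stay below ~10 V and band spectral magnitudes
    below ~10^3 V-samples, so dividing by these keeps the informative
    features well inside [0, 1] instead of collapsing them to ~1e-4 (which
    would let the L2 penalty of the linear fitters erase them). The
    original acquisition chain used divisors of 1e4 / 1e6 for its own,
    unreported, raw units; those remain available as STUDY_*_DIVISOR.
    """

    time_divisor: float = 10.0
    freq_divisor: float = 1e3
    demo_divisors: dict[str, float] = field(default_factory=_default_demo_divisors)

    def __post_init__(self) -> None:
        if self.time_divisor <= 0 or self.freq_divisor <= 0:
            raise ConfigurationError("divisors must be > 0")
        for name, d in self.demo_divisors.items():
            if d <= 0:
                raise ConfigurationError(f"divisor for {name} must be > 0")

    def divisors(self) -> np.ndarray:
        out = np.empty(N_FEATURES)
        out[:N_TIME] = self.time_divisor
        out[N_TIME:N_TIME + N_FREQ] = self.freq_divisor
        for i, name in enumerate(DEMO_NAMES):
            out[N_TIME + N_FREQ + i] = self.demo_divisors[name]
        return out


@dataclass
class FeatureVector:
    """Ordered, scaled 70-entry feature set plus its schema fingerprint."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES
    schema_hash: str = SCHEMA_HASH

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ContractError(
                f"feature vector length {self.values.size} != {len(self.names)}")


def check_schema(schema_hash: str) -> None:
    if schema_hash != SCHEMA_HASH:
        raise ContractError(
            f"feature schema mismatch: expected {SCHEMA_HASH}, got {schema_hash}")


def _bin_means(x: np.ndarray, width: int, count: int) -> np.ndarray:
    return x[: width * count].reshape(count, width).mean(axis=1)


def time_features(rectified: AlignedTrace,
                  window: tuple[float, float] = TIME_WINDOW) -> np.ndarray:
    """34 down-sampled time features from the rectified aligned trace."""
    seg, _, _ = window_time(rectified, *window)
    n4 = int(round(4e-6 * rectified.sampling_rate))
    if len(seg) < N_T4 * n4:
        raise ConfigurationError(
            f"time window holds {len(seg)} samples; need {N_T4 * n4}")
    t4 = _bin_means(seg, n4, N_T4)
    t8 = _bin_means(seg, 2 * n4, N_T8)
    return np.concatenate([t4, t8])


def freq_features(spec: Spectrum) -> np.ndarray:
    """25 down-sampled spectral features (62.5 kHz bins, 125 kHz bins, DC).

    Requires the 6.25 kHz resolution produced by the standard 2000-sample
    window, so that 10- and 20-sample bins are exactly 62.5 and 125 kHz.
    """
    expected = 6.25e3
    if abs(spec.resolution - expected) > 1e-6 * expected:
        raise ConfigurationError(
            f"expected {expected:.0f} Hz resolution, got {spec.resolution:.3f}")
    mag = spec.magnitude
    if mag.size < 20 * N_F125:
        raise ConfigurationError("spectrum too short for 125 kHz bins")
    f62 = _bin_means(mag, 10, N_F62)
    f125 = _bin_means(mag, 20, N_F125)
    return np.concatenate([f62, f125, [mag[0]]])


def demo_features(participant: Participant) -> np.ndarray:
    """11 demographic/physical-metric features in schema order."""
    if participant.sex not in ("M", "F"):
        raise DataError(f"sex must be M or F, got {participant.sex!r}")
    mapping = {
        "sex": 0.0 if participant.sex == "M" else 1.0,
        "age": participant.age,
        "height": participant.height,
        "weight": participant.weight,
        "bmi": participant.bmi,
        "circ_waist": participant.circumference_waist,
        "circ_navel": participant.circumference_navel,
        "circ_sternum": participant.circumference_sternum,
        "len_navel_sternum": participant.length_navel_sternum,
        "len_navel_chin": participant.length_navel_chin,
        "len_hip_armpit": participant.length_hip_armpit,
    }
    out = np.empty(N_DEMO)
    for i, name in enumerate(DEMO_NAMES):
        value = mapping[name]
        if value is None or (name != "sex" and not value > 0):
            raise DataError(f"participant field {name} missing or nonpositive")
        out[i] = value
    return out


def scale(raw: np.ndarray, table: ScalingTable = ScalingTable()) -> FeatureVector:
    """Divide each raw entry by its divisor, then clip into [0, 1]."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (N_FEATURES,):
        raise ConfigurationError(f"raw vector must have length {N_FEATURES}")
    return FeatureVector(np.clip(raw / table.divisors(), 0.0, 1.0))


def bin_index(freq_hz: float, bin_width_hz: float) -> int:
    """1-based index of the half-open bin [k*w, (k+1)*w) containing freq."""
    if freq_hz < 0 or bin_width_hz <= 0:
        raise ConfigurationError("freq must be >= 0 and width > 0")
    return int(freq_hz // bin_width_hz) + 1


def extract(trace, participant: Participant,
            table: ScalingTable = ScalingTable(),
            use_known_t0: bool = False) -> FeatureVector:
    """Full per-trace pipeline: align, rectify/transform, bin, scale."""
    from .preprocess import align, rectify, spectrum

    aligned = align(trace, use_known_t0=use_known_t0)
    tf = time_features(rectify(aligned))
    ff = freq_features(spectrum(aligned))
    df = demo_features(participant)
    return scale(np.concatenate([tf, ff, df]), table)


def feature_table(dataset, table: ScalingTable = ScalingTable(),
                  use_known_t0: bool = False):
    """Feature matrix for a whole dataset as a pandas DataFrame.

    Columns are participant_id, location, rep followed by the 70 schema
    names; rows follow the dataset's trace order.
    """
    import pandas as pd

    rows = []
    for tr in dataset.traces:
        fv = extract(tr, dataset.participant(tr.participant_id), table,
                     use_known_t0=use_known_t0)
        rows.append((tr.participant_id, tr.location, tr.rep, *fv.values))
    return pd.DataFrame(
        rows, columns=["participant_id", "location", "rep", *FEATURE_NAMES])
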