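"""Synthetic six-sensor e-nose recordings.

Emulates the measurement protocol of a metal-oxide gas-sensor array sampling
the headspace above caged honeybee workers: a 600-s exposure phase in which
each sensor rises exponentially to a class-dependent plateau, followed by a
600-s regeneration phase on filtered ambient air in which the signal decays
back to the device baseline.  Four biological-status classes are modelled:

    1  empty chamber (control; zero odor amplitude)
    5  young workers
    6  old workers
    7  workers from colonies with physiological laying workers

Two twin devices (M1, M2) differ by additive per-sensor baseline offsets, and
the chamber insert material (wooden or polystyrene) contributes its own
additive odor shift during exposure.  Per-second readings carry i.i.d.
Gaussian measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SENSORS",
    "CLASSES",
    "DEVICES",
    "INSERTS",
    "N_SECONDS",
    "CSV_COLUMNS",
    "GeneratorConfig",
    "RawMeasurement",
    "generate_measurement",
    "generate_study",
    "measurements_to_frame",
    "write_device_csv",
    "write_study",
]

SENSORS = ("TGS823", "TGS826", "TGS832", "TGS2600", "TGS2602", "TGS2603")
CLASSES = (1, 5, 6, 7)
DEVICES = ("M1", "M2")
INSERTS = ("wooden", "polystyrene")
N_SECONDS = 600  # readings per phase, one per second

CSV_COLUMNS = ("object_id", "class", "device", "insert", "phase", "second") + SENSORS

# Plateau amplitudes above baseline, sensor units, at separation = 1.
# Class 1 (empty chamber) is identically zero.  Raw magnitudes are a
# convention: the study device records arbitrary intensity units.
_BASE_AMPLITUDE = {
    1: np.zeros(6),
    5: np.array([30.0, 45.0, 20.0, 50.0, 60.0, 40.0]),
    6: np.array([36.0, 40.0, 26.0, 56.0, 50.0, 48.0]),
    7: np.array([52.0, 56.0, 34.0, 70.0, 80.0, 64.0]),
}

_BASE_BASELINE = {
    "M1": np.array([100.0, 120.0, 90.0, 110.0, 130.0, 105.0]),
    "M2": np.array([112.0, 128.0, 84.0, 119.0, 138.0, 111.0]),
}

# Wooden inserts release noticeably more volatiles than polystyrene.
_BASE_INSERT_SHIFT = {
    "wooden": np.array([8.0, 6.0, 10.0, 5.0, 7.0, 6.0]),
    "polystyrene": np.array([2.0, 1.0, 2.0, 1.0, 1.0, 1.0]),
}


def _as_matrix(mapping: dict, keys: tuple) -> dict:
    out = {}
    for k in keys:
        if k not in mapping:
            raise ValueError(f"missing entry for {k!r}")
        v = np.asarray(mapping[k], dtype=float)
        if v.shape != (6,):
            raise ValueError(f"entry for {k!r} must be a 6-vector, got shape {v.shape}")
        out[k] = v
    return out


@dataclass
class GeneratorConfig:
    """Stated world of the synthetic study.

    Parameters
    ----------
    amplitude
        Per-class 6-vector of plateau rises above baseline (sensor units).
        The class-1 row must be zero (empty chamber emits no odor).
    baseline
        Per-device additive sensor offsets (sensor units).
    insert_shift
        Additive odor contribution of the chamber insert material during
        exposure (sensor units); absent during regeneration (filtered air).
    tau_rise, tau_decay
        Exponential time constants in seconds.  ``tau_rise`` must satisfy
        exp(-270/tau_rise) < 0.01 so the signal is stabilized well before
        the 270-s feature reference point.
    noise_sd
        Standard deviation of per-second Gaussian measurement noise.
    n_per_class
        Objects per class for each device x insert run (default 10,
        matching ten samples of 100 workers per group).
    seed
        Root seed; per-object seeds are derived deterministically from it.
    """

    amplitude: dict = field(default_factory=lambda: {c: _BASE_AMPLITUDE[c].copy() for c in CLASSES})
    baseline: dict = field(default_factory=lambda: {d: _BASE_BASELINE[d].copy() for d in DEVICES})
    insert_shift: dict = field(
        default_factory=lambda: {i: _BASE_INSERT_SHIFT[i].copy() for i in INSERTS}
    )
    tau_rise: float = 40.0
    tau_decay: float = 40.0
    noise_sd: float | None = None
    n_per_class: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.amplitude = _as_matrix(self.amplitude, CLASSES)
        self.baseline = _as_matrix(self.baseline, DEVICES)
        self.insert_shift = _as_matrix(self.insert_shift, INSERTS)
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be positive")
        if math.exp(-270.0 / self.tau_rise) >= 0.01:
            raise ValueError(
                "tau_rise too slow: exp(-270/tau_rise) must be < 0.01 so the "
                "signal has stabilized at the 270-s reference point"
            )
        if np.any(self.amplitude[1] != 0.0):
            raise ValueError("class-1 (empty chamber) amplitude must be the zero vector")
        if any(np.any(a < 0) for a in self.amplitude.values()):
            raise ValueError("amplitudes must be non-negative")
        if self.noise_sd is None:
            self.noise_sd = 0.01 * max(float(a.max()) for a in self.amplitude.values())
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be at least 1")

    @classmethod
    def default(cls, separation: float = 1.0, **kwargs) -> "GeneratorConfig":
        """Default world with a scalar class-separation knob.

        ``separation`` scales the spread of the class-5/6/7 amplitude vectors
        about their common mean: 1 is the stated default, values near 0 make
        the odor-emitting classes nearly indistinguishable (a hard task),
        larger values pull them apart (an easy, near-separable task).  The
        class-1 control stays at zero amplitude throughout.
        """
        mean = np.mean([_BASE_AMPLITUDE[c] for c in (5, 6, 7)], axis=0)
        amp = {1: np.zeros(6)}
        for c in (5, 6, 7):
            amp[c] = mean + separation * (_BASE_AMPLITUDE[c] - mean)
        return cls(amplitude=amp, **kwargs)


@dataclass
class RawMeasurement:
    """One object's full recording: 600-s exposure plus 600-s regeneration."""

    object_id: str
    class_label: int
    device: str
    insert: str
    exposure: np.ndarray  # (600, 6)
    regeneration: np.ndarray  # (600, 6)

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}; expected one of {CLASSES}")
        if self.device not in DEVICES:
            raise ValueError(f"unknown device {self.device!r}; expected one of {DEVICES}")
        if self.insert not in INSERTS:
            raise ValueError(f"unknown insert {self.insert!r}; expected one of {INSERTS}")
        self.exposure = np.asarray(self.exposure, dtype=float)
        self.regeneration = np.asarray(self.regeneration, dtype=float)
        for name, arr in (("exposure", self.exposure), ("regeneration", self.regeneration)):
            if arr.shape != (N_SECONDS, len(SENSORS)):
                raise ValueError(
                    f"{name} must be a {N_SECONDS} x {len(SENSORS)} matrix, got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite readings")


def _object_seed(seed: int, device: str, insert: str, class_label: int, replicate: int) -> int:
    """Stable per-object seed from the run seed and object coordinates."""
    ss = np.random.SeedSequence(
        entropy=seed,
        spawn_key=(DEVICES.index(device), INSERTS.index(insert), class_label, replicate),
    )
    return int(ss.generate_state(1)[0])


def generate_measurement(
    config: GeneratorConfig,
    class_label: int,
    device: str,
    insert: str,
    object_seed: int,
    object_id: str | None = None,
) -> RawMeasurement:
    """Simulate one object's exposure and regeneration time series.

    Exposure: baseline + insert shift + amplitude * (1 - exp(-t/tau_rise)) + noise.
    Regeneration (filtered air, no insert odor): baseline + amplitude *
    exp(-t/tau_decay) + noise.  Seconds are 1-based (t = 1..600).  Identical
    arguments reproduce bit-identical matrices.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label {class_label!r}; expected one of {CLASSES}")
    if device not in DEVICES:
        raise ValueError(f"unknown device {device!r}; expected one of {DEVICES}")
    if insert not in INSERTS:
        raise ValueError(f"unknown insert {insert!r}; expected one of {INSERTS}")

    t = np.arange(1, N_SECONDS + 1, dtype=float)[:, None]
    amp = config.amplitude[class_label][None, :]
    base = config.baseline[device][None, :]
    shift = config.insert_shift[insert][None, :]

    rng = np.random.default_rng(object_seed)
    exposure = base + shift + amp * (1.0 - np.exp(-t / config.tau_rise))
    regeneration = base + amp * np.exp(-t / config.tau_decay)
    if config.noise_sd > 0:
        exposure = exposure + rng.normal(0.0, config.noise_sd, exposure.shape)
        regeneration = regeneration + rng.normal(0.0, config.noise_sd, regeneration.shape)

    if object_id is None:
        object_id = f"{device}_{insert}_c{class_label}_s{object_seed}"
    return RawMeasurement(object_id, class_label, device, insert, exposure, regeneration)


def generate_study(config: GeneratorConfig) -> list[RawMeasurement]:
    """Full factorial study: every device x insert x class x replicate.

    With the default ``n_per_class = 10`` this yields 40 objects per
    device/insert run and 160 in total.
    """
    out = []
    for device in DEVICES:
        for insert in INSERTS:
            for class_label in CLASSES:
                for rep in range(config.n_per_class):
                    seed = _object_seed(config.seed, device, insert, class_label, rep)
                    oid = f"{device}_{insert}_c{class_label}_{rep:02d}"
                    out.append(
                        generate_measurement(config, class_label, device, insert, seed, oid)
                    )
    return out


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def measurements_to_frame(measurements) -> "pd.DataFrame":
    """Long-format per-second frame in the pipeline's CSV dialect."""
    import pandas as pd

    records = []
    seconds = np.arange(1, N_SECONDS + 1)
    for m in measurements:
        for phase, mat in (("exposure", m.exposure), ("regeneration", m.regeneration)):
            block = pd.DataFrame(mat, columns=list(SENSORS))
            block.insert(0, "second", seconds)
            block.insert(0, "phase", phase)
            block.insert(0, "insert", m.insert)
            block.insert(0, "device", m.device)
            block.insert(0, "class", m.class_label)
            block.insert(0, "object_id", m.object_id)
            records.append(block)
    if not records:
        import pandas as pd

        return pd.DataFrame(columns=list(CSV_COLUMNS))
    frame = pd.concat(records, ignore_index=True)
    return frame[list(CSV_COLUMNS)]


def write_device_csv(measurements, path) -> None:
    """Write one device/insert run in the CSV dialect (6-decimal readings)."""
    frame = measurements_to_frame(measurements)
    frame.to_csv(path, index=False, float_format="%.6f")


def write_study(study, outdir) -> dict:
    """Write one CSV per device/insert run; returns a manifest dict."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"files": [], "n_objects": len(study)}
    for device in DEVICES:
        for insert in INSERTS:
            subset = [m for m in study if m.device == device and m.insert == insert]
            if not subset:
                continue
            name = f"signals_{device}_{insert}.csv"
            write_device_csv(subset, outdir / name)
            manifest["files"].append(
                {"path": name, "device": device, "insert": insert, "n_objects": len(subset)}
            )
    return manifest
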