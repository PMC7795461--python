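"""Feature extraction: per-second recordings -> six-descriptor vectors.

Each object's time series is reduced to one reading per sensor at a fixed
reference second (270 s by default, chosen after signal stabilization).
Optional baseline differential correction subtracts the mean of the object's
own 600-s regeneration phase (the ambient-air record of that measurement)
from the reference reading, removing device and ambient offsets.

The labelled feature vectors of one device x insert run form a decision
table: numeric conditional attributes (the six sensors) with a categorical
decision class, plus per-attribute min/max used by normalization-based
classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import CLASSES, CSV_COLUMNS, DEVICES, INSERTS, N_SECONDS, SENSORS, RawMeasurement

__all__ = [
    "OPTIONS",
    "FeatureVector",
    "DecisionTable",
    "CSVFormatError",
    "read_device_csv",
    "extract_feature",
    "build_decision_table",
    "table_to_frame",
]

# The study's eight evaluation options: (device, insert, baseline correction).
OPTIONS = {
    "I": ("M1", "wooden", False),
    "II": ("M1", "polystyrene", False),
    "III": ("M2", "wooden", False),
    "IV": ("M2", "polystyrene", False),
    "V": ("M1", "wooden", True),
    "VI": ("M1", "polystyrene", True),
    "VII": ("M2", "wooden", True),
    "VIII": ("M2", "polystyrene", True),
}


class CSVFormatError(ValueError):
    """Raised when a signal CSV violates the dialect."""


@dataclass
class FeatureVector:
    """Six sensor descriptors plus object metadata."""

    descriptors: np.ndarray
    class_label: object  # 1/5/6/7 or a merged rest-label such as "156"
    object_id: str
    device: str
    insert: str
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.descriptors = np.asarray(self.descriptors, dtype=float)
        if self.descriptors.shape != (len(SENSORS),):
            raise ValueError(f"expected {len(SENSORS)} descriptors, got {self.descriptors.shape}")
        if not np.all(np.isfinite(self.descriptors)):
            raise ValueError("descriptors must be finite")


def _label_key(label):
    """Deterministic label order: numeric classes ascending, then merged labels."""
    return (0, int(label), "") if not isinstance(label, str) else (1, 0, label)


@dataclass
class DecisionTable:
    """Labelled feature vectors with per-attribute extrema."""

    rows: list
    attr_min: np.ndarray = field(init=False)
    attr_max: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("decision table must contain at least one row")
        X = self.X
        self.attr_min = X.min(axis=0)
        self.attr_max = X.max(axis=0)

    @property
    def X(self) -> np.ndarray:
        return np.vstack([r.descriptors for r in self.rows])

    @property
    def labels(self) -> list:
        return [r.class_label for r in self.rows]

    @property
    def class_set(self) -> list:
        return sorted(set(self.labels), key=_label_key)

    def __len__(self) -> int:
        return len(self.rows)


def read_device_csv(path) -> list[RawMeasurement]:
    """Read a device/insert run CSV back into measurements.

    Validates the dialect: every object must have exactly 600 exposure and
    600 regeneration rows with seconds 1..600, numeric readings, and known
    phase names.  Rows within a phase are re-sorted by second.
    """
    frame = pd.read_csv(path, dtype={"object_id": str, "phase": str})
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise CSVFormatError(f"{path}: missing columns {missing}")
    if frame.empty:
        return []

    bad_phase = ~frame["phase"].isin(["exposure", "regeneration"])
    if bad_phase.any():
        i = int(np.flatnonzero(bad_phase.to_numpy())[0])
        raise CSVFormatError(
            f"{path}: unknown phase {frame['phase'].iloc[i]!r} for object "
            f"{frame['object_id'].iloc[i]!r} (line {i + 2})"
        )
    for col in SENSORS:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.isna().to_numpy()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise CSVFormatError(
                f"{path}: non-numeric {col} reading for object "
                f"{frame['object_id'].iloc[i]!r} (line {i + 2})"
            )
        frame[col] = vals

    out = []
    for oid, grp in frame.groupby("object_id", sort=False):
        phases = {}
        for phase in ("exposure", "regeneration"):
            block = grp[grp["phase"] == phase].sort_values("second")
            seconds = block["second"].to_numpy()
            if len(block) != N_SECONDS or not np.array_equal(
                seconds, np.arange(1, N_SECONDS + 1)
            ):
                raise CSVFormatError(
                    f"{path}: object {oid!r} has {len(block)} {phase} rows / "
                    f"malformed seconds; expected exactly 1..{N_SECONDS}"
                )
            phases[phase] = block[list(SENSORS)].to_numpy(dtype=float)
        meta = grp.iloc[0]
        out.append(
            RawMeasurement(
                object_id=str(oid),
                class_label=int(meta["class"]),
                device=str(meta["device"]),
                insert=str(meta["insert"]),
                exposure=phases["exposure"],
                regeneration=phases["regeneration"],
            )
        )
    return out


def extract_feature(
    m: RawMeasurement,
    t_ref: int = 270,
    baseline_correct: bool = False,
    regen_stat: str = "mean",
    window: int = 1,
) -> FeatureVector:
    """Reduce one measurement to its six-descriptor feature vector.

    Parameters
    ----------
    t_ref
        Reference second into the exposure phase, 1-based (default 270).
    baseline_correct
        Subtract the ambient-air reference taken from the object's own
        regeneration phase.
    regen_stat
        How the 600-s regeneration record is aggregated into the reference:
        ``"mean"`` (default; the plural "values" read as an average) or
        ``"last"`` (single final reading).
    window
        Width of a trailing mean window ending at ``t_ref`` (default 1:
        the single raw reading at the reference second).
    """
    if not 1 <= t_ref <= N_SECONDS:
        raise ValueError(f"t_ref must be in 1..{N_SECONDS}, got {t_ref}")
    if window < 1 or window > t_ref:
        raise ValueError("window must be in 1..t_ref")
    if regen_stat not in ("mean", "last"):
        raise ValueError(f"regen_stat must be 'mean' or 'last', got {regen_stat!r}")

    desc = m.exposure[t_ref - window : t_ref].mean(axis=0)
    if baseline_correct:
        if regen_stat == "mean":
            ref = m.regeneration.mean(axis=0)
        else:
            ref = m.regeneration[-1]
        desc = desc - ref
    return FeatureVector(
        descriptors=desc,
        class_label=m.class_label,
        object_id=m.object_id,
        device=m.device,
        insert=m.insert,
        baseline_corrected=baseline_correct,
    )


def build_decision_table(
    measurements,
    device: str,
    insert: str,
    baseline_correct: bool = False,
    t_ref: int = 270,
    regen_stat: str = "mean",
    window: int = 1,
) -> DecisionTable:
    """Filter a study to one device/insert run and extract its feature table.

    The (device, insert, baseline_correct) triple indexes the study's eight
    evaluation options (see ``OPTIONS``).
    """
    if device not in DEVICES:
        raise ValueError(f"unknown device {device!r}; expected one of {DEVICES}")
    if insert not in INSERTS:
        raise ValueError(f"unknown insert {insert!r}; expected one of {INSERTS}")
    subset = [m for m in measurements if m.device == device and m.insert == insert]
    if not subset:
        raise ValueError(f"no measurements for device={device!r}, insert={insert!r}")
    rows = [
        extract_feature(m, t_ref=t_ref, baseline_correct=baseline_correct,
                        regen_stat=regen_stat, window=window)
        for m in subset
    ]
    return DecisionTable(rows=rows)


def table_to_frame(table: DecisionTable) -> pd.DataFrame:
    """Export a decision table as a tidy frame (CSV-ready)."""
    data = {
        "object_id": [r.object_id for r in table.rows],
        "class": [r.class_label for r in table.rows],
        "device": [r.device for r in table.rows],
        "insert": [r.insert for r in table.rows],
    }
    X = table.X
    for j, s in enumerate(SENSORS):
        data[s] = X[:, j]
    return pd.DataFrame(data)
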