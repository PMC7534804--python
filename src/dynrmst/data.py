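"""Subject-level right-censored two-arm survival data.

The central container is :class:`SurvivalDataset`: one record per subject
with a nonnegative follow-up time, a binary event indicator (1 = event
observed, 0 = right-censored) and an arm label taking exactly two values,
one of which is designated the control.  Single-arm slices are represented
by the lighter :class:`ArmData`.

Input/output is plain delimited text with a header row.  Event indicators
coded as TRUE/FALSE (any case) are accepted and mapped to 1/0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "ArmData",
    "SurvivalDataset",
    "read_dataset",
    "write_dataset",
    "arm_split",
    "max_observed_time",
]

_TRUTHY = {"true": 1, "false": 0, "t": 1, "f": 0}


@dataclass(frozen=True)
class ArmData:
    """Follow-up times and event indicators for a single trial arm."""

    label: str
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "event", np.asarray(self.event, dtype=int))

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def max_time(self) -> float:
        """Largest observed time, event or censored."""
        return float(self.time.max())


@dataclass(frozen=True)
class SurvivalDataset:
    """Validated two-arm right-censored survival data.

    Parameters
    ----------
    time, event, arm
        Per-subject arrays of equal length.  Times must be finite and
        nonnegative; events in {0, 1}; exactly two arm labels must occur,
        each with at least two subjects and at least one event.
    control_label
        Which of the two labels plays the control role; the other label is
        the treatment.
    """

    time: np.ndarray
    event: np.ndarray
    arm: np.ndarray
    control_label: str
    treatment_label: str = field(default="", compare=False)

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        arm = np.asarray(self.arm, dtype=object)
        try:
            event = _coerce_events(np.asarray(self.event, dtype=object))
        except ValueError as exc:
            raise ValidationError(str(exc)) from None
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        object.__setattr__(self, "arm", arm)
        _validate(time, event, arm)

        labels = set(str(a) for a in arm)
        control = str(self.control_label)
        if control not in labels:
            raise ValidationError(
                f"control label {control!r} not present in arm column (labels: {sorted(labels)})"
            )
        treatment = (labels - {control}).pop()
        object.__setattr__(self, "control_label", control)
        object.__setattr__(self, "treatment_label", treatment)

        for label in (control, treatment):
            mask = self._mask(label)
            if mask.sum() < 2:
                raise ValidationError(f"arm {label!r} has fewer than 2 subjects")
            if event[mask].sum() < 1:
                rows = np.nonzero(mask)[0].tolist()
                raise ValidationError(f"arm {label!r} has zero events (rows {rows})")

    def _mask(self, label: str) -> np.ndarray:
        return np.asarray([str(a) == label for a in self.arm])

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def labels(self) -> tuple[str, str]:
        """(control, treatment) labels."""
        return self.control_label, self.treatment_label

    def arm_data(self, label: str) -> ArmData:
        mask = self._mask(str(label))
        if not mask.any():
            raise ValidationError(f"unknown arm label {label!r}")
        return ArmData(str(label), self.time[mask], self.event[mask])

    @property
    def control(self) -> ArmData:
        return self.arm_data(self.control_label)

    @property
    def treatment(self) -> ArmData:
        return self.arm_data(self.treatment_label)

    def default_tau(self) -> float:
        """Default restriction horizon: min over arms of each arm's largest
        observed time (event or censored)."""
        lo, hi = self.max_observed_time(per_arm=True)
        return min(lo, hi)

    def max_observed_time(self, per_arm: bool = False):
        if per_arm:
            return self.control.max_time, self.treatment.max_time
        return float(self.time.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event, "arm": [str(a) for a in self.arm]}
        )


def _coerce_events(raw: np.ndarray) -> np.ndarray:
    out = np.empty(raw.size, dtype=int)
    bad = []
    for i, v in enumerate(raw):
        if isinstance(v, str):
            key = v.strip().lower()
            if key in _TRUTHY:
                out[i] = _TRUTHY[key]
                continue
            try:
                v = float(key)
            except ValueError:
                bad.append(i)
                continue
        if isinstance(v, (bool, np.bool_)):
            out[i] = int(v)
            continue
        fv = float(v)
        if fv not in (0.0, 1.0):
            bad.append(i)
        else:
            out[i] = int(fv)
    if bad:
        raise ValueError(f"event indicator must be 0/1 (or TRUE/FALSE); offending rows: {bad}")
    return out


def _validate(time: np.ndarray, event: np.ndarray, arm: np.ndarray) -> None:
    if not (time.size == event.size == arm.size):
        raise ValidationError("time, event and arm must have equal length")
    if time.size == 0:
        raise ValidationError("empty dataset")
    nonfinite = np.nonzero(~np.isfinite(time))[0]
    if nonfinite.size:
        raise ValidationError(f"nonfinite times at rows {nonfinite.tolist()}")
    negative = np.nonzero(time < 0)[0]
    if negative.size:
        raise ValidationError(f"negative times at rows {negative.tolist()}")
    labels = sorted(set(str(a) for a in arm))
    if len(labels) != 2:
        raise ValidationError(
            f"expected exactly 2 arm labels, found {len(labels)}: {labels}"
        )


def read_dataset(
    path,
    time_col: str = "time",
    event_col: str = "event",
    arm_col: str = "arm",
    control_label: str | None = None,
    delimiter: str = ",",
) -> SurvivalDataset:
    """Read a delimited text file into a validated :class:`SurvivalDataset`.

    Records are preserved in input order.  When ``control_label`` is None the
    first label encountered in the file is taken as the control.
    """
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in (time_col, event_col, arm_col) if c not in df.columns]
    if missing:
        raise FormatError(
            f"missing column(s) {missing} in {path} (found: {list(df.columns)})"
        )
    arm = df[arm_col].astype(str).to_numpy()
    if control_label is None:
        control_label = str(arm[0])
    return SurvivalDataset(
        time=df[time_col].to_numpy(),
        event=df[event_col].to_numpy(),
        arm=arm,
        control_label=str(control_label),
    )


def write_dataset(ds: SurvivalDataset, path, delimiter: str = ",") -> None:
    """Write a dataset back to delimited text with the standard header."""
    ds.to_frame().to_csv(path, sep=delimiter, index=False)


def arm_split(ds: SurvivalDataset) -> tuple[ArmData, ArmData]:
    """Split into (control, treatment) single-arm data, roles honored."""
    return ds.control, ds.treatment


def max_observed_time(ds: SurvivalDataset, per_arm: bool = False):
    """Largest observed time (event or censored), overall or per arm."""
    return ds.max_observed_time(per_arm=per_arm)
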