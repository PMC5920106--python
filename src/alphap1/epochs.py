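"""The epoched-EEG container and its HDF5 persistence.

An :class:`EpochSet` is the trials x channels x samples tensor for one
subject, with a time axis in milliseconds relative to cue onset, the target
onset time, per-trial labels, a montage, and a unit tag. The unit tag flips
exactly once, from microvolts to current-source-density units, when the
surface Laplacian is applied; stages guard on it so the pipeline order
(rejection in the voltage domain, Laplacian before both analysis branches)
cannot be violated silently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError
from .montage import Montage

UNITS_VOLT = "uV"
UNITS_CSD = "uV/cm2"

LABEL_COLUMNS = ("subject", "condition", "trial_type")


@dataclass
class EpochSet:
    data: np.ndarray  # (n_trials, n_channels, n_samples)
    times_ms: np.ndarray  # relative to cue onset, uniform
    sfreq: float
    target_time_ms: float
    labels: pd.DataFrame  # columns: subject, condition, trial_type
    montage: Montage
    units: str = UNITS_VOLT
    filtered: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise SchemaError("data must be trials x channels x samples")
        n_trials, n_ch, n_samp = self.data.shape
        if n_ch != self.montage.n_channels:
            raise SchemaError(
                f"{n_ch} data channels vs {self.montage.n_channels} montage channels"
            )
        if self.times_ms.shape != (n_samp,):
            raise SchemaError("time axis length mismatch")
        dt = np.diff(self.times_ms)
        step = 1000.0 / self.sfreq
        if n_samp > 1 and not np.allclose(dt, step, rtol=0, atol=1e-6 * step):
            raise SchemaError("time axis must be uniform at 1000/sampling_rate ms")
        if n_samp > 1 and dt[0] <= 0:
            raise SchemaError("time axis must be strictly increasing")
        if len(self.labels) != n_trials:
            raise SchemaError("label table length != number of trials")
        missing = [c for c in LABEL_COLUMNS if c not in self.labels.columns]
        if missing:
            raise SchemaError(f"label table missing columns {missing}")
        if self.units not in (UNITS_VOLT, UNITS_CSD):
            raise SchemaError(f"unknown unit tag {self.units!r}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def times_rel_target(self) -> np.ndarray:
        return self.times_ms - self.target_time_ms

    def time_mask(self, window, ref: str = "cue") -> np.ndarray:
        """Boolean sample mask for a (start, end) ms window, inclusive.

        ``ref`` is ``"cue"`` (times as stored) or ``"target"``.
        """
        lo, hi = window
        if not lo < hi:
            raise ConfigError(f"empty or reversed window {window}")
        t = self.times_ms if ref == "cue" else self.times_rel_target()
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
            raise ConfigError(f"window {window} ({ref}-relative) outside epoch")
        return (t >= lo - 1e-9) & (t <= hi + 1e-9)

    def with_data(self, data, **changes) -> "EpochSet":
        return replace(self, data=data, **changes)

    def select_trials(self, index) -> "EpochSet":
        return replace(
            self,
            data=self.data[index],
            labels=self.labels.iloc[index].reset_index(drop=True),
        )

    def select_channels(self, channels) -> "EpochSet":
        """Restrict to a channel subset (name list or group name)."""
        idx = self.montage.index(channels)
        sub = self.montage.subset([self.montage.names[i] for i in idx])
        return replace(self, data=self.data[:, idx, :], montage=sub)

    def condition_mask(self, condition: str) -> np.ndarray:
        return (self.labels["condition"] == condition).to_numpy()


def write_epochs(epochs: EpochSet, path) -> None:
    """Persist an EpochSet losslessly to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("time_ms", data=epochs.times_ms)
        f.create_dataset(
            "channels", data=np.array(epochs.montage.names, dtype=h5py.string_dtype())
        )
        f.create_dataset("positions", data=epochs.montage.positions)
        lab = f.create_group("labels")
        for col in LABEL_COLUMNS:
            vals = epochs.labels[col]
            if vals.dtype == object or str(vals.dtype).startswith("str"):
                lab.create_dataset(
                    col, data=vals.astype(str).to_numpy(dtype=object),
                    dtype=h5py.string_dtype(),
                )
            else:
                lab.create_dataset(col, data=vals.to_numpy())
        grp = f.create_group("groups")
        for gname, members in epochs.montage.groups.items():
            grp.create_dataset(
                gname, data=np.array(members, dtype=h5py.string_dtype())
            )
        f.attrs["sampling_rate"] = epochs.sfreq
        f.attrs["units"] = epochs.units
        f.attrs["cue_time_ms"] = 0.0
        f.attrs["target_time_ms"] = epochs.target_time_ms
        f.attrs["filtered"] = epochs.filtered


def read_epochs(path) -> EpochSet:
    """Read an EpochSet; raises :class:`SchemaError` naming any missing key."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise SchemaError(f"unreadable epochs container {path}: {exc}") from None
    with f:
        for key in ("data", "time_ms", "channels", "positions", "labels"):
            if key not in f:
                raise SchemaError(f"epochs container missing dataset {key!r}")
        for attr in ("sampling_rate", "units", "target_time_ms"):
            if attr not in f.attrs:
                raise SchemaError(f"epochs container missing attribute {attr!r}")
        names = tuple(s.decode() if isinstance(s, bytes) else str(s) for s in f["channels"][:])
        groups = {}
        if "groups" in f:
            for gname in f["groups"]:
                groups[gname] = tuple(
                    s.decode() if isinstance(s, bytes) else str(s)
                    for s in f["groups"][gname][:]
                )
        montage = Montage(names, f["positions"][:], groups)
        lab = {}
        for col in LABEL_COLUMNS:
            if col not in f["labels"]:
                raise SchemaError(f"label table missing column {col!r}")
            vals = f["labels"][col][:]
            if vals.dtype.kind in "SO":
                vals = np.array([v.decode() if isinstance(v, bytes) else v for v in vals])
            lab[col] = vals
        return EpochSet(
            data=f["data"][:],
            times_ms=f["time_ms"][:],
            sfreq=float(f.attrs["sampling_rate"]),
            target_time_ms=float(f.attrs["target_time_ms"]),
            labels=pd.DataFrame(lab),
            montage=montage,
            units=str(f.attrs["units"]),
            filtered=bool(f.attrs.get("filtered", False)),
        )
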