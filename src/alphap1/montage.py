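"""Electrode montages on the unit sphere.

A :class:`Montage` holds extended 10-20 channel labels with unit-norm 3-D
positions and named channel groups. The package ships a 60-channel montage
(``data/montage60.tsv``) whose left/right posterior groups are the
occipito-parietal regions of interest used throughout the analysis:
PO3/4, P3/4, P7/8, P9/10 and O1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigError, SingularGeometryError

LEFT_POSTERIOR = ("PO3", "P3", "P7", "P9", "O1")
RIGHT_POSTERIOR = ("PO4", "P4", "P8", "P10", "O2")

#: extra channels surrounding the posterior ROIs, used by the reduced
#: "posterior patch" montage for fast synthetic studies
_PATCH_EXTRAS = ("P5", "P6", "P1", "P2", "Pz", "POz", "CP3", "CP4", "CPz", "Cz")


@dataclass(frozen=True)
class Montage:
    """Channel labels, unit-sphere positions and named channel groups."""

    names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm
    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.names), 3):
            raise ConfigError(
                f"positions shape {pos.shape} inconsistent with {len(self.names)} channels"
            )
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms == 0):
            raise ConfigError("zero-length electrode position")
        object.__setattr__(self, "positions", pos / norms[:, None])
        if len(set(self.names)) != len(self.names):
            raise ConfigError("duplicate channel names")
        seen: set[str] = set()
        for gname, members in self.groups.items():
            missing = [ch for ch in members if ch not in self.names]
            if missing:
                raise ConfigError(f"group {gname!r} members not in montage: {missing}")
            overlap = seen.intersection(members)
            if overlap:
                raise ConfigError(f"groups are not disjoint: {sorted(overlap)}")
            seen.update(members)

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, channels) -> np.ndarray:
        """Integer indices of ``channels`` (a name, group name, or sequence)."""
        if isinstance(channels, str):
            channels = self.groups.get(channels, (channels,))
        lookup = {nm: i for i, nm in enumerate(self.names)}
        try:
            return np.array([lookup[ch] for ch in channels], dtype=int)
        except KeyError as exc:
            raise ConfigError(f"unknown channel {exc.args[0]!r}") from None

    def cosine_angles(self) -> np.ndarray:
        """Pairwise cos(angle) matrix; raises on coincident electrodes."""
        cosang = np.clip(self.positions @ self.positions.T, -1.0, 1.0)
        off = cosang - np.eye(self.n_channels)
        if np.any(off > 1.0 - 1e-10):
            raise SingularGeometryError("coincident electrode positions")
        return cosang

    def subset(self, channels) -> "Montage":
        """New montage restricted to ``channels``; groups are intersected."""
        idx = self.index(channels)
        keep = [self.names[i] for i in idx]
        groups = {}
        for gname, members in self.groups.items():
            inter = tuple(ch for ch in members if ch in keep)
            if inter:
                groups[gname] = inter
        return Montage(tuple(keep), self.positions[idx], groups)


def load_montage(path) -> Montage:
    """Read a montage from a delimited text table with columns name, x, y, z."""
    table = pd.read_csv(path, sep=None, engine="python")
    required = {"name", "x", "y", "z"}
    if not required.issubset(table.columns):
        raise ConfigError(f"montage table must have columns {sorted(required)}")
    names = tuple(table["name"].astype(str))
    pos = table[["x", "y", "z"]].to_numpy(float)
    groups = {}
    if set(LEFT_POSTERIOR).issubset(names) and set(RIGHT_POSTERIOR).issubset(names):
        groups = {"left_posterior": LEFT_POSTERIOR, "right_posterior": RIGHT_POSTERIOR}
    return Montage(names, pos, groups)


def default_montage() -> Montage:
    """The packaged 60-channel extended 10-20 montage."""
    with resources.as_file(resources.files("alphap1.data") / "montage60.tsv") as p:
        return load_montage(p)


def posterior_patch_montage() -> Montage:
    """20-channel posterior subset of the default montage.

    Both posterior ROIs plus a ring of surrounding parieto-central channels;
    used for fast synthetic cohort studies where full-head coverage adds
    nothing to the measured contrasts.
    """
    return default_montage().subset(LEFT_POSTERIOR + RIGHT_POSTERIOR + _PATCH_EXTRAS)


def fibonacci_montage(n: int = 128) -> Montage:
    """Quasi-uniform n-channel full-sphere montage (Fibonacci lattice).

    A synthetic dense montage for analytic validation of the spherical-spline
    operators; not a physically realizable EEG cap.
    """
    i = np.arange(n)
    phi = (1 + 5**0.5) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1 - z**2))
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return Montage(tuple(f"S{k:03d}" for k in i), pos)
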