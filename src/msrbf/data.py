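"""In-memory containers for the two task modes.

A :class:`Dataset` holds tabular patterns with targets: ``+1``/``-1``
labels for binary classification or real amplitudes for regression.  A
:class:`Waveform` is the 1-D regression special case used for
large-footprint LiDAR-style signals: strictly increasing bin positions
(elevation or time) with one amplitude per bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = ["Dataset", "Waveform", "read_dataset", "write_dataset"]


@dataclass
class Dataset:
    """Feature matrix ``X`` (n x d) with targets ``y`` (n,).

    task is ``"classify"`` (y in {+1, -1}) or ``"regress"``.
    """

    X: np.ndarray
    y: np.ndarray
    task: str = "classify"
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.ndim == 2 and self.X.shape[0] == 1 and len(np.asarray(self.y)) > 1:
            self.X = self.X.T
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValidationError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]}"
            )
        if self.task not in ("classify", "regress"):
            raise ValidationError(f"unknown task {self.task!r}")
        if self.task == "classify":
            bad = np.flatnonzero(~np.isin(self.y, (-1.0, 1.0)))
            if bad.size:
                raise FormatError(
                    f"label {self.y[bad[0]]!r} at row {bad[0]} not in {{+1, -1}}"
                )
        if not self.feature_names:
            self.feature_names = [f"x{j}" for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["label" if self.task == "classify" else "target"] = self.y
        return df


@dataclass
class Waveform:
    """Amplitude series over strictly increasing bin positions."""

    positions: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).ravel()
        self.amplitudes = np.asarray(self.amplitudes, dtype=float).ravel()
        if self.positions.shape != self.amplitudes.shape:
            raise ValidationError("positions and amplitudes differ in length")
        d = np.diff(self.positions)
        if d.size and np.any(d <= 0):
            row = int(np.flatnonzero(d <= 0)[0]) + 1
            raise FormatError(f"bin positions not strictly increasing at row {row}")

    @property
    def n_bins(self) -> int:
        return self.positions.size

    @property
    def span(self) -> float:
        """Time/space length of the record (last minus first bin position)."""
        return float(self.positions[-1] - self.positions[0])

    def as_dataset(self) -> Dataset:
        return Dataset(self.positions[:, None], self.amplitudes, task="regress")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_position": self.positions, "amplitude": self.amplitudes}
        )


def write_dataset(obj: Dataset | Waveform, path) -> None:
    """Write as headerized comma-delimited text."""
    obj.to_frame().to_csv(path, index=False)


def read_dataset(path, task: str) -> Dataset | Waveform:
    """Read a delimited-text file written by :func:`write_dataset`.

    ``task="classify"`` expects feature columns then a ``label`` column of
    +1/-1; ``task="regress"`` with two columns named ``bin_position`` and
    ``amplitude`` yields a :class:`Waveform`, otherwise a regression
    :class:`Dataset` whose last column is the target.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least two columns")
    if task == "regress" and list(df.columns) == ["bin_position", "amplitude"]:
        return Waveform(df["bin_position"].to_numpy(), df["amplitude"].to_numpy())
    X = df.iloc[:, :-1].to_numpy(dtype=float)
    y = df.iloc[:, -1].to_numpy(dtype=float)
    return Dataset(X, y, task=task, feature_names=list(df.columns[:-1]))
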