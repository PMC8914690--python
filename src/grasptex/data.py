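"""Datasets of labeled two-channel sEMG trials.

Supports the public "sEMG for Basic Hand movements" repository layout
(MAT-files with per-class trials x samples matrices, two channels), a
plain-CSV interchange format, and a synthetic generator that emulates
class-dependent amplitude-modulated colored noise for testing the full
pipeline without any download.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.io
import scipy.signal

__all__ = [
    "GraspClass",
    "SignalRecord",
    "Dataset",
    "concat_channels",
    "load_basic_hand_movements",
    "build_db3",
    "synth_dataset",
    "DEFAULT_MAT_NAMES",
]


class GraspClass(enum.Enum):
    """The six basic grasp types, in canonical row/column order."""

    C = "cylindrical"
    H = "hook"
    L = "lateral"
    P = "palmar"
    S = "spherical"
    T = "tip"

    @classmethod
    def ordered(cls) -> list["GraspClass"]:
        return [cls.C, cls.H, cls.L, cls.P, cls.S, cls.T]

    @property
    def index(self) -> int:
        return GraspClass.ordered().index(self)


#: Default MAT variable stems used by the public repository files
#: (e.g. ``cyl_ch1``/``cyl_ch2``). Override via ``mat_names=``.
DEFAULT_MAT_NAMES: Mapping[GraspClass, str] = {
    GraspClass.C: "cyl",
    GraspClass.H: "hook",
    GraspClass.L: "lat",
    GraspClass.P: "palm",
    GraspClass.S: "spher",
    GraspClass.T: "tip",
}


@dataclasses.dataclass
class SignalRecord:
    """One labeled two-channel sEMG trial."""

    ch1: np.ndarray
    ch2: np.ndarray
    fs: float
    label: GraspClass
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        if self.ch1.ndim != 1 or self.ch2.ndim != 1:
            raise ValueError("channels must be one-dimensional")
        if len(self.ch1) != len(self.ch2) or len(self.ch1) == 0:
            raise ValueError("channels must have equal, nonzero lengths")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def signal(self) -> np.ndarray:
        """The concatenated two-channel signal (channel 1 then channel 2)."""
        return concat_channels(self.ch1, self.ch2)


@dataclasses.dataclass
class Dataset:
    """An ordered collection of :class:`SignalRecord` sharing a sampling rate."""

    records: list[SignalRecord]
    name: str = "unnamed"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("dataset must contain at least one record")
        fs = {r.fs for r in self.records}
        if len(fs) != 1:
            raise ValueError(f"records must share one sampling rate, got {sorted(fs)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def fs(self) -> float:
        return self.records[0].fs

    @property
    def labels(self) -> list[GraspClass]:
        return [r.label for r in self.records]

    def class_counts(self) -> dict[GraspClass, int]:
        counts = {c: 0 for c in GraspClass.ordered()}
        for r in self.records:
            counts[r.label] += 1
        return counts

    def to_csv(self, path: str | Path) -> None:
        """Write interchange CSV: one row per trial channel (label, channel, samples)."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# dataset={self.name} fs={self.fs:g}\n")
            for rec in self.records:
                for chan, data in ((1, rec.ch1), (2, rec.ch2)):
                    vals = ",".join(repr(float(v)) for v in data)
                    fh.write(f"{rec.label.name},{chan},{vals}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        name, fs = "csv", 500.0
        rows: list[tuple[GraspClass, int, np.ndarray]] = []
        with path.open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    for tok in line.lstrip("#").split():
                        key, _, val = tok.partition("=")
                        if key == "dataset":
                            name = val
                        elif key == "fs":
                            fs = float(val)
                    continue
                parts = line.split(",")
                label = GraspClass[parts[0]]
                chan = int(parts[1])
                rows.append((label, chan, np.array([float(v) for v in parts[2:]])))
        if len(rows) % 2 != 0:
            raise ValueError("interchange CSV must pair channel 1/2 rows")
        records = []
        for (lab1, c1, ch1), (lab2, c2, ch2) in zip(rows[0::2], rows[1::2]):
            if lab1 is not lab2 or (c1, c2) != (1, 2):
                raise ValueError("malformed interchange CSV: expected ch1 row then ch2 row")
            records.append(SignalRecord(ch1, ch2, fs, lab1))
        return cls(records, name=name)


def concat_channels(ch1: Sequence[float], ch2: Sequence[float]) -> np.ndarray:
    """Concatenate the two channels into the single input sEMG signal.

    The output holds channel 1 followed by channel 2, order preserved.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.ndim != 1 or ch2.ndim != 1:
        raise ValueError("channels must be one-dimensional")
    if len(ch1) == 0 or len(ch2) == 0:
        raise ValueError("channels must be nonempty")
    if len(ch1) != len(ch2):
        raise ValueError(f"channel length mismatch: {len(ch1)} != {len(ch2)}")
    return np.concatenate([ch1, ch2])


def _read_mat(path: Path) -> dict[str, np.ndarray]:
    """Read a level-5 or v7.3 (HDF5) MAT-file into plain arrays."""
    try:
        raw = scipy.io.loadmat(path)
        return {k: np.asarray(v) for k, v in raw.items() if not k.startswith("__")}
    except NotImplementedError:
        import h5py

        out: dict[str, np.ndarray] = {}
        with h5py.File(path, "r") as fh:
            for key in fh:
                if key.startswith("#"):
                    continue
                # MATLAB v7.3 stores arrays transposed
                out[key] = np.asarray(fh[key]).T
        return out


def load_basic_hand_movements(
    path: str | Path,
    dataset_id: str = "DB1",
    fs: float = 500.0,
    mat_names: Mapping[GraspClass, str] = DEFAULT_MAT_NAMES,
) -> Dataset:
    """Load a directory of per-subject/session MAT-files.

    Each file must hold, per class, two trials-by-samples matrices named
    ``<stem>_ch1`` and ``<stem>_ch2``. Records are ordered by class
    (C,H,L,P,S,T), then by sorted file name, then by trial row, so two
    loads of the same directory are identical.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {path}")
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".mat")
    if not files:
        raise FileNotFoundError(f"no MAT-files in {path}")
    contents = [(p.name, _read_mat(p)) for p in files]

    records: list[SignalRecord] = []
    for cls in GraspClass.ordered():
        stem = mat_names[cls]
        for fname, variables in contents:
            k1, k2 = f"{stem}_ch1", f"{stem}_ch2"
            if k1 not in variables or k2 not in variables:
                raise ValueError(
                    f"{fname}: expected variables {k1!r}/{k2!r}; "
                    f"found {sorted(variables)} (pass mat_names= for other dialects)"
                )
            m1, m2 = np.atleast_2d(variables[k1]), np.atleast_2d(variables[k2])
            if m1.shape != m2.shape:
                raise ValueError(
                    f"{fname}: channel matrices disagree: {m1.shape} vs {m2.shape}"
                )
            for trial in range(m1.shape[0]):
                records.append(
                    SignalRecord(
                        m1[trial],
                        m2[trial],
                        fs,
                        cls,
                        meta={"file": fname, "trial": trial, "dataset": dataset_id},
                    )
                )
    return Dataset(records, name=dataset_id)


def build_db3(db1: Dataset, db2: Dataset) -> Dataset:
    """Merge two labeled datasets into the fused dataset."""
    if abs(db1.fs - db2.fs) > 0:
        raise ValueError(f"sampling-rate mismatch: {db1.fs} vs {db2.fs}")
    c1, c2 = db1.class_counts(), db2.class_counts()
    if set(k for k, v in c1.items() if v) != set(k for k, v in c2.items() if v):
        raise ValueError("class-set mismatch between datasets")
    return Dataset(list(db1.records) + list(db2.records), name="DB3")


# Class-dependent AR(4) resonator frequencies (Hz at fs=500): two conjugate
# pole pairs per class, spread apart by `separation`.
_BASE_F1 = 30.0
_BASE_F2 = 90.0
_STEP_F1 = 12.0
_STEP_F2 = 16.0
_POLE_RADIUS = 0.95


def _ar4_coeffs(f1: float, f2: float, fs: float) -> np.ndarray:
    poles = []
    for f in (f1, f2):
        w = 2 * np.pi * f / fs
        poles += [_POLE_RADIUS * np.exp(1j * w), _POLE_RADIUS * np.exp(-1j * w)]
    return np.real(np.poly(poles))


def synth_dataset(
    n_per_class: int = 30,
    duration_s: float = 6.0,
    fs: float = 500.0,
    seed: int = 0,
    separation: float = 1.0,
) -> Dataset:
    """Generate a labeled synthetic two-channel dataset.

    Each grasp class is an order-4 autoregressive process (two resonant
    pole pairs at class-specific frequencies, spread by ``separation``)
    with unit-variance Gaussian innovations under a class-scaled Hann
    amplitude envelope — sEMG modeled as amplitude-modulated colored
    noise. Fully reproducible from ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    n_samples = int(round(duration_s * fs))
    if 2 * n_samples < 49:
        raise ValueError("duration_s * fs too small: concatenated length must be >= 49")
    rng = np.random.default_rng(seed)
    envelope = 0.25 + np.hanning(n_samples)
    records: list[SignalRecord] = []
    for cls in GraspClass.ordered():
        k = cls.index
        f1 = _BASE_F1 + _STEP_F1 * k * separation
        f2 = _BASE_F2 + _STEP_F2 * k * separation
        a = _ar4_coeffs(f1, f2, fs)
        amp = 1.0 + 0.2 * k
        for trial in range(n_per_class):
            chans = []
            for _ in range(2):
                x = scipy.signal.lfilter([1.0], a, rng.standard_normal(n_samples))
                chans.append(amp * envelope * x)
            records.append(
                SignalRecord(
                    chans[0],
                    chans[1],
                    fs,
                    cls,
                    meta={"trial": trial, "dataset": "synthetic"},
                )
            )
    return Dataset(records, name="synthetic")
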