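"""Reading, cleaning, windowing and splitting of wearable-sensor recordings.

Two on-disk dialects are supported: the UCI Pamap2 per-subject files
(54 space-separated columns at 100 Hz; wrist, chest and ankle IMUs) and
the UCI Opportunity per-run files (250 columns at 30 Hz; five upper-body
IMUs).  Both readers keep only the triaxial accelerometer, gyroscope and
magnetometer signals — 27 signals for Pamap2, 45 for Opportunity — and
the activity/gesture label track, interpolate missing samples and, for
Pamap2, decimate 100 Hz to 50 Hz.

The column layouts live in versioned JSON maps under
``cbamhar/column_maps/`` rather than in code.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "Recording",
    "WindowedDataset",
    "FormatError",
    "read_pamap2",
    "write_pamap2",
    "read_opportunity",
    "write_opportunity",
    "segment_windows",
    "windows_from_recordings",
    "split_holdout",
    "kfold",
    "pamap2_class_names",
    "opportunity_class_names",
]


class FormatError(ValueError):
    """An input file does not match the expected on-disk dialect."""


def _load_column_map(name: str) -> dict:
    with resources.files("cbamhar.column_maps").joinpath(f"{name}.json").open() as fh:
        return json.load(fh)


def pamap2_class_names() -> list[str]:
    return [a["name"] for a in _load_column_map("pamap2")["protocol_activities"]]


def opportunity_class_names() -> list[str]:
    return [g["name"] for g in _load_column_map("opportunity")["gestures"]]


@dataclass
class Recording:
    """A contiguous multichannel sensor stream with per-step labels."""

    signals: np.ndarray  # (T, D)
    labels: np.ndarray  # (T,) integer class ids
    sample_rate: float
    source_id: str = ""

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.signals.ndim != 2:
            raise FormatError("signals must be a (time, signals) matrix")
        if len(self.signals) != len(self.labels):
            raise FormatError("signals and labels must have equal length")
        if self.sample_rate <= 0:
            raise FormatError("sample rate must be positive")

    @property
    def n_steps(self) -> int:
        return self.signals.shape[0]

    @property
    def n_signals(self) -> int:
        return self.signals.shape[1]


@dataclass
class WindowedDataset:
    """Fixed-length windows with labels, optional split/fold assignment.

    ``recording_ids`` and ``starts`` record where each window came from;
    they give windows a stable identity so that split assignment does not
    depend on the order windows happen to be stored in.
    """

    windows: np.ndarray  # (N, H, D)
    labels: np.ndarray  # (N,)
    class_names: list[str]
    recording_ids: np.ndarray  # (N,) str
    starts: np.ndarray  # (N,) int, start sample within the recording
    split: Optional[np.ndarray] = None  # entries in {"train", "val", "test"}
    fold: Optional[np.ndarray] = None  # (N,) int fold index
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.windows = np.asarray(self.windows)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.windows.ndim != 3:
            raise FormatError("windows must be (N, H, D)")
        n = len(self.windows)
        if not (len(self.labels) == len(self.recording_ids) == len(self.starts) == n):
            raise FormatError("per-window arrays must share the leading dimension")
        if n and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise FormatError("window labels outside [0, n_classes)")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def window_shape(self) -> tuple[int, int]:
        return self.windows.shape[1], self.windows.shape[2]

    def subset(self, split: Optional[str] = None, fold: Optional[int] = None,
               exclude_fold: Optional[int] = None) -> "WindowedDataset":
        mask = np.ones(len(self.windows), dtype=bool)
        if split is not None:
            if self.split is None:
                raise ValueError("dataset has no split assignment")
            mask &= self.split == split
        if fold is not None:
            if self.fold is None:
                raise ValueError("dataset has no fold assignment")
            mask &= self.fold == fold
        if exclude_fold is not None:
            if self.fold is None:
                raise ValueError("dataset has no fold assignment")
            mask &= self.fold != exclude_fold
        return WindowedDataset(
            windows=self.windows[mask],
            labels=self.labels[mask],
            class_names=list(self.class_names),
            recording_ids=self.recording_ids[mask],
            starts=self.starts[mask],
            split=None if self.split is None else self.split[mask],
            fold=None if self.fold is None else self.fold[mask],
            provenance=dict(self.provenance),
        )

    # -- serialization: one array container plus a JSON sidecar ------------

    def save(self, path) -> None:
        path = Path(path)
        arrays = dict(
            windows=self.windows,
            labels=self.labels,
            recording_ids=self.recording_ids.astype(str),
            starts=self.starts,
        )
        if self.split is not None:
            arrays["split"] = self.split.astype(str)
        if self.fold is not None:
            arrays["fold"] = self.fold
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        sidecar = dict(class_names=self.class_names, provenance=self.provenance)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "WindowedDataset":
        path = Path(path)
        with np.load(path.with_suffix(".npz"), allow_pickle=False) as z:
            arrays = {k: z[k] for k in z.files}
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            windows=arrays["windows"],
            labels=arrays["labels"],
            class_names=sidecar["class_names"],
            recording_ids=arrays["recording_ids"],
            starts=arrays["starts"],
            split=arrays.get("split"),
            fold=arrays.get("fold"),
            provenance=sidecar.get("provenance", {}),
        )


# ---------------------------------------------------------------------------
# cleaning helpers


def _interpolate_nan(signals: np.ndarray) -> np.ndarray:
    """Linear interpolation of interior NaN runs, nearest value at edges."""
    df = pd.DataFrame(signals)
    df = df.interpolate(method="linear", limit_direction="both", axis=0)
    return df.to_numpy()


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) index ranges of True runs in *mask*."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts, stops))


# ---------------------------------------------------------------------------
# Pamap2


def read_pamap2(paths: Iterable, accelerometer: str = "16g",
                target_rate: float = 50.0) -> list[Recording]:
    """Read UCI Pamap2 ``.dat`` files into cleaned recordings.

    Keeps accelerometer/gyroscope/magnetometer x, y, z of the wrist,
    chest and ankle IMUs (27 signals), the 12 protocol activities, drops
    transient/optional rows, interpolates NaNs and decimates 100 Hz to
    *target_rate*.  Each contiguous run of kept rows becomes its own
    :class:`Recording` so no window can span a gap.

    Parameters
    ----------
    accelerometer:
        Which of the two Pamap2 accelerometers to use, ``"16g"`` or
        ``"6g"``.
    """
    cmap = _load_column_map("pamap2")
    if accelerometer not in ("16g", "6g"):
        raise ValueError("accelerometer must be '16g' or '6g'")
    acc_key = f"acc_{accelerometer}"
    offsets = cmap["imu_block_offsets"]
    signal_cols = []
    for block_start in cmap["imu_blocks"].values():
        for key in (acc_key, "gyro", "mag"):
            signal_cols += [block_start + o for o in offsets[key]]
    id_to_class = {a["id"]: i for i, a in enumerate(cmap["protocol_activities"])}
    native = cmap["native_rate_hz"]
    factor = max(1, int(round(native / target_rate)))

    recordings: list[Recording] = []
    for path in paths:
        path = Path(path)
        try:
            table = pd.read_csv(path, sep=r"\s+", header=None, comment=None)
        except pd.errors.EmptyDataError:
            continue
        if table.shape[1] != cmap["n_columns"]:
            raise FormatError(
                f"{path}: expected {cmap['n_columns']} columns, found {table.shape[1]}"
            )
        raw = table.to_numpy(dtype=float)
        activity = raw[:, cmap["activity_col"]].astype(int)
        keep = np.isin(activity, list(id_to_class))
        for run_no, (start, stop) in enumerate(_contiguous_runs(keep)):
            signals = _interpolate_nan(raw[start:stop, signal_cols])
            labels = np.array([id_to_class[a] for a in activity[start:stop]])
            signals = signals[::factor]
            labels = labels[::factor]
            if len(signals) == 0:
                continue
            recordings.append(
                Recording(signals, labels, native / factor,
                          source_id=f"{path.stem}#{run_no}")
            )
    return recordings


def write_pamap2(rec: Recording, path, class_names: Optional[Sequence[str]] = None
                 ) -> None:
    """Write a 27-signal recording in the Pamap2 dialect (for fixtures).

    Unused columns (temperature, the other accelerometer, orientation,
    heart rate) are emitted as NaN.
    """
    cmap = _load_column_map("pamap2")
    if rec.n_signals != 27:
        raise FormatError("Pamap2 dialect requires 27 signals")
    names = list(class_names or pamap2_class_names())
    class_to_id = {
        names.index(a["name"]): a["id"]
        for a in cmap["protocol_activities"] if a["name"] in names
    }
    offsets = cmap["imu_block_offsets"]
    n = rec.n_steps
    out = np.full((n, cmap["n_columns"]), np.nan)
    out[:, cmap["timestamp_col"]] = np.arange(n) / rec.sample_rate
    out[:, cmap["activity_col"]] = [class_to_id[l] for l in rec.labels]
    col = 0
    for block_start in cmap["imu_blocks"].values():
        for key in ("acc_16g", "gyro", "mag"):
            for o in offsets[key]:
                out[:, block_start + o] = rec.signals[:, col]
                col += 1
    _write_dat(out, path)


# ---------------------------------------------------------------------------
# Opportunity


def read_opportunity(paths: Iterable) -> list[Recording]:
    """Read UCI Opportunity ``.dat`` files into cleaned recordings.

    Keeps accelerometer/gyroscope/magnetometer x, y, z of the five
    upper-body IMUs (45 signals) and the mid-level gesture label track
    (17 gestures plus the dominant null class).  The native 30 Hz rate is
    retained; NaNs are interpolated.
    """
    cmap = _load_column_map("opportunity")
    signal_cols = [
        block - 1 + o
        for block in cmap["imu_blocks"].values()
        for o in cmap["imu_signal_offsets"]
    ]
    label_col = cmap["gesture_label_col"] - 1
    code_to_class = {g["code"]: i for i, g in enumerate(cmap["gestures"])}

    recordings: list[Recording] = []
    for path in paths:
        path = Path(path)
        try:
            table = pd.read_csv(path, sep=r"\s+", header=None)
        except pd.errors.EmptyDataError:
            continue
        if table.shape[1] != cmap["n_columns"]:
            raise FormatError(
                f"{path}: expected {cmap['n_columns']} columns, found {table.shape[1]}"
            )
        raw = table.to_numpy(dtype=float)
        codes = raw[:, label_col].astype(int)
        unknown = set(np.unique(codes)) - set(code_to_class)
        if unknown:
            raise FormatError(f"{path}: unknown gesture codes {sorted(unknown)}")
        signals = _interpolate_nan(raw[:, signal_cols])
        labels = np.array([code_to_class[c] for c in codes])
        if len(np.unique(labels)) == 1:
            warnings.warn(f"{path}: single-class recording (all '"
                          f"{cmap['gestures'][labels[0]]['name']}')", stacklevel=2)
        recordings.append(
            Recording(signals, labels, cmap["native_rate_hz"], source_id=path.stem)
        )
    return recordings


def write_opportunity(rec: Recording, path) -> None:
    """Write a 45-signal recording in the Opportunity dialect (for fixtures)."""
    cmap = _load_column_map("opportunity")
    if rec.n_signals != 45:
        raise FormatError("Opportunity dialect requires 45 signals")
    codes = [g["code"] for g in cmap["gestures"]]
    n = rec.n_steps
    out = np.full((n, cmap["n_columns"]), np.nan)
    out[:, cmap["timestamp_col"] - 1] = np.arange(n) * 1000.0 / rec.sample_rate
    out[:, cmap["gesture_label_col"] - 1] = [codes[l] for l in rec.labels]
    col = 0
    for block in cmap["imu_blocks"].values():
        for o in cmap["imu_signal_offsets"]:
            out[:, block - 1 + o] = rec.signals[:, col]
            col += 1
    _write_dat(out, path)


def _write_dat(matrix: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for row in matrix:
            fh.write(" ".join("NaN" if np.isnan(v) else f"{v:.6g}" for v in row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# windowing


def _window_label(labels: np.ndarray) -> int:
    """Majority label; on a tie prefer the last time step's label, then the
    tied label occurring latest in the window."""
    counts = np.bincount(labels)
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if len(tied) == 1:
        return int(tied[0])
    last = labels[-1]
    if last in tied:
        return int(last)
    last_pos = {int(l): i for i, l in enumerate(labels)}
    return int(max(tied, key=lambda l: last_pos[int(l)]))


def segment_windows(rec: Recording, window_length: int, overlap: float,
                    class_names: Optional[Sequence[str]] = None) -> WindowedDataset:
    """Slide fixed-length windows over one recording.

    Step is ``round(H * (1 - overlap))`` (at least 1); the tail shorter
    than one window is dropped, so a recording shorter than ``H`` yields
    zero windows.  Each window is labelled by majority vote.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    if window_length < 1:
        raise ValueError("window length must be >= 1")
    h = int(window_length)
    step = max(1, int(round(h * (1.0 - overlap))))
    starts = np.arange(0, rec.n_steps - h + 1, step)
    windows = np.stack([rec.signals[s:s + h] for s in starts]) if len(starts) else \
        np.empty((0, h, rec.n_signals))
    labels = np.array([_window_label(rec.labels[s:s + h]) for s in starts], dtype=int)
    if class_names is None:
        n_cls = int(rec.labels.max()) + 1 if rec.n_steps else 0
        class_names = [f"class_{i}" for i in range(n_cls)]
    return WindowedDataset(
        windows=windows,
        labels=labels,
        class_names=list(class_names),
        recording_ids=np.array([rec.source_id] * len(starts), dtype=str),
        starts=starts.astype(int),
        provenance=dict(window_length=h, overlap=overlap, step=step),
    )


def windows_from_recordings(recordings: Sequence[Recording], window_length: int,
                            overlap: float, class_names: Sequence[str]
                            ) -> WindowedDataset:
    """Window each recording separately and concatenate; no window spans a
    recording boundary."""
    parts = [segment_windows(r, window_length, overlap, class_names)
             for r in recordings]
    parts = [p for p in parts if len(p.windows)]
    if not parts:
        h = int(window_length)
        d = recordings[0].n_signals if recordings else 0
        return WindowedDataset(np.empty((0, h, d)), np.empty(0, dtype=int),
                               list(class_names), np.empty(0, dtype=str),
                               np.empty(0, dtype=int))
    return WindowedDataset(
        windows=np.concatenate([p.windows for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        class_names=list(class_names),
        recording_ids=np.concatenate([p.recording_ids for p in parts]),
        starts=np.concatenate([p.starts for p in parts]),
        provenance=parts[0].provenance,
    )


# ---------------------------------------------------------------------------
# splits


def _canonical_order(ds: WindowedDataset) -> np.ndarray:
    """Window identity order (recording id, start sample) — independent of
    storage order."""
    return np.lexsort((ds.starts, ds.recording_ids))


def split_holdout(ds: WindowedDataset, fractions=(0.60, 0.20, 0.20),
                  seed: int = 0) -> WindowedDataset:
    """Stratified random train/test/val assignment.

    *fractions* are (train, test, val) shares.  Assignment is computed on
    the canonical window order, so shuffling the dataset's storage order
    does not change which window lands in which split.  A class with
    fewer than 3 windows is kept whole in the training split (with a
    warning).
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = _canonical_order(ds)
    split = np.empty(len(ds.windows), dtype="<U5")
    names = ("train", "test", "val")
    for cls in range(ds.n_classes):
        cls_idx = order[ds.labels[order] == cls]
        n = len(cls_idx)
        if n == 0:
            continue
        if n < 3:
            warnings.warn(
                f"class {ds.class_names[cls]!r} has only {n} window(s); kept in train",
                stacklevel=2,
            )
            split[cls_idx] = "train"
            continue
        perm = cls_idx[rng.permutation(n)]
        # largest-remainder allocation of the three shares
        exact = np.array(fractions) * n
        counts = np.floor(exact).astype(int)
        rem = np.argsort(-(exact - counts))
        for i in range(n - counts.sum()):
            counts[rem[i % 3]] += 1
        pos = 0
        for name, cnt in zip(names, counts):
            split[perm[pos:pos + cnt]] = name
            pos += cnt
    out = ds.subset()  # copy
    out.split = split
    out.provenance = dict(ds.provenance, split_seed=seed,
                          split_fractions=tuple(fractions), split_mode="window-wise")
    return out


def kfold(ds: WindowedDataset, k: int = 5, seed: int = 0) -> WindowedDataset:
    """Stratified k-fold assignment over windows (canonical order)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ds.windows) < k:
        raise ValueError(f"need at least k={k} windows, have {len(ds.windows)}")
    order = _canonical_order(ds)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(len(ds.windows), dtype=int)
    y = ds.labels[order]
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold[order[test_idx]] = f
    out = ds.subset()
    out.fold = fold
    out.provenance = dict(ds.provenance, kfold_seed=seed, k=k,
                          split_mode="window-wise")
    return out
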