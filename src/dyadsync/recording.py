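"""Core containers and on-disk formats for dual-EEG sessions.

A recording is stored as one numeric matrix per subject (``subject1.npy``,
``subject2.npy``; channels x samples, microvolts) plus a JSON sidecar with
sampling rate, channel labels and subject roles. Segment tables are TSV.
Time coordinates are milliseconds, 0-based, with half-open intervals
[onset, offset).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import EOG_CHANNELS

#: behavioral segment identifiers of one room-clearing trial
SEGMENT_IDS: tuple[str, ...] = (
    "s0", "s1", "s2", "s3", "s4", "s5", "s6", "s7a", "s7b", "s8", "s9",
)

ROLES = ("leader", "follower")


@dataclass
class DualRecording:
    """Synchronized two-subject multichannel EEG + EOG.

    Attributes
    ----------
    samples : ndarray, shape (2, n_channels, n_samples)
        Signals in microvolts; subject axis first.
    fs : float
        Sampling rate in Hz, shared by both subjects.
    channels : tuple of two tuples of str
        Ordered channel labels per subject (scalp + EOG).
    roles : tuple of str
        Role of each subject, e.g. ``("leader", "follower")``.
    t0 : float
        Recording start time in ms.
    """

    samples: np.ndarray
    fs: float
    channels: tuple[tuple[str, ...], tuple[str, ...]]
    roles: tuple[str, str] = ROLES
    t0: float = 0.0
    eog_labels: frozenset[str] = frozenset(EOG_CHANNELS)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 3 or self.samples.shape[0] != 2:
            raise ValueError("samples must have shape (2, n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channels = (tuple(self.channels[0]), tuple(self.channels[1]))
        for s, labels in enumerate(self.channels):
            if len(labels) != len(set(labels)):
                raise ValueError(f"duplicate channel labels for subject {s + 1}")
            if len(labels) != self.samples.shape[1]:
                raise ValueError(
                    f"subject {s + 1}: {len(labels)} labels for "
                    f"{self.samples.shape[1]} channel rows"
                )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if sorted(self.roles) != sorted(ROLES):
            raise ValueError(f"roles must be a permutation of {ROLES}")

    # -- geometry -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.samples.shape[2]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.fs

    def scalp_indices(self, subject: int) -> np.ndarray:
        return np.array(
            [i for i, lbl in enumerate(self.channels[subject])
             if lbl not in self.eog_labels],
            dtype=int,
        )

    def scalp_labels(self, subject: int) -> tuple[str, ...]:
        return tuple(lbl for lbl in self.channels[subject]
                     if lbl not in self.eog_labels)

    @property
    def n_scalp(self) -> int:
        """Scalp electrode count k per subject (equal for both subjects)."""
        k0, k1 = len(self.scalp_indices(0)), len(self.scalp_indices(1))
        if k0 != k1:
            raise ValueError("subjects have unequal scalp channel counts")
        return k0

    def scalp_data(self, subject: int) -> np.ndarray:
        """(k, n_samples) scalp signals of one subject, montage order."""
        return self.samples[subject, self.scalp_indices(subject), :]

    def dyad_data(self) -> np.ndarray:
        """(2k, n_samples) scalp signals of the dyad.

        Dyad electrodes are numbered subject 1 first (rows 0..k-1) then
        subject 2 (rows k..2k-1), matching the pair-indexing convention
        used for coherence.
        """
        return np.vstack([self.scalp_data(0), self.scalp_data(1)])

    def eog_data(self, subject: int, label: str = "VEOG") -> np.ndarray:
        try:
            idx = self.channels[subject].index(label)
        except ValueError:
            raise KeyError(f"subject {subject + 1} has no channel {label!r}")
        return self.samples[subject, idx, :]

    def subject_of_role(self, role: str) -> int:
        return self.roles.index(role)

    def ms_to_sample(self, t_ms: float) -> int:
        return int(round((t_ms - self.t0) * self.fs / 1000.0))


# -- recording container I/O ------------------------------------------


def save_recording(rec: DualRecording, path: str | Path) -> Path:
    """Write a recording to a directory container (npy + JSON sidecar)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for s in (0, 1):
        np.save(path / f"subject{s + 1}.npy", rec.samples[s])
    meta = {
        "fs": rec.fs,
        "t0": rec.t0,
        "roles": list(rec.roles),
        "channels": [list(rec.channels[0]), list(rec.channels[1])],
        "units": "uV",
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def load_recording(path: str | Path,
                   subject_map: dict | None = None) -> DualRecording:
    """Load a recording container written by :func:`save_recording`.

    Parameters
    ----------
    subject_map : dict, optional
        Optional requirements: ``{"roles": (r1, r2), "require_channels":
        [labels...]}``. Missing required channels raise a descriptive error.
    """
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise FileNotFoundError(f"no recording container at {path}")
    meta = json.loads(meta_file.read_text())
    mats = [np.load(path / f"subject{s + 1}.npy") for s in (0, 1)]
    if mats[0].shape[1] != mats[1].shape[1]:
        raise ValueError(
            f"subjects have mismatched sample counts: "
            f"{mats[0].shape[1]} vs {mats[1].shape[1]}"
        )
    channels = (tuple(meta["channels"][0]), tuple(meta["channels"][1]))
    roles = tuple(meta["roles"])
    if subject_map:
        roles = tuple(subject_map.get("roles", roles))
        for lbl in subject_map.get("require_channels", ()):
            for s in (0, 1):
                if lbl not in channels[s]:
                    raise KeyError(
                        f"channel {lbl!r} missing for subject {s + 1}"
                    )
    return DualRecording(
        samples=np.stack(mats), fs=float(meta["fs"]), channels=channels,
        roles=roles, t0=float(meta.get("t0", 0.0)),
    )


# -- segment table -----------------------------------------------------


@dataclass
class SegmentTable:
    """Per-trial onsets/offsets (ms, half-open) of behavioral segments.

    Rows are sorted by (trial, onset); segments within a trial must be
    non-overlapping and have positive duration.
    """

    df: pd.DataFrame = field(repr=False)

    COLUMNS = ("trial", "segment", "onset_ms", "offset_ms")

    def __post_init__(self) -> None:
        df = self.df
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"segment table missing columns {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        unknown = set(df["segment"]) - set(SEGMENT_IDS)
        if unknown:
            raise ValueError(f"unknown segment ids {sorted(unknown)}")
        if (df["offset_ms"] <= df["onset_ms"]).any():
            bad = df.loc[df["offset_ms"] <= df["onset_ms"], "trial"].tolist()
            raise ValueError(f"segments with offset <= onset in trials {bad}")
        df = df.sort_values(["trial", "onset_ms"], kind="mergesort")
        for trial, grp in df.groupby("trial"):
            on = grp["onset_ms"].to_numpy()
            off = grp["offset_ms"].to_numpy()
            if (on[1:] < off[:-1]).any():
                raise ValueError(f"overlapping segments in trial {trial}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def trials(self) -> np.ndarray:
        return self.df["trial"].unique()

    def rows(self, segment: str | None = None,
             trial: int | None = None) -> pd.DataFrame:
        df = self.df
        if segment is not None:
            df = df[df["segment"] == segment]
        if trial is not None:
            df = df[df["trial"] == trial]
        return df

    def s1_durations(self) -> pd.Series:
        """Segment-s1 duration per trial (ms); trials without s1 are absent."""
        s1 = self.rows(segment="s1")
        return (s1["offset_ms"] - s1["onset_ms"]).set_axis(s1["trial"].values)


def save_segments(table: SegmentTable, path: str | Path) -> Path:
    path = Path(path)
    table.df.to_csv(path, sep="\t", index=False)
    return path


def load_segments(path: str | Path) -> SegmentTable:
    """Read a TSV segment table (columns trial, segment, onset_ms, offset_ms)."""
    df = pd.read_csv(path, sep="\t")
    return SegmentTable(df)
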