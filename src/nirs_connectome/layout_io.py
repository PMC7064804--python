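"""Channel layouts, hemoglobin recordings, matrices and cohort tables.

Every file format used by the pipeline is tab-delimited UTF-8 text: a
layout table describing the optode channels, plain numeric matrices for
recordings and connectivity, and a cohort table with group labels,
covariates and symptom scores.  Channel ordering is always the layout-file
order; matrices never carry their own ordering.

Floats are written with ``%.17g`` so every ``write`` / ``load`` pair is the
identity on IEEE-754 doubles.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import numpy as np
import pandas as pd

NETWORK_LABELS = frozenset(
    {
        "default",
        "frontoparietal",
        "ventral_attention",
        "somatomotor",
        "dorsal_attention",
        "visual",
        "unassigned",
    }
)
HEMISPHERES = frozenset({"left", "right", "midline"})
SPECIES = frozenset({"HbO", "HbR"})
GROUPS = frozenset({"patient", "control"})
SEXES = frozenset({"male", "female"})

LAYOUT_COLUMNS = [
    "channel_id",
    "source_id",
    "detector_id",
    "x_mm",
    "y_mm",
    "z_mm",
    "network_label",
    "hemisphere",
    "homolog_id",
]

COHORT_COLUMNS = [
    "subject_id",
    "group",
    "age_months",
    "sex",
    "education_years",
    "inattentive",
    "hyperactive_impulsive",
    "total",
]

_FLOAT_FMT = "%.17g"


class LayoutError(ValueError):
    """Raised when a channel layout violates its invariants."""


class RecordingError(ValueError):
    """Raised when a recording file is malformed."""


class CohortError(ValueError):
    """Raised when a cohort table violates its invariants."""


@dataclasses.dataclass(frozen=True)
class ChannelMap:
    """Per-channel metadata for a multichannel fNIRS montage.

    ``homolog_id`` of 0 means the channel has no contralateral homolog
    (midline channels, or montages without mirror symmetry).
    """

    channel_id: np.ndarray  # int, 1..N contiguous
    source_id: np.ndarray
    detector_id: np.ndarray
    position: np.ndarray  # (N, 3) mm, arbitrary head frame
    network_label: np.ndarray  # str
    hemisphere: np.ndarray  # str
    homolog_id: np.ndarray  # int, 0 = none

    def __post_init__(self) -> None:
        ids = np.asarray(self.channel_id, dtype=int)
        n = ids.size
        if n == 0:
            raise LayoutError("layout has no channels")
        if len(set(ids.tolist())) != n:
            raise LayoutError("duplicate channel_id values")
        if not np.array_equal(np.sort(ids), np.arange(1, n + 1)):
            raise LayoutError("channel_ids must be contiguous 1..N")
        bad = set(self.network_label.tolist()) - NETWORK_LABELS
        if bad:
            raise LayoutError(f"unknown network label(s): {sorted(bad)}")
        bad = set(self.hemisphere.tolist()) - HEMISPHERES
        if bad:
            raise LayoutError(f"unknown hemisphere value(s): {sorted(bad)}")
        if self.position.shape != (n, 3):
            raise LayoutError("position must be an (N, 3) array")
        # Symmetric homolog closure: homolog(homolog(c)) == c, and a pair
        # never shares a hemisphere; midline channels have no homolog.
        idx = {c: i for i, c in enumerate(ids.tolist())}
        for i, h in enumerate(np.asarray(self.homolog_id, dtype=int).tolist()):
            if h == 0:
                continue
            if h not in idx:
                raise LayoutError(
                    f"channel {ids[i]} lists unknown homolog {h}"
                )
            j = idx[h]
            if int(self.homolog_id[j]) != int(ids[i]):
                raise LayoutError(
                    f"asymmetric homolog pair: channel {ids[i]} lists {h} "
                    f"but channel {h} lists {int(self.homolog_id[j])}"
                )
            if self.hemisphere[i] == self.hemisphere[j]:
                raise LayoutError(
                    f"homolog pair ({ids[i]}, {h}) shares hemisphere "
                    f"'{self.hemisphere[i]}'"
                )
            if self.hemisphere[i] == "midline" or self.hemisphere[j] == "midline":
                raise LayoutError(
                    f"midline channel in homolog pair ({ids[i]}, {h})"
                )

    def __len__(self) -> int:
        return int(self.channel_id.size)

    @property
    def n_channels(self) -> int:
        return len(self)

    def index_of(self, channel_id: int) -> int:
        """Row index of a channel id (ids are contiguous 1..N in file order)."""
        pos = int(np.flatnonzero(self.channel_id == channel_id)[0])
        return pos

    def homolog_of(self, channel_id: int) -> int | None:
        h = int(self.homolog_id[self.index_of(channel_id)])
        return h if h != 0 else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_id": self.channel_id,
                "source_id": self.source_id,
                "detector_id": self.detector_id,
                "x_mm": self.position[:, 0],
                "y_mm": self.position[:, 1],
                "z_mm": self.position[:, 2],
                "network_label": self.network_label,
                "hemisphere": self.hemisphere,
                "homolog_id": self.homolog_id,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChannelMap":
        missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
        if missing:
            raise LayoutError(f"layout missing column(s): {missing}")
        return cls(
            channel_id=df["channel_id"].to_numpy(dtype=int),
            source_id=df["source_id"].to_numpy(dtype=int),
            detector_id=df["detector_id"].to_numpy(dtype=int),
            position=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
            network_label=df["network_label"].to_numpy(dtype=str),
            hemisphere=df["hemisphere"].to_numpy(dtype=str),
            homolog_id=df["homolog_id"].fillna(0).to_numpy(dtype=int),
        )


@dataclasses.dataclass
class HemoglobinRecording:
    """Channels x samples concentration-change time series (micromolar)."""

    subject_id: str
    species: str  # "HbO" or "HbR"
    data: np.ndarray  # (n_channels, n_samples)
    fs: float  # Hz
    channel_ids: np.ndarray  # ordered, matching rows

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        if self.species not in SPECIES:
            raise RecordingError(f"unknown species {self.species!r}")
        if self.fs <= 0:
            raise RecordingError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise RecordingError("data must be a 2-D channels x samples array")
        if self.channel_ids.size != self.data.shape[0]:
            raise RecordingError("channel_ids length must match row count")
        if not np.isfinite(self.data).all():
            raise RecordingError("recording contains NaN or infinite samples")

    @property
    def n_channels(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "HemoglobinRecording":
        return HemoglobinRecording(
            subject_id=self.subject_id,
            species=self.species,
            data=np.asarray(data, dtype=float),
            fs=self.fs,
            channel_ids=self.channel_ids.copy(),
        )


def load_channel_layout(path: str | Path) -> ChannelMap:
    """Read a tab-delimited channel layout and validate its invariants.

    Rejects duplicate ids, asymmetric homolog pairs, homolog pairs sharing
    a hemisphere, and unknown network labels, with descriptive errors.
    """
    df = pd.read_csv(path, sep="\t")
    return ChannelMap.from_frame(df)


def write_channel_layout(layout: ChannelMap, path: str | Path) -> None:
    layout.to_frame().to_csv(path, sep="\t", index=False)


def load_recording(
    path: str | Path,
    fs: float,
    subject_id: str | None = None,
    species: str | None = None,
    layout: ChannelMap | None = None,
) -> HemoglobinRecording:
    """Load a channels x samples recording from a plain numeric TSV.

    ``subject_id`` and ``species`` default to the ``<subject>_<species>.tsv``
    file-name convention.  If a layout is given, the row count must match.
    """
    path = Path(path)
    if subject_id is None or species is None:
        m = re.match(r"(?P<sid>.+)_(?P<sp>HbO|HbR)$", path.stem)
        if m is None:
            raise RecordingError(
                f"cannot infer subject/species from file name {path.name!r}; "
                "pass subject_id and species explicitly"
            )
        subject_id = subject_id or m.group("sid")
        species = species or m.group("sp")
    try:
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise RecordingError(f"non-numeric cell in {path.name}: {exc}") from exc
    if layout is not None and data.shape[0] != layout.n_channels:
        raise RecordingError(
            f"{path.name}: {data.shape[0]} rows but layout has "
            f"{layout.n_channels} channels"
        )
    ids = (
        layout.channel_id.copy()
        if layout is not None
        else np.arange(1, data.shape[0] + 1)
    )
    return HemoglobinRecording(
        subject_id=subject_id, species=species, data=data, fs=fs, channel_ids=ids
    )


def write_recording(recording: HemoglobinRecording, path: str | Path) -> None:
    np.savetxt(path, recording.data, fmt=_FLOAT_FMT, delimiter="\t")


def recording_filename(subject_id: str, species: str) -> str:
    return f"{subject_id}_{species}.tsv"


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Write a square matrix as plain TSV at full double precision."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix must be square, got shape {matrix.shape}")
    np.savetxt(path, matrix, fmt=_FLOAT_FMT, delimiter="\t")


def load_matrix(path: str | Path) -> np.ndarray:
    matrix = np.loadtxt(path, delimiter="\t", ndmin=2)
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError(
            f"{Path(path).name}: expected square matrix, got {matrix.shape}"
        )
    return matrix


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"cohort missing column(s): {missing}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortError(f"duplicate subject_id values: {dup}")
    bad = set(df["group"]) - GROUPS
    if bad:
        raise CohortError(f"unknown group value(s): {sorted(bad)}")
    bad = set(df["sex"]) - SEXES
    if bad:
        raise CohortError(f"unknown sex value(s): {sorted(bad)}")
    for col in ("age_months", "education_years"):
        if (df[col].to_numpy(dtype=float) <= 0).any():
            raise CohortError(f"{col} must be positive")
    for col in ("inattentive", "hyperactive_impulsive", "total"):
        if (df[col].to_numpy(dtype=float) < 0).any():
            raise CohortError(f"{col} must be non-negative")
    return df.reset_index(drop=True)


def load_cohort(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path, sep="\t"))


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(df)[COHORT_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


_NETWORK_BLOCKS = [
    "default",
    "frontoparietal",
    "ventral_attention",
    "somatomotor",
    "dorsal_attention",
    "visual",
]


def make_default_layout(n_channels: int = 80) -> ChannelMap:
    """A plausible whole-head montage for simulation and examples.

    Synthetic stand-in layout: channel positions, network labels and
    homolog pairings are constructed, not taken from any acquisition.
    Channels 1..N/2 sit on the left hemisphere and are mirror-paired with
    channels N/2+1..N on the right; network labels are assigned in
    contiguous blocks per hemisphere covering the six large-scale
    functional networks.
    """
    if n_channels % 2 != 0 or n_channels < 2:
        raise LayoutError("default layout requires an even channel count >= 2")
    half = n_channels // 2
    # Split each hemisphere's channels into six contiguous network blocks.
    labels_half = np.concatenate(
        [
            np.repeat(lbl, len(chunk))
            for lbl, chunk in zip(
                _NETWORK_BLOCKS, np.array_split(np.arange(half), len(_NETWORK_BLOCKS))
            )
            if len(chunk)
        ]
    )
    # Positions: anterior-to-posterior arcs at lateral offsets.
    t = np.linspace(0.0, np.pi, half)
    y = 90.0 * np.cos(t)
    z = 40.0 + 50.0 * np.sin(t)
    pos_left = np.column_stack([-55.0 * np.ones(half), y, z])
    pos_right = np.column_stack([55.0 * np.ones(half), y, z])
    channel_id = np.arange(1, n_channels + 1)
    homolog = np.concatenate([channel_id[:half] + half, channel_id[:half]])
    return ChannelMap(
        channel_id=channel_id,
        source_id=(channel_id + 1) // 2,
        detector_id=(channel_id + 2) // 2,
        position=np.vstack([pos_left, pos_right]),
        network_label=np.concatenate([labels_half, labels_half]),
        hemisphere=np.array(["left"] * half + ["right"] * half),
        homolog_id=homolog,
    )
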