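"""Recording data model, plain-text persistence, and train/val/test splits.

A recording is a 100 Hz multichannel trace from ten logical force-sensing
resistor (FSR) channels — five anatomical sites per foot (toe, first
metatarsal, fifth metatarsal, cuboid, heel) — together with a per-sample
walking-condition label stream and the sample indices at which the walking
condition changed.

Recordings are stored in a small CSV dialect: ``#``-prefixed ``key=value``
metadata header lines followed by one row per sample.  The format is
deliberately plain so that fixtures are inspectable and diff-able.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical walking-condition codes, in label order 0..4.
WALKING_CONDITIONS: tuple[str, ...] = ("LW", "SA", "SD", "RA", "RD")

WC_TO_CODE: dict[str, int] = {wc: i for i, wc in enumerate(WALKING_CONDITIONS)}

#: Anatomical site order within one foot, proximal channels last.
SITE_ORDER: tuple[str, ...] = ("toe", "meta1", "meta5", "cuboid", "heel")

#: Channel order used everywhere (CSV columns, force matrices): left foot
#: first, then right foot, each in SITE_ORDER.
CHANNEL_NAMES: tuple[str, ...] = tuple(
    f"{side}_{site}" for side in ("L", "R") for site in SITE_ORDER
)

N_CHANNELS = len(CHANNEL_NAMES)

SAMPLING_RATE_HZ = 100.0

# Column indices of the right-foot heel channel (phase anchor) and the
# fore/back regional groups per foot.
RIGHT_HEEL = CHANNEL_NAMES.index("R_heel")
FORE_SITES = ("toe", "meta1", "meta5")
BACK_SITES = ("cuboid", "heel")
FORE_IDX = {
    side: [CHANNEL_NAMES.index(f"{side}_{s}") for s in FORE_SITES] for side in ("L", "R")
}
BACK_IDX = {
    side: [CHANNEL_NAMES.index(f"{side}_{s}") for s in BACK_SITES] for side in ("L", "R")
}


class FormatError(ValueError):
    """Raised when a recording file violates the CSV dialect."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DataError(ValueError):
    """Raised for protocol-level data problems (missing trials, labels...)."""


@dataclass
class FsrRecording:
    """One trial of bilateral insole FSR data sampled at 100 Hz.

    Attributes
    ----------
    subject_id, scenario_id : str
        Identity of the subject and the walking scenario.
    trial_index : int
        1-based repetition index of this scenario for this subject.
    time : ndarray, shape (n,)
        Sample times in seconds on a strict 0.01 s grid.
    forces : ndarray, shape (n, 10)
        Channel forces in ``CHANNEL_NAMES`` order.  Unitless; ``normalized``
        flags whether min–max scaling has been applied.
    wc : ndarray of int8, shape (n,)
        Per-sample walking-condition code (index into ``WALKING_CONDITIONS``;
        -1 for unknown).
    events : list of int
        Sample indices of walking-condition transitions.
    phase : ndarray or None
        Optional ground-truth gait phase per sample, in [0, 100), anchored at
        right heel strike (populated by the simulator).
    heel_strikes : list of int
        Optional ground-truth right heel-strike sample indices.
    """

    subject_id: str
    scenario_id: str
    trial_index: int
    time: np.ndarray
    forces: np.ndarray
    wc: np.ndarray
    events: list = field(default_factory=list)
    normalized: bool = False
    phase: np.ndarray | None = None
    heel_strikes: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def validate(self) -> None:
        if self.trial_index < 1:
            raise DataError(f"trial index must be >= 1, got {self.trial_index}")
        n = self.n_samples
        if self.forces.shape != (n, N_CHANNELS):
            raise DataError(
                f"forces shape {self.forces.shape} does not match "
                f"({n}, {N_CHANNELS})"
            )
        if len(self.wc) != n:
            raise DataError("walking-condition labels length mismatch")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise DataError("sample times are not strictly increasing")
            if not np.allclose(dt, 1.0 / SAMPLING_RATE_HZ, atol=1e-6):
                raise DataError("sample times are not on a 100 Hz grid")
        if self.phase is not None and len(self.phase) != n:
            raise DataError("phase array length mismatch")

    def with_forces(self, forces: np.ndarray, normalized: bool) -> "FsrRecording":
        """Copy of this recording with a replaced force matrix."""
        return replace(self, forces=forces, normalized=normalized)

    def key(self) -> tuple[str, str, int]:
        return (self.subject_id, self.scenario_id, self.trial_index)


_HEADER_MAGIC = "# gaitphase-recording v1"


def write_recording(recording: FsrRecording, path: str | os.PathLike) -> None:
    """Write a recording to the plain-text CSV dialect."""
    recording.validate()
    r = recording
    lines = [
        _HEADER_MAGIC,
        f"# subject={r.subject_id}",
        f"# scenario={r.scenario_id}",
        f"# trial={r.trial_index}",
        f"# normalized={'true' if r.normalized else 'false'}",
        f"# events={','.join(str(int(e)) for e in r.events)}",
        f"# heel_strikes={','.join(str(int(s)) for s in r.heel_strikes)}",
        f"# channels={','.join(CHANNEL_NAMES)}",
    ]
    cols = {"time": r.time}
    for j, name in enumerate(CHANNEL_NAMES):
        cols[name] = r.forces[:, j]
    codes = np.asarray(r.wc, dtype=int)
    cols["wc"] = [WALKING_CONDITIONS[c] if 0 <= c < 5 else "NA" for c in codes]
    if r.phase is not None:
        cols["phase"] = r.phase
    df = pd.DataFrame(cols)
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.9g")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        fh.write(buf.getvalue())


def read_recording(path: str | os.PathLike) -> FsrRecording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`FormatError` (with a line number) on malformed input.
    """
    with open(path) as fh:
        raw = fh.readlines()
    if not raw:
        raise FormatError("empty file", line=1)
    if raw[0].rstrip("\n") != _HEADER_MAGIC:
        raise FormatError(f"missing magic header {_HEADER_MAGIC!r}", line=1)
    meta: dict[str, str] = {}
    body_start = None
    for i, line in enumerate(raw[1:], start=2):
        if line.startswith("#"):
            text = line[1:].strip()
            if "=" not in text:
                raise FormatError(f"malformed metadata line {text!r}", line=i)
            key, _, value = text.partition("=")
            meta[key.strip()] = value.strip()
        else:
            body_start = i
            break
    if body_start is None:
        raise FormatError("no data rows", line=len(raw))
    for key in ("subject", "scenario", "trial", "channels"):
        if key not in meta:
            raise FormatError(f"missing metadata key {key!r}", line=body_start - 1)
    channels = tuple(meta["channels"].split(","))
    if channels != CHANNEL_NAMES:
        raise FormatError(
            f"unexpected channel list {channels!r}", line=body_start - 1
        )
    try:
        df = pd.read_csv(io.StringIO("".join(raw[body_start - 1:])))
    except Exception as exc:  # pandas error -> dialect error with position
        raise FormatError(f"could not parse data rows: {exc}", line=body_start)
    expected = ["time", *CHANNEL_NAMES, "wc"]
    got_force_cols = [c for c in df.columns if c not in ("time", "wc", "phase")]
    if list(df.columns[: len(expected)]) != expected or len(got_force_cols) != N_CHANNELS:
        raise FormatError(
            f"expected columns {expected} (+ optional 'phase'), got "
            f"{list(df.columns)}",
            line=body_start,
        )
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax())
        raise FormatError("ragged or non-numeric row", line=body_start + 1 + bad)
    wc_codes = np.array([WC_TO_CODE.get(w, -1) for w in df["wc"]], dtype=np.int8)
    events = [int(x) for x in meta.get("events", "").split(",") if x != ""]
    strikes = [int(x) for x in meta.get("heel_strikes", "").split(",") if x != ""]
    rec = FsrRecording(
        subject_id=meta["subject"],
        scenario_id=meta["scenario"],
        trial_index=int(meta["trial"]),
        time=df["time"].to_numpy(float),
        forces=df[list(CHANNEL_NAMES)].to_numpy(float),
        wc=wc_codes,
        events=events,
        normalized=meta.get("normalized", "false") == "true",
        phase=df["phase"].to_numpy(float) if "phase" in df.columns else None,
        heel_strikes=strikes,
    )
    try:
        rec.validate()
    except DataError as exc:
        raise FormatError(str(exc), line=body_start) from exc
    return rec


@dataclass
class DataSplit:
    """Recording-level train/validation/test partition.

    Each entry is ``(recording, slice)`` where the slice selects the sample
    range belonging to that partition.  Test recordings are held out whole;
    the remaining recordings are cut into two contiguous time blocks so that
    overlapping training and validation windows cannot share samples.
    """

    train: list
    validation: list
    test: list

    def _recs(self, part):
        return [rec for rec, _ in part]

    def check_no_leakage(self) -> None:
        test_ids = {rec.key() for rec, _ in self.test}
        fit_ids = {rec.key() for rec, _ in self.train} | {
            rec.key() for rec, _ in self.validation
        }
        if test_ids & fit_ids:
            raise DataError(f"test recordings leak into training: {test_ids & fit_ids}")

    @property
    def train_recordings(self):
        return self._recs(self.train)

    @property
    def test_recordings(self):
        return self._recs(self.test)


def make_split(
    dataset: list,
    test_trial_index: int = 3,
    val_fraction: float = 0.2,
) -> DataSplit:
    """Partition a dataset of recordings by the held-out trial protocol.

    The trial with index ``test_trial_index`` of every (subject, scenario)
    pair goes to the test set; the remaining recordings are split into a
    leading training block and a trailing validation block of roughly
    ``val_fraction`` of the samples.
    """
    if not 0.0 <= val_fraction < 1.0:
        raise ValueError("val_fraction must be in [0, 1)")
    groups: dict[tuple[str, str], list] = {}
    for rec in dataset:
        groups.setdefault((rec.subject_id, rec.scenario_id), []).append(rec)
    train, validation, test = [], [], []
    for (subject, scenario), recs in groups.items():
        trials = {r.trial_index for r in recs}
        if test_trial_index not in trials:
            raise DataError(
                f"subject {subject}, scenario {scenario} has no trial "
                f"{test_trial_index} (found {sorted(trials)})"
            )
        for rec in recs:
            n = rec.n_samples
            if rec.trial_index == test_trial_index:
                test.append((rec, slice(0, n)))
            else:
                cut = int(round(n * (1.0 - val_fraction)))
                train.append((rec, slice(0, cut)))
                if cut < n:
                    validation.append((rec, slice(cut, n)))
    split = DataSplit(train=train, validation=validation, test=test)
    split.check_no_leakage()
    return split
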