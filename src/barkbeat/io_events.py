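"""Reading, writing and validating bark-bout annotations.

Bouts arrive either as Raven Pro selection tables (tab-delimited export of
the Raven sound-analysis software, one row per selected sound) or as a
plain two-column event CSV.  A manifest CSV maps each source file to a
bout id, an individual id and an age class.  All times are absolute
seconds on the recording timeline; downstream metrics re-zero to the
first onset.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

AGE_CLASSES = ("adult", "pup")

RAVEN_BEGIN = "Begin Time (s)"
RAVEN_END = "End Time (s)"


class FormatError(ValueError):
    """Input file does not match the expected dialect."""


class BoutValidationError(ValueError):
    """An event series violates the bout invariants."""


@dataclass(frozen=True)
class BarkEvent:
    """One bark: onset/offset in seconds from the recording start."""

    onset: float
    offset: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def __post_init__(self) -> None:
        if not (self.onset == self.onset and abs(self.onset) != float("inf")):
            raise BoutValidationError(f"non-finite onset {self.onset!r}")
        if self.onset < 0:
            raise BoutValidationError(f"negative onset {self.onset!r}")
        if self.offset < self.onset:
            raise BoutValidationError(
                f"offset {self.offset!r} precedes onset {self.onset!r}"
            )


@dataclass(frozen=True)
class BarkBout:
    """Ordered bark events from one individual's uninterrupted bout."""

    events: tuple[BarkEvent, ...]
    bout_id: str | None = None
    individual_id: str | None = None
    age_class: str | None = None
    source_file: str | None = None
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.events) < 1:
            raise BoutValidationError("a bout needs at least one event")
        onsets = [e.onset for e in self.events]
        for a, b in zip(onsets, onsets[1:]):
            if b <= a:
                raise BoutValidationError(
                    f"onsets must be strictly increasing (got {a} then {b})"
                )
        if self.age_class is not None and self.age_class not in AGE_CLASSES:
            raise BoutValidationError(
                f"age_class must be one of {AGE_CLASSES}, got {self.age_class!r}"
            )

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> list[float]:
        return [e.onset for e in self.events]

    @property
    def offsets(self) -> list[float]:
        return [e.offset for e in self.events]

    @property
    def durations(self) -> list[float]:
        return [e.duration for e in self.events]


@dataclass(frozen=True)
class Manifest:
    """Maps source files to (bout_id, individual_id, age_class)."""

    rows: tuple[tuple[str, str, str, str], ...]  # source_file, bout, indiv, age

    def __post_init__(self) -> None:
        seen_bouts: set[str] = set()
        for src, bout_id, _indiv, age in self.rows:
            if age not in AGE_CLASSES:
                raise BoutValidationError(
                    f"manifest age_class {age!r} for {src!r} not in {AGE_CLASSES}"
                )
            if bout_id in seen_bouts:
                raise BoutValidationError(f"duplicate bout_id {bout_id!r}")
            seen_bouts.add(bout_id)

    def lookup(self, source_file: str) -> tuple[str, str, str] | None:
        base = os.path.basename(source_file)
        for src, bout_id, indiv, age in self.rows:
            if src == source_file or os.path.basename(src) == base:
                return bout_id, indiv, age
        return None


def _events_from_frame(
    onsets: Sequence[float], offsets: Sequence[float], where: str
) -> tuple[BarkEvent, ...]:
    pairs = sorted(zip(onsets, offsets), key=lambda p: p[0])
    for (a, _), (b, _) in zip(pairs, pairs[1:]):
        if a == b:
            raise BoutValidationError(
                f"{where}: two events share onset {a}; a bark cannot start "
                "twice at the same instant"
            )
    return tuple(BarkEvent(onset=float(a), offset=float(b)) for a, b in pairs)


def read_raven_selection_table(path: str | Path) -> BarkBout:
    """Parse a Raven Pro selection table into a bout (metadata unset).

    Raven exports one row per selection per view; rows duplicating the same
    selection across "Spectrogram 1" / "Waveform 1" views are deduplicated
    by the "Selection" id, keeping the first.  Required columns are matched
    by their exact Raven names "Begin Time (s)" and "End Time (s)".
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as tab-delimited table: {exc}")
    if df.shape[1] <= 1:
        # fall back: multi-space separated export of the same header
        df = pd.read_csv(path, sep=r"\s{2,}", engine="python", dtype=str)
    for col in (RAVEN_BEGIN, RAVEN_END):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if "Selection" in df.columns:
        df = df.drop_duplicates(subset="Selection", keep="first")
    if len(df) == 0:
        raise FormatError(f"{path}: no selection rows after deduplication")
    times = {}
    for col in (RAVEN_BEGIN, RAVEN_END):
        try:
            times[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise FormatError(
                f"{path}: non-numeric value in {col!r} at row {bad + 2}"
            )
        if not times[col].map(lambda v: v == v and abs(v) != float("inf")).all():
            raise FormatError(f"{path}: non-finite value in {col!r}")
    extra_cols = [c for c in df.columns if c not in (RAVEN_BEGIN, RAVEN_END)]
    events = _events_from_frame(
        times[RAVEN_BEGIN].tolist(), times[RAVEN_END].tolist(), str(path)
    )
    return BarkBout(
        events=events,
        source_file=str(path),
        extra={"raven_columns": {c: df[c].tolist() for c in extra_cols}},
    )


def read_event_csv(path: str | Path) -> BarkBout:
    """Read a plain ``onset,offset`` CSV (seconds) into a bout."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    for col in ("onset", "offset"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise FormatError(f"{path}: no event rows")
    cols = {}
    for col in ("onset", "offset"):
        try:
            cols[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise FormatError(f"{path}: non-numeric {col!r} at row {bad + 2}")
    events = _events_from_frame(cols["onset"].tolist(), cols["offset"].tolist(), str(path))
    return BarkBout(events=events, source_file=str(path))


def write_event_csv(bout: BarkBout, path: str | Path) -> None:
    """Write a bout as an ``onset,offset`` CSV at 6-decimal precision."""
    with open(path, "w", newline="") as fh:
        fh.write("onset,offset\n")
        for ev in bout.events:
            fh.write(f"{ev.onset:.6f},{ev.offset:.6f}\n")


def read_manifest(path: str | Path) -> Manifest:
    df = pd.read_csv(path, dtype=str)
    required = ("source_file", "bout_id", "individual_id", "age_class")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: manifest missing column {col!r}")
    rows = tuple(
        (r.source_file, r.bout_id, r.individual_id, r.age_class)
        for r in df.itertuples()
    )
    return Manifest(rows=rows)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("source_file,bout_id,individual_id,age_class\n")
        for src, bout_id, indiv, age in manifest.rows:
            fh.write(f"{src},{bout_id},{indiv},{age}\n")


def apply_manifest(bouts: Iterable[BarkBout], manifest: Manifest) -> list[BarkBout]:
    """Attach bout/individual/age metadata from the manifest; count preserved."""
    out: list[BarkBout] = []
    for bout in bouts:
        if bout.source_file is None:
            raise BoutValidationError("bout has no source_file to match")
        hit = manifest.lookup(bout.source_file)
        if hit is None:
            raise BoutValidationError(
                f"source file {bout.source_file!r} not present in manifest"
            )
        bout_id, indiv, age = hit
        out.append(
            replace(bout, bout_id=bout_id, individual_id=indiv, age_class=age)
        )
    return out


def load_study(
    input_dir: str | Path, manifest_path: str | Path
) -> list[BarkBout]:
    """Load every file named in the manifest from ``input_dir``.

    Files ending in ``.txt`` are parsed as Raven selection tables,
    everything else as event CSVs.
    """
    input_dir = Path(input_dir)
    manifest = read_manifest(manifest_path)
    bouts = []
    for src, *_ in manifest.rows:
        path = input_dir / os.path.basename(src)
        if not path.exists():
            raise FormatError(f"manifest references missing file {path}")
        if path.suffix.lower() == ".txt":
            bouts.append(read_raven_selection_table(path))
        else:
            bouts.append(read_event_csv(path))
    return apply_manifest(bouts, manifest)
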