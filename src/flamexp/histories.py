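"""Encounter-history containers and I/O.

An encounter history records, for one individually marked bird, the ringing
occasion (release as a chick, age 0) followed by one code per later breeding
season: 1 = seen breeding at the colony, 0 = not seen.  Non-breeders are
assumed absent from the colony and therefore unobservable, so a 0 is
ambiguous between "dead", "alive but skipping" and "breeding but missed".

Two on-disk dialects are supported:

* CSV — columns ``id``, ``cohort_year``, then one 0/1 column per occasion
  year.  Cells before the ringing year must be 0 (or empty).
* INP — MARK-style lines ``h1h2...hT freq;``.  The ringing occasion is
  written as a release marker ``1``; an optional leading ``/* cohort=YEAR */``
  comment pins the cohort explicitly (required for all-zero histories, where
  no release marker can be distinguished from a detection).  Internally the
  release record is always stored as code 0 and never counts as a detection.

Identical histories are aggregated with a multiplicity for likelihood speed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

__all__ = [
    "EncounterHistory",
    "HistorySet",
    "HistorySummary",
    "ValidationError",
    "read_histories",
    "write_histories",
    "summarize",
]

#: age (in breeding seasons since ringing) below which breeding is impossible
MIN_BREEDING_AGE = 3


class ValidationError(ValueError):
    """An encounter history violates a structural constraint."""


@dataclass(frozen=True)
class EncounterHistory:
    """One marked individual (or a group of identical histories).

    Parameters
    ----------
    individual_id : str
        Opaque label; purely for reporting.
    cohort_index : int
        0-based occasion index of ringing (release as a chick, age 0).
    events : tuple of int
        Codes over occasions ``cohort_index .. T-1``; ``events[0]`` is the
        ringing record and is 0 by convention.
    multiplicity : int
        Number of identical histories this record stands for.
    """

    individual_id: str
    cohort_index: int
    events: tuple[int, ...]
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.cohort_index < 0:
            raise ValidationError(
                f"{self.individual_id}: negative cohort index {self.cohort_index}"
            )
        if self.multiplicity < 1:
            raise ValidationError(
                f"{self.individual_id}: multiplicity must be positive"
            )
        if len(self.events) < 1:
            raise ValidationError(f"{self.individual_id}: empty event sequence")
        if any(c not in (0, 1) for c in self.events):
            raise ValidationError(
                f"{self.individual_id}: event codes must be 0 or 1, got {self.events}"
            )
        if self.events[0] != 0:
            raise ValidationError(
                f"{self.individual_id}: the ringing record (release as a chick) "
                "must be stored as code 0"
            )
        for age, code in enumerate(self.events):
            if code == 1 and age < MIN_BREEDING_AGE:
                raise ValidationError(
                    f"{self.individual_id}: breeding detection at age {age} "
                    f"(< {MIN_BREEDING_AGE}, below sexual maturity)"
                )

    @property
    def n_detections(self) -> int:
        return sum(self.events)

    def key(self) -> tuple[int, tuple[int, ...]]:
        """Aggregation key: identical histories share (cohort, events)."""
        return (self.cohort_index, self.events)


@dataclass
class HistorySet:
    """A collection of encounter histories on a shared occasion axis."""

    occasion_labels: tuple[str, ...]
    histories: list[EncounterHistory] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.occasion_labels = tuple(str(y) for y in self.occasion_labels)
        T = self.n_occasions
        for h in self.histories:
            if h.cohort_index + len(h.events) != T:
                raise ValidationError(
                    f"{h.individual_id}: events cover occasions "
                    f"{h.cohort_index}..{h.cohort_index + len(h.events) - 1}, "
                    f"expected through {T - 1}"
                )

    @property
    def n_occasions(self) -> int:
        return len(self.occasion_labels)

    @property
    def n_individuals(self) -> int:
        return sum(h.multiplicity for h in self.histories)

    def aggregate(self) -> "HistorySet":
        """Merge identical histories, summing multiplicities."""
        merged: dict[tuple, EncounterHistory] = {}
        for h in self.histories:
            k = h.key()
            if k in merged:
                prev = merged[k]
                merged[k] = EncounterHistory(
                    prev.individual_id, prev.cohort_index, prev.events,
                    prev.multiplicity + h.multiplicity,
                )
            else:
                merged[k] = h
        return HistorySet(self.occasion_labels, list(merged.values()),
                          self.provenance)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HistorySet):
            return NotImplemented
        if self.occasion_labels != other.occasion_labels:
            return False
        def norm(hs: "HistorySet"):
            agg: dict[tuple, int] = {}
            for h in hs.histories:
                agg[h.key()] = agg.get(h.key(), 0) + h.multiplicity
            return agg
        return norm(self) == norm(other)

    def __len__(self) -> int:
        return len(self.histories)


@dataclass
class HistorySummary:
    """Tabular summary of a HistorySet."""

    cohort_counts: pd.DataFrame       # individuals ringed per cohort
    detection_counts: pd.DataFrame    # breeding detections per occasion
    detections_per_individual: pd.DataFrame  # distribution of detection counts

    def __str__(self) -> str:
        parts = []
        for title, df in [
            ("Individuals per cohort", self.cohort_counts),
            ("Breeding detections per occasion", self.detection_counts),
            ("Detections per individual", self.detections_per_individual),
        ]:
            parts.append(title)
            parts.append(df.to_string(index=False))
            parts.append("")
        return "\n".join(parts)


# ---------------------------------------------------------------------------
# readers / writers

_INP_LINE = re.compile(
    r"^\s*(?:/\*\s*(?P<comment>[^*]*?)\s*\*/)?\s*"
    r"(?P<codes>[01]+)\s+(?P<freq>\d+)\s*;\s*$"
)
_COHORT_FIELD = re.compile(r"cohort\s*=\s*(?P<val>\S+)")
_ID_FIELD = re.compile(r"id\s*=\s*(?P<val>\S+)")


def read_histories(path: str | Path, dialect: str) -> HistorySet:
    """Read a HistorySet from ``path`` in the given dialect ("inp" or "csv").

    Frequencies of identical histories are aggregated.  Structural
    violations (codes outside {0,1}, breeding detections before age 3,
    malformed lines) raise errors naming the offending line or individual.
    """
    path = Path(path)
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "inp":
        return _read_inp(path)
    raise ValueError(f"unsupported dialect {dialect!r} (use 'csv' or 'inp')")


def write_histories(hs: HistorySet, path: str | Path, dialect: str) -> Path:
    """Write ``hs`` to ``path``; the file re-reads to an identical set."""
    path = Path(path)
    if dialect == "csv":
        _write_csv(hs, path)
    elif dialect == "inp":
        _write_inp(hs, path)
    else:
        raise ValueError(f"unsupported dialect {dialect!r} (use 'csv' or 'inp')")
    return path


def _read_csv(path: Path) -> HistorySet:
    df = pd.read_csv(path, dtype=str).fillna("0")
    required = ["id", "cohort_year"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    year_cols = [c for c in df.columns if c not in required]
    labels = tuple(year_cols)
    year_index = {y: i for i, y in enumerate(labels)}
    histories = []
    for i in range(len(df)):
        row_no = i + 2  # header is line 1
        rid = str(df.iloc[i]["id"])
        cohort_year = str(df.iloc[i]["cohort_year"])
        if cohort_year not in year_index:
            raise ValueError(
                f"{path}:{row_no}: cohort_year {cohort_year!r} is not an "
                "occasion column"
            )
        cohort = year_index[cohort_year]
        codes = []
        for col in labels:
            raw = str(df.iloc[i][col]).strip() or "0"
            if raw not in ("0", "1"):
                raise ValidationError(
                    f"{path}:{row_no}: code {raw!r} in column {col} "
                    "is not 0 or 1"
                )
            codes.append(int(raw))
        if any(codes[:cohort]):
            raise ValidationError(
                f"{path}:{row_no}: individual {rid} has a nonzero code "
                "before its ringing year"
            )
        try:
            histories.append(
                EncounterHistory(rid, cohort, tuple(codes[cohort:]))
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{row_no}: {exc}") from exc
    return HistorySet(labels, histories, provenance=f"read from {path}").aggregate()


def _write_csv(hs: HistorySet, path: Path) -> None:
    labels = hs.occasion_labels
    rows = []
    for n, h in enumerate(hs.histories):
        full = [0] * h.cohort_index + list(h.events)
        for rep in range(h.multiplicity):
            rid = h.individual_id if h.multiplicity == 1 else f"{h.individual_id}.{rep}"
            rows.append([rid, labels[h.cohort_index]] + full)
    df = pd.DataFrame(rows, columns=["id", "cohort_year", *labels])
    df.to_csv(path, index=False)


def _read_inp(path: Path) -> HistorySet:
    lines = Path(path).read_text().splitlines()
    T = None
    labels: tuple[str, ...] | None = None
    histories = []
    n_seen = 0
    for line_no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("/*") and line.endswith("*/") and ";" not in line:
            m = re.search(r"occasions\s*=\s*(\S+)", line)
            if m:
                labels = tuple(m.group(1).split(","))
                T = len(labels)
            continue
        m = _INP_LINE.match(line)
        if m is None:
            raise ValueError(f"{path}:{line_no}: malformed .inp line: {line!r}")
        codes = [int(c) for c in m.group("codes")]
        if T is None:
            T = len(codes)
        if len(codes) != T:
            raise ValueError(
                f"{path}:{line_no}: history length {len(codes)} != {T}"
            )
        freq = int(m.group("freq"))
        comment = m.group("comment") or ""
        cm = _COHORT_FIELD.search(comment)
        im = _ID_FIELD.search(comment)
        if cm:
            cohort_label = cm.group("val")
            if labels is not None and cohort_label in labels:
                cohort = labels.index(cohort_label)
            else:
                cohort = int(cohort_label)
        else:
            # no explicit cohort: the first nonzero column is the release marker
            nonzero = [i for i, c in enumerate(codes) if c]
            if not nonzero:
                raise ValueError(
                    f"{path}:{line_no}: all-zero history without a "
                    "/* cohort=... */ comment is ambiguous"
                )
            cohort = nonzero[0]
        if any(codes[:cohort]):
            raise ValidationError(
                f"{path}:{line_no}: nonzero code before the ringing occasion"
            )
        events = list(codes[cohort:])
        events[0] = 0  # release marker, not a detection
        rid = im.group("val") if im else f"line{line_no}"
        n_seen += 1
        try:
            histories.append(EncounterHistory(rid, cohort, tuple(events), freq))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{line_no}: {exc}") from exc
    if T is None:
        raise ValueError(f"{path}: no histories and no occasions header")
    if labels is None:
        labels = tuple(str(i) for i in range(T))
    return HistorySet(labels, histories, provenance=f"read from {path}").aggregate()


def _write_inp(hs: HistorySet, path: Path) -> None:
    out = [f"/* occasions={','.join(hs.occasion_labels)} */"]
    for h in hs.histories:
        codes = [0] * h.cohort_index + list(h.events)
        codes[h.cohort_index] = 1  # release marker
        s = "".join(str(c) for c in codes)
        out.append(
            f"/* id={h.individual_id} cohort={hs.occasion_labels[h.cohort_index]} */ "
            f"{s} {h.multiplicity};"
        )
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# summaries

def summarize(hs: HistorySet) -> HistorySummary:
    """Per-cohort release counts, per-occasion detection counts and the
    distribution of the number of breeding detections per individual."""
    labels = hs.occasion_labels
    cohort_counts = {lab: 0 for lab in labels}
    det_counts = {lab: 0 for lab in labels}
    per_ind: dict[int, int] = {}
    for h in hs.histories:
        cohort_counts[labels[h.cohort_index]] += h.multiplicity
        for offset, code in enumerate(h.events):
            if code:
                det_counts[labels[h.cohort_index + offset]] += h.multiplicity
        per_ind[h.n_detections] = per_ind.get(h.n_detections, 0) + h.multiplicity
    cohorts = pd.DataFrame(
        [(lab, n) for lab, n in cohort_counts.items() if n],
        columns=["cohort_year", "n_released"],
    )
    dets = pd.DataFrame(
        list(det_counts.items()), columns=["occasion_year", "n_detections"]
    )
    dist = pd.DataFrame(
        sorted(per_ind.items()), columns=["n_detections", "n_individuals"]
    )
    return HistorySummary(cohorts, dets, dist)
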