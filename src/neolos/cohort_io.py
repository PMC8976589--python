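"""Two-timepoint cohort data model and delimited-text I/O.

One row of a cohort file is one suspected-sepsis *episode*: the culture
outcome plus marker observations at the timing of suspicion (``t1``) and
24-48 hours later (``t2``).

Column dictionary (UTF-8, comma- or tab-delimited, one header row):

================  =========================================================
column            meaning
================  =========================================================
episode_id        unique opaque identifier (required)
culture_positive  blood/urine/CSF culture outcome; accepts 0/1, true/false,
                  yes/no case-insensitively (required)
gestational_age_weeks   weeks at birth (study population is < 32)
birthweight_g     grams
organism          free-text isolate label (positives only, cosmetic)
<marker>_t1/_t2   wbc (x10^9/L), plt (x10^9/L), crp (mg/L), vent_mode
                  (none/non_invasive/invasive), spo2 (%), fio2 (fraction),
                  sf_ratio (dimensionless)
================  =========================================================

Unparseable numeric cells become missing values with a logged warning
carrying the row/column coordinates; the row count is preserved.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import List, Optional

from .score_core import (
    MissingPolicy,
    ScoreError,
    TimingObservation,
    VentMode,
    compute_breakdown,
    Rubric,
    DEFAULT_RUBRIC,
)

__all__ = [
    "Episode",
    "ChangeIndicators",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "derive_changes",
    "write_report",
    "SchemaError",
    "COLUMNS",
]

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Raised when a cohort file does not match the column dictionary."""


_MARKERS = ("wbc", "plt", "crp", "vent_mode", "spo2", "fio2", "sf_ratio")
_META_NUMERIC = ("gestational_age_weeks", "birthweight_g")

#: full ordered column dictionary of the cohort file
COLUMNS: tuple = (
    ("episode_id", "culture_positive")
    + _META_NUMERIC
    + ("organism",)
    + tuple(f"{m}_t1" for m in _MARKERS)
    + tuple(f"{m}_t2" for m in _MARKERS)
)

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


@dataclass(frozen=True)
class Episode:
    """Culture outcome plus the two timing observations for one neonate."""

    episode_id: str
    culture_positive: bool
    obs_t1: TimingObservation
    obs_t2: TimingObservation
    gestational_age_weeks: Optional[float] = None
    birthweight_g: Optional[float] = None
    organism: Optional[str] = None

    def __post_init__(self) -> None:
        ga = self.gestational_age_weeks
        if ga is not None and not 22.0 <= ga < 32.0:
            raise ValueError(
                f"episode {self.episode_id}: gestational age {ga} outside the "
                "study's [22, 32) week inclusion window"
            )
        if self.birthweight_g is not None and self.birthweight_g <= 0:
            raise ValueError(f"episode {self.episode_id}: non-positive birthweight")


@dataclass(frozen=True)
class ChangeIndicators:
    """Paired-change flags between the two timings.

    Each flag is ``None`` when either underlying value is missing.
    ``intubated_between`` is true iff the neonate was not invasively
    ventilated at suspicion but was 24-48 h later.
    """

    score_increased: Optional[bool]
    plt_decreased: Optional[bool]
    crp_increased: Optional[bool]
    intubated_between: Optional[bool]


@dataclass
class Cohort:
    """Ordered collection of episodes with load provenance."""

    episodes: List[Episode]
    source: Optional[str] = None
    loaded_at: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [e.episode_id for e in self.episodes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicate episode_id values: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.episodes)

    def __iter__(self):
        return iter(self.episodes)

    @property
    def n_positive(self) -> int:
        return sum(e.culture_positive for e in self.episodes)

    @property
    def n_negative(self) -> int:
        return len(self.episodes) - self.n_positive

    def split(self) -> tuple:
        """(culture-negative episodes, culture-positive episodes)."""
        neg = [e for e in self.episodes if not e.culture_positive]
        pos = [e for e in self.episodes if e.culture_positive]
        return neg, pos


def _parse_bool(raw: str, row: int, col: str) -> bool:
    token = raw.strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise SchemaError(
        f"row {row}, column {col}: cannot read {raw!r} as a boolean "
        "(accepted: 0/1, true/false, yes/no)"
    )


def _parse_float(raw: str, row: int, col: str) -> Optional[float]:
    token = raw.strip()
    if token == "":
        return None
    try:
        value = float(token)
    except ValueError:
        log.warning("row %d, column %s: unparseable numeric cell %r treated as missing",
                    row, col, raw)
        return None
    if not math.isfinite(value):
        log.warning("row %d, column %s: non-finite value %r treated as missing",
                    row, col, raw)
        return None
    return value


def _obs_from_row(row: dict, idx: int, suffix: str) -> TimingObservation:
    kwargs = {}
    for m in _MARKERS:
        col = f"{m}_{suffix}"
        raw = row.get(col, "") or ""
        if m == "vent_mode":
            token = raw.strip()
            kwargs["vent_mode"] = VentMode.parse(token) if token else None
        else:
            kwargs[m] = _parse_float(raw, idx, col)
    return TimingObservation(**kwargs)


def _sniff_delimiter(path: Path, dialect: Optional[str]) -> str:
    if dialect:
        return {"comma": ",", "tab": "\t"}.get(dialect, dialect)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_cohort(path, dialect: Optional[str] = None) -> Cohort:
    """Read a cohort file into a :class:`Cohort`.

    ``dialect`` may be ``"comma"``, ``"tab"`` or an explicit delimiter;
    by default the delimiter is sniffed from the header row.
    """
    path = Path(path)
    delim = _sniff_delimiter(path, dialect)
    episodes: List[Episode] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected a header row")
        missing = {"episode_id", "culture_positive"} - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s) {sorted(missing)}")
        for idx, row in enumerate(reader, start=2):
            eid = (row.get("episode_id") or "").strip()
            if not eid:
                raise SchemaError(f"row {idx}: blank episode_id")
            episodes.append(
                Episode(
                    episode_id=eid,
                    culture_positive=_parse_bool(row["culture_positive"], idx, "culture_positive"),
                    gestational_age_weeks=_parse_float(
                        row.get("gestational_age_weeks", "") or "", idx, "gestational_age_weeks"
                    ),
                    birthweight_g=_parse_float(row.get("birthweight_g", "") or "", idx, "birthweight_g"),
                    organism=(row.get("organism") or "").strip() or None,
                    obs_t1=_obs_from_row(row, idx, "t1"),
                    obs_t2=_obs_from_row(row, idx, "t2"),
                )
            )
    return Cohort(
        episodes=episodes,
        source=str(path),
        loaded_at=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, VentMode):
        return value.value
    if isinstance(value, float):
        return repr(value)  # shortest round-trippable representation
    return str(value)


def write_cohort(cohort: Cohort, path, delimiter: str = ",") -> None:
    """Write a cohort back to delimited text (full numeric precision)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(COLUMNS)
        for ep in cohort:
            row = [ep.episode_id, ep.culture_positive, ep.gestational_age_weeks,
                   ep.birthweight_g, ep.organism]
            for obs in (ep.obs_t1, ep.obs_t2):
                # sf_ratio written only when it was provided independently
                derived = None
                if obs.spo2 is not None and obs.fio2 is not None:
                    derived = obs.spo2 / obs.fio2
                sf = obs.sf_ratio if obs.sf_ratio != derived else None
                row.extend([obs.wbc, obs.plt, obs.crp, obs.vent_mode,
                            obs.spo2, obs.fio2, sf])
            writer.writerow([_fmt(v) for v in row])


def derive_changes(
    ep: Episode,
    tolerance: float = 0.0,
    rubric: Rubric = DEFAULT_RUBRIC,
) -> ChangeIndicators:
    """Derive the paired-change indicators for one episode.

    Strict inequalities; a change of magnitude <= ``tolerance`` counts
    as "not changed".  Score totals are computed under the
    ``propagate_missing`` policy, so the score indicator is missing
    whenever any component is missing at either timing.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")

    def _cmp(v1, v2, direction: int) -> Optional[bool]:
        if v1 is None or v2 is None:
            return None
        return direction * (v2 - v1) > tolerance

    t1 = compute_breakdown(ep.obs_t1, MissingPolicy.PROPAGATE_MISSING, rubric)
    t2 = compute_breakdown(ep.obs_t2, MissingPolicy.PROPAGATE_MISSING, rubric)
    intubated = None
    if ep.obs_t1.vent_mode is not None and ep.obs_t2.vent_mode is not None:
        intubated = (
            ep.obs_t1.vent_mode is not VentMode.INVASIVE
            and ep.obs_t2.vent_mode is VentMode.INVASIVE
        )
    return ChangeIndicators(
        score_increased=_cmp(t1.total, t2.total, +1),
        plt_decreased=_cmp(ep.obs_t1.plt, ep.obs_t2.plt, -1),
        crp_increased=_cmp(ep.obs_t1.crp, ep.obs_t2.crp, +1),
        intubated_between=intubated,
    )


def write_report(report, path, delimiter: str = "\t") -> None:
    """Write an analysis report as a delimited table plus JSON sidecar.

    ``report`` must expose ``table_rows()`` (header + rows of the
    human-readable summary table) and ``to_jsonable()`` (nested dict of
    every computed statistic); the JSON goes to ``<path>.json``.
    """
    path = Path(path)
    header, rows = report.table_rows()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)
    with open(path.with_suffix(path.suffix + ".json"), "w", encoding="utf-8") as fh:
        json.dump(report.to_jsonable(), fh, indent=2, sort_keys=True)
        fh.write("\n")
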