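"""Composite severity score for suspected neonatal late-onset sepsis.

The score combines three analytical markers (white blood cell count,
platelet count, C-reactive protein) and two respiratory parameters
(ventilation support, SpO2/FiO2 ratio) into a 0-13 total:

====================  ======================================  ======
component             bins (value on the data scale)          score
====================  ======================================  ======
WBC (x10^9/L)         4 <= wbc <= 20                          0
                      wbc < 4 or wbc > 20                     1
PLT (x10^9/L)         plt >= 150                              0
                      100 <= plt < 150                        1
                      50 <= plt < 100                         2
                      plt < 50                                3
CRP (mg/L)            crp < 10                                0
                      10 <= crp < 30                          1
                      30 <= crp < 50                          2
                      crp >= 50                               3
ventilation           none / non-invasive / invasive          0/1/2
S/F ratio             sf >= 300                                0
                      200 <= sf < 300                         1
                      150 <= sf < 200                         2
                      100 <= sf < 150                         3
                      sf < 100                                4
====================  ======================================  ======

Boundary convention: every graded component is binned lower-bound
inclusive, so a value sitting exactly on a cut-off belongs to the bin
that starts there (PLT 150 -> 0, CRP 50 -> 3, S/F 300 -> 0).  The WBC
normal band is closed on both sides, [4, 20].

The S/F ratio is SpO2 in percent divided by FiO2 as a fraction, so a
well-saturated neonate on room air sits near 98 / 0.21 ~ 467.

All cut-offs live in :class:`Rubric` and can be loaded from a YAML file;
the shipped defaults implement the table above.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Optional, Sequence

import yaml

__all__ = [
    "VentMode",
    "MissingPolicy",
    "TimingObservation",
    "ScoreBreakdown",
    "Rubric",
    "DEFAULT_RUBRIC",
    "score_wbc",
    "score_plt",
    "score_crp",
    "score_vent",
    "score_sf",
    "compute_breakdown",
    "ScoreError",
]

#: total score when every component is at its ceiling (1+3+3+2+4)
MAX_TOTAL = 13


class ScoreError(ValueError):
    """Raised for invalid marker values or rubric configuration."""


class VentMode(str, Enum):
    """Ventilation support at one timing."""

    NONE = "none"
    NON_INVASIVE = "non_invasive"
    INVASIVE = "invasive"

    @classmethod
    def parse(cls, value: "str | VentMode") -> "VentMode":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            accepted = ", ".join(m.value for m in cls)
            raise ScoreError(
                f"unknown ventilation mode {value!r}; accepted values: {accepted}"
            ) from None


class MissingPolicy(str, Enum):
    """How :func:`compute_breakdown` treats an unrecorded component.

    * ``strict`` -- missing component is an error.
    * ``zero_impute`` -- missing components contribute 0 and are counted
      in ``n_missing_components``.
    * ``propagate_missing`` -- a missing component makes the affected
      sub-score and the total missing (``None``).
    """

    STRICT = "strict"
    ZERO_IMPUTE = "zero_impute"
    PROPAGATE_MISSING = "propagate_missing"


def _check_value(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ScoreError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ScoreError(f"{name} must be non-negative, got {value!r}")
    return value


@dataclass(frozen=True)
class TimingObservation:
    """Marker values for one neonate at one timing.

    ``sf_ratio`` may be given directly or derived as ``spo2 / fio2``
    (SpO2 in percent, FiO2 as a fraction).  A provided ratio wins over
    recomputation; a disagreement of more than one unit triggers a
    warning, not an error.
    """

    wbc: Optional[float] = None
    plt: Optional[float] = None
    crp: Optional[float] = None
    vent_mode: Optional[VentMode] = None
    spo2: Optional[float] = None
    fio2: Optional[float] = None
    sf_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("wbc", "plt", "crp", "spo2", "fio2", "sf_ratio"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, _check_value(name, v))
        if self.spo2 is not None and not 0 <= self.spo2 <= 100:
            raise ScoreError(f"spo2 must be a percentage in [0, 100], got {self.spo2}")
        if self.fio2 is not None and not 0.21 <= self.fio2 <= 1.0:
            raise ScoreError(f"fio2 must be a fraction in [0.21, 1.0], got {self.fio2}")
        if self.vent_mode is not None:
            object.__setattr__(self, "vent_mode", VentMode.parse(self.vent_mode))
        derived = None
        if self.spo2 is not None and self.fio2 is not None:
            derived = self.spo2 / self.fio2
        if self.sf_ratio is None:
            if derived is not None:
                object.__setattr__(self, "sf_ratio", derived)
        elif derived is not None and abs(self.sf_ratio - derived) > 1.0:
            warnings.warn(
                f"sf_ratio={self.sf_ratio:.1f} disagrees with spo2/fio2="
                f"{derived:.1f}; keeping the provided ratio",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ScoreBreakdown:
    """Component scores, sub-scores and total for one observation.

    Fields are ``None`` when the underlying marker was missing and the
    policy was ``propagate_missing``.
    """

    wbc_score: Optional[int]
    plt_score: Optional[int]
    crp_score: Optional[int]
    vent_score: Optional[int]
    sf_score: Optional[int]
    analytical_subscore: Optional[int]
    respiratory_subscore: Optional[int]
    total: Optional[int]
    n_missing_components: int = 0


# -- rubric ----------------------------------------------------------------

# Bin table format: ordered [lower_bound, score] pairs covering [0, inf);
# a value maps to the last bin whose lower bound is <= value.
_WBC_UPPER = math.nextafter(20.0, math.inf)  # keeps the [4, 20] band closed

_DEFAULT_BINS = {
    "wbc": [[0.0, 1], [4.0, 0], [_WBC_UPPER, 1]],
    "plt": [[0.0, 3], [50.0, 2], [100.0, 1], [150.0, 0]],
    "crp": [[0.0, 0], [10.0, 1], [30.0, 2], [50.0, 3]],
    "sf": [[0.0, 4], [100.0, 3], [150.0, 2], [200.0, 1], [300.0, 0]],
}
_VENT_SCORES = {VentMode.NONE: 0, VentMode.NON_INVASIVE: 1, VentMode.INVASIVE: 2}


@dataclass(frozen=True)
class Rubric:
    """Cut-off configuration for the graded components.

    ``bins`` maps component name -> ordered ``[lower_bound, score]``
    pairs; the first lower bound must be 0 and bounds must strictly
    increase.  ``vent_scores`` maps ventilation mode -> score.
    """

    bins: dict = field(default_factory=lambda: {k: [list(p) for p in v] for k, v in _DEFAULT_BINS.items()})
    vent_scores: dict = field(default_factory=lambda: dict(_VENT_SCORES))

    def __post_init__(self) -> None:
        for comp in ("wbc", "plt", "crp", "sf"):
            if comp not in self.bins:
                raise ScoreError(f"rubric is missing bins for component {comp!r}")
            pairs = self.bins[comp]
            bounds = [float(lb) for lb, _ in pairs]
            if bounds[0] != 0.0:
                raise ScoreError(f"{comp} bins must start at 0, got {bounds[0]}")
            if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
                raise ScoreError(f"{comp} bin bounds must strictly increase")
            for _, s in pairs:
                if int(s) != s or s < 0:
                    raise ScoreError(f"{comp} scores must be non-negative integers")
        for mode in VentMode:
            if mode not in self.vent_scores:
                raise ScoreError(f"rubric is missing a score for ventilation {mode.value}")

    def lookup(self, component: str, value: float) -> int:
        """Map ``value`` to its score: last bin with lower bound <= value."""
        value = _check_value(component, value)
        score = None
        for lb, s in self.bins[component]:
            if value >= lb:
                score = s
            else:
                break
        assert score is not None  # first bound is 0 and value >= 0
        return int(score)

    @property
    def max_total(self) -> int:
        graded = sum(max(s for _, s in self.bins[c]) for c in ("wbc", "plt", "crp", "sf"))
        return graded + max(self.vent_scores.values())

    @classmethod
    def from_yaml(cls, path) -> "Rubric":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "bins" not in raw:
            raise ScoreError(f"rubric file {path} must contain a 'bins' mapping")
        vent = {VentMode.parse(k): int(v) for k, v in raw.get("vent_scores", {}).items()}
        if not vent:
            vent = dict(_VENT_SCORES)
        bins = {k: [[float(lb), int(s)] for lb, s in v] for k, v in raw["bins"].items()}
        return cls(bins=bins, vent_scores=vent)

    @classmethod
    def default(cls) -> "Rubric":
        return cls()


DEFAULT_RUBRIC = Rubric()


def default_rubric_path():
    """Path to the shipped YAML rubric (editable copy of the defaults)."""
    return resources.files("neolos").joinpath("data/default_rubric.yaml")


# -- component scorers ------------------------------------------------------

def score_wbc(wbc: float, rubric: Rubric = DEFAULT_RUBRIC) -> int:
    """1 if the white-cell count is outside the [4, 20] x10^9/L band, else 0."""
    return rubric.lookup("wbc", wbc)


def score_plt(plt: float, rubric: Rubric = DEFAULT_RUBRIC) -> int:
    """0-3; thrombocytopenia scores higher (3 below 50 x10^9/L)."""
    return rubric.lookup("plt", plt)


def score_crp(crp: float, rubric: Rubric = DEFAULT_RUBRIC) -> int:
    """0-3; 0 below 10 mg/L, 3 at or above 50 mg/L."""
    return rubric.lookup("crp", crp)


def score_vent(vent_mode: "str | VentMode", rubric: Rubric = DEFAULT_RUBRIC) -> int:
    """0 for no support, 1 for non-invasive, 2 for invasive ventilation."""
    return int(rubric.vent_scores[VentMode.parse(vent_mode)])


def score_sf(sf_ratio: float, rubric: Rubric = DEFAULT_RUBRIC) -> int:
    """0-4; worsening oxygenation (lower S/F) scores higher."""
    return rubric.lookup("sf", sf_ratio)


def compute_breakdown(
    obs: TimingObservation,
    missing_policy: "str | MissingPolicy" = MissingPolicy.PROPAGATE_MISSING,
    rubric: Rubric = DEFAULT_RUBRIC,
) -> ScoreBreakdown:
    """Score one observation and sum components into sub-scores and total.

    The analytical sub-score is WBC + PLT + CRP; the respiratory
    sub-score is ventilation + S/F; the total is their sum (max 13 under
    the default rubric).  Missing components are handled per
    :class:`MissingPolicy`.
    """
    policy = MissingPolicy(missing_policy)
    components: dict[str, Optional[int]] = {
        "wbc": None if obs.wbc is None else score_wbc(obs.wbc, rubric),
        "plt": None if obs.plt is None else score_plt(obs.plt, rubric),
        "crp": None if obs.crp is None else score_crp(obs.crp, rubric),
        "vent": None if obs.vent_mode is None else score_vent(obs.vent_mode, rubric),
        "sf": None if obs.sf_ratio is None else score_sf(obs.sf_ratio, rubric),
    }
    missing = [k for k, v in components.items() if v is None]
    if missing and policy is MissingPolicy.STRICT:
        raise ScoreError(f"missing component(s) under strict policy: {', '.join(missing)}")

    def subsum(names: Sequence[str]) -> Optional[int]:
        vals = [components[n] for n in names]
        if policy is MissingPolicy.ZERO_IMPUTE:
            return sum(v or 0 for v in vals)
        if any(v is None for v in vals):
            return None
        return sum(vals)  # type: ignore[arg-type]

    analytical = subsum(("wbc", "plt", "crp"))
    respiratory = subsum(("vent", "sf"))
    total = None if (analytical is None or respiratory is None) else analytical + respiratory
    return ScoreBreakdown(
        wbc_score=components["wbc"],
        plt_score=components["plt"],
        crp_score=components["crp"],
        vent_score=components["vent"],
        sf_score=components["sf"],
        analytical_subscore=analytical,
        respiratory_subscore=respiratory,
        total=total,
        n_missing_components=len(missing),
    )
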