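"""Synthetic two-timepoint cohorts for suspected late-onset sepsis.

Real per-patient data for this kind of study are never deposited, so the
generator emulates the *published statistical structure* of a small
preterm cohort: group-wise medians and IQRs of each analyte at each
timing, within-subject correlation between the two timings, ventilation
transitions (escalation to invasive ventilation between suspicion and
the 24-48 h re-evaluation), and per-field missingness.

Markers are drawn from two-piece distributions whose theoretical
median and quartiles equal the configured targets exactly:

* ``lognormal`` -- value = m * exp(s * z) with z ~ N(0, 1) and a
  separate log-scale s for each half (s_lo = ln(m/q1)/z75 below the
  median, s_up = ln(q3/m)/z75 above, z75 = 0.6745).  Used for
  right-skewed positive analytes (platelets, CRP).
* ``normal`` -- value = m + s * z with per-half s, clipped at 0
  (clipping below zero never moves the three target quantiles as long
  as they are positive).  Used for roughly symmetric analytes (WBC).

The two timings share a latent standard normal: z2 = rho * z1 +
sqrt(1 - rho^2) * eps, a rank-preserving coupling, so the paired-change
indicators have realistic within-subject dependence.

The S/F ratio is never drawn directly: SpO2 and FiO2 are simulated and
the observation derives the ratio, mirroring how the quantity arises at
the cot side.  Unventilated episodes breathe room air (FiO2 0.21).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from .cohort_io import Cohort, Episode
from .score_core import TimingObservation, VentMode

__all__ = [
    "QuartileTarget",
    "MarkerSpec",
    "GeneratorConfig",
    "SyntheticCohort",
    "sample_marker",
    "generate",
    "default_config_from_table1",
    "ConfigError",
    "GENERATOR_VERSION",
]

GENERATOR_VERSION = "1.0"

Z75 = 0.6744897501960817  # 75th percentile of the standard normal

_GROUPS = ("neg", "pos")
_TIMINGS = ("t1", "t2")


class ConfigError(ValueError):
    """Raised when generator targets are inconsistent or infeasible."""


@dataclass(frozen=True)
class QuartileTarget:
    """A (median, q1, q3) target on the data scale."""

    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ConfigError(
                f"quartile target out of order: q1={self.q1}, "
                f"median={self.median}, q3={self.q3}"
            )

    @property
    def degenerate(self) -> bool:
        return self.q1 == self.median == self.q3


def _two_piece(z: np.ndarray, t: QuartileTarget, family: str) -> np.ndarray:
    """Map standard-normal draws to a two-piece distribution hitting ``t``."""
    if t.degenerate:
        return np.full_like(z, t.median, dtype=float)
    if family == "lognormal":
        if t.q1 <= 0 or t.median <= 0:
            raise ConfigError(
                f"lognormal family needs positive median and q1, got {t}"
            )
        s_lo = math.log(t.median / t.q1) / Z75
        s_up = math.log(t.q3 / t.median) / Z75
        return t.median * np.exp(np.where(z >= 0, s_up, s_lo) * z)
    if family == "normal":
        s_lo = (t.median - t.q1) / Z75
        s_up = (t.q3 - t.median) / Z75
        return np.maximum(t.median + np.where(z >= 0, s_up, s_lo) * z, 0.0)
    raise ConfigError(f"unknown distribution family {family!r}")


def sample_marker(
    median: float,
    iqr: Tuple[float, float],
    n: int,
    family: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` values whose theoretical median/quartiles equal the targets.

    ``family`` is ``"lognormal"`` or ``"normal"`` (truncated at 0).  A
    degenerate target (q1 == median == q3) yields a constant sample.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    target = QuartileTarget(median=median, q1=iqr[0], q3=iqr[1])
    if not target.q1 <= median <= target.q3:
        raise ConfigError("median must lie inside the IQR")
    return _two_piece(rng.standard_normal(n), target, family)


@dataclass(frozen=True)
class MarkerSpec:
    """Distribution targets for one marker: per group x timing, plus the
    cross-timing latent correlation."""

    family: str
    targets: Dict[str, QuartileTarget]  # keys "neg_t1", "neg_t2", "pos_t1", "pos_t2"
    correlation: float = 0.5

    def __post_init__(self) -> None:
        expected = {f"{g}_{t}" for g in _GROUPS for t in _TIMINGS}
        if set(self.targets) != expected:
            raise ConfigError(f"marker targets must have keys {sorted(expected)}")
        if not 0.0 <= self.correlation < 1.0:
            raise ConfigError("cross-timing correlation must be in [0, 1)")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full calibration of the synthetic cohort generator."""

    n_negative: int = 15
    n_positive: int = 18
    markers: Dict[str, MarkerSpec] = field(default_factory=dict)
    spo2: MarkerSpec = None  # type: ignore[assignment]
    fio2_supplement: MarkerSpec = None  # type: ignore[assignment]
    # P(none), P(non_invasive), P(invasive) at suspicion, per group
    vent_t1_probs: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {"neg": (0.45, 0.55, 0.0), "pos": (0.45, 0.55, 0.0)}
    )
    # P(escalation to invasive between timings | not invasive at t1)
    intubation_transition_prob: Dict[str, float] = field(
        default_factory=lambda: {"neg": 0.0, "pos": 7.0 / 17.0}
    )
    gestational_age: Dict[str, QuartileTarget] = field(default_factory=dict)
    birthweight: Dict[str, QuartileTarget] = field(default_factory=dict)
    missing_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_negative < 1 or self.n_positive < 1:
            raise ConfigError("each group needs at least one episode")
        if not self.markers or self.spo2 is None or self.fio2_supplement is None:
            raise ConfigError(
                "markers, spo2 and fio2_supplement must all be specified; "
                "start from default_config_from_table1() for the shipped calibration"
            )
        for d, what in ((self.gestational_age, "gestational_age"),
                        (self.birthweight, "birthweight")):
            if set(d) != set(_GROUPS):
                raise ConfigError(f"{what} needs a target for each of {_GROUPS}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be a probability in [0, 1)")
        for g, probs in self.vent_t1_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ConfigError(f"vent_t1_probs[{g!r}] must be a probability vector")
        for g, p in self.intubation_transition_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"intubation_transition_prob[{g!r}] not in [0, 1]")

    # -- YAML round-trip ---------------------------------------------------

    def to_yaml(self, path) -> None:
        raw = json.loads(json.dumps(asdict(self)))  # tuples -> lists
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)

        def qt(d) -> QuartileTarget:
            return QuartileTarget(**d)

        def spec(d) -> MarkerSpec:
            return MarkerSpec(
                family=d["family"],
                targets={k: qt(v) for k, v in d["targets"].items()},
                correlation=d.get("correlation", 0.5),
            )

        return cls(
            n_negative=raw["n_negative"],
            n_positive=raw["n_positive"],
            markers={k: spec(v) for k, v in raw["markers"].items()},
            spo2=spec(raw["spo2"]),
            fio2_supplement=spec(raw["fio2_supplement"]),
            vent_t1_probs={k: tuple(v) for k, v in raw["vent_t1_probs"].items()},
            intubation_transition_prob=dict(raw["intubation_transition_prob"]),
            gestational_age={k: qt(v) for k, v in raw["gestational_age"].items()},
            birthweight={k: qt(v) for k, v in raw["birthweight"].items()},
            missing_rate=raw["missing_rate"],
            seed=raw["seed"],
        )


@dataclass(frozen=True)
class SyntheticCohort:
    cohort: Cohort
    config: GeneratorConfig
    version: str = GENERATOR_VERSION


def _targets(m, q1, q3):
    return QuartileTarget(median=m, q1=q1, q3=q3)


def default_config_from_table1(seed: int = 0, scale: int = 1) -> GeneratorConfig:
    """The shipped calibration: published group-wise marker distributions.

    ``scale`` multiplies both group sizes (15 negative / 18 positive by
    default) without touching any distributional target.  The
    escalation-to-invasive probability for the positive group is 7/17
    (the published transition fraction); negatives never escalate.
    """
    markers = {
        "wbc": MarkerSpec(
            family="normal",
            targets={
                "neg_t1": _targets(21.3, 10.5, 23.9),
                "pos_t1": _targets(16.3, 9.0, 25.1),
                "neg_t2": _targets(17.1, 8.8, 23.3),
                "pos_t2": _targets(14.0, 10.2, 20.3),
            },
        ),
        "plt": MarkerSpec(
            family="lognormal",
            targets={
                "neg_t1": _targets(420.0, 301.0, 549.0),
                "pos_t1": _targets(230.0, 170.0, 325.0),
                "neg_t2": _targets(395.0, 222.0, 529.0),
                "pos_t2": _targets(153.0, 99.0, 288.0),
            },
        ),
        "crp": MarkerSpec(
            family="lognormal",
            targets={
                "neg_t1": _targets(9.5, 2.2, 18.4),
                "pos_t1": _targets(17.5, 4.9, 39.9),
                "neg_t2": _targets(5.8, 1.1, 14.5),
                "pos_t2": _targets(40.8, 14.9, 82.4),
            },
        ),
    }
    spo2 = MarkerSpec(
        family="normal",
        targets={f"{g}_{t}": _targets(95.0, 93.0, 97.5) for g in _GROUPS for t in _TIMINGS},
    )
    # FiO2 above room air for episodes on respiratory support; positives
    # need more oxygen at the second timing (worsening oxygenation).
    fio2_supplement = MarkerSpec(
        family="lognormal",
        targets={
            "neg_t1": _targets(0.04, 0.015, 0.09),
            "neg_t2": _targets(0.04, 0.015, 0.09),
            "pos_t1": _targets(0.04, 0.015, 0.09),
            "pos_t2": _targets(0.12, 0.05, 0.28),
        },
    )
    return GeneratorConfig(
        n_negative=15 * scale,
        n_positive=18 * scale,
        markers=markers,
        spo2=spo2,
        fio2_supplement=fio2_supplement,
        gestational_age={
            "neg": _targets(27.6, 26.6, 29.4),
            "pos": _targets(28.2, 27.6, 30.3),
        },
        birthweight={
            "neg": _targets(1030.0, 855.0, 1400.0),
            "pos": _targets(1043.0, 940.0, 1360.0),
        },
        seed=seed,
    )


_ORGANISMS = (
    "Escherichia coli",
    "Enterococcus faecalis",
    "Klebsiella pneumoniae",
    "Candida albicans",
)

_MASKABLE = ("wbc", "plt", "crp", "vent_mode", "spo2", "fio2")


def _correlated_pair(rng: np.random.Generator, n: int, rho: float):
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    return z1, z2


def generate(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a deterministic synthetic cohort from ``config``.

    The same config (including its seed) always yields an identical
    cohort.  Culture labels are fixed by group; markers at the two
    timings share a latent normal with the configured correlation;
    ventilation is a two-state escalation process; each maskable field
    is independently set missing at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    episodes = []
    eid = 0
    for group in _GROUPS:
        n = config.n_negative if group == "neg" else config.n_positive
        values: Dict[str, np.ndarray] = {}
        for name in sorted(config.markers):
            spec = config.markers[name]
            z1, z2 = _correlated_pair(rng, n, spec.correlation)
            values[f"{name}_t1"] = _two_piece(z1, spec.targets[f"{group}_t1"], spec.family)
            values[f"{name}_t2"] = _two_piece(z2, spec.targets[f"{group}_t2"], spec.family)

        z1, z2 = _correlated_pair(rng, n, config.spo2.correlation)
        spo2_t1 = np.clip(_two_piece(z1, config.spo2.targets[f"{group}_t1"], config.spo2.family), 80.0, 100.0)
        spo2_t2 = np.clip(_two_piece(z2, config.spo2.targets[f"{group}_t2"], config.spo2.family), 80.0, 100.0)

        z1, z2 = _correlated_pair(rng, n, config.fio2_supplement.correlation)
        supp_t1 = _two_piece(z1, config.fio2_supplement.targets[f"{group}_t1"], config.fio2_supplement.family)
        supp_t2 = _two_piece(z2, config.fio2_supplement.targets[f"{group}_t2"], config.fio2_supplement.family)

        p_none, p_niv, p_inv = config.vent_t1_probs[group]
        u = rng.random(n)
        vent_t1 = np.where(u < p_none, 0, np.where(u < p_none + p_niv, 1, 2))
        p_trans = config.intubation_transition_prob[group]
        escalate = rng.random(n) < p_trans
        vent_t2 = np.where(vent_t1 == 2, 2, np.where(escalate, 2, vent_t1))

        fio2_t1 = np.where(vent_t1 == 0, 0.21, np.clip(0.21 + supp_t1, 0.21, 1.0))
        fio2_t2 = np.where(vent_t2 == 0, 0.21, np.clip(0.21 + supp_t2, 0.21, 1.0))

        ga = np.clip(_two_piece(rng.standard_normal(n),
                                config.gestational_age[group], "normal"), 22.0, 31.9)
        bw = _two_piece(rng.standard_normal(n), config.birthweight[group], "lognormal")

        organism = [None] * n
        if group == "pos":
            u_org = rng.random(n)
            idx = rng.integers(0, len(_ORGANISMS), size=n)
            organism = [
                "Staphylococcus epidermidis" if u_org[i] < 2.0 / 3.0 else _ORGANISMS[idx[i]]
                for i in range(n)
            ]

        mask = {
            f"{f}_{t}": rng.random(n) < config.missing_rate
            for t in _TIMINGS for f in _MASKABLE
        }

        vent_modes = (VentMode.NONE, VentMode.NON_INVASIVE, VentMode.INVASIVE)
        for i in range(n):
            eid += 1

            def _field(arr, key, i=i):
                return None if mask[key][i] else float(arr[i])

            obs = {}
            for t, vent, spo2_a, fio2_a in (
                ("t1", vent_t1, spo2_t1, fio2_t1),
                ("t2", vent_t2, spo2_t2, fio2_t2),
            ):
                obs[t] = TimingObservation(
                    wbc=_field(values[f"wbc_{t}"], f"wbc_{t}"),
                    plt=_field(values[f"plt_{t}"], f"plt_{t}"),
                    crp=_field(values[f"crp_{t}"], f"crp_{t}"),
                    vent_mode=None if mask[f"vent_mode_{t}"][i] else vent_modes[int(vent[i])],
                    spo2=_field(spo2_a, f"spo2_{t}"),
                    fio2=_field(fio2_a, f"fio2_{t}"),
                )
            episodes.append(
                Episode(
                    episode_id=f"SYN-{eid:05d}",
                    culture_positive=(group == "pos"),
                    gestational_age_weeks=float(ga[i]),
                    birthweight_g=float(bw[i]),
                    organism=organism[i],
                    obs_t1=obs["t1"],
                    obs_t2=obs["t2"],
                )
            )
    cohort = Cohort(episodes=episodes, source=f"synthetic(seed={config.seed})")
    return SyntheticCohort(cohort=cohort, config=config)
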