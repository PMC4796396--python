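"""Model inputs: clinical transition parameters, costs, utilities, economic
settings, and age-specific background-mortality life tables.

All defaults are the published base-case values of the decision model:
2010 US dollars, utilities on the 0–1 dead/full-health scale, annual
probabilities and rates. A :class:`ParameterSet` bundles the four blocks and
round-trips losslessly through YAML, so a study configuration is a small
text file that overrides only what it needs.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "ParameterError",
    "LifeTableError",
    "ClinicalParameters",
    "CostParameters",
    "UtilityParameters",
    "EconomicSettings",
    "ParameterSet",
    "LifeTable",
    "load_parameters",
    "dump_parameters",
    "load_life_table",
]


class ParameterError(ValueError):
    """Raised for out-of-range, unknown, or malformed model inputs."""


class LifeTableError(ValueError):
    """Raised for malformed or incomplete life tables."""


def _check_unit(name: str, value: float, lo: float = 0.0, hi: float = 1.0,
                lo_open: bool = False) -> None:
    ok = (lo < value if lo_open else lo <= value) and value <= hi
    if not ok:
        bracket = "(" if lo_open else "["
        raise ParameterError(
            f"{name}={value!r} outside {bracket}{lo}, {hi}]"
        )


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ParameterError(f"{name}={value!r} must be >= 0")


@dataclass(frozen=True)
class ClinicalParameters:
    """Transition inputs of the four-state model.

    The disease-free→recurrence hazard for the first five cycles derives
    from the trial's cumulative 5-year disease-free survival in the
    chemotherapy-only arm (``p_dfs_5y_act``), reduced on the hazard scale by
    ``hr_dfs`` in the trastuzumab arm while its benefit lasts
    (``benefit_duration`` years).  Later cycles use pooled annual recurrence
    rates by time band.  ``metastatic_death_rate`` is read as an annual
    probability by default; set ``metastatic_death_is_rate`` to treat it as
    an instantaneous rate (converted via ``1 - exp(-r)``).

    ``local_to_metastatic_annual`` — the probability that a survivor of a
    loco-regional recurrence progresses to distant disease rather than
    returning to the disease-free state — is not published and is fixed by
    calibration (see :mod:`trastuzumab_cea.calibration`).
    """

    p_dfs_5y_act: float = 0.75
    hr_dfs: float = 0.64
    hr_post_benefit: float = 1.0
    recur_rate_y5_9: float = 0.0489
    recur_rate_y10_14: float = 0.0354
    recur_rate_y15plus: float = 0.0266
    frac_locoregional: float = 0.25
    chf_incidence_act: float = 0.007
    chf_incidence_acth: float = 0.02
    metastatic_death_rate: float = 0.328
    metastatic_death_is_rate: bool = False
    local_to_metastatic_annual: float = 0.5
    benefit_duration: int = 5
    horizon: int = 20
    cycle_length: int = 1
    start_age: int = 50

    def __post_init__(self) -> None:
        _check_unit("p_dfs_5y_act", self.p_dfs_5y_act, lo_open=True)
        _check_unit("hr_dfs", self.hr_dfs, lo_open=True)
        if self.hr_post_benefit <= 0:
            raise ParameterError("hr_post_benefit must be > 0")
        for name in ("recur_rate_y5_9", "recur_rate_y10_14", "recur_rate_y15plus"):
            _check_nonneg(name, getattr(self, name))
        _check_unit("frac_locoregional", self.frac_locoregional)
        _check_unit("chf_incidence_act", self.chf_incidence_act)
        _check_unit("chf_incidence_acth", self.chf_incidence_acth)
        _check_unit("local_to_metastatic_annual", self.local_to_metastatic_annual)
        if self.metastatic_death_is_rate:
            _check_nonneg("metastatic_death_rate", self.metastatic_death_rate)
        else:
            _check_unit("metastatic_death_rate", self.metastatic_death_rate)
        if self.cycle_length != 1:
            raise ParameterError("cycle_length must be 1 year (annual-cycle model)")
        if self.horizon != 20:
            raise ParameterError("horizon must be 20 years (recurrence schedule "
                                 "is defined over years 1-20)")
        if self.benefit_duration != 5:
            raise ParameterError("benefit_duration must be 5 years")
        if self.start_age < 0:
            raise ParameterError("start_age must be >= 0")


@dataclass(frozen=True)
class CostParameters:
    """Direct medical costs, 2010 USD, health-system perspective.

    One-off costs (regimens, loco-regional episode, heart-failure episode)
    versus per-cycle costs (disease-free follow-up for the first
    ``dfs_followup_years`` cycles, metastatic annual management).
    """

    act_regimen_total: float = 3294.0
    trastuzumab_drug: float = 48850.0
    trastuzumab_admin: float = 425.0
    dfs_followup_annual: float = 47.0
    dfs_followup_years: int = 3
    locoregional_episode: float = 4138.0
    metastatic_annual: float = 7865.0
    chf_episode: float = 675.0

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_nonneg(f.name, getattr(self, f.name))


@dataclass(frozen=True)
class UtilityParameters:
    """Health-state utility weights (0 = dead, 1 = full health).

    ``u_treatment`` applies during the first (adjuvant-treatment) cycle in
    both arms, replacing the disease-free weight; ``u_chf`` replaces it for
    the fraction of the cohort experiencing congestive heart failure.
    """

    u_treatment: float = 0.94
    u_dfs: float = 0.98
    u_chf: float = 0.64
    u_local: float = 0.615
    u_metastatic: float = 0.615
    u_death: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_unit(f.name, getattr(self, f.name))
        if self.u_death != 0.0:
            raise ParameterError("u_death is fixed at 0")


@dataclass(frozen=True)
class EconomicSettings:
    """Discounting and the willingness-to-pay threshold (USD per QALY)."""

    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    wtp_threshold: float = 15000.0

    def __post_init__(self) -> None:
        _check_nonneg("discount_rate_costs", self.discount_rate_costs)
        _check_nonneg("discount_rate_effects", self.discount_rate_effects)
        if self.wtp_threshold <= 0:
            raise ParameterError("wtp_threshold must be > 0")


_SECTIONS = {
    "clinical": ClinicalParameters,
    "costs": CostParameters,
    "utilities": UtilityParameters,
    "economics": EconomicSettings,
}


@dataclass(frozen=True)
class ParameterSet:
    """Complete model input: clinical, cost, utility and economic blocks."""

    clinical: ClinicalParameters = field(default_factory=ClinicalParameters)
    costs: CostParameters = field(default_factory=CostParameters)
    utilities: UtilityParameters = field(default_factory=UtilityParameters)
    economics: EconomicSettings = field(default_factory=EconomicSettings)

    def to_dict(self) -> dict[str, dict[str, Any]]:
        return {name: dataclasses.asdict(getattr(self, name)) for name in _SECTIONS}

    @classmethod
    def from_dict(cls, data: Mapping[str, Mapping[str, Any]]) -> "ParameterSet":
        unknown = set(data) - set(_SECTIONS)
        if unknown:
            raise ParameterError(f"unknown config section(s): {sorted(unknown)}")
        blocks = {}
        for name, block_cls in _SECTIONS.items():
            overrides = dict(data.get(name) or {})
            valid = {f.name for f in fields(block_cls)}
            bad = set(overrides) - valid
            if bad:
                raise ParameterError(
                    f"unknown key(s) in section '{name}': {sorted(bad)}")
            blocks[name] = block_cls(**overrides)
        return cls(**blocks)

    def with_override(self, path: str, value: Any) -> "ParameterSet":
        """Return a copy with the dotted ``section.field`` path replaced."""
        try:
            section, name = path.split(".")
        except ValueError:
            raise ParameterError(f"parameter path {path!r} is not 'section.field'")
        if section not in _SECTIONS:
            raise ParameterError(f"unknown section in path {path!r}")
        block = getattr(self, section)
        if name not in {f.name for f in fields(block)}:
            raise ParameterError(f"unknown field in path {path!r}")
        return replace(self, **{section: replace(block, **{name: value})})

    def get(self, path: str) -> Any:
        section, name = path.split(".")
        return getattr(getattr(self, section), name)


def load_parameters(source: str | Path | Mapping | None = None) -> ParameterSet:
    """Build a :class:`ParameterSet` from YAML text, a file path, or a mapping.

    Keys absent from the source take the published base-case defaults;
    unknown sections or keys are rejected.  ``None`` or an empty document
    yields the full default set.
    """
    if source is None:
        return ParameterSet()
    if isinstance(source, Mapping):
        return ParameterSet.from_dict(source)
    text = Path(source).read_text() if isinstance(source, Path) else str(source)
    if isinstance(source, str) and "\n" not in source and Path(source).is_file():
        text = Path(source).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # report the offending line if known
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ParameterError(f"malformed config{where}: {exc}") from exc
    if data is None:
        return ParameterSet()
    if not isinstance(data, Mapping):
        raise ParameterError("config root must be a mapping of sections")
    return ParameterSet.from_dict(data)


def dump_parameters(params: ParameterSet) -> str:
    """Serialize to YAML; ``load_parameters`` reproduces it field-for-field."""
    return yaml.safe_dump(params.to_dict(), sort_keys=False)


class LifeTable:
    """Age-indexed annual probabilities of death from other causes (female).

    Ages must be contiguous one-year classes; lookups beyond the last age
    clamp to the final probability (the model stops at age 70 in the base
    case, so the tail matters little).  Non-decreasing ``qx`` is required
    for synthetic tables and advisory (a warning) for user-supplied ones.
    """

    def __init__(self, ages: Iterable[int], qx: Iterable[float], *,
                 require_monotone: bool = False) -> None:
        self.ages = np.asarray(list(ages), dtype=int)
        self.qx = np.asarray(list(qx), dtype=float)
        if self.ages.size == 0:
            raise LifeTableError("life table is empty")
        if self.ages.size != self.qx.size:
            raise LifeTableError("ages and qx differ in length")
        if np.any(np.diff(self.ages) != 1):
            raise LifeTableError("ages must be contiguous one-year classes")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise LifeTableError("every q must lie in [0, 1]")
        if np.any(np.diff(self.qx) < 0):
            if require_monotone:
                raise LifeTableError("synthetic life table must have "
                                     "non-decreasing q by age")
            warnings.warn("life table q is not non-decreasing in age",
                          stacklevel=2)

    def __len__(self) -> int:
        return int(self.ages.size)

    def lookup(self, age: int) -> float:
        """Annual death probability at ``age``; clamps past the last age."""
        if age < self.ages[0]:
            raise LifeTableError(
                f"age {age} below first tabulated age {self.ages[0]}")
        idx = min(int(age) - int(self.ages[0]), len(self) - 1)
        return float(self.qx[idx])

    def covers(self, lo: int, hi: int) -> bool:
        return self.ages[0] <= lo and self.ages[-1] >= hi

    def to_csv(self, path: str | Path) -> None:
        lines = ["age,qx"] + [f"{a},{q:.10g}" for a, q in zip(self.ages, self.qx)]
        Path(path).write_text("\n".join(lines) + "\n")


def load_life_table(source: str | Path) -> LifeTable:
    """Read an ``age,qx`` CSV (header row, one-year age classes).

    Accepts a path or the CSV text itself.  Gaps in age or probabilities
    outside [0, 1] raise :class:`LifeTableError`.
    """
    text = str(source)
    if "\n" not in text and Path(text).is_file():
        text = Path(text).read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].lower().replace(" ", "") != "age,qx":
        raise LifeTableError("expected header 'age,qx'")
    ages, qx = [], []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split(",")
        if len(parts) != 2:
            raise LifeTableError(f"line {i}: expected two comma-separated values")
        try:
            age = int(parts[0])
            q = float(parts[1])
        except ValueError as exc:
            raise LifeTableError(f"line {i}: {exc}") from exc
        ages.append(age)
        qx.append(q)
    return LifeTable(ages, qx)
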