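"""Parameter table and scenario configuration.

The parameter table is the single source of model inputs: one row per
parameter with a name (following the ``prob_*`` / ``rr_*`` / ``cost_*`` /
``util_*`` / ``qaly_*`` mnemonic convention), the cohort it applies to
(``ischemic``, ``hemorrhagic`` or ``both``), its role, a base (deterministic)
value, an uncertainty distribution for probabilistic sensitivity analysis,
and a low/high range for one-way deterministic sensitivity analysis.

PSA distributions follow standard health-economic convention by role:
beta for probabilities, utilities and whole-pathway QALYs; gamma for costs;
lognormal for relative risks.  When a row supplies only a standard error (or
nothing, in which case the default is 20 % of the base value), the
distribution is fitted by the method of moments and the DSA range defaults
to its 2.5th/97.5th percentiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .model import Cohort, TimingConstants

__all__ = [
    "ParameterValidationError",
    "ROLE_PROBABILITY",
    "ROLE_RELATIVE_RISK",
    "ROLE_COST",
    "ROLE_UTILITY",
    "ROLE_WHOLE_PATHWAY_QALY",
    "ParameterSpec",
    "ParameterTable",
    "moments_to_dist",
    "read_parameter_table",
    "write_parameter_table",
    "sample_psa_draws",
    "ScenarioConfig",
    "apply_scenario",
    "read_scenario",
    "write_scenario",
]


class ParameterValidationError(ValueError):
    """Raised with one message per offending row/field."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid parameter table:\n  - "
                         + "\n  - ".join(self.problems))


ROLE_PROBABILITY = "probability"
ROLE_RELATIVE_RISK = "relative_risk"
ROLE_COST = "cost"
ROLE_UTILITY = "utility"
ROLE_WHOLE_PATHWAY_QALY = "whole_pathway_qaly"

ROLES = (ROLE_PROBABILITY, ROLE_RELATIVE_RISK, ROLE_COST, ROLE_UTILITY,
         ROLE_WHOLE_PATHWAY_QALY)

DIST_BETA = "beta"
DIST_GAMMA = "gamma"
DIST_LOGNORMAL = "lognormal"
DIST_FIXED = "fixed"

_ALLOWED_FAMILY = {
    ROLE_PROBABILITY: {DIST_BETA, DIST_FIXED},
    ROLE_UTILITY: {DIST_BETA, DIST_FIXED},
    ROLE_WHOLE_PATHWAY_QALY: {DIST_BETA, DIST_FIXED},
    ROLE_COST: {DIST_GAMMA, DIST_FIXED},
    ROLE_RELATIVE_RISK: {DIST_LOGNORMAL, DIST_FIXED},
}

#: default relative standard error when a row omits uncertainty entirely
DEFAULT_SE_FRACTION = 0.2

COHORT_VALUES = ("ischemic", "hemorrhagic", "both")


def moments_to_dist(role: str, mean: float, se: float):
    """Method-of-moments fit of the role's PSA distribution.

    Returns ``(family, (param1, param2))`` where the parameters are
    ``(alpha, beta)`` for beta, ``(shape, rate)`` for gamma, and
    ``(mu, sigma)`` of the underlying normal for lognormal.  The fitted
    distribution reproduces ``mean`` exactly (to floating point).
    """
    if not (math.isfinite(mean) and math.isfinite(se)):
        raise ValueError("mean and se must be finite")
    if se <= 0:
        raise ValueError("se must be > 0")
    if role in (ROLE_PROBABILITY, ROLE_UTILITY, ROLE_WHOLE_PATHWAY_QALY):
        if not 0 < mean < 1:
            raise ValueError(f"beta fit requires 0 < mean < 1, got {mean}")
        bound = mean * (1.0 - mean)
        if se ** 2 >= bound:
            raise ValueError(
                f"infeasible beta moments: require se^2 < mean*(1-mean) "
                f"= {bound:.6g}, got se^2 = {se ** 2:.6g}")
        nu = bound / se ** 2 - 1.0
        return DIST_BETA, (mean * nu, (1.0 - mean) * nu)
    if role == ROLE_COST:
        if mean <= 0:
            raise ValueError("gamma fit requires mean > 0")
        shape = (mean / se) ** 2
        rate = mean / se ** 2
        return DIST_GAMMA, (shape, rate)
    if role == ROLE_RELATIVE_RISK:
        if mean <= 0:
            raise ValueError("lognormal fit requires mean > 0")
        sigma2 = math.log1p((se / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return DIST_LOGNORMAL, (mu, math.sqrt(sigma2))
    raise ValueError(f"unknown role {role!r}")


def _dist_mean(family: str, p1: float, p2: float) -> float:
    if family == DIST_BETA:
        return p1 / (p1 + p2)
    if family == DIST_GAMMA:
        return p1 / p2
    if family == DIST_LOGNORMAL:
        return math.exp(p1 + p2 ** 2 / 2.0)
    raise ValueError(family)


def _dist_interval(family: str, p1: float, p2: float, q: float = 0.95):
    lo, hi = (1.0 - q) / 2.0, 1.0 - (1.0 - q) / 2.0
    if family == DIST_BETA:
        d = stats.beta(p1, p2)
    elif family == DIST_GAMMA:
        d = stats.gamma(p1, scale=1.0 / p2)
    elif family == DIST_LOGNORMAL:
        d = stats.lognorm(p2, scale=math.exp(p1))
    else:
        raise ValueError(family)
    return float(d.ppf(lo)), float(d.ppf(hi))


@dataclass(frozen=True)
class ParameterSpec:
    """One validated parameter record."""

    name: str
    cohort: str  # "ischemic" | "hemorrhagic" | "both"
    role: str
    base_value: float
    dist_family: str = ""
    dist_param1: float = math.nan
    dist_param2: float = math.nan
    se: float = math.nan
    dsa_low: float = math.nan
    dsa_high: float = math.nan
    strategy_rr: str = ""

    def validate(self) -> list[str]:
        """Return the list of violated invariants (empty when valid)."""
        problems = []
        if not self.name:
            problems.append("empty parameter name")
        if self.cohort not in COHORT_VALUES:
            problems.append(f"cohort must be one of {COHORT_VALUES}, "
                            f"got {self.cohort!r}")
        if self.role not in ROLES:
            problems.append(f"role must be one of {ROLES}, got {self.role!r}")
            return problems
        v = self.base_value
        if self.role in (ROLE_PROBABILITY, ROLE_UTILITY,
                         ROLE_WHOLE_PATHWAY_QALY):
            if not 0.0 <= v <= 1.0:
                problems.append(f"base_value={v} outside [0, 1] for "
                                f"role {self.role}")
        elif self.role == ROLE_COST:
            if not v >= 0.0:
                problems.append(f"base_value={v} < 0 for role cost")
        elif self.role == ROLE_RELATIVE_RISK:
            if not v > 0.0:
                problems.append(f"base_value={v} <= 0 for role relative_risk")
        if self.dist_family and self.dist_family not in \
                _ALLOWED_FAMILY.get(self.role, set()):
            problems.append(
                f"dist_family {self.dist_family!r} not allowed for role "
                f"{self.role} (allowed: {sorted(_ALLOWED_FAMILY[self.role])})")
        if (math.isfinite(self.dsa_low) and math.isfinite(self.dsa_high)
                and not (self.dsa_low <= v <= self.dsa_high)):
            problems.append(
                f"dsa range [{self.dsa_low}, {self.dsa_high}] does not "
                f"bracket base_value={v}")
        return problems

    @property
    def is_fixed(self) -> bool:
        return self.dist_family == DIST_FIXED


def _complete_spec(spec: ParameterSpec) -> ParameterSpec:
    """Fill in the distribution and DSA range from whatever was supplied.

    Precedence: explicit distribution parameters > supplied standard error >
    default 20 % relative SE.  Base values at a role boundary (0, or 1 for a
    probability-like role) cannot carry a beta/gamma distribution and become
    fixed.  The DSA range defaults to the fitted distribution's central 95 %
    interval (or the base value itself for fixed parameters).
    """
    family = spec.dist_family
    p1, p2 = spec.dist_param1, spec.dist_param2
    base = spec.base_value
    boundary = (base == 0.0 or (
        spec.role in (ROLE_PROBABILITY, ROLE_UTILITY, ROLE_WHOLE_PATHWAY_QALY)
        and base == 1.0))

    if family != DIST_FIXED and not (math.isfinite(p1) and math.isfinite(p2)):
        se = spec.se
        if not math.isfinite(se):
            se = DEFAULT_SE_FRACTION * abs(base)
        if se == 0.0 or boundary:
            family, p1, p2 = DIST_FIXED, math.nan, math.nan
        else:
            family, (p1, p2) = moments_to_dist(spec.role, base, se)
    elif not family:
        family = DIST_FIXED

    dsa_low, dsa_high = spec.dsa_low, spec.dsa_high
    if not (math.isfinite(dsa_low) and math.isfinite(dsa_high)):
        if family == DIST_FIXED:
            dsa_low = dsa_high = base
        else:
            dsa_low, dsa_high = _dist_interval(family, p1, p2)
    return replace(spec, dist_family=family, dist_param1=p1, dist_param2=p2,
                   dsa_low=dsa_low, dsa_high=dsa_high)


_COLUMNS = ["name", "cohort", "role", "base_value", "dist_family",
            "dist_param1", "dist_param2", "se", "dsa_low", "dsa_high",
            "strategy_rr"]


class ParameterTable:
    """Ordered collection of :class:`ParameterSpec`, unique per (name, cohort).

    A *resolved* view (see :meth:`for_cohort`) contains at most one row per
    name, with cohort-specific rows overriding ``both`` rows; the model and
    the PSA sampler operate on resolved views.
    """

    def __init__(self, specs: Iterable[ParameterSpec], complete: bool = True):
        raw = list(specs)
        problems: list[str] = []
        seen: set[tuple[str, str]] = set()
        completed: list[ParameterSpec] = []
        for i, s in enumerate(raw):
            row_problems = s.validate()
            for msg in row_problems:
                problems.append(f"row {i} ({s.name!r}): {msg}")
            key = (s.name, s.cohort)
            if key in seen:
                problems.append(f"row {i}: duplicated parameter "
                                f"{s.name!r} for cohort {s.cohort!r}")
            seen.add(key)
            if complete and not row_problems:
                try:
                    s = _complete_spec(s)
                except ValueError as exc:
                    problems.append(f"row {i} ({s.name!r}): {exc}")
            completed.append(s)
        if problems:
            raise ParameterValidationError(problems)
        specs = completed
        self.specs: list[ParameterSpec] = specs
        self._index = {(s.name, s.cohort): s for s in specs}

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{c: getattr(s, c) for c in _COLUMNS}
                             for s in self.specs])

    # -- lookup ------------------------------------------------------------

    def get(self, name: str, cohort: "Cohort | str | None" = None
            ) -> ParameterSpec:
        if cohort is not None:
            c = Cohort.parse(cohort).value
            spec = self._index.get((name, c)) or self._index.get(
                (name, "both"))
        else:
            spec = self._index.get((name, "both"))
            if spec is None:
                candidates = [s for s in self.specs if s.name == name]
                spec = candidates[0] if len(candidates) == 1 else None
        if spec is None:
            raise KeyError(f"no parameter {name!r}"
                           + (f" for cohort {cohort}" if cohort else ""))
        return spec

    def value(self, name: str, cohort: "Cohort | str | None" = None) -> float:
        return self.get(name, cohort).base_value

    def for_cohort(self, cohort: "Cohort | str") -> "ParameterTable":
        """Resolved single-cohort view: cohort rows override ``both`` rows."""
        c = Cohort.parse(cohort).value
        out: dict[str, ParameterSpec] = {}
        for s in self.specs:
            if s.cohort == "both" and s.name not in out:
                out[s.name] = s
            elif s.cohort == c:
                out[s.name] = s
        return ParameterTable(out.values(), complete=False)

    @property
    def is_resolved(self) -> bool:
        return len(set(self.names)) == len(self.specs)

    def cohort_values(self, cohort: "Cohort | str") -> dict[str, float]:
        view = self if self.is_resolved else self.for_cohort(cohort)
        return {s.name: s.base_value for s in view.specs}

    def strategy_rr_map(self, cohort: "Cohort | str | None" = None
                        ) -> dict[str, str]:
        view = self
        if cohort is not None and not self.is_resolved:
            view = self.for_cohort(cohort)
        return {s.name: s.strategy_rr for s in view.specs if s.strategy_rr}

    # -- modification ------------------------------------------------------

    def with_base(self, name: str, value: float,
                  cohort: "Cohort | str | None" = None,
                  refit: bool = False) -> "ParameterTable":
        """Copy of the table with one parameter's base value replaced.

        With ``refit=True`` the PSA distribution and DSA range are refitted
        around the new value (keeping the row's relative SE, or the default);
        otherwise only the deterministic value changes (the DSA convention).
        """
        target = self.get(name, cohort)
        new_specs = []
        for s in self.specs:
            if s is not target:
                new_specs.append(s)
                continue
            if refit and s.dist_family == DIST_FIXED:
                # a declared-fixed row stays fixed under scenario overrides
                s = replace(s, base_value=value, dsa_low=value,
                            dsa_high=value)
            elif refit:
                rel = (s.se / s.base_value
                       if math.isfinite(s.se) and s.base_value
                       else DEFAULT_SE_FRACTION)
                s = replace(s, base_value=value, se=rel * abs(value),
                            dist_param1=math.nan, dist_param2=math.nan,
                            dsa_low=math.nan, dsa_high=math.nan)
                s = _complete_spec(s)
            else:
                lo = min(s.dsa_low, value)
                hi = max(s.dsa_high, value)
                s = replace(s, base_value=value, dsa_low=lo, dsa_high=hi)
            new_specs.append(s)
        return ParameterTable(new_specs, complete=False)


def read_parameter_table(path) -> ParameterTable:
    """Read and validate a parameter-table CSV.

    Dialect: comma-separated, UTF-8, '.' decimal separator, header row
    required; lines starting with ``#`` are comments.  Missing optional
    columns (distribution parameters, se, DSA bounds, strategy_rr) are
    completed with the documented defaults.
    """
    df = pd.read_csv(path, comment="#", skip_blank_lines=True,
                     encoding="utf-8")
    required = {"name", "cohort", "role", "base_value"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterValidationError(
            [f"missing required column(s): {sorted(missing)}"])
    specs = []
    problems = []
    for i, row in df.iterrows():
        def _num(col, default=math.nan):
            v = row.get(col, default)
            return default if pd.isna(v) else float(v)

        def _str(col):
            v = row.get(col, "")
            return "" if pd.isna(v) else str(v).strip()

        try:
            spec = ParameterSpec(
                name=_str("name"), cohort=_str("cohort") or "both",
                role=_str("role"), base_value=_num("base_value"),
                dist_family=_str("dist_family"),
                dist_param1=_num("dist_param1"), dist_param2=_num("dist_param2"),
                se=_num("se"), dsa_low=_num("dsa_low"),
                dsa_high=_num("dsa_high"), strategy_rr=_str("strategy_rr"))
            specs.append(spec)
        except (TypeError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise ParameterValidationError(problems)
    return ParameterTable(specs)


def write_parameter_table(table: ParameterTable, path) -> None:
    """Write the CSV dialect read by :func:`read_parameter_table`."""
    table.to_frame().to_csv(path, index=False, encoding="utf-8")


def sample_psa_draws(table: ParameterTable, n: int,
                     seed: "int | Sequence[int] | np.random.Generator" = 0
                     ) -> pd.DataFrame:
    """Sample an ``n x p`` matrix of parameter draws (one column per row of a
    resolved table, in table order).

    Beta draws for probabilities/utilities/whole-pathway QALYs, gamma for
    costs, lognormal for relative risks, constant columns for fixed
    parameters; every column respects its role's bounds by construction.
    Reproducible: the same seed yields the same matrix.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not table.is_resolved:
        raise ValueError("sample_psa_draws requires a resolved (single "
                         "cohort) table; call for_cohort() first")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cols = {}
    for s in table.specs:
        if s.dist_family == DIST_FIXED:
            cols[s.name] = np.full(n, s.base_value)
        elif s.dist_family == DIST_BETA:
            cols[s.name] = rng.beta(s.dist_param1, s.dist_param2, n)
        elif s.dist_family == DIST_GAMMA:
            cols[s.name] = rng.gamma(s.dist_param1,
                                     scale=1.0 / s.dist_param2, size=n)
        elif s.dist_family == DIST_LOGNORMAL:
            cols[s.name] = rng.lognormal(s.dist_param1, s.dist_param2, n)
        else:  # pragma: no cover - excluded by validation
            raise ParameterValidationError(
                [f"{s.name}: unknown dist_family {s.dist_family!r}"])
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# scenarios


SCENARIO_RR = {"optimistic": 0.3, "conservative": 0.9}
DEFAULT_THRESHOLD = 75_000.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Analysis scenario: intervention effectiveness assumption and pricing.

    The optimistic scenario assumes a relative risk of ankle contracture for
    VACOM versus IPC plus manual ankle movement of 0.3; the conservative
    scenario assumes 0.9.  The ceiling cost-effectiveness threshold defaults
    to S$75,000 per QALY.
    """

    name: str = "custom"
    rr_ankle_contracture_vacom: float = 0.9
    price_premium: float = 150.0
    cohort: "Cohort | None" = None
    threshold: float = DEFAULT_THRESHOLD
    timing: TimingConstants = field(default_factory=TimingConstants)
    seed: int = 0
    n_psa: int = 5000

    def __post_init__(self) -> None:
        if self.name not in ("optimistic", "conservative", "custom"):
            raise ValueError("scenario name must be optimistic, conservative "
                             "or custom")
        if self.name in SCENARIO_RR and \
                self.rr_ankle_contracture_vacom != SCENARIO_RR[self.name]:
            raise ValueError(
                f"the {self.name} scenario is defined by "
                f"rr_ankle_contracture_vacom = {SCENARIO_RR[self.name]}")
        if self.rr_ankle_contracture_vacom <= 0:
            raise ValueError("rr_ankle_contracture_vacom must be > 0")
        if self.price_premium < 0:
            raise ValueError("price_premium must be >= 0")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.n_psa < 2:
            raise ValueError("n_psa must be >= 2")

    @property
    def label(self) -> str:
        return f"{self.name}_premium{self.price_premium:g}"


def apply_scenario(table: ParameterTable, scenario: ScenarioConfig
                   ) -> ParameterTable:
    """Return a copy of the table with the scenario's effectiveness
    assumption applied: the ankle-contracture RR base value is set to the
    scenario value and its PSA distribution/DSA range refitted around it."""
    return table.with_base("rr_ankcon_vac",
                           scenario.rr_ankle_contracture_vacom, refit=True)


def _scenario_to_dict(s: ScenarioConfig) -> dict:
    return {
        "name": s.name,
        "rr_ankle_contracture_vacom": s.rr_ankle_contracture_vacom,
        "price_premium": s.price_premium,
        "cohort": s.cohort.value if s.cohort else None,
        "threshold": s.threshold,
        "timing": {
            "horizon_months": s.timing.horizon_months,
            "inpatient_months": s.timing.inpatient_months,
            "inpatient_death_day": s.timing.inpatient_death_day,
            "postdischarge_event_month": s.timing.postdischarge_event_month,
        },
        "seed": s.seed,
        "n_psa": s.n_psa,
    }


def write_scenario(scenario: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_scenario_to_dict(scenario),
                                         sort_keys=False), encoding="utf-8")


def read_scenario(path) -> ScenarioConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    timing = TimingConstants(**raw.pop("timing", {}))
    cohort = raw.pop("cohort", None)
    return ScenarioConfig(
        timing=timing,
        cohort=Cohort.parse(cohort) if cohort else None,
        **raw)
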