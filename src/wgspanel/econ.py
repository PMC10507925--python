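"""Cost-consequence decision model for germline testing scenarios.

Three hypothetical national testing programmes for individuals referred to a
Familial Cancer Centre (FCC) with suspected hereditary cancer are compared on
annual cost and overall diagnostic yield:

* **Scenario 1** — standard of care: a fraction of referred individuals is
  offered targeted gene / gene-panel testing when specific genes are
  indicated.
* **Scenario 2** — standard of care followed by WGS: targeted testing as in
  Scenario 1, then whole-genome sequencing (WGS) with a virtual
  multidisciplinary-team (MDT) review offered both to individuals whose
  targeted test found no LP/P variant (subgroup *a*) and to individuals in
  whom no gene was indicated (subgroup *b*).
* **Scenario 3** — upfront WGS for every referred individual; only the
  *complex* fraction of cases is routed through a virtual MDT meeting.

The model is an expected-value cohort tree: counts flow through
offer → uptake → test → yield branches as real numbers and are rounded only
for display.  Costs accrue per branch from unit costs (pre-/post-test
counselling, test prices, MDT meetings, administration, programme overhead).
All monetary values are AUD at 2020 prices; a single 12-month horizon is
used and no discounting is applied.

Overall diagnostic yield is the number of individuals with an actionable
(LP/P) variant divided by the number referred.  The marginal cost per
additional actionable case between two scenarios is Δcost / Δcases.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "EconScenarioConfig",
    "EconResult",
    "default_config",
    "scale_national",
    "evaluate_scenario",
    "evaluate_all",
    "marginal_analysis",
    "one_way_sensitivity",
    "rounded_headline",
    "load_config",
    "save_config",
]


_FRACTION_FIELDS = (
    "offered_targeted_proportion",
    "targeted_uptake",
    "targeted_yield",
    "wgs_uptake_s2",
    "wgs_uptake_s3",
    "wgs_yield_s3",
    "wgs_yield_s2_subgroup_a",
    "wgs_yield_s2_subgroup_b",
    "wgs_offer_s2_subgroup_a",
    "wgs_offer_s2_subgroup_b",
    "complex_case_fraction",
)

_COST_FIELDS = (
    "cost_pretest_counselling",
    "cost_posttest_counselling_positive",
    "cost_posttest_counselling_negative",
    "cost_targeted_test",
    "cost_wgs",
    "cost_mdt_per_case",
    "cost_admin_complex",
    "cost_admin_noncomplex",
    "cost_programme_overhead",
)


@dataclass
class EconScenarioConfig:
    """Parameters of the three-scenario model (AUD 2020, one-year horizon).

    Uptake/yield fractions for the targeted arm and the Scenario-2 WGS
    subgroups, and the per-item unit costs, are programme-level estimates
    supplied by the user; the defaults returned by :func:`default_config`
    are placeholders calibrated so the base case reproduces the published
    scenario totals (see ``docs/methods.md``).
    """

    referred_national: float = 13230.0
    offered_targeted_proportion: float = 0.3504
    targeted_uptake: float = 0.85
    targeted_yield: float = 0.1165
    wgs_uptake_s2: float = 0.796
    wgs_uptake_s3: float = 0.968
    wgs_yield_s3: float = 0.384
    wgs_yield_s2_subgroup_a: float = 0.155
    wgs_yield_s2_subgroup_b: float = 0.1743
    wgs_offer_s2_subgroup_a: float = 1.0
    wgs_offer_s2_subgroup_b: float = 1.0
    complex_case_fraction: float = 0.54
    # unit costs, AUD 2020
    cost_pretest_counselling: float = 200.0
    cost_posttest_counselling_positive: float = 400.0
    cost_posttest_counselling_negative: float = 150.0
    cost_targeted_test: float = 870.0
    cost_wgs: float = 1750.0
    cost_mdt_per_case: float = 1450.0
    cost_admin_complex: float = 500.0
    cost_admin_noncomplex: float = 150.0
    cost_programme_overhead: float = 110.0
    # sensitivity switch: route every Scenario-3 case through a virtual MDT
    mdt_all_cases_s3: bool = False

    def __post_init__(self) -> None:
        if self.referred_national < 0:
            raise ValueError("referred_national must be >= 0")
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in _COST_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def replace(self, **kwargs) -> "EconScenarioConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EconScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown economic parameters: {sorted(unknown)}")
        return cls(**d)


def default_config() -> EconScenarioConfig:
    """Base-case configuration (calibrated placeholder unit costs)."""
    return EconScenarioConfig()


@dataclass
class EconResult:
    """Outputs of one scenario evaluation.

    ``branches`` holds one row per decision-tree node with the expected
    number of individuals entering, tested and found actionable, and the
    cost accrued on that branch.  Counts are real-valued expectations.
    """

    scenario: int
    branches: pd.DataFrame
    total_cost: float
    actionable_cases: float
    referred: float

    @property
    def overall_yield(self) -> float:
        return self.actionable_cases / self.referred

    @property
    def cost_per_actionable(self) -> float:
        return self.total_cost / self.actionable_cases


def scale_national(state_referred: float, state_population: float,
                   national_population: float) -> int:
    """Scale a state-level referral count to the nation by population ratio."""
    if state_population <= 0 or national_population <= 0:
        raise ValueError("populations must be positive")
    return round(state_referred * national_population / state_population)


def _branch(label: str, entering: float, tested: float, actionable: float,
            cost: float) -> dict:
    return {
        "branch": label,
        "n_entering": entering,
        "n_tested": tested,
        "n_actionable": actionable,
        "cost": cost,
    }


def _targeted_arm(cfg: EconScenarioConfig) -> tuple[list[dict], float, float, float]:
    """Targeted-testing arm shared by Scenarios 1 and 2.

    Returns (branches, n_tested, n_positive, n_not_offered).
    """
    referred = cfg.referred_national
    offered = referred * cfg.offered_targeted_proportion
    not_offered = referred - offered
    tested = offered * cfg.targeted_uptake
    positive = tested * cfg.targeted_yield
    negative = tested - positive
    cost = (
        tested * (cfg.cost_pretest_counselling + cfg.cost_targeted_test)
        + positive * cfg.cost_posttest_counselling_positive
        + negative * cfg.cost_posttest_counselling_negative
    )
    branches = [
        _branch("targeted:offered", offered, tested, positive, cost),
        _branch("targeted:not_offered", not_offered, 0.0, 0.0, 0.0),
    ]
    return branches, tested, positive, not_offered


def _wgs_mdt_cost(cfg: EconScenarioConfig, tested: float, positive: float) -> float:
    """Cost of a WGS-plus-virtual-MDT pathway (Scenario-2 style: MDT for all)."""
    negative = tested - positive
    per_test = (
        cfg.cost_wgs
        + cfg.cost_pretest_counselling
        + cfg.cost_mdt_per_case
        + cfg.cost_admin_complex
        + cfg.cost_programme_overhead
    )
    return (
        tested * per_test
        + positive * cfg.cost_posttest_counselling_positive
        + negative * cfg.cost_posttest_counselling_negative
    )


def evaluate_scenario(config: EconScenarioConfig, scenario: int) -> EconResult:
    """Evaluate one testing scenario and return its branch table and totals."""
    if scenario not in (1, 2, 3):
        raise ValueError(f"scenario must be 1, 2 or 3, got {scenario!r}")
    cfg = config
    referred = cfg.referred_national

    if scenario == 1:
        branches, _tested, positive, _ = _targeted_arm(cfg)

    elif scenario == 2:
        branches, tested, positive, not_offered = _targeted_arm(cfg)
        t_negative = tested - positive
        # subgroup (a): targeted-tested with no LP/P found
        a_tested = t_negative * cfg.wgs_offer_s2_subgroup_a * cfg.wgs_uptake_s2
        a_pos = a_tested * cfg.wgs_yield_s2_subgroup_a
        a_cost = _wgs_mdt_cost(cfg, a_tested, a_pos)
        branches.append(
            _branch("wgs_s2:tested_negative", t_negative, a_tested, a_pos, a_cost)
        )
        # subgroup (b): no gene indicated, never offered targeted testing
        b_tested = not_offered * cfg.wgs_offer_s2_subgroup_b * cfg.wgs_uptake_s2
        b_pos = b_tested * cfg.wgs_yield_s2_subgroup_b
        b_cost = _wgs_mdt_cost(cfg, b_tested, b_pos)
        branches.append(
            _branch("wgs_s2:not_offered", not_offered, b_tested, b_pos, b_cost)
        )
        positive = positive + a_pos + b_pos

    else:  # scenario 3: upfront WGS for all referred
        tested = referred * cfg.wgs_uptake_s3
        positive = tested * cfg.wgs_yield_s3
        negative = tested - positive
        complex_frac = 1.0 if cfg.mdt_all_cases_s3 else cfg.complex_case_fraction
        n_complex = tested * complex_frac
        n_noncomplex = tested - n_complex
        cost = (
            tested * (cfg.cost_wgs + cfg.cost_pretest_counselling
                      + cfg.cost_programme_overhead)
            + n_complex * (cfg.cost_mdt_per_case + cfg.cost_admin_complex)
            + n_noncomplex * cfg.cost_admin_noncomplex
            + positive * cfg.cost_posttest_counselling_positive
            + negative * cfg.cost_posttest_counselling_negative
        )
        branches = [_branch("wgs_s3:all_referred", referred, tested, positive, cost)]

    df = pd.DataFrame(branches)
    return EconResult(
        scenario=scenario,
        branches=df,
        total_cost=float(df["cost"].sum()),
        actionable_cases=float(df["n_actionable"].sum()),
        referred=referred,
    )


def evaluate_all(config: EconScenarioConfig) -> dict[int, EconResult]:
    return {s: evaluate_scenario(config, s) for s in (1, 2, 3)}


def marginal_analysis(target: EconResult, comparator: EconResult) -> float:
    """Marginal cost per additional actionable case of `target` over `comparator`."""
    d_cases = target.actionable_cases - comparator.actionable_cases
    if d_cases <= 0:
        raise ValueError(
            "marginal cost undefined: target does not detect more cases than comparator"
        )
    return (target.total_cost - comparator.total_cost) / d_cases


def rounded_headline(result: EconResult) -> dict:
    """Headline figures at publication granularity.

    Total cost rounded to the nearest $0.1M, case counts to the nearest
    individual, overall yield to one decimal percent.
    """
    total_m = round(result.total_cost / 1e6, 1)
    cases = round(result.actionable_cases)
    return {
        "scenario": result.scenario,
        "total_cost_musd": total_m,
        "actionable_cases": cases,
        "overall_yield_pct": round(100.0 * result.overall_yield, 1),
        "cost_per_actionable": total_m * 1e6 / cases,
    }


def one_way_sensitivity(
    config: EconScenarioConfig,
    param_name: str,
    values: Iterable,
    scenarios: Sequence[int] = (1, 2, 3),
) -> pd.DataFrame:
    """Re-evaluate the scenarios varying a single parameter.

    Returns a long-format table keyed by (param, value, scenario, metric).
    The base-case value should be included in `values` by the caller.
    """
    if param_name not in {f.name for f in dataclasses.fields(EconScenarioConfig)}:
        raise ValueError(f"unknown parameter: {param_name!r}")
    rows = []
    for value in values:
        cfg = config.replace(**{param_name: value})
        for s in scenarios:
            res = evaluate_scenario(cfg, s)
            for metric, v in (
                ("total_cost", res.total_cost),
                ("actionable_cases", res.actionable_cases),
                ("overall_yield", res.overall_yield),
                ("cost_per_actionable", res.cost_per_actionable),
            ):
                rows.append(
                    {
                        "param": param_name,
                        "value": value,
                        "scenario": s,
                        "metric": metric,
                        "result": v,
                    }
                )
    return pd.DataFrame(rows)


def load_config(path) -> EconScenarioConfig:
    with open(path) as fh:
        return EconScenarioConfig.from_dict(yaml.safe_load(fh))


def save_config(config: EconScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
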