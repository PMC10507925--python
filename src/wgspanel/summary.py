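"""Cohort-level tallies and percentages.

Aggregates the case table, the post-MDT reports and the returned-variant
table into the counts and percentages a study report prints: diagnostic
yield of causal LP/P findings, secondary findings, risk-management
changes, returned-variant breakdowns by class / tier / type / gene,
eligibility-criterion counts (which may sum past 100% because criteria
overlap), and the multi-phenotype fraction among reported cases.

Percentages follow the manuscript-table convention: 100·n/d rounded
half-up to one decimal place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .synth import PHENOTYPE_CATEGORIES

__all__ = ["pct", "CohortSummary", "summarise"]

_ELIG_COLS = (
    "elig_syndrome",
    "elig_two_primaries",
    "elig_three_primaries",
    "elig_polyposis",
    "elig_multi_criteria",
)

_KNOWN_PHENOTYPES = {name for name, _ in PHENOTYPE_CATEGORIES}


def pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (table convention)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Named counts/percentages; percentages carry one decimal place."""

    metrics: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.metrics[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"metric": k, "value": v} for k, v in self.metrics.items()]
        )


def summarise(cases: pd.DataFrame, reports: list, variants: pd.DataFrame) -> CohortSummary:
    """Compute the cohort summary from cases, reports and returned variants."""
    n_cases = len(cases)
    known = set(cases["case_id"])
    dangling = set(variants["case_id"]) - known
    if dangling:
        raise ValueError(f"variants reference unknown cases: {sorted(dangling)}")

    pheno_lists = cases["phenotypes"].str.split("|")
    unknown_ph = set(p for lst in pheno_lists for p in lst) - _KNOWN_PHENOTYPES
    if unknown_ph:
        raise ValueError(f"unknown phenotype categories: {sorted(unknown_ph)}")

    returned = variants[variants["mdt_verdict"] == "return"]
    lpp = returned[returned["acmg_class"].isin(["LP", "P"])]
    vus = returned[returned["acmg_class"] == "VUS"]

    causal_cases = set(returned.loc[returned["causal_for_phenotype"], "case_id"])
    lpp_cases = set(lpp["case_id"])
    secondary_cases = lpp_cases - causal_cases
    risk_cases = set(returned.loc[returned["risk_management_changed"], "case_id"])
    uninformative_cases = lpp_cases - risk_cases

    m: dict = {}
    m["n_cases"] = n_cases
    m["n_reported_cases"] = len({r.case_id for r in reports})
    m["n_returned_variants"] = len(returned)
    m["n_lp_p"] = len(lpp)
    m["n_vus"] = len(vus)
    for tier in ("A", "B", "C"):
        m[f"n_vus_{tier.lower()}"] = int((vus["vus_tier"] == tier).sum())

    m["n_causal_cases"] = len(causal_cases)
    m["pct_causal_cases"] = pct(len(causal_cases), n_cases)
    m["n_secondary_cases"] = len(secondary_cases)
    m["pct_secondary_cases"] = pct(len(secondary_cases), n_cases)
    m["n_risk_management_changed"] = len(risk_cases)
    m["pct_risk_management_changed"] = pct(len(risk_cases), n_cases)
    m["n_lp_p_uninformative"] = len(uninformative_cases)
    m["pct_lp_p_uninformative"] = pct(len(uninformative_cases), n_cases)

    by_type = returned["variant_type"].value_counts().to_dict()
    for t, c in sorted(by_type.items()):
        m[f"n_type_{t.lower()}"] = int(c)
    by_gene = returned["gene"].value_counts().to_dict()
    m["n_genes_with_return"] = len(by_gene)
    m["by_gene"] = {g: int(c) for g, c in sorted(by_gene.items())}

    for col in _ELIG_COLS:
        m[f"n_{col}"] = int(cases[col].sum())
        m[f"pct_{col}"] = pct(int(cases[col].sum()), n_cases)

    m["n_prior_testing_uninformative"] = int((cases["prior_testing"] == "uninformative").sum())
    m["n_prior_testing_none"] = int((cases["prior_testing"] == "none").sum())
    m["n_female"] = int((cases["sex"] == "F").sum())
    m["n_male"] = int((cases["sex"] == "M").sum())

    sizes = pd.Series([len(r.variant_ids) for r in reports])
    for k in (1, 2, 3):
        m[f"n_reports_{k}_variant"] = int((sizes == k).sum())

    reported_ids = {r.case_id for r in reports}
    multi = cases["case_id"].isin(reported_ids) & (pheno_lists.str.len() >= 2)
    m["n_reported_multi_phenotype"] = int(multi.sum())
    if reported_ids:
        m["pct_reported_multi_phenotype"] = pct(int(multi.sum()), len(reported_ids))
    lpp_multi = cases["case_id"].isin(lpp_cases) & (pheno_lists.str.len() >= 2)
    m["n_lp_p_multi_phenotype"] = int(lpp_multi.sum())

    return CohortSummary(metrics=m)
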