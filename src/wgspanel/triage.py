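"""Reportability gating, MDT verdict bookkeeping and case-report assembly.

Curated variants (ACMG/AMP class is an input annotation; curation judgement
itself is out of scope) pass through a reportability gate before entering a
preliminary research report for multidisciplinary-team (MDT) review:

* LP/P variants are always reported, even for recessive conditions or
  phenotype-discordant genes;
* variants not meeting benign/likely-benign criteria are *suppressed* if
  they match an exclusionary pattern — missense with REVEL < 0.5,
  synonymous with no predicted splice impact, or in-frame indel with
  PROVEAN > −2.5 — unless rescued by an apparent gene–phenotype
  association, an alternative deleteriousness predictor (CADD > 20), or an
  LP/P ClinVar classification from at least one submitter.

MDT verdicts are inputs, not computed: ``return`` verdicts (optionally
setting the VUS tier and finding flags), ``exclude``, and
``downgrade_B_LB`` (downgraded variants are never returned to the
clinician).  A variant returned without formal MDT review is modelled as a
``return`` verdict flagged ``direct_return``.  Post-MDT case reports list
only returned variants, with a finding category derived per LP/P variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REPORT", "SUPPRESS",
    "reportability_gate",
    "apply_mdt_verdicts",
    "CaseReport",
    "build_reports",
]

REPORT = "report"
SUPPRESS = "suppress"

_VERDICTS = {"return", "exclude", "downgrade_B_LB"}


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def reportability_gate(v) -> tuple[str, str]:
    """Decide whether a curated variant enters the preliminary report.

    `v` is a mapping with acmg_class, consequence, revel, provean,
    splice_impact_predicted, and the rescue fields gene_phenotype_match,
    cadd, clinvar_lp_p_any_submitter.  B/LB variants never reach this gate.
    Returns ``(decision, reason)``.
    """
    acmg = v["acmg_class"]
    if acmg in ("B", "LB"):
        raise ValueError("B/LB variants are excluded upstream of the reportability gate")
    if acmg in ("LP", "P"):
        return REPORT, "LP_P_ALWAYS_REPORTED"

    cons = v["consequence"]
    if cons == "missense":
        if _missing(v.get("revel")):
            raise ValueError("missense variant missing REVEL score")
        exclusionary = v["revel"] < 0.5
        rule = "MISSENSE_LOW_REVEL"
    elif cons == "synonymous":
        exclusionary = not bool(v.get("splice_impact_predicted", False))
        rule = "SYNONYMOUS_NO_SPLICE_IMPACT"
    elif cons == "inframe_indel":
        if _missing(v.get("provean")):
            raise ValueError("in-frame indel missing PROVEAN score")
        exclusionary = v["provean"] > -2.5
        rule = "INFRAME_HIGH_PROVEAN"
    else:
        # frameshift / splice / other consequences match no exclusionary
        # category and always pass
        return REPORT, "NO_EXCLUSIONARY_CATEGORY"

    if not exclusionary:
        return REPORT, "EXCLUSIONARY_CONDITION_NOT_MET"

    if bool(v.get("gene_phenotype_match", False)):
        return REPORT, "RESCUE_GENE_PHENOTYPE"
    cadd = v.get("cadd")
    if not _missing(cadd) and cadd > 20:
        return REPORT, "RESCUE_CADD"
    if bool(v.get("clinvar_lp_p_any_submitter", False)):
        return REPORT, "RESCUE_CLINVAR_SUBMITTER"
    return SUPPRESS, rule


def apply_mdt_verdicts(variants: pd.DataFrame, verdicts: pd.DataFrame) -> pd.DataFrame:
    """Stamp MDT verdicts onto a variant table.

    `verdicts` columns: variant_id, verdict, and optionally tier, causal,
    secondary, somatic, risk_changed, direct_return.  Variants without a
    verdict stay ``pending``.  A verdict for an unknown variant id is an
    error.
    """
    out = variants.copy()
    if "mdt_verdict" not in out.columns:
        out["mdt_verdict"] = "pending"
    known = set(out["variant_id"])
    for _, vrow in verdicts.iterrows():
        vid = vrow["variant_id"]
        if vid not in known:
            raise ValueError(f"verdict refers to unknown variant id {vid!r}")
        verdict = vrow["verdict"]
        if verdict not in _VERDICTS:
            raise ValueError(f"unknown MDT verdict {verdict!r}")
        mask = out["variant_id"] == vid
        out.loc[mask, "mdt_verdict"] = verdict
        if verdict == "return":
            for src, dst in (
                ("tier", "vus_tier"),
                ("causal", "causal_for_phenotype"),
                ("secondary", "secondary_finding"),
                ("somatic", "somatic_origin"),
                ("risk_changed", "risk_management_changed"),
                ("direct_return", "direct_return"),
            ):
                if src in vrow.index and not _missing(vrow[src]):
                    out.loc[mask, dst] = vrow[src]
    return out


@dataclass
class CaseReport:
    """Post-MDT research report for one index case."""

    case_id: str
    variant_ids: list[str] = field(default_factory=list)
    #: finding category per returned LP/P variant, keyed by variant id
    finding_categories: dict[str, str] = field(default_factory=dict)


def _finding_category(v) -> str:
    if bool(v.get("somatic_origin", False)):
        return "somatic"
    if bool(v.get("causal_for_phenotype", False)):
        return "causal"
    for col in ("finding_category",):
        if col in v and isinstance(v[col], str) and v[col]:
            return v[col]
    return "new_diagnosis"


def build_reports(cases: pd.DataFrame, variants: pd.DataFrame) -> list[CaseReport]:
    """One report per case holding at least one returned variant.

    Downgraded or excluded variants never appear; B/LB classes are
    rejected outright as a safety check.
    """
    returned = variants[variants["mdt_verdict"] == "return"]
    if (returned["acmg_class"].isin(["B", "LB"])).any():
        raise ValueError("B/LB variant marked for return — refusing to build reports")
    known_cases = set(cases["case_id"])
    dangling = set(returned["case_id"]) - known_cases
    if dangling:
        raise ValueError(f"returned variants reference unknown cases: {sorted(dangling)}")
    reports = []
    for case_id, grp in returned.groupby("case_id", sort=True):
        rep = CaseReport(case_id=case_id, variant_ids=list(grp["variant_id"]))
        for _, v in grp.iterrows():
            if v["acmg_class"] in ("LP", "P"):
                rep.finding_categories[v["variant_id"]] = _finding_category(v)
        reports.append(rep)
    return reports
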