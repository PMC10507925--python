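"""SNV/indel prioritisation cascade.

Annotated germline small-variant calls are reduced to candidates worth
curating by three per-variant gates applied in order:

1. **panel restriction** — the gene must belong to the virtual panel of
   cancer predisposition genes;
2. **frequency gate** — the variant is discarded if its allele frequency
   exceeds 1% in any eligible gnomAD subpopulation (exome- and
   genome-derived frequencies considered separately), in the study cohort,
   or in the in-house germline dataset — *unless* it carries a likely
   pathogenic / pathogenic (LP/P) ClinVar classification, which waives the
   frequency filters entirely;
3. **VAF gate** — a call-quality filter: SNVs (and dinucleotide
   substitutions) with variant allele fraction below 30%, and indels below
   20%, are removed.  The ClinVar rescue does not waive this gate.

All inequalities are strict, so a variant sitting exactly on a threshold
(AF = 1%, VAF = 30%/20%) is retained.  Missing allele frequencies are
treated as 0 (absence from a population resource implies rarity).

Every input variant receives an audit row recording each gate's decision
and the ordered list of rule identifiers that fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FilterDecision",
    "VARIANT_CLASSES",
    "CLINVAR_STATUSES",
    "VAF_MIN_SNV",
    "VAF_MIN_INDEL",
    "AF_MAX",
    "clinvar_rescue",
    "passes_frequency_gate",
    "passes_vaf_gate",
    "run_small_variant_cascade",
]

VARIANT_CLASSES = frozenset({"snv", "indel", "dnv"})
CLINVAR_STATUSES = frozenset({"none", "B", "LB", "VUS", "LP", "P"})

#: population allele-frequency ceiling (strict: > 1% drops)
AF_MAX = 0.01
#: minimum VAF retained for substitution calls (strict: < 30% drops)
VAF_MIN_SNV = 0.30
#: minimum VAF retained for indel calls (strict: < 20% drops)
VAF_MIN_INDEL = 0.20

# column prefixes for per-subpopulation gnomAD allele frequencies
GNOMAD_EXOME_PREFIX = "gnex_"
GNOMAD_GENOME_PREFIX = "gnge_"


@dataclass
class FilterDecision:
    """Outcome of one gate: keep/drop plus the ordered rule identifiers."""

    keep: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.keep and not self.reasons:
            raise ValueError("a drop decision must carry at least one reason")


def _af_value(v: Mapping, key: str) -> float:
    x = v.get(key, 0.0) if hasattr(v, "get") else getattr(v, key, 0.0)
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return 0.0
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"allele frequency {key}={x} outside [0, 1]")
    return x


def clinvar_rescue(v: Mapping) -> bool:
    """True iff the variant has an LP/P ClinVar classification.

    A rescued variant bypasses the frequency filters (not the VAF gate).
    """
    return v["clinvar_status"] in ("LP", "P")


def passes_frequency_gate(v: Mapping, eligible_subpops: Mapping[str, Mapping[str, bool]]) -> FilterDecision:
    """Apply the 1% population/cohort/in-house allele-frequency filter.

    `eligible_subpops` maps subpopulation label -> {"exome": bool,
    "genome": bool}; only eligible resources (those with at least 2000
    individuals) are consulted.  Exome- and genome-derived frequencies are
    considered separately.
    """
    reasons: list[str] = []
    for pop, elig in eligible_subpops.items():
        if elig.get("exome", False) and _af_value(v, GNOMAD_EXOME_PREFIX + pop) > AF_MAX:
            reasons.append(f"AF_GNOMAD_EXOME_{pop.upper()}")
        if elig.get("genome", False) and _af_value(v, GNOMAD_GENOME_PREFIX + pop) > AF_MAX:
            reasons.append(f"AF_GNOMAD_GENOME_{pop.upper()}")
    if _af_value(v, "cohort_af") > AF_MAX:
        reasons.append("COHORT_AF")
    if _af_value(v, "inhouse_af") > AF_MAX:
        reasons.append("INHOUSE_AF")
    if reasons and clinvar_rescue(v):
        return FilterDecision(keep=True, reasons=["CLINVAR_RESCUE"])
    return FilterDecision(keep=not reasons, reasons=reasons)


def passes_vaf_gate(v: Mapping) -> FilterDecision:
    """Apply the variant-allele-fraction call-quality filter."""
    vaf = v.get("vaf") if hasattr(v, "get") else getattr(v, "vaf", None)
    if vaf is None or (isinstance(vaf, float) and np.isnan(vaf)):
        raise ValueError("missing VAF")
    vaf = float(vaf)
    vclass = v["variant_class"]
    if vclass not in VARIANT_CLASSES:
        raise ValueError(f"unknown variant_class {vclass!r}")
    if vclass == "indel":
        if vaf < VAF_MIN_INDEL:
            return FilterDecision(keep=False, reasons=["VAF_INDEL"])
    else:  # snv and dnv use the substitution threshold
        if vaf < VAF_MIN_SNV:
            return FilterDecision(keep=False, reasons=["VAF_SNV"])
    return FilterDecision(keep=True)


def run_small_variant_cascade(
    table: pd.DataFrame,
    panel: list[str] | set[str],
    eligible_subpops: Mapping[str, Mapping[str, bool]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run panel restriction, frequency gate and VAF gate over a call table.

    Returns ``(kept, audit)``: `kept` is the subset of rows passing every
    gate; `audit` has one row per input variant with per-gate outcomes and
    the ordered, semicolon-joined rule identifiers.
    """
    if not panel:
        raise ValueError("gene panel must be non-empty")
    panel = set(panel)

    audit_rows = []
    keep_mask = []
    for idx, row in table.iterrows():
        reasons: list[str] = []
        in_panel = row["gene"] in panel
        if not in_panel:
            reasons.append("PANEL")
        freq = passes_frequency_gate(row, eligible_subpops)
        reasons.extend(freq.reasons)
        vaf = passes_vaf_gate(row)
        reasons.extend(vaf.reasons)
        keep = in_panel and freq.keep and vaf.keep
        keep_mask.append(keep)
        audit_rows.append(
            {
                "variant_id": row.get("variant_id", idx),
                "gate_panel": in_panel,
                "gate_frequency": freq.keep,
                "gate_vaf": vaf.keep,
                "keep": keep,
                "reasons": ";".join(reasons),
            }
        )
    audit = pd.DataFrame(
        audit_rows,
        columns=["variant_id", "gate_panel", "gate_frequency", "gate_vaf", "keep", "reasons"],
    )
    kept = table.loc[np.asarray(keep_mask, dtype=bool)] if len(table) else table.copy()
    return kept, audit
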