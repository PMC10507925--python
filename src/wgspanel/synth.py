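"""Seeded synthetic inputs for the prioritisation, triage and summary stages.

Everything the pipeline consumes can be generated here without any external
download: annotated small-variant tables, paired-caller SV/CNV call sets
with controllable reciprocal overlap, blacklist regions and gene
footprints, a deterministic cohort fixture reproducing the published
post-MDT tallies, and a calibrated economic base-case configuration.

The synthetic genome is a single linear coordinate space of configurable
length partitioned into five named pseudo-chromosomes; no reference
sequence is shipped.  The virtual gene panel mixes a handful of real
hereditary-cancer gene symbols (APC, ATM, MUTYH, MSH6, PALB2, BRCA2, BAP1)
with deterministic placeholders G008..Gnnn.

Small-variant and SV tables carry a ``truth_keep`` column: the ground-truth
"survives the cascade" label, computed at generation time by a deliberately
plain, brute-force application of the filtering rules.  This label is the
independent oracle the filter modules are tested against.

The generators do not attempt to mimic real allele-frequency spectra,
caller error profiles or read-level evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .econ import EconScenarioConfig, default_config

__all__ = [
    "GeneratorParams",
    "SUBPOPULATIONS",
    "NAMED_PANEL_GENES",
    "SvBundle",
    "make_panel",
    "chromosome_lengths",
    "gen_region_resources",
    "gen_small_variants",
    "gen_sv_cnv",
    "gen_sv_bundle",
    "gen_cohort_fixture",
    "gen_econ_config",
    "PHENOTYPE_CATEGORIES",
]

#: gnomAD-style subpopulations; the eligibility flags stand for the
#: "at least 2000 individuals in the resource" requirement and are part of
#: the resource description, not recomputed.
SUBPOPULATIONS: dict[str, dict[str, bool]] = {
    "afr": {"exome": True, "genome": True},
    "amr": {"exome": True, "genome": True},
    "asj": {"exome": True, "genome": False},
    "eas": {"exome": True, "genome": True},
    "fin": {"exome": True, "genome": True},
    "nfe": {"exome": True, "genome": True},
    "sas": {"exome": True, "genome": False},
}

NAMED_PANEL_GENES = ["APC", "ATM", "MUTYH", "MSH6", "PALB2", "BRCA2", "BAP1"]

_N_CHROMS = 5
_CONSEQUENCES = ["missense", "synonymous", "inframe_indel", "frameshift", "splice", "other"]


@dataclass
class GeneratorParams:
    """Knobs of the synthetic-input generators (all seeded, all validated)."""

    seed: int = 0
    n_small_variants: int = 1000
    n_sv_per_caller: int = 120
    n_genes: int = 120
    n_exclusion_regions: int = 40
    fraction_common: float = 0.3
    fraction_clinvar_lp_p: float = 0.05
    vaf_noise_sd: float = 0.05
    genome_length: int = 10_000_000

    def __post_init__(self) -> None:
        for name in ("n_small_variants", "n_sv_per_caller", "n_genes", "n_exclusion_regions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fraction_common", "fraction_clinvar_lp_p", "vaf_noise_sd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.genome_length < 100_000:
            raise ValueError("genome_length must be >= 100 kb")


def chromosome_lengths(params: GeneratorParams) -> dict[str, int]:
    """Pseudo-chromosome names and lengths partitioning the linear genome."""
    per = params.genome_length // _N_CHROMS
    return {f"pc{i + 1}": per for i in range(_N_CHROMS)}


def make_panel(params: GeneratorParams) -> list[str]:
    """Virtual panel: real hereditary-cancer symbols then G008..Gnnn."""
    n = params.n_genes
    named = NAMED_PANEL_GENES[:n]
    return named + [f"G{i + 1:03d}" for i in range(len(named), n)]


def _offpanel_symbols(params: GeneratorParams) -> list[str]:
    return [f"NP{i + 1:02d}" for i in range(max(3, params.n_genes // 10))]


def _rng(params: GeneratorParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stream])


# ----------------------------------------------------------------- regions

def gen_region_resources(params: GeneratorParams):
    """Exclusionary regions and the gene table.

    Returns ``(region_set, genes)`` where `region_set` is a
    :class:`~wgspanel.svcnv.RegionSet` of blacklist intervals and `genes`
    is a table (gene, chrom, tx_start, tx_end, strand) covering the panel
    plus a few off-panel genes.  Footprints derive from it via
    :func:`wgspanel.svcnv.build_footprints`.
    """
    from .svcnv import RegionSet

    rng = _rng(params, 1)
    chroms = chromosome_lengths(params)
    names = list(chroms)

    intervals = []
    for _ in range(params.n_exclusion_regions):
        chrom = names[rng.integers(len(names))]
        length = int(rng.integers(5_000, 60_000))
        start = int(rng.integers(0, max(1, chroms[chrom] - length)))
        intervals.append((chrom, start, start + length))
    region_set = RegionSet(intervals)

    rows = []
    for sym in make_panel(params) + _offpanel_symbols(params):
        chrom = names[rng.integers(len(names))]
        length = int(rng.integers(5_000, 80_000))
        start = int(rng.integers(2_000, max(2_001, chroms[chrom] - length - 2_000)))
        rows.append(
            {
                "gene": sym,
                "chrom": chrom,
                "tx_start": start,
                "tx_end": start + length,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    genes = pd.DataFrame(rows, columns=["gene", "chrom", "tx_start", "tx_end", "strand"])
    return region_set, genes


# ----------------------------------------------------- small variant calls

_SMALLVAR_COLUMNS = (
    ["variant_id", "chrom", "pos", "ref", "alt", "variant_class", "consequence",
     "gene", "clinvar_status", "vaf"]
    + [f"gnex_{p}" for p in SUBPOPULATIONS]
    + [f"gnge_{p}" for p in SUBPOPULATIONS]
    + ["cohort_af", "inhouse_af", "revel", "provean", "cadd",
       "splice_impact_predicted", "truth_keep"]
)


def _small_variant_keep(row: Mapping, panel: set[str],
                        subpops: Mapping[str, Mapping[str, bool]]) -> bool:
    # Brute-force restatement of the cascade rules, kept deliberately
    # independent of wgspanel.smallvar.
    if row["gene"] not in panel:
        return False
    if row["clinvar_status"] not in ("LP", "P"):
        for pop, elig in subpops.items():
            if elig["exome"] and row[f"gnex_{pop}"] > 0.01:
                return False
            if elig["genome"] and row[f"gnge_{pop}"] > 0.01:
                return False
        if row["cohort_af"] > 0.01 or row["inhouse_af"] > 0.01:
            return False
    if row["variant_class"] == "indel":
        return row["vaf"] >= 0.20
    return row["vaf"] >= 0.30


def gen_small_variants(params: GeneratorParams) -> pd.DataFrame:
    """Annotated SNV/indel call table with ground-truth cascade labels."""
    rng = _rng(params, 2)
    chroms = chromosome_lengths(params)
    names = list(chroms)
    panel = make_panel(params)
    offpanel = _offpanel_symbols(params)
    panel_set = set(panel)
    exome_pops = [p for p, e in SUBPOPULATIONS.items() if e["exome"]]
    genome_pops = [p for p, e in SUBPOPULATIONS.items() if e["genome"]]
    inelig_genome = [p for p, e in SUBPOPULATIONS.items() if not e["genome"]]

    rows = []
    for i in range(params.n_small_variants):
        gene = (
            panel[rng.integers(len(panel))]
            if rng.random() < 0.9
            else offpanel[rng.integers(len(offpanel))]
        )
        chrom = names[rng.integers(len(names))]
        pos = int(rng.integers(1, chroms[chrom]))
        vclass = ["snv", "indel", "dnv"][rng.choice(3, p=[0.7, 0.2, 0.1])]
        if vclass == "snv":
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        elif vclass == "dnv":
            ref, alt = "AC", "TG"
        else:
            ref, alt = ("ATG", "A") if rng.random() < 0.5 else ("A", "ATG")

        if rng.random() < params.fraction_clinvar_lp_p:
            clinvar = "LP" if rng.random() < 0.5 else "P"
        else:
            clinvar = ["none", "B", "LB", "VUS"][rng.choice(4, p=[0.7, 0.1, 0.1, 0.1])]

        afs = {f"gnex_{p}": float(rng.uniform(0, 0.008)) for p in SUBPOPULATIONS}
        afs.update({f"gnge_{p}": float(rng.uniform(0, 0.008)) for p in SUBPOPULATIONS})
        afs["cohort_af"] = float(rng.uniform(0, 0.008))
        afs["inhouse_af"] = float(rng.uniform(0, 0.008))
        if rng.random() < params.fraction_common:
            # place the offending frequency in one *eligible* resource
            route = rng.integers(4)
            high = float(rng.uniform(0.011, 0.30))
            if route == 0:
                afs[f"gnex_{exome_pops[rng.integers(len(exome_pops))]}"] = high
            elif route == 1:
                afs[f"gnge_{genome_pops[rng.integers(len(genome_pops))]}"] = high
            elif route == 2:
                afs["cohort_af"] = high
            else:
                afs["inhouse_af"] = high
        elif rng.random() < 0.05 and inelig_genome:
            # common only in an ineligible subpopulation: must NOT drop
            afs[f"gnge_{inelig_genome[rng.integers(len(inelig_genome))]}"] = float(
                rng.uniform(0.02, 0.10)
            )

        if rng.random() < 0.15:
            vaf = float(rng.uniform(0.02, 0.35))
        else:
            vaf = float(np.clip(rng.normal(0.5, params.vaf_noise_sd), 0.05, 1.0))

        row = {
            "variant_id": f"SM{i + 1:05d}",
            "chrom": chrom,
            "pos": pos,
            "ref": str(ref),
            "alt": str(alt),
            "variant_class": vclass,
            "consequence": _CONSEQUENCES[rng.integers(len(_CONSEQUENCES))],
            "gene": gene,
            "clinvar_status": clinvar,
            "vaf": vaf,
            **afs,
            "revel": float(rng.uniform(0, 1)) if rng.random() > 0.1 else np.nan,
            "provean": float(rng.normal(-1.5, 1.5)),
            "cadd": float(rng.uniform(0, 45)),
            "splice_impact_predicted": bool(rng.random() < 0.1),
        }
        row["truth_keep"] = _small_variant_keep(row, panel_set, SUBPOPULATIONS)
        rows.append(row)
    return pd.DataFrame(rows, columns=_SMALLVAR_COLUMNS)


# ------------------------------------------------------------ SV/CNV calls

_SV_COLUMNS = [
    "id", "sv_type", "chrom1", "pos1", "chrom2", "pos2", "caller",
    "q0", "gtscore", "af_gnomadsv", "af_inhouse", "af_cohort", "truth_keep",
]


@dataclass
class SvBundle:
    """The SV tables together with the resources their labels refer to."""

    calls_a: pd.DataFrame
    calls_b: pd.DataFrame
    regions: "object"           # wgspanel.svcnv.RegionSet
    genes: pd.DataFrame
    freq_resources: dict[str, pd.DataFrame]
    panel: list[str] = field(default_factory=list)


def _union_coverage(intervals: list[tuple[int, int]], start: int, end: int) -> float:
    clipped = sorted(
        (max(s, start), min(e, end)) for s, e in intervals if min(e, end) > max(s, start)
    )
    covered, cursor = 0, start
    for s, e in clipped:
        s = max(s, cursor)
        if e > s:
            covered += e - s
            cursor = e
    return covered / (end - start)


def _sv_keep(rec: Mapping, region_list: list[tuple[str, int, int]],
             resources: dict[str, pd.DataFrame], genes: pd.DataFrame,
             panel: set[str]) -> bool:
    # Brute-force restatement of the SV cascade, independent of wgspanel.svcnv.
    t = rec["sv_type"]
    if rec["caller"] == "B":
        q0, gt = rec["q0"], rec["gtscore"]
        if (q0 < 0 or q0 > 0.5) and not gt < 0.25:
            return False
    same1 = [(s, e) for c, s, e in region_list if c == rec["chrom1"]]
    if t in ("DEL", "DUP", "INV"):
        if _union_coverage(same1, rec["pos1"], rec["pos2"]) >= 0.80:
            return False
    else:
        hit1 = any(s <= rec["pos1"] < e for s, e in same1)
        same2 = [(s, e) for c, s, e in region_list if c == rec["chrom2"]]
        hit2 = any(s <= rec["pos2"] < e for s, e in same2)
        if hit1 or hit2:
            return False
    for res in resources.values():
        for _, r in res.iterrows():
            if r["sv_type"] != t:
                continue
            if t in ("DEL", "DUP", "INV"):
                if r["chrom1"] != rec["chrom1"]:
                    continue
                inter = min(rec["pos2"], r["pos2"]) - max(rec["pos1"], r["pos1"])
                if inter <= 0:
                    continue
                ro = min(inter / (rec["pos2"] - rec["pos1"]), inter / (r["pos2"] - r["pos1"]))
                if ro >= 0.80 and r["af"] > 0.05:
                    return False
            else:
                if (
                    r["chrom1"] == rec["chrom1"] and r["chrom2"] == rec["chrom2"]
                    and abs(r["pos1"] - rec["pos1"]) <= 100
                    and abs(r["pos2"] - rec["pos2"]) <= 100
                    and r["af"] > 0.05
                ):
                    return False
    hit_panel = False
    for _, g in genes.iterrows():
        if g["gene"] not in panel:
            continue
        if g["strand"] == "+":
            fs, fe = max(0, g["tx_start"] - 2000), g["tx_end"]
        else:
            fs, fe = g["tx_start"], g["tx_end"] + 2000
        if t in ("DEL", "DUP"):
            if g["chrom"] == rec["chrom1"] and rec["pos1"] < fe and fs < rec["pos2"]:
                hit_panel = True
                break
        else:
            if (g["chrom"] == rec["chrom1"] and fs <= rec["pos1"] < fe) or (
                g["chrom"] == rec["chrom2"] and fs <= rec["pos2"] < fe
            ):
                hit_panel = True
                break
    return hit_panel


def gen_sv_bundle(params: GeneratorParams) -> SvBundle:
    """Paired-caller SV/CNV tables plus the resources defining their labels.

    Caller A emulates a breakpoint-based SV caller (all five types); caller
    B a read-depth CNV caller (DEL/DUP only, with q0 and genotype score).
    A controllable share of DEL/DUP events appears in both callers, some
    with reciprocal overlap above the 80% concordance threshold and some
    below.
    """
    from .svcnv import RegionSet  # noqa: F401  (bundle carries a RegionSet)

    rng = _rng(params, 3)
    chroms = chromosome_lengths(params)
    names = list(chroms)
    region_set, genes = gen_region_resources(params)
    region_list = [
        (r["chrom"], int(r["start"]), int(r["end"]))
        for _, r in region_set.to_frame().iterrows()
    ]
    panel = make_panel(params)
    panel_set = set(panel)

    n = params.n_sv_per_caller
    n_pairs = int(n * 0.4)
    n_a_only_cnv = int(n * 0.2)
    n_other = n - n_pairs - n_a_only_cnv

    rows_a, rows_b = [], []
    res_rows: dict[str, list] = {"gnomad_sv": [], "inhouse": [], "cohort": []}
    res_names = list(res_rows)
    counter = [0]

    def next_id(caller: str) -> str:
        counter[0] += 1
        return f"SV{caller}{counter[0]:05d}"

    def rand_span(min_len=2_000, max_len=200_000):
        chrom = names[rng.integers(len(names))]
        length = int(rng.integers(min_len, max_len))
        start = int(rng.integers(0, max(1, chroms[chrom] - length)))
        return chrom, start, start + length

    def snap_into_region():
        c, s, e = region_list[rng.integers(len(region_list))]
        if e - s > 4_000:
            a = int(rng.integers(s, e - 2_000))
            return c, a, int(rng.integers(a + 1_000, e))
        return c, s, e

    def freqs_for(rec: dict) -> None:
        """Assign per-record AFs and, when marked common, a matching resource row."""
        rec["af_gnomadsv"] = float(rng.uniform(0, 0.03))
        rec["af_inhouse"] = float(rng.uniform(0, 0.03))
        rec["af_cohort"] = float(rng.uniform(0, 0.03))
        draw = rng.random()
        which = res_names[rng.integers(3)]
        if draw < params.fraction_common:
            af = float(rng.uniform(0.06, 0.5))
        elif draw < params.fraction_common + 0.3:
            af = float(rng.uniform(0, 0.05))
        else:
            return
        res_rows[which].append(
            {
                "sv_type": rec["sv_type"], "chrom1": rec["chrom1"], "pos1": rec["pos1"],
                "chrom2": rec["chrom2"], "pos2": rec["pos2"], "af": af,
            }
        )
        rec[f"af_{'gnomadsv' if which == 'gnomad_sv' else which}"] = af

    def b_quality(rec: dict) -> None:
        if rng.random() < 0.2:
            rec["q0"] = -1.0 if rng.random() < 0.5 else float(rng.uniform(0.51, 1.0))
        else:
            rec["q0"] = float(rng.uniform(0, 0.5))
        rec["gtscore"] = float(rng.uniform(0, 1))

    # concordant-candidate DEL/DUP pairs
    for _ in range(n_pairs):
        t = "DEL" if rng.random() < 0.6 else "DUP"
        chrom, s, e = rand_span()
        length = e - s
        if rng.random() < 0.6:
            shift = int(rng.integers(0, max(1, int(0.05 * length))))  # RO >= 0.95
        else:
            shift = int(rng.integers(int(0.3 * length), int(0.6 * length)))  # RO < 0.8
        ra = {"id": next_id("A"), "sv_type": t, "chrom1": chrom, "pos1": s,
              "chrom2": chrom, "pos2": e, "caller": "A", "q0": np.nan, "gtscore": np.nan}
        rb = {"id": next_id("B"), "sv_type": t, "chrom1": chrom, "pos1": s + shift,
              "chrom2": chrom, "pos2": e + shift, "caller": "B"}
        b_quality(rb)
        freqs_for(ra)
        freqs_for(rb)
        rows_a.append(ra)
        rows_b.append(rb)

    # caller-A-only CNVs
    for _ in range(n_a_only_cnv):
        t = "DEL" if rng.random() < 0.5 else "DUP"
        if region_list and rng.random() < 0.12:
            chrom, s, e = snap_into_region()
        else:
            chrom, s, e = rand_span()
        ra = {"id": next_id("A"), "sv_type": t, "chrom1": chrom, "pos1": s,
              "chrom2": chrom, "pos2": e, "caller": "A", "q0": np.nan, "gtscore": np.nan}
        freqs_for(ra)
        rows_a.append(ra)

    # caller-A non-CNV SVs
    for _ in range(n_other):
        t = ["INV", "INS", "TRA"][rng.integers(3)]
        if t == "TRA":
            c1 = names[rng.integers(len(names))]
            c2 = names[rng.integers(len(names))]
            p1 = int(rng.integers(0, chroms[c1]))
            p2 = int(rng.integers(0, chroms[c2]))
            if region_list and rng.random() < 0.12:
                rc, rs, re_ = region_list[rng.integers(len(region_list))]
                c1, p1 = rc, int(rng.integers(rs, re_))
            rec = {"id": next_id("A"), "sv_type": t, "chrom1": c1, "pos1": p1,
                   "chrom2": c2, "pos2": p2, "caller": "A", "q0": np.nan, "gtscore": np.nan}
        else:
            if t == "INV" and region_list and rng.random() < 0.12:
                chrom, s, e = snap_into_region()
            else:
                chrom, s, e = rand_span(1_000, 100_000)
            rec = {"id": next_id("A"), "sv_type": t, "chrom1": chrom, "pos1": s,
                   "chrom2": chrom, "pos2": e, "caller": "A", "q0": np.nan, "gtscore": np.nan}
        freqs_for(rec)
        rows_a.append(rec)

    # caller-B-only CNVs
    for _ in range(n - n_pairs):
        t = "DEL" if rng.random() < 0.5 else "DUP"
        chrom, s, e = rand_span()
        rb = {"id": next_id("B"), "sv_type": t, "chrom1": chrom, "pos1": s,
              "chrom2": chrom, "pos2": e, "caller": "B"}
        b_quality(rb)
        freqs_for(rb)
        rows_b.append(rb)

    # decoy frequency rows just outside the 100-bp breakpoint window
    for rec in rows_a:
        if rec["sv_type"] in ("INS", "TRA") and rng.random() < 0.2:
            res_rows["gnomad_sv"].append(
                {"sv_type": rec["sv_type"], "chrom1": rec["chrom1"],
                 "pos1": rec["pos1"] + 150, "chrom2": rec["chrom2"],
                 "pos2": rec["pos2"] + 150, "af": 0.4}
            )

    res_cols = ["sv_type", "chrom1", "pos1", "chrom2", "pos2", "af"]
    resources = {k: pd.DataFrame(v, columns=res_cols) for k, v in res_rows.items()}

    for rows in (rows_a, rows_b):
        for rec in rows:
            rec["truth_keep"] = _sv_keep(rec, region_list, resources, genes, panel_set)

    calls_a = pd.DataFrame(rows_a, columns=_SV_COLUMNS)
    calls_b = pd.DataFrame(rows_b, columns=_SV_COLUMNS)
    return SvBundle(
        calls_a=calls_a, calls_b=calls_b, regions=region_set, genes=genes,
        freq_resources=resources, panel=panel,
    )


def gen_sv_cnv(params: GeneratorParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two caller tables of :func:`gen_sv_bundle` (labels included)."""
    bundle = gen_sv_bundle(params)
    return bundle.calls_a, bundle.calls_b


# ---------------------------------------------------------- cohort fixture

#: broad tumour-associated phenotype categories with their cohort counts
PHENOTYPE_CATEGORIES: list[tuple[str, int]] = [
    ("breast", 43), ("endometrial", 12), ("ovarian", 9), ("cervical", 4),
    ("other_gynaecological", 2), ("renal_cell_carcinoma", 35), ("prostate", 6),
    ("urothelial_carcinoma", 3), ("other_urogenital", 13), ("thyroid", 29),
    ("non_thyroid_neuroendocrine", 26), ("adenomatous_polyposis", 28),
    ("serrated_polyps", 6), ("hyperplastic_polyps", 6),
    ("hamartomatous_polyps", 1), ("other_polyps", 6), ("colorectal", 28),
    ("upper_gastrointestinal", 11), ("melanoma", 21), ("non_melanoma_skin", 14),
    ("soft_tissue_sarcoma", 10), ("bone_sarcoma", 4), ("other_sarcoma", 3),
    ("respiratory", 12), ("head_and_neck", 8), ("brain", 8), ("lymphoma", 8),
    ("non_endocrine_pancreatic", 7), ("unknown_primary", 3),
    ("non_brain_neurological", 1), ("other", 43),
]

_N_CASES = 195

# germline LP/P gene -> consensus class used in the fixture
_LPP_CLASS = {
    "APC": "LP", "ATM": "LP", "BAP1": "LP", "BLM": "P", "BRCA1": "P",
    "BRCA2": "P", "CHEK2": "LP", "DICER1": "LP", "FANCA": "LP", "FANCC": "P",
    "FANCD2": "LP", "FANCI": "LP", "FH": "P", "LZTR1": "LP", "MSH6": "LP",
    "MUTYH": "P", "NBN": "LP", "PALB2": "P", "RAD51D": "LP", "RET": "LP",
    "SDHA": "P", "RUNX1": "P",
}


def _assign_phenotypes(slots: list[int]) -> list[list[str]]:
    """Deal the category multiset into per-case phenotype lists.

    Greedy max-remaining-category to max-remaining-slots assignment; no case
    receives the same category twice, so the per-category totals and the
    per-case multiplicities both come out exact.
    """
    remaining = dict(PHENOTYPE_CATEGORIES)
    assigned: list[list[str]] = [[] for _ in slots]
    open_slots = list(slots)
    total = sum(remaining.values())
    for _ in range(total):
        cat = max(remaining, key=lambda c: (remaining[c], c))
        best, best_slots = None, -1
        for i, free in enumerate(open_slots):
            if free > 0 and cat not in assigned[i] and free > best_slots:
                best, best_slots = i, free
        if best is None:
            raise RuntimeError("phenotype assignment infeasible")
        assigned[best].append(cat)
        open_slots[best] -= 1
        remaining[cat] -= 1
        if remaining[cat] == 0:
            del remaining[cat]
    if any(s != 0 for s in open_slots):
        raise RuntimeError("phenotype slots left unfilled")
    return assigned


def gen_cohort_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic cohort replicating the published post-MDT tallies.

    Returns ``(cases, variants)``: 195 index cases and the 119 returned
    variants (31 LP/P across 29 cases, 88 VUS in a 7/54/27 A/B/C tier
    split), with report multiplicities 67/23/2, ten causal and nineteen
    secondary LP/P cases, twenty risk-management changes and nine
    uninformative LP/P cases, one of somatic origin.  Code-generated, not
    random, so every tally is exact.
    """
    case_ids = [f"C{i + 1:03d}" for i in range(_N_CASES)]

    # --- per-case phenotype multiplicities -------------------------------
    # reported cases occupy indices 0..91:
    #   0..9    causal LP/P cases        (0..1 also carry two VUS each)
    #   10..28  secondary LP/P cases     (10..11 carry two LP/P each)
    #   29..91  VUS-only cases           (29..49 carry two VUS each)
    # index 92..194: enrolled cases without a returned finding
    slots = [0] * _N_CASES
    for i in range(_N_CASES):
        if i < 20:                 # 20 of the 29 LP/P cases: multi-phenotype
            slots[i] = 2
        elif i < 29:
            slots[i] = 1
        elif i < 72:               # 43 of the 63 VUS-only cases: multi
            slots[i] = 2
        elif i < 92:
            slots[i] = 1
        elif i < 141:              # unreported cases absorb the remainder
            slots[i] = 3
        else:
            slots[i] = 2
    phenotypes = _assign_phenotypes(slots)

    # --- eligibility flags (Table-1 style overlapping criteria) ----------
    elig = {k: [False] * _N_CASES for k in
            ("elig_syndrome", "elig_two_primaries", "elig_three_primaries",
             "elig_polyposis", "elig_multi_criteria")}
    for i in range(0, 83):
        elig["elig_two_primaries"][i] = True
    for i in range(83, 135):
        elig["elig_three_primaries"][i] = True
    for i in range(135, 177):
        elig["elig_multi_criteria"][i] = True
    for i in list(range(177, 195)) + list(range(0, 11)):
        elig["elig_polyposis"][i] = True
    for i in range(11, 39):
        elig["elig_syndrome"][i] = True

    sites = ["QLD"] * 46 + ["VIC"] * 58 + ["TAS"] * 14 + ["SA"] * 21 + ["NSW"] * 29 + ["WA"] * 27

    def age_for(i: int) -> int:
        if i < 16:
            return 6 + (i % 12)          # 18 and under
        if i < 141:
            return 19 + (i % 31)         # 19-49
        return 50 + (i % 30)             # 50 and over

    cases = pd.DataFrame(
        {
            "case_id": case_ids,
            "sex": ["F"] * 141 + ["M"] * 54,
            "age_at_first_diagnosis": [age_for(i) for i in range(_N_CASES)],
            "phenotypes": ["|".join(p) for p in phenotypes],
            **elig,
            "prior_testing": ["uninformative"] * 140 + ["none"] * 55,
            "recruitment_site": sites,
            "referral": ["direct"] * 157 + ["panel_assessment"] * 38,
            "panel_used": ["A"] * 24 + ["B"] * 171,
        }
    )

    # --- returned variants ------------------------------------------------
    causal_genes = ["APC", "BAP1", "BRCA1", "BRCA2", "BRCA2",
                    "MSH6", "MSH6", "FH", "RET", "DICER1"]
    causal_types = {0: "CNV", 4: "CNV"}          # promoter/exonic deletions
    secondary_single = ["ATM", "ATM", "BLM", "CHEK2", "DICER1", "FANCA",
                        "FANCD2", "FANCI", "LZTR1", "MUTYH", "MUTYH",
                        "PALB2", "PALB2", "PALB2", "RAD51D", "SDHA"]

    variants: list[dict] = []

    def add(case_idx: int, gene: str, acmg: str, vtype: str, consequence: str,
            tier: str = "", causal: bool = False, secondary: bool = False,
            somatic: bool = False) -> None:
        risk_changed = acmg in ("LP", "P") and case_idx < 20
        variants.append(
            {
                "variant_id": f"V{len(variants) + 1:03d}",
                "case_id": case_ids[case_idx],
                "gene": gene,
                "variant_type": vtype,
                "consequence": consequence,
                "acmg_class": acmg,
                "vus_tier": tier,
                "mdt_verdict": "return",
                "causal_for_phenotype": causal,
                "secondary_finding": secondary,
                "somatic_origin": somatic,
                "risk_management_changed": risk_changed,
            }
        )

    for i, gene in enumerate(causal_genes):
        vtype = causal_types.get(i, "SNV" if i % 3 else "INDEL")
        cons = "other" if vtype == "CNV" else ("missense" if i % 2 else "frameshift")
        add(i, gene, _LPP_CLASS[gene], vtype, cons, causal=True)

    # secondary LP/P: cases 10..11 carry two each, 12..27 one, 28 somatic SV
    for gene in ("FANCC", "MUTYH"):
        add(10, gene, _LPP_CLASS[gene], "SNV", "frameshift", secondary=True)
    for gene in ("NBN", "MUTYH"):
        add(11, gene, _LPP_CLASS[gene], "SNV", "missense", secondary=True)
    for j, gene in enumerate(secondary_single):
        vtype = "SV" if gene == "FANCD2" else ("SNV" if j % 3 else "INDEL")
        cons = "other" if vtype == "SV" else ("missense" if j % 2 else "splice")
        add(12 + j, gene, _LPP_CLASS[gene], vtype, cons, secondary=True)
    add(28, "RUNX1", "P", "SV", "other", secondary=True, somatic=True)

    # VUS: 4 on the two three-variant causal cases, 42 on two-VUS cases,
    # 42 on one-VUS cases; Fig-3-style gene concentrations for the panel's
    # most frequently reported genes.
    vus_genes = (["APC"] * 6 + ["ATM"] * 5 + ["MUTYH"] * 2 + ["MSH6"] * 2
                 + ["PALB2"] * 2 + ["BRCA2"] * 2 + ["BAP1"] * 2)
    vus_genes += [f"G{8 + j:03d}" for j in range(88 - len(vus_genes))]
    vus_cases = ([0, 0, 1, 1]
                 + [29 + j for j in range(21) for _ in range(2)]
                 + [50 + j for j in range(42)])
    assert len(vus_cases) == 88
    tiers = ["A"] * 7 + ["B"] * 54 + ["C"] * 27
    for k, (gene, cidx) in enumerate(zip(vus_genes, vus_cases)):
        if k < 4:
            vtype, cons = ("CNV", "other") if k % 2 == 0 else ("SV", "other")
        else:
            vtype = "SNV" if k % 6 else ("INDEL" if k % 2 else "DNV")
            # 70 missense among the 84 small VUS (83 missense of 111 small overall)
            cons = "missense" if (k - 4) % 6 != 5 else ("synonymous" if k % 2 else "inframe_indel")
        add(cidx, gene, "VUS", vtype, cons, tier=tiers[k])

    variants_df = pd.DataFrame(variants)

    # exact small/missense bookkeeping: top up missense to 83 of the 111
    small = variants_df["variant_type"].isin(["SNV", "INDEL", "DNV"])
    need = 83 - int((small & (variants_df["consequence"] == "missense")).sum())
    if need > 0:
        idx = variants_df.index[small & (variants_df["consequence"] != "missense")][:need]
        variants_df.loc[idx, "consequence"] = "missense"
    elif need < 0:
        idx = variants_df.index[
            small & (variants_df["consequence"] == "missense") & (variants_df["acmg_class"] == "VUS")
        ][:(-need)]
        variants_df.loc[idx, "consequence"] = "synonymous"

    return cases, variants_df


def gen_econ_config() -> EconScenarioConfig:
    """Calibrated base-case economic configuration."""
    return default_config()
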