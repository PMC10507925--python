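"""Structural-variant and copy-number flagging and exclusion cascade.

Germline SV/CNV calls from two callers — an SV caller (caller A: deletions,
duplications, inversions, insertions, translocations) and a read-depth CNV
caller (caller B: deletions and duplications only) — are reconciled and
filtered:

* caller-B calls with an extreme fraction of zero-mapping-quality reads
  (q0 < 0 or q0 > 0.5) are removed, unless their genotype score is < 0.25;
* CNVs (DEL/DUP) must be supported by both callers: two calls are the same
  event when they have the same type and >= 80% reciprocal overlap;
  single-caller CNVs are kept but flagged for manual review;
* calls covered >= 80% by exclusionary (poor-mappability / low-complexity)
  regions — any breakpoint overlap for translocations and insertions — are
  excluded;
* calls assigned a population allele frequency > 5% in any frequency
  resource are excluded (frequency assignment by >= 80% reciprocal overlap
  for DEL/DUP/INV, or breakpoints within a 100-bp window for TRA/INS);
* surviving calls are associated with genes via protein-coding gene
  footprints (2000 bp upstream of the transcription start through the
  transcription end) and restricted to the virtual panel.

All coordinates are 0-based half-open internally; BED files are read and
written natively in that convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "SV_TYPES",
    "CNV_TYPES",
    "SPAN_TYPES",
    "BREAKPOINT_TYPES",
    "RECIPROCAL_OVERLAP_MIN",
    "REGION_COVERAGE_MIN",
    "SV_AF_MAX",
    "BREAKPOINT_WINDOW",
    "UPSTREAM_BP",
    "RegionSet",
    "GeneFootprint",
    "reciprocal_overlap",
    "q0_flag",
    "match_cnv_calls",
    "region_exclusion_flag",
    "frequency_flag",
    "assign_max_af",
    "gene_footprint",
    "build_footprints",
    "associate_genes",
    "run_sv_cascade",
]

SV_TYPES = frozenset({"DEL", "DUP", "INV", "INS", "TRA"})
CNV_TYPES = frozenset({"DEL", "DUP"})
#: span-based types: interval arithmetic on [pos1, pos2)
SPAN_TYPES = frozenset({"DEL", "DUP", "INV"})
#: breakpoint-based types: point arithmetic on pos1 / pos2
BREAKPOINT_TYPES = frozenset({"INS", "TRA"})

RECIPROCAL_OVERLAP_MIN = 0.80
REGION_COVERAGE_MIN = 0.80
SV_AF_MAX = 0.05          # strict: > 5% excludes
BREAKPOINT_WINDOW = 100   # bp, for TRA/INS frequency assignment
UPSTREAM_BP = 2000        # promoter margin of the gene footprint

Q0_FLAG = "Q0_FLAG"
SINGLE_CALLER = "SINGLE_CALLER"
EXCLUDED_REGION = "EXCLUDED_REGION"
COMMON = "COMMON"
MANUAL_REVIEW = "MANUAL_REVIEW"


# ---------------------------------------------------------------- intervals

def reciprocal_overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Reciprocal overlap of two half-open intervals on the same chromosome.

    min(|a∩b|/|a|, |a∩b|/|b|); 0 if disjoint.
    """
    a0, a1 = a
    b0, b1 = b
    if a1 <= a0 or b1 <= b0:
        raise ValueError("zero-length interval")
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return min(inter / (a1 - a0), inter / (b1 - b0))


class RegionSet:
    """Set of genomic intervals (0-based half-open), point/interval queryable."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for chrom, start, end in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        if start >= end:
            raise ValueError(f"invalid interval [{start}, {end})")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def contains_point(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.at(pos))

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end) for iv in tree.overlap(start, end))

    def coverage_fraction(self, chrom: str, start: int, end: int) -> float:
        """Fraction of [start, end) covered by the union of the regions."""
        if start >= end:
            raise ValueError(f"invalid interval [{start}, {end})")
        covered = 0
        cursor = start
        for b, e in self.overlapping(chrom, start, end):
            b = max(b, cursor)
            e = min(e, end)
            if e > b:
                covered += e - b
                cursor = e
        return covered / (end - start)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": chrom, "start": iv.begin, "end": iv.end}
            for chrom, tree in sorted(self._trees.items())
            for iv in sorted(tree)
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass(frozen=True)
class GeneFootprint:
    """Promoter-inclusive gene interval used to associate SVs with genes."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("footprint end must exceed start")


# ----------------------------------------------------------------- filters

def q0_flag(v: Mapping) -> bool:
    """Flag an unreliable caller-B (read-depth) call by its q0 statistic.

    True iff q0 < 0 or q0 > 0.5, unless the genotype score is < 0.25.
    """
    q0 = v["q0"]
    if q0 is None or (isinstance(q0, float) and np.isnan(q0)):
        raise ValueError("caller-B record missing q0")
    gt = v.get("gtscore") if hasattr(v, "get") else getattr(v, "gtscore", None)
    extreme = q0 < 0 or q0 > 0.5
    low_gt = gt is not None and not (isinstance(gt, float) and np.isnan(gt)) and gt < 0.25
    return bool(extreme and not low_gt)


def match_cnv_calls(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Greedy one-to-one concordance matching of DEL/DUP calls across callers.

    Candidate pairs require the same type, same chromosome and reciprocal
    overlap >= 0.80; pairs are matched in order of descending overlap (ties
    broken by smaller record ids), each call at most once.  Returns the
    annotated union with ``concordant``, ``partner_id`` and
    ``reciprocal_overlap`` columns; unmatched calls carry the
    SINGLE_CALLER and MANUAL_REVIEW flags.
    """
    for df in (calls_a, calls_b):
        bad = set(df["sv_type"]) - CNV_TYPES
        if bad:
            raise ValueError(f"non-CNV types in CNV matching: {sorted(bad)}")

    a = calls_a.reset_index(drop=True)
    b = calls_b.reset_index(drop=True)
    pairs = []
    for ia, ra in a.iterrows():
        for ib, rb in b.iterrows():
            if ra["sv_type"] != rb["sv_type"] or ra["chrom1"] != rb["chrom1"]:
                continue
            ro = reciprocal_overlap((ra["pos1"], ra["pos2"]), (rb["pos1"], rb["pos2"]))
            if ro >= RECIPROCAL_OVERLAP_MIN:
                pairs.append((ro, str(ra["id"]), str(rb["id"]), ia, ib))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))

    # keys ("A", i) / ("B", i) keep the two callers' row indices apart
    partner: dict = {}
    ro_of: dict = {}
    for ro, _sa, _sb, ia, ib in pairs:
        if ("A", ia) in partner or ("B", ib) in partner:
            continue
        partner[("A", ia)] = b.loc[ib, "id"]
        partner[("B", ib)] = a.loc[ia, "id"]
        ro_of[("A", ia)] = ro_of[("B", ib)] = ro

    keys = [("A", i) for i in a.index] + [("B", i) for i in b.index]
    out = pd.concat([a, b], ignore_index=True)
    out["concordant"] = [k in partner for k in keys]
    out["partner_id"] = [partner.get(k) for k in keys]
    out["reciprocal_overlap"] = [ro_of.get(k, np.nan) for k in keys]
    out["flags"] = [
        "" if c else f"{SINGLE_CALLER};{MANUAL_REVIEW}" for c in out["concordant"]
    ]
    return out


def region_exclusion_flag(v: Mapping, regions: RegionSet) -> bool:
    """True if the call falls in exclusionary (blacklist) regions.

    DEL/DUP/INV: >= 80% of the span covered by the union of regions;
    TRA/INS: either breakpoint inside any region.
    """
    t = v["sv_type"]
    if t in SPAN_TYPES:
        return regions.coverage_fraction(v["chrom1"], v["pos1"], v["pos2"]) >= REGION_COVERAGE_MIN
    if t in BREAKPOINT_TYPES:
        return regions.contains_point(v["chrom1"], v["pos1"]) or regions.contains_point(
            v["chrom2"], v["pos2"]
        )
    raise ValueError(f"unknown sv_type {t!r}")


def assign_max_af(v: Mapping, resource: pd.DataFrame) -> float:
    """Population AF assigned to a call from one frequency resource.

    DEL/DUP/INV: maximum AF over same-type records with reciprocal overlap
    >= 0.80; TRA/INS: maximum AF over same-type records whose corresponding
    breakpoints each lie within 100 bp.  Returns 0.0 when nothing matches.
    """
    t = v["sv_type"]
    best = 0.0
    for _, r in resource.iterrows():
        if r["sv_type"] != t:
            continue
        if t in SPAN_TYPES:
            if r["chrom1"] != v["chrom1"]:
                continue
            ro = reciprocal_overlap((v["pos1"], v["pos2"]), (r["pos1"], r["pos2"]))
            if ro >= RECIPROCAL_OVERLAP_MIN:
                best = max(best, float(r["af"]))
        else:
            if (
                r["chrom1"] == v["chrom1"]
                and r["chrom2"] == v["chrom2"]
                and abs(r["pos1"] - v["pos1"]) <= BREAKPOINT_WINDOW
                and abs(r["pos2"] - v["pos2"]) <= BREAKPOINT_WINDOW
            ):
                best = max(best, float(r["af"]))
    return best


def frequency_flag(v: Mapping, resources: Mapping[str, pd.DataFrame]) -> bool:
    """True iff the assigned AF exceeds 5% in any frequency resource."""
    return any(assign_max_af(v, res) > SV_AF_MAX for res in resources.values())


# ------------------------------------------------------------------- genes

def gene_footprint(
    gene: str,
    chrom: str,
    tx_start: int,
    tx_end: int,
    strand: str,
    chrom_length: int | None = None,
    strand_aware: bool = True,
) -> GeneFootprint:
    """Extend a transcript interval 2000 bp upstream of its start.

    On the + strand the footprint is [tx_start - 2000, tx_end); on the −
    strand, [tx_start, tx_end + 2000).  With ``strand_aware=False`` the
    strandless convention [tx_start - 2000, tx_end) is applied throughout.
    Clipped at 0 and at `chrom_length` when given.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand {strand!r}")
    if strand == "+" or not strand_aware:
        start, end = tx_start - UPSTREAM_BP, tx_end
    else:
        start, end = tx_start, tx_end + UPSTREAM_BP
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GeneFootprint(gene=gene, chrom=chrom, start=start, end=end, strand=strand)


def build_footprints(
    genes: pd.DataFrame,
    chrom_lengths: Mapping[str, int] | None = None,
    strand_aware: bool = True,
) -> list[GeneFootprint]:
    """Footprints for a gene table (gene, chrom, tx_start, tx_end, strand)."""
    out = []
    for _, g in genes.iterrows():
        length = chrom_lengths.get(g["chrom"]) if chrom_lengths else None
        out.append(
            gene_footprint(
                g["gene"], g["chrom"], g["tx_start"], g["tx_end"], g["strand"],
                chrom_length=length, strand_aware=strand_aware,
            )
        )
    return out


def associate_genes(v: Mapping, footprints: Sequence[GeneFootprint]) -> list[str]:
    """Gene symbols a call touches.

    CNVs (DEL/DUP): any overlap (>= 1 bp) between span and footprint.
    Other SVs (INV/INS/TRA): one or both breakpoints inside the footprint.
    """
    t = v["sv_type"]
    genes = []
    for fp in footprints:
        if t in CNV_TYPES:
            if fp.chrom == v["chrom1"] and v["pos1"] < fp.end and fp.start < v["pos2"]:
                genes.append(fp.gene)
        else:
            hit1 = fp.chrom == v["chrom1"] and fp.start <= v["pos1"] < fp.end
            hit2 = fp.chrom == v["chrom2"] and fp.start <= v["pos2"] < fp.end
            if hit1 or hit2:
                genes.append(fp.gene)
    return genes


# ----------------------------------------------------------------- cascade

def run_sv_cascade(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    regions: RegionSet,
    freq_resources: Mapping[str, pd.DataFrame],
    footprints: Sequence[GeneFootprint],
    panel: list[str] | set[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full SV/CNV flagging cascade.

    Order: q0 removal (caller B, before concordance matching), dual-caller
    CNV concordance, blacklist-region exclusion, population-frequency
    exclusion, gene association and panel restriction.  Records with any
    exclusion flag or no panel gene are dropped; single-caller CNVs are
    retained but flagged MANUAL_REVIEW.  Returns (prioritised, audit).
    """
    panel = set(panel)
    empty_cols = list(calls_a.columns) if len(calls_a.columns) else []
    allc = pd.concat([calls_a, calls_b], ignore_index=True)
    if len(allc) == 0:
        audit = pd.DataFrame(columns=["id", "caller", "flags", "genes", "retained"])
        return pd.DataFrame(columns=empty_cols), audit

    bad = set(allc["sv_type"]) - SV_TYPES
    if bad:
        raise ValueError(f"unknown sv_type values: {sorted(bad)}")

    flags: dict[str, set] = {str(r["id"]): set() for _, r in allc.iterrows()}

    # q0 quality flag — removal happens before concordance matching
    q0_removed: set[str] = set()
    for _, r in calls_b.iterrows():
        if q0_flag(r):
            rid = str(r["id"])
            flags[rid].add(Q0_FLAG)
            q0_removed.add(rid)

    # dual-caller concordance for CNVs that survive the q0 filter
    cnv_a = calls_a[calls_a["sv_type"].isin(CNV_TYPES)]
    cnv_b = calls_b[
        calls_b["sv_type"].isin(CNV_TYPES)
        & ~calls_b["id"].astype(str).isin(q0_removed)
    ]
    matched = match_cnv_calls(cnv_a, cnv_b)
    for _, r in matched.iterrows():
        if not r["concordant"]:
            flags[str(r["id"])].update({SINGLE_CALLER, MANUAL_REVIEW})

    genes_of: dict[str, list[str]] = {}
    for _, r in allc.iterrows():
        rid = str(r["id"])
        if region_exclusion_flag(r, regions):
            flags[rid].add(EXCLUDED_REGION)
        if frequency_flag(r, freq_resources):
            flags[rid].add(COMMON)
        genes_of[rid] = sorted(set(associate_genes(r, footprints)))

    audit_rows = []
    keep_mask = []
    for _, r in allc.iterrows():
        rid = str(r["id"])
        f = flags[rid]
        panel_genes = sorted(panel.intersection(genes_of[rid]))
        retained = (
            Q0_FLAG not in f
            and EXCLUDED_REGION not in f
            and COMMON not in f
            and bool(panel_genes)
        )
        keep_mask.append(retained)
        audit_rows.append(
            {
                "id": rid,
                "caller": r["caller"],
                "flags": ";".join(sorted(f)),
                "genes": ";".join(genes_of[rid]),
                "panel_genes": ";".join(panel_genes),
                "retained": retained,
            }
        )

    audit = pd.DataFrame(audit_rows)
    prioritised = allc.loc[np.asarray(keep_mask, dtype=bool)].copy()
    prioritised["flags"] = [
        ";".join(sorted(flags[str(r["id"])])) for _, r in prioritised.iterrows()
    ]
    prioritised["panel_genes"] = [
        ";".join(sorted(panel.intersection(genes_of[str(r["id"])])))
        for _, r in prioritised.iterrows()
    ]
    return prioritised.reset_index(drop=True), audit
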