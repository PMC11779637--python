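"""Gene-level damage classification and 9p21 co-deletion profile groups.

A gene is damaged (loss of function, LoF) in a sample when it carries a
damaging small variant, is homozygously deleted, suffers a double hit
(heterozygous deletion plus a damaging variant on the retained allele), or —
for CDKN2A only — is epigenetically silenced (promoter methylation beta >=
0.3 at the TSS-proximal probe).  Heterozygous deletion alone is not damage.

Copy-number status of a gene is decided by the 25%-overlap rule: a gene is
amplified / homozygously deleted / heterozygously deleted when at least 25%
of its length (exonic length when exon coordinates are supplied) overlaps
segments with total CN > 2*ploidy / = 0 / = 1 respectively.

All TSV-facing coordinates are 1-based inclusive; internally they are
converted to 0-based half-open intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

NINE_P21_GENES = ("KLHL9", "IFNE", "MTAP", "CDKN2A", "CDKN2B", "DMRTA1")

TRUNCATING = {"stopgain", "stoploss", "frameshift"}
CONSEQUENCES = TRUNCATING | {"missense", "other"}

#: severity order used when several classes co-occur for one sample x gene
STATUS_PRECEDENCE = ("hom_del", "double_hit", "damaging_mutation",
                     "methylation_silenced", "amplified", "het_del", "wild_type")
LOF_STATUSES = {"damaging_mutation", "hom_del", "double_hit", "methylation_silenced"}

METHYLATION_BETA_THRESHOLD = 0.3
METHYLATION_GENES = {"CDKN2A"}  # only gene with a configured TSS-proximal probe


@dataclass(frozen=True)
class GeneDamageStatus:
    sample: str
    gene: str
    status: str
    lof: bool = field(init=False)

    def __post_init__(self):
        if self.status not in STATUS_PRECEDENCE:
            raise ValueError(f"unknown status {self.status!r}")
        object.__setattr__(self, "lof", self.status in LOF_STATUSES)


def classify_variant(consequence: str, predictor_support: int = 0,
                     support_threshold: int = 7) -> bool:
    """True iff the variant is damaging: truncating, or missense supported by
    at least ``support_threshold`` damaging predictions (default 7)."""
    if consequence not in CONSEQUENCES:
        raise ValueError(f"unknown consequence {consequence!r}; "
                         f"expected one of {sorted(CONSEQUENCES)}")
    if predictor_support < 0:
        raise ValueError("predictor_support must be >= 0")
    if consequence in TRUNCATING:
        return True
    if consequence == "missense":
        return predictor_support >= support_threshold
    return False


def _overlap_bp(intervals: list[tuple[int, int]], seg_start: int, seg_end: int) -> int:
    """Overlap in bp between 0-based half-open gene intervals and one segment."""
    total = 0
    for a, b in intervals:
        total += max(0, min(b, seg_end) - max(a, seg_start))
    return total


def gene_cna_status(gene: dict, segments: pd.DataFrame, ploidy: float = 2.0,
                    use_exons: bool | None = None) -> str:
    """Copy-number class of one gene in one sample.

    ``gene`` is a mapping with keys gene, chrom, start, end (1-based
    inclusive) and optionally ``exons`` as a list of (start, end) 1-based
    pairs.  ``segments`` is that sample's SEG-like table with columns chrom,
    start, end (1-based inclusive), total_cn.

    Returns 'amplified', 'hom_del', 'het_del' or 'neutral' by the 25%
    length-overlap rule; the fraction is computed against the exonic union
    when exons are given (or ``use_exons`` is True), the full span otherwise.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if use_exons is None:
        use_exons = bool(gene.get("exons"))
    if use_exons:
        iv = sorted((int(s) - 1, int(e)) for s, e in gene["exons"])
        merged: list[tuple[int, int]] = []
        for a, b in iv:  # union of exons so shared bases count once
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        intervals = merged
    else:
        intervals = [(int(gene["start"]) - 1, int(gene["end"]))]
    gene_len = sum(b - a for a, b in intervals)
    if gene_len <= 0:
        raise ValueError(f"gene {gene.get('gene')} has non-positive length")

    segs = segments[segments["chrom"].astype(str) == str(gene["chrom"])]
    segs = segs.sort_values("start")
    prev_end = None
    for row in segs.itertuples(index=False):
        if prev_end is not None and int(row.start) <= prev_end:
            raise ValueError(f"overlapping CNA segments on {gene['chrom']} "
                             "in one sample: ambiguous copy number")
        prev_end = int(row.end)

    overlap = {"amplified": 0, "hom_del": 0, "het_del": 0}
    for row in segs.itertuples(index=False):
        s0, s1, cn = int(row.start) - 1, int(row.end), int(row.total_cn)
        if cn > 2 * ploidy:
            key = "amplified"
        elif cn == 0:
            key = "hom_del"
        elif cn == 1:
            key = "het_del"
        else:
            continue
        overlap[key] += _overlap_bp(intervals, s0, s1)

    # hom_del checked before amplified: complete loss is the more severe call
    for key in ("hom_del", "amplified", "het_del"):
        if overlap[key] / gene_len >= 0.25:
            return key
    return "neutral"


def call_gene_damage(sample: str, gene: str, variants: pd.DataFrame | None,
                     cna_status: str = "neutral",
                     methylation_beta: float | None = None,
                     support_threshold: int = 7) -> GeneDamageStatus:
    """Combine variant, copy-number and methylation evidence for one
    sample x gene into a single damage status.

    Precedence when classes co-occur (most severe first):
    hom_del > double_hit > damaging_mutation > methylation_silenced >
    amplified > het_del > wild_type.
    """
    has_damaging = False
    if variants is not None and len(variants):
        has_damaging = any(
            classify_variant(row.consequence, int(getattr(row, "predictor_support", 0)),
                             support_threshold)
            for row in variants.itertuples(index=False))

    methylated = False
    if methylation_beta is not None:
        if gene not in METHYLATION_GENES:
            logger.warning("methylation beta supplied for %s, which has no "
                           "configured probe; ignored", gene)
        else:
            methylated = methylation_beta >= METHYLATION_BETA_THRESHOLD

    if cna_status == "hom_del":
        status = "hom_del"
    elif cna_status == "het_del" and has_damaging:
        status = "double_hit"
    elif has_damaging:
        status = "damaging_mutation"
    elif methylated:
        status = "methylation_silenced"
    elif cna_status == "amplified":
        status = "amplified"
    elif cna_status == "het_del":
        status = "het_del"
    else:
        status = "wild_type"
    return GeneDamageStatus(sample=sample, gene=gene, status=status)


@dataclass(frozen=True)
class GroupProfile:
    """A 9p21 co-deletion group: genes required LoF and genes required wild-type
    over the six survival-relevant genes; unlisted genes are unconstrained."""

    group_id: str
    required_lof: frozenset
    required_wt: frozenset = frozenset()

    def __post_init__(self):
        if self.required_lof & self.required_wt:
            raise ValueError(f"profile {self.group_id}: a gene cannot be both "
                             "required LoF and required wild-type")

    def matches(self, lof_flags: dict[str, bool]) -> bool:
        return (all(lof_flags[g] for g in self.required_lof)
                and not any(lof_flags[g] for g in self.required_wt))


def default_group_profiles() -> list[GroupProfile]:
    """Four nested 9p21 groups.  Group 1 is any CDKN2A LoF; groups 2-4 are
    subsets with progressively fewer co-lost neighbours, group 4 being
    CDKN2A-only loss.  Definitions are editable defaults."""
    six = set(NINE_P21_GENES)
    return [
        GroupProfile("group1", frozenset({"CDKN2A"})),
        GroupProfile("group2", frozenset(six)),
        GroupProfile("group3", frozenset({"MTAP", "CDKN2A"}), frozenset({"IFNE"})),
        GroupProfile("group4", frozenset({"CDKN2A"}), frozenset(six - {"CDKN2A"})),
    ]


def assign_9p21_group(lof_flags: dict[str, bool],
                      profiles: list[GroupProfile] | None = None) -> list[str]:
    """All matching group ids for one sample (membership is non-exclusive:
    group 1 contains groups 2-4).  Empty list when CDKN2A is wild-type."""
    if profiles is None:
        profiles = default_group_profiles()
    missing = [g for g in NINE_P21_GENES if g not in lof_flags]
    if missing:
        raise ValueError(f"LoF flags missing for genes: {missing}")
    return [p.group_id for p in profiles if p.matches(lof_flags)]


def enumerate_9p21_profiles(statuses: pd.DataFrame, gene_list: list[str],
                            min_fraction: float = 0.05):
    """Group a cohort by identical alteration profile over ``gene_list``.

    ``statuses`` is long-format with columns sample, gene, status.  Returns
    (profiles, wild_type_samples) where profiles is a list of dicts with the
    profile tuple and member samples, keeping only profiles whose membership
    is at least ``min_fraction`` of the cohort.  Samples wild-type across the
    whole locus form the reference set and are reported separately.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    if statuses.empty:
        raise ValueError("cohort is empty")
    wide = (statuses[statuses["gene"].isin(gene_list)]
            .pivot_table(index="sample", columns="gene", values="status",
                         aggfunc="first", fill_value="wild_type")
            .reindex(columns=gene_list, fill_value="wild_type"))
    n = len(wide)
    wt = tuple(["wild_type"] * len(gene_list))
    profiles = []
    wild_type_samples: list[str] = []
    for profile, grp in wide.groupby(list(gene_list), sort=True):
        profile = tuple(profile) if isinstance(profile, tuple) else (profile,)
        members = sorted(grp.index)
        if profile == wt:
            wild_type_samples = members
            continue
        if len(members) / n >= min_fraction:
            profiles.append({"profile": dict(zip(gene_list, profile)),
                             "samples": members})
    profiles.sort(key=lambda p: (-len(p["samples"]), sorted(p["profile"].items())))
    return profiles, wild_type_samples


def damage_table(statuses: list[GeneDamageStatus]) -> pd.DataFrame:
    """Long-format sample x gene damage table."""
    return pd.DataFrame(
        [{"sample": s.sample, "gene": s.gene, "status": s.status, "lof": s.lof}
         for s in statuses])
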