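"""Cohort-level summary statistics for dual-site editing experiments."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genotyping import FounderReport
from .linkage import PhaseCall


def round_half_up(x: float) -> int:
    """Deterministic nearest-integer rounding with .5 going up."""
    return int(math.floor(x + 0.5))


@dataclass
class CohortSummary:
    """Founder-level outcome percentages and counts.

    Percentages are rounded to whole percent for presentation; the raw
    fractions are kept alongside. Homozygosity percentages are denominated
    over the founders mutated at that site (the convention that reproduces
    published summaries of this design); the all-founder fractions are also
    emitted for audit.
    """

    n_founders: int
    pct_C_only: int
    pct_E_only: int
    pct_both: int
    pct_none: int
    pct_hom_C: int
    pct_hom_E: int
    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)
    linked_count: int = 0
    co_targeted_count: int = 0
    indel_founder_count: dict[str, int] = field(default_factory=dict)
    deletion_lengths: dict[str, list[int]] = field(default_factory=dict)
    large_deletion_count: int = 0


def _site_ids(report: FounderReport) -> list[str]:
    return list(report.sites.keys())


def summarize_cohort(
    reports: Sequence[FounderReport],
    phases: Optional[Sequence[PhaseCall]] = None,
    hom_denominator: str = "mutated",
) -> CohortSummary:
    """Aggregate founder reports (and optional phase calls) into a summary.

    ``hom_denominator`` selects the base of the homozygosity percentages:
    ``"mutated"`` (founders carrying the intended mutation at that site) or
    ``"all"`` founders.
    """
    ids = [r.founder_id for r in reports]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate founder_id in reports")
    n = len(reports)
    if n == 0:
        raise ValueError("empty cohort")
    sA, sB = _site_ids(reports[0])

    counts = {"C_only": 0, "E_only": 0, "both": 0, "none": 0}
    hom = {sA: 0, sB: 0}
    mutated = {sA: 0, sB: 0}
    indel_founders = {sA: 0, sB: 0}
    del_lengths: dict[str, list[int]] = {sA: [], sB: []}
    large_del = 0
    for r in reports:
        cls = {f"{sA}_only": "C_only", f"{sB}_only": "E_only",
               "both": "both", "none": "none"}[r.classification]
        counts[cls] += 1
        for sid in (sA, sB):
            sg = r.sites[sid]
            if sg.zygosity == "homozygous":
                hom[sid] += 1
            if sg.mutated:
                mutated[sid] += 1
            lengths = [
                -l for call in sg.allele_calls for (_, l, _) in call.indels if l < 0
            ]
            if any(cat == "indel" for cat in sg.allele_categories):
                indel_founders[sid] += 1
                del_lengths[sid].extend(sorted(lengths))
        if any(sg.allele_calls[i].large_deletion
               for sg in r.sites.values() for i in (0, 1)):
            large_del += 1

    pct = {k: round_half_up(100 * v / n) for k, v in counts.items()}
    hom_base = {sid: (mutated[sid] if hom_denominator == "mutated" else n)
                for sid in (sA, sB)}
    pct_hom = {
        sid: (round_half_up(100 * hom[sid] / hom_base[sid]) if hom_base[sid] else 0)
        for sid in (sA, sB)
    }

    phases = phases or []
    linked = sum(1 for p in phases if p.phase == "cis")

    fractions = {k: v / n for k, v in counts.items()}
    fractions.update({f"hom_{sid}_over_mutated":
                      (hom[sid] / mutated[sid] if mutated[sid] else 0.0)
                      for sid in (sA, sB)})
    fractions.update({f"hom_{sid}_over_all": hom[sid] / n for sid in (sA, sB)})
    all_counts = dict(counts)
    all_counts.update({f"hom_{sid}": hom[sid] for sid in (sA, sB)})
    all_counts.update({f"mutated_{sid}": mutated[sid] for sid in (sA, sB)})

    return CohortSummary(
        n_founders=n,
        pct_C_only=pct["C_only"], pct_E_only=pct["E_only"],
        pct_both=pct["both"], pct_none=pct["none"],
        pct_hom_C=pct_hom[sA], pct_hom_E=pct_hom[sB],
        counts=all_counts, fractions=fractions,
        linked_count=linked, co_targeted_count=counts["both"],
        indel_founder_count=indel_founders, deletion_lengths=del_lengths,
        large_deletion_count=large_del,
    )


def deletion_prevalence(reports: Sequence[FounderReport]) -> tuple[int, int]:
    """(founders with >=1 complete inter-site deletion allele, total founders)."""
    hit = 0
    for r in reports:
        sg = next(iter(r.sites.values()))
        if any(call.large_deletion for call in sg.allele_calls):
            hit += 1
    return hit, len(reports)


def indel_profile(reports: Sequence[FounderReport]) -> dict[str, dict]:
    """Per-site founder counts carrying indel alleles and their deletion lengths."""
    if not reports:
        return {}
    out: dict[str, dict] = {sid: {"founders": 0, "deletion_lengths": []}
                            for sid in _site_ids(reports[0])}
    for r in reports:
        for sid, sg in r.sites.items():
            if any(cat == "indel" for cat in sg.allele_categories):
                out[sid]["founders"] += 1
                for call in sg.allele_calls:
                    out[sid]["deletion_lengths"].extend(
                        -l for (_, l, _) in call.indels if l < 0
                    )
    for sid in out:
        out[sid]["deletion_lengths"].sort()
    return out
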