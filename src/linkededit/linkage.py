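"""Cis/trans phase determination for dual-site edited founders.

Two edits ~9 kb apart recombine at well under 0.01 cM, so offspring of a
founder x wild-type cross inherit each founder chromosome intact: a founder
with both edits on one chromosome (cis) produces only doubly-het or
doubly-WT offspring, while a trans founder produces only singly-het
offspring. Phase can therefore be read either directly from known diploid
allele sequences (simulation mode) or from offspring co-segregation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .types import FounderGenome

#: Assumed recombination probability across the inter-site interval per meiosis.
RECOMBINATION_RATE = 0.0

#: Fewest offspring for a confident co-segregation call; at n offspring the
#: chance that independently segregating edits mimic a perfect cis or trans
#: pattern is (1/2)**(n-1), i.e. <=12.5% at the default of 4.
MIN_OFFSPRING = 4

GENOTYPES = ("WT", "het", "hom")


@dataclass
class SegregationTable:
    """Per-site genotypes of a founder's offspring from a cross to wild type."""

    founder_id: str
    offspring: list[tuple[str, str, str]] = field(default_factory=list)
    # (offspring_id, siteC_genotype, siteE_genotype), genotypes in GENOTYPES

    def __post_init__(self):
        for oid, g1, g2 in self.offspring:
            if g1 not in GENOTYPES or g2 not in GENOTYPES:
                raise ValueError(f"offspring {oid}: genotypes must be WT/het/hom")
            if "hom" in (g1, g2):
                raise ValueError(
                    f"offspring {oid}: hom genotype impossible in a founder x WT cross"
                )


@dataclass
class PhaseCall:
    """Cis/trans determination for one founder with supporting counts."""

    founder_id: str
    phase: str                          # "cis", "trans", "uninformative"
    support: dict[str, int] = field(default_factory=lambda: {"co": 0, "separate": 0})
    reason: str = ""


def phase_from_alleles(founder: FounderGenome, site_ids: Sequence[str] = ("C", "E")) -> PhaseCall:
    """Phase directly from ground-truth diploid alleles (simulation mode).

    cis iff some single allele carries the intended edit at both sites; trans
    iff the two sites' intended edits sit on opposite alleles; founders
    lacking an intended edit at either site are uninformative.
    """
    s1, s2 = site_ids
    carries = {
        a: {s: founder.truth_outcome(a, s) == "intended" for s in (s1, s2)}
        for a in ("a", "b")
    }
    if any(carries[a][s1] and carries[a][s2] for a in ("a", "b")):
        return PhaseCall(founder.founder_id, "cis")
    has1 = any(carries[a][s1] for a in ("a", "b"))
    has2 = any(carries[a][s2] for a in ("a", "b"))
    if has1 and has2:
        return PhaseCall(founder.founder_id, "trans")
    return PhaseCall(founder.founder_id, "uninformative",
                     reason="intended edit absent at one or both sites")


def phase_from_offspring(
    founder_report,
    table: SegregationTable,
    min_offspring: int = MIN_OFFSPRING,
) -> PhaseCall:
    """Phase a double-heterozygous founder from offspring co-segregation.

    Assuming zero recombination over the interval, a cis founder yields only
    (het, het) or (WT, WT) offspring and a trans founder only (het, WT) or
    (WT, het). Mixed patterns, homozygous founders (every offspring inherits
    the edit, carrying no phase information) and undersized families are
    reported uninformative with the observed support counts.

    ``founder_report`` is a :class:`~linkededit.genotyping.FounderReport`.
    """
    if not table.offspring:
        raise ValueError("segregation table has no offspring")
    if table.founder_id != founder_report.founder_id:
        raise ValueError("segregation table does not match the founder report")
    fid = founder_report.founder_id
    zygs = [sg.zygosity for sg in founder_report.sites.values()]
    co = sum(1 for _, g1, g2 in table.offspring if g1 == g2)
    separate = len(table.offspring) - co
    support = {"co": co, "separate": separate}
    if any(z == "homozygous" for z in zygs):
        return PhaseCall(fid, "uninformative", support,
                         reason="founder homozygous at a site; segregation uninformative")
    if any(z != "heterozygous" for z in zygs):
        return PhaseCall(fid, "uninformative", support,
                         reason="founder not heterozygous at both sites")
    if len(table.offspring) < min_offspring:
        return PhaseCall(fid, "uninformative", support,
                         reason=f"fewer than {min_offspring} offspring")
    if separate == 0:
        return PhaseCall(fid, "cis", support)
    if co == 0:
        return PhaseCall(fid, "trans", support)
    return PhaseCall(fid, "uninformative", support,
                     reason="mixed segregation pattern")


def summarize_linkage(cohort: Sequence[PhaseCall]) -> dict[str, int]:
    """Count cis / trans / uninformative calls over distinct founders."""
    ids = [c.founder_id for c in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate founder_id in phase calls")
    counts = Counter(c.phase for c in cohort)
    return {"cis": counts.get("cis", 0),
            "trans": counts.get("trans", 0),
            "uninformative": counts.get("uninformative", 0)}
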