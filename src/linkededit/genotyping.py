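"""Per-site edit calling and founder genotype classification from amplicons.

Observed amplicon sequences are globally aligned to the reference window
with affine gap penalties (Biopython's PairwiseAligner), differences are
converted to reference-coordinate substitution and indel calls with
left-normalized (VCF-convention) indels, and each allele is classified into
one of the editing-outcome categories. Large deletions that abolish PCR
products entirely are detected separately from amplicon presence/absence
patterns plus long-range PCR product sizes (serial-PCR logic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio import Align

from .synthetic_data import ABSENT, AmpliconSet, emit_amplicons, emit_long_range
from .types import FounderGenome, TargetSite, ToyGenome

#: Allele-level outcome categories, in call-precedence order.
CATEGORIES = ("large_deletion", "indel", "intended", "bystander_only", "WT")

#: Site-level categories additionally include "mixed" (two different non-WT alleles).
SITE_CATEGORIES = CATEGORIES + ("mixed",)

MATCH_SCORE = 2.0
MISMATCH_SCORE = -3.0
OPEN_GAP_SCORE = -7.0     # score of the first position of a gap
EXTEND_GAP_SCORE = -2.0   # each subsequent gap position

#: Observed sequences shorter than this fraction of the reference are unalignable.
MIN_LENGTH_FRACTION = 0.3


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = OPEN_GAP_SCORE
    aligner.extend_gap_score = EXTEND_GAP_SCORE
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class AmpliconAlignment:
    """Global alignment of an observed amplicon against its reference window."""

    reference: str
    observed: str
    score: float = 0.0
    blocks: list[tuple[int, int, int, int]] = field(default_factory=list)
    # aligned blocks as (ref_start, ref_end, obs_start, obs_end), half-open
    unalignable: bool = False


def align_amplicon(observed: str, reference_window: str) -> AmpliconAlignment:
    """Globally align an amplicon to the reference window (affine gaps).

    Ties are broken deterministically by taking the aligner's first reported
    alignment; indels are left-normalized downstream. Observed sequences
    shorter than 30% of the reference are flagged unalignable rather than
    forced into a mostly-gap alignment.
    """
    if not observed or not reference_window:
        raise ValueError("both sequences must be non-empty")
    if len(observed) < MIN_LENGTH_FRACTION * len(reference_window):
        return AmpliconAlignment(reference_window, observed, unalignable=True)
    aln = _ALIGNER.align(reference_window, observed)[0]
    ref_blocks, obs_blocks = aln.aligned
    blocks = [
        (int(r0), int(r1), int(q0), int(q1))
        for (r0, r1), (q0, q1) in zip(ref_blocks, obs_blocks)
    ]
    return AmpliconAlignment(reference_window, observed, float(aln.score), blocks)


@dataclass
class EditCall:
    """All differences of one allele from the reference at one site's amplicon.

    Positions are genomic (plus strand, 0-based). Indels carry a signed
    length (+insertion / -deletion) and the inserted/deleted sequence.
    """

    site_id: str
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    indels: list[tuple[int, int, str]] = field(default_factory=list)
    large_deletion: bool = False

    def is_wt(self) -> bool:
        return not (self.substitutions or self.indels or self.large_deletion)


def _left_normalize_deletion(ref: str, start: int, seq: str) -> tuple[int, str]:
    while start > 0 and ref[start - 1] == seq[-1]:
        seq = ref[start - 1] + seq[:-1]
        start -= 1
    return start, seq


def _left_normalize_insertion(ref: str, start: int, seq: str) -> tuple[int, str]:
    while start > 0 and ref[start - 1] == seq[-1]:
        seq = ref[start - 1] + seq[:-1]
        start -= 1
    return start, seq


def call_site_edits(
    alignment: AmpliconAlignment,
    site: TargetSite,
    window_offset: int,
) -> EditCall:
    """Convert an alignment into substitution/indel calls in genome coordinates.

    ``window_offset`` is the genomic start of the reference window the
    alignment used. Gaps between aligned blocks become indels, mismatches
    within blocks become substitutions.
    """
    if alignment.unalignable:
        raise ValueError("cannot call edits from an unalignable amplicon")
    ref, obs = alignment.reference, alignment.observed
    call = EditCall(site_id=site.site_id)
    prev_r, prev_q = None, None
    for r0, r1, q0, q1 in alignment.blocks:
        if prev_r is not None:
            dr, dq = r0 - prev_r, q0 - prev_q
            if dr and dq:
                # Simultaneous gap in both: emit as deletion + insertion.
                s, seq_del = _left_normalize_deletion(ref, prev_r, ref[prev_r:r0])
                call.indels.append((window_offset + s, -dr, seq_del))
                s, seq_ins = _left_normalize_insertion(ref, prev_r, obs[prev_q:q0])
                call.indels.append((window_offset + s, dq, seq_ins))
            elif dr:
                s, seq_del = _left_normalize_deletion(ref, prev_r, ref[prev_r:r0])
                call.indels.append((window_offset + s, -dr, seq_del))
            elif dq:
                s, seq_ins = _left_normalize_insertion(ref, prev_r, obs[prev_q:q0])
                call.indels.append((window_offset + s, dq, seq_ins))
        for k in range(r1 - r0):
            if ref[r0 + k] != obs[q0 + k]:
                call.substitutions.append((window_offset + r0 + k, ref[r0 + k], obs[q0 + k]))
        prev_r, prev_q = r1, q1
    # Unaligned tails of a global alignment (rare with affine scores) -> indels.
    if alignment.blocks:
        r_end, q_end = alignment.blocks[-1][1], alignment.blocks[-1][3]
        if r_end < len(ref):
            call.indels.append((window_offset + r_end, -(len(ref) - r_end), ref[r_end:]))
        if q_end < len(obs):
            call.indels.append((window_offset + r_end, len(obs) - q_end, obs[q_end:]))
    return call


def _target_substitutions(site: TargetSite) -> set[tuple[int, str, str]]:
    return {site.proto_base_edit(p) for p in site.target_base_offsets}


def _window_substitutions(site: TargetSite) -> set[tuple[int, str, str]]:
    out = set()
    for p in site.window_positions():
        idx = site.genome_index(p)
        ref, alt = ("C", "T") if site.strand == "+" else ("G", "A")
        out.add((idx, ref, alt))
    return out


def carries_intended(call: EditCall, site: TargetSite) -> bool:
    """True if every intended target C->T conversion is present in the call."""
    if call.large_deletion:
        return False
    subs = set(call.substitutions)
    return _target_substitutions(site) <= subs


def classify_allele(call: EditCall, site: TargetSite) -> str:
    """Map an allele's edit call to an outcome category.

    Precedence: large_deletion > indel > intended > bystander_only > WT.
    ``intended`` requires all target offsets converted; window C->T edits at
    non-target offsets alone give ``bystander_only``.
    """
    if call.large_deletion:
        return "large_deletion"
    if call.indels:
        return "indel"
    if carries_intended(call, site):
        return "intended"
    subs = set(call.substitutions)
    if subs & (_window_substitutions(site) - _target_substitutions(site)) or \
            subs & _target_substitutions(site):
        return "bystander_only"
    return "WT"


@dataclass
class SiteGenotype:
    """Diploid classification of one founder at one site."""

    site_id: str
    category: str                       # one of SITE_CATEGORIES
    zygosity: str                       # "WT" / "heterozygous" / "homozygous"
    allele_calls: tuple[EditCall, EditCall]

    @property
    def mutated(self) -> bool:
        """Counts as carrying the intended target mutation (>=1 intended allele)."""
        return any(c == "intended" for c in self.allele_categories)

    @property
    def allele_categories(self) -> tuple[str, str]:
        # recomputed lazily; stored at construction by genotype_founder
        return self._cats

    _cats: tuple[str, str] = ("WT", "WT")


@dataclass
class FounderReport:
    """Per-founder summary: one SiteGenotype per site plus the dual-site class."""

    founder_id: str
    sites: dict[str, SiteGenotype]
    classification: str                 # none / C_only / E_only / both


def _site_genotype(site: TargetSite, call_a: EditCall, call_b: EditCall) -> SiteGenotype:
    cats = (classify_allele(call_a, site), classify_allele(call_b, site))
    n_int = sum(carries_intended(c, site) for c in (call_a, call_b))
    zyg = "homozygous" if n_int == 2 else "heterozygous" if n_int == 1 else "WT"
    non_wt = [c for c in cats if c != "WT"]
    if not non_wt:
        category = "WT"
    elif len(set(non_wt)) == 1:
        category = non_wt[0]
    else:
        category = "mixed"
    sg = SiteGenotype(site.site_id, category, zyg, (call_a, call_b))
    sg._cats = cats
    return sg


def genotype_founder(
    founder_id: str,
    allele_calls: Mapping[str, tuple[EditCall, EditCall]],
    sites: Sequence[TargetSite],
) -> FounderReport:
    """Combine per-allele calls at both sites into a founder report.

    A site counts as mutated when at least one allele's category is
    ``intended`` (bystander-only or indel-only alleles do not count toward
    the dual-site classification).
    """
    site_genos = {}
    for site in sites:
        call_a, call_b = allele_calls[site.site_id]
        site_genos[site.site_id] = _site_genotype(site, call_a, call_b)
    ids = [s.site_id for s in sites]
    mut = [site_genos[sid].mutated for sid in ids]
    if all(mut):
        classification = "both"
    elif mut[0]:
        classification = f"{ids[0]}_only"
    elif mut[1]:
        classification = f"{ids[1]}_only"
    else:
        classification = "none"
    return FounderReport(founder_id, site_genos, classification)


@dataclass
class LargeDeletionCall:
    """Result of serial-PCR large-deletion logic for one allele."""

    deleted: bool
    warning: Optional[str] = None


def detect_large_deletion(
    amplicon_presence: Mapping[str, bool],
    long_range_product_length: Optional[int],
    ref_long_range_length: int,
    inter_site_distance: int,
    tolerance: int = 50,
) -> LargeDeletionCall:
    """Call a complete inter-site deletion from serial PCR results for one allele.

    A deletion is called when *both* site-internal amplicons are absent and
    the long-range product is shorter than the reference span by at least
    the inter-site distance minus ``tolerance``. A single absent amplicon is
    reported as no-deletion with a warning (one primer site disrupted, e.g.
    by a local indel, rather than the whole segment lost).
    """
    absent = [sid for sid, present in amplicon_presence.items() if not present]
    if len(amplicon_presence) < 2:
        raise ValueError("presence pattern must cover both sites")
    if len(absent) == 0:
        return LargeDeletionCall(False)
    if len(absent) == 1:
        return LargeDeletionCall(
            False, warning=f"single absent amplicon at site {absent[0]}; "
                           f"not consistent with an inter-site deletion"
        )
    if long_range_product_length is None:
        return LargeDeletionCall(
            False, warning="both amplicons absent but no long-range product; "
                           "deletion cannot be sized"
        )
    shortfall = ref_long_range_length - long_range_product_length
    if shortfall >= inter_site_distance - tolerance:
        return LargeDeletionCall(True)
    return LargeDeletionCall(
        False, warning=f"long-range product only {shortfall} bp short of reference"
    )


# ---------------------------------------------------------------------------
# Cohort-level driver
# ---------------------------------------------------------------------------

def genotype_cohort(
    genome: ToyGenome,
    founders: Sequence[FounderGenome],
    amplicon_len: int = 450,
) -> list[FounderReport]:
    """Run the full genotyping pipeline over simulated founders.

    For each founder and site, site-internal amplicons are generated per
    allele; absent products trigger the serial-PCR/long-range deletion
    logic, present ones are aligned and their edits called.
    """
    sites = list(genome.sites)
    cuts = sorted(s.cut_position for s in sites)
    inter_site = cuts[-1] - cuts[0]
    reports = []
    for founder in founders:
        amp_sets: dict[str, AmpliconSet] = {
            s.site_id: emit_amplicons(founder, genome, s, amplicon_len) for s in sites
        }
        long_set = emit_long_range(founder, genome)
        calls: dict[str, list[EditCall]] = {s.site_id: [] for s in sites}
        for allele in ("a", "b"):
            presence = {
                sid: amp_sets[sid].products[allele] is not ABSENT for sid in calls
            }
            product = long_set.products[allele]
            del_call = detect_large_deletion(
                presence,
                None if product is ABSENT else len(product),
                len(long_set.ref_window),
                inter_site,
            )
            for site in sites:
                amp = amp_sets[site.site_id]
                obs = amp.products[allele]
                if obs is ABSENT:
                    calls[site.site_id].append(
                        EditCall(site.site_id, large_deletion=del_call.deleted)
                    )
                    continue
                aln = align_amplicon(obs, amp.ref_window)
                calls[site.site_id].append(call_site_edits(aln, site, amp.ref_start))
        allele_calls = {sid: (pair[0], pair[1]) for sid, pair in calls.items()}
        reports.append(genotype_founder(founder.founder_id, allele_calls, sites))
    return reports
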