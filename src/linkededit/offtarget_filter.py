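"""The WGS off-target variant-filtration cascade and predicted-site scan.

Three variant channels are filtered independently — GATK-style SNPs, simple
(alignment-derived) indels, and complex indels from split/discordant-read
callers — with hard annotation filters, blacklist/repeat region masks,
genotype/depth/frequency/quality gates and cross-channel proximity rules,
followed by control-population subtraction and intersection with candidate
off-target sites enumerated by exhaustive mismatch scanning. Removal
conditions follow strict inequalities (e.g. "depth smaller than 10"), so
keep-side boundaries are inclusive: DP=10, AF=0.10 and QUAL=130 survive.

Every stage is monotone (survivors are a subset of the input) and
idempotent, and :func:`run_cascade` emits a telescoping per-stage ledger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from numpy.lib.stride_tricks import sliding_window_view

from .dna import IUPAC, revcomp
from .types import (
    IntervalTrack,
    TargetSite,
    ToyGenome,
    VariantRecord,
    WgsVariantSet,
)

__all__ = [
    "FilterConfig", "OffTargetSite", "FilterReport", "StageCount",
    "hard_filter_snps", "hard_filter_indels", "region_filter",
    "genotype_filter", "depth_filter", "genotype_depth_filter",
    "af_qual_filter", "indel_proximity_filter", "simple_complex_overlap_filter",
    "population_subtract", "find_offtarget_sites", "intersect_sites", "run_cascade",
    "VariantRecord", "WgsVariantSet",
]

KEPT_GENOTYPES = ("0/1", "1/1")


@dataclass
class FilterConfig:
    """Every numeric threshold of the cascade in one auditable object.

    ``strict_missing`` controls whether a missing annotation fires a hard
    filter clause; the default (False) mirrors GATK, which does not fail
    records on absent annotations. ``excess_depth_sigma`` sets the d + k*sqrt(d)
    read-depth ceiling. ``simple_indel_qual_min`` is None by default: the
    quality gates are stated for SNPs (130) and complex indels (100) only.
    """

    # SNP hard-filter clauses (a record is removed iff ANY clause fires)
    snp_qd_min: float = 2.0
    snp_fs_max: float = 60.0
    snp_mq_min: float = 40.0
    snp_mq_rank_sum_min: float = -12.5
    snp_read_pos_rank_sum_min: float = -8.0
    snp_sor_max: float = 3.0
    # indel hard-filter clauses
    indel_qd_min: float = 2.0
    indel_fs_max: float = 200.0
    indel_read_pos_rank_sum_min: float = -20.0
    indel_sor_max: float = 10.0
    # genotype / depth / frequency / quality gates
    dp_min: int = 10
    excess_depth_sigma: float = 3.0
    af_min: float = 0.10
    snp_qual_min: float = 130.0
    complex_indel_qual_min: float = 100.0
    simple_indel_qual_min: Optional[float] = None
    indel_border_bp: int = 5
    strict_missing: bool = False

    def depth_ceiling(self, d: float) -> float:
        """Real-valued excess-depth ceiling d + k*sqrt(d); DP above it is removed."""
        return d + self.excess_depth_sigma * math.sqrt(d)


DEFAULT_CONFIG = FilterConfig()


def _fails(value: Optional[float], low: Optional[float], high: Optional[float],
           strict_missing: bool) -> bool:
    """One hard-filter clause: value < low or value > high (strict)."""
    if value is None:
        return strict_missing
    if low is not None and value < low:
        return True
    if high is not None and value > high:
        return True
    return False


def hard_filter_snps(records: Sequence[VariantRecord],
                     cfg: FilterConfig = DEFAULT_CONFIG) -> list[VariantRecord]:
    """GATK-style SNP hard filter; any firing clause removes the record."""
    out = []
    for r in records:
        sm = cfg.strict_missing
        removed = (
            _fails(r.qd, cfg.snp_qd_min, None, sm)
            or _fails(r.fs, None, cfg.snp_fs_max, sm)
            or _fails(r.mq, cfg.snp_mq_min, None, sm)
            or _fails(r.mq_rank_sum, cfg.snp_mq_rank_sum_min, None, sm)
            or _fails(r.read_pos_rank_sum, cfg.snp_read_pos_rank_sum_min, None, sm)
            or _fails(r.sor, None, cfg.snp_sor_max, sm)
        )
        if not removed:
            out.append(r)
    return out


def hard_filter_indels(records: Sequence[VariantRecord],
                       cfg: FilterConfig = DEFAULT_CONFIG) -> list[VariantRecord]:
    """Hard filter with the indel-specific thresholds."""
    out = []
    for r in records:
        sm = cfg.strict_missing
        removed = (
            _fails(r.qd, cfg.indel_qd_min, None, sm)
            or _fails(r.fs, None, cfg.indel_fs_max, sm)
            or _fails(r.read_pos_rank_sum, cfg.indel_read_pos_rank_sum_min, None, sm)
            or _fails(r.sor, None, cfg.indel_sor_max, sm)
        )
        if not removed:
            out.append(r)
    return out


def _build_tree(tracks: Sequence[IntervalTrack]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for track in tracks:
        for chrom, start, end in track.intervals:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def region_filter(records: Sequence[VariantRecord],
                  tracks: Sequence[IntervalTrack]) -> list[VariantRecord]:
    """Remove variants whose reference span overlaps any masked interval."""
    trees = _build_tree(tracks)
    out = []
    for r in records:
        s, e = r.span
        tree = trees.get(r.chrom)
        if tree is None or not tree.overlap(s, e):
            out.append(r)
    return out


def genotype_filter(records: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Keep heterozygous and homozygous-alt calls only."""
    return [r for r in records if r.gt in KEPT_GENOTYPES]


def depth_filter(records: Sequence[VariantRecord], d: float,
                 cfg: FilterConfig = DEFAULT_CONFIG,
                 apply_min: bool = True) -> list[VariantRecord]:
    """Remove low-depth (DP < dp_min) and excess-depth (DP > d + k*sqrt(d)) calls."""
    ceiling = cfg.depth_ceiling(d)
    out = []
    for r in records:
        if apply_min and r.dp < cfg.dp_min:
            continue
        if r.dp > ceiling:
            continue
        out.append(r)
    return out


def genotype_depth_filter(records: Sequence[VariantRecord], d: float,
                          cfg: FilterConfig = DEFAULT_CONFIG) -> list[VariantRecord]:
    """Keep records with GT in {0/1, 1/1} and dp_min <= DP <= d + k*sqrt(d)."""
    return depth_filter(genotype_filter(records), d, cfg)


def af_qual_filter(records: Sequence[VariantRecord], kind: str,
                   cfg: FilterConfig = DEFAULT_CONFIG) -> list[VariantRecord]:
    """Allele-fraction and quality gates; thresholds depend on the channel.

    AF is computed from AD as alt/(ref+alt). SNPs require AF >= af_min and
    QUAL >= snp_qual_min; complex indels require QUAL >= complex_indel_qual_min;
    simple indels have no quality gate unless configured.
    """
    qual_min = {"snp": cfg.snp_qual_min,
                "simple_indel": cfg.simple_indel_qual_min,
                "complex_indel": cfg.complex_indel_qual_min}[kind]
    out = []
    for r in records:
        if kind == "snp":
            af = r.allele_fraction
            if af is None or af < cfg.af_min:
                continue
        if qual_min is not None and r.qual < qual_min:
            continue
        out.append(r)
    return out


def indel_proximity_filter(snps: Sequence[VariantRecord],
                           indels: Sequence[VariantRecord],
                           cfg: FilterConfig = DEFAULT_CONFIG) -> list[VariantRecord]:
    """Remove SNPs within +/- ``indel_border_bp`` of any indel border (inclusive).

    The border is the first/last reference base of the indel's span, so a SNP
    exactly 5 bp away is removed and one 6 bp away survives.
    """
    pad = cfg.indel_border_bp
    trees: dict[str, IntervalTree] = {}
    for ind in indels:
        s, e = ind.span
        trees.setdefault(ind.chrom, IntervalTree()).addi(s - pad, e + pad)
    out = []
    for r in snps:
        tree = trees.get(r.chrom)
        pos0 = r.pos - 1
        if tree is None or not tree.overlap(pos0, pos0 + 1):
            out.append(r)
    return out


def simple_complex_overlap_filter(
    simple_indels: Sequence[VariantRecord],
    complex_indels: Sequence[VariantRecord],
) -> list[VariantRecord]:
    """Remove simple indels whose reference span overlaps any complex indel."""
    trees: dict[str, IntervalTree] = {}
    for c in complex_indels:
        s, e = c.span
        trees.setdefault(c.chrom, IntervalTree()).addi(s, e)
    out = []
    for r in simple_indels:
        s, e = r.span
        tree = trees.get(r.chrom)
        if tree is None or not tree.overlap(s, e):
            out.append(r)
    return out


def population_subtract(
    edited_records: Sequence[VariantRecord],
    control_sets: Sequence[WgsVariantSet],
) -> list[VariantRecord]:
    """Remove variants observed (same chrom,pos,ref,alt) in any control sample.

    A mutation present in the population, not only in edited animals, cannot
    be a consequence of editing.
    """
    seen = {r.key for cs in control_sets for r in cs.records}
    return [r for r in edited_records if r.key not in seen]


# ---------------------------------------------------------------------------
# Predicted off-target sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OffTargetSite:
    """A PAM-adjacent protospacer match with up to ``max_mm`` mismatches."""

    chrom: str
    start: int                 # 0-based protospacer span on the plus strand
    end: int
    strand: str
    protospacer_match: str     # genomic sequence in protospacer orientation
    n_mismatches: int
    guide_id: str


def _pam_mask(seq_codes: np.ndarray, pam: str) -> np.ndarray:
    """Boolean mask over windows whose PAM columns match the degenerate pattern."""
    mask = np.ones(seq_codes.shape[0], dtype=bool)
    for j, sym in enumerate(pam.upper()):
        allowed = np.frombuffer("".join(IUPAC[sym]).encode(), dtype=np.uint8)
        mask &= np.isin(seq_codes[:, j], allowed)
    return mask


def _scan_strand(seq: str, guide: TargetSite, max_mm: int) -> list[tuple[int, str, int]]:
    """(window_start, matched_protospacer, n_mm) for one strand's sequence."""
    k = 20 + len(guide.pam)
    if len(seq) < k:
        return []
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    win = sliding_window_view(codes, k)
    proto = win[:, :20]
    guide_codes = np.frombuffer(guide.protospacer.encode(), dtype=np.uint8)
    mm = (proto != guide_codes).sum(axis=1)
    ok = (mm <= max_mm) & _pam_mask(win[:, 20:], guide.pam)
    return [(int(i), seq[i : i + 20], int(mm[i])) for i in np.nonzero(ok)[0]]


def find_offtarget_sites(
    genome: ToyGenome,
    guide: TargetSite,
    max_mm: int = 4,
    tracks: Sequence[IntervalTrack] = (),
) -> list[OffTargetSite]:
    """Enumerate candidate off-target sites by exhaustive mismatch scan.

    Both strands are scanned for 20-mers followed immediately by a PAM of
    the guide's class, with Hamming distance to the protospacer <= ``max_mm``
    (bulges are not modelled). Sites overlapping any supplied blacklist or
    repeat track are removed, matching the treatment of variant calls.
    """
    if len(guide.protospacer) != 20:
        raise ValueError("guide protospacer must be 20 nt")
    L = len(genome.sequence)
    sites: list[OffTargetSite] = []
    for i, match, n_mm in _scan_strand(genome.sequence, guide, max_mm):
        sites.append(OffTargetSite(genome.name, i, i + 20, "+", match, n_mm, guide.site_id))
    rc = revcomp(genome.sequence)
    for i, match, n_mm in _scan_strand(rc, guide, max_mm):
        # protospacer occupies rc[i:i+20] == plus-strand [L-i-20, L-i)
        sites.append(OffTargetSite(genome.name, L - i - 20, L - i, "-", match, n_mm,
                                   guide.site_id))
    if tracks:
        trees = _build_tree(tracks)
        sites = [s for s in sites
                 if s.chrom not in trees or not trees[s.chrom].overlap(s.start, s.end)]
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def intersect_sites(records: Sequence[VariantRecord],
                    sites: Sequence[OffTargetSite]) -> list[VariantRecord]:
    """Keep variants whose reference span overlaps a predicted off-target site."""
    trees: dict[str, IntervalTree] = {}
    for s in sites:
        trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end)
    out = []
    for r in records:
        a, b = r.span
        tree = trees.get(r.chrom)
        if tree is not None and tree.overlap(a, b):
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

@dataclass
class StageCount:
    sample_id: str
    channel: str
    stage: str
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class FilterReport:
    """Telescoping per-stage ledger plus the final candidate list."""

    stages: list[StageCount] = field(default_factory=list)
    survivors: dict[str, dict[str, list[VariantRecord]]] = field(default_factory=dict)
    candidates: list[tuple[str, VariantRecord]] = field(default_factory=list)

    def record_stage(self, sample_id, channel, stage, before, after):
        self.stages.append(
            StageCount(sample_id, channel, stage, len(before),
                       len(before) - len(after), len(after))
        )

    def to_ledger(self) -> list[dict]:
        return [vars(s).copy() for s in self.stages]


def run_cascade(
    edited_sets: Sequence[WgsVariantSet],
    control_sets: Sequence[WgsVariantSet],
    tracks: Sequence[IntervalTrack],
    sites: Sequence[OffTargetSite],
    config: FilterConfig = DEFAULT_CONFIG,
) -> FilterReport:
    """Run all three filter channels, control subtraction and site intersection.

    Channel stage order:
      * SNPs: hard -> region -> genotype/depth -> AF+QUAL -> indel proximity
      * simple indels: hard -> region -> genotype/depth -> complex overlap
      * complex indels: genotype -> QUAL -> excess depth -> region

    then per-channel control-population subtraction, then intersection of
    the union of survivors with predicted off-target site spans.
    """
    report = FilterReport()
    for sample in edited_sets:
        d = sample.mean_depth
        snps = [r for r in sample.records if r.kind == "snp"]
        simple = [r for r in sample.records if r.kind == "simple_indel"]
        cplx = [r for r in sample.records if r.kind == "complex_indel"]
        rec = report.record_stage

        # -- complex indel channel (needed by the SNP proximity stage) ------
        s0 = cplx
        s1 = genotype_filter(s0); rec(sample.sample_id, "complex", "genotype", s0, s1)
        s2 = af_qual_filter(s1, "complex_indel", config)
        rec(sample.sample_id, "complex", "qual", s1, s2)
        s3 = depth_filter(s2, d, config, apply_min=False)
        rec(sample.sample_id, "complex", "excess_depth", s2, s3)
        s4 = region_filter(s3, tracks); rec(sample.sample_id, "complex", "region", s3, s4)
        cplx_surv = s4

        # -- simple indel channel ------------------------------------------
        t0 = simple
        t1 = hard_filter_indels(t0, config); rec(sample.sample_id, "simple", "hard", t0, t1)
        t2 = region_filter(t1, tracks); rec(sample.sample_id, "simple", "region", t1, t2)
        t3 = genotype_depth_filter(t2, d, config)
        rec(sample.sample_id, "simple", "genotype_depth", t2, t3)
        t4 = simple_complex_overlap_filter(t3, cplx_surv)
        rec(sample.sample_id, "simple", "complex_overlap", t3, t4)
        simple_surv = t4

        # -- SNP channel ----------------------------------------------------
        u0 = snps
        u1 = hard_filter_snps(u0, config); rec(sample.sample_id, "snp", "hard", u0, u1)
        u2 = region_filter(u1, tracks); rec(sample.sample_id, "snp", "region", u1, u2)
        u3 = genotype_depth_filter(u2, d, config)
        rec(sample.sample_id, "snp", "genotype_depth", u2, u3)
        u4 = af_qual_filter(u3, "snp", config)
        rec(sample.sample_id, "snp", "af_qual", u3, u4)
        u5 = indel_proximity_filter(u4, list(simple_surv) + list(cplx_surv), config)
        rec(sample.sample_id, "snp", "indel_proximity", u4, u5)
        snp_surv = u5

        # -- population subtraction ----------------------------------------
        channel_surv = {}
        for channel, surv in (("snp", snp_surv), ("simple", simple_surv),
                              ("complex", cplx_surv)):
            after = population_subtract(surv, control_sets)
            rec(sample.sample_id, channel, "population_subtract", surv, after)
            channel_surv[channel] = after
        report.survivors[sample.sample_id] = channel_surv

        # -- predicted-site intersection -----------------------------------
        merged = channel_surv["snp"] + channel_surv["simple"] + channel_surv["complex"]
        hits = intersect_sites(merged, sites)
        rec(sample.sample_id, "all", "site_intersection", merged, hits)
        report.candidates.extend((sample.sample_id, r) for r in hits)
    return report
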