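"""Seeded generators for every input the pipeline consumes.

This module emulates the experimental design of a dual-site base-editing
founder study: a single-chromosome toy reference carrying two editable
transcription-factor motifs ~9 kb apart (a STAT5 site targeted through an
NGA PAM and an ETS/ELF5 site targeted through an NGG PAM on the opposite
strand), diploid founders whose alleles independently acquire editing
outcomes, PCR amplicons, whole-genome variant call sets for edited and
control animals, and blacklist/repeat interval tracks.

All randomness flows from a single top-level seed that fans out to fixed
per-component child streams (see :func:`component_rng`), so identical seeds
and configurations yield byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .dna import BASES, random_sequence, revcomp
from .types import (
    ConfigError,
    EditTruth,
    FounderGenome,
    IntervalTrack,
    TargetSite,
    ToyGenome,
    VariantRecord,
    WgsVariantSet,
)

#: Fixed child-stream ids: child rng = default_rng([seed, stream_id]).
_STREAM_IDS = {
    "reference": 1,
    "founders": 2,
    "amplicons": 3,
    "wgs": 4,
    "tracks": 5,
    "offspring": 6,
    "plant": 7,
}


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component child generator derived from one top-level seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, _STREAM_IDS[component]])


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteSpec:
    """Placement-free description of a target site to embed in a toy reference."""

    site_id: str
    protospacer: str
    pam: str                    # degenerate pattern (NGA / NGG)
    pam_concrete: str           # the concrete PAM written into the reference
    strand: str
    motif: str
    target_base_offsets: tuple[int, ...]
    editing_window: tuple[int, int] = (4, 8)


# Site C: plus strand, VQR-BE3 (NGA PAM). Protospacer positions 3-11 spell the
# STAT5 motif TTCNNNGAA; the target C sits at position 5, a second window C at
# position 7 leaves room for bystander deamination.
# Site E: minus strand, BE4 (NGG PAM). Protospacer positions 5-8 are TTCC,
# whose plus-strand reverse complement is the ETS/ELF5 core GGAA (GGAW);
# the target C is position 7, position 8 is the bystander candidate.
DEFAULT_SITE_SPECS: tuple[SiteSpec, ...] = (
    SiteSpec("C", "GATTCTCGGAAAGTGATGGA", "NGA", "TGA", "+",
             "TTCNNNGAA", (5,)),
    SiteSpec("E", "GTAATTCCTAGAGTGATGAG", "NGG", "TGG", "-",
             "GGAW", (7,)),
)

#: Distance between the two protospacer starts, bp.
DEFAULT_SITE_SPACING = 9_000


def _embed_block(seq: list[str], start: int, block: str) -> None:
    seq[start : start + len(block)] = list(block)


def make_reference(
    length: int = 100_000,
    seed: int = 0,
    site_specs: Sequence[SiteSpec] = DEFAULT_SITE_SPECS,
    spacing: int = DEFAULT_SITE_SPACING,
    name: str = "chrT",
    margin: int = 1_000,
) -> ToyGenome:
    """Build a random reference with the two target sites embedded ``spacing`` bp apart.

    Raises :class:`ConfigError` naming the offending site if a site cannot be
    embedded (e.g. the genome is too short for the requested geometry).
    """
    if len(site_specs) != 2:
        raise ConfigError("exactly two site specs are required")
    if length < 20_000:
        raise ConfigError(
            f"cannot embed site {site_specs[0].site_id}: genome of {length} bp is too "
            f"short (need >= 20 kb for two sites {spacing} bp apart plus margins)"
        )
    first_start = (length - spacing) // 2
    if first_start < margin or first_start + spacing + 23 + margin > length:
        raise ConfigError(
            f"cannot embed site {site_specs[1].site_id}: {spacing} bp spacing does not "
            f"fit in a {length} bp genome with {margin} bp margins"
        )

    rng = component_rng(seed, "reference")
    seq = list(random_sequence(length, rng))

    sites: list[TargetSite] = []
    features: list[tuple[str, int, int]] = []
    for i, spec in enumerate(site_specs):
        start = first_start + i * spacing
        if spec.strand == "+":
            block = spec.protospacer + spec.pam_concrete
            _embed_block(seq, start, block)
        else:
            block = revcomp(spec.protospacer + spec.pam_concrete)
            _embed_block(seq, start - len(spec.pam_concrete), block)
        site = TargetSite(
            site_id=spec.site_id,
            protospacer=spec.protospacer,
            pam=spec.pam,
            strand=spec.strand,
            start=start,
            editing_window=spec.editing_window,
            motif=spec.motif,
            target_base_offsets=spec.target_base_offsets,
        )
        sites.append(site)
        features.append((f"site_{spec.site_id}", start, start + 20))

    genome = ToyGenome(name=name, sequence="".join(seq), sites=sites, features=features)
    for site in sites:
        genome.validate_site(site)
    return genome


def plant_offtarget_sites(
    genome: ToyGenome,
    site: TargetSite,
    positions: Sequence[int],
    n_mismatches: int = 3,
    seed: int = 0,
) -> ToyGenome:
    """Return a copy of the genome with near-match decoys of ``site`` planted.

    Each decoy is the guide's protospacer with ``n_mismatches`` substitutions
    at PAM-proximal positions 9-16 (keeping the editing window intact so a
    C->T off-target edit remains possible there), followed by a concrete PAM
    of the guide's class, written on the plus strand.
    """
    rng = component_rng(seed, "plant")
    seq = list(genome.sequence)
    features = list(genome.features)
    pam_concrete = "T" + site.pam[1:].replace("N", "T")
    for pos in positions:
        if not 0 <= pos <= len(seq) - 23:
            raise ConfigError(f"planted off-target position {pos} outside genome")
        proto = list(site.protospacer)
        mut_at = rng.choice(np.arange(8, 16), size=n_mismatches, replace=False)
        for j in sorted(int(x) for x in mut_at):
            proto[j] = rng.choice([b for b in BASES if b != proto[j]])
        _embed_block(seq, pos, "".join(proto) + pam_concrete)
        features.append((f"offtarget_{site.site_id}_{pos}", pos, pos + 23))
    return ToyGenome(genome.name, "".join(seq), list(genome.sites), features)


# ---------------------------------------------------------------------------
# Founder simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Per-allele outcome rates for a simulated founder cohort.

    Rates are free parameters of the simulation; the defaults approximate the
    founder-level outcome distribution of a dual-site base-editing experiment
    (roughly half of founders mutated at each site, occasional bystander
    edits and nickase-derived small indels). ``p_large_deletion`` models the
    Cas9 double-strand-break failure mode and must be zero in ``base_edit``
    mode: cytosine base editors nick rather than cut, so the sequence between
    the two target sites is never excised.
    """

    n_founders: int = 32
    mode: str = "base_edit"              # "base_edit" or "cas9"
    p_intended_C: float = 0.34
    p_intended_E: float = 0.42
    p_bystander: float = 0.05
    p_small_indel: float = 0.08
    p_large_deletion: float = 0.0
    phase_bias: float = 0.6              # P(co-edits land on the same allele)
    seed: int = 0

    def validate(self) -> None:
        if self.n_founders < 1:
            raise ConfigError("n_founders must be >= 1")
        if self.mode not in ("base_edit", "cas9"):
            raise ConfigError("mode must be 'base_edit' or 'cas9'")
        probs = (self.p_intended_C, self.p_intended_E, self.p_bystander,
                 self.p_small_indel, self.p_large_deletion, self.phase_bias)
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        for p_int in (self.p_intended_C, self.p_intended_E):
            if p_int + self.p_bystander + self.p_small_indel > 1.0 + 1e-9:
                raise ConfigError("per-site outcome probabilities must sum to <= 1")
        if self.mode == "base_edit" and self.p_large_deletion > 0:
            raise ConfigError("large deletions cannot occur in base_edit mode")


def _resolve_detail(
    genome: ToyGenome, site: TargetSite, outcome: str, detail, rng: Optional[np.random.Generator]
):
    """Fill in the stochastic parts of an outcome's detail tuple."""
    if outcome == "bystander":
        candidates = [
            p for p in site.window_positions()
            if p not in site.target_base_offsets
            and genome.sequence[site.genome_index(p)] == ("C" if site.strand == "+" else "G")
        ]
        if not candidates:
            raise ConfigError(f"site {site.site_id} has no bystander-editable window C")
        if detail is not None:
            return ("bystander", tuple(detail[1]))
        if rng is None:
            raise ValueError("rng required to draw a bystander subset")
        chosen = [p for p in candidates if rng.random() < 0.5]
        if not chosen:
            chosen = [candidates[int(rng.integers(len(candidates)))]]
        return ("bystander", tuple(chosen))
    if outcome == "indel":
        if detail is not None and len(detail) >= 4:
            return detail
        if detail is not None:
            kind, length = detail[0], int(detail[1])
        else:
            if rng is None:
                raise ValueError("rng required to draw an indel")
            kind = "del" if rng.random() < 0.85 else "ins"
            length = int(rng.integers(1, 16))
        cut = site.cut_position
        if kind == "del":
            start = cut - length // 2
            return ("del", length, start, start + length)
        ins_seq = (random_sequence(length, rng) if rng is not None
                   else "A" * length)
        return ("ins", length, cut, ins_seq)
    return detail


def build_allele(
    genome: ToyGenome,
    outcomes: Sequence[tuple[str, str, Optional[tuple]]],
    rng: Optional[np.random.Generator] = None,
) -> tuple[str, list[EditTruth]]:
    """Apply per-site outcomes to the reference, returning (sequence, resolved truth).

    ``outcomes`` is a list of (site_id, outcome, detail) triples; ``detail``
    may be ``None`` to have the stochastic parts drawn from ``rng``, which is
    how :func:`simulate_founders` uses it, or fully specified for
    deterministic reconstruction (as the packaged fixture does).
    """
    ops: list[tuple] = []          # ("sub", idx, alt) / ("del", s, e) / ("ins", pos, seq)
    truths: list[EditTruth] = []
    large_del_applied = False
    for site_id, outcome, detail in outcomes:
        site = genome.site(site_id)
        if outcome == "WT":
            truths.append(EditTruth(site_id, "WT"))
            continue
        if outcome == "large_deletion":
            if not large_del_applied:
                cuts = sorted(s.cut_position for s in genome.sites)
                ops.append(("del", cuts[0], cuts[-1]))
                large_del_applied = True
            truths.append(EditTruth(site_id, "large_deletion", ("large_del",)))
            continue
        detail = _resolve_detail(genome, site, outcome, detail, rng)
        if outcome == "intended":
            for p in site.target_base_offsets:
                idx, _, alt = site.proto_base_edit(p)
                ops.append(("sub", idx, alt))
            truths.append(EditTruth(site_id, "intended", ("targets", site.target_base_offsets)))
        elif outcome == "bystander":
            for p in detail[1]:
                idx, _, alt = site.proto_base_edit(p)
                ops.append(("sub", idx, alt))
            truths.append(EditTruth(site_id, "bystander", detail))
        elif outcome == "indel":
            if detail[0] == "del":
                ops.append(("del", detail[2], detail[3]))
            else:
                ops.append(("ins", detail[2], detail[3]))
            truths.append(EditTruth(site_id, "indel", detail))
        else:
            raise ValueError(f"unknown outcome {outcome!r}")

    seq = genome.sequence
    for op in sorted(ops, key=lambda o: -o[1]):
        if op[0] == "sub":
            seq = seq[: op[1]] + op[2] + seq[op[1] + 1 :]
        elif op[0] == "del":
            seq = seq[: op[1]] + seq[op[2] :]
        else:
            seq = seq[: op[1]] + op[2] + seq[op[1] :]
    return seq, truths


def _draw_site_outcome(rng: np.random.Generator, p_intended: float,
                       p_bystander: float, p_indel: float) -> str:
    u = rng.random()
    if u < p_intended:
        return "intended"
    if u < p_intended + p_bystander:
        return "bystander"
    if u < p_intended + p_bystander + p_indel:
        return "indel"
    return "WT"


def simulate_founders(genome: ToyGenome, cfg: CohortConfig) -> list[FounderGenome]:
    """Simulate a diploid founder cohort under the configured editing mode.

    Each allele draws an outcome per site; when exactly one allele is edited
    at each of the two sites, the co-edits land on the same allele (cis) with
    probability ``phase_bias``. In ``cas9`` mode an allele may instead lose
    the entire inter-site segment (both cut sites firing on the same
    chromosome); in ``base_edit`` mode this cannot happen by construction.
    """
    cfg.validate()
    rng = component_rng(cfg.seed, "founders")
    site_ids = [s.site_id for s in genome.sites]
    p_int = {site_ids[0]: cfg.p_intended_C, site_ids[1]: cfg.p_intended_E}

    founders = []
    for i in range(cfg.n_founders):
        fid = f"F{i + 1:03d}"
        large = [cfg.mode == "cas9" and rng.random() < cfg.p_large_deletion
                 for _ in range(2)]
        pairs: dict[str, list[str]] = {}
        for sid in site_ids:
            pairs[sid] = [
                "large_deletion" if large[a] else
                _draw_site_outcome(rng, p_int[sid], cfg.p_bystander, cfg.p_small_indel)
                for a in range(2)
            ]
        # Phase co-edits: applies when each site has exactly one edited allele.
        ca, cb = pairs[site_ids[0]]
        ea, eb = pairs[site_ids[1]]
        c_edited = [o != "WT" for o in (ca, cb)]
        e_edited = [o != "WT" for o in (ea, eb)]
        if sum(c_edited) == 1 and sum(e_edited) == 1 and not any(large):
            ci = c_edited.index(True)
            want_same = rng.random() < cfg.phase_bias
            ei = e_edited.index(True)
            if (ei == ci) != want_same:
                pairs[site_ids[1]] = [eb, ea]

        alleles = {}
        truth = {}
        for a, name in enumerate("ab"):
            outcomes = [(sid, pairs[sid][a], None) for sid in site_ids]
            seq, truths = build_allele(genome, outcomes, rng)
            alleles[name] = seq
            truth[name] = truths
        founders.append(FounderGenome(fid, alleles["a"], alleles["b"], truth))
    return founders


# ---------------------------------------------------------------------------
# PCR amplicons
# ---------------------------------------------------------------------------

#: Sentinel meaning a primer pair produced no product on an allele.
ABSENT = None


@dataclass
class AmpliconSet:
    """Per-allele PCR products of one primer pair, plus the reference window."""

    site_id: str
    ref_start: int
    ref_window: str
    products: dict[str, Optional[str]]   # allele name -> sequence or ABSENT


def emit_amplicons(
    founder: FounderGenome,
    genome: ToyGenome,
    site: TargetSite,
    amplicon_len: int = 450,
    primer_len: int = 20,
) -> AmpliconSet:
    """Simulate site-internal PCR: primers from the reference window's two ends.

    An allele in which either primer's binding sequence was deleted (the
    serial-PCR signature of a large deletion) yields :data:`ABSENT`.
    """
    if not 100 <= amplicon_len <= 10_000:
        raise ConfigError("amplicon_len must lie in [100, 10000]")
    center = site.start + 10
    wstart = center - amplicon_len // 2
    wend = wstart + amplicon_len
    if wstart < 0 or wend > len(genome.sequence):
        raise ConfigError(f"primer window for site {site.site_id} outside genome")
    ref_window = genome.sequence[wstart:wend]
    fwd = ref_window[:primer_len]
    rev = ref_window[-primer_len:]

    products: dict[str, Optional[str]] = {}
    for name, allele in founder.alleles.items():
        i = allele.find(fwd)
        if i < 0:
            products[name] = ABSENT
            continue
        j = allele.find(rev, i + primer_len)
        products[name] = ABSENT if j < 0 else allele[i : j + primer_len]
    return AmpliconSet(site.site_id, wstart, ref_window, products)


def emit_long_range(
    founder: FounderGenome,
    genome: ToyGenome,
    margin: int = 500,
    primer_len: int = 20,
) -> AmpliconSet:
    """Long-range PCR spanning both target sites; products shorten with deletions."""
    lo = min(s.start for s in genome.sites) - margin
    hi = max(s.end for s in genome.sites) + margin
    if lo < 0 or hi > len(genome.sequence):
        raise ConfigError("long-range primer window outside genome")
    ref_window = genome.sequence[lo:hi]
    fwd, rev = ref_window[:primer_len], ref_window[-primer_len:]
    products: dict[str, Optional[str]] = {}
    for name, allele in founder.alleles.items():
        i = allele.find(fwd)
        if i < 0:
            products[name] = ABSENT
            continue
        j = allele.find(rev, i + primer_len)
        products[name] = ABSENT if j < 0 else allele[i : j + primer_len]
    return AmpliconSet("long_range", lo, ref_window, products)


def simulate_offspring(founder: FounderGenome, genome: ToyGenome, n: int, seed: int = 0):
    """Offspring genotypes of a founder x wild-type cross with no recombination.

    Each offspring inherits one founder allele intact (the two sites are only
    ~9 kb apart, <<0.01 cM) plus a wild-type allele, so its per-site genotype
    is het where the transmitted allele carries the intended edit, else WT.
    """
    from .linkage import SegregationTable

    rng = component_rng(seed, "offspring")
    site_ids = [s.site_id for s in genome.sites]
    rows = []
    for k in range(n):
        allele = "ab"[int(rng.integers(2))]
        genos = tuple(
            "het" if founder.truth_outcome(allele, sid) == "intended" else "WT"
            for sid in site_ids
        )
        rows.append((f"{founder.founder_id}-o{k + 1}", genos[0], genos[1]))
    return SegregationTable(founder_id=founder.founder_id, offspring=rows)


# ---------------------------------------------------------------------------
# WGS variant simulation
# ---------------------------------------------------------------------------

@dataclass
class WgsCohortSpec:
    """Composition of a simulated WGS cohort (controls + edited founders).

    ``shared_snp_rate`` and ``private_rate`` are per-bp; shared population
    variants are written into every sample, private ones into a single
    sample. ``spiked_offtargets`` lists (pos, "C->T") plus-strand positions
    (0-based) that receive a passing C->T (or G->A) edit in edited samples
    only. ``exclude_spans`` keeps background variants out of given spans so
    assay loci stay clean.
    """

    n_controls: int = 30
    n_edited: int = 2
    shared_snp_rate: float = 1e-3
    private_rate: float = 2e-4
    spiked_offtargets: list[tuple[int, str]] = field(default_factory=list)
    p_simple_indel: float = 0.08
    p_complex_indel: float = 0.04
    annot_fail_rate: float = 0.15
    exclude_spans: list[tuple[int, int]] = field(default_factory=list)


_SNP_FAIL_MODES = ("hard", "gt", "dp_low", "dp_high", "af", "qual")
_SIMPLE_FAIL_MODES = ("hard", "gt", "dp_low", "dp_high")
_COMPLEX_FAIL_MODES = ("gt", "qual", "dp_high")


def _passing_annotations(rng, kind):
    ann = {
        "qd": float(rng.uniform(15, 35)),
        "fs": float(rng.uniform(0, 5)),
        "mq": float(rng.uniform(50, 60)),
        "mq_rank_sum": float(rng.uniform(-3, 3)),
        "read_pos_rank_sum": float(rng.uniform(-4, 4)),
        "sor": float(rng.uniform(0.3, 2.5)),
    }
    if kind != "snp":
        ann["mq"] = None if rng.random() < 0.3 else ann["mq"]
    # Rank-sum annotations are hom-ref-vs-alt statistics and are often absent.
    if rng.random() < 0.05:
        ann["mq_rank_sum"] = None
    return ann


def _failing_hard_annotation(rng, ann, kind):
    if kind == "snp":
        clause = rng.choice(["qd", "fs", "mq", "mq_rank_sum", "read_pos_rank_sum", "sor"])
        ranges = {"qd": (0, 1.9), "fs": (61, 200), "mq": (5, 39),
                  "mq_rank_sum": (-30, -12.6), "read_pos_rank_sum": (-30, -8.1),
                  "sor": (3.1, 9.9)}
    else:
        clause = rng.choice(["qd", "fs", "read_pos_rank_sum", "sor"])
        ranges = {"qd": (0, 1.9), "fs": (201, 400),
                  "read_pos_rank_sum": (-40, -20.1), "sor": (10.1, 20)}
    lo, hi = ranges[clause]
    ann[clause] = float(rng.uniform(lo, hi))
    return ann


def _draw_sample_fields(rng, kind, d, fail_mode=None):
    """GT/DP/AD/QUAL/annotations for one record in one sample."""
    dp_hi = int(math.floor(d + 3 * math.sqrt(d)))
    gt = "0/1" if rng.random() < 0.6 else "1/1"
    dp = int(np.clip(rng.poisson(d), 10, dp_hi))
    ann = _passing_annotations(rng, kind)
    qual = float(rng.uniform(200, 1500)) if kind != "complex_indel" else float(rng.uniform(150, 900))

    if gt == "1/1":
        ref_reads = int(rng.binomial(dp, 0.02))
        alt = dp - ref_reads
    else:
        alt = int(rng.binomial(dp, 0.5))
        alt = min(max(alt, max(1, math.ceil(0.15 * dp))), dp)
        ref_reads = dp - alt

    if fail_mode == "hard":
        ann = _failing_hard_annotation(rng, ann, kind)
    elif fail_mode == "gt":
        gt = "0/0" if rng.random() < 0.7 else "./."
    elif fail_mode == "dp_low":
        dp = int(rng.integers(0, 10))
        alt = max(dp - 1, 0)
        ref_reads = dp - alt
    elif fail_mode == "dp_high":
        dp = dp_hi + 1 + int(rng.integers(0, 30))
        alt = dp // 2
        ref_reads = dp - alt
    elif fail_mode == "af":
        dp = max(dp, 30)
        alt = max(1, int(dp * rng.uniform(0.01, 0.08)))
        ref_reads = dp - alt
    elif fail_mode == "qual":
        qual = float(rng.uniform(0, 129.0 if kind == "snp" else 99.0))
    return gt, dp, (ref_reads, alt), qual, ann


def _draw_variant_defs(rng, genome, n, spec, taken, exclude):
    """(pos, ref, alt, kind) tuples at fresh positions outside excluded spans."""
    defs = []
    seq = genome.sequence
    L = len(seq)
    attempts = 0
    while len(defs) < n and attempts < 100 * n + 1000:
        attempts += 1
        pos = int(rng.integers(200, L - 500))
        if pos in taken or any(s - 150 <= pos < e + 150 for s, e in exclude):
            continue
        u = rng.random()
        if u < spec.p_complex_indel:
            kind = "complex_indel"
            dl = int(rng.integers(30, 120))
            ref, alt = seq[pos : pos + 1 + dl], seq[pos]
        elif u < spec.p_complex_indel + spec.p_simple_indel:
            kind = "simple_indel"
            dl = int(rng.integers(1, 11))
            if rng.random() < 0.5:
                ref, alt = seq[pos : pos + 1 + dl], seq[pos]
            else:
                ref, alt = seq[pos], seq[pos] + random_sequence(dl, rng)
        else:
            kind = "snp"
            ref = seq[pos]
            alt = rng.choice([b for b in BASES if b != ref])
        taken.add(pos)
        defs.append((pos, str(ref), str(alt), kind))
    if len(defs) < n:
        raise ConfigError("could not place requested variants outside excluded spans")
    return defs


def simulate_wgs_variants(
    genome: ToyGenome,
    spec: WgsCohortSpec,
    d: float = 60.0,
    seed: int = 0,
) -> list[WgsVariantSet]:
    """Simulate per-sample variant call sets for a control + edited cohort.

    Shared population variants appear in every sample (so control subtraction
    can remove them); private variants in exactly one; spiked off-target
    edits only in edited samples, always with passing annotations. Every
    record carries a ground-truth label in ``WgsVariantSet.truth``.
    """
    if d < 10:
        raise ConfigError("mean depth must be >= 10")
    rng = component_rng(seed, "wgs")
    L = len(genome.sequence)
    taken: set[int] = set()

    for pos, _ in spec.spiked_offtargets:
        if not 0 <= pos < L:
            raise ConfigError(f"spiked position {pos} outside genome")
        if genome.sequence[pos] not in "CG":
            raise ConfigError(f"spiked position {pos} is not a C/G in the reference")

    n_shared = int(round(spec.shared_snp_rate * L))
    shared_defs = _draw_variant_defs(rng, genome, n_shared, spec, taken, spec.exclude_spans)

    spike_defs = []
    for pos, _ in spec.spiked_offtargets:
        ref = genome.sequence[pos]
        alt = "T" if ref == "C" else "A"
        spike_defs.append((pos, ref, alt, "snp"))
        taken.add(pos)

    def _make_record(pos, ref, alt, kind, fields):
        gt, dp, ad, qual, ann = fields
        return VariantRecord(
            chrom=genome.name, pos=pos + 1, ref=ref, alt=alt, kind=kind,
            gt=gt, dp=dp, ad=ad, qual=qual, **ann,
        )

    samples: list[WgsVariantSet] = []
    groups = [("control", f"ctrl{i + 1:02d}") for i in range(spec.n_controls)]
    groups += [("edited", f"edit{i + 1:02d}") for i in range(spec.n_edited)]
    for group, sample_id in groups:
        records, truth = [], {}
        for pos, ref, alt, kind in shared_defs:
            fail = None
            if rng.random() < spec.annot_fail_rate:
                modes = {"snp": _SNP_FAIL_MODES, "simple_indel": _SIMPLE_FAIL_MODES,
                         "complex_indel": _COMPLEX_FAIL_MODES}[kind]
                fail = str(rng.choice(modes))
            rec = _make_record(pos, ref, alt, kind, _draw_sample_fields(rng, kind, d, fail))
            records.append(rec)
            truth[rec.key] = {"origin": "shared", "expect_pass": fail is None}
        n_private = int(rng.poisson(spec.private_rate * L))
        for pos, ref, alt, kind in _draw_variant_defs(
            rng, genome, n_private, spec, taken, spec.exclude_spans
        ):
            fail = None
            if rng.random() < spec.annot_fail_rate:
                modes = {"snp": _SNP_FAIL_MODES, "simple_indel": _SIMPLE_FAIL_MODES,
                         "complex_indel": _COMPLEX_FAIL_MODES}[kind]
                fail = str(rng.choice(modes))
            rec = _make_record(pos, ref, alt, kind, _draw_sample_fields(rng, kind, d, fail))
            records.append(rec)
            truth[rec.key] = {"origin": "private", "expect_pass": fail is None}
        if group == "edited":
            for pos, ref, alt, kind in spike_defs:
                rec = _make_record(pos, ref, alt, kind, _draw_sample_fields(rng, kind, d, None))
                records.append(rec)
                truth[rec.key] = {"origin": "spiked", "expect_pass": True}
        samples.append(WgsVariantSet(sample_id, group, records, mean_depth=d, truth=truth))
    return samples


# ---------------------------------------------------------------------------
# Interval tracks
# ---------------------------------------------------------------------------

def emit_tracks(
    genome: ToyGenome,
    fraction_masked: float = 0.2,
    seed: int = 0,
    min_len: int = 200,
    max_len: int = 1_500,
    site_margin: int = 600,
) -> tuple[IntervalTrack, IntervalTrack]:
    """Random non-overlapping blacklist + repeat tracks covering ~``fraction_masked``.

    Target sites (and any planted decoy features) are never masked; the two
    tracks split the masked fraction roughly evenly and do not overlap each
    other.
    """
    if not 0.0 <= fraction_masked <= 0.5:
        raise ConfigError("fraction_masked must lie in [0, 0.5]")
    rng = component_rng(seed, "tracks")
    L = len(genome.sequence)
    forbidden = [(max(0, s - site_margin), min(L, e + site_margin))
                 for _, s, e in genome.features]
    placed: list[tuple[int, int]] = []

    def clashes(s, e):
        return any(s < fe and fs < e for fs, fe in forbidden) or \
               any(s < pe and ps < e for ps, pe in placed)

    target_total = fraction_masked * L
    intervals: list[list[tuple[str, int, int]]] = [[], []]
    cum = 0
    attempts = 0
    while cum < target_total - 1 and attempts < 200_000:
        attempts += 1
        length = int(min(rng.integers(min_len, max_len + 1), math.ceil(target_total - cum)))
        length = max(length, 1)
        start = int(rng.integers(0, L - length))
        if clashes(start, start + length):
            continue
        placed.append((start, start + length))
        intervals[len(placed) % 2].append((genome.name, start, start + length))
        cum += length
    if cum < target_total * 0.99:
        raise ConfigError("could not place masked intervals at the requested coverage")
    return (
        IntervalTrack("blacklist", intervals[0]),
        IntervalTrack("repeats", intervals[1]),
    )
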