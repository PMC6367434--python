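"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere in memory; 1-based coordinates
appear only at VCF boundaries. Protospacer positions are 1-based along the
protospacer in its own strand orientation (position 1 is PAM-distal), the
convention used throughout the base-editing literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .dna import complement, find_motif, iupac_match, revcomp


class ConfigError(ValueError):
    """Invalid user-supplied configuration."""


# ---------------------------------------------------------------------------
# Target sites and genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetSite:
    """A genomic base-editing target: protospacer + PAM + editing window + TF motif.

    ``start`` is the 0-based position of the protospacer span on the plus
    strand of the reference; for a minus-strand site the protospacer sequence
    is the reverse complement of the genomic span and the PAM lies on the
    5' side of the span in plus-strand coordinates.
    """

    site_id: str
    protospacer: str          # 20 nt, in protospacer-strand orientation
    pam: str                  # degenerate pattern, e.g. "NGA" or "NGG"
    strand: str               # "+" or "-"
    start: int                # protospacer span start on the plus strand
    editing_window: tuple[int, int] = (4, 8)   # closed, 1-based protospacer positions
    motif: str = ""           # degenerate TF motif expected on the plus strand
    target_base_offsets: tuple[int, ...] = ()  # protospacer positions whose C->T is intended

    def __post_init__(self):
        if len(self.protospacer) != 20:
            raise ConfigError(f"site {self.site_id}: protospacer must be 20 nt")
        if self.strand not in "+-":
            raise ConfigError(f"site {self.site_id}: strand must be + or -")
        lo, hi = self.editing_window
        if not all(lo <= p <= hi for p in self.target_base_offsets):
            raise ConfigError(
                f"site {self.site_id}: target_base_offsets must lie in the editing window"
            )

    @property
    def end(self) -> int:
        return self.start + 20

    def genome_index(self, proto_pos: int) -> int:
        """Plus-strand genome index of 1-based protospacer position ``proto_pos``."""
        if not 1 <= proto_pos <= 20:
            raise ValueError("protospacer positions are 1..20")
        if self.strand == "+":
            return self.start + proto_pos - 1
        return self.start + (20 - proto_pos)

    @property
    def pam_span(self) -> tuple[int, int]:
        """Plus-strand half-open span of the PAM."""
        if self.strand == "+":
            return self.end, self.end + len(self.pam)
        return self.start - len(self.pam), self.start

    @property
    def cut_position(self) -> int:
        """Plus-strand coordinate of the Cas9 blunt cut / nick locus.

        The nick falls between protospacer positions 17 and 18 (3 bp from the
        PAM); we return the half-open boundary coordinate.
        """
        if self.strand == "+":
            return self.start + 17
        return self.start + 3

    def proto_base_edit(self, proto_pos: int) -> tuple[int, str, str]:
        """Plus-strand (index, ref_base, alt_base) for a C->T edit at a protospacer position."""
        idx = self.genome_index(proto_pos)
        if self.strand == "+":
            return idx, "C", "T"
        return idx, "G", "A"

    def window_positions(self) -> list[int]:
        lo, hi = self.editing_window
        return list(range(lo, hi + 1))


@dataclass
class ToyGenome:
    """A synthetic single-chromosome reference with embedded target sites."""

    name: str
    sequence: str
    sites: list[TargetSite] = field(default_factory=list)
    features: list[tuple[str, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    def site(self, site_id: str) -> TargetSite:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def protospacer_in_genome(self, site: TargetSite) -> str:
        span = self.sequence[site.start : site.end]
        return span if site.strand == "+" else revcomp(span)

    def pam_in_genome(self, site: TargetSite) -> str:
        a, b = site.pam_span
        span = self.sequence[a:b]
        return span if site.strand == "+" else revcomp(span)

    def validate_site(self, site: TargetSite) -> None:
        """Check the site's invariants against this reference sequence."""
        if not (0 <= site.start and site.end <= len(self.sequence)):
            raise ConfigError(f"site {site.site_id} outside genome bounds")
        if self.protospacer_in_genome(site) != site.protospacer:
            raise ConfigError(f"site {site.site_id}: protospacer does not match reference")
        if not iupac_match(site.pam, self.pam_in_genome(site)):
            raise ConfigError(f"site {site.site_id}: PAM {self.pam_in_genome(site)!r} "
                              f"does not match pattern {site.pam}")
        if site.motif:
            lo = max(0, site.start - len(site.motif) + 1)
            window = self.sequence[lo : site.end + len(site.motif) - 1]
            if not find_motif(window, site.motif):
                raise ConfigError(
                    f"site {site.site_id}: motif {site.motif} absent from protospacer locus"
                )
        for p in site.target_base_offsets:
            idx, ref, _ = site.proto_base_edit(p)
            if self.sequence[idx] != ref:
                raise ConfigError(
                    f"site {site.site_id}: target offset {p} is not a C on the protospacer strand"
                )


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------

#: Per-allele outcome vocabulary at one site.
OUTCOMES = ("WT", "intended", "bystander", "indel", "large_deletion")


@dataclass(frozen=True)
class EditTruth:
    """Ground-truth outcome of one allele at one site."""

    site_id: str
    outcome: str                      # one of OUTCOMES
    detail: Optional[tuple] = None    # e.g. ("del", 9) / ("ins", 3) / ("bystander", (7,))

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")


@dataclass
class FounderGenome:
    """A diploid founder: two full-locus allele sequences plus ground truth."""

    founder_id: str
    allele_a: str
    allele_b: str
    truth: dict[str, list[EditTruth]] = field(default_factory=dict)  # "a"/"b" -> truths

    @property
    def alleles(self) -> dict[str, str]:
        return {"a": self.allele_a, "b": self.allele_b}

    def truth_outcome(self, allele: str, site_id: str) -> str:
        for t in self.truth.get(allele, []):
            if t.site_id == site_id:
                return t.outcome
        return "WT"


# ---------------------------------------------------------------------------
# Variants and interval tracks
# ---------------------------------------------------------------------------

VARIANT_KINDS = ("snp", "simple_indel", "complex_indel")


@dataclass
class VariantRecord:
    """One called variant with the annotations consumed by the filter cascade.

    ``pos`` is 1-based (VCF convention). Annotation values may be missing
    (``None``), mirroring absent INFO keys in real call sets.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str                      # snp / simple_indel / complex_indel
    gt: str = "0/1"                # "0/0", "0/1", "1/1", "./."
    dp: int = 0
    ad: tuple[int, int] = (0, 0)   # (ref_reads, alt_reads)
    qual: float = 0.0
    qd: Optional[float] = None
    fs: Optional[float] = None
    mq: Optional[float] = None
    mq_rank_sum: Optional[float] = None
    read_pos_rank_sum: Optional[float] = None
    sor: Optional[float] = None

    def __post_init__(self):
        if self.kind not in VARIANT_KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if min(self.ad) < 0:
            raise ValueError("AD components must be non-negative")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open reference span covered by the REF allele."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))

    @property
    def allele_fraction(self) -> Optional[float]:
        total = self.ad[0] + self.ad[1]
        return None if total == 0 else self.ad[1] / total


@dataclass
class WgsVariantSet:
    """All called variants of one whole-genome-sequenced sample."""

    sample_id: str
    group: str                     # "control" or "edited"
    records: list[VariantRecord]
    mean_depth: float = 60.0
    truth: dict[tuple, dict] = field(default_factory=dict)  # key -> {"origin","expect_pass"}

    def __post_init__(self):
        if self.group not in ("control", "edited"):
            raise ValueError("group must be 'control' or 'edited'")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")
        self.records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))


@dataclass
class IntervalTrack:
    """A labelled set of masked genomic intervals (0-based half-open)."""

    label: str                     # "blacklist" or "repeats"
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
        self.intervals.sort()

    def total_span(self) -> int:
        return sum(e - s for _, s, e in self.intervals)
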