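"""Packaged 32-founder reference cohort (synthetic reconstruction).

The original study's founder allele sequences exist only as a figure; this
module encodes a synthetic reconstruction of the cohort constrained by every
number the text reports: 3 founders mutated only at site C, 6 only at site
E, 15 at both, 8 unmutated; homozygous founders 166/169/175/186 at both
sites plus one more per site (F883 at C); 9 of the 15 co-targeted founders
with the two edits in cis; five founders carrying 2-11 bp deletions at site
E and one a 93 bp deletion at site C; and no founder lacking the inter-site
sequence. It is a stand-in for the deposited data, not a transcription of
real alleles.

The fixture stores per-allele outcome labels; allele sequences are rebuilt
deterministically on any toy reference, so the genotyping pipeline can be
exercised end to end.
"""

from __future__ import annotations

from typing import Optional

from .linkage import PhaseCall, phase_from_alleles
from .synthetic_data import build_allele, make_reference
from .types import FounderGenome, ToyGenome

FIXTURE_NAME = "founder_fixture_synthetic"

#: (founder_id, allele, site_id, outcome, detail) — sites absent from an
#: allele's rows are wild type. Indel details are ("del", length).
_ROWS: list[tuple[str, str, str, str, Optional[tuple]]] = [
    # -- both sites, homozygous at both (cis by construction) --------------
    *[(fid, al, sid, "intended", None)
      for fid in ("166", "169", "175", "186")
      for al in ("a", "b") for sid in ("C", "E")],
    # -- both sites, cis, second allele carries the 93 bp site-C deletion --
    ("183", "a", "C", "intended", None), ("183", "a", "E", "intended", None),
    ("183", "b", "C", "indel", ("del", 93)),
    # -- both sites, cis, second allele carries a small site-E deletion ----
    ("170", "a", "C", "intended", None), ("170", "a", "E", "intended", None),
    ("170", "b", "E", "indel", ("del", 2)),
    ("171", "a", "C", "intended", None), ("171", "a", "E", "intended", None),
    ("171", "b", "E", "indel", ("del", 4)),
    ("176", "a", "C", "intended", None), ("176", "a", "E", "intended", None),
    ("176", "b", "E", "indel", ("del", 6)),
    ("188", "a", "C", "intended", None), ("188", "a", "E", "intended", None),
    ("188", "b", "E", "indel", ("del", 11)),
    # -- both sites, trans -------------------------------------------------
    *[(fid, "a", "C", "intended", None) for fid in
      ("172", "173", "177", "179", "181", "185")],
    *[(fid, "b", "E", "intended", None) for fid in
      ("172", "173", "177", "179", "181", "185")],
    # -- site C only -------------------------------------------------------
    ("883", "a", "C", "intended", None), ("883", "b", "C", "intended", None),
    ("901", "a", "C", "intended", None),
    ("902", "b", "C", "intended", None),
    # -- site E only -------------------------------------------------------
    ("910", "a", "E", "intended", None), ("910", "b", "E", "intended", None),
    ("911", "a", "E", "intended", None),
    ("912", "b", "E", "intended", None),
    ("913", "a", "E", "intended", None),
    ("915", "b", "E", "intended", None),
    ("914", "a", "E", "intended", None), ("914", "b", "E", "indel", ("del", 9)),
    # -- no mutation -------------------------------------------------------
    # founders 920-927 carry reference alleles only (no rows)
]

_WT_FOUNDERS = [str(i) for i in range(920, 928)]


def fixture_founder_ids() -> list[str]:
    ids = []
    for fid, *_ in _ROWS:
        if fid not in ids:
            ids.append(fid)
    return ids + _WT_FOUNDERS


def fixture_outcomes() -> dict[str, dict[str, list[tuple[str, str, Optional[tuple]]]]]:
    """founder_id -> allele -> list of (site_id, outcome, detail)."""
    out: dict[str, dict[str, list]] = {
        fid: {"a": [], "b": []} for fid in fixture_founder_ids()
    }
    for fid, allele, sid, outcome, detail in _ROWS:
        out[fid][allele].append((sid, outcome, detail))
    return out


def build_fixture_cohort(
    genome: Optional[ToyGenome] = None, seed: int = 0
) -> tuple[ToyGenome, list[FounderGenome]]:
    """Materialize the 32 founders as diploid sequences on a toy reference."""
    if genome is None:
        genome = make_reference(seed=seed)
    founders = []
    for fid, alleles in fixture_outcomes().items():
        seqs, truths = {}, {}
        for al in ("a", "b"):
            seqs[al], truths[al] = build_allele(genome, alleles[al], rng=None)
        founders.append(FounderGenome(fid, seqs["a"], seqs["b"], truths))
    return genome, founders


def fixture_phase_calls(founders: list[FounderGenome]) -> list[PhaseCall]:
    """Allele-truth phase calls for the co-targeted fixture founders."""
    return [phase_from_alleles(f) for f in founders]


def fixture_tsv() -> str:
    """The fixture as a TSV string (founder, allele, site, outcome, detail)."""
    lines = ["founder_id\tallele\tsite\toutcome\tdetail"]
    for fid, allele, sid, outcome, detail in _ROWS:
        d = "" if detail is None else f"{detail[0]}:{detail[1]}"
        lines.append(f"{fid}\t{allele}\t{sid}\t{outcome}\t{d}")
    for fid in _WT_FOUNDERS:
        lines.append(f"{fid}\t.\t.\tWT\t")
    return "\n".join(lines) + "\n"
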