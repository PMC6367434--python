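"""Readers and writers for the standard formats at the package boundary.

FASTA (plain text, 60-column wrap; read back with pyfaidx), BED3 interval
tracks, VCF v4.2 per-sample variant sets (written and read with pysam),
founder-report / phase-call / segregation TSVs (pandas) and target-site
YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import pysam
import yaml

from .genotyping import EditCall, FounderReport
from .linkage import PhaseCall, SegregationTable
from .types import IntervalTrack, TargetSite, ToyGenome, VariantRecord, WgsVariantSet

# ---------------------------------------------------------------------------
# FASTA / BED
# ---------------------------------------------------------------------------


def write_fasta(path, records: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    import pyfaidx

    with pyfaidx.Fasta(str(path), as_raw=True, rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_bed(path, track: IntervalTrack) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path, label: str = "blacklist") -> IntervalTrack:
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            intervals.append((chrom, int(start), int(end)))
    return IntervalTrack(label, intervals)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_INFO_FIELDS = [
    ("QD", "Float", "Quality by depth"),
    ("FS", "Float", "Fisher strand bias"),
    ("MQ", "Float", "RMS mapping quality"),
    ("MQRankSum", "Float", "Mapping-quality rank-sum"),
    ("ReadPosRankSum", "Float", "Read-position rank-sum"),
    ("SOR", "Float", "Strand odds ratio"),
    ("KIND", "String", "Variant channel: snp/simple_indel/complex_indel"),
]

_ANN_ATTRS = {
    "QD": "qd", "FS": "fs", "MQ": "mq", "MQRankSum": "mq_rank_sum",
    "ReadPosRankSum": "read_pos_rank_sum", "SOR": "sor",
}


def write_vcf(path, varset: WgsVariantSet, contigs: dict[str, int]) -> None:
    """Write one sample's variant set as VCF v4.2."""
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    for name, typ, desc in _INFO_FIELDS:
        header.info.add(name, 1, typ, desc)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.add_sample(varset.sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in varset.records:
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref, r.alt), qual=round(r.qual, 2),
            )
            rec.info["KIND"] = r.kind
            for key, attr in _ANN_ATTRS.items():
                val = getattr(r, attr)
                if val is not None:
                    rec.info[key] = round(val, 3)
            sample = rec.samples[varset.sample_id]
            if r.gt == "./.":
                sample["GT"] = (None, None)
            else:
                sample["GT"] = tuple(int(x) for x in r.gt.split("/"))
            sample["DP"] = r.dp
            sample["AD"] = list(r.ad)
            vcf.write(rec)


def read_vcf(path, group: str = "edited", mean_depth: float = 60.0) -> WgsVariantSet:
    """Read a single-sample VCF back into a WgsVariantSet."""
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_id = list(vcf.header.samples)[0]
        for rec in vcf:
            sample = rec.samples[sample_id]
            gt_tuple = sample.get("GT")
            if gt_tuple is None or any(g is None for g in gt_tuple):
                gt = "./."
            else:
                gt = f"{gt_tuple[0]}/{gt_tuple[1]}"
            ad = sample.get("AD") or (0, 0)
            info = rec.info
            kind = info.get("KIND", "snp")
            ref, alt = rec.ref, rec.alts[0]
            if kind is None or kind == "snp":
                kind = "snp" if len(ref) == len(alt) == 1 else "simple_indel"

            def _opt(key):
                val = info.get(key)
                return None if val is None else float(val)

            records.append(VariantRecord(
                chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt, kind=str(kind),
                gt=gt, dp=int(sample.get("DP") or 0),
                ad=(int(ad[0]), int(ad[1])), qual=float(rec.qual or 0.0),
                qd=_opt("QD"), fs=_opt("FS"), mq=_opt("MQ"),
                mq_rank_sum=_opt("MQRankSum"),
                read_pos_rank_sum=_opt("ReadPosRankSum"), sor=_opt("SOR"),
            ))
    return WgsVariantSet(sample_id, group, records, mean_depth=mean_depth)


# ---------------------------------------------------------------------------
# Reports / tables
# ---------------------------------------------------------------------------


def founder_reports_to_frame(reports: Sequence[FounderReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"founder_id": r.founder_id, "classification": r.classification}
        for sid, sg in r.sites.items():
            row[f"category_{sid}"] = sg.category
            row[f"zygosity_{sid}"] = sg.zygosity
            row[f"mutated_{sid}"] = sg.mutated
        rows.append(row)
    return pd.DataFrame(rows)


def write_founder_reports(path, reports: Sequence[FounderReport]) -> None:
    founder_reports_to_frame(reports).to_csv(path, sep="\t", index=False)


def write_edit_calls_jsonl(path, reports: Sequence[FounderReport]) -> None:
    """Per-allele EditCall JSON-lines file."""
    with open(path, "w") as fh:
        for r in reports:
            for sid, sg in r.sites.items():
                for allele, call in zip("ab", sg.allele_calls):
                    fh.write(json.dumps({
                        "founder_id": r.founder_id, "site_id": sid, "allele": allele,
                        "substitutions": call.substitutions, "indels": call.indels,
                        "large_deletion": call.large_deletion,
                    }) + "\n")


def write_phase_calls(path, calls: Sequence[PhaseCall]) -> None:
    pd.DataFrame([
        {"founder_id": c.founder_id, "phase": c.phase,
         "co": c.support.get("co", 0), "separate": c.support.get("separate", 0),
         "reason": c.reason}
        for c in calls
    ]).to_csv(path, sep="\t", index=False)


def read_segregation_tables(path) -> list[SegregationTable]:
    """TSV with columns founder_id, offspring_id, siteC, siteE."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    tables = []
    for fid, sub in df.groupby("founder_id", sort=True):
        tables.append(SegregationTable(
            founder_id=str(fid),
            offspring=[(row.offspring_id, row.siteC, row.siteE)
                       for row in sub.itertuples()],
        ))
    return tables


def write_segregation_table(path, table: SegregationTable) -> None:
    pd.DataFrame(
        [{"founder_id": table.founder_id, "offspring_id": oid,
          "siteC": g1, "siteE": g2} for oid, g1, g2 in table.offspring]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Target-site YAML
# ---------------------------------------------------------------------------


def write_sites_yaml(path, genome: ToyGenome) -> None:
    data = {
        "genome": genome.name,
        "length": len(genome.sequence),
        "sites": [
            {
                "site_id": s.site_id, "protospacer": s.protospacer, "pam": s.pam,
                "strand": s.strand, "start": s.start,
                "editing_window": list(s.editing_window), "motif": s.motif,
                "target_base_offsets": list(s.target_base_offsets),
            }
            for s in genome.sites
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_sites_yaml(path) -> list[TargetSite]:
    data = yaml.safe_load(Path(path).read_text())
    return [
        TargetSite(
            site_id=d["site_id"], protospacer=d["protospacer"], pam=d["pam"],
            strand=d["strand"], start=int(d["start"]),
            editing_window=tuple(d["editing_window"]), motif=d.get("motif", ""),
            target_base_offsets=tuple(d.get("target_base_offsets", ())),
        )
        for d in data["sites"]
    ]
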