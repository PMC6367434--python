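"""Independent brute-force oracles used by the filter and scan tests.

These deliberately re-derive results with flat, single-pass logic (explicit
per-record boolean conditions, quadratic interval scans, character-level
sequence comparison) so they share no code path with the implementation.
"""

import math

from linkededit.dna import IUPAC, revcomp


# ---------------------------------------------------------------------------
# Cascade oracle
# ---------------------------------------------------------------------------

def _masked(record, tracks):
    s, e = record.pos - 1, record.pos - 1 + len(record.ref)
    for track in tracks:
        for chrom, a, b in track.intervals:
            if chrom == record.chrom and s < b and a < e:
                return True
    return False


def _snp_hard_ok(r, cfg):
    if r.qd is not None and r.qd < cfg.snp_qd_min:
        return False
    if r.fs is not None and r.fs > cfg.snp_fs_max:
        return False
    if r.mq is not None and r.mq < cfg.snp_mq_min:
        return False
    if r.mq_rank_sum is not None and r.mq_rank_sum < cfg.snp_mq_rank_sum_min:
        return False
    if r.read_pos_rank_sum is not None and \
            r.read_pos_rank_sum < cfg.snp_read_pos_rank_sum_min:
        return False
    if r.sor is not None and r.sor > cfg.snp_sor_max:
        return False
    return True


def _indel_hard_ok(r, cfg):
    if r.qd is not None and r.qd < cfg.indel_qd_min:
        return False
    if r.fs is not None and r.fs > cfg.indel_fs_max:
        return False
    if r.read_pos_rank_sum is not None and \
            r.read_pos_rank_sum < cfg.indel_read_pos_rank_sum_min:
        return False
    if r.sor is not None and r.sor > cfg.indel_sor_max:
        return False
    return True


def cascade_oracle(edited_sets, control_sets, tracks, sites, cfg):
    """(survivor key sets per sample/channel, candidate (sample, key) set)."""
    control_keys = {r.key for cs in control_sets for r in cs.records}
    survivors = {}
    candidates = set()
    for sample in edited_sets:
        d = sample.mean_depth
        ceiling = d + cfg.excess_depth_sigma * math.sqrt(d)

        def gt_dp_ok(r, with_min=True):
            if r.gt not in ("0/1", "1/1"):
                return False
            if with_min and r.dp < cfg.dp_min:
                return False
            return r.dp <= ceiling

        cx = [r for r in sample.records if r.kind == "complex_indel"
              and r.gt in ("0/1", "1/1") and r.qual >= cfg.complex_indel_qual_min
              and r.dp <= ceiling and not _masked(r, tracks)]

        simple = []
        for r in sample.records:
            if r.kind != "simple_indel":
                continue
            if not _indel_hard_ok(r, cfg) or _masked(r, tracks) or not gt_dp_ok(r):
                continue
            s, e = r.pos - 1, r.pos - 1 + len(r.ref)
            if any(c.chrom == r.chrom and s < c.pos - 1 + len(c.ref) and c.pos - 1 < e
                   for c in cx):
                continue
            simple.append(r)

        snps = []
        for r in sample.records:
            if r.kind != "snp":
                continue
            if not _snp_hard_ok(r, cfg) or _masked(r, tracks) or not gt_dp_ok(r):
                continue
            total = r.ad[0] + r.ad[1]
            if total == 0 or r.ad[1] / total < cfg.af_min:
                continue
            if r.qual < cfg.snp_qual_min:
                continue
            pos0 = r.pos - 1
            near_indel = any(
                i.chrom == r.chrom
                and i.pos - 1 - cfg.indel_border_bp <= pos0
                <= i.pos - 1 + len(i.ref) - 1 + cfg.indel_border_bp
                for i in list(simple) + list(cx)
            )
            if near_indel:
                continue
            snps.append(r)

        per_channel = {}
        for name, recs in (("snp", snps), ("simple", simple), ("complex", cx)):
            per_channel[name] = {r.key for r in recs if r.key not in control_keys}
        survivors[sample.sample_id] = per_channel

        for name, keys in per_channel.items():
            for r in sample.records:
                if r.key not in keys:
                    continue
                s, e = r.pos - 1, r.pos - 1 + len(r.ref)
                if any(st.chrom == r.chrom and s < st.end and st.start < e
                       for st in sites):
                    candidates.add((sample.sample_id, r.key))
    return survivors, candidates


# ---------------------------------------------------------------------------
# Mismatch-scan oracle
# ---------------------------------------------------------------------------

def naive_offtarget_scan(sequence, guide_protospacer, pam_pattern, max_mm):
    """Exhaustive per-position scan; returns {(start, strand, n_mm)} on plus coords."""
    hits = set()
    L = len(sequence)
    npam = len(pam_pattern)
    for i in range(L - 20 - npam + 1):
        proto = sequence[i : i + 20]
        pam = sequence[i + 20 : i + 20 + npam]
        if all(b in IUPAC[p] for p, b in zip(pam_pattern, pam)):
            mm = sum(a != b for a, b in zip(proto, guide_protospacer))
            if mm <= max_mm:
                hits.add((i, "+", mm))
    for j in range(npam, L - 20 + 1):
        # minus-strand window: protospacer on [j, j+20), PAM on [j-npam, j)
        proto = revcomp(sequence[j : j + 20])
        pam = revcomp(sequence[j - npam : j])
        if all(b in IUPAC[p] for p, b in zip(pam_pattern, pam)):
            mm = sum(a != b for a, b in zip(proto, guide_protospacer))
            if mm <= max_mm:
                hits.add((j, "-", mm))
    return hits
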