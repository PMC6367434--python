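"""Filter-cascade tests: boundaries, oracles, monotonicity/idempotence, scan."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import cascade_oracle, naive_offtarget_scan
from linkededit.dna import random_sequence
from linkededit.offtarget_filter import (
    DEFAULT_CONFIG,
    FilterConfig,
    OffTargetSite,
    af_qual_filter,
    find_offtarget_sites,
    genotype_depth_filter,
    hard_filter_indels,
    hard_filter_snps,
    indel_proximity_filter,
    population_subtract,
    region_filter,
    run_cascade,
    simple_complex_overlap_filter,
)
from linkededit.synthetic_data import (
    WgsCohortSpec,
    emit_tracks,
    make_reference,
    plant_offtarget_sites,
    simulate_wgs_variants,
)
from linkededit.types import IntervalTrack, TargetSite, ToyGenome, VariantRecord


def rec(kind="snp", pos=1000, **kw):
    defaults = dict(
        chrom="chrT", ref="A", alt="T", gt="0/1", dp=60, ad=(30, 30), qual=500.0,
        qd=20.0, fs=1.0, mq=60.0, mq_rank_sum=0.0, read_pos_rank_sum=0.0, sor=1.0,
    )
    if kind != "snp":
        defaults["ref"] = "ATTTT"
    defaults.update(kw)
    return VariantRecord(pos=pos, kind=kind, **defaults)


class TestBoundaries:
    """The Methods phrase removals with strict inequalities: boundaries are kept."""

    def test_qd_below_2_removed_at_2_kept(self):
        assert hard_filter_snps([rec(qd=1.9)]) == []
        assert len(hard_filter_snps([rec(qd=2.0)])) == 1

    def test_indel_fs_at_200_kept_sor_above_10_removed(self):
        assert len(hard_filter_indels([rec("simple_indel", fs=200.0)])) == 1
        assert hard_filter_indels([rec("simple_indel", sor=10.1)]) == []

    def test_dp_10_kept_dp_9_removed(self):
        assert len(genotype_depth_filter([rec(dp=10, ad=(5, 5))], 60.0)) == 1
        assert genotype_depth_filter([rec(dp=9, ad=(4, 5))], 60.0) == []

    def test_excess_depth_ceiling_at_d60_is_83_23(self):
        ceiling = DEFAULT_CONFIG.depth_ceiling(60.0)
        assert ceiling == pytest.approx(60 + 3 * math.sqrt(60))
        assert len(genotype_depth_filter([rec(dp=83)], 60.0)) == 1
        assert genotype_depth_filter([rec(dp=84)], 60.0) == []

    def test_hom_ref_and_nocall_genotypes_removed(self):
        assert genotype_depth_filter([rec(gt="0/0"), rec(gt="./.")], 60.0) == []

    def test_af_exactly_10_percent_kept_below_removed(self):
        assert len(af_qual_filter([rec(ad=(90, 10))], "snp")) == 1
        assert af_qual_filter([rec(ad=(91, 9))], "snp") == []

    def test_snp_qual_130_kept_129_9_removed(self):
        assert len(af_qual_filter([rec(qual=130.0)], "snp")) == 1
        assert af_qual_filter([rec(qual=129.9)], "snp") == []

    def test_complex_qual_100_kept_simple_unfiltered(self):
        assert len(af_qual_filter([rec("complex_indel", qual=100.0)], "complex_indel")) == 1
        assert af_qual_filter([rec("complex_indel", qual=99.9)], "complex_indel") == []
        assert len(af_qual_filter([rec("simple_indel", qual=5.0)], "simple_indel")) == 1

    def test_snp_5bp_from_indel_border_removed_6bp_kept(self):
        indel = rec("simple_indel", pos=1000, ref="ATTTT", alt="A")  # span 999..1004
        # borders at 999 and 1003 (0-based); +/-5 inclusive
        snp_at_5 = rec(pos=1009)    # 0-based 1008 == 1003 + 5 -> removed
        snp_at_6 = rec(pos=1010)    # 1009 == 1003 + 6 -> kept
        assert indel_proximity_filter([snp_at_5], [indel]) == []
        assert len(indel_proximity_filter([snp_at_6], [indel])) == 1

    def test_missing_annotation_never_fires_a_clause(self):
        assert len(hard_filter_snps([rec(mq_rank_sum=None, sor=None)])) == 1
        strict = FilterConfig(strict_missing=True)
        assert hard_filter_snps([rec(mq_rank_sum=None)], strict) == []

    def test_region_filter_half_open_edge(self):
        track = IntervalTrack("blacklist", [("chrT", 500, 999)])
        # SNP at 1-based 1000 occupies [999, 1000): just outside the interval
        assert len(region_filter([rec(pos=1000)], [track])) == 1
        assert region_filter([rec(pos=999)], [track]) == []

    def test_one_bp_overlap_removes_simple_indel(self):
        cx = rec("complex_indel", pos=1004, ref="A" * 40, alt="A")
        assert simple_complex_overlap_filter([rec("simple_indel", pos=1000)], [cx]) == []
        far = rec("simple_indel", pos=100)
        assert len(simple_complex_overlap_filter([far], [cx])) == 1


# ---------------------------------------------------------------------------
# Randomized clause-by-clause oracles
# ---------------------------------------------------------------------------

def _random_records(rng, n=1000):
    out = []
    for i in range(n):
        kind = ["snp", "simple_indel", "complex_indel"][int(rng.integers(3))]
        reflen = 1 if kind == "snp" else int(rng.integers(1, 40)) + 1
        ad_alt = int(rng.integers(0, 80))
        ad_ref = int(rng.integers(0, 80))

        def maybe(x):
            return None if rng.random() < 0.1 else float(x)

        out.append(VariantRecord(
            chrom="chrT", pos=int(rng.integers(1, 50_000)), ref="A" * reflen,
            alt="T", kind=kind,
            gt=["0/0", "0/1", "1/1", "./."][int(rng.integers(4))],
            dp=int(rng.integers(0, 120)), ad=(ad_ref, ad_alt),
            qual=float(rng.uniform(0, 400)),
            qd=maybe(rng.uniform(0, 40)), fs=maybe(rng.uniform(0, 300)),
            mq=maybe(rng.uniform(0, 70)), mq_rank_sum=maybe(rng.uniform(-20, 5)),
            read_pos_rank_sum=maybe(rng.uniform(-30, 6)),
            sor=maybe(rng.uniform(0, 15)),
        ))
    return out


def test_hard_filters_match_clause_oracle():
    from oracles import _indel_hard_ok, _snp_hard_ok

    rng = np.random.default_rng(11)
    records = _random_records(rng)
    cfg = DEFAULT_CONFIG
    assert hard_filter_snps(records, cfg) == [r for r in records if _snp_hard_ok(r, cfg)]
    assert hard_filter_indels(records, cfg) == \
        [r for r in records if _indel_hard_ok(r, cfg)]


def test_region_filter_matches_quadratic_oracle():
    from oracles import _masked

    rng = np.random.default_rng(13)
    records = _random_records(rng, 400)
    intervals = [("chrT", int(a), int(a) + int(rng.integers(1, 500)))
                 for a in rng.integers(0, 50_000, size=40)]
    tracks = [IntervalTrack("blacklist", intervals[:20]),
              IntervalTrack("repeats", intervals[20:])]
    assert region_filter(records, tracks) == \
        [r for r in records if not _masked(r, tracks)]


def test_population_subtract_removes_any_control_hit(genome):
    spec = WgsCohortSpec(n_controls=4, n_edited=1, shared_snp_rate=3e-4)
    sets = simulate_wgs_variants(genome, spec, 60.0, seed=21)
    controls = [s for s in sets if s.group == "control"]
    edited = next(s for s in sets if s.group == "edited")
    surv = population_subtract(edited.records, controls)
    surv_keys = {r.key for r in surv}
    for r in edited.records:
        origin = edited.truth[r.key]["origin"]
        assert (r.key in surv_keys) == (origin != "shared")
    # a variant carried by a single control is still subtracted
    one = controls[0].records[0]
    assert population_subtract([one], controls[:1]) == []


# ---------------------------------------------------------------------------
# Monotonicity / idempotence properties
# ---------------------------------------------------------------------------

annot = st.one_of(st.none(), st.floats(-50, 400, allow_nan=False))
record_strategy = st.builds(
    VariantRecord,
    chrom=st.just("chrT"),
    pos=st.integers(1, 10_000),
    ref=st.sampled_from(["A", "AT", "ATTTT"]),
    alt=st.just("G"),
    kind=st.sampled_from(["snp", "simple_indel", "complex_indel"]),
    gt=st.sampled_from(["0/0", "0/1", "1/1", "./."]),
    dp=st.integers(0, 150),
    ad=st.tuples(st.integers(0, 80), st.integers(0, 80)),
    qual=st.floats(0, 2000, allow_nan=False),
    qd=annot, fs=annot, mq=annot, mq_rank_sum=annot,
    read_pos_rank_sum=annot, sor=annot,
)

_STAGES = [
    lambda rs: hard_filter_snps(rs),
    lambda rs: hard_filter_indels(rs),
    lambda rs: genotype_depth_filter(rs, 60.0),
    lambda rs: af_qual_filter(rs, "snp"),
    lambda rs: region_filter(rs, [IntervalTrack("blacklist", [("chrT", 100, 5000)])]),
]


@settings(max_examples=60, derandomize=True)
@given(st.lists(record_strategy, max_size=40), st.integers(0, len(_STAGES) - 1))
def test_stages_are_monotone_and_idempotent(records, stage_idx):
    stage = _STAGES[stage_idx]
    once = stage(records)
    assert set(id(r) for r in once) <= set(id(r) for r in records)
    assert stage(once) == once


# ---------------------------------------------------------------------------
# Off-target scan
# ---------------------------------------------------------------------------

def _toy_guide(protospacer, pam="NGG"):
    return TargetSite("g", protospacer, pam, "+", 0, motif="",
                      target_base_offsets=())


def test_scan_finds_own_on_target_with_zero_mismatches(genome):
    for guide in genome.sites:
        sites = find_offtarget_sites(genome, guide, max_mm=0)
        assert any(s.start == guide.start and s.n_mismatches == 0 for s in sites)


def test_scan_finds_planted_three_mismatch_site(genome):
    g = plant_offtarget_sites(genome, genome.site("C"), [25_000], 3, seed=3)
    sites = find_offtarget_sites(g, g.site("C"), max_mm=4)
    assert any(s.start == 25_000 and s.n_mismatches == 3 for s in sites)


def test_scan_matches_naive_oracle_on_random_genomes():
    rng = np.random.default_rng(17)
    for trial in range(6):
        seq = random_sequence(5_000, rng)
        genome = ToyGenome("toy", seq)
        guide = _toy_guide(random_sequence(20, rng),
                           pam="NGA" if trial % 2 else "NGG")
        got = {(s.start, s.strand, s.n_mismatches)
               for s in find_offtarget_sites(genome, guide, max_mm=4)}
        assert got == naive_offtarget_scan(seq, guide.protospacer, guide.pam, 4)


def test_scan_respects_region_tracks():
    rng = np.random.default_rng(19)
    seq = random_sequence(3_000, rng)
    guide = _toy_guide(seq[1_000:1_020], pam="NNN")
    genome = ToyGenome("toy", seq)
    unmasked = find_offtarget_sites(genome, guide, max_mm=0)
    assert any(s.start == 1_000 for s in unmasked)
    masked = find_offtarget_sites(
        genome, guide, max_mm=0,
        tracks=[IntervalTrack("blacklist", [("toy", 990, 1_030)])],
    )
    assert all(s.start != 1_000 for s in masked)


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def _cascade_inputs(seed, with_spikes=True):
    genome = make_reference(length=60_000, seed=seed)
    genome = plant_offtarget_sites(genome, genome.sites[0], [12_000, 48_000], 3,
                                   seed=seed)
    tracks = list(emit_tracks(genome, 0.15, seed=seed))
    sites = []
    for guide in genome.sites:
        sites.extend(find_offtarget_sites(genome, guide, 4, tracks=tracks))
    spans = [(s.start - 10, s.end + 10) for s in sites]
    spikes = []
    if with_spikes:
        for s in sites:
            if s.n_mismatches > 0:
                for i in range(s.start, s.end):
                    if genome.sequence[i] in "CG":
                        spikes.append((i, "C->T"))
                        break
    spec = WgsCohortSpec(n_controls=30, n_edited=2, shared_snp_rate=6e-4,
                         private_rate=2e-4, spiked_offtargets=spikes,
                         exclude_spans=spans)
    sets = simulate_wgs_variants(genome, spec, 60.0, seed=seed)
    edited = [s for s in sets if s.group == "edited"]
    controls = [s for s in sets if s.group == "control"]
    return genome, tracks, sites, edited, controls, spikes


def test_cascade_matches_brute_force_oracle_over_seeds():
    for seed in range(8):
        _, tracks, sites, edited, controls, _ = _cascade_inputs(seed)
        report = run_cascade(edited, controls, tracks, sites)
        oracle_surv, oracle_cand = cascade_oracle(
            edited, controls, tracks, sites, DEFAULT_CONFIG)
        got_surv = {
            sid: {ch: {r.key for r in recs} for ch, recs in chans.items()}
            for sid, chans in report.survivors.items()
        }
        assert got_surv == oracle_surv
        assert {(sid, r.key) for sid, r in report.candidates} == oracle_cand


def test_cascade_ledger_telescopes():
    _, tracks, sites, edited, controls, _ = _cascade_inputs(3)
    report = run_cascade(edited, controls, tracks, sites)
    for s in report.stages:
        assert s.n_in - s.n_removed == s.n_out
    # within each sample/channel, consecutive stages chain
    from itertools import groupby

    keyf = lambda s: (s.sample_id, s.channel)
    for _, group in groupby(report.stages, keyf):
        group = list(group)
        for a, b in zip(group, group[1:]):
            assert a.n_out == b.n_in


def test_no_spikes_yields_empty_candidates():
    _, tracks, sites, edited, controls, _ = _cascade_inputs(5, with_spikes=False)
    report = run_cascade(edited, controls, tracks, sites)
    assert report.candidates == []


def test_all_passing_spikes_recovered():
    _, tracks, sites, edited, controls, spikes = _cascade_inputs(7)
    assert spikes
    report = run_cascade(edited, controls, tracks, sites)
    got = {(sid, r.pos - 1) for sid, r in report.candidates}
    for sample in edited:
        for pos, _ in spikes:
            assert (sample.sample_id, pos) in got


def test_control_order_invariance():
    _, tracks, sites, edited, controls, _ = _cascade_inputs(2)
    a = run_cascade(edited, controls, tracks, sites)
    b = run_cascade(edited, list(reversed(controls)), tracks, sites)
    assert [(s, r.key) for s, r in a.candidates] == [(s, r.key) for s, r in b.candidates]
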