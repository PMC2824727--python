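import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bacomap.rearrange import canonical_equal
from bacomap.simulate import (
    AncestralGenome,
    DerivedGenome,
    RearrangementEvent,
    SimConfig,
    apply_events,
    emit_alignments,
    emit_bes_fasta,
    emit_marker_table,
    make_ancestor,
    sample_clones,
    simulate_screening,
)


def one_chrom_config(length=90_000_000, spacing=30_000_000, **kw):
    return SimConfig(n_chromosomes=1, chrom_lengths=(length,),
                     marker_spacing=spacing, **kw)


class TestSimConfig:
    def test_defaults_anchor_study_values(self):
        c = SimConfig()
        assert c.insert_mean == 139_000
        assert (c.insert_min, c.insert_max) == (100_000, 200_000)
        assert c.read_len_mean == 728
        assert c.gc == pytest.approx(0.418)
        assert c.marker_spacing == 30_000_000

    def test_invalid_insert_window(self):
        with pytest.raises(ValueError):
            SimConfig(insert_min=150_000, insert_mean=139_000)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            SimConfig(gc=1.2)

    def test_lengths_must_match_count(self):
        with pytest.raises(ValueError):
            SimConfig(n_chromosomes=2, chrom_lengths=(1_000_000,))


class TestMakeAncestor:
    def test_grid_construction(self):
        anc = make_ancestor(one_chrom_config())
        assert anc.n_markers == 3
        pos = [p for _, p in anc.chromosomes[0]]
        assert pos == sorted(pos)
        assert all(0 <= p < 90_000_000 for p in pos)

    def test_zero_markers(self):
        anc = make_ancestor(one_chrom_config(n_markers=0))
        assert anc.n_markers == 0

    def test_deterministic(self):
        c = one_chrom_config(seed=99)
        assert make_ancestor(c).chromosomes == make_ancestor(c).chromosomes

    def test_sizing_error(self):
        with pytest.raises(ValueError):
            make_ancestor(SimConfig(n_chromosomes=1, chrom_lengths=(10,),
                                    n_markers=100, insert_min=1,
                                    insert_mean=2, insert_max=3))

    def test_unique_ids_enforced(self):
        with pytest.raises(ValueError, match="duplicate"):
            AncestralGenome([[("M1", 5), ("M1", 10)]], (100,))


class TestApplyEvents:
    def test_k_zero_identity(self, small_sim_config):
        anc = make_ancestor(small_sim_config)
        derived, log = apply_events(anc, k=0, seed=1)
        assert derived == DerivedGenome(anc)
        assert log.events == []

    def test_single_marker_inversion_flips_sign(self):
        anc = make_ancestor(one_chrom_config())
        # invert the middle marker only: cut at the two inter-marker midpoints
        pos = [p for _, p in anc.chromosomes[0]]
        b1 = (pos[0] + pos[1]) // 2
        b2 = (pos[1] + pos[2]) // 2
        ev = RearrangementEvent("inversion", (0,), (b1, b2))
        derived, _ = apply_events(anc, events=[ev])
        q, t, _names = derived.to_signed_genome()
        assert q.chromosomes == ((1, -2, 3),)
        assert t.chromosomes == ((1, 2, 3),)

    def test_fusion_decreases_chromosome_count(self):
        cfg = SimConfig(n_chromosomes=2, chrom_lengths=(60_000_000,) * 2)
        anc = make_ancestor(cfg)
        ev = RearrangementEvent("fusion", (0, 1), (), (0, 0))
        derived, _ = apply_events(anc, events=[ev])
        assert len(derived.chromosomes) == 1
        q, t, _ = derived.to_signed_genome()
        assert canonical_equal(q, type(q)([(1, 2, 3, 4)]))

    def test_fission_increases_chromosome_count(self):
        anc = make_ancestor(one_chrom_config())
        derived, log = apply_events(anc, k=1, seed=3,
                                    kind_weights={"fission": 1})
        assert len(derived.chromosomes) == 2
        assert log.events[0].kind == "fission"

    def test_illegal_event_exhausts_retries(self):
        cfg = one_chrom_config(length=40_000_000)  # one marker only
        anc = make_ancestor(cfg)
        with pytest.raises(RuntimeError, match="retries"):
            apply_events(anc, k=1, seed=0, kind_weights={"fission": 1})

    def test_replay_reproduces_derived_exactly(self, dense_sim_config):
        anc = make_ancestor(dense_sim_config)
        for seed in range(5):
            derived, log = apply_events(anc, k=4, seed=seed)
            replayed, _ = apply_events(anc, events=log.events)
            assert replayed == derived

    def test_marker_multiset_invariant(self, dense_sim_config):
        anc = make_ancestor(dense_sim_config)
        all_markers = {m for c in anc.chromosomes for m, _ in c}
        for seed in range(4):
            derived, _ = apply_events(anc, k=6, seed=seed)
            seen = {
                m for i in range(len(derived.chromosomes))
                for m, _, _ in derived.markers_on(i)
            }
            assert seen == all_markers


class TestSampleClones:
    def test_empirical_mean_matches_config(self, small_sim_config):
        cfg = SimConfig(**{**small_sim_config.__dict__, "n_clones": 10_000})
        derived = DerivedGenome(make_ancestor(cfg))
        clones = sample_clones(derived, cfg)
        lengths = np.array([c.insert_length for c in clones])
        se = lengths.std(ddof=1) / math.sqrt(len(lengths))
        assert abs(lengths.mean() - 139_000) < 2 * se
        assert lengths.min() >= 100_000 and lengths.max() <= 200_000

    def test_degenerate_insert_distribution(self, small_sim_config):
        cfg = SimConfig(**{**small_sim_config.__dict__,
                           "insert_min": 150_000, "insert_mean": 150_000,
                           "insert_max": 150_000})
        derived = DerivedGenome(make_ancestor(cfg))
        clones = sample_clones(derived, cfg)
        assert {c.insert_length for c in clones} == {150_000}

    def test_truth_bookkeeping_no_events(self, small_sim_config):
        derived = DerivedGenome(make_ancestor(small_sim_config))
        clones = sample_clones(derived, small_sim_config)
        assert not any(c.spans_breakpoint for c in clones)

    def test_precondition_short_chromosome(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths=(150_000,))
        derived = DerivedGenome(make_ancestor(cfg))
        with pytest.raises(ValueError, match="insert_max"):
            sample_clones(derived, cfg)


class TestEmitAlignments:
    def test_noise_free_geometry(self, small_sim_config):
        derived = DerivedGenome(make_ancestor(small_sim_config))
        clones = sample_clones(derived, small_sim_config)
        aln, truth = emit_alignments(clones, derived, small_sim_config)
        assert len(aln) == 2 * len(clones)
        by_clone = aln.groupby(aln["qseqid"].str.rsplit("_", n=1).str[0])
        for cid, grp in by_clone:
            assert len(grp) == 2
            strands = {"+" if r.sstart <= r.send else "-"
                       for r in grp.itertuples()}
            assert strands == {"+", "-"}
            lo = min(min(r.sstart, r.send) for r in grp.itertuples())
            hi = max(max(r.sstart, r.send) for r in grp.itertuples())
            clone = next(c for c in clones if c.clone_id == cid)
            assert hi - lo + 1 == clone.insert_length

    def test_multimap_boundary(self, small_sim_config):
        cfg = SimConfig(**{**small_sim_config.__dict__, "p_multimap": 1.0})
        derived = DerivedGenome(make_ancestor(cfg))
        clones = sample_clones(derived, cfg)
        aln, _ = emit_alignments(clones, derived, cfg)
        assert (aln.groupby("qseqid").size() >= 2).all()

    def test_unmapped_boundary(self, small_sim_config):
        cfg = SimConfig(**{**small_sim_config.__dict__, "p_unmapped": 1.0})
        derived = DerivedGenome(make_ancestor(cfg))
        clones = sample_clones(derived, cfg)
        aln, truth = emit_alignments(clones, derived, cfg)
        assert aln.empty
        assert not truth["emitted"].any()

    def test_translocation_straddlers_split_chromosomes(self, dense_sim_config):
        # derived oracle: replay the event log, find breakpoint-straddling
        # clones, and confirm their ends are emitted on different ancestor
        # chromosomes
        cfg = SimConfig(**{**dense_sim_config.__dict__, "n_clones": 4000,
                           "chrom_lengths": (6_000_000,) * 5,
                           "marker_spacing": 500_000})
        anc = make_ancestor(cfg)
        derived, log = apply_events(anc, k=1, seed=2,
                                    kind_weights={"translocation": 1})
        clones = sample_clones(derived, cfg, log=log)
        junctions = {i: derived.junctions(i)
                     for i in range(len(derived.chromosomes))}
        # junction must clear both end reads, else one read is clipped to
        # the far block and the clone yields single-sided evidence
        rl = cfg.read_len_mean
        straddlers = [
            c for c in clones if c.spans_breakpoint
            and any(c.start + rl <= j <= c.end - rl
                    for j in junctions[c.chrom])
        ]
        assert straddlers, "expected some breakpoint-straddling clones"
        aln, truth = emit_alignments(clones, derived, cfg)
        t = truth.set_index("read_id")
        for c in straddlers:
            chroms = {t.loc[f"{c.clone_id}_{e}", "true_chrom"]
                      for e in ("T7", "SP6")}
            assert len(chroms) == 2


class TestEmitBesFasta:
    def test_gc_boundary(self, small_sim_config):
        cfg = SimConfig(**{**small_sim_config.__dict__, "gc": 1.0,
                           "n_clones": 5})
        derived = DerivedGenome(make_ancestor(cfg))
        clones = sample_clones(derived, cfg)
        fasta = emit_bes_fasta(clones, cfg)
        seq = "".join(l for l in fasta.splitlines() if not l.startswith(">"))
        assert set(seq) <= {"G", "C"}

    def test_gc_fraction_within_2se(self, small_sim_config):
        cfg = SimConfig(**{**small_sim_config.__dict__, "n_clones": 500})
        derived = DerivedGenome(make_ancestor(cfg))
        clones = sample_clones(derived, cfg)
        fasta = emit_bes_fasta(clones, cfg)
        seq = "".join(l for l in fasta.splitlines() if not l.startswith(">"))
        n = len(seq)
        gc = (seq.count("G") + seq.count("C")) / n
        se = math.sqrt(0.418 * (1 - 0.418) / n)
        assert abs(gc - 0.418) < 2 * se

    def test_read_length_within_2se(self, small_sim_config):
        cfg = SimConfig(**{**small_sim_config.__dict__, "n_clones": 500})
        derived = DerivedGenome(make_ancestor(cfg))
        clones = sample_clones(derived, cfg)
        fasta = emit_bes_fasta(clones, cfg)
        lengths = []
        cur = 0
        for line in fasta.splitlines():
            if line.startswith(">"):
                if cur:
                    lengths.append(cur)
                cur = 0
            else:
                cur += len(line)
        lengths.append(cur)
        arr = np.array(lengths)
        se = arr.std(ddof=1) / math.sqrt(len(arr))
        assert abs(arr.mean() - 728) < 2 * se

    def test_record_naming(self, small_sim_config):
        cfg = SimConfig(**{**small_sim_config.__dict__, "n_clones": 2})
        derived = DerivedGenome(make_ancestor(cfg))
        clones = sample_clones(derived, cfg)
        fasta = emit_bes_fasta(clones, cfg)
        headers = [l for l in fasta.splitlines() if l.startswith(">")]
        assert headers == [">C000001_T7", ">C000001_SP6",
                           ">C000002_T7", ">C000002_SP6"]


class TestSimulateScreening:
    def test_zero_depth(self):
        df = simulate_screening(10, 0.0, seed=0)
        assert (df["clone_id"] == "").all()
        assert df["probe_id"].nunique() == 10

    def test_negative_depth_error(self):
        with pytest.raises(ValueError):
            simulate_screening(10, -1.0)

    def test_mean_within_poisson_se(self):
        rng = np.random.default_rng(8)
        df = simulate_screening(54, 10.2, rng=rng)
        counts = df[df["clone_id"] != ""].groupby("probe_id").size()
        counts = counts.reindex(df["probe_id"].unique(), fill_value=0)
        assert abs(counts.mean() - 10.2) < 3 * math.sqrt(10.2 / 54)

    def test_variance_matches_mean(self):
        rng = np.random.default_rng(9)
        df = simulate_screening(5000, 6.0, rng=rng)
        counts = df[df["clone_id"] != ""].groupby("probe_id").size()
        counts = counts.reindex(df["probe_id"].unique(), fill_value=0)
        assert counts.var() == pytest.approx(counts.mean(), rel=0.1)


class TestEmitMarkerTable:
    def test_colinear_when_no_events(self, small_sim_config):
        derived = DerivedGenome(make_ancestor(small_sim_config))
        df = emit_marker_table(derived, small_sim_config)
        for _, grp in df.groupby("query_chrom"):
            pos = grp.sort_values("query_rank")["target_pos"].tolist()
            assert pos == sorted(pos)

    def test_inversion_breaks_monotonicity(self):
        cfg = one_chrom_config()
        anc = make_ancestor(cfg)
        pos = [p for _, p in anc.chromosomes[0]]
        ev = RearrangementEvent("inversion", (0,),
                                ((pos[0] + pos[1]) // 2, 90_000_000))
        derived, _ = apply_events(anc, events=[ev])
        df = emit_marker_table(derived, cfg)
        tp = df.sort_values("query_rank")["target_pos"].tolist()
        assert tp != sorted(tp)

    def test_floor_rule_one_marker_per_chromosome(self):
        cfg = SimConfig(n_chromosomes=2, chrom_lengths=(40_000_000,) * 2,
                        marker_spacing=30_000_000)
        derived = DerivedGenome(make_ancestor(cfg))
        df = emit_marker_table(derived, cfg)
        assert df.groupby("query_chrom").size().min() >= 1


class TestDeterminism:
    def test_emitters_byte_identical_across_runs(self, small_sim_config):
        def run():
            cfg = small_sim_config
            anc = make_ancestor(cfg)
            derived, log = apply_events(anc, k=2, rng=cfg.stream("events"))
            clones = sample_clones(derived, cfg, log=log)
            aln, truth = emit_alignments(clones, derived, cfg)
            fasta = emit_bes_fasta(clones, cfg)
            markers = emit_marker_table(derived, cfg)
            return (aln.to_csv(), truth.to_csv(), fasta, markers.to_csv(),
                    log.to_json())

        assert run() == run()


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 10_000), k=st.integers(0, 5))
def test_property_replay_round_trip(seed, k):
    cfg = SimConfig(n_chromosomes=3, chrom_lengths=(240_000_000,) * 3,
                    seed=seed)
    anc = make_ancestor(cfg)
    derived, log = apply_events(anc, k=k, seed=seed)
    replayed, _ = apply_events(anc, events=log.events)
    assert replayed == derived
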