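"""Simulator contracts: ancestral structure, determinism, null model, the six
event operators, conservation, and the transcript generator."""

import json

import numpy as np
import pytest

from snoevo import io as sio
from snoevo.records import SnoRNAAnnotation
from snoevo.sequences import revcomp
from snoevo.simulate import (
    ConfigError,
    SimulationConfig,
    benchmark_config,
    build_ancestral_cluster,
    evolve_along_tree,
    render,
    run_simulation,
    simulate_transcripts,
    write_outputs,
)

TWO_LEAF = "(A,B)root;"


def test_ancestral_structure_pattern():
    anc = build_ancestral_cluster(SimulationConfig(seed=1, n_snorna_families=3))
    kinds = [e.kind for e in anc.architecture.elements]
    assert kinds == ["exon", "intron", "exon", "intron", "exon", "intron", "exon"]
    fams = [e.snorna_family for e in anc.architecture.introns]
    assert fams == ["snR78", "snR77", "snR76"]


def test_every_intron_has_canonical_signals(benchmark_result):
    for leaf in benchmark_result.leaves.values():
        for intron in leaf.introns:
            s, e = intron.interval
            seq = leaf.record.sequence[s:e]
            assert seq.startswith("GT") and seq.endswith("AG")
            assert intron.donor.startswith("GT")
            assert intron.acceptor.endswith("AG")


def test_snorna_boxes_and_guide_planted(small_ancestor):
    rrna = small_ancestor.rrna
    for sno in small_ancestor.snornas:
        s, e = sno.interval
        seq = small_ancestor.record.sequence[s:e]
        cs, ce = sno.box_c.interval
        ds, de = sno.box_d.interval
        assert small_ancestor.record.sequence[cs:ce] == "TGATGA"
        assert small_ancestor.record.sequence[ds:de] in ("CTGA", "ATGA")
        g = sno.guide
        guide_seq = seq[g.offset : g.offset + g.length]
        assert revcomp(guide_seq) == rrna[g.rrna_offset : g.rrna_offset + g.length]
        assert 10 <= g.length <= 21


def test_determinism_byte_identical(tmp_path):
    cfg = benchmark_config(7)
    outs = []
    for run in range(2):
        d = tmp_path / f"run{run}"
        write_outputs(run_simulation(cfg), d)
        outs.append({p.name: p.read_bytes() for p in sorted(d.iterdir())})
    assert outs[0].keys() == outs[1].keys()
    for name in outs[0]:
        assert outs[0][name] == outs[1][name], name


def test_null_model_leaves_identical_to_ancestor(null_result):
    anc_cluster = null_result.ancestor.record.sequence
    assert null_result.events == []
    for leaf in null_result.leaves.values():
        assert leaf.record.sequence == anc_cluster


def test_forced_deletion_on_two_leaf_tree():
    cfg = SimulationConfig(seed=11, tree=TWO_LEAF, p_deletion_loss=1.0,
                           n_snorna_families=3)
    anc = build_ancestral_cluster(cfg)
    res = evolve_along_tree(anc, cfg)
    lo, hi = cfg.residual_stub_length_range
    for label, leaf in res.leaves.items():
        assert all(s.family != "snR77" for s in leaf.snornas)
    for ev in res.events:
        assert ev.kind == "deletion_loss"
        assert lo <= ev.details["stub_len"] <= hi
        # the stub sits in the leaf genome verbatim (no mutation here)
        leaf = res.leaves[ev.branch]
        assert ev.details["stub_seq"] in leaf.record.sequence


def test_forced_excision_moves_and_conserves_copy_number():
    cfg = SimulationConfig(seed=13)
    anc = build_ancestral_cluster(cfg)
    res = evolve_along_tree(
        anc, cfg, forced_events=[{"branch": "Scer", "kind": "excision_insertion",
                                  "family": "snR72"}],
    )
    leaf = res.leaves["Scer"]
    counts = leaf.sim.family_copy_number()
    assert counts["snR72"] == 1
    (ev,) = res.events
    assert ev.kind == "excision_insertion"
    # relocated copy is a full intron unit >= 500 nt from the cluster
    reloc = [s for s in leaf.snornas if s.family == "snR72"]
    assert len(reloc) == 1
    cluster_span = leaf.architecture.span
    s, e = reloc[0].interval
    assert e <= cluster_span[0] - 500 or s >= cluster_span[1] + 500
    host = [x for x in leaf.introns if x.contained_snorna == "snR72"]
    assert len(host) == 1
    hs, he = host[0].interval
    seq = leaf.record.sequence
    assert seq[hs : hs + 2] == "GT" and seq[he - 2 : he] == "AG"


def test_forced_excision_plants_direct_repeat():
    cfg = SimulationConfig(seed=17)
    anc = build_ancestral_cluster(cfg)
    res = evolve_along_tree(
        anc, cfg, forced_events=[{"branch": "Umay", "kind": "excision_insertion",
                                  "family": "snR75"}],
    )
    (ev,) = res.events
    w = ev.details["repeat_word"]
    lo, hi = cfg.direct_repeat_length_range
    assert lo <= len(w) <= hi
    leaf = res.leaves["Umay"]
    host = next(x for x in leaf.introns if x.contained_snorna == "snR75")
    s, e = host.interval
    seq = leaf.record.sequence
    assert seq[s - len(w) : s] == w and seq[e : e + len(w)] == w


def test_forced_recombination_builds_chimera():
    cfg = SimulationConfig(seed=19)
    anc = build_ancestral_cluster(cfg)
    res = evolve_along_tree(
        anc, cfg, forced_events=[{"branch": "Rory", "kind": "recombination",
                                  "family_5p": "snR78", "family_3p": "snR72"}],
    )
    leaf = res.leaves["Rory"]
    chim = next(s for s in leaf.snornas if s.chimeric is not None)
    assert chim.family == "snR78/snR72"
    s, e = chim.interval
    seq = leaf.record.sequence[s:e]
    bp = chim.chimeric[2]
    assert seq[:bp] == anc.references["snR78"][:bp]
    tail = len(seq) - bp
    assert seq[bp:] == anc.references["snR72"][-tail:]
    # exactly one box C and one terminal box D annotated
    assert seq.count("TGATGA") >= 1
    assert leaf.record.sequence[slice(*chim.box_c.interval)] == "TGATGA"
    assert leaf.record.sequence[slice(*chim.box_d.interval)] in ("CTGA", "ATGA")
    # both parents consumed from the cluster
    fams = {s.family for s in leaf.snornas}
    assert "snR78" not in fams and "snR72" not in fams


def test_forced_exon_loss_creates_adjacent_introns():
    cfg = SimulationConfig(seed=23)
    anc = build_ancestral_cluster(cfg)
    res = evolve_along_tree(
        anc, cfg, forced_events=[{"branch": "Ncra", "kind": "exon_loss",
                                  "exon": "snR77|snR76"}],
    )
    leaf = res.leaves["Ncra"]
    introns = {x.contained_snorna: x.interval for x in leaf.introns}
    assert introns["snR77"][1] == introns["snR76"][0]


def test_forced_intron_gain_plants_inverted_repeat():
    cfg = SimulationConfig(seed=29)
    anc = build_ancestral_cluster(cfg)
    res = evolve_along_tree(
        anc, cfg, forced_events=[{"branch": "Dhan", "kind": "intron_gain"}],
    )
    (ev,) = res.events
    arm = ev.details["arm_seq"]
    assert 8 <= len(arm) <= 12
    leaf = res.leaves[ev.branch]
    gained = next(x for x in leaf.introns if x.contained_snorna is None)
    s, e = gained.interval
    seq = leaf.record.sequence
    # exon-terminal word immediately 5' of the intron ...
    assert seq[s - len(arm) : s] == arm
    # ... and its reverse complement within the intron's last 20 nt
    assert revcomp(arm) in seq[e - 20 : e]


def test_intron_gain_into_snorna_between_guide_and_box_d():
    cfg = SimulationConfig(seed=31)
    anc = build_ancestral_cluster(cfg)
    res = evolve_along_tree(
        anc, cfg,
        forced_events=[{"branch": "Ylip", "kind": "intron_gain",
                        "target": "snorna", "family": "snR74"}],
    )
    (ev,) = res.events
    assert ev.details["target"] == "snorna"
    leaf = res.leaves["Ylip"]
    sno = next(s for s in leaf.snornas if s.family == "snR74")
    gained = next(x for x in leaf.introns if x.intron_id == ev.subject)
    gs, ge = gained.interval
    # nested inside the snoRNA, after the guide, before box D
    assert sno.interval[0] < gs and ge <= sno.box_d.interval[0]
    seq = leaf.record.sequence[gs:ge]
    assert seq.startswith("GT") and seq.endswith("AG")


def test_forced_deintronization_preserves_sequence_kills_signals():
    cfg = SimulationConfig(seed=37)
    anc = build_ancestral_cluster(cfg)
    res = evolve_along_tree(
        anc, cfg, forced_events=[{"branch": "Spom", "kind": "deintronization",
                                  "family": "snR76"}],
    )
    leaf = res.leaves["Spom"]
    sno = next(s for s in leaf.snornas if s.family == "snR76")
    assert sno.status == "exonic"
    assert all(x.contained_snorna != "snR76" for x in leaf.introns)
    # snoRNA sequence itself is untouched
    s, e = sno.interval
    assert leaf.record.sequence[s:e] == anc.references["snR76"]


def test_event_log_matches_exhaustive_leaf_diff(benchmark_result):
    """Every family whose leaf state differs from the intron-rich ancestor is
    explained by at least one logged event on the root-to-leaf path."""
    res = benchmark_result
    node_by_label = {}
    for node in res.tree.preorder_node_iter():
        label = node.taxon.label if node.taxon else node.label
        node_by_label[label] = node

    def path_labels(leaf_label):
        out = []
        node = node_by_label[leaf_label]
        while node is not None:
            label = node.taxon.label if node.taxon else node.label
            out.append(label)
            node = node.parent_node
        return set(out)

    families = set(res.references)
    for label, leaf in res.leaves.items():
        on_path = [ev for ev in res.events if ev.branch in path_labels(label)]
        state = {}
        for sno in leaf.snornas:
            if sno.chimeric is not None:
                for f in sno.chimeric[:2]:
                    state[f] = "chimeric"
            else:
                state[sno.family] = sno.status
        for fam in families:
            observed = state.get(fam, "absent")
            if observed == "intronic":
                continue  # ancestral condition (possibly relocated)
            touching = [
                ev for ev in on_path
                if fam == ev.subject or fam in ev.subject.split("/")
            ]
            assert touching, (label, fam, observed)


def test_config_validation():
    with pytest.raises(ConfigError):
        SimulationConfig(intron_length_range=(10, 60))
    with pytest.raises(ConfigError):
        SimulationConfig(p_deletion_loss=1.5)
    with pytest.raises(ConfigError):
        SimulationConfig(exon_length_range=(80, 5))


def test_truth_outputs_on_disk(tmp_path, null_result):
    write_outputs(null_result, tmp_path)
    names = {p.name for p in tmp_path.iterdir()}
    assert "refs.fasta" in names and "rrna.fasta" in names
    assert "truth_events.json" in names and "tree.nwk" in names
    assert json.loads((tmp_path / "truth_events.json").read_text()) == []
    gff = sio.read_gff3(tmp_path / "Scer.truth.gff3")
    snos = [a for a in gff if isinstance(a, SnoRNAAnnotation)]
    assert len(snos) == 7


# ---------------------------------------------------------------------------
# transcripts

def test_stepwise_transcripts_are_prefixes(small_ancestor):
    _tx, truth = simulate_transcripts(
        small_ancestor.record, small_ancestor.architecture, "stepwise", 200, seed=5
    )
    k = 3
    prefixes = {frozenset(range(1, j + 1)) for j in range(k + 1)}
    assert set(truth) <= prefixes
    assert all(t in prefixes for t in truth)


def test_violation_transcripts_break_prefix_rule(small_ancestor):
    _tx, truth = simulate_transcripts(
        small_ancestor.record, small_ancestor.architecture, "violation", 10, seed=5
    )
    prefixes = {frozenset(range(1, j + 1)) for j in range(4)}
    assert any(t not in prefixes for t in truth)


def test_transcript_sequences_match_excision(small_ancestor):
    tx, truth = simulate_transcripts(
        small_ancestor.record, small_ancestor.architecture, "stepwise", 20, seed=6
    )
    span = small_ancestor.architecture.span
    full = small_ancestor.record.sequence[span[0] : span[1]]
    introns = [e.interval for e in small_ancestor.architecture.introns]
    for (tid, seq), removed in zip(tx, truth):
        expected = full
        for idx in sorted(removed, reverse=True):
            s, e = introns[idx - 1]
            expected = expected[: s - span[0]] + expected[e - span[0] :]
        assert seq == expected


def test_transcripts_bad_n_rejected(small_ancestor):
    with pytest.raises(ValueError):
        simulate_transcripts(
            small_ancestor.record, small_ancestor.architecture, "stepwise", 0, seed=1
        )
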