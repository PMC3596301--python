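"""Direct/inverted junction repeats: planted cases, brute-force oracle
equivalence, maximality, orientation symmetry, and event enrichment."""

import numpy as np
import pytest

from snoevo.repeats import (
    annotate_event_junctions,
    default_direct_mismatch,
    find_direct_repeats,
    find_inverted_repeats,
)
from snoevo.sequences import hamming, revcomp
from snoevo.simulate import SimulationConfig, build_ancestral_cluster, evolve_along_tree


def rand_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# independent oracles: plain quadruple-loop enumeration of the same contract

def oracle_direct(left, insert, right, min_len, max_len, budget=None):
    budget = budget or default_direct_mismatch
    b = budget if callable(budget) else (lambda L: budget)
    cands = set()
    for L in range(min_len, max_len + 1):
        arms = []
        if len(left) >= L:
            arms.append(("L", left[-L:]))
        if len(right) >= L:
            arms.append(("R", right[:L]))
        for side, a1 in arms:
            for j in range(len(insert) - L + 1):
                mm = hamming(a1, insert[j : j + L])
                if mm <= b(L):
                    if j <= max_len:
                        cands.add((side + "5", j, L, mm))
                    if len(insert) - (j + L) <= max_len:
                        cands.add((side + "3", j, L, mm))
        if len(left) >= L and len(right) >= L:
            mm = hamming(left[-L:], right[:L])
            if mm <= b(L):
                cands.add(("LR", 0, L, mm))

    def extendable(cls, j, L):
        if L + 1 > max_len:
            return False
        bb = b(L + 1)
        if cls in ("L5", "L3"):
            return (len(left) >= L + 1 and j >= 1
                    and hamming(left[-(L + 1):], insert[j - 1 : j + L]) <= bb)
        if cls in ("R5", "R3"):
            return (j + L + 1 <= len(insert) and len(right) >= L + 1
                    and hamming(right[: L + 1], insert[j : j + L + 1]) <= bb)
        return (len(left) >= L + 1 and len(right) >= L + 1
                and hamming(left[-(L + 1):], right[: L + 1]) <= bb)

    return {c for c in cands if not extendable(*c[:3])}


def oracle_inverted(exon, intron, min_len, max_len, max_mm, window):
    hits = set()
    for L in range(min_len, max_len + 1):
        for i in range(max(0, len(exon) - window), len(exon) - L + 1):
            for j in range(max(0, len(intron) - window), len(intron) - L + 1):
                if hamming(revcomp(exon[i : i + L]), intron[j : j + L]) <= max_mm:
                    hits.add((i, j, L))
    return {
        (i, j, L) for (i, j, L) in hits
        if (i - 1, j, L + 1) not in hits
        and (i, j - 1, L + 1) not in hits
        and (i - 1, j - 1, L + 2) not in hits
    }


def _direct_key(rep, left_len):
    # map a JunctionRepeat back onto the oracle's (class, j, L) key space
    if rep.arm1[0] == (left_len - rep.arm_length, left_len):
        side = "L"
    else:
        side = "R"
    return (side, rep.arm2[0][0], rep.arm_length, rep.mismatches)


# ---------------------------------------------------------------------------
# direct repeats

def test_planted_target_site_duplication():
    rng = np.random.default_rng(10)
    word = "ACGTT"
    left = rand_dna(rng, 30) + word
    right = word + rand_dna(rng, 30)
    insert = "GT" + rand_dna(rng, 60) + "AG"
    reps = find_direct_repeats(left, insert, right, 3, 8)
    exact5 = [r for r in reps if r.arm_length >= 5 and r.mismatches == 0
              and r.arm1[1][-5:] == word]
    assert exact5, reps


def test_no_shared_word_empty():
    left, insert, right = "CCCCCCCCCC", "GGGGGGGGGGGG", "TTTTTTTTTT"
    assert find_direct_repeats(left, insert, right, 3, 8, max_mismatch=0) == []


def test_direct_min_max_validation():
    with pytest.raises(ValueError):
        find_direct_repeats("AAA", "CCC", "GGG", 5, 3)


@pytest.mark.parametrize("trial", range(25))
def test_direct_matches_bruteforce_oracle(trial):
    rng = np.random.default_rng(100 + trial)
    left = rand_dna(rng, int(rng.integers(8, 30)))
    right = rand_dna(rng, int(rng.integers(8, 30)))
    insert = rand_dna(rng, int(rng.integers(10, 120)))
    if trial % 2:  # plant a duplication half the time
        w = rand_dna(rng, int(rng.integers(3, 8)))
        left, right = left + w, w + right
    got = find_direct_repeats(left, insert, right, 3, 8)
    want = oracle_direct(left, insert, right, 3, 8)
    got_keys = {(r.kind,) + _direct_key(r, len(left)) for r in got}
    want_keys = set()
    for cls, j, L, mm in want:
        side = "LR" if cls == "LR" else cls
        if cls == "LR":
            want_keys.add(("direct", "L", 0, L, mm))
        else:
            want_keys.add(("direct", cls[0], j, L, mm))
    assert got_keys == want_keys


# ---------------------------------------------------------------------------
# inverted repeats

def test_planted_inverted_repeat():
    exon = "CCCCCCCCCCCC" + "GCATTGCC"
    intron = "GTAAGT" + "C" * 40 + "GGCAATGC" + "CCCC"
    reps = find_inverted_repeats(exon, intron, 8, 12, 0, 20)
    assert any(r.arm_length == 8 and r.arm1[1] == "GCATTGCC" for r in reps)


def test_poly_a_has_no_inverted_repeat():
    assert find_inverted_repeats("A" * 30, "A" * 50, 8, 12, 0, 20) == []


@pytest.mark.parametrize("trial", range(25))
def test_inverted_matches_bruteforce_oracle(trial):
    rng = np.random.default_rng(200 + trial)
    exon = rand_dna(rng, int(rng.integers(15, 60)))
    intron = rand_dna(rng, int(rng.integers(15, 120)))
    if trial % 2:
        arm = rand_dna(rng, int(rng.integers(8, 12)))
        exon = exon[:-len(arm)] + arm
        pos = len(intron) - int(rng.integers(len(arm) + 2, 18))
        rc = revcomp(arm)
        intron = intron[:pos] + rc + intron[pos + len(rc):]
    got = find_inverted_repeats(exon, intron, 8, 12, 0, 20)
    want = oracle_inverted(exon, intron, 8, 12, 0, 20)
    assert {(r.arm1[0][0], r.arm2[0][0], r.arm_length) for r in got} == want


def test_inverted_orientation_symmetry():
    """On window-covered inputs, pairs map one-to-one onto the pairs found in
    reverse-complemented, swapped inputs."""
    rng = np.random.default_rng(11)
    for _ in range(10):
        x = rand_dna(rng, 20)
        y = rand_dna(rng, 20)
        arm = rand_dna(rng, 9)
        x = x[:-9] + arm
        y = revcomp(arm) + y[9:]
        fwd = find_inverted_repeats(x, y, 8, 12, 0, 20)
        swp = find_inverted_repeats(revcomp(y), revcomp(x), 8, 12, 0, 20)
        fwd_arms = {frozenset((r.arm1[1], r.arm2[1])) for r in fwd}
        swp_arms = {frozenset((revcomp(r.arm2[1]), revcomp(r.arm1[1]))) for r in swp}
        assert fwd_arms == swp_arms


def test_maximality_no_reported_pair_extendable():
    rng = np.random.default_rng(12)
    for _ in range(20):
        exon = rand_dna(rng, 40)
        intron = rand_dna(rng, 60)
        for r in find_inverted_repeats(exon, intron, 8, 12, 1, 20):
            (i, _), (j, _) = r.arm1[0], r.arm2[0]
            L = r.arm_length
            for di, dj, dL in ((-1, 0, 1), (0, -1, 1), (-1, -1, 2)):
                ii, jj, LL = i + di, j + dj, L + dL
                if ii < 0 or jj < 0 or ii + LL > len(exon) or jj + LL > len(intron):
                    continue
                if LL > 12:
                    continue
                assert hamming(revcomp(exon[ii : ii + LL]), intron[jj : jj + LL]) > 1


# ---------------------------------------------------------------------------
# event enrichment against simulator truth

def test_excision_event_carries_planted_direct_repeat():
    cfg = SimulationConfig(seed=51)
    anc = build_ancestral_cluster(cfg)
    res = evolve_along_tree(
        anc, cfg, forced_events=[{"branch": "Cgla", "kind": "excision_insertion",
                                  "family": "snR73"}],
    )
    from snoevo.pipeline import run_pipeline_on_simulation

    pipe = run_pipeline_on_simulation(res)
    (ev,) = [e for e in pipe.events if e.kind == "excision_insertion"]
    genomes = {l: leaf.record for l, leaf in res.leaves.items()}
    annotate_event_junctions(ev, genomes)
    planted = res.events[0].details["repeat_word"]
    direct = [r for r in ev.repeats if r.kind == "direct"]
    # maximal pair may extend the planted duplication by a tolerated mismatch
    assert any(
        len(planted) <= r.arm_length
        and (planted in r.arm1[1] or planted in r.arm2[1])
        for r in direct
    ), (planted, direct)


def test_intron_gain_event_carries_inverted_repeat():
    cfg = SimulationConfig(seed=53)
    anc = build_ancestral_cluster(cfg)
    res = evolve_along_tree(
        anc, cfg, forced_events=[{"branch": "Anid", "kind": "intron_gain"}],
    )
    from snoevo.pipeline import run_pipeline_on_simulation

    pipe = run_pipeline_on_simulation(res)
    gains = [e for e in pipe.events if e.kind == "intron_gain"]
    assert len(gains) == 1
    genomes = {l: leaf.record for l, leaf in res.leaves.items()}
    annotate_event_junctions(gains[0], genomes)
    inverted = [r for r in gains[0].repeats if r.kind == "inverted"]
    assert inverted
    assert any(8 <= r.arm_length <= 12 for r in inverted)


def test_deletion_event_has_no_junction_insert():
    cfg = SimulationConfig(seed=55)
    anc = build_ancestral_cluster(cfg)
    res = evolve_along_tree(
        anc, cfg, forced_events=[{"branch": "Spom", "kind": "deletion_loss",
                                  "family": "snR77"}],
    )
    from snoevo.pipeline import run_pipeline_on_simulation

    pipe = run_pipeline_on_simulation(res)
    (ev,) = [e for e in pipe.events if e.kind == "deletion_loss"]
    genomes = {l: leaf.record for l, leaf in res.leaves.items()}
    annotate_event_junctions(ev, genomes)
    assert ev.repeats == []
    assert ev.kind == "deletion_loss"  # enrichment never changes the kind
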