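"""Short direct and inverted repeats at intron insertion junctions.

Direct repeats (target-site duplications) are the footprint of staggered
double-strand-break repair: an identical short word ends one flank at the
junction and recurs at an insert end or at the opposite flank's start.
Inverted repeats pair a word near an exon end with its reverse complement
near the opposite end of a gained intron (8-12 bp in the motivating
observations).  All maximal (non-extendable) pairs are reported; ranking is
left to callers.
"""

from __future__ import annotations

from .records import Evidence, EvolutionEvent, GenomeRecord, JunctionRepeat
from .sequences import hamming, revcomp


def default_direct_mismatch(L: int) -> int:
    """Default mismatch budget for direct repeats: 1 for arms >= 6 nt."""
    return 1 if L >= 6 else 0


def _budget(max_mismatch, L: int) -> int:
    return max_mismatch(L) if callable(max_mismatch) else max_mismatch


# classes of direct-repeat pair anchoring:
#   L5 / L3: arm1 = left-flank suffix, arm2 in the insert's first/last zone
#   R5 / R3: arm1 = right-flank prefix, arm2 in the insert's first/last zone
#   LR:      arm1 = left-flank suffix, arm2 = right-flank prefix
_DIRECT_CLASSES = ("L5", "L3", "LR", "R5", "R3")


def _direct_candidates(left: str, insert: str, right: str, min_len: int,
                       max_len: int, max_mismatch):
    for L in range(min_len, max_len + 1):
        b = _budget(max_mismatch, L)
        a_left = left[-L:] if len(left) >= L else None
        a_right = right[:L] if len(right) >= L else None
        for j in range(0, len(insert) - L + 1):
            in5 = j <= max_len
            in3 = len(insert) - (j + L) <= max_len
            if not (in5 or in3):
                continue
            word = insert[j : j + L]
            if a_left is not None and hamming(a_left, word) <= b:
                if in5:
                    yield ("L5", j, L, hamming(a_left, word))
                if in3:
                    yield ("L3", j, L, hamming(a_left, word))
            if a_right is not None and hamming(a_right, word) <= b:
                if in5:
                    yield ("R5", j, L, hamming(a_right, word))
                if in3:
                    yield ("R3", j, L, hamming(a_right, word))
        if a_left is not None and a_right is not None:
            mm = hamming(a_left, a_right)
            if mm <= b:
                yield ("LR", 0, L, mm)


def find_direct_repeats(
    left_flank: str,
    insert: str,
    right_flank: str,
    min_len: int = 3,
    max_len: int = 8,
    max_mismatch=None,
) -> list[JunctionRepeat]:
    """Direct repeats at an insertion junction.

    arm1 is a word ending the left flank at the junction (suffix) or starting
    the right flank (prefix); arm2 is its partner within the first/last
    *max_len* nt of the insert, or the word anchored at the opposite flank's
    junction.  Only maximal pairs are reported, sorted by decreasing arm
    length.  ``max_mismatch`` may be an int or a callable of the arm length;
    the default allows 1 mismatch for arms of at least 6 nt.

    arm1 intervals are local to their flank, arm2 intervals local to the
    insert (or, for flank-to-flank pairs, to the right flank).
    """
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    mmb = default_direct_mismatch if max_mismatch is None else max_mismatch
    cands = list(_direct_candidates(left_flank, insert, right_flank,
                                    min_len, max_len, mmb))
    index = {(cls, j, L) for cls, j, L, _ in cands}

    def extendable(cls: str, j: int, L: int) -> bool:
        if L + 1 > max_len:
            return False
        b = _budget(mmb, L + 1)
        if cls in ("L5", "L3"):
            # arm1 grows leftward (away from the junction); arm2 grows leftward
            return (len(left_flank) >= L + 1 and j >= 1
                    and hamming(left_flank[-(L + 1):], insert[j - 1 : j + L]) <= b)
        if cls in ("R5", "R3"):
            return (len(right_flank) >= L + 1 and j + L + 1 <= len(insert)
                    and hamming(right_flank[: L + 1], insert[j : j + L + 1]) <= b)
        # LR: both arms anchored at the junction
        return (len(left_flank) >= L + 1 and len(right_flank) >= L + 1
                and hamming(left_flank[-(L + 1):], right_flank[: L + 1]) <= b)

    out: list[JunctionRepeat] = []
    seen = set()
    for cls, j, L, mm in sorted(cands, key=lambda t: (-t[2], t[0], t[1])):
        if extendable(cls, j, L):
            continue
        arm1_iv = (len(left_flank) - L, len(left_flank)) if cls.startswith("L") else (0, L)
        arm1_seq = left_flank[-L:] if cls.startswith("L") else right_flank[:L]
        if cls == "LR":
            arm2_iv, arm2_seq = (0, L), right_flank[:L]
        else:
            arm2_iv, arm2_seq = (j, j + L), insert[j : j + L]
        key = (cls, arm1_iv, arm2_iv)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            JunctionRepeat(kind="direct", arm_length=L, arm1=(arm1_iv, arm1_seq),
                           arm2=(arm2_iv, arm2_seq), mismatches=mm)
        )
    return out


def find_inverted_repeats(
    exon_end: str,
    intron: str,
    min_len: int = 8,
    max_len: int = 12,
    max_mismatch: int = 0,
    search_window: int = 20,
) -> list[JunctionRepeat]:
    """Inverted repeats between the last *search_window* nt of *exon_end* and
    the last *search_window* nt of *intron* (the end opposite the junction):
    arm2 must equal the reverse complement of arm1.  Maximal pairs only,
    sorted by decreasing arm length.  Intervals are local to the full inputs.
    """
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    ex_lo = max(0, len(exon_end) - search_window)
    in_lo = max(0, len(intron) - search_window)
    hits: list[tuple[int, int, int, int]] = []
    for L in range(min_len, max_len + 1):
        for i in range(ex_lo, len(exon_end) - L + 1):
            w = revcomp(exon_end[i : i + L])
            for j in range(in_lo, len(intron) - L + 1):
                mm = hamming(w, intron[j : j + L])
                if mm <= max_mismatch:
                    hits.append((i, j, L, mm))
    # reverse-complement pairing couples extending the exon arm leftward with
    # extending the intron arm rightward (and vice versa)
    index = {(i, j, L) for i, j, L, _ in hits}

    def extendable(i: int, j: int, L: int) -> bool:
        return (
            (i - 1, j, L + 1) in index
            or (i, j - 1, L + 1) in index
            or (i - 1, j - 1, L + 2) in index
        )

    out = []
    for i, j, L, mm in sorted(hits, key=lambda t: (-t[2], t[0], t[1])):
        if extendable(i, j, L):
            continue
        out.append(
            JunctionRepeat(
                kind="inverted", arm_length=L,
                arm1=((i, i + L), exon_end[i : i + L]),
                arm2=((j, j + L), intron[j : j + L]),
                mismatches=mm,
            )
        )
    return out


def annotate_event_junctions(
    event: EvolutionEvent,
    genomes: dict[str, GenomeRecord],
    flank_window: int = 20,
    direct_min: int = 3,
    direct_max: int = 8,
    inverted_min: int = 8,
    inverted_max: int = 12,
) -> EvolutionEvent:
    """Attach direct/inverted junction-repeat evidence to an event in place.

    The event's first evidence record must carry a resolvable locus
    ({"species", "interval"}); when it does not, the repeat evidence is
    marked unavailable and the event is returned unchanged otherwise.  The
    event's kind is never altered.
    """
    locus = None
    for ev in event.evidence:
        if "species" in ev.detail and "interval" in ev.detail:
            locus = (ev.detail["species"], tuple(ev.detail["interval"]))
            break
    if locus is None or locus[0] not in genomes:
        event.evidence.append(Evidence("junction_repeats_unavailable", {}))
        return event
    species, (s, e) = locus
    seq = genomes[species].sequence
    left = seq[max(0, s - flank_window) : s]
    insert = seq[s:e]
    right = seq[e : e + flank_window]
    if event.kind in ("excision_insertion", "intron_gain"):
        event.repeats.extend(
            find_direct_repeats(left, insert, right, direct_min, direct_max)
        )
        event.repeats.extend(
            find_inverted_repeats(left, insert, inverted_min, inverted_max,
                                  max_mismatch=0, search_window=flank_window)
        )
    return event
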