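"""Box C/D snoRNA detection: motif scanning, guide scoring, family assignment
and chimera detection, plus the whole-genome scan driver.

Box C (TGATGA) and box D (CTGA/ATGA) are searched with small mismatch
allowances; candidate regions are then anchored by alignment to reference
family sequences (BLAST-style ortholog search on a desk scale), scored for an
antisense guide element against the rRNA, and resolved for overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align

from .records import BoxMotif, GenomeRecord, GuideHit, SnoRNAAnnotation
from .sequences import BOX_C, BOX_D, motif_mismatches, revcomp


@dataclass
class ScanParams:
    max_mismatch_c: int = 1
    max_mismatch_d: int = 0
    separation: tuple[int, int] = (50, 150)
    guide_min_length: int = 10
    guide_max_length: int = 30
    guide_max_mismatch: int = 1
    min_identity: float = 0.6
    chimera_trigger_identity: float = 0.8
    min_segment_identity: float = 0.7
    min_segment_length: int = 20
    keep_novel: bool = False
    window_pad: int = 6


# ---------------------------------------------------------------------------
# box motif scanning

def _motif_hits(seq: str, motif: str, max_mm: int) -> list[int]:
    n, m = len(seq), len(motif)
    if n < m:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mm = np.zeros(n - m + 1, dtype=np.int16)
    is_n = arr == ord("N")
    for j, ch in enumerate(motif):
        seg = arr[j : j + n - m + 1]
        mm += (seg != ord(ch)) | is_n[j : j + n - m + 1]
    return [int(i) for i in np.nonzero(mm <= max_mm)[0]]


def scan_box_motifs(
    sequence: str,
    max_mismatch_c: int = 1,
    max_mismatch_d: int = 0,
    separation: tuple[int, int] = (50, 150),
) -> list[tuple[int, int]]:
    """All (box C position, box D position) pairs where a tolerant TGATGA match
    precedes a tolerant CTGA/ATGA match at a start-to-start separation within
    *separation*, ordered by box C then box D position."""
    if not sequence:
        raise ValueError("empty sequence")
    c_hits = _motif_hits(sequence, BOX_C, max_mismatch_c)
    d_hits = sorted(
        set(_motif_hits(sequence, BOX_D[0], max_mismatch_d))
        | set(_motif_hits(sequence, BOX_D[1], max_mismatch_d))
    )
    lo, hi = separation
    pairs: list[tuple[int, int]] = []
    d_arr = np.asarray(d_hits, dtype=np.int64)
    for c in c_hits:
        if d_arr.size == 0:
            break
        j0 = int(np.searchsorted(d_arr, c + lo, side="left"))
        j1 = int(np.searchsorted(d_arr, c + hi, side="right"))
        pairs.extend((c, int(d)) for d in d_arr[j0:j1])
    return pairs


# ---------------------------------------------------------------------------
# guide scoring

def score_guide(
    candidate: str,
    rrna: str,
    min_length: int = 10,
    max_mismatch: int = 0,
    max_length: int = 30,
) -> GuideHit | None:
    """Longest window of *candidate* whose reverse complement matches a window
    of *rrna* with at most *max_mismatch* mismatches and length >= min_length.
    Ties: fewer mismatches, then leftmost candidate offset, then leftmost
    rRNA offset."""
    if min_length < 8:
        raise ValueError("min_length must be >= 8")
    n, m = len(candidate), len(rrna)
    if n < min_length or m < min_length:
        return None
    rc = revcomp(candidate)  # rc offset i corresponds to candidate offset n-1-i-(L-1)
    a = np.frombuffer(rc.encode(), dtype=np.uint8)
    b = np.frombuffer(rrna.encode(), dtype=np.uint8)
    mm = (a[:, None] != b[None, :]) | (a[:, None] == ord("N")) | (b[None, :] == ord("N"))
    mm = mm.astype(np.int32)
    # diagonal cumulative sums: S[i,j] = mm[i,j] + S[i-1,j-1]
    S = mm.copy()
    for i in range(1, n):
        S[i, 1:] += S[i - 1, :-1]
    best: tuple | None = None  # (-length, mismatches, cand_off, rrna_off)
    hi_l = min(max_length, n, m)
    for L in range(hi_l, min_length - 1, -1):
        w = S[L - 1 :, L - 1 :].copy()
        w[1:, 1:] -= S[: n - L + 1 - 1, : m - L + 1 - 1]
        ii, jj = np.nonzero(w <= max_mismatch)
        if ii.size == 0:
            continue
        # rc window start i -> candidate offset n - i - L
        cand_off = n - ii - L
        key = np.lexsort((jj, cand_off, w[ii, jj]))
        k = key[0]
        best = (-L, int(w[ii[k], jj[k]]), int(cand_off[k]), int(jj[k]))
        break  # lengths are scanned in decreasing order: first hit is longest
    if best is None:
        return None
    L, mmc, coff, roff = -best[0], best[1], best[2], best[3]
    return GuideHit(offset=coff, rrna_offset=roff, length=L, mismatches=mmc)


# ---------------------------------------------------------------------------
# family assignment

def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -1
    return al


_GLOBAL_ALIGNER = _aligner()


def alignment_identity(a: str, b: str) -> float:
    """Identity (matches / alignment columns) of the best global alignment
    with unit match/mismatch and affine gaps (open 2, extend 1)."""
    if not a or not b:
        return 0.0
    aln = _GLOBAL_ALIGNER.align(a, b)[0]
    matches = 0
    columns = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        seg1, seg2 = a[s1:e1], b[s2:e2]
        matches += sum(x == y for x, y in zip(seg1, seg2))
        columns += e1 - s1
    # count gap columns
    total_cols = aln.length if hasattr(aln, "length") else max(len(a), len(b))
    return matches / total_cols if total_cols else 0.0


def assign_family(
    candidate_seq: str,
    references: dict[str, str],
    min_identity: float = 0.6,
) -> tuple[str, float]:
    """Best-family global-alignment identity; 'novel' below *min_identity*."""
    if not references:
        raise ValueError("references must be nonempty")
    best_fam, best_id = "novel", 0.0
    for fam, ref in references.items():
        ident = alignment_identity(candidate_seq, ref)
        if ident > best_id:
            best_fam, best_id = fam, ident
    if best_id < min_identity:
        return "novel", best_id
    return best_fam, best_id


# ---------------------------------------------------------------------------
# chimera detection

def _prefix_identity(query: str, ref: str) -> float:
    """Identity of *query* against the best-matching prefix of *ref*
    (semi-global: free end gaps on the reference)."""
    if not query:
        return 0.0
    res = edlib.align(query, ref, mode="SHW", task="distance")
    return max(0.0, 1.0 - res["editDistance"] / len(query))


def _suffix_identity(query: str, ref: str) -> float:
    return _prefix_identity(query[::-1], ref[::-1])


def detect_chimera(
    candidate_seq: str,
    references: dict[str, str],
    min_segment_identity: float = 0.7,
    min_segment_length: int = 20,
    max_segment_overhang: int = 15,
) -> tuple[str, str, int] | None:
    """Exhaustive breakpoint scan: split the candidate at every position,
    align the 5' segment to reference prefixes and the 3' segment to reference
    suffixes, and report the split maximizing summed identity when both
    segments pass thresholds with two distinct families.

    A segment longer than its parent reference (beyond ``max_segment_overhang``
    slack) cannot descend from it and is not considered: free-end-gap identity
    would otherwise absorb unrelated flanking sequence."""
    n = len(candidate_seq)
    best = None  # (score, split, fam5, fam3)

    def best_fit(seg: str, scorer) -> tuple[str | None, float]:
        fam_best, id_best = None, -1.0
        for fam, ref in references.items():
            if len(seg) > len(ref) + max_segment_overhang:
                continue
            ident = scorer(seg, ref)
            if ident > id_best:
                fam_best, id_best = fam, ident
        return fam_best, id_best

    for split in range(min_segment_length, n - min_segment_length + 1):
        seg5, seg3 = candidate_seq[:split], candidate_seq[split:]
        f5, i5 = best_fit(seg5, _prefix_identity)
        f3, i3 = best_fit(seg3, _suffix_identity)
        if f5 is None or f3 is None or f5 == f3:
            continue
        if i5 < min_segment_identity or i3 < min_segment_identity:
            continue
        score = i5 + i3
        if best is None or score > best[0]:
            best = (score, split, f5, f3)
    if best is None:
        return None
    return (best[2], best[3], best[1])


# ---------------------------------------------------------------------------
# genome scan driver

@dataclass
class ScanHit:
    annotation: SnoRNAAnnotation
    guide: GuideHit | None = None


def _refine_interval(window_seq: str, window_start: int, ref: str) -> tuple[int, int] | None:
    """Locate *ref* inside the window (infix alignment); genome interval."""
    res = edlib.align(ref, window_seq, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    s, e = res["locations"][0]
    return (window_start + s, window_start + e + 1)


def _locate_boxes(seq: str, max_mm_c: int, max_mm_d: int) -> tuple[BoxMotif, BoxMotif] | None:
    """Best box C in the first 10 nt and box D in the last 10 nt."""
    c_best = None
    for i in range(0, min(11, max(1, len(seq) - 6))):
        mm = motif_mismatches(seq[i : i + 6], BOX_C) if i + 6 <= len(seq) else 99
        if mm <= max_mm_c and (c_best is None or mm < c_best[0]):
            c_best = (mm, i)
    d_best = None
    for i in range(max(0, len(seq) - 14), len(seq) - 3):
        word = seq[i : i + 4]
        if len(word) < 4:
            continue
        mm = min(motif_mismatches(word, BOX_D[0]), motif_mismatches(word, BOX_D[1]))
        if mm <= max_mm_d and (d_best is None or mm <= d_best[0]):
            d_best = (mm, i)  # prefer the rightmost (closest to the 3' end)
    if c_best is None or d_best is None:
        return None
    ci, di = c_best[1], d_best[1]
    if ci + 6 > di:
        return None
    return (
        BoxMotif((ci, ci + 6), seq[ci : ci + 6]),
        BoxMotif((di, di + 4), seq[di : di + 4]),
    )


def scan_genome(
    genome: GenomeRecord,
    references: dict[str, str],
    rrna: str,
    params: ScanParams | None = None,
) -> list[SnoRNAAnnotation]:
    """Detect box C/D snoRNAs in one genome record.

    Pipeline: box-pair candidates -> boundary refinement against the
    best-matching reference -> guide-element scoring -> family / chimera
    assignment -> overlap resolution.  Candidates without a guide hit, or
    without a family (or chimera) call, are dropped unless ``keep_novel``.
    """
    p = params or ScanParams()
    seq = genome.sequence
    pairs = scan_box_motifs(seq, p.max_mismatch_c, p.max_mismatch_d, p.separation)
    raw: list[SnoRNAAnnotation] = []
    seen_windows: set[tuple[int, int]] = set()
    for c, d in pairs:
        ws = max(0, c - p.window_pad)
        we = min(len(seq), d + 4 + p.window_pad)
        if (ws, we) in seen_windows:
            continue
        seen_windows.add((ws, we))
        window = seq[ws:we]
        # anchor boundaries on the best-matching reference
        best_iv, best_fam, best_ident = None, "novel", 0.0
        for fam, ref in references.items():
            iv = _refine_interval(window, ws, ref)
            if iv is None:
                continue
            ident = alignment_identity(seq[iv[0] : iv[1]], ref)
            if ident > best_ident:
                best_iv, best_fam, best_ident = iv, fam, ident
        chim = None
        # a refined interval that stops well short of the anchoring box pair
        # means the best single family explains only part of the candidate --
        # the signature of a chimeric fusion
        covers_boxes = best_iv is not None and best_iv[0] <= c + 6 and best_iv[1] >= d + 4 - 6
        if best_ident < p.chimera_trigger_identity or not covers_boxes:
            chim = detect_chimera(
                window, references, p.min_segment_identity, p.min_segment_length
            )
            if chim is not None:
                best_iv = (ws, we)
        if best_iv is None or best_ident < p.min_identity:
            if chim is None and not p.keep_novel:
                continue
            if best_iv is None:
                best_iv = (ws, we)
        cand_seq = seq[best_iv[0] : best_iv[1]]
        boxes = _locate_boxes(cand_seq, p.max_mismatch_c, p.max_mismatch_d)
        if boxes is None:
            continue
        guide = score_guide(
            cand_seq, rrna, p.guide_min_length, p.guide_max_mismatch, p.guide_max_length
        )
        if guide is None:
            continue
        if chim is not None:
            family, identity = "novel", best_ident
        else:
            family, identity = assign_family(cand_seq, references, p.min_identity)
            if family == "novel" and not p.keep_novel:
                continue
        box_c = BoxMotif(
            (best_iv[0] + boxes[0].interval[0], best_iv[0] + boxes[0].interval[1]),
            boxes[0].sequence,
        )
        box_d = BoxMotif(
            (best_iv[0] + boxes[1].interval[0], best_iv[0] + boxes[1].interval[1]),
            boxes[1].sequence,
        )
        fam_label = f"{chim[0]}/{chim[1]}" if chim is not None else family
        chim_genome = (chim[0], chim[1], best_iv[0] + chim[2]) if chim is not None else None
        ann = SnoRNAAnnotation(
            record_id=genome.record_id,
            interval=best_iv,
            family=fam_label,
            box_c=box_c,
            box_d=box_d,
            guide=guide,
            family_identity=identity if chim is None else best_ident,
            chimeric=chim_genome,
        )
        raw.append(ann)
    return _resolve_overlaps(raw)


def _guide_rank(ann: SnoRNAAnnotation) -> tuple:
    g = ann.guide
    glen = g.length if g else 0
    gmm = g.mismatches if g else 99
    length = ann.interval[1] - ann.interval[0]
    return (-glen, gmm, -length, ann.interval[0])


def _resolve_overlaps(hits: list[SnoRNAAnnotation]) -> list[SnoRNAAnnotation]:
    """Keep the better candidate among overlapping ones: better guide
    (longer, fewer mismatches), then longer candidate, then leftmost."""
    kept: list[SnoRNAAnnotation] = []
    for ann in sorted(hits, key=_guide_rank):
        s, e = ann.interval
        if any(not (e <= k.interval[0] or k.interval[1] <= s) for k in kept):
            continue
        kept.append(ann)
    kept.sort(key=lambda a: a.interval)
    counts: dict[str, int] = {}
    for ann in kept:
        counts[ann.family] = counts.get(ann.family, 0) + 1
        ann.sno_id = ann.family if counts[ann.family] == 1 else f"{ann.family}_{counts[ann.family]}"
    return kept
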