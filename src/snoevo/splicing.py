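"""Spliced-product resolution and the stepwise 5'->3' splicing test.

Each transcript is compared against the 2^k possible removed-intron subsets
of a k-intron cluster (k <= 12); the best-fitting hypothesis gives the
product's removed/retained sets.  A product set is consistent with stepwise
splicing when every removed set is a 5'-contiguous prefix of the intron
order.  The same product classes are also predicted by a single-donor /
alternative-acceptor model; the two are observationally equivalent on
products alone, which is reported but never adjudicated.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations

import edlib

from .records import ClusterArchitecture, GenomeRecord, SplicedProduct
from .simulate import spliced_sequence

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII"]

MAX_INTRONS = 12


def _label(removed: frozenset[int], k: int) -> str:
    if not removed:
        return "unspliced"
    if removed == frozenset(range(1, k + 1)):
        return "all_removed"
    if removed == frozenset(range(1, len(removed) + 1)):
        return "+".join(_ROMAN[i - 1] for i in sorted(removed)) + "_removed"
    return "other"


def resolve_product(
    transcript: str,
    architecture: ClusterArchitecture,
    genome: GenomeRecord,
    max_mismatch_rate: float = 0.03,
    transcript_id: str = "t",
) -> SplicedProduct | None:
    """Best removed-intron hypothesis for one transcript, or None.

    All 2^k removed subsets are enumerated; each predicted spliced sequence is
    compared to the transcript by global alignment (edit distance).  The
    lowest-distance hypothesis wins if its mismatch rate is within
    *max_mismatch_rate*; ties prefer fewer removed introns, then the
    lexicographically smallest index set.
    """
    k = len(architecture.introns)
    if k < 1:
        raise ValueError("architecture has no introns")
    if k > MAX_INTRONS:
        raise ValueError(
            f"{k} introns: hypothesis space 2^{k} exceeds the supported maximum "
            f"(k <= {MAX_INTRONS})"
        )
    best = None  # (rate, distance, n_removed, sorted_indices, removed)
    for r in range(k + 1):
        for combo in combinations(range(1, k + 1), r):
            removed = frozenset(combo)
            predicted = spliced_sequence(genome, architecture, removed)
            # free end-gaps on the longer sequence: the transcript may extend
            # beyond the annotated cluster span, or be a truncated (partial)
            # read covering only part of it
            if len(transcript) >= len(predicted):
                dist = edlib.align(predicted, transcript, mode="HW",
                                   task="distance")["editDistance"]
                rate = dist / max(1, len(predicted))
            else:
                dist = edlib.align(transcript, predicted, mode="HW",
                                   task="distance")["editDistance"]
                rate = dist / max(1, len(transcript))
            key = (rate, dist, r, tuple(sorted(combo)))
            if best is None or key < best[:4]:
                best = key + (removed, len(predicted))
    rate, dist, _, _, removed, pred_len = best
    if rate > max_mismatch_rate:
        return None
    all_idx = frozenset(range(1, k + 1))
    return SplicedProduct(
        transcript_id=transcript_id,
        cluster_id=architecture.cluster_id,
        removed=removed,
        retained=all_idx - removed,
        alignment_mismatches=dist,
        classification=_label(removed, k),
        partial=len(transcript) < 0.9 * pred_len,
    )


def classify_products(products: list[SplicedProduct]) -> dict[str, int]:
    """Counts per removed-set class, plus a 'total' entry."""
    clusters = {p.cluster_id for p in products}
    if len(clusters) > 1:
        raise ValueError(f"products from multiple clusters: {sorted(clusters)}")
    counts = Counter(p.classification for p in products)
    out = dict(sorted(counts.items()))
    out["total"] = len(products)
    return out


def test_stepwise(
    products: list[SplicedProduct],
    intron_order: list[int] | None = None,
) -> tuple[str, list[SplicedProduct]]:
    """Stepwise 5'->3' splicing verdict.

    Consistent iff every product's removed set is a 5'-contiguous prefix of
    the intron order (empty and full sets allowed).  Returns
    ('consistent'|'violated', violating products).
    """
    violations = []
    for p in products:
        order = intron_order or sorted(p.removed | p.retained)
        rank = {idx: i for i, idx in enumerate(order)}
        rem_ranks = {rank[i] for i in p.removed if i in rank}
        if rem_ranks and rem_ranks != set(range(len(rem_ranks))):
            violations.append(p)
    return ("violated" if violations else "consistent", violations)


def note_alternative_model(products: list[SplicedProduct]) -> bool:
    """Whether the observed classes are ALSO compatible with the single-donor
    / alternative-acceptor model.

    True exactly when every non-empty removed set is a 5' prefix -- the two
    models predict identical product classes, so products alone cannot
    distinguish them.  Purely annotational.
    """
    verdict, _ = test_stepwise(products)
    return verdict == "consistent"
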