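"""Intron delineation around snoRNAs, cluster architecture assembly, and
complex-intron detection.

An intron is called when a (donor, branch point, acceptor) triple flanks the
snoRNA with a combined consensus score above threshold; otherwise the snoRNA
is classified exonic (de-intronized).  Scoring is by matches to the donor
consensus GTAAGT (GT prefix required), the branch consensus TACTAAC (<= 2
mismatches) and the acceptor AG, for a maximum of 15.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import (
    ArchElement,
    ClusterArchitecture,
    GenomeRecord,
    IntronAnnotation,
    SnoRNAAnnotation,
)
from .sequences import BRANCH, DONOR, motif_mismatches


@dataclass
class AnnotateParams:
    min_intron_length: int = 40
    max_intron_length: int = 1000
    branch_window: tuple[int, int] = (5, 100)   # nt upstream of the acceptor
    # combined (donor + branch + acceptor) score threshold, of a maximum 15.
    # The default demands exact-consensus signals: in the validated regime
    # functional splice signals are conserved, so any lower-scoring triple is
    # noise (e.g. a residual-stub donor plus a chance branch-like word) that
    # would re-call de-intronized snoRNAs as intronic.  Lower it for
    # permissive scanning of real genomes with degenerate signals.
    score_threshold: int = 15
    max_branch_mismatch: int = 2
    cluster_gap: int = 400          # max snoRNA spacing within one cluster
    exon_margin: int = 30           # cluster span margin beyond outer snoRNAs
    allow_shared_nt: bool = False
    # snoRNA-free (gained) intron scan: exact consensus signals and a
    # pyrimidine run before the acceptor
    gained_branch_to_acceptor: tuple[int, int] = (5, 40)
    gained_min_py: int = 4
    # how far beyond the snoRNA-anchored span terminal exons (and gains into
    # them) are searched
    gained_scan_extension: int = 300


class AnnotationConflict(ValueError):
    pass


# ---------------------------------------------------------------------------
# splice-signal candidates

def find_splice_signals(
    sequence: str,
    region: tuple[int, int],
    params: AnnotateParams | None = None,
):
    """Candidate donors, branch points and acceptors within *region*.

    donors: positions starting GT, scored by matches to GTAAGT (2..6);
    branch points: 7-mers within 2 mismatches of TACTAAC, scored 7 - mm;
    acceptors: positions where an AG ends (position = index of the A).
    Each list is sorted by position.
    """
    p = params or AnnotateParams()
    s, e = region
    if s < 0 or e > len(sequence) or s >= e:
        raise ValueError(f"region {region} outside sequence")
    donors: list[tuple[int, int]] = []
    branches: list[tuple[int, int]] = []
    acceptors: list[int] = []
    for i in range(s, e - 1):
        if sequence[i : i + 2] == "GT":
            word = sequence[i : i + 6]
            score = 2 + sum(
                1 for a, b in zip(word[2:], DONOR[2:]) if a == b
            ) if len(word) == 6 else 2
            donors.append((i, score))
        if sequence[i : i + 2] == "AG":
            acceptors.append(i)
        word = sequence[i : i + 7]
        if len(word) == 7:
            mm = motif_mismatches(word, BRANCH)
            if mm <= p.max_branch_mismatch:
                branches.append((i, 7 - mm))
    return donors, branches, acceptors


# ---------------------------------------------------------------------------
# intron delineation

def delineate_intron(
    snorna: SnoRNAAnnotation,
    genome: GenomeRecord,
    params: AnnotateParams | None = None,
    other_snornas: list[SnoRNAAnnotation] | None = None,
) -> IntronAnnotation | None:
    """Delineate the host intron of *snorna*, or return None (exonic).

    The search extends up to max_intron_length on each side but never past a
    neighbouring snoRNA: each intron hosts one snoRNA, so a candidate intron
    containing another detected snoRNA is not considered.  The best-scoring
    (donor, branch, acceptor) triple wins; ties prefer the shortest intron,
    then the leftmost donor.
    """
    p = params or AnnotateParams()
    seq = genome.sequence
    s0, e0 = snorna.interval
    if s0 < 0 or e0 > len(seq):
        raise ValueError("snoRNA outside genome bounds")
    lo_bound, hi_bound = 0, len(seq)
    if other_snornas:
        for o in other_snornas:
            if o.interval == snorna.interval:
                continue
            if o.interval[1] <= s0:
                lo_bound = max(lo_bound, o.interval[1])
            elif o.interval[0] >= e0:
                hi_bound = min(hi_bound, o.interval[0])
    lo = max(lo_bound, s0 - p.max_intron_length)
    hi = min(hi_bound, e0 + p.max_intron_length)
    if lo >= s0 or e0 >= hi:
        return None

    donors, _, _ = find_splice_signals(seq, (lo, s0), p)
    _, branches, acceptors = find_splice_signals(seq, (e0, hi), p)

    best = None  # (-score, length, donor_pos, branch, acc)
    for acc in acceptors:
        end = acc + 2
        for bpos, bscore in branches:
            if not (p.branch_window[0] <= end - bpos <= p.branch_window[1]):
                continue
            if bpos + 7 > acc:
                continue
            for dpos, dscore in donors:
                length = end - dpos
                if not (p.min_intron_length <= length <= p.max_intron_length):
                    continue
                score = dscore + bscore + 2
                if score < p.score_threshold:
                    continue
                key = (-score, length, dpos)
                if best is None or key < best[:3]:
                    best = (key[0], key[1], key[2], (bpos, bscore), acc)
    if best is None:
        return None
    score = -best[0]
    dpos, (bpos, bscore), acc = best[2], best[3], best[4]
    end = acc + 2
    return IntronAnnotation(
        record_id=genome.record_id,
        interval=(dpos, end),
        donor=seq[dpos : dpos + 6],
        branch_point=(((bpos, bpos + 7)), seq[bpos : bpos + 7]),
        acceptor=seq[end - 2 : end],
        contained_snorna=snorna.family,
        signal_score=float(score),
        intron_id=f"intron_{snorna.sno_id or snorna.family}",
    )


# ---------------------------------------------------------------------------
# snoRNA-free (gained) intron scan

def find_gained_introns(
    genome: GenomeRecord,
    region: tuple[int, int],
    exclude: list[tuple[int, int]],
    params: AnnotateParams | None = None,
) -> list[IntronAnnotation]:
    """Scan *region* for snoRNA-free introns with exact consensus signals.

    Requires an exact donor GTAAGT, an exact branch TACTAAC, the first AG
    after the branch within the configured distance, and a pyrimidine run of
    at least ``gained_min_py`` immediately before the AG.  Known intron
    intervals in *exclude* are skipped.
    """
    p = params or AnnotateParams()
    seq = genome.sequence
    s, e = region
    out: list[IntronAnnotation] = []

    def overlaps_known(a: int, b: int) -> bool:
        return any(not (b <= ks or ke <= a) for ks, ke in exclude)

    i = s
    while i < e - 6:
        if seq[i : i + 6] != DONOR or overlaps_known(i, i + 6):
            i += 1
            continue
        found = None
        limit = min(e, i + p.max_intron_length)
        j = seq.find(BRANCH, i + 6, limit)
        while j != -1:
            lo_d, hi_d = p.gained_branch_to_acceptor
            for acc in range(j + 7, min(limit - 1, j + hi_d)):
                if seq[acc : acc + 2] != "AG":
                    continue
                end = acc + 2
                if end - j < lo_d:
                    continue
                py = seq[max(0, acc - p.gained_min_py) : acc]
                if len(py) < p.gained_min_py or any(c not in "CT" for c in py):
                    continue
                length = end - i
                if p.min_intron_length <= length <= p.max_intron_length \
                        and not overlaps_known(i, end):
                    found = (i, end, j)
                break  # first qualifying AG only
            if found:
                break
            j = seq.find(BRANCH, j + 1, limit)
        if found:
            a, b, j = found
            out.append(
                IntronAnnotation(
                    record_id=genome.record_id,
                    interval=(a, b),
                    donor=seq[a : a + 6],
                    branch_point=(((j, j + 7)), seq[j : j + 7]),
                    acceptor=seq[b - 2 : b],
                    contained_snorna=None,
                    signal_score=15.0,
                    intron_id=f"gained_{a}",
                )
            )
            i = b
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# architecture

def assemble_architecture(
    genome: GenomeRecord,
    snornas: list[SnoRNAAnnotation],
    introns: list[IntronAnnotation],
    cluster_id: str = "cluster1",
    params: AnnotateParams | None = None,
) -> ClusterArchitecture:
    """Partition the cluster span into exons and the given introns."""
    p = params or AnnotateParams()
    intr = sorted(introns, key=lambda x: x.interval)
    for a, b in zip(intr, intr[1:]):
        if b.interval[0] < a.interval[1]:
            raise AnnotationConflict(
                f"overlapping introns {a.interval} and {b.interval}"
            )
    anchors = [iv for ann in snornas for iv in [ann.interval]] + [
        x.interval for x in intr
    ]
    if not anchors:
        raise ValueError("nothing to assemble")
    span_s = max(0, min(a[0] for a in anchors) - p.exon_margin)
    span_e = min(genome.length, max(a[1] for a in anchors) + p.exon_margin)
    elements: list[ArchElement] = []
    pos = span_s
    for x in intr:
        s, e = x.interval
        if s > pos:
            elements.append(ArchElement("exon", (pos, s)))
        elements.append(
            ArchElement("intron", (s, e), snorna_family=x.contained_snorna,
                        intron_id=x.intron_id)
        )
        pos = e
    if span_e > pos:
        elements.append(ArchElement("exon", (pos, span_e)))
    return ClusterArchitecture(cluster_id, genome.record_id, elements)


def detect_complex_introns(architecture: ClusterArchitecture) -> list[list[int]]:
    """Maximal runs of >= 2 adjacent introns (1-based intron order indices)."""
    runs: list[list[int]] = []
    cur: list[int] = []
    order = 0
    for el in architecture.elements:
        if el.kind == "intron":
            order += 1
            cur.append(order)
        else:
            if len(cur) >= 2:
                runs.append(cur)
            cur = []
    if len(cur) >= 2:
        runs.append(cur)
    return runs


# ---------------------------------------------------------------------------
# per-genome annotation driver

@dataclass
class GenomeAnnotation:
    genome: GenomeRecord
    snornas: list[SnoRNAAnnotation]          # all detected snoRNAs, with status
    introns: list[IntronAnnotation]          # all introns (cluster + relocated + gained)
    architecture: ClusterArchitecture | None
    cluster_snornas: list[SnoRNAAnnotation]
    relocated_snornas: list[SnoRNAAnnotation]


def annotate_genome(
    genome: GenomeRecord,
    snornas: list[SnoRNAAnnotation],
    params: AnnotateParams | None = None,
) -> GenomeAnnotation:
    """Delineate introns for every detected snoRNA, split snoRNAs into the
    main cluster vs relocated singletons, scan the cluster for snoRNA-free
    gained introns, and assemble the cluster architecture."""
    p = params or AnnotateParams()
    snos = sorted(snornas, key=lambda a: a.interval)
    introns: list[IntronAnnotation] = []
    for ann in snos:
        intron = delineate_intron(ann, genome, p, other_snornas=snos)
        if intron is None:
            ann.status = "exonic"
        else:
            ann.status = "intronic"
            introns.append(intron)

    # group snoRNAs into clusters by spacing; the largest group is the cluster
    groups: list[list[SnoRNAAnnotation]] = []
    for ann in snos:
        if groups and ann.interval[0] - groups[-1][-1].interval[1] <= p.cluster_gap:
            groups[-1].append(ann)
        else:
            groups.append([ann])
    if not groups:
        return GenomeAnnotation(genome, [], [], None, [], [])
    # the host-gene cluster: most snoRNAs; ties prefer a group holding an
    # exonic (de-intronized) snoRNA -- relocated copies are always intronic
    # single-intron units -- then the leftmost group
    main = max(
        groups,
        key=lambda g: (
            len(g),
            any(a.status == "exonic" for a in g),
            -g[0].interval[0],
        ),
    )
    cluster_snos = main
    relocated = [a for g in groups for a in g if g is not main]

    cluster_ids = {id(a) for a in cluster_snos}
    cluster_introns = [
        x for x in introns
        if any(
            id(a) in cluster_ids
            and x.interval[0] <= a.interval[0] and a.interval[1] <= x.interval[1]
            for a in cluster_snos
        )
    ]
    arch = None
    if cluster_snos:
        pre = assemble_architecture(genome, cluster_snos, cluster_introns, params=p)
        scan_region = (
            max(0, pre.span[0] - p.gained_scan_extension),
            min(genome.length, pre.span[1] + p.gained_scan_extension),
        )
        gained = find_gained_introns(
            genome, scan_region, [x.interval for x in introns], p
        )
        introns.extend(gained)
        arch = assemble_architecture(
            genome, cluster_snos, cluster_introns + gained, params=p
        )
    return GenomeAnnotation(
        genome=genome,
        snornas=snos,
        introns=sorted(introns, key=lambda x: x.interval),
        architecture=arch,
        cluster_snornas=cluster_snos,
        relocated_snornas=relocated,
    )
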