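"""Cross-species comparison: presence/absence matrix, mechanistic evidence
(residual stubs, relocated intron units, chimeras), and tree-aware placement
of classified evolution events by Fitch small parsimony.

The ancestral cluster is assumed intron-rich (root-state prior: every family
intronic), so parsimony ties break toward intronic states and losses are
inferred rather than parallel gains.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import dendropy
import edlib

from .annotate import GenomeAnnotation
from .records import EVENT_KINDS, Evidence, EvolutionEvent, GenomeRecord

FAMILY_STATES = ("intronic", "exonic", "absent")


@dataclass
class CompareParams:
    relocated_min_identity: float = 0.7
    relocated_min_coverage: float = 0.8
    stub_min_len: int = 5
    stub_min_identity: float = 0.8
    stub_end_window: int = 30       # reference-intron terminal window searched
    gained_group_identity: float = 0.7
    min_unit_length: int = 40


# ---------------------------------------------------------------------------
# presence/absence matrix

@dataclass
class PresenceAbsenceMatrix:
    species: list[str]
    rows: dict[str, dict[str, str]]     # row key -> species -> cell state
    row_kind: dict[str, str]            # row key -> "family" | "gained"
    chimeras: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    gained_members: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def polymorphic_rows(self) -> list[str]:
        out = []
        for key, cells in self.rows.items():
            states = {s for s in cells.values() if s != "unknown"}
            if len(states) > 1:
                out.append(key)
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {sp: {k: self.rows[k].get(sp, "unknown") for k in self.rows}
             for sp in self.species}
        )


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return max(0.0, 1.0 - d / max(len(a), len(b)))


def _base_families(ann: GenomeAnnotation) -> dict[str, list]:
    """family -> snoRNA annotations, expanding chimeras to their parents."""
    fams: dict[str, list] = {}
    for sno in ann.snornas:
        if sno.chimeric is not None:
            for f in sno.chimeric[:2]:
                fams.setdefault(f, []).append(sno)
        else:
            fams.setdefault(sno.family, []).append(sno)
    return fams


def build_matrix(
    annotations: dict[str, GenomeAnnotation],
    families: list[str] | None = None,
    params: CompareParams | None = None,
) -> PresenceAbsenceMatrix:
    """Cell states per snoRNA family x species, plus orthology-grouped rows
    for snoRNA-free gained introns.

    States: chimeric > relocated > intronic > exonic > absent; unknown never
    arises from the simulator (the cluster region is always present).
    """
    p = params or CompareParams()
    if len(annotations) < 2:
        raise ValueError("need >= 2 species")
    species = sorted(annotations)
    if families is None:
        families = sorted(
            {f for ann in annotations.values() for f in _base_families(ann)}
        )
    rows: dict[str, dict[str, str]] = {}
    row_kind: dict[str, str] = {}
    chimeras: dict[tuple[str, str], list[str]] = {}

    for sp in species:
        ann = annotations[sp]
        for sno in ann.snornas:
            if sno.chimeric is not None:
                pair = (sno.chimeric[0], sno.chimeric[1])
                chimeras.setdefault(pair, []).append(sp)

    for fam in families:
        cells: dict[str, str] = {}
        for sp in species:
            ann = annotations[sp]
            cluster_ids = {id(a) for a in ann.cluster_snornas}
            reloc_ids = {id(a) for a in ann.relocated_snornas}
            state = "absent"
            hits = _base_families(ann).get(fam, [])
            for sno in hits:
                if sno.chimeric is not None:
                    state = "chimeric"
                    break
                if id(sno) in cluster_ids:
                    state = sno.status if sno.status in ("intronic", "exonic") else "intronic"
                    break
                if id(sno) in reloc_ids:
                    state = "relocated"
            cells[sp] = state
        rows[fam] = cells
        row_kind[fam] = "family"

    # snoRNA-free gained introns: group across species by sequence identity
    gained: list[tuple[str, tuple[int, int], str]] = []  # (species, interval, seq)
    for sp in species:
        ann = annotations[sp]
        if ann.architecture is None:
            continue
        for el in ann.architecture.elements:
            if el.kind == "intron" and el.snorna_family is None:
                s, e = el.interval
                gained.append((sp, (s, e), ann.genome.sequence[s:e]))
    parent = list(range(len(gained)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(gained)):
        for j in range(i + 1, len(gained)):
            if _identity(gained[i][2], gained[j][2]) >= p.gained_group_identity:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(gained)):
        groups.setdefault(find(i), []).append(i)
    gained_members: dict[str, dict[str, tuple[int, int]]] = {}
    for members in groups.values():
        rep = min(gained[i][2] for i in members)
        key = "gain_" + hashlib.sha1(rep.encode()).hexdigest()[:8]
        cells = {sp: "absent" for sp in species}
        gained_members[key] = {}
        for i in members:
            sp, iv, _seq = gained[i]
            cells[sp] = "intronic"
            gained_members[key][sp] = iv
        rows[key] = cells
        row_kind[key] = "gained"

    return PresenceAbsenceMatrix(
        species=species, rows=rows, row_kind=row_kind, chimeras=chimeras,
        gained_members=gained_members,
    )


# ---------------------------------------------------------------------------
# evidence

def detect_residual_stub(
    junction_seq: str,
    reference_intron: str,
    min_stub: int = 5,
    min_identity: float = 0.8,
    end_window: int = 30,
) -> dict | None:
    """Evidence that a missing intron left a residual stub at the exon-exon
    junction.

    A stub is a terminal fragment of the intron, so each intron end is
    aligned as an anchored prefix (5') or suffix (3'): the reported length is
    the longest terminal window found in the junction region at
    >= min_identity.  Anchoring counts every edit over the whole window --
    unlike free local alignment, long chance hits cannot reach the identity
    threshold by gapping -- which makes lengths comparable across species
    (descendants of one deletion share the stub length; independent deletions
    differ).  The longer end wins (ties: 5').

    Returns {"end": "5prime"|"3prime", "length", "identity",
    "junction_offset"} or None."""
    if not junction_seq or not reference_intron:
        return None
    best = None
    hi = min(end_window, len(reference_intron))
    for end in ("5prime", "3prime"):
        for L in range(hi, min_stub - 1, -1):
            q = reference_intron[:L] if end == "5prime" else reference_intron[-L:]
            if len(junction_seq) < L:
                continue
            res = edlib.align(q, junction_seq, mode="HW", task="locations")
            if res["editDistance"] < 0:
                continue
            ident = 1.0 - res["editDistance"] / L
            if ident < min_identity:
                continue
            j0 = res["locations"][0][0]
            cand = {"end": end, "length": L, "identity": round(ident, 3),
                    "junction_offset": int(j0)}
            if best is None or cand["length"] > best["length"]:
                best = cand
            break  # longest qualifying window for this end
    return best


def search_relocated(
    genome: GenomeRecord,
    unit_seq: str,
    min_identity: float = 0.7,
    min_coverage: float = 0.8,
    exclude_span: tuple[int, int] | None = None,
) -> dict | None:
    """Best infix alignment of a lost intron unit against the genome outside
    the donor cluster span; a hit consumes the whole unit, so coverage is 1
    by construction and the identity threshold carries the decision."""
    if len(unit_seq) < 40:
        raise ValueError("unit too short (< 40 nt)")
    seq = genome.sequence
    segments: list[tuple[int, str]] = []
    if exclude_span is None:
        segments.append((0, seq))
    else:
        s, e = exclude_span
        if s > 0:
            segments.append((0, seq[:s]))
        if e < len(seq):
            segments.append((e, seq[e:]))
    best = None
    for off, seg in segments:
        if len(seg) < len(unit_seq) * min_coverage:
            continue
        res = edlib.align(unit_seq, seg, mode="HW", task="locations")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        ident = 1.0 - res["editDistance"] / len(unit_seq)
        if ident < min_identity:
            continue
        s0, e0 = res["locations"][0]
        cand = {"interval": (off + s0, off + e0 + 1), "identity": round(ident, 3)}
        if best is None or cand["identity"] > best["identity"]:
            best = cand
    return best


# ---------------------------------------------------------------------------
# Fitch small parsimony

def fitch_changes(
    tree: dendropy.Tree,
    leaf_states: dict[str, str | None],
    prior_order: list[str],
) -> list[tuple[str, str, str]]:
    """Unordered Fitch parsimony with a root-state prior.

    *leaf_states* maps leaf label -> state (None = unknown wildcard).  The
    first entry of *prior_order* acts as a virtual observation at the root
    (the intron-rich-ancestor assumption), so characters observed only in a
    derived clade are reconstructed as changes, not as the ancestral state.
    Returns (child_label, parent_state, child_state) for every edge on which
    the assigned state changes."""
    universe = set(prior_order) | {s for s in leaf_states.values() if s}
    down: dict[dendropy.Node, set[str]] = {}
    union_formed: dict[dendropy.Node, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            st = leaf_states.get(_label(node))
            down[node] = {st} if st else set(universe)
            union_formed[node] = False
        else:
            sets = [down[c] for c in node.child_nodes()]
            inter = set.intersection(*sets)
            union_formed[node] = not inter
            down[node] = inter if inter else set.union(*sets)
    root = tree.seed_node
    prior = {prior_order[0]}
    if down[root] & prior:
        down[root] = down[root] & prior
    else:
        down[root] = down[root] | prior
        union_formed[root] = True
    # Swofford-Maddison up-pass to most-parsimonious state sets, then a
    # deterministic assignment that prefers the parent's state: genuinely
    # ambiguous changes are thereby delayed toward the tips, where the
    # per-species mechanistic evidence lives.
    final: dict[dendropy.Node, set[str]] = {}
    up: dict[dendropy.Node, str] = {}
    changes = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            final[node] = set(down[node])
            up[node] = _pick(final[node], prior_order)
            continue
        fp = final[node.parent_node]
        if fp <= down[node]:
            final[node] = set(fp)
        elif union_formed[node]:
            final[node] = down[node] | fp
        elif node.is_leaf():
            final[node] = set(down[node])
        else:
            child_union = set.union(*[down[c] for c in node.child_nodes()])
            final[node] = down[node] | (fp & child_union)
        pstate = up[node.parent_node]
        up[node] = pstate if pstate in final[node] else _pick(final[node], prior_order)
        if up[node] != pstate:
            changes.append((_label(node), pstate, up[node]))
    return changes


def _label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else (node.label or "")


def _pick(states: set[str], prior_order: list[str]) -> str:
    for s in prior_order:
        if s in states:
            return s
    return sorted(states)[0]


def _leaves_under(tree: dendropy.Tree, child_label: str) -> list[str]:
    for node in tree.preorder_node_iter():
        if _label(node) == child_label:
            return [_label(lf) for lf in node.leaf_iter()]
    return []


def _mrca_edge(tree: dendropy.Tree, labels: list[str]) -> str | None:
    taxa = [t for t in tree.taxon_namespace if t.label in set(labels)]
    if not taxa:
        return None
    node = tree.mrca(taxa=taxa)
    if node is None or node.parent_node is None:
        return None if node is tree.seed_node and len(labels) == len(tree.leaf_nodes()) \
            else _label(node)
    return _label(node)


# ---------------------------------------------------------------------------
# event placement

def _cluster_intron_of(ann: GenomeAnnotation, family: str):
    for x in ann.introns:
        if x.contained_snorna == family:
            for sno in ann.cluster_snornas:
                if sno.family == family and x.interval[0] <= sno.interval[0] \
                        and sno.interval[1] <= x.interval[1]:
                    return x
    return None


def _reference_intron_seq(annotations: dict[str, GenomeAnnotation], family: str) -> str | None:
    for sp in sorted(annotations):
        x = _cluster_intron_of(annotations[sp], family)
        if x is not None:
            s, e = x.interval
            return annotations[sp].genome.sequence[s:e]
    return None


def _junction_region(
    ann: GenomeAnnotation, family: str, family_order: list[str]
) -> str | None:
    """Exon region between the nearest present neighbours of *family* in the
    cluster, where the lost intron would have sat."""
    if ann.architecture is None:
        return None
    idx = family_order.index(family) if family in family_order else -1
    if idx < 0:
        return None
    left = right = None
    for f in reversed(family_order[:idx]):
        left = _cluster_intron_of(ann, f)
        if left is not None:
            break
    for f in family_order[idx + 1 :]:
        right = _cluster_intron_of(ann, f)
        if right is not None:
            break
    span = ann.architecture.span
    s = left.interval[1] if left is not None else span[0]
    e = right.interval[0] if right is not None else span[1]
    if e <= s:
        return None
    return ann.genome.sequence[s:e]


def place_events(
    matrix: PresenceAbsenceMatrix,
    tree: dendropy.Tree,
    annotations: dict[str, GenomeAnnotation],
    family_order: list[str] | None = None,
    params: CompareParams | None = None,
) -> list[EvolutionEvent]:
    """Fitch state changes per row, classified by mechanistic evidence.

    Relocated-copy evidence outranks stub evidence; a state loss on the same
    branch as a recombination of that family is attributed to the
    recombination and not reported separately."""
    p = params or CompareParams()
    leaf_labels = {_label(lf) for lf in tree.leaf_node_iter()}
    if set(matrix.species) != leaf_labels:
        raise ValueError("matrix species do not match tree leaves")
    family_order = family_order or [
        k for k in matrix.rows if matrix.row_kind[k] == "family"
    ]
    events: list[EvolutionEvent] = []

    # recombination events from chimeras; carriers are grouped by chimera
    # sequence similarity so that one shared fusion gives one event at the
    # carriers' MRCA while unrelated (or misassigned) chimeras stay separate
    recomb_by_family: dict[str, set[str]] = {}
    for (f5, f3), species_list in matrix.chimeras.items():
        items = []
        for sp in sorted(set(species_list)):
            sno = next(
                (s for s in annotations[sp].snornas
                 if s.chimeric is not None and s.chimeric[:2] == (f5, f3)),
                None,
            )
            if sno is None:
                continue
            s0, e0 = sno.interval
            items.append((sp, (sno, annotations[sp].genome.sequence[s0:e0])))
        for group in _group_leaves(
            items, lambda a, b: _identity(a[1], b[1]) >= 0.6
        ):
            leaves = [sp for sp, _ in group]
            branch = _mrca_edge(tree, leaves)
            if branch is None:
                continue
            sno = group[0][1][0]
            events.append(
                EvolutionEvent(
                    kind="recombination", branch=branch, subject=f"{f5}/{f3}",
                    evidence=[Evidence("chimera", {
                        "species": group[0][0], "interval": list(sno.interval),
                        "breakpoint": sno.chimeric[2],
                    })],
                    confidence="supported",
                )
            )
            recomb_by_family.setdefault(f5, set()).add(branch)
            recomb_by_family.setdefault(f3, set()).add(branch)

    for key, cells in matrix.rows.items():
        kind_of_row = matrix.row_kind[key]
        if kind_of_row == "family":
            leaf_states = {}
            for sp in matrix.species:
                st = cells[sp]
                if st in ("relocated", "chimeric"):
                    st = "absent"
                leaf_states[sp] = None if st == "unknown" else st
            changes = fitch_changes(tree, leaf_states, ["intronic", "exonic", "absent"])
            for child, pstate, cstate in changes:
                if cstate == "absent" and child in recomb_by_family.get(key, ()):
                    continue    # consumed by the recombination on this branch
                events.extend(
                    _classify_family_change(
                        key, child, pstate, cstate, matrix, tree, annotations,
                        family_order, p,
                    )
                )
        else:  # gained-intron row
            leaf_states = {
                sp: None if cells[sp] == "unknown" else
                ("present" if cells[sp] == "intronic" else "absent")
                for sp in matrix.species
            }
            changes = fitch_changes(tree, leaf_states, ["absent", "present"])
            for child, pstate, cstate in changes:
                if pstate == "absent" and cstate == "present":
                    bearing = [
                        sp for sp in _leaves_under(tree, child)
                        if cells.get(sp) == "intronic"
                    ]
                    detail = {}
                    if bearing:
                        sp0 = sorted(bearing)[0]
                        detail = {"species": sp0,
                                  "interval": list(matrix.gained_members[key][sp0])}
                    events.append(
                        EvolutionEvent(
                            kind="intron_gain", branch=child, subject=key,
                            evidence=[Evidence("gained_intron", detail)],
                            confidence="supported" if bearing else "inferred",
                        )
                    )
                else:
                    events.append(
                        EvolutionEvent(kind="deletion_loss", branch=child,
                                       subject=key, confidence="inferred")
                    )

    events.extend(exon_loss_events(annotations, tree, family_order, matrix))
    return events


def _relocated_signature(ann: GenomeAnnotation, family: str, flank: int = 25) -> tuple | None:
    """(sno, flanking-sequence fingerprint) for a relocated copy of *family*.

    Copies descending from one shared insertion sit at homologous positions,
    so their insertion-site flanks stay alignable; independent insertions
    land in unrelated background."""
    sno = next(
        (s for s in ann.relocated_snornas
         if s.family == family or (s.chimeric and family in s.chimeric[:2])),
        None,
    )
    if sno is None:
        return None
    host = next(
        (x for x in ann.introns
         if x.interval[0] <= sno.interval[0] and sno.interval[1] <= x.interval[1]),
        None,
    )
    s, e = host.interval if host is not None else sno.interval
    seq = ann.genome.sequence
    return sno, (s, e), seq[max(0, s - flank) : s] + seq[e : e + flank]


def _group_leaves(items: list[tuple[str, object]], same) -> list[list[tuple[str, object]]]:
    """Single-linkage grouping of (leaf, evidence) items under predicate *same*."""
    groups: list[list[tuple[str, object]]] = []
    for item in items:
        placed = False
        for g in groups:
            if any(same(item[1], other[1]) for other in g):
                g.append(item)
                placed = True
                break
        if not placed:
            groups.append([item])
    return groups


def _classify_family_change(
    family: str,
    child: str,
    pstate: str,
    cstate: str,
    matrix: PresenceAbsenceMatrix,
    tree: dendropy.Tree,
    annotations: dict[str, GenomeAnnotation],
    family_order: list[str],
    p: CompareParams,
) -> list[EvolutionEvent]:
    subtree = set(_leaves_under(tree, child))
    if pstate == "intronic" and cstate == "exonic":
        sp0 = sorted(
            sp for sp in subtree if matrix.rows[family].get(sp) == "exonic"
        )
        detail = {}
        if sp0:
            sno = next(
                (s for s in annotations[sp0[0]].cluster_snornas
                 if s.family == family and s.status == "exonic"), None,
            )
            if sno is not None:
                detail = {"species": sp0[0], "interval": list(sno.interval)}
        return [EvolutionEvent(
            kind="deintronization", branch=child, subject=family,
            evidence=[Evidence("degraded_signals", detail)],
            confidence="supported" if detail else "inferred",
        )]
    if cstate == "absent":
        events: list[EvolutionEvent] = []
        # relocated copies: group by insertion-site flanks; one shared
        # insertion -> one event at the carriers' MRCA, independent
        # insertions -> separate events
        reloc_items = []
        for sp in sorted(subtree):
            if matrix.rows[family].get(sp) == "relocated":
                sig = _relocated_signature(annotations[sp], family)
                if sig is not None:
                    reloc_items.append((sp, sig))
        for group in _group_leaves(
            reloc_items, lambda a, b: _identity(a[2], b[2]) >= 0.6
        ):
            leaves = [sp for sp, _ in group]
            branch = _mrca_edge(tree, leaves) or child
            if len(leaves) == len(subtree):
                branch = child
            sno, unit_iv, _sig = group[0][1]
            events.append(EvolutionEvent(
                kind="excision_insertion", branch=branch, subject=family,
                evidence=[Evidence("relocated", {
                    "species": group[0][0],
                    "interval": list(unit_iv),
                    "identity": round(sno.family_identity, 3),
                })],
                confidence="supported",
            ))
        covered = {sp for sp, _ in reloc_items}
        remaining = sorted(
            sp for sp in subtree
            if matrix.rows[family].get(sp) == "absent" and sp not in covered
        )
        if not remaining:
            return events
        # residual stubs: a shared deletion leaves the same-length stub in
        # every descendant (the mutation model has no indels); different stub
        # lengths flag independent deletions
        ref = _reference_intron_seq(annotations, family)
        stub_items = []
        no_stub = []
        for sp in remaining:
            stub = None
            if ref is not None:
                junc = _junction_region(annotations[sp], family, family_order)
                if junc is not None:
                    stub = detect_residual_stub(
                        junc, ref, p.stub_min_len, p.stub_min_identity,
                        p.stub_end_window,
                    )
            if stub is not None:
                stub_items.append((sp, stub))
            else:
                no_stub.append(sp)
        if not stub_items:
            events.append(EvolutionEvent(
                kind="deletion_loss", branch=child, subject=family,
                confidence="inferred",
            ))
            return events
        groups = _group_leaves(
            stub_items, lambda a, b: abs(a["length"] - b["length"]) <= 3
        )
        if len(groups) == 1 and not covered:
            # all observed junctions agree: one event on this branch
            stub = dict(groups[0][0][1])
            stub["species"] = groups[0][0][0]
            events.append(EvolutionEvent(
                kind="deletion_loss", branch=child, subject=family,
                evidence=[Evidence("stub", stub)],
                confidence="supported",
            ))
            return events
        claimed: set[str] = set()
        for group in groups:
            leaves = [sp for sp, _ in group]
            branch = _mrca_edge(tree, leaves) or child
            stub = dict(group[0][1])
            stub["species"] = group[0][0]
            claimed.update(leaves)
            events.append(EvolutionEvent(
                kind="deletion_loss", branch=branch, subject=family,
                evidence=[Evidence("stub", stub)],
                confidence="supported",
            ))
        for sp in no_stub:
            if sp not in claimed:
                events.append(EvolutionEvent(
                    kind="deletion_loss", branch=sp, subject=family,
                    confidence="inferred",
                ))
        return events
    if cstate == "intronic" and pstate in ("absent", "exonic"):
        return [EvolutionEvent(
            kind="intron_gain", branch=child, subject=family, confidence="inferred"
        )]
    return []


# ---------------------------------------------------------------------------
# exon loss

def exon_presence(
    annotations: dict[str, GenomeAnnotation],
) -> dict[tuple[str, str], dict[str, str]]:
    """Per species, for each pair of families hosted by consecutive cluster
    introns: 'present' when exon nucleotides separate them, 'absent' when the
    introns are adjacent, 'unknown' when the pair is not consecutive there."""
    rows: dict[tuple[str, str], dict[str, str]] = {}
    for sp, ann in sorted(annotations.items()):
        if ann.architecture is None:
            continue
        sno_introns = [
            el for el in ann.architecture.elements
            if el.kind == "intron" and el.snorna_family is not None
        ]
        for a, b in zip(sno_introns, sno_introns[1:]):
            fa = a.snorna_family
            fb = b.snorna_family
            gap_nt = 0
            inside = False
            for el in ann.architecture.elements:
                if el is a:
                    inside = True
                    continue
                if el is b:
                    break
                if inside and el.kind == "exon":
                    gap_nt += el.interval[1] - el.interval[0]
            rows.setdefault((fa, fb), {})[sp] = "present" if gap_nt > 0 else "absent"
    for pair, cells in rows.items():
        for sp in annotations:
            cells.setdefault(sp, "unknown")
    return rows


def exon_loss_events(
    annotations: dict[str, GenomeAnnotation],
    tree: dendropy.Tree,
    family_order: list[str],
    matrix: PresenceAbsenceMatrix | None = None,
) -> list[EvolutionEvent]:
    events = []
    for (fa, fb), cells in sorted(exon_presence(annotations).items()):
        leaf_states = {
            sp: None if st == "unknown" else st for sp, st in cells.items()
        }
        for sp in (matrix.species if matrix else leaf_states):
            leaf_states.setdefault(sp, None)
        changes = fitch_changes(tree, leaf_states, ["present", "absent"])
        for child, pstate, cstate in changes:
            if pstate == "present" and cstate == "absent":
                events.append(
                    EvolutionEvent(
                        kind="exon_loss", branch=child, subject=f"{fa}|{fb}",
                        evidence=[Evidence("adjacent_introns", {})],
                        confidence="supported",
                    )
                )
    return events


def count_exon_loss(
    annotations: dict[str, GenomeAnnotation],
    tree: dendropy.Tree,
    family_order: list[str] | None = None,
) -> tuple[int, list[EvolutionEvent]]:
    evs = exon_loss_events(annotations, tree, family_order or [])
    return len(evs), evs


# ---------------------------------------------------------------------------
# recovery scoring

def event_recovery(
    true_events: list, predicted: list[EvolutionEvent]
) -> dict[str, float]:
    """Multiset precision/recall on (kind, branch) pairs."""
    from collections import Counter

    t = Counter((ev.kind, ev.branch) for ev in true_events)
    q = Counter((ev.kind, ev.branch) for ev in predicted)
    inter = sum((t & q).values())
    precision = inter / sum(q.values()) if q else 1.0
    recall = inter / sum(t.values()) if t else 1.0
    return {
        "precision": precision,
        "recall": recall,
        "n_true": sum(t.values()),
        "n_predicted": sum(q.values()),
        "n_matched": inter,
    }
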