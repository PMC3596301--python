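"""Synthetic evolution of polycistronic box C/D snoRNA gene clusters.

The simulator builds an ancestral non-coding host gene whose introns each
carry one box C/D snoRNA, then evolves it along a species tree under six
mechanistic operators -- de-intronization, genomic deletion loss,
excision-and-insertion (DNA-level intron relocation with target-site
duplication), intron recombination (chimeric snoRNAs), internal exon loss and
intron gain (with planted junction inverted repeats) -- plus neutral point
mutation.  Every applied event is recorded in a ground-truth log, and every
leaf genome is emitted together with truth annotations.

Design notes
------------
* Random cluster-internal filler avoids exact splice-donor words and 7-mers
  within 2 mismatches of the branch consensus, so the planted signals are the
  unique exact-consensus splice signals of a cluster (unambiguous truth).
* Every planted intron ends branch + pyrimidine tract + AG: the first AG
  downstream of the branch point is the true acceptor, as in AG-scanning
  splicing.
* Functional motifs (boxes, guide, splice signals including the pyrimidine
  tract) are mutation-protected by default (`protect_motifs`).
"""

from __future__ import annotations

import copy
import functools
import json
import os
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from . import io as sio
from .records import (
    ArchElement,
    BoxMotif,
    ClusterArchitecture,
    GenomeRecord,
    GuideHit,
    IntronAnnotation,
    SnoRNAAnnotation,
)
from .sequences import (
    ACCEPTOR,
    BOX_C,
    BOX_D,
    BRANCH,
    DONOR,
    is_clean,
    motif_mismatches,
    mutate,
    random_dna,
    random_dna_clean,
    revcomp,
)


class ConfigError(ValueError):
    """Simulation configuration that cannot be realized."""


class SimulationError(RuntimeError):
    pass


#: cluster I family names (5'->3'); extended synthetically beyond 7 families
FAMILY_NAMES = ["snR78", "snR77", "snR76", "snR75", "snR74", "snR73", "snR72"]

#: default 12-leaf species tree with labeled ancestral nodes
DEFAULT_TREE = (
    "((((Scer,Spar)n1,(Cgla,Klac)n2)n3,((Dhan,Calb)n4,(Ylip,Spom)n5)n6)n7,"
    "((Ncra,Anid)n8,(Umay,Rory)n9)n10)root;"
)

EVENT_PRIORITY = [
    "deletion_loss",
    "recombination",
    "excision_insertion",
    "deintronization",
    "intron_gain",
    "exon_loss",
]


@functools.lru_cache(maxsize=1)
def rrna_decoy(length: int = 1600) -> str:
    """Deterministic decoy rRNA used as the methylation-guide target."""
    rng = np.random.default_rng(58547)
    return random_dna(rng, length)


@dataclass
class SimulationConfig:
    seed: int = 42
    tree: str = DEFAULT_TREE
    n_snorna_families: int = 7
    snorna_length_range: tuple[int, int] = (70, 100)
    intron_length_range: tuple[int, int] = (60, 200)
    exon_length_range: tuple[int, int] = (5, 80)
    flank_length: int = 2000
    point_mutation_rate: float = 0.0
    p_deintronization: float = 0.0
    p_deletion_loss: float = 0.0
    p_excision_insertion: float = 0.0
    p_recombination: float = 0.0
    p_exon_loss: float = 0.0
    p_intron_gain: float = 0.0
    residual_stub_length_range: tuple[int, int] = (5, 25)
    direct_repeat_length_range: tuple[int, int] = (3, 8)
    inverted_repeat_length_range: tuple[int, int] = (8, 12)
    splice_donor: str = DONOR
    splice_branch: str = BRANCH
    splice_acceptor: str = ACCEPTOR
    protect_motifs: bool = True
    #: probability that an intron gain targets a snoRNA rather than an exon
    p_gain_into_snorna: float = 0.0
    min_insert_distance: int = 500

    def __post_init__(self):
        for name in (
            "snorna_length_range",
            "intron_length_range",
            "exon_length_range",
            "residual_stub_length_range",
            "direct_repeat_length_range",
            "inverted_repeat_length_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ConfigError(f"bad range {name}={lo, hi}")
        for name in (
            "p_deintronization",
            "p_deletion_loss",
            "p_excision_insertion",
            "p_recombination",
            "p_exon_loss",
            "p_intron_gain",
            "p_gain_into_snorna",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0,1]")
        # smallest realizable intron: donor + 3 + snoRNA + 3 + branch + py(4) + AG
        min_fit = 6 + 3 + self.snorna_length_range[0] + 3 + 7 + 4 + 2
        if self.intron_length_range[1] < min_fit:
            raise ConfigError(
                f"intron_length_range too small to host a snoRNA (needs >= {min_fit})"
            )


def benchmark_config(seed: int = 42) -> SimulationConfig:
    """The 12-leaf benchmark conditions: 2% neutral divergence per branch,
    motif protection on, and event rates chosen to yield roughly thirty
    events across all six mechanisms on the default tree."""
    return SimulationConfig(
        seed=seed,
        point_mutation_rate=0.02,
        p_deintronization=0.05,
        p_deletion_loss=0.05,
        p_excision_insertion=0.05,
        p_recombination=0.05,
        p_exon_loss=0.05,
        p_intron_gain=0.05,
    )


# ---------------------------------------------------------------------------
# internal genome model

@dataclass
class SimSno:
    family: str
    seq: str
    box_c: tuple[int, int]
    box_d: tuple[int, int]
    guide: tuple[int, int]
    rrna_offset: int
    chimera: tuple[str, str, int] | None = None
    extra_protected: frozenset[int] = frozenset()
    nested: list = field(default_factory=list)  # [(offset, length, gained_id, rel_protected)]

    def protected(self) -> set[int]:
        out = set(range(*self.box_c)) | set(range(*self.box_d)) | set(range(*self.guide))
        out |= set(self.extra_protected)
        for off, _length, _gid, rel in self.nested:
            out |= {off + i for i in rel}
        return out


@dataclass
class SimIntron:
    seq: str
    sno: SimSno | None
    sno_off: int | None
    branch_off: int
    py_off: int
    py_len: int
    intronic: bool = True
    gained_id: str | None = None
    arm: tuple[int, int] | None = None   # intron-local inverted-repeat arm
    frozen: set[int] = field(default_factory=set)
    relocated: bool = False

    kind = "intron"

    def protected(self, protect_motifs: bool = True) -> set[int]:
        out = set(self.frozen)
        if not protect_motifs:
            return out
        n = len(self.seq)
        if self.intronic:
            out |= set(range(0, 6))                       # donor
            out |= set(range(self.branch_off, self.branch_off + 7))
            out |= set(range(self.py_off, self.py_off + self.py_len))
            out |= {n - 2, n - 1}                          # acceptor AG
        if self.sno is not None:
            out |= {self.sno_off + i for i in self.sno.protected()}
        return out


@dataclass
class SimExon:
    seq: str

    kind = "exon"

    def protected(self, protect_motifs: bool = True) -> set[int]:
        return set()


@dataclass
class SimGenome:
    """left flank parts + cluster elements + right flank parts.

    Flank parts are ("bg", str) or ("unit", SimIntron) pairs; relocated intron
    units live in the flanks."""

    label: str
    left: list
    elements: list
    right: list

    def clone(self, label: str) -> "SimGenome":
        g = copy.deepcopy(self)
        g.label = label
        return g

    def sno_introns(self) -> list[SimIntron]:
        return [
            e for e in self.elements
            if isinstance(e, SimIntron) and e.intronic and e.sno is not None
        ]

    def family_copy_number(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.elements:
            if isinstance(e, SimIntron) and e.sno is not None:
                counts[e.sno.family] = counts.get(e.sno.family, 0) + 1
        for flank in (self.left, self.right):
            for kind, payload in flank:
                if kind == "unit" and payload.sno is not None:
                    counts[payload.sno.family] = counts.get(payload.sno.family, 0) + 1
        return counts


@dataclass
class TrueEvent:
    kind: str
    branch: str
    subject: str
    details: dict = field(default_factory=dict)


@dataclass
class LeafTruth:
    record: GenomeRecord
    snornas: list[SnoRNAAnnotation]
    introns: list[IntronAnnotation]
    architecture: ClusterArchitecture
    sim: SimGenome


@dataclass
class AncestralState:
    record: GenomeRecord
    architecture: ClusterArchitecture
    snornas: list[SnoRNAAnnotation]
    introns: list[IntronAnnotation]
    sim: SimGenome
    references: dict[str, str]
    rrna: str


@dataclass
class SimulationResult:
    config: SimulationConfig
    tree: dendropy.Tree
    ancestor: AncestralState
    leaves: dict[str, LeafTruth]
    events: list[TrueEvent]
    references: dict[str, str]
    rrna: str


# ---------------------------------------------------------------------------
# ancestral cluster

def _family_names(n: int) -> list[str]:
    names = list(FAMILY_NAMES[:n])
    while len(names) < n:
        names.append(f"snRx{len(names) + 1}")
    return names


def _clean_guide_offset(rrna: str, start: int, length: int) -> int:
    """First offset >= start whose reverse-complemented window is free of
    confounding splice motifs, including across the junction with box D."""
    off = start
    while off + length <= len(rrna):
        guide = revcomp(rrna[off : off + length])
        if is_clean(guide) and is_clean(guide + BOX_D[0]):
            return off
        off += 1
    raise ConfigError("rRNA decoy exhausted while placing guides")


def _build_sno(family: str, rrna: str, rrna_off_hint: int, cfg: SimulationConfig,
               rng: np.random.Generator) -> SimSno:
    lo, hi = cfg.snorna_length_range
    for _ in range(50):
        total = int(rng.integers(lo, hi + 1))
        pad5 = int(rng.integers(2, 5))
        pad3 = int(rng.integers(2, 5))
        guide_len = int(rng.integers(10, 22))
        core = total - pad5 - len(BOX_C) - guide_len - len(BOX_D[0]) - pad3
        if core < 1:
            continue
        rrna_off = _clean_guide_offset(rrna, rrna_off_hint, guide_len)
        guide = revcomp(rrna[rrna_off : rrna_off + guide_len])
        seq = (
            random_dna_clean(rng, pad5)
            + BOX_C
            + random_dna_clean(rng, core)
            + guide
            + BOX_D[0]
            + random_dna_clean(rng, pad3)
        )
        if not is_clean(seq):
            continue
        c0 = pad5
        g0 = pad5 + len(BOX_C) + core
        d0 = g0 + guide_len
        return SimSno(
            family=family,
            seq=seq,
            box_c=(c0, c0 + len(BOX_C)),
            box_d=(d0, d0 + len(BOX_D[0])),
            guide=(g0, g0 + guide_len),
            rrna_offset=rrna_off,
        )
    raise ConfigError(f"could not build snoRNA for {family} within configured ranges")


def _build_intron(sno: SimSno | None, cfg: SimulationConfig, rng: np.random.Generator,
                  gained_id: str | None = None, rc_arm: str | None = None) -> SimIntron:
    lo, hi = cfg.intron_length_range
    if sno is not None:
        py_len = int(rng.integers(4, 9))
        fixed = 6 + len(sno.seq) + 7 + py_len + 2
        min_total = fixed + 6           # two spacers >= 3 nt
        if min_total > hi:
            raise ConfigError("intron_length_range cannot fit snoRNA intron")
        total = int(rng.integers(max(lo, min_total), hi + 1))
        spacers = total - fixed
        s1 = int(rng.integers(3, spacers - 2))
        s2 = spacers - s1
        sp1 = random_dna_clean(rng, s1)
        sp2 = random_dna_clean(rng, s2)
        py = "".join("CT"[i] for i in rng.integers(0, 2, size=py_len))
        seq = DONOR + sp1 + sno.seq + sp2 + BRANCH + py + "AG"
        sno_off = 6 + s1
        branch_off = sno_off + len(sno.seq) + s2
        return SimIntron(
            seq=seq, sno=sno, sno_off=sno_off,
            branch_off=branch_off, py_off=branch_off + 7, py_len=py_len,
        )
    # snoRNA-free gained intron: donor + spacer + branch + rc(arm) + py + AG
    assert rc_arm is not None
    py_len = int(rng.integers(4, 7))
    fixed = 6 + 7 + len(rc_arm) + py_len + 2
    min_total = fixed + 3
    if min_total > hi:
        raise ConfigError("intron_length_range cannot fit gained intron")
    total = int(rng.integers(max(lo, min_total), hi + 1))
    sp = random_dna_clean(rng, total - fixed)
    py = "".join("CT"[i] for i in rng.integers(0, 2, size=py_len))
    seq = DONOR + sp + BRANCH + rc_arm + py + "AG"
    branch_off = 6 + len(sp)
    arm_off = branch_off + 7
    return SimIntron(
        seq=seq, sno=None, sno_off=None,
        branch_off=branch_off, py_off=arm_off + len(rc_arm), py_len=py_len,
        gained_id=gained_id, arm=(arm_off, arm_off + len(rc_arm)),
    )


def build_ancestral_cluster(config: SimulationConfig) -> AncestralState:
    """Build the intron-rich ancestor: one cluster of ``n_snorna_families``
    intronic snoRNAs separated by exons, inside neutral flanks."""
    rng = np.random.default_rng([config.seed, 0])
    rrna = rrna_decoy()
    names = _family_names(config.n_snorna_families)

    elements: list = []
    references: dict[str, str] = {}
    elo, ehi = config.exon_length_range
    elements.append(SimExon(random_dna_clean(rng, int(rng.integers(elo, ehi + 1)))))
    for i, family in enumerate(names):
        sno = _build_sno(family, rrna, 50 + i * 190, config, rng)
        references[family] = sno.seq
        elements.append(_build_intron(sno, config, rng))
        elements.append(SimExon(random_dna_clean(rng, int(rng.integers(elo, ehi + 1)))))

    sim = SimGenome(
        label="ancestor",
        left=[("bg", random_dna(rng, config.flank_length))],
        elements=elements,
        right=[("bg", random_dna(rng, config.flank_length))],
    )
    record, snos, introns, arch, _pos = render(sim, species="ancestor")
    return AncestralState(
        record=record, architecture=arch, snornas=snos, introns=introns,
        sim=sim, references=references, rrna=rrna,
    )


# ---------------------------------------------------------------------------
# rendering a SimGenome into a genome record + truth annotations

def render(sim: SimGenome, species: str | None = None):
    """Concatenate the genome model into sequence + truth annotations.

    Returns (record, snornas, introns, architecture, positions) where
    positions maps id(SimIntron) -> genome interval.
    """
    species = species or sim.label
    chunks: list[str] = []
    pos = 0
    snos: list[SnoRNAAnnotation] = []
    introns: list[IntronAnnotation] = []
    positions: dict[int, tuple[int, int]] = {}

    def emit_intron_unit(intron: SimIntron, start: int):
        end = start + len(intron.seq)
        positions[id(intron)] = (start, end)
        if intron.intronic:
            branch_iv = (start + intron.branch_off, start + intron.branch_off + 7)
            introns.append(
                IntronAnnotation(
                    record_id=species,
                    interval=(start, end),
                    donor=intron.seq[:6],
                    branch_point=(branch_iv, intron.seq[intron.branch_off : intron.branch_off + 7]),
                    acceptor=intron.seq[-2:],
                    contained_snorna=intron.sno.family if intron.sno else None,
                    signal_score=15.0,
                    intron_id=intron.gained_id,
                )
            )
        if intron.sno is not None:
            s0 = start + intron.sno_off
            sno = intron.sno
            snos.append(
                SnoRNAAnnotation(
                    record_id=species,
                    interval=(s0, s0 + len(sno.seq)),
                    family=sno.family,
                    box_c=BoxMotif((s0 + sno.box_c[0], s0 + sno.box_c[1]),
                                   sno.seq[sno.box_c[0] : sno.box_c[1]]),
                    box_d=BoxMotif((s0 + sno.box_d[0], s0 + sno.box_d[1]),
                                   sno.seq[sno.box_d[0] : sno.box_d[1]]),
                    guide=GuideHit(offset=sno.guide[0], rrna_offset=sno.rrna_offset,
                                   length=sno.guide[1] - sno.guide[0], mismatches=0),
                    chimeric=sno.chimera,
                    status="intronic" if intron.intronic else "exonic",
                )
            )
            # nested gained introns inside the snoRNA
            for off, length, gid, _rel in sno.nested:
                g0 = s0 + off
                introns.append(
                    IntronAnnotation(
                        record_id=species,
                        interval=(g0, g0 + length),
                        donor=sno.seq[off : off + 6],
                        branch_point=((g0, g0), ""),
                        acceptor=sno.seq[off + length - 2 : off + length],
                        contained_snorna=None,
                        intron_id=gid,
                    )
                )

    def walk_flank(parts):
        nonlocal pos
        for kind, payload in parts:
            if kind == "bg":
                chunks.append(payload)
                pos += len(payload)
            else:
                emit_intron_unit(payload, pos)
                chunks.append(payload.seq)
                pos += len(payload.seq)

    walk_flank(sim.left)

    cluster_start = pos
    arch_elements: list[ArchElement] = []
    exon_start = pos
    for el in sim.elements:
        if isinstance(el, SimIntron) and el.intronic:
            if pos > exon_start:
                arch_elements.append(ArchElement("exon", (exon_start, pos)))
            emit_intron_unit(el, pos)
            chunks.append(el.seq)
            pos += len(el.seq)
            fam = el.sno.family if el.sno else None
            arch_elements.append(
                ArchElement("intron", (positions[id(el)]), snorna_family=fam,
                            intron_id=el.gained_id or (f"intron_{fam}" if fam else None))
            )
            exon_start = pos
        else:
            if isinstance(el, SimIntron):   # de-intronized: sequence is exonic now
                emit_intron_unit(el, pos)
            chunks.append(el.seq)
            pos += len(el.seq)
    if pos > exon_start:
        arch_elements.append(ArchElement("exon", (exon_start, pos)))

    walk_flank(sim.right)

    sequence = "".join(chunks)
    record = GenomeRecord(record_id=species, species=species, sequence=sequence)
    # stable ids: first copy of a family keeps the bare name, later copies _2, _3...
    snos.sort(key=lambda a: a.interval)
    counts: dict[str, int] = {}
    for ann in snos:
        counts[ann.family] = counts.get(ann.family, 0) + 1
        ann.sno_id = ann.family if counts[ann.family] == 1 else f"{ann.family}_{counts[ann.family]}"
    introns.sort(key=lambda a: a.interval)
    for intr in introns:
        if intr.intron_id is None and intr.contained_snorna is not None:
            inner = [a for a in snos if intr.interval[0] <= a.interval[0]
                     and a.interval[1] <= intr.interval[1] and a.family == intr.contained_snorna]
            intr.intron_id = f"intron_{inner[0].sno_id}" if inner else f"intron_{intr.interval[0]}"
        elif intr.intron_id is None:
            intr.intron_id = f"intron_{intr.interval[0]}"
    arch = ClusterArchitecture("cluster1", species, arch_elements)
    return record, snos, introns, arch, positions


# ---------------------------------------------------------------------------
# event operators

def _normalize(elements: list) -> list:
    out: list = []
    for el in elements:
        if isinstance(el, SimExon) and not el.seq:
            continue
        if isinstance(el, SimExon) and out and isinstance(out[-1], SimExon):
            out[-1] = SimExon(out[-1].seq + el.seq)
        else:
            out.append(el)
    return out


def _exon_key(sim: SimGenome, index: int) -> str:
    """Name an exon by the snoRNA families of the nearest hosting introns."""
    left = right = "."
    for e in reversed(sim.elements[:index]):
        if isinstance(e, SimIntron) and e.intronic and e.sno is not None:
            left = e.sno.family
            break
    for e in sim.elements[index + 1 :]:
        if isinstance(e, SimIntron) and e.intronic and e.sno is not None:
            right = e.sno.family
            break
    return f"{left}|{right}"


def apply_deletion_loss(sim: SimGenome, intron: SimIntron, config: SimulationConfig,
                        rng: np.random.Generator, branch: str) -> TrueEvent:
    """Genomic deletion of the intron + snoRNA, keeping a 5' residual stub."""
    i = sim.elements.index(intron)
    lo, hi = config.residual_stub_length_range
    stub_len = int(rng.integers(lo, hi + 1))
    stub = intron.seq[:stub_len]
    sim.elements[i] = SimExon(stub)
    sim.elements[:] = _normalize(sim.elements)
    return TrueEvent(
        kind="deletion_loss", branch=branch,
        subject=intron.sno.family if intron.sno else (intron.gained_id or "?"),
        details={"stub_seq": stub, "stub_len": stub_len, "stub_end": "5prime"},
    )


def apply_deintronization(sim: SimGenome, intron: SimIntron, config: SimulationConfig,
                          rng: np.random.Generator, branch: str) -> TrueEvent:
    """Degenerate the donor GT and branch motif; the sequence (and snoRNA)
    stays in the unspliced transcript."""
    seq = list(intron.seq)
    seq[0] = "C" if rng.random() < 0.5 else "A"
    seq[1] = "C" if rng.random() < 0.5 else "A"
    for _ in range(100):
        word = random_dna(rng, 7)
        if motif_mismatches(word, BRANCH) >= 3 and is_clean(word):
            break
    seq[intron.branch_off : intron.branch_off + 7] = word
    intron.seq = "".join(seq)
    intron.intronic = False
    intron.frozen |= {0, 1} | set(range(intron.branch_off, intron.branch_off + 7))
    return TrueEvent(
        kind="deintronization", branch=branch, subject=intron.sno.family,
        details={"donor_mutated": intron.seq[:6], "branch_mutated": word},
    )


def apply_excision_insertion(sim: SimGenome, intron: SimIntron, config: SimulationConfig,
                             rng: np.random.Generator, branch: str) -> TrueEvent:
    """Excise the full intron unit at the DNA level and re-insert it into a
    staggered double-strand break elsewhere, duplicating the target-site word
    as flanking direct repeats."""
    _rec, _s, _i, _a, pos_before = render(sim)
    donor_iv = pos_before[id(intron)]
    i = sim.elements.index(intron)
    sim.elements.pop(i)
    sim.elements[:] = _normalize(sim.elements)
    intron.relocated = True

    wlen = int(rng.integers(config.direct_repeat_length_range[0],
                            config.direct_repeat_length_range[1] + 1))
    dmin = config.min_insert_distance
    sides = []
    left_len = sum(len(p.seq) if k == "unit" else len(p) for k, p in sim.left)
    right_len = sum(len(p.seq) if k == "unit" else len(p) for k, p in sim.right)
    if left_len - dmin - wlen > 20:
        sides.append("left")
    if right_len - dmin - wlen > 20:
        sides.append("right")
    if not sides:
        raise SimulationError("no insertion site >= min_insert_distance from the cluster")
    side = sides[int(rng.integers(0, len(sides)))]
    flank = sim.left if side == "left" else sim.right

    # eligible global positions within this flank (distance measured to cluster)
    if side == "left":
        lo_g, hi_g = 20, left_len - dmin - wlen
    else:
        lo_g, hi_g = dmin, right_len - wlen - 20
    p_global = int(rng.integers(lo_g, hi_g + 1))
    # map to a background part (retry nearby if it lands in a previous unit)
    new_parts = []
    placed = False
    offset = 0
    for kind, payload in flank:
        plen = len(payload.seq) if kind == "unit" else len(payload)
        if not placed and kind == "bg" and offset <= p_global and p_global + wlen <= offset + plen:
            p_local = p_global - offset
            word = payload[p_local : p_local + wlen]
            new_parts.append(("bg", payload[: p_local + wlen]))
            new_parts.append(("unit", intron))
            new_parts.append(("bg", payload[p_local:]))
            placed = True
        else:
            new_parts.append((kind, payload))
        offset += plen
    if not placed:  # fell inside an earlier insert; put it right after that part
        for j, (kind, payload) in enumerate(new_parts):
            if kind == "bg" and len(payload) > wlen + 1:
                word = payload[-wlen:] if side == "left" else payload[:wlen]
                if side == "left":
                    new_parts[j + 1 : j + 1] = [("unit", intron), ("bg", word)]
                else:
                    new_parts[j:j] = [("bg", word), ("unit", intron)]
                placed = True
                break
        if not placed:
            raise SimulationError("no background segment available for insertion")
    flank[:] = new_parts

    _rec, _s, _i, _a, pos_after = render(sim)
    target_iv = pos_after[id(intron)]
    return TrueEvent(
        kind="excision_insertion", branch=branch, subject=intron.sno.family,
        details={
            "donor_interval": list(donor_iv),
            "target_interval": list(target_iv),
            "repeat_word": word,
            "repeat_len": wlen,
        },
    )


def apply_recombination(sim: SimGenome, intron_a: SimIntron, intron_b: SimIntron,
                        config: SimulationConfig, rng: np.random.Generator,
                        branch: str) -> TrueEvent:
    """Fuse two snoRNA introns into one chimeric intron: 5' of *a* through its
    guide element joined to 3' of *b* from its guide element onward."""
    a, b = intron_a.sno, intron_b.sno
    if a.family == b.family:
        raise ConfigError("recombination requires two distinct families")
    cut_a = intron_a.sno_off + a.guide[1]          # end of a's guide, intron-local
    cut_b = intron_b.sno_off + b.guide[0]          # start of b's guide, intron-local
    chim_seq = intron_a.seq[:cut_a] + intron_b.seq[cut_b:]
    shift = (a.guide[1]) - (b.guide[0])            # sno-local shift for b features
    chim_sno_seq = a.seq[: a.guide[1]] + b.seq[b.guide[0] :]
    chim = SimSno(
        family=f"{a.family}/{b.family}",
        seq=chim_sno_seq,
        box_c=a.box_c,
        box_d=(b.box_d[0] + shift, b.box_d[1] + shift),
        guide=(b.guide[0] + shift, b.guide[1] + shift),
        rrna_offset=b.rrna_offset,
        chimera=(a.family, b.family, a.guide[1]),
        extra_protected=frozenset(range(a.guide[0], a.guide[1])),
    )
    new_intron = SimIntron(
        seq=chim_seq,
        sno=chim,
        sno_off=intron_a.sno_off,
        branch_off=intron_b.branch_off - cut_b + cut_a,
        py_off=intron_b.py_off - cut_b + cut_a,
        py_len=intron_b.py_len,
    )
    ia = sim.elements.index(intron_a)
    ib = sim.elements.index(intron_b)
    assert ia < ib
    sim.elements[ia : ib + 1] = [new_intron]
    sim.elements[:] = _normalize(sim.elements)
    return TrueEvent(
        kind="recombination", branch=branch, subject=f"{a.family}/{b.family}",
        details={"parent_5p": a.family, "parent_3p": b.family,
                 "breakpoint_sno_local": a.guide[1]},
    )


def _exon_loss_eligible(sim: SimGenome, i: int) -> bool:
    """Exon loss joins two neighbour introns into a complex intron, so both
    adjacent elements must be spliced introns."""
    if i <= 0 or i >= len(sim.elements) - 1:
        return False
    left, right = sim.elements[i - 1], sim.elements[i + 1]
    return (
        isinstance(left, SimIntron) and left.intronic
        and isinstance(right, SimIntron) and right.intronic
    )


def apply_exon_loss(sim: SimGenome, exon: SimExon, config: SimulationConfig,
                    rng: np.random.Generator, branch: str) -> TrueEvent:
    i = sim.elements.index(exon)
    if not _exon_loss_eligible(sim, i):
        raise ConfigError("exon_loss requires an internal exon flanked by introns")
    key = _exon_key(sim, i)
    sim.elements.pop(i)
    sim.elements[:] = _normalize(sim.elements)
    return TrueEvent(kind="exon_loss", branch=branch, subject=key, details={})


def apply_intron_gain(sim: SimGenome, target, config: SimulationConfig,
                      rng: np.random.Generator, branch: str) -> TrueEvent | None:
    """Insert a new snoRNA-free intron and plant an inverted repeat: one arm
    is the insertion-point-adjacent upstream sequence, the reverse-complement
    arm sits near the intron's 3' end (before the pyrimidine tract)."""
    lo, hi = config.inverted_repeat_length_range
    arm_len = int(rng.integers(lo, hi + 1))
    # gid drawn from the branch rng: deterministic per run, unique w.h.p.
    gid = f"gain_{branch}_{int(rng.integers(0, 1_000_000)):06d}"
    if isinstance(target, SimExon):
        seq = target.seq
        candidates = [p for p in range(max(arm_len, 3), len(seq) - 2)]
        if not candidates:
            return None
        rng.shuffle(candidates)
        for p in candidates:
            arm = seq[p - arm_len : p]
            rc = revcomp(arm)
            if "AG" in rc or not is_clean(rc) or "N" in arm:
                continue
            gained = _build_intron(None, config, rng, gained_id=gid, rc_arm=rc)
            i = sim.elements.index(target)
            key = _exon_key(sim, i)
            sim.elements[i : i + 1] = [SimExon(seq[:p]), gained, SimExon(seq[p:])]
            sim.elements[:] = _normalize(sim.elements)
            return TrueEvent(
                kind="intron_gain", branch=branch, subject=gid,
                details={"arm_seq": arm, "arm_len": arm_len, "exon": key,
                         "target": "exon"},
            )
        return None
    # target is a SimSno hosted by an intron: insert between guide end and box D
    # target is a snoRNA: insertion point is fixed at the guide/box D junction,
    # so the arm is the guide's 3' end.  An AG inside the reverse-complement
    # arm is tolerated here: nested gains are not subject to the exon scan.
    sno: SimSno = target
    p = sno.guide[1]
    rc = None
    for cand_len in [arm_len] + [x for x in range(lo, hi + 1) if x != arm_len]:
        arm = sno.seq[p - cand_len : p]     # 3' end of the guide element
        rc = revcomp(arm)
        if is_clean(rc):
            arm_len = cand_len
            break
        rc = None
    if rc is None:
        return None
    gained = _build_intron(None, config, rng, gained_id=gid, rc_arm=rc)
    glen = len(gained.seq)
    sno.seq = sno.seq[:p] + gained.seq + sno.seq[p:]
    sno.box_d = (sno.box_d[0] + glen, sno.box_d[1] + glen)
    rel_protected = gained.protected(True)
    sno.nested.append((p, glen, gid, frozenset(rel_protected)))
    host = next(
        e for e in sim.elements
        if isinstance(e, SimIntron) and e.sno is sno
    )
    host.seq = host.seq[: host.sno_off + p] + gained.seq + host.seq[host.sno_off + p :]
    host.branch_off += glen
    host.py_off += glen
    return TrueEvent(
        kind="intron_gain", branch=branch, subject=gid,
        details={"arm_seq": arm, "arm_len": arm_len, "target": "snorna",
                 "host_family": sno.family},
    )


# ---------------------------------------------------------------------------
# evolution along the tree

def _node_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else (node.label or "")


def _label_tree(tree: dendropy.Tree) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if node.taxon is None and not node.label:
            node.label = f"anc{i}" if i else "root"
            i += 1
        else:
            i += 1


def _sample_branch_events(sim: SimGenome, config: SimulationConfig,
                          rng: np.random.Generator) -> list[tuple]:
    """Sample (kind, targets...) proposals for one branch, then resolve
    conflicts: fixed priority, at most one event per element per branch."""
    proposals: list[tuple[int, str, tuple]] = []
    elements = list(sim.elements)
    n = len(elements)
    for idx, el in enumerate(elements):
        if isinstance(el, SimIntron) and el.intronic and el.sno is not None:
            if el.sno.chimera is not None:
                continue  # chimeric introns are not subject to further events
            if rng.random() < config.p_deletion_loss:
                proposals.append((0, "deletion_loss", (el,)))
            if rng.random() < config.p_recombination:
                # partner = nearest downstream snoRNA-bearing intron with no
                # other snoRNA in between (the fusion consumes the whole span)
                partner = None
                for e in elements[idx + 1 :]:
                    if isinstance(e, SimIntron) and e.sno is not None:
                        if (e.intronic and e.sno.chimera is None
                                and e.sno.family != el.sno.family):
                            partner = e
                        break
                if partner is not None:
                    proposals.append((1, "recombination", (el, partner)))
            if rng.random() < config.p_excision_insertion:
                proposals.append((2, "excision_insertion", (el,)))
            if rng.random() < config.p_deintronization:
                proposals.append((3, "deintronization", (el,)))
        elif isinstance(el, SimExon):
            if rng.random() < config.p_intron_gain:
                if (rng.random() < config.p_gain_into_snorna) and sim.sno_introns():
                    hosts = sim.sno_introns()
                    host = hosts[int(rng.integers(0, len(hosts)))]
                    proposals.append((4, "intron_gain", (host.sno,)))
                else:
                    proposals.append((4, "intron_gain", (el,)))
            if _exon_loss_eligible(sim, idx) and rng.random() < config.p_exon_loss:
                proposals.append((5, "exon_loss", (el,)))
    proposals.sort(key=lambda t: t[0])
    claimed: set[int] = set()
    chosen: list[tuple[str, tuple]] = []
    for _prio, kind, targets in proposals:
        ids = {id(t) for t in targets}
        if kind == "recombination":
            a, b = targets
            ia, ib = elements.index(a), elements.index(b)
            ids |= {id(e) for e in elements[ia : ib + 1]}
        if ids & claimed:
            continue
        claimed |= ids
        chosen.append((kind, targets))
    return chosen


def _apply_event(sim: SimGenome, kind: str, targets: tuple, config: SimulationConfig,
                 rng: np.random.Generator, branch: str) -> TrueEvent | None:
    try:
        if kind == "deletion_loss":
            return apply_deletion_loss(sim, targets[0], config, rng, branch)
        if kind == "recombination":
            return apply_recombination(sim, targets[0], targets[1], config, rng, branch)
        if kind == "excision_insertion":
            return apply_excision_insertion(sim, targets[0], config, rng, branch)
        if kind == "deintronization":
            return apply_deintronization(sim, targets[0], config, rng, branch)
        if kind == "intron_gain":
            return apply_intron_gain(sim, targets[0], config, rng, branch)
        if kind == "exon_loss":
            return apply_exon_loss(sim, targets[0], config, rng, branch)
    except SimulationError:
        return None
    except ValueError:
        # target element was consumed by an earlier event on this branch
        return None
    raise ValueError(kind)


def _mutate_genome(sim: SimGenome, rate: float, config: SimulationConfig,
                   rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    pm = config.protect_motifs
    for flank in (sim.left, sim.right):
        for j, (kind, payload) in enumerate(flank):
            if kind == "bg":
                flank[j] = ("bg", mutate(payload, rate, rng))
            else:
                payload.seq = mutate(payload.seq, rate, rng, payload.protected(pm))
    for el in sim.elements:
        el.seq = mutate(el.seq, rate, rng, el.protected(pm))


def evolve_along_tree(
    ancestor: AncestralState,
    config: SimulationConfig,
    forced_events: list[dict] | None = None,
) -> SimulationResult:
    """Pre-order traversal: on each branch apply sampled (and forced) events,
    then neutral point mutation, yielding leaf genomes plus the truth log.

    ``forced_events`` entries look like
    ``{"branch": "Scer", "kind": "deletion_loss", "family": "snR76"}``
    (or ``"exon": "snR77|snR76"`` / ``"target": "exon"`` for gains).
    """
    tree = sio.tree_from_string(config.tree)
    _label_tree(tree)
    leaves_expected = len(tree.leaf_nodes())
    if leaves_expected < 2:
        raise ConfigError("tree must have >= 2 leaves")
    forced = forced_events or []

    states: dict[dendropy.Node, SimGenome] = {}
    events: list[TrueEvent] = []
    leaves: dict[str, LeafTruth] = {}
    warnings: list[str] = []

    for bidx, node in enumerate(tree.preorder_node_iter()):
        label = _node_label(node)
        if node.parent_node is None:
            states[node] = ancestor.sim
            continue
        parent = states[node.parent_node]
        sim = parent.clone(label)
        rng = np.random.default_rng([config.seed, 7919, bidx])

        branch_forced = [f for f in forced if f["branch"] == label]
        claimed: set[int] = set()
        for f in branch_forced:
            ev = _apply_forced(sim, f, config, rng, label)
            if ev is not None:
                events.append(ev)
        for kind, targets in _sample_branch_events(sim, config, rng):
            if any(id(t) in claimed for t in targets):
                continue
            ev = _apply_event(sim, kind, targets, config, rng, label)
            if ev is not None:
                events.append(ev)
                claimed |= {id(t) for t in targets}
        if not sim.sno_introns():
            warnings.append(f"cluster emptied of intronic snoRNAs at {label}")
        blen = node.edge.length if node.edge.length is not None else 1.0
        _mutate_genome(sim, config.point_mutation_rate * blen, config, rng)
        states[node] = sim
        if node.is_leaf():
            record, snos, introns, arch, _pos = render(sim, species=label)
            leaves[label] = LeafTruth(record, snos, introns, arch, sim)

    result = SimulationResult(
        config=config, tree=tree, ancestor=ancestor, leaves=leaves,
        events=events, references=ancestor.references, rrna=ancestor.rrna,
    )
    result.warnings = warnings
    return result


def _apply_forced(sim: SimGenome, f: dict, config: SimulationConfig,
                  rng: np.random.Generator, branch: str) -> TrueEvent | None:
    kind = f["kind"]
    fam = f.get("family")
    if kind in ("deletion_loss", "excision_insertion", "deintronization"):
        el = next(e for e in sim.sno_introns() if e.sno.family == fam)
        return _apply_event(sim, kind, (el,), config, rng, branch)
    if kind == "recombination":
        a = next(e for e in sim.sno_introns() if e.sno.family == f["family_5p"])
        b = next(e for e in sim.sno_introns() if e.sno.family == f["family_3p"])
        return _apply_event(sim, kind, (a, b), config, rng, branch)
    if kind == "exon_loss":
        for i, el in enumerate(sim.elements):
            if isinstance(el, SimExon) and 0 < i < len(sim.elements) - 1:
                if _exon_key(sim, i) == f["exon"]:
                    return _apply_event(sim, kind, (el,), config, rng, branch)
        raise ConfigError(f"no internal exon {f['exon']!r}")
    if kind == "intron_gain":
        if f.get("target") == "snorna":
            host = next(e for e in sim.sno_introns() if e.sno.family == fam)
            return _apply_event(sim, kind, (host.sno,), config, rng, branch)
        exon = f.get("exon")
        for i, el in enumerate(sim.elements):
            if isinstance(el, SimExon) and (exon is None or _exon_key(sim, i) == exon):
                return _apply_event(sim, kind, (el,), config, rng, branch)
        raise ConfigError("no exon available for intron gain")
    raise ValueError(kind)


# ---------------------------------------------------------------------------
# transcripts

def simulate_transcripts(
    genome: GenomeRecord,
    architecture: ClusterArchitecture,
    mode: str,
    n: int,
    seed: int,
    prefix_weights: list[float] | None = None,
    error_rate: float = 0.0,
):
    """Spliced products of the cluster precursor.

    stepwise mode: each product's removed-intron set is a 5'-contiguous prefix
    of the intron order (empty through full), sampled by ``prefix_weights``
    (uniform by default over the k+1 prefixes).
    violation mode: at least one product removes an intron while retaining a
    more-5' one.

    Returns (transcripts, truth) with transcripts = [(id, sequence)] and truth
    the matching removed-index frozensets (1-based intron order indices).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if mode not in ("stepwise", "violation"):
        raise ValueError(f"unknown mode {mode!r}")
    introns = architecture.introns
    k = len(introns)
    if k < 1:
        raise ValueError("architecture has no introns")
    rng = np.random.default_rng(seed)
    if prefix_weights is None:
        weights = np.full(k + 1, 1.0 / (k + 1))
    else:
        weights = np.asarray(prefix_weights, dtype=float)
        if len(weights) != k + 1 or weights.sum() <= 0:
            raise ValueError("prefix_weights must have k+1 nonnegative entries")
        weights = weights / weights.sum()

    all_sets = [frozenset(range(1, j + 1)) for j in range(k + 1)]
    prefix_set = set(all_sets)
    nonprefix = [frozenset(s) for s in _subsets(k) if frozenset(s) not in prefix_set]

    transcripts, truth = [], []
    for t in range(n):
        if mode == "stepwise":
            removed = all_sets[int(rng.choice(k + 1, p=weights))]
        else:
            force = t == 0 or rng.random() < 0.5
            removed = (
                nonprefix[int(rng.integers(0, len(nonprefix)))]
                if force and nonprefix
                else all_sets[int(rng.choice(k + 1, p=weights))]
            )
        seq = spliced_sequence(genome, architecture, removed)
        if error_rate > 0:
            seq = mutate(seq, error_rate, rng)
        transcripts.append((f"t{t}", seq))
        truth.append(removed)
    return transcripts, truth


def _subsets(k: int):
    for mask in range(2 ** k):
        yield {i + 1 for i in range(k) if mask >> i & 1}


def spliced_sequence(genome: GenomeRecord, architecture: ClusterArchitecture,
                     removed: frozenset[int] | set[int]) -> str:
    """Cluster-span sequence with the given introns (1-based order) excised."""
    order = {i + 1: e for i, e in enumerate(architecture.introns)}
    drop = [order[i].interval for i in removed]
    s0, e0 = architecture.span
    seq = []
    pos = s0
    for ds, de in sorted(drop):
        seq.append(genome.sequence[pos:ds])
        pos = de
    seq.append(genome.sequence[pos:e0])
    return "".join(seq)


# ---------------------------------------------------------------------------
# output writing

def write_outputs(result: SimulationResult, outdir: str | os.PathLike) -> None:
    """Per-leaf FASTA + truth GFF3, references, rRNA decoy, tree, event log."""
    os.makedirs(outdir, exist_ok=True)
    for label, leaf in sorted(result.leaves.items()):
        sio.write_fasta([leaf.record], os.path.join(outdir, f"{label}.fasta"))
        sio.write_gff3(
            list(leaf.snornas) + list(leaf.introns),
            os.path.join(outdir, f"{label}.truth.gff3"),
            record_lengths={leaf.record.record_id: leaf.record.length},
        )
    sio.write_fasta(
        [GenomeRecord(fam, fam, seq) for fam, seq in result.references.items()],
        os.path.join(outdir, "refs.fasta"),
    )
    sio.write_fasta(
        [GenomeRecord("rRNA", "rRNA", result.rrna)],
        os.path.join(outdir, "rrna.fasta"),
    )
    result.tree.write(path=os.path.join(outdir, "tree.nwk"), schema="newick",
                      suppress_rooting=True)
    with open(os.path.join(outdir, "truth_events.json"), "w") as fh:
        json.dump([asdict(ev) for ev in result.events], fh, indent=1, sort_keys=True)


def run_simulation(config: SimulationConfig,
                   forced_events: list[dict] | None = None) -> SimulationResult:
    """build_ancestral_cluster + evolve_along_tree in one call."""
    ancestor = build_ancestral_cluster(config)
    return evolve_along_tree(ancestor, config, forced_events=forced_events)
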