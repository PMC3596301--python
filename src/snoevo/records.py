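"""Domain types: genome records, annotations, architectures, events, products.

Intervals are 0-based half-open tuples ``(start, end)`` on the forward strand;
GFF3 1-based inclusive coordinates exist only at the file boundary (snoevo.io).
"""

from __future__ import annotations

from dataclasses import dataclass, field


Interval = tuple[int, int]

EVENT_KINDS = (
    "deintronization",
    "deletion_loss",
    "excision_insertion",
    "recombination",
    "exon_loss",
    "intron_gain",
)

CELL_STATES = ("intronic", "exonic", "absent", "relocated", "chimeric", "unknown")


@dataclass(frozen=True)
class GenomeRecord:
    """One genomic sequence of one species."""

    record_id: str
    species: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"invalid characters in {self.record_id}: {bad}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BoxMotif:
    interval: Interval
    sequence: str


@dataclass(frozen=True)
class GuideHit:
    """Antisense element: reverse complement of an rRNA window."""

    offset: int          # offset within the snoRNA/candidate
    rrna_offset: int     # matched window start on the rRNA
    length: int
    mismatches: int


@dataclass
class SnoRNAAnnotation:
    """A located box C/D snoRNA."""

    record_id: str
    interval: Interval
    family: str                     # e.g. "snR78", or "novel"
    box_c: BoxMotif
    box_d: BoxMotif
    guide: GuideHit | None = None
    family_identity: float = 0.0
    chimeric: tuple[str, str, int] | None = None  # (family_5p, family_3p, breakpoint nt)
    status: str = "intronic"        # "intronic" | "exonic"
    sno_id: str | None = None       # stable id (family, or family_2 for extra copies)

    def validate(self) -> None:
        s, e = self.interval
        if not (s <= self.box_c.interval[0] and self.box_c.interval[1] <= e):
            raise ValueError("box C outside snoRNA interval")
        if not (s <= self.box_d.interval[0] and self.box_d.interval[1] <= e):
            raise ValueError("box D outside snoRNA interval")
        if self.box_c.interval[1] > self.box_d.interval[0]:
            raise ValueError("box C must precede box D")
        if self.box_c.interval[0] - s > 10:
            raise ValueError("box C not within 10 nt of snoRNA 5' end")
        if e - self.box_d.interval[1] > 10:
            raise ValueError("box D not within 10 nt of snoRNA 3' end")
        if self.chimeric is not None and self.chimeric[0] == self.chimeric[1]:
            raise ValueError("chimeric assignment requires two distinct families")


@dataclass
class IntronAnnotation:
    """A spliceosomal intron delineated around (or independent of) a snoRNA."""

    record_id: str
    interval: Interval
    donor: str                      # first 2-6 nt
    branch_point: tuple[Interval, str]
    acceptor: str                   # last 2 nt
    contained_snorna: str | None = None
    signal_score: float = 0.0
    intron_id: str | None = None

    def validate(self) -> None:
        if not self.donor.startswith("GT"):
            raise ValueError("canonical intron must start GT")
        if not self.acceptor.endswith("AG"):
            raise ValueError("canonical intron must end AG")
        (bs, be), _ = self.branch_point
        s, e = self.interval
        if not (s <= bs and be <= e):
            raise ValueError("branch point outside intron")


@dataclass(frozen=True)
class ArchElement:
    kind: str            # "exon" | "intron"
    interval: Interval
    snorna_family: str | None = None
    intron_id: str | None = None


@dataclass
class ClusterArchitecture:
    """Ordered exon/intron layout of one polycistronic cluster."""

    cluster_id: str
    record_id: str
    elements: list[ArchElement]

    def __post_init__(self):
        for a, b in zip(self.elements, self.elements[1:]):
            if a.interval[1] != b.interval[0]:
                raise ValueError("architecture elements must tile contiguously")

    @property
    def span(self) -> Interval:
        return (self.elements[0].interval[0], self.elements[-1].interval[1])

    @property
    def introns(self) -> list[ArchElement]:
        return [e for e in self.elements if e.kind == "intron"]

    def intron_order(self) -> dict[str, int]:
        """1-based 5'->3' order index keyed by intron_id."""
        return {e.intron_id: i + 1 for i, e in enumerate(self.introns)}


@dataclass
class Evidence:
    kind: str                       # "stub" | "relocated" | "chimera" | "degraded_signals" | ...
    detail: dict = field(default_factory=dict)


@dataclass
class EvolutionEvent:
    """One mechanistically classified change placed on a tree branch."""

    kind: str                       # one of EVENT_KINDS
    branch: str                     # child-node label of the edge
    subject: str                    # snoRNA family, exon key or gained-intron id
    evidence: list[Evidence] = field(default_factory=list)
    confidence: str = "inferred"    # "supported" | "inferred"
    repeats: list = field(default_factory=list)  # JunctionRepeat evidence

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class JunctionRepeat:
    """A short direct or inverted repeat at an insertion junction."""

    kind: str                       # "direct" | "inverted"
    arm_length: int
    arm1: tuple[Interval, str]      # in exon/flank
    arm2: tuple[Interval, str]      # in insert/intron
    mismatches: int = 0

    def __post_init__(self):
        if self.kind not in ("direct", "inverted"):
            raise ValueError("repeat kind must be direct or inverted")
        if len(self.arm1[1]) != self.arm_length or len(self.arm2[1]) != self.arm_length:
            raise ValueError("arm sequences must have arm_length")


@dataclass
class SplicedProduct:
    """One transcript's removed/retained intron sets relative to a cluster."""

    transcript_id: str
    cluster_id: str
    removed: frozenset[int]
    retained: frozenset[int]
    alignment_mismatches: int = 0
    classification: str = ""
    partial: bool = False
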