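"""Reading and writing the external formats: FASTA, GFF3, newick, YAML, TSV.

Internal coordinates are 0-based half-open; GFF3 1-based inclusive coordinates
are produced/consumed only here.
"""

from __future__ import annotations

import io as _io
import os
from typing import Iterable

import dendropy
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    BoxMotif,
    GenomeRecord,
    IntronAnnotation,
    SnoRNAAnnotation,
)


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike, species: str | None = None) -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords.

    Sequences are uppercased; characters outside {A,C,G,T,N} (including
    alignment gaps) are rejected; duplicate ids are a format error.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            GenomeRecord(record_id=rec.id, species=species or rec.id, sequence=str(rec.seq))
        )
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | os.PathLike, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.record_id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# GFF3

_GFF_SOURCE = "snoevo"


def _attr_str(pairs: list[tuple[str, str]]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs)


def write_gff3(
    annotations: Iterable[SnoRNAAnnotation | IntronAnnotation],
    path: str | os.PathLike,
    record_lengths: dict[str, int] | None = None,
) -> None:
    """Write snoRNA and intron annotations as GFF3.

    Attribute layout is deliberately minimal and deterministic so that two
    annotation sets describing the same features serialize to identical bytes.
    snoRNA attributes: ID, family, status(intronic|exonic), [chimera].
    intron attributes: ID, snorna(family or .).
    """
    lines: list[tuple[tuple, str]] = []
    for ann in annotations:
        s, e = ann.interval
        if s < 0 or e <= s:
            raise ValueError(f"bad interval {ann.interval}")
        if record_lengths is not None:
            length = record_lengths.get(ann.record_id)
            if length is None:
                raise ValueError(f"unknown record {ann.record_id!r}")
            if e > length:
                raise ValueError(
                    f"annotation {ann.interval} outside record {ann.record_id!r} bounds"
                )
        if isinstance(ann, SnoRNAAnnotation):
            ftype = "snoRNA"
            attrs = [("ID", ann.sno_id or ann.family), ("family", ann.family), ("status", ann.status)]
            if ann.chimeric is not None:
                attrs.append(("chimera", f"{ann.chimeric[0]}|{ann.chimeric[1]}|{ann.chimeric[2]}"))
        elif isinstance(ann, IntronAnnotation):
            ftype = "intron"
            attrs = [
                ("ID", ann.intron_id or f"intron_{s}"),
                ("snorna", ann.contained_snorna or "."),
            ]
        else:
            raise TypeError(type(ann))
        line = "\t".join(
            [
                ann.record_id,
                _GFF_SOURCE,
                ftype,
                str(s + 1),
                str(e),
                ".",
                "+",
                ".",
                _attr_str(attrs),
            ]
        )
        # introns sort before the snoRNAs they contain (by start, then span desc)
        lines.append(((ann.record_id, s, -(e - s), ftype), line))
    lines.sort(key=lambda t: t[0])
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, line in lines:
            fh.write(line + "\n")


def read_gff3(path: str | os.PathLike) -> list[SnoRNAAnnotation | IntronAnnotation]:
    """Parse a GFF3 file written by :func:`write_gff3` back into annotations."""
    out: list[SnoRNAAnnotation | IntronAnnotation] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"bad GFF3 line: {line!r}")
            rec_id, _src, ftype, start1, end1, _score, _strand, _phase, attr_s = fields
            start, end = int(start1) - 1, int(end1)
            attrs = dict(kv.split("=", 1) for kv in attr_s.split(";") if kv)
            if ftype == "snoRNA":
                ann = SnoRNAAnnotation(
                    record_id=rec_id,
                    interval=(start, end),
                    family=attrs.get("family", "novel"),
                    box_c=BoxMotif((start, start), ""),
                    box_d=BoxMotif((end, end), ""),
                )
                ann.sno_id = attrs.get("ID", "")
                ann.status = attrs.get("status", "intronic")
                if "chimera" in attrs:
                    f5, f3, bp = attrs["chimera"].split("|")
                    ann.chimeric = (f5, f3, int(bp))
                out.append(ann)
            elif ftype == "intron":
                sno = attrs.get("snorna", ".")
                out.append(
                    IntronAnnotation(
                        record_id=rec_id,
                        interval=(start, end),
                        donor="GT",
                        branch_point=((start, start), ""),
                        acceptor="AG",
                        contained_snorna=None if sno == "." else sno,
                        intron_id=attrs.get("ID"),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# newick

def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    """Read a single rooted tree; leaf labels must be unique."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises various parse errors
        raise FormatError(f"newick parse error in {path}: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate leaf labels in tree")
    tree.is_rooted = True
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate leaf labels in tree")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# YAML config

def load_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError("config must be a YAML mapping")
    return data
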