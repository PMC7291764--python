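"""Readers and writers for the formats the pipeline touches.

* training-set FASTA (lineage headers, the classifier training dialect)
* plain FASTA
* abundance sidecars (";size=N" id suffixes or two-column TSV)
* BLAST tabular (outfmt 6) recruitment hit tables
* newick trees with branch lengths (patristic-distance queries)

All writers emit UTF-8 with LF line endings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import dendropy
from Bio import SeqIO

from .core import (
    AbundanceTable,
    HabitaxError,
    Lineage,
    MalformedTrainingSetError,
    NucleotideSequence,
    TrainingSequence,
    TrainingSet,
)

PathLike = Union[str, Path]

_SIZE_RE = re.compile(r";size=(\d+)$")


class ParseError(HabitaxError):
    pass


# ---------------------------------------------------------------------------
# plain FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> list[NucleotideSequence]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() or None
        records.append(NucleotideSequence(rec.id, str(rec.seq), desc))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Iterable[NucleotideSequence], path: PathLike,
                width: int = 70) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in seqs:
            header = s.id if s.description is None else f"{s.id} {s.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# training-set FASTA dialect
# ---------------------------------------------------------------------------
#
# The canonical training format carries only the lineage in the header:
#
#   >Bacteria;Firmicutes;...;Dolosigranulum;pigrum;pigrum
#
# Such records have no stable per-record id, so deterministic synthetic ids
# TS_000001, ... are assigned in file order and the species label doubles as
# the taxon id.  A superset dialect keeps explicit identity:
#
#   >seqid|taxon_id Bacteria;Firmicutes;...;pigrum;pigrum
#
# Both round-trip through write_training_fasta/read_training_fasta.

_AUTO_ID_FMT = "TS_{:06d}"
_AUTO_ID_RE = re.compile(r"^TS_\d{6}$")


def read_training_fasta(path: PathLike, expected_depth: Optional[int] = None,
                        ) -> TrainingSet:
    """Read a lineage-annotated training FASTA.

    Depth (7 or 8) is inferred from the first record and must be uniform;
    ``expected_depth`` additionally pins it.  A trailing ";" on headers is
    tolerated.  Raises :class:`MalformedTrainingSetError` naming the offending
    header on ragged or mismatched depth, and :class:`ParseError` on an empty
    file.
    """
    members: list[TrainingSequence] = []
    depth: Optional[int] = None
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        header = rec.description
        if " " in header:
            token, lineage_text = header.split(None, 1)
            if "|" in token:
                seq_id, taxon_id = token.split("|", 1)
            else:
                seq_id, taxon_id = token, ""
        else:
            seq_id, taxon_id, lineage_text = _AUTO_ID_FMT.format(i), "", header
        lineage = Lineage.from_header(lineage_text)
        if not taxon_id:
            taxon_id = lineage.species
        if depth is None:
            depth = lineage.depth
            if expected_depth is not None and depth != expected_depth:
                raise MalformedTrainingSetError(
                    f"expected depth {expected_depth}, file has depth {depth} "
                    f"(header {header!r})"
                )
        elif lineage.depth != depth:
            raise MalformedTrainingSetError(
                f"ragged lineage depth: header {header!r} has depth "
                f"{lineage.depth}, previous records have {depth}"
            )
        members.append(TrainingSequence(
            NucleotideSequence(seq_id, str(rec.seq)), lineage, taxon_id))
    if not members:
        raise ParseError(f"no records in training FASTA {path}")
    return TrainingSet(members, depth=depth)


def write_training_fasta(ts: TrainingSet, path: PathLike, width: int = 70,
                         ) -> None:
    """Write a training set in the lineage-header dialect.

    Records whose ids were auto-assigned on read (and whose taxon id is the
    species-label fallback) are written with bare lineage headers; everything
    else keeps its explicit ``id|taxon_id`` token.  Record order is preserved,
    so write -> read is the identity on (id, seq, lineage).
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for m in ts.members:
            bare = (_AUTO_ID_RE.match(m.id) is not None
                    and m.taxon_id == m.lineage.species)
            if bare:
                fh.write(f">{m.lineage.to_header()}\n")
            else:
                fh.write(f">{m.id}|{m.taxon_id} {m.lineage.to_header()}\n")
            for i in range(0, len(m.sequence.seq), width):
                fh.write(m.sequence.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# abundances
# ---------------------------------------------------------------------------

def strip_size_annotation(seq_id: str) -> tuple[str, Optional[int]]:
    """Split a ";size=N" suffix off a FASTA id, if present."""
    m = _SIZE_RE.search(seq_id)
    if m:
        return seq_id[:m.start()], int(m.group(1))
    return seq_id, None


def read_abundances(source: PathLike,
                    fasta: bool = False) -> AbundanceTable:
    """Load an abundance table.

    ``fasta=True`` reads ";size=N" annotations from FASTA ids; otherwise the
    source is a two-column (id TAB count) TSV sidecar.  Records without a size
    annotation get count 0.
    """
    counts: dict[str, int] = {}
    if fasta:
        for rec in SeqIO.parse(str(source), "fasta"):
            base, size = strip_size_annotation(rec.id)
            counts[base] = size if size is not None else 0
        return AbundanceTable(counts)
    with open(source, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{source}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}")
            counts[parts[0]] = int(parts[1])
    return AbundanceTable(counts)


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

@dataclass
class RecruitmentHit:
    """One reference-vs-candidate alignment considered for recruitment.

    ``coverage`` is the aligned reference span divided by the reference
    length, x100.  ``subject_seq`` / ``aligned_portion`` are filled in when
    sequences are available (built-in alignment mode, or attached from a
    candidate pool); the tabular reader leaves them None.
    """

    ref_id: str
    subject_id: str
    percent_identity: float
    coverage: float
    subject_length: Optional[int] = None
    subject_seq: Optional[NucleotideSequence] = None
    aligned_portion: Optional[NucleotideSequence] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"percent_identity out of range: "
                             f"{self.percent_identity}")
        if not (0.0 <= self.coverage <= 100.0 + 1e-9):
            raise ValueError(f"coverage out of range: {self.coverage}")


BLAST6_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch",
                  "gapopen", "qstart", "qend", "sstart", "send",
                  "evalue", "bitscore")


def read_blast_tabular(path: PathLike,
                       ref_lengths: Mapping[str, int],
                       subject_lengths: Optional[Mapping[str, int]] = None,
                       ) -> list[RecruitmentHit]:
    """Parse a 12-column BLAST tabular hit file (queries are the references).

    Coverage is computed as aligned reference span (qend - qstart + 1) over
    the reference length from ``ref_lengths``, x100.  A 13th column, when
    present, is taken as the subject length (slen); otherwise subject lengths
    may be supplied via ``subject_lengths``.  An empty file yields an empty
    list; a line with the wrong column count raises :class:`ParseError` with
    its line number.
    """
    hits: list[RecruitmentHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                raise ParseError(
                    f"{path}:{lineno}: expected 12 (or 13 with slen) "
                    f"tab-separated columns, got {len(parts)}")
            qid, sid = parts[0], parts[1]
            pident = float(parts[2])
            qstart, qend = int(parts[6]), int(parts[7])
            if qid not in ref_lengths:
                raise ParseError(
                    f"{path}:{lineno}: no reference length for query {qid!r}")
            span = abs(qend - qstart) + 1
            coverage = 100.0 * span / ref_lengths[qid]
            slen: Optional[int] = None
            if len(parts) == 13:
                slen = int(parts[12])
            elif subject_lengths is not None:
                slen = subject_lengths.get(sid)
            hits.append(RecruitmentHit(qid, sid, pident,
                                       min(coverage, 100.0), slen))
    return hits


# ---------------------------------------------------------------------------
# newick / patristic distances
# ---------------------------------------------------------------------------

class PatristicTree:
    """A rooted/unrooted newick tree supporting patristic-distance queries.

    The patristic distance between two leaves is the sum of branch lengths
    along the path connecting them.  Construction fails if any edge (other
    than the root edge) lacks a branch length or if leaf names repeat.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ParseError("duplicate leaf names in tree")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ParseError(
                    "tree edge without branch length; patristic distances "
                    "are undefined")
        self._pdm = tree.phylogenetic_distance_matrix()
        self._taxa = {t.label: t for t in tree.taxon_namespace}

    @property
    def leaf_names(self) -> list[str]:
        return sorted(self._taxa)

    def distance(self, a: str, b: str) -> float:
        try:
            ta, tb = self._taxa[a], self._taxa[b]
        except KeyError as e:
            raise KeyError(f"leaf {e.args[0]!r} not in tree") from None
        if a == b:
            return 0.0
        return float(self._pdm.patristic_distance(ta, tb))


def read_newick(path: PathLike) -> PatristicTree:
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except dendropy.utility.error.DataParseError as e:
        raise ParseError(f"invalid newick in {path}: {e}") from e
    return PatristicTree(tree)


def parse_newick(text: str) -> PatristicTree:
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except dendropy.utility.error.DataParseError as e:
        raise ParseError(f"invalid newick: {e}") from e
    return PatristicTree(tree)
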