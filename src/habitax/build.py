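"""Training-set construction: reference trimming, sequence recruitment,
full-length compilation, region extraction, identical-sequence curation and
supraspecies definition.

The pipeline mirrors the way habitat-specific classifier training sets are
built from a curated full-length 16S reference database:

1. references trimmed to a fixed primer window so percent identity is
   computed on comparable spans;
2. public/candidate sequences recruited to each reference at high identity
   and coverage and pooled per taxon ("compilation" training set, which
   captures the natural within-taxon sequence variability);
3. the compilation trimmed to the sequenced sub-region (e.g. V1-V3);
4. region-identical sequences from different species collapsed into single
   records with ":"-concatenated names;
5. species whose region sequences are phylogenetically closer than a small
   distance threshold grouped under a training-set-specific "supraspecies"
   rank inserted between genus and species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Optional, Sequence

import edlib
import numpy as np

from .core import (
    FULL_LENGTH,
    GAP_CHARS,
    HabitaxError,
    Lineage,
    NucleotideSequence,
    TrainingSequence,
    TrainingSet,
    concat_label,
    label_components,
)
from .io import PatristicTree, RecruitmentHit

logger = logging.getLogger(__name__)


class BuildError(HabitaxError):
    pass


@dataclass
class BuildParams:
    """All constants of the construction pipeline.

    Positions are 1-based inclusive.  ``trim_start``/``trim_end`` delimit the
    primer window on the full-length references; ``region_start``/``region_end``
    are columns of the gapped reference alignment delimiting the sequenced
    sub-region.  Identity/coverage thresholds are percentages.
    """

    trim_start: int = 28
    trim_end: int = 1373
    recruit_min_identity: float = 99.0
    recruit_min_coverage: float = 98.0
    candidate_min_identity: float = 97.0
    min_subject_len: int = 1000
    whole_subject_max_len: int = 2000
    region_start: int = 40
    region_end: int = 880
    region_name: str = "V1V3"
    supraspecies_distance: float = 0.005
    intergenus_min_support: int = 4
    intergenus_policy: Literal["drop-minority", "drop-all",
                               "keep-best-supported"] = "drop-minority"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("recruit_min_identity", "recruit_min_coverage",
                     "candidate_min_identity"):
            v = getattr(self, name)
            if not (0.0 < v <= 100.0):
                raise ValueError(f"{name} must be in (0, 100], got {v}")
        if self.trim_start >= self.trim_end:
            raise ValueError("trim_start must be < trim_end")
        if self.region_start >= self.region_end:
            raise ValueError("region_start must be < region_end")
        if self.supraspecies_distance <= 0:
            raise ValueError("supraspecies_distance must be positive")


# ---------------------------------------------------------------------------
# reference trimming
# ---------------------------------------------------------------------------

def trim_reference(ref: NucleotideSequence,
                   params: BuildParams) -> NucleotideSequence:
    """Trim a full-length reference to the [trim_start, trim_end] window.

    References shorter than ``trim_start`` leave an empty window and are an
    error; references shorter than ``trim_end`` are truncated with a logged
    warning (hanging 5'/3' ends would otherwise bias identity).
    """
    if len(ref) < params.trim_start:
        raise BuildError(
            f"reference {ref.id!r} ({len(ref)} nt) is shorter than "
            f"trim_start={params.trim_start}; trim window is empty")
    if len(ref) < params.trim_end:
        logger.warning(
            "reference %s (%d nt) shorter than trim_end=%d; output truncated",
            ref.id, len(ref), params.trim_end)
    trimmed = ref.seq[params.trim_start - 1:params.trim_end]
    return NucleotideSequence(ref.id, trimmed, ref.description)


# ---------------------------------------------------------------------------
# built-in recruitment (candidate-pool mode)
# ---------------------------------------------------------------------------

def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops: list[tuple[int, str]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops


def _identity_and_coverage(cigar: str, ref_len: int) -> tuple[float, float]:
    """Percent identity and reference coverage from a ref-vs-candidate cigar.

    The cigar comes from aligning the reference (query) into the candidate
    (target): "=" match, "X" mismatch, "I" reference-only column, "D"
    candidate-only column.  Terminal reference-only runs are reference bases
    the candidate does not cover: they reduce coverage and are excluded from
    the identity denominator (identity is over the aligned span, as a local
    aligner would report it).
    """
    ops = _parse_cigar(cigar)
    lead = ops[0][0] if ops and ops[0][1] == "I" else 0
    trail = ops[-1][0] if len(ops) > 1 and ops[-1][1] == "I" else 0
    matches = columns = 0
    for n, op in ops:
        columns += n
        if op == "=":
            matches += n
    aligned_cols = columns - lead - trail
    identity = 100.0 * matches / aligned_cols if aligned_cols else 0.0
    coverage = 100.0 * (ref_len - lead - trail) / ref_len
    return identity, coverage


def align_candidates(refs: Sequence[NucleotideSequence],
                     pool: Sequence[NucleotideSequence],
                     params: BuildParams) -> list[RecruitmentHit]:
    """Align every candidate against every (trimmed) reference.

    This is the network-free replacement for a remote BLAST recruitment
    search.  Each reference is aligned semi-globally into each candidate
    (gaps at the candidate's ends are free, so full-length candidates with
    primer overhangs are not penalized); identity and reference coverage
    come from the resulting edit-distance alignment, and pairs below
    ``candidate_min_identity`` produce no hit.  The candidate span covering
    the reference is recorded as the aligned portion, used when only a
    fragment of a long subject (e.g. a genome) should be recruited.
    """
    hits: list[RecruitmentHit] = []
    for cand in pool:
        for ref in refs:
            k = (int(math.ceil(
                    (1.0 - params.candidate_min_identity / 100.0) * len(ref)))
                 + int(math.ceil(
                    (1.0 - params.recruit_min_coverage / 100.0) * len(ref)))
                 + 8)
            res = edlib.align(ref.seq, cand.seq, mode="HW", task="path", k=k)
            if res["editDistance"] < 0:
                continue
            identity, coverage = _identity_and_coverage(res["cigar"],
                                                        len(ref))
            if identity < params.candidate_min_identity:
                continue
            t_start, t_end = res["locations"][0]
            aligned = NucleotideSequence(cand.id,
                                         cand.seq[t_start:t_end + 1],
                                         cand.description)
            hits.append(RecruitmentHit(
                ref_id=ref.id, subject_id=cand.id,
                percent_identity=identity, coverage=min(coverage, 100.0),
                subject_length=len(cand), subject_seq=cand,
                aligned_portion=aligned))
    return hits


# ---------------------------------------------------------------------------
# hit filtering and taxon assignment
# ---------------------------------------------------------------------------

def filter_recruitment_hits(hits: Iterable[RecruitmentHit],
                            params: BuildParams,
                            pool: Optional[Mapping[str, NucleotideSequence]]
                            = None) -> list[RecruitmentHit]:
    """Keep hits passing the recruitment thresholds and resolve members.

    A hit is retained when identity >= ``recruit_min_identity``, coverage >=
    ``recruit_min_coverage`` and the subject is at least ``min_subject_len``
    nt.  Subjects up to ``whole_subject_max_len`` nt contribute their whole
    sequence; longer subjects (e.g. whole genomes) contribute only the aligned
    portion.  ``pool`` supplies subject sequences for hits read from tabular
    files.
    """
    kept: list[RecruitmentHit] = []
    for h in hits:
        if h.subject_length is None:
            raise BuildError(
                f"hit {h.ref_id}->{h.subject_id} lacks a subject length; "
                "supply slen or a subject-length mapping")
        if (h.percent_identity < params.recruit_min_identity
                or h.coverage < params.recruit_min_coverage
                or h.subject_length < params.min_subject_len):
            continue
        h = replace(h)
        if h.subject_seq is None and pool is not None:
            h.subject_seq = pool.get(h.subject_id)
        if h.subject_length <= params.whole_subject_max_len:
            if h.subject_seq is None:
                raise BuildError(
                    f"hit {h.ref_id}->{h.subject_id}: whole subject sequence "
                    "needed but not available")
            h.aligned_portion = h.subject_seq
        else:
            if h.aligned_portion is None:
                raise BuildError(
                    f"hit {h.ref_id}->{h.subject_id}: aligned portion needed "
                    f"for long subject ({h.subject_length} nt) but not "
                    "available")
        kept.append(h)
    return kept


@dataclass
class CompilationCluster:
    """Recruited sequences pooled under one taxon."""

    taxon_id: str
    reference_ids: list[str]
    member_sequences: list[NucleotideSequence] = field(default_factory=list)


def assign_members_to_taxa(filtered_hits: Sequence[RecruitmentHit],
                           ref_taxa: Mapping[str, str],
                           params: BuildParams,
                           ) -> list[CompilationCluster]:
    """Assign every recruited subject to exactly one taxon.

    A subject hitting several taxa goes to the taxon of its best hit
    (identity, then coverage); exact ties are broken by a seeded uniform
    choice, making the otherwise irreproducible random assignment
    reproducible under ``params.rng_seed``.  Per-taxon member counts are
    logged.
    """
    rng = np.random.default_rng(params.rng_seed)
    by_subject: dict[str, list[RecruitmentHit]] = {}
    for h in filtered_hits:
        by_subject.setdefault(h.subject_id, []).append(h)

    clusters: dict[str, CompilationCluster] = {}
    refs_per_taxon: dict[str, set[str]] = {}
    for ref_id, taxon in ref_taxa.items():
        refs_per_taxon.setdefault(taxon, set()).add(ref_id)

    for subject_id in sorted(by_subject):
        shits = by_subject[subject_id]
        best_per_taxon: dict[str, RecruitmentHit] = {}
        for h in shits:
            try:
                taxon = ref_taxa[h.ref_id]
            except KeyError:
                raise BuildError(f"hit references unknown reference "
                                 f"{h.ref_id!r}") from None
            cur = best_per_taxon.get(taxon)
            if cur is None or ((h.percent_identity, h.coverage)
                               > (cur.percent_identity, cur.coverage)):
                best_per_taxon[taxon] = h
        ranked = sorted(best_per_taxon.items(),
                        key=lambda kv: (-kv[1].percent_identity,
                                        -kv[1].coverage, kv[0]))
        top_score = (ranked[0][1].percent_identity, ranked[0][1].coverage)
        tied = [t for t, h in ranked
                if (h.percent_identity, h.coverage) == top_score]
        taxon = tied[0] if len(tied) == 1 else tied[int(rng.integers(len(tied)))]
        member = best_per_taxon[taxon].aligned_portion
        if member is None:
            member = best_per_taxon[taxon].subject_seq
        if member is None:
            raise BuildError(f"no member sequence for subject {subject_id!r}")
        cl = clusters.setdefault(
            taxon, CompilationCluster(taxon, sorted(refs_per_taxon.get(taxon,
                                                                       ()))))
        cl.member_sequences.append(member)

    result = [clusters[t] for t in sorted(clusters)]
    for cl in result:
        logger.info("taxon %s: %d recruited members", cl.taxon_id,
                    len(cl.member_sequences))
    return result


def compile_full_length_ts(refs_with_lineages: Sequence[TrainingSequence],
                           clusters: Sequence[CompilationCluster],
                           ) -> TrainingSet:
    """Assemble the full-length compilation training set.

    Every reference is a member; every cluster member carries its taxon's
    lineage.  With no clusters this degenerates to the references-only
    training set (one-to-few sequences per taxon).
    """
    lineage_by_taxon: dict[str, Lineage] = {}
    for r in refs_with_lineages:
        if r.lineage.depth != 7:
            raise BuildError("reference lineages must be depth 7")
        lineage_by_taxon.setdefault(r.taxon_id, r.lineage)
    members: list[TrainingSequence] = list(refs_with_lineages)
    seen = {m.id for m in members}
    for cl in clusters:
        if cl.taxon_id not in lineage_by_taxon:
            raise BuildError(f"cluster taxon {cl.taxon_id!r} has no lineage")
        lineage = lineage_by_taxon[cl.taxon_id]
        for seq in cl.member_sequences:
            if seq.id in seen:
                raise BuildError(
                    f"member {seq.id!r} appears in more than one cluster")
            seen.add(seq.id)
            members.append(TrainingSequence(seq, lineage, cl.taxon_id))
    return TrainingSet(members, depth=7, region=FULL_LENGTH)


# ---------------------------------------------------------------------------
# region extraction
# ---------------------------------------------------------------------------

def extract_region(gapped_alignment: Mapping[str, str],
                   member_ids: Sequence[str],
                   params: BuildParams) -> list[NucleotideSequence]:
    """Take alignment columns [region_start, region_end] and degap.

    ``gapped_alignment`` maps sequence id to its gapped row.  Members whose
    region slice is all gaps are dropped with a warning; a member missing from
    the alignment, or a region extending past the alignment width, is an
    error.
    """
    out: list[NucleotideSequence] = []
    for mid in member_ids:
        if mid not in gapped_alignment:
            raise BuildError(f"member {mid!r} missing from gapped alignment")
        row = gapped_alignment[mid]
        if params.region_end > len(row):
            raise BuildError(
                f"region end {params.region_end} beyond alignment width "
                f"{len(row)}")
        piece = row[params.region_start - 1:params.region_end]
        degapped = "".join(c for c in piece if c not in GAP_CHARS)
        if not degapped:
            logger.warning("member %s has no aligned bases in the region; "
                           "dropped", mid)
            continue
        out.append(NucleotideSequence(mid, degapped))
    return out


def extract_region_by_reference(ref: NucleotideSequence,
                                members: Sequence[NucleotideSequence],
                                region_start: int, region_end: int,
                                ) -> list[NucleotideSequence]:
    """Built-in region extraction without a precomputed multiple alignment.

    Each member is globally aligned to its reference and the member bases
    aligned to (ungapped) reference positions [region_start, region_end]
    (1-based inclusive) are returned, gaps removed.  Members with no bases in
    the region are dropped with a warning.
    """
    if region_end > len(ref):
        raise BuildError(f"region end {region_end} beyond reference length "
                         f"{len(ref)}")
    out: list[NucleotideSequence] = []
    for mem in members:
        res = edlib.align(mem.seq, ref.seq, mode="NW", task="path")
        start, end = _member_span_for_ref_window(res["cigar"], region_start,
                                                 region_end)
        if end <= start:
            logger.warning("member %s has no aligned bases in the region; "
                           "dropped", mem.id)
            continue
        out.append(NucleotideSequence(mem.id, mem.seq[start:end],
                                      mem.description))
    return out


def _member_span_for_ref_window(cigar: str, ref_start: int, ref_end: int,
                                ) -> tuple[int, int]:
    """Member 0-based [start, end) span aligned to reference [start, end]."""
    ops: list[tuple[int, str]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    mpos = rpos = 0  # consumed member / reference bases
    mstart = mend = None
    for n, op in ops:
        consumes_m = op in ("=", "X", "I")
        consumes_r = op in ("=", "X", "D")
        for _ in range(n):
            if consumes_r:
                rpos += 1
                if rpos == ref_start:
                    mstart = mpos
                if rpos == ref_end:
                    mend = mpos + (1 if consumes_m else 0)
            if consumes_m:
                mpos += 1
        if mend is not None:
            break
    if mstart is None:
        mstart = mpos
    if mend is None:
        mend = mpos
    return mstart, mend


# ---------------------------------------------------------------------------
# identical-sequence curation (collapse)
# ---------------------------------------------------------------------------

@dataclass
class CollapseEvent:
    """Record of one duplicate-sequence group resolution."""

    sequence: str
    member_ids: list[str]
    taxon_ids: list[str]
    action: str          # "collapsed" | "intergenus-collapsed" |
                         # "intergenus-rejected"
    kept_id: Optional[str] = None
    detail: str = ""


def collapse_identical(raw_ts: TrainingSet, params: BuildParams,
                       ) -> tuple[TrainingSet, list[CollapseEvent]]:
    """Collapse exactly identical region sequences into single records.

    Duplicates within one species keep their name; duplicates across species
    of one genus get the ":"-concatenation of the species labels (components
    sorted lexicographically).  Duplicates spanning two or more genera are
    accepted only when supported by at least ``intergenus_min_support``
    sequences, in which case both genus and species labels are concatenated;
    otherwise the merge is rejected and resolved by ``intergenus_policy``:

    * ``drop-minority`` (default): drop the sequences of all but the
      best-supported genus in the group, then collapse the rest;
    * ``drop-all``: drop the whole group;
    * ``keep-best-supported``: like drop-minority (the best-supported genus's
      record is kept) but logs the dropped taxa explicitly.

    Region-specific by construction: refuses full-length input.  Idempotent.
    """
    if raw_ts.region == FULL_LENGTH:
        raise BuildError("collapse_identical operates on region-trimmed "
                         "training sets")
    groups: dict[str, list[TrainingSequence]] = {}
    order: list[str] = []
    for m in raw_ts.members:
        if m.sequence.seq not in groups:
            order.append(m.sequence.seq)
        groups.setdefault(m.sequence.seq, []).append(m)

    events: list[CollapseEvent] = []
    out: list[TrainingSequence] = []
    for seq in order:
        grp = groups[seq]
        if len(grp) == 1:
            out.append(grp[0])
            continue
        genera = {m.lineage.genus for m in grp}
        if len(genera) == 1:
            rec = _merge_group(grp)
            out.append(rec)
            events.append(CollapseEvent(
                seq, [m.id for m in grp], sorted({m.taxon_id for m in grp}),
                "collapsed", rec.id))
            continue
        # intergenus duplicate group
        if len(grp) >= params.intergenus_min_support:
            rec = _merge_group(grp, intergenus=True)
            out.append(rec)
            events.append(CollapseEvent(
                seq, [m.id for m in grp], sorted({m.taxon_id for m in grp}),
                "intergenus-collapsed", rec.id,
                detail=f"supported by {len(grp)} sequences"))
        else:
            support = {g: sum(1 for m in grp if m.lineage.genus == g)
                       for g in genera}
            best = max(sorted(support), key=lambda g: support[g])
            if params.intergenus_policy == "drop-all":
                kept: list[TrainingSequence] = []
            else:  # drop-minority / keep-best-supported
                kept = [m for m in grp if m.lineage.genus == best]
            detail = (f"supported by only {len(grp)} sequences "
                      f"(< {params.intergenus_min_support}); "
                      f"policy={params.intergenus_policy}, "
                      f"kept genus {best!r}" if kept else
                      f"supported by only {len(grp)} sequences; all dropped")
            rec_id = None
            if kept:
                rec = _merge_group(kept)
                out.append(rec)
                rec_id = rec.id
            events.append(CollapseEvent(
                seq, [m.id for m in grp], sorted({m.taxon_id for m in grp}),
                "intergenus-rejected", rec_id, detail))
            logger.info("rejected intergenus collapse (%s): %s",
                        ",".join(sorted(genera)), detail)
    return TrainingSet(out, depth=raw_ts.depth, region=raw_ts.region), events


def _merge_group(grp: Sequence[TrainingSequence],
                 intergenus: bool = False) -> TrainingSequence:
    """One record for a duplicate group; names concatenated as needed."""
    keeper = min(grp, key=lambda m: m.id)
    species = concat_label(m.lineage.species for m in grp)
    lineage = keeper.lineage.replace("Species", species)
    if intergenus:
        for rank in ("Genus", "Family", "Order", "Class", "Phylum",
                     "Kingdom"):
            labels = {m.lineage.label(rank) for m in grp}
            if len(labels) > 1:
                lineage = lineage.replace(rank, concat_label(labels))
    taxon_id = concat_label(m.taxon_id for m in grp)
    return TrainingSequence(keeper.sequence, lineage, taxon_id)


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------

def jukes_cantor(p: float) -> float:
    """JC69 distance for an observed proportion p of differing sites."""
    if p < 0:
        raise ValueError("p must be >= 0")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def pairwise_distances(seqs: Sequence[NucleotideSequence],
                       backend: Literal["jc69_pairwise",
                                        "patristic"] = "jc69_pairwise",
                       tree: Optional[PatristicTree] = None,
                       ) -> tuple[list[str], np.ndarray]:
    """Symmetric, zero-diagonal distance matrix over the given sequences.

    ``jc69_pairwise`` applies the Jukes-Cantor correction
    -(3/4) ln(1 - (4/3) p) to the proportion p of differing sites over
    columns where both sequences have an unambiguous base (gap/ambiguity
    columns excluded pairwise); sequences must be aligned (equal length).
    p >= 0.75 yields +inf.  ``patristic`` sums branch lengths on a supplied
    newick tree whose leaf names match the sequence ids.
    """
    ids = [s.id for s in seqs]
    n = len(seqs)
    if backend == "patristic":
        if tree is None:
            raise BuildError("patristic backend requires a tree")
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = tree.distance(ids[i], ids[j])
        return ids, d
    lengths = {len(s.seq) for s in seqs}
    if len(lengths) != 1:
        raise BuildError(
            "jc69_pairwise requires aligned (equal-length) sequences; "
            f"got lengths {sorted(lengths)}")
    L = lengths.pop()
    codes = np.empty((n, L), dtype=np.uint8)
    for i, s in enumerate(seqs):
        codes[i] = _CODE[np.frombuffer(s.seq.encode("ascii"), dtype=np.uint8)]
    valid = codes < 4
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diff = (codes[i] != codes[i + 1:]) & both
        sites = both.sum(axis=1)
        ndiff = diff.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(sites > 0, ndiff / np.maximum(sites, 1), 0.0)
        row = np.array([jukes_cantor(float(x)) for x in p])
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    return ids, d


# ---------------------------------------------------------------------------
# supraspecies definition
# ---------------------------------------------------------------------------

@dataclass
class SupraspeciesGroup:
    """Two or more taxa merged under one supraspecies label."""

    member_taxon_ids: list[str]
    concatenated_label: str

    def __post_init__(self) -> None:
        if len(self.member_taxon_ids) < 2:
            raise ValueError("a supraspecies group needs >= 2 member taxa")


def define_supraspecies(curated_ts: TrainingSet,
                        ids: Sequence[str],
                        distances: np.ndarray,
                        params: BuildParams,
                        ) -> tuple[TrainingSet, list[SupraspeciesGroup]]:
    """Insert the supraspecies rank by single-linkage taxon grouping.

    Two taxa join one supraspecies when any pair of their sequences is at
    distance strictly below ``supraspecies_distance``; groups are the
    connected components of that relation (single linkage).  Sequences are
    carried over untouched; only headers change.  For merged taxa the
    supraspecies label is the ":"-concatenation of all member species labels;
    records that already carry a concatenated species label (from the
    collapse step) keep it at both levels; unmerged taxa repeat their species
    label at the supraspecies level.
    """
    if curated_ts.depth != 7:
        raise BuildError("define_supraspecies expects a depth-7 training set")
    idx = {sid: i for i, sid in enumerate(ids)}
    for m in curated_ts.members:
        if m.id not in idx:
            raise BuildError(f"no distances for member {m.id!r}")

    # nodes are component taxon ids; a collapsed record ties its components
    # together at distance zero (they share that very sequence).
    taxa_of_member = {m.id: sorted(label_components(m.taxon_id))
                      for m in curated_ts.members}
    # species label per component taxon: plain (uncollapsed) records are the
    # authoritative source; components seen only inside collapsed records fall
    # back to the record's full concatenated species label (the supraspecies
    # label is a component union, so this stays correct).
    species_of_taxon: dict[str, str] = {}
    for m in curated_ts.members:
        comps = taxa_of_member[m.id]
        if len(comps) == 1:
            species_of_taxon.setdefault(comps[0], m.lineage.species)
    for m in curated_ts.members:
        for t in taxa_of_member[m.id]:
            species_of_taxon.setdefault(t, m.lineage.species)

    parent: dict[str, str] = {t: t for ts_ in taxa_of_member.values()
                              for t in ts_}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for m in curated_ts.members:
        comps = taxa_of_member[m.id]
        for t in comps[1:]:
            union(comps[0], t)

    members = curated_ts.members
    for i, mi in enumerate(members):
        for j in range(i + 1, len(members)):
            mj = members[j]
            if set(taxa_of_member[mi.id]) & set(taxa_of_member[mj.id]):
                continue
            if distances[idx[mi.id], idx[mj.id]] < params.supraspecies_distance:
                union(taxa_of_member[mi.id][0], taxa_of_member[mj.id][0])

    comps_by_root: dict[str, list[str]] = {}
    for t in parent:
        comps_by_root.setdefault(find(t), []).append(t)

    groups: list[SupraspeciesGroup] = []
    supra_label: dict[str, str] = {}
    for root, taxa in sorted(comps_by_root.items()):
        label = concat_label(species_of_taxon[t] for t in taxa)
        for t in taxa:
            supra_label[t] = label
        if len(taxa) >= 2:
            groups.append(SupraspeciesGroup(sorted(taxa), label))

    new_members: list[TrainingSequence] = []
    for m in curated_ts.members:
        supra = supra_label[taxa_of_member[m.id][0]]
        new_members.append(TrainingSequence(
            m.sequence, m.lineage.with_supraspecies(supra), m.taxon_id))
    ts8 = TrainingSet(new_members, depth=8, region=curated_ts.region)
    return ts8, groups
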