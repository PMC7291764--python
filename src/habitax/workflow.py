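"""End-to-end drivers tying the construction, simulation, classification and
evaluation steps together.

`build_training_sets` runs the full construction ladder on a reference
database plus candidate pool and returns the five classic training sets:

* ``fl_refs``          - references only (one-to-few sequences per taxon)
* ``fl_compilation``   - references + recruited sequences, full length
* ``region_raw``       - the compilation trimmed to the sequenced sub-region
* ``region_curated``   - identical region sequences collapsed/concatenated
* ``region_supraspecies`` - curated set re-headered with the supraspecies rank

`classify_dataset` and `sweep_datasets` run the bootstrap classifier over
simulated or real reads and produce threshold sweeps.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .build import (
    BuildParams,
    CollapseEvent,
    SupraspeciesGroup,
    align_candidates,
    assign_members_to_taxa,
    collapse_identical,
    compile_full_length_ts,
    define_supraspecies,
    extract_region_by_reference,
    filter_recruitment_hits,
    pairwise_distances,
    trim_reference,
)
from .classifier import ClassificationResult, WordModel, classify, train
from .core import NucleotideSequence, TrainingSequence, TrainingSet
from .evaluate import SweepRow, bootstrap_sweep
from .simulate import SimParams, SimulatedRead, simulate_dataset


@dataclass
class BuildResult:
    training_sets: dict[str, TrainingSet]
    collapse_events: list[CollapseEvent]
    supraspecies_groups: list[SupraspeciesGroup]
    manifest: dict

    def __getitem__(self, name: str) -> TrainingSet:
        return self.training_sets[name]


def build_training_sets(references: TrainingSet,
                        pool: Sequence[NucleotideSequence],
                        params: Optional[BuildParams] = None) -> BuildResult:
    """Run the construction ladder on a reference set + candidate pool.

    References are trimmed to the primer window, candidates are recruited by
    global alignment against the trimmed references, and the sub-region is
    taken as (ungapped) trimmed-reference positions
    [region_start, region_end] mapped through each member's pairwise
    alignment to its reference.
    """
    params = params or BuildParams()
    trimmed_refs = [trim_reference(m.sequence, params)
                    for m in references.members]
    trimmed_ref_ts = TrainingSet(
        [TrainingSequence(t, m.lineage, m.taxon_id)
         for t, m in zip(trimmed_refs, references.members)],
        depth=7, region=references.region)

    ref_taxa = {m.id: m.taxon_id for m in references.members}
    hits = align_candidates(trimmed_refs, pool, params)
    kept = filter_recruitment_hits(hits, params,
                                   pool={c.id: c for c in pool})
    clusters = assign_members_to_taxa(kept, ref_taxa, params)

    fl_refs = TrainingSet(list(trimmed_ref_ts.members), depth=7,
                          region=references.region)
    fl_compilation = compile_full_length_ts(trimmed_ref_ts.members, clusters)

    # region extraction: per-taxon, each member aligned to its own reference
    ref_by_taxon = {m.taxon_id: m for m in trimmed_ref_ts.members}
    region_members: list[TrainingSequence] = []
    lineage_by_taxon = {m.taxon_id: m.lineage for m in trimmed_ref_ts.members}
    members_by_taxon: dict[str, list[NucleotideSequence]] = {}
    for m in fl_compilation.members:
        members_by_taxon.setdefault(m.taxon_id, []).append(m.sequence)
    for taxon_id in sorted(members_by_taxon):
        ref = ref_by_taxon[taxon_id].sequence
        extracted = extract_region_by_reference(
            ref, members_by_taxon[taxon_id],
            params.region_start, params.region_end)
        for seq in extracted:
            region_members.append(TrainingSequence(
                seq, lineage_by_taxon[taxon_id], taxon_id))
    region_raw = TrainingSet(region_members, depth=7,
                             region=params.region_name)

    region_curated, collapse_events = collapse_identical(region_raw, params)

    ids, dmat = pairwise_distances(
        [m.sequence for m in region_curated.members], backend="jc69_pairwise")
    region_supraspecies, groups = define_supraspecies(
        region_curated, ids, dmat, params)

    manifest = {
        "params": {k: v for k, v in asdict(params).items()},
        "n_references": len(references),
        "n_candidates": len(pool),
        "n_hits": len(hits),
        "n_recruited": sum(len(c.member_sequences) for c in clusters),
        "members_per_taxon": {c.taxon_id: len(c.member_sequences) + 1
                              for c in clusters},
        "n_collapse_events": len(collapse_events),
        "n_supraspecies_groups": len(groups),
        "supraspecies_groups": [
            {"taxa": g.member_taxon_ids, "label": g.concatenated_label}
            for g in groups],
        "collapse_log": [
            {"action": e.action, "taxa": e.taxon_ids, "kept": e.kept_id,
             "detail": e.detail} for e in collapse_events],
    }
    return BuildResult(
        training_sets={
            "fl_refs": fl_refs,
            "fl_compilation": fl_compilation,
            "region_raw": region_raw,
            "region_curated": region_curated,
            "region_supraspecies": region_supraspecies,
        },
        collapse_events=collapse_events,
        supraspecies_groups=groups,
        manifest=manifest)


def simulate_reads(ts: TrainingSet, params: SimParams,
                   n_reads: Optional[int] = None) -> list[SimulatedRead]:
    """Simulated reads from a region training set.

    One read per unique sequence per pass; when ``n_reads`` exceeds the
    number of unique sequences, additional passes with spawned seeds are
    concatenated and the list truncated to ``n_reads``.
    """
    reads = simulate_dataset(ts, params)
    if n_reads is None:
        return reads
    passno = 1
    while len(reads) < n_reads:
        p = SimParams(error_rate=params.error_rate, r2_len=params.r2_len,
                      r1_len=params.r1_len,
                      rng_seed=params.rng_seed + passno,
                      reverse_complement_r1=params.reverse_complement_r1)
        reads.extend(simulate_dataset(ts, p))
        passno += 1
    return reads[:n_reads]


def classify_dataset(model: WordModel, reads: Sequence[SimulatedRead],
                     n_boot: int = 100, rng_seed: int = 0,
                     ) -> dict[str, ClassificationResult]:
    """Classify every read with a per-read seed spawned from ``rng_seed``."""
    seeds = np.random.SeedSequence(rng_seed).spawn(len(reads))
    out: dict[str, ClassificationResult] = {}
    for read, ss in zip(reads, seeds):
        rng_seed_i = int(ss.generate_state(1)[0] % (2 ** 31))
        out[read.read_id] = classify(model, read.as_sequence(),
                                     n_boot=n_boot, rng_seed=rng_seed_i)
    return out


def sweep_datasets(training_sets: Mapping[str, TrainingSet],
                   reads: Sequence[SimulatedRead],
                   thresholds=range(50, 101),
                   n_boot: int = 100, rng_seed: int = 0,
                   ) -> dict[str, list[SweepRow]]:
    """Train on each set, classify the reads once, sweep all thresholds."""
    truths = {r.read_id: r.truth_lineage for r in reads}
    sweeps: dict[str, list[SweepRow]] = {}
    for name, ts in training_sets.items():
        model = train(ts)
        results = classify_dataset(model, reads, n_boot=n_boot,
                                   rng_seed=rng_seed)
        sweeps[name] = bootstrap_sweep(truths, results, thresholds)
    return sweeps
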