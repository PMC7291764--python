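"""Error-bearing simulated amplicon reads and synthetic habitat fixtures.

Reads mimic non-overlapping paired-end sequencing of a hypervariable region:
a fixed fraction of bases of each unique training sequence is substituted,
the mutated sequence is cut into an R2 fragment (from the 5'/V1 end) and an
R1 fragment (from the 3'/V3 end), and the two are joined as R2-10N-R1.  The
ten N's contribute no classifier words, so classification sees exactly the
union of the two fragments' word sets.

The synthetic habitat generator emulates the phylogenetic structure of a
curated habitat database: a few genera (~10% divergent), congeneric species
(~2% divergent), within-species sequence variants (<=0.5% divergent), and
optionally congeneric species pairs that are identical over the sequenced
sub-region — the situation that forces identical-sequence curation and the
supraspecies rank downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    FULL_LENGTH,
    HabitaxError,
    Lineage,
    NucleotideSequence,
    TrainingSequence,
    TrainingSet,
)

BASES = "ACGT"
LINKER = "N" * 10


class SimulationError(HabitaxError):
    pass


@dataclass
class SimParams:
    """Read-simulation parameters.

    ``error_rate`` is the fraction of bases substituted per read (each
    selected base changes to a different base).  ``r2_len`` counts from the
    5' (V1) end, ``r1_len`` from the 3' (V3) end; both fragments are kept in
    the training-set (forward) orientation before linking.
    """

    error_rate: float = 0.01
    r2_len: int = 250
    r1_len: int = 100
    rng_seed: int = 0
    reverse_complement_r1: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if self.r1_len < 0 or self.r2_len < 0:
            raise ValueError("fragment lengths must be >= 0")


@dataclass
class SimulatedRead:
    read_id: str
    parent_id: str
    truth_lineage: Lineage
    seq: str
    r1_len: int
    r2_len: int
    error_rate: float

    def __post_init__(self) -> None:
        if len(self.seq) != self.r1_len + self.r2_len + len(LINKER):
            raise ValueError("read length != r1_len + r2_len + 10")

    def as_sequence(self) -> NucleotideSequence:
        desc = f"parent={self.parent_id}|{self.truth_lineage.to_header()}"
        return NucleotideSequence(self.read_id, self.seq, desc)


MutationLog = list[tuple[int, str, str]]  # (1-based position, from, to)


def _round_half_away(x: float) -> int:
    import math
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def mutate(seq: str, error_rate: float,
           rng: np.random.Generator) -> tuple[str, MutationLog]:
    """Substitute exactly round(error_rate x L) distinct positions.

    Positions are drawn without replacement; each selected base becomes a
    uniformly chosen *different* base.  Rounding is half-away-from-zero, so
    the per-read substitution count is forced by the rule, not merely its
    expectation.
    """
    L = len(seq)
    n_mut = _round_half_away(error_rate * L)
    if n_mut == 0:
        return seq, []
    positions = rng.choice(L, size=n_mut, replace=False)
    chars = list(seq)
    log: MutationLog = []
    for pos in sorted(int(p) for p in positions):
        old = chars[pos]
        alternatives = [b for b in BASES if b != old]
        new = alternatives[int(rng.integers(3))] if old in BASES \
            else BASES[int(rng.integers(4))]
        chars[pos] = new
        log.append((pos + 1, old, new))
    return "".join(chars), log


def fragment_and_link(mutated: str, params: SimParams) -> str:
    """Cut R2 (5' end) and R1 (3' end) fragments and join as R2-10N-R1."""
    if params.r1_len + params.r2_len > len(mutated):
        raise SimulationError(
            f"fragments overlap: r1_len + r2_len = "
            f"{params.r1_len + params.r2_len} > sequence length "
            f"{len(mutated)}")
    r2 = mutated[:params.r2_len]
    r1 = mutated[len(mutated) - params.r1_len:] if params.r1_len else ""
    if params.reverse_complement_r1 and r1:
        from .classifier import REVCOMP
        r1 = r1.translate(REVCOMP)[::-1]
    return r2 + LINKER + r1


def simulate_dataset(ts: TrainingSet, params: SimParams,
                     ) -> list[SimulatedRead]:
    """One error-bearing linked read per *unique sequence* in the set.

    Records sharing an identical sequence string contribute a single read
    (the first record provides the parent id and truth lineage).  The output
    is deterministic under ``params.rng_seed``.
    """
    parents = ts.unique_sequences()
    seeds = np.random.SeedSequence(params.rng_seed).spawn(len(parents))
    reads: list[SimulatedRead] = []
    for parent, ss in zip(parents, seeds):
        rng = np.random.default_rng(ss)
        mutated, _ = mutate(parent.sequence.seq, params.error_rate, rng)
        linked = fragment_and_link(mutated, params)
        reads.append(SimulatedRead(
            read_id=f"{parent.id}_sim{params.rng_seed}",
            parent_id=parent.id,
            truth_lineage=parent.lineage,
            seq=linked,
            r1_len=params.r1_len, r2_len=params.r2_len,
            error_rate=params.error_rate))
    return reads


# ---------------------------------------------------------------------------
# synthetic habitat
# ---------------------------------------------------------------------------

@dataclass
class SyntheticHabitat:
    """A generated habitat: reference database, candidate pool, truth."""

    references: TrainingSet                 # one reference per species, depth 7
    pool: list[NucleotideSequence]          # recruited-sequence candidates
    truth: dict[str, Lineage]               # pool id -> lineage
    taxon_of: dict[str, str]                # pool id -> taxon id
    forced_identical_pairs: list[tuple[str, str]]  # taxon-id pairs
    region_span: tuple[int, int]            # 1-based inclusive, on references
    sequence_length: int


def _mutate_n(seq: str, n: int, rng: np.random.Generator,
              positions: Optional[np.ndarray] = None) -> str:
    if n == 0:
        return seq
    if positions is None:
        positions = np.arange(len(seq))
    picked = rng.choice(positions, size=n, replace=False)
    chars = list(seq)
    for pos in picked:
        old = chars[int(pos)]
        alternatives = [b for b in BASES if b != old]
        chars[int(pos)] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def make_synthetic_habitat(n_genera: int = 6,
                           species_per_genus: int = 4,
                           variants_per_species: int = 10,
                           inter_genus_div: float = 0.10,
                           inter_species_div: float = 0.02,
                           intra_species_div: float = 0.005,
                           identical_region_pairs: int = 0,
                           identical_variants: int = 3,
                           region_span: tuple[int, int] = (67, 907),
                           sequence_length: int = 1400,
                           rng_seed: int = 0) -> SyntheticHabitat:
    """Generate a habitat with a controlled phylogenetic structure.

    Divergences are pairwise targets: genus roots are derived from one
    ancestor at ``inter_genus_div/2`` substitutions each, species roots from
    their genus root at ``inter_species_div/2``, and variants from their
    species root at ``intra_species_div/2``, so expected pairwise divergence
    between two genera / congeneric species / conspecific variants is close
    to the stated value.

    ``identical_region_pairs`` congeneric species pairs are forced to share
    an identical sub-region: the second species' root copies the first's
    bases over ``region_span``, and the first ``identical_variants`` variants
    of each such species mutate only *outside* the region (so the duplicated
    region sequence survives into the trimmed training set and exercises
    collapse and supraspecies construction downstream).

    The first variant of every species is the species root itself (public
    repositories contain the reference's own record), so a pool with
    ``variants_per_species=1`` reproduces the reference sequences exactly.

    Returns the reference database (one reference per species, the species
    root), the candidate pool (all variants) and truth tables.
    """
    if not (intra_species_div < inter_species_div < inter_genus_div):
        raise ValueError(
            "divergences must satisfy intra < inter_species < inter_genus")
    if identical_region_pairs * 2 > species_per_genus * n_genera:
        raise ValueError("too many identical-region pairs requested")
    if identical_region_pairs > 0 and species_per_genus < 2:
        raise ValueError("identical-region pairs need >= 2 species per genus")

    rng = np.random.default_rng(rng_seed)
    L = sequence_length
    rs, re = region_span
    if not (1 <= rs < re <= L):
        raise ValueError(f"region_span {region_span} outside sequence "
                         f"length {L}")
    region_idx = np.arange(rs - 1, re)
    outside_idx = np.setdiff1d(np.arange(L), region_idx)

    ancestor = "".join(BASES[int(b)] for b in rng.integers(4, size=L))

    refs: list[TrainingSequence] = []
    pool: list[NucleotideSequence] = []
    truth: dict[str, Lineage] = {}
    taxon_of: dict[str, str] = {}
    forced: list[tuple[str, str]] = []

    n_genus_mut = _round_half_away(inter_genus_div / 2 * L)
    n_species_mut = _round_half_away(inter_species_div / 2 * L)
    n_variant_mut = _round_half_away(intra_species_div / 2 * L)

    taxon_counter = 0
    pairs_left = identical_region_pairs
    for g in range(n_genera):
        genus_root = _mutate_n(ancestor, n_genus_mut, rng)
        genus = f"Genus{g + 1:02d}"
        base_lineage = (
            "Bacteria", "Synthophyta", "Synthobacteria",
            f"Synthales{g + 1:02d}", f"Synthaceae{g + 1:02d}", genus)
        species_roots: list[str] = []
        species_ids: list[str] = []
        forced_here = pairs_left > 0
        for s in range(species_per_genus):
            taxon_counter += 1
            taxon_id = f"SHT-{taxon_counter:03d}"
            species = f"sp{g + 1:02d}x{s + 1:02d}"
            root = _mutate_n(genus_root, n_species_mut, rng)
            if forced_here and s == 1:
                # second species copies the first's region -> identical over
                # the sequenced sub-region, divergent elsewhere
                chars = list(root)
                chars[rs - 1:re] = species_roots[0][rs - 1:re]
                root = "".join(chars)
                forced.append((species_ids[0], taxon_id))
                pairs_left -= 1
            species_roots.append(root)
            species_ids.append(taxon_id)
            lineage = Lineage(base_lineage + (species,))
            ref_id = f"{taxon_id}ref"
            refs.append(TrainingSequence(
                NucleotideSequence(ref_id, root), lineage, taxon_id))
            in_forced_pair = forced_here and s in (0, 1)
            for v in range(variants_per_species):
                vid = f"{taxon_id}.v{v + 1:02d}"
                if v == 0:
                    # public repositories contain the reference's own record;
                    # the first variant is therefore the root itself
                    variant = root
                else:
                    keep_region = in_forced_pair and v < identical_variants
                    positions = outside_idx if keep_region else None
                    variant = _mutate_n(root, n_variant_mut, rng, positions)
                pool.append(NucleotideSequence(vid, variant))
                truth[vid] = lineage
                taxon_of[vid] = taxon_id
    references = TrainingSet(refs, depth=7, region=FULL_LENGTH)
    return SyntheticHabitat(references=references, pool=pool, truth=truth,
                            taxon_of=taxon_of,
                            forced_identical_pairs=forced,
                            region_span=region_span, sequence_length=L)
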