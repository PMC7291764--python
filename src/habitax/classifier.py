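"""Bootstrap naive Bayesian k-mer classifier (RDP/Wang-style).

The model treats every length-k word (k-mer, default k=8) over {A,C,G,T} as a
feature.  With N training sequences of which n(w) contain word w, the word
prior is

    Pi(w) = (n(w) + 0.5) / (N + 1)

and for a leaf class c (a unique full lineage) with M_c sequences of which
m_c(w) contain w, the log conditional used for scoring is

    L_c(w) = log( (m_c(w) + Pi(w)) / (M_c + 1) ).

A query is scored by summing L_c over its *distinct* words (presence, not
multiplicity) and assigned to the argmax class.  Confidence comes from
bootstrapping: each of n_boot iterations draws floor(W/8) of the query's W
distinct words with replacement and re-runs the argmax; the bootstrap
percentage of a rank is the share of iterations whose winning leaf carries
that rank's modal label.  Because every leaf vote also votes for all its
ancestors, bootstrap percentages never increase from kingdom to species.

Words containing any non-ACGT symbol are skipped, so the 10-N linker used to
join paired-read fragments contributes no words at all.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .core import HabitaxError, Lineage, NucleotideSequence, TrainingSet

DEFAULT_K = 8


class TooShortQueryError(HabitaxError):
    """Query has fewer than k usable distinct words."""


_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i


def _word_codes(seq: str, k: int) -> np.ndarray:
    """Distinct valid k-mer codes (base-4 encoding) of a sequence."""
    codes = _LUT[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    words = win[valid].astype(np.int64) @ powers
    return np.unique(words)


def extract_words(seq: NucleotideSequence | str,
                  k: int = DEFAULT_K) -> Counter:
    """Multiset of the valid length-k words of a sequence.

    Windows containing any symbol outside A/C/G/T (ambiguity codes, N, gaps)
    are skipped.  Sequences shorter than k yield an empty multiset.
    """
    s = seq.seq if isinstance(seq, NucleotideSequence) else seq
    s = s.upper()
    out: Counter = Counter()
    for i in range(len(s) - k + 1):
        w = s[i:i + k]
        if set(w) <= {"A", "C", "G", "T"}:
            out[w] += 1
    return out


@dataclass
class WordModel:
    """Trained word statistics.

    ``m`` is the (classes x 4^k) matrix of per-class word presence counts,
    ``M`` the per-class sequence counts, ``pi`` the word priors.  Classes are
    unique full lineages, sorted for determinism.
    """

    k: int
    n_total: int                      # N: training sequences in the model
    class_lineages: list[Lineage]
    M: np.ndarray                     # (C,) int64
    m: np.ndarray                     # (C, 4^k) uint16
    pi: np.ndarray                    # (4^k,) float64

    @property
    def n_classes(self) -> int:
        return len(self.class_lineages)

    def log_conditionals(self, word_codes: np.ndarray) -> np.ndarray:
        """L_c(w) for the given word codes; shape (C, len(word_codes))."""
        num = self.m[:, word_codes].astype(np.float64) + self.pi[word_codes]
        den = (self.M + 1).astype(np.float64)[:, None]
        return np.log(num) - np.log(den)


def train(ts: TrainingSet, k: int = DEFAULT_K) -> WordModel:
    """Build word statistics from a training set.

    Word *presence* within a sequence (not multiplicity) increments the
    counts.  Training sequences shorter than k carry no words and are
    excluded with a warning.
    """
    import logging
    logger = logging.getLogger(__name__)

    by_class: dict[tuple[str, ...], list[np.ndarray]] = {}
    for mem in ts.members:
        if len(mem.sequence.seq) < k:
            logger.warning("training sequence %s shorter than k=%d; excluded",
                           mem.id, k)
            continue
        codes = _word_codes(mem.sequence.seq, k)
        by_class.setdefault(mem.lineage.labels, []).append(codes)
    if not by_class:
        raise ValueError("no usable training sequences")

    class_keys = sorted(by_class)
    C = len(class_keys)
    n_words = 4 ** k
    m = np.zeros((C, n_words), dtype=np.uint16)
    M = np.zeros(C, dtype=np.int64)
    for ci, key in enumerate(class_keys):
        for codes in by_class[key]:
            m[ci, codes] += 1
        M[ci] = len(by_class[key])
    N = int(M.sum())
    n_w = m.sum(axis=0, dtype=np.int64)
    pi = (n_w + 0.5) / (N + 1)
    return WordModel(k=k, n_total=N,
                     class_lineages=[Lineage(key) for key in class_keys],
                     M=M, m=m, pi=pi)


# ---------------------------------------------------------------------------
# classification results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankCall:
    rank: str
    label: Optional[str]          # None = unassigned (masked or NA)
    bootstrap: float              # percentage 0-100


@dataclass(frozen=True)
class ClassificationResult:
    """Per-rank assignment with bootstrap support for one query."""

    query_id: str
    calls: tuple[RankCall, ...]
    n_bootstrap: int
    full_word_lineage: Optional[Lineage] = None
    min_boot: Optional[float] = None   # threshold already applied, if any

    @property
    def depth(self) -> int:
        return len(self.calls)

    def call(self, rank: str) -> RankCall:
        for c in self.calls:
            if c.rank == rank:
                return c
        raise KeyError(rank)

    def assigned(self, rank: str) -> Optional[str]:
        return self.call(rank).label


def _break_ties(scores: np.ndarray, rng: np.random.Generator) -> int:
    """Argmax with exact ties broken by a seeded uniform choice."""
    mx = scores.max()
    tied = np.flatnonzero(scores == mx)
    if tied.size == 1:
        return int(tied[0])
    return int(tied[int(rng.integers(tied.size))])


def classify(model: WordModel, query: NucleotideSequence,
             n_boot: int = 100, rng_seed: Optional[int] = None,
             ) -> ClassificationResult:
    """Classify one query sequence.

    Raises :class:`TooShortQueryError` when the query yields fewer than k
    distinct usable words.  With the same model, query and seed the result is
    bit-identical.
    """
    qwords = _word_codes(query.seq, model.k)
    if qwords.size < model.k:
        raise TooShortQueryError(
            f"query {query.id!r} yields {qwords.size} distinct words; "
            f"need >= {model.k}")
    rng = np.random.default_rng(rng_seed)
    W = qwords.size
    Lq = model.log_conditionals(qwords)            # (C, W)

    s = max(1, W // model.k)
    idx = rng.integers(0, W, size=(n_boot, s))
    boot_scores = Lq[:, idx].sum(axis=2)           # (C, n_boot)
    mx = boot_scores.max(axis=0)
    is_max = boot_scores == mx[None, :]
    winners = np.argmax(boot_scores, axis=0)
    multi = np.flatnonzero(is_max.sum(axis=0) > 1)
    for col in multi:
        tied = np.flatnonzero(is_max[:, col])
        winners[col] = tied[int(rng.integers(tied.size))]

    full_winner = _break_ties(Lq.sum(axis=1), rng)
    full_lineage = model.class_lineages[full_winner]

    depth = model.class_lineages[0].depth
    rank_names = model.class_lineages[0].rank_names
    calls: list[RankCall] = []
    for level in range(depth):
        votes = Counter(model.class_lineages[w].labels[level]
                        for w in winners)
        top = max(votes.values())
        tied_labels = sorted(lab for lab, v in votes.items() if v == top)
        label = (tied_labels[0] if len(tied_labels) == 1
                 else tied_labels[int(rng.integers(len(tied_labels)))])
        calls.append(RankCall(rank_names[level], label,
                              100.0 * votes[label] / n_boot))
    return ClassificationResult(query.id, tuple(calls), n_boot, full_lineage)


REVCOMP = str.maketrans("ACGTRYKMBVDHN", "TGCAYRMKVBHDN")


def classify_try_rc(model: WordModel, query: NucleotideSequence,
                    n_boot: int = 100, rng_seed: Optional[int] = None,
                    ) -> ClassificationResult:
    """Classify both orientations and keep the higher species bootstrap.

    Off by default in all pipelines; queries are normally classified as
    given.
    """
    fwd = classify(model, query, n_boot, rng_seed)
    rc_seq = NucleotideSequence(query.id, query.seq.translate(REVCOMP)[::-1])
    try:
        rev = classify(model, rc_seq, n_boot, rng_seed)
    except TooShortQueryError:
        return fwd
    return fwd if fwd.calls[-1].bootstrap >= rev.calls[-1].bootstrap else rev


def apply_threshold(result: ClassificationResult,
                    min_boot: float) -> ClassificationResult:
    """Mask ranks whose bootstrap falls below ``min_boot``.

    Masking is monotone: once a rank is masked, every deeper rank is masked
    too (an assignment is only meaningful under an assigned ancestor).
    """
    masked = False
    calls: list[RankCall] = []
    for c in result.calls:
        if masked or c.bootstrap < min_boot or c.label is None:
            masked = True
            calls.append(RankCall(c.rank, None, c.bootstrap))
        else:
            calls.append(c)
    return replace(result, calls=tuple(calls), min_boot=min_boot)


def eight_to_seven(result: ClassificationResult) -> ClassificationResult:
    """Convert a depth-8 (supraspecies) result to seven levels.

    When the species level is unassigned its slot takes the supraspecies
    label and bootstrap; the supraspecies level is then deleted and the
    merged last level is reported simply as species.  Typically applied
    after :func:`apply_threshold`, so a low-confidence species call defaults
    to its supraspecies rather than all the way to genus.
    """
    if result.depth != 8:
        raise ValueError("eight_to_seven requires a depth-8 result")
    calls = list(result.calls)
    supra, species = calls[6], calls[7]
    if species.label is None:
        species = RankCall("Species", supra.label, supra.bootstrap)
    new_calls = tuple(calls[:6]) + (species,)
    full = result.full_word_lineage
    if full is not None and full.depth == 8:
        full = Lineage(full.labels[:6] + (full.labels[7],))
    return replace(result, calls=new_calls, full_word_lineage=full)
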