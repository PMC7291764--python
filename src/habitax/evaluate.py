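"""Accuracy evaluation: truth scoring, bootstrap-threshold sweeps, operating
point selection, and assignment-set comparisons.

A "sweep" classifies a simulated dataset once, stores the raw bootstrap
values, and then applies every threshold (minBoot 50..100) post hoc: at each
threshold a read is *classified* at the species (or merged
species/supraspecies) level if its call survives masking, *misclassified* if
the surviving call contradicts the read's known parent lineage, and
*unclassified* otherwise.  Because thresholding only removes assignments,
the percentage classified is non-increasing in the threshold.

Concatenated (":"-joined) labels are compared by component set: an
assignment is correct when its component set shares a member with the truth
label's component set, so "dispar:parvula" is a correct assignment for a
read of Veillonella parvula, while order of components never matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd

from .core import AbundanceTable, HabitaxError, Lineage, label_components
from .classifier import ClassificationResult, apply_threshold, eight_to_seven

Status = Literal["correct", "misclassified", "unclassified"]


class EvaluationError(HabitaxError):
    pass


def _labels_agree(truth: str, assigned: str) -> bool:
    return bool(label_components(truth) & label_components(assigned))


def score_read(truth: Lineage, result: ClassificationResult,
               ) -> dict[str, Status]:
    """Score one thresholded result against its truth lineage, per rank.

    ``result`` must be depth-7 (apply :func:`eight_to_seven` first when the
    model carried a supraspecies level).  At every rank: unassigned ->
    "unclassified"; otherwise "correct" iff the assigned label's component
    set intersects the truth label's component set (a concatenated label
    containing the truth species is correct).
    """
    if result.depth != truth.depth:
        if result.depth == 8:
            raise EvaluationError(
                "depth-8 result: apply eight_to_seven before scoring")
        raise EvaluationError(
            f"truth depth {truth.depth} vs result depth {result.depth}")
    out: dict[str, Status] = {}
    for call, (rank, truth_label) in zip(result.calls, truth.items()):
        if call.label is None:
            out[rank] = "unclassified"
        elif _labels_agree(truth_label, call.label):
            out[rank] = "correct"
        else:
            out[rank] = "misclassified"
    return out


@dataclass(frozen=True)
class SweepRow:
    """Species-level accuracy at one bootstrap threshold."""

    min_boot: int
    pct_classified: float      # % of reads assigned at species level
    pct_misclassified: float   # % of *classified* reads contradicting truth
    pct_unclassified: float    # 100 - pct_classified
    n_reads: int
    n_classified: int
    n_misclassified: int


def _species_truth(lineage: Lineage) -> str:
    return lineage.species


def bootstrap_sweep(truths: Mapping[str, Lineage],
                    results: Mapping[str, ClassificationResult],
                    thresholds: Iterable[int] = range(50, 101),
                    ) -> list[SweepRow]:
    """One classification pass served to every threshold.

    ``results`` must hold raw (unthresholded) calls; depth-8 results are
    converted with :func:`eight_to_seven` after masking, so a species call
    below threshold falls back to its supraspecies label, which then counts
    as classified at the merged species/supraspecies level.
    """
    if set(truths) != set(results):
        missing = set(truths) ^ set(results)
        raise EvaluationError(f"truth/result id mismatch: {sorted(missing)[:5]}")
    ids = sorted(truths)
    rows: list[SweepRow] = []
    for t in thresholds:
        n_classified = n_mis = 0
        for rid in ids:
            res = apply_threshold(results[rid], t)
            if res.depth == 8:
                res = eight_to_seven(res)
            truth = truths[rid]
            if truth.depth == 8:
                truth = Lineage(truth.labels[:6] + (truth.labels[7],))
            call = res.calls[-1]
            if call.label is None:
                continue
            n_classified += 1
            if not _labels_agree(truth.species, call.label):
                n_mis += 1
        n = len(ids)
        pct_cls = 100.0 * n_classified / n
        pct_mis = 100.0 * n_mis / n_classified if n_classified else 0.0
        rows.append(SweepRow(t, pct_cls, pct_mis, 100.0 - pct_cls,
                             n, n_classified, n_mis))
    return rows


@dataclass(frozen=True)
class OperatingPoint:
    satisfiable: bool
    min_boot: Optional[int]
    row: Optional[SweepRow]
    closest: Optional[SweepRow] = None


def pick_operating_point(sweep: Sequence[SweepRow],
                         max_misclassified: Optional[float] = None,
                         max_unclassified: Optional[float] = None,
                         ) -> OperatingPoint:
    """Choose a bootstrap threshold from an accuracy/coverage bound.

    With ``max_misclassified``: the smallest threshold whose misclassified
    percentage is within the bound (more reads kept).  With
    ``max_unclassified``: the largest threshold whose unclassified percentage
    is within the bound (most conservative calls).  When no row satisfies
    the bound the result is flagged unsatisfiable and carries the closest
    row.
    """
    if not sweep:
        raise EvaluationError("empty sweep")
    if (max_misclassified is None) == (max_unclassified is None):
        raise EvaluationError(
            "specify exactly one of max_misclassified / max_unclassified")
    if max_misclassified is not None:
        ordered = sorted(sweep, key=lambda r: r.min_boot)
        ok = [r for r in ordered if r.pct_misclassified <= max_misclassified]
        if ok:
            return OperatingPoint(True, ok[0].min_boot, ok[0])
        closest = min(ordered, key=lambda r: r.pct_misclassified)
        return OperatingPoint(False, None, None, closest)
    ordered = sorted(sweep, key=lambda r: -r.min_boot)
    ok = [r for r in ordered if r.pct_unclassified <= max_unclassified]
    if ok:
        return OperatingPoint(True, ok[0].min_boot, ok[0])
    closest = min(ordered, key=lambda r: r.pct_unclassified)
    return OperatingPoint(False, None, None, closest)


def sweep_table(sweep: Sequence[SweepRow]) -> pd.DataFrame:
    """Sweep as a DataFrame with percentages rounded to one decimal."""
    df = pd.DataFrame([{
        "min_boot": r.min_boot,
        "pct_classified": round(r.pct_classified, 1),
        "pct_misclassified": round(r.pct_misclassified, 1),
        "pct_unclassified": round(r.pct_unclassified, 1),
        "n_classified": r.n_classified,
        "n_misclassified": r.n_misclassified,
    } for r in sweep])
    return df


# ---------------------------------------------------------------------------
# assignment-set comparison (two methods over the same items)
# ---------------------------------------------------------------------------

@dataclass
class AssignmentComparison:
    """Item-by-item comparison of two assignment maps."""

    records: pd.DataFrame          # item, label_a, label_b, agree, stratum
    n_items: int                   # items with at least one assignment
    n_differential: int
    pct_items_differential: float
    pct_reads_differential: Optional[float] = None


def _as_species_label(value) -> Optional[str]:
    if value is None:
        return None
    if isinstance(value, Lineage):
        return value.species
    return str(value)


def compare_assignments(a: Mapping[str, object], b: Mapping[str, object],
                        abundances: Optional[AbundanceTable] = None,
                        ) -> AssignmentComparison:
    """Compare species-level assignments of two methods.

    Items may map to a :class:`Lineage`, a plain label, or None
    (unassigned).  Labels compare by component-set equality, so
    "parvula:dispar" equals "dispar:parvula".  The differential percentage
    is computed over items with at least one assignment; NA-vs-assigned
    items are differential and reported in their own stratum.
    """
    if set(a) != set(b):
        raise EvaluationError("assignment maps cover different items")
    recs = []
    for item in sorted(a):
        la, lb = _as_species_label(a[item]), _as_species_label(b[item])
        if la is None and lb is None:
            agree, stratum = True, "both-na"
        elif la is None or lb is None:
            agree, stratum = False, "na-vs-assigned"
        else:
            agree = label_components(la) == label_components(lb)
            stratum = "both-assigned"
        recs.append({"item": item, "label_a": la, "label_b": lb,
                     "agree": agree, "stratum": stratum})
    df = pd.DataFrame(recs)
    informative = df[df["stratum"] != "both-na"]
    n_items = len(informative)
    diff = informative[~informative["agree"]]
    n_diff = len(diff)
    pct_items = 100.0 * n_diff / n_items if n_items else 0.0
    pct_reads = None
    if abundances is not None:
        total = abundances.total(list(informative["item"]))
        diff_reads = abundances.total(list(diff["item"]))
        pct_reads = 100.0 * diff_reads / total if total else 0.0
    return AssignmentComparison(df, n_items, n_diff, pct_items, pct_reads)


def table1_summary(assignments: Mapping[str, Mapping[str, object]],
                   abundances: AbundanceTable) -> pd.DataFrame:
    """Per-method summary of subgenus-level assignment rates.

    ``assignments`` maps method name to {item id -> species/supraspecies
    label or None}; an item counts as assigned when its label is not None.
    Reports counts and percentages of items and of reads, one row per
    method.
    """
    rows = []
    for method, amap in assignments.items():
        items = sorted(amap)
        if not items:
            raise EvaluationError(f"method {method!r} has no items")
        assigned = [i for i in items if _as_species_label(amap[i]) is not None]
        n_reads_total = abundances.total(items)
        n_reads = abundances.total(assigned)
        rows.append({
            "method": method,
            "n_items_assigned": len(assigned),
            "n_reads_assigned": n_reads,
            "pct_items": round(100.0 * len(assigned) / len(items), 1),
            "pct_reads": (round(100.0 * n_reads / n_reads_total, 1)
                          if n_reads_total else 0.0),
        })
    return pd.DataFrame(rows)


def plot_sweep(sweeps: Mapping[str, Sequence[SweepRow]], path: str,
               title: str = "") -> None:
    """Write classified/misclassified sweep curves (PNG/SVG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for name, sweep in sweeps.items():
        xs = [r.min_boot for r in sweep]
        ax1.plot(xs, [r.pct_classified for r in sweep], label=name)
        ax2.plot(xs, [r.pct_misclassified for r in sweep], label=name)
    ax1.set_xlabel("minBoot"), ax1.set_ylabel("% reads classified")
    ax2.set_xlabel("minBoot"), ax2.set_ylabel("% classified reads misclassified")
    ax1.legend(fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
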