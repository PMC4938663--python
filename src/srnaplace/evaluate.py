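"""Scoring placements against simulated truth.

Outcome classes follow the standard benchmark definitions for aligners run
on reads of known origin:

* TP - placed, and the primary site matches the true origin exactly on
  (reference, strand, leftmost position);
* FP - placed at any other site;
* TN - unplaced, and the read has no valid alignment position at all;
* FN - unplaced despite at least one valid alignment position (suppressed
  ties, overflow reads, and mode-N discards all land here).

Alignability for the TN/FN split is the aligner's own site count under the
same settings used for placement, so an error-bearing read that happens to
align somewhere is scored honestly.

Derived metrics: precision TP/(TP+FP), sensitivity TP/(TP+FN), F1 (their
harmonic mean), and two false-negative rates: ``fnr_printed`` = FN/(FP+TP)
(the form printed in the source method's report) and the conventional
``fnr_conventional`` = FN/(FN+TP). Zero denominators yield missing values,
never faults. Metrics can be stratified by MMAP-value (exact n and
cumulative n <= cutoff), and the library-retention curve and top/bottom
strand ratio of primaries are also computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .place import PlacementDecision

OUTCOMES = ("TP", "FP", "TN", "FN")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def classify_decision(
    decision: PlacementDecision,
    true_reference: str,
    true_start: int,
    true_strand: str,
) -> str:
    """Outcome class of one read given its true origin. The read's
    alignability (n >= 1, or overflow) comes from the decision itself."""
    if decision.placed:
        site = decision.site
        ok = (
            site.reference == true_reference
            and site.pos == true_start
            and site.strand == true_strand
        )
        return "TP" if ok else "FP"
    if decision.n == 0 and not decision.overflow:
        return "TN"
    return "FN"


def evaluate_library(
    decisions: Sequence[PlacementDecision],
    truth: pd.DataFrame,
) -> pd.DataFrame:
    """Per-read outcome table joining decisions with the truth table.

    Raises if any decision's read is absent from the truth table. Returns
    one row per decision: read_id, n, overflow, placed, outcome.
    """
    lookup = dict(
        zip(
            truth["read_id"],
            zip(
                truth["true_reference"].astype(str),
                truth["true_start"].astype(int),
                truth["true_strand"].astype(str),
            ),
        )
    )
    rows = []
    for d in decisions:
        if d.read_id not in lookup:
            raise KeyError(f"read {d.read_id!r} absent from the truth table")
        ref, start, strand = lookup[d.read_id]
        rows.append(
            (d.read_id, d.n, d.overflow, d.placed, classify_decision(d, ref, start, strand))
        )
    return pd.DataFrame(
        rows, columns=["read_id", "n", "overflow", "placed", "outcome"]
    )


def confusion_counts(per_read: pd.DataFrame) -> ConfusionCounts:
    c = per_read["outcome"].value_counts()
    return ConfusionCounts(
        int(c.get("TP", 0)), int(c.get("FP", 0)), int(c.get("TN", 0)), int(c.get("FN", 0))
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(counts: ConfusionCounts) -> dict:
    """Precision, sensitivity, F1 and both FNR variants; NaN where the
    denominator is zero."""
    p = _ratio(counts.tp, counts.tp + counts.fp)
    s = _ratio(counts.tp, counts.tp + counts.fn)
    f1 = 2 * p * s / (p + s) if np.isfinite(p) and np.isfinite(s) and (p + s) > 0 else float("nan")
    return {
        "tp": counts.tp,
        "fp": counts.fp,
        "tn": counts.tn,
        "fn": counts.fn,
        "precision": p,
        "sensitivity": s,
        "f1": f1,
        "fnr_printed": _ratio(counts.fn, counts.fp + counts.tp),
        "fnr_conventional": _ratio(counts.fn, counts.fn + counts.tp),
    }


def metrics_table(per_read: pd.DataFrame) -> pd.DataFrame:
    """Whole-library and MMAP-only metric rows."""
    rows = []
    for scope, sub in (
        ("all", per_read),
        ("mmap_only", per_read[(per_read["n"] >= 2) | per_read["overflow"]]),
    ):
        rows.append({"scope": scope, **compute_metrics(confusion_counts(sub))})
    return pd.DataFrame(rows)


def metrics_by_mmap(per_read: pd.DataFrame, max_n: int | None = None) -> pd.DataFrame:
    """Per-MMAP-value and cumulative metric rows.

    ``per_mmap(n)`` covers reads with exactly n candidate positions (n = 1
    is the unique-read row); ``cumulative_le(n)`` covers reads with
    MMAP-value <= n. Overflow reads (site count beyond the cap) have an
    unknown exact n and are excluded from both stratifications.
    """
    known = per_read[~per_read["overflow"] & (per_read["n"] >= 1)]
    if max_n is None:
        max_n = int(known["n"].max()) if len(known) else 1
    rows = []
    for n in range(1, max_n + 1):
        sub = known[known["n"] == n]
        if len(sub):
            rows.append({"scope": f"per_mmap({n})", "mmap": n,
                         **compute_metrics(confusion_counts(sub))})
        cum = known[known["n"] <= n]
        if len(cum):
            rows.append({"scope": f"cumulative_le({n})", "mmap": n,
                         **compute_metrics(confusion_counts(cum))})
    return pd.DataFrame(rows)


def retention_curve(
    groups_or_per_read,
    cutoffs: Sequence[int],
) -> pd.DataFrame:
    """Fraction of aligned reads with MMAP-value <= cutoff, per cutoff.

    The denominator is the number of reads with at least one alignment
    (overflow included); overflow reads count at their capped value and are
    never retained below the cap, matching their treatment at placement.
    """
    if isinstance(groups_or_per_read, pd.DataFrame):
        n = groups_or_per_read["n"].to_numpy()
        overflow = groups_or_per_read["overflow"].to_numpy()
    else:
        n = np.array([g.n for g in groups_or_per_read])
        overflow = np.array([g.overflow for g in groups_or_per_read])
    aligned = (n >= 1) | overflow
    total = int(aligned.sum())
    rows = []
    for cut in cutoffs:
        kept = int(((n >= 1) & (n <= cut) & ~overflow).sum())
        rows.append({"cutoff": cut, "retained": _ratio(kept, total)})
    return pd.DataFrame(rows)


def strand_bias(decisions: Sequence[PlacementDecision]) -> float:
    """Ratio of top-strand to bottom-strand primary records; NaN when no
    bottom-strand primaries (or no placed reads) exist."""
    plus = sum(1 for d in decisions if d.placed and d.site.strand == "+")
    minus = sum(1 for d in decisions if d.placed and d.site.strand == "-")
    return _ratio(plus, minus)
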