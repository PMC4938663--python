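"""Local-context weighted placement of multi-mapping reads.

The genome is divided into 50-nt bins; an alignment belongs to the bin of
its leftmost aligned nucleotide, strand-independent, with no pro-rating
across bin boundaries. The *vicinity* of a candidate site is the five-bin
(~250 nt) window centered on its bin, truncated at reference ends.

A single pass over the all-alignment map tallies, per bin,

* ``u``: alignments of uniquely aligned (n = 1) reads, and
* ``f``: fractional weight, each alignment contributing 1/n for its read,

and placement probabilities for a read with sites i = 1..n are

* mode R: uniform 1/n (emulating random placement),
* mode U: p_i = u_i / sum_j u_j over vicinity unique counts,
* mode F: p_i = f_i / sum_j f_j over vicinity fractional weights,

with the read's own contributions excluded from its vicinities. The
probabilities weight a categorical draw that designates the primary
alignment per read (identical sequences can land at different primaries);
all other candidate sites become secondary records. When every vicinity
weight is equal (including the all-zero case) the placement is a tie:
tied reads with more than ``tie_suppression_threshold`` positions are
suppressed (marked unmapped), the rest are placed uniformly at random.
Mode N ignores multi-mapping reads entirely, and reads whose site count
exceeded ``max_sites`` are marked unmapped in every mode. Tallies are
computed once up front; there is no iterative re-weighting.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pysam

from .align import (
    TAG_MMAP,
    TAG_OVERFLOW,
    TAG_PROB,
    TAG_STATUS,
    AlignmentGroup,
    AlignmentSite,
    _sam_header,
)
from .dna import revcomp

MODES = ("R", "U", "F", "N")

# placement statuses
PLACED = "placed"
PLACED_TIE = "placed_tie"
SUPPRESSED = "suppressed"              # tie across > threshold positions
UNMAPPED_OVERFLOW = "unmapped_overflow"  # site count exceeded max_sites
UNMAPPED_NOALIGN = "unmapped_noalign"    # no candidate sites at all
IGNORED_MMAP = "ignored_mmap"            # mode N, n > 1

_STATUS_CHAR = {
    PLACED: "P",
    PLACED_TIE: "T",
    SUPPRESSED: "S",
    UNMAPPED_OVERFLOW: "O",
    UNMAPPED_NOALIGN: "U",
    IGNORED_MMAP: "N",
}
_CHAR_STATUS = {v: k for k, v in _STATUS_CHAR.items()}

TIE = "TIE"  # sentinel returned by placement_probabilities

_TIE_RTOL = 1e-9


@dataclass
class PlacementConfig:
    mode: str = "U"
    bin_size: int = 50
    window_bins: int = 5
    max_sites: int = 50
    tie_suppression_threshold: int = 3
    rng_seed: int = 0

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.window_bins < 1 or self.window_bins % 2 == 0:
            raise ValueError("window_bins must be odd and >= 1")
        if self.tie_suppression_threshold < 1:
            raise ValueError("tie_suppression_threshold must be >= 1")
        if self.max_sites < 1:
            raise ValueError("max_sites must be >= 1")


@dataclass
class PlacementDecision:
    read_id: str
    probabilities: np.ndarray | None  # over the read's sites; None if suppressed
    chosen: int | None                # site index, or None when unmapped
    status: str
    mode: str
    n: int                            # MMAP-value of the read
    overflow: bool
    site: AlignmentSite | None = None

    @property
    def placed(self) -> bool:
        return self.chosen is not None


def bin_of(pos_or_site, bin_size: int = 50) -> int:
    """Bin index of an alignment: floor(leftmost pos / bin_size), regardless
    of strand."""
    pos = pos_or_site.pos if isinstance(pos_or_site, AlignmentSite) else pos_or_site
    return pos // bin_size


class BinTallyMap:
    """Per-reference, per-bin unique counts (u) and fractional weights (f),
    with precomputed sliding-window sums over the vicinity."""

    def __init__(
        self,
        ref_lengths: dict[str, int],
        bin_size: int = 50,
        window_bins: int = 5,
    ):
        self.bin_size = bin_size
        self.window_bins = window_bins
        self._half = window_bins // 2
        self.u: dict[str, np.ndarray] = {}
        self.f: dict[str, np.ndarray] = {}
        for name, length in ref_lengths.items():
            nbins = max(1, -(-length // bin_size))
            self.u[name] = np.zeros(nbins)
            self.f[name] = np.zeros(nbins)
        self._uwin: dict[str, np.ndarray] | None = None
        self._fwin: dict[str, np.ndarray] | None = None

    def add_group(self, group: AlignmentGroup) -> None:
        """Tally one read: 1/n fractional weight at every site's bin, plus a
        unique count when n = 1. Overflow and unaligned groups are skipped."""
        if group.overflow or group.n == 0:
            return
        w = 1.0 / group.n
        for site in group.sites:
            b = bin_of(site, self.bin_size)
            self.f[site.reference][b] += w
            if group.n == 1:
                self.u[site.reference][b] += 1.0
        self._uwin = None
        self._fwin = None

    def _window_sums(self, per_bin: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for name, x in per_bin.items():
            c = np.concatenate([[0.0], np.cumsum(x)])
            idx = np.arange(x.size)
            lo = np.maximum(idx - self._half, 0)
            hi = np.minimum(idx + self._half + 1, x.size)
            out[name] = c[hi] - c[lo]
        return out

    def finalize(self) -> "BinTallyMap":
        self._uwin = self._window_sums(self.u)
        self._fwin = self._window_sums(self.f)
        return self

    def window(self, site: AlignmentSite) -> tuple[float, float]:
        """Raw (u, f) vicinity sums for a site, no self-exclusion."""
        if self._uwin is None or self._fwin is None:
            self.finalize()
        b = bin_of(site, self.bin_size)
        return float(self._uwin[site.reference][b]), float(self._fwin[site.reference][b])


def build_tallies(
    groups: Sequence[AlignmentGroup],
    config: PlacementConfig,
    ref_lengths: dict[str, int],
) -> BinTallyMap:
    """Single pass over all candidate sites of a library."""
    tallies = BinTallyMap(ref_lengths, config.bin_size, config.window_bins)
    for g in groups:
        tallies.add_group(g)
    return tallies.finalize()


def vicinity_weight(
    site: AlignmentSite,
    tallies: BinTallyMap,
    config: PlacementConfig,
    exclude: AlignmentGroup | None = None,
) -> tuple[float, float]:
    """(u, f) vicinity sums at a site, with the contributions of the
    ``exclude`` read's own candidate sites subtracted."""
    u, f = tallies.window(site)
    if exclude is not None and not exclude.overflow and exclude.n > 0:
        half = config.window_bins // 2
        b = bin_of(site, config.bin_size)
        w = 1.0 / exclude.n
        for other in exclude.sites:
            if other.reference != site.reference:
                continue
            if abs(bin_of(other, config.bin_size) - b) <= half:
                f -= w
                if exclude.n == 1:
                    u -= 1.0
    return max(u, 0.0), max(f, 0.0)


def placement_probabilities(
    group: AlignmentGroup,
    tallies: BinTallyMap,
    config: PlacementConfig,
):
    """Probability vector over a read's candidate sites, or the TIE flag.

    R is uniform by definition and never ties; U and F tie when their
    vicinity weights are all equal (within a relative tolerance robust to
    floating-point accumulation), including the all-zero case.
    """
    n = group.n
    if n < 1 or n > config.max_sites:
        raise ValueError(f"read {group.read_id!r}: n={n} outside [1, max_sites]")
    if config.mode == "N":
        raise ValueError("mode N does not compute probabilities")
    if n == 1:
        return np.array([1.0])
    if config.mode == "R":
        return np.full(n, 1.0 / n)
    weights = np.empty(n)
    for i, site in enumerate(group.sites):
        u, f = vicinity_weight(site, tallies, config, exclude=group)
        weights[i] = u if config.mode == "U" else f
    total = weights.sum()
    if total <= 0.0:
        return TIE
    if np.allclose(weights, weights[0], rtol=_TIE_RTOL, atol=0.0):
        return TIE
    return weights / total


def choose_primary(
    group: AlignmentGroup,
    probabilities,
    config: PlacementConfig,
    rng: np.random.Generator,
) -> PlacementDecision:
    """Designate the primary site by a probability-weighted draw; resolve
    ties by uniform choice up to the suppression threshold."""
    if group.overflow:
        return PlacementDecision(
            group.read_id, None, None, UNMAPPED_OVERFLOW, config.mode,
            group.n, True,
        )
    if group.n == 0:
        return PlacementDecision(
            group.read_id, None, None, UNMAPPED_NOALIGN, config.mode, 0, False
        )
    if isinstance(probabilities, str) and probabilities == TIE:
        if group.n > config.tie_suppression_threshold:
            return PlacementDecision(
                group.read_id, None, None, SUPPRESSED, config.mode,
                group.n, False,
            )
        chosen = int(rng.integers(group.n))
        probs = np.full(group.n, 1.0 / group.n)
        return PlacementDecision(
            group.read_id, probs, chosen, PLACED_TIE, config.mode,
            group.n, False, group.sites[chosen],
        )
    probs = np.asarray(probabilities, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"read {group.read_id!r}: probabilities do not sum to 1")
    chosen = int(rng.choice(probs.size, p=probs)) if probs.size > 1 else 0
    return PlacementDecision(
        group.read_id, probs, chosen, PLACED, config.mode,
        group.n, False, group.sites[chosen],
    )


def place_library(
    groups: Sequence[AlignmentGroup],
    config: PlacementConfig,
    ref_lengths: dict[str, int],
) -> list[PlacementDecision]:
    """Place every read of a library under one mode.

    Tallies are computed once from the full all-alignment map before any
    placement. Mode N places unique reads and marks every n > 1 read
    unmapped; modes R/U/F place every eligible read via choose_primary.
    """
    config.validate()
    seen: set[str] = set()
    for g in groups:
        if g.read_id in seen:
            raise ValueError(f"duplicate read_id {g.read_id!r}")
        seen.add(g.read_id)

    tallies = (
        build_tallies(groups, config, ref_lengths)
        if config.mode in ("U", "F")
        else BinTallyMap(ref_lengths, config.bin_size, config.window_bins).finalize()
    )
    rng = np.random.default_rng(config.rng_seed)
    decisions = []
    for g in groups:
        if g.overflow or g.n == 0:
            decisions.append(choose_primary(g, None, config, rng))
        elif g.n == 1:
            decisions.append(
                PlacementDecision(
                    g.read_id, np.array([1.0]), 0, PLACED, config.mode,
                    1, False, g.sites[0],
                )
            )
        elif config.mode == "N":
            decisions.append(
                PlacementDecision(
                    g.read_id, None, None, IGNORED_MMAP, config.mode,
                    g.n, False,
                )
            )
        else:
            probs = placement_probabilities(g, tallies, config)
            decisions.append(choose_primary(g, probs, config, rng))
    return decisions


def write_placed_sam(
    groups: Sequence[AlignmentGroup],
    decisions: Sequence[PlacementDecision],
    ref_lengths: dict[str, int],
    path: str | os.PathLike,
) -> None:
    """Exactly one primary record per placed read; all other candidate
    sites emitted as secondary; suppressed/overflow/unaligned reads emitted
    unmapped, each record tagged with MMAP-value, chosen-site probability,
    and placement status."""
    header = _sam_header(ref_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for g, d in zip(groups, decisions):
            status_char = _STATUS_CHAR[d.status]
            if not d.placed:
                rec = pysam.AlignedSegment(header)
                rec.query_name = g.read_id
                rec.query_sequence = g.sequence
                rec.is_unmapped = True
                rec.set_tag(TAG_MMAP, g.n)
                rec.set_tag(TAG_STATUS, status_char)
                if g.overflow:
                    rec.set_tag(TAG_OVERFLOW, 1)
                out.write(rec)
                continue
            for i, site in enumerate(g.sites):
                rec = pysam.AlignedSegment(header)
                rec.query_name = g.read_id
                flag = 0x10 if site.strand == "-" else 0
                if i != d.chosen:
                    flag |= 0x100
                rec.flag = flag
                rec.reference_name = site.reference
                rec.reference_start = site.pos
                rec.mapping_quality = 255
                rec.cigarstring = f"{site.length}M"
                rec.query_sequence = (
                    revcomp(g.sequence) if site.strand == "-" else g.sequence
                )
                rec.set_tag(TAG_MMAP, g.n)
                rec.set_tag(TAG_STATUS, status_char)
                if i == d.chosen and d.probabilities is not None:
                    rec.set_tag(TAG_PROB, float(d.probabilities[i]))
                out.write(rec)


def read_placed_sam(path: str | os.PathLike) -> list[PlacementDecision]:
    """Recover placement decisions (primary site, status, MMAP-value) from a
    placed SAM; secondary records are skipped."""
    decisions: dict[str, PlacementDecision] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as fh:
        for rec in fh:
            if rec.is_secondary:
                continue
            n = int(rec.get_tag(TAG_MMAP)) if rec.has_tag(TAG_MMAP) else 0
            status = (
                _CHAR_STATUS[rec.get_tag(TAG_STATUS)]
                if rec.has_tag(TAG_STATUS)
                else (UNMAPPED_NOALIGN if rec.is_unmapped else PLACED)
            )
            overflow = rec.has_tag(TAG_OVERFLOW)
            if rec.is_unmapped:
                decisions[rec.query_name] = PlacementDecision(
                    rec.query_name, None, None, status, "?", n, overflow
                )
            else:
                site = AlignmentSite(
                    rec.reference_name,
                    rec.reference_start,
                    "-" if rec.is_reverse else "+",
                    rec.query_length,
                )
                prob = (
                    np.array([float(rec.get_tag(TAG_PROB))])
                    if rec.has_tag(TAG_PROB)
                    else None
                )
                decisions[rec.query_name] = PlacementDecision(
                    rec.query_name, prob, 0, status, "?", n, overflow, site
                )
    return list(decisions.values())
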