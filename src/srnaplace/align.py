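"""All-alignment enumeration of exact-match read placements.

The internal aligner reports *every* best (exact, 0-mismatch) match of a
read against both strands of the genome, capped at a user-adjustable limit
(default 50 alignments per read). Minus-strand hits are reported by the
leftmost plus-strand coordinate of the reverse complement's match, matching
SAM conventions. Externally produced all-alignment SAM (bowtie -a style)
can be read in as an alternative to internal alignment, so mismatch-aware
aligners can be used upstream of placement.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam

from .dna import DNA_ALPHABET, revcomp

DEFAULT_MAX_SITES = 50
DEFAULT_LENGTH_RANGE = (20, 25)

# package-defined SAM tags; readers should not assume any other aligner's vocabulary
TAG_MMAP = "XV"    # integer MMAP-value of the owning read
TAG_PROB = "XP"    # float placement probability of the chosen site
TAG_STATUS = "XT"  # single-character placement status
TAG_OVERFLOW = "XO"  # present (=1) when the site list was truncated at the cap


@dataclass(frozen=True, order=True)
class AlignmentSite:
    """One candidate placement: reference, 0-based leftmost position, strand,
    aligned length. Ordering is (reference, pos, strand) lexicographic."""

    reference: str
    pos: int
    strand: str
    length: int


@dataclass
class AlignmentGroup:
    """All candidate sites of one read; ``n`` is the MMAP-value."""

    read_id: str
    sequence: str
    sites: list[AlignmentSite] = field(default_factory=list)
    overflow: bool = False

    @property
    def n(self) -> int:
        return len(self.sites)


class GenomeIndex:
    """Exact-substring lookup over both strands of a genome.

    Indexes all ``min_length``-mers of the plus strand; longer queries are
    verified by extension, so any read length within ``length_range`` can be
    searched. Queries containing characters outside ACGT find nothing.
    """

    def __init__(
        self,
        genome: dict[str, str],
        length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    ):
        if not genome:
            raise ValueError("cannot index an empty genome")
        lo, hi = length_range
        if lo > hi or lo < 1:
            raise ValueError(f"invalid length range {length_range}")
        self.length_range = (lo, hi)
        self._k = lo
        self._refs = {name: seq.upper() for name, seq in genome.items()}
        self.ref_lengths = {name: len(seq) for name, seq in self._refs.items()}
        index: dict[str, list[tuple[str, int]]] = {}
        k = self._k
        for name, seq in self._refs.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((name, i))
        self._index = index

    def find_exact(self, query: str) -> list[tuple[str, int]]:
        """All (reference, pos) where `query` occurs on the plus strand."""
        q = query.upper()
        k = self._k
        hits = []
        for name, i in self._index.get(q[:k], ()):
            if len(q) == k or self._refs[name][i : i + len(q)] == q:
                hits.append((name, i))
        return hits


def brute_force_sites(
    genome: dict[str, str], sequence: str
) -> list[AlignmentSite]:
    """Reference scanner: naive O(genome x read) enumeration of exact
    matches on both strands. Used as an independent check on the index."""
    seq = sequence.upper()
    out = []
    for strand, q in (("+", seq), ("-", revcomp(seq))):
        for name, ref in genome.items():
            refu = ref.upper()
            i = refu.find(q)
            while i != -1:
                out.append(AlignmentSite(name, i, strand, len(seq)))
                i = refu.find(q, i + 1)
    return sorted(out, key=lambda s: (s.reference, s.pos, s.strand))


def align_read(
    read_id: str,
    sequence: str,
    index: GenomeIndex,
    max_sites: int = DEFAULT_MAX_SITES,
) -> AlignmentGroup:
    """Enumerate all exact-match sites of one read, both strands, in
    deterministic (reference, pos, strand) order; truncate at ``max_sites``
    with the overflow flag set."""
    lo, hi = index.length_range
    if not lo <= len(sequence) <= hi:
        raise ValueError(
            f"read {read_id!r}: length {len(sequence)} outside the indexed "
            f"range [{lo}, {hi}]"
        )
    seq = sequence.upper()
    if set(seq) - set(DNA_ALPHABET):
        return AlignmentGroup(read_id, sequence, [])
    sites = [AlignmentSite(r, p, "+", len(seq)) for r, p in index.find_exact(seq)]
    sites += [
        AlignmentSite(r, p, "-", len(seq)) for r, p in index.find_exact(revcomp(seq))
    ]
    sites.sort(key=lambda s: (s.reference, s.pos, s.strand))
    overflow = len(sites) > max_sites
    if overflow:
        sites = sites[:max_sites]
    return AlignmentGroup(read_id, sequence, sites, overflow)


def align_library(
    reads: Iterable[tuple[str, str]],
    index: GenomeIndex,
    max_sites: int = DEFAULT_MAX_SITES,
) -> list[AlignmentGroup]:
    """Align many reads, caching site lists per distinct sequence (placement
    stays per-read: identical sequences share sites, not decisions)."""
    cache: dict[str, tuple[list[AlignmentSite], bool]] = {}
    groups = []
    for read_id, seq in reads:
        hit = cache.get(seq)
        if hit is None:
            g = align_read(read_id, seq, index, max_sites)
            cache[seq] = (g.sites, g.overflow)
            groups.append(g)
        else:
            groups.append(AlignmentGroup(read_id, seq, list(hit[0]), hit[1]))
    return groups


# --- SAM I/O ---------------------------------------------------------------

def _sam_header(ref_lengths: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": name, "LN": length} for name, length in ref_lengths.items()],
        }
    )


def write_all_alignment_sam(
    groups: Sequence[AlignmentGroup],
    ref_lengths: dict[str, int],
    path: str | os.PathLike,
) -> None:
    """Write one record per candidate site (all flagged secondary, pending
    placement); reads with no sites get a single unmapped record."""
    header = _sam_header(ref_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for g in groups:
            if g.n == 0:
                rec = pysam.AlignedSegment(header)
                rec.query_name = g.read_id
                rec.query_sequence = g.sequence
                rec.is_unmapped = True
                rec.set_tag(TAG_MMAP, 0)
                out.write(rec)
                continue
            for site in g.sites:
                rec = pysam.AlignedSegment(header)
                rec.query_name = g.read_id
                rec.flag = 0x100 | (0x10 if site.strand == "-" else 0)
                rec.reference_name = site.reference
                rec.reference_start = site.pos
                rec.mapping_quality = 255
                rec.cigarstring = f"{site.length}M"
                rec.query_sequence = (
                    revcomp(g.sequence) if site.strand == "-" else g.sequence
                )
                rec.set_tag(TAG_MMAP, g.n)
                if g.overflow:
                    rec.set_tag(TAG_OVERFLOW, 1)
                out.write(rec)


def read_all_alignment_sam(path: str | os.PathLike) -> list[AlignmentGroup]:
    """Group an all-alignment SAM by query name (records for one read need
    not be adjacent); SAM 1-based POS becomes internal 0-based; strand comes
    from FLAG 0x10; unmapped records yield n = 0 groups."""
    groups: dict[str, AlignmentGroup] = {}
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=True) as fh:
            for rec in fh:
                seq = rec.query_sequence
                if seq is None:
                    raise ValueError(f"record {rec.query_name!r} has no sequence")
                if rec.is_reverse:
                    seq = revcomp(seq)
                g = groups.get(rec.query_name)
                if g is None:
                    g = AlignmentGroup(rec.query_name, seq, [])
                    groups[rec.query_name] = g
                elif len(g.sequence) != len(seq):
                    raise ValueError(
                        f"read {rec.query_name!r}: inconsistent sequence lengths "
                        f"across records ({len(g.sequence)} vs {len(seq)})"
                    )
                if rec.has_tag(TAG_OVERFLOW):
                    g.overflow = True
                if rec.is_unmapped:
                    continue
                site = AlignmentSite(
                    rec.reference_name,
                    rec.reference_start,
                    "-" if rec.is_reverse else "+",
                    rec.query_length,
                )
                if site in g.sites:
                    raise ValueError(
                        f"read {rec.query_name!r}: duplicate candidate site {site}"
                    )
                g.sites.append(site)
    except ValueError:
        raise
    except Exception as exc:  # htslib parse errors carry the line context
        raise ValueError(f"malformed SAM file {path}: {exc}") from exc
    for g in groups.values():
        g.sites.sort(key=lambda s: (s.reference, s.pos, s.strand))
    return list(groups.values())


def read_sam_ref_lengths(path: str | os.PathLike) -> dict[str, int]:
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as fh:
        return dict(zip(fh.references, fh.lengths))
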