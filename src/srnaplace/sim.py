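"""Ground-truth small RNA-seq simulation.

Generates (1) a synthetic genome with planted small RNA loci, including
repeat families whose identical core segments make reads multi-mapping in a
controlled way, and (2) a traceable read library emulating the composition
of plant sRNA-seq data: ~65% heterochromatic siRNA (primarily 24 nt, from
200-1000 nt loci, both strands), ~30% miRNA (21 nt, 125 nt hairpin loci,
miRNA/miRNA* duplex pattern), and ~5% tasiRNA (21 nt, 140 nt loci, phased
registers on both strands), with misprocessing length/5' variants and a
sequencing-error rate of one mis-sequenced base per 10,000 reads.

Every read ID encodes its true origin (locus|reference|start|strand|serial),
and a tab-separated truth table is the canonical record of origins, so
placements can be scored exactly.

Repeat families model partially repetitive siRNA loci: each family is one
*expressed* locus containing an identical core of ``unit_length`` nt, with
``copy_number - 1`` silent copies of that core planted elsewhere in the
genome. Reads wholly inside the core align to every copy (MMAP-value =
copy_number); reads overlapping the locus's unique flanks align uniquely and
provide the local-context signal that vicinity weighting exploits. Fully
duplicated, fully co-expressed loci would leave no unique reads anywhere
near any copy and would make context-based placement impossible in
principle, which is not how repeat-derived siRNA loci behave.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .dna import COMP_U8, seq_to_u8

CLASS_HC = "hc_siRNA"
CLASS_MIR = "miRNA"
CLASS_TAS = "tasiRNA"
CLASSES = (CLASS_HC, CLASS_MIR, CLASS_TAS)

HC_LOCUS_LEN_RANGE = (200, 1000)
MIR_LOCUS_LEN = 125
TAS_LOCUS_LEN = 140

HC_READ_LEN = 24      # canonical hc-siRNA length
SRNA_READ_LEN = 21    # canonical miRNA / tasiRNA length
READ_LEN_MIN = 20
READ_LEN_MAX = 25

# miRNA hairpin geometry: mature miRNA on the 5' arm at a fixed offset; the
# miRNA* is its duplex partner on the 3' arm with the canonical 2-nt 3'
# overhang. Both arms sit on the plus strand of the (transcribed) locus.
MIR_MATURE_OFFSET = 20
MIR_STAR_OFFSET = MIR_LOCUS_LEN - MIR_MATURE_OFFSET - SRNA_READ_LEN - 2

# tasiRNA phasing: 21-nt registers anchored at the locus start on the plus
# strand; minus-strand registers offset by the 2-nt duplex overhang.
TAS_PHASE = 21
TAS_MINUS_SHIFT = 2
TAS_N_REGISTERS = 6  # per strand, within a 140-nt locus

STRAND_CHARS = ("+", "-")

TRUTH_COLUMNS = [
    "read_id", "locus_id", "class", "true_reference", "true_start",
    "true_strand", "length", "family_id", "has_error",
]


@dataclass
class SimGenomeConfig:
    """Layout of the synthetic genome and its planted loci.

    ``repeat_families`` is a list of (copy_number, unit_length) pairs; each
    entry creates one expressed hc-siRNA locus whose ``unit_length``-nt core
    is planted, base-identical, at ``copy_number`` genomic positions in
    total (the locus itself plus copy_number - 1 silent copies).
    """

    n_references: int = 1
    reference_length: int = 1_000_000
    gc_content: float = 0.37
    n_loci: int = 200
    class_fractions: tuple[float, float, float] = (0.65, 0.30, 0.05)
    repeat_families: list[tuple[int, int]] = field(default_factory=list)
    min_locus_gap: int = 250
    min_core_flank: int = 75
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_references < 1 or self.reference_length < 1:
            raise ValueError("need at least one reference of positive length")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_loci < 0:
            raise ValueError("n_loci must be non-negative")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9 or min(self.class_fractions) < 0:
            raise ValueError("class_fractions must be non-negative and sum to 1")
        for copy_number, unit_length in self.repeat_families:
            if copy_number < 1:
                raise ValueError("repeat family copy_number must be >= 1")
            lo, hi = HC_LOCUS_LEN_RANGE
            if unit_length + 2 * self.min_core_flank > hi:
                raise ValueError(
                    f"repeat unit of {unit_length} nt cannot fit inside a "
                    f"<= {hi} nt hc-siRNA locus with {self.min_core_flank} nt flanks"
                )
            if unit_length < READ_LEN_MAX:
                raise ValueError("repeat unit shorter than the longest read")


@dataclass
class SimLocus:
    """One planted small RNA locus (0-based half-open coordinates)."""

    locus_id: str
    locus_class: str
    reference: str
    start: int
    end: int
    strand_mode: str            # 'both' or 'plus_hairpin'
    family_id: str | None
    abundance_weight: float
    core_start: int | None = None   # identical repeated core, family loci only
    core_end: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatUnit:
    """One planted copy of a repeat-family core segment."""

    family_id: str
    reference: str
    start: int
    end: int
    locus_id: str | None  # owning expressed locus, None for silent copies


@dataclass
class SimGenome:
    references: dict[str, str]
    loci: list[SimLocus]
    repeat_units: list[RepeatUnit]
    config: SimGenomeConfig


@dataclass
class SimLibraryConfig:
    """Read-sampling model of the simulated library."""

    n_reads: int = 100_000
    class_weights: tuple[float, float, float] = (0.65, 0.30, 0.05)
    error_rate: float = 1e-4
    # misprocessing: canonical read length +offset with the paired probability
    length_offsets: tuple[int, ...] = (0, -1, 1, -2, 2)
    length_probs: tuple[float, ...] = (0.80, 0.08, 0.08, 0.02, 0.02)
    shift_prob: float = 0.10          # 5' start shifted by +/-1 nt
    mir_star_ratio: float = 10.0      # mature miRNA : miRNA* abundance
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        if abs(sum(self.class_weights) - 1.0) > 1e-12 or min(self.class_weights) < 0:
            raise ValueError("class_weights must be non-negative and sum to 1")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if abs(sum(self.length_probs) - 1.0) > 1e-9:
            raise ValueError("length_probs must sum to 1")
        if not 0.0 <= self.shift_prob <= 1.0:
            raise ValueError("shift_prob must be in [0, 1]")
        if self.mir_star_ratio <= 0:
            raise ValueError("mir_star_ratio must be positive")


@dataclass
class SimReadRecord:
    read_id: str
    sequence: str
    has_error: bool


@dataclass
class SimLibrary:
    """A simulated library: sequences plus the canonical truth table."""

    read_ids: list[str]
    sequences: list[str]
    truth: pd.DataFrame

    def __len__(self) -> int:
        return len(self.read_ids)

    def records(self) -> Iterator[SimReadRecord]:
        errs = self.truth["has_error"].to_numpy()
        for rid, seq, err in zip(self.read_ids, self.sequences, errs):
            yield SimReadRecord(rid, seq, bool(err))

    def write_fastq(self, path) -> None:
        from .seqio import write_fastq

        write_fastq(zip(self.read_ids, self.sequences), path)

    def write_truth(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _apportion(total: int, fractions: Sequence[float]) -> list[int]:
    """Integer split of `total` by `fractions` (largest remainder)."""
    raw = [total * f for f in fractions]
    counts = [math.floor(x) for x in raw]
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[: total - sum(counts)]:
        counts[i] += 1
    return counts


def _layout_items(
    lengths: list[int], ref_length: int, gap: int, rng: np.random.Generator
) -> list[int]:
    """Random non-overlapping starts for items of the given lengths, keeping
    at least `gap` nt between items and from the reference ends."""
    k = len(lengths)
    if k == 0:
        return []
    free = ref_length - sum(lengths) - gap * (k + 1)
    if free < 0:
        raise ValueError(
            f"cannot fit {k} loci totalling {sum(lengths)} nt (plus {gap} nt "
            f"gaps) into a {ref_length} nt reference"
        )
    cuts = rng.random(k + 1)
    cuts = cuts / cuts.sum() * free
    starts = []
    x = gap + cuts[0]
    for i, length in enumerate(lengths):
        starts.append(int(x))
        x += length + gap + cuts[i + 1]
    return starts


def generate_genome(config: SimGenomeConfig) -> SimGenome:
    """Build the synthetic genome and its planted-locus table.

    Background sequence is i.i.d. with the configured GC content; repeat
    family cores are exact copies (zero divergence), so a read lying wholly
    inside a core has exactly ``copy_number`` best alignments.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    n_hc, n_mir, n_tas = _apportion(config.n_loci, config.class_fractions)
    n_fam = len(config.repeat_families)
    if n_fam > n_hc:
        raise ValueError(
            f"{n_fam} repeat families but only {n_hc} hc-siRNA loci planned"
        )

    # --- plan items to place: expressed loci and silent repeat copies ---
    # item: (kind, locus_class, length, family_index, core_offset, unit_len)
    items: list[tuple] = []
    lo, hi = HC_LOCUS_LEN_RANGE
    for j, (copy_number, unit_len) in enumerate(config.repeat_families):
        min_len = max(lo, unit_len + 2 * config.min_core_flank)
        length = int(rng.integers(min_len, hi + 1))
        core_off = int(
            rng.integers(config.min_core_flank, length - unit_len - config.min_core_flank + 1)
        )
        items.append(("locus", CLASS_HC, length, j, core_off, unit_len))
        for _ in range(copy_number - 1):
            items.append(("silent", None, unit_len, j, None, unit_len))
    for length in rng.integers(lo, hi + 1, size=n_hc - n_fam):
        items.append(("locus", CLASS_HC, int(length), None, None, None))
    items += [("locus", CLASS_MIR, MIR_LOCUS_LEN, None, None, None)] * n_mir
    items += [("locus", CLASS_TAS, TAS_LOCUS_LEN, None, None, None)] * n_tas

    order = rng.permutation(len(items))
    ref_names = [f"ref{i + 1}" for i in range(config.n_references)]
    per_ref: dict[int, list[tuple]] = {i: [] for i in range(config.n_references)}
    for rank, idx in enumerate(order):
        per_ref[rank % config.n_references].append(items[idx])

    # --- background sequence ---
    gc = config.gc_content
    base_probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    ref_arrays = {
        name: letters[rng.choice(4, size=config.reference_length, p=base_probs)]
        for name in ref_names
    }

    # --- place items and overwrite family cores with shared unit sequences ---
    unit_seqs: dict[int, np.ndarray] = {}
    placed: list[tuple] = []  # (kind, cls, ref, start, length, fam_idx, core_off, unit_len)
    for ref_idx, ref_items in per_ref.items():
        lengths = [it[2] for it in ref_items]
        starts = _layout_items(lengths, config.reference_length, config.min_locus_gap, rng)
        for it, start in zip(ref_items, starts):
            placed.append((it[0], it[1], ref_names[ref_idx], start, it[2], it[3], it[4], it[5]))

    for kind, _cls, ref, start, length, fam_idx, core_off, unit_len in placed:
        if fam_idx is None:
            continue
        if fam_idx not in unit_seqs:
            unit_seqs[fam_idx] = letters[rng.choice(4, size=unit_len, p=base_probs)]
        unit = unit_seqs[fam_idx]
        core_at = start + (core_off if kind == "locus" else 0)
        ref_arrays[ref][core_at : core_at + unit_len] = unit

    references = {name: arr.tobytes().decode("ascii") for name, arr in ref_arrays.items()}

    # --- build locus and repeat tables, sorted by coordinate ---
    placed.sort(key=lambda t: (t[2], t[3]))
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_loci)
    loci: list[SimLocus] = []
    repeat_units: list[RepeatUnit] = []
    li = 0
    for kind, cls, ref, start, length, fam_idx, core_off, unit_len in placed:
        fam_id = None if fam_idx is None else f"F{fam_idx:03d}"
        if kind == "silent":
            repeat_units.append(RepeatUnit(fam_id, ref, start, start + length, None))
            continue
        locus_id = f"L{li:04d}"
        strand_mode = "plus_hairpin" if cls == CLASS_MIR else "both"
        core_start = core_end = None
        if fam_idx is not None:
            core_start = start + core_off
            core_end = core_start + unit_len
            repeat_units.append(
                RepeatUnit(fam_id, ref, core_start, core_end, locus_id)
            )
        loci.append(
            SimLocus(
                locus_id, cls, ref, start, start + length, strand_mode,
                fam_id, float(weights[li]), core_start, core_end,
            )
        )
        li += 1

    return SimGenome(references, loci, repeat_units, config)


def default_benchmark_genome_config(rng_seed: int = 0) -> SimGenomeConfig:
    """The stock benchmark genome: one 1-Mb reference, 200 loci, 30% of the
    hc-siRNA loci carrying repeat-family cores of copy number 2-8."""
    rng = np.random.default_rng(rng_seed)
    n_loci = 200
    fractions = (0.65, 0.30, 0.05)
    n_hc = _apportion(n_loci, fractions)[0]
    n_fam = round(0.30 * n_hc)
    families = [
        (int(rng.integers(2, 9)), int(rng.integers(100, 251))) for _ in range(n_fam)
    ]
    return SimGenomeConfig(
        n_references=1,
        reference_length=1_000_000,
        n_loci=n_loci,
        class_fractions=fractions,
        repeat_families=families,
        rng_seed=rng_seed,
    )


def _clip_lengths(canonical: int, offsets, probs, m: int, rng) -> np.ndarray:
    off = rng.choice(np.asarray(offsets), size=m, p=np.asarray(probs))
    return np.clip(canonical + off, READ_LEN_MIN, READ_LEN_MAX)


def _shifts(m: int, shift_prob: float, rng) -> np.ndarray:
    return rng.choice(
        np.array([-1, 0, 1]),
        size=m,
        p=[shift_prob / 2, 1 - shift_prob, shift_prob / 2],
    )


def simulate_library(
    references: dict[str, str],
    loci: Sequence[SimLocus],
    config: SimLibraryConfig,
) -> SimLibrary:
    """Draw a traceable read library from planted loci.

    Each read is sampled by (1) class from ``class_weights``, (2) locus from
    per-locus abundance weights within the class, (3) position/strand/length
    from the class's pattern model, and (4) optionally one substitution
    error with probability ``error_rate``.
    """
    config.validate()
    n = config.n_reads
    if n == 0:
        truth = pd.DataFrame({c: pd.Series(dtype=object) for c in TRUTH_COLUMNS})
        return SimLibrary([], [], truth)
    if not loci:
        raise ValueError("n_reads > 0 but the locus list is empty")

    rng = np.random.default_rng(config.rng_seed)
    weights = np.asarray(config.class_weights, dtype=float)

    class_loci = {cls: [i for i, l in enumerate(loci) if l.locus_class == cls] for cls in CLASSES}
    for cls, w in zip(CLASSES, weights):
        if w > 0 and not class_loci[cls]:
            raise ValueError(f"class {cls} has weight {w} but no loci")

    lstart = np.array([l.start for l in loci], dtype=np.int64)
    lend = np.array([l.end for l in loci], dtype=np.int64)
    labund = np.array([l.abundance_weight for l in loci], dtype=float)

    cls_draw = rng.choice(3, size=n, p=weights)
    loc_idx = np.empty(n, dtype=np.int64)
    start = np.empty(n, dtype=np.int64)
    length = np.empty(n, dtype=np.int64)
    strand = np.zeros(n, dtype=np.uint8)  # 0 = '+', 1 = '-'

    lo_off, lo_p = config.length_offsets, config.length_probs

    # hc-siRNA: uniform positions, both strands
    sel = np.flatnonzero(cls_draw == 0)
    if sel.size:
        cand = np.array(class_loci[CLASS_HC])
        p = labund[cand] / labund[cand].sum()
        li = cand[rng.choice(cand.size, size=sel.size, p=p)]
        L = _clip_lengths(HC_READ_LEN, lo_off, lo_p, sel.size, rng)
        span = lend[li] - lstart[li] - L + 1
        s = lstart[li] + np.floor(rng.random(sel.size) * span).astype(np.int64)
        loc_idx[sel], start[sel], length[sel] = li, s, L
        strand[sel] = rng.integers(0, 2, size=sel.size, dtype=np.uint8)

    # miRNA: mature and star registers on the plus strand of the hairpin
    sel = np.flatnonzero(cls_draw == 1)
    if sel.size:
        cand = np.array(class_loci[CLASS_MIR])
        p = labund[cand] / labund[cand].sum()
        li = cand[rng.choice(cand.size, size=sel.size, p=p)]
        star = rng.random(sel.size) < 1.0 / (1.0 + config.mir_star_ratio)
        L = _clip_lengths(SRNA_READ_LEN, lo_off, lo_p, sel.size, rng)
        base = lstart[li] + np.where(star, MIR_STAR_OFFSET, MIR_MATURE_OFFSET)
        s = np.clip(base + _shifts(sel.size, config.shift_prob, rng), lstart[li], lend[li] - L)
        loc_idx[sel], start[sel], length[sel] = li, s, L

    # tasiRNA: phased 21-nt registers on both strands, weights drawn per locus
    sel = np.flatnonzero(cls_draw == 2)
    if sel.size:
        cand = np.array(class_loci[CLASS_TAS])
        p = labund[cand] / labund[cand].sum()
        li = cand[rng.choice(cand.size, size=sel.size, p=p)]
        L = _clip_lengths(SRNA_READ_LEN, lo_off, lo_p, sel.size, rng)
        sh = _shifts(sel.size, config.shift_prob, rng)
        reg = np.empty(sel.size, dtype=np.int64)
        for lidx in class_loci[CLASS_TAS]:
            rw = rng.lognormal(0.0, 1.0, size=2 * TAS_N_REGISTERS)
            mask = np.flatnonzero(li == lidx)
            if mask.size:
                reg[mask] = rng.choice(2 * TAS_N_REGISTERS, size=mask.size, p=rw / rw.sum())
        minus = reg >= TAS_N_REGISTERS
        base = lstart[li] + TAS_PHASE * (reg % TAS_N_REGISTERS) + np.where(minus, TAS_MINUS_SHIFT, 0)
        s = np.clip(base + sh, lstart[li], lend[li] - L)
        loc_idx[sel], start[sel], length[sel] = li, s, L
        strand[sel] = minus.astype(np.uint8)

    # --- extract sequences (vectorised per reference/length/strand group) ---
    ref_names = list(references)
    ref_code = {name: i for i, name in enumerate(ref_names)}
    ref_u8 = {i: seq_to_u8(references[name]) for i, name in enumerate(ref_names)}
    locus_ref_code = np.array([ref_code[l.reference] for l in loci], dtype=np.int64)
    read_ref = locus_ref_code[loc_idx]

    sequences: list[str | None] = [None] * n
    for ri in range(len(ref_names)):
        arr = ref_u8[ri]
        in_ref = read_ref == ri
        for L in range(READ_LEN_MIN, READ_LEN_MAX + 1):
            for st in (0, 1):
                grp = np.flatnonzero(in_ref & (length == L) & (strand == st))
                if not grp.size:
                    continue
                mat = arr[start[grp][:, None] + np.arange(L)]
                if st == 1:
                    mat = COMP_U8[mat][:, ::-1]
                rows = np.ascontiguousarray(mat).view(f"S{L}").ravel().tolist()
                for i, b in zip(grp.tolist(), rows):
                    sequences[i] = b.decode("ascii")

    # --- sequencing errors: at most one substitution per read ---
    has_error = rng.random(n) < config.error_rate
    alphabet = "ACGT"
    for i in np.flatnonzero(has_error).tolist():
        seq = sequences[i]
        pos = int(rng.integers(len(seq)))
        alternatives = [b for b in alphabet if b != seq[pos]]
        new = alternatives[int(rng.integers(3))]
        sequences[i] = seq[:pos] + new + seq[pos + 1 :]

    # --- identifiers and truth table ---
    locus_ids = [l.locus_id for l in loci]
    fam_ids = [l.family_id if l.family_id is not None else "." for l in loci]
    fam_cats = sorted(set(fam_ids))
    strand_str = np.where(strand == 0, "+", "-")
    read_ids = [
        f"{locus_ids[l]}|{ref_names[r]}|{s}|{c}|{i}"
        for i, (l, r, s, c) in enumerate(
            zip(loc_idx.tolist(), read_ref.tolist(), start.tolist(), strand_str.tolist())
        )
    ]

    truth = pd.DataFrame(
        {
            "read_id": read_ids,
            "locus_id": pd.Categorical.from_codes(loc_idx, categories=locus_ids),
            "class": pd.Categorical.from_codes(cls_draw, categories=list(CLASSES)),
            "true_reference": pd.Categorical.from_codes(read_ref, categories=ref_names),
            "true_start": start,
            "true_strand": pd.Categorical.from_codes(strand, categories=["+", "-"]),
            "length": length,
            "family_id": pd.Categorical.from_codes(
                np.array([fam_cats.index(f) for f in fam_ids], dtype=np.int64)[loc_idx],
                categories=fam_cats,
            ),
            "has_error": has_error,
        }
    )
    return SimLibrary(read_ids, sequences, truth)  # type: ignore[arg-type]


# --- table I/O -------------------------------------------------------------

def write_loci_bed(loci: Sequence[SimLocus], path) -> None:
    """BED6+1: reference, start, end, locus_id, abundance rank, '.', class."""
    ranks = {
        l.locus_id: r + 1
        for r, l in enumerate(sorted(loci, key=lambda x: -x.abundance_weight))
    }
    with open(path, "w") as fh:
        for l in loci:
            fh.write(
                f"{l.reference}\t{l.start}\t{l.end}\t{l.locus_id}\t"
                f"{ranks[l.locus_id]}\t.\t{l.locus_class}\n"
            )


def loci_to_frame(loci: Sequence[SimLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in loci],
            "class": [l.locus_class for l in loci],
            "reference": [l.reference for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "strand_mode": [l.strand_mode for l in loci],
            "family_id": [l.family_id if l.family_id else "." for l in loci],
            "abundance_weight": [l.abundance_weight for l in loci],
            "core_start": [l.core_start if l.core_start is not None else -1 for l in loci],
            "core_end": [l.core_end if l.core_end is not None else -1 for l in loci],
        }
    )


def write_loci_tsv(loci: Sequence[SimLocus], path) -> None:
    loci_to_frame(loci).to_csv(path, sep="\t", index=False)


def read_loci_tsv(path) -> list[SimLocus]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.to_dict("records"):
        out.append(
            SimLocus(
                row["locus_id"], row["class"], row["reference"],
                int(row["start"]), int(row["end"]), row["strand_mode"],
                None if row["family_id"] == "." else row["family_id"],
                float(row["abundance_weight"]),
                None if row["core_start"] < 0 else int(row["core_start"]),
                None if row["core_end"] < 0 else int(row["core_end"]),
            )
        )
    return out


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
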