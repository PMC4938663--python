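"""Placement: binning, tallies, vicinity weighting, mode probabilities,
primary selection and whole-library placement."""

import numpy as np
import pytest

from srnaplace import place
from srnaplace.align import AlignmentGroup, AlignmentSite
from srnaplace.place import (
    IGNORED_MMAP,
    PLACED,
    PLACED_TIE,
    SUPPRESSED,
    TIE,
    UNMAPPED_OVERFLOW,
    PlacementConfig,
    bin_of,
    build_tallies,
    choose_primary,
    place_library,
    placement_probabilities,
    vicinity_weight,
)

REF = {"ref1": 100_000}


def _group(read_id, positions, length=21, ref="ref1", strand="+", overflow=False):
    sites = sorted(
        (AlignmentSite(ref, p, strand, length) for p in positions),
        key=lambda s: (s.reference, s.pos, s.strand),
    )
    return AlignmentGroup(read_id, "A" * length, sites, overflow)


@pytest.mark.parametrize(
    "pos,bin_size,expected",
    [(0, 50, 0), (49, 50, 0), (50, 50, 1), (120, 50, 2), (999, 100, 9)],
)
def test_bin_of(pos, bin_size, expected):
    assert bin_of(pos, bin_size) == expected
    # strand-independent: the leftmost aligned nucleotide defines the bin
    assert bin_of(AlignmentSite("r", pos, "-", 21), bin_size) == expected


def test_build_tallies_examples():
    cfg = PlacementConfig()
    t = build_tallies([_group("u", [10])], cfg, REF)
    assert t.u["ref1"][0] == 1.0 and t.f["ref1"][0] == 1.0
    assert t.u["ref1"][1:].sum() == 0 and t.f["ref1"][1:].sum() == 0

    t = build_tallies([_group("m", [10, 500])], cfg, REF)
    assert t.u["ref1"].sum() == 0
    assert t.f["ref1"][0] == 0.5 and t.f["ref1"][10] == 0.5

    t = build_tallies([], cfg, REF)
    assert t.u["ref1"].sum() == 0 and t.f["ref1"].sum() == 0


def test_tallies_conserve_total_weight(small_simulation):
    """Every read with 1 <= n <= max_sites contributes total weight 1."""
    _, _, index, groups = small_simulation
    cfg = PlacementConfig()
    t = build_tallies(groups, cfg, index.ref_lengths)
    eligible = sum(1 for g in groups if 1 <= g.n and not g.overflow)
    total_f = sum(arr.sum() for arr in t.f.values())
    assert total_f == pytest.approx(eligible, rel=1e-9)


def test_vicinity_window_and_truncation():
    cfg = PlacementConfig()
    groups = [_group(f"u{b}", [b * 50 + 5]) for b in range(15)]  # one unique per bin
    t = build_tallies(groups, cfg, REF)
    # interior site in bin 10 sums bins 8..12
    u, f = vicinity_weight(AlignmentSite("ref1", 500, "+", 21), t, cfg)
    assert (u, f) == (5.0, 5.0)
    # left-truncated window at bin 0 sums bins 0..2
    u, f = vicinity_weight(AlignmentSite("ref1", 0, "+", 21), t, cfg)
    assert (u, f) == (3.0, 3.0)


def test_worked_example_probabilities(worked_example):
    """The two-locus textbook case: U mode 87.5%/12.5%, F mode 73.7%/26.3%
    (vicinity weights 7 vs 1 + 3x0.5 with the read's own weight excluded),
    R mode 50%/50%."""
    ref_lengths, groups, green = worked_example
    cfg_u = PlacementConfig(mode="U")
    tallies = build_tallies(groups, cfg_u, ref_lengths)
    p_u = placement_probabilities(green, tallies, cfg_u)
    assert p_u == pytest.approx([0.875, 0.125])
    p_f = placement_probabilities(green, tallies, PlacementConfig(mode="F"))
    assert p_f == pytest.approx([7 / 9.5, 2.5 / 9.5])
    assert round(100 * p_f[0], 1) == 73.7 and round(100 * p_f[1], 1) == 26.3
    p_r = placement_probabilities(green, tallies, PlacementConfig(mode="R"))
    assert p_r == pytest.approx([0.5, 0.5])


def test_self_exclusion_changes_f_probabilities(worked_example):
    """Without excluding the placed read's own 1/n contributions the F split
    would be 7.5/3.0 = 71.4%/28.6% instead of 73.7%/26.3%."""
    ref_lengths, groups, green = worked_example
    cfg = PlacementConfig(mode="F")
    tallies = build_tallies(groups, cfg, ref_lengths)
    raw = [tallies.window(s)[1] for s in green.sites]
    assert raw == pytest.approx([7.5, 3.0])
    excl = [vicinity_weight(s, tallies, cfg, exclude=green)[1] for s in green.sites]
    assert excl == pytest.approx([7.0, 2.5])


def test_tie_on_zero_and_equal_vicinities():
    cfg = PlacementConfig(mode="U")
    g = _group("g", [1000, 5000, 9000, 13000])
    t = build_tallies([g], cfg, REF)
    assert placement_probabilities(g, t, cfg) == TIE
    # equal nonzero vicinities also tie
    anchors = [_group(f"a{i}", [p + 30]) for i, p in enumerate([1000, 5000])]
    g2 = _group("g2", [1000, 5000])
    t = build_tallies([g2] + anchors, cfg, REF)
    assert placement_probabilities(g2, t, cfg) == TIE


def test_unique_read_probability_is_one():
    cfg = PlacementConfig(mode="U")
    g = _group("u", [123])
    t = build_tallies([g], cfg, REF)
    assert placement_probabilities(g, t, cfg) == pytest.approx([1.0])


def test_choose_primary_deterministic_cases():
    rng = np.random.default_rng(0)
    cfg = PlacementConfig(mode="U")
    g = _group("g", [100, 5000])
    for _ in range(20):
        d = choose_primary(g, np.array([1.0, 0.0]), cfg, rng)
        assert d.chosen == 0 and d.status == PLACED


def test_tie_suppression_threshold():
    cfg = PlacementConfig(mode="U")
    rng = np.random.default_rng(1)
    d4 = choose_primary(_group("g4", [0, 1000, 2000, 3000]), TIE, cfg, rng)
    assert d4.status == SUPPRESSED and not d4.placed and d4.probabilities is None
    chosen = set()
    for seed in range(60):
        d3 = choose_primary(
            _group("g3", [0, 1000, 2000]), TIE, cfg, np.random.default_rng(seed)
        )
        assert d3.status == PLACED_TIE and d3.placed
        assert d3.probabilities == pytest.approx([1 / 3] * 3)
        chosen.add(d3.chosen)
    assert chosen == {0, 1, 2}  # uniform guess uses every position


def test_overflow_is_unmapped_in_every_mode():
    g = _group("big", range(0, 60 * 500, 500), overflow=True)
    for mode in place.MODES:
        cfg = PlacementConfig(mode=mode)
        d = place_library([g], cfg, REF)[0]
        assert d.status == UNMAPPED_OVERFLOW and not d.placed


def test_categorical_sampler_frequency():
    """10,000 draws from probabilities (0.8, 0.2) put the first site within
    4 binomial SE of 80%."""
    cfg = PlacementConfig(mode="U")
    g = _group("g", [100, 5000])
    rng = np.random.default_rng(42)
    hits = sum(
        choose_primary(g, np.array([0.8, 0.2]), cfg, rng).chosen == 0
        for _ in range(10_000)
    )
    se = np.sqrt(10_000 * 0.8 * 0.2)
    assert abs(hits - 8000) < 4 * se


def test_mode_n_discards_mmap_reads():
    cfg = PlacementConfig(mode="N")
    decisions = place_library([_group("m", [0, 1000]), _group("u", [5000])], cfg, REF)
    assert decisions[0].status == IGNORED_MMAP and not decisions[0].placed
    assert decisions[1].placed and decisions[1].site.pos == 5000


def test_unique_only_library_identical_across_modes():
    groups = [_group(f"u{i}", [i * 700]) for i in range(10)]
    placements = {}
    for mode in place.MODES:
        d = place_library(groups, PlacementConfig(mode=mode, rng_seed=3), REF)
        placements[mode] = [(x.read_id, x.site.pos) for x in d]
    assert len({tuple(v) for v in placements.values()}) == 1


def test_per_read_placement_of_identical_sequences(worked_example):
    """100 reads of one sequence with probabilities (0.8, 0.2) use both
    sites, splitting roughly 80/20: placement is per read, not per
    sequence."""
    ref_lengths, groups, green = worked_example
    anchors = [g for g in groups if g.read_id != "green"]
    copies = [
        AlignmentGroup(f"copy{i}", green.sequence, list(green.sites)) for i in range(100)
    ]
    # engineer u-vicinities (8, 2) -> probabilities (0.8, 0.2)
    extra = [
        AlignmentGroup("u1x", "C" * 21, [AlignmentSite("ref1", 1005, "+", 21)]),
        AlignmentGroup("u2x", "C" * 21, [AlignmentSite("ref1", 5015, "+", 21)]),
    ]
    cfg = PlacementConfig(mode="U", rng_seed=5)
    decisions = place_library(anchors + extra + copies, cfg, ref_lengths)
    by_copy = [d for d in decisions if d.read_id.startswith("copy")]
    assert all(d.probabilities == pytest.approx([0.8, 0.2]) for d in by_copy)
    first = sum(d.site.pos == 1000 for d in by_copy)
    assert 0 < first < 100  # both sites used
    assert abs(first - 80) < 4 * np.sqrt(100 * 0.8 * 0.2)


def test_probability_normalization(small_simulation):
    _, _, index, groups = small_simulation
    for mode in ("R", "U", "F"):
        cfg = PlacementConfig(mode=mode, rng_seed=8)
        decisions = place_library(groups, cfg, index.ref_lengths)
        for d in decisions:
            if d.probabilities is not None:
                assert d.probabilities.sum() == pytest.approx(1.0, abs=1e-9)


def test_read_conservation(small_simulation):
    """Primaries plus unmapped reads partition the input exactly."""
    _, _, index, groups = small_simulation
    for mode in place.MODES:
        decisions = place_library(groups, PlacementConfig(mode=mode), index.ref_lengths)
        placed = sum(d.placed for d in decisions)
        unmapped = sum(not d.placed for d in decisions)
        assert placed + unmapped == len(groups)
        assert len({d.read_id for d in decisions}) == len(groups)


def test_duplicate_read_ids_rejected():
    groups = [_group("dup", [0]), _group("dup", [1000])]
    with pytest.raises(ValueError, match="duplicate"):
        place_library(groups, PlacementConfig(), REF)


def test_u_equals_f_without_mmap_neighbors():
    """With no multi-mapping reads in any vicinity, U and F weights are the
    same counts, so the probability vectors coincide."""
    anchors = [_group(f"a{i}", [1000 + 10 * i]) for i in range(4)]
    anchors += [_group(f"b{i}", [8000 + 10 * i]) for i in range(2)]
    g = _group("g", [1020, 8020])
    cfg_u = PlacementConfig(mode="U")
    t = build_tallies(anchors + [g], cfg_u, REF)
    p_u = placement_probabilities(g, t, cfg_u)
    p_f = placement_probabilities(g, t, PlacementConfig(mode="F"))
    assert p_u == pytest.approx(p_f)
    assert p_u == pytest.approx([4 / 6, 2 / 6])


def test_seed_determinism_of_placed_sam(tmp_path, small_simulation):
    _, _, index, groups = small_simulation
    cfg = PlacementConfig(mode="U", rng_seed=77)
    payloads = []
    for tag in ("a", "b"):
        decisions = place_library(groups, cfg, index.ref_lengths)
        path = tmp_path / f"{tag}.sam"
        place.write_placed_sam(groups, decisions, index.ref_lengths, path)
        payloads.append(path.read_bytes())
    assert payloads[0] == payloads[1]
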