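"""The deterministic filter cascade: boundaries, attribution, idempotence."""

import itertools

import pytest

from epicmarkers.intron_filters import (
    FilterConfig,
    ambiguity_filter,
    build_intron_sets,
    flank_length_filter,
    length_difference_filter,
    length_window_filter,
    redundancy_filter,
    run_cascade,
)

from conftest import ANCHORS, make_set


@pytest.mark.parametrize(
    "ref_len,kept",
    [(423, True), (199, False), (200, True), (1600, True), (1601, False)],
)
def test_length_window_boundaries(filter_cfg, ref_len, kept):
    """The 200-1600 bp window on the reference species is a closed interval."""
    s = make_set(lengths={"mus": ref_len, "rat": 500, "cavia": 500, "homo": 500})
    assert length_window_filter(s, filter_cfg)[0] is kept


def test_length_window_ignores_other_species(filter_cfg):
    s = make_set(lengths={"mus": 500, "rat": 5, "cavia": 9000, "homo": 7})
    assert length_window_filter(s, filter_cfg)[0]


def test_length_window_missing_reference_rejects_with_distinct_reason(filter_cfg):
    s = make_set()
    records = {sp: r for sp, r in s.records.items() if sp != "mus"}
    s2 = type(s)(marker_id=s.marker_id, records=records, intron_index=1)
    ok, reason = length_window_filter(s2, filter_cfg)
    assert not ok and reason == "missing_reference_record"


@pytest.mark.parametrize(
    "rodent_len,kept", [(1900, False), (1899, True), (100, False), (101, True)]
)
def test_length_difference_outgroup_tier_worked_example(filter_cfg, rodent_len, kept):
    """With a 1000 bp outgroup intron, admissible rodent lengths are strictly
    between 100 and 1900 bp (the 90% rule)."""
    s = make_set(
        lengths={"mus": rodent_len, "rat": rodent_len, "cavia": rodent_len,
                 "homo": 1000}
    )
    ok, reason = length_difference_filter(s, filter_cfg)
    assert ok is kept
    if not kept:
        assert reason == "length_difference"


def test_length_difference_mid_and_ingroup_tiers(filter_cfg):
    # mid tier: |rat - cavia| < 0.8 * cavia
    s = make_set(lengths={"mus": 1000, "rat": 1800, "cavia": 1000, "homo": 1000})
    assert not length_difference_filter(s, filter_cfg)[0]
    # ingroup tier: |rat - mus| < 0.7 * mus
    s = make_set(lengths={"mus": 1000, "rat": 1700, "cavia": 1500, "homo": 1400})
    assert not length_difference_filter(s, filter_cfg)[0]


def test_length_difference_equal_lengths_always_pass(filter_cfg):
    s = make_set(lengths={sp: 777 for sp in ANCHORS})
    assert length_difference_filter(s, filter_cfg)[0]


def test_length_difference_zero_denominator_distinct_reason(filter_cfg):
    s = make_set(lengths={"mus": 500, "rat": 500, "cavia": 500, "homo": 0})
    assert length_difference_filter(s, filter_cfg) == (False, "zero_length_denominator")


def test_redundancy_exact_duplicate_interval(filter_cfg):
    a = make_set(marker="gA-1")
    b = make_set(marker="gB-1")  # same default reference interval as a
    c = make_set(marker="gC-1", lengths={"mus": 600, "rat": 500, "cavia": 500, "homo": 500})
    kept, rejections = redundancy_filter([b, a, c], filter_cfg)
    assert [s.marker_id for s in kept] == ["gA-1", "gC-1"]
    assert rejections == {"gB-1": "redundancy"}


def test_redundancy_overlapping_but_distinct_intervals_kept(filter_cfg):
    a = make_set(marker="gA-1")
    b = make_set(marker="gB-1", ref_interval=("chr1", 1100))  # overlaps a
    kept, rejections = redundancy_filter([a, b], filter_cfg)
    assert len(kept) == 2 and not rejections


@pytest.mark.parametrize(
    "char,n,kept", [("N", 10, False), ("N", 9, True), ("R", 10, False)]
)
def test_ambiguity_boundary_and_alphabet(filter_cfg, char, n, kept):
    """More than nine non-ACGT residues (any IUPAC ambiguity code) reject."""
    seq = "ACGT" * 100 + char * n
    s = make_set(introns={"rat": seq},
                 lengths={sp: 400 + n for sp in ANCHORS})
    assert ambiguity_filter(s, filter_cfg)[0] is kept


def test_ambiguity_checked_in_every_species(filter_cfg):
    s = make_set(introns={sp: "ACGT" * 100 + "N" * 9 for sp in ANCHORS},
                 lengths={sp: 409 for sp in ANCHORS})
    assert ambiguity_filter(s, filter_cfg)[0]


@pytest.mark.parametrize(
    "flanks,kept", [((39, 200), False), ((40, 40), True), ((0, 500), False)]
)
def test_flank_length_boundaries(filter_cfg, flanks, kept):
    s = make_set(flanks={"cavia": flanks})
    assert flank_length_filter(s, filter_cfg)[0] is kept


# ---------------------------------------------------------------------------
# cascade behaviour
# ---------------------------------------------------------------------------


def _violator_battery():
    clean = make_set(marker="m_clean-1")
    violators = {
        "length_window": make_set(
            marker="m_window-1",
            lengths={"mus": 50, "rat": 500, "cavia": 500, "homo": 500},
        ),
        "length_difference": make_set(
            marker="m_diff-1",
            lengths={"mus": 1599, "rat": 300, "cavia": 300, "homo": 300},
        ),
        "redundancy": make_set(marker="m_redundant-1"),  # same interval as clean
        "ambiguity": make_set(
            marker="m_ambig-1",
            introns={"homo": "ACGT" * 100 + "N" * 10},
            lengths={"mus": 410, "rat": 410, "cavia": 410, "homo": 410},
            ref_interval=("chr2", 10),
        ),
        "flank": make_set(
            marker="m_flank-1", flanks={"rat": (39, 100)},
            lengths={"mus": 555, "rat": 555, "cavia": 555, "homo": 555},
        ),
    }
    return clean, violators


def test_cascade_attributes_each_planted_violator_to_its_stage(filter_cfg):
    clean, violators = _violator_battery()
    # "m_clean" sorts after "m_redundant"? lowest marker_id survives the
    # redundancy stage: 'm_clean-1' < 'm_redundant-1', so clean survives.
    sets = [clean] + list(violators.values())
    survivors, trace = run_cascade(sets, filter_cfg)
    assert [s.marker_id for s in survivors] == ["m_clean-1"]
    for stage, marker in [
        ("length_window", "m_window-1"),
        ("length_difference", "m_diff-1"),
        ("redundancy", "m_redundant-1"),
        ("ambiguity", "m_ambig-1"),
        ("flank", "m_flank-1"),
    ]:
        assert trace.rejections[marker] == stage
    # each stage removes exactly one marker
    assert [(n_in - n_out) for _, n_in, n_out in trace.stages] == [1, 1, 1, 1, 1]


def test_cascade_first_fail_attribution(filter_cfg):
    """A marker violating two rules is counted once, at the first stage."""
    s = make_set(
        marker="m_double-1",
        lengths={"mus": 50, "rat": 500, "cavia": 500, "homo": 500},
        flanks={"mus": (10, 10)},
    )
    _, trace = run_cascade([s], filter_cfg)
    assert trace.rejections == {"m_double-1": "length_window"}
    assert sum(n_in - n_out for _, n_in, n_out in trace.stages) == 1


def test_cascade_empty_input(filter_cfg):
    survivors, trace = run_cascade([], filter_cfg)
    assert survivors == []
    assert all(n_in == n_out == 0 for _, n_in, n_out in trace.stages)


def test_cascade_idempotent(filter_cfg):
    clean, violators = _violator_battery()
    survivors, _ = run_cascade([clean] + list(violators.values()), filter_cfg)
    again, trace = run_cascade(survivors, filter_cfg)
    assert [s.marker_id for s in again] == [s.marker_id for s in survivors]
    assert not trace.rejections


def test_per_marker_predicates_order_independent(filter_cfg):
    """Any ordering of the pure per-marker predicate stages yields the same
    survivor membership."""
    clean, violators = _violator_battery()
    sets = [clean] + [v for k, v in violators.items() if k != "redundancy"]
    baseline = None
    for order in itertools.permutations(["length_window", "ambiguity", "flank"]):
        survivors, _ = run_cascade(sets, filter_cfg, stages=list(order))
        ids = sorted(s.marker_id for s in survivors)
        baseline = ids if baseline is None else baseline
        assert ids == baseline


def test_removals_plus_survivors_account_for_all_markers(filter_cfg):
    clean, violators = _violator_battery()
    sets = [clean] + list(violators.values())
    survivors, trace = run_cascade(sets, filter_cfg)
    assert len(survivors) + len(trace.rejections) == len(sets)
    for (_, _, n_out), (_, n_in_next, _) in zip(trace.stages, trace.stages[1:]):
        assert n_out == n_in_next


def test_unknown_stage_name_is_hard_error(filter_cfg):
    with pytest.raises(ValueError, match="unknown filter stage"):
        run_cascade([], filter_cfg, stages=["no_such_stage"])


def test_filter_config_yaml_round_trip(tmp_path):
    cfg = FilterConfig(anchor_order=ANCHORS, min_len=150, k_max=0.1)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    loaded = FilterConfig.from_yaml(path)
    assert loaded.min_len == 150
    assert loaded.k_max == 0.1
    assert loaded.anchor_order == tuple(ANCHORS)
    assert loaded.tier_fractions == dict(cfg.tier_fractions)


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(min_len=0)
    with pytest.raises(ValueError):
        FilterConfig(tier_fractions={"outgroup_tier": 1.5, "mid_tier": 0.8,
                                     "ingroup_tier": 0.7})


def test_build_intron_sets_names_and_completeness(sim_dataset):
    """Sets are named <refgene>-<index> and only complete quartets yield sets."""
    from epicmarkers.genome_io import extract_introns
    from epicmarkers.orthology import cross_tables, equal_exon_count_filter

    data = sim_dataset
    idx = data.models_index()
    records = {}
    for (sp, gid), m in idx.items():
        for rec in extract_introns(m, data.genomes):
            records[(sp, gid, rec.intron_index)] = rec
    quartets = cross_tables(data.tables, data.config.anchor_order)
    quartets, _ = equal_exon_count_filter(quartets, idx)
    sets = build_intron_sets(quartets, records)
    assert sets
    for s in sets:
        gene, i = s.marker_id.rsplit("-", 1)
        assert s.intron_index == int(i)
        assert set(s.records) == set(data.config.anchor_order)
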