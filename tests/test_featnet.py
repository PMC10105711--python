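import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from syndeep.featnet import (GROUPS, FeatureSchema, assemble_pair_vector,
                             build_block_matrix, build_design_matrix,
                             drug_profile, russell_rao_similarity)
from syndeep.labels import PairRecord


# ---------------------------------------------------------------- Russell-Rao

def _russell_rao_loop(a, b):
    """Positional brute-force oracle: count both-one positions, divide by d."""
    matches = 0
    for x, y in zip(a, b):
        if x == 1 and y == 1:
            matches += 1
    return matches / len(a)


def test_russell_rao_worked_example():
    a = np.array([1, 0, 1, 1, 0])
    b = np.array([1, 1, 1, 0, 0])
    assert russell_rao_similarity(a, b) == pytest.approx(0.4)


def test_russell_rao_identity_and_zero_cases():
    ones = np.ones(7, dtype=int)
    assert russell_rao_similarity(ones, ones) == 1.0
    assert russell_rao_similarity(np.zeros(7, dtype=int), ones) == 0.0


def test_russell_rao_self_similarity_is_density():
    a = np.array([1, 1, 0, 1, 0, 0])
    assert russell_rao_similarity(a, a) == pytest.approx(np.sum(a) / a.size)


def test_russell_rao_dimension_errors():
    with pytest.raises(ValueError):
        russell_rao_similarity(np.ones(3), np.ones(4))
    with pytest.raises(ValueError):
        russell_rao_similarity(np.empty(0), np.empty(0))


@given(st.integers(min_value=1, max_value=64), st.integers(min_value=0, max_value=2**31 - 1))
def test_russell_rao_matches_brute_force_and_is_symmetric(d, seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, size=d)
    b = rng.integers(0, 2, size=d)
    s = russell_rao_similarity(a, b)
    assert s == pytest.approx(_russell_rao_loop(a, b))
    assert s == russell_rao_similarity(b, a)
    assert 0.0 <= s <= 1.0


# ---------------------------------------------------------------- block matrix

def test_indicator_blocks_match_relations(toy_universe):
    bm = build_block_matrix(toy_universe)
    # drug A targets T1 only -> row A has a single 1 at column T1
    row_a = bm.d_dt[toy_universe.drugs.index("A")]
    assert row_a.tolist() == [1, 0, 0, 0]
    assert bm.d_dt.sum() == len(toy_universe.dt_edges)
    # indicator blocks contain only {0, 1}
    for block in (bm.d_dt, bm.dt_ppi, bm.dt_pmi, bm.dt_gm, bm.dt_ge, bm.dt_dm):
        assert set(np.unique(block)) <= {0, 1}


def test_ppi_block_is_symmetric_in_shared_proteins(toy_universe):
    bm = build_block_matrix(toy_universe)
    ti = {t: i for i, t in enumerate(toy_universe.targets)}
    pi = {p: i for i, p in enumerate(toy_universe.proteins)}
    # undirected edge (T2, T3): each target row marks the other protein
    assert bm.dt_ppi[ti["T2"], pi["T3"]] == 1
    assert bm.dt_ppi[ti["T3"], pi["T2"]] == 1


def test_empty_relation_gives_zero_block(toy_universe):
    toy_universe.pmi_edges = set()
    bm = build_block_matrix(toy_universe)
    assert bm.dt_pmi.sum() == 0


def test_cl_block_marks_screened_pairs(toy_universe):
    recs = [PairRecord("A", "B", "cl1", 1.0, 1)]
    bm = build_block_matrix(toy_universe, records=recs)
    assert bm.d_cl.sum() == 2  # (A, cl1) and (B, cl1) only
    assert build_block_matrix(toy_universe).d_cl.sum() == 9  # default: all


def test_all_related_counting():
    from syndeep.universe import RelationalUniverse
    u = RelationalUniverse(
        drugs=["A", "B", "C"], targets=["T1", "T2", "T3", "T4"],
        cell_lines=["cl"], proteins=[], metabolites=[],
        dt_edges={(d, t) for d in "ABC" for t in ["T1", "T2", "T3", "T4"]},
        chem={d: np.zeros(2) for d in "ABC"},
    )
    assert build_block_matrix(u).d_dt.sum() == 12


# ---------------------------------------------------------------- drug profile

def test_profile_of_drug_without_targets(toy_universe):
    toy_universe.drugs.append("D")
    toy_universe.chem["D"] = np.zeros(3)
    profiles = drug_profile(toy_universe, "D")
    for vec in profiles.values():
        assert vec.sum() == 0


def test_pmi_profile_union_rule(toy_universe):
    # B hits T2 (metabolite M1) and T3 (none) -> single 1 at M1
    profiles = drug_profile(toy_universe, "B")
    assert profiles["pmi"].tolist() == [1, 0]


def test_genomic_profiles_depend_only_on_target_set(toy_universe):
    toy_universe.drugs.append("E")
    toy_universe.chem["E"] = np.ones(3)
    toy_universe.dt_edges |= {("E", "T2"), ("E", "T3")}  # same targets as B
    pb, pe = drug_profile(toy_universe, "B"), drug_profile(toy_universe, "E")
    for key in ("gm", "ge", "dm", "ppi", "pmi"):
        np.testing.assert_array_equal(pb[key], pe[key])


def test_unknown_drug_lookup_error(toy_universe):
    with pytest.raises(KeyError, match="ZZ"):
        drug_profile(toy_universe, "ZZ")


# ---------------------------------------------------------------- pair vectors

def test_toy_group_lengths(toy_universe):
    schema = FeatureSchema.from_universe(toy_universe)
    assert schema.group_lengths() == {1: 7, 2: 9, 3: 11, 4: 13, 5: 19, 6: 21}


def test_group_length_identity(toy_universe):
    schema = FeatureSchema.from_universe(toy_universe)
    lengths = [schema.group_length(g) for g in range(1, 7)]
    assert lengths[5] == lengths[4] + 2
    assert lengths == sorted(lengths)


def test_pair_vector_blocks(toy_universe):
    schema = FeatureSchema.from_universe(toy_universe)
    pv = assemble_pair_vector(toy_universe, "A", "B", "cl2", 6, schema=schema)
    assert pv.values.shape == (21,)
    sl = schema.block_slices(6)
    # DT union: A->{T1}, B->{T2,T3}
    assert pv.values[sl["DT"]].tolist() == [1, 1, 1, 0]
    # ones in the DT segment = |targets(A) union targets(B)|
    assert pv.values[sl["DT"]].sum() == 3
    # CF concatenates canonical-order chemical vectors
    np.testing.assert_array_equal(
        pv.values[sl["CF"]],
        np.concatenate([toy_universe.chem["A"], toy_universe.chem["B"]]),
    )
    # cell-line one-hot
    assert pv.values[sl["CL"]].tolist() == [0, 1, 0]
    # similarity scalars bounded
    assert np.all(pv.values[sl["SIM"]] >= 0) and np.all(pv.values[sl["SIM"]] <= 1)


def test_pair_vector_similarity_matches_profiles(toy_universe):
    schema = FeatureSchema.from_universe(toy_universe)
    pv = assemble_pair_vector(toy_universe, "B", "C", "cl1", 6, schema=schema)
    pb, pc = drug_profile(toy_universe, "B"), drug_profile(toy_universe, "C")
    sim = pv.values[schema.block_slices(6)["SIM"]]
    assert sim[0] == pytest.approx(russell_rao_similarity(pb["ppi"], pc["ppi"]))
    assert sim[1] == pytest.approx(russell_rao_similarity(pb["pmi"], pc["pmi"]))


def test_pair_vector_invariant_to_drug_order(toy_universe):
    schema = FeatureSchema.from_universe(toy_universe)
    for g in GROUPS:
        ab = assemble_pair_vector(toy_universe, "A", "B", "cl1", g, schema=schema)
        ba = assemble_pair_vector(toy_universe, "B", "A", "cl1", g, schema=schema)
        np.testing.assert_array_equal(ab.values, ba.values)


def test_self_pair_and_unknown_errors(toy_universe):
    with pytest.raises(ValueError, match="self-pair"):
        assemble_pair_vector(toy_universe, "A", "A", "cl1", 6)
    with pytest.raises(KeyError):
        assemble_pair_vector(toy_universe, "A", "B", "nope", 6)


def test_missing_chem_vector_is_hard_error(toy_universe):
    del toy_universe.chem["B"]
    with pytest.raises(ValueError, match="chemical"):
        assemble_pair_vector(toy_universe, "A", "B", "cl1", 5)


def test_design_matrix_shape_and_alignment(toy_universe):
    records = [
        PairRecord("A", "B", "cl1", 2.0, 1),
        PairRecord("A", "C", "cl2", -3.0, 0),
        PairRecord("B", "C", "cl3", 1.0, 1),
    ]
    X, y = build_design_matrix(toy_universe, records, 6)
    assert X.shape == (3, 21)
    assert y.tolist() == [1, 0, 1]
    row0 = assemble_pair_vector(toy_universe, "A", "B", "cl1", 6).values
    np.testing.assert_array_equal(X[0], row0)


def test_design_matrix_empty_records(toy_universe):
    X, y = build_design_matrix(toy_universe, [], 6)
    assert X.shape == (0, 21) and y.shape == (0,)
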