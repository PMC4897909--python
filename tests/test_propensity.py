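"""Triplet interface propensity statistics against hand-computed values."""

import math

import numpy as np
import pytest

from rbres import propensity as pr


def _stats(sequence, binding=None, contacts=None, rsa=None, ss3=None, breaks=None):
    n = len(sequence)
    return pr.ChainStats(
        sequence=sequence,
        rsa_all=np.full(n, 50.0) if rsa is None else np.asarray(rsa, float),
        ss3=np.full(n, 3, int) if ss3 is None else np.asarray(ss3, int),
        binding=np.zeros(n, bool) if binding is None else np.asarray(binding, bool),
        contacts=np.zeros(n, int) if contacts is None else np.asarray(contacts, int),
        breaks_after=np.zeros(max(n - 1, 0), bool) if breaks is None
        else np.asarray(breaks, bool),
    )


def hand_check_chain():
    """Documented single-chain toy: 12 residues, all surface, KRG appearing
    twice among the 10 surface triplets; one interface instance (subtype 2,
    helix center) holding 4 of the chain's 8 RNA-contacting heavy atoms.

    Hand evaluation: f_{KRG,2} = 4/8, f_{KRG'} = 2/10, so
    R_KRG2 = 0.5·ln(0.5/0.2) = 0.5·ln(2.5); I_{KRG,helix} = 1/2.
    """
    seq = "KRGAAAKRGAAA"
    binding = np.zeros(12, bool)
    binding[[0, 1, 11]] = True          # K0, R1 bind; pos 11 holds extra contacts
    contacts = np.zeros(12, int)
    contacts[[0, 1]] = 2                # 4 atoms inside the KRG instance
    contacts[11] = 4                    # N_all = 8
    ss3 = np.full(12, 3, int)
    ss3[1] = 1                          # interface KRG center is helical
    return _stats(seq, binding=binding, contacts=contacts, ss3=ss3)


# ---------------------------------------------------------------------------
# surface triplets and subtypes

def test_surface_triplet_enumeration():
    stats = _stats("AAAAA")
    trips = pr.surface_triplets(stats)
    assert [(i, t) for i, t in trips] == [(1, "AAA"), (2, "AAA"), (3, "AAA")]


def test_buried_residue_excludes_windows():
    rsa = [50, 50, 1.0, 50, 50]
    trips = pr.surface_triplets(_stats("AAAAA", rsa=rsa))
    assert [i for i, _ in trips] == []
    rsa = [50, 50, 50, 50, 1.0]
    trips = pr.surface_triplets(_stats("AAAAA", rsa=rsa))
    assert [i for i, _ in trips] == [1, 2]


def test_chain_break_excludes_windows():
    breaks = [False, True, False, False]
    trips = pr.surface_triplets(_stats("AAAAA", breaks=breaks))
    assert [i for i, _ in trips] == [3]


def test_short_chain_yields_no_triplets():
    assert pr.surface_triplets(_stats("AA")) == []


@pytest.mark.parametrize("first,third,expected", [
    (True, True, 1), (True, False, 2), (False, True, 3), (False, False, 4),
])
def test_subtype_classification(first, third, expected):
    assert pr.classify_subtype(first, third) == expected


def test_subtype_requires_binding_center():
    with pytest.raises(ValueError):
        pr.classify_subtype(True, True, center_binds=False)


# ---------------------------------------------------------------------------
# table construction: hand-evaluated toy

def test_hand_check_R_and_I_values():
    table = pr.build_table_from_stats([hand_check_chain()])
    r = table.R["KRG"]
    assert r[1] == pytest.approx(0.5 * math.log(2.5), abs=1e-9)
    assert r[0] == 0 and r[2] == 0 and r[3] == 0
    i = table.I["KRG"]
    assert i[0] == pytest.approx(0.5, abs=1e-9)     # helix
    assert i[1] == 0 and i[2] == 0
    # the I table is a sub-probability over secondary-structure states
    for trip, vec in table.I.items():
        assert np.all(vec >= 0) and np.all(vec <= 1)
        assert vec.sum() <= 1 + 1e-12


def test_hand_check_feature_product():
    """Residue feature = I_{x,s} · (R_x1..R_x4): (0, 0.5·0.5·ln 2.5, 0, 0)."""
    stats = hand_check_chain()
    table = pr.build_table_from_stats([stats])
    feat = pr.triplet_feature(stats, 1, table)
    assert feat[1] == pytest.approx(0.5 * 0.5 * math.log(2.5), abs=1e-9)
    assert feat[0] == 0 and feat[2] == 0 and feat[3] == 0
    assert feat[1] == pytest.approx(0.229, abs=1e-3)


def test_unseen_and_terminal_windows_are_zero():
    stats = hand_check_chain()
    table = pr.build_table_from_stats([stats])
    assert "QQQ" not in table.R
    np.testing.assert_array_equal(table.lookup("QQQ", 1), np.zeros(4))
    feats = pr.triplet_features(stats, table)
    np.testing.assert_array_equal(feats[0], np.zeros(4))     # N-terminus
    np.testing.assert_array_equal(feats[-1], np.zeros(4))    # C-terminus


def test_buried_window_feature_zero():
    stats = hand_check_chain()
    table = pr.build_table_from_stats([stats])
    query = _stats("AKRGA", rsa=[50, 50, 1.0, 50, 50], ss3=[3, 3, 1, 3, 3])
    np.testing.assert_array_equal(pr.triplet_features(query, table),
                                  np.zeros((5, 4)))


def test_prediction_never_reads_query_labels():
    """Feature lookup must depend only on the table + query RSA/SS."""
    stats = hand_check_chain()
    table = pr.build_table_from_stats([stats])
    unlabeled = _stats(stats.sequence, rsa=stats.rsa_all, ss3=stats.ss3)
    np.testing.assert_array_equal(pr.triplet_features(stats, table),
                                  pr.triplet_features(unlabeled, table))


def test_empty_training_set_rejected():
    with pytest.raises(ValueError):
        pr.build_table_from_stats([])
    with pytest.raises(ValueError):
        pr.build_table_from_stats([_stats("AA")])   # no surface triplets


def test_table_determinism_and_serialization(tmp_path, planted_small):
    from rbres.annotate import annotate_complex

    stats = [annotate_complex(cx)[0].stats() for cx in planted_small.complexes]
    t1 = pr.build_table_from_stats(stats)
    t2 = pr.build_table_from_stats(stats)
    assert pr.table_hash(t1) == pr.table_hash(t2)
    for trip in t1.R:
        np.testing.assert_array_equal(t1.R[trip], t2.R[trip])
    path = tmp_path / "table.json"
    pr.save_table(t1, path)
    t3 = pr.load_table(path)
    assert pr.table_hash(t3) == pr.table_hash(t1)


def test_planted_triplet_enrichment_recovered(planted_small):
    """The triplet planted on the contact faces ranks above the background
    median by summed propensity."""
    from rbres.annotate import annotate_complex

    stats = [annotate_complex(cx)[0].stats() for cx in planted_small.complexes]
    table = pr.build_table_from_stats(stats)
    planted = planted_small.manifest["enriched_triplet"]
    assert planted in table.R
    summed = {t: table.summed_R(t) for t in table.R}
    background = [v for t, v in summed.items() if t != planted]
    assert summed[planted] > np.median(background)
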