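"""Structure parsing, charge assignment, binding labels, SS and PSSM I/O."""

import numpy as np
import pytest

from rbres import structure as st
from rbres.fixtures import (ToyComplexSpec, complex_to_pdb, generate_toy_complex,
                            toy_complex, toy_dssp_text, toy_pssm_text)


# ---------------------------------------------------------------------------
# PDB reading

def test_parse_round_trip_preserves_atoms_and_order(toy):
    cx, _ = toy
    chain = cx.protein_chains[0]
    text = complex_to_pdb(chain, cx.rna_chains[0])
    cx2 = st.read_complex(text)
    chain2 = cx2.protein_chains[0]
    assert len(chain2) == len(chain)
    assert chain2.sequence == chain.sequence
    for r1, r2 in zip(chain.residues, chain2.residues):
        assert [a.name for a in r1.atoms] == [a.name for a in r2.atoms]
        np.testing.assert_allclose(
            np.array([a.coord for a in r1.atoms]),
            np.array([a.coord for a in r2.atoms]), atol=1e-3)
    assert len(cx2.rna_chains) == 1
    assert len(cx2.rna_chains[0]) == len(cx.rna_chains[0])


def test_missing_calpha_rejected():
    text, _ = generate_toy_complex(ToyComplexSpec(seed=0))
    # drop every CA of residue 3
    lines = [l for l in text.splitlines()
             if not (l.startswith("ATOM") and l[12:16].strip() == "CA"
                     and l[22:26].strip() == "3")]
    with pytest.raises(st.MissingAlphaCarbonError, match="3"):
        st.read_complex("\n".join(lines))


def test_apo_mode_empty_rna():
    text, _ = generate_toy_complex(ToyComplexSpec(seed=0))
    cx = st.read_complex(text, rna_chains=[])
    assert cx.rna_chains == []
    assert len(cx.protein_chains) == 1


def test_water_stripped():
    text, _ = generate_toy_complex(ToyComplexSpec(seed=0))
    text = text.replace("END", "ATOM  9999  O   HOH W   1       0.000   0.000"
                               "   0.000  1.00  0.00           O\nEND")
    cx = st.read_complex(text)
    names = {r.aa_type for ch in cx.protein_chains for r in ch.residues}
    assert "HOH" not in names


# ---------------------------------------------------------------------------
# charges

def test_builtin_backbone_carbonyl_negative(toy):
    """PARSE assigns the backbone carbonyl oxygen a negative partial charge."""
    cx, _ = toy_complex(ToyComplexSpec(seed=5))
    st.assign_charges(cx)
    res = cx.protein_chains[0].residues[3]
    assert res.get_atom("O").charge < 0
    assert res.get_atom("C").charge > 0


def test_builtin_formal_charges():
    assert st.builtin_charge("K", "NZ")[0] == pytest.approx(1.0)
    assert st.builtin_charge("D", "OD1")[0] == pytest.approx(-0.5)
    assert st.builtin_charge("A", "ZZ9") is None


def test_pqr_fields_copied_and_mismatch_detected():
    cx, _ = toy_complex(ToyComplexSpec(seed=2))
    chain = cx.protein_chains[0]
    rows = []
    serial = 1
    for res in chain.residues:
        for a in res.atoms:
            rows.append(
                f"ATOM {serial} {a.name} {st.AA_1TO3[res.aa_type]} A {res.pdb_number}"
                f" {a.coord[0]:.3f} {a.coord[1]:.3f} {a.coord[2]:.3f} -0.550 1.500")
            serial += 1
    st.assign_charges(cx, "\n".join(rows))
    assert all(a.charge == pytest.approx(-0.55)
               for r in chain.residues for a in r.atoms)
    bad = rows[0].replace(" A 1 ", " A 999 ")
    cx2, _ = toy_complex(ToyComplexSpec(seed=2))
    with pytest.raises(st.AlignmentError):
        st.assign_charges(cx2, "\n".join([bad] + rows[1:]))


# ---------------------------------------------------------------------------
# binding labels

def test_label_distance_threshold_behaviour():
    """A heavy atom at 4.9 Å binds at the 5 Å cutoff but not at 3.5 Å."""
    prot = st.Chain("A", [st.Residue("A", 0, "1", "A", [
        st.Atom("CA", "C", np.zeros(3)),
        st.Atom("CB", "C", np.array([4.9, 0.0, 0.0])),
    ])])
    rna = st.Chain("R", [st.Residue("R", 0, "1", "A", [
        st.Atom("P", "P", np.array([9.8, 0.0, 0.0])),
    ])])
    cx = st.Complex([prot], [rna])
    assert st.label_binding_residues(cx, 5.0).labels["A"][0]
    assert not st.label_binding_residues(cx, 3.5).labels["A"][0]


@pytest.mark.parametrize("fold,face", [("helix", (8, 9, 10, 11, 12, 13)),
                                       ("strand", (8, 9, 10, 11)),
                                       ("coil", (10, 11, 12))])
def test_label_monotonicity_in_cutoff(fold, face):
    cx, _ = toy_complex(ToyComplexSpec(seed=4, fold=fold, contact_face=face))
    tight = st.label_binding_residues(cx, 3.5).labels["A"]
    loose = st.label_binding_residues(cx, 5.0).labels["A"]
    assert np.all(loose[tight]), "3.5 Å labels must be a subset of 5 Å labels"


def test_label_requires_rna():
    text, _ = generate_toy_complex(ToyComplexSpec(seed=0))
    cx = st.read_complex(text, rna_chains=[])
    with pytest.raises(st.StructureError, match="apo"):
        st.label_binding_residues(cx)


# ---------------------------------------------------------------------------
# secondary structure

@pytest.mark.parametrize("ss8,expected", [
    ("H", 1), ("G", 1), ("I", 1),       # helices
    ("E", 2), ("B", 2),                 # sheets
    ("T", 3), ("S", 3), (" ", 3), ("-", 3), ("?", 3),
])
def test_ss8_to_ss3_mapping(ss8, expected):
    assert st.map_ss8_to_ss3(ss8) == expected


def test_ss3_mapping_total_and_stable():
    for code in "HGIEBTS -X":
        s3 = st.map_ss8_to_ss3(code)
        assert s3 in (1, 2, 3)


def test_torsion_fallback_on_ideal_folds():
    cx, _ = toy_complex(ToyComplexSpec(seed=0, noise=0.0))
    st.assign_ss_fallback(cx)
    interior = [r.ss3 for r in cx.protein_chains[0].residues[1:-1]]
    assert all(s == 1 for s in interior), "ideal alpha-helix must map to helix"
    cxs, _ = toy_complex(ToyComplexSpec(seed=0, fold="strand",
                                        contact_face=(8, 9, 10, 11), noise=0.0))
    st.assign_ss_fallback(cxs)
    interior = [r.ss3 for r in cxs.protein_chains[0].residues[1:-1]]
    assert all(s == 2 for s in interior), "ideal strand must map to sheet"


def test_dssp_round_trip_and_mismatch(tmp_path, toy):
    cx, _ = toy_complex(ToyComplexSpec(seed=0))
    chain = cx.protein_chains[0]
    codes = "H" * (len(chain) - 2) + "E "
    path = tmp_path / "toy.dssp"
    path.write_text(toy_dssp_text(chain, codes))
    st.read_dssp(path, cx)
    assert [r.ss8 for r in chain.residues] == list(codes)
    assert chain.residues[-2].ss3 == 2 and chain.residues[-1].ss3 == 3
    # file covering only half the chain -> alignment error
    short = toy_dssp_text(st.Chain("A", chain.residues[:10]), "H" * 10)
    (tmp_path / "short.dssp").write_text(short)
    cx2, _ = toy_complex(ToyComplexSpec(seed=0))
    with pytest.raises(st.AlignmentError):
        st.read_dssp(tmp_path / "short.dssp", cx2)


# ---------------------------------------------------------------------------
# PSSM

def test_pssm_round_trip_and_missing_row_removal(toy):
    cx, _ = toy_complex(ToyComplexSpec(seed=3))
    chain = cx.protein_chains[0]
    text = toy_pssm_text(chain, seed=7)
    prof = st.read_pssm(text, chain)
    assert prof.length == len(chain) and not prof.fallback
    # structure missing residues 5-6: rows dropped, length matches
    reduced = st.Chain("A", chain.residues[:5] + chain.residues[7:])
    prof2 = st.read_pssm(text, reduced)
    assert prof2.length == len(chain) - 2
    np.testing.assert_array_equal(prof2.matrix[:5], prof.matrix[:5])
    np.testing.assert_array_equal(prof2.matrix[5:], prof.matrix[7:])


def test_pssm_malformed_row_rejected(toy):
    cx, _ = toy_complex(ToyComplexSpec(seed=3))
    chain = cx.protein_chains[0]
    lines = toy_pssm_text(chain, seed=7).splitlines()
    # truncate one data row to 19 score columns
    lines[3] = lines[3][: 8 + 19 * 4]
    with pytest.raises(st.FormatError):
        st.read_pssm("\n".join(lines), chain)


def test_pssm_fallback_flagged(toy):
    cx, _ = toy
    prof = st.fallback_pssm(cx.protein_chains[0])
    assert prof.fallback
    assert prof.matrix.shape == (len(cx.protein_chains[0]), 20)
    # a BLOSUM self-score is the row maximum for most residue types
    chain = cx.protein_chains[0]
    idx = st.PSSM_ALPHABET.index(chain.residues[0].aa_type)
    assert prof.matrix[0, idx] == prof.matrix[0].max()


def test_chain_list_parsing(tmp_path):
    p = tmp_path / "chains.txt"
    p.write_text("# comment\n1ABC_A\n2XYZ_B\n")
    assert st.read_chain_list(p) == [("1ABC", "A"), ("2XYZ", "B")]
    p.write_text("notachain\n")
    with pytest.raises(st.FormatError):
        st.read_chain_list(p)
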