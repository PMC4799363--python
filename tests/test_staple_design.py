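"""Cross-linker model, staple-site search, mutations and record validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import plan_and_build
from helixfuse.fixtures import make_blocking_domain, make_ideal_helix, make_two_helix_domain
from helixfuse.helix_geometry import assign_helices, segment_from_residues
from helixfuse.staple_design import (
    EY_CBS,
    CrosslinkerSpec,
    DesignRecord,
    apply_staple_mutations,
    crosslinker_mw,
    exposure_score,
    find_staple_sites,
    load_packaged_design_table,
    parse_design_table,
    validate_design_record,
)
from helixfuse.structure_io import Structure


# ---------------------------------------------------------------------------
# molecular weight


@pytest.mark.parametrize("formula,expected,tol", [
    ({"H": 2, "O": 1}, 18.02, 0.01),
    ({"C": 2, "H": 5, "N": 1, "O": 2}, 75.07, 0.02),   # glycine
])
def test_crosslinker_mw_known_compounds(formula, expected, tol):
    assert crosslinker_mw(formula) == pytest.approx(expected, abs=tol)


def test_ey_cbs_weighs_521_daltons():
    # C18H14Cl2N2O8S2: two chloroacetamido-benzenesulfonic acid halves
    # bridged by an ethyne
    assert round(EY_CBS.molecular_weight) == 521


def test_crosslinker_mw_rejects_unknown_element():
    with pytest.raises(ValueError, match="element"):
        crosslinker_mw({"Zz": 1})


@settings(max_examples=30, deadline=None, derandomize=True)
@given(a=st.dictionaries(st.sampled_from(["C", "H", "N", "O", "S"]),
                         st.integers(1, 20), max_size=3),
       b=st.dictionaries(st.sampled_from(["P", "Cl", "F", "Br"]),
                         st.integers(1, 20), max_size=3))
def test_mw_is_additive_over_disjoint_formulas(a, b):
    merged = {**a, **b}
    assert crosslinker_mw(merged) == pytest.approx(
        crosslinker_mw(a) + crosslinker_mw(b), abs=1e-9)


def test_crosslinker_spec_invariants():
    with pytest.raises(ValueError, match="spacing"):
        CrosslinkerSpec(spacing=0)
    with pytest.raises(ValueError, match="window"):
        CrosslinkerSpec(anchor_ca_distance=20.0, anchor_ca_window=(15.5, 18.1))


# ---------------------------------------------------------------------------
# exposure


def test_exposure_isolated_vs_buried():
    helix = make_ideal_helix(20)
    open_count = exposure_score(helix, ("A", 10))
    assert open_count < 25
    cb = helix.chains[0].residue(10).atom("CB").coord
    blocker = make_blocking_domain(center=cb + np.array([3.0, 0.0, 0.0]))
    packed = Structure(id="packed", chains=[helix.chains[0], blocker.chains[0]])
    buried_count = exposure_score(packed, ("A", 10))
    assert buried_count > open_count  # monotone under added atoms
    assert buried_count > 22          # fails the default exposure filter


def test_terminal_residue_more_exposed_than_core():
    dom = make_two_helix_domain()
    terminal = exposure_score(dom, ("A", 27))   # C-terminal helix end
    # most buried mid-helix-2 position (its packing face looks at helix 1)
    core = max(exposure_score(dom, ("A", n)) for n in range(18, 25))
    assert terminal < core


# ---------------------------------------------------------------------------
# staple-site search


def test_find_staple_sites_straddle_junction_and_pass_filters(fused_design):
    design = fused_design
    model = design.fused_model
    lo, hi = design.fusion_span
    chain = model.chains[0]
    seg = segment_from_residues(
        [r for r in chain.residues if lo <= r.seq_number <= hi])
    sites = find_staple_sites(model, seg, design.junction_fused,
                              exposure_threshold=60)
    assert sites
    for s in sites:
        # brute re-check of every filter the search claims to apply
        assert s.j_position - s.i_position == EY_CBS.spacing
        assert s.i_position <= design.junction_fused < s.j_position
        d = np.linalg.norm(chain.residue(s.i_position).ca.coord
                           - chain.residue(s.j_position).ca.coord)
        assert d == pytest.approx(s.ca_distance, abs=1e-9)
        assert EY_CBS.anchor_ca_window[0] <= d <= EY_CBS.anchor_ca_window[1]
        assert exposure_score(model, ("A", s.i_position)) == s.exposure_i
        assert s.exposure_i <= 60 and s.exposure_j <= 60
    # subset of all (i, i+spacing) pairs inside the span
    all_pairs = {(i, i + EY_CBS.spacing) for i in range(lo, hi + 1)
                 if i + EY_CBS.spacing <= hi}
    assert {(s.i_position, s.j_position) for s in sites} <= all_pairs
    # ranking: by distance from the 16.8 A target, ties by burial
    keys = [(abs(s.ca_distance - EY_CBS.anchor_ca_distance),
             s.exposure_i + s.exposure_j) for s in sites]
    assert keys == sorted(keys)


def test_donor_only_pairs_are_excluded():
    # a 16-residue donor helix leaves room for pairs entirely donor-side
    donor = make_two_helix_domain(helix_lengths=(10, 16))
    donor.id = "donor"
    acceptor = make_two_helix_domain()
    acceptor.id = "acceptor"
    dh = assign_helices(donor.chains[0])[-1]
    ah = assign_helices(acceptor.chains[0])[0]
    design = plan_and_build(donor, dh, acceptor, ah)
    lo, hi = design.fusion_span
    chain = design.fused_model.chains[0]
    seg = segment_from_residues(
        [r for r in chain.residues if lo <= r.seq_number <= hi])
    sites = find_staple_sites(design.fused_model, seg, design.junction_fused,
                              exposure_threshold=10_000)
    assert sites
    assert all(s.i_position <= design.junction_fused < s.j_position for s in sites)
    assert find_staple_sites.last_rejections["junction"] > 0


def test_buried_position_rejected_by_exposure_filter(fused_design):
    design = fused_design
    lo, hi = design.fusion_span
    model = design.fused_model.copy()
    chain = model.chains[0]
    seg = segment_from_residues(
        [r for r in chain.residues if lo <= r.seq_number <= hi])
    open_sites = find_staple_sites(model, seg, design.junction_fused,
                                   exposure_threshold=60)
    assert open_sites
    # bury the best site's i anchor under a blocking pseudo-domain
    cb = chain.residue(open_sites[0].i_position).atom("CB").coord
    blocker = make_blocking_domain(center=cb + np.array([2.0, 0, 0]))
    model.chains.append(blocker.chains[0])
    blocked = find_staple_sites(model, seg, design.junction_fused,
                                exposure_threshold=60)
    assert open_sites[0].i_position not in {s.i_position for s in blocked}


def test_short_helix_errors():
    helix = make_ideal_helix(14)
    seg = segment_from_residues(helix.chains[0].residues[:8])
    with pytest.raises(ValueError, match="short"):
        find_staple_sites(helix, seg, 4)


# ---------------------------------------------------------------------------
# applying mutations


@pytest.fixture()
def flanked_design():
    """Fusion whose 14-residue helix carries the published 3,311 flanks,
    so stapling at the (2, 13) site yields LCKNKAQQAAFYCI."""
    donor = make_two_helix_domain(sequence="A" * 12 + "AAA" + "A" + "LAKNKA" + "AAAAA")
    donor.id = "donor"
    acceptor = make_two_helix_domain(sequence="AAA" + "QQAAFYTI" + "A" + "AAA" + "A" * 12)
    acceptor.id = "acceptor"
    dh = assign_helices(donor.chains[0])[-1]
    ah = assign_helices(acceptor.chains[0])[0]
    from helixfuse.fusion_design import build_fusion_model, plan_terminal_fusion
    design = plan_terminal_fusion(donor, dh, 22, acceptor, ah, 4)
    build_fusion_model(design)
    return design


def test_staple_mutations_reproduce_published_sequence(flanked_design):
    design = flanked_design
    assert design.fusion_helix_sequence() == "LAKNKAQQAAFYTI"
    lo, hi = design.fusion_span
    chain = design.fused_model.chains[0]
    seg = segment_from_residues(
        [r for r in chain.residues if lo <= r.seq_number <= hi])
    sites = find_staple_sites(design.fused_model, seg, design.junction_fused,
                              exposure_threshold=40)
    site = next(s for s in sites if s.i_position == lo + 1)  # helix position 2
    seq, model = apply_staple_mutations(design, site)
    assert seq == "LCKNKAQQAAFYCI"
    # i+4 and i+7 were already Ala: no mutation recorded there
    assert {m[0] for m in site.mutations} == {site.i_position, site.j_position}
    # cysteines modelled to CB+SG, nothing beyond
    cys = model.chains[0].residue(site.i_position)
    assert cys.res_name == "CYS"
    assert {a.name for a in cys.atoms} == {"N", "CA", "C", "O", "CB", "SG"}


def test_apply_staple_mutations_is_idempotent(flanked_design):
    design = flanked_design
    lo, hi = design.fusion_span
    chain = design.fused_model.chains[0]
    seg = segment_from_residues(
        [r for r in chain.residues if lo <= r.seq_number <= hi])
    site = find_staple_sites(design.fused_model, seg, design.junction_fused,
                             exposure_threshold=40)[0]
    seq1, m1 = apply_staple_mutations(design, site)
    seq2, m2 = apply_staple_mutations(design, site)
    assert seq1 == seq2
    for r1, r2 in zip(m1.chains[0].residues, m2.chains[0].residues):
        for a1 in r1.atoms:
            np.testing.assert_allclose(r2.atom(a1.name).coord, a1.coord, atol=1e-12)


def test_mutations_confined_to_fusion_helix(flanked_design):
    design = flanked_design
    lo, hi = design.fusion_span
    before = {(r.seq_number, r.res_name, tuple(a.name for a in r.atoms))
              for r in design.fused_model.chains[0].residues
              if not lo <= r.seq_number <= hi}
    chain = design.fused_model.chains[0]
    seg = segment_from_residues(
        [r for r in chain.residues if lo <= r.seq_number <= hi])
    site = find_staple_sites(design.fused_model, seg, design.junction_fused,
                             exposure_threshold=40)[0]
    _, model = apply_staple_mutations(design, site)
    after = {(r.seq_number, r.res_name, tuple(a.name for a in r.atoms))
             for r in model.chains[0].residues
             if not lo <= r.seq_number <= hi}
    assert before == after


# ---------------------------------------------------------------------------
# design records


def test_validate_published_records():
    records = {r.name: r for r in load_packaged_design_table()}
    r3311 = validate_design_record(records["3,311"])
    assert r3311.spacing_ok and r3311.ala_i4_ok and r3311.ala_i7_ok
    r3305 = validate_design_record(records["3,305"])
    assert r3305.spacing_ok and r3305.ala_i4_ok and not r3305.ala_i7_ok  # Glu at i+7
    assert any("i+7" in n for n in r3305.notes)


def test_validate_rejects_wrong_cys_counts():
    rec = DesignRecord("toy", "X", "Y", 1, 1, "ACDEFG")
    rep = validate_design_record(rec)
    assert not rep.spacing_ok and rep.n_cys == 1
    with pytest.raises(ValueError, match="empty"):
        validate_design_record(DesignRecord("void", "X", "Y", 1, 1, ""))


def test_parse_design_table(tmp_path):
    recs = load_packaged_design_table()
    assert len(recs) == 21
    # lowercase sequences are normalized
    p = tmp_path / "t.tsv"
    p.write_text("name\tfirst_protein\tsecond_protein\tfirst_junction_residue\t"
                 "second_junction_residue\tfusion_helix_sequence\n"
                 "x\tA\tB\t10\t20\tqcareaareaaacd\n")
    rec = parse_design_table(p)[0]
    assert rec.fusion_helix_sequence == "QCAREAAREAAACD"
    # empty file -> empty list
    empty = tmp_path / "empty.tsv"
    empty.write_text("")
    assert parse_design_table(empty) == []
    # missing column named in the error
    bad = tmp_path / "bad.tsv"
    bad.write_text("name\tfirst_protein\n1\t2\n")
    with pytest.raises(ValueError, match="fusion_helix_sequence"):
        parse_design_table(bad)


def test_all_published_sequences_share_the_staple_geometry():
    for rec in load_packaged_design_table():
        seq = rec.fusion_helix_sequence
        assert len(seq) == 14
        cys = [k + 1 for k, aa in enumerate(seq) if aa == "C"]
        assert cys == [2, 13]  # offset 11
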