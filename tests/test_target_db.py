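"""AP/MBS candidate selection, target-database assembly and its features."""

import numpy as np
import pytest

from splicebench import (
    CIS,
    DeNovoCandidate,
    GroundTruthParams,
    TRAPPING,
    ap_select_candidates,
    build_index,
    build_target_db,
    compute_alc_cutoff,
    mbs_select_candidates,
    target_db_features,
)
from splicebench.ground_truth import GroundTruthBundle, VerificationReport
from splicebench.splice_mapper import NONSPLICED, TRANS
from splicebench.target_db import (
    AP,
    MBS,
    RetainedCandidate,
    SPLICED_TAG,
    read_denovo_table,
    write_denovo_table,
)

from conftest import as_proteome

# Proteome engineered so candidate categories are known by construction:
#   "LPETG"            -> substring of P1 (NONSPLICED)
#   "MKGAL"            -> cis in P1 (MK + GAL, intervening 5)
#   "MKCCW"            -> trans (MK on P1, CCW only on P2)
#   "WWWWW"            -> unexplainable
#   "MKGAW"            -> cis only with intervening 26 (P3) -> rejected at 25
REF = as_proteome(
    [
        ("P1", "MKLLPETGAL"),
        ("P2", "CCWDDDDD"),
        ("P3", "MK" + "A" * 26 + "GAW"),
    ],
    il_collapsed=False,
)
INDEX = build_index(REF)


def cand(sid, rank, seq, alc, min_lcs=None):
    """Candidate with flat LCS == alc, optionally dipping one residue."""
    lcs = [alc] * len(seq)
    if min_lcs is not None:
        lcs[len(seq) // 2] = min_lcs
        alc = float(np.mean(lcs))
    return DeNovoCandidate(sid, rank, seq, alc, tuple(lcs))


# ---------------------------------------------------------------------------
# DeNovoCandidate validation
# ---------------------------------------------------------------------------


def test_candidate_lcs_length_must_match():
    with pytest.raises(ValueError, match="LCS length"):
        DeNovoCandidate("s1", 1, "MKGAL", 90.0, (90.0, 90.0))


def test_candidate_alc_must_be_mean_of_lcs():
    with pytest.raises(ValueError, match="mean"):
        DeNovoCandidate("s1", 1, "MKG", 95.0, (90.0, 90.0, 90.0))
    DeNovoCandidate("s1", 1, "MKG", 90.5, (90.0, 90.0, 90.0))  # within 0.51


# ---------------------------------------------------------------------------
# ALC cutoff
# ---------------------------------------------------------------------------


def _agreeing_table(alcs):
    table, confident = [], {}
    for i, alc in enumerate(alcs):
        sid = f"s{i}"
        table.append(cand(sid, 1, "LPETG", alc))
        confident[sid] = "LPETG"
    return table, confident


def test_alc_cutoff_quantile_zero_is_minimum():
    table, confident = _agreeing_table([80, 85, 90, 95, 100])
    assert compute_alc_cutoff(table, confident, quantile=0.0) == 80


def test_alc_cutoff_constant_distribution():
    table, confident = _agreeing_table([90] * 5)
    for q in (0.0, 0.05, 0.5, 1.0):
        assert compute_alc_cutoff(table, confident, q) == 90


def test_alc_cutoff_matches_sort_and_index_oracle():
    rng = np.random.default_rng(77)
    alcs = np.round(rng.uniform(60, 100, size=100), 1)
    table, confident = _agreeing_table(list(alcs))
    got = compute_alc_cutoff(table, confident, quantile=0.05)
    expected = sorted(alcs)[int(np.floor(0.05 * (len(alcs) - 1)))]  # lower order stat
    assert got == expected


def test_alc_cutoff_ignores_disagreeing_and_low_rank():
    table = [
        cand("s1", 1, "LPETG", 80),
        cand("s1", 2, "LPETG", 50),  # rank 2: ignored
        cand("s2", 1, "MKGAL", 40),  # disagrees with confident sequence
    ]
    confident = {"s1": "LPETG", "s2": "LPETG"}
    assert compute_alc_cutoff(table, confident, 0.0) == 80


def test_alc_cutoff_errors_without_agreement():
    with pytest.raises(ValueError, match="manual"):
        compute_alc_cutoff([cand("s1", 1, "MKGAL", 90)], {"s1": "LPETG"})


# ---------------------------------------------------------------------------
# AP selection
# ---------------------------------------------------------------------------


def test_ap_discards_spectrum_with_nonspliced_candidate():
    table = [cand("s1", 1, "MKGAL", 90), cand("s1", 2, "LPETG", 85)]
    assert ap_select_candidates(table, INDEX, alc_cutoff=0) == {}


def test_ap_keeps_highest_alc_cis_over_trans():
    table = [
        cand("s1", 1, "MKCCW", 99),  # trans, best ALC
        cand("s1", 2, "MKGAL", 92),  # cis
        cand("s1", 3, "GALMK", 88),  # cis (reverse)
    ]
    retained = ap_select_candidates(table, INDEX, alc_cutoff=0)
    assert retained["s1"].candidate.sequence == "MKGAL"
    assert retained["s1"].category == CIS


def test_ap_falls_back_to_trans_then_nothing():
    trans_only = [cand("s1", 1, "MKCCW", 90), cand("s1", 2, "WWWWW", 85)]
    retained = ap_select_candidates(trans_only, INDEX, alc_cutoff=0)
    assert retained["s1"].candidate.sequence == "MKCCW"
    assert retained["s1"].category == TRANS
    none_only = [cand("s2", 1, "WWWWW", 95)]
    assert ap_select_candidates(none_only, INDEX, alc_cutoff=0) == {}


def test_ap_alc_filter_is_strict():
    table = [cand("s1", 1, "MKGAL", 90.0)]
    assert ap_select_candidates(table, INDEX, alc_cutoff=90.0) == {}
    assert ap_select_candidates(table, INDEX, alc_cutoff=89.9) != {}


def test_ap_respects_exclusion_list():
    table = [cand("s1", 1, "MKGAL", 90)]
    assert ap_select_candidates(table, INDEX, 0, excluded_spectra={"s1"}) == {}


# ---------------------------------------------------------------------------
# MBS selection
# ---------------------------------------------------------------------------


def test_mbs_requires_min_lcs_80_per_residue():
    ok = cand("s1", 1, "MKGAL", 85, min_lcs=80)
    low = cand("s2", 1, "MKGAL", 85, min_lcs=79)
    retained = mbs_select_candidates([ok, low], INDEX)
    assert set(retained) == {"s1"}


def test_mbs_rejects_intervening_26_at_cap_25():
    table = [cand("s1", 1, "MKGAW", 95)]
    assert mbs_select_candidates(table, INDEX) == {}


def test_mbs_rejects_nonspliced_and_trans_keeps_multiple_cis():
    table = [
        cand("s1", 1, "LPETG", 95),  # nonspliced
        cand("s1", 2, "MKCCW", 94),  # trans
        cand("s1", 3, "MKGAL", 93),  # cis
        cand("s1", 4, "GALMK", 92),  # cis
    ]
    retained = mbs_select_candidates(table, INDEX)
    assert [rc.candidate.sequence for rc in retained["s1"]] == ["MKGAL", "GALMK"]


# ---------------------------------------------------------------------------
# database assembly + features
# ---------------------------------------------------------------------------


def _retained(seqs):
    return {
        f"s{i}": RetainedCandidate(cand(f"s{i}", 1, s, 90), CIS)
        for i, s in enumerate(seqs)
    }


def test_build_ap_concatenates_into_chunks():
    db = build_target_db(_retained(["MKGAL", "GALMK", "MKCCW"]), REF, mode=AP, chunk_size=25)
    assert len(db.spliced_entries) == 1
    entry = db.spliced_entries[0]
    assert entry.accession.startswith(SPLICED_TAG + "AP")
    assert len(entry.sequence) == 15
    full = db.full_proteome()
    assert len(full) == len(REF) + 1


def test_build_ap_chunking_splits_entries():
    db = build_target_db(_retained(["MKGAL", "GALMK", "MKCCW"]), REF, mode=AP, chunk_size=2)
    assert [len(e.sequence) for e in db.spliced_entries] == [10, 5]


def test_build_mbs_one_entry_per_candidate():
    db = build_target_db(_retained(["MKGAL", "GALMK", "MKCCW"]), REF, mode=MBS)
    assert [e.sequence for e in db.spliced_entries] == ["MKGAL", "GALMK", "MKCCW"]


def test_build_empty_retention_is_reference_identity():
    db = build_target_db({}, REF, mode=AP)
    assert db.spliced_entries == []
    assert [e.sequence for e in db.full_proteome()] == [e.sequence for e in REF]


def _truth(cis_peps):
    labels = {p: CIS for p in cis_peps}
    return GroundTruthBundle(REF, labels, [], VerificationReport([]))


def test_features_perfect_overlap():
    db = build_target_db(_retained(["MKGAL", "GALMK"]), REF, mode=MBS)
    f = target_db_features(db, _truth(["MKGAL", "GALMK"]))
    assert f.precision_potential == 1.0 and f.recall_potential == 1.0


def test_features_disjoint():
    db = build_target_db(_retained(["MKCCW"]), REF, mode=MBS)
    f = target_db_features(db, _truth(["MKGAL"]))
    assert f.precision_potential == 0.0 and f.recall_potential == 0.0


def test_features_counting_example():
    candidates = [f"CCWDDDD{a}" for a in "ACDEFG"] + ["MKGAL", "GALMK", "MKCCW", "LPETG"]
    true_cis = ["MKGAL", "GALMK", "MKCCW", "LPETG"][:4] + [f"XTRUE{i}" for i in range(4)]
    db = build_target_db(_retained(candidates), REF, mode=MBS)
    f = target_db_features(db, _truth(true_cis))
    assert f.n_candidates == 10 and f.n_true_candidates == 4 and f.n_true_total == 8
    assert f.precision_potential == pytest.approx(0.4)
    assert f.recall_potential == pytest.approx(0.5)


def test_denovo_table_roundtrip(tmp_path):
    table = [
        cand("s1", 1, "MKGAL", 90.0),
        cand("s1", 2, "GALMK", 84.4, min_lcs=62.0),
        cand("s2", 1, "LPETG", 77.7),
    ]
    path = tmp_path / "denovo.tsv"
    write_denovo_table(table, path)
    back = read_denovo_table(path)
    assert [(c.spectrum_id, c.rank, c.sequence) for c in back] == [
        (c.spectrum_id, c.rank, c.sequence) for c in table
    ]
    for a, b in zip(back, table):
        assert a.alc == pytest.approx(b.alc, abs=0.06)
        assert np.allclose(a.lcs, b.lcs, atol=0.06)
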