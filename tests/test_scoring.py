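"""Interface-masked Hamiltonian scores, selection calls, validation metrics."""

import numpy as np
import pytest

from tcspec.alignment_io import Alignment
from tcspec.contacts import ContactMask
from tcspec.dca import PottsModel
from tcspec.errors import ScoringError
from tcspec.scoring import (
    SelectionCall,
    SpecificityMatrix,
    classify_selection,
    empirical_null_score,
    htcs,
    htcs_matrix,
    htcs_specific,
    specificity_matrix,
    validation_metrics,
)

from oracles import brute_classify, brute_htcs, random_mask, random_potts_model


def _setup(rng, l_hk=4, l_rr=4, q=4, n_mask=2):
    model = random_potts_model(rng, l_hk + l_rr, q)
    mask = random_mask(rng, l_hk, l_rr, n_mask)
    hk = rng.integers(0, q, size=l_hk)
    rr = rng.integers(0, q, size=l_rr)
    return model, mask, hk, rr


# -------------------------------------------------------------------- htcs


def test_empty_mask_gives_pure_field_score(rng):
    model, _, hk, rr = _setup(rng)
    mask = ContactMask(pairs=set(), l_hk=4, l_rr=4)
    s = np.concatenate([hk, rr])
    expected = -sum(model.fields[i, s[i]] for i in range(8))
    got = htcs(model, mask, hk, rr)
    assert got.total == pytest.approx(expected, abs=1e-12)
    assert got.coupling_sum == 0.0


def test_htcs_matches_brute_force(rng):
    for _ in range(100):
        model, mask, hk, rr = _setup(rng)
        got = htcs(model, mask, hk, rr)
        expected = brute_htcs(model.couplings, model.fields, mask.pairs, hk, rr, 4)
        assert got.total == pytest.approx(expected, abs=1e-9)
        assert got.total == pytest.approx(-got.coupling_sum - got.field_sum, abs=1e-12)


def test_htcs_ignores_couplings_outside_mask(rng):
    model, mask, hk, rr = _setup(rng)
    base = htcs(model, mask, hk, rr).total
    # perturb a coupling not in the mask (including an intra-HK one)
    outside = next(
        (i, j)
        for i in range(4)
        for j in range(4, 8)
        if (i, j) not in mask.pairs
    )
    perturbed = PottsModel(couplings=model.couplings.copy(), fields=model.fields)
    perturbed.couplings[outside[0], outside[1]] += 5.0
    perturbed.couplings[1, 2] += 7.0  # intra-HK block never contributes
    assert htcs(perturbed, mask, hk, rr).total == pytest.approx(base, abs=1e-12)


def test_htcs_width_mismatch_rejected(rng):
    model, mask, hk, rr = _setup(rng)
    with pytest.raises(ScoringError):
        htcs(model, mask, hk[:-1], rr)


# ----------------------------------------------------------- htcs_specific


def test_identical_models_score_zero(rng):
    model, mask, hk, rr = _setup(rng)
    null = PottsModel(
        couplings=model.couplings, fields=model.fields, provenance="scrambled"
    )
    assert htcs_specific(model, null, mask, hk, rr) == pytest.approx(0.0, abs=1e-12)


def test_specific_is_difference_of_brute_totals(rng):
    for _ in range(100):
        model, mask, hk, rr = _setup(rng)
        null = random_potts_model(rng, 8, 4)
        null.provenance = "scrambled"
        got = htcs_specific(model, null, mask, hk, rr)
        expected = brute_htcs(model.couplings, model.fields, mask.pairs, hk, rr, 4) - brute_htcs(
            null.couplings, null.fields, mask.pairs, hk, rr, 4
        )
        assert got == pytest.approx(expected, abs=1e-9)


def test_provenance_mismatch_warns_or_raises(rng):
    model, mask, hk, rr = _setup(rng)
    not_null = random_potts_model(rng, 8, 4)  # provenance "cognate"
    with pytest.warns(UserWarning):
        htcs_specific(model, not_null, mask, hk, rr)
    with pytest.raises(ScoringError):
        htcs_specific(model, not_null, mask, hk, rr, on_provenance_mismatch="raise")


# ------------------------------------------------------- specificity matrix


def _alignments(rng, n_hk=3, n_rr=4, l_hk=4, l_rr=4):
    letters = "ACDEFGHIKLMNPQRSTVWY-"
    hk = Alignment(
        ids=[f"hk{i}" for i in range(n_hk)],
        rows=["".join(rng.choice(list(letters), size=l_hk)) for _ in range(n_hk)],
        domain_tag="HK",
    )
    rr = Alignment(
        ids=[f"rr{i}" for i in range(n_rr)],
        rows=["".join(rng.choice(list(letters), size=l_rr)) for _ in range(n_rr)],
        domain_tag="RR",
    )
    return hk, rr


def test_matrix_cells_equal_scalar_scores(rng):
    from tcspec.alphabet import PROTEIN_ALPHABET

    q = 21
    model = random_potts_model(rng, 8, q, scale=0.3)
    null = random_potts_model(rng, 8, q, scale=0.3)
    null.provenance = "scrambled"
    mask = random_mask(rng, 4, 4, 3)
    hk, rr = _alignments(rng)
    matrix = specificity_matrix(model, null, mask, hk, rr)
    for h, hid in enumerate(matrix.hk_ids):
        for r, rid in enumerate(matrix.rr_ids):
            cell = htcs_specific(
                model, null, mask,
                PROTEIN_ALPHABET.encode(hk.row(hid)), PROTEIN_ALPHABET.encode(rr.row(rid)),
            )
            assert matrix.scores[h, r] == pytest.approx(cell, abs=1e-9)


def test_matrix_permutation_equivariance(rng):
    model = random_potts_model(rng, 8, 21, scale=0.3)
    null = random_potts_model(rng, 8, 21, scale=0.3)
    null.provenance = "scrambled"
    mask = random_mask(rng, 4, 4, 3)
    hk, rr = _alignments(rng)
    base = specificity_matrix(model, null, mask, hk, rr)
    perm = [2, 0, 3, 1]
    rr_perm = Alignment(
        ids=[rr.ids[k] for k in perm], rows=[rr.rows[k] for k in perm], domain_tag="RR"
    )
    permuted = specificity_matrix(model, null, mask, hk, rr_perm)
    assert np.allclose(permuted.scores, base.scores[:, perm], atol=1e-12)


def test_wrong_width_sequences_excluded_with_warning(rng):
    model = random_potts_model(rng, 8, 21, scale=0.3)
    null = random_potts_model(rng, 8, 21, scale=0.3)
    null.provenance = "scrambled"
    mask = random_mask(rng, 4, 4, 2)
    _, rr = _alignments(rng)
    bad_hk = Alignment(ids=["bad1", "bad2"], rows=["ACDEF", "GHIKL"], domain_tag="HK")
    with pytest.warns(UserWarning, match="bad1"):
        matrix = specificity_matrix(model, null, mask, bad_hk, rr)
    assert matrix.hk_ids == [] and matrix.scores.shape == (0, 4)


def test_gauge_shift_leaves_verdicts_unchanged(rng):
    """Adding a constant to one field row shifts every score equally."""
    model = random_potts_model(rng, 8, 21, scale=0.3)
    null = random_potts_model(rng, 8, 21, scale=0.3)
    null.provenance = "scrambled"
    mask = random_mask(rng, 4, 4, 3)
    hk, rr = _alignments(rng, n_hk=3, n_rr=3)
    base = specificity_matrix(model, null, mask, hk, rr)
    shifted_model = PottsModel(
        couplings=model.couplings, fields=model.fields.copy(), provenance="cognate"
    )
    shifted_model.fields[5] += 2.5
    shifted = specificity_matrix(shifted_model, null, mask, hk, rr)
    assert np.allclose(shifted.scores - base.scores, shifted.scores[0, 0] - base.scores[0, 0])
    cmap = {"hk0": "rr0", "hk1": "rr1", "hk2": "rr2"}
    calls_a, _ = classify_selection(base, cmap)
    calls_b, _ = classify_selection(shifted, cmap)
    assert [(c.positive, c.negative) for c in calls_a] == [
        (c.positive, c.negative) for c in calls_b
    ]


# ----------------------------------------------------------- classification


def _matrix(scores, n_hk=None, n_rr=None):
    scores = np.asarray(scores, dtype=float)
    return SpecificityMatrix(
        hk_ids=[f"hk{i}" for i in range(scores.shape[0])],
        rr_ids=[f"rr{j}" for j in range(scores.shape[1])],
        scores=scores,
    )


def test_double_minimum_is_both_selections():
    m = _matrix([[-5.0, 1.0], [2.0, 0.5]])
    calls, _ = classify_selection(m, {"hk0": "rr0"})
    (c,) = calls
    assert c.positive and c.negative and c.verdict == "true_positive"


def test_negative_only_detection():
    # cognate cell is the best in its column but not in its row: the
    # weak-but-dominant interaction situation
    m = _matrix([[-1.0, -3.0], [0.5, 2.0]])
    calls, _ = classify_selection(m, {"hk0": "rr0"})
    (c,) = calls
    assert not c.positive and c.negative and c.verdict == "true_positive"


def test_tie_defeats_selection():
    m = _matrix([[-2.0, -2.0], [0.0, 1.0]])
    calls, _ = classify_selection(m, {"hk0": "rr0"})
    (c,) = calls
    assert not c.positive  # row tie
    assert c.negative


def test_classification_matches_argmin_oracle(rng):
    for _ in range(100):
        scores = rng.normal(size=(4, 4))
        m = _matrix(scores)
        cmap = {f"hk{i}": f"rr{rng.integers(0, 4)}" for i in range(4)}
        calls, _ = classify_selection(m, cmap)
        expected = brute_classify(scores, m.hk_ids, m.rr_ids, cmap)
        got = {(c.hk_id, c.rr_id): (c.positive, c.negative) for c in calls}
        assert got == expected


def test_monotone_transform_invariance(rng):
    scores = rng.normal(size=(5, 5))
    cmap = {f"hk{i}": f"rr{i}" for i in range(5)}
    calls_a, _ = classify_selection(_matrix(scores), cmap)
    transformed = np.exp(scores / 2.0) * 3.0 - 1.0  # strictly increasing
    calls_b, _ = classify_selection(_matrix(transformed), cmap)
    assert [(c.positive, c.negative) for c in calls_a] == [
        (c.positive, c.negative) for c in calls_b
    ]


def test_missing_cognate_skipped(rng):
    m = _matrix(rng.normal(size=(2, 2)))
    with pytest.warns(UserWarning):
        calls, skipped = classify_selection(m, {"hk0": "rr0", "ghost": "rr1"})
    assert len(calls) == 1 and skipped == [("ghost", "rr1")]


# -------------------------------------------------------------- validation


def _calls(tp_both, tp_pos_only, tp_neg_only, fn):
    calls = []
    calls += [SelectionCall("h", "r", True, True)] * tp_both
    calls += [SelectionCall("h", "r", True, False)] * tp_pos_only
    calls += [SelectionCall("h", "r", False, True)] * tp_neg_only
    calls += [SelectionCall("h", "r", False, False)] * fn
    return calls


def test_pooled_printed_counts_give_084():
    """Pooling 14/3, 5/1 and 7/1 TP/FN counts over three organisms yields
    sensitivity 26/31 = 0.84 at two decimals."""
    calls = _calls(17, 3, 6, 5)  # 26 detected, 5 missed, 31 evaluated
    s = validation_metrics(calls)
    assert s.tp == 26 and s.fn == 5
    assert round(s.sensitivity, 2) == 0.84
    assert s.accuracy == s.sensitivity
    # the published selection-mode fractions match the evaluated denominator
    assert round(100 * s.fraction_both, 1) == 54.8
    assert round(100 * s.fraction_negative_only, 1) == 19.4


def test_all_true_positive():
    s = validation_metrics(_calls(2, 1, 0, 0))
    assert s.sensitivity == 1.0 and s.fn == 0


def test_metrics_match_direct_counting(rng):
    for _ in range(50):
        flags = rng.integers(0, 2, size=(20, 2)).astype(bool)
        calls = [SelectionCall("h", "r", bool(p), bool(n)) for p, n in flags]
        s = validation_metrics(calls)
        tp = int(sum(1 for p, n in flags if p or n))
        assert s.tp == tp and s.fn == 20 - tp
        assert s.sensitivity == pytest.approx(tp / 20)


def test_empty_calls_rejected():
    with pytest.raises(ScoringError):
        validation_metrics([])


# ------------------------------------------------------ empirical baseline


def test_empirical_null_is_mean_of_random_pairings(rng):
    model = random_potts_model(rng, 8, 21, scale=0.3)
    mask = random_mask(rng, 4, 4, 3)
    hk, rr = _alignments(rng, n_hk=2, n_rr=2)
    base = empirical_null_score(model, mask, hk, rr, rounds=50, seed=5)
    raw = htcs_matrix(model, mask, hk, rr)
    # with 2x2 sequences the average over random pairings must lie within
    # the range of the four raw scores
    assert raw.scores.min() - 1e-9 <= base <= raw.scores.max() + 1e-9
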