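"""Mean-field DCA: reweighting, frequencies, inversion, DI, Hamiltonian."""

import numpy as np
import pytest

from tcspec.alignment_io import EncodedAlignment
from tcspec.alphabet import Alphabet
from tcspec.dca import (
    DIMatrix,
    PottsModel,
    compute_weights,
    count_frequencies,
    direct_information,
    fit_mfdca,
    hamiltonian,
    load_model,
    save_model,
)
from tcspec.errors import InferenceError, ScoringError

from oracles import brute_frequencies, brute_hamiltonian, brute_weights, random_potts_model


def toy_alphabet(q):
    return Alphabet(symbols="ACDEFGHIKLMNPQRSTVWY"[: q - 1] + "-")


def enc_of(matrix, q):
    return EncodedAlignment(matrix=np.asarray(matrix), alphabet=toy_alphabet(q))


# ------------------------------------------------------------- reweighting


def test_identical_rows_share_weight():
    enc = enc_of(np.zeros((8, 5), dtype=int), q=4)
    w, m_eff = compute_weights(enc, 0.8)
    assert np.allclose(w, 1 / 8) and np.isclose(m_eff, 1.0)


def test_distinct_rows_full_weight():
    # rows constructed to share < 80% identity pairwise
    m = np.array([[0, 1, 2, 3], [1, 2, 3, 4], [2, 3, 4, 5], [3, 4, 5, 0]])
    w, m_eff = compute_weights(enc_of(m, q=6), 0.8)
    assert np.allclose(w, 1.0) and np.isclose(m_eff, 4.0)


def test_weights_match_brute_force(rng):
    m = rng.integers(0, 4, size=(50, 10))
    enc = enc_of(m, q=5)
    w, m_eff = compute_weights(enc, 0.7)
    bw, bm = brute_weights(m, 0.7)
    assert np.allclose(w, bw) and np.isclose(m_eff, bm)


def test_empty_alignment_rejected():
    with pytest.raises(InferenceError):
        compute_weights(enc_of(np.zeros((0, 3), dtype=int), q=3), 0.8)


# ------------------------------------------------------------- frequencies


def test_single_sequence_one_hot():
    enc = enc_of([[0, 2, 1]], q=3)
    fr = count_frequencies(enc, np.ones(1), lam=0.0)
    assert fr.f1[0, 0] == 1.0 and fr.f1[1, 2] == 1.0 and fr.f1[2, 1] == 1.0


def test_large_pseudocount_limit():
    enc = enc_of([[0, 1], [1, 0]], q=3)
    fr = count_frequencies(enc, np.ones(2), lam=1e9)
    assert np.allclose(fr.f1, 1 / 3, atol=1e-8)
    assert np.allclose(fr.f2[0, 1], 1 / 9, atol=1e-8)


def test_frequencies_match_brute_force(rng):
    q = 4
    m = rng.integers(0, q, size=(30, 6))
    w = rng.uniform(0.2, 1.0, size=30)
    fr = count_frequencies(enc_of(m, q), w, lam=2.5)
    bf1, bf2 = brute_frequencies(m, w, q, 2.5)
    assert np.allclose(fr.f1, bf1, atol=1e-12)
    assert np.allclose(fr.f2, bf2, atol=1e-12)


def test_marginal_consistency(rng):
    q = 5
    m = rng.integers(0, q, size=(40, 7))
    fr = count_frequencies(enc_of(m, q), np.ones(40), lam=10.0)
    # sum_b f2(i,j)(a,b) = f1(i,a); f2 symmetric; f1 rows sum to 1
    assert np.allclose(fr.f1.sum(axis=1), 1.0, atol=1e-12)
    assert np.allclose(fr.f2.sum(axis=3), np.broadcast_to(fr.f1[:, None, :], fr.f2.shape[:3]), atol=1e-12)
    assert np.allclose(fr.f2, fr.f2.transpose(1, 0, 3, 2), atol=1e-12)


# -------------------------------------------------------------- mf inversion


def test_independent_data_gives_small_couplings():
    # independent columns sampled at large M: inferred couplings are pure
    # sampling noise (local seed keeps the statistical threshold stable)
    local = np.random.default_rng(1234)
    q, L, M = 4, 5, 20000
    probs = local.dirichlet(np.full(q, 5.0), size=L)
    m = np.stack([local.choice(q, size=M, p=probs[i]) for i in range(L)], axis=1)
    fr = count_frequencies(enc_of(m, q), np.ones(M), lam=0.01 * M)
    model = fit_mfdca(fr)
    off = [np.linalg.norm(model.couplings[i, j]) for i in range(L) for j in range(L) if i != j]
    assert max(off) < 0.5  # block norms stay an order below planted-signal scale


def test_two_site_closed_form_inversion():
    # q=2, L=2: the reduced correlation matrix is 2x2 and invertible by hand
    q, L = 2, 2
    p_joint = np.array([[0.35, 0.15], [0.10, 0.40]])  # known two-site law
    M = 50000
    seqs = [(a, b) for a in range(2) for b in range(2)]
    m = np.array(seqs)
    w = np.array([p_joint[a, b] * M for a, b in seqs])  # exact-probability weights
    lam = 0.5 * M
    fr = count_frequencies(enc_of(m, q), w, lam=lam)
    model = fit_mfdca(fr)
    # independent hand computation from the definition
    f1, f2 = brute_frequencies(m, w, q, lam)
    C = np.array(
        [
            [f1[0, 0] - f1[0, 0] ** 2, f2[0, 1, 0, 0] - f1[0, 0] * f1[1, 0]],
            [f2[0, 1, 0, 0] - f1[0, 0] * f1[1, 0], f1[1, 0] - f1[1, 0] ** 2],
        ]
    )
    e_red = -np.linalg.inv(C)[0, 1]  # e_01(0,0) in the reference gauge
    # convert the single reduced coupling to the zero-sum gauge by hand
    e_ref = np.zeros((2, 2))
    e_ref[0, 0] = e_red
    e_zs = e_ref - e_ref.mean(0, keepdims=True) - e_ref.mean(1, keepdims=True) + e_ref.mean()
    assert np.allclose(model.couplings[0, 1], e_zs, atol=1e-9)


def test_zero_sum_gauge_and_symmetry(rng):
    q = 4
    m = rng.integers(0, q, size=(200, 6))
    fr = count_frequencies(enc_of(m, q), np.ones(200))
    model = fit_mfdca(fr)
    assert np.abs(model.couplings.sum(axis=2)).max() < 1e-9
    assert np.abs(model.couplings.sum(axis=3)).max() < 1e-9
    assert np.allclose(model.couplings, model.couplings.transpose(1, 0, 3, 2), atol=1e-12)
    assert np.abs(model.couplings[np.arange(6), np.arange(6)]).max() == 0.0


# -------------------------------------------------------------- Hamiltonian


def test_hamiltonian_trivial_cases():
    zero = PottsModel(couplings=np.zeros((2, 2, 3, 3)), fields=np.zeros((2, 3)))
    assert hamiltonian(zero, [0, 1]) == 0.0
    single = PottsModel(couplings=np.zeros((1, 1, 3, 3)), fields=np.array([[1.0, 0, 0]]))
    assert hamiltonian(single, [0]) == -1.0


def test_hamiltonian_matches_brute_force(rng):
    for _ in range(100):
        L, q = 6, 4
        model = random_potts_model(rng, L, q)
        seq = rng.integers(0, q, size=L)
        assert abs(hamiltonian(model, seq) - brute_hamiltonian(model.couplings, model.fields, seq)) < 1e-9


def test_hamiltonian_difference_gauge_invariant(rng):
    # a uniform shift of any h_i row changes all energies equally
    model = random_potts_model(rng, 5, 4)
    s1, s2 = rng.integers(0, 4, size=5), rng.integers(0, 4, size=5)
    d0 = hamiltonian(model, s1) - hamiltonian(model, s2)
    shifted = PottsModel(couplings=model.couplings, fields=model.fields.copy())
    shifted.fields[2] += 3.7
    d1 = hamiltonian(shifted, s1) - hamiltonian(shifted, s2)
    assert abs(d0 - d1) < 1e-9


def test_hamiltonian_rejects_bad_states():
    model = PottsModel(couplings=np.zeros((2, 2, 3, 3)), fields=np.zeros((2, 3)))
    with pytest.raises(ScoringError):
        hamiltonian(model, [0, 5])


# ---------------------------------------------------------------------- DI


def test_di_zero_for_uncoupled(rng):
    q, L = 4, 3
    m = rng.integers(0, q, size=(100, L))
    fr = count_frequencies(enc_of(m, q), np.ones(100))
    model = PottsModel(couplings=np.zeros((L, L, q, q)), fields=np.zeros((L, q)))
    di = direct_information(model, fr)
    assert np.abs(di.di).max() < 1e-9


def test_di_symmetric_nonnegative(rng):
    q, L = 4, 5
    m = rng.integers(0, q, size=(300, L))
    fr = count_frequencies(enc_of(m, q), np.ones(300))
    di = direct_information(fit_mfdca(fr), fr)
    assert np.allclose(di.di, di.di.T)
    assert di.di.min() >= 0.0
    assert np.abs(np.diag(di.di)).max() == 0.0


def test_di_equals_mi_of_direct_distribution(rng):
    """Independent oracle: iterative proportional fitting of the q=3 direct
    distribution, then its mutual information."""
    q = 3
    e = rng.normal(0, 1.0, size=(q, q))
    fi = np.array([0.5, 0.3, 0.2])
    fj = np.array([0.25, 0.25, 0.5])
    L = 2
    couplings = np.zeros((L, L, q, q))
    couplings[0, 1] = e
    couplings[1, 0] = e.T
    model = PottsModel(couplings=couplings, fields=np.zeros((L, q)))
    from tcspec.dca import SiteFrequencies

    f1 = np.stack([fi, fj])
    fr = SiteFrequencies(f1=f1, f2=np.zeros((L, L, q, q)), m_eff=1.0, lam=0.0, weights=np.ones(1))
    di = direct_information(model, fr)
    # oracle: RAS scaling of exp(e) to the target marginals
    P = np.exp(e)
    for _ in range(5000):
        P = P * (fi / P.sum(axis=1))[:, None]
        P = P * (fj / P.sum(axis=0))[None, :]
    P /= P.sum()
    mi = float((P * np.log(P / np.outer(fi, fj))).sum())
    assert abs(di.di[0, 1] - mi) < 1e-6


def test_di_below_permutation_null_on_independent_data():
    """On independent columns, the fitted model's max DI is statistically
    indistinguishable from column-shuffled replicas."""
    rng = np.random.default_rng(555)
    q, L, M = 4, 6, 400
    m = rng.integers(0, q, size=(M, L))

    def max_di(mat):
        fr = count_frequencies(enc_of(mat, q), np.ones(M))
        return direct_information(fit_mfdca(fr), fr).di.max()

    observed = max_di(m)
    null = []
    for _ in range(200):
        shuffled = np.stack([rng.permutation(m[:, i]) for i in range(L)], axis=1)
        null.append(max_di(shuffled))
    assert observed <= np.quantile(null, 0.999)


def test_di_ranking_tie_break():
    di = np.zeros((3, 3))
    di[0, 2] = di[2, 0] = 1.0
    di[0, 1] = di[1, 0] = 1.0
    ranking = DIMatrix(di=di).ranking()
    assert ranking[0][:2] == (0, 1) and ranking[1][:2] == (0, 2)


# ------------------------------------------------------------ serialization


def test_model_save_load_roundtrip(tmp_path, rng):
    model = random_potts_model(rng, 4, 3)
    save_model(model, tmp_path / "m.npz")
    back = load_model(tmp_path / "m.npz")
    assert np.allclose(back.couplings, model.couplings)
    assert np.allclose(back.fields, model.fields)
    assert back.provenance == model.provenance
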