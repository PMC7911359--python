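"""Mean-field Direct Coupling Analysis.

Fits a q-state Potts model

    H(s) = - sum_{i<j} e_ij(s_i, s_j) - sum_i h_i(s_i)

to an encoded alignment by the mean-field route: sequences are reweighted
by local identity clustering, single- and pair-site frequencies are
pseudocounted, and the couplings are read off the inverse of the connected
correlation matrix restricted to q-1 states per site (the gap is the
reference state, which removes the exact linear dependency among states).
Couplings and fields are re-expressed in the zero-sum gauge so norms and
direct-information values are comparable across site pairs. The partition
function is never computed — all downstream scores are unnormalized
Hamiltonians, and only Hamiltonian differences carry meaning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .alignment_io import EncodedAlignment
from .errors import InferenceError, ScoringError

DEFAULT_IDENTITY_THRESHOLD = 0.8


@dataclass
class SiteFrequencies:
    """Reweighted, pseudocounted single- and pair-site frequencies."""

    f1: np.ndarray  # (L, q)
    f2: np.ndarray  # (L, L, q, q)
    m_eff: float
    lam: float
    weights: np.ndarray

    @property
    def L(self) -> int:
        return self.f1.shape[0]

    @property
    def q(self) -> int:
        return self.f1.shape[1]


@dataclass
class PottsModel:
    """Couplings e_ij(a,b) and fields h_i(a) of a pairwise Potts model."""

    couplings: np.ndarray  # (L, L, q, q), e_ij(a,b) = e_ji(b,a), e_ii = 0
    fields: np.ndarray  # (L, q)
    gauge_tag: str = "zero-sum"
    provenance: str = "cognate"  # {"cognate", "scrambled"}
    meta: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return self.fields.shape[0]

    @property
    def q(self) -> int:
        return self.fields.shape[1]


@dataclass
class DIMatrix:
    """Direct-information scores for all site pairs."""

    di: np.ndarray  # (L, L), symmetric, zero diagonal, non-negative
    non_converged: list = field(default_factory=list)

    def ranking(self) -> list:
        """Pairs (i, j, di) with i < j, sorted by descending DI; ties broken
        by (i, j) lexicographic order."""
        L = self.di.shape[0]
        iu, ju = np.triu_indices(L, k=1)
        order = sorted(range(len(iu)), key=lambda k: (-self.di[iu[k], ju[k]], iu[k], ju[k]))
        return [(int(iu[k]), int(ju[k]), float(self.di[iu[k], ju[k]])) for k in order]


def compute_weights(enc: EncodedAlignment, identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD):
    """Identity-based sequence reweighting.

    The weight of a sequence is 1/n where n counts the sequences (itself
    included) with fractional identity >= threshold. Returns ``(weights,
    M_eff)`` with ``M_eff = sum(weights)``.
    """
    if not 0 < identity_threshold <= 1:
        raise InferenceError("identity_threshold must be in (0, 1]")
    X = enc.matrix
    M, L = X.shape
    if M == 0:
        raise InferenceError("cannot reweight an empty alignment")
    # blocked all-pairs match counting on uint8 states; the block keeps the
    # (block, M, L) comparison buffer near cache-friendly sizes
    Xu = X.astype(np.uint8)
    min_matches = identity_threshold * L
    counts = np.empty(M, dtype=np.int64)
    block = 512
    for start in range(0, M, block):
        eq = (Xu[start : start + block, None, :] == Xu[None, :, :]).sum(axis=2)
        counts[start : start + block] = (eq >= min_matches - 1e-9).sum(axis=1)
    weights = 1.0 / counts
    return weights, float(weights.sum())


def count_frequencies(
    enc: EncodedAlignment, weights: np.ndarray, lam: float | None = None
) -> SiteFrequencies:
    """Weighted, pseudocounted frequency counts.

    f1(i,a) = (λ/q + Σ_s w_s δ(x_si = a)) / (λ + M_eff) and analogously
    f2 with λ/q² for i ≠ j; the diagonal blocks are f2(i,i)(a,b) =
    δ(a,b) f1(i,a). ``lam=None`` uses λ = M_eff (relative pseudocount 0.5),
    the standard choice for mean-field inversion stability.
    """
    X = enc.matrix
    M, L = X.shape
    q = enc.alphabet.q
    weights = np.asarray(weights, dtype=np.float64)
    m_eff = float(weights.sum())
    if lam is None:
        lam = m_eff
    if lam < 0:
        raise InferenceError("pseudocount must be >= 0")
    denom = lam + m_eff

    onehot = np.zeros((M, L, q), dtype=np.float64)
    onehot[np.arange(M)[:, None], np.arange(L)[None, :], X] = 1.0
    f1 = (lam / q + np.einsum("m,mia->ia", weights, onehot)) / denom

    flat = onehot.reshape(M, L * q)
    pair_counts = (flat * weights[:, None]).T @ flat  # (L q, L q)
    f2 = ((lam / q**2 + pair_counts) / denom).reshape(L, q, L, q).transpose(0, 2, 1, 3)
    idx, aq = np.arange(L), np.arange(q)
    f2[idx, idx] = 0.0
    f2[idx[:, None], idx[:, None], aq[None, :], aq[None, :]] = f1  # δ(a,b)·f1(i,a)
    return SiteFrequencies(f1=f1, f2=f2, m_eff=m_eff, lam=float(lam), weights=weights)


def _zero_sum_gauge(e_ref: np.ndarray, h_ref: np.ndarray):
    """Re-express reference-gauge parameters in the zero-sum gauge,
    preserving the Hamiltonian up to an additive constant."""
    row_mean = e_ref.mean(axis=3)  # (L, L, q): mean over b
    col_mean = e_ref.mean(axis=2)  # (L, L, q): mean over a
    tot_mean = e_ref.mean(axis=(2, 3))  # (L, L)
    e = e_ref - row_mean[:, :, :, None] - col_mean[:, :, None, :] + tot_mean[:, :, None, None]
    # absorb the removed row means into the fields (sum over partners j)
    h = h_ref + (row_mean - tot_mean[:, :, None]).sum(axis=1)
    h = h - h.mean(axis=1, keepdims=True)
    return e, h


def fit_mfdca(freqs: SiteFrequencies, provenance: str = "cognate") -> PottsModel:
    """Infer Potts parameters by mean-field inversion.

    The connected correlation C(i,a)(j,b) = f2 - f1·f1 over the q-1
    non-gap states is inverted densely; couplings are e_ij(a,b) =
    -(C⁻¹)(i,a)(j,b) extended with a zero gap row/column, fields come from
    the mean-field self-consistency relation, and both are returned in the
    zero-sum gauge with e_ii = 0.
    """
    L, q = freqs.L, freqs.q
    r = q - 1  # reduced states: all but the gap (assumed to be the last state)
    f1, f2 = freqs.f1, freqs.f2
    C = (f2 - f1[:, None, :, None] * f1[None, :, None, :])[:, :, :r, :r]
    C = C.transpose(0, 2, 1, 3).reshape(L * r, L * r)
    try:
        Cinv = scipy.linalg.inv(C)
    except scipy.linalg.LinAlgError as exc:
        raise InferenceError(
            "connected-correlation matrix is singular; raise the pseudocount lam"
        ) from exc
    e_red = -Cinv.reshape(L, r, L, r).transpose(0, 2, 1, 3)

    e_ref = np.zeros((L, L, q, q))
    e_ref[:, :, :r, :r] = e_red
    idx = np.arange(L)
    e_ref[idx, idx] = 0.0
    e_ref = 0.5 * (e_ref + e_ref.transpose(1, 0, 3, 2))  # enforce e_ij(a,b)=e_ji(b,a)

    # mean-field self-consistency, gap as reference state: h_i(gap) = 0
    h_ref = np.log(f1 / f1[:, -1:])
    h_ref -= np.einsum("ijab,jb->ia", e_ref, f1)
    e, h = _zero_sum_gauge(e_ref, h_ref)
    return PottsModel(
        couplings=e,
        fields=h,
        gauge_tag="zero-sum",
        provenance=provenance,
        meta={"lam": freqs.lam, "m_eff": freqs.m_eff},
    )


def direct_information(
    model: PottsModel, freqs: SiteFrequencies, tol: float = 1e-6, max_sweeps: int = 200
) -> DIMatrix:
    """Direct information for every site pair.

    For each (i, j) the two-site "direct" distribution P_dir(a,b) ∝
    exp(e_ij(a,b)) · μ_i(a) · μ_j(b) is fitted so its marginals match
    f1(i), f1(j) (iterative proportional scaling, total-variation tolerance
    ``tol``, at most ``max_sweeps`` sweeps); DI is the mutual information
    of P_dir against the product of the single-site frequencies.
    """
    if model.L != freqs.L or model.q != freqs.q:
        raise ScoringError("model and frequencies disagree on L or q")
    L, q = model.L, model.q
    f1 = freqs.f1
    di = np.zeros((L, L))
    non_converged = []
    for i in range(L):
        fi = f1[i]
        for j in range(i + 1, L):
            fj = f1[j]
            W = np.exp(model.couplings[i, j])
            mu_i = np.full(q, 1.0 / q)
            mu_j = np.full(q, 1.0 / q)
            ok = False
            for _ in range(max_sweeps):
                new_i = fi / (W @ mu_j)
                new_i /= new_i.sum()
                new_j = fj / (W.T @ new_i)
                new_j /= new_j.sum()
                dev = max(np.abs(new_i - mu_i).sum(), np.abs(new_j - mu_j).sum())
                mu_i, mu_j = new_i, new_j
                if dev < tol:
                    ok = True
                    break
            if not ok:
                non_converged.append((i, j))
            P = W * np.outer(mu_i, mu_j)
            P /= P.sum()
            ref = np.outer(fi, fj)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(P > 0, P * np.log(P / ref), 0.0)
            di[i, j] = di[j, i] = max(float(terms.sum()), 0.0)
    return DIMatrix(di=di, non_converged=non_converged)


def hamiltonian(model: PottsModel, seq: np.ndarray) -> float:
    """Full Potts energy H(s) = -Σ_{i<j} e_ij(s_i,s_j) - Σ_i h_i(s_i)."""
    seq = np.asarray(seq)
    L = model.L
    if seq.shape != (L,):
        raise ScoringError(f"sequence length {seq.shape} does not match model L={L}")
    if seq.min() < 0 or seq.max() >= model.q:
        raise ScoringError("sequence state out of range")
    pair = model.couplings[np.arange(L)[:, None], np.arange(L)[None, :], seq[:, None], seq[None, :]]
    coupling_sum = float(np.triu(pair, k=1).sum())
    field_sum = float(model.fields[np.arange(L), seq].sum())
    return -coupling_sum - field_sum


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: PottsModel, path) -> None:
    """Save a model as an .npz archive with a JSON sidecar of metadata."""
    path = Path(path)
    np.savez_compressed(path, couplings=model.couplings, fields=model.fields)
    sidecar = {
        "L": model.L,
        "q": model.q,
        "gauge_tag": model.gauge_tag,
        "provenance": model.provenance,
        **model.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_model(path) -> PottsModel:
    path = Path(path)
    npz = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return PottsModel(
        couplings=npz["couplings"],
        fields=npz["fields"],
        gauge_tag=meta.pop("gauge_tag", "zero-sum"),
        provenance=meta.pop("provenance", "cognate"),
        meta={k: v for k, v in meta.items() if k not in ("L", "q")},
    )


def write_di_table(di: DIMatrix, path) -> None:
    """Write DI as TSV (i, j, di), 1-based positions, descending DI."""
    with open(path, "w") as fh:
        fh.write("# i\tj\tdi\n")
        for i, j, v in di.ranking():
            fh.write(f"{i + 1}\t{j + 1}\t{v:.6f}\n")
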