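"""Interface-masked Hamiltonian specificity scores and selection calls.

For a kinase sequence A and regulator sequence B in the concatenated frame,
the raw score restricts the coupling energy to the structural interface
mask while keeping every local field:

    H_TCS(A+B) = - sum_{(i,j) in mask} e_ij(A_i, B_j) - sum_i h_i(s_i)

Evaluating the same pair under a model trained on *scrambled* pairings
gives the null score H_TCS0, which carries only the attributes shared by
all HK–RR pairs; the specificity score is the difference

    H_TCSspecific = H_TCS - H_TCS0.

Negative values indicate encoded specificity, values near zero indicate
shared attributes only, positive values a loss of shared attributes. A
cognate pair is under *positive selection* when its score is the strict
minimum of the kinase's row (the HK prefers its cognate RR over all
others) and under *negative selection* when it is the strict minimum of
the regulator's column; either one counts the pair as detected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alignment_io import Alignment, PairTable, encode_alignment
from .alphabet import PROTEIN_ALPHABET
from .contacts import ContactMask
from .dca import PottsModel
from .errors import ScoringError

#: Scores closer than this after rounding count as a tie (no strict minimum).
TIE_TOL = 1e-9


@dataclass
class ScoreComponents:
    """Decomposition of one H_TCS evaluation.

    ``total = -coupling_sum - field_sum`` by construction, kept explicit so
    the identity is assertable.
    """

    coupling_sum: float  # Σ over mask pairs of e_ij(s_i, s_j)
    field_sum: float  # Σ over all positions of h_i(s_i)
    total: float


@dataclass
class SpecificityMatrix:
    """H_TCSspecific for every HK × RR combination of one network."""

    hk_ids: list
    rr_ids: list
    scores: np.ndarray  # (n_hk, n_rr)
    model_provenance: dict | None = None

    def value(self, hk_id: str, rr_id: str) -> float:
        return float(self.scores[self.hk_ids.index(hk_id), self.rr_ids.index(rr_id)])


@dataclass
class SelectionCall:
    """Per-cognate-pair selection classification."""

    hk_id: str
    rr_id: str
    positive: bool
    negative: bool

    @property
    def verdict(self) -> str:
        return "true_positive" if (self.positive or self.negative) else "false_negative"


@dataclass
class ValidationSummary:
    """Sensitivity and selection-mode breakdown over evaluated cognate pairs.

    ``accuracy`` equals ``sensitivity`` by convention — the evaluation
    defines no true negatives, so the two coincide; the field exists to
    make that explicit. Fractions are reported over all evaluated pairs
    and, separately, over the detected (true-positive) pairs, because both
    denominators appear in practice.
    """

    tp: int
    fn: int
    sensitivity: float
    accuracy: float
    fraction_both: float
    fraction_negative_only: float
    fraction_both_of_detected: float
    fraction_negative_only_of_detected: float


def _check_widths(model: PottsModel, mask: ContactMask, hk_seq, rr_seq):
    hk_seq = np.asarray(hk_seq)
    rr_seq = np.asarray(rr_seq)
    if hk_seq.shape != (mask.l_hk,) or rr_seq.shape != (mask.l_rr,):
        raise ScoringError(
            f"sequence widths ({hk_seq.size}, {rr_seq.size}) do not match "
            f"mask blocks ({mask.l_hk}, {mask.l_rr})"
        )
    if model.L != mask.l_hk + mask.l_rr:
        raise ScoringError(f"model L={model.L} does not match mask frame {mask.l_hk + mask.l_rr}")
    return hk_seq, rr_seq


def htcs(model: PottsModel, mask: ContactMask, hk_seq, rr_seq) -> ScoreComponents:
    """Interface-masked Hamiltonian score of one HK–RR sequence pair."""
    hk_seq, rr_seq = _check_widths(model, mask, hk_seq, rr_seq)
    s = np.concatenate([hk_seq, rr_seq])
    if s.size and (s.min() < 0 or s.max() >= model.q):
        raise ScoringError("sequence state out of range")
    coupling = 0.0
    for i, j in mask.pairs:
        coupling += model.couplings[i, j, s[i], s[j]]
    fields = float(model.fields[np.arange(model.L), s].sum())
    return ScoreComponents(coupling_sum=float(coupling), field_sum=fields, total=-coupling - fields)


def htcs_specific(
    cognate: PottsModel,
    null: PottsModel,
    mask: ContactMask,
    hk_seq,
    rr_seq,
    on_provenance_mismatch: str = "warn",
) -> float:
    """H_TCSspecific = H_TCS (cognate model) − H_TCS0 (scrambled model)."""
    if null.provenance != "scrambled":
        msg = f"null model provenance is {null.provenance!r}, expected 'scrambled'"
        if on_provenance_mismatch == "raise":
            raise ScoringError(msg)
        warnings.warn(msg)
    if (cognate.L, cognate.q) != (null.L, null.q):
        raise ScoringError("cognate and null models disagree on L or q")
    return htcs(cognate, mask, hk_seq, rr_seq).total - htcs(null, mask, hk_seq, rr_seq).total


def _block_scores(model: PottsModel, mask: ContactMask, hk_states, rr_states) -> np.ndarray:
    """Vectorized H_TCS over all HK × RR combinations."""
    L, l_hk = model.L, mask.l_hk
    # field terms are separable between the two blocks
    fh = model.fields[:l_hk][np.arange(l_hk)[None, :], hk_states].sum(axis=1)  # (n_hk,)
    fr = model.fields[l_hk:][np.arange(L - l_hk)[None, :], rr_states].sum(axis=1)  # (n_rr,)
    coupling = np.zeros((hk_states.shape[0], rr_states.shape[0]))
    for i, j in mask.pairs:
        coupling += model.couplings[i, j][hk_states[:, i][:, None], rr_states[:, j - l_hk][None, :]]
    return -coupling - fh[:, None] - fr[None, :]


def _encode_block(aln, width, tag, alphabet):
    ids, rows = [], []
    for sid, row in zip(aln.ids, aln.rows):
        if len(row) != width:
            warnings.warn(f"excluding {tag} sequence {sid!r}: width {len(row)} != {width}")
            continue
        ids.append(sid)
        rows.append(alphabet.encode(row))
    return ids, np.stack(rows) if rows else np.zeros((0, width), dtype=np.int64)


def htcs_matrix(
    model: PottsModel, mask: ContactMask, hk_set: Alignment, rr_set: Alignment,
    alphabet=PROTEIN_ALPHABET,
) -> SpecificityMatrix:
    """Raw (single-model) H_TCS for every HK × RR combination."""
    hk_ids, hk_states = _encode_block(hk_set, mask.l_hk, "HK", alphabet)
    rr_ids, rr_states = _encode_block(rr_set, mask.l_rr, "RR", alphabet)
    return SpecificityMatrix(
        hk_ids=hk_ids,
        rr_ids=rr_ids,
        scores=_block_scores(model, mask, hk_states, rr_states),
        model_provenance={"cognate": model.provenance, "null": None},
    )


def specificity_matrix(
    cognate: PottsModel,
    null: PottsModel,
    mask: ContactMask,
    hk_set: Alignment,
    rr_set: Alignment,
    alphabet=PROTEIN_ALPHABET,
    on_provenance_mismatch: str = "warn",
) -> SpecificityMatrix:
    """Score every HK × RR combination of an organism's sequence sets.

    Sequences whose width does not match the model blocks are excluded
    with a warning naming them.
    """
    if null.provenance != "scrambled":
        msg = f"null model provenance is {null.provenance!r}, expected 'scrambled'"
        if on_provenance_mismatch == "raise":
            raise ScoringError(msg)
        warnings.warn(msg)

    hk_ids, hk_states = _encode_block(hk_set, mask.l_hk, "HK", alphabet)
    rr_ids, rr_states = _encode_block(rr_set, mask.l_rr, "RR", alphabet)
    scores = _block_scores(cognate, mask, hk_states, rr_states) - _block_scores(
        null, mask, hk_states, rr_states
    )
    return SpecificityMatrix(
        hk_ids=hk_ids,
        rr_ids=rr_ids,
        scores=scores,
        model_provenance={"cognate": cognate.provenance, "null": null.provenance},
    )


def empirical_null_score(
    cognate: PottsModel,
    mask: ContactMask,
    hk_set: Alignment,
    rr_set: Alignment,
    rounds: int = 25,
    seed: int = 0,
    alphabet=PROTEIN_ALPHABET,
) -> float:
    """Null score as the average cognate-model H_TCS over random re-pairings.

    Alternative estimator of the shared-attribute baseline: instead of
    training a second model on a scrambled alignment, average the cognate
    model's H_TCS over ``rounds`` random concatenations of every HK with a
    random RR. Returns a single scalar baseline for the sequence sets.
    """
    rng = np.random.default_rng(seed)
    hk_states = encode_alignment(hk_set, alphabet).matrix
    rr_states = encode_alignment(rr_set, alphabet).matrix
    l_hk = mask.l_hk
    fh = cognate.fields[:l_hk][np.arange(l_hk)[None, :], hk_states].sum(axis=1)
    totals = []
    for _ in range(rounds):
        rr_idx = rng.integers(0, rr_states.shape[0], size=hk_states.shape[0])
        rr = rr_states[rr_idx]
        fr = cognate.fields[l_hk:][np.arange(mask.l_rr)[None, :], rr].sum(axis=1)
        coupling = np.zeros(hk_states.shape[0])
        for i, j in mask.pairs:
            coupling += cognate.couplings[i, j][hk_states[:, i], rr[:, j - l_hk]]
        totals.append(float(np.mean(-coupling - fh - fr)))
    return float(np.mean(totals))


def classify_selection(matrix: SpecificityMatrix, cognates: dict, tie_tol: float = TIE_TOL):
    """Classify each cognate pair by positive/negative selection.

    ``cognates`` maps hk_id → rr_id (orphans simply absent). The most
    negative score is the highest specificity. Positive selection requires
    the cognate cell to be the strict minimum of its row, negative
    selection the strict minimum of its column; a tie (equality within
    ``tie_tol``) defeats strictness, since a tie cannot evidence selection.

    Returns ``(calls, skipped)`` where ``skipped`` lists cognate pairs
    whose ids are missing from the matrix.
    """
    calls, skipped = [], []
    for hk_id, rr_id in cognates.items():
        if hk_id not in matrix.hk_ids or rr_id not in matrix.rr_ids:
            skipped.append((hk_id, rr_id))
            continue
        h = matrix.hk_ids.index(hk_id)
        r = matrix.rr_ids.index(rr_id)
        v = matrix.scores[h, r]
        row = np.delete(matrix.scores[h, :], r)
        col = np.delete(matrix.scores[:, r], h)
        positive = bool(row.size == 0 or (row > v + tie_tol).all())
        negative = bool(col.size == 0 or (col > v + tie_tol).all())
        calls.append(SelectionCall(hk_id=hk_id, rr_id=rr_id, positive=positive, negative=negative))
    if skipped:
        warnings.warn(f"cognate pairs skipped (missing from matrix): {skipped}")
    return calls, skipped


def validation_metrics(calls) -> ValidationSummary:
    """Sensitivity and selection-mode fractions from selection calls."""
    if not calls:
        raise ScoringError("no selection calls to summarize")
    tp = sum(1 for c in calls if c.verdict == "true_positive")
    fn = len(calls) - tp
    both = sum(1 for c in calls if c.positive and c.negative)
    neg_only = sum(1 for c in calls if c.negative and not c.positive)
    sens = tp / (tp + fn)
    return ValidationSummary(
        tp=tp,
        fn=fn,
        sensitivity=sens,
        accuracy=sens,
        fraction_both=both / len(calls),
        fraction_negative_only=neg_only / len(calls),
        fraction_both_of_detected=both / tp if tp else float("nan"),
        fraction_negative_only_of_detected=neg_only / tp if tp else float("nan"),
    )


def cognate_map_from_pairs(table: PairTable) -> dict:
    """hk_id → rr_id map from a cognate pair table (first pairing wins)."""
    out = {}
    for h, r in table.pairs:
        out.setdefault(h, r)
    return out
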