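"""In-silico mutation of HK/RR sequences and incremental network rescoring.

Mutations are substitutions within the fixed concatenated frame —
introducing a gap ('-') is a substitution like any other, and an
"insertion" is only possible into an existing gap column, so the frame
width never changes. Because the Hamiltonian is pairwise, a single
substitution changes only the terms touching its column, which makes exact
incremental rescoring cheap: only the mutated HK's row (or RR's column) of
the specificity matrix needs recomputation.

Positions in mutation specs are 1-based within the concatenated frame
(HK block first), matching all serialized output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .alignment_io import Alignment
from .alphabet import PROTEIN_ALPHABET, GAP_CHAR
from .contacts import ContactMask
from .dca import PottsModel
from .errors import MutationError
from .scoring import SpecificityMatrix, specificity_matrix

_SPEC_RE = re.compile(r"^(?P<sid>[^:]+):(?P<pos>\d+)(?P<char>[A-Za-z\-])$")


@dataclass
class MutationSpec:
    """One substitution: sequence id, 1-based concatenated-frame position,
    and the new amino-acid character (or '-' for a gap)."""

    seq_id: str
    position: int  # 1-based within the concatenated frame
    new_state: str
    target: str | None = None  # {"HK", "RR"} once resolved against the sets

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        """Parse the text form ``<seq_id>:<pos><new_char>``, e.g. ``cusR:74Q``."""
        m = _SPEC_RE.match(text.strip())
        if not m:
            raise MutationError(f"cannot parse mutation spec {text!r}")
        return cls(seq_id=m["sid"], position=int(m["pos"]), new_state=m["char"].upper())


@dataclass
class MutationResult:
    """Rescored network after mutation, with per-cell deltas."""

    mutated_matrix: SpecificityMatrix
    deltas: np.ndarray
    wt_matrix: SpecificityMatrix
    specs: list = field(default_factory=list)


def _validate_spec(spec: MutationSpec, frame_width: int, alphabet) -> int:
    if not 1 <= spec.position <= frame_width:
        raise MutationError(
            f"spec {spec.seq_id}:{spec.position}{spec.new_state}: position outside [1, {frame_width}]"
        )
    c = spec.new_state.upper()
    if c != GAP_CHAR and c not in alphabet.symbols:
        raise MutationError(
            f"spec {spec.seq_id}:{spec.position}{spec.new_state}: {c!r} not in alphabet"
        )
    return alphabet.encode_char(c)


def apply_mutations(seq, specs, alphabet=PROTEIN_ALPHABET) -> np.ndarray:
    """Apply substitutions to an encoded concatenated row.

    Width is always preserved; only the specified positions change.
    """
    seq = np.asarray(seq)
    out = seq.copy()
    for spec in specs:
        state = _validate_spec(spec, seq.size, alphabet)
        out[spec.position - 1] = state
    return out


def delta_hamiltonian(
    model: PottsModel, mask: ContactMask, pair, spec: MutationSpec, alphabet=PROTEIN_ALPHABET
) -> float:
    """Exact H_TCS change of a single substitution.

    Only terms touching the mutated column contribute:
    Δ = −[h_i(b) − h_i(a)] − Σ_{(i,j) ∈ mask ∋ i} [e_ij(b, s_j) − e_ij(a, s_j)].
    """
    pair = np.asarray(pair)
    if pair.size != model.L:
        raise MutationError(f"paired row length {pair.size} != model L={model.L}")
    b = _validate_spec(spec, pair.size, alphabet)
    i = spec.position - 1
    a = pair[i]
    delta = -(model.fields[i, b] - model.fields[i, a])
    for p, r in mask.pairs:
        if p == i:
            delta -= model.couplings[p, r, b, pair[r]] - model.couplings[p, r, a, pair[r]]
        elif r == i:
            delta -= model.couplings[p, r, pair[p], b] - model.couplings[p, r, pair[p], a]
    return float(delta)


def delta_table(
    model: PottsModel, mask: ContactMask, pair, alphabet=PROTEIN_ALPHABET
) -> np.ndarray:
    """Precompute the H_TCS change of every single substitution.

    Returns an (L, q) array whose (i, b) entry is the score change of
    substituting state b at 0-based column i of the given paired row —
    the tabulated form a score server would keep per pair. Wild-type
    entries are exactly zero.
    """
    pair = np.asarray(pair)
    L, q = model.L, model.q
    if pair.size != L:
        raise MutationError(f"paired row length {pair.size} != model L={L}")
    table = -(model.fields - model.fields[np.arange(L), pair][:, None])
    for p, r in mask.pairs:
        table[p] -= model.couplings[p, r, :, pair[r]] - model.couplings[p, r, pair[p], pair[r]]
        table[r] -= model.couplings[p, r, pair[p], :] - model.couplings[p, r, pair[p], pair[r]]
    return table


def mutate_alignment(
    aln: Alignment, specs, block: str, l_hk: int, alphabet=PROTEIN_ALPHABET
) -> Alignment:
    """Apply concatenated-frame mutation specs to one domain alignment.

    ``block`` names which half of the frame the alignment holds ("HK" or
    "RR"); frame positions are translated to block-local columns, and a
    spec pointing into the other block is rejected.
    """
    rows = dict(zip(aln.ids, aln.rows))
    width = aln.n_columns
    for spec in specs:
        if spec.seq_id not in rows:
            raise MutationError(f"unknown sequence id {spec.seq_id!r}")
        if block == "HK":
            local = spec.position - 1
            if not 0 <= local < l_hk:
                raise MutationError(
                    f"spec {spec.seq_id}:{spec.position}{spec.new_state} targets the RR block"
                )
        else:
            local = spec.position - 1 - l_hk
            if local < 0:
                raise MutationError(
                    f"spec {spec.seq_id}:{spec.position}{spec.new_state} targets the HK block"
                )
        if local >= width:
            raise MutationError(f"spec position {spec.position} outside the {block} block")
        c = spec.new_state.upper()
        if c != GAP_CHAR and c not in alphabet.symbols:
            raise MutationError(f"{c!r} not in alphabet")
        row = rows[spec.seq_id]
        rows[spec.seq_id] = row[:local] + c + row[local + 1 :]
    return Alignment(ids=list(aln.ids), rows=[rows[i] for i in aln.ids], domain_tag=aln.domain_tag)


def rescore_after_mutation(
    wt: SpecificityMatrix,
    cognate: PottsModel,
    null: PottsModel,
    mask: ContactMask,
    hk_set: Alignment,
    rr_set: Alignment,
    specs,
    alphabet=PROTEIN_ALPHABET,
) -> MutationResult:
    """Rescore the network after mutations, recomputing only affected cells.

    Each spec's id must belong to either the HK or the RR set (ids present
    in the wild-type matrix). The mutated rows/columns are recomputed from
    scratch against the same models and mask, so the result equals a full
    ``specificity_matrix`` on the mutated inputs to machine precision.
    """
    hk_specs = [s for s in specs if s.seq_id in hk_set.ids]
    rr_specs = [s for s in specs if s.seq_id in rr_set.ids]
    unknown = [s.seq_id for s in specs if s.seq_id not in hk_set.ids and s.seq_id not in rr_set.ids]
    if unknown:
        raise MutationError(f"unknown sequence ids in mutation specs: {sorted(set(unknown))}")
    mut_hk = mutate_alignment(hk_set, hk_specs, "HK", mask.l_hk, alphabet) if hk_specs else hk_set
    mut_rr = mutate_alignment(rr_set, rr_specs, "RR", mask.l_hk, alphabet) if rr_specs else rr_set

    scores = wt.scores.copy()
    touched_hk = sorted({wt.hk_ids.index(s.seq_id) for s in hk_specs})
    touched_rr = sorted({wt.rr_ids.index(s.seq_id) for s in rr_specs})
    if touched_hk or touched_rr:
        full = specificity_matrix(
            cognate,
            null,
            mask,
            Alignment(
                ids=[mut_hk.ids[i] for i in touched_hk],
                rows=[mut_hk.rows[i] for i in touched_hk],
                domain_tag="HK",
            )
            if touched_hk
            else Alignment(ids=[], rows=[], domain_tag="HK"),
            mut_rr,
            alphabet=alphabet,
            on_provenance_mismatch="warn",
        )
        for k, h in enumerate(touched_hk):
            scores[h, :] = full.scores[k, :]
        if touched_rr:
            col_matrix = specificity_matrix(
                cognate,
                null,
                mask,
                mut_hk,
                Alignment(
                    ids=[mut_rr.ids[j] for j in touched_rr],
                    rows=[mut_rr.rows[j] for j in touched_rr],
                    domain_tag="RR",
                ),
                alphabet=alphabet,
                on_provenance_mismatch="warn",
            )
            for k, r in enumerate(touched_rr):
                scores[:, r] = col_matrix.scores[:, k]
    mutated = SpecificityMatrix(
        hk_ids=list(wt.hk_ids),
        rr_ids=list(wt.rr_ids),
        scores=scores,
        model_provenance=wt.model_provenance,
    )
    return MutationResult(
        mutated_matrix=mutated, deltas=scores - wt.scores, wt_matrix=wt, specs=list(specs)
    )


def write_mutation_report(result: MutationResult, path) -> None:
    """TSV report (hk_id, rr_id, wt_score, mut_score, delta) of changed cells."""
    with open(path, "w") as fh:
        fh.write("# hk_id\trr_id\twt_score\tmut_score\tdelta\n")
        for h, hk_id in enumerate(result.wt_matrix.hk_ids):
            for r, rr_id in enumerate(result.wt_matrix.rr_ids):
                if result.deltas[h, r] != 0.0:
                    fh.write(
                        f"{hk_id}\t{rr_id}\t{result.wt_matrix.scores[h, r]:.6f}\t"
                        f"{result.mutated_matrix.scores[h, r]:.6f}\t{result.deltas[h, r]:.6f}\n"
                    )
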