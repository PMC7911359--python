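"""Synthetic Potts alignments and toy two-component-system worlds.

Every pipeline stage is testable offline against planted ground truth:
``sample_potts`` draws sequences from the Boltzmann distribution of an
arbitrary Potts model (exact enumeration for tiny state spaces, parallel
Gibbs chains otherwise), and ``make_toy_world`` builds a miniature
signaling proteome — several HK families, their cognate RR families, and a
generating model whose inter-domain couplings live only on a planted
interface mask. Samples are i.i.d. given the model; phylogenetic
(tree-structured) dependence is deliberately not emulated.

All randomness flows from a single seed through named substreams, so
identical seeds yield byte-identical worlds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np

from .alignment_io import (
    Alignment,
    EncodedAlignment,
    PairTable,
    write_alignment,
    write_pair_table,
)
from .alphabet import PROTEIN_ALPHABET, Alphabet
from .contacts import ContactMask, write_mask
from .dca import PottsModel
from .errors import TcspecError

#: Hard cap on exact enumeration (q^L states).
MAX_ENUMERATION = 10**6


@dataclass
class ToyWorld:
    """A planted miniature TCS proteome with known ground truth."""

    hk_alignment: Alignment
    rr_alignment: Alignment
    pair_table: PairTable
    planted_mask: ContactMask
    generating_model: PottsModel
    seed: int
    n_families: int
    family_of_hk: dict  # hk_id -> family index
    family_of_rr: dict


def _substream(seed: int, label: str) -> np.random.Generator:
    """Named substream of a master seed."""
    h = int.from_bytes(label.encode(), "little") % (2**32)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(h,)))


def enumerate_states(L: int, q: int) -> np.ndarray:
    """All q^L state vectors, lexicographic order (first column slowest)."""
    n = q**L
    grid = np.indices([q] * L).reshape(L, n).T
    return grid


def boltzmann_probabilities(model: PottsModel) -> tuple[np.ndarray, np.ndarray]:
    """Exact state space and Boltzmann probabilities (small models only)."""
    L, q = model.L, model.q
    if q**L > MAX_ENUMERATION:
        raise TcspecError(f"enumeration of q^L = {q}^{L} = {q**L} states exceeds {MAX_ENUMERATION}")
    states = enumerate_states(L, q)
    energies = np.zeros(len(states))
    for i in range(L):
        energies -= model.fields[i, states[:, i]]
        for j in range(i + 1, L):
            energies -= model.couplings[i, j, states[:, i], states[:, j]]
    w = np.exp(energies.min() - energies)
    return states, w / w.sum()


def _gibbs_sample(
    model: PottsModel,
    M: int,
    rng: np.random.Generator,
    burn_in: int = 1000,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """M parallel random-scan Gibbs chains; returns the states after burn-in."""
    L, q = model.L, model.q
    S = rng.integers(0, q, size=(M, L)) if init is None else init.copy()
    # only columns actually coupled to i enter its conditional
    neighbors = [
        np.flatnonzero([np.any(model.couplings[i, j]) and j != i for j in range(L)])
        for i in range(L)
    ]
    for _ in range(burn_in):
        for i in rng.permutation(L):
            logits = np.broadcast_to(model.fields[i][:, None], (q, M)).copy()
            for j in neighbors[i]:
                logits += model.couplings[i, j][:, S[:, j]]
            gumbel = rng.gumbel(size=(q, M))
            S[:, i] = np.argmax(logits + gumbel, axis=0)
    return S


def sample_potts(
    model: PottsModel,
    M: int,
    seed: int = 0,
    method: str = "gibbs",
    burn_in: int = 1000,
    alphabet: Alphabet | None = None,
    init: np.ndarray | None = None,
) -> EncodedAlignment:
    """Draw M sequences from the Boltzmann distribution of a Potts model.

    ``method="exact_enumeration"`` enumerates the full state space (only
    feasible for q^L <= 1e6) and samples exactly; ``method="gibbs"`` runs M
    independent random-scan Gibbs chains for ``burn_in`` sweeps each.
    Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    if method == "exact_enumeration":
        states, probs = boltzmann_probabilities(model)
        idx = rng.choice(len(states), size=M, p=probs)
        matrix = states[idx]
    elif method == "gibbs":
        matrix = _gibbs_sample(model, M, rng, burn_in=burn_in, init=init)
    else:
        raise TcspecError(f"unknown sampling method: {method!r}")
    if alphabet is None:
        alphabet = PROTEIN_ALPHABET if model.q == PROTEIN_ALPHABET.q else _generic_alphabet(model.q)
    return EncodedAlignment(matrix=matrix, alphabet=alphabet)


def _generic_alphabet(q: int) -> Alphabet:
    """A q-state alphabet for toy models (gap last, like the protein one)."""
    letters = "ACDEFGHIKLMNPQRSTVWYBJOUXZ"
    if q - 1 > len(letters):
        raise TcspecError(f"no generic alphabet for q={q}")
    return Alphabet(symbols=letters[: q - 1] + "-")


def make_toy_world(
    n_hk_families: int = 5,
    l_hk: int = 8,
    l_rr: int = 10,
    n_interface_pairs: int = 6,
    coupling_strength: float = 3.0,
    M_per_family: int = 500,
    seed: int = 0,
    family_field_scale: float = 1.0,
    background_field_sd: float = 0.1,
    gibbs_burn_in: int = 300,
) -> ToyWorld:
    """Build a planted toy TCS world.

    The generating Potts model has inter-domain couplings only on
    ``n_interface_pairs`` planted column pairs (disjoint columns). Each
    family f owns one preferred state per interface column (a random
    permutation per column keeps states balanced across columns), and the
    couplings reward each family's preferred state *combination* with
    ``coupling_strength``. Family sequences are sampled by Gibbs under the
    shared couplings plus family-preference fields of strength
    ``family_field_scale × coupling_strength`` on the interface columns;
    tying the field to the coupling strength makes ``coupling_strength=0``
    collapse to an unstructured world, so downstream detection falls to
    chance there. Chains are initialized at the family's preferred
    interface states, i.e. inside the intended mode.

    The cognate pair table joins row m of family f's HK sample to row m of
    its RR sample.
    """
    if n_interface_pairs > min(l_hk, l_rr):
        raise TcspecError(
            "n_interface_pairs must not exceed min(l_hk, l_rr): planted pairs use disjoint columns"
        )
    q = PROTEIN_ALPHABET.q
    if n_hk_families > q - 1:
        raise TcspecError(f"at most {q - 1} families with q={q}")
    L = l_hk + l_rr
    rng_model = _substream(seed, "model")
    rng_sample = _substream(seed, "sampling")

    hk_cols = np.sort(rng_model.choice(l_hk, size=n_interface_pairs, replace=False))
    rr_cols = np.sort(rng_model.choice(l_rr, size=n_interface_pairs, replace=False)) + l_hk
    mask_pairs = list(zip(hk_cols.tolist(), rr_cols.tolist()))

    # preferred (non-gap) state of family f at each interface column
    pref = {}
    for c in np.concatenate([hk_cols, rr_cols]):
        pref[int(c)] = rng_model.permutation(q - 1)[:n_hk_families]

    couplings = np.zeros((L, L, q, q))
    for i, j in mask_pairs:
        for f in range(n_hk_families):
            couplings[i, j, pref[i][f], pref[j][f]] += coupling_strength
        couplings[j, i] = couplings[i, j].T
    fields = rng_model.normal(0.0, background_field_sd, size=(L, q))
    model = PottsModel(
        couplings=couplings,
        fields=fields,
        gauge_tag="raw",
        provenance="generating",
        meta={"seed": seed, "coupling_strength": coupling_strength},
    )

    beta = family_field_scale * coupling_strength
    hk_ids, hk_rows, rr_ids, rr_rows, pairs = [], [], [], [], []
    family_of_hk, family_of_rr = {}, {}
    for f in range(n_hk_families):
        fam_fields = fields.copy()
        init = rng_sample.integers(0, q, size=(M_per_family, L))
        for c in np.concatenate([hk_cols, rr_cols]):
            fam_fields[int(c), pref[int(c)][f]] += beta
            init[:, int(c)] = pref[int(c)][f]
        fam_model = PottsModel(couplings=couplings, fields=fam_fields, gauge_tag="raw")
        sample_seed = int(rng_sample.integers(0, 2**31))
        enc = sample_potts(
            fam_model, M_per_family, seed=sample_seed, method="gibbs",
            burn_in=gibbs_burn_in, init=init,
        )
        for m in range(M_per_family):
            hid, rid = f"hk{f}_{m}", f"rr{f}_{m}"
            hk_ids.append(hid)
            rr_ids.append(rid)
            hk_rows.append(PROTEIN_ALPHABET.decode(enc.matrix[m, :l_hk]))
            rr_rows.append(PROTEIN_ALPHABET.decode(enc.matrix[m, l_hk:]))
            pairs.append((hid, rid))
            family_of_hk[hid] = f
            family_of_rr[rid] = f

    mask = ContactMask(
        pairs=frozenset(mask_pairs), l_hk=l_hk, l_rr=l_rr, cutoff_a=0.0, metric_tag="planted"
    )
    return ToyWorld(
        hk_alignment=Alignment(ids=hk_ids, rows=hk_rows, domain_tag="HK"),
        rr_alignment=Alignment(ids=rr_ids, rows=rr_rows, domain_tag="RR"),
        pair_table=PairTable(pairs=pairs, provenance="cognate"),
        planted_mask=mask,
        generating_model=model,
        seed=seed,
        n_families=n_hk_families,
        family_of_hk=family_of_hk,
        family_of_rr=family_of_rr,
    )


def family_representatives(world: ToyWorld) -> tuple[Alignment, Alignment, dict]:
    """Per-family consensus HK and RR sequences and their cognate map.

    The consensus (column-wise modal state, ties to the lowest state) of
    each family plays the role of one organism's protein; the returned map
    pairs family f's HK representative with its RR representative.
    """

    def consensus(rows: list) -> str:
        X = np.stack([PROTEIN_ALPHABET.encode(r) for r in rows])
        out = []
        for col in X.T:
            counts = np.bincount(col, minlength=PROTEIN_ALPHABET.q)
            out.append(int(counts.argmax()))
        return PROTEIN_ALPHABET.decode(out)

    hk_ids, hk_rows, rr_ids, rr_rows, cmap = [], [], [], [], {}
    for f in range(world.n_families):
        fam_hk = [r for i, r in zip(world.hk_alignment.ids, world.hk_alignment.rows)
                  if world.family_of_hk[i] == f]
        fam_rr = [r for i, r in zip(world.rr_alignment.ids, world.rr_alignment.rows)
                  if world.family_of_rr[i] == f]
        hk_ids.append(f"HK_fam{f}")
        rr_ids.append(f"RR_fam{f}")
        hk_rows.append(consensus(fam_hk))
        rr_rows.append(consensus(fam_rr))
        cmap[f"HK_fam{f}"] = f"RR_fam{f}"
    return (
        Alignment(ids=hk_ids, rows=hk_rows, domain_tag="HK"),
        Alignment(ids=rr_ids, rows=rr_rows, domain_tag="RR"),
        cmap,
    )


def write_toy_world(world: ToyWorld, directory) -> None:
    """Write a toy world as FASTA alignments, TSV pair table and mask, and a
    JSON model sidecar (couplings stored separately as .npz)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_alignment(world.hk_alignment, directory / "hk.fasta")
    write_alignment(world.rr_alignment, directory / "rr.fasta")
    write_pair_table(world.pair_table, directory / "pairs.tsv")
    write_mask(world.planted_mask, directory / "mask.tsv")
    np.savez_compressed(
        directory / "generating_model.npz",
        couplings=world.generating_model.couplings,
        fields=world.generating_model.fields,
    )
    sidecar = {
        "seed": world.seed,
        "n_families": world.n_families,
        "l_hk": world.planted_mask.l_hk,
        "l_rr": world.planted_mask.l_rr,
        "family_of_hk": world.family_of_hk,
        "family_of_rr": world.family_of_rr,
    }
    (directory / "world.json").write_text(json.dumps(sidecar, indent=2) + "\n")
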