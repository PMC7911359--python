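"""Reading, encoding, filtering, pairing and scrambling of domain alignments.

The scoring model consumes a *paired* alignment: each row is the HisKA
domain of a histidine kinase concatenated with the REC domain of a response
regulator. With the standard Pfam domain widths this is 67 + 112 = 179
columns. Cognate rows come from an explicit pair table; a scrambled
counterpart (each HK joined to random RRs over several rounds) provides the
training data for the null model that absorbs attributes shared by all
HK–RR pairs.

Columns are 0-based internally; every serialized output uses 1-based
positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import Alphabet, PROTEIN_ALPHABET
from .errors import AlignmentError, PairingError

#: Standard HisKA-domain alignment width.
HK_WIDTH = 67
#: Standard REC-domain alignment width.
RR_WIDTH = 112
#: Width of the concatenated HK+RR frame. A 176-column convention exists in
#: parts of the literature; 67 + 112 = 179 is the internally consistent one
#: and is used everywhere here.
FRAME_WIDTH = HK_WIDTH + RR_WIDTH

_FORMATS = {"fasta": "fasta", "stockholm": "stockholm"}


@dataclass
class Alignment:
    """A fixed-width multiple sequence alignment of one domain family."""

    ids: list
    rows: list
    domain_tag: str = "HK"  # one of {"HK", "RR", "PAIRED"}

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            dup = next(i for i in self.ids if self.ids.count(i) > 1)
            raise AlignmentError(f"duplicate sequence id: {dup!r}")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            bad = next(i for i, r in zip(self.ids, self.rows) if len(r) != len(self.rows[0]))
            raise AlignmentError(f"ragged alignment: row {bad!r} has unexpected width")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise PairingError(f"id {seq_id!r} not found in {self.domain_tag} alignment") from None


@dataclass
class EncodedAlignment:
    """Integer-state matrix view of an alignment (M rows × L columns)."""

    matrix: np.ndarray
    alphabet: Alphabet
    ids: list | None = None

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PairTable:
    """Explicit (hk_id, rr_id) pairing with provenance.

    Cognate pairing in real data is defined genomically (adjacent loci);
    here it is always supplied explicitly, which decouples scoring from
    genome annotation.
    """

    pairs: list  # list of (hk_id, rr_id)
    provenance: str = "cognate"  # {"cognate", "scrambled"}


@dataclass
class PairedAlignment:
    """Concatenated HK+RR alignment with its pairing provenance."""

    alignment: Alignment
    l_hk: int
    l_rr: int
    pair_table: PairTable
    seed: int | None = None  # set when rows were produced by scrambling

    def __post_init__(self):
        if self.alignment.rows and self.alignment.n_columns != self.l_hk + self.l_rr:
            raise AlignmentError(
                f"paired width {self.alignment.n_columns} != {self.l_hk} + {self.l_rr}"
            )


def _normalize_row(row: str) -> str:
    """Apply the Pfam/A2M dialect rule: lowercase letters and '.' mark insert
    states and are removed; match-state characters are uppercased."""
    return "".join(c.upper() for c in row if not (c.islower() or c == "."))


def read_alignment(path, format: str = "fasta", domain_tag: str = "HK") -> Alignment:
    """Read a FASTA or Stockholm alignment.

    Insert-state characters (lowercase, '.') are removed before the uniform
    width check; gap characters '-' are preserved.
    """
    fmt = _FORMATS.get(format)
    if fmt is None:
        raise AlignmentError(f"unknown alignment format: {format!r}")
    path = Path(path)
    records = list(SeqIO.parse(str(path), fmt))
    if not records:
        raise AlignmentError(f"no sequences parsed from {path}")
    ids = [r.id for r in records]
    rows = [_normalize_row(str(r.seq)) for r in records]
    return Alignment(ids=ids, rows=rows, domain_tag=domain_tag)


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    """Write an alignment in FASTA or Stockholm format."""
    fmt = _FORMATS.get(format)
    if fmt is None:
        raise AlignmentError(f"unknown alignment format: {format!r}")
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(r), id=i, description="") for i, r in zip(aln.ids, aln.rows)]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, fmt)


def encode_alignment(aln: Alignment, alphabet: Alphabet = PROTEIN_ALPHABET) -> EncodedAlignment:
    """Encode alignment rows into integer states.

    Bijective on canonical symbols; non-canonical residue letters fall back
    to the gap state so that q stays fixed.
    """
    if aln.n_rows == 0:
        matrix = np.zeros((0, aln.n_columns), dtype=np.int64)
    else:
        matrix = np.stack([alphabet.encode(r) for r in aln.rows])
    return EncodedAlignment(matrix=matrix, alphabet=alphabet, ids=list(aln.ids))


def decode_alignment(enc: EncodedAlignment, domain_tag: str = "HK") -> Alignment:
    """Decode an encoded alignment back to character rows."""
    ids = enc.ids if enc.ids is not None else [f"seq{i}" for i in range(enc.n_rows)]
    rows = [enc.alphabet.decode(row) for row in enc.matrix]
    return Alignment(ids=list(ids), rows=rows, domain_tag=domain_tag)


def longest_gap_run(row: str) -> int:
    """Length of the longest contiguous run of '-' in a row."""
    best = cur = 0
    for c in row:
        if c == "-":
            cur += 1
            best = max(best, cur)
        else:
            cur = 0
    return best


def filter_by_gap_run(aln: Alignment, max_run: int, mode: str = "run"):
    """Drop rows with too much gap.

    With ``mode="run"`` (default) a row is removed when its longest
    *contiguous* gap run is ``>= max_run`` — e.g. HisKA rows with a gap of 5
    residues or larger, REC rows with 6 or larger. ``mode="total"`` removes
    rows whose *total* gap count is ``>= max_run``.

    Returns
    -------
    (Alignment, list of (id, longest_gap_run))
        The surviving alignment (order preserved) and the removal report.
    """
    if max_run < 1:
        raise AlignmentError("max_run must be >= 1")
    if mode not in ("run", "total"):
        raise AlignmentError(f"unknown gap-filter mode: {mode!r}")
    keep_ids, keep_rows, removed = [], [], []
    for i, r in zip(aln.ids, aln.rows):
        stat = longest_gap_run(r) if mode == "run" else r.count("-")
        if stat >= max_run:
            removed.append((i, longest_gap_run(r)))
        else:
            keep_ids.append(i)
            keep_rows.append(r)
    return Alignment(ids=keep_ids, rows=keep_rows, domain_tag=aln.domain_tag), removed


def _paired_ids(raw_ids: Iterable[str]) -> list:
    """Deduplicate concatenated-row ids by suffixing '#k'."""
    seen, out = {}, []
    for rid in raw_ids:
        n = seen.get(rid, 0)
        seen[rid] = n + 1
        out.append(rid if n == 0 else f"{rid}#{n + 1}")
    return out


def concatenate_pairs(hk: Alignment, rr: Alignment, pairs: PairTable) -> PairedAlignment:
    """Join HK and RR rows into the concatenated frame, in pair-table order."""
    l_hk, l_rr = hk.n_columns, rr.n_columns
    rows = [hk.row(h) + rr.row(r) for h, r in pairs.pairs]
    ids = _paired_ids(f"{h}|{r}" for h, r in pairs.pairs)
    aln = Alignment(ids=ids, rows=rows, domain_tag="PAIRED")
    if not rows:
        # preserve the frame width even for an empty table
        aln = Alignment(ids=[], rows=[], domain_tag="PAIRED")
    paired = PairedAlignment(alignment=aln, l_hk=l_hk, l_rr=l_rr, pair_table=pairs)
    return paired


def scramble_pairs(
    hk: Alignment,
    rr: Alignment,
    rounds: int = 25,
    seed: int = 0,
    n_per_round: int | None = None,
) -> PairedAlignment:
    """Build a scrambled paired alignment for null-model training.

    In each of ``rounds`` passes every HK row appears exactly once, joined
    to an RR drawn uniformly at random with replacement, for a total of
    ``rounds × M_HK`` rows (``n_per_round`` overrides the per-round HK
    population size by sampling HKs uniformly, for non-default populations).
    """
    if rounds < 1:
        raise AlignmentError("rounds must be >= 1")
    if hk.n_rows == 0 or rr.n_rows == 0:
        raise AlignmentError("both alignments must be non-empty")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(rounds):
        if n_per_round is None:
            hk_idx = np.arange(hk.n_rows)
        else:
            hk_idx = rng.integers(0, hk.n_rows, size=n_per_round)
        rr_idx = rng.integers(0, rr.n_rows, size=len(hk_idx))
        pairs.extend((hk.ids[a], rr.ids[b]) for a, b in zip(hk_idx, rr_idx))
    table = PairTable(pairs=pairs, provenance="scrambled")
    rows = [hk.row(h) + rr.row(r) for h, r in pairs]
    per_round = len(pairs) // rounds
    ids = _paired_ids(f"r{k // per_round + 1}:{h}|{r}" for k, (h, r) in enumerate(pairs))
    aln = Alignment(ids=ids, rows=rows, domain_tag="PAIRED")
    return PairedAlignment(
        alignment=aln, l_hk=hk.n_columns, l_rr=rr.n_columns, pair_table=table, seed=seed
    )


# ---------------------------------------------------------------------------
# Tabular side formats


def read_pair_table(path, provenance: str = "cognate") -> PairTable:
    """Read a 2-column TSV (hk_id, rr_id); '#' starts a comment line."""
    pairs = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise PairingError(f"{path}:{ln}: expected 2 tab-separated fields")
        pairs.append((parts[0], parts[1]))
    return PairTable(pairs=pairs, provenance=provenance)


def write_pair_table(table: PairTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# provenance: {table.provenance}\n# hk_id\trr_id\n")
        for h, r in table.pairs:
            fh.write(f"{h}\t{r}\n")


def write_removal_report(removed: Sequence, path) -> None:
    """Write the gap-filter removal report as TSV (id, longest_gap_run)."""
    with open(path, "w") as fh:
        fh.write("# id\tlongest_gap_run\n")
        for rid, run in removed:
            fh.write(f"{rid}\t{run}\n")
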