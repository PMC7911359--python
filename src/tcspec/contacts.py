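"""Interfacial contact extraction from a template HK–RR complex.

Specificity scoring only uses inter-domain couplings whose column pair lies
on the structurally verified kinase–regulator interface. The template is a
resolved HK–RR complex (classically the Thermotoga maritima HK853–RR468
structure); residue pairs whose minimum heavy-atom distance is below a
cutoff (12 Å by default, strict inequality) become the contact mask after
being mapped onto concatenated-alignment columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .errors import StructureError

DEFAULT_CUTOFF_A = 12.0


@dataclass
class StructureChain:
    """One polymer chain: ordered residues with heavy-atom coordinates."""

    chain_id: str
    residues: list  # list of (residue_number, residue_name, coords (n_atoms, 3))
    atom_names: list | None = None  # parallel list of per-residue atom-name lists

    def __post_init__(self):
        nums = [r[0] for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise StructureError(f"chain {self.chain_id}: residue numbers not strictly increasing")
        if any(len(r[2]) == 0 for r in self.residues):
            raise StructureError(f"chain {self.chain_id}: residue without atoms")


@dataclass
class TemplateMapping:
    """Structure residue numbers → concatenated-alignment columns.

    ``hk_map`` targets the HK block [0, l_hk); ``rr_map`` targets the RR
    block [l_hk, l_hk + l_rr) (already offset).
    """

    hk_map: dict
    rr_map: dict
    l_hk: int
    l_rr: int

    def __post_init__(self):
        for name, m, lo, hi in (
            ("hk_map", self.hk_map, 0, self.l_hk),
            ("rr_map", self.rr_map, self.l_hk, self.l_hk + self.l_rr),
        ):
            if len(set(m.values())) != len(m):
                raise StructureError(f"{name} is not injective")
            if any(not lo <= c < hi for c in m.values()):
                raise StructureError(f"{name} column outside [{lo}, {hi})")


@dataclass
class ContactMask:
    """Inter-domain column pairs within the structural cutoff."""

    pairs: frozenset  # of (i, j) with i in [0, l_hk), j in [l_hk, l_hk + l_rr)
    l_hk: int
    l_rr: int
    cutoff_a: float = DEFAULT_CUTOFF_A
    metric_tag: str = "min_heavy_atom"
    dists: dict = field(default_factory=dict)  # optional (i, j) -> min distance

    def __post_init__(self):
        self.pairs = frozenset(self.pairs)
        for i, j in self.pairs:
            if not (0 <= i < self.l_hk <= j < self.l_hk + self.l_rr):
                raise StructureError(f"mask pair ({i}, {j}) does not straddle the domain boundary")


def parse_structure(path, include_hetatm: bool = False) -> list:
    """Parse a PDB file into chains of heavy-atom residues.

    First MODEL only; hydrogens dropped; for disordered atoms the
    highest-occupancy conformer is kept (ties go to altloc 'A'); HETATM
    records are ignored unless requested.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = PDBParser(QUIET=True).get_structure("template", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise StructureError(f"malformed PDB file {path}: {exc}") from exc
    model = next(structure.get_models())  # first model only
    chains = []
    for chain in model:
        residues, names = [], []
        for res in chain:
            if res.id[0] != " " and not include_hetatm:
                continue
            coords, res_names = [], []
            for atom in res:
                if atom.is_disordered():
                    # highest occupancy; Bio.PDB orders ties with 'A' first
                    atom = max(
                        atom.disordered_get_list(),
                        key=lambda a: (a.get_occupancy() or 0.0, a.get_altloc() == "A"),
                    )
                if atom.element == "H":
                    continue
                coords.append(atom.coord)
                res_names.append(atom.get_name())
            if coords:
                residues.append((res.id[1], res.get_resname(), np.asarray(coords, dtype=float)))
                names.append(res_names)
        if residues:
            chains.append(StructureChain(chain_id=chain.id, residues=residues, atom_names=names))
    if not chains:
        raise StructureError(f"no usable chains in {path}")
    return chains


def _single_atom_view(chain: StructureChain, wanted: str) -> StructureChain:
    """Restrict a chain to one named atom per residue (for Cα/Cβ metrics)."""
    if chain.atom_names is None:
        raise StructureError(f"metric requires atom names; chain {chain.chain_id} has none")
    residues = []
    for res, names in zip(chain.residues, chain.atom_names):
        if wanted in names:
            residues.append((res[0], res[1], res[2][[names.index(wanted)]]))
    return StructureChain(chain_id=chain.chain_id, residues=residues)


def interface_contacts(
    a: StructureChain,
    b: StructureChain,
    cutoff_a: float = DEFAULT_CUTOFF_A,
    metric: str = "min_heavy_atom",
) -> list:
    """Residue pairs of two chains within the distance cutoff.

    A pair is a contact when the minimum inter-residue distance is
    *strictly* below ``cutoff_a`` (a pair exactly at the cutoff is not a
    contact). ``metric`` is ``"min_heavy_atom"`` (default, the convention
    behind the 12 Å interface cutoff), ``"ca"`` or ``"cb"``; the latter two
    measure between the named backbone/sidechain atoms only and skip
    residues lacking them (e.g. glycine for Cβ).

    Returns a list of (resnum_a, resnum_b, min_distance).
    """
    if cutoff_a <= 0:
        raise StructureError("cutoff must be positive")
    if metric in ("ca", "cb"):
        wanted = "CA" if metric == "ca" else "CB"
        a = _single_atom_view(a, wanted)
        b = _single_atom_view(b, wanted)
    elif metric != "min_heavy_atom":
        raise StructureError(f"unknown distance metric: {metric!r}")
    if not a.residues or not b.residues:
        warnings.warn("empty chain in interface_contacts; returning no contacts")
        return []

    coords_a = np.concatenate([r[2] for r in a.residues])
    coords_b = np.concatenate([r[2] for r in b.residues])
    owner_a = np.repeat(np.arange(len(a.residues)), [len(r[2]) for r in a.residues])
    owner_b = np.repeat(np.arange(len(b.residues)), [len(r[2]) for r in b.residues])
    d = cdist(coords_a, coords_b)
    # reduce atom-atom distances to per-residue-pair minima
    mins = np.full((len(a.residues), len(b.residues)), np.inf)
    np.minimum.at(mins, (owner_a[:, None], owner_b[None, :]), d)
    out = []
    for ia, ra in enumerate(a.residues):
        for ib, rb in enumerate(b.residues):
            if mins[ia, ib] < cutoff_a:
                out.append((ra[0], rb[0], float(mins[ia, ib])))
    return out


def map_contacts_to_columns(contacts: list, mapping: TemplateMapping, cutoff_a: float = DEFAULT_CUTOFF_A, metric_tag: str = "min_heavy_atom"):
    """Translate residue-pair contacts into a column-pair ContactMask.

    Pairs with either endpoint missing from the mapping are dropped and
    returned in the report.
    """
    pairs, dists, dropped = set(), {}, []
    for entry in contacts:
        ra, rb = entry[0], entry[1]
        d = float(entry[2]) if len(entry) > 2 else float("nan")
        if ra in mapping.hk_map and rb in mapping.rr_map:
            ij = (mapping.hk_map[ra], mapping.rr_map[rb])
            pairs.add(ij)
            if ij not in dists or d < dists[ij]:
                dists[ij] = d
        else:
            dropped.append((ra, rb))
    mask = ContactMask(
        pairs=frozenset(pairs),
        l_hk=mapping.l_hk,
        l_rr=mapping.l_rr,
        cutoff_a=cutoff_a,
        metric_tag=metric_tag,
        dists=dists,
    )
    return mask, dropped


def overlap_with_top_di(mask: ContactMask, di, k: int) -> int:
    """How many of the top-k inter-domain DI pairs fall inside the mask."""
    if k < 1:
        raise ValueError("k must be >= 1")
    inter = [(i, j, v) for i, j, v in di.ranking() if i < mask.l_hk <= j]
    top = inter[:k]
    return sum(1 for i, j, _ in top if (i, j) in mask.pairs)


# ---------------------------------------------------------------------------
# Tabular side formats


def read_mapping(hk_path, rr_path, l_hk: int, l_rr: int) -> TemplateMapping:
    """Read two 2-column TSVs (residue_number, 1-based column within the
    block); the RR block is offset by l_hk internally."""

    def read_one(path):
        out = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise StructureError(f"{path}:{ln}: expected 2 tab-separated fields")
            out[int(parts[0])] = int(parts[1]) - 1
        return out

    hk_map = read_one(hk_path)
    rr_map = {k: v + l_hk for k, v in read_one(rr_path).items()}
    return TemplateMapping(hk_map=hk_map, rr_map=rr_map, l_hk=l_hk, l_rr=l_rr)


def write_mask(mask: ContactMask, path) -> None:
    """Write the mask as TSV (hk_col, rr_col, min_dist_A), 1-based columns."""
    with open(path, "w") as fh:
        fh.write(f"# cutoff_A: {mask.cutoff_a}\n# metric: {mask.metric_tag}\n")
        fh.write(f"# l_hk: {mask.l_hk}\n# l_rr: {mask.l_rr}\n")
        fh.write("# hk_col\trr_col\tmin_dist_A\n")
        for i, j in sorted(mask.pairs):
            d = mask.dists.get((i, j), float("nan"))
            fh.write(f"{i + 1}\t{j + 1}\t{d:.3f}\n")


def read_mask(path) -> ContactMask:
    """Read a mask TSV written by :func:`write_mask`."""
    meta, pairs, dists = {}, set(), {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
            continue
        i, j, d = line.split("\t")
        ij = (int(i) - 1, int(j) - 1)
        pairs.add(ij)
        dists[ij] = float(d)
    if "l_hk" not in meta or "l_rr" not in meta:
        raise StructureError(f"mask file {path} lacks l_hk/l_rr header lines")
    return ContactMask(
        pairs=frozenset(pairs),
        l_hk=int(meta["l_hk"]),
        l_rr=int(meta["l_rr"]),
        cutoff_a=float(meta.get("cutoff_A", DEFAULT_CUTOFF_A)),
        metric_tag=meta.get("metric", "min_heavy_atom"),
        dists=dists,
    )
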