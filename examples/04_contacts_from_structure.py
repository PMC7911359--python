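"""Extract an interface contact mask from a template complex structure.

Writes a miniature synthetic two-chain PDB file, extracts residue pairs
whose minimum heavy-atom distance is strictly below 12 A, and maps them
onto concatenated-alignment columns. With a real kinase-regulator complex
(and its residue-to-column mapping) the same three calls produce the mask
that restricts specificity scoring to the structural interface.
"""

import tempfile
from pathlib import Path

from tcspec import TemplateMapping, interface_contacts, map_contacts_to_columns, parse_structure

# synthetic template: chain A (kinase side) along x, chain B (regulator side) nearby
pdb_text = "".join(
    f"ATOM  {k + 1:>5}  CA  ALA A{k + 1:>4}    {k * 10.0:8.3f}{0.0:8.3f}{0.0:8.3f}"
    f"{1.0:6.2f}  0.00           C\n"
    for k in range(4)
) + "".join(
    f"ATOM  {k + 5:>5}  CA  GLY B{k + 1:>4}    {k * 10.0:8.3f}{8.0:8.3f}{0.0:8.3f}"
    f"{1.0:6.2f}  0.00           C\n"
    for k in range(3)
) + "END\n"

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "synthetic_template.pdb"
    path.write_text(pdb_text)
    chains = {c.chain_id: c for c in parse_structure(path)}

contacts = interface_contacts(chains["A"], chains["B"], cutoff_a=12.0)
print(f"{len(contacts)} residue pairs under the strict 12 A cutoff:")
for ra, rb, d in contacts:
    print(f"  A:{ra} -- B:{rb}  min distance {d:.2f} A")

mapping = TemplateMapping(
    hk_map={i + 1: i for i in range(4)},          # chain A residues -> HK columns 0..3
    rr_map={i + 1: i + 4 for i in range(3)},      # chain B residues -> RR columns 4..6
    l_hk=4, l_rr=3,
)
mask, dropped = map_contacts_to_columns(contacts, mapping)
print(f"\ncontact mask (0-based columns; serialized files use 1-based): "
      f"{sorted(mask.pairs)}, {len(dropped)} pairs unmapped")
print("only couplings on these column pairs enter the H_TCS coupling term.")
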