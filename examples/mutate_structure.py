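"""Structure-level mutagenesis bookkeeping on a synthetic peptide.

Builds a small synthetic tripeptide (GLY-LEU-SER), applies an L93A
variant by side-chain truncation, and assigns the mobile/boundary/frozen
simulation regions around a chosen center atom.  The truncated residue
keeps exactly the {N, CA, C, O, CB} heavy atoms; the region labels follow
the 17/20 Å multi-layer scheme with 10/200 kcal/mol/Å² restraints.
"""

from evbscreen import (
    apply_variant,
    assign_regions,
    parse_variant,
    read_structure,
    write_structure,
)

PDB = """\
ATOM      1  N   GLY A  92       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A  92       1.400   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A  92       2.000   1.300   0.000  1.00  0.00           C
ATOM      4  O   GLY A  92       1.400   2.400   0.000  1.00  0.00           O
ATOM      5  N   LEU A  93       3.300   1.300   0.000  1.00  0.00           N
ATOM      6  CA  LEU A  93       4.100   2.500   0.000  1.00  0.00           C
ATOM      7  C   LEU A  93       5.600   2.200   0.000  1.00  0.00           C
ATOM      8  O   LEU A  93       6.100   1.100   0.000  1.00  0.00           O
ATOM      9  CB  LEU A  93       3.800   3.400   1.200  1.00  0.00           C
ATOM     10  CG  LEU A  93       4.400   4.800   1.200  1.00  0.00           C
ATOM     11  CD1 LEU A  93       3.900   5.600   2.400  1.00  0.00           C
ATOM     12  CD2 LEU A  93       4.100   5.600   0.000  1.00  0.00           C
ATOM     13  N   SER A  94       6.300   3.300   0.000  1.00  0.00           N
ATOM     14  CA  SER A  94       7.800   3.200   0.000  1.00  0.00           C
ATOM     15  C   SER A  94       8.400   4.600   0.000  1.00  0.00           C
ATOM     16  O   SER A  94       7.700   5.600   0.000  1.00  0.00           O
ATOM     17  CB  SER A  94       8.300   2.400  25.000  1.00  0.00           C
ATOM     18  OG  SER A  94       9.700   2.200  19.000  1.00  0.00           O
END
"""

structure = read_structure(PDB)
variant = parse_variant("L93A")
mutated = apply_variant(structure, variant)

_, res = mutated.find_residue("A", 93)
heavy = sorted(a.name for a in res if not a.is_hydrogen())
print(f"residue 93 after {variant.label}: {res.name}, heavy atoms {heavy}")

regions = assign_regions(mutated, center=("A", 93, "CA"))
print("region counts:", regions.counts())
print(f"radii {regions.radii} A, restraints {regions.force_constants} "
      "kcal/mol/A^2")

text = write_structure(mutated, variant_label=variant.label)
print("first line of the written PDB:", text.splitlines()[0])
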