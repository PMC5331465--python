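"""PDB-level bookkeeping for in-silico mutagenesis.

This module does the *structural* part of a screening campaign that can be
done without any force field: reading and writing coordinates, checking
that the wild-type residue at each substitution site is what the variant
label claims, truncating side chains to alanine/glycine (the built-in
scan chemistry), assigning the mobile/boundary/frozen simulation regions
of the multi-layer spherical setup, and dispatching every other
substitution to an external rotamer-placement adapter with an exclusion
set of reacting-region atoms that must not move.

PDB I/O is delegated to gemmi; the wrapper resolves alternate locations
(highest occupancy, ties to label 'A') so downstream code sees one
location per atom, and preserves residue numbering and insertion codes
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Tuple

import gemmi
import numpy as np

from .errors import (
    CannotTruncateError,
    EmptyStructureError,
    IdentityError,
    PDBParseError,
    SelectorError,
    StructureError,
    UnsupportedSubstitutionError,
)
from .variants import Variant

__all__ = [
    "Structure",
    "RegionAssignment",
    "read_structure",
    "write_structure",
    "truncate_to_alanine",
    "apply_variant",
    "assign_regions",
    "ONE_TO_THREE",
    "THREE_TO_ONE",
]

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

_BACKBONE = ("N", "CA", "C", "O")
_KEEP = {"ALA": set(_BACKBONE) | {"CB"}, "GLY": set(_BACKBONE)}

#: remoteness letter of a hydrogen name -> heavy-atom prefix it rides on
_H_PARENT_PREFIX = {"": "N", "A": "CA", "B": "CB", "G": "CG", "D": "CD",
                    "E": "CE", "Z": "CZ", "H": "CH"}


class TruncationNotice(UserWarning):
    """Residue already matched the truncation target (no-op)."""


def _h_parent(name: str) -> str:
    """Heavy-atom prefix a hydrogen is bonded to, by naming convention."""
    if len(name) < 2:
        return "N"  # bare backbone 'H'
    remote = name[1]
    if remote.isdigit():  # H1/H2/H3 terminal amine
        return "N"
    return _H_PARENT_PREFIX.get(remote, "C?")


@dataclass
class Structure:
    """Thin wrapper over a single-model gemmi structure."""

    st: gemmi.Structure
    notes: List[str] = field(default_factory=list)

    @property
    def model(self) -> gemmi.Model:
        return self.st[0]

    def residues(self):
        for chain in self.model:
            for res in chain:
                yield chain.name, res

    def find_residue(self, chain: Optional[str], resnum: int,
                     icode: str = " ") -> Tuple[str, gemmi.Residue]:
        """Residue by (chain, number, insertion code).

        ``chain=None`` means the first (default) chain.
        """
        for ch in self.model:
            if chain is not None and ch.name != chain:
                continue
            for res in ch:
                r_icode = res.seqid.icode if res.seqid.icode.strip() else " "
                if res.seqid.num == resnum and r_icode == (icode or " "):
                    return ch.name, res
            if chain is None:
                break
        raise StructureError(
            f"residue {resnum}{icode.strip()} not found in chain "
            f"{chain or '<first>'}"
        )

    def atom_table(self):
        """(chain, resnum, resname, atom name, xyz) for every atom."""
        rows = []
        for ch_name, res in self.residues():
            for atom in res:
                rows.append((ch_name, res.seqid.num, res.name, atom.name,
                             np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
        return rows

    def clone(self) -> "Structure":
        return Structure(st=self.st.clone(), notes=list(self.notes))

    def n_atoms(self) -> int:
        return sum(1 for _ in self._iter_atoms())

    def _iter_atoms(self):
        for _, res in self.residues():
            yield from res


def _resolve_altlocs(st: gemmi.Structure) -> None:
    """Keep one location per atom: highest occupancy, ties to label 'A'."""
    for model in st:
        for chain in model:
            for res in chain:
                by_name: Dict[str, List[gemmi.Atom]] = {}
                for atom in res:
                    by_name.setdefault(atom.name, []).append(atom)
                doomed = []
                for name, group in by_name.items():
                    if len(group) == 1:
                        group[0].altloc = "\x00"
                        continue
                    best = sorted(
                        group,
                        key=lambda a: (-a.occ, a.altloc or "~"),
                    )[0]
                    for i, atom in enumerate(res):
                        if atom.name == name and atom is not best:
                            doomed.append(i)
                    best.altloc = "\x00"
                for i in sorted(doomed, reverse=True):
                    del res[i]


def read_structure(pdb_content: str) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Alternate locations are resolved immediately; waters and heteroatoms
    are retained.  Raises :class:`EmptyStructureError` when no ATOM or
    HETATM records are present and :class:`PDBParseError` on content gemmi
    cannot parse.
    """
    try:
        st = gemmi.read_pdb_string(pdb_content)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"PDB parse failure: {exc}") from exc
    n = sum(model.count_atom_sites() for model in st)
    if n == 0:
        raise EmptyStructureError("no ATOM/HETATM records in input")
    _resolve_altlocs(st)
    return Structure(st=st)


def write_structure(s: Structure, variant_label: Optional[str] = None) -> str:
    """PDB text; a REMARK records the applied variant, when given."""
    text = s.st.make_pdb_string()
    if variant_label:
        text = f"REMARK 220 VARIANT {variant_label}\n" + text
    return text


def truncate_to_alanine(
    s: Structure,
    chain: Optional[str],
    resnum: int,
    target: str = "ALA",
) -> Structure:
    """Delete a side chain down to alanine (or glycine) in a copy.

    ALA keeps {N, CA, C, O, CB} plus hydrogens riding on kept heavy
    atoms; GLY keeps the backbone only.  Prolines (and any residue whose
    backbone ring participation makes deletion a backbone change) are
    declared unsupported.  Truncation is idempotent: hitting the target
    residue type again is a no-op with a notice.
    """
    if target not in _KEEP:
        raise CannotTruncateError(f"unsupported truncation target {target}")
    out = s.clone()
    ch_name, res = out.find_residue(chain, resnum)
    if res.name == "PRO":
        raise CannotTruncateError(
            f"{ch_name}{resnum} is PRO: ring removal alters the backbone; "
            "unsupported"
        )
    if res.name == target:
        warnings.warn(
            f"{ch_name}{resnum} already {target}: truncation is a no-op",
            TruncationNotice,
        )
        return out
    names = {a.name for a in res}
    missing = [n for n in ("N", "CA", "C", "O") if n not in names]
    if missing:
        raise CannotTruncateError(
            f"{ch_name}{resnum} lacks backbone atoms {missing}; cannot "
            "truncate"
        )
    keep_heavy = _KEEP[target]
    doomed = []
    for i, atom in enumerate(res):
        if atom.is_hydrogen():
            if _h_parent(atom.name) not in keep_heavy:
                doomed.append(i)
        elif atom.name not in keep_heavy:
            doomed.append(i)
    for i in sorted(doomed, reverse=True):
        del res[i]
    res.name = target
    out.notes.append(f"truncated {ch_name}{resnum} to {target}")
    return out


def apply_variant(
    s: Structure,
    v: Variant,
    rotamer_adapter: Optional[Callable] = None,
    chain: Optional[str] = None,
    exclusion_set: Iterable[Tuple[str, int, str]] = (),
) -> Structure:
    """Apply every substitution of a variant to a copy of the structure.

    All wild-type identities are verified *before* any change.  Ala/Gly
    targets are truncated internally; any other target is dispatched to
    ``rotamer_adapter(structure, substitution, frozen_atoms)``, with
    ``exclusion_set`` naming (chain, resnum, atom-name) triples — the
    reacting-region atoms — that the adapter must not move.
    """
    # identity pass first: fail before touching anything
    for sub in v.substitutions:
        ch_name, res = s.find_residue(chain, sub.position)
        found = THREE_TO_ONE.get(res.name, "X")
        if found != sub.wt_aa:
            raise IdentityError(
                f"position {sub.position} ({ch_name}): found {res.name} "
                f"({found}), variant expects {sub.wt_aa}"
            )
    out = s.clone()
    for sub in v.substitutions:
        if sub.new_aa in ("A", "G"):
            out = truncate_to_alanine(
                out, chain, sub.position, ONE_TO_THREE[sub.new_aa]
            )
        else:
            if rotamer_adapter is None:
                raise UnsupportedSubstitutionError(
                    f"{sub.label}: non-Ala/Gly target requires a rotamer "
                    "adapter"
                )
            out = rotamer_adapter(out, sub, frozenset(exclusion_set))
    out.notes.append(f"variant {v.label}")
    return out


@dataclass(frozen=True)
class RegionAssignment:
    """Per-atom mobility labels of the multi-layer spherical setup."""

    labels: tuple  # 'mobile' | 'boundary' | 'frozen', atom order
    center: tuple
    radii: Tuple[float, float]
    force_constants: Tuple[float, float]  # (boundary, frozen), kcal/mol/Å²

    def counts(self) -> Dict[str, int]:
        out = {"mobile": 0, "boundary": 0, "frozen": 0}
        for lab in self.labels:
            out[lab] += 1
        return out


def assign_regions(
    s: Structure,
    center: Tuple[Optional[str], int, str],
    radii: Tuple[float, float] = (17.0, 20.0),
    force_constants: Tuple[float, float] = (10.0, 200.0),
) -> RegionAssignment:
    """Label every atom mobile / boundary / frozen by distance to a center.

    ``center`` is a (chain, residue number, atom name) selector that must
    match exactly one atom.  Atoms strictly inside the mobile radius are
    fully mobile; atoms out to the boundary radius get the weak positional
    restraint (default 10 kcal/mol/Å²); everything beyond is frozen with
    the strong restraint (default 200).
    """
    r_mobile, r_boundary = radii
    if not (0 < r_mobile < r_boundary):
        raise SelectorError("radii must satisfy 0 < mobile < boundary")
    ch_sel, resnum, atom_name = center
    hits = []
    for ch_name, res in s.residues():
        if ch_sel is not None and ch_name != ch_sel:
            continue
        if res.seqid.num != resnum:
            continue
        for atom in res:
            if atom.name == atom_name:
                hits.append(np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
    if len(hits) != 1:
        raise SelectorError(
            f"center selector {center} matched {len(hits)} atoms, need "
            "exactly 1"
        )
    c = hits[0]
    coords = np.array([row[4] for row in s.atom_table()])
    d = np.linalg.norm(coords - c, axis=1)
    labels = np.where(d < r_mobile, "mobile",
                      np.where(d <= r_boundary, "boundary", "frozen"))
    return RegionAssignment(
        labels=tuple(labels.tolist()),
        center=tuple(c.tolist()),
        radii=(float(r_mobile), float(r_boundary)),
        force_constants=(float(force_constants[0]),
                         float(force_constants[1])),
    )
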