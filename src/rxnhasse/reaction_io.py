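"""Parsing and validation of atom-mapped reaction inputs.

The common currency of the package is the RDKit ``Mol`` with explicit
hydrogen atoms and atom-map numbers on every atom.  Reactions are kept as
:class:`AtomMappedReaction`, a thin container of reactant and product
molecules plus the original text line.

Input conventions
-----------------
* Reaction SMILES: ``reactants>agents>products`` or ``reactants>>products``.
  Agents (the middle field) do not contribute atoms to the transformation
  and are dropped with a warning.
* Every heavy atom must carry a map number.  Hydrogens may be implicit in
  the text; they are materialized as atom nodes on parsing and, where
  possible, numbered consistently on both sides (paired by parent heavy
  atom).  Hydrogens that migrate between heavy atoms cannot be paired
  automatically and must be mapped explicitly in the input.
* Stereo descriptors are parsed and retained on the molecules but are never
  used for template extraction; they only matter during stereo filtering at
  scoring time.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from rdkit import Chem

logger = logging.getLogger(__name__)

__all__ = [
    "AtomMappedReaction",
    "ReactionParseError",
    "UnmappedAtomError",
    "BalanceError",
    "parse_reaction_smiles",
    "ensure_explicit_hydrogens",
    "validate_balance",
    "reaction_to_smiles",
    "read_reaction_file",
    "read_substrate_file",
]


class ReactionParseError(ValueError):
    """Raised when a reaction line cannot be parsed into molecules."""


class UnmappedAtomError(ReactionParseError):
    """Raised when a heavy atom lacks an atom-map number."""


class BalanceError(ReactionParseError):
    """Raised when the two sides of a reaction are not atom-balanced."""


@dataclass
class AtomMappedReaction:
    """A balanced, fully atom-mapped reaction.

    Attributes
    ----------
    reactants, products:
        Lists of RDKit molecules with explicit hydrogens; every atom carries
        a nonzero, side-unique map number and the multiset of
        ``(map, element)`` pairs agrees between the two sides.
    source_text:
        The original reaction-SMILES line the reaction was parsed from.
    """

    reactants: list[Chem.Mol]
    products: list[Chem.Mol]
    source_text: str = ""

    def mapped_atoms(self, side: str) -> dict[int, Chem.Atom]:
        """Map number -> atom for one side ('r' or 'p')."""
        mols = self.reactants if side == "r" else self.products
        out: dict[int, Chem.Atom] = {}
        for mol in mols:
            for atom in mol.GetAtoms():
                if atom.GetAtomMapNum():
                    out[atom.GetAtomMapNum()] = atom
        return out


def _parse_side(text: str, line: str) -> list[Chem.Mol]:
    if not text:
        raise ReactionParseError(f"empty reaction side in line: {line!r}")
    mol = Chem.MolFromSmiles(text, sanitize=False)
    if mol is None:
        raise ReactionParseError(f"could not parse {text!r} in line: {line!r}")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - rdkit raises various types
        raise ReactionParseError(f"sanitization failed for {text!r}: {exc}") from exc
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return [Chem.Mol(f) for f in frags]


def parse_reaction_smiles(line: str) -> AtomMappedReaction:
    """Parse one reaction-SMILES line into an :class:`AtomMappedReaction`.

    The line must contain exactly one ``>...>`` separator structure.  A
    nonempty agents field is dropped with a warning.  Implicit hydrogens are
    materialized and auto-numbered (paired by parent heavy atom); heavy
    atoms without a map number raise :class:`UnmappedAtomError` and an
    unbalanced result raises :class:`BalanceError`.
    """
    line = line.strip()
    parts = line.split(">")
    if len(parts) != 3:
        raise ReactionParseError(
            f"expected 'reactants>agents>products' with two '>' separators: {line!r}"
        )
    r_text, a_text, p_text = parts
    if a_text:
        logger.warning("dropping agents field %r of line %r", a_text, line)
    reactants = _parse_side(r_text, line)
    products = _parse_side(p_text, line)

    for mol in reactants + products:
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() != 1 and atom.GetAtomMapNum() == 0:
                raise UnmappedAtomError(
                    f"heavy atom {atom.GetSymbol()} without map number in line: {line!r}"
                )

    rxn = AtomMappedReaction(reactants=reactants, products=products, source_text=line)
    rxn = _materialize_and_pair_hydrogens(rxn)
    violations = validate_balance(rxn)
    if violations:
        raise BalanceError(f"unbalanced reaction {line!r}: " + "; ".join(violations))
    return rxn


def ensure_explicit_hydrogens(mol: Chem.Mol, assign_maps: bool = False,
                              next_map: int | None = None) -> Chem.Mol:
    """Return a copy of *mol* with all implicit hydrogens as explicit atoms.

    Idempotent: a fully explicit molecule is returned structurally
    unchanged.  With ``assign_maps`` new hydrogen atoms receive fresh map
    numbers starting at ``next_map`` (default: one above the largest map
    number present).
    """
    out = Chem.AddHs(Chem.Mol(mol))
    if assign_maps:
        if next_map is None:
            next_map = max(
                (a.GetAtomMapNum() for a in out.GetAtoms()), default=0
            ) + 1
        for atom in out.GetAtoms():
            if atom.GetAtomicNum() == 1 and atom.GetAtomMapNum() == 0:
                atom.SetAtomMapNum(next_map)
                next_map += 1
    return out


def _materialize_and_pair_hydrogens(rxn: AtomMappedReaction) -> AtomMappedReaction:
    """Make hydrogens explicit and pair unmapped ones across sides.

    Unmapped hydrogens are matched between the two sides by the map number
    of their parent heavy atom and given fresh shared numbers.  A leftover
    unmatched hydrogen (as in a hydrogen transfer between heavy atoms)
    cannot be paired automatically and raises :class:`UnmappedAtomError`.
    """
    reactants = [Chem.AddHs(m) for m in rxn.reactants]
    products = [Chem.AddHs(m) for m in rxn.products]

    def unmapped_h_by_parent(mols: list[Chem.Mol]) -> dict[int, list[Chem.Atom]]:
        by_parent: dict[int, list[Chem.Atom]] = {}
        for mol in mols:
            for atom in mol.GetAtoms():
                if atom.GetAtomicNum() == 1 and atom.GetAtomMapNum() == 0:
                    nbrs = atom.GetNeighbors()
                    parent = nbrs[0].GetAtomMapNum() if nbrs else 0
                    by_parent.setdefault(parent, []).append(atom)
        return by_parent

    used = {
        a.GetAtomMapNum()
        for m in reactants + products
        for a in m.GetAtoms()
        if a.GetAtomMapNum()
    }
    next_map = max(used, default=0) + 1

    h_r = unmapped_h_by_parent(reactants)
    h_p = unmapped_h_by_parent(products)
    for parent in sorted(set(h_r) | set(h_p)):
        hs_r = h_r.get(parent, [])
        hs_p = h_p.get(parent, [])
        if len(hs_r) != len(hs_p):
            raise UnmappedAtomError(
                "cannot auto-number hydrogens: heavy atom map "
                f"{parent} carries {len(hs_r)} unmapped H on the reactant side "
                f"but {len(hs_p)} on the product side (migrating hydrogens "
                "must be mapped explicitly); line: " + repr(rxn.source_text)
            )
        for a_r, a_p in zip(hs_r, hs_p):
            a_r.SetAtomMapNum(next_map)
            a_p.SetAtomMapNum(next_map)
            next_map += 1
    return AtomMappedReaction(reactants, products, rxn.source_text)


def validate_balance(rxn: AtomMappedReaction) -> list[str]:
    """Return a list of balance violations (empty means balanced).

    Checks that map numbers are unique within each side and that the
    multiset of ``(map, element)`` pairs agrees between the sides.
    """
    violations: list[str] = []

    def side_pairs(mols: list[Chem.Mol], name: str) -> Counter:
        pairs: Counter = Counter()
        seen: set[int] = set()
        for mol in mols:
            for atom in mol.GetAtoms():
                num = atom.GetAtomMapNum()
                if num == 0:
                    violations.append(
                        f"unmapped {atom.GetSymbol()} atom on {name} side"
                    )
                    continue
                if num in seen:
                    violations.append(f"duplicate map number {num} on {name} side")
                seen.add(num)
                pairs[(num, atom.GetSymbol())] += 1
        return pairs

    r_pairs = side_pairs(rxn.reactants, "reactant")
    p_pairs = side_pairs(rxn.products, "product")
    for key in sorted(set(r_pairs) | set(p_pairs)):
        num, sym = key
        if r_pairs[key] != p_pairs[key]:
            violations.append(
                f"map {num} ({sym}): {r_pairs[key]} on reactant side vs "
                f"{p_pairs[key]} on product side"
            )
    return violations


def reaction_to_smiles(rxn: AtomMappedReaction) -> str:
    """Write a reaction back to mapped reaction-SMILES text."""
    r = ".".join(Chem.MolToSmiles(m) for m in rxn.reactants)
    p = ".".join(Chem.MolToSmiles(m) for m in rxn.products)
    return f"{r}>>{p}"


def read_reaction_file(path: str) -> Iterator[tuple[int, str]]:
    """Yield ``(line_number, line)`` for reaction lines of a text file.

    Blank lines and ``#`` comment lines are skipped.
    """
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield i, line


def read_substrate_file(path: str) -> list[Chem.Mol]:
    """Read one molecule per line; hydrogens are made explicit."""
    mols = []
    for i, line in read_reaction_file(path):
        mol = Chem.MolFromSmiles(line)
        if mol is None:
            raise ReactionParseError(f"could not parse substrate on line {i}: {line!r}")
        mols.append(Chem.AddHs(mol))
    return mols
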