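"""Built-in reaction families and a synthetic family generator.

Two kinds of inputs live here:

* Hand-mapped literature examples — the three aldol/retro-aldol cleavage
  reactions of 4-hydroxy-2-oxoglutarate lyase (EC 4.1.3.42) and the
  oxidation of lactate by lactate oxidase (EC 1.1.3.2).  The structures
  are encoded from the compound names; atom maps were assigned by hand
  once and are frozen here.
* A deterministic generator of synthetic reaction families sharing a core
  transformation (a dehydrogenation of a secondary alcohol, or a toy
  transamination) on randomly decorated carbon skeletons.  Families from
  the generator drive the property-based tests: the conserved shell around
  the reaction center is known by construction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from rdkit import Chem

from .reaction_io import AtomMappedReaction, parse_reaction_smiles

__all__ = [
    "FamilySpec",
    "ec_4_1_3_42_reactions",
    "lactate_oxidation",
    "transaminase_toy",
    "generate_family",
    "generate_family_smiles",
]


# ---------------------------------------------------------------------------
# literature examples
# ---------------------------------------------------------------------------

# 4-hydroxy-2-oxoglutarate lyase splits the C3-C4 bond next to the hydroxyl
# group; the hydroxyl proton moves to C3 and the pyruvate moiety
# (maps 1-8 + the migrating H 11) is common to all three reactions.
_EC_4_1_3_42 = [
    # 4-hydroxy-2-oxoglutarate -> pyruvate + glyoxylate
    "[O-:3][C:1](=[O:2])[C:4](=[O:5])[C:6]([H:7])([H:8])"
    "[C:9]([H:12])([O:10][H:11])[C:13](=[O:14])[O-:15]"
    ">>[O-:3][C:1](=[O:2])[C:4](=[O:5])[C:6]([H:7])([H:8])[H:11]"
    ".[H:12][C:9](=[O:10])[C:13](=[O:14])[O-:15]",
    # 4-hydroxy-2-oxobutanoate -> pyruvate + formaldehyde
    "[O-:3][C:1](=[O:2])[C:4](=[O:5])[C:6]([H:7])([H:8])"
    "[C:9]([H:12])([H:16])[O:10][H:11]"
    ">>[O-:3][C:1](=[O:2])[C:4](=[O:5])[C:6]([H:7])([H:8])[H:11]"
    ".[H:12][C:9](=[O:10])[H:16]",
    # oxaloacetate -> pyruvate + carbon dioxide
    "[O-:3][C:1](=[O:2])[C:4](=[O:5])[C:6]([H:7])([H:8])"
    "[C:9](=[O:17])[O:10][H:11]"
    ">>[O-:3][C:1](=[O:2])[C:4](=[O:5])[C:6]([H:7])([H:8])[H:11]"
    ".[O:17]=[C:9]=[O:10]",
]

# lactate + O2 -> pyruvate + H2O2 (lactate oxidase); the carbinol H and the
# hydroxyl H both end up on the peroxide.
_LACTATE_OXIDATION = (
    "[C:1]([H:2])([H:3])([H:4])[C:5]([H:6])([O:7][H:8])[C:9](=[O:10])[O-:11]"
    ".[O:12]=[O:13]"
    ">>[C:1]([H:2])([H:3])([H:4])[C:5](=[O:7])[C:9](=[O:10])[O-:11]"
    ".[H:6][O:12][O:13][H:8]"
)


def ec_4_1_3_42_reactions() -> list[AtomMappedReaction]:
    """The three known reactions of 4-hydroxy-2-oxoglutarate lyase
    (EC 4.1.3.42): 4-hydroxy-2-oxoglutarate, 4-hydroxy-2-oxobutanoate and
    oxaloacetate each split into pyruvate plus glyoxylate, formaldehyde or
    carbon dioxide, respectively."""
    return [parse_reaction_smiles(line) for line in _EC_4_1_3_42]


def ec_4_1_3_42_smiles() -> list[str]:
    """The raw mapped reaction-SMILES lines of the lyase family."""
    return list(_EC_4_1_3_42)


def lactate_oxidation() -> AtomMappedReaction:
    """Oxidation of lactate to pyruvate by lactate oxidase (EC 1.1.3.2),
    with molecular oxygen reduced to hydrogen peroxide."""
    return parse_reaction_smiles(_LACTATE_OXIDATION)


def transaminase_toy(pairs=((0, 0), (0, 1), (1, 0), (1, 1))) -> list[AtomMappedReaction]:
    """Toy amine-transfer reactions for cosubstrate-proposal tests.

    Each pair ``(a, d)`` yields one reaction of the ketone acceptor
    ``CH3-CO-CH2-(CH2)_a-H`` with the amine donor
    ``CH3-CH(NH2)-CH2-(CH2)_d-H``: the amino group and alpha hydrogen of
    the donor swap with the carbonyl oxygen of the acceptor.  The default
    trains on all four combinations of two acceptors and two donors.
    """
    out = []
    for a_len, d_len in pairs:
        line = (
            "[C:1]([H:2])([H:3])([H:4])[C:5](=[O:6])[C:7]([H:8])([H:9])A"
            ".[C:10]([H:11])([H:12])([H:13])[C:14]([H:15])([N:16]([H:17])[H:18])"
            "[C:19]([H:20])([H:21])D"
            ">>"
            "[C:1]([H:2])([H:3])([H:4])[C:5]([H:15])([N:16]([H:17])[H:18])"
            "[C:7]([H:8])([H:9])A"
            ".[C:10]([H:11])([H:12])([H:13])[C:14](=[O:6])"
            "[C:19]([H:20])([H:21])D"
        )
        line = line.replace("A", _chain_tail(a_len, 30))
        line = line.replace("D", _chain_tail(d_len, 60))
        out.append(parse_reaction_smiles(line))
    return out


def _chain_tail(n_carbons: int, base: int) -> str:
    """Mapped ``-(CH2)_n-H`` tail starting at map number *base*."""
    if n_carbons == 0:
        return f"[H:{base}]"
    m = base
    parts = []
    for _ in range(n_carbons):
        parts.append(f"[C:{m}]([H:{m + 1}])([H:{m + 2}])")
        m += 3
    return "".join(parts) + f"[H:{m}]"


# ---------------------------------------------------------------------------
# synthetic family generator
# ---------------------------------------------------------------------------

#: substituents available for random decoration; each pair differs already
#: at the attachment atom, so the conserved region of a family is exactly
#: the set of positions decorated identically in every member
DEFAULT_ALPHABET = ("H", "F", "Cl", "Br", "C", "O")

_SUB_SMILES = {
    "H": "[H]",
    "F": "F",
    "Cl": "Cl",
    "Br": "Br",
    "C": "C([H])([H])[H]",
    "O": "O[H]",
}


@dataclass(frozen=True)
class FamilySpec:
    """Specification of a synthetic reaction family.

    A family consists of *n_reactions* dehydrogenations of secondary
    alcohols ``CH3-CH(OH)-(C(R,R'))_depth-H`` sharing the reaction center,
    where each skeleton carbon beyond the carbinol carries two substituent
    slots filled from *alphabet*.  Slots listed in *conserved* (as
    ``(position, slot) -> substituent``) are fixed across the family; all
    other slots are drawn independently per reaction.  Deterministic under
    a fixed *seed*.
    """

    n_reactions: int = 3
    depth: int = 2
    alphabet: tuple[str, ...] = ("H", "F", "Cl", "C")
    conserved: tuple = ()  # ((position, slot, substituent), ...)
    seed: int = 0

    def __post_init__(self):
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for sub in self.alphabet:
            if sub not in _SUB_SMILES:
                raise ValueError(f"unknown substituent {sub!r}")


def _substrate_smiles(decorations: list[tuple[str, str]], maps: "_MapCounter"):
    """Mapped SMILES of CH3-CH(OH)-C(R1a,R1b)-...-C(Rka,Rkb)-H, plus the
    map numbers of the reacting carbinol atoms."""
    m = maps
    methyl = f"[C:{m()}]([H:{m()}])([H:{m()}])([H:{m()}])"
    carbinol_c, carbinol_h, o, oh = m(), m(), m(), m()
    parts = [
        methyl,
        f"[C:{carbinol_c}]([H:{carbinol_h}])([O:{o}][H:{oh}])",
    ]
    for ra, rb in decorations:
        parts.append(f"[C:{m()}]({_mapped_sub(ra, m)})({_mapped_sub(rb, m)})")
    parts.append(f"[H:{m()}]")
    return "".join(parts), (carbinol_c, carbinol_h, o, oh)


def _mapped_sub(sub: str, m: "_MapCounter") -> str:
    smi = _SUB_SMILES[sub]
    out = ""
    i = 0
    while i < len(smi):
        # map every atom token of the tiny substituent patterns
        if smi.startswith("Cl", i) or smi.startswith("Br", i):
            out += f"[{smi[i:i + 2]}:{m()}]"
            i += 2
        elif smi[i] in "FCON":
            out += f"[{smi[i]}:{m()}]"
            i += 1
        elif smi.startswith("[H]", i):
            out += f"[H:{m()}]"
            i += 3
        else:
            out += smi[i]
            i += 1
    return out


class _MapCounter:
    def __init__(self):
        self.n = 0

    def __call__(self) -> int:
        self.n += 1
        return self.n


def generate_family_smiles(spec: FamilySpec) -> list[str]:
    """Mapped reaction-SMILES lines for a synthetic family.

    Each reaction is the dehydrogenation of a decorated secondary alcohol:
    ``R-CH(OH)-R' -> R-CO-R' + H2`` (carbinol C-H and O-H both leave as
    molecular hydrogen).  All members share an isomorphic reaction center.
    """
    rng = random.Random(spec.seed)
    fixed = {(pos, slot): sub for pos, slot, sub in spec.conserved}
    lines = []
    seen = set()
    attempts = 0
    while len(lines) < spec.n_reactions:
        attempts += 1
        if attempts > 100 * spec.n_reactions:
            raise RuntimeError(
                "could not generate enough distinct family members; "
                "enlarge the alphabet or depth"
            )
        decorations = []
        for pos in range(spec.depth):
            ra = fixed.get((pos, 0)) or rng.choice(spec.alphabet)
            rb = fixed.get((pos, 1)) or rng.choice(spec.alphabet)
            decorations.append((ra, rb))
        maps = _MapCounter()
        substrate, (c, ch, o, oh) = _substrate_smiles(decorations, maps)
        # distinct members must differ structurally, not just textually
        mol = Chem.MolFromSmiles(substrate)
        for atom in mol.GetAtoms():
            atom.SetAtomMapNum(0)
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        product = (
            substrate.replace(f"([H:{ch}])", "")
            .replace(f"([O:{o}][H:{oh}])", f"(=[O:{o}])")
        )
        h2 = f"[H:{ch}][H:{oh}]"
        lines.append(f"{substrate}>>{product}.{h2}")
    return lines


def generate_family(spec: FamilySpec) -> list[AtomMappedReaction]:
    """Parse the generated family into validated mapped reactions."""
    return [parse_reaction_smiles(line) for line in generate_family_smiles(spec)]
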