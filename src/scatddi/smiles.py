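"""A small SMILES reader for the organic subset.

Covers what drug structure strings in this pipeline need: organic-subset
atoms (B, C, N, O, P, S, F, Cl, Br, I), aromatic lowercase forms, branches,
ring-bond closures (including ``%nn``), and explicit bond orders
(``-``, ``=``, ``#``, ``:``).  Charges, isotopes, stereo marks and bracket
atoms are out of scope.  Parse errors report the 0-based character position.

Bonds between two aromatic atoms written without an explicit order are
recorded with the order tag ``"ar"``; hydrogens stay implicit.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MolecularGraph", "SmilesParseError", "parse_smiles_to_graph"]

_TWO_LETTER = ("Cl", "Br")
_ORGANIC = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
_AROMATIC = {"b", "c", "n", "o", "p", "s"}
_BOND_ORDERS = {"-": 1, "=": 2, "#": 3, ":": "ar"}


class SmilesParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass
class MolecularGraph:
    """Atoms as element symbols; bonds as undirected (i, j, order) edges."""

    atoms: list[str]
    bonds: list[tuple[int, int, object]]
    aromatic: list[bool]

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            if i == j:
                raise ValueError(f"self-loop on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    def neighbors(self, i: int) -> list[tuple[int, object]]:
        out = []
        for a, b, order in self.bonds:
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out


def parse_smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`."""
    if not smiles:
        raise SmilesParseError("empty SMILES", 0)

    atoms: list[str] = []
    aromatic: list[bool] = []
    bonds: list[tuple[int, int, object]] = []
    prev: int | None = None          # atom awaiting a bond to the next atom
    pending_order = None             # explicit bond order for the next bond
    branch_stack: list[tuple[int, int]] = []  # (atom index, '(' position)
    ring_open: dict[int, tuple[int, object, int]] = {}  # num -> (atom, order, pos)

    def add_bond(i: int, j: int, order, pos: int) -> None:
        if order is None:
            order = "ar" if aromatic[i] and aromatic[j] else 1
        if i == j or any({a, b} == {i, j} for a, b, _ in bonds):
            raise SmilesParseError("duplicate or self bond", pos)
        bonds.append((i, j, order))

    k, n = 0, len(smiles)
    while k < n:
        ch = smiles[k]
        two = smiles[k:k + 2]
        if two in _TWO_LETTER or ch in _ORGANIC or ch in _AROMATIC:
            symbol = two if two in _TWO_LETTER else ch
            is_ar = symbol in _AROMATIC
            atoms.append(symbol.capitalize())
            aromatic.append(is_ar)
            idx = len(atoms) - 1
            if prev is not None:
                add_bond(prev, idx, pending_order, k)
            pending_order = None
            prev = idx
            k += len(symbol)
        elif ch in _BOND_ORDERS:
            pending_order = _BOND_ORDERS[ch]
            k += 1
        elif ch == "(":
            if prev is None:
                raise SmilesParseError("branch before any atom", k)
            branch_stack.append((prev, k))
            k += 1
        elif ch == ")":
            if not branch_stack:
                raise SmilesParseError("unbalanced ')'", k)
            prev = branch_stack.pop()[0]
            k += 1
        elif ch.isdigit() or ch == "%":
            if ch == "%":
                if k + 2 >= n or not smiles[k + 1:k + 3].isdigit():
                    raise SmilesParseError("'%' needs two digits", k)
                num, step = int(smiles[k + 1:k + 3]), 3
            else:
                num, step = int(ch), 1
            if prev is None:
                raise SmilesParseError("ring closure before any atom", k)
            if num in ring_open:
                other, order_o, _ = ring_open.pop(num)
                add_bond(other, prev, pending_order or order_o, k)
            else:
                ring_open[num] = (prev, pending_order, k)
            pending_order = None
            k += step
        else:
            raise SmilesParseError(f"unsupported character {ch!r}", k)

    if branch_stack:
        raise SmilesParseError("unbalanced '('", branch_stack[0][1])
    if ring_open:
        num, (_, _, pos) = next(iter(ring_open.items()))
        raise SmilesParseError(f"unclosed ring index {num}", pos)
    return MolecularGraph(atoms, bonds, aromatic)
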