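"""Recursive cleavage rules and the site-finding engine.

A protease is modelled as a list of :class:`CleavageRule` trees.  Each root
is anchored on one residue (Schechter-Berger P1 for an ``after`` rule, P1'
for a ``before`` rule); sub-rules test neighbouring residues at signed
offsets relative to the anchor and refine the cleave/no-cleave decision.

Decision semantics
------------------
At a position whose residue equals a root's anchor, the tree is walked: a
node *matches* when the residue at ``pos + index`` exists and equals the
node's residue (wildcard nodes match any residue; out-of-bounds offsets
never match).  Along fully-matched root-to-node paths, every *decisive*
node (``cleave is not None``) casts a vote; the vote of the deepest matched
decisive node wins, i.e. the most specific context dominates.  If two
matched decisive nodes at the same maximal depth disagree, no-cleave wins:
exceptions are authoritative.  An enzyme cleaves a bond when at least one
of its roots resolves to cleave=True there.

Bonds are numbered 1..len-1 between residues; bonds at the sequence ends
are suppressed so no empty peptide is ever produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from .alphabet import RESIDUES, AlphabetError

BEFORE = "before"
AFTER = "after"


@dataclass
class CleavageRule:
    """One node of a cleavage-rule tree.

    Parameters
    ----------
    amino_acid : str or None
        Lowercase one-letter residue the node requires, or None for a
        wildcard that matches any residue (still requires the offset to be
        inside the sequence).
    index : int
        Offset relative to the anchor position: 0 = anchor (P1 for an
        after-rule, P1' for a before-rule), -1 one residue N-terminal,
        +1 one residue C-terminal.
    cleave : bool or None
        The decision this node casts when matched; None marks a
        pass-through context node (required context that does not itself
        decide).
    side : {"before", "after"}
        Side of the anchor the scissile bond lies on.  Meaningful on roots
        only; sub-rules inherit the root's side.
    sub_rules : list of CleavageRule
        Refinements/exceptions, tested only when this node matches.
    """

    amino_acid: Optional[str]
    index: int
    cleave: Optional[bool]
    side: str = AFTER
    sub_rules: list["CleavageRule"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.amino_acid is not None:
            aa = self.amino_acid.lower()
            if aa not in RESIDUES:
                raise ValueError(f"unknown residue in rule: {self.amino_acid!r}")
            self.amino_acid = aa
        if self.side not in (BEFORE, AFTER):
            raise ValueError(f"side must be 'before' or 'after', got {self.side!r}")

    def walk(self) -> Iterator["CleavageRule"]:
        yield self
        for sub in self.sub_rules:
            yield from sub.walk()

    def max_offset(self) -> int:
        """Largest |index| anywhere in the tree (the context window radius)."""
        return max(abs(node.index) for node in self.walk())


@dataclass
class Enzyme:
    """A named protease: a list of root rules plus a default miscleavage %."""

    name: str
    rules: list[CleavageRule]
    default_miscleavage: float = 0.0
    definition: list[tuple[str, bool]] = field(default_factory=list)
    provenance: str = "builtin"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("enzyme name must be nonempty")
        if not self.rules:
            raise ValueError(f"enzyme {self.name!r} has no rules")
        if not 0.0 <= self.default_miscleavage <= 100.0:
            raise ValueError("default_miscleavage must be in [0, 100]")
        for root in self.rules:
            if root.index != 0:
                raise ValueError(f"root rule of {self.name!r} must have index 0")
            if root.amino_acid is None:
                raise ValueError(f"root rule of {self.name!r} may not be a wildcard")
            if root.cleave is None:
                raise ValueError(f"root rule of {self.name!r} must carry a decision")

    def max_offset(self) -> int:
        return max(root.max_offset() for root in self.rules)


def _matches(node: CleavageRule, sequence: str, pos: int) -> bool:
    i = pos + node.index
    if not 0 <= i < len(sequence):
        return False
    return node.amino_acid is None or sequence[i] == node.amino_acid


def _resolve_root(root: CleavageRule, sequence: str, pos: int) -> bool:
    """Effective decision of one matched root at *pos* (deepest match wins)."""
    best_depth = 0
    best_cleave = bool(root.cleave)
    stack = [(sub, 1) for sub in root.sub_rules]
    while stack:
        node, depth = stack.pop()
        if not _matches(node, sequence, pos):
            continue
        if node.cleave is not None:
            if depth > best_depth:
                best_depth, best_cleave = depth, node.cleave
            elif depth == best_depth:
                # tie between equally specific contexts: no-cleave dominates
                best_cleave = best_cleave and node.cleave
        stack.extend((sub, depth + 1) for sub in node.sub_rules)
    return best_cleave


def cleavage_bonds_at(sequence: str, pos: int, enzyme: Enzyme) -> tuple[int, ...]:
    """All scissile bonds the enzyme opens at position *pos*.

    Returns bond indices in [1, len-1]; bonds falling on the sequence ends
    are suppressed.  Usually empty or a single bond; an enzyme with both a
    before- and an after-side root on the same residue can return two.
    """
    n = len(sequence)
    if not 0 <= pos < n:
        raise IndexError(f"position {pos} outside sequence of length {n}")
    residue = sequence[pos]
    if residue not in RESIDUES:
        raise AlphabetError(residue, pos)
    bonds = set()
    for root in enzyme.rules:
        if root.amino_acid != residue:
            continue
        if _resolve_root(root, sequence, pos):
            bond = pos if root.side == BEFORE else pos + 1
            if 0 < bond < n:
                bonds.add(bond)
    return tuple(sorted(bonds))


def evaluate_position(sequence: str, pos: int, enzyme: Enzyme) -> Optional[int]:
    """Bond index where *enzyme* cleaves at *pos*, or None.

    If both sides of the residue are cleaved (only possible for an enzyme
    with before- and after-rules on the same anchor), the N-terminal bond
    is returned; :func:`find_sites` accounts for both.
    """
    bonds = cleavage_bonds_at(sequence, pos, enzyme)
    return bonds[0] if bonds else None


def find_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """Sorted, duplicate-free cleavage bond indices over the whole sequence.

    The sequence must be normalized (lowercase, valid alphabet) and
    nonempty.  Two rules firing on the same bond yield one site.
    """
    if not sequence:
        raise ValueError("cannot scan an empty sequence")
    n = len(sequence)
    by_anchor: dict[str, list[CleavageRule]] = {}
    for root in enzyme.rules:
        by_anchor.setdefault(root.amino_acid, []).append(root)
    sites: set[int] = set()
    for pos, residue in enumerate(sequence):
        if residue not in RESIDUES:
            raise AlphabetError(residue, pos)
        for root in by_anchor.get(residue, ()):
            if _resolve_root(root, sequence, pos):
                bond = pos if root.side == BEFORE else pos + 1
                if 0 < bond < n:
                    sites.add(bond)
    return sorted(sites)
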