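"""The protease-definition grammar.

A protease is written as one rule per line in a notation that stays close
to Schechter-Berger position nomenclature.  Each parenthesis system is one
position (P2)(P1)(P1')...; a comma marks the scissile bond; ``or`` lists
alternative residues within a position; an empty system ``()`` is a
wildcard matching any residue.  Examples::

    (n,)(g)                  cleave between n (P1) and g (P1')
    (k or a or y,)           cleave after k, a or y
    (,f or l or w or y,)     cleave before AND after any of f/l/w/y
    n,g                      bare form, allowed when every position is a
                             single residue

A definition may also carry *exceptions*: rules with the same syntax that
block, rather than trigger, cleavage.  An exception attaches as a sub-rule
to every already-defined main rule whose anchor residue and side match.

Compilation turns each rule into one :class:`~pepdigest.rules.CleavageRule`
root per anchor residue, with the non-anchor positions chained beneath it
as required context (nearest positions first, N-side then C-side); the
deepest chain node carries the decision - cleave for a rule, no-cleave for
an exception.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .alphabet import RESIDUES
from .rules import AFTER, BEFORE, CleavageRule, Enzyme, find_sites

WILDCARD = None  # an empty position-system () matches any residue


class GrammarError(ValueError):
    """Syntax or semantic error in a protease definition."""

    def __init__(self, message: str, column: int | None = None):
        self.column = column
        if column is not None:
            message = f"{message} (column {column + 1})"
        super().__init__(message)


class LinkageError(GrammarError):
    """An exception line has no main rule to attach to."""


@dataclass(frozen=True)
class Token:
    kind: str  # LPAR RPAR COMMA OR RES
    value: str
    column: int


def tokenize(text: str) -> list[Token]:
    """Split a definition line into tokens; uppercase residues are folded."""
    tokens: list[Token] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "(":
            tokens.append(Token("LPAR", ch, i))
            i += 1
        elif ch == ")":
            tokens.append(Token("RPAR", ch, i))
            i += 1
        elif ch == ",":
            tokens.append(Token("COMMA", ch, i))
            i += 1
        elif ch.isalpha():
            start = i
            while i < len(text) and text[i].isalpha():
                i += 1
            word = text[start:i].lower()
            if word == "or":
                tokens.append(Token("OR", word, start))
            else:
                for k, letter in enumerate(word):
                    if letter not in RESIDUES:
                        raise GrammarError(
                            f"unknown residue {letter!r}", start + k
                        )
                    tokens.append(Token("RES", letter, start + k))
        else:
            raise GrammarError(f"illegal character {ch!r}", i)
    return tokens


@dataclass(frozen=True)
class RuleExpression:
    """A parsed rule: position-systems, the anchor system and the bond side.

    ``systems`` holds one frozenset of residues per position (None for the
    wildcard); ``anchor`` indexes the system carrying the comma; ``side``
    says whether the bond is N-terminal (before) or C-terminal (after) of
    the anchor residue.
    """

    systems: tuple[Optional[frozenset[str]], ...]
    anchor: int
    side: str

    def offsets(self) -> list[tuple[int, Optional[frozenset[str]]]]:
        """Non-anchor systems as (signed offset, residue set), nearest
        positions first, N-side before C-side."""
        ctx = [
            (j - self.anchor, sys)
            for j, sys in enumerate(self.systems)
            if j != self.anchor
        ]
        return sorted(ctx, key=lambda t: (t[0] > 0, abs(t[0])))


def _parse_paren(tokens: list[Token], text: str) -> list[RuleExpression]:
    systems: list[Optional[frozenset[str]]] = []
    commas: list[tuple[int, str]] = []  # (system index, side)
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok.kind != "LPAR":
            raise GrammarError(
                "with parentheses, every position must be parenthesized",
                tok.column,
            )
        i += 1
        leading_comma = False
        if i < len(tokens) and tokens[i].kind == "COMMA":
            leading_comma = True
            i += 1
        residues: list[str] = []
        expect_res = True
        while i < len(tokens) and tokens[i].kind == "RES":
            residues.append(tokens[i].value)
            i += 1
            if i < len(tokens) and tokens[i].kind == "OR":
                i += 1
                if i >= len(tokens) or tokens[i].kind != "RES":
                    raise GrammarError("'or' must join two residues", tokens[i - 1].column)
            else:
                break
        trailing_comma = False
        if i < len(tokens) and tokens[i].kind == "COMMA":
            trailing_comma = True
            i += 1
        if i >= len(tokens) or tokens[i].kind != "RPAR":
            col = tokens[i].column if i < len(tokens) else len(text)
            raise GrammarError("unbalanced or malformed parenthesis system", col)
        i += 1
        idx = len(systems)
        if residues:
            systems.append(frozenset(residues))
        else:
            if leading_comma or trailing_comma:
                raise GrammarError(
                    "the cleavage position-system must name residues", tok.column
                )
            systems.append(WILDCARD)
        if leading_comma:
            commas.append((idx, BEFORE))
        if trailing_comma:
            commas.append((idx, AFTER))
    return _finish(systems, commas)


def _parse_bare(tokens: list[Token], text: str) -> list[RuleExpression]:
    systems: list[Optional[frozenset[str]]] = []
    commas: list[tuple[int, str]] = []
    for tok in tokens:
        if tok.kind == "OR":
            raise GrammarError(
                "ambiguous rule: 'or' requires every position to be "
                "parenthesized, e.g. (a)(c or d,)",
                tok.column,
            )
        if tok.kind == "RES":
            systems.append(frozenset(tok.value))
        elif tok.kind == "COMMA":
            if not systems:
                commas.append((0, BEFORE))
            else:
                commas.append((len(systems) - 1, AFTER))
        else:  # pragma: no cover - kinds exhausted
            raise GrammarError("unexpected token", tok.column)
    for idx, side in commas:
        if side == BEFORE and not systems:
            raise GrammarError("a comma needs an adjacent residue")
        if idx >= len(systems):
            raise GrammarError("a comma needs an adjacent residue")
    return _finish(systems, commas)


def _finish(
    systems: list[Optional[frozenset[str]]], commas: list[tuple[int, str]]
) -> list[RuleExpression]:
    if not systems:
        raise GrammarError("empty rule")
    if not commas:
        raise GrammarError("a rule must contain a comma marking the cleavage site")
    if len(commas) == 1:
        idx, side = commas[0]
        return [RuleExpression(tuple(systems), idx, side)]
    if len(commas) == 2:
        (i1, s1), (i2, s2) = commas
        if i1 == i2 and {s1, s2} == {BEFORE, AFTER}:
            # before-and-after form: expands to two independent rules
            return [
                RuleExpression(tuple(systems), i1, BEFORE),
                RuleExpression(tuple(systems), i1, AFTER),
            ]
        raise GrammarError(
            "two commas are only allowed inside the same parenthesis system"
        )
    raise GrammarError("a rule may contain at most two commas")


def parse_rule(text: str) -> list[RuleExpression]:
    """Parse one definition line into rule expressions.

    Returns a single expression, or two for the before-and-after
    (two-comma) form.  The bare, parenthesis-free form is accepted only
    when every position is a single residue.
    """
    tokens = tokenize(text)
    if not tokens:
        raise GrammarError("empty rule")
    if any(t.kind in ("LPAR", "RPAR") for t in tokens):
        return _parse_paren(tokens, text)
    return _parse_bare(tokens, text)


def format_expression(expr: RuleExpression) -> str:
    """Canonical, fully parenthesized rendering of a parsed rule."""
    parts = []
    for j, sys in enumerate(expr.systems):
        inner = "" if sys is WILDCARD else " or ".join(sorted(sys))
        if j == expr.anchor:
            inner = "," + inner if expr.side == BEFORE else inner + ","
        parts.append(f"({inner})")
    return "".join(parts)


def _context_chain(
    contexts: Sequence[tuple[int, Optional[frozenset[str]]]], decision: bool
) -> list[CleavageRule]:
    """Nest context systems into sub-rule chains.

    Every system is required; alternative residues within one system
    branch into sibling nodes sharing identical sub-chains.  Only the
    deepest node decides; intermediates are pass-through (cleave=None).
    """
    (offset, sys), rest = contexts[0], contexts[1:]
    residues: list[Optional[str]] = [None] if sys is WILDCARD else sorted(sys)
    nodes = []
    for aa in residues:
        node = CleavageRule(aa, offset, None if rest else decision)
        if rest:
            node.sub_rules = _context_chain(rest, decision)
        nodes.append(node)
    return nodes


def _build_roots(expr: RuleExpression) -> list[CleavageRule]:
    anchor_sys = expr.systems[expr.anchor]
    if anchor_sys is WILDCARD:
        raise GrammarError("the cleavage position may not be a wildcard")
    contexts = expr.offsets()
    roots = []
    for aa in sorted(anchor_sys):
        if contexts:
            root = CleavageRule(aa, 0, False, expr.side)
            root.sub_rules = _context_chain(contexts, True)
        else:
            root = CleavageRule(aa, 0, True, expr.side)
        roots.append(root)
    return roots


def _attach_exception(
    roots: list[CleavageRule], expr: RuleExpression, text: str
) -> None:
    anchor_sys = expr.systems[expr.anchor]
    if anchor_sys is WILDCARD:
        raise GrammarError("the cleavage position may not be a wildcard")
    contexts = expr.offsets()
    if not contexts:
        raise GrammarError(
            f"exception {text.strip()!r} adds no context: it would simply "
            "erase its main rule"
        )
    for aa in sorted(anchor_sys):
        targets = [r for r in roots if r.amino_acid == aa and r.side == expr.side]
        if not targets:
            raise LinkageError(
                f"orphan exception {text.strip()!r}: every exception must be "
                f"linked to a main rule (none cleaves {expr.side} {aa!r})"
            )
        for root in targets:
            root.sub_rules.extend(_context_chain(contexts, False))


def compile_enzyme(
    name: str,
    rule_texts: Iterable[tuple[str, bool]],
    default_miscleavage: float = 0.0,
    provenance: str = "builtin",
) -> Enzyme:
    """Compile definition lines into an :class:`~pepdigest.rules.Enzyme`.

    ``rule_texts`` is an ordered list of (text, is_exception); main rules
    must precede the exceptions that modify them.
    """
    roots: list[CleavageRule] = []
    definition: list[tuple[str, bool]] = []
    for text, is_exception in rule_texts:
        for expr in parse_rule(text):
            if is_exception:
                _attach_exception(roots, expr, text)
            else:
                roots.extend(_build_roots(expr))
            definition.append((format_expression(expr), is_exception))
    if not roots:
        raise GrammarError(f"enzyme {name!r} defines no main rule")
    return Enzyme(
        name,
        roots,
        default_miscleavage=default_miscleavage,
        definition=definition,
        provenance=provenance,
    )


def format_enzyme(enzyme: Enzyme) -> str:
    """Render an enzyme's definition back in grammar form, one line each."""
    lines = []
    for text, is_exception in enzyme.definition:
        tag = "EXCEPTION" if is_exception else "RULE"
        lines.append(f"{tag}: {text}")
    return "\n".join(lines)


def equivalent(
    enzyme_a: Enzyme,
    enzyme_b: Enzyme,
    alphabet: Iterable[str],
    max_len: int,
) -> bool:
    """Exhaustively test behavioural identity of two enzymes.

    Enumerates every sequence of length 1..max_len over *alphabet* and
    compares cleavage-site sets.  Intended for small alphabets/lengths
    (<= ~6 letters, length <= ~7).
    """
    letters = sorted(set(alphabet))
    for length in range(1, max_len + 1):
        for combo in itertools.product(letters, repeat=length):
            seq = "".join(combo)
            if find_sites(seq, enzyme_a) != find_sites(seq, enzyme_b):
                return False
    return True
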