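"""Enzyme catalog: built-in protease definitions plus user registration.

Built-ins live as grammar-format text files under ``pepdigest/enzymes``;
they are parsed and compiled on first access.  Users can register extra
definition files with the same format::

    # optional comments
    NAME: my-protease
    RULE: (k or r,)
    EXCEPTION: (k or r,)(p)

A file may hold several NAME blocks.  Main rules must precede the
exceptions that refine them; an exception with no matching main rule is a
linkage error reported with its file and line number.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterator

from .grammar import GrammarError, compile_enzyme, format_enzyme, parse_rule
from .rules import Enzyme

logger = logging.getLogger(__name__)


class CatalogError(KeyError):
    """Unknown enzyme name, duplicate registration, or bad definition file."""


def parse_definition_text(text: str, source: str = "<string>") -> list[Enzyme]:
    """Parse one definition file's content into compiled enzymes."""
    enzymes: list[Enzyme] = []
    name: str | None = None
    name_line = 0
    provenance = "builtin"
    lines: list[tuple[str, bool]] = []

    def flush() -> None:
        nonlocal name, lines, provenance
        if name is None:
            return
        try:
            enzymes.append(
                compile_enzyme(name, lines, provenance=provenance)
            )
        except GrammarError as exc:
            raise CatalogError(
                f"{source}, enzyme {name!r} (line {name_line}): {exc}"
            ) from exc
        name, lines, provenance = None, [], "builtin"

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition(":")
        key = key.strip().upper()
        value = value.strip()
        if key == "NAME":
            flush()
            if not value:
                raise CatalogError(f"{source}, line {lineno}: empty NAME")
            name, name_line = value.lower(), lineno
        elif key == "PROVENANCE":
            provenance = value or "builtin"
        elif key in ("RULE", "EXCEPTION"):
            if name is None:
                raise CatalogError(
                    f"{source}, line {lineno}: {key} before any NAME"
                )
            try:
                # parse eagerly so syntax errors carry the right line number
                parse_rule(value)
            except GrammarError as exc:
                raise CatalogError(f"{source}, line {lineno}: {exc}") from exc
            lines.append((value, key == "EXCEPTION"))
        else:
            raise CatalogError(
                f"{source}, line {lineno}: expected NAME/RULE/EXCEPTION, got {raw!r}"
            )
    flush()
    return enzymes


class EnzymeCatalog:
    """Built-in and user-registered enzymes, addressed case-insensitively."""

    def __init__(self, load_builtins: bool = True):
        self._builtin: dict[str, Enzyme] = {}
        self._user: dict[str, Enzyme] = {}
        if load_builtins:
            self._load_builtins()

    def _load_builtins(self) -> None:
        pkg = resources.files(__package__) / "enzymes"
        for entry in sorted(pkg.iterdir(), key=lambda e: e.name):
            if not entry.name.endswith(".txt"):
                continue
            for enzyme in parse_definition_text(
                entry.read_text(encoding="utf-8"), source=entry.name
            ):
                if enzyme.name in self._builtin:
                    raise CatalogError(
                        f"duplicate built-in enzyme {enzyme.name!r}"
                    )
                self._builtin[enzyme.name] = enzyme

    # -- lookup -------------------------------------------------------

    def names(self) -> list[str]:
        return sorted({**self._builtin, **self._user})

    def __iter__(self) -> Iterator[Enzyme]:
        for name in self.names():
            yield self.get(name)

    def __contains__(self, name: str) -> bool:
        key = name.lower()
        return key in self._builtin or key in self._user

    def get(self, name: str) -> Enzyme:
        key = name.lower()
        enzyme = self._user.get(key) or self._builtin.get(key)
        if enzyme is None:
            raise CatalogError(
                f"unknown enzyme {name!r}; available: {', '.join(self.names())}"
            )
        return enzyme

    # -- registration -------------------------------------------------

    def register(self, enzyme: Enzyme) -> None:
        if enzyme.name in self:
            raise CatalogError(f"enzyme {enzyme.name!r} already registered")
        self._user[enzyme.name] = enzyme

    def register_user_file(self, path: str | Path) -> list[str]:
        """Register every enzyme defined in *path*; returns added names."""
        path = Path(path)
        enzymes = parse_definition_text(
            path.read_text(encoding="utf-8"), source=str(path)
        )
        if not enzymes:
            logger.warning("enzyme file %s defines no enzymes", path)
            return []
        for enzyme in enzymes:
            if enzyme.provenance == "builtin":
                enzyme.provenance = "user"
        names = []
        for enzyme in enzymes:
            self.register(enzyme)
            names.append(enzyme.name)
        return names

    def register_user_dir(self, path: str | Path) -> list[str]:
        """Register every ``*.txt`` definition file under *path*."""
        path = Path(path)
        if not path.is_dir():
            raise CatalogError(f"{path} is not a directory")
        names = []
        for entry in sorted(path.glob("*.txt")):
            names.extend(self.register_user_file(entry))
        return names

    def describe(self, name: str) -> str:
        enzyme = self.get(name)
        return f"{enzyme.name}:\n{format_enzyme(enzyme)}"


_default: EnzymeCatalog | None = None


def default_catalog() -> EnzymeCatalog:
    """The shared catalog of built-in enzymes (loaded once per process)."""
    global _default
    if _default is None:
        _default = EnzymeCatalog()
    return _default


def load_builtin(name: str) -> Enzyme:
    """Fetch one built-in enzyme by (case-insensitive) name."""
    return default_catalog().get(name)
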