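"""Synthetic protein generator with planted cleavage motifs.

Random test proteins are built from a *neutral* background alphabet
(a, s, t, v, i - residues that do not trigger, or complete the context
of, any planted motif) with known motifs inserted at recorded positions,
separated by at least one background residue so adjacent motifs cannot
create unplanned sites.  The sidecar manifest makes expected site counts
computable without re-deriving them from the engine under test.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

#: Background residues: inert for every default motif below.
BACKGROUND = "astvi"

#: Motifs exercising the different engine paths: full-context cleavage
#: (lvprgs), context-dependent trypsin behaviour (wkp vs kp), simple
#: P1/P1' pairs (ng), and the e-run handled by glutamate-specific rules.
DEFAULT_MOTIFS = ("lvprgs", "wkp", "kp", "ng", "ee")


@dataclass(frozen=True)
class PlantedMotif:
    motif: str
    start: int  # 0-based position in the record's sequence


@dataclass
class FixtureRecord:
    id: str
    sequence: str
    planted: list[PlantedMotif] = field(default_factory=list)

    def count(self, motif: str) -> int:
        return sum(1 for p in self.planted if p.motif == motif)


def generate_fixtures(
    seed: int,
    n_records: int = 10,
    length_range: tuple[int, int] = (50, 200),
    motifs: tuple[str, ...] = DEFAULT_MOTIFS,
    motif_rate: float = 0.08,
) -> list[FixtureRecord]:
    """Deterministically generate records with planted motifs.

    ``motif_rate`` is the per-position chance of starting a motif instead
    of a background residue.  Record lengths fall inside ``length_range``
    (motif insertion may not overshoot the upper bound: motifs are only
    started while they still fit).
    """
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length range")
    rng = random.Random(seed)
    records = []
    for i in range(n_records):
        target = rng.randint(lo, hi)
        parts: list[str] = []
        planted: list[PlantedMotif] = []
        pos = 0
        last_was_motif = False
        while pos < target:
            motif = None
            if not last_was_motif and rng.random() < motif_rate:
                candidate = rng.choice(motifs)
                if pos + len(candidate) + 1 <= target:
                    motif = candidate
            if motif is not None:
                planted.append(PlantedMotif(motif, pos))
                parts.append(motif)
                pos += len(motif)
                last_was_motif = True  # force a background spacer next
            else:
                parts.append(rng.choice(BACKGROUND))
                pos += 1
                last_was_motif = False
        records.append(FixtureRecord(f"synth_{seed}_{i}", "".join(parts), planted))
    return records


def to_fasta(records: list[FixtureRecord]) -> str:
    """Render fixture records as multi-FASTA text (uppercase residues)."""
    return "".join(f">{r.id}\n{r.sequence.upper()}\n" for r in records)
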