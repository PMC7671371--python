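"""Digestion of protein sequences by one or more proteases.

Two modes are provided.  *Sequential* digestion runs each enzyme
independently over the intact protein, as if each were a separate
experiment.  *Concurrent* digestion simulates all enzymes acting together
for an unlimited time: fragments produced by one enzyme are re-examined by
every enzyme, so a cut can expose sites that were blocked by context in
the intact protein (context beyond a fragment boundary is invisible).
Concurrent digestion is a fixed-point iteration over a FIFO worklist of
fragments and, with 0% miscleavage, terminates because every cut strictly
shortens its fragment.

Miscleavage is a per-site Bernoulli event: each detected site survives
with probability ``miscleavage_pct/100`` (one uniform draw per site, in
left-to-right order, from the job's seeded generator).
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .physchem import DEFAULT_PKA_SET, isoelectric_point, peptide_mass
from .rules import Enzyme, find_sites

SEQUENTIAL = "sequential"
CONCURRENT = "concurrent"


@dataclass(frozen=True)
class Peptide:
    """One product of a digestion.

    ``cleavage_position`` is the 1-based bond index in the *parent*
    sequence at the peptide's C-terminal end (equivalently the 1-based
    position of the P1 residue); the final peptide of a digestion reports
    0, marking the sequence end.
    """

    parent_id: str
    enzyme_name: str
    ordinal: int  # 1-based peptide number within its digestion
    cleavage_position: int
    sequence: str
    mass: float
    pI: float

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class DigestJob:
    """Everything needed to run a digestion reproducibly."""

    enzymes: Sequence[Enzyme]
    mode: str = SEQUENTIAL
    miscleavage: Mapping[str, float] = field(default_factory=dict)
    seed: int | None = None
    pka_set: str = DEFAULT_PKA_SET

    def __post_init__(self) -> None:
        if self.mode not in (SEQUENTIAL, CONCURRENT):
            raise ValueError(f"mode must be '{SEQUENTIAL}' or '{CONCURRENT}'")
        if not self.enzymes:
            raise ValueError("a digestion needs at least one enzyme")
        names = {e.name for e in self.enzymes}
        for name, pct in self.miscleavage.items():
            if name not in names:
                raise ValueError(f"miscleavage given for unselected enzyme {name!r}")
            if not 0.0 <= pct <= 100.0:
                raise ValueError("miscleavage percentage must be in [0, 100]")

    def rng(self) -> random.Random:
        return random.Random(self.seed)

    def pct(self, enzyme: Enzyme) -> float:
        return self.miscleavage.get(enzyme.name, enzyme.default_miscleavage)


def _as_record(record) -> tuple[str, str]:
    if isinstance(record, tuple):
        return record
    return record.id, record.sequence


def _assemble(
    parent_id: str,
    enzyme_name: str,
    sequence: str,
    cut_bonds: Sequence[int],
    pka_set: str,
) -> list[Peptide]:
    """Split at 1-based bond indices and annotate the products."""
    bounds = [0, *cut_bonds, len(sequence)]
    peptides = []
    for ordinal, (start, end) in enumerate(zip(bounds, bounds[1:]), start=1):
        pep = sequence[start:end]
        peptides.append(
            Peptide(
                parent_id=parent_id,
                enzyme_name=enzyme_name,
                ordinal=ordinal,
                cleavage_position=end if end < len(sequence) else 0,
                sequence=pep,
                mass=peptide_mass(pep),
                pI=isoelectric_point(pep, pka_set),
            )
        )
    return peptides


def _keep_site(rng: random.Random | None, pct: float) -> bool:
    if pct <= 0.0:
        return True
    if rng is None:
        raise ValueError("miscleavage sampling requires a random generator")
    return rng.uniform(0.0, 100.0) >= pct


def digest_one(
    sequence: str,
    enzyme: Enzyme,
    miscleavage_pct: float = 0.0,
    rng: random.Random | None = None,
    parent_id: str = "sequence",
    pka_set: str = DEFAULT_PKA_SET,
) -> list[Peptide]:
    """Digest one sequence with one enzyme on the intact protein.

    Sites are detected on the full sequence (context is never truncated),
    then each site is kept or dropped by the miscleavage draw, left to
    right; the final peptide always runs to the sequence end.
    """
    if not 0.0 <= miscleavage_pct <= 100.0:
        raise ValueError("miscleavage percentage must be in [0, 100]")
    sites = find_sites(sequence, enzyme)
    kept = [s for s in sites if _keep_site(rng, miscleavage_pct)]
    return _assemble(parent_id, enzyme.name, sequence, kept, pka_set)


def digest_sequential(records: Iterable, job: DigestJob) -> Iterator[Peptide]:
    """Independent digestion of every record by every enzyme.

    Yields peptides record-major, enzymes in the order given; identical to
    running each enzyme in its own job (with its own slice of the random
    stream).
    """
    rng = job.rng()
    empty = True
    for record in records:
        empty = False
        yield from digest_record(record, job, rng)
    if empty:
        raise ValueError("no input records")


def _concurrent_bonds(
    sequence: str,
    start: int,
    end: int,
    enzymes: Sequence[Enzyme],
) -> dict[int, list[Enzyme]]:
    """Union of all enzymes' sites on the fragment, in parent coordinates,
    with the enzymes proposing each bond (in enzyme order)."""
    fragment = sequence[start:end]
    proposals: dict[int, list[Enzyme]] = {}
    for enzyme in enzymes:
        for site in find_sites(fragment, enzyme):
            proposals.setdefault(start + site, []).append(enzyme)
    return proposals


def _concurrent_record(
    parent_id: str, sequence: str, job: DigestJob, rng: random.Random
) -> list[Peptide]:
    label = "+".join(e.name for e in job.enzymes)
    finals: list[tuple[int, int]] = []
    work: deque[tuple[int, int, frozenset[int]]] = deque(
        [(0, len(sequence), frozenset())]
    )
    while work:
        start, end, rejected = work.popleft()
        proposals = _concurrent_bonds(sequence, start, end, job.enzymes)
        kept: list[int] = []
        newly_rejected: set[int] = set()
        for bond in sorted(proposals):
            if bond in rejected:
                continue
            if any(_keep_site(rng, job.pct(e)) for e in proposals[bond]):
                kept.append(bond)
            else:
                newly_rejected.add(bond)
        if not kept:
            finals.append((start, end))
            continue
        lineage = rejected | frozenset(newly_rejected)
        for lo, hi in zip([start, *kept], [*kept, end]):
            work.append((lo, hi, lineage))
    finals.sort()
    peptides = []
    for ordinal, (start, end) in enumerate(finals, start=1):
        pep = sequence[start:end]
        peptides.append(
            Peptide(
                parent_id=parent_id,
                enzyme_name=label,
                ordinal=ordinal,
                cleavage_position=end if end < len(sequence) else 0,
                sequence=pep,
                mass=peptide_mass(pep),
                pI=isoelectric_point(pep, job.pka_set),
            )
        )
    return peptides


def digest_record(
    record, job: DigestJob, rng: random.Random | None = None
) -> list[Peptide]:
    """Digest a single record according to the job's mode.

    Callers digesting many records should pass one shared *rng* so the
    random stream is continuous across records (the job-level entry
    points do this automatically).
    """
    if rng is None:
        rng = job.rng()
    parent_id, sequence = _as_record(record)
    if job.mode == CONCURRENT:
        return _concurrent_record(parent_id, sequence, job, rng)
    peptides = []
    for enzyme in job.enzymes:
        peptides.extend(
            digest_one(
                sequence,
                enzyme,
                miscleavage_pct=job.pct(enzyme),
                rng=rng,
                parent_id=parent_id,
                pka_set=job.pka_set,
            )
        )
    return peptides


def digest_concurrent(records: Iterable, job: DigestJob) -> Iterator[Peptide]:
    """All enzymes digesting together until no fragment can be cut.

    Fragments are processed from a FIFO worklist; each fragment is scanned
    by every enzyme *as a free peptide*, so blocking context beyond a
    fragment boundary no longer applies.  A site rejected by miscleavage
    is remembered along the fragment's lineage and not re-drawn for its
    descendants (newly exposed sites are still drawn fresh); this keeps
    the iteration terminating and the output deterministic under a seed.
    Peptides are reported sorted by their start in the parent sequence.
    """
    rng = job.rng()
    empty = True
    for record in records:
        empty = False
        parent_id, sequence = _as_record(record)
        yield from _concurrent_record(parent_id, sequence, job, rng)
    if empty:
        raise ValueError("no input records")


def digest(records: Iterable, job: DigestJob) -> Iterator[Peptide]:
    """Dispatch on the job's mode."""
    if job.mode == CONCURRENT:
        return digest_concurrent(records, job)
    return digest_sequential(records, job)


@dataclass(frozen=True)
class SizeRangeSummary:
    """Peptides and residues inside an inclusive mass window."""

    count: int
    fraction: float
    residues: int
    residue_fraction: float
    total_peptides: int
    total_residues: int


def size_range_summary(
    peptides: Iterable[Peptide], lo_da: float = 600.0, hi_da: float = 5000.0
) -> SizeRangeSummary:
    """Count peptides with lo <= mass <= hi and the residues they contain.

    The default window is the 600-5000 Da range commonly quoted as optimal
    for bottom-up MS/MS.
    """
    if lo_da > hi_da:
        raise ValueError("size range: lower bound exceeds upper bound")
    count = residues = total = total_residues = 0
    for pep in peptides:
        total += 1
        total_residues += pep.length
        if lo_da <= pep.mass <= hi_da:
            count += 1
            residues += pep.length
    return SizeRangeSummary(
        count=count,
        fraction=count / total if total else 0.0,
        residues=residues,
        residue_fraction=residues / total_residues if total_residues else 0.0,
        total_peptides=total,
        total_residues=total_residues,
    )
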