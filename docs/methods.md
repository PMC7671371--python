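# Methods

## Cleavage-rule model

A protease is a list of rule trees. Every node holds a residue (or a
wildcard), a signed offset relative to the anchor position (0 = anchor,
−1 one residue N-terminal, +1 C-terminal), an optional cleave/no-cleave
decision, and child nodes. Root nodes are anchored at offset 0 on a
concrete residue and carry the side of the scissile bond (`after`: the
bond follows the anchor, P1 convention; `before`: it precedes it, P1').
Sub-rules inherit the root's side; their own side is irrelevant.

At a sequence position whose residue equals a root's anchor, the tree is
walked. A node *matches* when `pos + offset` lies inside the sequence and
the residue there equals the node's residue (wildcards match anything in
bounds; out-of-bounds offsets never match — this is what lets concurrent
digestion free sites near fragment ends). Along fully matched paths every
decisive node votes, and the vote of the **deepest matched decisive node
wins**; if equally deep matched nodes disagree, no-cleave wins. The root
is always decisive; context chain nodes in the middle of a required
context carry no decision (`cleave=None`) so a partially matched chain
cannot override anything. An enzyme cleaves a bond when at least one of
its roots resolves to cleave there; distinct roots are independent and
their cleaving bonds are unioned.

The deepest-match rule is the package's resolution of rule/exception
conflicts, chosen over declaration-order or blanket "exceptions always
win" schemes for one concrete reason: trypsin. Its `(k or r,)(p)`
exception attaches to *every* k- and r-anchored root, including the
`(w)(k,)(p)` rule that re-enables cleavage inside the `wkp` motif. Only
specificity ordering lets the deeper, more specific `wkp` context
override the shallower proline block while the block still wins elsewhere;
the tie-break to no-cleave keeps genuinely ambiguous definitions
conservative. A corollary for rule authors: an exception that must
override a rule with required context (e.g. thrombin's acidic-P1'
exclusion against its four-position hydrophobic rule) has to repeat that
context so that its chain is at least as deep — the shipped catalog
definitions do this.

Bonds are indexed 1..len−1 between residues; bonds at 0 or len are
suppressed, so every peptide has at least one residue and digestion of a
sequence always reconstructs it by concatenation.

## Grammar and compilation

Definitions are one rule per line. Each parenthesis system is one
Schechter–Berger position; `or` lists alternatives within a system and is
evaluated before the comma, which marks the bond (leading comma = cleave
before the system's residue, trailing = after; both commas in one system
expand into the two corresponding rules). The bare form (`n,g`) is only
accepted when every position is a single residue; any `or` without full
parenthesization is rejected as ambiguous. An empty system `()` is a
wildcard position.

Compilation emits one root per residue of the comma system. Context
systems become chains of sub-rules ordered nearest-first (N-side, then
C-side); multi-residue systems branch into sibling alternatives with
copies of the remaining chain. For a plain rule the root carries
cleave=True; with required context the root carries False and only the
deepest chain node True. Exception lines compile the same way with the
deepest node False and attach to every previously defined root whose
anchor residue and side match; an exception with no such root is a
linkage error, as is an exception with no context at all (it would merely
erase its main rule).

Definition files (`NAME:` / `RULE:` / `EXCEPTION:` lines, `#` comments,
optional `PROVENANCE:`) are this package's own format; the grammar
proper has no way to mark a line as an exception, so the file format
makes it explicit. Exceptions nested under exceptions are expressible to
the engine but not the file format. The catalog ships the enzymes whose
rules are fully documented plus the classical PeptideCutter set; entries
transcribed from PeptideCutter's published specificity tables are marked
`provenance: external` in the files. Ficin has no published rule set in
either source and is omitted.

## Mass, charge and isoelectric point

Residue masses are the ExPASy average masses for the 22 proteinogenic
amino acids (including pyrrolysine and selenocysteine); a peptide's mass
adds one water, 18.01528 Da (average mass; hydrolysis leaves H/OH at the
new termini). Masses are computed at full float precision and displayed
to four decimals; consequently splitting a protein into k peptides adds
exactly (k−1) waters, which the tests assert to 1e−6 Da. Ambiguity codes
(B, Z, X, J), `*` and gaps are rejected up front rather than silently
producing wrong masses.

Net charge at a pH is compositional: one term per terminus plus one per
ionizable side chain (C, D, E, H, K, R, Y), positive groups contributing
1/(1+10^(pH−pKa)) and negative ones −1/(1+10^(pKa−pH)). Side-chain pKa
values are not perturbed near termini. Two pKa sets are built in: the
peptide-calibrated IPC set (default) and textbook values. The pI is
located by bisection from the midpoint pH 7 until the bracket is narrower
than 0.01, and reported to two decimals. Since each term is strictly
decreasing in pH and every peptide has both termini, the root is unique
and bracketed in (0, 14) for both sets. Against an independent dense grid
search (step 0.001, vectorized) the bisection agrees within 0.01 on 1000
random peptides; two implementations can legitimately differ by one 0.01
step on either side of the root.

## Digestion

**Sequential** mode digests the intact protein with each enzyme
independently; sites are found on the full sequence (context is never
truncated by earlier cuts), then each site survives an optional
miscleavage draw (uniform on [0,100), kept when the draw is at least the
percentage), left to right, from a single seeded generator per job.
Output is record-major with enzymes in the given order, so a multi-record
job equals the concatenation of single-record jobs.

**Concurrent** mode iterates to a fixed point over a FIFO worklist of
fragments (tracked as parent-coordinate spans). Each fragment is scanned
by every enzyme *as a free peptide* — context beyond the fragment
boundary is invisible, which is exactly what lets one enzyme's cut expose
another's blocked site. All kept bonds split the fragment and the pieces
re-enter the worklist; a fragment with no kept bond is final. With 0%
miscleavage every cut strictly shortens a fragment, so termination is
structural. With miscleavage, a site rejected once is remembered along
the fragment's lineage and not re-drawn for descendants (freshly exposed
sites still get their own draw); this keeps the procedure terminating and
seed-deterministic, at the cost of being one heuristic among several
defensible readings of "infinite time with random misses". When several
enzymes propose the same bond, each proposer draws in enzyme order until
one keeps it. Final peptides are reported sorted by start coordinate,
labelled with the joined enzyme names, since no single enzyme owns a
concurrent product.

Peptides carry a 1-based ordinal, and `cleavage_position` is the 1-based
parent-sequence position of the P1 residue of the cut that ends the
peptide; the final peptide reports 0 to mark the sequence end. The engine
itself is 0-based with half-open spans; the conversion lives in the
assembly step only.

## Synthetic data

The fixture generator builds proteins from an inert background alphabet
(a, s, t, v, i — residues that neither trigger nor complete the context
of any planted motif) and inserts known motifs (`lvprgs`, `wkp`, `kp`,
`ng`, `ee`) at recorded positions, always separated by at least one
background residue. Expected site counts are therefore computable from
the manifest alone: hydroxylamine sites equal planted `ng` counts,
trypsin sites equal planted `wkp` plus `lvprgs` counts, and plain `kp`
plants exercise the proline block without adding sites. Default sizes —
10 records of 50–200 residues, motif start probability 0.08 per position —
give a few dozen sites per record set, enough for exact-count assertions.
What these fixtures deliberately lack: realistic residue composition
(background is 5 letters), homology structure, and any notion of
real-protein cleavage density. Passing tests therefore demonstrate engine
correctness, not biological realism of any particular enzyme definition;
the latter rests on the transcribed specificity tables and on the
full-protein peptide-count benchmark.

The miscleavage statistic uses a purpose-built sequence (`a` + `nga`×200:
exactly 200 sites) at 20% miscleavage over 10 000 trials and checks the
kept-site total against Binomial(2 000 000, 0.8) within 4σ.

## Validation sizes and numerical choices

Exhaustive oracle checks enumerate all sequences up to length 6 over
5-letter per-enzyme alphabets (length 5 for larger alphabets), comparing
compiled rules against independently hand-written predicates; the
compact/expanded trypsin equivalence runs over two 6-letter alphabets at
length 6 (111 972 sequences). The pI oracle uses 1000 random peptides of
length ≤ 35. A 35 991-residue digestion runs in well under a second per
enzyme, so whole-proteome screens are practical. All randomness flows
from explicit seeds; identical seeds give byte-identical output files.

## Limitations

Cleavage is sequence-only: no solvent accessibility, pH, temperature,
enzyme concentration or kinetics; miscleavage is a per-site Bernoulli
event, not a time course. No post-translational or digestion-induced
modifications are modelled beyond the water of hydrolysis, and masses are
averages, not monoisotopic. Isoelectric points from fixed pKa values are
approximations — good for short peptides, rougher for whole proteins.
Concurrent-mode miscleavage is heuristic as described above. Catalog
entries marked `external` reproduce published specificity tables and can
drift from vendor-specific "sequencing grade" behaviour; only the
documented sequencing-grade thrombin is included as such.
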