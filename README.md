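# pepdigest

In silico digestion of protein sequences by sequence-specific proteases,
for bottom-up proteomics planning: predict cleavage sites, generate the
resulting peptides, and annotate each with its length, average molecular
mass and isoelectric point (pI).

Choosing proteases for an MS/MS experiment is expensive to do empirically:
each enzyme (trypsin, pepsin, thrombin, chemical agents such as CNBr...)
cuts at different sequence motifs, and only peptides in roughly the
600–5000 Da window ionize and fragment well. `pepdigest` simulates the
digestion so that protease combinations can be screened on whole protein
families before any wet-lab work.

## The model

A protease is a list of *cleavage rules* in Schechter–Berger notation:
residues N-terminal of the scissile bond are P1, P2, ... and C-terminal
P1', P2', ...; the enzyme cuts between P1 and P1'. Each rule is a
recursive tree: a root anchored on one residue, with sub-rules testing
neighbouring positions that refine the cleave/no-cleave decision (required
context, or exceptions that block). At every position of a sequence the
most specific matching context decides; on a tie, no-cleave wins. Bonds at
the sequence ends are suppressed, so no empty peptides arise.

Rules are written in a small grammar: `(n,)(g)` cuts between n (P1) and
g (P1'); `(k or a or y,)` cuts after any of k/a/y; `(,f or l,)` cuts
before *and* after; `()` is a wildcard position; exception lines block
cleavage (e.g. trypsin's `(k or r,)(p)`). A built-in catalog covers the
classical proteases; new ones are registered from plain-text files.

For every peptide the package reports its average molecular mass (sum of
ExPASy residue masses plus one water, since hydrolysis adds H to the new
N-terminus and OH to the C-terminus) and its pI, the root of the
compositional Henderson–Hasselbalch charge model

    Z(pH) = Σ_pos 1/(1+10^(pH−pKa))  −  Σ_neg 1/(1+10^(pKa−pH))

found by bisection on [0, 14] to 0.01 pH units, with a peptide-calibrated
pKa set (`ipc_peptide`, default) or textbook values (`typical`).

Two digestion modes are provided: **sequential** (each enzyme digests the
intact protein independently — N separate experiments) and **concurrent**
(all enzymes act together indefinitely; a cut by one enzyme can expose
sites whose blocking context the fragmentation removed). Miscleavage is a
per-site Bernoulli event with a per-enzyme probability.

## Worked example

```
$ cat demo.fasta
>demo insulin-like test
LVPRGSAEERTWKPANG
$ pepdigest -i demo.fasta -e trypsin,hydroxylamine --fmt csv -o demo.csv
INFO: demo: 6 peptide(s)
$ cat demo.csv
parent_id,enzyme,ordinal,cleavage_position,length,mass,pI,sequence
demo,trypsin,1,4,4,483.6115,11.04,LVPR
demo,trypsin,2,10,6,647.6427,4.32,GSAEER
demo,trypsin,3,13,3,433.5077,10.04,TWK
demo,trypsin,4,0,4,357.3665,5.97,PANG
demo,hydroxylamine,1,16,16,1811.0306,10.03,LVPRGSAEERTWKPAN
demo,hydroxylamine,2,0,1,75.0672,5.97,G
```

Trypsin cuts after r and k — including after the k of the `WKP` motif,
where w in P2 overrides the usual proline block (`TWK` | `PANG`), but not
at an ordinary `KP` bond. Hydroxylamine cuts only between n and g.
`cleavage_position` is the 1-based position of the P1 residue in the
parent (0 marks the final peptide); masses are averages in Da to four
decimals, pI to two. Library use mirrors the CLI:

```python
from pepdigest import DigestJob, digest_sequential, load_builtin
job = DigestJob([load_builtin("trypsin")])
peptides = list(digest_sequential([("demo", "lvprgsaeertwkpang")], job))
```

`pepdigest --list-enzymes` prints every definition in grammar form;
`--enzyme-file`/`--enzyme-dir` register user proteases; `--mode
concurrent`, `--miscleavage NAME=PCT` and `--seed` control the digestion.

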