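# Proteases and chemical cleavage agents transcribed from PeptideCutter's
# published specificity tables.  provenance: external.

NAME: arg-c
PROVENANCE: external
RULE: (r,)

NAME: asp-n-pepc
# PeptideCutter's Asp-N: before d only (asp-n also accepts c).
PROVENANCE: external
RULE: (,d)

NAME: asp-n-glu-n
# Asp-N endopeptidase plus N-terminal glutamate cleavage.
PROVENANCE: external
RULE: (,d)
RULE: (e,)

NAME: bnps-skatole
PROVENANCE: external
RULE: (w,)

NAME: cnbr
# Cyanogen bromide: after methionine.
PROVENANCE: external
RULE: (m,)

NAME: clostripain
PROVENANCE: external
RULE: (r,)

NAME: enterokinase-pepc
# PeptideCutter ignores P5 and beyond: three acidic positions only.
PROVENANCE: external
RULE: (d or e)(d or e)(d or e)(k,)

NAME: factor-xa
PROVENANCE: external
RULE: (a or f or g or i or l or t or v or w)(d or e)(g)(r,)

NAME: formic-acid
PROVENANCE: external
RULE: (d,)

NAME: glu-c
PROVENANCE: external
RULE: (d or e,)

NAME: glutamyl-endopeptidase
PROVENANCE: external
RULE: (e,)

NAME: granzyme-b
PROVENANCE: external
RULE: (i)(e)(p)(d,)

NAME: iodosobenzoic-acid
PROVENANCE: external
RULE: (w,)

NAME: ntcb
# 2-nitro-5-thiocyanobenzoic acid: before cysteine.
PROVENANCE: external
RULE: (,c)

NAME: neutrophil-elastase
PROVENANCE: external
RULE: (a or v,)

NAME: papain
PROVENANCE: external
RULE: (a or f or i or l or v or w or y)(k or r,)
EXCEPTION: (a or f or i or l or v or w or y)(k or r,)(v)

NAME: proline-endopeptidase
PROVENANCE: external
RULE: (h or k or r)(p,)
EXCEPTION: (h or k or r)(p,)(p)

NAME: proteinase-k
PROVENANCE: external
RULE: (a or e or f or i or l or t or v or w or y,)

NAME: chymotrypsin-low
# Low specificity: after f/l/y/w/m/h with residue-specific blockers.
PROVENANCE: external
RULE: (f or l or y or w or m or h,)
EXCEPTION: (f or l or y or w or m or h,)(p)
EXCEPTION: (w,)(m)
EXCEPTION: (m,)(y)
EXCEPTION: (h,)(d or m or w)

NAME: pepsin-ph1.3
# Before or after f/l; blocked by p in P2/P1'/P2', r in P1, h/k/r in P3.
PROVENANCE: external
RULE: (,f or l)
EXCEPTION: (,f or l)(p)
EXCEPTION: (r)(,f or l)
EXCEPTION: (p)()(,f or l)
EXCEPTION: (h or k or r)()()(,f or l)
RULE: (f or l,)
EXCEPTION: (f or l,)()(p)
EXCEPTION: (p)(f or l,)
EXCEPTION: (h or k or r)()(f or l,)

NAME: pepsin-ph2
# As pepsin-ph1.3 with the aromatic w/y also accepted (pH > 2).
PROVENANCE: external
RULE: (,f or l or w or y)
EXCEPTION: (,f or l or w or y)(p)
EXCEPTION: (r)(,f or l or w or y)
EXCEPTION: (p)()(,f or l or w or y)
EXCEPTION: (h or k or r)()()(,f or l or w or y)
RULE: (f or l or w or y,)
EXCEPTION: (f or l or w or y,)()(p)
EXCEPTION: (p)(f or l or w or y,)
EXCEPTION: (h or k or r)()(f or l or w or y,)

NAME: thermolysin
# Before a/f/i/l/m/v, unless preceded by d/e or followed by p.
PROVENANCE: external
RULE: (,a or f or i or l or m or v)
EXCEPTION: (d or e)(,a or f or i or l or m or v)
EXCEPTION: (,a or f or i or l or m or v)(p)

NAME: thrombin
# gr|g, or hydrophobic P4/P3 with p in P2, r in P1 and no acidic P1'/P2'.
PROVENANCE: external
RULE: (g)(r,)(g)
RULE: (a or f or g or i or l or t or v or w)(a or f or g or i or l or t or v or w)(p)(r,)
EXCEPTION: (a or f or g or i or l or t or v or w)(a or f or g or i or l or t or v or w)(p)(r,)(d or e)
EXCEPTION: (a or f or g or i or l or t or v or w)(a or f or g or i or l or t or v or w)(p)(r,)()(d or e)

NAME: tev-pepc
# PeptideCutter's truncated recognition (P5 and beyond ignored).
PROVENANCE: external
RULE: (y)()(q,)(g or s)
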