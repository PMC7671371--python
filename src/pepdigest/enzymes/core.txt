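# Core protease definitions, written in the pepdigest rule grammar.
# One NAME block per enzyme; RULE lines trigger cleavage, EXCEPTION lines
# block it and must follow the main rule they refine.

NAME: trypsin
# Cleaves after k or r; p in P1' usually blocks, except in the wkp motif
# (and mrp for r).  Several P2/P1' combinations also block.
RULE: (k or r,)
RULE: (w)(k,)(p)
RULE: (m)(r,)(p)
EXCEPTION: (k or r,)(p)
EXCEPTION: (d)(k,)(d)
EXCEPTION: (c)(k,)(d or h or y)
EXCEPTION: (r)(r,)(h or r)
EXCEPTION: (c)(r,)(k)

NAME: trypsin-expanded
# Fully expanded formulation of trypsin (no 'or' merging); behaviourally
# identical to 'trypsin' - kept for grammar-equivalence validation.
RULE: (k,)
RULE: (r,)
RULE: (w)(k,)(p)
RULE: (m)(r,)(p)
EXCEPTION: (k,)(p)
EXCEPTION: (r,)(p)
EXCEPTION: (d)(k,)(d)
EXCEPTION: (c)(k,)(d)
EXCEPTION: (c)(k,)(h)
EXCEPTION: (c)(k,)(y)
EXCEPTION: (r)(r,)(h)
EXCEPTION: (c)(r,)(k)
EXCEPTION: (r)(r,)(r)

NAME: staphylococcal-peptidase-i
# After e, unless preceded by another e (e|e still cleaves).
RULE: (e,)
EXCEPTION: (e)(e,)

NAME: hydroxylamine
# Chemical cleavage between n and g.
RULE: (n,)(g)

NAME: thrombin-sg
# Sequencing-grade thrombin: cleaves only the full lvpr|gs motif.
RULE: (l)(v)(p)(r,)(g)(s)

NAME: chymotrypsin-high
# High specificity: after f, y or w, not before p; w also not before m.
RULE: (f or y or w,)
EXCEPTION: (f or y or w,)(p)
EXCEPTION: (w,)(m)

NAME: bromelain
RULE: (k or a or y,)

NAME: pepsin-simplified
# Around f/l/w/y, both sides; the real pepsins carry many exceptions
# (see pepsin-ph1.3 and pepsin-ph2).
RULE: (,f or l or w or y,)

NAME: enterokinase
# Full-length recognition: four acidic positions before the k.
RULE: (d or e)(d or e)(d or e)(d or e)(k,)

NAME: tev
# Tobacco etch virus protease, full e-x-x-y-x-q|(g/s) recognition.
RULE: (e)()()(y)()(q,)(g or s)

NAME: asp-n
# Before d or c.
RULE: (,d or c)

NAME: lys-n
RULE: (,k)

NAME: lys-c
RULE: (k,)
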