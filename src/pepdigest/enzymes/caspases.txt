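# Caspase family, transcribed from PeptideCutter's specificity tables.
# All cleave after the d of a tetrapeptide motif; most are additionally
# blocked by p/e/d/q/k/r in P1'.  provenance: external.

NAME: caspase-1
PROVENANCE: external
RULE: (f or l or w or y)()(h or a or t)(d,)
EXCEPTION: (f or l or w or y)()(h or a or t)(d,)(p or e or d or q or k or r)

NAME: caspase-2
PROVENANCE: external
RULE: (d)(v)(a)(d,)
RULE: (d)(e)(h)(d,)
EXCEPTION: (d)(v)(a)(d,)(p or e or d or q or k or r)
EXCEPTION: (d)(e)(h)(d,)(p or e or d or q or k or r)

NAME: caspase-3
PROVENANCE: external
RULE: (d)(e)(v)(d,)
RULE: (d)(m)(q)(d,)
EXCEPTION: (d)(e)(v)(d,)(p or e or d or q or k or r)
EXCEPTION: (d)(m)(q)(d,)(p or e or d or q or k or r)

NAME: caspase-4
PROVENANCE: external
RULE: (l)(e)(v)(d,)
RULE: (l or w)(e)(h)(d,)
EXCEPTION: (l)(e)(v)(d,)(p or e or d or q or k or r)
EXCEPTION: (l or w)(e)(h)(d,)(p or e or d or q or k or r)

NAME: caspase-5
PROVENANCE: external
RULE: (l or w)(e)(h)(d,)

NAME: caspase-6
PROVENANCE: external
RULE: (v)(e)(h or i)(d,)
EXCEPTION: (v)(e)(h or i)(d,)(p or e or d or q or k or r)

NAME: caspase-7
PROVENANCE: external
RULE: (d)(e)(v)(d,)
EXCEPTION: (d)(e)(v)(d,)(p or e or d or q or k or r)

NAME: caspase-8
PROVENANCE: external
RULE: (i or l)(e)(t)(d,)
EXCEPTION: (i or l)(e)(t)(d,)(p or e or d or q or k or r)

NAME: caspase-9
PROVENANCE: external
RULE: (l)(e)(h)(d,)

NAME: caspase-10
PROVENANCE: external
RULE: (i)(e)(a)(d,)
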