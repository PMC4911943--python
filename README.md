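# taxalign

RCC-5 alignment of taxonomic concept hierarchies.

## The problem

Classifications change between treatments: species are split after
reassessment, new species are described from newly collected material,
genera are lumped, names move. Because the Linnaean name alone does not say
*which circumscription* an author meant, integrating data across two
editions of a standard requires aligning *taxonomic concepts* — a name as
used according to a specific source ("name sec. author") — rather than bare
names. `taxalign` is for systematists and biodiversity informaticians who
need that alignment to be logically explicit and machine-readable.

Each taxonomy is a rooted forest of concepts linked by parent/child
(*is_a*) edges. An expert articulates selected cross-taxonomy concept pairs
with the five RCC-5 relations on nonempty regions —

| symbol | reading |
| --- | --- |
| `==` | congruence |
| `>`  | proper inclusion |
| `<`  | inverse proper inclusion |
| `><` | overlap |
| `!`  | exclusion (`\|` accepted on input) |

— possibly as a disjunction when uncertain (`{== >}`). Three global
constraints apply: **nonemptiness** (every concept denotes something),
**sibling disjointness** (children of one parent are mutually exclusive)
and **coverage** (a parent is exactly the union of its children, so a
monotypic parent is congruent with its only child). Given taxonomies T2
(later) and T1 (earlier) plus articulations A, the reasoner decides whether
the constraints are consistent, enumerates the *possible worlds* (globally
consistent assignments of one base relation to every cross-taxonomy pair),
and derives the **Maximally Informative Relations (MIR)**: for each of the
|C2| × |C1| cross pairs, the set of base relations realized in at least one
world. Merge graphs visualize the result; metrics
quantify how reliably names track meanings.

## Worked example

The shipped mouse-lemur fixture aligns *Microcebus*/*Mirza* sec. 2005 (11
concepts) against *Microcebus* sec. 1993 (4 concepts) with nine input
articulations:

```sh
taxalign simulate --preset fig1 -o fig1
taxalign align fig1/alignment.txt --ranks fig1/ranks.tsv -o out
```

prints

```
consistent: 2 possible world(s)
MIR cells: 44 (1 ambiguous)
input articulations: 9
information expression ratio: 4.9x
relative congruence: 75.0%
reliable names: 1
unreliable names: 3
reliability ratio: 1 : 3.0
```

Nine input statements expand to 44 machine-readable MIR rows (`out/mir.csv`),
a 4.9× information expression. Two worlds exist because nothing says whether
the three narrowed 2005 concepts exhaust the earlier *M. murinus*: the single
ambiguous cell is `2005.Microcebus {> ><} 1993.Microcebus_murinus`. The
monotypic *Mirza* is congruent with its only child under coverage, hence
both are congruent with `1993.Microcebus_coquereli` (one gray class in
`out/reduced.dot`); the two genus-level *Microcebus* concepts overlap, and
`out/combined.dot` resolves that overlap into the three Euler subregions.
Of the four same-rank name comparisons, only *M. rufus* keeps both its name
and its meaning — reliability 1 : 3.

The same library calls are available in Python (`parse_alignment`,
`check_consistency`, `enumerate_worlds`, `compute_mir`, `build_merge`,
`compute_metrics`, `diagnose`), and `taxalign simulate` generates synthetic
alignments with known ground truth (splits, acquisitions, lumps, renames).

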