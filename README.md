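# mitoforms

Structural analysis of circular plant mitochondrial genomes: dispersed
repeats, the alternative genome conformations they mediate through
homologous recombination, long-read evidence for those conformations, and
the resulting multipartite genome model — together with SSR/tandem-repeat
scans, pairwise shared-DNA fractions, plastid-transfer (MTPT) detection
and descriptive genome statistics.

**Who it is for.** Researchers assembling or analysing organelle genomes
who need to answer: *is this circular assembly the only arrangement of
this mitogenome, or do its repeats recombine it into subgenomic circles —
and what do the long reads say?*

## The model

A plant mitogenome assembled as a single circular "master" molecule of
length *L* interconverts in vivo with recombination products of its
dispersed repeat pairs.  For a **direct** pair with copies starting at
*a₁* and *a₂*, crossover splits the master circle into two subgenomic
circles of sizes

&nbsp;&nbsp;&nbsp;&nbsp;*s₁* = (*a₂* − *a₁*) mod *L* and *s₂* = *L* − *s₁*,

each retaining one repeat copy; an **inverted** pair instead inverts the
inter-repeat segment, conserving *L*.  Which arrangement a long read
supports is decided at the repeat's junctions: a read is informative only
if it spans a repeat copy with ≥ *anchor* (100 bp) alignable bases in
both flanks at ≥ 85 % identity, because the upstream/downstream flank
pairing is the only signal distinguishing conformations.  Per repeat,

&nbsp;&nbsp;&nbsp;&nbsp;frac_alt = 100 · n_alt / (n_master + n_alt),

over informative reads, and a repeat with frac_alt above a configurable
activity threshold (default 20 %) contributes its circles to the
multipartite model.

Repeat and homology search uses 7-mer seeding with gapless X-drop
extension and deterministic (length ≥ 100 bp, identity ≥ 90 %) filters;
shared-DNA and MTPT statistics are computed on overlap-merged intervals
against each genome's own length, rounded half-up to two decimals.

## Worked example

`examples/03_conformations_and_read_support.py` plants a 3 kb direct
repeat on a 100 kb circle, simulates 500 ultralong reads from a 50/50
master/recombinant mixture at 5 % error, and classifies them:

```
repeat R1: 3001 bp direct pair
alternative conformation: two circles of 50,000 and 50,000 bp (sum = 100,000 = master length)

read support: 196 master / 205 alternative (99 uninformative of 500)
frac_master = 48.88 %, frac_alt = 51.12 %
```

Reading the numbers: 401 of 500 reads spanned the repeat with both flank
anchors and are informative; their 51.12 % alternative support recovers
the planted 50 % mixture within sampling error, so the repeat is called
recombinationally active and the model reports the master circle plus two
50 kb subgenomic circles (printed as JSON by the example).  The 99
uninformative reads either missed the repeat or ended inside it.

The other examples cover genome simulation (`01`), the three repeat
detectors (`02`), shared DNA and MTPT detection (`04`) and the one-config
end-to-end pipeline with its Markdown report (`05`).

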