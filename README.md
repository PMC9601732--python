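# radmap

Integrated (both-parent) genetic linkage maps from RAD tags in an outbred
F1 hybrid population.

## The problem

In outbred species — forest trees especially — inbred lines and F2
populations are out of reach, so linkage mapping traditionally falls back
on the *pseudo-testcross*: markers heterozygous in one parent and
homozygous in the other segregate 1:1 in the F1 progeny and behave like
backcross markers, but each such marker is informative for only one
parent's meiosis. The result is two separate parental maps, each blind to
half of the recombination in the cross.

`radmap` implements a strategy that gets a single map carrying **both**
parents' recombination information from ordinary 1:1 SNPs. The key object
is a **RAD tag**: a short (< 1 kb) locus carrying one female-informative
SNP (segregation *ab*×*aa*) and one male-informative SNP (*aa*×*ab*).
Because the two SNPs are essentially at one map position, a tag is
informative for both meioses at once. Adjacent tags are required to be
≥ 100 kb apart so that crossovers between them occur at a useful rate.

## The model

For two markers scored in the same meiosis, with R recombinant progeny out
of n complete pairs, the backcross MLE of the recombination fraction is

    r̂ = min(R, n − R) / n,      LOD = (n − R′)·log10 2(1 − r̂) + R′·log10 2r̂

with R′ = min(R, n − R); the fold at ½ is the **linkage phase** (coupling
vs repulsion). Along an ordered group, every repulsion-phase marker's
progeny calls are relabelled (HET ↔ HOM), which provably changes no
pairwise statistic but turns the whole dataset into a standard backcross
layout. The harmonized female and male datasets over the same tags are
then stacked into one 2N-row pseudo-backcross, on which:

- interval recombination fractions are estimated by EM on a two-state
  hidden Markov model of the meiosis (missing calls emit 1; optionally a
  symmetric miscall rate ε enters the emission and is itself estimated,
  which prevents the classical error-driven map inflation);
- marker orders are found by greedy chaining plus window-ripple and 2-opt
  local search over an adjacent-pair profile likelihood, and scored by the
  full multipoint log10-likelihood;
- distances are reported in Kosambi centimorgans, d = 25·ln((1+2r)/(1−2r));
- alternative orders (female-, male-, integrated-estimated) are compared by
  their profile multipoint likelihood on the merged data;
- each group's order is checked against reference-genome coordinates by
  counting **discordant regions** — maximal runs of consecutive markers off
  the longest strictly monotone backbone of genome positions.

Pairwise-LOD single-linkage clustering (thresholds 5–17, with an r̂ ≤ 0.45
guard) assigns tags to linkage groups; 1:1 markers are pre-filtered by a
df-1 chi-square test against the Mendelian 1:1 ratio (p < 0.01 removed)
and a 20% missing-call ceiling (inclusive).

A simulator (`radmap.simgen`) generates the whole design — two
heterozygous parents, sex-specific interval recombination fractions
(female above male by default), random parental phases, genotyping error
and missingness — together with the ground truth needed to verify every
stage.

## Worked example

`examples/02_simulate_and_map.py` simulates 4 chromosomes × 30 tags for
257 progeny (10% missing calls, 0.5% miscalls) and runs the full pipeline:

```
simulated 240 SNPs on 4 chromosomes, 257 progeny
tags selected: 118; linkage groups: 4 (LOD threshold 5)

flavor       est cM   true cM   mean adjacent cM
INTEGRATED    560.2     547.9         4.91
FEMALE        619.8     618.0         5.44
MALE          508.4     478.4         4.46
```

The female map is the longest (the female meiosis recombines more), the
integrated map lies between the two parental maps — its intervals pool the
gametes of both meioses — and each total tracks the Kosambi-transformed
simulated truth. The other example scripts walk through two-point basics,
the phase transformation and merge, order-likelihood comparison, and
genome concordance.

The same pipeline is available from the shell:

```
radmap simulate --seed 11 --chromosomes 4 --tags-per-chromosome 30 --out-prefix sim/pop
radmap run-all sim/pop.vcf --seed 11 --out sim/out
```

which writes the tag table, group membership, per-flavor maps, the
Table-style summaries (map lengths, order likelihoods, discordant
regions), the merged pseudo-backcross matrices, a per-marker filter audit
and a machine-readable run log.

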