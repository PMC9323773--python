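# hervtrace

Tools for studying the deep evolutionary history of endogenous
retroviruses (ERVs) in primate genomes: finding full-length proviruses,
tracing orthologous insertions across a time-calibrated species tree to
date vertical-transmission events, flagging LTR-discordant element pairs
as candidates for inter-element recombination, and calling ncRNA
co-option by strand-aware containment.

It is written for molecular evolution / paleovirology work where the
question is not "how many repeats does this genome have" but "which
proviral insertions are shared identically-by-descent between species,
when did they integrate, and what happened to them since".

## The analysis

A full-length provirus consists of two long terminal repeats (LTRs)
flanking `gag`–`pro`–`pol`–`env`, with the reverse-transcriptase (RT)
domain of `pol` as the most conserved, diagnostic region.  The pipeline:

1. **Discovery** — translated RT search (e ≤ 10⁻⁵) against all six
   frames; merge footprints < 1000 bp apart; drop candidates whose best
   hit is a host or non-retroviral protein; extend ± 10 kb and locate the
   LTR pair as the best direct repeat; annotate internal genes (≥ 100 aa);
   call full-length iff an RT-bearing `pol` exists and the observed genes
   are ordered `gag`–`pro`–`pol`–`env`; classify by nearest RT reference
   (≥ 60 % identity, else `Unknown`).
2. **Vertical transmission** — an insertion inherited through speciation
   sits at the same locus in both species.  A cross-species element pair
   is orthologous iff element identity and coverage are ≥ 90 %, both
   ~2 kb flank pairs match at > 90 % identity, and both flank coverages
   exceed 25 % with at least one ≥ 80 %.  Accepted pairs form a graph;
   connected components are events; each event is dated by the age of the
   most recent common ancestor (MRCA) of its species set — a minimum
   integration age.
3. **LTR recombination** — the two LTRs of one element are identical at
   integration, so each LTR's best relative should be its own partner.
   Within a (species × supergroup) stratum, a pair is called when each
   LTR of *both* elements scores strictly higher against the other
   element's LTRs than against its own partner, mapping onto the other
   element's two distinct LTRs.
4. **ncRNA co-option** — a provirus and an annotated transcript are
   paired iff they share contig and strand, overlap, and one of the two
   is 100 % contained.  A packaged 107-row human provirus/ncRNA table
   drives the human summaries.

All alignment runs through an exact Smith–Waterman core (Biopython's
`PairwiseAligner`) with Karlin–Altschul bit scores and e-values, validated
in the test suite against an independent dynamic-programming reference
implementation.  Because the original genome-scale survey is not
reproducible at desk scale, a synthetic-cohort simulator
(`hervtrace.simulate`) plants orthologous insertions on a 6-leaf primate
tree (splits at 6.7 / 9.1 / 15.8 / 20.2 / 29.4 MYA), evolves them by
per-branch Jukes–Cantor substitution, and emits ground truth for every
stage.  See `docs/methods.md` for models, parameters and limitations.

## Worked example

Run the numbered analyses (a simulated cohort end to end, then the human
annotation table):

```sh
python analysis/01_simulate_cohort.py      # six genomes + ground truth
python analysis/02_discover_ervs.py        # provirus discovery per genome
python analysis/03_vertical_transmission.py
python analysis/04_ltr_recombination.py
python analysis/05_ncrna_cooption.py
```

The transmission step prints, for the shipped cohort:

```
36 flanked elements -> 47 accepted pairs -> 10 events
  VT0000: node node1 @ 9.1 MYA, 3 species, HERVK
  VT0001: node node2 @ 15.8 MYA, 4 species, HUERSP
  VT0002: node node3 @ 20.2 MYA, 5 species, HERVW9
  VT0003: node node1 @ 9.1 MYA, 2 species, HSERVIII
  ...
```

Every multi-species insertion planted by the simulator is recovered as
one event at its true node: `VT0002` is an insertion in the ancestor of
all apes in the cohort (20.2 MYA), and `VT0003` is carried by only
*Homo sapiens* and *Gorilla gorilla gorilla* — the simulator deleted the
chimpanzee copy — so its species set dates it to the human–gorilla split
at 9.1 MYA.  The two single-species insertions in the cohort produce no
events, and the recombination step reports zero calls because no LTR
swaps were planted:

```
36 elements, 0 non-clustered, 0 recombination calls
```

The ncRNA step summarises the packaged human table:

```
107 annotated proviruses; top chromosomes: chr6=12, chr2=11, chr4=10
classes: {'HERVHF': 104, 'HERVK': 2, 'HUERSP': 1}
81 rows satisfy strand-aware 100% containment; 26 printed rows are internally inconsistent
```

(Chromosomes 1 and 4 both hold 10; the validator flags printed rows whose
transcript and provirus intervals cannot satisfy the containment rule.)

The same stages are available as a CLI (`hervtrace simulate / discover /
transmit / recombine / ncrna / report`) whose subcommands read/write
FASTA, BED6, GTF and TSV and leave a `manifest.json` (config snapshot,
input checksums, stage counts) per run.

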