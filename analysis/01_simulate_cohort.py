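"""Simulate the six-species study cohort with ground truth.

Plants orthologous proviral insertions on the internal nodes of the
packaged primate tree (splits at 6.7 / 9.1 / 15.8 / 20.2 / 29.4 MYA),
including one insertion lost in Pan so that a Homo+Gorilla-only event
exists, and writes per-species FASTAs, reference panels and truth tables
under results/cohort/.
"""

import pathlib
import sys

import pandas as pd

from hervtrace.io import write_fasta
from hervtrace.simulate import (SimulationConfig, emit_reference_panels,
                                simulate_cohort)

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "cohort"

COHORT_CONFIG = dict(
    n_insertions=12,
    insertion_nodes=("node0", "node1", "node2", "node3", "node1", "node2",
                     "node0", "node1", "node3", "node2", "Homo_sapiens",
                     "Macaca_mulatta"),
    # losing the Pan copy of insertion 4 leaves a Homo+Gorilla-only event
    losses={4: ("Pan_troglodytes",)},
)


def main(seed: int = 5) -> None:
    cfg = SimulationConfig(seed=seed, **COHORT_CONFIG)
    cohort = simulate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    for sp, contigs in cohort.genomes.items():
        write_fasta(contigs, OUT / f"{sp}.fasta")
    for name, refs in emit_reference_panels(cfg).items():
        write_fasta(refs, OUT / f"panel_{name}.faa")
    rows = []
    for ins in cohort.truth.insertions:
        for sp, (contig, start, end) in sorted(ins.species_coords.items()):
            rows.append(dict(group=ins.group_id, node=ins.node,
                             classification=ins.classification, species=sp,
                             contig=contig, start=start, end=end))
    pd.DataFrame(rows).to_csv(OUT / "truth_insertions.tsv", sep="\t",
                              index=False)
    n_multi = sum(len(t.species_coords) > 1 for t in cohort.truth.insertions)
    print(f"cohort: {len(cohort.genomes)} species, "
          f"{len(cohort.truth.insertions)} insertions "
          f"({n_multi} shared across >1 species) -> {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 5)
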