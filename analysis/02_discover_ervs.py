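"""Run provirus discovery on every cohort genome.

Reads results/cohort/ (from 01_simulate_cohort.py), runs the discovery
pipeline per species and writes BED/GTF element annotations plus the
per-stage survivor funnel under results/discovery/.
"""

import pathlib

import pandas as pd

from hervtrace.discovery import discover, elements_to_bed, elements_to_gtf
from hervtrace.io import read_fasta, write_bed, write_gtf

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort_dir = BASE / "cohort"
    out = BASE / "discovery"
    out.mkdir(parents=True, exist_ok=True)
    panels = {f.stem.removeprefix("panel_"): read_fasta(f)
              for f in sorted(cohort_dir.glob("panel_*.faa"))}
    funnel_rows = []
    for fasta in sorted(cohort_dir.glob("*.fasta")):
        species = fasta.stem
        genome = read_fasta(fasta)
        elements, funnel = discover(genome, panels, species=species)
        write_bed(elements_to_bed(elements), out / f"{species}.elements.bed")
        write_gtf(elements_to_gtf(elements), out / f"{species}.elements.gtf")
        ltr_rows = [(iv.contig, iv.start, iv.end, f"{e.element_id}:{side}",
                     round(e.ltrs.ltr_identity_pct, 2), e.interval.strand)
                    for e in elements
                    for side, iv in (("5p", e.ltrs.five_prime),
                                     ("3p", e.ltrs.three_prime))]
        write_bed(ltr_rows, out / f"{species}.ltrs.bed")
        funnel_rows.append(dict(species=species, **funnel))
        print(f"{species}: {funnel}")
    pd.DataFrame(funnel_rows).to_csv(out / "funnel.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
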