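"""Screen each (species, supergroup) stratum for LTR-discordant elements.

Builds per-stratum LTR bit-score matrices from the discovered elements
(02), flags elements whose LTRs cluster better with another element's, and
calls reciprocally matching pairs as recombination candidates.  Writes
calls and summaries under results/recombination/.
"""

import pathlib

import pandas as pd

from hervtrace.discovery import elements_from_bed
from hervtrace.io import read_fasta
from hervtrace.recombination import (ltr_records_from_elements, scan_strata,
                                     summarize_recombination)

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = BASE / "recombination"
    out.mkdir(parents=True, exist_ok=True)
    elements = []
    genomes = {}
    for bed in sorted((BASE / "discovery").glob("*.elements.bed")):
        species = bed.name.removesuffix(".elements.bed")
        genomes[species] = read_fasta(BASE / "cohort" / f"{species}.fasta")
        elements.extend(elements_from_bed(
            bed, bed.with_name(f"{species}.ltrs.bed"), species))
    with_ltrs = [e for e in elements if e.ltrs is not None]
    records = ltr_records_from_elements(with_ltrs, genomes)
    calls, flags = scan_strata(records)
    pd.DataFrame([dict(element_1=c.element_1, element_2=c.element_2,
                       match_5p=c.matching["5p"], match_3p=c.matching["3p"])
                  for c in calls]).to_csv(out / "calls.tsv", sep="\t",
                                          index=False)
    summarize_recombination(calls, with_ltrs).to_csv(out / "summary.tsv",
                                                     sep="\t", index=False)
    pd.DataFrame([dict(element_id=k, nonclustered=v)
                  for k, v in sorted(flags.items())]).to_csv(
        out / "nonclustered.tsv", sep="\t", index=False)
    print(f"{len(with_ltrs)} elements, {sum(flags.values())} non-clustered, "
          f"{len(calls)} recombination calls")


if __name__ == "__main__":
    main()
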