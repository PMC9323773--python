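"""Date vertical-transmission events from the discovered elements.

Takes the per-species discoveries (02), extracts each full-length element
with ~2 kb flanks, screens all cross-species pairs through the
three-condition orthology test, clusters accepted pairs into events and
maps each event to its MRCA node on the primate fixture tree.  Writes
events and per-node/per-species summaries under results/transmission/.
"""

import pathlib

import pandas as pd

from hervtrace.discovery import elements_from_bed
from hervtrace.io import read_fasta
from hervtrace.report import events_per_node
from hervtrace.transmission import (FlankedElement, infer_transmission,
                                    summarize_events)
from hervtrace.trees import TimedSpeciesTree

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tree = TimedSpeciesTree.default_fixture()
    out = BASE / "transmission"
    out.mkdir(parents=True, exist_ok=True)
    flanked = []
    for bed in sorted((BASE / "discovery").glob("*.elements.bed")):
        species = bed.name.removesuffix(".elements.bed")
        genome = read_fasta(BASE / "cohort" / f"{species}.fasta")
        for e in elements_from_bed(bed, None, species):
            if e.is_full_length:
                flanked.append(FlankedElement.from_element(e, genome))
    events, pairs = infer_transmission(flanked, tree)
    pd.DataFrame([dict(event_id=ev.event_id, node=ev.mrca_node,
                       age_mya=ev.age_mya, classification=ev.classification,
                       species=";".join(sorted(ev.species_set)),
                       members=";".join(ev.members))
                  for ev in events]).to_csv(out / "events.tsv", sep="\t",
                                            index=False)
    per_node, per_species = summarize_events(events, tree)
    events_per_node(per_node).to_csv(out / "per_node.tsv", sep="\t", index=False)
    per_species.to_csv(out / "per_species.tsv", sep="\t", index=False)
    print(f"{len(flanked)} flanked elements -> {len(pairs)} accepted pairs "
          f"-> {len(events)} events")
    for ev in events:
        print(f"  {ev.event_id}: node {ev.mrca_node} @ {ev.age_mya:.1f} MYA, "
              f"{len(ev.species_set)} species, {ev.classification}")


if __name__ == "__main__":
    main()
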