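"""Run manifests and figure-shaped summary tables.

Every pipeline stage writes a manifest (command, config snapshot, input
checksums, seed, stage counts) so a run is reproducible byte-for-byte; the
reporting helpers reshape stage outputs into per-species classification
histograms, per-node event tables, recombination summaries and
per-chromosome co-option counts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .io import sha256_of


@dataclass
class RunManifest:
    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    def add_input(self, path) -> None:
        p = Path(path)
        self.input_checksums[p.name] = sha256_of(p)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def per_species_classification(elements: pd.DataFrame) -> pd.DataFrame:
    """Element counts by species and classification (distribution histogram)."""
    if elements.empty:
        return pd.DataFrame(columns=["species", "classification", "n"])
    out = (elements.groupby(["species", "classification"]).size()
           .rename("n").reset_index())
    return out.sort_values(["species", "classification"]).reset_index(drop=True)


def events_per_node(per_node: pd.DataFrame) -> pd.DataFrame:
    """Node table ordered old-to-young (bubble-chart shape)."""
    return per_node.sort_values("age_mya", ascending=False).reset_index(drop=True)


def plot_species_histogram(table: pd.DataFrame, path) -> None:
    """Stacked per-species classification bar chart (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = table.pivot_table(index="species", columns="classification",
                              values="n", fill_value=0, aggfunc="sum")
    ax = pivot.plot(kind="bar", stacked=True, figsize=(8, 4))
    ax.set_ylabel("elements")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=120)
    plt.close(ax.figure)
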