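"""Synthetic multi-species cohort with planted endogenous retroviruses.

Generates orthologous genomic segments (one contig per locus, per species)
along a time-calibrated species tree.  Each planted provirus consists of two
initially identical LTRs flanking an internal region of back-translated
gag/pro/pol/env proteins (pol carrying an RT domain).  An insertion assigned
to tree node N appears, with the same flanking context, in all and only N's
descendant leaves; every part of the locus then evolves independently down
each branch under a Jukes-Cantor substitution process (optional transition
bias, optional small indels), so expected pairwise divergence between two
leaves is ``2 * rate * split_age``.

The module also emits the protein reference panels that the discovery stage
screens with (RT per supergroup, per-gene panels, host and non-retroviral
viral decoys), a single-genome variant for discovery benchmarking, and a
lightweight per-stratum LTR simulator for recombination analyses.  Ground
truth (insertions, orthology groups, losses, recombination swaps, ncRNA
containment) is returned as a TruthTable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trees import TimedSpeciesTree

SUPERGROUPS = ("MLLV", "HERVERI", "HERVFRDLIKE", "HEPSI", "HUERSP",
               "HERVW9", "HERVIPADP", "MER50like", "HERVHF", "HERVK",
               "HSERVIII")

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# codon per amino acid, plus the full table for randomised back-translation
_CODONS: dict[str, list[str]] = {}
from Bio.Data.CodonTable import standard_dna_table as _tbl  # noqa: E402

for _codon, _aa in sorted(_tbl.forward_table.items()):
    _CODONS.setdefault(_aa, []).append(_codon)


class SimulationError(ValueError):
    pass


def _rng_for(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *tags])


def random_nt(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(_NT[rng.choice(4, size=n, p=p)]).decode()


def random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA20), size=n))


def back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_CODONS[aa]) for aa in protein)


_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def _revcomp(seq: str) -> str:
    return seq.encode().translate(_COMP)[::-1].decode()


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def mutate_nt(seq: str, p: float, rng: np.random.Generator,
              transition_bias: float = 1.0, indel_rate: float = 0.0) -> str:
    """Substitute each site with probability ``p`` (JC, optional ts bias).

    ``indel_rate`` is the per-site probability of starting a 1-3 bp
    insertion or deletion.
    """
    if p <= 0 and indel_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < p)[0]
    for i in hit:
        base = chr(arr[i])
        if base == "N":
            continue
        ts = _TRANSITION[base]
        tv = [b for b in "ACGT" if b != base and b != ts]
        w = np.array([transition_bias, 1.0, 1.0])
        choice = rng.choice([ts, *tv], p=w / w.sum())
        arr[i] = ord(choice)
    out = arr.tobytes().decode()
    if indel_rate > 0:
        pieces = []
        last = 0
        for i in np.nonzero(rng.random(len(out)) < indel_rate)[0]:
            if i < last:
                continue
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion
                pieces.append(out[last:i])
                last = i + size
            else:  # insertion
                pieces.append(out[last:i] + random_nt(rng, size))
                last = i
        pieces.append(out[last:])
        out = "".join(pieces)
    return out


# ---------------------------------------------------------------------------
# reference families and panels


@dataclass(frozen=True)
class ProvirusFamily:
    """Consensus sequences of one retroviral supergroup used for planting."""

    supergroup: str
    ltr: str
    gag: str
    pro: str
    pol: str  # pol_n + rt + pol_c
    env: str
    rt_slice: tuple[int, int]  # RT domain within pol, aa coords

    @property
    def rt(self) -> str:
        return self.pol[self.rt_slice[0]:self.rt_slice[1]]


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Rates are per site per million years.  With the default substitution
    rate of 0.002/site/MY, orthologs split at 9.1 MYA sit near 96.4%
    expected identity and the 90% identity floor of the orthology test is
    crossed a little beyond the 25 MYA split depth, mirroring the loss of
    detectability for the deepest primate splits.
    """

    seed: int = 0
    tree_newick: str | None = None  # default: packaged 6-leaf primate fixture
    segment_flank_bp: int = 2600
    n_insertions: int = 12
    insertion_nodes: tuple[str, ...] | None = None  # one node label per insertion
    losses: dict[int, tuple[str, ...]] = field(default_factory=dict)
    ltr_length_bp: int = 350
    internal_gene_layout: tuple[tuple[str, int], ...] = (
        ("gag", 140), ("pro", 110), ("pol", 340), ("env", 130))
    substitution_rate: float = 0.002
    transition_bias: float = 1.0
    indel_rate: float = 0.0
    post_insertion_divergence: float = 0.0  # extra per-LTR divergence at planting
    minus_strand_fraction: float = 0.25
    supergroups: tuple[str, ...] = ("HERVHF", "HERVK", "HUERSP", "HERVW9",
                                    "HSERVIII")
    n_recombination_swaps: int = 0
    ncrna_species: str = "Homo_sapiens"
    ncrna_contained_fraction: float = 0.5
    n_ncrna_decoys: int = 4
    gc_content: float = 0.41

    def resolve_tree(self) -> TimedSpeciesTree:
        if self.tree_newick is None:
            return TimedSpeciesTree.default_fixture()
        return TimedSpeciesTree.from_newick(self.tree_newick)


def make_families(cfg: SimulationConfig) -> dict[str, ProvirusFamily]:
    """Deterministic consensus family per supergroup used by the cohort.

    Families for all 11 supergroups are derived from the seed so reference
    panels stay consistent whether or not a supergroup is planted.
    """
    fams = {}
    layout = dict(cfg.internal_gene_layout)
    pol_len = layout.get("pol", 340)
    rt_len = min(180, pol_len - 60)
    rt_start = (pol_len - rt_len) // 2
    for k, sg in enumerate(SUPERGROUPS):
        rng = _rng_for(cfg.seed, 101, k)
        fams[sg] = ProvirusFamily(
            supergroup=sg,
            ltr=random_nt(rng, cfg.ltr_length_bp, cfg.gc_content),
            gag=random_aa(rng, layout.get("gag", 140)),
            pro=random_aa(rng, layout.get("pro", 110)),
            pol=random_aa(rng, pol_len),
            env=random_aa(rng, layout.get("env", 130)),
            rt_slice=(rt_start, rt_start + rt_len))
    return fams


def emit_reference_panels(cfg: SimulationConfig) -> dict[str, dict[str, str]]:
    """Protein panels consumed by the discovery stage.

    Returns ``{"rt": .., "gag": .., "pro": .., "pol": .., "env": ..,
    "host": .., "other_virus": ..}``; RT entries are named
    ``<supergroup>_rt`` so classification labels parse from the panel.
    """
    fams = make_families(cfg)
    rng = _rng_for(cfg.seed, 102)
    panels: dict[str, dict[str, str]] = {
        "rt": {f"{sg}_rt": fam.rt for sg, fam in fams.items()},
        "gag": {f"{sg}_gag": fam.gag for sg, fam in fams.items()},
        "pro": {f"{sg}_pro": fam.pro for sg, fam in fams.items()},
        "pol": {f"{sg}_pol": fam.pol for sg, fam in fams.items()},
        "env": {f"{sg}_env": fam.env for sg, fam in fams.items()},
        "host": {f"host_decoy_{i}": random_aa(rng, 300) for i in range(3)},
        "other_virus": {f"virus_decoy_{i}": random_aa(rng, 300) for i in range(3)},
    }
    return panels


# ---------------------------------------------------------------------------
# truth records


@dataclass
class InsertionTruth:
    group_id: str
    node: str
    classification: str
    strand: str
    species_coords: dict[str, tuple[str, int, int]]  # species -> (contig, start, end)
    ltr_left: dict[str, tuple[int, int]]  # genome-forward left repeat span
    ltr_right: dict[str, tuple[int, int]]
    lost_in: tuple[str, ...]

    @property
    def species_set(self) -> frozenset[str]:
        return frozenset(self.species_coords)


@dataclass
class RecombinationTruth:
    species: str
    element_a: str
    element_b: str
    swapped_side: str  # which LTR was exchanged


@dataclass
class NcrnaTruth:
    ncrna_id: str
    contig: str
    start: int
    end: int
    strand: str
    relation: str  # contains / partial / opposite_strand / background
    herv_group: str | None


@dataclass
class TruthTable:
    insertions: list[InsertionTruth]
    recombinations: list[RecombinationTruth]
    ncrnas: list[NcrnaTruth]

    def element_name(self, ins: InsertionTruth, species: str) -> str:
        contig, start, end = ins.species_coords[species]
        return f"{species}_{contig}_{start + 1}-{end}-{ins.classification}"


@dataclass
class Cohort:
    genomes: dict[str, dict[str, str]]  # species -> contig -> sequence
    truth: TruthTable
    config: SimulationConfig


# ---------------------------------------------------------------------------
# cohort simulation


def _evolve_parts(parts: dict[str, str | None], p: float,
                  rng: np.random.Generator, cfg: SimulationConfig) -> dict:
    out = {}
    for key, seq in parts.items():
        out[key] = None if seq is None else mutate_nt(
            seq, p, rng, cfg.transition_bias, cfg.indel_rate)
    return out


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    tree = cfg.resolve_tree()
    fams = make_families(cfg)
    planted = [sg for sg in cfg.supergroups if sg in fams]
    if not planted:
        raise SimulationError("no valid supergroups configured")
    internal = [lbl for lbl, _ in tree.internal_nodes()]
    if cfg.insertion_nodes is not None:
        if len(cfg.insertion_nodes) != cfg.n_insertions:
            raise SimulationError("insertion_nodes length != n_insertions")
        nodes = list(cfg.insertion_nodes)
    else:
        nodes = [internal[i % len(internal)] for i in range(cfg.n_insertions)]
    known = set(internal) | set(tree.leaves)
    for nd in nodes:
        if nd not in known:
            raise SimulationError(f"unknown insertion node: {nd}")

    # ancestral loci and elements
    loci = []
    for i in range(cfg.n_insertions):
        rng = _rng_for(cfg.seed, 201, i)
        fam = fams[planted[i % len(planted)]]
        strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
        ltr = mutate_nt(fam.ltr, 0.02, rng)  # insertion-specific LTR variant
        genes_nt = []
        for gene, _ in cfg.internal_gene_layout:
            genes_nt.append(back_translate(getattr(fam, gene), rng))
            genes_nt.append(random_nt(rng, 30, cfg.gc_content))  # spacer
        internal_nt = "".join(genes_nt[:-1])
        ltr5 = mutate_nt(ltr, cfg.post_insertion_divergence, rng)
        ltr3 = mutate_nt(ltr, cfg.post_insertion_divergence, rng)
        loci.append(dict(
            index=i, node=nodes[i], family=fam, strand=strand,
            parts=dict(
                up=random_nt(rng, cfg.segment_flank_bp, cfg.gc_content),
                ltr5=ltr5, internal=internal_nt, ltr3=ltr3,
                down=random_nt(rng, cfg.segment_flank_bp, cfg.gc_content)),
        ))

    # evolve each locus down the tree
    leaf_states: dict[int, dict[str, dict]] = {i: {} for i in range(cfg.n_insertions)}
    for locus in loci:
        i = locus["index"]
        states: dict[str, dict] = {}
        for k, (parent, label, brlen, is_leaf) in enumerate(tree.preorder_edges()):
            rng = _rng_for(cfg.seed, 202, i, k)
            if parent is None:
                parts = dict(locus["parts"])
                if locus["node"] != label:
                    parts = {**parts, "ltr5": None, "internal": None, "ltr3": None}
                state = parts
            else:
                p = cfg.substitution_rate * brlen
                state = _evolve_parts(states[parent], p, rng, cfg)
                if locus["node"] == label:
                    state["ltr5"] = locus["parts"]["ltr5"]
                    state["internal"] = locus["parts"]["internal"]
                    state["ltr3"] = locus["parts"]["ltr3"]
            states[label] = state
            if is_leaf:
                leaf_states[i][label] = state

    # leaf-level recombination swaps (exchange 5' LTRs between two elements
    # of the same species and supergroup)
    recomb_truth: list[RecombinationTruth] = []
    if cfg.n_recombination_swaps:
        rng = _rng_for(cfg.seed, 203)
        candidates = []
        for sp in tree.leaves:
            by_family: dict[str, list[int]] = {}
            for locus in loci:
                i = locus["index"]
                st = leaf_states[i].get(sp)
                if (st and st["ltr5"] is not None
                        and sp not in cfg.losses.get(i, ())):
                    by_family.setdefault(locus["family"].supergroup, []).append(i)
            for sg, idxs in sorted(by_family.items()):
                for a in range(0, len(idxs) - 1, 2):
                    candidates.append((sp, sg, idxs[a], idxs[a + 1]))
        if len(candidates) < cfg.n_recombination_swaps:
            raise SimulationError(
                f"only {len(candidates)} swap opportunities available")
        pick = rng.choice(len(candidates), size=cfg.n_recombination_swaps,
                          replace=False)
        for ci in sorted(pick):
            sp, sg, ia, ib = candidates[ci]
            sa, sb = leaf_states[ia][sp], leaf_states[ib][sp]
            sa["ltr5"], sb["ltr5"] = sb["ltr5"], sa["ltr5"]
            recomb_truth.append(RecombinationTruth(
                species=sp, element_a=f"locus{ia:03d}", element_b=f"locus{ib:03d}",
                swapped_side="5p"))

    # assemble genomes + insertion truth
    genomes: dict[str, dict[str, str]] = {sp: {} for sp in tree.leaves}
    ins_truth: list[InsertionTruth] = []
    for locus in loci:
        i = locus["index"]
        contig = f"locus{i:03d}"
        coords: dict[str, tuple[str, int, int]] = {}
        lts: dict[str, tuple[int, int]] = {}
        rts: dict[str, tuple[int, int]] = {}
        lost = tuple(sorted(cfg.losses.get(i, ())))
        for sp in tree.leaves:
            st = leaf_states[i][sp]
            up, down = st["up"], st["down"]
            if st["ltr5"] is None or sp in lost:
                genomes[sp][contig] = up + down
                continue
            elem = st["ltr5"] + st["internal"] + st["ltr3"]
            if locus["strand"] == "-":
                elem = _revcomp(elem)
                left_len, right_len = len(st["ltr3"]), len(st["ltr5"])
            else:
                left_len, right_len = len(st["ltr5"]), len(st["ltr3"])
            start = len(up)
            end = start + len(elem)
            genomes[sp][contig] = up + elem + down
            coords[sp] = (contig, start, end)
            lts[sp] = (start, start + left_len)
            rts[sp] = (end - right_len, end)
        ins_truth.append(InsertionTruth(
            group_id=contig, node=locus["node"],
            classification=locus["family"].supergroup,
            strand=locus["strand"], species_coords=coords,
            ltr_left=lts, ltr_right=rts, lost_in=lost))

    # ncRNA annotations over elements of the designated species
    ncrna_truth: list[NcrnaTruth] = []
    rng = _rng_for(cfg.seed, 204)
    sp = cfg.ncrna_species
    present = [t for t in ins_truth if sp in t.species_coords]
    n_contained = int(round(cfg.ncrna_contained_fraction * len(present)))
    for j, t in enumerate(present):
        contig, start, end = t.species_coords[sp]
        clen = len(genomes[sp][contig])
        if j < n_contained:
            a = max(0, start - int(rng.integers(50, 400)))
            b = min(clen, end + int(rng.integers(50, 400)))
            ncrna_truth.append(NcrnaTruth(
                f"SYN_NC{j:04d}", contig, a, b, t.strand, "contains",
                t.classification))
        elif rng.random() < 0.5:
            mid = (start + end) // 2
            ncrna_truth.append(NcrnaTruth(
                f"SYN_NC{j:04d}", contig, mid, min(clen, end + 600),
                t.strand, "partial", t.classification))
        else:
            flip = "-" if t.strand == "+" else "+"
            a = max(0, start - 100)
            b = min(clen, end + 100)
            ncrna_truth.append(NcrnaTruth(
                f"SYN_NC{j:04d}", contig, a, b, flip, "opposite_strand",
                t.classification))
    for d in range(cfg.n_ncrna_decoys):
        if not present:
            break
        t = present[int(rng.integers(len(present)))]
        contig = t.species_coords[sp][0]
        clen = len(genomes[sp][contig])
        a = int(rng.integers(0, max(1, clen - 700)))
        ncrna_truth.append(NcrnaTruth(
            f"SYN_BG{d:04d}", contig, a, min(clen, a + 600),
            "+" if rng.random() < 0.5 else "-", "background", None))

    return Cohort(genomes=genomes,
                  truth=TruthTable(ins_truth, recomb_truth, ncrna_truth),
                  config=cfg)


# ---------------------------------------------------------------------------
# single-genome variant for discovery benchmarking


def simulate_discovery_genome(n_elements: int = 50, seed: int = 0,
                              post_insertion_divergence: float = 0.025,
                              element_divergence: float = 0.02,
                              flank_bp: int = 2600,
                              species: str = "Homo_sapiens",
                              cfg: SimulationConfig | None = None):
    """One genome with planted full-length proviruses and an element-free
    control of identical size and base composition.

    ``post_insertion_divergence`` mutates each LTR copy independently, so
    twin-LTR identity is about ``(1 - p)**2`` (95% at the default 2.5%).
    Returns ``(genome, control, truth, cfg)`` with a cohort-style truth
    table whose insertions carry single-species coordinates.
    """
    cfg = cfg or SimulationConfig(seed=seed)
    fams = make_families(cfg)
    planted = [sg for sg in cfg.supergroups if sg in fams]
    genome: dict[str, str] = {}
    control: dict[str, str] = {}
    truth: list[InsertionTruth] = []
    for i in range(n_elements):
        rng = _rng_for(seed, 301, i)
        fam = fams[planted[i % len(planted)]]
        strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
        ltr = mutate_nt(fam.ltr, 0.02, rng)
        genes = []
        for gene, _ in cfg.internal_gene_layout:
            genes.append(back_translate(getattr(fam, gene), rng))
            genes.append(random_nt(rng, 30, cfg.gc_content))
        internal_nt = mutate_nt("".join(genes[:-1]), element_divergence, rng)
        ltr5 = mutate_nt(ltr, post_insertion_divergence, rng)
        ltr3 = mutate_nt(ltr, post_insertion_divergence, rng)
        elem = ltr5 + internal_nt + ltr3
        if strand == "-":
            elem = _revcomp(elem)
            left_len, right_len = len(ltr3), len(ltr5)
        else:
            left_len, right_len = len(ltr5), len(ltr3)
        up = random_nt(rng, flank_bp, cfg.gc_content)
        down = random_nt(rng, flank_bp, cfg.gc_content)
        contig = f"locus{i:03d}"
        genome[contig] = up + elem + down
        control[contig] = random_nt(rng, len(genome[contig]), cfg.gc_content)
        start, end = len(up), len(up) + len(elem)
        truth.append(InsertionTruth(
            group_id=contig, node=species, classification=fam.supergroup,
            strand=strand, species_coords={species: (contig, start, end)},
            ltr_left={species: (start, start + left_len)},
            ltr_right={species: (end - right_len, end)},
            lost_in=()))
    return genome, control, TruthTable(truth, [], []), cfg


# ---------------------------------------------------------------------------
# per-stratum LTR simulator for recombination analyses


def simulate_ltr_stratum(n_elements: int, seed: int = 0, ltr_len: int = 300,
                         element_divergence: float = 0.06,
                         twin_divergence: float = 0.01,
                         post_swap_divergence: float = 0.005,
                         n_swaps: int = 0, species: str = "Homo_sapiens",
                         classification: str = "HERVHF"):
    """LTR records of one (species, classification) stratum.

    Each element descends from a shared family LTR consensus with
    ``element_divergence`` private divergence; its two LTR copies then
    diverge from each other by ``twin_divergence`` per copy.  ``n_swaps``
    disjoint element pairs exchange their 5' LTRs, after which every LTR
    accumulates ``post_swap_divergence`` further mutation.  Returns
    ``(records, swapped_pairs)`` where records are
    ``{element_id: {"5p": seq, "3p": seq}}``.
    """
    rng = _rng_for(seed, 401)
    consensus = random_nt(rng, ltr_len)
    records: dict[str, dict[str, str]] = {}
    ids = [f"{species}_chr1_{1000 * (k + 1)}-{1000 * (k + 1) + 5000}-{classification}"
           for k in range(n_elements)]
    for k, eid in enumerate(ids):
        own = mutate_nt(consensus, element_divergence, rng)
        records[eid] = {"5p": mutate_nt(own, twin_divergence, rng),
                        "3p": mutate_nt(own, twin_divergence, rng)}
    if 2 * n_swaps > n_elements:
        raise SimulationError("not enough elements for requested swaps")
    order = rng.permutation(n_elements)
    swapped = []
    for s in range(n_swaps):
        a, b = ids[order[2 * s]], ids[order[2 * s + 1]]
        records[a]["5p"], records[b]["5p"] = records[b]["5p"], records[a]["5p"]
        swapped.append(tuple(sorted((a, b))))
    for eid in ids:
        for side in ("5p", "3p"):
            records[eid][side] = mutate_nt(records[eid][side],
                                           post_swap_divergence, rng)
    return records, swapped
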