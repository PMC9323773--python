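"""Vertical-transmission inference from orthologous proviral insertions.

An insertion inherited through speciation leaves the same element at the
same locus — recognisable because both the element and its flanking host
sequence stay highly similar between species.  A cross-species element pair
is accepted as orthologous when three conditions hold simultaneously:

1. the two element sequences align at >= 90% identity with >= 90% coverage
   (of the shorter element);
2. both LTR-flanking sequence pairs (upstream with upstream, downstream
   with downstream) match at > 90% identity;
3. both flank alignments cover > 25% of the (shorter) flank and at least
   one covers >= 80%.

Accepted pairs form a graph whose connected components are transmission
events; an event's minimum integration age is the age of the most recent
common ancestor of the species carrying its members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .alignment import PairwiseHit, ScoringScheme, SearchParams, local_align_nt
from .discovery import ErvElement
from .trees import TimedSpeciesTree

FLANK_TARGET_BP = 2000
#: clipped flanks shorter than this cannot satisfy the coverage condition
MIN_FLANK_BP = 250

_PERMISSIVE = SearchParams(evalue_cutoff=1e-3)


@dataclass(frozen=True)
class VtThresholds:
    element_min_cov_pct: float = 90.0
    element_min_identity_pct: float = 90.0
    flank_min_identity_pct: float = 90.0
    flank_min_cov_both_pct: float = 25.0
    flank_min_cov_one_pct: float = 80.0

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not (0 < v <= 100):
                raise ValueError(f"{name} must be in (0, 100]")


@dataclass
class FlankedElement:
    """An element plus up to 2 kb of flanking host sequence on each side."""

    element: ErvElement
    element_seq: str
    upstream_flank: str
    downstream_flank: str

    @property
    def element_id(self) -> str:
        return self.element.element_id

    @property
    def species(self) -> str:
        return self.element.species

    @property
    def full_sequence(self) -> str:
        return self.upstream_flank + self.element_seq + self.downstream_flank

    @classmethod
    def from_element(cls, element: ErvElement, genome: dict[str, str],
                     flank_bp: int = FLANK_TARGET_BP) -> "FlankedElement":
        seq = genome[element.interval.contig]
        start, end = element.interval.start, element.interval.end
        return cls(element=element,
                   element_seq=seq[start:end],
                   upstream_flank=seq[max(0, start - flank_bp):start],
                   downstream_flank=seq[end:end + flank_bp])


@dataclass
class OrthologPair:
    element_a: str
    element_b: str
    species_a: str
    species_b: str
    condition_flags: tuple[bool, bool, bool]
    supporting_hits: list[PairwiseHit] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return all(self.condition_flags)

    def key(self) -> frozenset[str]:
        return frozenset((self.element_a, self.element_b))


@dataclass
class TransmissionEvent:
    event_id: str
    members: tuple[str, ...]
    member_species: tuple[str, ...]
    species_set: frozenset[str]
    classifications: tuple[str, ...]
    mrca_node: str | None = None
    age_mya: float | None = None

    @property
    def classification(self) -> str:
        """Majority classification of the member elements."""
        counts: dict[str, int] = {}
        for c in self.classifications:
            counts[c] = counts.get(c, 0) + 1
        return max(sorted(counts), key=lambda c: counts[c])


def _top_hit(query: str, subject: str, scoring: ScoringScheme):
    hits = local_align_nt(query, subject, scoring=scoring, params=_PERMISSIVE,
                          max_hits=1)
    return hits[0] if hits else None


def _identity_and_cov(query: str, subject: str, scoring: ScoringScheme
                      ) -> tuple[float, float, PairwiseHit | None]:
    """(identity%, coverage% of the shorter sequence) of the best local hit."""
    if not query or not subject:
        return 0.0, 0.0, None
    hit = _top_hit(query, subject, scoring)
    if hit is None:
        return 0.0, 0.0, None
    cov = hit.q_cov_pct if len(query) <= len(subject) else hit.s_cov_pct
    return hit.identity_pct, cov, hit


def ortholog_pair_test(a: FlankedElement, b: FlankedElement,
                       thresholds: VtThresholds | None = None,
                       scoring: ScoringScheme | None = None) -> OrthologPair:
    """Evaluate the three orthology conditions for a cross-species pair.

    All three flags are computed and reported even when the pair fails.
    Same-species pairs are rejected outright (paralogy/recombination
    territory, not orthology).
    """
    if a.species == b.species:
        raise ValueError(
            f"same-species pair {a.element_id} / {b.element_id}: "
            "within-genome duplicates are not orthology candidates")
    th = thresholds or VtThresholds()
    scoring = scoring or ScoringScheme.nucleotide()
    # canonical orientation so the test is exactly symmetric
    if (b.species, b.element_id) < (a.species, a.element_id):
        a, b = b, a
    hits: list[PairwiseHit] = []

    ident, cov, hit = _identity_and_cov(a.element_seq, b.element_seq, scoring)
    if hit:
        hits.append(hit)
    cond1 = (ident >= th.element_min_identity_pct
             and cov >= th.element_min_cov_pct)

    flank_stats = []
    for qa, qb in ((a.upstream_flank, b.upstream_flank),
                   (a.downstream_flank, b.downstream_flank)):
        if len(qa) < MIN_FLANK_BP or len(qb) < MIN_FLANK_BP:
            flank_stats.append((0.0, 0.0))
            continue
        fident, fcov, fhit = _identity_and_cov(qa, qb, scoring)
        if fhit:
            hits.append(fhit)
        flank_stats.append((fident, fcov))
    cond2 = all(fident > th.flank_min_identity_pct
                for fident, _ in flank_stats)
    covs = [fcov for _, fcov in flank_stats]
    cond3 = (all(c > th.flank_min_cov_both_pct for c in covs)
             and max(covs) >= th.flank_min_cov_one_pct)

    return OrthologPair(element_a=a.element_id, element_b=b.element_id,
                        species_a=a.species, species_b=b.species,
                        condition_flags=(cond1, cond2, cond3),
                        supporting_hits=hits)


def _shared_kmers(a: str, b_kmers: set[str], k: int) -> int:
    return sum(1 for i in range(0, len(a) - k + 1, k) if a[i:i + k] in b_kmers)


def screen_ortholog_pairs(elements: list[FlankedElement],
                          thresholds: VtThresholds | None = None,
                          scoring: ScoringScheme | None = None,
                          prescreen_k: int = 16,
                          prescreen_min: int = 5) -> list[OrthologPair]:
    """All-vs-all cross-species orthology screen.

    Pairs whose element sequences share almost no ``prescreen_k``-mers
    cannot reach 90% identity over 90% coverage, so the expensive
    three-condition test is skipped for them.
    """
    from .alignment import reverse_complement

    kmer_sets = []
    for fe in elements:
        s = fe.element_seq
        ks = {s[i:i + prescreen_k] for i in range(len(s) - prescreen_k + 1)}
        rc = reverse_complement(s)
        ks |= {rc[i:i + prescreen_k] for i in range(len(rc) - prescreen_k + 1)}
        kmer_sets.append(ks)
    accepted: list[OrthologPair] = []
    for i in range(len(elements)):
        for j in range(i + 1, len(elements)):
            if elements[i].species == elements[j].species:
                continue
            if _shared_kmers(elements[i].element_seq, kmer_sets[j],
                             prescreen_k) < prescreen_min:
                continue
            pair = ortholog_pair_test(elements[i], elements[j], thresholds,
                                      scoring)
            if pair.accepted:
                accepted.append(pair)
    return accepted


def build_event_graph(pairs: list[OrthologPair],
                      classifications: dict[str, str] | None = None
                      ) -> list[TransmissionEvent]:
    """Connected components of the accepted-pair graph, as event skeletons.

    Components of size 1 cannot witness transmission and are dropped.
    """
    graph = nx.Graph()
    seen = set()
    species = {}
    for p in pairs:
        if not p.accepted or p.key() in seen:
            continue
        seen.add(p.key())
        graph.add_edge(p.element_a, p.element_b)
        species[p.element_a] = p.species_a
        species[p.element_b] = p.species_b
    events = []
    comps = sorted((sorted(c) for c in nx.connected_components(graph)),
                   key=lambda c: c[0])
    for n, comp in enumerate(comps):
        if len(comp) < 2:
            continue
        cls = tuple((classifications or {}).get(m, m.rsplit("-", 1)[-1])
                    for m in comp)
        events.append(TransmissionEvent(
            event_id=f"VT{n:04d}", members=tuple(comp),
            member_species=tuple(species[m] for m in comp),
            species_set=frozenset(species[m] for m in comp),
            classifications=cls))
    return events


def map_event_to_tree(event: TransmissionEvent,
                      tree: TimedSpeciesTree) -> TransmissionEvent:
    """Attach the MRCA node and its age (a minimum integration age)."""
    node, age = tree.mrca(event.species_set)
    event.mrca_node = node
    event.age_mya = age
    return event


def summarize_events(events: list[TransmissionEvent], tree: TimedSpeciesTree
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-node event counts by classification, and per-species element counts."""
    node_rows = {label: {"node": label, "age_mya": age, "n_events": 0}
                 for label, age in tree.internal_nodes()}
    species_rows: dict[tuple[str, str], int] = {}
    for ev in events:
        if ev.mrca_node is None:
            raise ValueError(f"event {ev.event_id} not mapped to the tree")
        row = node_rows.setdefault(
            ev.mrca_node, {"node": ev.mrca_node,
                           "age_mya": tree.node_age(ev.mrca_node),
                           "n_events": 0})
        row["n_events"] += 1
        cls = ev.classification
        row[cls] = row.get(cls, 0) + 1
        for sp, mcls in zip(ev.member_species, ev.classifications):
            species_rows[(sp, mcls)] = species_rows.get((sp, mcls), 0) + 1
    per_node = pd.DataFrame(node_rows.values()).fillna(0)
    per_species = pd.DataFrame(
        [{"species": sp, "classification": c, "n_elements": n}
         for (sp, c), n in sorted(species_rows.items())])
    return per_node, per_species


def infer_transmission(flanked: list[FlankedElement], tree: TimedSpeciesTree,
                       thresholds: VtThresholds | None = None
                       ) -> tuple[list[TransmissionEvent], list[OrthologPair]]:
    """Screen pairs, cluster into events and date them on the tree."""
    pairs = screen_ortholog_pairs(flanked, thresholds)
    classifications = {fe.element_id: fe.element.classification
                       for fe in flanked}
    events = build_event_graph(pairs, classifications)
    for ev in events:
        map_event_to_tree(ev, tree)
    return events, pairs
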