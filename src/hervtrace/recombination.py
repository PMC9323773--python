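"""LTR-discordance screening for provirus-mediated genomic rearrangement.

The two LTRs of one provirus are identical at integration and drift apart
only by post-insertion mutation, so each LTR's closest relative should be
its own partner.  When instead each LTR of an element scores higher against
the LTRs of another element of the same species and supergroup — and the
two map onto that element's two distinct LTRs (the reciprocal pattern) —
the pair is flagged as a candidate inter-element recombination.

Comparisons are stratified by (species, classification) and phrased in
best-local-hit bit scores; ties never flag (a conservative reading of
"higher").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import ScoringScheme, best_local_score_nt
from .discovery import ErvElement

SIDES = ("5p", "3p")


@dataclass(frozen=True)
class LtrRecord:
    element_id: str
    side: str  # 5p or 3p
    sequence: str
    species: str
    classification: str


@dataclass
class LtrScoreMatrix:
    """Symmetric best-hit bit-score matrix over one stratum's LTR records."""

    records: list[LtrRecord]
    bits: np.ndarray  # records x records; diagonal NaN

    @property
    def index(self) -> dict[tuple[str, str], int]:
        return {(r.element_id, r.side): i for i, r in enumerate(self.records)}


@dataclass
class RecombinationCall:
    element_1: str
    element_2: str
    matching: dict[str, str]  # side of element_1 -> side of element_2
    own_pair_scores: tuple[float, float]
    cross_scores: tuple[float, float]

    def key(self) -> frozenset[str]:
        return frozenset((self.element_1, self.element_2))


def ltr_records_from_elements(elements: list[ErvElement],
                              genomes: dict[str, dict[str, str]]
                              ) -> list[LtrRecord]:
    """Extract 5'/3' LTR sequences (element-sense sides) from genomes."""
    out = []
    for e in elements:
        seq = genomes[e.species][e.interval.contig]
        left = seq[e.ltrs.five_prime.start:e.ltrs.five_prime.end]
        right = seq[e.ltrs.three_prime.start:e.ltrs.three_prime.end]
        if e.interval.strand == "-":
            left, right = right, left
        if not left or not right:
            continue
        out.append(LtrRecord(e.element_id, "5p", left, e.species,
                             e.classification))
        out.append(LtrRecord(e.element_id, "3p", right, e.species,
                             e.classification))
    return out


def stratify(records: list[LtrRecord]) -> dict[tuple[str, str], list[LtrRecord]]:
    strata: dict[tuple[str, str], list[LtrRecord]] = {}
    complete: dict[tuple[str, str], set[str]] = {}
    for r in records:
        key = (r.species, r.classification)
        strata.setdefault(key, []).append(r)
        complete.setdefault(key, set())
    # keep only elements contributing both sides
    out = {}
    for key, recs in strata.items():
        sides: dict[str, set[str]] = {}
        for r in recs:
            sides.setdefault(r.element_id, set()).add(r.side)
        keep = {eid for eid, s in sides.items() if s == set(SIDES)}
        out[key] = sorted((r for r in recs if r.element_id in keep),
                          key=lambda r: (r.element_id, r.side))
    return out


def build_score_matrix(records: list[LtrRecord],
                       scoring: ScoringScheme | None = None) -> LtrScoreMatrix:
    """All-vs-all best local bit scores within one stratum (both strands)."""
    scoring = scoring or ScoringScheme.nucleotide()
    n = len(records)
    bits = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            raw = best_local_score_nt(records[i].sequence, records[j].sequence,
                                      scoring)
            bits[i, j] = bits[j, i] = scoring.bit_score(raw)
    return LtrScoreMatrix(records=records, bits=bits)


def _element_sides(matrix: LtrScoreMatrix) -> dict[str, dict[str, int]]:
    by_elem: dict[str, dict[str, int]] = {}
    for i, r in enumerate(matrix.records):
        by_elem.setdefault(r.element_id, {})[r.side] = i
    return {eid: s for eid, s in by_elem.items() if set(s) == set(SIDES)}


def flag_nonclustered(matrix: LtrScoreMatrix) -> dict[str, bool]:
    """Element -> True when some foreign LTR outscores its own LTR pair.

    A score-based surrogate for "the element's two LTRs do not form a
    sibling pair on the LTR tree": the element is non-clustered iff, for at
    least one of its LTRs, a different element's LTR achieves a strictly
    higher bit score than the element's own partner LTR does.
    """
    elems = _element_sides(matrix)
    flags: dict[str, bool] = {}
    for eid, sides in elems.items():
        i5, i3 = sides["5p"], sides["3p"]
        own = matrix.bits[i5, i3]
        non = False
        for idx in (i5, i3):
            for j, rec in enumerate(matrix.records):
                if rec.element_id == eid:
                    continue
                if matrix.bits[idx, j] > own:
                    non = True
        flags[eid] = non
    return flags


def detect_recombination(matrix: LtrScoreMatrix) -> list[RecombinationCall]:
    """Reciprocally matching discordant LTR pairs within one stratum.

    A call (e1, e2) requires, for both elements, that each of its LTRs
    scores strictly higher against some LTR of the other element than
    against its own partner, with the two LTRs mapping to the other
    element's two distinct LTRs.
    """
    elems = _element_sides(matrix)
    ids = sorted(elems)
    calls: list[RecombinationCall] = []

    def best_partner(idx: int, other: str) -> tuple[str, float]:
        cand = [(matrix.bits[idx, elems[other][s]], s) for s in SIDES]
        score, side = max(cand)
        return side, score

    for a_i, e1 in enumerate(ids):
        i5, i3 = elems[e1]["5p"], elems[e1]["3p"]
        own1 = matrix.bits[i5, i3]
        for e2 in ids[a_i + 1:]:
            j5, j3 = elems[e2]["5p"], elems[e2]["3p"]
            own2 = matrix.bits[j5, j3]
            m5, s5 = best_partner(i5, e2)
            m3, s3 = best_partner(i3, e2)
            if not (s5 > own1 and s3 > own1 and m5 != m3):
                continue
            r5, t5 = best_partner(j5, e1)
            r3, t3 = best_partner(j3, e1)
            if not (t5 > own2 and t3 > own2 and r5 != r3):
                continue
            calls.append(RecombinationCall(
                element_1=e1, element_2=e2,
                matching={"5p": m5, "3p": m3},
                own_pair_scores=(float(own1), float(own2)),
                cross_scores=(float(s5), float(s3))))
    return calls


def scan_strata(records: list[LtrRecord],
                scoring: ScoringScheme | None = None
                ) -> tuple[list[RecombinationCall], dict[str, bool]]:
    """Run non-clustered flagging and recombination detection per stratum."""
    calls: list[RecombinationCall] = []
    flags: dict[str, bool] = {}
    for key, recs in sorted(stratify(records).items()):
        if len({r.element_id for r in recs}) < 2:
            for r in recs:
                flags.setdefault(r.element_id, False)
            continue
        matrix = build_score_matrix(recs, scoring)
        flags.update(flag_nonclustered(matrix))
        calls.extend(detect_recombination(matrix))
    return calls, flags


def summarize_recombination(calls: list[RecombinationCall],
                            elements: list[ErvElement]) -> pd.DataFrame:
    """Counts of recombination-involved elements by species and classification."""
    info = {e.element_id: (e.species, e.classification) for e in elements}
    involved = sorted({eid for c in calls for eid in (c.element_1, c.element_2)})
    rows: dict[tuple[str, str], int] = {}
    for eid in involved:
        sp, cls = info.get(eid, (eid.split("_")[0], eid.rsplit("-", 1)[-1]))
        rows[(sp, cls)] = rows.get((sp, cls), 0) + 1
    return pd.DataFrame(
        [{"species": sp, "classification": c, "n_elements": n}
         for (sp, c), n in sorted(rows.items())])
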