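"""Full-length provirus discovery.

The pipeline screens a genome with reverse-transcriptase (RT) protein
references in translated search, merges nearby footprints, discards
candidates that align better to host or non-retroviral viral proteins,
extends surviving candidates and locates the two LTRs as the best pair of
direct repeats, annotates internal gag/pro/pol/env genes, calls an element
full-length when an RT-bearing pol is present and the genes observed lie in
gag-pro-pol-env order, and classifies it to a retroviral supergroup by
nearest RT reference identity.

Coordinates are 0-based half-open throughout; element names follow the
``species_contig_start-end-CLASS`` convention with a 1-based start, so the
class parses from the suffix after the final hyphen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .alignment import (AlignmentInputError, PairwiseHit, SearchParams,
                        local_align_nt, translated_search)

SUPERGROUP_LABELS = ("MLLV", "HERVERI", "HERVFRDLIKE", "HEPSI", "HUERSP",
                     "HERVW9", "HERVIPADP", "MER50like", "HERVHF", "HERVK",
                     "HSERVIII", "Unknown")

GENE_ORDER = ("gag", "pro", "pol", "env")


class DiscoveryInputError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.contig:
            raise DiscoveryInputError("empty contig name")
        if self.end <= self.start:
            raise DiscoveryInputError(
                f"end must exceed start: {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RtCandidate:
    interval: GenomicInterval
    best_ref: str
    best_bit: float
    category: str  # erv / host / other_virus

    @property
    def surviving(self) -> bool:
        return self.category == "erv"


@dataclass
class LtrPair:
    five_prime: GenomicInterval  # left repeat in genome-forward coordinates
    three_prime: GenomicInterval
    ltr_identity_pct: float


@dataclass
class GeneAnnotation:
    gene: str
    interval: GenomicInterval
    aa_length: int
    domain_hits: list[tuple[str, PairwiseHit]] = field(default_factory=list)

    @property
    def has_rt_domain(self) -> bool:
        return any(dom == "RT" for dom, _ in self.domain_hits)


@dataclass
class ErvElement:
    element_id: str
    species: str
    interval: GenomicInterval
    ltrs: LtrPair
    genes: list[GeneAnnotation]
    classification: str
    is_full_length: bool


@dataclass(frozen=True)
class DiscoveryConfig:
    evalue_cutoff: float = 1e-5
    merge_gap_bp: int = 1000
    extension_bp: int = 10_000
    min_gene_aa: int = 100
    ltr_min_len: int = 100
    ltr_max_len: int = 3000
    ltr_min_identity_pct: float = 80.0
    ltr_search_window_bp: int = 10_000
    classify_min_identity_pct: float = 60.0

    def __post_init__(self):
        for name in ("evalue_cutoff", "merge_gap_bp", "extension_bp",
                     "min_gene_aa", "ltr_min_len", "ltr_max_len",
                     "ltr_min_identity_pct", "classify_min_identity_pct"):
            if getattr(self, name) <= 0:
                raise DiscoveryInputError(f"{name} must be positive")


def _search_params(cfg: DiscoveryConfig) -> SearchParams:
    return SearchParams(evalue_cutoff=cfg.evalue_cutoff)


def screen_rt(genome: dict[str, str], rt_panel: dict[str, str],
              cfg: DiscoveryConfig) -> list[GenomicInterval]:
    """Nucleotide footprints of translated RT hits passing the e-value cutoff."""
    if not genome:
        raise DiscoveryInputError("empty genome")
    if not rt_panel:
        raise AlignmentInputError("empty protein reference panel")
    params = _search_params(cfg)
    seen = set()
    out: list[GenomicInterval] = []
    for contig in genome:
        for hit in translated_search(genome[contig], rt_panel, params=params,
                                     subject_id=contig):
            key = (contig, hit.s_start, hit.s_end)
            if key in seen:
                continue
            seen.add(key)
            out.append(GenomicInterval(contig, hit.s_start, hit.s_end, hit.strand))
    out.sort(key=lambda iv: (iv.contig, iv.start, iv.end))
    return out


def merge_hits(intervals: list[GenomicInterval], merge_gap_bp: int) -> list[GenomicInterval]:
    """Merge intervals on the same contig separated by < ``merge_gap_bp``."""
    by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    merged: list[GenomicInterval] = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        strands = {ivs[0].strand}
        for iv in ivs[1:]:
            if iv.start - cur_end < merge_gap_bp:
                cur_end = max(cur_end, iv.end)
                strands.add(iv.strand)
            else:
                merged.append(GenomicInterval(
                    contig, cur_start, cur_end,
                    strands.pop() if len(strands) == 1 else "."))
                cur_start, cur_end, strands = iv.start, iv.end, {iv.strand}
        merged.append(GenomicInterval(
            contig, cur_start, cur_end,
            strands.pop() if len(strands) == 1 else "."))
    return merged


def competitive_filter(intervals: list[GenomicInterval], genome: dict[str, str],
                       erv_refs: dict[str, str], host_refs: dict[str, str],
                       other_virus_refs: dict[str, str],
                       cfg: DiscoveryConfig) -> list[RtCandidate]:
    """Label each interval by the panel holding its best-bit-score reference.

    Ties favour retention: erv > other_virus > host.
    """
    params = _search_params(cfg)
    panels = (("erv", erv_refs), ("other_virus", other_virus_refs),
              ("host", host_refs))
    out = []
    for iv in intervals:
        seq = genome[iv.contig][iv.start:iv.end]
        best = None  # (bit, priority, ref, category, strand)
        for prio, (cat, refs) in enumerate(panels):
            if not refs:
                continue
            hits = translated_search(seq, refs, params=params)
            if hits:
                h = hits[0]
                cand = (h.bit_score, -prio, h.query_id, cat, h.strand)
                if best is None or cand[:2] > best[:2]:
                    best = cand
        if best is None:
            continue
        bit, _, ref, cat, strand = best
        out.append(RtCandidate(
            interval=GenomicInterval(iv.contig, iv.start, iv.end, strand),
            best_ref=ref, best_bit=bit, category=cat))
    return out


_REFINE_MAX_BP = 100


_ANCHOR_IN = 25      # re-anchor this far inside each repeat end
_ANCHOR_WIN = 20     # window used to vote the pairing offset
_ANCHOR_DMAX = 6     # largest alignment-end offset correction considered


def _refine_repeat_ends(seq: str, qa: int, qb: int, sa: int, sb: int,
                        identity_fraction: float = 0.95
                        ) -> tuple[int, int, int, int]:
    """Move repeat-pair boundaries to the repeat/flank changepoint.

    Local alignment ends are noisy in both directions: terminal columns
    whose suffix scores negative get clipped (boundary lands inside the
    repeat), and a lucky gapped extension can overshoot into unrelated
    flank.  Each end is therefore re-anchored a fixed distance inside the
    repeat, the pairing offset between the two copies is re-estimated by a
    best-matching-window vote (correcting for spurious end gaps), and an
    ungapped walk outward from the anchor places the boundary at its score
    argmax -- extending through isolated mismatches yet stopping quickly
    once the sequences decorrelate.  The walk's mismatch penalty is the
    likelihood-ratio optimum for the observed repeat identity p against a
    random (25% match) background: ``-ln((1-p)/0.75) / ln(p/0.25)`` per
    match unit.
    """
    import math

    p = min(0.97, max(0.70, identity_fraction))
    pen = min(2.5, max(1.0, -math.log((1 - p) / 0.75) / math.log(p / 0.25)))

    def vote_offset(q0: int, s0: int, step: int) -> int | None:
        # compare windows growing inward from the anchors
        best_d, best_m = None, -1
        for d in range(-_ANCHOR_DMAX, _ANCHOR_DMAX + 1):
            m = 0
            for k in range(_ANCHOR_WIN):
                qi, si = q0 + step * k, s0 + d + step * k
                if not (0 <= qi < len(seq) and 0 <= si < len(seq)):
                    m = -1
                    break
                m += seq[qi] == seq[si]
            if m > best_m:
                best_m, best_d = m, d
        return best_d if best_m >= int(0.6 * _ANCHOR_WIN) else None

    def walk(q0: int, s0: int, step: int, lo_q: int, hi_q: int) -> int:
        # outward ungapped walk; returns signed shift of the boundary
        best, score, shift = 0.0, 0.0, 0
        for k in range(_ANCHOR_IN + _REFINE_MAX_BP):
            qi, si = q0 + step * k, s0 + step * k
            if not (lo_q <= qi < hi_q and 0 <= si < len(seq)):
                break
            score += 1.0 if seq[qi] == seq[si] else -pen
            if score > best:
                best, shift = score, k + 1
        return shift

    out = [qa, qb, sa, sb]
    # end side: anchors _ANCHOR_IN inside the repeat ends, walking forward
    q0, s0 = qb - _ANCHOR_IN, sb - _ANCHOR_IN
    d = vote_offset(q0 - _ANCHOR_WIN, s0 - _ANCHOR_WIN, 1)
    if d is not None:
        hi_q = sa if sa > q0 else len(seq)
        shift = walk(q0, s0 + d, 1, 0, hi_q)
        if shift:
            out[1], out[3] = q0 + shift, s0 + d + shift
    # start side: anchors inside the repeat starts, walking backward
    q0, s0 = qa + _ANCHOR_IN - 1, sa + _ANCHOR_IN - 1
    d = vote_offset(q0 + 1, s0 + 1, 1)
    if d is not None:
        shift = walk(q0, s0 + d, -1, 0, out[1])
        if shift:
            out[0], out[2] = q0 - shift + 1, s0 + d - shift + 1
    qa2, qb2, sa2, sb2 = out
    if qb2 <= qa2 or sb2 <= sa2 or sa2 < qb2:
        return qa, qb, sa, sb  # refinement collapsed; keep alignment ends
    return qa2, qb2, sa2, sb2


def extend_and_find_ltrs(candidate: RtCandidate, genome: dict[str, str],
                         cfg: DiscoveryConfig) -> LtrPair | None:
    """Best qualifying pair of direct repeats around the candidate footprint."""
    iv = candidate.interval
    seq = genome[iv.contig]
    left_lo = max(0, iv.start - cfg.extension_bp)
    right_hi = min(len(seq), iv.end + cfg.extension_bp)
    left = seq[left_lo:iv.start]
    right = seq[iv.end:right_hi]
    if len(left) < cfg.ltr_min_len or len(right) < cfg.ltr_min_len:
        return None
    hits = local_align_nt(left, right, params=SearchParams(evalue_cutoff=1e-3),
                          both_strands=False, max_hits=8)
    for h in hits:
        qa, qb, sa, sb = _refine_repeat_ends(
            seq, left_lo + h.q_start, left_lo + h.q_end,
            iv.end + h.s_start, iv.end + h.s_end,
            identity_fraction=h.identity_pct / 100.0)
        len5 = qb - qa
        len3 = sb - sa
        if not (cfg.ltr_min_len <= len5 <= cfg.ltr_max_len
                and cfg.ltr_min_len <= len3 <= cfg.ltr_max_len):
            continue
        if max(len5, len3) > 2 * min(len5, len3):
            continue
        if h.identity_pct < cfg.ltr_min_identity_pct:
            continue
        return LtrPair(
            five_prime=GenomicInterval(iv.contig, qa, qb, "+"),
            three_prime=GenomicInterval(iv.contig, sa, sb, "+"),
            ltr_identity_pct=h.identity_pct)
    return None


def annotate_genes(element_span: GenomicInterval, genome: dict[str, str],
                   gene_panels: dict[str, dict[str, str]],
                   cfg: DiscoveryConfig,
                   rt_panel: dict[str, str] | None = None,
                   strand: str | None = None) -> list[GeneAnnotation]:
    """Annotate internal genes between the LTRs.

    Per-gene hit footprints are merged like RT hits; merged annotations
    shorter than ``min_gene_aa`` amino acids are discarded.  When
    ``rt_panel`` is given, RT domain hits inside the pol footprint are
    attached to the pol annotation.
    """
    params = _search_params(cfg)
    seq = genome[element_span.contig][element_span.start:element_span.end]
    out: list[GeneAnnotation] = []
    for gene in GENE_ORDER:
        refs = gene_panels.get(gene)
        if not refs:
            continue
        hits = [h for h in translated_search(seq, refs, params=params)
                if strand is None or h.strand == strand]
        if not hits:
            continue
        footprints = merge_hits(
            [GenomicInterval("x", h.s_start, h.s_end, h.strand) for h in hits],
            cfg.merge_gap_bp)
        for fp in footprints:
            aa_len = fp.length // 3
            if aa_len < cfg.min_gene_aa:
                continue
            ann = GeneAnnotation(
                gene=gene,
                interval=GenomicInterval(element_span.contig,
                                         element_span.start + fp.start,
                                         element_span.start + fp.end,
                                         fp.strand),
                aa_length=aa_len,
                domain_hits=[(gene, h) for h in hits
                             if fp.start <= h.s_start and h.s_end <= fp.end])
            if gene == "pol" and rt_panel:
                sub = seq[fp.start:fp.end]
                rt_hits = [h for h in translated_search(sub, rt_panel,
                                                        params=params)
                           if strand is None or h.strand == strand]
                for h in rt_hits:
                    shifted = replace(h, s_start=fp.start + h.s_start,
                                      s_end=fp.start + h.s_end)
                    ann.domain_hits.append(("RT", shifted))
            out.append(ann)
    out.sort(key=lambda a: a.interval.start)
    return out


def call_full_length(ltrs: LtrPair | None, genes: list[GeneAnnotation],
                     strand: str = "+") -> bool:
    """True iff an RT-bearing pol exists and gene order fits gag-pro-pol-env.

    Gene order is read along the element strand; the genes present must be
    a subsequence of (gag, pro, pol, env).
    """
    if ltrs is None or not genes:
        return False
    if not any(g.gene == "pol" and g.has_rt_domain for g in genes):
        return False
    ordered = sorted(genes, key=lambda g: g.interval.start,
                     reverse=(strand == "-"))
    names = [g.gene for g in ordered]
    it = iter(GENE_ORDER)
    return all(any(ref == name for ref in it) for name in names)


def classify(rt_nt_sequence: str, rt_panel: dict[str, str],
             cfg: DiscoveryConfig,
             labels: dict[str, str] | None = None) -> str:
    """Supergroup of the highest-identity RT reference, else Unknown.

    ``labels`` maps panel reference ids to supergroup names; by default the
    supergroup is the reference id's prefix before the first underscore.
    Ties break by higher bit score, then lexicographic label.
    """
    if not rt_nt_sequence:
        raise DiscoveryInputError("element has no RT sequence to classify")
    hits = translated_search(rt_nt_sequence, rt_panel,
                             params=SearchParams(evalue_cutoff=1e-3))
    best: dict[str, tuple[float, float]] = {}
    for h in hits:
        cur = best.get(h.query_id)
        cand = (h.identity_pct, h.bit_score)
        if cur is None or cand > cur:
            best[h.query_id] = cand
    scored = []
    for ref, (ident, bit) in best.items():
        label = labels[ref] if labels else ref.split("_")[0]
        scored.append((-ident, -bit, label))
    scored.sort()
    if not scored or -scored[0][0] < cfg.classify_min_identity_pct:
        return "Unknown"
    return scored[0][2]


def discover(genome: dict[str, str], panels: dict[str, dict[str, str]],
             cfg: DiscoveryConfig | None = None,
             species: str = "unknown_species") -> tuple[list[ErvElement], dict[str, int]]:
    """Run the full discovery pipeline on one genome.

    ``panels`` must provide "rt", per-gene ("gag".."env"), "host" and
    "other_virus" protein sets.  Returns the elements (full-length or not)
    and the per-stage survivor counts.
    """
    cfg = cfg or DiscoveryConfig()
    funnel: dict[str, int] = {}
    raw = screen_rt(genome, panels["rt"], cfg)
    funnel["rt_hits"] = len(raw)
    merged = merge_hits(raw, cfg.merge_gap_bp)
    funnel["merged_candidates"] = len(merged)
    candidates = [c for c in competitive_filter(
        merged, genome, panels["rt"], panels.get("host", {}),
        panels.get("other_virus", {}), cfg) if c.surviving]
    funnel["post_competitive"] = len(candidates)
    elements: list[ErvElement] = []
    gene_panels = {g: panels.get(g, {}) for g in GENE_ORDER}
    for cand in candidates:
        ltrs = extend_and_find_ltrs(cand, genome, cfg)
        if ltrs is None:
            continue
        strand = cand.interval.strand if cand.interval.strand in "+-" else "+"
        span = GenomicInterval(cand.interval.contig, ltrs.five_prime.end,
                               ltrs.three_prime.start, strand)
        genes = annotate_genes(span, genome, gene_panels, cfg,
                               rt_panel=panels["rt"], strand=strand)
        full = call_full_length(ltrs, genes, strand)
        classification = "Unknown"
        rt_hits = [h for g in genes for dom, h in g.domain_hits if dom == "RT"]
        if rt_hits:
            best_rt = max(rt_hits, key=lambda h: h.bit_score)
            rt_nt = genome[span.contig][span.start + best_rt.s_start:
                                        span.start + best_rt.s_end]
            classification = classify(rt_nt, panels["rt"], cfg)
        interval = GenomicInterval(cand.interval.contig, ltrs.five_prime.start,
                                   ltrs.three_prime.end, strand)
        element_id = (f"{species}_{interval.contig}_{interval.start + 1}-"
                      f"{interval.end}-{classification}")
        elements.append(ErvElement(
            element_id=element_id, species=species, interval=interval,
            ltrs=ltrs, genes=genes, classification=classification,
            is_full_length=full))
    funnel["with_ltrs"] = len(elements)
    funnel["full_length"] = sum(e.is_full_length for e in elements)
    funnel["classified"] = sum(e.classification != "Unknown" for e in elements)
    return elements, funnel


def elements_to_bed(elements: list[ErvElement]):
    for e in elements:
        yield (e.interval.contig, e.interval.start, e.interval.end,
               e.element_id, int(e.is_full_length), e.interval.strand)


def elements_to_gtf(elements: list[ErvElement]):
    for e in elements:
        yield (e.interval.contig, "ERV", e.interval.start, e.interval.end,
               e.interval.strand,
               {"element_id": e.element_id, "classification": e.classification,
                "is_full_length": str(e.is_full_length).lower()})


def elements_from_bed(bed_path, ltr_bed_path=None,
                      species: str = "unknown_species") -> list[ErvElement]:
    """Rebuild minimal elements from discovery's BED outputs.

    The elements BED carries the element span, id (class in the name
    suffix), full-length flag in the score column and strand; the optional
    LTR BED (names ``<element_id>:5p/3p``) restores the repeat intervals.
    Gene annotations are not round-tripped.
    """
    from .io import read_bed

    ltrs: dict[str, dict[str, GenomicInterval]] = {}
    if ltr_bed_path is not None:
        for contig, start, end, name, _score, strand in read_bed(ltr_bed_path):
            eid, side = name.rsplit(":", 1)
            ltrs.setdefault(eid, {})[side] = GenomicInterval(
                contig, start, end, strand)
    elements = []
    for contig, start, end, name, score, strand in read_bed(bed_path):
        pair = None
        if name in ltrs and set(ltrs[name]) == {"5p", "3p"}:
            lt = ltrs[name]
            left, right = sorted((lt["5p"], lt["3p"]), key=lambda iv: iv.start)
            pair = LtrPair(left, right, 100.0)
        elements.append(ErvElement(
            element_id=name, species=species,
            interval=GenomicInterval(contig, start, end, strand),
            ltrs=pair, genes=[],
            classification=name.rsplit("-", 1)[-1],
            is_full_length=str(score) == "1"))
    return elements
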