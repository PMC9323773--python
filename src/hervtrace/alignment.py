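"""Pairwise local alignment core.

Every downstream stage of the pipeline (retrovirus discovery, orthologous
insertion testing, LTR comparison) consumes the same alignment currency:
identity, query/subject coverage, raw score, bit score and e-value of the
best local alignments between two sequences.  This module produces those
quantities for nucleotide-nucleotide comparisons and for protein queries
against six-frame translations of nucleotide sequences.

The dynamic programming itself is delegated to Biopython's
:class:`Bio.Align.PairwiseAligner` (an exact Smith-Waterman with affine
gaps).  For pairs too large for a full matrix we seed candidate windows with
shared k-mers and run the exact aligner inside each window; hit scores are
therefore always true local alignment scores of a concrete path.

Scores are converted to bit scores and e-values with Karlin-Altschul
statistics: ``bits = (lambda * S - ln K) / ln 2`` and
``E = K * m * n * exp(-lambda * S)`` with ``m`` and ``n`` the full lengths
of query and subject in the units of the comparison (nt or aa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

NT_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

#: full-matrix DP is used below this cell count; above it, seeded windows
FULL_DP_MAX_CELLS = 30_000_000

_SEED_K_NT = 12
_SEED_K_AA = 4
_DIAG_BAND = 64


class AlignmentInputError(ValueError):
    """Raised for empty sequences, bad alphabets or empty reference panels."""


@dataclass(frozen=True)
class ScoringScheme:
    """Scoring parameters plus Karlin-Altschul constants.

    ``gap_open`` is the penalty of the first residue of a gap and
    ``gap_extend`` of each subsequent residue, so a gap of length L costs
    ``gap_open + (L - 1) * gap_extend``.  ``lambda_`` is in nats per
    raw-score unit.
    """

    match_score: int = 1
    mismatch_score: int = -2
    gap_open: float = 2.5
    gap_extend: float = 2.5
    lambda_: float = 1.28
    k_const: float = 0.46
    protein_matrix_id: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if not (self.match_score > 0 > self.mismatch_score):
            raise ValueError("need match_score > 0 > mismatch_score")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must be <= gap_open")
        for name in ("lambda_", "k_const"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive")

    @classmethod
    def nucleotide(cls) -> "ScoringScheme":
        return cls()

    @classmethod
    def protein(cls) -> "ScoringScheme":
        # ungapped BLOSUM62 Karlin-Altschul constants
        return cls(match_score=11, mismatch_score=-4, gap_open=11.0,
                   gap_extend=1.0, lambda_=0.3176, k_const=0.134)

    def bit_score(self, raw_score: float) -> float:
        return (self.lambda_ * raw_score - math.log(self.k_const)) / math.log(2)

    def e_value(self, raw_score: float, m: int, n: int) -> float:
        return self.k_const * m * n * math.exp(-self.lambda_ * raw_score)


@dataclass(frozen=True)
class SearchParams:
    evalue_cutoff: float = 1e-5
    min_raw_score: float = 0.0
    frames: tuple[int, ...] = (1, 2, 3, -1, -2, -3)

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        bad = set(self.frames) - {1, 2, 3, -1, -2, -3}
        if bad:
            raise ValueError(f"invalid frames: {sorted(bad)}")


@dataclass
class PairwiseHit:
    """One local alignment, coordinates 0-based half-open on forward strands."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # orientation of the subject: '+' or '-'
    aligned_cols: int
    identities: int
    q_cov_pct: float
    s_cov_pct: float
    raw_score: float
    bit_score: float
    e_value: float

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identities / self.aligned_cols if self.aligned_cols else 0.0


def _validate_nt(seq: str, name: str) -> str:
    if not seq:
        raise AlignmentInputError(f"{name}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - NT_ALPHABET
    if bad:
        raise AlignmentInputError(
            f"{name}: invalid nucleotide symbol {sorted(bad)[0]!r}")
    return seq


def _validate_aa(seq: str, name: str) -> str:
    if not seq:
        raise AlignmentInputError(f"{name}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise AlignmentInputError(
            f"{name}: invalid amino-acid symbol {sorted(bad)[0]!r}")
    return seq


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def nt_substitution_matrix(scoring: ScoringScheme):
    """ACGTN matrix; N scores as a mismatch against everything, itself included."""
    alpha = "ACGTN"
    m = np.full((5, 5), float(scoring.mismatch_score))
    for i in range(4):
        m[i, i] = float(scoring.match_score)
    return substitution_matrices.Array(alphabet=alpha, dims=2, data=m)


def protein_substitution_matrix(scoring: ScoringScheme):
    """Protein matrix with stop codons made unalignable (terminate frames)."""
    base = substitution_matrices.load(scoring.protein_matrix_id)
    alpha = base.alphabet
    if "*" not in alpha:
        alpha = alpha + "*"
    arr = np.zeros((len(alpha), len(alpha)))
    for i, a in enumerate(alpha):
        for j, b in enumerate(alpha):
            if a == "*" or b == "*":
                arr[i, j] = -1e4
            else:
                arr[i, j] = base[a, b]
    return substitution_matrices.Array(alphabet=alpha, dims=2, data=arr)


def _make_aligner(matrix, scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


_TIEBREAK_EPS = 2.0 ** -13  # dyadic: perturbed sums stay exact in doubles


def _tiebreak_matrix(matrix, skip: str = "N*"):
    """Copy of ``matrix`` with identical-residue cells nudged up by epsilon.

    Used only to pick, among co-optimal local alignments, the path with the
    most identities; the nudge (eps * alignment length << score granularity)
    cannot change which paths are optimal under the true scoring.  The
    returned path's score is re-verified against the true optimum and the
    unperturbed aligner is used as a fallback if they ever disagree.
    """
    alpha = matrix.alphabet
    arr = np.array(matrix, dtype=float)
    for i, a in enumerate(alpha):
        if a not in skip:
            arr[i, i] += _TIEBREAK_EPS
    return substitution_matrices.Array(alphabet=alpha, dims=2, data=arr)


def _alignment_stats(alignment, q: str, s: str, matrix,
                     scoring: ScoringScheme, protein: bool):
    """(q_start, q_end, s_start, s_end, aligned_cols, identities, path_score).

    ``path_score`` is the alignment path's score under the true scoring,
    recomputed from scratch.  In nucleotide mode N never counts as an
    identity; in protein mode N is asparagine and does.
    """
    qb, sb = alignment.aligned
    q_start, q_end = int(qb[0][0]), int(qb[-1][1])
    s_start, s_end = int(sb[0][0]), int(sb[-1][1])
    cols = 0
    idents = 0
    path_score = 0.0
    for (qs, qe), (ss, se) in zip(qb, sb):
        cols += qe - qs
        for a, b in zip(q[qs:qe], s[ss:se]):
            path_score += matrix[a, b]
            if a == b and (protein or a != "N"):
                idents += 1
    for k in range(1, len(qb)):
        for gap in (qb[k][0] - qb[k - 1][1], sb[k][0] - sb[k - 1][1]):
            cols += gap
            if gap > 0:
                path_score -= scoring.gap_open + (gap - 1) * scoring.gap_extend
    return q_start, q_end, s_start, s_end, cols, idents, path_score


def _seed_windows(q: str, s: str, k: int) -> list[tuple[int, int]]:
    """Subject windows likely to contain an alignment, from shared k-mers."""
    index: dict[str, list[int]] = {}
    for i in range(len(q) - k + 1):
        index.setdefault(q[i:i + k], []).append(i)
    matches: list[tuple[int, int]] = []  # (diagonal, s_pos)
    for j in range(len(s) - k + 1):
        for i in index.get(s[j:j + k], ()):
            matches.append((j - i, j))
    if not matches:
        return []
    matches.sort()
    pad = len(q) + _DIAG_BAND
    clusters: list[list[tuple[int, int]]] = []
    for d, j in matches:
        if clusters and d - clusters[-1][-1][0] <= _DIAG_BAND:
            clusters[-1].append((d, j))
        else:
            clusters.append([(d, j)])
    windows = []
    for cl in clusters:
        lo = max(0, min(j for _, j in cl) - pad)
        hi = min(len(s), max(j for _, j in cl) + k + pad)
        windows.append((lo, hi))
    windows.sort()
    merged = [list(windows[0])]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def _search_one_strand(q: str, s: str, aligners, scoring: ScoringScheme,
                       params: SearchParams, m: int, n: int,
                       max_hits: int, protein: bool = False) -> list[dict]:
    """Iterated best-hit search of q against s (forward orientation of s).

    Full DP when the matrix is small; otherwise exact DP inside seeded
    windows.  After each accepted hit the subject span is masked so further
    hits elsewhere can surface.
    """
    seed_k = _SEED_K_AA if protein else _SEED_K_NT
    if len(q) * len(s) <= FULL_DP_MAX_CELLS:
        windows = [(0, len(s))]
    else:
        windows = _seed_windows(q, s, seed_k)
    hits: list[dict] = []
    mask_char = "X" if protein else "N"
    aligner, tiebreak = aligners
    matrix = aligner.substitution_matrix
    for lo, hi in windows:
        sub = s[lo:hi]
        for _ in range(max_hits):
            # score-only first: skip path retrieval for hits that cannot
            # pass the e-value cutoff
            score = float(aligner.score(q, sub))
            if score <= 0 or score < params.min_raw_score:
                break
            e = scoring.e_value(score, m, n)
            if e > params.evalue_cutoff:
                break
            alignment = tiebreak.align(q, sub)[0]
            qs, qe, ss, se, cols, idents, path_score = _alignment_stats(
                alignment, q, sub, matrix, scoring, protein)
            if abs(path_score - score) > 1e-6:
                # tie-break path drifted off the true optimum; use the
                # unperturbed aligner's path instead
                alignment = aligner.align(q, sub)[0]
                qs, qe, ss, se, cols, idents, _ = _alignment_stats(
                    alignment, q, sub, matrix, scoring, protein)
            hits.append(dict(q_start=qs, q_end=qe, s_start=lo + ss,
                             s_end=lo + se, aligned_cols=cols,
                             identities=idents, raw_score=score,
                             bit_score=scoring.bit_score(score),
                             e_value=e))
            sub = sub[:ss] + mask_char * (se - ss) + sub[se:]
    return hits


def local_align_nt(query: str, subject: str, scoring: ScoringScheme | None = None,
                   params: SearchParams | None = None, query_id: str = "query",
                   subject_id: str = "subject", max_hits: int = 16,
                   both_strands: bool = True) -> list[PairwiseHit]:
    """Local nucleotide alignment of ``query`` against both strands of ``subject``.

    Returns hits sorted by descending bit score with subject coordinates on
    the forward strand; hits whose e-value exceeds ``params.evalue_cutoff``
    are excluded.
    """
    scoring = scoring or ScoringScheme.nucleotide()
    params = params or SearchParams()
    query = _validate_nt(query, "query")
    subject = _validate_nt(subject, "subject")
    matrix = nt_substitution_matrix(scoring)
    aligners = (_make_aligner(matrix, scoring),
                _make_aligner(_tiebreak_matrix(matrix), scoring))
    m, n = len(query), len(subject)
    hits: list[PairwiseHit] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        s = subject if strand == "+" else reverse_complement(subject)
        for h in _search_one_strand(query, s, aligners, scoring, params, m, n,
                                    max_hits):
            ss, se = h.pop("s_start"), h.pop("s_end")
            if strand == "-":
                ss, se = n - se, n - ss
            hits.append(PairwiseHit(
                query_id=query_id, subject_id=subject_id, strand=strand,
                s_start=ss, s_end=se,
                q_cov_pct=100.0 * (h["q_end"] - h["q_start"]) / m,
                s_cov_pct=100.0 * (se - ss) / n, **h))
    hits.sort(key=lambda h: (-h.bit_score, h.s_start, h.strand))
    return hits


_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def translate_frame(nt: str, frame: int) -> str:
    """Translate one frame (+1..+3 forward, -1..-3 on the reverse complement)."""
    s = nt if frame > 0 else reverse_complement(nt)
    off = abs(frame) - 1
    trimmed = s[off:off + 3 * ((len(s) - off) // 3)]
    return str(Seq(trimmed).translate())


def _aa_span_to_nt(aa_start: int, aa_end: int, frame: int, nt_len: int) -> tuple[int, int]:
    off = abs(frame) - 1
    if frame > 0:
        return off + 3 * aa_start, off + 3 * aa_end
    return nt_len - (off + 3 * aa_end), nt_len - (off + 3 * aa_start)


def translated_search(subject_nt: str, protein_refs: dict[str, str],
                      scoring: ScoringScheme | None = None,
                      params: SearchParams | None = None,
                      subject_id: str = "subject",
                      max_hits: int = 16) -> list[PairwiseHit]:
    """Search protein references against all translation frames of ``subject_nt``.

    Subject coordinates of each hit are reported in nucleotide space on the
    forward strand; protein-level identity and coverage are in amino-acid
    columns.  Stop codons are unalignable, so hits never cross a stop.
    """
    if not protein_refs:
        raise AlignmentInputError("empty protein reference panel")
    scoring = scoring or ScoringScheme.protein()
    params = params or SearchParams()
    subject_nt = _validate_nt(subject_nt, "subject")
    matrix = protein_substitution_matrix(scoring)
    aligners = (_make_aligner(matrix, scoring),
                _make_aligner(_tiebreak_matrix(matrix, skip="*"), scoring))
    nt_len = len(subject_nt)
    hits: list[PairwiseHit] = []
    frames = {f: translate_frame(subject_nt, f) for f in params.frames}
    for ref_id, ref_seq in protein_refs.items():
        ref = _validate_aa(ref_seq, ref_id)
        m = len(ref)
        for frame, aa in frames.items():
            if len(aa) == 0:
                continue
            for h in _search_one_strand(ref, aa, aligners, scoring, params,
                                        m, len(aa), max_hits, protein=True):
                ss, se = _aa_span_to_nt(h.pop("s_start"), h.pop("s_end"),
                                        frame, nt_len)
                hits.append(PairwiseHit(
                    query_id=ref_id, subject_id=subject_id,
                    strand="+" if frame > 0 else "-",
                    s_start=ss, s_end=se,
                    q_cov_pct=100.0 * (h["q_end"] - h["q_start"]) / m,
                    s_cov_pct=100.0 * (se - ss) / nt_len, **h))
    hits.sort(key=lambda h: (-h.bit_score, h.s_start, h.strand))
    return hits


def local_align_aa(query: str, subject: str, scoring: ScoringScheme | None = None,
                   params: SearchParams | None = None, query_id: str = "query",
                   subject_id: str = "subject") -> list[PairwiseHit]:
    """Protein-protein local alignment with the same hit contract."""
    scoring = scoring or ScoringScheme.protein()
    params = params or SearchParams()
    query = _validate_aa(query, "query")
    subject = _validate_aa(subject, "subject")
    matrix = protein_substitution_matrix(scoring)
    aligners = (_make_aligner(matrix, scoring),
                _make_aligner(_tiebreak_matrix(matrix, skip="*"), scoring))
    m, n = len(query), len(subject)
    hits = []
    for h in _search_one_strand(query, subject, aligners, scoring, params,
                                m, n, 8, protein=True):
        ss, se = h.pop("s_start"), h.pop("s_end")
        hits.append(PairwiseHit(
            query_id=query_id, subject_id=subject_id, strand="+",
            s_start=ss, s_end=se,
            q_cov_pct=100.0 * (h["q_end"] - h["q_start"]) / m,
            s_cov_pct=100.0 * (se - ss) / n, **h))
    hits.sort(key=lambda h: -h.bit_score)
    return hits


def best_local_score_nt(a: str, b: str, scoring: ScoringScheme | None = None,
                        both_strands: bool = True) -> float:
    """Score-only best local alignment (used where only bit scores matter)."""
    scoring = scoring or ScoringScheme.nucleotide()
    a = _validate_nt(a, "a")
    b = _validate_nt(b, "b")
    aligner = _make_aligner(nt_substitution_matrix(scoring), scoring)
    best = float(aligner.score(a, b))
    if both_strands:
        best = max(best, float(aligner.score(a, reverse_complement(b))))
    return best


def parse_blast_tabular(text: str, scoring: ScoringScheme | None = None) -> list[PairwiseHit]:
    """Adapter for an external BLAST-family backend (disabled by default).

    Parses '-outfmt 6'-style tabular output (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore, 1-based
    inclusive coordinates) into the internal hit contract.  Raw score is
    back-computed from the bit score.  Query/subject coverage cannot be
    derived from the table alone and is set to NaN.
    """
    scoring = scoring or ScoringScheme.nucleotide()
    hits = []
    for line in text.strip().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        qs, qe = int(f[6]) - 1, int(f[7])
        s1, s2 = int(f[8]), int(f[9])
        strand = "+" if s2 >= s1 else "-"
        ss, se = (s1 - 1, s2) if strand == "+" else (s2 - 1, s1)
        cols = int(f[3])
        bit = float(f[11])
        raw = (bit * math.log(2) + math.log(scoring.k_const)) / scoring.lambda_
        hits.append(PairwiseHit(
            query_id=f[0], subject_id=f[1], q_start=qs, q_end=qe,
            s_start=ss, s_end=se, strand=strand, aligned_cols=cols,
            identities=round(float(f[2]) / 100.0 * cols),
            q_cov_pct=float("nan"), s_cov_pct=float("nan"),
            raw_score=raw, bit_score=bit, e_value=float(f[10])))
    hits.sort(key=lambda h: -h.bit_score)
    return hits
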