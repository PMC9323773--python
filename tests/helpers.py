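"""Independent oracles and small constructors shared by the test suite.

Everything here deliberately avoids the production code paths it checks:
the containment oracle is a nested loop, distances for the NJ oracle come
from the reference DP aligner, and the random ultrametric trees are built
directly as newick strings.
"""

from __future__ import annotations

import numpy as np

from hervtrace.swdp import sw_best

NT = "ACGT"


def rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(NT), size=n))


def substitute(seq: str, positions, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in positions:
        out[i] = rng.choice([c for c in NT if c != out[i]])
    return "".join(out)


def mutate_frac(seq: str, frac: float, rng: np.random.Generator) -> str:
    k = int(round(frac * len(seq)))
    pos = rng.choice(len(seq), size=k, replace=False)
    return substitute(seq, pos, rng)


def brute_force_containment(hervs, ncrnas):
    """All-pairs scan: same contig+strand, >=1 bp overlap, one side 100%."""
    pairs = set()
    for h in hervs:
        for n in ncrnas:
            if h.contig != n.contig or h.strand != n.strand:
                continue
            ov = min(h.end, n.end) - max(h.start, n.start)
            if ov < 1:
                continue
            if ov == (h.end - h.start) or ov == (n.end - n.start):
                pairs.add((h.feature_id, n.feature_id, ov))
    return pairs


def oracle_identity_fraction(a: str, b: str) -> float:
    """Identity of the best local alignment per the reference DP."""
    score, *_rest, cols, idents = sw_best(a, b)
    return idents / cols if cols else 0.0


def nj_sibling_clustered(records: dict[str, dict[str, str]]) -> dict[str, bool]:
    """NJ-tree oracle: is each element's LTR pair a sibling cherry?

    Distances are alignment distances (1 - identity) from the reference DP
    aligner; the tree is built with scikit-bio's neighbour joining.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    names = [f"{eid}|{side}" for eid in sorted(records) for side in ("5p", "3p")]
    seqs = {f"{eid}|{side}": records[eid][side]
            for eid in records for side in ("5p", "3p")}
    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - oracle_identity_fraction(seqs[names[i]], seqs[names[j]])
            dm[i, j] = dm[j, i] = d
    tree = nj(DistanceMatrix(dm, ids=names))
    clustered = {}
    for eid in records:
        tip5 = tree.find(f"{eid}|5p")
        siblings = {t.name for t in tip5.parent.children if t.is_tip()}
        clustered[eid] = f"{eid}|3p" in siblings
    return clustered


def random_ultrametric_newick(rng: np.random.Generator, n_leaves: int,
                              root_age: float = 30.0) -> str:
    """Random ultrametric tree via recursive splitting with shrinking ages."""
    leaves = [f"sp{i}" for i in range(n_leaves)]

    def build(tips: list[str], age: float) -> tuple[str, float]:
        # returns (newick without branch length, node age)
        if len(tips) == 1:
            return tips[0], 0.0
        k = int(rng.integers(1, len(tips)))
        left, la = build(tips[:k], age * float(rng.uniform(0.3, 0.9)))
        right, ra = build(tips[k:], age * float(rng.uniform(0.3, 0.9)))
        return f"({left}:{age - la:.12f},{right}:{age - ra:.12f})", age

    nwk, _ = build(leaves, root_age)
    return nwk + ";"
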