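"""Strand-aware containment intersection of proviruses with ncRNA features.

A provirus is a co-option candidate when it shares its location and
orientation with an annotated (non-coding) transcript: the pair must lie on
the same contig and strand, overlap by at least 1 bp, and at least one of
the two features must be 100% contained in the overlap.  The module also
provides the per-chromosome and per-supergroup summaries over the packaged
human annotation table.

The packaged table (``data/table1_ncrna.tsv``) lists 107 human provirus /
ncRNA pairs with 1-based inclusive transcript coordinates; provirus
coordinates parse from the element name
(``Homo_sapiens_<chrom>_<start>-<end>-<class>``).  A few printed rows have
transcript and provirus intervals that do not physically overlap; they are
retained for the summaries but flagged by the validator rather than being
silently reconciled.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import data_path

TABLE1_FILE = "table1_ncrna.tsv"


class FeatureInputError(ValueError):
    pass


@dataclass(frozen=True)
class TranscriptFeature:
    feature_id: str
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    source: str = "ensembl-like"

    def __post_init__(self):
        if self.end <= self.start:
            raise FeatureInputError(
                f"{self.feature_id}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OverlapPair:
    herv_id: str
    ncrna_id: str
    overlap_bp: int
    herv_cov_pct: float
    ncrna_cov_pct: float
    strand: str


def _check_stranded(features, what: str) -> None:
    for f in features:
        if f.strand not in "+-":
            raise FeatureInputError(
                f"strand-aware intersection requires a strand on every "
                f"{what} feature; {f.feature_id} has {f.strand!r}")


def containment_intersect(hervs: list[TranscriptFeature],
                          ncrnas: list[TranscriptFeature]
                          ) -> list[OverlapPair]:
    """Same-strand overlapping pairs where one feature is fully contained.

    Implemented as a per-(contig, strand) sorted sweep; coordinates are
    0-based half-open.
    """
    _check_stranded(hervs, "provirus")
    _check_stranded(ncrnas, "ncRNA")
    by_key: dict[tuple[str, str], list[TranscriptFeature]] = {}
    for f in ncrnas:
        by_key.setdefault((f.contig, f.strand), []).append(f)
    for key in by_key:
        by_key[key].sort(key=lambda f: (f.start, f.end))
    out: list[OverlapPair] = []
    for h in sorted(hervs, key=lambda f: (f.contig, f.strand, f.start, f.end)):
        for n in by_key.get((h.contig, h.strand), ()):
            if n.start >= h.end:
                break
            ov = min(h.end, n.end) - max(h.start, n.start)
            if ov < 1:
                continue
            h_cov = 100.0 * ov / h.length
            n_cov = 100.0 * ov / n.length
            if max(h_cov, n_cov) < 100.0:
                continue
            out.append(OverlapPair(h.feature_id, n.feature_id, ov,
                                   h_cov, n_cov, h.strand))
    return out


# ---------------------------------------------------------------------------
# packaged human annotation table


def parse_element_name(name: str) -> tuple[str, str, int, int, str]:
    """(species, contig, start0, end, classification) from an element name.

    Names follow ``<species>_<contig>_<start>-<end>-<class>`` with 1-based
    inclusive coordinates, e.g.
    ``Homo_sapiens_1_23000272-23002212-HERVHF``.
    """
    try:
        head, cls = name.rsplit("-", 1)
        body, coords = head.rsplit("_", 1)
        species, contig = body.rsplit("_", 1)
        start_s, end_s = coords.split("-")
        return species, contig, int(start_s) - 1, int(end_s), cls
    except ValueError as exc:
        raise FeatureInputError(f"unparseable element name: {name}") from exc


def load_table1(path=None) -> pd.DataFrame:
    """Load the packaged provirus/ncRNA table, converting to half-open coords.

    Adds ``herv_start``/``herv_end`` (parsed from the element name),
    ``classification`` and a ``consistent`` flag marking rows whose printed
    transcript interval overlaps the provirus interval with one feature
    fully contained.
    """
    df = pd.read_csv(path or data_path(TABLE1_FILE), sep="\t",
                     dtype={"Chromosome": str})
    df["nc_start"] = df["Start"] - 1
    df["nc_end"] = df["End"]
    parsed = df["HERVname"].map(parse_element_name)
    df["herv_start"] = [p[2] for p in parsed]
    df["herv_end"] = [p[3] for p in parsed]
    df["classification"] = [p[4] for p in parsed]
    ov = (df[["nc_end", "herv_end"]].min(axis=1)
          - df[["nc_start", "herv_start"]].max(axis=1))
    herv_len = df["herv_end"] - df["herv_start"]
    nc_len = df["nc_end"] - df["nc_start"]
    df["consistent"] = (ov >= 1) & ((ov == herv_len) | (ov == nc_len))
    return df


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Rows whose printed coordinates violate the containment contract."""
    return df[~df["consistent"]]


def summarize_by_chromosome(df: pd.DataFrame) -> pd.Series:
    """Distinct provirus count per chromosome, descending."""
    if df.empty:
        return pd.Series(dtype=int)
    counts = (df.drop_duplicates("HERVname").groupby("Chromosome").size()
              .sort_values(ascending=False))
    counts.name = "n_hervs"
    return counts


def summarize_by_class(df: pd.DataFrame) -> pd.Series:
    """Provirus count per supergroup; unparseable names count as Unknown."""
    if df.empty:
        return pd.Series(dtype=int)

    def cls_of(name: str) -> str:
        try:
            return parse_element_name(name)[4]
        except (ValueError, FeatureInputError):
            return "Unknown"

    counts = (df["HERVname"].map(cls_of).value_counts())
    counts.name = "n_hervs"
    return counts


def table_to_features(df: pd.DataFrame
                      ) -> tuple[list[TranscriptFeature], list[TranscriptFeature]]:
    """(herv features, ncRNA features) from the annotation table."""
    hervs, ncrnas = [], []
    for _, row in df.iterrows():
        hervs.append(TranscriptFeature(
            row["HERVname"], str(row["Chromosome"]), int(row["herv_start"]),
            int(row["herv_end"]), row["Strand"], source="ensembl-like"))
        src = ("noncode-like" if str(row["Related-ncRNA"]).startswith("NON")
               else "ensembl-like")
        ncrnas.append(TranscriptFeature(
            row["Related-ncRNA"], str(row["Chromosome"]), int(row["nc_start"]),
            int(row["nc_end"]), row["Strand"], source=src))
    return hervs, ncrnas
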