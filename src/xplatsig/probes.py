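"""Cross-platform probe mapping by genomic center distance.

Microarray platforms interrogate the same transcript with probes placed
at different positions.  Given BED-style genomic coordinates for the
probes of two platforms, this module pairs each probe with the nearest
probe of the other platform *on the same gene* (distance = |center A −
center B| in bp, centers taken exactly as (start+end)/2 on 0-based
half-open intervals), flags pairs that are each other's nearest as
*mutual best matches*, and merges two expression matrices over the
retained pairs so that row i of one matrix measures the same transcript
region as row i of the other.

Equidistant candidates are resolved deterministically: smaller start
coordinate first, then lexicographically smaller probe id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .concordance import DistanceBins, bin_by_distance

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeLocus",
    "MappingFilter",
    "MappingTable",
    "MergedDataset",
    "probe_center",
    "pair_distance",
    "nearest_cross_platform",
    "find_mutual_best_matches",
    "filter_mapping",
    "merge_datasets",
    "read_probe_bed",
    "write_probe_bed",
]

PAIR_COLUMNS = ["probe_a", "probe_b", "gene_id", "distance_bp", "mutual", "bin"]


@dataclass(frozen=True)
class ProbeLocus:
    """A probe's aligned genomic interval (0-based, half-open) plus gene."""

    probe_id: str
    platform_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    gene_id: str = ""

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"{self.probe_id}: start must be >= 0")
        if self.end <= self.start:
            raise ValueError(f"{self.probe_id}: end must exceed start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.probe_id}: strand must be + or -")

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class MappingFilter:
    """Retention rule for probe pairs: mutual-only within a distance cap.

    ``max_distance_bp`` is inclusive ("within 1000 bp" keeps a pair at
    exactly 1000 bp).
    """

    max_distance_bp: float = 1000.0
    mutual_only: bool = True

    def __post_init__(self):
        if self.max_distance_bp <= 0:
            raise ValueError("max_distance_bp must be positive")


@dataclass
class MappingTable:
    """Annotated cross-platform probe pairs.

    ``pairs`` columns: probe_a, probe_b, gene_id, distance_bp, mutual,
    bin.  Mutual pairs form a one-to-one matching: a probe id appears at
    most once on its side among the mutual rows.
    """

    pairs: pd.DataFrame
    platform_a_id: str = "A"
    platform_b_id: str = "B"
    filter_record: Optional[MappingFilter] = None

    def __post_init__(self):
        missing = [c for c in PAIR_COLUMNS if c not in self.pairs.columns]
        if missing:
            raise ValueError(f"mapping table lacks column(s): {missing}")
        mut = self.pairs[self.pairs["mutual"]]
        if mut["probe_a"].duplicated().any() or mut["probe_b"].duplicated().any():
            raise ValueError("mutual pairs must form a one-to-one matching")

    def __len__(self) -> int:
        return len(self.pairs)

    def mutual_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["mutual"]]

    def translation(self, reverse: bool = False) -> dict:
        """probe_a -> probe_b over mutual pairs (or b -> a if reverse)."""
        mut = self.mutual_pairs()
        src, dst = ("probe_b", "probe_a") if reverse else ("probe_a", "probe_b")
        return dict(zip(mut[src], mut[dst]))

    def write(self, path, header_comments: Sequence[str] = ()) -> None:
        path = Path(path)
        with open(path, "w") as handle:
            for line in header_comments:
                handle.write(f"# {line}\n")
            handle.write(f"# platform_a={self.platform_a_id}\tplatform_b={self.platform_b_id}\n")
            if self.filter_record is not None:
                handle.write(
                    f"# filter max_distance_bp={self.filter_record.max_distance_bp:g}"
                    f"\tmutual_only={self.filter_record.mutual_only}\n"
                )
            self.pairs.to_csv(handle, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def read(cls, path) -> "MappingTable":
        path = Path(path)
        platform_a, platform_b, filt = "A", "B", None
        with open(path) as handle:
            pos = handle.tell()
            for line in iter(handle.readline, ""):
                if not line.startswith("#"):
                    handle.seek(pos)
                    break
                text = line[1:].strip()
                if text.startswith("platform_a="):
                    fields = dict(f.split("=", 1) for f in text.split("\t"))
                    platform_a = fields.get("platform_a", platform_a)
                    platform_b = fields.get("platform_b", platform_b)
                elif text.startswith("filter "):
                    fields = dict(f.split("=", 1) for f in text[7:].split("\t"))
                    filt = MappingFilter(
                        max_distance_bp=float(fields["max_distance_bp"]),
                        mutual_only=fields["mutual_only"] == "True",
                    )
                pos = handle.tell()
            pairs = pd.read_csv(handle, sep="\t",
                                dtype={"probe_a": str, "probe_b": str,
                                       "gene_id": str, "bin": str})
        pairs["mutual"] = pairs["mutual"].astype(bool)
        pairs["distance_bp"] = pairs["distance_bp"].astype(float)
        return cls(pairs=pairs, platform_a_id=platform_a,
                   platform_b_id=platform_b, filter_record=filt)


@dataclass
class MergedDataset:
    """Two expression matrices row-aligned over matched probe pairs."""

    a: pd.DataFrame
    b: pd.DataFrame
    pairs: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self):
        if not (len(self.a) == len(self.b) == len(self.pairs)):
            raise ValueError("merged matrices and pair table must be row-aligned")


def probe_center(locus: ProbeLocus) -> float:
    """Exact interval midpoint, (start + end) / 2 — may be a half-integer."""
    return locus.center


def pair_distance(a: ProbeLocus, b: ProbeLocus) -> float:
    """|center(a) − center(b)| in bp; loci must share a chromosome."""
    if a.chrom != b.chrom:
        raise ValueError(
            f"loci on different chromosomes are incomparable: "
            f"{a.probe_id}@{a.chrom} vs {b.probe_id}@{b.chrom}"
        )
    return abs(a.center - b.center)


def _loci_frame(loci: Iterable[ProbeLocus]) -> pd.DataFrame:
    rows = [(p.probe_id, p.platform_id, p.chrom, p.start, p.end, p.strand,
             p.gene_id, p.center) for p in loci]
    frame = pd.DataFrame(rows, columns=["probe_id", "platform_id", "chrom",
                                        "start", "end", "strand", "gene_id",
                                        "center"])
    dup = frame.duplicated(subset=["platform_id", "probe_id"])
    if dup.any():
        raise ValueError(
            f"duplicate probe id(s) within a platform: "
            f"{frame.loc[dup, 'probe_id'].unique()[:5]}"
        )
    return frame


def nearest_cross_platform(query: ProbeLocus,
                           candidates: Iterable[ProbeLocus]) -> Optional[str]:
    """Id of the same-gene, same-chromosome candidate nearest to ``query``.

    Ties go to the smaller start coordinate, then the lexicographically
    smaller probe id.  Returns None when no admissible candidate exists.
    """
    pool = [c for c in candidates
            if c.gene_id == query.gene_id and c.chrom == query.chrom]
    if not pool:
        return None
    best = min(pool, key=lambda c: (abs(c.center - query.center), c.start,
                                    c.probe_id))
    return best.probe_id


def _nearest_per_group(queries: pd.DataFrame, cands: pd.DataFrame) -> pd.Series:
    """Vectorised nearest-candidate id for every query, per (gene, chrom)."""
    # candidates sorted by (start, probe_id): argmin then returns the
    # tie-rule winner because numpy argmin keeps the first minimum
    out = pd.Series(index=queries.index, dtype=object)
    cand_groups = {key: grp.sort_values(["start", "probe_id"], kind="stable")
                   for key, grp in cands.groupby(["gene_id", "chrom"], sort=False)}
    for key, q in queries.groupby(["gene_id", "chrom"], sort=False):
        grp = cand_groups.get(key)
        if grp is None:
            continue
        centers = grp["center"].to_numpy()
        ids = grp["probe_id"].to_numpy()
        dist = np.abs(q["center"].to_numpy()[:, None] - centers[None, :])
        out.loc[q.index] = ids[np.argmin(dist, axis=1)]
    return out


def find_mutual_best_matches(set_a: Iterable[ProbeLocus],
                             set_b: Iterable[ProbeLocus],
                             bins: DistanceBins = DistanceBins()) -> MappingTable:
    """Build the full cross-platform pair table from both platforms' loci.

    For every probe of platform A the nearest same-gene platform-B probe
    is recorded, and vice versa; the union is deduplicated.  A pair is
    mutual exactly when each probe is the other's nearest.  Distances and
    distance bins are annotated on every pair.
    """
    frame_a = _loci_frame(set_a)
    frame_b = _loci_frame(set_b)
    platform_a = frame_a["platform_id"].iloc[0] if len(frame_a) else "A"
    platform_b = frame_b["platform_id"].iloc[0] if len(frame_b) else "B"

    nearest_b = _nearest_per_group(frame_a, frame_b)  # per A probe
    nearest_a = _nearest_per_group(frame_b, frame_a)  # per B probe

    center_a = dict(zip(frame_a["probe_id"], frame_a["center"]))
    center_b = dict(zip(frame_b["probe_id"], frame_b["center"]))
    gene_a = dict(zip(frame_a["probe_id"], frame_a["gene_id"]))
    best_of_a = dict(zip(frame_a["probe_id"], nearest_b))
    best_of_b = dict(zip(frame_b["probe_id"], nearest_a))

    seen = {}
    for a_id, b_id in best_of_a.items():
        if isinstance(b_id, str):
            seen[(a_id, b_id)] = True
    for b_id, a_id in best_of_b.items():
        if isinstance(a_id, str):
            seen.setdefault((a_id, b_id), True)

    rows = []
    for (a_id, b_id) in seen:
        mutual = best_of_a.get(a_id) == b_id and best_of_b.get(b_id) == a_id
        rows.append((a_id, b_id, gene_a[a_id],
                     abs(center_a[a_id] - center_b[b_id]), mutual))
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS[:5])
    if len(pairs):
        pairs["bin"] = bin_by_distance(pairs["distance_bp"].to_numpy(), bins)
        pairs = pairs.sort_values(["gene_id", "probe_a", "probe_b"],
                                  kind="stable").reset_index(drop=True)
    else:
        pairs["bin"] = pd.Series(dtype=object)
    return MappingTable(pairs=pairs, platform_a_id=platform_a,
                        platform_b_id=platform_b)


def filter_mapping(table: MappingTable, filt: MappingFilter) -> MappingTable:
    """Retain (mutual if requested) pairs within the distance cap (inclusive)."""
    pairs = table.pairs
    keep = pairs["distance_bp"] <= filt.max_distance_bp
    if filt.mutual_only:
        keep &= pairs["mutual"]
    return MappingTable(pairs=pairs[keep].reset_index(drop=True),
                        platform_a_id=table.platform_a_id,
                        platform_b_id=table.platform_b_id,
                        filter_record=filt)


def merge_datasets(expr_a: pd.DataFrame, expr_b: pd.DataFrame,
                   table: MappingTable) -> MergedDataset:
    """Row-align two expression matrices over the table's probe pairs.

    Pairs whose probes are absent from either matrix are dropped (count
    logged).  Zero surviving pairs is an error.
    """
    pairs = table.pairs
    present = (pairs["probe_a"].isin(expr_a.index)
               & pairs["probe_b"].isin(expr_b.index))
    n_dropped = int((~present).sum())
    if n_dropped:
        logger.warning("merge: dropped %d pair(s) absent from the matrices",
                       n_dropped)
    kept = pairs[present].reset_index(drop=True)
    if not len(kept):
        raise ValueError("no probe pair is present in both expression matrices")
    # same samples hybridised to both platforms -> restrict to the shared
    # sample ids so rows can be correlated profile-against-profile
    shared = [c for c in expr_a.columns if c in set(expr_b.columns)]
    cols_a = shared if shared else list(expr_a.columns)
    cols_b = shared if shared else list(expr_b.columns)
    a = expr_a.loc[kept["probe_a"], cols_a]
    b = expr_b.loc[kept["probe_b"], cols_b]
    return MergedDataset(a=a, b=b, pairs=kept, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# BED I/O (BED6 + gene_id + platform_id)


def read_probe_bed(path) -> list:
    """Load probe loci from BED6+2 (chrom start end name score strand
    gene_id platform_id), tab-separated, '#' comments allowed."""
    loci = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected 8 BED6+2 columns, "
                                 f"got {len(fields)}")
            chrom, start, end, name, _score, strand, gene_id, platform_id = fields[:8]
            loci.append(ProbeLocus(probe_id=name, platform_id=platform_id,
                                   chrom=chrom, start=int(start), end=int(end),
                                   strand=strand, gene_id=gene_id))
    ids = [(p.platform_id, p.probe_id) for p in loci]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate (platform, probe) ids")
    return loci


def write_probe_bed(loci: Iterable[ProbeLocus], path,
                    header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as handle:
        for line in header_comments:
            handle.write(f"# {line}\n")
        for p in loci:
            handle.write("\t".join([p.chrom, str(p.start), str(p.end),
                                    p.probe_id, "0", p.strand, p.gene_id,
                                    p.platform_id]) + "\n")
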