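"""Dereplication and greedy 90%-identity clustering of variable regions.

Identity between two sequences is defined by a global alignment scored
match +1, mismatch 0, gap 0 and chosen to maximise the number of matching
columns (among such alignments, the one with the fewest columns, i.e. the
fewest gaps, is taken):

    identity = matches / alignment_columns

so identical strings score 1.0 and sequences with no common subsequence
score 0.0.  Clustering is greedy abundance-ordered centroid clustering in
the CD-HIT / USEARCH style: unique sequences are visited in descending
total count (ties broken lexicographically); each joins the first existing
centroid at identity >= threshold (boundary inclusive) or founds a new
cluster.  Clustering is performed jointly over all samples so one cluster
id tracks the same sequence family across every selection branch.

The inner loop is exact but screened: cheap necessary conditions (length
ratio, shared base composition, an edit-distance bound evaluated with
edlib) discard centroids that cannot reach the threshold before the full
dynamic program runs.  The screens are mathematically implied by the
identity definition, so the result is identical to brute force.
"""

from __future__ import annotations

import hashlib
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from numba import njit

from .readprep import VariableRegionRecord

_BIG = 4096  # > max alignment columns; packs (matches, paired columns) into one int

_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@njit(cache=True)
def _match_pairs(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    """(max matches, paired columns at that maximum) for global alignment of a, b."""
    la, lb = a.size, b.size
    prev = np.zeros(lb + 1, dtype=np.int64)
    cur = np.zeros(lb + 1, dtype=np.int64)
    for i in range(1, la + 1):
        ai = a[i - 1]
        cur[0] = 0
        for j in range(1, lb + 1):
            best = prev[j - 1] + (_BIG + 1 if ai == b[j - 1] else 1)
            if prev[j] > best:
                best = prev[j]
            if cur[j - 1] > best:
                best = cur[j - 1]
            cur[j] = best
        prev, cur = cur, prev
    s = prev[lb]
    return s // _BIG, s % _BIG


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching columns under the max-matches global alignment."""
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    m, p = _match_pairs(_encode(a), _encode(b))
    return m / (len(a) + len(b) - p)


@dataclass(frozen=True)
class ClusterParams:
    identity_threshold: float = 0.90
    min_report_copies: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.min_report_copies < 1:
            raise ValueError("min_report_copies must be >= 1")


@dataclass
class Cluster:
    cluster_id: str
    representative: str
    copies: dict[str, int]
    members: list[str] = field(default_factory=list, repr=False)

    @property
    def total(self) -> int:
        return sum(self.copies.values())


@dataclass
class ClusterTable:
    clusters: list[Cluster]
    sample_totals: dict[str, int]

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self):
        import pandas as pd

        samples = list(self.sample_totals)
        rows = {
            c.cluster_id: [c.representative]
            + [c.copies.get(s, 0) for s in samples]
            + [c.total]
            for c in self.clusters
        }
        frame = pd.DataFrame.from_dict(
            rows, orient="index", columns=["representative"] + samples + ["total"]
        )
        frame.index.name = "cluster_id"
        return frame

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.clusters:
                fh.write(f">{c.cluster_id}\n{c.representative}\n")

    @classmethod
    def read_tsv(cls, path) -> "ClusterTable":
        import pandas as pd

        frame = pd.read_csv(path, sep="\t", index_col="cluster_id")
        samples = [c for c in frame.columns if c not in ("representative", "total")]
        clusters = [
            Cluster(
                cluster_id=str(idx),
                representative=row["representative"],
                copies={s: int(row[s]) for s in samples},
            )
            for idx, row in frame.iterrows()
        ]
        totals = {s: int(frame[s].sum()) for s in samples}
        return cls(clusters, totals)


def cluster_id_for(representative: str) -> str:
    """Stable cluster label derived from the representative sequence."""
    return "c" + hashlib.sha1(representative.encode("ascii")).hexdigest()[:10]


def dereplicate(
    records: Iterable[VariableRegionRecord | tuple[str, str]],
) -> list[tuple[str, dict[str, int]]]:
    """Collapse exact duplicates into (sequence, per-sample count) entries."""
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for sample_id, sequence in records:
        counts[sequence][sample_id] += 1
    return [(seq, dict(per)) for seq, per in counts.items()]


def _greedy_order(uniques):
    return sorted(uniques, key=lambda e: (-sum(e[1].values()), e[0]))


class _CentroidIndex:
    """Growable arrays of centroid lengths and base compositions for screening."""

    def __init__(self) -> None:
        self.seqs: list[str] = []
        self._cap = 256
        self.lengths = np.empty(self._cap, dtype=np.float64)
        self.comp = np.empty((self._cap, 4), dtype=np.float64)
        self.n = 0

    def add(self, seq: str) -> None:
        if self.n == self._cap:
            self._cap *= 2
            self.lengths = np.resize(self.lengths, self._cap)
            self.comp = np.resize(self.comp, (self._cap, 4))
        enc = _CODE[_encode(seq)]
        self.lengths[self.n] = len(seq)
        self.comp[self.n] = np.bincount(enc, minlength=4)
        self.seqs.append(seq)
        self.n += 1

    def candidates(self, seq: str, threshold: float) -> np.ndarray:
        """Indices (founding order) of centroids that may reach the threshold.

        identity <= min(la,lb)/max(la,lb) and
        identity <= sum_base min(count_a, count_b)/max(la,lb); both bounds
        are necessary, so no true join is screened out.
        """
        n = self.n
        if n == 0:
            return np.empty(0, dtype=np.intp)
        length = float(len(seq))
        lens = self.lengths[:n]
        lo = np.minimum(lens, length)
        hi = np.maximum(lens, length)
        comp = np.bincount(_CODE[_encode(seq)], minlength=4).astype(np.float64)
        shared = np.minimum(self.comp[:n], comp).sum(axis=1)
        mask = (lo >= threshold * hi) & (shared / hi >= threshold)
        return np.nonzero(mask)[0]


def _edlib_bound(la: int, lb: int, threshold: float) -> int:
    # identity >= t implies an alignment with mm+gaps <= matches*(1/t - 1)
    # <= min(la, lb)*(1 - t)/t, which upper-bounds the edit distance
    return int(min(la, lb) * (1.0 - threshold) / threshold)


def cluster(
    uniques: Sequence[tuple[str, Mapping[str, int]]],
    params: ClusterParams = ClusterParams(),
    sample_order: Sequence[str] | None = None,
) -> ClusterTable:
    """Greedy abundance-ordered centroid clustering of dereplicated sequences."""
    t = params.identity_threshold
    ordered = _greedy_order(uniques)

    index = _CentroidIndex()
    member_lists: list[list[tuple[str, Mapping[str, int]]]] = []

    for seq, counts in ordered:
        joined = False
        for ci in index.candidates(seq, t):
            cent = index.seqs[ci]
            k = _edlib_bound(len(seq), len(cent), t)
            if edlib.align(seq, cent, task="distance", k=k)["editDistance"] == -1:
                continue
            if pairwise_identity(seq, cent) >= t:
                member_lists[ci].append((seq, counts))
                joined = True
                break
        if not joined:
            index.add(seq)
            member_lists.append([(seq, counts)])

    samples: list[str] = list(sample_order) if sample_order is not None else []
    seen = set(samples)
    clusters: list[Cluster] = []
    for members in member_lists:
        copies: dict[str, int] = defaultdict(int)
        for _seq, counts in members:
            for sample_id, n in counts.items():
                copies[sample_id] += n
                if sample_id not in seen:
                    seen.add(sample_id)
                    samples.append(sample_id)
        # representative: member with highest total count, tie -> smallest sequence
        rep = min(members, key=lambda e: (-sum(e[1].values()), e[0]))[0]
        clusters.append(
            Cluster(
                cluster_id=cluster_id_for(rep),
                representative=rep,
                copies=dict(copies),
                members=[seq for seq, _ in members],
            )
        )

    clusters.sort(key=lambda c: (-c.total, c.representative))
    # totals are retained-read counts and stay fixed even if low-copy
    # clusters are dropped from the report
    totals = {s: sum(c.copies.get(s, 0) for c in clusters) for s in samples}
    if params.min_report_copies > 1:
        clusters = [c for c in clusters if c.total >= params.min_report_copies]
    return ClusterTable(clusters, totals)


def cluster_records(
    records: Iterable[VariableRegionRecord],
    params: ClusterParams = ClusterParams(),
    sample_order: Sequence[str] | None = None,
) -> ClusterTable:
    """Dereplicate + cluster in one call."""
    return cluster(dereplicate(records), params, sample_order)


def cluster_table_from_counts(
    sequences: Sequence[str], counts_by_sample: Mapping[str, Sequence[int]]
) -> ClusterTable:
    """Build a one-cluster-per-sequence table directly from count vectors.

    Convenience constructor for simulation studies where exact per-member
    counts are known and no read-level clustering is required.
    """
    samples = list(counts_by_sample)
    clusters = []
    for i, seq in enumerate(sequences):
        copies = {s: int(counts_by_sample[s][i]) for s in samples}
        copies = {s: n for s, n in copies.items() if n}
        if not copies:
            continue
        clusters.append(
            Cluster(cluster_id=cluster_id_for(seq), representative=seq, copies=copies,
                    members=[seq])
        )
    clusters.sort(key=lambda c: (-c.total, c.representative))
    totals = {s: int(np.sum(counts_by_sample[s])) for s in samples}
    return ClusterTable(clusters, totals)
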