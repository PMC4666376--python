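"""Raw paired-end reads -> per-sample variable-region sequences.

The amplicon top strand is laid out as::

    barcode_fwd + fwd_constant + variable + rev_constant + revcomp(barcode_rev)

so the forward read starts with the forward barcode and the reverse read
(being the 5' end of the bottom strand) starts with the reverse barcode.

Processing is two-staged:

1. :func:`demultiplex` assigns each read pair to a sample by its barcode pair
   (exact by default) and strips the barcodes;
2. :func:`pair_to_variable` reverse-complements the reverse read, merges the
   pair by maximal exact suffix/prefix overlap, verifies both constant
   regions and extracts the variable region, rejecting pairs whose variable
   region falls outside the configured length bounds or contains N.

Rejection is data, not failure: both stages return per-reason counts and
conserve ``assigned + rejected == total``.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import LibraryDesign, SampleSheet, revcomp

# rejection reason codes
NO_BARCODE_MATCH = "no_barcode_match"
AMBIGUOUS_BARCODE = "ambiguous_barcode"
MERGE_FAILED = "merge_failed"
CONSTANT_MISMATCH = "constant_mismatch"
LENGTH_OUT_OF_RANGE = "length_out_of_range"
AMBIGUOUS_BASE = "ambiguous_base"


class ReadPair(NamedTuple):
    read_id: str
    fwd_seq: str
    fwd_qual: str
    rev_seq: str
    rev_qual: str


class VariableRegionRecord(NamedTuple):
    sample_id: str
    sequence: str


@dataclass
class DemuxReport:
    assigned: Counter = field(default_factory=Counter)   # sample_id -> count
    rejected: Counter = field(default_factory=Counter)   # reason -> count

    @property
    def n_assigned(self) -> int:
        return sum(self.assigned.values())

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())


@dataclass
class FilterReport:
    """Per-sample outcome counts of variable-region extraction."""

    accepted: Counter = field(default_factory=Counter)            # sample_id -> count
    rejected: Counter = field(default_factory=Counter)            # (sample_id, reason) -> count


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming mismatches between equal-length prefixes, early exit past `limit`."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                break
    return n


def _match_entry(pair: ReadPair, entry, max_mismatch: int) -> str | None:
    """'fwd' / 'swapped' / None depending on which orientation the barcodes match."""
    bf, br = entry.barcode_fwd, entry.barcode_rev
    if (
        _mismatches(pair.fwd_seq[: len(bf)], bf, max_mismatch) <= max_mismatch
        and _mismatches(pair.rev_seq[: len(br)], br, max_mismatch) <= max_mismatch
    ):
        return "fwd"
    if (
        _mismatches(pair.fwd_seq[: len(br)], br, max_mismatch) <= max_mismatch
        and _mismatches(pair.rev_seq[: len(bf)], bf, max_mismatch) <= max_mismatch
    ):
        return "swapped"
    return None


def demultiplex_iter(
    pairs: Iterable[ReadPair],
    sheet: SampleSheet,
    max_mismatch: int = 0,
    report: DemuxReport | None = None,
) -> Iterator[tuple[str, ReadPair]]:
    """Yield ``(sample_id, barcode-stripped pair)`` for each assignable pair.

    A pair is assigned iff exactly one sheet entry matches at the allowed
    mismatch level; the two physical files may be swapped (the orientation is
    recognised from the barcodes and the pair is flipped to the canonical
    forward/reverse orientation before stripping).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    entries = list(sheet)

    # fast path: exact prefix lookup keyed on (fwd_prefix, rev_prefix)
    exact = max_mismatch == 0
    if exact:
        lf = {len(e.barcode_fwd) for e in entries}
        lr = {len(e.barcode_rev) for e in entries}
        uniform = len(lf) == 1 and len(lr) == 1
        if uniform:
            nf, nr = lf.pop(), lr.pop()
            fwd_map = {(e.barcode_fwd, e.barcode_rev): e for e in entries}
            swp_map = {(e.barcode_rev, e.barcode_fwd): e for e in entries}
        else:
            exact = False

    for pair in pairs:
        if exact:
            entry_f = fwd_map.get((pair.fwd_seq[:nf], pair.rev_seq[:nr]))
            entry_s = swp_map.get((pair.fwd_seq[:nr], pair.rev_seq[:nf]))
            if entry_f is not None and entry_s is not None and entry_f is not entry_s:
                if report is not None:
                    report.rejected[AMBIGUOUS_BARCODE] += 1
                continue
            if entry_f is not None:
                entry, orientation = entry_f, "fwd"
            elif entry_s is not None:
                entry, orientation = entry_s, "swapped"
            else:
                if report is not None:
                    report.rejected[NO_BARCODE_MATCH] += 1
                continue
        else:
            hits = [(e, o) for e in entries if (o := _match_entry(pair, e, max_mismatch))]
            if not hits:
                if report is not None:
                    report.rejected[NO_BARCODE_MATCH] += 1
                continue
            if len(hits) > 1:
                if report is not None:
                    report.rejected[AMBIGUOUS_BARCODE] += 1
                continue
            entry, orientation = hits[0]

        if orientation == "swapped":
            pair = ReadPair(
                pair.read_id, pair.rev_seq, pair.rev_qual, pair.fwd_seq, pair.fwd_qual
            )
        stripped = ReadPair(
            pair.read_id,
            pair.fwd_seq[len(entry.barcode_fwd):],
            pair.fwd_qual[len(entry.barcode_fwd):],
            pair.rev_seq[len(entry.barcode_rev):],
            pair.rev_qual[len(entry.barcode_rev):],
        )
        if report is not None:
            report.assigned[entry.sample_id] += 1
        yield entry.sample_id, stripped


def demultiplex(
    pairs: Iterable[ReadPair], sheet: SampleSheet, max_mismatch: int = 0
) -> tuple[dict[str, list[ReadPair]], DemuxReport]:
    """Collect :func:`demultiplex_iter` output into per-sample lists."""
    report = DemuxReport()
    out: dict[str, list[ReadPair]] = {e.sample_id: [] for e in sheet}
    for sample_id, pair in demultiplex_iter(pairs, sheet, max_mismatch, report):
        out[sample_id].append(pair)
    return out, report


def _find_with_mismatches(hay: str, needle: str, start: int, limit: int) -> int:
    """Leftmost position >= start where `needle` matches within `limit` mismatches."""
    if limit == 0:
        return hay.find(needle, start)
    n = len(needle)
    for pos in range(start, len(hay) - n + 1):
        if _mismatches(hay[pos : pos + n], needle, limit) <= limit:
            return pos
    return -1


def merge_pair(fwd: str, rev: str, min_overlap: int = 10) -> str | None:
    """Merge forward read and reverse read by maximal exact suffix/prefix overlap.

    The reverse read is reverse-complemented first; the merge requires an
    exact overlap of at least ``min_overlap`` nt (0 mismatches in the
    overlap).  Returns the merged top-strand sequence or None.
    """
    rc = revcomp(rev)
    max_k = min(len(fwd), len(rc))
    for k in range(max_k, min_overlap - 1, -1):
        if fwd[-k:] == rc[:k]:
            return fwd + rc[k:]
    return None


def _extract(merged: str, design: LibraryDesign, cm: int) -> tuple[str | None, str | None]:
    f, r = design.fwd_constant, design.rev_constant
    if len(merged) < len(f) + len(r):
        return None, CONSTANT_MISMATCH
    if _mismatches(merged[: len(f)], f, cm) > cm:
        return None, CONSTANT_MISMATCH
    if _mismatches(merged[len(merged) - len(r):], r, cm) > cm:
        return None, CONSTANT_MISMATCH
    var = merged[len(f): len(merged) - len(r)]
    if not design.var_len_min <= len(var) <= design.var_len_max:
        return None, LENGTH_OUT_OF_RANGE
    if "N" in var:
        return None, AMBIGUOUS_BASE
    return var, None


def _extract_contained(
    read: str, design: LibraryDesign, cm: int
) -> tuple[str | None, str | None]:
    """Variable region from a single read carrying both flank anchors.

    Used when the pair has no usable exact overlap but one read spans
    fwd_constant, variable region and rev_constant completely.  Returns
    ``(None, None)`` when the anchors are not found in this read.
    """
    f, r = design.fwd_constant, design.rev_constant
    if _mismatches(read[: len(f)], f, cm) > cm:
        return None, None
    pos = _find_with_mismatches(read, r, len(f), cm)
    if pos == -1:
        return None, None
    var = read[len(f): pos]
    if not design.var_len_min <= len(var) <= design.var_len_max:
        return None, LENGTH_OUT_OF_RANGE
    if "N" in var:
        return None, AMBIGUOUS_BASE
    return var, None


def pair_to_variable(
    pair: ReadPair,
    design: LibraryDesign,
    constant_mismatch: int = 0,
    min_overlap: int = 10,
    allow_unmerged: bool = True,
) -> tuple[str | None, str | None]:
    """Extract the variable region from a demultiplexed read pair.

    Returns ``(sequence, None)`` on success or ``(None, reason)`` with a
    reason in {merge_failed, constant_mismatch, length_out_of_range,
    ambiguous_base}.
    """
    merged = merge_pair(pair.fwd_seq, pair.rev_seq, min_overlap)
    if merged is not None:
        return _extract(merged, design, constant_mismatch)
    if allow_unmerged:
        # no usable exact overlap: one read may still span both
        # constant-region anchors on its own
        for read in (pair.fwd_seq, revcomp(pair.rev_seq)):
            var, reason = _extract_contained(read, design, constant_mismatch)
            if var is not None or reason is not None:
                return var, reason
    return None, MERGE_FAILED


def extract_variable_regions(
    assigned: Iterable[tuple[str, ReadPair]],
    design: LibraryDesign,
    constant_mismatch: int = 0,
    min_overlap: int = 10,
    report: FilterReport | None = None,
) -> Iterator[VariableRegionRecord]:
    """Run :func:`pair_to_variable` over a demultiplexed stream."""
    for sample_id, pair in assigned:
        var, reason = pair_to_variable(pair, design, constant_mismatch, min_overlap)
        if var is None:
            if report is not None:
                report.rejected[(sample_id, reason)] += 1
            continue
        if report is not None:
            report.accepted[sample_id] += 1
        yield VariableRegionRecord(sample_id, var)


def process_run(
    pairs: Iterable[ReadPair],
    design: LibraryDesign,
    sheet: SampleSheet,
    barcode_mismatch: int = 0,
    constant_mismatch: int = 0,
    min_overlap: int = 10,
) -> tuple[list[VariableRegionRecord], DemuxReport, FilterReport]:
    """Demultiplex + variable-region extraction for one lane of read pairs."""
    demux_report = DemuxReport()
    filter_report = FilterReport()
    records = list(
        extract_variable_regions(
            demultiplex_iter(pairs, sheet, barcode_mismatch, demux_report),
            design,
            constant_mismatch,
            min_overlap,
            filter_report,
        )
    )
    return records, demux_report, filter_report


# ---------------------------------------------------------------------------
# file-level helpers


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_read_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Stream paired FASTQ files (plain or gzip) as :class:`ReadPair`."""
    with _open_text(r1_path) as h1, _open_text(r2_path) as h2:
        for (id1, seq1, q1), (_id2, seq2, q2) in zip(
            FastqGeneralIterator(h1), FastqGeneralIterator(h2), strict=True
        ):
            yield ReadPair(id1.split()[0], seq1.upper(), q1, seq2.upper(), q2)


def write_sample_fastas(records: Iterable[VariableRegionRecord], outdir) -> dict[str, int]:
    """Write one ``<sample_id>.fasta`` per sample; record ids are running indices."""
    import os

    os.makedirs(outdir, exist_ok=True)
    handles: dict[str, object] = {}
    counts: Counter = Counter()
    try:
        for rec in records:
            fh = handles.get(rec.sample_id)
            if fh is None:
                fh = open(os.path.join(outdir, f"{rec.sample_id}.fasta"), "w")
                handles[rec.sample_id] = fh
            counts[rec.sample_id] += 1
            fh.write(f">{counts[rec.sample_id]}\n{rec.sequence}\n")
    finally:
        for fh in handles.values():
            fh.close()
    return dict(counts)


def write_rejection_report(
    demux_report: DemuxReport, filter_report: FilterReport, path
) -> None:
    """TSV of (sample_id, reason, count); demultiplex rejects use sample_id '-'."""
    with open(path, "w") as fh:
        fh.write("sample_id\treason\tcount\n")
        for reason, count in sorted(demux_report.rejected.items()):
            fh.write(f"-\t{reason}\t{count}\n")
        for (sample_id, reason), count in sorted(filter_report.rejected.items()):
            fh.write(f"{sample_id}\t{reason}\t{count}\n")
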