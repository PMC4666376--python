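"""Conserved-motif discovery within an aptamer family.

A greedy seed-and-extend finder for short, highly conserved, ungapped
motifs of the kind branched-selection families share.  Each round:

1. every ``width_min``-mer is scored by the number of distinct family
   members containing it outside already-masked regions;
2. the best-supported seed (ties broken lexicographically) collects its
   leftmost unmasked occurrence per member (zero-or-one occurrence per
   sequence);
3. the window is extended left/right while every added column keeps the
   majority-base frequency at or above ``conservation_min`` and the width
   within bounds;
4. the motif is emitted, its sites masked, and the search repeats until
   ``max_motifs`` or no seed reaches ``min_sites`` support.

Consensus letters follow the >=``conservation_min`` rule: a single base if
one base alone reaches the conservation level, otherwise the minimal IUPAC
degenerate code whose bases cumulatively do.  Motifs are written in MEME
minimal format so externally computed motifs can be substituted
transparently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class MotifParams:
    width_min: int = 5
    width_max: int = 40
    max_motifs: int = 25
    min_sites: int = 10
    max_sites: int = 300
    conservation_min: float = 0.90

    def __post_init__(self) -> None:
        if not 1 <= self.width_min <= self.width_max:
            raise ValueError("need 1 <= width_min <= width_max")
        if not 0 < self.conservation_min <= 1:
            raise ValueError("conservation_min must be in (0, 1]")
        if self.min_sites < 1 or self.max_sites < self.min_sites:
            raise ValueError("need 1 <= min_sites <= max_sites")


@dataclass
class Motif:
    consensus: str
    width: int
    sites: list[tuple[int, int]]          # (sequence index, offset)
    per_position_freqs: np.ndarray        # width x 4, columns ordered ACGT
    n_sites: int


def _column_freqs(bases: Sequence[str]) -> np.ndarray:
    counts = np.zeros(4)
    for b in bases:
        counts[_BASE_INDEX[b]] += 1
    return counts / len(bases)


def consensus_letter(freqs: np.ndarray, conservation_min: float) -> str:
    """IUPAC letter for one column of base frequencies.

    A single base if its frequency alone reaches ``conservation_min``,
    otherwise the minimal degenerate code whose bases cumulatively reach it
    (bases added in decreasing frequency, ties alphabetical).
    """
    order = sorted(range(4), key=lambda i: (-freqs[i], BASES[i]))
    if freqs[order[0]] >= conservation_min:
        return BASES[order[0]]
    chosen = []
    cum = 0.0
    for i in order:
        if freqs[i] <= 0 and cum > 0:
            break
        chosen.append(BASES[i])
        cum += freqs[i]
        if cum >= conservation_min:
            break
    return IUPAC.get(frozenset(chosen), "N")


def consensus_string(
    per_position_freqs: np.ndarray, conservation_min: float = 0.90
) -> str:
    """Map a width x 4 frequency matrix to an IUPAC degenerate string."""
    return "".join(
        consensus_letter(row, conservation_min) for row in np.asarray(per_position_freqs)
    )


def _seed_support(family, masks, k):
    """k-mer -> set of member indices containing it fully unmasked."""
    support: dict[str, set[int]] = {}
    for idx, (seq, mask) in enumerate(zip(family, masks)):
        seen: set[str] = set()
        for pos in range(len(seq) - k + 1):
            if mask[pos: pos + k].any():
                continue
            kmer = seq[pos: pos + k]
            if kmer in seen:
                continue
            seen.add(kmer)
            support.setdefault(kmer, set()).add(idx)
    return support


def find_motifs(
    family: Sequence[str], params: MotifParams = MotifParams()
) -> list[Motif]:
    """Greedy seed-and-extend discovery of conserved ungapped motifs."""
    family = [s.upper() for s in family]
    if len(family) < params.min_sites:
        warnings.warn(
            f"family of {len(family)} sequences is smaller than "
            f"min_sites={params.min_sites}; no motifs searched"
        )
        return []
    k = params.width_min
    masks = [np.zeros(len(s), dtype=bool) for s in family]
    motifs: list[Motif] = []

    while len(motifs) < params.max_motifs:
        support = _seed_support(family, masks, k)
        eligible = {s: members for s, members in support.items()
                    if len(members) >= params.min_sites}
        if not eligible:
            break
        seed = min(eligible, key=lambda s: (-len(eligible[s]), s))
        members = sorted(eligible[seed])[: params.max_sites]

        # leftmost unmasked occurrence per member (zero-or-one rule)
        sites: list[tuple[int, int]] = []
        for idx in members:
            seq, mask = family[idx], masks[idx]
            pos = -1
            while True:
                pos = seq.find(seed, pos + 1)
                if pos == -1:
                    break
                if not mask[pos: pos + k].any():
                    sites.append((idx, pos))
                    break

        start, width = 0, k  # window relative to each site offset
        def column_ok(delta: int) -> np.ndarray | None:
            bases = []
            for idx, off in sites:
                p = off + delta
                if p < 0 or p >= len(family[idx]) or masks[idx][p]:
                    return None
                bases.append(family[idx][p])
            freqs = _column_freqs(bases)
            return freqs if freqs.max() >= params.conservation_min else None

        grew = True
        while grew and width < params.width_max:
            grew = False
            if width < params.width_max and column_ok(start + width) is not None:
                width += 1
                grew = True
            if width < params.width_max and column_ok(start - 1) is not None:
                start -= 1
                width += 1
                grew = True

        final_sites = [(idx, off + start) for idx, off in sites]
        freqs = np.vstack(
            [
                _column_freqs([family[idx][off + w] for idx, off in final_sites])
                for w in range(width)
            ]
        )
        motifs.append(
            Motif(
                consensus=consensus_string(freqs, params.conservation_min),
                width=width,
                sites=final_sites,
                per_position_freqs=freqs,
                n_sites=len(final_sites),
            )
        )
        for idx, off in final_sites:
            masks[idx][off: off + width] = True
    return motifs


def write_meme(motifs: Sequence[Motif], path) -> None:
    """Write motifs in MEME minimal text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for i, m in enumerate(motifs, start=1):
            fh.write(f"MOTIF m{i} {m.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {m.n_sites} E= 0\n"
            )
            for row in m.per_position_freqs:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def write_sites_tsv(motifs: Sequence[Motif], path) -> None:
    with open(path, "w") as fh:
        fh.write("motif\tsequence_index\toffset\n")
        for i, m in enumerate(motifs, start=1):
            for idx, off in m.sites:
                fh.write(f"m{i}\t{idx}\t{off}\n")


def export_family_fasta(cluster_ids: Sequence[str], table, path) -> int:
    """Write cluster representatives as FASTA for external motif/structure tools."""
    by_id = {c.cluster_id: c.representative for c in table.clusters}
    missing = [cid for cid in cluster_ids if cid not in by_id]
    if missing:
        raise KeyError(f"unknown cluster ids: {missing[:5]}")
    if not cluster_ids:
        warnings.warn("exporting empty family FASTA")
    with open(path, "w") as fh:
        for cid in cluster_ids:
            fh.write(f">{cid}\n{by_id[cid]}\n")
    return len(cluster_ids)


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
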