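"""Ground-truth branched-selection simulator.

Generates an enriched-pool snapshot (aptamer families sharing planted
motifs on top of a long tail of background sequences), subjects it to one
round of parallel selection under a proportional-capture affinity model,
and emits barcoded paired-end reads — the inverse of the analysis
pipeline, with the truth (frequencies, affinities, binding sites,
conformation and competition labels) retained as the oracle.

Selection model: a branch with per-member capture affinities a_i and a
small non-specific background retention b transforms pool frequencies as

    f'_i = f_i (a_i + b) / sum_j f_j (a_j + b)

so the exact expected enrichment factor of member i is
(a_i + b) / sum_j f_j (a_j + b): linear, non-saturating capture, the
simplest model under which enrichment tracks target-variant affinity.
Immobilisation modes are replicate branches with identical affinities and
independent read sampling.  Sequencing error is i.i.d. substitution only.

All randomness flows from a single seed through `numpy.random.SeedSequence`
spawn keys, so every sample is independently reproducible.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    BranchDescriptor,
    ConfigurationError,
    LibraryDesign,
    SampleEntry,
    SampleSheet,
    revcomp,
)
from .profiler import DEFAULT_PANEL
from .readprep import ReadPair

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: realistic default flanks; the reverse constant region is the reverse
#: complement of the RT/reverse-primer binding site of the library
DEFAULT_FWD_CONSTANT = "GGGAGACAAGAATAAACGCTCAA"
DEFAULT_REV_CONSTANT = "TTCGACAGGAGGCTCACAACAGGC"

LATENT_CONDITION = "latent"
COMPLEX_CONDITION = "PAI1_VN"


@dataclass(frozen=True)
class Family:
    family_id: str
    master: str
    motifs: tuple[str, ...]
    motif_offsets: tuple[int, ...]
    profile: frozenset[str]               # ground-truth binding-site residues
    conformation: str                     # binds_both | active_preferring
    competition: str                      # complex_compatible | ligand_competed


@dataclass(frozen=True)
class PoolMember:
    sequence: str
    frequency: float
    family_id: str | None                 # None for background sequences


@dataclass
class TruthPool:
    members: list[PoolMember]
    families: dict[str, Family]

    def __post_init__(self) -> None:
        total = sum(m.frequency for m in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"frequencies sum to {total}, expected 1")

    @property
    def sequences(self) -> list[str]:
        return [m.sequence for m in self.members]

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([m.frequency for m in self.members])

    def family_members(self, family_id: str) -> list[int]:
        return [i for i, m in enumerate(self.members) if m.family_id == family_id]


@dataclass
class AffinityModel:
    """member x condition matrix of relative capture affinities."""

    affinity: pd.DataFrame                # rows align with TruthPool.members
    background: float = 0.01

    def column(self, condition: str) -> np.ndarray:
        return self.affinity[condition].to_numpy()


@dataclass
class SimConfig:
    design: LibraryDesign
    sheet: SampleSheet
    n_reads: int = 200_000
    error_rate: float = 0.001
    seed: int = 0
    min_overlap: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.1:
            raise ConfigurationError("error_rate must be in [0, 0.1)")
        if self.n_reads < 1:
            raise ConfigurationError("n_reads must be >= 1")


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    """Counter-based stream splitting: one seed, disjoint spawn keys per purpose."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=spawn_key))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def _mutate_outside(
    rng: np.random.Generator, master: str, n_subs: int, protected: np.ndarray
) -> str:
    free = np.nonzero(~protected)[0]
    if n_subs == 0 or free.size == 0:
        return master
    positions = rng.choice(free, size=min(n_subs, free.size), replace=False)
    seq = bytearray(master.encode("ascii"))
    for p in positions:
        old = seq[p]
        choices = [b for b in _BASES if b != old]
        seq[p] = choices[rng.integers(0, 3)]
    return seq.decode("ascii")


def default_library_design() -> LibraryDesign:
    return LibraryDesign(DEFAULT_FWD_CONSTANT, DEFAULT_REV_CONSTANT)


def _barcodes(n: int, length: int = 6) -> list[str]:
    """Deterministic list of distinct barcodes."""
    out = []
    for combo in itertools.product("ACGT", repeat=length):
        out.append("".join(combo))
        if len(out) == 4 * n:  # stride through the list for diversity
            break
    return out[:: max(1, len(out) // n)][:n]


def default_sample_sheet(
    panel: Sequence[str] = DEFAULT_PANEL,
    modes: Sequence[str] = ("poly_ab", "mono_ab"),
    include_latent: bool = True,
    include_complex: bool = True,
    replicate_inputs: int = 1,
) -> SampleSheet:
    """Build the branch layout of a full characterisation run.

    One unselected input sample (optionally replicated), a wild-type branch
    per immobilisation mode, every panel mutant in every mode, a
    latent-conformation branch (first mode) and a target:ligand-complex
    branch displayed on the natural ligand.
    """
    branches: list[tuple[str, BranchDescriptor]] = []
    for i in range(replicate_inputs):
        sid = "input" if replicate_inputs == 1 else f"input_rep{i + 1}"
        branches.append((sid, BranchDescriptor("input", "none", "active")))
    for mode in modes:
        branches.append((f"wt_{mode}", BranchDescriptor("wt", mode, "active")))
        for mutant in panel:
            branches.append((f"{mutant}_{mode}", BranchDescriptor(mutant, mode, "active")))
    if include_latent:
        branches.append(("latent", BranchDescriptor(LATENT_CONDITION, modes[0], "latent")))
    if include_complex:
        branches.append(
            ("complex_vn", BranchDescriptor(COMPLEX_CONDITION, "vitronectin", "active"))
        )
    codes = _barcodes(2 * len(branches))
    entries = [
        SampleEntry(sid, codes[2 * i], codes[2 * i + 1], branch)
        for i, (sid, branch) in enumerate(branches)
    ]
    return SampleSheet(entries)


def make_truth_pool(
    n_families: int = 5,
    family_size: int = 20,
    n_background: int = 5000,
    seed: int = 0,
    var_len: tuple[int, int] = (25, 45),
    identity_threshold: float = 0.90,
    panel: Sequence[str] = DEFAULT_PANEL,
    neutral: Sequence[str] = ("K71A",),
    master_weights: Sequence[float] | None = None,
    member_decay: float = 0.6,
    rare_binder_frequency: float | None = None,
) -> TruthPool:
    """Simulate a fifth-round-style enriched pool with known ground truth.

    Families are built from a master sequence carrying two planted motifs
    (one 8-9-mer, one 5-mer); members mutate the master at up to
    ``(1 - identity_threshold)`` of its positions outside the motifs, so
    every member stays within the clustering threshold of its master.
    Member abundances decay geometrically from the master
    (``master_weights`` defaults to 0.6%% down to 0.15%%); the background is
    a log-normal tail spanning high-copy sequences down to singleton scale.
    ``rare_binder_frequency`` optionally plants one extra tiny
    complex-compatible family (the needle for EF-ranking searches).
    """
    rng = _rng(seed, 100)
    lo, hi = var_len
    if master_weights is None:
        # keep total planted binder mass well below the background retention
        # mass so branch normalisation stays near unity and relative EFs
        # track the planted affinity folds (~0.1-0.15% per family)
        master_weights = [0.0006 * (0.9 ** i) for i in range(n_families)]
    if len(master_weights) < n_families:
        raise ConfigurationError("need one master weight per family")

    mutable = [m for m in panel if m not in neutral]
    families: dict[str, Family] = {}
    members: list[tuple[str, float, str | None]] = []

    def build_family(fid, master_len, motif_lens, weight, size, profile,
                     conformation, competition):
        master = _random_seq(rng, master_len)
        if sum(motif_lens) + 2 > master_len:
            raise ConfigurationError("motifs longer than the variable region")
        m1 = _random_seq(rng, motif_lens[0])
        m2 = _random_seq(rng, motif_lens[1])
        off1 = int(rng.integers(0, master_len - motif_lens[0] - motif_lens[1] - 1))
        off2 = int(rng.integers(off1 + motif_lens[0] + 1, master_len - motif_lens[1] + 1))
        master = master[:off1] + m1 + master[off1 + motif_lens[0]: off2] + m2 \
            + master[off2 + motif_lens[1]:]
        protected = np.zeros(master_len, dtype=bool)
        protected[off1: off1 + motif_lens[0]] = True
        protected[off2: off2 + motif_lens[1]] = True
        max_subs = int((1 - identity_threshold) * master_len)
        fam = Family(fid, master, (m1, m2), (off1, off2), frozenset(profile),
                     conformation, competition)
        families[fid] = fam
        seen = {master}
        for j in range(size):
            if j == 0:
                seq = master
            else:
                for _attempt in range(50):
                    n_subs = int(rng.integers(1, max_subs + 1))
                    seq = _mutate_outside(rng, master, n_subs, protected)
                    if seq not in seen:
                        break
                seen.add(seq)
            members.append((seq, weight * member_decay ** j, fid))

    for i in range(n_families):
        profile = rng.choice(mutable, size=int(rng.integers(2, 5)), replace=False)
        conformation = "binds_both" if i % 2 == 0 else "active_preferring"
        competition = "ligand_competed" if i % 2 == 0 else "complex_compatible"
        master_len = int(rng.integers(max(lo + 5, 35), hi - 2))
        build_family(
            f"fam{i + 1}", master_len, (int(rng.integers(8, 10)), 5),
            master_weights[i], family_size, profile, conformation, competition,
        )

    if rare_binder_frequency is not None:
        build_family(
            "rare", int(rng.integers(max(lo + 5, 35), hi - 2)), (8, 5),
            rare_binder_frequency, 1, mutable[:2], "binds_both", "complex_compatible",
        )

    family_mass = sum(w for _s, w, _f in members)
    if family_mass >= 1:
        raise ConfigurationError("family abundances exceed the whole pool")

    # background: log-normal abundance tail, unique random sequences
    seen_bg = {s for s, _w, _f in members}
    bg_seqs = []
    while len(bg_seqs) < n_background:
        seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        if seq not in seen_bg:
            seen_bg.add(seq)
            bg_seqs.append(seq)
    weights = rng.lognormal(mean=0.0, sigma=1.6, size=n_background)
    weights = weights / weights.sum() * (1.0 - family_mass)
    for seq, w in zip(bg_seqs, weights):
        members.append((seq, float(w), None))

    return TruthPool(
        [PoolMember(s, w, f) for s, w, f in members], families
    )


def make_affinity_model(
    pool: TruthPool,
    panel: Sequence[str] = DEFAULT_PANEL,
    seed: int = 0,
    fold_range: tuple[float, float] = (4.0, 10.0),
    background: float = 0.01,
    rare_complex_affinity: float = 100.0,
) -> AffinityModel:
    """Affinities per member and condition consistent with the ground truth.

    Binders have wild-type affinity 1.  A mutant in a family's binding-site
    profile divides the affinity by a per-(family, mutant) fold drawn from
    ``fold_range`` (at least twice the analysis fold threshold, so planted
    sites are detectable); neutral mutants leave it unchanged.  The latent
    branch applies the same treatment for active-preferring families, the
    complex branch for ligand-competed families.  Background sequences have
    affinity 0 everywhere and are retained only through ``background``.
    """
    rng = _rng(seed, 101)
    conditions = ["wt", *panel, LATENT_CONDITION, COMPLEX_CONDITION]
    n = len(pool.members)
    a = pd.DataFrame(0.0, index=range(n), columns=conditions)

    for fid, fam in pool.families.items():
        idx = pool.family_members(fid)
        # sorted: set iteration order must not steer rng consumption
        folds = {m: rng.uniform(*fold_range) for m in sorted(fam.profile)}
        latent_fold = rng.uniform(*fold_range)
        complex_fold = rng.uniform(*fold_range)
        for cond in conditions:
            if cond == "wt":
                val = 1.0
            elif cond == LATENT_CONDITION:
                val = 1.0 if fam.conformation == "binds_both" else 1.0 / latent_fold
            elif cond == COMPLEX_CONDITION:
                if fid == "rare":
                    val = rare_complex_affinity
                elif fam.competition == "complex_compatible":
                    val = 1.0
                else:
                    val = 1.0 / complex_fold
            else:
                val = 1.0 / folds[cond] if cond in fam.profile else 1.0
            a.loc[idx, cond] = val
    return AffinityModel(a, background)


def select_round(
    pool: TruthPool | np.ndarray, model: AffinityModel, condition: str
) -> np.ndarray:
    """Post-selection frequencies under the proportional-capture model."""
    f = pool.frequencies if isinstance(pool, TruthPool) else np.asarray(pool, float)
    a = model.column(condition) + model.background
    z = float(f @ a)
    if z <= 0:
        raise ConfigurationError("all-zero capture affinities for this branch")
    return f * a / z


def analytic_expected_ef(
    pool: TruthPool, model: AffinityModel, condition: str, member: int | None = None
):
    """Exact expected EF ignoring read sampling and sequencing error.

    EF_i = (a_i + b) / sum_j f_j (a_j + b); returns the full vector when
    ``member`` is None.
    """
    f = pool.frequencies
    a = model.column(condition) + model.background
    z = float(f @ a)
    ef = a / z
    return ef if member is None else float(ef[member])


# ---------------------------------------------------------------------------
# read emission


def sample_counts(
    frequencies: np.ndarray, n_reads: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial read counts for one sample."""
    return rng.multinomial(n_reads, frequencies)


def _apply_errors(read: str, k: int, rng: np.random.Generator) -> str:
    arr = bytearray(read.encode("ascii"))
    for p in rng.choice(len(arr), size=k, replace=False):
        old = arr[p]
        choices = [b for b in _BASES if b != old]
        arr[p] = choices[rng.integers(0, 3)]
    return arr.decode("ascii")


def emit_pairs(
    sequences: Sequence[str],
    counts: np.ndarray,
    entry: SampleEntry,
    config: SimConfig,
) -> list[ReadPair]:
    """Wrap variable regions in flanks+barcodes and split into paired reads.

    Amplicon top strand: barcode_fwd + fwd_constant + variable +
    rev_constant + revcomp(barcode_rev).  The forward read is the first
    ``read_length`` nt of the top strand, the reverse read the first
    ``read_length`` nt of the bottom strand.  Substitution errors are
    applied i.i.d. at ``error_rate`` per base.
    """
    design = config.design
    rl = design.read_length
    sample_index = config.sheet.sample_ids.index(entry.sample_id)
    rng = _rng(config.seed, 1, sample_index)

    flank_len = (
        len(entry.barcode_fwd) + len(design.fwd_constant)
        + len(design.rev_constant) + len(entry.barcode_rev)
    )
    max_amp = design.var_len_max + flank_len
    if max_amp > 2 * rl - config.min_overlap:
        raise ConfigurationError(
            "amplicon can exceed 2*read_length - min_overlap; pairs would not overlap"
        )

    pairs: list[ReadPair] = []
    eps = config.error_rate
    serial = 0
    for seq, c in zip(sequences, counts):
        if c == 0:
            continue
        amplicon = (
            entry.barcode_fwd + design.fwd_constant + seq
            + design.rev_constant + revcomp(entry.barcode_rev)
        )
        fwd = amplicon[:rl]
        rev = revcomp(amplicon)[:rl]
        qf, qr = "I" * len(fwd), "I" * len(rev)
        if eps > 0:
            err_f = rng.binomial(len(fwd), eps, size=c)
            err_r = rng.binomial(len(rev), eps, size=c)
        else:
            err_f = err_r = np.zeros(c, dtype=int)
        for i in range(int(c)):
            serial += 1
            f = _apply_errors(fwd, err_f[i], rng) if err_f[i] else fwd
            r = _apply_errors(rev, err_r[i], rng) if err_r[i] else rev
            pairs.append(ReadPair(f"{entry.sample_id}_{serial}", f, qf, r, qr))
    return pairs


@dataclass
class SimulatedRun:
    pool: TruthPool
    model: AffinityModel
    config: SimConfig
    counts: pd.DataFrame                  # member x sample read counts
    pairs_by_sample: dict[str, list[ReadPair]] = field(default_factory=dict)

    def all_pairs(self) -> list[ReadPair]:
        """All samples' pairs concatenated, as one sequencing lane."""
        out: list[ReadPair] = []
        for sample_id in self.config.sheet.sample_ids:
            out.extend(self.pairs_by_sample.get(sample_id, []))
        return out


def simulate_run(
    pool: TruthPool,
    model: AffinityModel,
    config: SimConfig,
    emit_reads: bool = True,
    n_reads_by_sample: Mapping[str, int] | None = None,
) -> SimulatedRun:
    """One round of branched selection + sequencing for every sheet sample."""
    seqs = pool.sequences
    counts = {}
    pairs_by_sample: dict[str, list[ReadPair]] = {}
    for i, entry in enumerate(config.sheet):
        condition = entry.branch.condition
        freqs = (
            pool.frequencies
            if condition == "input"
            else select_round(pool, model, condition)
        )
        n_reads = (
            n_reads_by_sample.get(entry.sample_id, config.n_reads)
            if n_reads_by_sample
            else config.n_reads
        )
        rng = _rng(config.seed, 0, i)
        counts[entry.sample_id] = sample_counts(freqs, n_reads, rng)
        if emit_reads:
            pairs_by_sample[entry.sample_id] = emit_pairs(
                seqs, counts[entry.sample_id], entry, config
            )
    frame = pd.DataFrame(counts, index=range(len(seqs)))
    return SimulatedRun(pool, model, config, frame, pairs_by_sample)


def write_fastq(pairs: Sequence[ReadPair], r1_path, r2_path) -> None:
    def _open(path):
        path = str(path)
        return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")

    with _open(r1_path) as h1, _open(r2_path) as h2:
        for p in pairs:
            h1.write(f"@{p.read_id}/1\n{p.fwd_seq}\n+\n{p.fwd_qual}\n")
            h2.write(f"@{p.read_id}/2\n{p.rev_seq}\n+\n{p.rev_qual}\n")


def write_truth_tsv(run: SimulatedRun, path) -> None:
    rows = []
    for i, member in enumerate(run.pool.members):
        fam = run.pool.families.get(member.family_id) if member.family_id else None
        rows.append(
            {
                "member": i,
                "sequence": member.sequence,
                "family": member.family_id or "-",
                "frequency": member.frequency,
                "profile": ",".join(sorted(fam.profile)) if fam else "-",
                "conformation": fam.conformation if fam else "-",
                "competition": fam.competition if fam else "-",
                **{
                    f"affinity_{c}": run.model.affinity.loc[i, c]
                    for c in run.model.affinity.columns
                },
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
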