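"""Pool fractions and enrichment factors.

A sequence's *pool fraction* in a sample is its copy number divided by the
sample's total retained read count, expressed in percent.  The
*enrichment factor* against condition X is

    EF_X = (% of pool after selection to X) / (% of pool before selection)

and the *relative enrichment factor* normalises a target-variant branch to
the wild-type branch under the same immobilisation mode:

    EF_variant / EF_wt.

EFs of sequences absent before selection are undefined and flagged (never
replaced by a pseudo-count by default); EFs of sequences lost during
selection are exactly 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import ClusterTable
from .design import (
    INPUT_CONDITION,
    WT_CONDITION,
    BranchDescriptor,
    ConfigurationError,
    is_point_mutant,
)


def pool_fraction(copies: int, total: int) -> float:
    """Copy number as percent of the sample's total retained reads."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= copies <= total:
        raise ValueError("copies must satisfy 0 <= copies <= total")
    return 100.0 * copies / total


def enrichment_factor(pct_after: float, pct_before: float) -> float | None:
    """EF = pct_after / pct_before, or None (undefined) when pct_before is 0."""
    if pct_after < 0 or pct_before < 0:
        raise ValueError("pool fractions must be non-negative")
    if pct_before == 0:
        return None
    return pct_after / pct_before


def relative_ef(ef_variant: float, ef_wt: float) -> float | None:
    """EF_variant / EF_wt, or None (undefined) when EF_wt is 0."""
    if ef_wt < 0:
        raise ValueError("ef_wt must be non-negative")
    if ef_wt == 0:
        return None
    return ef_variant / ef_wt


@dataclass
class PoolFractionTable:
    """cluster x sample matrix of pool fractions in percent."""

    frame: pd.DataFrame                      # index cluster_id, columns sample_id
    sample_totals: dict[str, int]

    @property
    def samples(self) -> list[str]:
        return list(self.frame.columns)

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


def pool_fractions(table: ClusterTable) -> PoolFractionTable:
    """Convert a copy-number table to pool fractions (percent per sample)."""
    frame = table.to_frame()
    samples = [c for c in frame.columns if c not in ("representative", "total")]
    counts = frame[samples].astype(float)
    totals = pd.Series(table.sample_totals, dtype=float)
    zero = [s for s in samples if table.sample_totals.get(s, 0) <= 0]
    if zero:
        raise ValueError(f"samples with zero retained reads: {zero}")
    pct = 100.0 * counts / totals[samples]
    return PoolFractionTable(pct, dict(table.sample_totals))


@dataclass
class EnrichmentTable:
    """Long-form EF records for every (cluster, non-input branch) pair.

    ``frame`` columns: cluster_id, sample, condition, immobilisation,
    conformation, ef, ef_defined, ef_rel_wt, rel_defined.  Undefined values
    are NaN with their flag set False — flagged, never dropped.
    """

    frame: pd.DataFrame
    metadata: dict[str, BranchDescriptor]
    input_sample: str
    input_pct: pd.Series            # cluster_id -> percent of input pool
    input_copies: pd.Series         # cluster_id -> copy number in the input pool
    wt_samples: dict[str, str] = field(default_factory=dict)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.input_pct.index)

    def branch_frame(self, sample: str) -> pd.DataFrame:
        sub = self.frame[self.frame["sample"] == sample]
        return sub.set_index("cluster_id")

    def ef_series(self, sample: str) -> pd.Series:
        return self.branch_frame(sample)["ef"]

    def rel_ef_series(self, sample: str) -> pd.Series:
        return self.branch_frame(sample)["ef_rel_wt"]

    def sample_for(self, condition: str, immobilisation: str) -> str:
        for sample_id, branch in self.metadata.items():
            if branch.condition == condition and branch.immobilisation == immobilisation:
                return sample_id
        raise KeyError((condition, immobilisation))

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def build_enrichment_table(
    fractions: PoolFractionTable,
    input_sample: str,
    wt_samples: dict[str, str],
    metadata: dict[str, BranchDescriptor],
    input_copies: pd.Series | None = None,
    pseudocount: float = 0.0,
) -> EnrichmentTable:
    """Assemble EF and EF_variant/EF_wt for every cluster and selection branch.

    ``wt_samples`` maps immobilisation mode -> wild-type sample id; a mode
    that carries point-mutant branches but no wild-type reference is a
    configuration error.  ``pseudocount`` (percent) is added to both
    numerator and denominator for exploratory use only; the default of 0
    keeps the undefined-EF flagging semantics.
    """
    if input_sample not in fractions.frame.columns:
        raise ConfigurationError(f"input sample {input_sample!r} missing from fractions")
    for mode, wt in wt_samples.items():
        if wt not in fractions.frame.columns:
            raise ConfigurationError(f"wt sample {wt!r} for mode {mode!r} missing")
    for sample_id, branch in metadata.items():
        if sample_id == input_sample or branch.condition in (INPUT_CONDITION, WT_CONDITION):
            continue
        if is_point_mutant(branch.condition) and branch.immobilisation not in wt_samples:
            raise ConfigurationError(
                f"mode {branch.immobilisation!r} has mutant branch "
                f"{sample_id!r} but no wt reference"
            )

    before = fractions.frame[input_sample] + pseudocount
    branch_samples = [s for s in fractions.frame.columns if s != input_sample]

    ef_cols: dict[str, pd.Series] = {}
    for s in branch_samples:
        after = fractions.frame[s] + pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            ef = after / before
        ef[before == 0] = np.nan
        ef_cols[s] = ef

    rows = []
    for s in branch_samples:
        branch = metadata[s]
        ef = ef_cols[s]
        wt = wt_samples.get(branch.immobilisation)
        if wt is not None:
            ef_wt = ef_cols[wt]
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = ef / ef_wt
            rel[(ef_wt == 0) | ef_wt.isna() | ef.isna()] = np.nan
        else:
            rel = pd.Series(np.nan, index=ef.index)
        rows.append(
            pd.DataFrame(
                {
                    "cluster_id": ef.index,
                    "sample": s,
                    "condition": branch.condition,
                    "immobilisation": branch.immobilisation,
                    "conformation": branch.conformation,
                    "ef": ef.to_numpy(),
                    "ef_defined": ~np.isnan(ef.to_numpy()),
                    "ef_rel_wt": rel.to_numpy(),
                    "rel_defined": ~np.isnan(rel.to_numpy()),
                }
            )
        )
    frame = pd.concat(rows, ignore_index=True)

    input_pct = fractions.frame[input_sample]
    if input_copies is None:
        total = fractions.sample_totals[input_sample]
        input_copies = (input_pct / 100.0 * total).round().astype(int)
    return EnrichmentTable(
        frame=frame,
        metadata=dict(metadata),
        input_sample=input_sample,
        input_pct=input_pct,
        input_copies=input_copies,
        wt_samples=dict(wt_samples),
    )


def enrichment_from_clusters(
    table: ClusterTable,
    input_sample: str,
    wt_samples: dict[str, str],
    metadata: dict[str, BranchDescriptor],
    pseudocount: float = 0.0,
) -> tuple[PoolFractionTable, EnrichmentTable]:
    """ClusterTable -> (pool fractions, enrichment table) in one step."""
    fractions = pool_fractions(table)
    frame = table.to_frame()
    input_copies = frame[input_sample].astype(int)
    enrichment = build_enrichment_table(
        fractions, input_sample, wt_samples, metadata, input_copies, pseudocount
    )
    return fractions, enrichment


def replicate_variability(
    fractions: PoolFractionTable, replicate_samples: list[str], top_n: int = 50
) -> pd.DataFrame:
    """Per-sequence relative standard deviation across replicate preparations.

    For the ``top_n`` sequences most abundant on average across the
    replicates, returns a frame with ``mean_pct`` (mean pool fraction,
    percent of pool) and ``rsd_pct`` (sample standard deviation as percent
    of the mean) — the statistic used to gauge the experimental variability
    of library preparation plus sequencing.
    """
    if len(replicate_samples) < 2:
        raise ValueError("need at least two replicate samples")
    sub = fractions.frame[replicate_samples]
    mean = sub.mean(axis=1)
    top = mean.sort_values(ascending=False).head(top_n).index
    sub = sub.loc[top]
    mean = mean.loc[top]
    if (mean == 0).any():
        raise ValueError("top sequences must have non-zero mean abundance")
    rsd = 100.0 * sub.std(axis=1, ddof=1) / mean
    return pd.DataFrame({"mean_pct": mean, "rsd_pct": rsd})


def ef_standard_error(
    ef: float, f_before: float, f_after: float, n_before: int, n_after: int
) -> float:
    """Delta-method standard error of an estimated EF under binomial sampling.

    ``f_before`` / ``f_after`` are the (expected) pool fractions as
    *fractions* (not percent) and ``n_*`` the read counts of the two
    samples.  var(EF)/EF^2 = (1-f_b)/(n_b f_b) + (1-f_a)/(n_a f_a).
    """
    if f_before <= 0 or f_after <= 0:
        return math.inf
    rel_var = (1 - f_before) / (n_before * f_before) + (1 - f_after) / (n_after * f_after)
    return ef * math.sqrt(rel_var)
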