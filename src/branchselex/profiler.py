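"""Binding-site profiles, conformation and ligand-competition calls.

The logic mirrors alanine-scanning interpretation of branched-selection
enrichment: a more than ``fold_threshold``-fold reduction of
EF_variant/EF_wt (strictly below 1/fold_threshold) implicates the mutated
residue in aptamer binding.  The same fold threshold classifies
conformational preference (latent vs active target) and ligand competition
(target–ligand complex vs antibody display).  Undefined EFs propagate as
"indeterminate" rather than being coerced to 0, so rare sequences never
produce spurious binding-site calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import ConfigurationError
from .quantify import EnrichmentTable

#: the alanine panel used throughout the examples (wild-type excluded)
DEFAULT_PANEL = ("K71A", "R78A", "Y81A", "K82A", "F116A", "R120A", "K124A")


@dataclass(frozen=True)
class ProfilerParams:
    fold_threshold: float = 2.0
    min_copies: int = 10
    top_n: int = 1000
    ef_wt_min: float = 1.0

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if self.min_copies < 1:
            raise ValueError("min_copies must be >= 1")

    @property
    def cutoff(self) -> float:
        """Relative-EF value below which a residue is called (1/fold_threshold)."""
        return 1.0 / self.fold_threshold


@dataclass(frozen=True)
class BindingProfile:
    """Set of target residues implicated in binding for one cluster."""

    residues: frozenset[str]
    indeterminate: bool = False

    def __bool__(self) -> bool:
        return not self.indeterminate and bool(self.residues)


@dataclass(frozen=True)
class ProfileCall:
    cluster_id: str
    profile_by_mode: dict[str, BindingProfile]
    concordant: bool


@dataclass(frozen=True)
class ConformationCall:
    cluster_id: str
    label: str                     # binds_both | active_preferring | indeterminate
    ratio: float                   # EF_latent / EF_active (NaN if indeterminate)


@dataclass(frozen=True)
class CompetitionCall:
    cluster_id: str
    label: str                     # complex_compatible | ligand_competed | indeterminate
    ratio: float                   # EF_complex / EF_antibody (NaN if indeterminate)


def _is_undefined(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def infer_binding_profile(
    rel_efs: Mapping[str, float | None], params: ProfilerParams = ProfilerParams()
) -> BindingProfile:
    """Residues whose mutation reduces EF more than fold_threshold-fold.

    The inequality is strict (a reduction of exactly fold_threshold-fold is
    *not* called).  Any undefined relative EF makes the whole profile
    indeterminate rather than guessing.
    """
    if any(_is_undefined(v) for v in rel_efs.values()):
        return BindingProfile(frozenset(), indeterminate=True)
    cutoff = params.cutoff
    return BindingProfile(frozenset(m for m, v in rel_efs.items() if v < cutoff))


def profile_calls(
    table: EnrichmentTable,
    panel: Sequence[str],
    modes: Sequence[str],
    params: ProfilerParams = ProfilerParams(),
) -> list[ProfileCall]:
    """Infer a binding profile per cluster in every immobilisation mode."""
    rel_by_mode: dict[str, dict[str, pd.Series]] = {}
    for mode in modes:
        per_mutant = {}
        for mutant in panel:
            try:
                sample = table.sample_for(mutant, mode)
            except KeyError:
                raise ConfigurationError(
                    f"no branch for mutant {mutant!r} in mode {mode!r}"
                ) from None
            per_mutant[mutant] = table.rel_ef_series(sample)
        rel_by_mode[mode] = per_mutant

    calls = []
    for cid in table.cluster_ids:
        by_mode = {
            mode: infer_binding_profile(
                {m: rel_by_mode[mode][m].get(cid, np.nan) for m in panel}, params
            )
            for mode in modes
        }
        profiles = list(by_mode.values())
        concordant = (
            all(not p.indeterminate for p in profiles)
            and len({p.residues for p in profiles}) == 1
        )
        calls.append(ProfileCall(cid, by_mode, concordant))
    return calls


def scan_profile_matches(
    table: EnrichmentTable,
    reference: BindingProfile | frozenset[str] | Iterable[str],
    params: ProfilerParams = ProfilerParams(),
    modes: Sequence[str] = ("poly_ab", "mono_ab"),
    panel: Sequence[str] = DEFAULT_PANEL,
) -> list[str]:
    """Clusters matching a reference binding profile in every requested mode.

    Only clusters observed at least ``min_copies`` times in the input pool
    are scanned; matching is exact set equality, required concordantly in
    all modes; the result is sorted by input-pool abundance (descending).
    """
    if isinstance(reference, BindingProfile):
        ref = reference.residues
    else:
        ref = frozenset(reference)
    eligible = set(table.input_copies[table.input_copies >= params.min_copies].index)
    hits = []
    for call in profile_calls(table, panel, modes, params):
        if call.cluster_id not in eligible:
            continue
        if not call.concordant:
            continue
        if next(iter(call.profile_by_mode.values())).residues == ref:
            hits.append(call.cluster_id)
    hits.sort(key=lambda cid: (-table.input_pct[cid], cid))
    return hits


def _ratio_call(numerator: float, denominator: float) -> float:
    if _is_undefined(numerator) or _is_undefined(denominator) or denominator == 0:
        return np.nan
    return numerator / denominator


def conformation_call(
    ef_active: float,
    ef_latent: float,
    params: ProfilerParams = ProfilerParams(),
    cluster_id: str = "",
) -> ConformationCall:
    """Classify conformational preference from active- vs latent-target EFs.

    ratio = EF_latent/EF_active; below 1/fold_threshold the aptamer prefers
    the active conformation, otherwise it binds both (ratios above the fold
    threshold also map to binds_both: the latent form is bound at least as
    well).  A zero or undefined active EF is indeterminate.
    """
    ratio = _ratio_call(ef_latent, ef_active)
    if np.isnan(ratio):
        label = "indeterminate"
    elif ratio < params.cutoff:
        label = "active_preferring"
    else:
        label = "binds_both"
    return ConformationCall(cluster_id, label, ratio)


def competition_call(
    ef_antibody: float,
    ef_complex: float,
    params: ProfilerParams = ProfilerParams(),
    cluster_id: str = "",
) -> CompetitionCall:
    """Classify natural-ligand competition from antibody- vs complex-display EFs.

    ratio = EF_complex/EF_antibody; below 1/fold_threshold the aptamer loses
    enrichment when the target is presented on its natural ligand
    (ligand_competed), otherwise it is complex_compatible.
    """
    ratio = _ratio_call(ef_complex, ef_antibody)
    if np.isnan(ratio):
        label = "indeterminate"
    elif ratio < params.cutoff:
        label = "ligand_competed"
    else:
        label = "complex_compatible"
    return CompetitionCall(cluster_id, label, ratio)


@dataclass
class HotspotSummary:
    """Global mutant-sensitivity summary over the most abundant clusters."""

    n_top: int
    n_qualifying: int                       # clusters with EF_wt > ef_wt_min
    fraction_reduced: pd.Series             # mutant -> fraction of qualifying clusters
    fraction_unaffected: float              # qualifying clusters with no mutant called
    points: dict[str, pd.DataFrame]         # mutant -> (ef_wt, ef_variant) scatter data

    def write_tsv(self, path) -> None:
        frame = self.fraction_reduced.rename("fraction_reduced").to_frame()
        frame.loc["(none)"] = self.fraction_unaffected
        frame.to_csv(path, sep="\t", index_label="mutant")


def hotspot_summary(
    table: EnrichmentTable,
    mode: str,
    panel: Sequence[str] = DEFAULT_PANEL,
    params: ProfilerParams = ProfilerParams(),
) -> HotspotSummary:
    """Per-mutant fraction of strongly enriched clusters losing enrichment.

    Over the ``top_n`` most abundant input-pool clusters, restricted to
    those with EF_wt > ``ef_wt_min``: the fraction whose relative EF drops
    below 1/fold_threshold for each mutant, the fraction unaffected by every
    mutant, and the per-mutant (EF_wt, EF_variant) point clouds for
    scatter plots.
    """
    order = table.input_pct.sort_values(ascending=False)
    if len(order) < params.top_n:
        warnings.warn(
            f"only {len(order)} clusters available; top_n={params.top_n} truncated"
        )
    top = order.head(params.top_n).index

    wt_sample = table.wt_samples.get(mode)
    if wt_sample is None:
        raise ConfigurationError(f"no wt reference for mode {mode!r}")
    ef_wt = table.ef_series(wt_sample).reindex(top)
    qualifying = top[(ef_wt > params.ef_wt_min).fillna(False)]

    reduced = {}
    points = {}
    any_reduced = pd.Series(False, index=qualifying)
    for mutant in panel:
        sample = table.sample_for(mutant, mode)
        rel = table.rel_ef_series(sample).reindex(qualifying)
        ef_var = table.ef_series(sample).reindex(top)
        hit = (rel < params.cutoff).fillna(False)
        reduced[mutant] = hit.mean() if len(qualifying) else np.nan
        any_reduced |= hit
        points[mutant] = pd.DataFrame(
            {"ef_wt": ef_wt.reindex(top), "ef_variant": ef_var}
        )
    fraction_unaffected = (
        float((~any_reduced).mean()) if len(qualifying) else np.nan
    )
    return HotspotSummary(
        n_top=len(top),
        n_qualifying=len(qualifying),
        fraction_reduced=pd.Series(reduced),
        fraction_unaffected=fraction_unaffected,
        points=points,
    )


def plot_hotspot_scatter(summary: HotspotSummary, outdir) -> list[str]:
    """One EF_wt-vs-EF_variant scatter per mutant (log axes, identity line)."""
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(outdir, exist_ok=True)
    paths = []
    for mutant, pts in summary.points.items():
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(pts["ef_wt"], pts["ef_variant"], s=6, alpha=0.5, edgecolors="none")
        lims = (1e-2, max(10.0, float(np.nanmax(pts.to_numpy(), initial=1)) * 1.5))
        ax.plot(lims, lims, lw=0.8, color="grey")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlim(lims)
        ax.set_ylim(lims)
        ax.set_xlabel("EF wild type")
        ax.set_ylabel(f"EF {mutant}")
        fig.tight_layout()
        path = os.path.join(outdir, f"ef_scatter_{mutant}.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def rank_by_ef(table: EnrichmentTable, branch_sample: str) -> list[str]:
    """Clusters sorted by EF for a branch, descending; undefined EFs last.

    Ties are broken by input-pool abundance (descending) then cluster id.
    """
    ef = table.ef_series(branch_sample)
    pct = table.input_pct

    def key(cid: str):
        v = ef.get(cid, np.nan)
        undefined = _is_undefined(v)
        return (undefined, -(0.0 if undefined else v), -pct.get(cid, 0.0), cid)

    return sorted(ef.index, key=key)


def write_profiles_tsv(calls: Iterable[ProfileCall], path) -> None:
    rows = []
    for call in calls:
        row: dict[str, object] = {"cluster_id": call.cluster_id}
        for mode, profile in call.profile_by_mode.items():
            row[f"profile_{mode}"] = (
                "indeterminate"
                if profile.indeterminate
                else ",".join(sorted(profile.residues))
            )
        row["concordant"] = call.concordant
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
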