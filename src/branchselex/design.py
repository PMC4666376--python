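"""Library design, sample sheet and branch descriptors.

A branched-SELEX sequencing run is described by two pieces of metadata:

* a :class:`LibraryDesign` — the constant regions flanking the variable
  (randomised) region of the library and the length bounds a valid variable
  region must satisfy;
* a :class:`SampleSheet` — one entry per PCR sample, mapping the pair of
  5'-barcodes carried by the amplification primers to a selection branch
  (which target variant, which immobilisation handle, which conformation).

Sequences are stored in the DNA alphabet (T, not U) throughout: sequencing
reads cDNA, and all comparisons happen on the cDNA side.  Coordinates are
0-based half-open internally and never appear in file outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

DNA = frozenset("ACGT")
DNA_N = frozenset("ACGTN")

IMMOBILISATION_MODES = ("poly_ab", "mono_ab", "vitronectin", "none")
CONFORMATIONS = ("active", "latent", "n/a")

#: condition label of the unselected pool sample
INPUT_CONDITION = "input"
#: condition label of the wild-type target branch
WT_CONDITION = "wt"

_MUTANT_RE = re.compile(r"^[A-Z]\d+[A-Z]$")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_point_mutant(condition: str) -> bool:
    """True for single-residue substitution labels such as ``R78A``."""
    return bool(_MUTANT_RE.match(condition))


class ConfigurationError(ValueError):
    """Raised for inconsistent run metadata (duplicate barcodes, missing references)."""


def _check_alphabet(name: str, seq: str, alphabet=DNA) -> None:
    if not seq:
        raise ConfigurationError(f"{name} must be non-empty")
    bad = set(seq) - alphabet
    if bad:
        raise ConfigurationError(f"{name} contains non-DNA characters: {sorted(bad)}")


@dataclass(frozen=True)
class LibraryDesign:
    """Constant flanks and variable-region length bounds defining a valid amplicon.

    ``rev_constant`` is given in the orientation of the amplicon top strand,
    i.e. the strand that reads ``fwd_constant + variable + rev_constant``.
    """

    fwd_constant: str
    rev_constant: str
    var_len_min: int = 25
    var_len_max: int = 45
    read_length: int = 90

    def __post_init__(self) -> None:
        _check_alphabet("fwd_constant", self.fwd_constant)
        _check_alphabet("rev_constant", self.rev_constant)
        if self.var_len_min < 1:
            raise ConfigurationError("var_len_min must be >= 1")
        if self.var_len_min > self.var_len_max:
            raise ConfigurationError("var_len_min must be <= var_len_max")
        if self.read_length < 1:
            raise ConfigurationError("read_length must be >= 1")


@dataclass(frozen=True)
class BranchDescriptor:
    """What a selection branch was selected against and how the target was displayed."""

    condition: str
    immobilisation: str = "poly_ab"
    conformation: str = "active"

    def __post_init__(self) -> None:
        if self.immobilisation not in IMMOBILISATION_MODES:
            raise ConfigurationError(
                f"unknown immobilisation {self.immobilisation!r}; "
                f"expected one of {IMMOBILISATION_MODES}"
            )
        if self.conformation not in CONFORMATIONS:
            raise ConfigurationError(
                f"unknown conformation {self.conformation!r}; "
                f"expected one of {CONFORMATIONS}"
            )
        if self.condition == INPUT_CONDITION and self.immobilisation != "none":
            raise ConfigurationError("input branch must have immobilisation 'none'")


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    barcode_fwd: str
    barcode_rev: str
    branch: BranchDescriptor

    def __post_init__(self) -> None:
        _check_alphabet(f"barcode_fwd[{self.sample_id}]", self.barcode_fwd)
        _check_alphabet(f"barcode_rev[{self.sample_id}]", self.barcode_rev)


@dataclass
class SampleSheet:
    """Barcode pair -> selection branch mapping for one sequencing lane."""

    entries: list[SampleEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("sample_ids must be unique")
        pairs = [(e.barcode_fwd, e.barcode_rev) for e in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ConfigurationError("duplicate (barcode_fwd, barcode_rev) pair in sheet")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    def entry(self, sample_id: str) -> SampleEntry:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e
        raise KeyError(sample_id)

    def branches(self) -> dict[str, BranchDescriptor]:
        return {e.sample_id: e.branch for e in self.entries}

    def input_sample(self) -> str:
        """Sample id of the unselected pool."""
        hits = [e.sample_id for e in self.entries if e.branch.condition == INPUT_CONDITION]
        if len(hits) != 1:
            raise ConfigurationError(
                f"expected exactly one '{INPUT_CONDITION}' sample, found {len(hits)}"
            )
        return hits[0]

    def wt_samples(self) -> dict[str, str]:
        """Map immobilisation mode -> sample id of the wild-type branch in that mode."""
        out: dict[str, str] = {}
        for e in self.entries:
            if e.branch.condition == WT_CONDITION:
                if e.branch.immobilisation in out:
                    raise ConfigurationError(
                        f"multiple wt samples for mode {e.branch.immobilisation!r}"
                    )
                out[e.branch.immobilisation] = e.sample_id
        return out

    def sample_for(self, condition: str, immobilisation: str) -> str:
        for e in self.entries:
            if (
                e.branch.condition == condition
                and e.branch.immobilisation == immobilisation
            ):
                return e.sample_id
        raise KeyError((condition, immobilisation))


# ---------------------------------------------------------------------------
# YAML round-trip


def design_to_dict(design: LibraryDesign) -> dict:
    return {
        "fwd_constant": design.fwd_constant,
        "rev_constant": design.rev_constant,
        "var_len_min": design.var_len_min,
        "var_len_max": design.var_len_max,
        "read_length": design.read_length,
    }


def sheet_to_dict(sheet: SampleSheet) -> list[dict]:
    return [
        {
            "sample_id": e.sample_id,
            "barcode_fwd": e.barcode_fwd,
            "barcode_rev": e.barcode_rev,
            "condition": e.branch.condition,
            "immobilisation": e.branch.immobilisation,
            "conformation": e.branch.conformation,
        }
        for e in sheet.entries
    ]


def dump_config(design: LibraryDesign, sheet: SampleSheet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"design": design_to_dict(design), "samples": sheet_to_dict(sheet)},
            fh,
            sort_keys=False,
        )


def load_config(path) -> tuple[LibraryDesign, SampleSheet]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    design = LibraryDesign(**raw["design"])
    entries = [
        SampleEntry(
            sample_id=s["sample_id"],
            barcode_fwd=s["barcode_fwd"],
            barcode_rev=s["barcode_rev"],
            branch=BranchDescriptor(
                condition=s["condition"],
                immobilisation=s.get("immobilisation", "poly_ab"),
                conformation=s.get("conformation", "active"),
            ),
        )
        for s in raw["samples"]
    ]
    return design, SampleSheet(entries)
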