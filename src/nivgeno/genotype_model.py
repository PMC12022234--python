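"""Core domain types for replicate-based microsatellite genotyping.

The in-memory model mirrors how noninvasive genetic monitoring data are
organised in practice: a marker panel (autosomal microsatellites plus an
amelogenin sex marker), per-replicate genotype calls, and per-sample
metadata. Allele labels are integer fragment sizes in base pairs, the unit
electropherogram scoring produces; anything else is rejected rather than
coerced.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Optional, Sequence, Tuple


class CallStatus(str, enum.Enum):
    """Outcome of scoring one locus in one replicate (or consensus)."""

    CALLED = "called"
    MISSING = "missing"
    CONTAMINATED = "contaminated"
    DISPUTED = "disputed"


SAMPLE_TYPES = ("scat", "urine", "hair", "tissue", "blood")
#: sample types amplified in duplicate rather than quadruplicate
INVASIVE_TYPES = ("tissue", "blood")


@dataclass(frozen=True)
class Locus:
    """One marker of the panel.

    ``allele_size_range`` bounds the fragment sizes (bp) the marker can
    produce; it is used for validation and by the simulator's false-allele
    lattice.
    """

    name: str
    multiplex_id: int = 1
    allele_size_range: Tuple[int, int] = (100, 300)
    is_sex_marker: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.allele_size_range
        if not lo < hi:
            raise ValueError(
                f"locus {self.name}: allele_size_range min must be < max, got {self.allele_size_range}"
            )


@dataclass(frozen=True)
class LocusPanel:
    """Ordered marker panel; at most one locus may be the sex marker."""

    loci: Tuple[Locus, ...]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            dupes = [n for n, c in Counter(names).items() if c > 1]
            raise ValueError(f"duplicate locus names in panel: {dupes}")
        n_sex = sum(l.is_sex_marker for l in self.loci)
        if n_sex > 1:
            raise ValueError(f"panel may contain at most one sex marker, got {n_sex}")

    @property
    def locus_names(self) -> Tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    @property
    def autosomal_loci(self) -> Tuple[Locus, ...]:
        return tuple(l for l in self.loci if not l.is_sex_marker)

    @property
    def autosomal_names(self) -> Tuple[str, ...]:
        return tuple(l.name for l in self.autosomal_loci)

    @property
    def sex_marker(self) -> Optional[Locus]:
        for l in self.loci:
            if l.is_sex_marker:
                return l
        return None

    def __len__(self) -> int:
        return len(self.loci)

    def __getitem__(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(l.name == name for l in self.loci)


@dataclass(frozen=True)
class GenotypeCall:
    """Unordered diploid allele pair (or a non-called status) at one locus.

    Alleles are stored in nondecreasing order; a homozygote is an equal
    pair. Non-called statuses (missing, contaminated, disputed) carry no
    alleles and behave as missing in every comparison.
    """

    status: CallStatus = CallStatus.MISSING
    alleles: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.status is CallStatus.CALLED:
            if self.alleles is None or len(self.alleles) != 2:
                raise ValueError("called genotype requires exactly two alleles")
            a, b = self.alleles
            if not (isinstance(a, int) and isinstance(b, int)):
                raise TypeError(f"allele labels must be integers (bp sizes), got {self.alleles!r}")
            if a > b:
                object.__setattr__(self, "alleles", (b, a))
        elif self.alleles is not None:
            raise ValueError(f"status {self.status.value} must not carry alleles")

    @classmethod
    def called(cls, a: int, b: int) -> "GenotypeCall":
        return cls(CallStatus.CALLED, (a, b))

    @classmethod
    def missing(cls) -> "GenotypeCall":
        return cls(CallStatus.MISSING)

    @classmethod
    def contaminated(cls) -> "GenotypeCall":
        return cls(CallStatus.CONTAMINATED)

    @classmethod
    def disputed(cls) -> "GenotypeCall":
        return cls(CallStatus.DISPUTED)

    @property
    def is_called(self) -> bool:
        return self.status is CallStatus.CALLED

    @property
    def is_heterozygous(self) -> bool:
        return self.is_called and self.alleles[0] != self.alleles[1]

    @property
    def is_homozygous(self) -> bool:
        return self.is_called and self.alleles[0] == self.alleles[1]

    @property
    def allele_set(self) -> frozenset:
        return frozenset(self.alleles) if self.is_called else frozenset()


@dataclass
class ReplicateRecord:
    """Genotype calls of one PCR replicate of one sample across the panel."""

    sample_id: str
    replicate_index: int
    calls: dict  # locus name -> GenotypeCall

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")

    def validate_against(self, panel: LocusPanel) -> None:
        missing = set(panel.locus_names) - set(self.calls)
        extra = set(self.calls) - set(panel.locus_names)
        if missing or extra:
            raise ValueError(
                f"replicate {self.sample_id}/{self.replicate_index} does not cover the panel "
                f"(missing: {sorted(missing)}, unknown: {sorted(extra)})"
            )


@dataclass
class SampleMeta:
    """Field metadata attached to one sample."""

    sample_id: str
    sample_type: str = "scat"
    collection_date: Optional[date] = None
    location: Optional[object] = None  # free text or (lat, lon) pair

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"unknown sample type {self.sample_type!r}; expected one of {SAMPLE_TYPES}"
            )


# ---------------------------------------------------------------------------
# Elementary comparisons
# ---------------------------------------------------------------------------

def allele_mismatches(g1: GenotypeCall, g2: GenotypeCall) -> int:
    """Count non-shared alleles between two calls at the same locus (0-2).

    Counted per allele under the best pairing of the two unordered pairs,
    so 120/124 vs 120/120 is one mismatch. A non-called status on either
    side counts as similarity (0 mismatches), the convention used when
    matching noninvasive samples whose genotypes are incomplete.
    """
    if not (g1.is_called and g2.is_called):
        return 0
    shared = sum((Counter(g1.alleles) & Counter(g2.alleles)).values())
    return 2 - shared


def shared_complete_loci(a, b, panel: LocusPanel) -> int:
    """Number of autosomal loci called (no missing data) in both samples.

    ``a`` and ``b`` expose a ``calls`` mapping (sample or individual
    consensus objects). The sex marker never counts toward the total.
    """
    names = panel.autosomal_names
    for obj in (a, b):
        lacking = set(names) - set(obj.calls)
        if lacking:
            raise ValueError(f"sample does not cover the panel; missing loci {sorted(lacking)}")
    return sum(1 for n in names if a.calls[n].is_called and b.calls[n].is_called)


# ---------------------------------------------------------------------------
# Default wolf panel
# ---------------------------------------------------------------------------

# 22 autosomal microsatellites routinely used for European gray wolf
# monitoring (incl. the dog/wolf hybrid-informative subset) plus amelogenin.
_DEFAULT_LOCI = (
    "AHT103", "AHT111", "AHTk211", "FH2096", "CPH02", "FH2088", "C09.173",
    "CPH05", "FH2004", "CFX30371", "CXX279", "C09.250", "FH2161", "FH2140",
    "INU030", "FH2137", "FH2054", "C27.442", "Dbar1", "REN162C04", "PEZ17",
    "FH2010",
)


def default_wolf_panel() -> LocusPanel:
    """The 22-autosomal-locus + amelogenin panel, split over two multiplexes."""
    loci = []
    for i, name in enumerate(_DEFAULT_LOCI):
        lo = 100 + 10 * (i % 8)
        loci.append(
            Locus(
                name=name,
                multiplex_id=1 if i < 11 else 2,
                allele_size_range=(lo, lo + 60),
            )
        )
    loci.append(Locus(name="Amelogenin", multiplex_id=2, allele_size_range=(190, 220), is_sex_marker=True))
    return LocusPanel(tuple(loci))
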