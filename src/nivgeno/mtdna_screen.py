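"""Species and mitotype assignment of mitochondrial control-region sequences.

Sanger consensus sequences (~605 bp of the control region) are compared
against a curated reference haplotype panel by Hamming distance over the
shared aligned length. Only haplotypes specific to gray wolves confirm the
species; haplotypes shared between domestic dog and gray wolf yield a
*Canis* sp. verdict, since a wandering dog cannot be excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

from .consensus_builder import percentage

VALID_SPECIFICITY = ("wolf", "shared", "other")
_DNA = set("ACGTN")

#: default acceptance radius (mismatches over the shared region)
DEFAULT_MAX_MISMATCH = 2
#: consensus sequences shorter than this are too poor to identify a species
DEFAULT_MIN_LENGTH = 500


@dataclass(frozen=True)
class MitotypeRef:
    """One reference control-region haplotype (e.g. w22, Italo-Alpine)."""

    name: str
    specificity: str  # wolf | shared | other
    sequence: str

    def __post_init__(self) -> None:
        if self.specificity not in VALID_SPECIFICITY:
            raise ValueError(
                f"mitotype {self.name}: specificity must be one of {VALID_SPECIFICITY}"
            )
        seq = self.sequence.upper()
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(f"mitotype {self.name}: non-DNA characters {sorted(bad)}")
        if not seq:
            raise ValueError(f"mitotype {self.name}: empty sequence")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class MitotypeAssignment:
    sample_id: str
    best_match: Optional[str]
    distance: Optional[int]
    verdict: str  # wolf | canis_sp | non_target | unidentified


def hamming(a: str, b: str) -> int:
    """Mismatches over the shared prefix; N is a wildcard on either side."""
    return sum(
        1 for x, y in zip(a, b) if x != y and x != "N" and y != "N"
    )


def assign_mitotype(
    seq: str,
    refs: Sequence[MitotypeRef],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_length: int = DEFAULT_MIN_LENGTH,
    sample_id: str = "",
) -> MitotypeAssignment:
    """Assign one consensus sequence to its closest reference haplotype.

    The verdict follows the reference's species specificity; a sequence
    shorter than ``min_length``, farther than ``max_mismatch`` from every
    reference, or equidistant from several references is unidentified.
    """
    if not refs:
        raise ValueError("reference panel is empty")
    seq = seq.upper()
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters in query sequence: {sorted(bad)}")
    if len(seq) < min_length:
        return MitotypeAssignment(sample_id, None, None, "unidentified")

    dists = [(hamming(seq, r.sequence), r) for r in refs]
    best_d = min(d for d, _ in dists)
    best = [r for d, r in dists if d == best_d]
    if len(best) > 1 or best_d > max_mismatch:
        return MitotypeAssignment(sample_id, None, best_d, "unidentified")
    ref = best[0]
    verdict = {"wolf": "wolf", "shared": "canis_sp", "other": "non_target"}[ref.specificity]
    return MitotypeAssignment(sample_id, ref.name, best_d, verdict)


def screen_dataset(assignments: Sequence[MitotypeAssignment]) -> Dict[str, object]:
    """Per-verdict and per-mitotype tallies of a screened sample set.

    Verdict percentages use the number of submitted samples as denominator;
    mitotype percentages use the number of wolf-verdict samples (the share
    of each lineage within confirmed wolves), both rounded to one decimal.
    """
    n = len(assignments)
    verdicts = Counter(a.verdict for a in assignments)
    mitotypes = Counter(a.best_match for a in assignments if a.verdict == "wolf")
    identified = sum(c for v, c in verdicts.items() if v != "unidentified")
    n_wolf = verdicts.get("wolf", 0)
    summary: Dict[str, object] = {
        "n_submitted": n,
        "n_identified": identified,
        "verdict_counts": dict(verdicts),
        "mitotype_counts": dict(mitotypes),
    }
    if n:
        summary["pct_identified"] = percentage(identified, n)
        summary["verdict_pct"] = {v: percentage(c, n) for v, c in verdicts.items()}
    if n_wolf:
        summary["mitotype_pct"] = {m: percentage(c, n_wolf) for m, c in mitotypes.items()}
    return summary
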