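"""Per-sample consensus genotypes from PCR replicates (multitube approach).

Each amplified allele that survives artifact screening is treated as a
true allele and retained in the consensus -- a single amplification
suffices for each allele of heterozygous and homozygous loci. Screening
plays the role of the trained analyst reading electropherograms: an
allele observed in exactly one replicate while at least three replicates
were informative for the locus is discarded as an unconfirmed (false)
allele, since with typical error rates a single-replicate allele is far
more likely a polymerase artifact than a real allele that dropped out of
every other replicate. More than two distinct screened alleles at a locus
-- within one replicate or pooled across replicates -- is biologically
impossible for one diploid individual and flags the whole sample as
contaminated; contaminated samples are excluded from individual matching
and diversity stages downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from .genotype_model import (
    CallStatus,
    GenotypeCall,
    LocusPanel,
    ReplicateRecord,
)


@dataclass
class SampleConsensus:
    """Consensus genotype of one sample with its quality annotations.

    ``qi_per_locus`` and ``mean_qi`` are populated by the quality module;
    until then ``mean_qi`` is NaN.
    """

    sample_id: str
    calls: Dict[str, GenotypeCall]
    n_replicates: int
    contaminated: bool = False
    qi_per_locus: Dict[str, float] = field(default_factory=dict)
    mean_qi: float = math.nan
    #: locus -> allele -> number of replicates in which the allele was seen;
    #: empty for consensus objects built outside the replicate pipeline
    allele_support: Dict[str, Dict[int, int]] = field(default_factory=dict)

    @property
    def all_missing(self) -> bool:
        return not any(c.is_called for c in self.calls.values())


def build_consensus(replicates: Sequence[ReplicateRecord], panel: LocusPanel) -> SampleConsensus:
    """Combine 1-4 replicates of one sample into a consensus genotype.

    Per locus the consensus alleles are the distinct alleles observed
    across called replicates after unconfirmed-allele screening (see the
    module docstring): one allele -> homozygote, two -> heterozygote,
    none -> missing. A contaminated replicate call, or >2 screened
    distinct alleles, flags the sample as contaminated (the offending
    locus is scored missing in the consensus).
    """
    if not replicates:
        raise ValueError("build_consensus requires at least one replicate")
    ids = {r.sample_id for r in replicates}
    if len(ids) > 1:
        raise ValueError(f"replicates mix several samples: {sorted(ids)}")
    for r in replicates:
        r.validate_against(panel)

    sample_id = replicates[0].sample_id
    calls: Dict[str, GenotypeCall] = {}
    support: Dict[str, Dict[int, int]] = {}
    contaminated = False
    for locus in panel.locus_names:
        locus_support: Dict[int, int] = {}
        informative = 0
        for rep in replicates:
            call = rep.calls[locus]
            if call.status is CallStatus.CONTAMINATED:
                contaminated = True
            elif call.is_called:
                informative += 1
                for a in set(call.alleles):
                    locus_support[a] = locus_support.get(a, 0) + 1
        # analyst-style screening: drop single-replicate alleles when the
        # locus had enough informative replicates to confirm a real allele
        if informative >= 3:
            screened = {a: s for a, s in locus_support.items() if s >= 2}
            if screened:
                locus_support = screened
        support[locus] = locus_support
        alleles = set(locus_support)
        if len(alleles) == 0:
            calls[locus] = GenotypeCall.missing()
        elif len(alleles) == 1:
            (a,) = alleles
            calls[locus] = GenotypeCall.called(a, a)
        elif len(alleles) == 2:
            a, b = sorted(alleles)
            calls[locus] = GenotypeCall.called(a, b)
        else:
            contaminated = True
            calls[locus] = GenotypeCall.missing()

    return SampleConsensus(
        sample_id=sample_id,
        calls=calls,
        n_replicates=len(replicates),
        contaminated=contaminated,
        allele_support=support,
    )


def build_consensus_dataset(
    replicates: Iterable[ReplicateRecord], panel: LocusPanel
) -> List[SampleConsensus]:
    """Group a replicate table by sample and build every consensus."""
    by_sample: Dict[str, List[ReplicateRecord]] = {}
    for rec in replicates:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    return [build_consensus(reps, panel) for _, reps in sorted(by_sample.items())]


def consensus_dataset_counts(samples: Sequence[SampleConsensus]) -> Dict[str, float]:
    """Summary counts of a sample-consensus dataset.

    ``no_amplification`` counts samples where no locus amplified in any
    replicate; contaminated samples are counted separately (a contaminated
    sample with otherwise empty calls counts as contaminated, not as
    amplification failure). Percentages use the genotyped-sample total as
    denominator, rounded to one decimal.
    """
    n = len(samples)
    contaminated = sum(1 for s in samples if s.contaminated)
    no_amp = sum(1 for s in samples if s.all_missing and not s.contaminated)
    retained = n - contaminated - no_amp
    counts: Dict[str, float] = {
        "n_samples": n,
        "no_amplification": no_amp,
        "contaminated": contaminated,
        "retained": retained,
    }
    if n:
        counts["pct_no_amplification"] = percentage(no_amp, n)
        counts["pct_contaminated"] = percentage(contaminated, n)
        counts["pct_retained"] = percentage(retained, n)
    return counts


def percentage(numerator: int, denominator: int) -> float:
    """Share of a total expressed in percent, rounded to one decimal."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, 1)
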