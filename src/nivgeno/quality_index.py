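"""Quality scoring of replicates against their consensus, PCR success,
and the high-quality retention filter.

Each replicate x locus is scored 1 if it reproduces the consensus
genotype, 0.5 if it shows an allelic dropout relative to a heterozygous
consensus (the call still carries genotype information), and 0 when it is
missing, contaminated, disputed, or otherwise disagrees. The per-sample
quality index (QI) averages these scores over replicates and over the
autosomal panel, ranging from 0 (failed sample) to 1 (perfect agreement).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .consensus_builder import SampleConsensus
from .genotype_model import GenotypeCall, LocusPanel, ReplicateRecord

DEFAULT_QI_THRESHOLD = 0.5


@dataclass
class QualitySummary:
    """Per-locus and per-sample quality aggregates of a whole dataset."""

    per_locus_qi: Dict[str, float] = field(default_factory=dict)
    per_locus_pcr_success: Dict[str, float] = field(default_factory=dict)
    per_sample_mean_qi: Dict[str, float] = field(default_factory=dict)

    @property
    def mean_locus_qi(self) -> float:
        return fmean(self.per_locus_qi.values())

    @property
    def mean_pcr_success(self) -> float:
        return fmean(self.per_locus_pcr_success.values())


def score_replicate_locus(replicate_call: GenotypeCall, consensus_call: GenotypeCall) -> float:
    """Agreement score of one replicate call against the sample consensus.

    1 for an exact genotype match; 0.5 when the consensus is heterozygous
    and the replicate is homozygous for one consensus allele (allelic
    dropout); 0 otherwise (missing, contamination, dispute, or any other
    disagreement, including a spurious allele against a homozygous
    consensus).
    """
    if not replicate_call.is_called:
        return 0.0
    if not consensus_call.is_called:
        return 0.0
    if replicate_call.alleles == consensus_call.alleles:
        return 1.0
    if (
        consensus_call.is_heterozygous
        and replicate_call.is_homozygous
        and replicate_call.alleles[0] in consensus_call.alleles
    ):
        return 0.5
    return 0.0


def sample_qi(
    sample: SampleConsensus, replicates: Sequence[ReplicateRecord], panel: LocusPanel
) -> SampleConsensus:
    """Fill ``qi_per_locus`` and ``mean_qi`` of one sample (in place).

    The locus score is the mean over that sample's replicates; the sample
    QI is the mean of the locus scores over all autosomal panel loci, so a
    locus that never amplified contributes 0 for every replicate.
    """
    if not replicates:
        raise ValueError("sample_qi requires the sample's replicates")
    per_locus: Dict[str, float] = {}
    for locus in panel.autosomal_names:
        scores = [score_replicate_locus(r.calls[locus], sample.calls[locus]) for r in replicates]
        per_locus[locus] = fmean(scores)
    sample.qi_per_locus = per_locus
    sample.mean_qi = fmean(per_locus.values())
    return sample


def quality_summary(
    samples: Sequence[SampleConsensus],
    replicates_by_sample: Mapping[str, Sequence[ReplicateRecord]],
    panel: LocusPanel,
) -> QualitySummary:
    """Dataset-wide per-locus QI and PCR success, plus per-sample QI.

    Per-locus values pool all replicates of all samples; PCR success is
    the fraction of attempted amplifications (replicate x locus cells)
    that produced a called genotype.
    """
    summary = QualitySummary()
    score_sums: Dict[str, float] = {n: 0.0 for n in panel.autosomal_names}
    called: Dict[str, int] = {n: 0 for n in panel.locus_names}
    attempted: Dict[str, int] = {n: 0 for n in panel.locus_names}

    n_reps = 0
    for sample in samples:
        reps = replicates_by_sample[sample.sample_id]
        n_reps += len(reps)
        if not sample.qi_per_locus:
            sample_qi(sample, reps, panel)
        for rep in reps:
            for locus in panel.locus_names:
                attempted[locus] += 1
                if rep.calls[locus].is_called:
                    called[locus] += 1
            for locus in panel.autosomal_names:
                score_sums[locus] += score_replicate_locus(rep.calls[locus], sample.calls[locus])
        summary.per_sample_mean_qi[sample.sample_id] = sample.mean_qi

    for locus in panel.autosomal_names:
        summary.per_locus_qi[locus] = score_sums[locus] / n_reps if n_reps else float("nan")
    for locus in panel.locus_names:
        summary.per_locus_pcr_success[locus] = (
            called[locus] / attempted[locus] if attempted[locus] else float("nan")
        )
    return summary


def filter_high_quality(
    samples: Sequence[SampleConsensus], qi_threshold: float = DEFAULT_QI_THRESHOLD
) -> Tuple[List[SampleConsensus], float]:
    """Retain uncontaminated samples with mean QI strictly above threshold.

    Returns the retained subset and the retention fraction; a sample at
    exactly the threshold is excluded.
    """
    if not 0.0 <= qi_threshold <= 1.0:
        raise ValueError(f"qi_threshold must lie in [0, 1], got {qi_threshold}")
    retained = [
        s for s in samples if not s.contaminated and s.mean_qi > qi_threshold
    ]
    fraction = len(retained) / len(samples) if samples else 0.0
    return retained, fraction
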