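"""Staged genotyping-error estimation.

Errors are quantified at three stages of the pipeline, always as events
per successful amplification at the locus:

* ``AD``       -- allelic dropout in replicates vs their sample consensus,
                  over all uncontaminated samples;
* ``AD_high``  -- the same restricted to high-quality (QI > 0.5) samples;
* ``AD_res`` / ``FA_res`` -- residual dropout / false-allele rates after
                  consensus correction, from comparing the sample
                  consensus genotypes of recaptured individuals against
                  their individual consensus.

Dropout is only observable against a heterozygous reference (the observed
call is homozygous for exactly one reference allele); an observation
carrying any allele absent from the reference is a false-allele event,
including a homozygote for a foreign allele and a heterozygote sharing
only one allele with the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .consensus_builder import SampleConsensus
from .genotype_model import GenotypeCall, LocusPanel, ReplicateRecord
from .individual_matching import IndividualRecord
from .quality_index import DEFAULT_QI_THRESHOLD


@dataclass
class RateEstimate:
    """An error rate with its auditable numerator and denominator."""

    numerator: int = 0
    denominator: int = 0

    @property
    def rate(self) -> Optional[float]:
        # zero denominator => not estimable, never silently 0
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator


@dataclass
class ErrorEvent:
    stage: str
    sample_id: str
    locus: str
    replicate: Optional[int]
    kind: str  # dropout | false_allele


@dataclass
class ErrorRateTable:
    """Per-locus staged error rates with panel means and an event log."""

    pcr_success: Dict[str, RateEstimate]
    ad: Dict[str, RateEstimate]
    ad_high: Dict[str, RateEstimate]
    ad_res: Dict[str, RateEstimate]
    fa_res: Dict[str, RateEstimate]
    n_recaptured_samples: int = 0
    events: List[ErrorEvent] = field(default_factory=list)

    def mean(self, which: str) -> Optional[float]:
        """Unweighted mean over estimable loci (None if none estimable)."""
        rates = [e.rate for e in getattr(self, which).values() if e.rate is not None]
        return fmean(rates) if rates else None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for locus in self.pcr_success:
            row = {"locus": locus}
            for name in ("pcr_success", "ad", "ad_high", "ad_res", "fa_res"):
                est = getattr(self, name)[locus]
                row[name] = est.rate
                row[f"{name}_num"] = est.numerator
                row[f"{name}_den"] = est.denominator
            rows.append(row)
        return pd.DataFrame(rows)


def is_dropout(obs: GenotypeCall, ref: GenotypeCall) -> bool:
    """Observed homozygote for exactly one allele of a heterozygous reference."""
    return (
        ref.is_heterozygous
        and obs.is_called
        and obs.is_homozygous
        and obs.alleles[0] in ref.alleles
    )


def is_false_allele(obs: GenotypeCall, ref: GenotypeCall) -> bool:
    """Observed call carries at least one allele absent from the reference."""
    if not (obs.is_called and ref.is_called):
        return False
    return bool(obs.allele_set - ref.allele_set)


def allelic_dropout_rate(
    comparisons: Iterable[Tuple[str, GenotypeCall, GenotypeCall]],
) -> Dict[str, RateEstimate]:
    """Per-locus dropout rate from (locus, observed, reference) pairs.

    Only reference-heterozygous loci enter the denominator, and only
    called observations (a missing observation is a failed PCR, not a
    dropout). The observation side may be a replicate call or a sample
    consensus, depending on the stage.
    """
    rates: Dict[str, RateEstimate] = {}
    for locus, obs, ref in comparisons:
        if not ref.is_heterozygous or not obs.is_called:
            continue
        est = rates.setdefault(locus, RateEstimate())
        est.denominator += 1
        if is_dropout(obs, ref):
            est.numerator += 1
    return rates


def false_allele_rate(
    comparisons: Iterable[Tuple[str, GenotypeCall, GenotypeCall]],
) -> Dict[str, RateEstimate]:
    """Per-locus false-allele rate: events per successful amplification."""
    rates: Dict[str, RateEstimate] = {}
    for locus, obs, ref in comparisons:
        if not ref.is_called or not obs.is_called:
            continue
        est = rates.setdefault(locus, RateEstimate())
        est.denominator += 1
        if is_false_allele(obs, ref):
            est.numerator += 1
    return rates


def staged_error_report(
    replicates_by_sample: Mapping[str, Sequence[ReplicateRecord]],
    samples: Sequence[SampleConsensus],
    individuals: Sequence[IndividualRecord],
    panel: LocusPanel,
    qi_threshold: float = DEFAULT_QI_THRESHOLD,
) -> ErrorRateTable:
    """All staged error rates for one dataset.

    ``samples`` is the full sample-consensus dataset (contaminated samples
    are skipped, their consensus being undefined); ``individuals`` the
    clustering of the high-quality subset. Loci without a single valid
    comparison are reported as not estimable.
    """
    names = panel.autosomal_names
    table = ErrorRateTable(
        pcr_success={n: RateEstimate() for n in names},
        ad={n: RateEstimate() for n in names},
        ad_high={n: RateEstimate() for n in names},
        ad_res={n: RateEstimate() for n in names},
        fa_res={n: RateEstimate() for n in names},
    )

    # stage 1: replicates vs sample consensus
    for sample in samples:
        if sample.contaminated:
            continue
        high = sample.mean_qi > qi_threshold
        for rep in replicates_by_sample[sample.sample_id]:
            for locus in names:
                obs, ref = rep.calls[locus], sample.calls[locus]
                table.pcr_success[locus].denominator += 1
                if obs.is_called:
                    table.pcr_success[locus].numerator += 1
                if not ref.is_heterozygous or not obs.is_called:
                    continue
                table.ad[locus].denominator += 1
                if high:
                    table.ad_high[locus].denominator += 1
                if is_dropout(obs, ref):
                    table.ad[locus].numerator += 1
                    if high:
                        table.ad_high[locus].numerator += 1
                    table.events.append(
                        ErrorEvent("replicate", sample.sample_id, locus, rep.replicate_index, "dropout")
                    )

    # stage 2: sample consensus vs individual consensus (recaptures only)
    for ind in individuals:
        if len(ind.members) < 2:
            continue
        table.n_recaptured_samples += len(ind.members)
        for sample in ind.members:
            for locus in names:
                obs, ref = sample.calls[locus], ind.consensus[locus]
                if not obs.is_called or not ref.is_called:
                    continue
                if ref.is_heterozygous:
                    table.ad_res[locus].denominator += 1
                    if is_dropout(obs, ref):
                        table.ad_res[locus].numerator += 1
                        table.events.append(
                            ErrorEvent("recapture", sample.sample_id, locus, None, "dropout")
                        )
                table.fa_res[locus].denominator += 1
                if is_false_allele(obs, ref):
                    table.fa_res[locus].numerator += 1
                    table.events.append(
                        ErrorEvent("recapture", sample.sample_id, locus, None, "false_allele")
                    )
    return table
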