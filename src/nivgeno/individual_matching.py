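"""Grouping high-quality samples into individuals, and the binomial
mismatch model that motivates the matching thresholds.

Two samples are attributed to the same animal when they share at least 12
autosomal loci with no missing data and differ by at most 3 alleles over
those loci. The tolerance follows from a binomial error model: with a
per-locus dropout probability p among high-quality samples, the chance of
at least one mismatch across n compared loci is 1 - (1-p)^n (0.587 at
n = 12, p = 0.071), and almost all genuine same-individual comparisons
fall within 1-3 mismatches.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from datetime import date
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from scipy import stats

from .consensus_builder import SampleConsensus
from .genotype_model import (
    GenotypeCall,
    LocusPanel,
    SampleMeta,
    allele_mismatches,
    shared_complete_loci,
)


@dataclass(frozen=True)
class MatchRule:
    """Thresholds for assigning two samples to the same individual."""

    min_shared_loci: int = 12
    max_mismatches: int = 3

    def __post_init__(self) -> None:
        if self.min_shared_loci < 1:
            raise ValueError("min_shared_loci must be >= 1")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass
class IndividualRecord:
    """One animal: its member samples, consensus genotype and sex."""

    individual_id: str
    sample_ids: List[str]
    consensus: Dict[str, GenotypeCall]
    sex: str = "unknown"
    first_capture: Optional[date] = None
    last_capture: Optional[date] = None
    members: List[SampleConsensus] = field(default_factory=list)

    @property
    def calls(self) -> Dict[str, GenotypeCall]:
        # lets IndividualRecord reuse the sample-level comparison helpers
        return self.consensus

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


# ---------------------------------------------------------------------------
# Binomial mismatch model
# ---------------------------------------------------------------------------

def mismatch_probability(n: int, p: float) -> float:
    """Probability of observing at least one mismatch across n loci."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return 1.0 - (1.0 - p) ** n


def mismatch_range_probability(
    n: int, p: float, lo: int, hi: int, conditional_on_at_least_one: bool = False
) -> float:
    """Probability that the mismatch count falls in [lo, hi].

    With ``conditional_on_at_least_one`` the mass is renormalised by
    P(X >= 1), answering "given that two same-individual samples disagree
    at all, how many mismatches do they show?".
    """
    if not 0 <= lo <= hi <= n:
        raise ValueError(f"need 0 <= lo <= hi <= n, got lo={lo}, hi={hi}, n={n}")
    dist = stats.binom(n, p)
    mass = dist.cdf(hi) - (dist.cdf(lo - 1) if lo > 0 else 0.0)
    if conditional_on_at_least_one:
        p_ge1 = 1.0 - dist.pmf(0)
        if p_ge1 == 0.0:
            return 0.0
        mass /= p_ge1
    return float(mass)


# ---------------------------------------------------------------------------
# Pairwise comparison and clustering
# ---------------------------------------------------------------------------

def pairwise_compare(a, b, panel: LocusPanel) -> Tuple[int, int]:
    """(shared complete loci, total allele mismatches over shared loci)."""
    shared = shared_complete_loci(a, b, panel)
    mism = 0
    for name in panel.autosomal_names:
        ca, cb = a.calls[name], b.calls[name]
        if ca.is_called and cb.is_called:
            mism += allele_mismatches(ca, cb)
    return shared, mism


def _merge_consensus(
    members: Sequence[SampleConsensus], panel: LocusPanel
) -> Dict[str, GenotypeCall]:
    """Individual consensus from member samples.

    Per locus the candidate alleles are the union over the called member
    calls. Because residual dropout is far more common than a residual
    false allele, an allele seen in only one member is normally kept --
    except when it was observed in a single PCR replicate while at least
    three replicates were informative for the locus across members, in
    which case it is discarded as an unconfirmed (false) allele. If more
    than two well-supported alleles remain, the majority genotype among
    member calls wins, ties resolved toward the higher-QI member (then
    lowest sample id). Samples built without replicate support
    information are trusted as confirmed calls.
    """
    consensus: Dict[str, GenotypeCall] = {}
    ordered = sorted(members, key=lambda s: (-(s.mean_qi if s.mean_qi == s.mean_qi else 0.0), s.sample_id))
    for name in panel.locus_names:
        called = [(s, s.calls[name]) for s in ordered if s.calls[name].is_called]
        if not called:
            consensus[name] = GenotypeCall.missing()
            continue
        support: Counter = Counter()
        n_informative_reps = 0
        for s, c in called:
            locus_support = s.allele_support.get(name)
            if locus_support is None:
                # no replicate information: count the call as confirmed
                locus_support = {a: 2 for a in c.alleles}
            for a in set(c.alleles):
                support[a] += locus_support.get(a, 2)
            n_informative_reps += max(locus_support.values(), default=0)
        union = sorted(support)
        if len(called) >= 2 and n_informative_reps >= 3:
            kept = [a for a in union if support[a] >= 2]
            if kept:
                union = kept
        if len(union) == 1:
            consensus[name] = GenotypeCall.called(union[0], union[0])
        elif len(union) == 2:
            consensus[name] = GenotypeCall.called(union[0], union[1])
        else:
            votes = Counter(c.alleles for _, c in called)
            top = max(votes.values())
            # first member (highest QI, then id) holding a majority genotype
            for s, c in called:
                if votes[c.alleles] == top:
                    consensus[name] = c
                    break
    return consensus


def assign_sex(consensus: Mapping[str, GenotypeCall], panel: LocusPanel) -> str:
    """Sex from the amelogenin marker: heterozygote = male, homozygote =
    female (canid convention), missing = unknown."""
    marker = panel.sex_marker
    if marker is None:
        raise ValueError("panel has no sex marker")
    call = consensus.get(marker.name, GenotypeCall.missing())
    if not call.is_called:
        return "unknown"
    return "male" if call.is_heterozygous else "female"


def cluster_individuals(
    samples: Sequence[SampleConsensus],
    panel: LocusPanel,
    rule: MatchRule = MatchRule(),
    metas: Optional[Mapping[str, SampleMeta]] = None,
) -> List[IndividualRecord]:
    """Deterministic greedy agglomeration of samples into individuals.

    Samples are processed by descending mean QI (ties by sample id); each
    joins the existing individual with the fewest mismatches among those
    whose consensus satisfies the match rule (ties: most shared loci, then
    lowest individual id), else founds a new individual. The individual
    consensus is rebuilt after every join, so the outcome is invariant to
    the input order.
    """
    bad = [s.sample_id for s in samples if s.contaminated]
    if bad:
        raise ValueError(f"contaminated samples must be excluded before matching: {bad[:5]}")

    ordered = sorted(samples, key=lambda s: (-s.mean_qi, s.sample_id))
    individuals: List[IndividualRecord] = []
    for sample in ordered:
        best = None  # (mismatches, -shared, index)
        for idx, ind in enumerate(individuals):
            shared, mism = pairwise_compare(sample, ind, panel)
            if shared >= rule.min_shared_loci and mism <= rule.max_mismatches:
                key = (mism, -shared, idx)
                if best is None or key < best:
                    best = key
        if best is None:
            ind = IndividualRecord(
                individual_id=f"IND{len(individuals) + 1:04d}",
                sample_ids=[sample.sample_id],
                consensus={},
                members=[sample],
            )
            individuals.append(ind)
        else:
            ind = individuals[best[2]]
            ind.sample_ids.append(sample.sample_id)
            ind.members.append(sample)
        ind.consensus = _merge_consensus(ind.members, panel)

    for ind in individuals:
        ind.sample_ids.sort()
        if panel.sex_marker is not None:
            ind.sex = assign_sex(ind.consensus, panel)
        if metas:
            dates = [
                metas[sid].collection_date
                for sid in ind.sample_ids
                if sid in metas and metas[sid].collection_date is not None
            ]
            if dates:
                ind.first_capture = min(dates)
                ind.last_capture = max(dates)
    return individuals


def audit_individuals(
    individuals: Sequence[IndividualRecord], panel: LocusPanel, rule: MatchRule = MatchRule()
) -> List[Tuple[str, str, int, int]]:
    """Post-hoc check that every member sample still satisfies the match
    rule against the final individual consensus.

    Returns violations as (individual_id, sample_id, shared, mismatches);
    an empty list certifies the clustering. Single-sample individuals are
    trivially consistent.
    """
    violations = []
    for ind in individuals:
        if len(ind.members) < 2:
            continue
        for sample in ind.members:
            shared, mism = pairwise_compare(sample, ind, panel)
            if shared < rule.min_shared_loci or mism > rule.max_mismatches:
                violations.append((ind.individual_id, sample.sample_id, shared, mism))
    return violations


def threshold_sensitivity(
    samples: Sequence[SampleConsensus],
    panel: LocusPanel,
    rules: Sequence[MatchRule],
    metas: Optional[Mapping[str, SampleMeta]] = None,
) -> List[Dict[str, float]]:
    """Re-cluster under each rule; report counts and change vs the first."""
    if not rules:
        raise ValueError("at least one rule required")
    out = []
    baseline = None
    for rule in rules:
        n = len(cluster_individuals(samples, panel, rule, metas))
        if baseline is None:
            baseline = n
        out.append({
            "min_shared_loci": rule.min_shared_loci,
            "max_mismatches": rule.max_mismatches,
            "n_individuals": n,
            "pct_change": 100.0 * (n - baseline) / baseline if baseline else 0.0,
        })
    return out


def review_spatiotemporal(
    individuals: Sequence[IndividualRecord],
    metas: Mapping[str, SampleMeta],
    max_km: float = 50.0,
) -> List[Tuple[str, str, str, float]]:
    """Flag same-day member samples farther apart than ``max_km``.

    Advisory only (sample quality, date and location are confirmation
    aids, not automatic split criteria): returns
    (individual_id, sample_a, sample_b, km) tuples for review.
    """
    flags = []
    for ind in individuals:
        sids = [s for s in ind.sample_ids if s in metas]
        for a, b in itertools.combinations(sids, 2):
            ma, mb = metas[a], metas[b]
            if (
                ma.collection_date is None or mb.collection_date is None
                or ma.collection_date != mb.collection_date
                or not isinstance(ma.location, tuple) or not isinstance(mb.location, tuple)
            ):
                continue
            km = _haversine_km(ma.location, mb.location)
            if km > max_km:
                flags.append((ind.individual_id, a, b, km))
    return flags


def _haversine_km(p1: Tuple[float, float], p2: Tuple[float, float]) -> float:
    lat1, lon1, lat2, lon2 = map(math.radians, (*p1, *p2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * 6371.0 * math.asin(math.sqrt(h))
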