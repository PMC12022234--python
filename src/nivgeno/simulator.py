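"""Synthetic replicate-genotype generator with full truth logs.

The generator emulates the statistical structure the pipeline assumes:
diploid multi-locus genotypes drawn under Hardy-Weinberg equilibrium from
per-locus allele frequencies; a capture-recapture sampling structure
(individuals yield 1-35 samples); four PCR replicates per noninvasive
sample and two per tissue/blood sample; and per-replicate error processes
-- amplification failure, per-allele dropout, false alleles and
sample-level contamination -- each of which is logged with its exact
coordinates so that estimators can be validated against ground truth.

Error injection per sample x replicate x locus, in order:
(1) contamination (sample-level) pools a second individual's alleles into
    the amplifiable set; (2) amplification failure blanks the cell;
(3) each distinct amplifiable allele drops independently with probability
    d (all dropping blanks the cell); (4) with probability f a wrong
    allele from the locus size lattice is injected -- substituting one
    surviving allele of a two-allele call (a mis-scored fragment) or
    added to a single-allele call. The emitted call is missing (0
    alleles), a homozygote (1), a heterozygote (2), or a contaminated
    flag (>2 alleles in the cell).

Per-sample quality heterogeneity follows a two-class (good/poor) mixture
of multipliers on the failure and dropout probabilities, reproducing the
bimodal quality-index distribution of field datasets where fresh tissue
coexists with weathered scat.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import adjusted_rand_score, rand_score

from .consensus_builder import build_consensus_dataset
from .error_rates import is_dropout, is_false_allele, staged_error_report
from .genotype_model import (
    CallStatus,
    GenotypeCall,
    INVASIVE_TYPES,
    LocusPanel,
    ReplicateRecord,
    SampleMeta,
    default_wolf_panel,
)
from .individual_matching import MatchRule, cluster_individuals
from .quality_index import filter_high_quality, quality_summary

#: per-locus allele counts of the default wolf panel (matching the
#: published diversity of the 22 markers, in panel order)
DEFAULT_ALLELE_COUNTS = (7, 8, 8, 6, 8, 7, 5, 6, 15, 4, 8, 7, 15, 13, 6, 16, 9, 6, 11, 9, 8, 6)


@dataclass(frozen=True)
class ErrorSpec:
    """Per-replicate error process parameters.

    ``failure`` is the per-cell amplification failure probability before
    quality multipliers; ``dropout`` the per-allele dropout probability d;
    ``false_allele`` the per-cell injection probability f; ``contamination``
    the per-sample probability of pooling a second individual.
    """

    failure: float = 0.20
    dropout: float = 0.07
    false_allele: float = 0.01
    contamination: float = 0.02

    def __post_init__(self) -> None:
        for name in ("failure", "dropout", "false_allele", "contamination"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class QualityMixture:
    """Per-sample quality classes: failed / poor / good.

    A ``failed`` sample (DNA too degraded) never amplifies at any locus;
    a ``poor`` sample multiplies the failure and dropout probabilities
    (capped at 1), reproducing weathered noninvasive material. Invasive
    samples (tissue, blood) are always good class. Draws are sequential:
    failed with probability ``failed_fraction``, else poor with
    probability ``poor_fraction``.
    """

    failed_fraction: float = 0.08
    poor_fraction: float = 0.25
    poor_failure_mult: float = 3.5
    poor_dropout_mult: float = 2.5


@dataclass(frozen=True)
class RecaptureSpec:
    """Samples per individual: zero-truncated with support 1-35.

    With probability ``singleton_prob`` an individual is sampled once;
    otherwise its sample count is 2 + Poisson(``recaptured_mean`` - 2)
    truncated at ``max_samples``. Defaults reproduce field monitoring
    where ~61% of animals are seen once and recaptured animals average
    ~4 samples.
    """

    singleton_prob: float = 0.607
    recaptured_mean: float = 4.03
    max_samples: int = 35


@dataclass(frozen=True)
class SimConfig:
    n_individuals: int = 50
    panel: LocusPanel = field(default_factory=default_wolf_panel)
    allele_counts: Tuple[int, ...] = DEFAULT_ALLELE_COUNTS
    #: symmetric-Dirichlet concentration for per-locus allele frequencies;
    #: 0.2 yields the skewed spectra and ~0.5 expected heterozygosity of a
    #: population founded by few individuals (E[He] = (K*a - a)/(K*a + 1))
    dirichlet_concentration: float = 0.2
    recapture: RecaptureSpec = RecaptureSpec()
    errors: ErrorSpec = ErrorSpec()
    quality: QualityMixture = QualityMixture()
    #: proportions over (scat, urine, hair, tissue, blood)
    sample_type_mix: Tuple[float, ...] = (0.838, 0.062, 0.020, 0.070, 0.010)
    replicates_noninvasive: int = 4
    replicates_invasive: int = 2
    sex_ratio: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if len(self.allele_counts) != len(self.panel.autosomal_loci):
            raise ValueError("allele_counts must match the autosomal panel size")
        if not math.isclose(sum(self.sample_type_mix), 1.0, abs_tol=1e-9):
            raise ValueError("sample_type_mix must sum to 1")


@dataclass
class SimEvent:
    kind: str  # failure | dropout | false_allele | contamination
    sample_id: str
    locus: Optional[str] = None
    replicate: Optional[int] = None
    allele: Optional[int] = None          # dropped or injected allele
    replaced_allele: Optional[int] = None  # substituted-out allele for FA
    contaminant: Optional[str] = None      # second individual for contamination


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    genotypes: Dict[str, Dict[str, Tuple[int, int]]]  # individual -> locus -> pair
    sex: Dict[str, str]
    sample_to_individual: Dict[str, str]
    sample_quality_class: Dict[str, str]
    sample_n_replicates: Dict[str, int] = field(default_factory=dict)
    events: List[SimEvent] = field(default_factory=list)


_SAMPLE_TYPES = ("scat", "urine", "hair", "tissue", "blood")


def _locus_alleles(locus, n_alleles: int) -> List[int]:
    lo, hi = locus.allele_size_range
    # dinucleotide lattice within the locus size range
    ladder = list(range(lo, hi + 1, 2))
    return ladder[:n_alleles] if len(ladder) >= n_alleles else ladder


def simulate_frequencies(config: SimConfig, rng: np.random.Generator) -> Dict[str, Dict[int, float]]:
    """Per-locus allele frequency vectors (symmetric Dirichlet draw)."""
    freqs: Dict[str, Dict[int, float]] = {}
    for locus, n_all in zip(config.panel.autosomal_loci, config.allele_counts):
        alleles = _locus_alleles(locus, n_all)
        if len(alleles) < 1:
            raise ValueError(f"locus {locus.name}: no alleles fit its size range")
        probs = rng.dirichlet([config.dirichlet_concentration] * len(alleles))
        freqs[locus.name] = dict(zip(alleles, probs.tolist()))
    return freqs


def simulate_individuals(
    config: SimConfig,
    rng: np.random.Generator,
    freqs: Optional[Mapping[str, Mapping[int, float]]] = None,
) -> Tuple[Dict[str, Dict[str, Tuple[int, int]]], Dict[str, str]]:
    """True genotypes under HWE: two alleles i.i.d. per locus; amelogenin
    heterozygous for males, drawn per the configured sex ratio."""
    if freqs is None:
        freqs = simulate_frequencies(config, rng)
    for locus, fv in freqs.items():
        if not fv or not math.isclose(sum(fv.values()), 1.0, abs_tol=1e-9):
            raise ValueError(f"degenerate frequency vector at {locus}")
    genotypes: Dict[str, Dict[str, Tuple[int, int]]] = {}
    sexes: Dict[str, str] = {}
    marker = config.panel.sex_marker
    for i in range(config.n_individuals):
        ind_id = f"W{i + 1:04d}"
        geno: Dict[str, Tuple[int, int]] = {}
        for locus_name, fv in freqs.items():
            alleles = np.array(list(fv.keys()))
            probs = np.array(list(fv.values()))
            a, b = rng.choice(alleles, size=2, p=probs)
            geno[locus_name] = (int(min(a, b)), int(max(a, b)))
        sex = "male" if rng.random() < config.sex_ratio else "female"
        if marker is not None:
            lo, _ = marker.allele_size_range
            x, y = lo + 4, lo + 10
            geno[marker.name] = (x, y) if sex == "male" else (x, x)
        genotypes[ind_id] = geno
        sexes[ind_id] = sex
    return genotypes, sexes


def _draw_n_samples(spec: RecaptureSpec, rng: np.random.Generator) -> int:
    if rng.random() < spec.singleton_prob:
        return 1
    n = 2 + rng.poisson(max(spec.recaptured_mean - 2.0, 0.0))
    return int(min(n, spec.max_samples))


def simulate_replicates(
    genotypes: Mapping[str, Mapping[str, Tuple[int, int]]],
    sexes: Mapping[str, str],
    config: SimConfig,
    rng: np.random.Generator,
) -> Tuple[List[ReplicateRecord], List[SampleMeta], SimulationTruth]:
    """Emit the replicate table for a set of true genotypes.

    Every injected failure, dropout, false allele and contamination event
    is logged; replaying the log against the truth genotypes regenerates
    the emitted calls exactly (see ``replay_events``).
    """
    truth = SimulationTruth(
        genotypes={k: dict(v) for k, v in genotypes.items()},
        sex=dict(sexes),
        sample_to_individual={},
        sample_quality_class={},
    )
    panel = config.panel
    records: List[ReplicateRecord] = []
    metas: List[SampleMeta] = []
    ind_ids = list(genotypes)
    err = config.errors
    counter = 0
    for ind_id in ind_ids:
        for _ in range(_draw_n_samples(config.recapture, rng)):
            counter += 1
            sid = f"S{counter:05d}"
            truth.sample_to_individual[sid] = ind_id
            stype = _SAMPLE_TYPES[rng.choice(len(_SAMPLE_TYPES), p=config.sample_type_mix)]
            invasive = stype in INVASIVE_TYPES
            n_rep = config.replicates_invasive if invasive else config.replicates_noninvasive
            if invasive:
                qclass = "good"
            elif rng.random() < config.quality.failed_fraction:
                qclass = "failed"
            elif rng.random() < config.quality.poor_fraction:
                qclass = "poor"
            else:
                qclass = "good"
            truth.sample_quality_class[sid] = qclass
            truth.sample_n_replicates[sid] = n_rep
            f_mult = config.quality.poor_failure_mult if qclass == "poor" else 1.0
            d_mult = config.quality.poor_dropout_mult if qclass == "poor" else 1.0
            if qclass == "failed":
                p_fail, p_drop = 1.0, 0.0
            else:
                p_fail = min(err.failure * f_mult * (0.2 if invasive else 1.0), 1.0)
                p_drop = min(err.dropout * d_mult * (0.2 if invasive else 1.0), 1.0)

            base: Dict[str, Tuple[int, ...]] = {
                name: tuple(genotypes[ind_id][name]) for name in panel.locus_names
            }
            if rng.random() < err.contamination:
                contaminant = ind_ids[int(rng.integers(len(ind_ids)))]
                if contaminant != ind_id:
                    truth.events.append(SimEvent("contamination", sid, contaminant=contaminant))
                    base = {
                        name: tuple(sorted(set(base[name]) | set(genotypes[contaminant][name])))
                        for name in panel.locus_names
                    }

            meta = SampleMeta(
                sample_id=sid,
                sample_type=stype,
                collection_date=_dt.date(2006, 1, 1) + _dt.timedelta(days=int(rng.integers(0, 6209))),
                location=(float(44.0 + rng.random() * 3.0), float(5.5 + rng.random() * 2.5)),
            )
            metas.append(meta)

            for rep_idx in range(1, n_rep + 1):
                calls: Dict[str, GenotypeCall] = {}
                for locus in panel.loci:
                    name = locus.name
                    distinct = sorted(set(base[name]))
                    if rng.random() < p_fail:
                        truth.events.append(SimEvent("failure", sid, name, rep_idx))
                        calls[name] = GenotypeCall.missing()
                        continue
                    surviving = []
                    for allele in distinct:
                        if rng.random() < p_drop:
                            truth.events.append(SimEvent("dropout", sid, name, rep_idx, allele=allele))
                        else:
                            surviving.append(allele)
                    if surviving and rng.random() < err.false_allele:
                        lo, hi = locus.allele_size_range
                        lattice = [a for a in range(lo, hi + 1, 2) if a not in distinct]
                        if lattice:
                            fa = int(lattice[int(rng.integers(len(lattice)))])
                            if len(surviving) >= 2:
                                out = surviving[int(rng.integers(len(surviving)))]
                                surviving = [a for a in surviving if a != out] + [fa]
                                truth.events.append(
                                    SimEvent("false_allele", sid, name, rep_idx, allele=fa, replaced_allele=out)
                                )
                            else:
                                surviving = surviving + [fa]
                                truth.events.append(SimEvent("false_allele", sid, name, rep_idx, allele=fa))
                    calls[name] = _call_from_alleles(surviving)
                records.append(ReplicateRecord(sid, rep_idx, calls))
    return records, metas, truth


def _call_from_alleles(alleles: Sequence[int]) -> GenotypeCall:
    distinct = sorted(set(alleles))
    if len(distinct) == 0:
        return GenotypeCall.missing()
    if len(distinct) == 1:
        return GenotypeCall.called(distinct[0], distinct[0])
    if len(distinct) == 2:
        return GenotypeCall.called(distinct[0], distinct[1])
    return GenotypeCall.contaminated()


def simulate_dataset(
    config: SimConfig,
) -> Tuple[List[ReplicateRecord], List[SampleMeta], SimulationTruth]:
    """Full draw: frequencies -> individuals -> samples -> replicates."""
    rng = np.random.default_rng(config.seed)
    genotypes, sexes = simulate_individuals(config, rng)
    return simulate_replicates(genotypes, sexes, config, rng)


def replay_events(
    truth: SimulationTruth, config: SimConfig
) -> Dict[Tuple[str, int, str], GenotypeCall]:
    """Regenerate every emitted call from the truth log alone.

    Used to verify that the event log reconciles exactly with the
    difference between truth genotypes and the emitted replicate table.
    """
    contamination = {
        e.sample_id: e.contaminant for e in truth.events if e.kind == "contamination"
    }
    failures = {(e.sample_id, e.replicate, e.locus) for e in truth.events if e.kind == "failure"}
    dropouts: Dict[Tuple[str, int, str], set] = {}
    for e in truth.events:
        if e.kind == "dropout":
            dropouts.setdefault((e.sample_id, e.replicate, e.locus), set()).add(e.allele)
    fas = {
        (e.sample_id, e.replicate, e.locus): e
        for e in truth.events
        if e.kind == "false_allele"
    }

    calls: Dict[Tuple[str, int, str], GenotypeCall] = {}
    for sid, ind_id in truth.sample_to_individual.items():
        base_geno = truth.genotypes[ind_id]
        cont = contamination.get(sid)
        n_rep = truth.sample_n_replicates[sid]
        for rep in range(1, n_rep + 1):
            for locus, pair in base_geno.items():
                alleles = set(pair)
                if cont is not None:
                    alleles |= set(truth.genotypes[cont][locus])
                key = (sid, rep, locus)
                if key in failures:
                    calls[key] = GenotypeCall.missing()
                    continue
                alleles -= dropouts.get(key, set())
                fa = fas.get(key)
                if fa is not None:
                    if fa.replaced_allele is not None:
                        alleles.discard(fa.replaced_allele)
                    alleles.add(fa.allele)
                calls[key] = _call_from_alleles(sorted(alleles))
    return calls


# ---------------------------------------------------------------------------
# Truth-referenced error frequencies and the recovery harness
# ---------------------------------------------------------------------------

def truth_error_frequencies(
    records: Sequence[ReplicateRecord],
    samples,
    individuals,
    truth: SimulationTruth,
    panel: LocusPanel,
) -> Dict[str, float]:
    """Empirical dropout / false-allele frequencies measured against the
    true genotypes, on the same comparison sets the estimators use.

    The denominators replicate the estimators' frames exactly (called
    observations at consensus-heterozygous loci for dropout; called
    observations at loci with a called individual consensus for residual
    rates), while the numerators classify each observation against the
    individual's TRUE genotype. The comparison therefore verifies that
    the estimators count genuine injected events -- neither leaking
    artifacts into the numerator nor missing logged events -- rather than
    re-deriving the injection parameters in closed form.
    """
    sample_by_id = {s.sample_id: s for s in samples}
    ad_num = ad_den = 0
    for rec in records:
        sample = sample_by_id[rec.sample_id]
        if sample.contaminated:
            continue
        true_geno = truth.genotypes[truth.sample_to_individual[rec.sample_id]]
        for locus in panel.autosomal_names:
            if not sample.calls[locus].is_heterozygous:
                continue
            obs = rec.calls[locus]
            if not obs.is_called:
                continue
            a, b = true_geno[locus]
            ref = GenotypeCall.called(a, b)
            ad_den += 1
            if is_dropout(obs, ref):
                ad_num += 1

    fa_num = fa_den = 0
    ad_res_num = ad_res_den = 0
    for ind in individuals:
        if len(ind.members) < 2:
            continue
        for sample in ind.members:
            true_geno = truth.genotypes[truth.sample_to_individual[sample.sample_id]]
            for locus in panel.autosomal_names:
                a, b = true_geno[locus]
                ref = GenotypeCall.called(a, b)
                obs = sample.calls[locus]
                ind_ref = ind.consensus[locus]
                if not obs.is_called or not ind_ref.is_called:
                    continue
                fa_den += 1
                if is_false_allele(obs, ref):
                    fa_num += 1
                if ind_ref.is_heterozygous:
                    ad_res_den += 1
                    if is_dropout(obs, ref):
                        ad_res_num += 1
    return {
        "ad_truth": ad_num / ad_den if ad_den else math.nan,
        "ad_res_truth": ad_res_num / ad_res_den if ad_res_den else math.nan,
        "fa_res_truth": fa_num / fa_den if fa_den else math.nan,
    }


def run_dataset_pipeline(
    records: Sequence[ReplicateRecord],
    panel: LocusPanel,
    rule: MatchRule = MatchRule(),
    qi_threshold: float = 0.5,
):
    """Consensus -> QI -> filter -> clustering -> staged error report."""
    samples = build_consensus_dataset(records, panel)
    by_sample: Dict[str, List[ReplicateRecord]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    quality_summary(samples, by_sample, panel)
    retained, _ = filter_high_quality(samples, qi_threshold)
    individuals = cluster_individuals(retained, panel, rule)
    errors = staged_error_report(by_sample, samples, individuals, panel, qi_threshold)
    return samples, retained, individuals, errors


def recovery_experiment(
    config: SimConfig,
    n_datasets: int,
    seed: int,
    rule: MatchRule = MatchRule(),
) -> Dict[str, object]:
    """Run the full pipeline over replicate simulated datasets.

    Reports, per dataset and averaged: estimated vs truth-referenced AD
    and residual FA rates, the (adjusted) Rand index of the recovered
    individual partition against the true sample-to-individual map, and
    the individual count vs truth.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    rows = []
    for i in range(n_datasets):
        cfg = dataclasses.replace(config, seed=(seed + i) % (2 ** 31))
        records, _, truth = simulate_dataset(cfg)
        samples, retained, individuals, errors = run_dataset_pipeline(records, config.panel, rule)
        truth_rates = truth_error_frequencies(records, samples, individuals, truth, config.panel)
        labels_true, labels_pred = [], []
        for ind in individuals:
            for sid in ind.sample_ids:
                labels_true.append(truth.sample_to_individual[sid])
                labels_pred.append(ind.individual_id)
        rows.append({
            "ad_est": errors.mean("ad"),
            "ad_high_est": errors.mean("ad_high"),
            "ad_res_est": errors.mean("ad_res"),
            "fa_res_est": errors.mean("fa_res"),
            "ad_truth": truth_rates["ad_truth"],
            "ad_res_truth": truth_rates["ad_res_truth"],
            "fa_res_truth": truth_rates["fa_res_truth"],
            "rand_index": rand_score(labels_true, labels_pred) if labels_true else math.nan,
            "adjusted_rand": adjusted_rand_score(labels_true, labels_pred) if labels_true else math.nan,
            "n_individuals": len(individuals),
            "n_true_individuals": len({truth.sample_to_individual[s.sample_id] for s in retained}),
        })
    report: Dict[str, object] = {"per_dataset": rows, "n_datasets": n_datasets}
    for key in ("ad_est", "ad_truth", "fa_res_est", "fa_res_truth", "rand_index"):
        vals = [r[key] for r in rows if r[key] is not None and not math.isnan(r[key])]
        report[f"mean_{key}"] = float(np.mean(vals)) if vals else math.nan
        report[f"se_{key}"] = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else math.nan
    return report
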