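"""Population-diversity statistics on the individual consensus dataset.

Per locus: allele counts (Na), observed heterozygosity (Ho), Nei's
unbiased expected heterozygosity (He), the fixation index
FIS = 1 - Ho/He, a permutation test of Hardy-Weinberg equilibrium, and
the probability of identity among siblings (PI_sibs) -- the conservative
chance that two full sibs share a multi-locus genotype, which bounds the
discriminatory power of the panel for individual identification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from statistics import fmean
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_model import GenotypeCall, LocusPanel
from .individual_matching import IndividualRecord


def _called_genotypes(individuals: Sequence[IndividualRecord], locus: str) -> List[Tuple[int, int]]:
    out = []
    for ind in individuals:
        call = ind.consensus.get(locus)
        if call is not None and call.is_called:
            out.append(call.alleles)
    return out


# ---------------------------------------------------------------------------
# Frequencies and heterozygosities
# ---------------------------------------------------------------------------

def allele_frequencies_from_genotypes(genotypes: Sequence[Tuple[int, int]]) -> Dict[int, float]:
    if not genotypes:
        raise ValueError("no called genotypes at this locus")
    counts: Dict[int, int] = {}
    for a, b in genotypes:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    total = 2 * len(genotypes)
    return {a: c / total for a, c in sorted(counts.items())}


def allele_frequencies(individuals: Sequence[IndividualRecord], locus: str) -> Dict[int, float]:
    """Allele frequencies over 2n called individual genotypes at a locus."""
    return allele_frequencies_from_genotypes(_called_genotypes(individuals, locus))


def heterozygosities_from_genotypes(genotypes: Sequence[Tuple[int, int]]) -> Tuple[float, float]:
    """(Ho, He): observed het fraction and Nei's unbiased gene diversity.

    He = (1 - sum p_i^2) * 2n / (2n - 1); the small-sample correction is
    negligible at large n.
    """
    n = len(genotypes)
    if n < 1:
        raise ValueError("no called genotypes")
    ho = sum(1 for a, b in genotypes if a != b) / n
    freqs = allele_frequencies_from_genotypes(genotypes)
    sum_p2 = sum(p * p for p in freqs.values())
    he = (1.0 - sum_p2) * (2 * n) / (2 * n - 1) if n > 1 else 1.0 - sum_p2
    return ho, he


def heterozygosities(individuals: Sequence[IndividualRecord], locus: str) -> Tuple[float, float]:
    return heterozygosities_from_genotypes(_called_genotypes(individuals, locus))


def fis_locus(ho: float, he: float) -> Optional[float]:
    """Per-locus fixation index 1 - Ho/He; undefined for monomorphic loci."""
    if he == 0:
        return None
    return 1.0 - ho / he


def fis_overall(
    ho_values: Sequence[float],
    he_values: Sequence[float],
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> Tuple[float, Tuple[float, float]]:
    """Panel FIS = 1 - mean(Ho)/mean(He) with a bootstrap-over-loci 95% CI."""
    ho = np.asarray(ho_values, dtype=float)
    he = np.asarray(he_values, dtype=float)
    if he.mean() == 0:
        raise ValueError("overall He is zero; FIS undefined")
    point = 1.0 - ho.mean() / he.mean()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(ho), size=(n_boot, len(ho)))
    boots = 1.0 - ho[idx].mean(axis=1) / he[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(point), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Hardy-Weinberg permutation test
# ---------------------------------------------------------------------------

def hwe_permutation_test_genotypes(
    genotypes: Sequence[Tuple[int, int]],
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> float:
    """Two-sided HWE test by permuting alleles within the population.

    The statistic is the per-locus FIS; the null distribution comes from
    re-pairing the pooled alleles at random (allele frequencies, hence
    He, are permutation-invariant, so only Ho varies). The add-one
    estimator p = (1 + #{|FIS*| >= |FIS|}) / (n_perm + 1) avoids p = 0.
    Monomorphic loci return p = 1 by convention.
    """
    n = len(genotypes)
    if n < 5:
        raise ValueError("HWE test needs at least 5 called genotypes")
    alleles = np.array([a for g in genotypes for a in g])
    if len(np.unique(alleles)) < 2:
        return 1.0
    sum_p2 = float(((np.unique(alleles, return_counts=True)[1] / (2 * n)) ** 2).sum())
    he_hat = 1.0 - sum_p2  # uncorrected: the correction cancels in the comparison
    ho_obs = sum(1 for a, b in genotypes if a != b) / n
    fis_obs = 1.0 - ho_obs / he_hat

    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(alleles, (n_perm, 1)), axis=1).reshape(n_perm, n, 2)
    ho_perm = (perm[:, :, 0] != perm[:, :, 1]).mean(axis=1)
    fis_perm = 1.0 - ho_perm / he_hat
    exceed = int(np.sum(np.abs(fis_perm) >= abs(fis_obs) - 1e-12))
    return (1 + exceed) / (n_perm + 1)


def hwe_permutation_test(
    individuals: Sequence[IndividualRecord],
    locus: str,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> float:
    return hwe_permutation_test_genotypes(_called_genotypes(individuals, locus), n_perm, seed)


# ---------------------------------------------------------------------------
# Probability of identity among siblings
# ---------------------------------------------------------------------------

def pi_sibs_locus(freqs: Mapping[int, float]) -> float:
    """PI_sibs = 0.25 + 0.5*S2 + 0.5*S2^2 - 0.25*S4 with Sk = sum p_i^k."""
    p = np.asarray(list(freqs.values()), dtype=float)
    if not math.isclose(float(p.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("allele frequencies must sum to 1")
    s2 = float((p ** 2).sum())
    s4 = float((p ** 4).sum())
    return 0.25 + 0.5 * s2 + 0.5 * s2 * s2 - 0.25 * s4


@dataclass(frozen=True)
class SubsetPIResult:
    """Multi-locus PI_sibs statistics over all size-k locus subsets."""

    k: int
    min: float
    max: float
    mean: float


def pi_sibs_subsets(per_locus_values: Sequence[float], k: int) -> SubsetPIResult:
    """min/max/mean of the product of per-locus PI_sibs over all C(n, k)
    locus subsets of size k.

    The mean is e_k(values) / C(n, k), with the elementary symmetric
    polynomial e_k computed by the incremental product recurrence (no
    subset enumeration); min and max are the products of the k smallest
    and k largest values.
    """
    values = list(per_locus_values)
    n = len(values)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    ordered = sorted(values)
    vmin = math.prod(ordered[:k])
    vmax = math.prod(ordered[-k:])
    # e_j recurrence (absorb one value at a time, updating high -> low)
    e = np.zeros(k + 1, dtype=float)
    e[0] = 1.0
    for x in values:
        for j in range(k, 0, -1):
            e[j] += x * e[j - 1]
    mean = float(e[k]) / math.comb(n, k)
    return SubsetPIResult(k=k, min=vmin, max=vmax, mean=mean)


def pi_sibs_panel(per_locus_values: Sequence[float]) -> float:
    """Cumulative PI_sibs over the whole panel (product across loci)."""
    return math.prod(per_locus_values)


# ---------------------------------------------------------------------------
# Null-allele maximum-likelihood estimation (EM)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullAlleleEstimate:
    frequency: float
    converged: bool
    n_iter: int
    log_likelihood: float


def null_allele_ml(
    genotypes: Sequence[Tuple[int, int]],
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> NullAlleleEstimate:
    """EM estimate of a single null-allele frequency at one locus.

    Observation model: genotypes follow HWE with visible alleles of
    frequency p_i and one null allele of frequency r. A heterozygote
    null carrier amplifies as an apparent homozygote for its visible
    allele; a null homozygote does not amplify at all and is therefore
    absent from the called genotypes (the likelihood conditions on
    amplification). Apparent-homozygote excess over HWE expectation is
    what drives the estimate.
    """
    n = len(genotypes)
    if n == 0:
        raise ValueError("no called genotypes")
    if n < 20:
        warnings.warn(f"null-allele estimate from only {n} genotypes is unreliable", stacklevel=2)

    alleles = sorted({a for g in genotypes for a in g})
    index = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    het_counts = np.zeros((k, k))
    hom_counts = np.zeros(k)
    for a, b in genotypes:
        if a == b:
            hom_counts[index[a]] += 1
        else:
            i, j = sorted((index[a], index[b]))
            het_counts[i, j] += 1
    het_allele_counts = het_counts.sum(axis=1) + het_counts.sum(axis=0)

    # init from observed frequencies with a small null mass
    r = 0.05
    p = np.array([(2 * hom_counts[i] + het_allele_counts[i]) for i in range(k)], dtype=float)
    p = p / p.sum() * (1.0 - r)

    def loglik(p: np.ndarray, r: float) -> float:
        denom = 1.0 - r * r
        ll = 0.0
        for i in range(k):
            for j in range(i + 1, k):
                if het_counts[i, j]:
                    ll += het_counts[i, j] * math.log(2 * p[i] * p[j] / denom)
            if hom_counts[i]:
                ll += hom_counts[i] * math.log((p[i] ** 2 + 2 * p[i] * r) / denom)
        return ll

    prev = loglik(p, r)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: expected null copies hidden in apparent homozygotes, and
        # expected count of unobserved null homozygotes (truncated class)
        with np.errstate(divide="ignore", invalid="ignore"):
            e_null = np.where(hom_counts > 0, hom_counts * 2 * r / (p + 2 * r), 0.0)
        m_hidden = n * r * r / (1.0 - r * r) if r > 0 else 0.0
        total_ind = n + m_hidden
        null_copies = e_null.sum() + 2.0 * m_hidden
        visible_copies = 2 * hom_counts - e_null + het_allele_counts
        # M-step
        r_new = null_copies / (2.0 * total_ind)
        p_new = visible_copies / (2.0 * total_ind)
        r, p = float(r_new), p_new
        cur = loglik(p, r)
        if abs(cur - prev) <= tol * (abs(prev) + 1.0):
            converged = True
            prev = cur
            break
        prev = cur
    return NullAlleleEstimate(frequency=r, converged=converged, n_iter=it, log_likelihood=prev)


# ---------------------------------------------------------------------------
# Sex ratio
# ---------------------------------------------------------------------------

def sex_ratio_test(individuals: Sequence[IndividualRecord]) -> Tuple[float, float, float]:
    """One-proportion z-test of the male share against 0.5.

    Returns (proportion male, z, two-sided p) over sexed individuals;
    unknown-sex individuals are excluded.
    """
    males = sum(1 for i in individuals if i.sex == "male")
    females = sum(1 for i in individuals if i.sex == "female")
    n = males + females
    if n == 0:
        raise ValueError("no sexed individuals")
    return sex_ratio_test_counts(males, n)


def sex_ratio_test_counts(n_males: int, n_sexed: int) -> Tuple[float, float, float]:
    phat = n_males / n_sexed
    z = (phat - 0.5) / math.sqrt(0.25 / n_sexed)
    p = 2.0 * sps.norm.sf(abs(z))
    return phat, z, float(p)


# ---------------------------------------------------------------------------
# Diversity report
# ---------------------------------------------------------------------------

def aggregate_diversity(per_locus: pd.DataFrame) -> Dict[str, float]:
    """Panel totals from a per-locus diversity table.

    Na is summed; Ho and He are unweighted means over loci; overall
    FIS = 1 - mean(Ho)/mean(He). PI_sibs multiplies across loci when the
    column is present.
    """
    totals = {
        "Na": int(per_locus["Na"].sum()),
        "Ho": float(per_locus["Ho"].mean()),
        "He": float(per_locus["He"].mean()),
    }
    totals["FIS"] = 1.0 - totals["Ho"] / totals["He"] if totals["He"] else math.nan
    if "pi_sibs" in per_locus:
        totals["pi_sibs"] = float(per_locus["pi_sibs"].prod())
    return totals


def diversity_report(
    individuals: Sequence[IndividualRecord],
    panel: LocusPanel,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    exclude: Sequence[str] = (),
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-locus diversity table plus panel aggregates.

    ``exclude`` drops loci (e.g. suspected null-allele carriers) before
    computing the aggregates, mirroring the practice of re-estimating the
    panel FIS without high-FIS loci.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for locus in panel.autosomal_names:
        if locus in exclude:
            continue
        genotypes = _called_genotypes(individuals, locus)
        if not genotypes:
            continue
        freqs = allele_frequencies_from_genotypes(genotypes)
        ho, he = heterozygosities_from_genotypes(genotypes)
        fis = fis_locus(ho, he)
        p = (
            hwe_permutation_test_genotypes(genotypes, n_perm, int(rng.integers(2 ** 31)))
            if len(genotypes) >= 5
            else math.nan
        )
        rows.append({
            "locus": locus,
            "Na": len(freqs),
            "Ho": ho,
            "He": he,
            "FIS": fis,
            "hwe_p": p,
            "pi_sibs": pi_sibs_locus(freqs),
        })
    table = pd.DataFrame(rows)
    totals = aggregate_diversity(table) if len(table) else {}
    if len(table) > 1:
        fis, ci = fis_overall(table["Ho"], table["He"], seed=int(rng.integers(2 ** 31)))
        totals["FIS_ci_low"], totals["FIS_ci_high"] = ci
    return table, totals
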