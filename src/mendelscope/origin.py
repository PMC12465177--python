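"""Allelic-fraction inference from per-sample read depths.

Two inferences share the binomial read-sampling model:

* **Parental origin of an extra (or retained) chromosome copy.** At sites
  where exactly one parent carries the alternate allele, the alternate
  read fraction in a trisomic child separates paternal-extra from
  maternal-extra copies: with two paternal copies carrying the alternate,
  about two-thirds of the reads carry it; with one of three copies, about
  one-third. Reads are assumed to sample the three copies uniformly, with
  no reference bias correction.

* **Low-level (germline) mosaicism in a parent.** A 0/0-called parent
  whose tissue shows more alternate reads than the per-read error rate
  explains (one-sided exact binomial test) but well below the
  constitutive-heterozygote band is a low-level mosaic; semen-positive /
  blood-negative marks gonadal (germline) mosaicism.

The error rate (0.005), the heterozygote band [0.35, 0.65] and the
log-likelihood-ratio threshold (10 nats) are operational defaults exposed
in the configs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .io import VariantRecord

__all__ = [
    "InformativeSite",
    "MosaicTestConfig",
    "OriginConfig",
    "classify_informative_sites",
    "estimate_alt_fraction",
    "infer_extra_copy_origin",
    "test_mosaicism",
    "classify_parental_mosaicism",
]


@dataclass(frozen=True)
class InformativeSite:
    variant_key: tuple
    klass: str  # sire_only_alt | dam_only_alt | uninformative
    alt_depth: int
    ref_depth: int

    @property
    def depth(self) -> int:
        return self.alt_depth + self.ref_depth


@dataclass(frozen=True)
class MosaicTestConfig:
    error_rate: float = 0.005
    alpha: float = 0.05
    min_depth: int = 10
    het_band: tuple[float, float] = (0.35, 0.65)

    def __post_init__(self) -> None:
        if not 0 < self.error_rate < 0.5:
            raise ValueError("error_rate must be in (0, 0.5)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class OriginConfig:
    min_depth: int = 10
    llr_threshold: float = 10.0  # nats


def classify_informative_sites(
    variants: list[VariantRecord], case_id: str, sire_id: str, dam_id: str
) -> list[InformativeSite]:
    """Label region sites by which single parent carries the alt allele.

    Sites where both or neither parent carries the alternate, or where any
    trio genotype is missing, are uninformative; sites where the case
    carries no alternate read evidence contribute nothing either way but
    are kept with their class for bookkeeping.
    """
    sites = []
    for v in variants:
        calls = [v.calls.get(s) for s in (case_id, sire_id, dam_id)]
        if any(c is None or c.dosage is None for c in calls):
            continue
        case, sire, dam = calls
        if case.alt_depth is None or case.ref_depth is None:
            continue
        sire_alt = sire.dosage >= 1
        dam_alt = dam.dosage >= 1
        if sire_alt and not dam_alt:
            klass = "sire_only_alt"
        elif dam_alt and not sire_alt:
            klass = "dam_only_alt"
        else:
            klass = "uninformative"
        sites.append(
            InformativeSite(
                variant_key=v.key,
                klass=klass,
                alt_depth=case.alt_depth,
                ref_depth=case.ref_depth,
            )
        )
    return sites


def estimate_alt_fraction(
    sites: list[InformativeSite], min_depth: int = 10, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Pooled alternate-read fraction with an exact (Clopper-Pearson) CI.

    Pools read counts across sites rather than averaging per-site
    fractions, mirroring aggregate "fraction of variant-containing reads"
    reporting.
    """
    usable = [s for s in sites if s.depth >= min_depth]
    if not usable:
        raise ValueError(f"no site with depth >= {min_depth}")
    alt = sum(s.alt_depth for s in usable)
    total = sum(s.depth for s in usable)
    if total == 0:
        raise ValueError("zero usable depth")
    ci = binomtest(alt, total).proportion_ci(confidence_level=1 - alpha, method="exact")
    return alt / total, (float(ci.low), float(ci.high))


def _binom_loglik(alt: np.ndarray, depth: np.ndarray, p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.sum(alt * math.log(p) + (depth - alt) * math.log(1 - p)))


def infer_extra_copy_origin(
    sites: list[InformativeSite], config: OriginConfig = OriginConfig()
) -> tuple[str, float]:
    """Paternal vs maternal origin of the extra chromosome copy.

    Binomial likelihood of the case's alternate reads under the
    paternal-extra hypothesis (alt fraction 2/3 at sire-only-alt sites
    where both paternal copies carry the alternate, 1/3 at dam-only-alt
    sites) against the mirrored maternal-extra hypothesis. Returns
    (origin, log-likelihood ratio paternal - maternal); origin is
    ``undetermined`` when |LLR| is below the threshold or no informative
    site passes the depth cut.
    """
    sire_sites = [
        s for s in sites if s.klass == "sire_only_alt" and s.depth >= config.min_depth
    ]
    dam_sites = [
        s for s in sites if s.klass == "dam_only_alt" and s.depth >= config.min_depth
    ]
    if not sire_sites and not dam_sites:
        return "undetermined", 0.0
    llr = 0.0
    for group, p_pat in ((sire_sites, 2 / 3), (dam_sites, 1 / 3)):
        if not group:
            continue
        alt = np.array([s.alt_depth for s in group], dtype=float)
        depth = np.array([s.depth for s in group], dtype=float)
        llr += _binom_loglik(alt, depth, p_pat) - _binom_loglik(alt, depth, 1 - p_pat)
    if llr > config.llr_threshold:
        return "paternal", llr
    if llr < -config.llr_threshold:
        return "maternal", llr
    return "undetermined", llr


def test_mosaicism(
    alt_depth: int, total_depth: int, config: MosaicTestConfig = MosaicTestConfig()
) -> str:
    """Classify one tissue's alternate-read evidence.

    ``low_level_mosaic``: the one-sided exact binomial test rejects
    "alternate reads are sequencing error" at ``alpha`` and the fraction
    sits below the heterozygote band. ``constitutive_het``: fraction
    within the band. ``absent``: otherwise. ``undetermined``: depth below
    the minimum.
    """
    if total_depth < config.min_depth:
        return "undetermined"
    frac = alt_depth / total_depth
    lo, hi = config.het_band
    if lo <= frac <= hi:
        return "constitutive_het"
    p = binomtest(alt_depth, total_depth, config.error_rate, alternative="greater").pvalue
    if p < config.alpha and frac < lo:
        return "low_level_mosaic"
    return "absent"


def classify_parental_mosaicism(tissue_results: dict[str, str]) -> str:
    """Combine per-tissue mosaicism statuses into a parental verdict.

    Semen-positive with blood-negative is the germline (gonadal) mosaic
    signature; positivity in both compartments implies the mosaicism arose
    early enough to seed soma and germline; a constitutive heterozygote in
    any tissue is simply a carrier.
    """
    statuses = set(tissue_results.values())
    if "constitutive_het" in statuses:
        return "not_mosaic"
    semen = tissue_results.get("semen")
    blood = tissue_results.get("blood")
    if semen == "low_level_mosaic" and blood == "absent":
        return "germline_mosaic"
    if semen == "low_level_mosaic" and blood == "low_level_mosaic":
        return "somatic_and_germline"
    if semen == "absent" and blood == "absent":
        return "not_mosaic"
    # a single negative tissue cannot rule out gonadal mosaicism
    return "indeterminate"
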