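"""Hypothesis-driven variant filtering against pedigrees and control cohorts.

Each filter encodes one mode-of-inheritance (MOI) hypothesis and retains
only the variants whose genotype configuration across cases, available
parents and the control cohort is compatible with that hypothesis:

* ``recessive_hom`` — homozygous (or hemizygous) alternate in every case,
  never homozygous-alternate in any control (heterozygous carriers are
  allowed), available parents heterozygous carriers.
* ``recessive_compound_het`` — gene-wise allele pairs, each case
  heterozygous for both; no control carries both alleles simultaneously or
  either in homozygosity; with parents available the two alleles must
  arrive in trans (one from each parent).
* ``dominant_private`` / ``x_linked`` — heterozygous (or hemizygous on
  the male X) in every case and carried by no control; unaffected parents
  in trio/single-parent designs must be genotype 0/0.

Privacy policy: missing control genotypes are treated as reference (the
filters never impute); a missing case genotype fails the filter. Both
policies are config-exposed. Retained variants are sorted by
(chrom, pos, alt) so output is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from scipy.stats import binomtest

from .io import VariantRecord

__all__ = [
    "FilterScenario",
    "FilterResult",
    "FilterPolicy",
    "ConsensusConfig",
    "ClassificationEvidence",
    "filter_recessive_hom",
    "filter_compound_het",
    "filter_dominant_private",
    "assess_de_novo",
    "consensus_deleterious",
    "classify_variant",
]

MOI_HYPOTHESES = ("recessive_hom", "recessive_compound_het", "dominant_private", "x_linked")
DESIGNS = ("trio", "single_parent", "half_sibs", "multiple_cases", "single_case")


@dataclass(frozen=True)
class FilterScenario:
    moi_hypothesis: str
    design: str
    case_ids: tuple[str, ...]
    control_ids: tuple[str, ...] = ()
    #: case id -> (sire id or None, dam id or None)
    parent_map: dict = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if self.moi_hypothesis not in MOI_HYPOTHESES:
            raise ValueError(f"unknown MOI hypothesis {self.moi_hypothesis!r}")
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "trio":
            for cid in self.case_ids:
                sire, dam = self.parent_map.get(cid, (None, None))
                if sire is None or dam is None:
                    raise ValueError(f"trio design requires both parents for case {cid}")


@dataclass(frozen=True)
class FilterPolicy:
    """How missing genotypes are treated (the permissive defaults)."""

    missing_control_is_ref: bool = True
    missing_case_fails: bool = True


@dataclass
class FilterResult:
    scenario: FilterScenario
    retained: list[VariantRecord] = field(default_factory=list)
    #: gene -> list of (VariantRecord, VariantRecord) pairs, compound-het only
    gene_pairs: dict = field(default_factory=dict)
    #: per-variant audit rows: {variant key, check, sample, passed}
    audit: list[dict] = field(default_factory=list)


def _dosage(variant: VariantRecord, sample: str) -> int | None:
    call = variant.calls.get(sample)
    return None if call is None else call.dosage


def _is_hom_alt(variant: VariantRecord, sample: str) -> bool:
    """Homozygous-alternate state, counting hemizygous-alt as homozygous."""
    call = variant.calls.get(sample)
    if call is None or call.dosage is None:
        return False
    return call.dosage == 2 or (call.hemizygous and call.dosage == 1)

def _carries(variant: VariantRecord, sample: str, policy: FilterPolicy) -> bool | None:
    """True if the sample carries >= 1 alt allele; None if missing and not imputed."""
    d = _dosage(variant, sample)
    if d is None:
        return False if policy.missing_control_is_ref else None
    return d >= 1


def _audit(result: FilterResult, variant: VariantRecord, check: str, sample: str, passed: bool):
    result.audit.append(
        {"variant": variant.key, "check": check, "sample": sample, "passed": passed}
    )


def filter_recessive_hom(
    variants: list[VariantRecord],
    scenario: FilterScenario,
    policy: FilterPolicy = FilterPolicy(),
) -> FilterResult:
    """Homozygous private variants under a simple recessive hypothesis."""
    if scenario.moi_hypothesis != "recessive_hom":
        raise ValueError("scenario is not recessive_hom")
    if not scenario.case_ids:
        raise ValueError("scenario has no cases")
    result = FilterResult(scenario=scenario)
    for v in variants:
        ok = True
        for cid in scenario.case_ids:
            passed = _is_hom_alt(v, cid)
            _audit(result, v, "case_hom_alt", cid, passed)
            ok = ok and passed
        if ok:
            for ctl in scenario.control_ids:
                passed = not _is_hom_alt(v, ctl)
                if passed is True and _dosage(v, ctl) is None and not policy.missing_control_is_ref:
                    passed = False  # cannot certify absence without a call
                _audit(result, v, "control_not_hom_alt", ctl, passed)
                ok = ok and passed
        if ok:
            for cid in scenario.case_ids:
                for parent in scenario.parent_map.get(cid, (None, None)):
                    if parent is None:
                        continue
                    pc = v.calls.get(parent)
                    if pc is None or pc.dosage is None:
                        passed = not policy.missing_case_fails
                    elif pc.hemizygous:
                        passed = pc.dosage == 1
                    else:
                        passed = pc.dosage == 1
                    _audit(result, v, "parent_carrier", parent, passed)
                    ok = ok and passed
        if ok:
            result.retained.append(v)
    result.retained.sort(key=lambda v: v.key)
    return result


def filter_dominant_private(
    variants: list[VariantRecord],
    scenario: FilterScenario,
    policy: FilterPolicy = FilterPolicy(),
) -> FilterResult:
    """Heterozygous private variants under a dominant (or X-linked) hypothesis."""
    if scenario.moi_hypothesis not in ("dominant_private", "x_linked"):
        raise ValueError("scenario is not dominant_private/x_linked")
    if not scenario.case_ids:
        raise ValueError("scenario has no cases")
    result = FilterResult(scenario=scenario)
    for v in variants:
        ok = True
        for cid in scenario.case_ids:
            call = v.calls.get(cid)
            if call is None or call.dosage is None:
                passed = False
            elif call.hemizygous:
                passed = call.dosage == 1
            else:
                passed = call.dosage == 1
            _audit(result, v, "case_het", cid, passed)
            ok = ok and passed
        if ok:
            for ctl in scenario.control_ids:
                carries = _carries(v, ctl, policy)
                passed = carries is False
                _audit(result, v, "control_absent", ctl, passed)
                ok = ok and passed
        if ok and scenario.design in ("trio", "single_parent"):
            for cid in scenario.case_ids:
                for parent in scenario.parent_map.get(cid, (None, None)):
                    if parent is None:
                        continue
                    passed = _dosage(v, parent) == 0
                    _audit(result, v, "parent_ref", parent, passed)
                    ok = ok and passed
        if ok:
            result.retained.append(v)
    result.retained.sort(key=lambda v: v.key)
    return result


def _trans_by_pedigree(
    v1: VariantRecord, v2: VariantRecord, sire: str | None, dam: str | None
) -> bool:
    """One allele from each parent. With a single sampled parent the check
    degrades to that parent carrying exactly one of the two alleles."""
    if sire is None and dam is None:
        return True  # no pedigree information: cannot refute trans
    if sire is not None and dam is not None:
        sire1, sire2 = _dosage(v1, sire), _dosage(v2, sire)
        dam1, dam2 = _dosage(v1, dam), _dosage(v2, dam)
        if None in (sire1, sire2, dam1, dam2):
            return True
        return (sire1 >= 1 and dam2 >= 1) or (sire2 >= 1 and dam1 >= 1)
    parent = sire if sire is not None else dam
    p1, p2 = _dosage(v1, parent), _dosage(v2, parent)
    if p1 is None or p2 is None:
        return True
    return (p1 >= 1) != (p2 >= 1)


def filter_compound_het(
    variants: list[VariantRecord],
    scenario: FilterScenario,
    policy: FilterPolicy = FilterPolicy(),
) -> FilterResult:
    """Gene-wise compound-heterozygous allele pairs.

    Controls may carry either allele singly (the published compound pairs
    had hundreds of single-copy carriers) but never both simultaneously,
    and never either in homozygosity.
    """
    if scenario.moi_hypothesis != "recessive_compound_het":
        raise ValueError("scenario is not recessive_compound_het")
    if not scenario.case_ids:
        raise ValueError("scenario has no cases")
    result = FilterResult(scenario=scenario)
    by_gene: dict[str, list[VariantRecord]] = {}
    n_unlabeled = 0
    for v in variants:
        if not v.gene:
            n_unlabeled += 1
            continue
        by_gene.setdefault(v.gene, []).append(v)
    if n_unlabeled:
        warnings.warn(
            f"{n_unlabeled} variant(s) lack a gene label and were skipped", stacklevel=2
        )
    for gene, gene_variants in sorted(by_gene.items()):
        gene_variants.sort(key=lambda v: v.key)
        # alleles heterozygous in every case
        het_in_cases = [
            v
            for v in gene_variants
            if all(_dosage(v, cid) == 1 for cid in scenario.case_ids)
        ]
        pairs = []
        for i, v1 in enumerate(het_in_cases):
            for v2 in het_in_cases[i + 1 :]:
                ok = True
                for ctl in scenario.control_ids:
                    if _is_hom_alt(v1, ctl) or _is_hom_alt(v2, ctl):
                        ok = False
                        break
                    c1 = _carries(v1, ctl, policy)
                    c2 = _carries(v2, ctl, policy)
                    if (c1 is not False) and (c2 is not False):
                        ok = False  # control carries (or may carry) both
                        break
                if not ok:
                    continue
                for cid in scenario.case_ids:
                    sire, dam = scenario.parent_map.get(cid, (None, None))
                    if not _trans_by_pedigree(v1, v2, sire, dam):
                        ok = False
                        break
                if ok:
                    pairs.append((v1, v2))
        if pairs:
            result.gene_pairs[gene] = pairs
            for v1, v2 in pairs:
                for v in (v1, v2):
                    if v not in result.retained:
                        result.retained.append(v)
    result.retained.sort(key=lambda v: v.key)
    return result


def assess_de_novo(
    variant: VariantRecord,
    case_id: str,
    sire_id: str | None,
    dam_id: str | None,
    min_depth: int = 10,
    max_parent_alt_reads: int = 0,
    error_rate: float = 0.005,
    alpha: float = 0.05,
) -> str:
    """Classify a case variant as de novo, inherited, or suggestive of
    parental mosaicism, from parental genotypes and allele depths.

    ``de_novo`` requires both parents called 0/0 with no more than
    ``max_parent_alt_reads`` alternate reads at depth >= ``min_depth``.
    A 0/0 parent whose alternate reads exceed what the sequencing error
    rate explains (one-sided exact binomial test at ``alpha``) makes the
    call ``mosaic_parent_suspected``. A missing parent -> ``undetermined``.
    """
    case_call = variant.calls.get(case_id)
    if case_call is None or not case_call.dosage:
        raise ValueError(f"variant {variant.key} is not present in case {case_id}")
    statuses = []
    for pid in (sire_id, dam_id):
        if pid is None or variant.calls.get(pid) is None:
            return "undetermined"
        call = variant.calls[pid]
        if call.dosage is None:
            return "undetermined"
        if call.dosage >= 1:
            return "inherited"
        depth = call.total_depth
        if depth is None or depth < min_depth:
            return "undetermined"
        alt = call.alt_depth
        if alt > max_parent_alt_reads:
            p = binomtest(alt, depth, error_rate, alternative="greater").pvalue
            if p < alpha:
                statuses.append("mosaic")
                continue
        statuses.append("clean")
    if "mosaic" in statuses:
        return "mosaic_parent_suspected"
    return "de_novo"


RECOGNIZED_PREDICTORS = (
    "PredictSNP1",
    "PolyPhen2",
    "SIFT",
    "SNAP",
    "MAPP",
    "PhD-SNP",
    "MutPred2",
)


@dataclass(frozen=True)
class ConsensusConfig:
    min_deleterious_tools: int = 2
    predictors: tuple[str, ...] = RECOGNIZED_PREDICTORS

    def __post_init__(self) -> None:
        if self.min_deleterious_tools < 1:
            raise ValueError("min_deleterious_tools must be >= 1")


def consensus_deleterious(
    annotations: dict[str, str], config: ConsensusConfig = ConsensusConfig()
) -> bool:
    """True iff at least ``min_deleterious_tools`` recognized predictors
    report 'deleterious'. Absent predictors count as non-deleterious."""
    n = sum(
        1
        for key in config.predictors
        if str(annotations.get(key, "")).lower() == "deleterious"
    )
    return n >= config.min_deleterious_tools


@dataclass(frozen=True)
class ClassificationEvidence:
    """Tri-state evidence flags feeding the classification ladder.

    ``consequence`` is one of {truncating, missense, inframe, intronic,
    other}. The remaining flags are True/False/None (unknown).
    """

    consequence: str = "other"
    known_disease_allele: bool | None = None
    gene_plausible: bool | None = None
    private: bool | None = None
    segregation_consistent: bool | None = None
    de_novo_or_mosaic_support: bool | None = None
    multiple_affected_carriers: bool | None = None
    predictor_consensus: bool | None = None


def classify_variant(evidence: ClassificationEvidence) -> str:
    """Deterministic rule ladder over the evidence flags.

    Pathogenic: (truncating consequence OR a known disease-allele match)
    AND private AND segregation-consistent AND (de novo/mosaic support OR
    multiple affected carriers). Likely pathogenic relaxes the consequence
    to missense/in-frame backed by predictor consensus. Everything else is
    of uncertain significance. This is an operational approximation of
    published classification guidance, validated against the case-series
    labels it reproduces.
    """
    e = evidence
    severe = e.consequence == "truncating" or e.known_disease_allele is True
    support = e.de_novo_or_mosaic_support is True or e.multiple_affected_carriers is True
    if severe and e.private is True and e.segregation_consistent is True and support:
        return "pathogenic"
    moderate = e.consequence in ("missense", "inframe") and e.predictor_consensus is True
    if (
        (severe or moderate)
        and e.private is True
        and e.segregation_consistent is True
    ):
        return "likely_pathogenic"
    return "uncertain"
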