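"""End-to-end diagnostic workflow binding the stages together.

Stage order mirrors diagnostic practice: parentage verification first
(identity-by-descent on the cohort genotypes; an excluded link aborts the
case unless overridden), then the applicable mode-of-inheritance filters
with classification of surviving candidates, and — only when no candidate
SNV/indel survives — the read-depth structural scan, followed by
parental-origin inference when an event is found and trio data exist.
Both SNV and CNV stages can be forced via flags; disabling the CNV stage
never changes SNV/indel findings.

Each stage logs the number of variants entering and surviving, providing
the audit trail for every candidate decision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from . import cnv, filters, kinship, origin
from .io import CoverageWindow, PedigreeSample, VariantRecord, detect_design

__all__ = ["PipelineConfig", "CaseReport", "ParentageError", "run_case", "cohort_summary"]


class ParentageError(RuntimeError):
    """A recorded parent-offspring link failed the IBD check."""


@dataclass(frozen=True)
class PipelineConfig:
    run_snv_stage: bool = True
    run_cnv_stage: bool = True
    force_cnv_stage: bool = False
    skip_parentage: bool = False
    ignore_parentage_exclusion: bool = False
    sex: str = "male"
    min_kinship_sites: int = 500
    filter_policy: filters.FilterPolicy = filters.FilterPolicy()
    kinship_config: kinship.KinshipConfig = kinship.KinshipConfig()
    cnv_config: cnv.CnvConfig = cnv.CnvConfig()
    origin_config: origin.OriginConfig = origin.OriginConfig()


@dataclass
class CaseReport:
    case_ids: list[str]
    design: str
    kinship_verdicts: dict = field(default_factory=dict)
    filter_hits: dict = field(default_factory=dict)  # hypothesis -> [variant keys]
    classifications: dict = field(default_factory=dict)  # variant key str -> label
    cnv_calls: list = field(default_factory=list)
    origin_call: str | None = None
    origin_llr: float | None = None
    stage_log: list = field(default_factory=list)
    outcome: str = "unsolved"

    def to_json(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            if isinstance(o, tuple):
                return list(o)
            return str(o)

        return json.dumps(asdict(self), default=default, indent=2)


_OUTCOME_RANK = {"pathogenic": 3, "likely_pathogenic": 2, "uncertain": 1}


def _classify_candidate(
    v: VariantRecord,
    scenario: filters.FilterScenario,
    pedigree_by_id: dict[str, PedigreeSample],
) -> str:
    """Build classification evidence for a filter-surviving variant."""
    consequence = v.annotations.get("consequence", "other")
    predictor_consensus = filters.consensus_deleterious(v.annotations)
    de_novo_support = None
    if scenario.moi_hypothesis in ("dominant_private", "x_linked"):
        for cid in scenario.case_ids:
            sire, dam = scenario.parent_map.get(cid, (None, None))
            try:
                status = filters.assess_de_novo(v, cid, sire, dam)
            except ValueError:
                continue
            if status in ("de_novo", "mosaic_parent_suspected"):
                de_novo_support = True
            elif status == "inherited":
                de_novo_support = False
    evidence = filters.ClassificationEvidence(
        consequence=consequence,
        private=True,  # it survived the privacy filter
        segregation_consistent=True,  # it survived the segregation checks
        de_novo_or_mosaic_support=de_novo_support,
        multiple_affected_carriers=len(scenario.case_ids) > 1 or None,
        predictor_consensus=predictor_consensus,
    )
    return filters.classify_variant(evidence)


def _build_scenarios(
    pedigree: list[PedigreeSample], design: str
) -> list[filters.FilterScenario]:
    case_ids = tuple(s.id for s in pedigree if s.role == "case")
    control_ids = tuple(s.id for s in pedigree if s.role == "control")
    by_id = {s.id: s for s in pedigree}
    parent_map = {}
    for cid in case_ids:
        s = by_id[cid]
        sire = s.sire_id if s.sire_id in by_id else None
        dam = s.dam_id if s.dam_id in by_id else None
        parent_map[cid] = (sire, dam)
    hyps = ["recessive_hom", "recessive_compound_het", "dominant_private"]
    scenarios = []
    for h in hyps:
        scenarios.append(
            filters.FilterScenario(
                moi_hypothesis=h,
                design=design,
                case_ids=case_ids,
                control_ids=control_ids,
                parent_map=parent_map,
            )
        )
    return scenarios


def run_case(
    variants: list[VariantRecord],
    pedigree: list[PedigreeSample],
    coverage: list[CoverageWindow] | None = None,
    config: PipelineConfig = PipelineConfig(),
    freqs=None,
    genotypes=None,
) -> CaseReport:
    """Execute the diagnostic workflow for one case (group).

    ``freqs``/``genotypes`` (site frequencies and an id -> dosage-vector
    map) enable the parentage stage; without them it is skipped with a log
    entry.
    """
    design = detect_design(pedigree)
    case_ids = [s.id for s in pedigree if s.role == "case"]
    by_id = {s.id: s for s in pedigree}
    report = CaseReport(case_ids=case_ids, design=design)

    # --- stage 1: parentage -------------------------------------------------
    if config.skip_parentage or genotypes is None or freqs is None:
        report.stage_log.append({"stage": "parentage", "status": "skipped"})
    else:
        n_sites = len(freqs)
        if n_sites < config.min_kinship_sites:
            report.stage_log.append(
                {"stage": "parentage", "status": "skipped", "reason": f"{n_sites} sites"}
            )
        else:
            verdicts = kinship.verify_pedigree(
                pedigree, genotypes, freqs, config.kinship_config
            )
            report.kinship_verdicts = {
                f"{child}~{parent}": rel.verdict for (child, parent), rel in verdicts.items()
            }
            excluded = [k for k, v in report.kinship_verdicts.items() if v == "excluded"]
            report.stage_log.append(
                {"stage": "parentage", "status": "done", "excluded": excluded}
            )
            if excluded and not config.ignore_parentage_exclusion:
                raise ParentageError(
                    f"parentage excluded for link(s) {', '.join(excluded)}; "
                    "re-run with ignore_parentage_exclusion to proceed"
                )

    # --- stage 2: MOI filters + classification ------------------------------
    best = None
    if config.run_snv_stage:
        for scenario in _build_scenarios(pedigree, design):
            if scenario.moi_hypothesis == "recessive_hom":
                res = filters.filter_recessive_hom(variants, scenario, config.filter_policy)
            elif scenario.moi_hypothesis == "recessive_compound_het":
                res = filters.filter_compound_het(variants, scenario, config.filter_policy)
            else:
                res = filters.filter_dominant_private(variants, scenario, config.filter_policy)
            report.filter_hits[scenario.moi_hypothesis] = [list(v.key) for v in res.retained]
            report.stage_log.append(
                {
                    "stage": f"filter:{scenario.moi_hypothesis}",
                    "n_in": len(variants),
                    "n_retained": len(res.retained),
                }
            )
            for v in res.retained:
                label = _classify_candidate(v, scenario, by_id)
                key = "{}:{}:{}>{}".format(*v.key)
                prev = report.classifications.get(key)
                if prev is None or _OUTCOME_RANK[label] > _OUTCOME_RANK[prev]:
                    report.classifications[key] = label
                if best is None or _OUTCOME_RANK[label] > _OUTCOME_RANK[best]:
                    best = label

    # --- stage 3: CNV fallback ----------------------------------------------
    snv_solved = best in ("pathogenic", "likely_pathogenic")
    if config.run_cnv_stage and coverage and (not snv_solved or config.force_cnv_stage):
        model = cnv.PloidyModel(sex=config.sex)
        normalized = cnv.normalize(coverage, model, config.cnv_config)
        calls, _ = cnv.genome_scan(normalized, model, config.cnv_config)
        events = [c for c in calls if c.call not in ("disomy", "no_call")]
        report.cnv_calls = [
            {
                "chrom": c.chrom,
                "call": c.call,
                "median_ratio": round(c.median_ratio, 4),
                "segment": [c.segment.start, c.segment.end] if c.segment else None,
            }
            for c in calls
        ]
        report.stage_log.append({"stage": "cnv", "n_events": len(events)})
        trisomies = [c for c in events if c.call == "trisomy"]
        sire = next((s.id for s in pedigree if s.id == by_id[case_ids[0]].sire_id), None)
        dam = next((s.id for s in pedigree if s.id == by_id[case_ids[0]].dam_id), None)
        if trisomies and sire and dam:
            region = [v for v in variants if v.chrom == trisomies[0].chrom]
            sites = origin.classify_informative_sites(region, case_ids[0], sire, dam)
            call, llr = origin.infer_extra_copy_origin(sites, config.origin_config)
            report.origin_call = call
            report.origin_llr = llr
            report.stage_log.append({"stage": "origin", "call": call, "n_sites": len(sites)})
        if events and best is None:
            best = "pathogenic"  # confirmed aneuploidy is diagnostic

    report.outcome = {
        "pathogenic": "pathogenic_found",
        "likely_pathogenic": "likely_pathogenic_found",
        "uncertain": "uncertain_only",
        None: "unsolved",
    }[best]
    return report


def cohort_summary(reports: list[CaseReport]) -> dict:
    """Outcome tabulation by design plus the cohort diagnostic rate."""
    if not reports:
        raise ValueError("no case reports to summarize")
    by_design: dict[str, dict[str, int]] = {}
    solved = 0
    for r in reports:
        d = by_design.setdefault(r.design, {})
        d[r.outcome] = d.get(r.outcome, 0) + 1
        if r.outcome in ("pathogenic_found", "likely_pathogenic_found"):
            solved += 1
    return {
        "n_cases": len(reports),
        "n_solved": solved,
        "diagnostic_rate": solved / len(reports),
        "by_design": by_design,
    }
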