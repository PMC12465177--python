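"""Synthetic cohorts, pedigrees, variant tables, allele depths and coverage
tracks with the statistical structure the analyses assume, plus ground
truth for recovery scoring.

The generator emulates the sequencing designs of a rare-disease cohort
study in ruminants: a control cohort of unrelated diploid genomes with
site-specific allele frequencies under Hardy-Weinberg equilibrium; trio,
paternal-half-sib and single-case family designs; planted causal variants
per mode-of-inheritance scenario (de novo dominant, autosomal recessive,
compound heterozygous, X-linked de novo, mosaic-sire transmission);
per-sample allele depths at ~20x short-read coverage; and windowed
coverage counts with planted ploidy events (whole-chromosome trisomy,
terminal monosomy) over a toy genome with sex-chromosome baselines.

What it does not emulate: linkage disequilibrium (background sites are
unlinked — none of the downstream inferences uses LD), GC or mappability
structure in coverage, recombination maps, and read-level artifacts
beyond a uniform per-read miscall rate.

Determinism: every operation derives its generator from ``config.seed``
plus a fixed component tag, so a fixed seed yields identical outputs
across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    CoverageWindow,
    GenomicInterval,
    GenotypeCall,
    PedigreeSample,
    VariantRecord,
)

__all__ = [
    "Chromosome",
    "DEFAULT_GENOME",
    "SimulationConfig",
    "ScenarioTruth",
    "SimDataset",
    "simulate_cohort",
    "simulate_family",
    "simulate_allele_depths",
    "simulate_tissue_depths",
    "simulate_coverage",
    "simulate_trisomy_read_fractions",
]

SCENARIOS = (
    "none",
    "de_novo_dominant",
    "recessive_hom",
    "compound_het",
    "x_linked_de_novo",
    "mosaic_sire",
    "trisomy",
    "terminal_monosomy",
)


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    klass: str  # autosome | X | Y

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("chromosome length must be positive")
        if self.klass not in ("autosome", "X", "Y"):
            raise ValueError(f"unknown chromosome class {self.klass!r}")


#: Toy genome for desk-scale testing: three autosomes + X + Y. Full bovine
#: chromosome lengths are unnecessary for the statistics being exercised.
DEFAULT_GENOME: tuple[Chromosome, ...] = (
    Chromosome("Chr1", 25_000_000, "autosome"),
    Chromosome("Chr2", 20_000_000, "autosome"),
    Chromosome("Chr3", 15_000_000, "autosome"),
    Chromosome("ChrX", 20_000_000, "X"),
    Chromosome("ChrY", 5_000_000, "Y"),
)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_controls: int = 500
    n_background_variants: int = 200
    #: allele-frequency prior Beta(a, b), truncated to [freq_min, freq_max]
    beta_a: float = 0.5
    beta_b: float = 0.5
    freq_min: float = 0.01
    freq_max: float = 0.99
    mean_depth: float = 20.0
    read_length: int = 150
    error_rate: float = 0.005
    genome: tuple[Chromosome, ...] = DEFAULT_GENOME
    scenario: str = "none"
    design: str = "trio"  # trio | single_parent | half_sibs | single_case
    n_cases: int = 1
    case_sex: str = "female"
    mosaic_fraction: float = 0.1
    semen_depth: float = 40.0
    event_chrom: str = "Chr2"
    event_origin: str = "paternal"  # parental origin of planted ploidy events
    terminal_loss_length: int = 2_700_000
    n_informative_sites: int = 500
    window_size: int = 10_000

    #: scenarios that need both parents sampled (de novo assessment, trans
    #: phasing, parental-origin inference)
    _TRIO_ONLY = ("de_novo_dominant", "x_linked_de_novo", "compound_het", "trisomy")

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario in self._TRIO_ONLY and self.design != "trio":
            raise ValueError(
                f"scenario {self.scenario!r} requires the trio design, "
                f"not {self.design!r}"
            )
        if self.scenario == "mosaic_sire" and self.design != "half_sibs":
            raise ValueError("mosaic_sire is a paternal half-sib scenario")

    def rng(self, component: str) -> np.random.Generator:
        tag = int.from_bytes(component.encode()[:4].ljust(4, b"\0"), "big")
        return np.random.default_rng(np.random.SeedSequence((self.seed, tag)))


@dataclass
class ScenarioTruth:
    scenario: str
    planted_keys: list = field(default_factory=list)  # variant keys
    moi: str = ""
    origin: str = ""  # paternal | maternal | ""
    mosaic_tissue_fractions: dict = field(default_factory=dict)
    event_chrom: str = ""
    event_segment: GenomicInterval | None = None
    #: planted-site alt copy counts (of 3) for trisomy informative sites
    alt_copies_of_three: dict = field(default_factory=dict)


@dataclass
class SimDataset:
    config: SimulationConfig
    pedigree: list[PedigreeSample]
    variants: list[VariantRecord]
    freqs: np.ndarray  # background-site alt frequencies (truth)
    truth: ScenarioTruth

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.pedigree]

    def genotype_matrix(self, sample_ids=None) -> np.ndarray:
        """Sites x samples dosage matrix (NaN for missing)."""
        ids = sample_ids if sample_ids is not None else self.sample_ids
        mat = np.full((len(self.variants), len(ids)), np.nan)
        for i, v in enumerate(self.variants):
            for j, s in enumerate(ids):
                call = v.calls.get(s)
                if call is not None and call.dosage is not None:
                    mat[i, j] = call.dosage
        return mat


def _draw_freqs(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    f = rng.beta(config.beta_a, config.beta_b, size=n)
    return np.clip(f, config.freq_min, config.freq_max)


def _background_positions(config: SimulationConfig, n: int) -> list[tuple[str, int]]:
    """Evenly spaced positions across the autosomes (deterministic layout)."""
    autosomes = [c for c in config.genome if c.klass == "autosome"]
    total = sum(c.length for c in autosomes)
    positions = []
    for i in range(n):
        offset = int((i + 0.5) / n * total)
        for c in autosomes:
            if offset < c.length:
                positions.append((c.name, offset + 1))
                break
            offset -= c.length
    return positions


_BASES = ("A", "C", "G", "T")


def _alleles(rng: np.random.Generator) -> tuple[str, str]:
    i = int(rng.integers(0, 4))
    j = (i + 1 + int(rng.integers(0, 3))) % 4
    return _BASES[i], _BASES[j]


def simulate_cohort(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Control-cohort genotypes under Hardy-Weinberg equilibrium.

    Returns (freqs, genotypes) with genotypes shaped
    (n_background_variants, n_controls); the drawn frequencies are the
    recorded truth.
    """
    rng = config.rng("cohort")
    freqs = _draw_freqs(config, rng, config.n_background_variants)
    genotypes = rng.binomial(2, freqs[:, None], size=(config.n_background_variants, config.n_controls))
    return freqs, genotypes


def _transmit(parent_dosage: int, rng: np.random.Generator) -> int:
    """One allele drawn from a diploid parent genotype."""
    if parent_dosage == 0:
        return 0
    if parent_dosage == 2:
        return 1
    return int(rng.integers(0, 2))


def _make_pedigree(config: SimulationConfig) -> list[PedigreeSample]:
    sire = PedigreeSample(id="sire", sex="male", role="parent", tissue="blood")
    dam = PedigreeSample(id="dam", sex="female", role="parent", tissue="blood")
    cases = [
        PedigreeSample(
            id=f"case{i+1}" if config.n_cases > 1 else "case",
            sire_id="sire" if config.design in ("trio", "single_parent", "half_sibs") else None,
            dam_id="dam" if config.design == "trio" else None,
            sex=config.case_sex,
            affected=True,
            role="case",
            tissue="ear",
        )
        for i in range(config.n_cases)
    ]
    ped: list[PedigreeSample] = []
    if config.design == "trio":
        ped = [sire, dam] + cases
    elif config.design in ("single_parent", "half_sibs"):
        ped = [sire] + cases
    else:
        ped = cases
    controls = [
        PedigreeSample(id=f"ctl{i+1}", role="control", tissue="blood")
        for i in range(config.n_controls)
    ]
    return ped + controls


def _planted_record(
    config: SimulationConfig,
    rng: np.random.Generator,
    chrom: str,
    pos: int,
    gene: str = "",
) -> VariantRecord:
    ref, alt = _alleles(rng)
    return VariantRecord(
        interval=GenomicInterval(chrom, pos, pos), ref=ref, alt=alt, gene=gene
    )


def simulate_family(config: SimulationConfig) -> SimDataset:
    """Pedigree + genotypes by Mendelian transmission, with the scenario's
    causal variant (or ploidy event) planted and recorded as truth.

    Background sites: parental genotypes are drawn from the cohort
    frequencies and offspring receive one allele from each sampled parent
    (a population draw stands in for an unsampled parent). Controls are
    independent Hardy-Weinberg draws at the same frequencies.
    """
    rng = config.rng("family")
    freqs, control_geno = simulate_cohort(config)
    pedigree = _make_pedigree(config)
    family_ids = [s.id for s in pedigree if s.role != "control"]
    control_ids = [s.id for s in pedigree if s.role == "control"]
    positions = _background_positions(config, config.n_background_variants)

    variants: list[VariantRecord] = []
    for i, (chrom, pos) in enumerate(positions):
        f = freqs[i]
        sire_d = int(rng.binomial(2, f))
        dam_d = int(rng.binomial(2, f))
        calls: dict[str, GenotypeCall] = {}
        for s in pedigree:
            if s.role == "control":
                continue
            if s.id == "sire":
                calls["sire"] = GenotypeCall(dosage=sire_d)
            elif s.id == "dam":
                calls["dam"] = GenotypeCall(dosage=dam_d)
            else:
                paternal = _transmit(sire_d, rng)
                # unsampled dam in half-sib/single designs: population draw
                maternal = (
                    _transmit(dam_d, rng)
                    if config.design == "trio"
                    else int(rng.random() < f)
                )
                calls[s.id] = GenotypeCall(dosage=paternal + maternal)
        for j, ctl in enumerate(control_ids):
            calls[ctl] = GenotypeCall(dosage=int(control_geno[i, j]))
        ref, alt = _alleles(rng)
        variants.append(
            VariantRecord(
                interval=GenomicInterval(chrom, pos, pos),
                ref=ref,
                alt=alt,
                gene=f"BG{i % 50}",  # coarse gene labels for gene-wise ops
                calls=calls,
            )
        )

    truth = ScenarioTruth(scenario=config.scenario)
    case_ids = [s.id for s in pedigree if s.role == "case"]
    zero = {cid: GenotypeCall(dosage=0) for cid in control_ids}

    def plant(record: VariantRecord, family_calls: dict, control_calls=None):
        record.calls = {**(control_calls or zero), **family_calls}
        variants.append(record)
        truth.planted_keys.append(record.key)

    auto = [c for c in config.genome if c.klass == "autosome"][0]
    if config.scenario == "de_novo_dominant":
        rec = _planted_record(config, rng, auto.name, auto.length // 3, gene="CAUSAL1")
        fam = {cid: GenotypeCall(dosage=1) for cid in case_ids}
        if "sire" in family_ids:
            fam["sire"] = GenotypeCall(dosage=0)
        if "dam" in family_ids:
            fam["dam"] = GenotypeCall(dosage=0)
        plant(rec, fam)
        truth.moi = "dominant_private"
    elif config.scenario == "recessive_hom":
        rec = _planted_record(config, rng, auto.name, auto.length // 3, gene="CAUSAL1")
        fam = {cid: GenotypeCall(dosage=2) for cid in case_ids}
        if "sire" in family_ids:
            fam["sire"] = GenotypeCall(dosage=1)
        if "dam" in family_ids:
            fam["dam"] = GenotypeCall(dosage=1)
        plant(rec, fam)
        truth.moi = "recessive_hom"
    elif config.scenario == "compound_het":
        pos1 = auto.length // 3
        rec1 = _planted_record(config, rng, auto.name, pos1, gene="CAUSAL1")
        rec2 = _planted_record(config, rng, auto.name, pos1 + 5000, gene="CAUSAL1")
        fam1 = {cid: GenotypeCall(dosage=1) for cid in case_ids}
        fam2 = {cid: GenotypeCall(dosage=1) for cid in case_ids}
        if "sire" in family_ids:
            fam1["sire"] = GenotypeCall(dosage=1)
            fam2["sire"] = GenotypeCall(dosage=0)
        if "dam" in family_ids:
            fam1["dam"] = GenotypeCall(dosage=0)
            fam2["dam"] = GenotypeCall(dosage=1)
        # controls may carry each allele singly, never both, never homozygous
        n_ctl = len(control_ids)
        carriers1 = control_ids[: min(5, n_ctl // 4)]
        carriers2 = control_ids[min(5, n_ctl // 4) : min(5, n_ctl // 4) + min(10, n_ctl // 4)]
        ctl1 = dict(zero)
        ctl2 = dict(zero)
        for c in carriers1:
            ctl1[c] = GenotypeCall(dosage=1)
        for c in carriers2:
            ctl2[c] = GenotypeCall(dosage=1)
        plant(rec1, fam1, ctl1)
        plant(rec2, fam2, ctl2)
        truth.moi = "recessive_compound_het"
    elif config.scenario == "x_linked_de_novo":
        x = [c for c in config.genome if c.klass == "X"][0]
        rec = _planted_record(config, rng, x.name, x.length // 2, gene="CAUSALX")
        fam = {cid: GenotypeCall(dosage=1) for cid in case_ids}  # female case het
        if "sire" in family_ids:
            fam["sire"] = GenotypeCall(dosage=0, hemizygous=True)
        if "dam" in family_ids:
            fam["dam"] = GenotypeCall(dosage=0)
        plant(rec, fam)
        truth.moi = "x_linked"
    elif config.scenario == "mosaic_sire":
        rec = _planted_record(config, rng, auto.name, auto.length // 3, gene="CAUSAL1")
        fam = {cid: GenotypeCall(dosage=1) for cid in case_ids}
        fam["sire"] = GenotypeCall(dosage=0)  # blood call: wildtype
        plant(rec, fam)
        truth.moi = "dominant_private"
        truth.mosaic_tissue_fractions = {"semen": config.mosaic_fraction, "blood": 0.0}
    elif config.scenario == "trisomy":
        event = next(c for c in config.genome if c.name == config.event_chrom)
        truth.event_chrom = event.name
        truth.origin = config.event_origin
        truth.moi = "aneuploidy"
        # informative sites along the trisomic chromosome
        step = max(event.length // (config.n_informative_sites + 1), 1)
        for k in range(config.n_informative_sites):
            pos = (k + 1) * step
            ref, alt = _alleles(rng)
            sire_only = bool(rng.integers(0, 2))
            if sire_only:
                sire_call, dam_call = GenotypeCall(dosage=1), GenotypeCall(dosage=0)
                alt_copies = 2 if config.event_origin == "paternal" else 1
            else:
                sire_call, dam_call = GenotypeCall(dosage=0), GenotypeCall(dosage=1)
                alt_copies = 1 if config.event_origin == "paternal" else 2
            rec = VariantRecord(
                interval=GenomicInterval(event.name, pos, pos),
                ref=ref,
                alt=alt,
                gene="",
                calls={
                    "sire": sire_call,
                    "dam": dam_call,
                    **{cid: GenotypeCall(dosage=1) for cid in case_ids},
                    **zero,
                },
            )
            variants.append(rec)
            truth.planted_keys.append(rec.key)
            truth.alt_copies_of_three[rec.key] = alt_copies
    elif config.scenario == "terminal_monosomy":
        event = next(c for c in config.genome if c.name == config.event_chrom)
        truth.event_chrom = event.name
        truth.origin = config.event_origin
        truth.moi = "aneuploidy"
        truth.event_segment = GenomicInterval(
            event.name, event.length - config.terminal_loss_length + 1, event.length
        )

    variants.sort(key=lambda v: v.key)
    return SimDataset(
        config=config, pedigree=pedigree, variants=variants, freqs=freqs, truth=truth
    )


def simulate_allele_depths(dataset: SimDataset) -> SimDataset:
    """Attach Poisson/binomial read depths to every genotype call.

    Per-sample site depth ~ Poisson(mean_depth x ploidy/2); alternate
    reads ~ Binomial(depth, f) with f = error for hom-ref, 0.5 for het,
    1 - error for hom/hemizygous alt, and copy-dosage/3 at planted
    trisomic sites of the case.
    """
    config = dataset.config
    rng = config.rng("depths")
    eps = config.error_rate
    case_ids = {s.id for s in dataset.pedigree if s.role == "case"}
    for v in dataset.variants:
        trisomic = v.key in dataset.truth.alt_copies_of_three
        for sample, call in v.calls.items():
            if call.dosage is None:
                continue
            ploidy = 1 if call.hemizygous else 2
            if trisomic and sample in case_ids:
                ploidy = 3
                f = dataset.truth.alt_copies_of_three[v.key] / 3
            elif call.hemizygous:
                f = 1 - eps if call.dosage == 1 else eps
            else:
                f = (eps, 0.5, 1 - eps)[call.dosage]
            depth = int(rng.poisson(config.mean_depth * ploidy / 2))
            alt = int(rng.binomial(depth, f)) if depth > 0 else 0
            v.calls[sample] = GenotypeCall(
                dosage=call.dosage,
                hemizygous=call.hemizygous,
                ref_depth=depth - alt,
                alt_depth=alt,
            )
    return dataset


def simulate_tissue_depths(dataset: SimDataset) -> dict[str, tuple[int, int]]:
    """Per-tissue (alt, total) read counts for the sire at the planted
    variant of a mosaic-sire scenario. Semen is sequenced at its own depth
    (targeted re-examination); blood at the genome-wide mean."""
    truth = dataset.truth
    if truth.scenario != "mosaic_sire":
        raise ValueError("tissue depths are defined for the mosaic_sire scenario")
    config = dataset.config
    rng = config.rng("tissue")
    out = {}
    for tissue, fraction in truth.mosaic_tissue_fractions.items():
        depth_mean = config.semen_depth if tissue == "semen" else config.mean_depth
        depth = int(rng.poisson(depth_mean))
        f = max(fraction, config.error_rate)
        alt = int(rng.binomial(depth, f)) if depth > 0 else 0
        out[tissue] = (alt, depth)
    return out


def simulate_coverage(config: SimulationConfig, sex: str = "male") -> list[CoverageWindow]:
    """Windowed read counts over the genome model with planted ploidy events.

    Window count ~ Poisson(rate x width x ploidy/2) with the diploid rate
    set so that coverage = mean_depth at read_length-bp reads. Ploidy per
    window comes from the chromosome class, the sample's sex, and the
    planted event (trisomy -> 3 on the event chromosome; terminal
    monosomy -> 1 within the terminal segment).
    """
    rng = config.rng("coverage")
    rate = config.mean_depth / config.read_length  # reads per bp, diploid
    windows: list[CoverageWindow] = []
    for chrom in config.genome:
        if chrom.klass == "autosome":
            ploidy = 2
        elif chrom.klass == "X":
            ploidy = 1 if sex == "male" else 2
        else:
            ploidy = 1 if sex == "male" else 0
        loss_start = None
        if config.scenario == "trisomy" and chrom.name == config.event_chrom:
            ploidy = 3
        if config.scenario == "terminal_monosomy" and chrom.name == config.event_chrom:
            loss_start = chrom.length - config.terminal_loss_length + 1
        start = 1
        while start <= chrom.length:
            end = min(start + config.window_size - 1, chrom.length)
            width = end - start + 1
            w_ploidy = ploidy
            if loss_start is not None and start >= loss_start:
                w_ploidy = 1
            lam = rate * width * w_ploidy / 2
            count = int(rng.poisson(lam))
            windows.append(
                CoverageWindow(
                    interval=GenomicInterval(chrom.name, start, end),
                    count=count,
                    partial=width < config.window_size,
                )
            )
            start = end + 1
    return windows


def simulate_trisomy_read_fractions(
    n_sites: int, depth: float, origin: str, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized generator of (is_sire_only, alt_reads, depths) for a
    trisomic region — the fast path for replicate-heavy power studies.

    Under a paternal extra copy, sire-only-alt sites carry the alternate
    on 2 of 3 copies and dam-only-alt sites on 1 of 3 (mirrored for a
    maternal extra copy).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x7269)))
    sire_only = rng.integers(0, 2, size=n_sites).astype(bool)
    if origin == "paternal":
        frac = np.where(sire_only, 2 / 3, 1 / 3)
    elif origin == "maternal":
        frac = np.where(sire_only, 1 / 3, 2 / 3)
    else:
        raise ValueError(f"origin must be paternal or maternal, got {origin!r}")
    depths = rng.poisson(depth * 1.5, size=n_sites)
    alt = rng.binomial(depths, frac)
    return sire_only, alt, depths
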