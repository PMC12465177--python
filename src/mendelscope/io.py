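"""Readers and writers for the standard formats the pipeline touches.

All coordinates are 1-based inclusive (HGVS/VCF convention). Coverage
windows are stored as (chrom, 1-based start, 1-based end); the terminal
window of a chromosome may be shorter than the nominal window size and is
flagged ``partial``.

VCF handling goes through :mod:`pysam`; only the ``GT`` and ``AD`` FORMAT
fields are consumed. Multiallelic sites are decomposed into one biallelic
record per ALT allele at load time. X-chromosome calls in males are
re-coded hemizygous when a pedigree (or sex map) is supplied; the
pseudoautosomal region is not modeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
import pysam

__all__ = [
    "GenomicInterval",
    "GenotypeCall",
    "VariantRecord",
    "PedigreeSample",
    "CoverageWindow",
    "read_vcf",
    "write_vcf",
    "read_ped",
    "write_ped",
    "read_coverage",
    "write_coverage",
    "detect_design",
]

#: chromosome names treated as the X chromosome when re-coding hemizygosity
X_NAMES = frozenset({"X", "chrX", "ChrX", "x"})
Y_NAMES = frozenset({"Y", "chrY", "ChrY", "y"})


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval; a point when start == end."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site.

    ``dosage`` is the alt-allele count (0/1/2 diploid, 0/1 hemizygous) or
    ``None`` when the genotype is missing. Depths are read counts from the
    AD field, ``None`` when AD was absent.
    """

    dosage: int | None
    hemizygous: bool = False
    ref_depth: int | None = None
    alt_depth: int | None = None

    def __post_init__(self) -> None:
        if self.dosage is not None and self.dosage not in (0, 1, 2):
            raise ValueError(f"dosage must be 0, 1, 2 or None, got {self.dosage}")
        if self.hemizygous and self.dosage == 2:
            raise ValueError("hemizygous call cannot have dosage 2")
        for d in (self.ref_depth, self.alt_depth):
            if d is not None and d < 0:
                raise ValueError("read depths must be non-negative")

    @property
    def total_depth(self) -> int | None:
        if self.ref_depth is None or self.alt_depth is None:
            return None
        return self.ref_depth + self.alt_depth


_ALLELE_CHARS = frozenset("ACGT")


@dataclass
class VariantRecord:
    """One biallelic site with per-sample genotype calls.

    ``annotations`` carries free-form keys (predictor verdicts,
    consequence labels); it is never interpreted by the readers.
    """

    interval: GenomicInterval
    ref: str
    alt: str
    gene: str = ""
    cds_pos: int | None = None
    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _ALLELE_CHARS:
                raise ValueError(
                    f"alleles must be non-empty strings over ACGT; got {allele!r} "
                    "(symbolic alleles are rejected)"
                )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def pos(self) -> int:
        return self.interval.start

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PedigreeSample:
    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = "unknown"  # male | female | unknown
    affected: bool = False
    role: str = "control"  # case | parent | control
    tissue: str = "unknown"  # blood | semen | ear | unknown

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.role not in ("case", "parent", "control"):
            raise ValueError(f"invalid role {self.role!r}")
        if self.tissue not in ("blood", "semen", "ear", "unknown"):
            raise ValueError(f"invalid tissue {self.tissue!r}")
        if self.id in (self.sire_id, self.dam_id):
            raise ValueError(f"sample {self.id} is its own parent")


@dataclass
class CoverageWindow:
    """Fixed-width read-count bin; ``ratio`` is filled by cnv.normalize."""

    interval: GenomicInterval
    count: int
    ratio: float | None = None
    partial: bool = False

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"negative read count {self.count}")

    @property
    def width(self) -> int:
        return self.interval.length


# ---------------------------------------------------------------------------
# VCF


def _decompose_call(gt: tuple, ad, alt_index: int, hemizygous: bool) -> GenotypeCall:
    """Re-code one sample's multiallelic GT/AD against a single ALT.

    The per-allele dosage is the count of ``alt_index`` among the called
    alleles, so the total allele count at the site is conserved across the
    decomposed records.
    """
    alleles = [a for a in gt if a is not None]
    if not alleles:
        dosage = None
    else:
        dosage = sum(1 for a in alleles if a == alt_index)
    hemi = hemizygous or (len(alleles) == 1 and len(gt) == 1)
    ref_depth = alt_depth = None
    if ad is not None:
        try:
            ref_depth = int(ad[0]) if ad[0] is not None else None
            alt_depth = int(ad[alt_index]) if ad[alt_index] is not None else None
        except (IndexError, TypeError):
            ref_depth = alt_depth = None
    if hemi and dosage == 2:
        dosage = 1
    return GenotypeCall(dosage=dosage, hemizygous=hemi, ref_depth=ref_depth, alt_depth=alt_depth)


def read_vcf(
    path: str,
    roster: list[str] | None = None,
    sex_by_sample: dict[str, str] | None = None,
) -> list[VariantRecord]:
    """Read a VCF into biallelic :class:`VariantRecord` objects.

    Parameters
    ----------
    path:
        Plain-text or bgzipped VCF with GT (and ideally AD) per sample.
    roster:
        Samples that must be present; defaults to all header samples.
        A roster sample absent from the header is an error.
    sex_by_sample:
        Optional sample -> {male, female, unknown} map; male calls on the
        X chromosome (and any call on Y) are re-coded hemizygous.
    """
    sex_by_sample = sex_by_sample or {}
    records: list[VariantRecord] = []
    with pysam.VariantFile(path) as vcf:
        header_samples = list(vcf.header.samples)
        if roster is None:
            roster = header_samples
        missing = [s for s in roster if s not in header_samples]
        if missing:
            raise ValueError(f"roster sample(s) absent from VCF header: {', '.join(missing)}")
        if "AD" not in vcf.header.formats:
            warnings.warn(f"{path}: no AD FORMAT field; read depths set missing", stacklevel=2)
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                if set(alt) - _ALLELE_CHARS:
                    warnings.warn(
                        f"{rec.chrom}:{rec.pos} symbolic/non-ACGT alt {alt!r} skipped",
                        stacklevel=2,
                    )
                    continue
                end = rec.pos + len(rec.ref) - 1
                interval = GenomicInterval(rec.chrom, rec.pos, end)
                gene = rec.info.get("GENE", "") if "GENE" in rec.info else ""
                if isinstance(gene, tuple):
                    gene = gene[0] or ""
                cds = rec.info.get("CDS", None) if "CDS" in rec.info else None
                annotations = {}
                for k, v in rec.info.items():
                    if k in ("GENE", "CDS"):
                        continue
                    annotations[k] = ",".join(map(str, v)) if isinstance(v, tuple) else str(v)
                calls: dict[str, GenotypeCall] = {}
                for sample in roster:
                    s = rec.samples[sample]
                    gt = s.get("GT", (None,))
                    ad = s.get("AD", None)
                    hemi = rec.chrom in Y_NAMES or (
                        rec.chrom in X_NAMES and sex_by_sample.get(sample) == "male"
                    )
                    calls[sample] = _decompose_call(gt, ad, alt_index, hemi)
                records.append(
                    VariantRecord(
                        interval=interval,
                        ref=rec.ref,
                        alt=alt,
                        gene=str(gene),
                        cds_pos=int(cds) if cds is not None else None,
                        calls=calls,
                        annotations=annotations,
                    )
                )
    return records


def write_vcf(
    records: list[VariantRecord],
    path: str,
    samples: list[str] | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write biallelic records as a plain-text VCF v4.2 with GT and AD."""
    if samples is None:
        seen: dict[str, None] = {}
        for rec in records:
            for s in rec.calls:
                seen.setdefault(s)
        samples = list(seen)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">'
    )
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=CDS,Number=1,Type=Integer,Description="1-based CDS position">')
    contigs: dict[str, int] = dict(contig_lengths or {})
    for rec in records:
        contigs[rec.chrom] = max(contigs.get(rec.chrom, 0), rec.interval.end)
    for chrom, length in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in sorted(records, key=lambda r: r.key):
            vr = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.interval.end,
                alleles=(rec.ref, rec.alt),
            )
            if rec.gene:
                vr.info["GENE"] = rec.gene
            if rec.cds_pos is not None:
                vr.info["CDS"] = rec.cds_pos
            for s in samples:
                call = rec.calls.get(s)
                if call is None:
                    vr.samples[s]["GT"] = (None, None)
                    continue
                if call.hemizygous:
                    gt = (None,) if call.dosage is None else (min(call.dosage, 1),)
                elif call.dosage is None:
                    gt = (None, None)
                else:
                    gt = ((0, 0), (0, 1), (1, 1))[call.dosage]
                vr.samples[s]["GT"] = gt
                if call.ref_depth is not None and call.alt_depth is not None:
                    vr.samples[s]["AD"] = (call.ref_depth, call.alt_depth)
            out.write(vr)


# ---------------------------------------------------------------------------
# PED


_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}


def read_ped(path: str) -> list[PedigreeSample]:
    """Read a 6-column PED file (family, id, sire, dam, sex, phenotype).

    Roles are inferred: affected individuals become cases, parents of a
    case become parents, everyone else is a control. "0" parent codes map
    to unknown. Duplicate ids and pedigree cycles are errors.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["family", "id", "sire", "dam", "sex", "phenotype"],
        dtype=str,
        comment="#",
    )
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicated sample id(s) in pedigree: {', '.join(dups)}")
    parents: dict[str, tuple[str | None, str | None]] = {}
    rows = []
    for row in df.itertuples(index=False):
        sire = None if row.sire in ("0", "", None) else row.sire
        dam = None if row.dam in ("0", "", None) else row.dam
        if row.id in (sire, dam):
            raise ValueError(f"sample {row.id} is its own parent")
        parents[row.id] = (sire, dam)
        rows.append((row.id, sire, dam, _SEX_CODES.get(str(row.sex), "unknown"), str(row.phenotype) == "2"))
    # cycle check: walk ancestors of every sample
    for sample in parents:
        stack, seen = [sample], set()
        while stack:
            cur = stack.pop()
            for p in parents.get(cur, (None, None)):
                if p is None:
                    continue
                if p == sample:
                    raise ValueError(f"pedigree cycle involving {sample}")
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
    case_parents = set()
    for sid, sire, dam, _sex, affected in rows:
        if affected:
            case_parents.update(p for p in (sire, dam) if p is not None)
    samples = []
    for sid, sire, dam, sex, affected in rows:
        role = "case" if affected else ("parent" if sid in case_parents else "control")
        samples.append(
            PedigreeSample(id=sid, sire_id=sire, dam_id=dam, sex=sex, affected=affected, role=role)
        )
    by_id = {s.id: s for s in samples}
    for s in samples:
        if s.sire_id and s.sire_id in by_id and by_id[s.sire_id].sex == "female":
            raise ValueError(f"sire {s.sire_id} of {s.id} is recorded female")
        if s.dam_id and s.dam_id in by_id and by_id[s.dam_id].sex == "male":
            raise ValueError(f"dam {s.dam_id} of {s.id} is recorded male")
    return samples


def write_ped(samples: list[PedigreeSample], path: str, family: str = "FAM1") -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for s in samples:
            fh.write(
                "\t".join(
                    [
                        family,
                        s.id,
                        s.sire_id or "0",
                        s.dam_id or "0",
                        sex_code[s.sex],
                        "2" if s.affected else "1",
                    ]
                )
                + "\n"
            )


def detect_design(samples: list[PedigreeSample]) -> str:
    """Classify the sampling design of a pedigree.

    Returns one of ``trio``, ``single_parent``, ``half_sibs``,
    ``multiple_cases`` or ``single_case``, mirroring the cohort designs
    used for sequencing (complete trios, paternal half-siblings, multiple
    cases, isolated single cases).
    """
    by_id = {s.id: s for s in samples}
    cases = [s for s in samples if s.role == "case"]
    if not cases:
        raise ValueError("pedigree contains no affected case")

    def present(pid: str | None) -> bool:
        return pid is not None and pid in by_id

    if len(cases) == 1:
        c = cases[0]
        if present(c.sire_id) and present(c.dam_id):
            return "trio"
        if present(c.sire_id) or present(c.dam_id):
            return "single_parent"
        return "single_case"
    sires = {c.sire_id for c in cases}
    dams = {c.dam_id for c in cases}
    if len(sires) == 1 and None not in sires and len(dams) > 1:
        return "half_sibs"
    return "multiple_cases"


# ---------------------------------------------------------------------------
# Coverage TSV


def read_coverage(path: str, window_size: int) -> list[CoverageWindow]:
    """Read a BED-like coverage TSV into sorted :class:`CoverageWindow` rows.

    Accepts 3 columns (chrom, 1-based start, count; ends are inferred from
    ``window_size``) or 4 columns (chrom, start, end, count). Windows must
    be non-overlapping and of uniform width except for the terminal window
    of each chromosome, which may be shorter and is flagged partial.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 3:
        df.columns = ["chrom", "start", "count"]
        df["end"] = df["start"] + window_size - 1
    elif df.shape[1] == 4:
        df.columns = ["chrom", "start", "end", "count"]
    else:
        raise ValueError(f"expected 3 or 4 columns, got {df.shape[1]}")
    if (df["count"] < 0).any():
        raise ValueError("negative read count in coverage table")
    df = df.sort_values(["chrom", "start"], kind="stable")
    windows: list[CoverageWindow] = []
    for chrom, grp in df.groupby("chrom", sort=True):
        prev_end = 0
        starts = grp["start"].tolist()
        ends = grp["end"].tolist()
        counts = grp["count"].tolist()
        n = len(starts)
        for i in range(n):
            if starts[i] <= prev_end:
                raise ValueError(f"overlapping windows on {chrom} at start {starts[i]}")
            width = ends[i] - starts[i] + 1
            terminal = i == n - 1
            if width > window_size or (width != window_size and not terminal):
                raise ValueError(
                    f"inconsistent window width {width} on {chrom} at {starts[i]} "
                    f"(expected {window_size})"
                )
            windows.append(
                CoverageWindow(
                    interval=GenomicInterval(str(chrom), int(starts[i]), int(ends[i])),
                    count=int(counts[i]),
                    partial=width < window_size,
                )
            )
            prev_end = ends[i]
    return windows


def write_coverage(windows: list[CoverageWindow], path: str) -> None:
    with open(path, "w") as fh:
        for w in sorted(windows, key=lambda w: (w.interval.chrom, w.interval.start)):
            fh.write(f"{w.interval.chrom}\t{w.interval.start}\t{w.interval.end}\t{w.count}\n")
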