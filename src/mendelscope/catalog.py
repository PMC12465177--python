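"""Machine-readable nosology of ruminant skeletal disorders and the studied
case series, with the query operations behind the published summary counts.

The package ships three tab-delimited tables (see ``data/catalog_schema.json``):

* ``nosology.tsv`` — previously reported disorders with a known molecular
  cause, one row per (category, disorder, breed-group, gene) entry; horn
  phenotypes carry ``horn_trait = 1`` so queries can include or exclude them.
* ``cases.tsv`` — the newly investigated case series, one row per case
  group (same disorder, breed and finding), with case ids and the final
  variant classification.
* ``alleles.tsv`` — one row per distinct SNV/indel allele with its
  g./c./p. descriptions; an allele shared by two cases appears once and is
  referenced by both case ids.

Counting conventions (deliberate, and the only ones jointly consistent
with the published tallies): disorder identity is the (disorder, species)
pair; allele-level classification tallies count distinct SNV/indel alleles
(shared alleles deduplicated, aneuploidies excluded); finding-level tallies
count case-group rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "Catalog",
    "CatalogEntry",
    "VariantAlleleEntry",
    "load_catalog",
    "count_distinct",
    "tally_classifications",
    "diagnostic_rate",
]

MOI_CODES = frozenset({"AR", "AD", "AcD", "AID", "XLD", "unknown"})
CLASSIFICATIONS = frozenset({"pathogenic", "likely_pathogenic", "uncertain", "none"})
ZYGOSITIES = frozenset({"heterozygous", "homozygous", "compound-partner", "hemizygous"})


@dataclass(frozen=True)
class CatalogEntry:
    table: str  # nosology | cases
    category: str
    disorder: str
    species: str
    breeds: tuple[str, ...]
    gene: str
    moi: str
    variant_kinds: tuple[str, ...]
    classification: str = "none"
    case_ids: tuple[int, ...] = ()
    omia_id: str = ""
    horn_trait: bool = False
    notes: str = ""


@dataclass(frozen=True)
class VariantAlleleEntry:
    allele_id: str
    label: str
    case_ids: tuple[int, ...]
    gene: str
    hgvs_g: str
    hgvs_c: str
    hgvs_p: str
    zygosity: str
    kind: str
    classification: str
    codon_consistent: bool
    notes: str = ""


def _split(value, sep=",") -> tuple[str, ...]:
    if pd.isna(value) or not str(value).strip():
        return ()
    return tuple(part.strip() for part in str(value).split(sep) if part.strip())


def _ids(value) -> tuple[int, ...]:
    return tuple(int(x) for x in _split(value))


@dataclass
class Catalog:
    nosology: list[CatalogEntry]
    cases: list[CatalogEntry]
    alleles: list[VariantAlleleEntry]

    def validate(self) -> None:
        seen_ids: set[int] = set()
        for entry in self.cases:
            if not entry.case_ids:
                raise ValueError(f"cases-table entry {entry.disorder!r} has no case ids")
            overlap = seen_ids.intersection(entry.case_ids)
            if overlap:
                raise ValueError(f"duplicate case id(s) across cases table: {sorted(overlap)}")
            seen_ids.update(entry.case_ids)
        for entry in self.nosology + self.cases:
            if entry.moi not in MOI_CODES:
                raise ValueError(f"unknown MOI code {entry.moi!r} for {entry.disorder!r}")
            if entry.classification not in CLASSIFICATIONS:
                raise ValueError(f"unknown classification {entry.classification!r}")
        allele_ids = [a.allele_id for a in self.alleles]
        if len(allele_ids) != len(set(allele_ids)):
            raise ValueError("duplicate allele_id in alleles table")
        for a in self.alleles:
            if a.zygosity not in ZYGOSITIES:
                raise ValueError(f"unknown zygosity {a.zygosity!r} for {a.allele_id}")
            bad = set(a.case_ids) - seen_ids
            if bad:
                raise ValueError(f"allele {a.allele_id} references unknown case id(s) {sorted(bad)}")


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("mendelscope.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def load_catalog(
    nosology_path: str | None = None,
    cases_path: str | None = None,
    alleles_path: str | None = None,
) -> Catalog:
    """Load and validate the catalog, from the packaged tables by default."""
    read = lambda path, name: (
        pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if path
        else _read_packaged(name)
    )
    nos_df = read(nosology_path, "nosology.tsv")
    cases_df = read(cases_path, "cases.tsv")
    alleles_df = read(alleles_path, "alleles.tsv")
    nosology = [
        CatalogEntry(
            table="nosology",
            category=r["category"],
            disorder=r["disorder"],
            species=r["species"],
            breeds=_split(r["breeds"]),
            gene=r["gene"],
            moi=r["moi"] or "unknown",
            variant_kinds=_split(r["variant_kinds"]),
            omia_id=r["omia_id"],
            horn_trait=r["horn_trait"] == "1",
            notes=r.get("notes", ""),
        )
        for _, r in nos_df.iterrows()
    ]
    cases = [
        CatalogEntry(
            table="cases",
            category=r["category"],
            disorder=r["disorder"],
            species=r["species"],
            breeds=_split(r["breeds"]),
            gene=r["gene"],
            moi=r["moi"] or "unknown",
            variant_kinds=_split(r["variant_kinds"]),
            classification=r["classification"] or "none",
            case_ids=_ids(r["case_ids"]),
            notes=r.get("notes", ""),
        )
        for _, r in cases_df.iterrows()
    ]
    alleles = [
        VariantAlleleEntry(
            allele_id=r["allele_id"],
            label=r["label"],
            case_ids=_ids(r["case_ids"]),
            gene=r["gene"],
            hgvs_g=r["hgvs_g"],
            hgvs_c=r["hgvs_c"],
            hgvs_p=r.get("hgvs_p", ""),
            zygosity=r["zygosity"],
            kind=r["kind"],
            classification=r["classification"],
            codon_consistent=r["codon_consistent"] == "1",
            notes=r.get("notes", ""),
        )
        for _, r in alleles_df.iterrows()
    ]
    catalog = Catalog(nosology=nosology, cases=cases, alleles=alleles)
    catalog.validate()
    return catalog


_FIELDS = {
    "category": lambda e: e.category,
    "disorder": lambda e: e.disorder,
    "species": lambda e: e.species,
    "gene": lambda e: e.gene,
    "moi": lambda e: e.moi,
    "case_id": None,  # expanded specially
}


def count_distinct(catalog: Catalog, table: str, field) -> int:
    """Distinct count of a field (or field tuple) over one catalog table.

    ``case_id`` expands the per-row id lists (cases table); the
    (disorder, species) tuple is the disorder-identity key.
    """
    if table not in ("nosology", "cases"):
        raise ValueError(f"unknown table {table!r}; expected 'nosology' or 'cases'")
    entries = catalog.nosology if table == "nosology" else catalog.cases
    fields = (field,) if isinstance(field, str) else tuple(field)
    for f in fields:
        if f not in _FIELDS:
            raise ValueError(f"unknown field {f!r}; valid fields: {sorted(_FIELDS)}")
    if "case_id" in fields:
        if fields != ("case_id",):
            raise ValueError("case_id cannot be combined with other fields")
        return len({cid for e in entries for cid in e.case_ids})
    keys = {tuple(_FIELDS[f](e) for f in fields) for e in entries}
    return len(keys)


def tally_classifications(catalog: Catalog, level: str = "allele") -> dict[str, int]:
    """Classification tallies at allele or finding level.

    ``allele`` counts distinct SNV/indel alleles (the alleles table:
    shared alleles appear once, aneuploidies are not alleles and are
    excluded). ``finding`` counts case-group rows of the cases table, so
    the tallies sum to the number of rows.
    """
    tally: dict[str, int] = {}
    if level == "allele":
        for a in catalog.alleles:
            tally[a.classification] = tally.get(a.classification, 0) + 1
    elif level == "finding":
        for e in catalog.cases:
            tally[e.classification] = tally.get(e.classification, 0) + 1
    else:
        raise ValueError(f"level must be 'allele' or 'finding', got {level!r}")
    return tally


def diagnostic_rate(
    catalog: Catalog, include_aneuploidies: bool = True
) -> tuple[int, int, float]:
    """(solved cases, total cases, fraction) over the cases table.

    A case counts as solved when its entry is classified pathogenic or
    likely pathogenic; ``include_aneuploidies=False`` drops aneuploidy
    findings from the numerator.
    """
    if not catalog.cases:
        raise ValueError("empty cases catalog")
    total = len({cid for e in catalog.cases for cid in e.case_ids})
    solved = 0
    for e in catalog.cases:
        if e.classification not in ("pathogenic", "likely_pathogenic"):
            continue
        if not include_aneuploidies and "aneuploidy" in e.variant_kinds:
            continue
        solved += len(e.case_ids)
    return solved, total, solved / total
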