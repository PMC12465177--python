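"""Shared fixtures and independent brute-force oracles.

The oracles re-evaluate each filter's textual definition literally,
independent of the library implementation, so that equivalence tests mean
something. They are deliberately naive (nested loops over samples and
variant pairs) and only suitable for toy cohorts.
"""

from __future__ import annotations

import numpy as np
import pytest

from mendelscope.catalog import load_catalog
from mendelscope.io import GenomicInterval, GenotypeCall, VariantRecord


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


def make_variant(chrom="Chr1", pos=100, ref="A", alt="G", gene="", calls=None, **kw):
    return VariantRecord(
        interval=GenomicInterval(chrom, pos, pos),
        ref=ref,
        alt=alt,
        gene=gene,
        calls=calls or {},
        **kw,
    )


def call(dosage, hemizygous=False, ref_depth=None, alt_depth=None):
    return GenotypeCall(
        dosage=dosage, hemizygous=hemizygous, ref_depth=ref_depth, alt_depth=alt_depth
    )


# ---------------------------------------------------------------------------
# brute-force oracles for the MOI filters


def _hom_alt(v, s):
    c = v.calls.get(s)
    return c is not None and c.dosage is not None and (
        c.dosage == 2 or (c.hemizygous and c.dosage == 1)
    )


def _dos(v, s):
    c = v.calls.get(s)
    return None if c is None else c.dosage


def oracle_recessive(variants, cases, controls, parent_map):
    """Homozygous in all cases; no control homozygous-alt; available
    parents heterozygous carriers. Missing case genotype fails."""
    kept = []
    for v in variants:
        if not all(_hom_alt(v, c) for c in cases):
            continue
        if any(_hom_alt(v, ctl) for ctl in controls):
            continue
        ok = True
        for c in cases:
            for p in parent_map.get(c, (None, None)):
                if p is not None and _dos(v, p) != 1:
                    ok = False
        if ok:
            kept.append(v)
    return sorted(kept, key=lambda v: v.key)


def oracle_dominant(variants, cases, controls, parent_map, check_parents):
    """Het (or hemizygous-alt) in all cases; carried by no control
    (missing control treated as reference); sampled parents 0/0 in
    trio/single-parent designs."""
    kept = []
    for v in variants:
        if not all(_dos(v, c) == 1 for c in cases):
            continue
        if any((_dos(v, ctl) or 0) >= 1 for ctl in controls):
            continue
        ok = True
        if check_parents:
            for c in cases:
                for p in parent_map.get(c, (None, None)):
                    if p is not None and _dos(v, p) != 0:
                        ok = False
        if ok:
            kept.append(v)
    return sorted(kept, key=lambda v: v.key)


def oracle_compound_het(variants, cases, controls, parent_map):
    """Gene-wise pairs: every case het for both; no control carries both
    simultaneously nor either in homozygosity; with both parents sampled
    the alleles must be explainable as one from each parent."""
    by_gene = {}
    for v in variants:
        if v.gene:
            by_gene.setdefault(v.gene, []).append(v)
    pairs = {}
    for gene, vs in by_gene.items():
        vs = sorted(vs, key=lambda v: v.key)
        for i in range(len(vs)):
            for j in range(i + 1, len(vs)):
                v1, v2 = vs[i], vs[j]
                if not all(_dos(v1, c) == 1 and _dos(v2, c) == 1 for c in cases):
                    continue
                bad = False
                for ctl in controls:
                    d1, d2 = _dos(v1, ctl) or 0, _dos(v2, ctl) or 0
                    if d1 == 2 or d2 == 2 or (d1 >= 1 and d2 >= 1):
                        bad = True
                if bad:
                    continue
                for c in cases:
                    sire, dam = parent_map.get(c, (None, None))
                    if sire is not None and dam is not None:
                        s1, s2 = _dos(v1, sire), _dos(v2, sire)
                        m1, m2 = _dos(v1, dam), _dos(v2, dam)
                        if None not in (s1, s2, m1, m2):
                            trans = (s1 >= 1 and m2 >= 1) or (s2 >= 1 and m1 >= 1)
                            if not trans:
                                bad = True
                    elif sire is not None or dam is not None:
                        p = sire if sire is not None else dam
                        p1, p2 = _dos(v1, p), _dos(v2, p)
                        if None not in (p1, p2) and (p1 >= 1) == (p2 >= 1):
                            bad = True
                if not bad:
                    pairs.setdefault(gene, []).append((v1, v2))
    return pairs


def random_toy_cohort(rng, max_samples=8, max_variants=50):
    """Random genotype configuration on a toy cohort for oracle equivalence.

    Returns (variants, cases, controls, parent_map). Samples split into
    1-2 cases, optional parents, remaining controls; dosages drawn from
    {0, 1, 2, missing} with weights favoring reference.
    """
    n_samples = int(rng.integers(3, max_samples + 1))
    n_variants = int(rng.integers(1, max_variants + 1))
    ids = [f"s{i}" for i in range(n_samples)]
    n_cases = int(rng.integers(1, min(2, n_samples - 1) + 1))
    cases = ids[:n_cases]
    rest = ids[n_cases:]
    parent_map = {}
    n_parents = int(rng.integers(0, min(2, len(rest)) + 1))
    parents = rest[:n_parents]
    for c in cases:
        sire = parents[0] if n_parents >= 1 else None
        dam = parents[1] if n_parents >= 2 else None
        parent_map[c] = (sire, dam)
    controls = rest[n_parents:]
    genes = ["G1", "G2", "G3"]
    variants = []
    for k in range(n_variants):
        calls = {}
        for s in ids:
            d = rng.choice([0, 0, 0, 1, 1, 2, None], p=[0.3, 0.2, 0.1, 0.15, 0.1, 0.1, 0.05])
            calls[s] = GenotypeCall(dosage=None if d is None else int(d))
        variants.append(
            VariantRecord(
                interval=GenomicInterval("Chr1", 1000 + k, 1000 + k),
                ref="A",
                alt="G",
                gene=str(rng.choice(genes)),
                calls=calls,
            )
        )
    return variants, cases, controls, parent_map
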