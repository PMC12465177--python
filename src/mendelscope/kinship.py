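"""Parentage verification: opposing-homozygote counting and
method-of-moments identity-by-descent (IBD) estimation.

The IBD estimator follows the classical method-of-moments formulation used
for pairwise relatedness in whole-genome tools: per-site identity-by-state
(IBS) counts are compared with their expectations given the cohort allele
frequencies under IBD states 0/1/2, the linear system is solved for the
state proportions, negative or >1 solutions are truncated and the vector
renormalized, and ``pi_hat = P(IBD=1)/2 + P(IBD=2)``. No small-sample
frequency corrections are applied; frequencies are taken from the control
cohort and sites are restricted to an informative frequency window.

Parent-offspring pairs expect pi_hat ~= 0.5, near-zero P(IBD=0), and an
opposing-homozygote rate at the genotyping-error floor: two individuals
homozygous for different alleles cannot be parent and child absent error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KinshipConfig",
    "PairRelatedness",
    "opposing_homozygote_rate",
    "moment_ibd",
    "verify_pedigree",
]


@dataclass(frozen=True)
class KinshipConfig:
    freq_window: tuple[float, float] = (0.05, 0.95)
    pi_hat_parent_band: tuple[float, float] = (0.4, 0.6)
    max_p_ibd0_parent: float = 0.05
    #: opposing-homozygote rate allowed in a true parent-offspring pair
    #: (genotyping error at ~20x short reads)
    max_opposing_rate: float = 0.001
    min_sites: int = 500
    unrelated_pi_hat: float = 0.1


@dataclass
class PairRelatedness:
    pair: tuple[str, str]
    n_opposing_homozygotes: int
    n_comparable_sites: int
    p_ibd0: float
    p_ibd1: float
    p_ibd2: float
    pi_hat: float
    verdict: str  # parent_offspring_consistent | excluded | unrelated_like | ambiguous


def _as_arrays(g1, g2) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    return a, b


def opposing_homozygote_rate(g1, g2, min_sites: int = 500) -> tuple[float, int, int]:
    """Fraction of comparable sites where the pair is homozygous for
    opposite alleles. Genotypes are alt-allele dosages (0/1/2, NaN missing).
    """
    a, b = _as_arrays(g1, g2)
    both = ~np.isnan(a) & ~np.isnan(b)
    n = int(both.sum())
    if n < min_sites:
        raise ValueError(f"need >= {min_sites} jointly called sites, got {n}")
    opposing = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    return opposing / n, opposing, n


def moment_ibd(
    g1,
    g2,
    freqs,
    pair: tuple[str, str] = ("sample1", "sample2"),
    config: KinshipConfig = KinshipConfig(),
) -> PairRelatedness:
    """Method-of-moments IBD state estimation for one sample pair.

    ``freqs`` are alt-allele frequencies from the control cohort; sites
    outside the configured frequency window or missing in either sample
    are excluded.
    """
    a, b = _as_arrays(g1, g2)
    p = np.asarray(freqs, dtype=float)
    if p.shape != a.shape:
        raise ValueError("frequency vector length mismatch")
    lo, hi = config.freq_window
    use = ~np.isnan(a) & ~np.isnan(b) & (p >= lo) & (p <= hi)
    if not use.any():
        raise ValueError("no informative site in the frequency window")
    a, b, p = a[use], b[use], p[use]
    q = 1.0 - p
    n = a.size

    ibs = 2 - np.abs(a - b)
    ibs[((a == 0) & (b == 2)) | ((a == 2) & (b == 0))] = 0
    obs0 = float((ibs == 0).sum())
    obs1 = float((ibs == 1).sum())
    obs2 = float((ibs == 2).sum())

    # expected IBS counts per IBD state, summed over sites
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e2_ibd0 = float(n - np.sum(2 * p**2 * q**2 + 4 * p**3 * q + 4 * p * q**3))
    e1_ibd1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e2_ibd1 = float(n - np.sum(2 * p**2 * q + 2 * p * q**2))

    p0 = obs0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
    p1 = (obs1 - p0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    p2 = (obs2 - p0 * e2_ibd0 - p1 * e2_ibd1) / n

    # truncate to [0, 1] and renormalize
    probs = np.clip([p0, p1, p2], 0.0, 1.0)
    total = probs.sum()
    probs = probs / total if total > 0 else np.array([1.0, 0.0, 0.0])
    pi_hat = float(np.clip(probs[1] / 2 + probs[2], 0.0, 1.0))

    opposing = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    opp_rate = opposing / n
    band_lo, band_hi = config.pi_hat_parent_band
    if (
        band_lo <= pi_hat <= band_hi
        and probs[0] < config.max_p_ibd0_parent
        and opp_rate <= config.max_opposing_rate
    ):
        verdict = "parent_offspring_consistent"
    elif pi_hat < config.unrelated_pi_hat:
        verdict = "unrelated_like"
    elif opp_rate > config.max_opposing_rate and pi_hat < band_lo:
        verdict = "excluded"
    else:
        verdict = "ambiguous"
    return PairRelatedness(
        pair=pair,
        n_opposing_homozygotes=opposing,
        n_comparable_sites=n,
        p_ibd0=float(probs[0]),
        p_ibd1=float(probs[1]),
        p_ibd2=float(probs[2]),
        pi_hat=pi_hat,
        verdict=verdict,
    )


def verify_pedigree(
    pedigree,
    genotypes: dict[str, np.ndarray],
    freqs,
    config: KinshipConfig = KinshipConfig(),
) -> dict[tuple[str, str], PairRelatedness]:
    """Test every recorded parent-offspring link in a pedigree.

    ``pedigree`` is a list of PedigreeSample; ``genotypes`` maps sample id
    to a dosage vector aligned with ``freqs``. A link whose pair verdict
    is not parent-offspring-consistent is reported as ``excluded`` with
    the full evidence attached.
    """
    results: dict[tuple[str, str], PairRelatedness] = {}
    for s in pedigree:
        for parent in (s.sire_id, s.dam_id):
            if parent is None or parent not in genotypes or s.id not in genotypes:
                continue
            rel = moment_ibd(
                genotypes[s.id], genotypes[parent], freqs, pair=(s.id, parent), config=config
            )
            if rel.verdict != "parent_offspring_consistent":
                rel.verdict = "excluded"
            results[(s.id, parent)] = rel
    return results
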