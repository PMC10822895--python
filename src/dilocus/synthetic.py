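"""Seeded generator of two-locus case-control cohorts.

The population model: individuals are formed by random union of two
haplotypes drawn i.i.d. from a four-haplotype distribution (which
guarantees Hardy-Weinberg proportions at each locus), disease status is
Bernoulli with the odds of disease scaled by ``effect_or`` for the
exposed genotype class at locus 1, and case-control ascertainment is
simulated by rejection: the population is sampled until both the case
and the control quota are filled.  The odds ratio is invariant to this
retrospective sampling, which is what makes the generator a faithful
test bed for the association estimators.

Default parameters reproduce the control-population conditions of the
bundled rectal-cancer cohort: ref-allele frequencies 0.60 and 0.65,
signed D' of -0.12 between the loci, a dominant effect of OR 2.27 on
the reference-allele class, baseline disease probability 0.10, and
97 cases vs 119 controls.

Randomness: a single ``numpy.random.default_rng(seed)`` stream, consumed
in batches in the fixed order (haplotype 1, haplotype 2, sex, disease);
cohorts are byte-identical across runs for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .genotype_data import DEFAULT_LOCI, LocusDef, Sample

__all__ = ["SimConfig", "FeasibilityError", "haplotype_freqs_from_ld", "simulate_cohort"]


class FeasibilityError(ValueError):
    """Requested LD configuration has no valid haplotype distribution."""


@dataclass
class SimConfig:
    """Parameters of a simulated two-locus case-control cohort.

    ``p1``/``p2`` are reference-allele frequencies, ``d_prime_signed``
    the signed normalised LD between the reference alleles,
    ``effect_or`` the odds multiplier applied to the exposed genotype
    class at locus 1 (which class that is depends on ``model`` and
    ``risk_allele``), and ``baseline_prob`` the disease probability of
    the unexposed class.
    """

    p1: float = 0.60
    p2: float = 0.65
    d_prime_signed: float = -0.12
    model: str = "dominant"  # dominant | recessive | multiplicative | null
    effect_or: float = 2.27
    baseline_prob: float = 0.10
    n_cases: int = 97
    n_controls: int = 119
    sex_ratio: float = 0.6  # fraction male
    risk_allele: str = "ref"  # which allele's class carries the effect
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p1 < 1 or not 0 < self.p2 < 1:
            raise ValueError("allele frequencies must lie in (0, 1)")
        if self.model not in ("dominant", "recessive", "multiplicative", "null"):
            raise ValueError(f"unknown effect model {self.model!r}")
        if self.effect_or <= 0:
            raise ValueError("effect_or must be positive")
        if not 0 < self.baseline_prob < 1:
            raise ValueError("baseline_prob must lie in (0, 1)")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("target counts must be non-negative")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.risk_allele not in ("ref", "alt"):
            raise ValueError("risk_allele must be 'ref' or 'alt'")
        # validate LD feasibility eagerly
        haplotype_freqs_from_ld(self.p1, self.p2, self.d_prime_signed)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def haplotype_freqs_from_ld(
    p1: float, p2: float, d_prime_signed: float
) -> np.ndarray:
    """Four haplotype frequencies (r1r2, r1a2, a1r2, a1a2) implied by the
    allele frequencies and a signed D'.

    Inverse of the LD summary: D = D' * D_max with D_max the bound
    matching the sign of D, then frequencies are the independence
    products shifted by +/-D.  Any |D'| <= 1 is feasible for interior
    allele frequencies; |D'| = 1 places one haplotype exactly at zero.
    """
    if not 0 < p1 < 1 or not 0 < p2 < 1:
        raise FeasibilityError("allele frequencies must lie in (0, 1)")
    if abs(d_prime_signed) > 1:
        raise FeasibilityError(
            f"signed D' = {d_prime_signed} infeasible; the feasible range is [-1, 1]"
        )
    q1, q2 = 1 - p1, 1 - p2
    d_max = min(p1 * p2, q1 * q2) if d_prime_signed < 0 else min(p1 * q2, q1 * p2)
    d = d_prime_signed * d_max
    freqs = np.array([p1 * p2 + d, p1 * q2 - d, q1 * p2 - d, q1 * q2 + d])
    # exact zeros at |D'|=1 may round to tiny negatives
    freqs = np.clip(freqs, 0.0, None)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise FeasibilityError("implied haplotype frequencies do not sum to 1")
    return freqs / freqs.sum()


def _exposure_odds_factor(n_alt: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Odds multiplier per individual given alt-allele dosage at locus 1.

    The exposed class mirrors the estimator's genotype-class splits:
    the dominant split is hom-ref vs carriers, the recessive split is
    hom-alt vs the rest, and ``risk_allele`` selects which side of the
    split carries ``effect_or`` (so the matching model fit recovers the
    effect in the same orientation).
    """
    if cfg.model == "null":
        return np.ones_like(n_alt, dtype=float)
    if cfg.model == "multiplicative":
        dose = n_alt if cfg.risk_allele == "alt" else 2 - n_alt
        return cfg.effect_or ** dose.astype(float)
    if cfg.model == "dominant":
        exposed = n_alt >= 1 if cfg.risk_allele == "alt" else n_alt == 0
    else:  # recessive
        exposed = n_alt == 2 if cfg.risk_allele == "alt" else n_alt <= 1
    return np.where(exposed, cfg.effect_or, 1.0)


def simulate_cohort(
    cfg: SimConfig,
    loci: tuple[LocusDef, LocusDef] = DEFAULT_LOCI,
    max_draws: Optional[int] = None,
) -> list[Sample]:
    """Draw a case-control cohort under the configured population model.

    Individuals are sampled in batches until both quotas are met;
    exceeding ``max_draws`` (default ``1000 * (n_cases + n_controls)``)
    raises, which catches configurations whose case (or control)
    probability is too extreme to ever fill its quota.
    """
    locus1, locus2 = loci
    rng = np.random.default_rng(cfg.seed)
    hap_freqs = haplotype_freqs_from_ld(cfg.p1, cfg.p2, cfg.d_prime_signed)
    target = cfg.n_cases + cfg.n_controls
    if max_draws is None:
        max_draws = max(1000 * target, 10_000)
    baseline_odds = cfg.baseline_prob / (1 - cfg.baseline_prob)

    # haplotype index -> (alt at locus1, alt at locus2)
    alt1 = np.array([0, 0, 1, 1])
    alt2 = np.array([0, 1, 0, 1])

    cases: list[Sample] = []
    controls: list[Sample] = []
    drawn = 0
    serial = 0
    while len(cases) < cfg.n_cases or len(controls) < cfg.n_controls:
        if drawn >= max_draws:
            raise RuntimeError(
                f"quota not reached after {drawn} draws "
                f"({len(cases)}/{cfg.n_cases} cases, "
                f"{len(controls)}/{cfg.n_controls} controls); "
                "disease probabilities too extreme for the requested design"
            )
        batch = int(min(max(2 * target, 256), max_draws - drawn))
        h1 = rng.choice(4, size=batch, p=hap_freqs)
        h2 = rng.choice(4, size=batch, p=hap_freqs)
        is_male = rng.random(batch) < cfg.sex_ratio
        u = rng.random(batch)
        drawn += batch

        dose1 = alt1[h1] + alt1[h2]
        dose2 = alt2[h1] + alt2[h2]
        odds = baseline_odds * _exposure_odds_factor(dose1, cfg)
        p_case = odds / (1 + odds)
        is_case = u < p_case

        for k in range(batch):
            bucket = cases if is_case[k] else controls
            quota = cfg.n_cases if is_case[k] else cfg.n_controls
            if len(bucket) >= quota:
                continue
            serial += 1
            bucket.append(
                Sample(
                    sample_id=f"S{serial:06d}",
                    group="case" if is_case[k] else "control",
                    sex="male" if is_male[k] else "female",
                    genotypes={
                        locus1.name: _gclass(dose1[k]),
                        locus2.name: _gclass(dose2[k]),
                    },
                )
            )
    return cases + controls


def _gclass(n_alt: int):
    from .genotype_data import GenotypeClass

    return GenotypeClass(int(n_alt))
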