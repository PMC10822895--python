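"""Two-locus analyses: combined genotypes, EM haplotype frequencies, LD.

For two biallelic loci the only phase-ambiguous genotype is the double
heterozygote, which is compatible with either the *cis* haplotype pair
(ref-ref + alt-alt) or the *trans* pair (ref-alt + alt-ref).  The EM
algorithm therefore reduces to iterating a single scalar: the fraction
``f`` of double heterozygotes resolved *cis*.  All other genotypes
contribute haplotypes by direct counting, so the estimated haplotype
frequencies always reproduce the observed allele frequencies exactly
(margin conservation), at every iteration.

Linkage disequilibrium is summarised by the raw coefficient
D = f(ref1,ref2) - p1 p2, its normalisation D' = |D| / D_max (with the
sign reported separately), and the squared allelic correlation
r^2 = D^2 / (p1 q1 p2 q2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import ModelResult, OddsRatioCI, Table2x2, chisq_yates, odds_ratio
from .genotype_data import GenotypeCounts, TwoLocusCounts

__all__ = [
    "HaplotypeEstimate",
    "LdStats",
    "EMConvergenceError",
    "combined_genotype_table",
    "combined_genotype_or",
    "ComboORResult",
    "em_haplotypes",
    "ld_stats",
    "haplotype_vs_rest_or",
    "TwoLocusHaplotype",
    "TwoLocusHaplotypeResults",
]


class EMConvergenceError(RuntimeError):
    """EM failed to converge; carries the log-likelihood trace."""

    def __init__(self, message: str, loglik_trace):
        super().__init__(message)
        self.loglik_trace = loglik_trace


@dataclass(frozen=True)
class HaplotypeEstimate:
    """EM-estimated four-haplotype frequencies for a locus pair.

    ``freqs`` and ``expected_counts`` are indexed by haplotype label in
    the fixed order (ref1 ref2, ref1 alt2, alt1 ref2, alt1 alt2) —
    e.g. CA, CC, TA, TC for the default loci.  ``freq_trace`` holds the
    frequency vector after every EM iteration (starting from the 50/50
    ambiguous split) so conservation properties can be checked per
    iteration.
    """

    labels: tuple
    freqs: np.ndarray
    expected_counts: np.ndarray
    loglik_trace: np.ndarray
    freq_trace: np.ndarray
    n_iter: int
    ambiguous_n: int

    def freq(self, label: str) -> float:
        return float(self.freqs[self.labels.index(label)])

    def as_dict(self) -> dict:
        return dict(zip(self.labels, map(float, self.freqs)))


@dataclass(frozen=True)
class LdStats:
    """Pairwise linkage-disequilibrium summary.

    ``d`` is the raw coefficient for the ref-ref haplotype, ``d_prime``
    the unsigned normalisation |D|/D_max in [0, 1] with the sign of D
    carried separately, and ``r2`` the squared allelic correlation.
    """

    d: float
    d_prime: float
    r2: float
    sign: int


def _hap_labels(t: TwoLocusCounts) -> tuple:
    r1, a1 = t.locus1.ref_allele, t.locus1.alt_allele
    r2, a2 = t.locus2.ref_allele, t.locus2.alt_allele
    return (r1 + r2, r1 + a2, a1 + r2, a1 + a2)


def combined_genotype_table(t: TwoLocusCounts) -> pd.DataFrame:
    """All nine two-locus genotype combinations with counts and percent
    of the group total, sorted by descending count."""
    rows = []
    n = t.n
    for i in range(3):
        for j in range(3):
            count = int(t.counts[i, j])
            rows.append(
                {
                    "combination": t.cell_label(i, j),
                    "count": count,
                    "percent": 100.0 * count / n if n else 0.0,
                }
            )
    df = pd.DataFrame(rows).sort_values(
        ["count", "combination"], ascending=[False, True], kind="mergesort"
    )
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class ComboORResult:
    """Combined-genotype vs all-others odds ratio, both orientations.

    ``risk`` is the odds of the combination among cases over controls;
    ``protective`` is its inverse (the orientation conventionally
    reported when the combination is under-represented in cases).
    """

    combo: str
    risk: OddsRatioCI
    protective: OddsRatioCI
    p_value: float
    table: Table2x2

    @property
    def reported(self) -> OddsRatioCI:
        """The >= 1 orientation, as association tables usually print."""
        if self.risk.undefined or self.risk.or_value >= 1:
            return self.risk
        return self.protective


def combined_genotype_or(
    cases: TwoLocusCounts,
    controls: TwoLocusCounts,
    combo: str,
    correction: str = "none",
) -> ComboORResult:
    """Odds ratio of one genotype combination versus all others pooled."""
    cells = {cases.cell_label(i, j): (i, j) for i in range(3) for j in range(3)}
    if combo not in cells:
        raise KeyError(f"unknown combination {combo!r}; expected one of {sorted(cells)}")
    i, j = cells[combo]
    a = int(cases.counts[i, j])
    b = int(controls.counts[i, j])
    c = cases.n - a
    d = controls.n - b
    t = Table2x2(a, b, c, d)
    risk = odds_ratio(t, correction)
    try:
        _, p = chisq_yates(t)
    except ValueError:
        from .association import fisher_exact

        p = fisher_exact(t)
    return ComboORResult(combo=combo, risk=risk, protective=risk.inverted(), p_value=p, table=t)


# ---------------------------------------------------------------------------
# EM haplotype estimation


def _base_hap_counts(grid: np.ndarray) -> np.ndarray:
    """Haplotype counts contributed by the eight unambiguous cells.

    Order: (r1r2, r1a2, a1r2, a1a2).  Each individual contributes two
    haplotypes; the double-heterozygote cell contributes nothing here.
    """
    g = np.asarray(grid, dtype=float)
    return np.array(
        [
            2 * g[0, 0] + g[0, 1] + g[1, 0],
            2 * g[0, 2] + g[0, 1] + g[1, 2],
            2 * g[2, 0] + g[2, 1] + g[1, 0],
            2 * g[2, 2] + g[2, 1] + g[1, 2],
        ]
    )


def _counts_at_split(grid: np.ndarray, f: float) -> np.ndarray:
    """Expected haplotype counts when a fraction ``f`` of double
    heterozygotes is resolved cis (r1r2 + a1a2)."""
    ndh = float(np.asarray(grid)[1, 1])
    return _base_hap_counts(grid) + ndh * np.array([f, 1 - f, 1 - f, f])


def genotype_loglik(grid: np.ndarray, freqs: Sequence[float]) -> float:
    """Multinomial log-likelihood of a 3x3 genotype grid under random
    union of gametes with the given haplotype frequencies."""
    p = np.asarray(freqs, dtype=float)
    h = {"rr": p[0], "ra": p[1], "ar": p[2], "aa": p[3]}
    probs = np.array(
        [
            [h["rr"] ** 2, 2 * h["rr"] * h["ra"], h["ra"] ** 2],
            [
                2 * h["rr"] * h["ar"],
                2 * (h["rr"] * h["aa"] + h["ra"] * h["ar"]),
                2 * h["ra"] * h["aa"],
            ],
            [h["ar"] ** 2, 2 * h["ar"] * h["aa"], h["aa"] ** 2],
        ]
    )
    g = np.asarray(grid, dtype=float)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    mask = g > 0
    if np.any(np.isneginf(logp[mask])):
        return -math.inf
    return float((g[mask] * logp[mask]).sum())


def em_haplotypes(
    t: TwoLocusCounts, tol: float = 1e-10, max_iter: int = 1000
) -> HaplotypeEstimate:
    """Maximum-likelihood haplotype frequencies by EM.

    E-step: split the ``2 * n_dhet`` ambiguous haplotypes between the
    cis (r1r2 + a1a2) and trans (r1a2 + a1r2) resolutions in proportion
    to the current frequency products.  M-step: renormalise counts.
    Iterates from an initial 50/50 split until the split fraction moves
    by less than ``tol``.  With no double heterozygotes the estimate is
    exact direct counting in a single iteration.
    """
    grid = t.counts
    n2 = 2.0 * t.n
    if n2 <= 0:
        raise ValueError("empty table: haplotype frequencies undefined")
    ndh = t.n_double_het
    labels = _hap_labels(t)

    f = 0.5
    freq_trace = []
    loglik_trace = []
    converged = ndh == 0
    n_iter = 0
    freqs = _counts_at_split(grid, f) / n2
    freq_trace.append(freqs)
    loglik_trace.append(genotype_loglik(grid, freqs))
    for n_iter in range(1, max_iter + 1):
        if ndh == 0:
            converged = True
            break
        cis = freqs[0] * freqs[3]
        trans = freqs[1] * freqs[2]
        f_new = 0.5 if cis + trans == 0 else cis / (cis + trans)
        freqs = _counts_at_split(grid, f_new) / n2
        freq_trace.append(freqs)
        loglik_trace.append(genotype_loglik(grid, freqs))
        if abs(f_new - f) < tol:
            converged = True
            f = f_new
            break
        f = f_new
    if not converged:
        raise EMConvergenceError(
            f"EM did not converge within {max_iter} iterations",
            np.asarray(loglik_trace),
        )
    return HaplotypeEstimate(
        labels=labels,
        freqs=freqs,
        expected_counts=freqs * n2,
        loglik_trace=np.asarray(loglik_trace),
        freq_trace=np.asarray(freq_trace),
        n_iter=n_iter,
        ambiguous_n=ndh,
    )


def ld_stats(
    h: HaplotypeEstimate, g1: GenotypeCounts, g2: GenotypeCounts
) -> LdStats:
    """LD statistics from haplotype frequencies and allele frequencies.

    D is computed for the ref-ref haplotype; D_max is
    min(p1 p2, q1 q2) when D < 0 and min(p1 q2, q1 p2) when D > 0,
    so D' = |D|/D_max lies in [0, 1].
    """
    from .association import allele_frequency

    p1, q1 = allele_frequency(g1)
    p2, q2 = allele_frequency(g2)
    if 0.0 in (p1, q1, p2, q2):
        raise ValueError("LD undefined for a monomorphic locus")
    # margins of the estimate must agree with the supplied counts
    if (
        abs(h.freqs[0] + h.freqs[1] - p1) > 1e-6
        or abs(h.freqs[0] + h.freqs[2] - p2) > 1e-6
    ):
        raise ValueError("haplotype margins inconsistent with genotype counts")
    d = float(h.freqs[0] - p1 * p2)
    if d == 0:
        return LdStats(d=0.0, d_prime=0.0, r2=0.0, sign=0)
    d_max = min(p1 * p2, q1 * q2) if d < 0 else min(p1 * q2, q1 * p2)
    return LdStats(
        d=d,
        d_prime=abs(d) / d_max,
        r2=d * d / (p1 * q1 * p2 * q2),
        sign=int(math.copysign(1, d)),
    )


def haplotype_vs_rest_or(
    case_counts: Sequence[float],
    control_counts: Sequence[float],
    hap: str,
    labels: Sequence[str] = ("CA", "CC", "TA", "TC"),
    correction: str = "none",
) -> ModelResult:
    """Odds ratio of one haplotype versus all others pooled, comparing
    case chromosomes with control chromosomes.

    Counts may be fractional (EM expected counts are used as-is in the
    OR and Woolf CI formulas).
    """
    ca = np.asarray(case_counts, dtype=float)
    co = np.asarray(control_counts, dtype=float)
    if ca.shape != (4,) or co.shape != (4,):
        raise ValueError("expected four haplotype counts per group")
    if (ca < 0).any() or (co < 0).any():
        raise ValueError("haplotype counts must be non-negative")
    idx = list(labels).index(hap)
    a = ca[idx]
    b = co[idx]
    c = ca.sum() - a
    d = co.sum() - b
    t = Table2x2(a, b, c, d)
    orci = odds_ratio(t, correction)
    try:
        _, p = chisq_yates(t)
        test = "chisq_yates"
    except ValueError:
        from .association import fisher_exact

        p = fisher_exact(t)
        test = "fisher"
    return ModelResult(
        model="haplotype",
        risk_class=hap,
        contrast=f"{hap} vs rest",
        or_value=orci.or_value,
        ci_low=orci.ci_low,
        ci_high=orci.ci_high,
        p_value=p,
        test_used=test,
        undefined_flag=orci.undefined,
        table=t,
    )


# ---------------------------------------------------------------------------
# model/results facade


class TwoLocusHaplotype:
    """Haplotype-frequency model for a two-locus genotype table.

    :meth:`fit` runs EM and returns a results object exposing the
    frequency estimates, the likelihood trace, LD statistics and a
    text summary.
    """

    def __init__(self, counts: TwoLocusCounts):
        self.counts = counts

    @classmethod
    def from_samples(cls, samples, locus1, locus2, group: Optional[str] = None):
        from .genotype_data import tabulate_pair

        return cls(tabulate_pair(samples, locus1, locus2, group=group)["all"])

    def fit(self, tol: float = 1e-10, max_iter: int = 1000) -> "TwoLocusHaplotypeResults":
        est = em_haplotypes(self.counts, tol=tol, max_iter=max_iter)
        return TwoLocusHaplotypeResults(model=self, estimate=est)


@dataclass
class TwoLocusHaplotypeResults:
    model: TwoLocusHaplotype
    estimate: HaplotypeEstimate

    def ld(self) -> LdStats:
        t = self.model.counts
        return ld_stats(self.estimate, t.margin1(), t.margin2())

    def to_frame(self) -> pd.DataFrame:
        est = self.estimate
        return pd.DataFrame(
            {
                "haplotype": est.labels,
                "frequency": est.freqs,
                "expected_count": est.expected_counts,
            }
        )

    def summary(self) -> str:
        est = self.estimate
        t = self.model.counts
        ld = self.ld()
        lines = [
            f"EM haplotype frequencies: {t.locus1.name} x {t.locus2.name} "
            f"(n={t.n}, {est.ambiguous_n} double heterozygotes, "
            f"{est.n_iter} iterations)",
        ]
        for label, freq, cnt in zip(est.labels, est.freqs, est.expected_counts):
            lines.append(f"  {label}: freq={freq:.4f}  expected count={cnt:.2f}")
        lines.append(
            f"  LD: D={ld.d:+.5f}  D'={ld.d_prime:.2f}  r2={ld.r2:.5f}  "
            f"sign={ld.sign:+d}"
        )
        return "\n".join(lines)
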