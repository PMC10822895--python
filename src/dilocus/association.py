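"""Single-locus case-control statistics.

Implements the classical toolkit for a biallelic SNP in a case-control
design: allele frequencies, the Pearson chi-square test of
Hardy-Weinberg equilibrium, 2x2 association tests (Yates-corrected
chi-square, Fisher's exact test), odds ratios with Woolf (log-normal)
confidence intervals, and the four standard genetic models —
codominant, dominant, recessive and overdominant.

The odds-ratio orientation convention: each 2x2 is laid out with the
*exposed* (risk) genotype class as row 1 and cases as column 1, so the
reported OR is the odds of carrying the risk class among cases over
controls.  Which side of the genotype spectrum is "exposed" is chosen
with ``risk_allele``: ``"ref"`` treats the reference-allele class as
the exposure (appropriate when the wild-type allele is the risk
allele, as in folate-pathway variants where the variant allele is
protective), ``"alt"`` the conventional variant-carrier exposure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_data import GenotypeCounts

__all__ = [
    "Table2x2",
    "OddsRatioCI",
    "ModelResult",
    "HweResult",
    "Z_95",
    "allele_frequency",
    "hwe_test",
    "odds_ratio",
    "chisq_pearson",
    "chisq_yates",
    "fisher_exact",
    "genetic_models",
    "CaseControlSNP",
    "CaseControlSNPResults",
]

#: 97.5% standard-normal quantile used in every 95% Woolf interval.
Z_95 = 1.959964

MODELS = ("codominant", "dominant", "recessive", "overdominant")


@dataclass(frozen=True)
class Table2x2:
    """2x2 count table: rows = genotype classes, columns = groups.

    ``a`` = class-1 cases, ``b`` = class-1 controls, ``c`` = class-2
    cases, ``d`` = class-2 controls.  The cross-product ``ad/bc`` is the
    odds of class-1 membership in cases relative to controls.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("table cells must be non-negative")
        if self.a + self.b + self.c + self.d <= 0:
            raise ValueError("table must contain at least one observation")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swapped_rows(self) -> "Table2x2":
        return Table2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class OddsRatioCI:
    """Odds ratio with a 95% Woolf confidence interval.

    ``undefined`` is set when a zero cell makes the OR (or its CI)
    undefined without a continuity correction; the numeric fields are
    then NaN.
    """

    or_value: float
    ci_low: float
    ci_high: float
    undefined: bool = False

    def inverted(self) -> "OddsRatioCI":
        if self.undefined:
            return self
        return OddsRatioCI(1 / self.or_value, 1 / self.ci_high, 1 / self.ci_low)


@dataclass(frozen=True)
class ModelResult:
    """One genetic-model (or class-vs-rest) comparison."""

    model: str
    risk_class: str
    contrast: str
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    test_used: str
    undefined_flag: bool = False
    table: Optional[Table2x2] = None


@dataclass(frozen=True)
class HweResult:
    """Pearson chi-square test of Hardy-Weinberg proportions (df = 1)."""

    chi2: float
    df: int
    p_value: float
    expected: tuple


def allele_frequency(g: GenotypeCounts) -> tuple[float, float]:
    """Reference- and alternate-allele frequencies from genotype counts."""
    if g.n == 0:
        raise ValueError("allele frequency undefined for an empty table")
    p_ref = g.ref_allele_count / (2 * g.n)
    return p_ref, 1.0 - p_ref


def hwe_test(g: GenotypeCounts) -> HweResult:
    """Pearson chi-square goodness-of-fit to Hardy-Weinberg proportions.

    Expected counts are n(p^2, 2pq, q^2) with p the observed
    reference-allele frequency; one degree of freedom (one estimated
    allele frequency).  Undefined for a monomorphic sample.
    """
    if g.n == 0:
        raise ValueError("HWE test undefined for an empty table")
    p, q = allele_frequency(g)
    if p == 0.0 or q == 0.0:
        raise ValueError("HWE test undefined for a monomorphic locus")
    expected = g.n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((g.as_array() - expected) ** 2 / expected).sum())
    return HweResult(
        chi2=chi2,
        df=1,
        p_value=float(stats.chi2.sf(chi2, 1)),
        expected=tuple(expected),
    )


def odds_ratio(t: Table2x2, correction: str = "none") -> OddsRatioCI:
    """Cross-product odds ratio with a 95% Woolf log-interval.

    CI = exp(ln OR +/- z sqrt(1/a + 1/b + 1/c + 1/d)), z = 1.959964.
    With ``correction="haldane"`` 0.5 is added to every cell before both
    the OR and the CI (Haldane-Anscombe); with ``"none"`` any zero cell
    yields an undefined result.
    """
    if correction not in ("none", "haldane"):
        raise ValueError(f"unknown correction {correction!r}")
    a, b, c, d = t.a, t.b, t.c, t.d
    if correction == "haldane":
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        return OddsRatioCI(math.nan, math.nan, math.nan, undefined=True)
    or_value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioCI(
        or_value=or_value,
        ci_low=or_value * math.exp(-Z_95 * se),
        ci_high=or_value * math.exp(Z_95 * se),
    )


def _margins(t: Table2x2):
    return (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d)


def chisq_pearson(t: Table2x2) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2x2 table (df 1)."""
    r1, r2, c1, c2 = _margins(t)
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined with a zero margin")
    n = r1 + r2
    chi2 = n * (t.a * t.d - t.b * t.c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def chisq_yates(t: Table2x2) -> tuple[float, float]:
    """Yates continuity-corrected chi-square on a 2x2 table (df 1).

    chi2 = N (|ad - bc| - N/2)^2 / (R1 R2 C1 C2), with the continuity
    term clamped at zero so it never overshoots past the null.
    """
    r1, r2, c1, c2 = _margins(t)
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined with a zero margin")
    n = r1 + r2
    num = max(abs(t.a * t.d - t.b * t.c) - n / 2, 0.0)
    chi2 = n * num**2 / (r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def fisher_exact(t: Table2x2) -> float:
    """Two-sided Fisher exact p: total hypergeometric probability of all
    tables with the observed margins no more probable than the observed
    table."""
    _, p = stats.fisher_exact(np.round(t.as_array()).astype(int), alternative="two-sided")
    return float(p)


def _check_small_expected(t: Table2x2) -> None:
    r1, r2, c1, c2 = _margins(t)
    n = r1 + r2
    expected = np.outer([r1, r2], [c1, c2]) / n
    if (expected < 5).any():
        warnings.warn(
            "a 2x2 expected cell is < 5; consider fisher_exact", stacklevel=3
        )


def _model_2x2(
    cases: GenotypeCounts,
    controls: GenotypeCounts,
    class1: Sequence[int],
    class2: Sequence[int],
) -> Table2x2:
    ca, co = cases.as_array(), controls.as_array()
    return Table2x2(
        int(ca[list(class1)].sum()),
        int(co[list(class1)].sum()),
        int(ca[list(class2)].sum()),
        int(co[list(class2)].sum()),
    )


def genetic_models(
    cases: GenotypeCounts,
    controls: GenotypeCounts,
    risk_allele: str = "ref",
    correction: str = "none",
) -> list[ModelResult]:
    """The four genetic-model analyses for one locus.

    Genotype classes are collapsed into 2x2 tables as

    ======================  =======================================
    codominant              het vs hom, and hom-alt vs hom (two ORs
                            sharing one joint Pearson chi-square p on
                            the full 2x3 table, df 2)
    dominant                hom-ref vs (het + hom-alt)
    recessive               (hom-ref + het) vs hom-alt
    overdominant            (hom-ref + hom-alt) vs het
    ======================  =======================================

    With ``risk_allele="ref"`` the class on the reference-allele side of
    each split is the exposure (row 1); with ``"alt"`` the variant-side
    class is.  2x2 p-values use the Yates-corrected chi-square.
    """
    if cases.locus.name != controls.locus.name:
        raise ValueError("case and control counts refer to different loci")
    if risk_allele not in ("ref", "alt"):
        raise ValueError("risk_allele must be 'ref' or 'alt'")
    locus = cases.locus
    lab = locus.genotype_label
    from .genotype_data import GenotypeClass as G

    results: list[ModelResult] = []

    # codominant: joint Pearson chi-square on the 2x3 genotype x group table
    # (genotype classes absent from both groups are dropped, reducing df)
    table23 = np.vstack([cases.as_array(), controls.as_array()])
    table23 = table23[:, table23.sum(axis=0) > 0]
    chi2_23, p_codom, _, _ = stats.chi2_contingency(table23, correction=False)
    for other in (1, 2):  # het, hom-alt each against hom-ref
        ref_side, var_side = [0], [other]
        class1, class2 = (ref_side, var_side) if risk_allele == "ref" else (var_side, ref_side)
        t = _model_2x2(cases, controls, class1, class2)
        orci = odds_ratio(t, correction)
        results.append(
            ModelResult(
                model="codominant",
                risk_class=_class_label(lab, class1),
                contrast=f"{_class_label(lab, class1)} vs {_class_label(lab, class2)}",
                or_value=orci.or_value,
                ci_low=orci.ci_low,
                ci_high=orci.ci_high,
                p_value=float(p_codom),
                test_used="chisq_pearson",
                undefined_flag=orci.undefined,
                table=t,
            )
        )

    splits = {
        "dominant": ([0], [1, 2]),
        "recessive": ([0, 1], [2]),
        "overdominant": ([0, 2], [1]),
    }
    for model, (ref_side, var_side) in splits.items():
        class1, class2 = (ref_side, var_side) if risk_allele == "ref" else (var_side, ref_side)
        t = _model_2x2(cases, controls, class1, class2)
        orci = odds_ratio(t, correction)
        try:
            _check_small_expected(t)
            _, p = chisq_yates(t)
            test = "chisq_yates"
        except ValueError:  # zero margin: fall back to the exact test
            p = fisher_exact(t)
            test = "fisher"
        results.append(
            ModelResult(
                model=model,
                risk_class=_class_label(lab, class1),
                contrast=f"{_class_label(lab, class1)} vs {_class_label(lab, class2)}",
                or_value=orci.or_value,
                ci_low=orci.ci_low,
                ci_high=orci.ci_high,
                p_value=p,
                test_used=test,
                undefined_flag=orci.undefined,
                table=t,
            )
        )
    return results


def _class_label(lab, classes) -> str:
    from .genotype_data import GenotypeClass as G

    return "+".join(lab(G(i)) for i in classes)


# ---------------------------------------------------------------------------
# model/results facade


class CaseControlSNP:
    """Case-control association model for one biallelic SNP.

    Built from genotype counts in each group; :meth:`fit` evaluates
    allele frequencies, Hardy-Weinberg equilibrium per group and the
    four genetic models, returning a :class:`CaseControlSNPResults`.

    Examples
    --------
    >>> from dilocus import datasets
    >>> cohort = datasets.load_mthfr_rectal_cohort()
    >>> res = CaseControlSNP(cohort.genotype_counts("MTHFR C677T", "patients"),
    ...                      cohort.genotype_counts("MTHFR C677T", "controls")).fit()
    >>> round(res.models[2].or_value, 2)   # dominant model
    2.27
    """

    def __init__(self, cases: GenotypeCounts, controls: GenotypeCounts):
        if cases.locus.name != controls.locus.name:
            raise ValueError("case and control counts refer to different loci")
        self.cases = cases
        self.controls = controls
        self.locus = cases.locus

    @classmethod
    def from_samples(cls, samples, locus, group_cases="case", group_controls="control"):
        from .genotype_data import tabulate

        cases = tabulate(samples, locus, group=group_cases)["all"]
        controls = tabulate(samples, locus, group=group_controls)["all"]
        return cls(cases, controls)

    def fit(self, risk_allele: str = "ref", correction: str = "none") -> "CaseControlSNPResults":
        models = genetic_models(self.cases, self.controls, risk_allele, correction)
        hwe = {}
        for label, g in (("cases", self.cases), ("controls", self.controls)):
            try:
                hwe[label] = hwe_test(g)
            except ValueError:
                hwe[label] = None
        return CaseControlSNPResults(
            model=self,
            models=models,
            allele_freqs={
                "cases": allele_frequency(self.cases),
                "controls": allele_frequency(self.controls),
            },
            hwe=hwe,
            risk_allele=risk_allele,
        )


@dataclass
class CaseControlSNPResults:
    """Fitted single-SNP association results."""

    model: CaseControlSNP
    models: list[ModelResult]
    allele_freqs: dict
    hwe: dict
    risk_allele: str

    def model_result(
        self, name: str, contrast: Optional[str] = None
    ) -> ModelResult:
        hits = [
            m
            for m in self.models
            if m.model == name and (contrast is None or contrast in m.contrast)
        ]
        if not hits:
            raise KeyError(f"no {name} result" + (f" for class {risk_class}" if risk_class else ""))
        return hits[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            rows.append(
                {
                    "model": m.model,
                    "risk_class": m.risk_class,
                    "contrast": m.contrast,
                    "OR": m.or_value,
                    "ci_low": m.ci_low,
                    "ci_high": m.ci_high,
                    "p_value": m.p_value,
                    "test": m.test_used,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        locus = self.model.locus
        lines = [
            f"Case-control association: {locus.name} ({locus.rsid})",
            f"  cases n={self.model.cases.n}, controls n={self.model.controls.n}",
        ]
        for label in ("cases", "controls"):
            p_ref, p_alt = self.allele_freqs[label]
            h = self.hwe[label]
            hwe_txt = (
                f"HWE chi2={h.chi2:.2f}, p={h.p_value:.3f}" if h else "HWE: undefined"
            )
            lines.append(
                f"  {label}: {locus.ref_allele}={p_ref:.2f} "
                f"{locus.alt_allele}={p_alt:.2f}; {hwe_txt}"
            )
        lines.append(f"  risk class orientation: {self.risk_allele} allele side")
        for m in self.models:
            if m.undefined_flag:
                or_txt = "NA"
            else:
                or_txt = f"{m.or_value:.2f} ({m.ci_low:.2f}-{m.ci_high:.2f})"
            lines.append(
                f"  {m.model:<12s} {m.contrast:<15s} OR {or_txt:<22s} "
                f"p={m.p_value:.3f} [{m.test_used}]"
            )
        return "\n".join(lines)
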