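import numpy as np
import pytest

from dilocus import GenotypeClass, MTHFR_A1298C, MTHFR_C677T, Sample
from dilocus.datasets import load_mthfr_rectal_cohort


@pytest.fixture(scope="session")
def cohort():
    return load_mthfr_rectal_cohort()


@pytest.fixture
def loci():
    return MTHFR_C677T, MTHFR_A1298C


def samples_from_grid(grid, group="case", locus1=MTHFR_C677T, locus2=MTHFR_A1298C,
                      sex="unknown", trg=None, prefix="S"):
    """Expand a 3x3 genotype grid into individual Sample objects."""
    grid = np.asarray(grid)
    samples = []
    k = 0
    for i in range(3):
        for j in range(3):
            for _ in range(int(grid[i, j])):
                k += 1
                samples.append(
                    Sample(
                        sample_id=f"{prefix}{k:04d}",
                        group=group,
                        sex=sex,
                        trg=trg,
                        genotypes={
                            locus1.name: GenotypeClass(i),
                            locus2.name: GenotypeClass(j),
                        },
                    )
                )
    return samples


def em_grid_oracle(grid, n_grid=20001):
    """Independent maximum-likelihood oracle for the EM estimator.

    Dense grid search over the cis-resolution fraction of the double
    heterozygotes, maximizing the multinomial genotype log-likelihood,
    followed by a local golden-section refinement.  Shares no code with
    the EM iteration.
    """
    from scipy.optimize import minimize_scalar

    grid = np.asarray(grid, dtype=float)
    n2 = 2 * grid.sum()
    ndh = grid[1, 1]
    base = np.array(
        [
            2 * grid[0, 0] + grid[0, 1] + grid[1, 0],
            2 * grid[0, 2] + grid[0, 1] + grid[1, 2],
            2 * grid[2, 0] + grid[2, 1] + grid[1, 0],
            2 * grid[2, 2] + grid[2, 1] + grid[1, 2],
        ]
    )

    def freqs_at(f):
        return (base + ndh * np.array([f, 1 - f, 1 - f, f])) / n2

    def negll(f):
        p = freqs_at(f)
        rr, ra, ar, aa = p
        probs = np.array(
            [
                [rr**2, 2 * rr * ra, ra**2],
                [2 * rr * ar, 2 * (rr * aa + ra * ar), 2 * ra * aa],
                [ar**2, 2 * ar * aa, aa**2],
            ]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(grid > 0, grid * np.log(probs), 0.0)
        if not np.isfinite(ll).all():
            return np.inf
        return -ll.sum()

    if ndh == 0:
        return freqs_at(0.5)
    fs = np.linspace(0.0, 1.0, n_grid)
    vals = np.array([negll(f) for f in fs])
    best = fs[np.argmin(vals)]
    lo = max(0.0, best - 2 / n_grid)
    hi = min(1.0, best + 2 / n_grid)
    res = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-14})
    f_opt = res.x if res.fun <= vals.min() else best
    return freqs_at(f_opt)


def fisher_enumeration_oracle(a, b, c, d):
    """Brute-force two-sided Fisher exact p by full enumeration of the
    hypergeometric support at the observed margins."""
    from math import comb

    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, c1)
    probs = {
        x: comb(r1, x) * comb(n - r1, c1 - x) / denom for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
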