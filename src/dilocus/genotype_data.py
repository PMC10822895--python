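"""Domain types and I/O for two-locus diploid genotype data.

Genotypes are unordered allele pairs; input order never carries phase
(phase information enters the pipeline only through EM haplotype
estimation).  Internally a diploid genotype is one of three classes —
homozygous reference, heterozygous, homozygous alternate — interpreted
against a :class:`LocusDef`.

The sample TSV dialect used throughout the package is:
columns ``sample_id, group, sex, trg`` followed by one column per locus
(named by the locus name), tab-separated, ``NA`` or empty = missing,
lines starting with ``#`` are comments.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeClass",
    "LocusDef",
    "Sample",
    "GenotypeCounts",
    "TwoLocusCounts",
    "MTHFR_C677T",
    "MTHFR_A1298C",
    "DEFAULT_LOCI",
    "read_samples_tsv",
    "write_samples_tsv",
    "read_vcf_two_snps",
    "call_genotype_from_fragments",
    "tabulate",
    "tabulate_pair",
    "validate_margins",
    "read_genotype_counts_tsv",
    "write_genotype_counts_tsv",
    "read_two_locus_counts_tsv",
    "write_two_locus_counts_tsv",
]


class GenotypeClass(enum.Enum):
    """Diploid genotype class at a biallelic locus."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


class GenotypeError(ValueError):
    """Raised for malformed or uninterpretable genotype input."""


@dataclass(frozen=True)
class LocusDef:
    """A biallelic SNP: identity, allele labels and RFLP fragment signature.

    Parameters
    ----------
    name : str
        Free-text locus name, e.g. ``"MTHFR C677T"``; used as the column
        header in sample TSVs.
    rsid : str
        dbSNP identifier, used to locate the variant in a VCF.
    ref_allele, alt_allele : str
        Single-character allele labels; must differ.
    fragment_map : mapping
        Restriction-fragment signature per genotype class: each of the
        three diploid genotypes maps to the set of fragment lengths (bp)
        its digest produces.  The three sets must be non-empty and
        mutually distinct so every clean digest is decodable.
    """

    name: str
    rsid: str
    ref_allele: str
    alt_allele: str
    fragment_map: Mapping[GenotypeClass, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.name}: ref and alt alleles must differ")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"{self.name}: allele labels must be single characters")
        if self.fragment_map:
            if set(self.fragment_map) != set(GenotypeClass):
                raise ValueError(
                    f"{self.name}: fragment_map must have exactly the three "
                    "genotype classes as keys"
                )
            sets = [frozenset(v) for v in self.fragment_map.values()]
            if any(not s for s in sets):
                raise ValueError(f"{self.name}: empty fragment set")
            if len(set(sets)) != 3:
                raise ValueError(f"{self.name}: fragment sets must be distinct")
            object.__setattr__(
                self,
                "fragment_map",
                {k: frozenset(v) for k, v in self.fragment_map.items()},
            )

    def genotype_label(self, gclass: GenotypeClass) -> str:
        """Two-letter label, e.g. ``CT`` for the heterozygote."""
        r, a = self.ref_allele, self.alt_allele
        return {
            GenotypeClass.HOM_REF: r + r,
            GenotypeClass.HET: r + a,
            GenotypeClass.HOM_ALT: a + a,
        }[gclass]

    def parse_genotype(self, text: str) -> GenotypeClass:
        """Parse a two-character allele string (either order, ``/`` allowed)."""
        alleles = sorted(text.replace("/", "").strip().upper())
        if len(alleles) != 2 or any(
            al not in (self.ref_allele, self.alt_allele) for al in alleles
        ):
            raise GenotypeError(
                f"cannot parse genotype {text!r} at {self.name} "
                f"(alleles {self.ref_allele}/{self.alt_allele})"
            )
        n_alt = sum(al == self.alt_allele for al in alleles)
        return GenotypeClass(n_alt)


# The two default loci with their published restriction-digest signatures.
# First locus: HinfI digest of a 198 bp amplicon (T allele cut into 175+23).
MTHFR_C677T = LocusDef(
    name="MTHFR C677T",
    rsid="rs1801133",
    ref_allele="C",
    alt_allele="T",
    fragment_map={
        GenotypeClass.HOM_REF: frozenset({198}),
        GenotypeClass.HET: frozenset({198, 175, 23}),
        GenotypeClass.HOM_ALT: frozenset({175, 23}),
    },
)

# Second locus: MboII digest of a 163 bp amplicon; the A allele yields
# 84+31+30+18, the C allele 56+31+30+28+18; the heterozygote shows the union.
MTHFR_A1298C = LocusDef(
    name="MTHFR A1298C",
    rsid="rs1801131",
    ref_allele="A",
    alt_allele="C",
    fragment_map={
        GenotypeClass.HOM_REF: frozenset({84, 31, 30, 18}),
        GenotypeClass.HET: frozenset({84, 56, 31, 30, 28, 18}),
        GenotypeClass.HOM_ALT: frozenset({56, 31, 30, 28, 18}),
    },
)

DEFAULT_LOCI = (MTHFR_C677T, MTHFR_A1298C)


@dataclass
class Sample:
    """One subject: case/control status, sex, optional tumor-regression grade
    (Mandard 1-5; only cases can carry one) and a genotype per locus."""

    sample_id: str
    group: str  # "case" | "control"
    sex: str = "unknown"  # "male" | "female" | "unknown"
    trg: Optional[int] = None
    genotypes: dict = field(default_factory=dict)  # locus name -> GenotypeClass | None

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValueError(f"{self.sample_id}: group must be case/control")
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"{self.sample_id}: bad sex {self.sex!r}")
        if self.trg is not None:
            if self.group != "case":
                raise ValueError(
                    f"{self.sample_id}: TRG given for a control (controls have no tumor)"
                )
            if not 1 <= int(self.trg) <= 5:
                raise ValueError(f"{self.sample_id}: TRG must be 1-5")

    @property
    def response(self) -> Optional[str]:
        """``responder`` (TRG 1-2), ``non-responder`` (TRG 3-5) or None."""
        if self.trg is None:
            return None
        return "responder" if self.trg <= 2 else "non-responder"


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts (hom-ref, het, hom-alt) for one locus in one group."""

    locus: LocusDef
    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def ref_allele_count(self) -> int:
        return 2 * self.n_hom_ref + self.n_het

    @property
    def alt_allele_count(self) -> int:
        return 2 * self.n_hom_alt + self.n_het

    def as_array(self) -> np.ndarray:
        return np.array([self.n_hom_ref, self.n_het, self.n_hom_alt])


@dataclass(frozen=True)
class TwoLocusCounts:
    """3x3 joint genotype counts for a locus pair in one group.

    ``counts[i, j]`` is the number of individuals with genotype class
    ``i`` at ``locus1`` and class ``j`` at ``locus2`` (0 = hom-ref,
    1 = het, 2 = hom-alt).
    """

    locus1: LocusDef
    locus2: LocusDef
    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3):
            raise ValueError("two-locus counts must form a 3x3 grid")
        if (arr < 0).any():
            raise ValueError("two-locus counts must be non-negative")
        object.__setattr__(self, "counts", arr.astype(int))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_double_het(self) -> int:
        return int(self.counts[1, 1])

    def margin1(self) -> GenotypeCounts:
        r = self.counts.sum(axis=1)
        return GenotypeCounts(self.locus1, int(r[0]), int(r[1]), int(r[2]))

    def margin2(self) -> GenotypeCounts:
        c = self.counts.sum(axis=0)
        return GenotypeCounts(self.locus2, int(c[0]), int(c[1]), int(c[2]))

    def cell_label(self, i: int, j: int) -> str:
        return (
            f"{self.locus1.genotype_label(GenotypeClass(i))}/"
            f"{self.locus2.genotype_label(GenotypeClass(j))}"
        )


# ---------------------------------------------------------------------------
# sample-level I/O

_FIXED_COLUMNS = ["sample_id", "group", "sex", "trg"]


def read_samples_tsv(path, loci: Sequence[LocusDef] = DEFAULT_LOCI) -> list[Sample]:
    """Read a sample TSV into :class:`Sample` objects.

    Locus columns are matched to ``loci`` by name; an unrecognised extra
    column raises an error naming the column, and malformed genotype
    strings raise with the offending line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise GenotypeError(f"{path}: no samples parsed") from None
    if df.empty:
        raise GenotypeError(f"{path}: no samples parsed")
    by_name = {loc.name: loc for loc in loci}
    for col in df.columns:
        if col not in _FIXED_COLUMNS and col not in by_name:
            raise GenotypeError(f"{path}: unknown locus column {col!r}")
    missing = [c for c in _FIXED_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise GenotypeError(f"{path}: missing required column(s) {missing}")

    samples = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        trg_raw = row.get("trg")
        trg = None if _is_na(trg_raw) else int(float(trg_raw))
        genotypes = {}
        for name, locus in by_name.items():
            raw = row.get(name)
            if _is_na(raw):
                genotypes[name] = None
            else:
                try:
                    genotypes[name] = locus.parse_genotype(raw)
                except GenotypeError as exc:
                    raise GenotypeError(f"{path}:{lineno}: {exc}") from exc
        sex = row.get("sex")
        samples.append(
            Sample(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                sex="unknown" if _is_na(sex) else str(sex),
                trg=trg,
                genotypes=genotypes,
            )
        )
    return samples


def _is_na(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or (
        isinstance(value, str) and value.strip() in ("", "NA")
    )


def write_samples_tsv(
    samples: Iterable[Sample],
    path,
    loci: Sequence[LocusDef] = DEFAULT_LOCI,
    header_comments: Sequence[str] = (),
) -> None:
    """Write samples in the TSV dialect read by :func:`read_samples_tsv`."""
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "group": s.group,
            "sex": s.sex,
            "trg": "NA" if s.trg is None else str(s.trg),
        }
        for locus in loci:
            g = s.genotypes.get(locus.name)
            row[locus.name] = "NA" if g is None else locus.genotype_label(g)
        rows.append(row)
    df = pd.DataFrame(rows, columns=_FIXED_COLUMNS + [loc.name for loc in loci])
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_vcf_two_snps(path, loci: Sequence[LocusDef] = DEFAULT_LOCI) -> list[Sample]:
    """Read genotypes for the two loci from a VCF (4.x) by matching record
    IDs against each locus rsid.

    Phased separators are accepted and collapsed to unphased classes;
    multiallelic records are rejected.  Returned samples carry genotypes
    only (group/sex/TRG are not encoded in a VCF) with group set to
    ``control`` as a neutral placeholder.
    """
    import pysam

    by_rsid = {loc.rsid: loc for loc in loci}
    found: dict[str, dict[str, Optional[GenotypeClass]]] = {}
    seen_ids = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            seen_ids.append(rec.id)
            locus = by_rsid.get(rec.id)
            if locus is None:
                continue
            if rec.alts is None or len(rec.alts) != 1:
                raise GenotypeError(
                    f"{path}: record {rec.id} is not biallelic "
                    f"(ALT={rec.alts})"
                )
            calls = {}
            for name in sample_names:
                gt = rec.samples[name].get("GT")
                if gt is None or any(a is None for a in gt):
                    calls[name] = None
                else:
                    calls[name] = GenotypeClass(sum(gt))
            found[locus.name] = calls
    absent = [loc.rsid for loc in loci if loc.name not in found]
    if absent:
        raise GenotypeError(
            f"{path}: rsid(s) {absent} not found; record IDs present: {seen_ids}"
        )
    return [
        Sample(
            sample_id=name,
            group="control",
            genotypes={loc.name: found[loc.name][name] for loc in loci},
        )
        for name in sample_names
    ]


# ---------------------------------------------------------------------------
# RFLP genotype calling


def call_genotype_from_fragments(
    observed: Iterable[float], locus: LocusDef, tolerance: float = 2.0
) -> GenotypeClass:
    """Decode a restriction-digest band pattern into a genotype.

    A genotype matches when its nominal fragment set and the observed
    set pair off one-to-one within ``tolerance`` bp (sorted order); no
    extra or missing bands are allowed.  On-chip electrophoresis sizing
    is approximate, hence the default +/-2 bp.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    obs = sorted(observed)
    if not obs:
        raise GenotypeError("empty fragment set")
    matches = []
    for gclass, frags in locus.fragment_map.items():
        nominal = sorted(frags)
        if len(nominal) == len(obs) and all(
            abs(o - e) <= tolerance for o, e in zip(obs, nominal)
        ):
            matches.append(gclass)
    if not matches:
        raise GenotypeError(
            f"uninterpretable pattern {obs} at {locus.name} (tolerance {tolerance} bp)"
        )
    if len(matches) > 1:
        raise GenotypeError(
            f"ambiguous pattern {obs} at {locus.name}: matches "
            f"{[locus.genotype_label(m) for m in matches]}"
        )
    return matches[0]


# ---------------------------------------------------------------------------
# tabulation


def _strata(samples: Sequence[Sample], stratifier: Optional[str]):
    if stratifier in (None, "none"):
        return {"all": list(samples)}
    if stratifier == "sex":
        return {
            sex: [s for s in samples if s.sex == sex] for sex in ("male", "female")
        }
    if stratifier == "response":
        out = {"responder": [], "non-responder": []}
        for s in samples:
            if s.response is not None:
                out[s.response].append(s)
        return out
    raise ValueError(f"unknown stratifier {stratifier!r}")


def tabulate(
    samples: Sequence[Sample],
    locus: LocusDef,
    stratifier: Optional[str] = None,
    group: Optional[str] = None,
) -> dict[str, GenotypeCounts]:
    """Count genotypes at one locus, optionally restricted to ``group``
    (case/control) and split by ``sex`` or ``response``.

    Samples missing the genotype or the stratifying label are excluded
    from that stratum; exclusions are logged.  An empty stratum warns
    and returns zero counts.
    """
    pool = [s for s in samples if group is None or s.group == group]
    result = {}
    for label, members in _strata(pool, stratifier).items():
        counts = [0, 0, 0]
        excluded = 0
        for s in members:
            g = s.genotypes.get(locus.name)
            if g is None:
                excluded += 1
            else:
                counts[g.value] += 1
        if excluded:
            logger.info(
                "%s/%s: excluded %d sample(s) missing genotype at %s",
                group or "all", label, excluded, locus.name,
            )
        if sum(counts) == 0:
            logger.warning("empty stratum %s at %s", label, locus.name)
        result[label] = GenotypeCounts(locus, *counts)
    return result


def tabulate_pair(
    samples: Sequence[Sample],
    locus1: LocusDef,
    locus2: LocusDef,
    stratifier: Optional[str] = None,
    group: Optional[str] = None,
) -> dict[str, TwoLocusCounts]:
    """Joint 3x3 genotype counts for a locus pair, per stratum.

    Only samples genotyped at both loci contribute.
    """
    pool = [s for s in samples if group is None or s.group == group]
    result = {}
    for label, members in _strata(pool, stratifier).items():
        grid = np.zeros((3, 3), dtype=int)
        excluded = 0
        for s in members:
            g1 = s.genotypes.get(locus1.name)
            g2 = s.genotypes.get(locus2.name)
            if g1 is None or g2 is None:
                excluded += 1
            else:
                grid[g1.value, g2.value] += 1
        if excluded:
            logger.info(
                "%s/%s: excluded %d sample(s) missing a genotype",
                group or "all", label, excluded,
            )
        result[label] = TwoLocusCounts(locus1, locus2, grid)
    return result


def validate_margins(
    two_locus: TwoLocusCounts, g1: GenotypeCounts, g2: GenotypeCounts
) -> list[str]:
    """Check that the 3x3 grid's margins reproduce the single-locus counts.

    Returns a list of human-readable mismatch descriptions; an empty
    list means the three tables are mutually consistent.
    """
    report = []
    for margin, single, locus in (
        (two_locus.margin1(), g1, two_locus.locus1),
        (two_locus.margin2(), g2, two_locus.locus2),
    ):
        for gclass in GenotypeClass:
            got = margin.as_array()[gclass.value]
            want = single.as_array()[gclass.value]
            if got != want:
                report.append(
                    f"{locus.name} {locus.genotype_label(gclass)} margin: "
                    f"grid gives {got}, single-locus table gives {want}"
                )
    return report


# ---------------------------------------------------------------------------
# count-table I/O

_CLASS_ROWS = ["hom_ref", "het", "hom_alt"]


def write_genotype_counts_tsv(g: GenotypeCounts, path) -> None:
    pd.DataFrame(
        {"genotype": _CLASS_ROWS, "label": [g.locus.genotype_label(c) for c in GenotypeClass],
         "count": g.as_array()}
    ).to_csv(path, sep="\t", index=False)


def read_genotype_counts_tsv(path, locus: LocusDef) -> GenotypeCounts:
    df = pd.read_csv(path, sep="\t", comment="#")
    rows = dict(zip(df["genotype"], df["count"]))
    try:
        return GenotypeCounts(locus, *(int(rows[r]) for r in _CLASS_ROWS))
    except KeyError as exc:
        raise GenotypeError(f"{path}: missing genotype row {exc}") from exc


def write_two_locus_counts_tsv(t: TwoLocusCounts, path) -> None:
    labels1 = [t.locus1.genotype_label(c) for c in GenotypeClass]
    labels2 = [t.locus2.genotype_label(c) for c in GenotypeClass]
    pd.DataFrame(t.counts, index=labels1, columns=labels2).to_csv(
        path, sep="\t", index_label=f"{t.locus1.name}\\{t.locus2.name}"
    )


def read_two_locus_counts_tsv(path, locus1: LocusDef, locus2: LocusDef) -> TwoLocusCounts:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.shape != (3, 3):
        raise GenotypeError(f"{path}: expected a 3x3 count grid, got {df.shape}")
    return TwoLocusCounts(locus1, locus2, df.to_numpy())
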