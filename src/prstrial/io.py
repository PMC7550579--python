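"""Core containers and file formats.

The package moves genotypes around as an additive dosage matrix
(individuals x variants, values 0/1/2 with NaN for missing calls) plus
variant metadata, and persists them either as a PLINK 1 binary fileset
(.bed/.bim/.fam) or as a self-contained plain-text TSV dialect.  GWAS
summary statistics travel as a TSV with columns SNP/CHR/BP/A1/A2/OR/P,
trial cohorts as a long CSV with one row per individual-timepoint.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = np.nan

TIMEPOINTS = ("pre", "post", "followup")


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One biallelic marker. ``allele_counted`` is the allele the dosage counts."""

    id: str
    chromosome: str
    position: int  # 1-based bp
    allele_counted: str
    allele_other: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"variant {self.id}: position must be >= 1")
        if not self.allele_counted or not self.allele_other:
            raise ValueError(f"variant {self.id}: empty allele")
        if self.allele_counted == self.allele_other:
            raise ValueError(f"variant {self.id}: alleles must differ")


class GenotypeMatrix:
    """Additive genotype dosages with aligned individual and variant labels.

    ``dosage`` is an (n_individuals, n_variants) float array holding 0, 1, 2
    or NaN (missing).  Dosages count copies of each variant's
    ``allele_counted``.
    """

    def __init__(
        self,
        dosage: np.ndarray,
        individual_ids: Sequence[str],
        variants: Sequence[VariantRecord],
    ) -> None:
        dosage = np.asarray(dosage, dtype=float)
        if dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x variants)")
        if dosage.shape != (len(individual_ids), len(variants)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(individual_ids)} individuals x {len(variants)} variants"
            )
        if len(set(individual_ids)) != len(individual_ids):
            raise ValueError("duplicate individual ids")
        vids = [v.id for v in variants]
        if len(set(vids)) != len(vids):
            raise ValueError("duplicate variant ids")
        ok = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        self.dosage = dosage
        self.individual_ids = list(individual_ids)
        self.variants = list(variants)

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self) -> dict[str, int]:
        return {v.id: j for j, v in enumerate(self.variants)}

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosage.copy(), list(self.individual_ids), list(self.variants)
        )

    def subset(
        self,
        individuals: Iterable[int] | None = None,
        variants: Iterable[int] | None = None,
    ) -> "GenotypeMatrix":
        irows = np.arange(self.n_individuals) if individuals is None else np.asarray(
            list(individuals), dtype=int
        )
        jcols = np.arange(self.n_variants) if variants is None else np.asarray(
            list(variants), dtype=int
        )
        return GenotypeMatrix(
            self.dosage[np.ix_(irows, jcols)],
            [self.individual_ids[i] for i in irows],
            [self.variants[j] for j in jcols],
        )

    # -- summaries used by QC and scoring -------------------------------
    def allele_counts(self) -> np.ndarray:
        """Per-variant genotype counts (n_hom_other, n_het, n_hom_counted)."""
        d = self.dosage
        return np.stack(
            [np.nansum(d == k, axis=0) for k in (0.0, 1.0, 2.0)], axis=1
        ).astype(int)

    def counted_allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.counted_allele_freq()
        return np.minimum(p, 1.0 - p)

    def marker_missingness(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def individual_missingness(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=1)

    def heterozygosity_rate(self) -> np.ndarray:
        """Per-individual fraction of heterozygous calls among non-missing calls."""
        het = (self.dosage == 1.0).sum(axis=1)
        called = (~np.isnan(self.dosage)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, het / called, np.nan)


# ---------------------------------------------------------------------------
# PLINK 1 binary fileset
# ---------------------------------------------------------------------------
# .bed: 3 magic bytes (0x6c, 0x1b, 0x01 = SNP-major), then for each variant
# ceil(n/4) bytes, 2 bits per individual, LSB first:
#   00 hom counted-allele(A1)=2 copies? -- PLINK convention: 00 = hom A1,
#   01 = missing, 10 = het, 11 = hom A2.  A1 in .bim column 5 is the allele
# counted by --recode A, so dosage(A1): 00 -> 2, 10 -> 1, 11 -> 0, 01 -> NaN.

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: MISSING, 0b10: 1.0, 0b11: 0.0}
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".fam"), "w") as fam:
        for iid in g.individual_ids:
            fam.write(f"{iid} {iid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as bim:
        for v in g.variants:
            bim.write(
                f"{v.chromosome}\t{v.id}\t0\t{v.position}\t{v.allele_counted}\t{v.allele_other}\n"
            )
    n = g.n_individuals
    nbytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as bed:
        bed.write(_BED_MAGIC)
        buf = bytearray(nbytes)
        for j in range(g.n_variants):
            col = g.dosage[:, j]
            for k in range(nbytes):
                buf[k] = 0
            for i in range(n):
                d = col[i]
                code = 0b01 if np.isnan(d) else _DOSAGE_TO_CODE[d]
                buf[i // 4] |= code << (2 * (i % 4))
            bed.write(buf)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str
    )
    individual_ids = fam.iloc[:, 1].tolist()
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None, dtype=str)
    variants = [
        VariantRecord(
            id=row[1],
            chromosome=str(row[0]),
            position=int(row[3]),
            allele_counted=row[4],
            allele_other=row[5],
        )
        for row in bim.itertuples(index=False)
    ]
    n, m = len(individual_ids), len(variants)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK 1 .bed file")
    nbytes = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != nbytes * m:
        raise ValueError(f"{prefix}.bed: unexpected size")
    body = body.reshape(m, nbytes)
    # unpack 2-bit codes, LSB first
    codes = np.stack(
        [(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(m, nbytes * 4)[:, :n]
    lut = np.array([2.0, MISSING, 1.0, 0.0])
    dosage = lut[codes].T
    return GenotypeMatrix(dosage, individual_ids, variants)


# ---------------------------------------------------------------------------
# Plain-text TSV dialect
# ---------------------------------------------------------------------------


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Single TSV: variant metadata columns then one dosage column per individual."""
    meta = pd.DataFrame(
        {
            "SNP": [v.id for v in g.variants],
            "CHR": [v.chromosome for v in g.variants],
            "BP": [v.position for v in g.variants],
            "A1": [v.allele_counted for v in g.variants],
            "A2": [v.allele_other for v in g.variants],
        }
    )
    dos = pd.DataFrame(g.dosage.T, columns=g.individual_ids)
    pd.concat([meta, dos], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "A1": str, "A2": str})
    variants = [
        VariantRecord(
            id=str(r.SNP),
            chromosome=str(r.CHR),
            position=int(r.BP),
            allele_counted=r.A1,
            allele_other=r.A2,
        )
        for r in df.itertuples(index=False)
    ]
    individual_ids = [c for c in df.columns if c not in ("SNP", "CHR", "BP", "A1", "A2")]
    dosage = df[individual_ids].to_numpy(dtype=float).T
    return GenotypeMatrix(dosage, individual_ids, variants)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


class SummaryStats:
    """Per-variant GWAS summary statistics: effect allele, OR, association P.

    Backed by a DataFrame with columns SNP, CHR, BP, A1 (effect allele),
    A2 (other allele), OR, P.
    """

    REQUIRED = ("SNP", "A1", "A2", "OR", "P")

    def __init__(self, table: pd.DataFrame) -> None:
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"summary stats missing columns: {missing}")
        if table["SNP"].duplicated().any():
            raise ValueError("duplicate variant ids in summary stats")
        if (table["OR"] <= 0).any():
            raise ValueError("odds ratios must be positive")
        if ((table["P"] <= 0) | (table["P"] > 1)).any():
            raise ValueError("P values must lie in (0, 1]")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def log_or(self) -> np.ndarray:
        return np.log(self.table["OR"].to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SummaryStats":
        return cls(pd.read_csv(path, sep="\t", dtype={"CHR": str, "A1": str, "A2": str}))


# ---------------------------------------------------------------------------
# Trial cohort
# ---------------------------------------------------------------------------

COHORT_INDIVIDUAL_COLS = [
    "id",
    "arm",
    "center",
    "age_group",
    "sex",
    "pc1",
    "pc2",
    "pc3",
    "pc4",
    "cnv_clinsig",
    "cnv_large",
    "adhd_comorbid",
]


class TrialCohort:
    """Two-arm longitudinal trial data.

    ``individuals``: one row per individual with arm (SSGT / standard_care),
    clinical center, age group, sex, four ancestry PCs, CNV carrier flags,
    ADHD comorbidity, optionally IQ and PRS z-score columns (``prs_<pheno>``).

    ``outcomes``: long table (id, timepoint, srs_total) with timepoint in
    {pre, post, followup}; every individual has a pre record, dropouts simply
    lack later rows.
    """

    def __init__(self, individuals: pd.DataFrame, outcomes: pd.DataFrame) -> None:
        for c in COHORT_INDIVIDUAL_COLS:
            if c not in individuals.columns:
                raise ValueError(f"cohort individuals table missing column {c!r}")
        if individuals["id"].duplicated().any():
            raise ValueError("duplicate individual ids")
        bad_tp = set(outcomes["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoints {sorted(bad_tp)}")
        if outcomes.duplicated(["id", "timepoint"]).any():
            raise ValueError("duplicate (id, timepoint) outcome records")
        ids = set(individuals["id"])
        if not set(outcomes["id"]) <= ids:
            raise ValueError("outcome record for unknown individual")
        with_pre = set(outcomes.loc[outcomes["timepoint"] == "pre", "id"])
        if ids - with_pre:
            raise ValueError("every individual needs a pre-intervention record")
        srs = outcomes["srs_total"]
        if ((srs < 0) | (srs > 195)).any():
            raise ValueError("SRS totals must lie in [0, 195]")
        self.individuals = individuals.reset_index(drop=True)
        self.outcomes = outcomes.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def prs_columns(self) -> list[str]:
        return [c for c in self.individuals.columns if c.startswith("prs_")]

    def arm_counts(self) -> dict[str, int]:
        return self.individuals["arm"].value_counts().to_dict()

    def n_with_timepoint(self, timepoint: str) -> int:
        return int((self.outcomes["timepoint"] == timepoint).sum())

    def long_table(self) -> pd.DataFrame:
        """Outcome rows joined with individual-level covariates."""
        return self.outcomes.merge(self.individuals, on="id", validate="m:1")

    def with_prs(self, prs: pd.DataFrame) -> "TrialCohort":
        """Return a cohort whose individuals table gains ``prs_*`` columns.

        ``prs`` must be indexed by individual id (or carry an ``id`` column).
        """
        tab = prs.reset_index() if prs.index.name == "id" else prs.copy()
        if "id" not in tab.columns:
            raise ValueError("PRS table needs an 'id' column or index")
        merged = self.individuals.merge(tab, on="id", how="left", validate="1:1")
        return TrialCohort(merged, self.outcomes)

    def to_csv(self, path: str | Path) -> None:
        self.long_table().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialCohort":
        long = pd.read_csv(path, dtype={"id": str, "center": str})
        ind_cols = [c for c in long.columns if c not in ("timepoint", "srs_total")]
        individuals = long[ind_cols].drop_duplicates("id").reset_index(drop=True)
        outcomes = long[["id", "timepoint", "srs_total"]].copy()
        return cls(individuals, outcomes)


# ---------------------------------------------------------------------------
# Gene locations and gene sets
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """Gene span on a chromosome, 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def read_gene_locations(path: str | Path) -> list[GeneRecord]:
    """Whitespace table: gene_id, chromosome, start, end (MAGMA gene-loc layout)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            genes.append(
                GeneRecord(fields[0], str(fields[1]), int(fields[2]), int(fields[3]))
            )
    return genes


def write_gene_locations(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chromosome}\t{g.start}\t{g.end}\n")


class GeneSetCollection:
    """Named gene sets, each tagged with a category label."""

    def __init__(
        self, sets: dict[str, list[str]], categories: dict[str, str] | None = None
    ) -> None:
        for name, members in sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = dict(sets)
        self.categories = dict(categories or {})

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        """GMT: one set per line, tab-separated: name, description, genes..."""
        sets: dict[str, list[str]] = {}
        cats: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    continue
                name, desc, genes = fields[0], fields[1], fields[2:]
                sets[name] = [g for g in genes if g]
                if desc:
                    cats[name] = desc
        return cls(sets, cats)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.categories.get(name, "")
                fh.write("\t".join([name, desc, *members]) + "\n")


def write_json(obj, path: str | Path) -> None:
    class _Enc(json.JSONEncoder):
        def default(self, o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return super().default(o)

    Path(path).write_text(json.dumps(obj, indent=2, cls=_Enc))
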