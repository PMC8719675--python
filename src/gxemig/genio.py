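"""Cohort I/O and the canonical in-memory data model.

Genotypes travel as hard-call dosage matrices counted on a per-SNP *effect
allele*; the effect allele is fixed once, as the minor allele of the loaded
(total) sample, so that effect directions remain comparable when the same
SNP is re-analysed in subsamples.

Formats: PLINK text ``.ped``/``.map`` (whitespace-delimited, missing
genotype ``0``), a phenotype TSV (``IID  MIGR  DEPR  SEX  AGE  POP``), and
an association-result TSV mirroring PLINK's ``.assoc.logistic`` column set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")
MISSING_ALLELE = "0"

#: Phenotype TSV column order.  ``MIGR`` and ``DEPR`` are 0/1, ``SEX`` is
#: 1 (male) / 2 (female) as in PLINK, ``AGE`` is in years, ``POP`` is a
#: cohort label (e.g. ``BUD``/``MAN``).
PHENO_COLUMNS = ["IID", "MIGR", "DEPR", "SEX", "AGE", "POP"]

ASSOC_COLUMNS = [
    "CHR", "SNP", "BP", "A1", "TEST", "NMISS",
    "OR", "SE", "L95", "U95", "STAT", "P",
]


class ParseError(ValueError):
    """Raised when a genotype or phenotype file is malformed."""


@dataclass
class GenotypeMatrix:
    """Individuals × SNPs hard-call dosage matrix with SNP metadata.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_individuals, n_snps)`` holding counts of
        the effect allele in ``{0, 1, 2}``; missing calls are ``NaN``.
    snp_meta
        One row per SNP with columns ``snp_id``, ``chrom``, ``pos``
        (1-based), ``allele_a`` (effect allele) and ``allele_b``.
    individual_ids
        Unique identifiers, one per row of ``dosages``.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        n_ind, n_snp = self.dosages.shape
        if len(self.individual_ids) != n_ind:
            raise ValueError("individual_ids length does not match dosage rows")
        if len(self.snp_meta) != n_snp:
            raise ValueError("snp_meta length does not match dosage columns")
        if len(set(self.individual_ids)) != n_ind:
            raise ValueError("duplicate individual ids")
        if self.snp_meta["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        if (self.snp_meta["pos"] < 0).any():
            raise ValueError("negative SNP positions")
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(self.dosages) & ~np.isin(self.dosages, (0.0, 1.0, 2.0))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["snp_id"].to_numpy()

    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if idx.size == 0:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix")
        return int(idx[0])

    # -- summaries ------------------------------------------------------
    def allele_frequencies(self) -> np.ndarray:
        """Effect-allele frequency per SNP over non-missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def snp_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def individual_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    # -- subsetting -----------------------------------------------------
    def subset(
        self,
        individuals: np.ndarray | None = None,
        snps: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a copy restricted to boolean/integer index selections."""
        dos = self.dosages
        ids = self.individual_ids
        meta = self.snp_meta
        if individuals is not None:
            dos = dos[individuals, :]
            ids = ids[individuals]
        if snps is not None:
            dos = dos[:, snps]
            meta = meta.iloc[np.arange(self.n_snps)[snps]]
        return GenotypeMatrix(dos.copy(), meta.copy(), ids.copy())

    def select_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.snp_index(s) for s in snp_ids]
        return self.subset(snps=np.asarray(idx, dtype=int))


@dataclass(frozen=True)
class AssociationRecord:
    """One per-SNP regression result in one analysis sample.

    ``test`` is ``"ADD"`` for the additive main-effect term and
    ``"ADDxDEPR"`` for the SNP×depression interaction term.  ``flag`` is
    empty for a clean fit, or one of ``"nonconverged"``, ``"separation"``,
    ``"monomorphic"``, ``"hwe_excluded"``.
    """

    snp_id: str
    sample: str            # BUD / MAN / TOTAL
    test: str              # ADD / ADDxDEPR
    effect_allele: str
    chrom: str
    pos: int
    n_used: int
    beta: float
    se: float
    p: float
    flag: str = ""

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - 1.959963984540054 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + 1.959963984540054 * self.se))

    @property
    def ok(self) -> bool:
        return self.flag == ""


# ---------------------------------------------------------------------------
# PLINK text .ped/.map
# ---------------------------------------------------------------------------

def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            chrom, snp_id, _cm, pos = parts
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad position {pos!r}") from exc
            rows.append((chrom, snp_id, pos_i))
    return pd.DataFrame(rows, columns=["chrom", "snp_id", "pos"])


def read_ped_map(prefix: str | Path) -> GenotypeMatrix:
    """Load a text ``.ped``/``.map`` pair into a :class:`GenotypeMatrix`.

    The effect allele (``allele_a``) of each SNP is set to the minor allele
    of the loaded sample, ties broken lexicographically; dosages count that
    allele.  ``"0 0"`` genotypes become missing.
    """
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    for p in (map_path, ped_path):
        if not p.exists():
            raise FileNotFoundError(p)
    meta = _read_map(map_path)
    n_snps = len(meta)

    individual_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields "
                    f"for {n_snps} mapped SNPs, got {len(parts)}"
                )
            individual_ids.append(parts[1])
            alleles = np.array(parts[6:], dtype=object)
            bad = [a for a in alleles if a not in VALID_ALLELES and a != MISSING_ALLELE]
            if bad:
                raise ParseError(
                    f"{ped_path}:{lineno}: invalid allele {bad[0]!r} "
                    "(expected A/C/G/T or 0)"
                )
            allele_rows.append(alleles)
    if not allele_rows:
        raise ParseError(f"{ped_path}: no individuals")

    alle = np.stack(allele_rows)                      # (n_ind, 2*n_snps)
    a1, a2 = alle[:, 0::2], alle[:, 1::2]
    dosages = np.full((len(individual_ids), n_snps), np.nan)
    allele_a, allele_b = [], []
    for j in range(n_snps):
        col = np.concatenate([a1[:, j], a2[:, j]])
        observed = sorted(set(col) - {MISSING_ALLELE})
        if len(observed) > 2:
            raise ParseError(
                f"{ped_path}: SNP {meta['snp_id'][j]!r} has >2 alleles {observed}"
            )
        if not observed:
            eff, ref = MISSING_ALLELE, MISSING_ALLELE
        elif len(observed) == 1:
            # Monomorphic: the minor allele was never seen.
            eff, ref = MISSING_ALLELE, observed[0]
        else:
            counts = {a: int(np.sum(col == a)) for a in observed}
            # Minor allele; lexicographic tie-break (sorted order).
            eff = min(observed, key=lambda a: (counts[a], a))
            ref = observed[0] if observed[1] == eff else observed[1]
        allele_a.append(eff)
        allele_b.append(ref)
        miss = (a1[:, j] == MISSING_ALLELE) | (a2[:, j] == MISSING_ALLELE)
        dos = (a1[:, j] == eff).astype(float) + (a2[:, j] == eff).astype(float)
        dos[miss] = np.nan
        dosages[:, j] = dos

    meta = meta.assign(allele_a=allele_a, allele_b=allele_b)
    meta = meta[["snp_id", "chrom", "pos", "allele_a", "allele_b"]]
    return GenotypeMatrix(dosages, meta, np.array(individual_ids, dtype=object))


def write_ped_map(G: GenotypeMatrix, pheno: pd.DataFrame, prefix: str | Path) -> None:
    """Write a genotype matrix and phenotype table as ``.ped``/``.map``.

    The ``.ped`` sex column comes from ``pheno`` and the affection column
    encodes migraine status as 1 (control) / 2 (case).  Missing dosages are
    written as the PLINK missing genotype ``0 0``.
    """
    if G.n_individuals == 0:
        raise ValueError("cannot write a cohort with 0 individuals")
    pheno = pheno.set_index("IID", drop=False).loc[list(G.individual_ids)]
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    meta = G.snp_meta
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, row in meta.iterrows():
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\n")
    eff = meta["allele_a"].to_numpy()
    ref = meta["allele_b"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(G.individual_ids):
            sex = int(pheno.loc[iid, "SEX"])
            status = int(pheno.loc[iid, "MIGR"]) + 1
            fields = [str(iid), str(iid), "0", "0", str(sex), str(status)]
            row = G.dosages[i]
            for j in range(G.n_snps):
                d = row[j]
                if np.isnan(d):
                    fields += [MISSING_ALLELE, MISSING_ALLELE]
                elif d == 0:
                    fields += [ref[j], ref[j]]
                elif d == 1:
                    fields += [eff[j], ref[j]]
                else:
                    fields += [eff[j], eff[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Phenotype TSV
# ---------------------------------------------------------------------------

def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise ParseError(f"phenotype table missing columns {missing}")
    if pheno["IID"].duplicated().any():
        raise ParseError("duplicate individual ids in phenotype table")
    for col in ("MIGR", "DEPR"):
        if not pheno[col].isin((0, 1)).all():
            raise ParseError(f"{col} must be binary 0/1")
    if not pheno["SEX"].isin((1, 2)).all():
        raise ParseError("SEX must be 1/2")
    return pheno


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", dtype={"IID": str, "POP": str})
    return validate_phenotypes(pheno)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(pheno)
    pheno.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Association TSV (PLINK .assoc.logistic dialect)
# ---------------------------------------------------------------------------

def write_assoc(records: Iterable[AssociationRecord], path: str | Path) -> None:
    """Write association records as a TSV, one file per analysis sample set.

    Columns: ``CHR SNP BP A1 TEST NMISS OR SE L95 U95 STAT P`` plus a
    ``SAMPLE`` and ``FLAG`` column; rows sorted by (chromosome, position,
    test, sample); floats printed with 6 significant digits.
    """
    records = list(records)
    if not records:
        raise ValueError("no association records to write")
    rows = []
    for r in records:
        rows.append({
            "CHR": r.chrom, "SNP": r.snp_id, "BP": r.pos, "A1": r.effect_allele,
            "TEST": r.test, "NMISS": r.n_used, "OR": r.odds_ratio, "SE": r.se,
            "L95": r.ci_low, "U95": r.ci_high,
            "STAT": r.beta / r.se if r.se > 0 else np.nan, "P": r.p,
            "SAMPLE": r.sample, "FLAG": r.flag,
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(["CHR", "BP", "TEST", "SAMPLE"], kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_assoc(path: str | Path) -> list[AssociationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "SNP": str, "A1": str})
    out = []
    for _, row in df.iterrows():
        beta = math.log(row["OR"])
        flag = row.get("FLAG", "")
        out.append(AssociationRecord(
            snp_id=row["SNP"], sample=row.get("SAMPLE", "TOTAL"),
            test=row["TEST"], effect_allele=row["A1"], chrom=str(row["CHR"]),
            pos=int(row["BP"]), n_used=int(row["NMISS"]), beta=beta,
            se=float(row["SE"]), p=float(row["P"]),
            flag="" if pd.isna(flag) else str(flag),
        ))
    return out
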