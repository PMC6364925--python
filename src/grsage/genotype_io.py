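"""Genotype, weight-table and phenotype I/O plus effect-allele harmonization.

Genotypes are read from VCF v4.x into a subjects x variants dosage matrix on
the ALT-allele scale.  A weight table lists, per variant, the risk-increasing
(effect) allele and its GWAS effect size; :func:`harmonize` re-orients the
dosage matrix so every column counts effect alleles, substituting proxy
variants (high-LD stand-ins, r^2 > 0.8) where an index SNP is absent from the
genotype data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

SNP_ALLELES = frozenset("ACGT")
#: strand-ambiguous complement pairs: indistinguishable after strand flip
AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})

MISSING = np.nan


class GenotypeIOError(ValueError):
    """Fatal error while reading or harmonizing genotype data."""


class StrandPolicy(str, Enum):
    """How to treat strand-ambiguous (A/T, C/G) SNPs during harmonization."""

    KEEP = "keep"
    DROP = "drop"


@dataclass(frozen=True)
class VariantKey:
    """Identity of a biallelic SNP as encoded in the genotype file."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise GenotypeIOError(f"{self.id}: position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise GenotypeIOError(f"{self.id}: ref equals alt ({self.ref})")
        for allele in (self.ref, self.alt):
            if allele not in SNP_ALLELES:
                raise GenotypeIOError(
                    f"{self.id}: non-SNP allele {allele!r} (only A/C/G/T accepted)"
                )

    @property
    def is_ambiguous(self) -> bool:
        return {self.ref, self.alt} in AMBIGUOUS_PAIRS


@dataclass(frozen=True)
class WeightEntry:
    """One scored SNP: effect allele, other allele and per-allele effect size."""

    id: str
    effect_allele: str
    other_allele: str
    beta: float
    proxy_id: Optional[str] = None
    proxy_r2: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta):
            raise GenotypeIOError(f"{self.id}: non-finite beta {self.beta}")
        if self.effect_allele == self.other_allele:
            raise GenotypeIOError(f"{self.id}: effect allele equals other allele")
        for allele in (self.effect_allele, self.other_allele):
            if allele not in SNP_ALLELES:
                raise GenotypeIOError(f"{self.id}: unknown allele character {allele!r}")
        if self.proxy_id is not None:
            if self.proxy_r2 is None or not self.proxy_r2 > 0.8:
                raise GenotypeIOError(
                    f"{self.id}: proxy {self.proxy_id} requires r^2 > 0.8, "
                    f"got {self.proxy_r2}"
                )


@dataclass(frozen=True)
class WeightTable:
    """Ordered list of scored SNPs for one trait (e.g. CAD or LDL-C)."""

    trait: str
    entries: tuple[WeightEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GenotypeIOError(f"duplicate rsIDs in weight table: {dupes}")

    @property
    def N(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    @property
    def betas(self) -> np.ndarray:
        return np.array([e.beta for e in self.entries], dtype=float)


@dataclass
class DosageMatrix:
    """Subjects x variants allele-dosage matrix.

    Dosages live in [0, 2]; hard calls are exactly {0, 1, 2}; missing
    genotypes are NaN.  ``oriented`` is False while dosages count ALT
    alleles as encoded in the VCF and True once they count effect alleles.
    """

    subject_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    oriented: bool = False

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.subject_ids) or m != len(self.variant_ids):
            raise GenotypeIOError("dosage matrix shape does not match id lists")
        if len(set(self.subject_ids)) != n:
            raise GenotypeIOError("duplicate subject IDs")
        if len(set(self.variant_ids)) != m:
            raise GenotypeIOError("duplicate variant IDs")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise GenotypeIOError("dosages outside [0, 2]")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


@dataclass
class HarmonizationReport:
    """Bookkeeping from harmonize: matched + dropped equals the table's N."""

    matched: int = 0
    proxied: int = 0
    flipped: int = 0
    dropped: int = 0
    ambiguous_kept: int = 0
    dropped_ids: list[str] = field(default_factory=list)


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Presentation(str, Enum):
    """Clinical presentation at first angiography."""

    STEMI = "STEMI"
    NSTEMI = "NSTEMI"
    UAP = "UAP"
    SAP = "SAP"


@dataclass
class SubjectRecord:
    """One phenotype row: demographics, risk factors, ancestry PCs."""

    id: str
    sex: Sex
    age_onset: float
    familial_cad: Optional[bool] = None
    smoking: Optional[bool] = None
    diabetes: Optional[bool] = None
    hypertension: Optional[bool] = None
    high_cholesterol: Optional[bool] = None
    bmi: Optional[float] = None
    presentation: Optional[Presentation] = None
    pc1: Optional[float] = None
    pc2: Optional[float] = None


# ---------------------------------------------------------------------------
# readers


def read_vcf(path: str | Path, prefer_dosage: bool = False) -> tuple[DosageMatrix, list[VariantKey]]:
    """Read a VCF into an ALT-dosage matrix plus the variant keys.

    Per record the dosage is the DS (imputed dosage) FORMAT value when
    ``prefer_dosage`` is set and DS is present, otherwise the hard GT ALT
    allele count.  Missing genotypes (./.) become NaN.  Multiallelic records
    and indels are rejected record-by-record with a logged count; duplicate
    sample IDs are fatal.
    """
    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises plain Exception subclasses
        raise GenotypeIOError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise GenotypeIOError(f"{path}: duplicate sample IDs in VCF header")

    keys: list[VariantKey] = []
    columns: list[np.ndarray] = []
    n_rejected = 0
    for lineno, rec in enumerate(vcf, start=1):
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1 \
                or rec.REF not in SNP_ALLELES or alts[0] not in SNP_ALLELES:
            n_rejected += 1
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        try:
            key = VariantKey(chrom=rec.CHROM, pos=rec.POS, id=vid,
                             ref=rec.REF, alt=alts[0])
        except GenotypeIOError as exc:
            raise GenotypeIOError(f"{path} record {lineno}: {exc}") from exc

        dosage = None
        if prefer_dosage:
            ds = rec.format("DS")
            if ds is not None:
                dosage = np.asarray(ds, dtype=float).reshape(-1)
        if dosage is None:
            gts = np.array(rec.genotypes, dtype=object)
            alleles = np.array([[g[0], g[1]] for g in gts], dtype=float)
            alleles[alleles < 0] = np.nan
            dosage = alleles.sum(axis=1)  # NaN propagates for ./.
        keys.append(key)
        columns.append(dosage)

    if n_rejected:
        logger.warning("%s: rejected %d non-SNP/multiallelic records", path, n_rejected)
    if not keys:
        raise GenotypeIOError(f"{path}: no biallelic SNP records found")

    dosages = np.column_stack(columns)
    matrix = DosageMatrix(subject_ids=samples,
                          variant_ids=[k.id for k in keys],
                          dosages=dosages, oriented=False)
    return matrix, keys


def read_weight_table(path: str | Path, trait: str) -> WeightTable:
    """Read a TSV/CSV effect-weight table (rsid, effect/other allele, beta,
    optional proxy_rsid/proxy_r2) into a validated :class:`WeightTable`."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"rsid": str})
    required = {"rsid", "effect_allele", "other_allele", "beta"}
    missing = required - set(df.columns)
    if missing:
        raise GenotypeIOError(f"{path}: missing columns {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        proxy_id = getattr(row, "proxy_rsid", None)
        if proxy_id is not None and (pd.isna(proxy_id) or proxy_id == ""):
            proxy_id = None
        proxy_r2 = getattr(row, "proxy_r2", None)
        if proxy_r2 is not None and pd.isna(proxy_r2):
            proxy_r2 = None
        beta = float(row.beta)
        if not math.isfinite(beta):
            raise GenotypeIOError(f"{path}: non-finite beta for {row.rsid}")
        entries.append(WeightEntry(id=str(row.rsid),
                                   effect_allele=str(row.effect_allele),
                                   other_allele=str(row.other_allele),
                                   beta=beta, proxy_id=proxy_id,
                                   proxy_r2=None if proxy_r2 is None else float(proxy_r2)))
    return WeightTable(trait=trait, entries=tuple(entries))


def write_weight_table(table: WeightTable, path: str | Path) -> None:
    rows = []
    for e in table.entries:
        rows.append({"rsid": e.id, "effect_allele": e.effect_allele,
                     "other_allele": e.other_allele, "beta": e.beta,
                     "proxy_rsid": e.proxy_id if e.proxy_id else "",
                     "proxy_r2": e.proxy_r2 if e.proxy_r2 is not None else ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n"}


def _parse_binary(value, path, row_id, column) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    text = str(value).strip().lower()
    if text in ("", "nan"):
        return None
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    try:
        return bool(int(float(text)))
    except ValueError:
        raise GenotypeIOError(
            f"{path}: row {row_id}: cannot parse {column}={value!r} as binary"
        ) from None


def read_phenotypes(path: str | Path) -> list[SubjectRecord]:
    """Read the per-subject phenotype table into typed records.

    Required columns: subject_id, sex, age_onset.  Presentation is restricted
    to the closed set {STEMI, NSTEMI, UAP, SAP}; ages outside (0, 120] are
    fatal row errors.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    required = {"subject_id", "sex", "age_onset"}
    missing = required - set(df.columns)
    if missing:
        raise GenotypeIOError(f"{path}: missing required columns {sorted(missing)}")

    records: list[SubjectRecord] = []
    for row in df.to_dict("records"):
        sid = str(row["subject_id"])
        try:
            sex = Sex(str(row["sex"]).strip().lower())
        except ValueError:
            raise GenotypeIOError(f"{path}: row {sid}: invalid sex {row['sex']!r}") from None
        age = float(row["age_onset"])
        if not (0 < age <= 120):
            raise GenotypeIOError(f"{path}: row {sid}: age {age} outside (0, 120]")
        pres = row.get("presentation")
        if pres is None or (isinstance(pres, float) and math.isnan(pres)) or str(pres).strip() == "":
            presentation = None
        else:
            try:
                presentation = Presentation(str(pres).strip().upper())
            except ValueError:
                raise GenotypeIOError(
                    f"{path}: row {sid}: presentation {pres!r} not in "
                    f"{[p.value for p in Presentation]}"
                ) from None

        def _float(col):
            v = row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return float(v)

        records.append(SubjectRecord(
            id=sid, sex=sex, age_onset=age,
            familial_cad=_parse_binary(row.get("familial_cad"), path, sid, "familial_cad"),
            smoking=_parse_binary(row.get("smoking"), path, sid, "smoking"),
            diabetes=_parse_binary(row.get("diabetes"), path, sid, "diabetes"),
            hypertension=_parse_binary(row.get("hypertension"), path, sid, "hypertension"),
            high_cholesterol=_parse_binary(row.get("high_cholesterol"), path, sid, "high_cholesterol"),
            bmi=_float("bmi"), presentation=presentation,
            pc1=_float("pc1"), pc2=_float("pc2")))
    return records


def phenotypes_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten SubjectRecords into an analysis DataFrame (binaries as float
    0/1 with NaN for missing, sex as a ``female`` indicator)."""
    def b(v):
        return np.nan if v is None else float(v)

    rows = []
    for r in records:
        rows.append({
            "subject_id": r.id,
            "female": 1.0 if r.sex is Sex.FEMALE else 0.0,
            "age_onset": r.age_onset,
            "familial_cad": b(r.familial_cad), "smoking": b(r.smoking),
            "diabetes": b(r.diabetes), "hypertension": b(r.hypertension),
            "high_cholesterol": b(r.high_cholesterol),
            "bmi": np.nan if r.bmi is None else r.bmi,
            "presentation": None if r.presentation is None else r.presentation.value,
            "pc1": np.nan if r.pc1 is None else r.pc1,
            "pc2": np.nan if r.pc2 is None else r.pc2,
        })
    return pd.DataFrame(rows).set_index("subject_id", drop=False)


def write_vcf(
    matrix: DosageMatrix,
    keys: Sequence[VariantKey],
    path: str | Path,
    ds_ids: Optional[set[str]] = None,
) -> None:
    """Write an ALT-dosage matrix as an uncompressed VCF v4.2.

    GT is derived from the (rounded) dosage; variants whose id is in
    ``ds_ids`` additionally carry a DS FORMAT field with the exact dosage,
    mimicking imputed genotypes.  NaN dosages are written as ./. .
    """
    if matrix.oriented:
        raise GenotypeIOError("write_vcf expects an unoriented (ALT-dosage) matrix")
    if len(keys) != matrix.n_variants:
        raise GenotypeIOError("keys do not match matrix columns")
    ds_ids = ds_ids or set()
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        seen: list[str] = []
        for key in keys:
            if key.chrom not in seen:
                seen.append(key.chrom)
                fh.write(f"##contig=<ID={key.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated ALT dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.subject_ids) + "\n")
        for j, key in enumerate(keys):
            with_ds = key.id in ds_ids
            fmt = "GT:DS" if with_ds else "GT"
            cells = []
            for d in matrix.dosages[:, j]:
                if np.isnan(d):
                    cells.append("./." + (":." if with_ds else ""))
                    continue
                gt = gt_codes[int(round(d))]
                cells.append(f"{gt}:{d:.4g}" if with_ds else gt)
            fh.write(f"{key.chrom}\t{key.pos}\t{key.id}\t{key.ref}\t{key.alt}"
                     f"\t.\t.\t.\t{fmt}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# harmonization


def harmonize(
    matrix: DosageMatrix,
    keys: Sequence[VariantKey],
    weights: WeightTable,
    policy: StrandPolicy | str = StrandPolicy.KEEP,
) -> tuple[DosageMatrix, HarmonizationReport]:
    """Orient ALT dosages so every column counts the risk-increasing allele.

    For each weight entry the variant is located by rsID, falling back to the
    entry's proxy rsID when the index SNP is absent.  If the effect allele is
    the VCF ALT the dosage is kept; if it is the REF the dosage becomes
    ``2 - d`` (missing stays missing).  Variants whose allele pair does not
    match the weight entry's pair are dropped; strand-ambiguous A/T and C/G
    SNPs are kept (with a warning count) or dropped per ``policy``.  The
    returned matrix has its columns in weight-table order and oriented=True.
    """
    if matrix.oriented:
        raise GenotypeIOError("matrix is already oriented; refusing to re-orient")
    policy = StrandPolicy(policy)

    key_by_id: dict[str, tuple[int, VariantKey]] = {}
    for idx, key in enumerate(keys):
        key_by_id.setdefault(key.id, (idx, key))

    report = HarmonizationReport()
    out_cols: list[np.ndarray] = []
    out_ids: list[str] = []
    for entry in weights.entries:
        located = key_by_id.get(entry.id)
        via_proxy = False
        if located is None and entry.proxy_id is not None:
            located = key_by_id.get(entry.proxy_id)
            via_proxy = located is not None
        if located is None:
            report.dropped += 1
            report.dropped_ids.append(entry.id)
            logger.warning("%s: not found in genotypes (no proxy match)", entry.id)
            continue
        col_idx, key = located
        if {key.ref, key.alt} != {entry.effect_allele, entry.other_allele}:
            report.dropped += 1
            report.dropped_ids.append(entry.id)
            logger.warning("%s: allele mismatch {%s,%s} vs {%s,%s}; dropped",
                           entry.id, key.ref, key.alt,
                           entry.effect_allele, entry.other_allele)
            continue
        if key.is_ambiguous:
            if policy is StrandPolicy.DROP:
                report.dropped += 1
                report.dropped_ids.append(entry.id)
                continue
            report.ambiguous_kept += 1
            logger.warning("%s: strand-ambiguous %s/%s kept (policy=keep)",
                           entry.id, key.ref, key.alt)

        dosage = matrix.dosages[:, col_idx].copy()
        if entry.effect_allele == key.ref:
            dosage = 2.0 - dosage  # NaN stays NaN
            report.flipped += 1
        report.matched += 1
        if via_proxy:
            report.proxied += 1
        out_cols.append(dosage)
        out_ids.append(entry.id)

    if not out_cols:
        raise GenotypeIOError(
            f"no variants of the {weights.trait} weight table matched the genotypes"
        )
    oriented = DosageMatrix(subject_ids=list(matrix.subject_ids),
                            variant_ids=out_ids,
                            dosages=np.column_stack(out_cols),
                            oriented=True)
    return oriented, report
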