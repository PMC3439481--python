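"""Readers and writers for pedigree, genotype, dosage, phenotype and result files.

All downstream modules consume only the in-memory types defined here:
:class:`PedRecord`, :class:`MarkerMeta` and :class:`GenotypeMatrix`.
Formats are deliberately plain text: whitespace-delimited pedigree files,
classic PLINK PED/MAP, and TSV tables with a header row.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateIdError, FormatError, RangeError

__all__ = [
    "PedRecord",
    "MarkerMeta",
    "GenotypeMatrix",
    "read_pedigree",
    "write_pedigree",
    "read_plink_ped_map",
    "write_plink_ped_map",
    "read_dosage",
    "write_dosage",
    "read_phenotypes",
    "write_phenotypes",
    "write_results",
]

SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}
VALID_ALLELES = set("ACGT12")


@dataclass(frozen=True)
class PedRecord:
    """One pedigree line: individual with optional parents and sex."""

    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"

    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class MarkerMeta:
    """Per-marker metadata; ``rsq`` is present iff the marker is imputed."""

    marker_id: str
    chromosome: str
    position: int
    allele_ref: str
    allele_alt: str
    is_imputed: bool = False
    rsq: float | None = None

    def __post_init__(self):
        if self.position < 0:
            raise RangeError(f"marker {self.marker_id}: negative position {self.position}")
        if self.is_imputed != (self.rsq is not None):
            raise FormatError(
                f"marker {self.marker_id}: rsq must be present iff marker is imputed"
            )
        if self.rsq is not None and not (0.0 <= self.rsq <= 1.0):
            raise RangeError(f"marker {self.marker_id}: rsq {self.rsq} outside [0,1]")


class GenotypeMatrix:
    """Subjects x markers genotype container.

    Values are floats: hard calls 0/1/2 counting copies of ``allele_alt``
    (the minor allele), continuous dosages in [0, 2] for imputed markers,
    and NaN for missing.
    """

    def __init__(self, subject_ids: Sequence[str], markers: Sequence[MarkerMeta],
                 values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(subject_ids), len(markers)):
            raise FormatError(
                f"genotype matrix shape {values.shape} does not match "
                f"{len(subject_ids)} subjects x {len(markers)} markers"
            )
        self.subject_ids = list(subject_ids)
        self.markers = list(markers)
        self.values = values
        self._index = {s: i for i, s in enumerate(self.subject_ids)}
        if len(self._index) != len(self.subject_ids):
            raise DuplicateIdError("duplicate subject id in genotype matrix")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def subject_index(self, subject_id: str) -> int:
        return self._index[subject_id]

    def column(self, marker_id: str) -> np.ndarray:
        j = self.marker_ids().index(marker_id)
        return self.values[:, j]

    def call_rate_per_marker(self) -> np.ndarray:
        return 1.0 - np.isnan(self.values).mean(axis=0)

    def call_rate_per_subject(self) -> np.ndarray:
        return 1.0 - np.isnan(self.values).mean(axis=1)

    def maf(self, subject_ids: Sequence[str] | None = None) -> np.ndarray:
        """Alt-allele frequency folded to [0, 0.5], optionally on a subject subset."""
        v = self.values
        if subject_ids is not None:
            rows = [self._index[s] for s in subject_ids if s in self._index]
            v = v[rows]
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(v, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset(self, subject_ids: Sequence[str] | None = None,
               marker_ids: Sequence[str] | None = None) -> "GenotypeMatrix":
        rows = (
            [self._index[s] for s in subject_ids]
            if subject_ids is not None else list(range(self.n_subjects))
        )
        if marker_ids is not None:
            midx = {m: j for j, m in enumerate(self.marker_ids())}
            cols = [midx[m] for m in marker_ids]
        else:
            cols = list(range(self.n_markers))
        return GenotypeMatrix(
            [self.subject_ids[i] for i in rows],
            [self.markers[j] for j in cols],
            self.values[np.ix_(rows, cols)],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.subject_ids, [dataclasses.replace(m) for m in self.markers],
                              self.values.copy())


# ---------------------------------------------------------------------------
# pedigree files

def read_pedigree(path: str | Path) -> list[PedRecord]:
    """Read a 5-column pedigree file (family, individual, father, mother, sex).

    ``0`` denotes a missing parent (PLINK convention). Parent ids must refer
    to individuals present in the file.
    """
    records: list[PedRecord] = []
    seen: set[tuple[str, str]] = set()
    all_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            fam, iid, fid, mid, sex = fields
            if sex not in SEX_CODES:
                raise FormatError(f"{path}:{lineno}: malformed sex code {sex!r}")
            if (fam, iid) in seen:
                raise DuplicateIdError(f"{path}:{lineno}: duplicate individual {iid!r} in family {fam!r}")
            if iid in all_ids:
                raise DuplicateIdError(f"{path}:{lineno}: individual id {iid!r} reused across families")
            seen.add((fam, iid))
            all_ids.add(iid)
            records.append(PedRecord(fam, iid, None if fid == "0" else fid,
                                     None if mid == "0" else mid, SEX_CODES[sex]))
    missing = []
    for r in records:
        for pid in (r.father_id, r.mother_id):
            if pid is not None and pid not in all_ids:
                missing.append(pid)
    if missing:
        raise FormatError(f"{path}: parent ids not present in file: {sorted(set(missing))}")
    return records


def write_pedigree(records: Iterable[PedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.family_id}\t{r.individual_id}\t{r.father_id or '0'}\t"
                     f"{r.mother_id or '0'}\t{SEX_TO_CODE[r.sex]}\n")


# ---------------------------------------------------------------------------
# PLINK classic text PED/MAP

def _minor_allele(pairs: list[tuple[str, str]], founder_mask: list[bool]) -> tuple[str, str]:
    """Return (ref, alt) with alt the rarer allele among founders.

    Ties break lexicographically (the lexicographically later allele is alt).
    Falls back to all subjects when no founder call is available.
    """
    from collections import Counter

    def count(mask_all: bool) -> Counter:
        c: Counter = Counter()
        for (a, b), is_f in zip(pairs, founder_mask):
            if a == "0":
                continue
            if mask_all or is_f:
                c[a] += 1
                c[b] += 1
        return c

    counts = count(mask_all=False)
    if not counts:
        counts = count(mask_all=True)
    alleles = sorted(counts)
    if len(alleles) == 1:
        return alleles[0], alleles[0]
    if len(alleles) > 2:
        raise FormatError(f"more than two alleles observed: {alleles}")
    a, b = alleles
    if counts[a] < counts[b] or (counts[a] == counts[b]):
        a, b = b, a  # a is now major; tie -> lexicographically later allele is alt
    return a, b


def read_plink_ped_map(ped_path: str | Path, map_path: str | Path
                       ) -> tuple[list[PedRecord], GenotypeMatrix, list[MarkerMeta]]:
    """Read classic PLINK text PED + MAP.

    Genotypes are recoded as counts of the minor allele, determined from
    founder allele frequencies (lexicographic tie-break); "0 0" is missing.
    """
    markers_raw = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            f = line.split()
            if not f:
                continue
            if len(f) != 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 columns, got {len(f)}")
            markers_raw.append((f[0], f[1], int(f[3])))
    n_markers = len(markers_raw)

    records: list[PedRecord] = []
    geno_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            f = line.split()
            if not f:
                continue
            if len(f) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} columns "
                    f"for {n_markers} markers, got {len(f)}"
                )
            fam, iid, fid, mid, sex = f[:5]
            if sex not in SEX_CODES:
                raise FormatError(f"{ped_path}:{lineno}: malformed sex code {sex!r}")
            records.append(PedRecord(fam, iid, None if fid == "0" else fid,
                                     None if mid == "0" else mid, SEX_CODES[sex]))
            row = []
            for j in range(n_markers):
                a, b = f[6 + 2 * j], f[7 + 2 * j]
                for al in (a, b):
                    if al not in VALID_ALLELES and al != "0":
                        raise FormatError(f"{ped_path}:{lineno}: invalid allele {al!r}")
                if (a == "0") != (b == "0"):
                    raise FormatError(f"{ped_path}:{lineno}: half-missing genotype {a} {b}")
                row.append((a, b))
            geno_pairs.append(row)

    founder_mask = [r.is_founder() for r in records]
    n = len(records)
    values = np.full((n, n_markers), np.nan)
    metas: list[MarkerMeta] = []
    for j, (chrom, mid_, pos) in enumerate(markers_raw):
        col = [geno_pairs[i][j] for i in range(n)]
        ref, alt = _minor_allele(col, founder_mask)
        metas.append(MarkerMeta(mid_, chrom, pos, ref, alt))
        for i, (a, b) in enumerate(col):
            if a != "0":
                values[i, j] = (a == alt) + (b == alt)
    gm = GenotypeMatrix([r.individual_id for r in records], metas, values)
    return records, gm, metas


def write_plink_ped_map(records: Sequence[PedRecord], g: GenotypeMatrix,
                        ped_path: str | Path, map_path: str | Path) -> None:
    """Write hard-call genotypes as classic PLINK text PED/MAP."""
    with open(map_path, "w") as fh:
        for m in g.markers:
            fh.write(f"{m.chromosome}\t{m.marker_id}\t0\t{m.position}\n")
    rec_by_id = {r.individual_id: r for r in records}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.subject_ids):
            r = rec_by_id[sid]
            fields = [r.family_id, r.individual_id, r.father_id or "0",
                      r.mother_id or "0", SEX_TO_CODE[r.sex], "-9"]
            for j, m in enumerate(g.markers):
                v = g.values[i, j]
                if np.isnan(v):
                    fields += ["0", "0"]
                else:
                    k = int(round(v))
                    fields += [m.allele_alt] * k + [m.allele_ref] * (2 - k)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# dosage TSV

def read_dosage(path: str | Path, meta: Sequence[MarkerMeta]) -> GenotypeMatrix:
    """Read a TSV of imputed dosages (subject id column + one column per marker).

    Values must lie in [0, 2]; markers are flagged imputed and must carry an
    RSQ in their supplied metadata.
    """
    df = pd.read_csv(path, sep="\t")
    df.iloc[:, 0] = df.iloc[:, 0].astype(str)
    meta_by_id = {m.marker_id: m for m in meta}
    marker_cols = list(df.columns[1:])
    unknown = [c for c in marker_cols if c not in meta_by_id]
    if unknown:
        raise FormatError(f"{path}: dosage columns without metadata: {unknown}")
    subject_ids = df.iloc[:, 0].tolist()
    values = df[marker_cols].to_numpy(dtype=float)
    bad = np.argwhere((values < 0) | (values > 2))
    if bad.size:
        i, j = bad[0]
        raise RangeError(
            f"{path}: dosage {values[i, j]} outside [0,2] at subject "
            f"{subject_ids[i]!r}, marker {marker_cols[j]!r}"
        )
    metas = []
    for c in marker_cols:
        m = meta_by_id[c]
        if not m.is_imputed:
            m = dataclasses.replace(m, is_imputed=True, rsq=m.rsq if m.rsq is not None else 1.0)
        metas.append(m)
    return GenotypeMatrix(subject_ids, metas, values)


def write_dosage(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(g.values, columns=g.marker_ids())
    df.insert(0, "subject_id", g.subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# phenotype and result tables

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype/covariate TSV with header; empty cells or "NA" are missing."""
    return pd.read_csv(path, sep="\t", dtype={"subject_id": str, "family_id": str},
                       na_values=["NA", ""])


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


RESULT_COLUMNS = ["marker_id", "chrom", "pos", "beta_t1", "beta_t2",
                  "se_t1", "se_t2", "wald", "df", "p", "n"]


def write_results(rows: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in RESULT_COLUMNS if c not in rows.columns]
    if missing:
        raise FormatError(f"result table missing columns: {missing}")
    rows[RESULT_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")
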