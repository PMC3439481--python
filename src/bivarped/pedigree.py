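"""Pedigree validation, kinship coefficients, sib pairs and Mendelian masking.

The kinship coefficient Phi_ij is the probability that one allele sampled at
random from individual i and one from j are identical by descent. It is
computed by the classic recursion over a topological (ancestors-first)
ordering: Phi_ii = 0.5 * (1 + Phi_fm) and Phi_ij = 0.5 * (Phi_fj + Phi_mj).
Additive genetic covariance between relatives scales with 2*Phi (the
numerator relationship matrix), which downstream modules use as the
polygenic covariance backbone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, PedigreeCycleError
from .io import GenotypeMatrix, PedRecord

__all__ = [
    "Pedigree",
    "KinshipMatrix",
    "build_pedigree",
    "kinship",
    "enumerate_sib_pairs",
    "mendelian_mask",
    "trio_consistent",
    "duo_consistent",
]


@dataclass
class Pedigree:
    """Validated family structure with founders and a deterministic order."""

    members: list[PedRecord]
    founder_set: set[str]
    generation_order: list[str]  # topological: ancestors before descendants
    by_id: dict[str, PedRecord] = field(repr=False, default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return [r.individual_id for r in self.members]

    @property
    def family_ids(self) -> list[str]:
        return sorted({r.family_id for r in self.members})

    def family_members(self, family_id: str) -> list[PedRecord]:
        return [r for r in self.members if r.family_id == family_id]


@dataclass
class KinshipMatrix:
    """Kinship coefficients for an ordered id list; zero across families."""

    ids: list[str]
    phi: np.ndarray

    def __post_init__(self):
        self._index = {s: i for i, s in enumerate(self.ids)}

    def get(self, id_i: str, id_j: str) -> float:
        return float(self.phi[self._index[id_i], self._index[id_j]])

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        idx = [self._index[s] for s in ids]
        return self.phi[np.ix_(idx, idx)]

    def to_pairs_tsv(self, path: str | Path) -> None:
        """Export nonzero kinship pairs as TSV (id_i, id_j, phi)."""
        with open(path, "w") as fh:
            fh.write("id_i\tid_j\tphi\n")
            n = len(self.ids)
            for i in range(n):
                for j in range(i, n):
                    if self.phi[i, j] > 0:
                        fh.write(f"{self.ids[i]}\t{self.ids[j]}\t{self.phi[i, j]:.8g}\n")


def build_pedigree(records: Iterable[PedRecord]) -> Pedigree:
    """Validate records into a :class:`Pedigree`.

    Checks acyclicity, parent sex consistency, and that parents belong to the
    same family as their offspring; derives founders and a deterministic
    ancestors-first ordering.
    """
    members = list(records)
    by_id = {r.individual_id: r for r in members}
    if len(by_id) != len(members):
        raise FormatError("duplicate individual ids passed to build_pedigree")
    for r in members:
        for pid, want_sex in ((r.father_id, "male"), (r.mother_id, "female")):
            if pid is None:
                continue
            p = by_id.get(pid)
            if p is None:
                raise FormatError(f"{r.individual_id}: parent {pid!r} not in pedigree")
            if p.family_id != r.family_id:
                raise FormatError(
                    f"{r.individual_id}: parent {pid!r} belongs to family "
                    f"{p.family_id!r}, not {r.family_id!r}"
                )
            if p.sex not in (want_sex, "unknown"):
                raise FormatError(
                    f"{r.individual_id}: listed {'father' if want_sex == 'male' else 'mother'} "
                    f"{pid!r} has sex {p.sex!r}"
                )
    graph = {r.individual_id: [p for p in (r.father_id, r.mother_id) if p is not None]
             for r in members}
    try:
        # sorted() inputs keep the ordering deterministic across runs
        ts = TopologicalSorter({k: sorted(v) for k, v in sorted(graph.items())})
        order = list(ts.static_order())
    except CycleError as exc:
        raise PedigreeCycleError(exc.args[1]) from exc
    founders = {r.individual_id for r in members if r.is_founder()}
    return Pedigree(members=members, founder_set=founders,
                    generation_order=order, by_id=by_id)


def kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship matrix by the ancestors-first recursion.

    Families are independent blocks (kinship is zero across families), so
    the recursion runs within each family over its members in generation
    order.
    """
    ids = ped.ids
    index = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))
    fam_order: dict[str, list[str]] = {}
    for a in ped.generation_order:
        fam_order.setdefault(ped.by_id[a].family_id, []).append(a)
    for fam, order in fam_order.items():
        local = {s: i for i, s in enumerate(order)}
        m = len(order)
        block = np.zeros((m, m))
        for a in order:
            i = local[a]
            rec = ped.by_id[a]
            f, mo = rec.father_id, rec.mother_id
            phi_fm = block[local[f], local[mo]] if (f and mo) else 0.0
            block[i, i] = 0.5 * (1.0 + phi_fm)
            for j in range(i):
                val = 0.0
                if f:
                    val += 0.5 * block[local[f], j]
                if mo:
                    val += 0.5 * block[local[mo], j]
                block[i, j] = block[j, i] = val
        rows = np.array([index[s] for s in order])
        phi[np.ix_(rows, rows)] = block
    return KinshipMatrix(ids=ids, phi=phi)


def enumerate_sib_pairs(ped: Pedigree) -> list[tuple[str, str]]:
    """All unordered full-sib pairs (both parents shared and known)."""
    from collections import defaultdict

    sibships: dict[tuple[str, str, str], list[str]] = defaultdict(list)
    for r in ped.members:
        if r.father_id is not None and r.mother_id is not None:
            sibships[(r.family_id, r.father_id, r.mother_id)].append(r.individual_id)
    pairs = []
    for sibs in sibships.values():
        sibs = sorted(sibs)
        for i in range(len(sibs)):
            for j in range(i + 1, len(sibs)):
                pairs.append((sibs[i], sibs[j]))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Mendelian consistency

def trio_consistent(father: float, mother: float, child: float) -> bool:
    """Is a (father, mother, child) hard-call triple Mendelian-consistent?

    Any NaN member makes the remaining duo/singleton constraint apply.
    Genotypes are minor-allele counts at a biallelic autosomal marker.
    """
    if np.isnan(child):
        return True
    if np.isnan(father) and np.isnan(mother):
        return True
    if np.isnan(father):
        return duo_consistent(mother, child)
    if np.isnan(mother):
        return duo_consistent(father, child)
    f, m, c = int(father), int(mother), int(child)
    # transmissible alleles: hom -> that allele only; het -> either
    f_alleles = {0: {0}, 1: {0, 1}, 2: {1}}[f]
    m_alleles = {0: {0}, 1: {0, 1}, 2: {1}}[m]
    return any(a + b == c for a in f_alleles for b in m_alleles)


def duo_consistent(parent: float, child: float) -> bool:
    """Parent-child compatibility when only one parent is genotyped."""
    if np.isnan(parent) or np.isnan(child):
        return True
    return not ((parent == 0 and child == 2) or (parent == 2 and child == 0))


def mendelian_mask(ped: Pedigree, g: GenotypeMatrix
                   ) -> tuple[GenotypeMatrix, list[tuple[str, str, tuple[str, ...]]]]:
    """Set Mendelian-inconsistent trio genotypes to missing.

    For every child with at least one genotyped parent, each marker whose
    (child, parents) genotypes are incompatible with Mendelian transmission
    is masked in the child AND the available parents (conservative: the paper
    does not identify the erroneous member). Dosage (non-integer) markers are
    skipped with a warning. Returns the masked matrix and a report of
    (family_id, marker_id, member_ids). Idempotent.
    """
    values = g.values.copy()
    hard = np.ones(g.n_markers, dtype=bool)
    for j in range(g.n_markers):
        col = values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            hard[j] = False
    if not hard.all():
        warnings.warn(f"mendelian_mask: skipped {int((~hard).sum())} dosage marker(s)")

    report: list[tuple[str, str, tuple[str, ...]]] = []
    sub_idx = {s: i for i, s in enumerate(g.subject_ids)}
    for r in ped.members:
        if r.is_founder() or r.individual_id not in sub_idx:
            continue
        ci = sub_idx[r.individual_id]
        fi = sub_idx.get(r.father_id) if r.father_id else None
        mi = sub_idx.get(r.mother_id) if r.mother_id else None
        if fi is None and mi is None:
            continue
        for j in np.nonzero(hard)[0]:
            fa = values[fi, j] if fi is not None else np.nan
            mo = values[mi, j] if mi is not None else np.nan
            if not trio_consistent(fa, mo, values[ci, j]):
                members = [r.individual_id]
                values[ci, j] = np.nan
                if fi is not None and not np.isnan(fa):
                    values[fi, j] = np.nan
                    members.append(r.father_id)
                if mi is not None and not np.isnan(mo):
                    values[mi, j] = np.nan
                    members.append(r.mother_id)
                report.append((r.family_id, g.markers[j].marker_id, tuple(members)))
    masked = GenotypeMatrix(g.subject_ids, g.markers, values)
    return masked, report
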