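"""Pedigree construction, kinship coefficients and the genetic relatedness matrix.

The cohort's pedigrees are maternal-line chains (grandmother -> mother ->
child) with fathers unobserved, so every family contributes a three-member
path and the relatedness matrix is block-diagonal by family.  Kinship is
computed by the standard recursive (tabular) algorithm; the GRM used by the
variance-component models is twice the kinship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "PedigreeMember",
    "Pedigree",
    "RelatednessMatrix",
    "build_pedigree",
    "kinship_coefficients",
    "grm",
    "read_fam",
    "write_fam",
]


class PedigreeError(ValueError):
    """The pedigree violates a structural invariant (dangling link, cycle, ...)."""


@dataclass(frozen=True)
class PedigreeMember:
    individual_id: str
    family_id: str
    mother_id: str | None
    father_id: str | None
    sex: str  # "female" | "male"


@dataclass
class Pedigree:
    """A validated, topologically ordered pedigree (parents precede offspring)."""

    members: list[PedigreeMember]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {m.individual_id: i for i, m in enumerate(self.members)}
        if len(self._index) != len(self.members):
            raise PedigreeError("duplicate individual ids")

    @property
    def ids(self) -> list[str]:
        return [m.individual_id for m in self.members]

    def __len__(self) -> int:
        return len(self.members)

    def index_of(self, individual_id: str) -> int:
        return self._index[individual_id]


def build_pedigree(individuals: pd.DataFrame) -> Pedigree:
    """Validate and topologically order a pedigree table.

    ``individuals`` needs columns ``individual_id``, ``family_id``, ``sex``
    and optionally ``mother_id`` / ``father_id`` (empty/NaN/"0" = unknown,
    making the individual a founder on that side).

    Raises :class:`PedigreeError` on dangling parent links, parent links
    crossing families, a male listed as a mother, or a cycle.
    """
    df = individuals
    members: dict[str, PedigreeMember] = {}
    for row in df.itertuples(index=False):
        mid = _clean_parent(getattr(row, "mother_id", None))
        fid = _clean_parent(getattr(row, "father_id", None))
        m = PedigreeMember(
            individual_id=str(row.individual_id),
            family_id=str(row.family_id),
            mother_id=mid,
            father_id=fid,
            sex=str(row.sex),
        )
        if m.individual_id in members:
            raise PedigreeError(f"duplicate individual id {m.individual_id}")
        members[m.individual_id] = m

    for m in members.values():
        for link, who in ((m.mother_id, "mother"), (m.father_id, "father")):
            if link is None:
                continue
            if link not in members:
                raise PedigreeError(
                    f"{m.individual_id}: dangling {who}_id {link!r}"
                )
            parent = members[link]
            if parent.family_id != m.family_id:
                raise PedigreeError(
                    f"{m.individual_id}: {who} {link} belongs to family "
                    f"{parent.family_id}, not {m.family_id}"
                )
            if who == "mother" and parent.sex != "female":
                raise PedigreeError(f"{m.individual_id}: mother {link} is not female")
            if who == "father" and parent.sex != "male":
                raise PedigreeError(f"{m.individual_id}: father {link} is not male")

    # topological sort by sequential sweeps, preserving input order when the
    # input is already parent-first; leftover nodes after a fruitless sweep
    # mean a cycle
    ordered: list[PedigreeMember] = []
    placed: set[str] = set()
    pending = dict(members)
    while pending:
        progressed = False
        for iid in list(pending):
            m = pending[iid]
            if (m.mother_id is None or m.mother_id in placed) and (
                m.father_id is None or m.father_id in placed
            ):
                ordered.append(m)
                placed.add(iid)
                del pending[iid]
                progressed = True
        if not progressed:
            raise PedigreeError(f"pedigree contains a cycle among {sorted(pending)}")
    return Pedigree(ordered)


def _clean_parent(v) -> str | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    s = str(v).strip()
    return None if s in ("", "0", "nan", "None") else s


def kinship_coefficients(ped: Pedigree) -> np.ndarray:
    """Kinship matrix phi by the recursive tabular algorithm.

    With individuals ordered so parents precede offspring:
    phi(i,i) = (1 + phi(mother_i, father_i)) / 2 and, for j earlier than i,
    phi(i,j) = (phi(mother_i, j) + phi(father_i, j)) / 2, an unknown parent
    contributing 0.  Maternal-line trios admit no inbreeding; an inbred loop
    (phi(mother, father) > 0) raises rather than silently computing.
    """
    n = len(ped)
    phi = np.zeros((n, n))
    idx = {m.individual_id: i for i, m in enumerate(ped.members)}
    for i, m in enumerate(ped.members):
        mi = idx.get(m.mother_id) if m.mother_id else None
        fi = idx.get(m.father_id) if m.father_id else None
        phi_mf = phi[mi, fi] if (mi is not None and fi is not None) else 0.0
        if phi_mf > 0:
            raise PedigreeError(
                f"{m.individual_id}: inbred mating loop (parental kinship {phi_mf})"
            )
        phi[i, i] = 0.5 * (1.0 + phi_mf)
        for j in range(i):
            v = 0.0
            if mi is not None:
                v += 0.5 * phi[mi, j]
            if fi is not None:
                v += 0.5 * phi[fi, j]
            phi[i, j] = phi[j, i] = v
    return phi


@dataclass(frozen=True)
class RelatednessMatrix:
    """A genetic relatedness matrix G = 2*phi with its individual ordering."""

    ids: tuple[str, ...]
    G: np.ndarray

    def __post_init__(self) -> None:
        G = self.G
        if G.shape != (len(self.ids), len(self.ids)):
            raise ValueError("G shape does not match ids")
        if not np.allclose(G, G.T):
            raise ValueError("G must be symmetric")
        w = np.linalg.eigvalsh(G)
        if w.min() < -1e-10:
            raise ValueError(f"G is not positive semi-definite (min eig {w.min():.3g})")

    def reorder(self, ids: list[str]) -> "RelatednessMatrix":
        """Return G restricted/permuted to ``ids`` (all must be present)."""
        pos = {iid: i for i, iid in enumerate(self.ids)}
        try:
            take = [pos[i] for i in ids]
        except KeyError as e:
            raise KeyError(f"id {e.args[0]!r} not in relatedness matrix") from None
        return RelatednessMatrix(tuple(ids), self.G[np.ix_(take, take)])


def grm(ped: Pedigree) -> RelatednessMatrix:
    """Genetic relatedness matrix G = 2 * kinship for a validated pedigree."""
    return RelatednessMatrix(tuple(ped.ids), 2.0 * kinship_coefficients(ped))


# ---------------------------------------------------------------------------
# FAM-style pedigree file I/O (PLINK .fam-compatible subset)
# ---------------------------------------------------------------------------

_SEX_CODE = {"male": "1", "female": "2"}
_SEX_DECODE = {"1": "male", "2": "female"}


def read_fam(path: str | Path) -> Pedigree:
    """Read a whitespace-delimited FAM pedigree file.

    Columns: family_id individual_id father_id mother_id sex, with 0 for a
    missing parent and sex coded 1=male, 2=female.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise PedigreeError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
        fam, iid, fid, mid, sex = parts[:5]
        if sex not in _SEX_DECODE:
            raise PedigreeError(f"{path}:{lineno}: sex code {sex!r} not in {{1,2}}")
        rows.append(
            dict(
                family_id=fam,
                individual_id=iid,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=_SEX_DECODE[sex],
            )
        )
    return build_pedigree(pd.DataFrame(rows))


def write_fam(ped: Pedigree, path: str | Path) -> None:
    """Write a pedigree in the FAM format accepted by :func:`read_fam`."""
    lines = [
        " ".join(
            (
                m.family_id,
                m.individual_id,
                m.father_id or "0",
                m.mother_id or "0",
                _SEX_CODE[m.sex],
            )
        )
        for m in ped.members
    ]
    Path(path).write_text("\n".join(lines) + "\n")
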