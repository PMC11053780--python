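"""Binding-mode comparison: RMSD_BM, heatmaps, ranking, torsion.

A ligand's binding mode against a protein is the vector of its per-residue
interaction energies (kcal/mol, ≤ 0 by convention, 0 = no interaction).
Two modes P = {p_i} and Q = {q_i} over a shared residue order are compared
with the root-mean-square deviation of the binding mode,

    RMSD_BM(P, Q) = sqrt( sum_i (p_i - q_i)^2 / m )

where the divisor m is configurable: the number of residues n, n − 1, or
only the residues engaged (nonzero) in at least one of the two vectors.
The same statistic applies to aligned 2D-fingerprint histograms of crystal
contacts, flattened over their (d_i, d_e) bins.

Also here: the signed glycosidic torsion angle from four labelled atom
positions, residue ranking by mean interaction strength, and the numeric
cores of the heatmap/radar figures.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import DomainError, GeometryError, SchemaError

__all__ = [
    "BindingModeVector",
    "BindingModePanel",
    "FingerprintHistogram",
    "RMSDBMResult",
    "TorsionInput",
    "rmsd_bm",
    "rmsd_bm_matrix",
    "fingerprint_rmsd_bm",
    "binding_heatmap_data",
    "residue_ranking",
    "radar_data",
    "torsion_angle",
]

DIVISOR_MODES = ("n", "n_minus_1", "engaged_only")


class BindingModeVector(BaseModel):
    """Ordered residue → interaction energy map for one ligand."""

    ligand_id: str
    entries: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "BindingModeVector":
        if not self.entries:
            raise ValueError(f"{self.ligand_id}: empty binding-mode vector")
        positive = [r for r, e in self.entries.items() if e > 0]
        if positive:
            warnings.warn(
                f"{self.ligand_id}: positive interaction energy at "
                f"{', '.join(positive)} (convention is <= 0); kept as given",
                UserWarning,
                stacklevel=2,
            )
        return self

    @property
    def residues(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def values(self) -> np.ndarray:
        return np.asarray(list(self.entries.values()), dtype=float)


class BindingModePanel(BaseModel):
    """Rectangular ligands × residues energy panel; no missing cells."""

    residues: list[str]
    ligands: list[BindingModeVector]
    metadata: dict[str, str] = {}

    @model_validator(mode="after")
    def _check(self) -> "BindingModePanel":
        if len(set(self.residues)) != len(self.residues):
            raise SchemaError("duplicate residue labels in panel")
        ids = [v.ligand_id for v in self.ligands]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate ligand ids in panel")
        for v in self.ligands:
            if list(v.residues) != self.residues:
                raise SchemaError(
                    f"{v.ligand_id}: residue order differs from panel order"
                )
        return self

    @property
    def ligand_ids(self) -> list[str]:
        return [v.ligand_id for v in self.ligands]

    def vector(self, ligand_id: str) -> BindingModeVector:
        for v in self.ligands:
            if v.ligand_id == ligand_id:
                return v
        raise LookupError(f"unknown ligand {ligand_id!r}")

    def to_frame(self) -> pd.DataFrame:
        """Residues as rows, ligands as columns (the on-disk CSV layout)."""
        return pd.DataFrame(
            {v.ligand_id: v.values() for v in self.ligands},
            index=pd.Index(self.residues, name="residue"),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict[str, str] | None = None) -> "BindingModePanel":
        residues = [str(r) for r in df.index]
        ligands = [
            BindingModeVector(
                ligand_id=str(c), entries=dict(zip(residues, df[c].astype(float)))
            )
            for c in df.columns
        ]
        return cls(residues=residues, ligands=ligands, metadata=metadata or {})


class FingerprintHistogram(BaseModel):
    """2D (d_i, d_e) fingerprint: bin edges in Å and percentage weights."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    di_edges: list[float]
    de_edges: list[float]
    weights: list[list[float]]
    contact_filter: Optional[str] = None
    structure_id: str = ""

    @model_validator(mode="after")
    def _check(self) -> "FingerprintHistogram":
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape != (len(self.di_edges) - 1, len(self.de_edges) - 1):
            raise SchemaError(
                f"weights shape {w.shape} does not match bin grid "
                f"({len(self.di_edges) - 1} x {len(self.de_edges) - 1})"
            )
        if (w < 0).any():
            raise ValueError("negative fingerprint weights")
        return self

    def flat(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float).ravel()


class RMSDBMResult(BaseModel):
    """One RMSD_BM evaluation with its divisor bookkeeping."""

    id_a: str
    id_b: str
    value: float
    divisor_mode: str
    n_used: int

    @model_validator(mode="after")
    def _check(self) -> "RMSDBMResult":
        if self.value < 0:
            raise ValueError("RMSD_BM cannot be negative")
        if self.n_used < 1:
            raise ValueError("divisor must be >= 1")
        if self.divisor_mode not in DIVISOR_MODES:
            raise ValueError(f"divisor_mode must be one of {DIVISOR_MODES}")
        return self


class TorsionInput(BaseModel):
    """Four labelled atom positions (Å) defining a dihedral, e.g. the
    glycosidic rotation C(2)–N(1)–C–O of a nucleoside."""

    atoms: list[str]
    coords: list[list[float]]

    @model_validator(mode="after")
    def _check(self) -> "TorsionInput":
        if len(self.atoms) != 4 or len(self.coords) != 4:
            raise SchemaError("a torsion needs exactly four labelled atoms")
        for row in self.coords:
            if len(row) != 3:
                raise SchemaError("coordinates must be 3D")
        return self


def _divisor(p: np.ndarray, q: np.ndarray, divisor_mode: str) -> int:
    n = p.size
    if divisor_mode == "n":
        return n
    if divisor_mode == "n_minus_1":
        if n < 2:
            raise DomainError("n_minus_1 divisor needs at least 2 residues")
        return n - 1
    if divisor_mode == "engaged_only":
        m = int(np.count_nonzero((p != 0) | (q != 0)))
        if m == 0:
            raise DomainError("no engaged residues in either vector")
        return m
    raise DomainError(f"divisor_mode must be one of {DIVISOR_MODES}, got {divisor_mode!r}")


def rmsd_bm(
    p: BindingModeVector, q: BindingModeVector, divisor_mode: str = "n"
) -> RMSDBMResult:
    """RMSD_BM between two binding-mode vectors sharing a residue order."""
    if p.residues != q.residues:
        raise SchemaError(
            f"residue order differs between {p.ligand_id!r} and {q.ligand_id!r}"
        )
    pv, qv = p.values(), q.values()
    m = _divisor(pv, qv, divisor_mode)
    value = float(np.sqrt(np.sum((pv - qv) ** 2) / m))
    return RMSDBMResult(
        id_a=p.ligand_id, id_b=q.ligand_id, value=value, divisor_mode=divisor_mode, n_used=m
    )


def rmsd_bm_matrix(panel: BindingModePanel, divisor_mode: str = "n") -> pd.DataFrame:
    """Symmetric all-pairs RMSD_BM matrix over a panel (zero diagonal)."""
    ids = panel.ligand_ids
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(panel.ligands):
        for b in panel.ligands[i + 1 :]:
            v = rmsd_bm(a, b, divisor_mode).value
            mat.loc[a.ligand_id, b.ligand_id] = v
            mat.loc[b.ligand_id, a.ligand_id] = v
    return mat


def fingerprint_rmsd_bm(
    a: FingerprintHistogram, b: FingerprintHistogram, divisor_mode: str = "n"
) -> RMSDBMResult:
    """RMSD_BM over aligned fingerprint grids (flattened bin weights)."""
    if a.di_edges != b.di_edges or a.de_edges != b.de_edges:
        raise SchemaError("fingerprint bin grids differ")
    if a.contact_filter != b.contact_filter:
        raise SchemaError(
            f"contact filters differ: {a.contact_filter!r} vs {b.contact_filter!r}"
        )
    av, bv = a.flat(), b.flat()
    m = _divisor(av, bv, divisor_mode)
    value = float(np.sqrt(np.sum((av - bv) ** 2) / m))
    return RMSDBMResult(
        id_a=a.structure_id or "a",
        id_b=b.structure_id or "b",
        value=value,
        divisor_mode=divisor_mode,
        n_used=m,
    )


def binding_heatmap_data(
    panel: BindingModePanel, reference_ligand: str | None = None
) -> pd.DataFrame:
    """Residues × ligands energies; difference mode subtracts the reference
    ligand's column (which then reads identically zero)."""
    df = panel.to_frame()
    if reference_ligand is None:
        return df
    if reference_ligand not in df.columns:
        raise LookupError(f"unknown reference ligand {reference_ligand!r}")
    return df.sub(df[reference_ligand], axis=0)


def residue_ranking(panel: BindingModePanel) -> pd.Series:
    """Residues sorted by mean interaction energy, strongest (most negative)
    first; ties broken alphabetically.  Returns the mean per residue."""
    df = panel.to_frame()
    means = df.mean(axis=1)
    order = sorted(means.index, key=lambda r: (means[r], r))
    return means.loc[order]


def radar_data(panel: BindingModePanel) -> dict[str, list[tuple[str, float]]]:
    """Closed polygon series per ligand over the residue axis order (first
    vertex repeated at the end), ready for a radar/spider plot."""
    out: dict[str, list[tuple[str, float]]] = {}
    for v in panel.ligands:
        pts = list(zip(panel.residues, v.values().tolist()))
        out[v.ligand_id] = pts + [pts[0]]
    return out


def torsion_angle(t: TorsionInput) -> float:
    """Signed dihedral in degrees, IUPAC convention, range (−180, 180].

    Positive angle = clockwise rotation of the far bond when sighting from
    atom 2 towards atom 3.
    """
    p = np.asarray(t.coords, dtype=float)
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    if (
        np.linalg.norm(b1) < 1e-12
        or np.linalg.norm(b2) < 1e-12
        or np.linalg.norm(b3) < 1e-12
    ):
        raise GeometryError("coincident consecutive atoms")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear atom triple; torsion undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2))
    angle = float(np.degrees(np.arctan2(y, x)))
    if angle <= -180.0:
        angle += 360.0
    return angle
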