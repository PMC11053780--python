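"""Hirshfeld-surface contact tables: composition, enrichment, distances.

A crystal structure's Hirshfeld surface partitions into close-contact
categories by the chemical species on either side (C···H, O···H, ...).
For species X the derived surface proportion is

    S_X = C_XX + 1/2 * sum_{Y != X} C_XY          (percent of the surface)

and the enrichment ratio compares observed contact percentages with the
random-mixing expectation R_XY = 2 S_X S_Y / 100 (X != Y) or S_X^2 / 100:

    E_XY = C_XY / R_XY        (> 1 privileged, < 1 disfavored)

Ratios whose denominator falls below a small epsilon are reported as null —
a few-percent species makes E numerically unstable (near-zero over
near-zero).  Distances between tables use the fixed category order and
either the plain Euclidean norm or its RMSD form (Euclidean / sqrt(k)).
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, model_validator

from .errors import DomainError, SchemaError

__all__ = [
    "DEFAULT_SPECIES",
    "PAIR_ORDER",
    "canonical_pair",
    "pair_order",
    "ContactTable",
    "SurfaceComposition",
    "EnrichmentMatrix",
    "surface_composition",
    "enrichment_matrix",
    "contribution_distance",
    "group_average_distance",
    "contact_heatmap_data",
]

DEFAULT_SPECIES: tuple[str, ...] = ("C", "H", "N", "O")

TOTAL_TOL = 1.0  # printed tables round; warn beyond 100 +/- this


def _label_order(species: Sequence[str]) -> list[str]:
    # crystallographic labelling convention: hydrogen is written second in
    # heteronuclear pairs (CH, NH, OH), heavy pairs follow species order
    return [s for s in species if s != "H"] + (["H"] if "H" in species else [])


def pair_order(species: Sequence[str] = DEFAULT_SPECIES) -> tuple[str, ...]:
    """Fixed category order: homonuclear pairs first, then heteronuclear in
    species order.  For (C, H, N, O) this is CC HH NN OO CH CN CO NH OH NO."""
    homo = [s + s for s in species]
    hetero = [
        canonical_pair(a + b, species) for a, b in itertools.combinations(species, 2)
    ]
    return tuple(homo + hetero)


def canonical_pair(pair: str, species: Sequence[str] = DEFAULT_SPECIES) -> str:
    """Normalize an unordered pair label ('HO' or 'OH') to canonical order."""
    if len(pair) != 2:
        raise SchemaError(f"pair label must be two species symbols, got {pair!r}")
    a, b = pair[0], pair[1]
    if a not in species or b not in species:
        raise SchemaError(f"unknown species in pair {pair!r} (species {species})")
    order = _label_order(species)
    if order.index(a) <= order.index(b):
        return a + b
    return b + a


PAIR_ORDER: tuple[str, ...] = pair_order()


class ContactTable(BaseModel):
    """Percentage contributions of each contact category to the surface.

    ``contributions`` is keyed by canonical pair label and must cover every
    category of the species set.  A total outside 100 ± 1 raises a
    ``UserWarning`` (not an error: some printed tables are internally
    inconsistent and must load as printed).
    """

    structure_id: str
    temperature: Optional[float] = None
    contributions: dict[str, float]
    species: tuple[str, ...] = DEFAULT_SPECIES

    @model_validator(mode="after")
    def _check(self) -> "ContactTable":
        expected = set(pair_order(self.species))
        canon = {canonical_pair(k, self.species): v for k, v in self.contributions.items()}
        if len(canon) != len(self.contributions):
            raise SchemaError(f"{self.structure_id}: duplicate pair labels after canonicalization")
        missing = expected - set(canon)
        extra = set(canon) - expected
        if missing or extra:
            raise SchemaError(
                f"{self.structure_id}: contact categories mismatch "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )
        for k, v in canon.items():
            if v < 0:
                raise ValueError(f"{self.structure_id}: negative percentage for {k}: {v}")
        object.__setattr__(self, "contributions", {p: canon[p] for p in pair_order(self.species)})
        total = sum(canon.values())
        if abs(total - 100.0) > TOTAL_TOL:
            warnings.warn(
                f"{self.structure_id}: contact percentages sum to {total:.1f}, "
                f"outside 100 ± {TOTAL_TOL}",
                UserWarning,
                stacklevel=2,
            )
        return self

    def vector(self) -> list[float]:
        return [self.contributions[p] for p in pair_order(self.species)]


class SurfaceComposition(BaseModel):
    """Per-species percentage of the molecular surface."""

    proportions: dict[str, float]
    structure_id: str = ""

    @model_validator(mode="after")
    def _check(self) -> "SurfaceComposition":
        for s, v in self.proportions.items():
            if v < 0:
                raise ValueError(f"negative surface proportion for {s}: {v}")
        total = sum(self.proportions.values())
        if abs(total - 100.0) > TOTAL_TOL:
            warnings.warn(
                f"{self.structure_id or 'surface composition'}: proportions sum "
                f"to {total:.2f}, outside 100 ± {TOTAL_TOL}",
                UserWarning,
                stacklevel=2,
            )
        return self


class EnrichmentMatrix(BaseModel):
    """E_XY ratios; ``None`` marks entries suppressed by a tiny denominator."""

    values: dict[str, Optional[float]]
    epsilon_used: float
    structure_id: str = ""
    species: tuple[str, ...] = DEFAULT_SPECIES

    @model_validator(mode="after")
    def _check(self) -> "EnrichmentMatrix":
        for k, v in self.values.items():
            if v is not None and v < 0:
                raise ValueError(f"negative enrichment for {k}: {v}")
        return self

    def vector(self) -> list[Optional[float]]:
        return [self.values[p] for p in pair_order(self.species)]


def surface_composition(t: ContactTable) -> SurfaceComposition:
    """Derive per-species surface proportions from a contact table."""
    props: dict[str, float] = {}
    for x in t.species:
        s = t.contributions[x + x]
        for y in t.species:
            if y == x:
                continue
            s += 0.5 * t.contributions[canonical_pair(x + y, t.species)]
        props[x] = s
    return SurfaceComposition(proportions=props, structure_id=t.structure_id)


def enrichment_matrix(
    t: ContactTable,
    s: SurfaceComposition | None = None,
    epsilon: float = 0.1,
) -> EnrichmentMatrix:
    """Enrichment ratios E_XY = C_XY / R_XY.

    ``s`` defaults to the composition derived from ``t`` itself; passing a
    printed composition reproduces published ratios exactly.  Entries with
    random-contact denominator R_XY < ``epsilon`` (percent) are null.
    """
    if epsilon <= 0:
        raise DomainError(f"epsilon must be positive, got {epsilon}")
    if s is None:
        s = surface_composition(t)
    values: dict[str, Optional[float]] = {}
    for pair in pair_order(t.species):
        x, y = pair[0], pair[1]
        if x == y:
            random = s.proportions[x] ** 2 / 100.0
        else:
            random = 2.0 * s.proportions[x] * s.proportions[y] / 100.0
        values[pair] = None if random < epsilon else t.contributions[pair] / random
    return EnrichmentMatrix(
        values=values, epsilon_used=epsilon, structure_id=t.structure_id, species=t.species
    )


def _paired_components(
    a: Union[ContactTable, EnrichmentMatrix],
    b: Union[ContactTable, EnrichmentMatrix],
) -> list[tuple[float, float]]:
    if type(a) is not type(b):
        raise SchemaError("distance operands must be of the same kind")
    if tuple(a.species) != tuple(b.species):
        raise SchemaError(f"species sets differ: {a.species} vs {b.species}")
    pairs = []
    for va, vb in zip(a.vector(), b.vector()):
        if va is None or vb is None:  # enrichment nulls: compare shared keys only
            continue
        pairs.append((va, vb))
    if not pairs:
        raise DomainError("no comparable components between the two inputs")
    return pairs


def contribution_distance(
    a: Union[ContactTable, EnrichmentMatrix],
    b: Union[ContactTable, EnrichmentMatrix],
    metric: str = "euclidean",
) -> float:
    """Euclidean or RMSD distance over the fixed category order.

    RMSD = Euclidean / sqrt(k) with k the number of compared components
    (all 10 for contact tables; non-null-in-both entries for enrichment).
    """
    pairs = _paired_components(a, b)
    sq = sum((x - y) ** 2 for x, y in pairs)
    if metric == "euclidean":
        return math.sqrt(sq)
    if metric == "rmsd":
        return math.sqrt(sq / len(pairs))
    raise DomainError(f"unknown metric {metric!r}; use 'euclidean' or 'rmsd'")


def group_average_distance(
    ref: ContactTable,
    group: Iterable[ContactTable],
    metric: str = "euclidean",
    mode: str = "mean_of_distances",
) -> float:
    """Average distance from ``ref`` to a group of structures.

    ``mode='mean_of_distances'`` (default) averages per-structure distances;
    ``mode='distance_of_mean'`` first averages the group's contribution
    vectors and measures the distance to that mean table.
    """
    members = list(group)
    if not members:
        raise DomainError("group must be non-empty")
    if mode == "mean_of_distances":
        return sum(contribution_distance(ref, m, metric) for m in members) / len(members)
    if mode == "distance_of_mean":
        order = pair_order(ref.species)
        mean = {
            p: sum(m.contributions[p] for m in members) / len(members) for p in order
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            mean_table = ContactTable(
                structure_id="<group mean>", contributions=mean, species=ref.species
            )
        return contribution_distance(ref, mean_table, metric)
    raise DomainError(f"unknown mode {mode!r}")


def contact_heatmap_data(
    tables: Sequence[ContactTable], reference: str | None = None
) -> pd.DataFrame:
    """Structures × categories matrix for heatmap rendering.

    With ``reference=None`` returns absolute percentages; otherwise each row
    is the difference against the named reference structure (whose own row
    becomes identically zero).
    """
    if not tables:
        raise DomainError("need at least one contact table")
    order = pair_order(tables[0].species)
    df = pd.DataFrame(
        [t.vector() for t in tables],
        index=[t.structure_id for t in tables],
        columns=list(order),
    )
    if reference is None:
        return df
    if reference not in df.index:
        raise LookupError(f"unknown reference structure {reference!r}")
    return df.sub(df.loc[reference], axis=1)
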