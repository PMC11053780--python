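"""Packaged table fixtures, schema readers/writers and the catalog.

All fixtures are plain CSV shipped with the package (UTF-8, dot-decimal,
mandatory header).  Each catalog entry parses into the typed object the
analysis modules consume; the few documented inconsistencies of the source
tables (one internally inconsistent NQR row, one contact row summing past
100, one positive docking energy) surface as warnings on load, never as
silent corrections.

Readers reject locale-comma decimals and malformed headers with
:class:`~bbkit.errors.SchemaError` carrying row context.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any, Callable, Union

import pandas as pd

from .binding import BindingModePanel
from .contacts import ContactTable, SurfaceComposition, pair_order
from .errors import CatalogError, SchemaError
from .nqr import NQRTriplet
from .reactivity import FrontierEnergies

__all__ = [
    "LIGAND_ALIASES",
    "canonical_ligand",
    "fixture_names",
    "fixture_info",
    "load_fixture",
    "read_contact_tables",
    "write_contact_tables",
    "read_panel",
    "write_panel",
    "read_frontier",
    "write_frontier",
    "read_nqr_triplets",
    "write_nqr_triplets",
    "to_json",
    "from_json",
]

# Canonical ligand ids vs the spellings used across the source tables.
LIGAND_ALIASES: dict[str, str] = {
    "Ara-C 1P5Z": "Ara-C 15PZ",
    "Ara-C, 1P5Z": "Ara-C 15PZ",
    "Ara-C *": "Ara-C 15PZ",
    "2′-deoxycytidine, 1P60": "2'-deoxycytidine 1P60",
    "2′-deoxycytidine,1P61": "2'-deoxycytidine 1P61",
    "2′-deoxycytidine": "2'-deoxycytidine",
    "Cytidine": "cytidine",
    "3′-deoxycytidine": "3'-deoxycytidine",
    "3′-dehydroxy, 3,4′-didehydrocytidine": "3'-dehydro-dideoxycytidine",
    "3′-dehydro-3,4-dideoxycytitine": "3'-dehydro-dideoxycytidine",
    "Gemcitabine,1P62": "Gemcitabine 1P62",
    "Vidaza": "5-azacytidine",
    "Vidaza (5-azacytidine)": "5-azacytidine",
    "Zalcitabine (2′-3′-dideoxycytidine)": "Zalcitabine",
    "2′,3′-dideoxycytidine (Zalcitabine)": "Zalcitabine",
    "5-aza-2′-deoxycytidine (Decitabine)": "Decitabine",
}


def canonical_ligand(name: str) -> str:
    """Map a source-table ligand spelling to its canonical id."""
    name = name.strip().replace("−", "-")  # unicode minus → ASCII
    return LIGAND_ALIASES.get(name, name)


# ---------------------------------------------------------------------------
# low-level CSV handling

def _read_csv(path_or_buf, **kw) -> pd.DataFrame:
    try:
        df = pd.read_csv(path_or_buf, **kw)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty or headerless file: {path_or_buf}") from exc
    return df


def _require_columns(df: pd.DataFrame, cols: list[str], where: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{where}: missing columns {missing} (got {list(df.columns)})")


def _as_float(value: Any, where: str):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        value = value.replace("−", "-").strip()
        if "," in value:
            raise SchemaError(
                f"{where}: locale-comma decimal {value!r} rejected; use dot-decimal"
            )
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{where}: cannot parse {value!r} as a number") from exc


# ---------------------------------------------------------------------------
# per-schema readers/writers (CSV); JSON mirrors the pydantic types

def read_contact_tables(path) -> list[ContactTable]:
    """Wide-format contact CSV → typed tables.

    Columns: structure_id, optional temperature_K, then the ten fixed
    contact categories.
    """
    df = _read_csv(path, dtype=str)
    order = list(pair_order())
    _require_columns(df, ["structure_id"] + order, str(path))
    if df["structure_id"].duplicated().any():
        dupes = df.loc[df["structure_id"].duplicated(), "structure_id"].tolist()
        raise SchemaError(f"{path}: duplicate structure ids {dupes}")
    tables = []
    for _, row in df.iterrows():
        sid = row["structure_id"]
        temp = None
        if "temperature_K" in df.columns:
            temp = _as_float(row["temperature_K"], f"{path}:{sid}")
        contributions = {
            p: _as_float(row[p], f"{path}:{sid}:{p}") for p in order
        }
        tables.append(
            ContactTable(structure_id=sid, temperature=temp, contributions=contributions)
        )
    return tables


def write_contact_tables(tables: list[ContactTable], path) -> None:
    order = list(pair_order(tables[0].species))
    rows = []
    for t in tables:
        row: dict[str, Any] = {"structure_id": t.structure_id, "temperature_K": t.temperature}
        row.update(t.contributions)
        rows.append(row)
    pd.DataFrame(rows, columns=["structure_id", "temperature_K"] + order).to_csv(
        path, index=False
    )


def read_panel(path, metadata: dict[str, str] | None = None) -> BindingModePanel:
    """Residues-as-rows, ligands-as-columns CSV → panel (kcal/mol)."""
    df = _read_csv(path, dtype=str)
    _require_columns(df, ["residue"], str(path))
    if df["residue"].duplicated().any():
        raise SchemaError(f"{path}: duplicate residue labels")
    df = df.set_index("residue")
    for col in df.columns:
        df[col] = [_as_float(v, f"{path}:{col}") for v in df[col]]
    return BindingModePanel.from_frame(df.astype(float), metadata=metadata)


def write_panel(panel: BindingModePanel, path) -> None:
    panel.to_frame().to_csv(path)


def read_frontier(path) -> list[FrontierEnergies]:
    df = _read_csv(path, dtype=str)
    _require_columns(df, ["ligand_id", "e_homo", "e_lumo"], str(path))
    if df["ligand_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate ligand ids")
    return [
        FrontierEnergies(
            ligand_id=row["ligand_id"],
            e_homo=_as_float(row["e_homo"], f"{path}:{row['ligand_id']}"),
            e_lumo=_as_float(row["e_lumo"], f"{path}:{row['ligand_id']}"),
        )
        for _, row in df.iterrows()
    ]


def write_frontier(panel: list[FrontierEnergies], path) -> None:
    pd.DataFrame(
        [{"ligand_id": f.ligand_id, "e_homo": f.e_homo, "e_lumo": f.e_lumo} for f in panel]
    ).to_csv(path, index=False)


def read_nqr_triplets(path) -> list[NQRTriplet]:
    """CSV with site,nu_plus,nu_minus[,nu_zero,assignment]; rows lacking
    nu_minus (incomplete spectra) are skipped."""
    df = _read_csv(path, dtype=str)
    _require_columns(df, ["site", "nu_plus", "nu_minus"], str(path))
    triplets = []
    for _, row in df.iterrows():
        where = f"{path}:{row['site']}"
        nu_minus = _as_float(row["nu_minus"], where)
        if nu_minus is None:
            continue
        assignment = row.get("assignment")
        if assignment is not None and pd.isna(assignment):
            assignment = None
        triplets.append(
            NQRTriplet(
                nu_plus=_as_float(row["nu_plus"], where),
                nu_minus=nu_minus,
                nu_zero=_as_float(row.get("nu_zero"), where),
                site_label=row["site"],
                assignment=assignment,
            )
        )
    return triplets


def write_nqr_triplets(triplets: list[NQRTriplet], path) -> None:
    pd.DataFrame(
        [
            {
                "site": t.site_label,
                "nu_plus": t.nu_plus,
                "nu_minus": t.nu_minus,
                "nu_zero": t.nu_zero,
                "assignment": t.assignment,
            }
            for t in triplets
        ]
    ).to_csv(path, index=False)


def to_json(obj, path=None) -> str:
    """Serialize any toolkit pydantic object (or list of them) to JSON."""
    if isinstance(obj, list):
        payload = [o.model_dump() for o in obj]
    else:
        payload = obj.model_dump()
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def from_json(text_or_path: Union[str, Path], model) -> Any:
    """Inverse of :func:`to_json` for a known model class."""
    p = Path(text_or_path) if not str(text_or_path).lstrip().startswith(("{", "[")) else None
    text = p.read_text() if p is not None and p.exists() else str(text_or_path)
    payload = json.loads(text)
    if isinstance(payload, list):
        return [model.model_validate(item) for item in payload]
    return model.model_validate(payload)


# ---------------------------------------------------------------------------
# fixture catalog

def _data_path(filename: str):
    return resources.files("bbkit").joinpath("data", filename)


def _load_df(filename: str) -> pd.DataFrame:
    with resources.as_file(_data_path(filename)) as p:
        return _read_csv(p)


def _load_nqr_triplets() -> list[NQRTriplet]:
    df = _load_df("table01_nqr.csv")
    triplets = []
    for _, row in df.iterrows():
        if pd.isna(row["nu_minus"]):
            continue
        triplets.append(
            NQRTriplet(
                nu_plus=float(row["nu_plus"]),
                nu_minus=float(row["nu_minus"]),
                nu_zero=None if pd.isna(row["nu_zero"]) else float(row["nu_zero"]),
                site_label=f"{row['compound']}:{row['site']}",
                assignment=row["assignment"],
            )
        )
    return triplets


def _load_contact_tables() -> list[ContactTable]:
    with resources.as_file(_data_path("table03_contacts.csv")) as p:
        return read_contact_tables(p)


def _load_surface() -> dict[str, SurfaceComposition]:
    df = _load_df("table05_surface.csv")
    return {
        row["structure_id"]: SurfaceComposition(
            structure_id=row["structure_id"],
            proportions={
                "C": row["S_C"], "H": row["S_H"], "N": row["S_N"], "O": row["S_O"]
            },
        )
        for _, row in df.iterrows()
    }


def _load_panel() -> BindingModePanel:
    with resources.as_file(_data_path("table10_panel.csv")) as p:
        return read_panel(
            p, metadata={"target": "dCK (PDB 1P5Z family)", "units": "kcal/mol"}
        )


def _load_frontier() -> list[FrontierEnergies]:
    df = _load_df("table14_frontier.csv")
    return [
        FrontierEnergies(
            ligand_id=row["ligand_id"],
            e_homo=float(row["e_homo"]),
            e_lumo=float(row["e_lumo"]),
        )
        for _, row in df.iterrows()
    ]


_CATALOG: dict[str, tuple[Callable[[], Any], str]] = {
    "nqr_triplets": (_load_nqr_triplets, "measured 14N frequency triplets (complete sites only)"),
    "nqr_table": (lambda: _load_df("table01_nqr.csv"), "measured frequencies with printed |e2qQ/h| and eta"),
    "nqr_calculated": (lambda: _load_df("table02_nqr_calc.csv"), "GGA-level calculated NQR parameters"),
    "contact_tables": (_load_contact_tables, "Hirshfeld contact percentage tables"),
    "surface_proportions": (_load_surface, "printed per-species surface proportions"),
    "enrichment_printed": (lambda: _load_df("table05_enrichment.csv"), "printed enrichment ratios (long format)"),
    "hbond_energies": (lambda: _load_df("table07_hbond_energies.csv"), "pair-model hydrogen-bond energies (inert fixture)"),
    "affinities": (lambda: _load_df("table09_affinity.csv"), "docking energy decomposition and affinity models"),
    "dck_panel": (_load_panel, "per-residue dCK binding energies, 18 residues x 13 ligands"),
    "rmsd_bm_printed": (lambda: _load_df("table11_rmsdbm.csv"), "published RMSD_BM values (long format)"),
    "hbond_contacts": (lambda: _load_df("table12_hbond_contacts.csv"), "categorical hydrogen-bond map (inert fixture)"),
    "torsions": (lambda: _load_df("table13_torsion.csv"), "glycosidic torsion angles, degrees"),
    "frontier": (_load_frontier, "HOMO/LUMO energies, eV"),
    "frontier_table": (lambda: _load_df("table14_frontier.csv"), "frontier energies with printed derived indices"),
    "activity": (lambda: _load_df("table15_activity.csv"), "biological-activity labels"),
}


def fixture_names() -> list[str]:
    return sorted(_CATALOG)


def fixture_info(name: str) -> str:
    if name not in _CATALOG:
        raise CatalogError(name)
    return _CATALOG[name][1]


def load_fixture(name: str):
    """Load a packaged fixture by catalog name into its typed object."""
    if name not in _CATALOG:
        raise CatalogError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        )
    return _CATALOG[name][0]()
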