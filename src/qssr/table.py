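"""The per-ligand descriptor table: assembly, validation, serialization.

The table is the hand-off object between every stage: one row per ligand,
named numeric descriptor columns (convention ``<property>_<site>_<source>``
with source FL = free preligand, CMC = cyclometalated complex), an optional
free-energy selectivity response (kcal/mol), an optional percent yield, and
an optional train/test split tag.

With ~22 ligands a silently dropped or imputed row destroys the analysis, so
every validation failure is loud and names the offending rows/columns, and no
operation reorders or drops rows implicitly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .steric import buried_volume, sterimol
from .structures import Molecule, RadiiTable

__all__ = [
    "DescriptorTable",
    "SchemaError",
    "StericSettings",
    "DEFAULT_ALIASES",
    "load_table",
    "save_table",
    "attach_computed_descriptors",
]

RESERVED_COLUMNS = ("ligand_id", "response", "yield_percent", "split")

# The field's shorthand for the headline descriptors -> canonical column names.
DEFAULT_ALIASES: dict[str, str] = {
    "s_C2_L": "s_C2_L_FL",
    "nbo_C2": "nbo_C2_CMC",
    "nbo_C6": "nbo_C6_CMC",
    "IE": "IE_CMC",
}


class SchemaError(ValueError):
    """Descriptor-table schema violation; message names rows/columns."""


@dataclass
class DescriptorTable:
    """Validated per-ligand descriptor table.

    ``df`` holds one row per ligand with a mandatory unique ``ligand_id``
    column; all non-reserved columns are numeric descriptors.  ``provenance``
    records, per column, where the values came from (e.g. steric-computation
    settings) and is serialized alongside the values.
    """

    df: pd.DataFrame
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df
        if "ligand_id" not in df.columns:
            raise SchemaError("missing mandatory column 'ligand_id'")
        dup = df["ligand_id"][df["ligand_id"].duplicated()].tolist()
        if dup:
            raise SchemaError(f"duplicate ligand_id values: {sorted(set(map(str, dup)))}")
        for col in df.columns:
            if col in ("ligand_id", "split"):
                continue
            if not pd.api.types.is_numeric_dtype(df[col]):
                bad = df.loc[pd.to_numeric(df[col], errors="coerce").isna()
                             & df[col].notna(), "ligand_id"].tolist()
                raise SchemaError(
                    f"column {col!r} is not numeric (offending rows: {bad})"
                )
        if "yield_percent" in df.columns:
            y = df["yield_percent"].dropna()
            bad = df.loc[(df["yield_percent"] < 0) | (df["yield_percent"] > 100),
                         "ligand_id"].tolist()
            if bad:
                raise SchemaError(f"yield_percent outside [0, 100] for rows: {bad}")
        if "split" in df.columns:
            allowed = {"train", "test", "none"}
            bad_vals = set(df["split"].dropna()) - allowed
            if bad_vals:
                raise SchemaError(
                    f"split tags must be one of {sorted(allowed)}, got {sorted(bad_vals)}"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ligand_ids(self) -> list[str]:
        return self.df["ligand_id"].astype(str).tolist()

    @property
    def descriptor_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in RESERVED_COLUMNS]

    def rows_with(self, columns: Sequence[str]) -> np.ndarray:
        """Boolean mask of rows with all ``columns`` present (non-missing)."""
        missing = [c for c in columns if c not in self.df.columns]
        if missing:
            raise SchemaError(f"columns not in table: {missing}")
        return self.df[list(columns)].notna().all(axis=1).to_numpy()

    def require_complete(self, columns: Sequence[str]) -> None:
        """Fail loudly if any row misses a value in ``columns``."""
        mask = self.rows_with(columns)
        if not mask.all():
            bad = self.df.loc[~mask, "ligand_id"].tolist()
            raise SchemaError(
                f"rows with missing values in {list(columns)}: {bad} "
                "(no silent imputation; fix or drop explicitly)"
            )

    def split_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(train_rows, test_rows) positional indices from the split column."""
        if "split" not in self.df.columns:
            raise SchemaError("table has no 'split' column")
        tags = self.df["split"].to_numpy()
        return np.flatnonzero(tags == "train"), np.flatnonzero(tags == "test")

    def matrix(self, features: Sequence[str], rows: np.ndarray | None = None) -> np.ndarray:
        cols = [resolve_alias(f, self.df.columns) for f in features]
        sub = self.df[cols] if rows is None else self.df[cols].iloc[rows]
        return sub.to_numpy(dtype=float)

    def column(self, name: str, rows: np.ndarray | None = None) -> np.ndarray:
        col = resolve_alias(name, self.df.columns)
        s = self.df[col] if rows is None else self.df[col].iloc[rows]
        return s.to_numpy(dtype=float)


def resolve_alias(name: str, columns: Sequence[str]) -> str:
    """Resolve a descriptor name, accepting the field's shorthand aliases."""
    if name in columns:
        return name
    alias = DEFAULT_ALIASES.get(name)
    if alias is not None and alias in columns:
        return alias
    raise SchemaError(f"descriptor {name!r} not found in table columns")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def load_table(path: str | Path, aliases: Mapping[str, str] | None = None) -> DescriptorTable:
    """Load a delimited descriptor table (CSV or TSV by extension).

    A sidecar ``<path>.provenance.json`` written by :func:`save_table` is
    restored when present.  Shorthand column headers listed in the alias map
    are renamed to their canonical form on load.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    rename = dict(DEFAULT_ALIASES if aliases is None else aliases)
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
    prov_path = path.with_name(path.name + ".provenance.json")
    provenance = {}
    if prov_path.exists():
        provenance = json.loads(prov_path.read_text())
    return DescriptorTable(df=df, provenance=provenance)


def save_table(table: DescriptorTable, path: str | Path, float_format: str = "%.12g") -> None:
    """Write the table plus its column-provenance sidecar JSON."""
    path = Path(path)
    table.df.to_csv(path, sep=_sep_for(path), index=False, float_format=float_format)
    prov_path = path.with_name(path.name + ".provenance.json")
    prov_path.write_text(json.dumps(table.provenance, indent=2, sort_keys=True))


@dataclass(frozen=True)
class StericSettings:
    """All knobs of the steric-descriptor computations, hashable for provenance."""

    sphere_radius: float = 3.5
    radii_scale: float = 1.17
    grid_spacing: float = 0.05
    include_h: bool = True
    angular_step: float = 1.0
    radii_provenance: str = "Bondi-1964"

    def settings_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def attach_computed_descriptors(
    table: DescriptorTable,
    geometries: Mapping[str, Molecule],
    settings: StericSettings = StericSettings(),
    radii: RadiiTable | None = None,
) -> DescriptorTable:
    """Add %V_bur and sterimol columns computed from per-ligand geometries.

    Every ligand row must have a geometry whose annotations name the atoms to
    measure: ``metal_center`` for %V_bur; ``attach_atom`` and
    ``substituent_root`` for sterimol (the substituent set defaults to every
    atom except the attach atom).  Row order and count never change; new
    columns carry the settings hash in their provenance.
    """
    ids = table.ligand_ids
    missing = [lig for lig in ids if lig not in geometries]
    if missing:
        raise SchemaError(f"no geometry supplied for ligands: {missing}")

    vbur_col: list[float] = []
    l_col: list[float] = []
    b1_col: list[float] = []
    b5_col: list[float] = []
    for lig in ids:
        mol = geometries[lig]
        ann = mol.annotations
        if "metal_center" not in ann:
            raise SchemaError(f"geometry for {lig!r} lacks a 'metal_center' annotation")
        bv = buried_volume(
            mol,
            center=ann["metal_center"],
            sphere_radius=settings.sphere_radius,
            radii_scale=settings.radii_scale,
            grid_spacing=settings.grid_spacing,
            include_h=settings.include_h,
            radii=radii,
        )
        vbur_col.append(bv.percent_buried)
        if "attach_atom" in ann and "substituent_root" in ann:
            # the substituent is the organic fragment: everything except the
            # attach atom and the metal center (Bondi has no metal-row radii)
            skip = {ann["attach_atom"], ann.get("metal_center", -1)}
            members = [i for i in range(len(mol.atoms)) if i not in skip]
            st = sterimol(
                mol,
                attach=ann["attach_atom"],
                root=ann["substituent_root"],
                substituent=members,
                angular_step=settings.angular_step,
                radii=radii,
            )
            l_col.append(st.L)
            b1_col.append(st.B1)
            b5_col.append(st.B5)
        else:
            l_col.append(np.nan)
            b1_col.append(np.nan)
            b5_col.append(np.nan)

    df = table.df.copy()
    df["vbur_M_CMC"] = vbur_col
    prov = dict(table.provenance)
    meta = {"settings": asdict(settings), "settings_hash": settings.settings_hash()}
    prov["vbur_M_CMC"] = meta
    if not all(np.isnan(v) for v in l_col):
        df["s_L_FL"] = l_col
        df["s_B1_FL"] = b1_col
        df["s_B5_FL"] = b5_col
        for c in ("s_L_FL", "s_B1_FL", "s_B5_FL"):
            prov[c] = meta
    return DescriptorTable(df=df, provenance=prov)
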