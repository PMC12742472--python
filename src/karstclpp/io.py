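"""Readers and writers for plate exports, OTU tables, environmental tables,
dilution counts, and the substrate registry.

All formats are plain TSV. Two plate-export dialects are supported:

* long — header ``well  wavelength_nm  time_h  od``, one reading per line;
* wide — repeated 8x12 OD grids, each preceded by a comment line
  ``# wavelength=<nm> time_h=<t>``, rows labelled A-H.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CultivationCondition,
    DilutionCount,
    EnvTable,
    OtuTable,
    ParseError,
    PlateLayout,
    PlateSeries,
    ROW_LABELS,
    ValidationError,
    logical_positions,
)

_RESERVED_ENV_COLUMNS = ("unit", "limit", "comparison")


def _data_path(name: str):
    return importlib.resources.files("karstclpp.data").joinpath(name)


# ---------------------------------------------------------------- substrate registry

def read_substrate_registry(path) -> PlateLayout:
    """Load a position → substrate registry (TSV with columns
    ``position`` and ``substrate``) into a :class:`PlateLayout`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"position", "substrate"}.issubset(df.columns):
        raise ParseError(f"{path}: registry needs columns position, substrate")
    mapping = dict(zip(df["position"].str.strip(), df["substrate"].str.strip()))
    return PlateLayout(substrate_map=mapping)


def default_layout() -> PlateLayout:
    """The standard EcoPlate layout: water control at A1 and 31 carbon
    sources at A2..H4."""
    with importlib.resources.as_file(_data_path("ecoplate_substrates.tsv")) as p:
        return read_substrate_registry(p)


# ---------------------------------------------------------------- plate series

def read_plate_series(
    path, layout: PlateLayout, condition: CultivationCondition,
    sample_id: str | None = None,
) -> PlateSeries:
    """Read a plate OD export (long or wide dialect, auto-detected)."""
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("#") and "wavelength=" in head:
        data = _read_plate_wide(path)
    else:
        data = pd.read_csv(path, sep="\t")
        required = {"well", "wavelength_nm", "time_h", "od"}
        if not required.issubset(data.columns):
            raise ParseError(
                f"{path}: long plate format needs columns {sorted(required)}"
            )
    return PlateSeries(
        sample_id=sample_id or path.stem,
        condition=condition,
        layout=layout,
        data=data[["well", "wavelength_nm", "time_h", "od"]].astype(
            {"wavelength_nm": int, "time_h": float, "od": float}
        ),
    )


def _read_plate_wide(path: Path) -> pd.DataFrame:
    records = []
    wavelength = time_h = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                fields = dict(
                    kv.split("=") for kv in line.lstrip("# ").split() if "=" in kv
                )
                try:
                    wavelength = int(fields["wavelength"])
                    time_h = float(fields["time_h"])
                except (KeyError, ValueError):
                    raise ParseError(
                        f"{path}:{lineno}: block header must carry "
                        f"wavelength=<nm> time_h=<t>"
                    ) from None
                continue
            if wavelength is None:
                raise ParseError(f"{path}:{lineno}: data before block header")
            cells = line.split("\t")
            row = cells[0].strip()
            if row not in ROW_LABELS:
                raise ParseError(f"{path}:{lineno}: bad row label {row!r}")
            if len(cells) != 13:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 OD values for row {row}"
                )
            for col, cell in enumerate(cells[1:], 1):
                try:
                    od = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric OD {cell!r} at "
                        f"{row}{col}"
                    ) from None
                records.append((f"{row}{col}", wavelength, time_h, od))
    return pd.DataFrame(records, columns=["well", "wavelength_nm", "time_h", "od"])


def write_plate_series(series: PlateSeries, path, dialect: str = "long") -> None:
    path = Path(path)
    if dialect == "long":
        out = series.data.sort_values(
            ["time_h", "wavelength_nm", "well"], kind="stable"
        )
        out.to_csv(path, sep="\t", index=False)
    elif dialect == "wide":
        with open(path, "w") as fh:
            for t in series.times_h:
                for wl in (590, 750):
                    od = series.od(wl, t)
                    fh.write(f"# wavelength={wl} time_h={t:g}\n")
                    for r in ROW_LABELS:
                        vals = [f"{od[f'{r}{c}']:.4f}" for c in range(1, 13)]
                        fh.write("\t".join([r] + vals) + "\n")
    else:
        raise ValidationError(f"unknown plate dialect {dialect!r}")


# ---------------------------------------------------------------- OTU tables

def read_otu_table(path, orientation: str = "taxa_by_samples") -> OtuTable:
    """Read a TSV count table. First column holds taxon labels
    (semicolon-delimited lineages accepted) unless
    ``orientation='samples_by_taxa'``, in which case rows are samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "samples_by_taxa":
        df = df.T
    elif orientation != "taxa_by_samples":
        raise ValidationError(f"unknown orientation {orientation!r}")
    return OtuTable(counts=df)


def write_otu_table(table: OtuTable, path) -> None:
    table.counts.rename_axis("taxon").to_csv(path, sep="\t")


# ---------------------------------------------------------------- environmental tables

def _parse_env_cell(cell: str, parameter: str, sample: str):
    """Return (value, censored). Censored cells look like ``<0.40``."""
    cell = str(cell).strip()
    if cell.startswith("<"):
        try:
            return float(cell[1:]), True
        except ValueError:
            raise ParseError(
                f"bad censored cell {cell!r} at parameter {parameter!r}, "
                f"sample {sample!r}"
            ) from None
    try:
        return float(cell), False
    except ValueError:
        raise ParseError(
            f"non-numeric cell {cell!r} at parameter {parameter!r}, "
            f"sample {sample!r}"
        ) from None


def read_env_table(path) -> EnvTable:
    """Read a physicochemical table: rows are parameters; columns are
    ``parameter, unit, limit, <sample...>[, comparison]``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).set_index(
        "parameter"
    )
    sample_cols = [c for c in df.columns if c not in _RESERVED_ENV_COLUMNS]
    values = pd.DataFrame(index=df.index, columns=sample_cols, dtype=float)
    censored = pd.DataFrame(False, index=df.index, columns=sample_cols)
    for p in df.index:
        for s in sample_cols:
            v, c = _parse_env_cell(df.loc[p, s], p, s)
            values.loc[p, s] = v
            censored.loc[p, s] = c
    units = df["unit"].fillna("") if "unit" in df.columns else pd.Series("", index=df.index)
    limits = None
    if "limit" in df.columns:
        limits = pd.to_numeric(df["limit"], errors="coerce")
    comparison = None
    if "comparison" in df.columns:
        comparison = pd.Series(
            [_parse_env_cell(df.loc[p, "comparison"], p, "comparison")[0] for p in df.index],
            index=df.index, dtype=float,
        )
    return EnvTable(
        values=values, units=units, censored=censored,
        regulatory_limit=limits, comparison=comparison,
    )


def write_env_table(table: EnvTable, path) -> None:
    out = pd.DataFrame(index=table.values.index)
    out["unit"] = table.units
    if table.regulatory_limit is not None:
        out["limit"] = table.regulatory_limit
    for s in table.samples:
        cells = []
        for p in table.parameters:
            v = table.values.loc[p, s]
            if table.censored.loc[p, s]:
                cells.append(f"<{v:g}")
            else:
                cells.append(f"{v:g}")
        out[s] = cells
    if table.comparison is not None:
        out["comparison"] = [f"{v:g}" for v in table.comparison]
    out.rename_axis("parameter").to_csv(path, sep="\t")


def load_sediment_geochemistry() -> EnvTable:
    """The packaged cave-sediment geochemistry table (8 samples, 22
    parameters, with regulatory soil limits and a comparison-site column)."""
    with importlib.resources.as_file(_data_path("sediment_geochemistry.tsv")) as p:
        return read_env_table(p)


def load_sediment_diversity_survey() -> pd.DataFrame:
    """Packaged per-sample sequencing summary (reads, OTU richness, Shannon,
    Simpson) for the 8 sediment samples."""
    with importlib.resources.as_file(_data_path("sediment_diversity_survey.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col=0)


# ---------------------------------------------------------------- dilution counts

_DILUTION_COLUMNS = [
    "sample_id", "medium", "condition", "counts", "dilution_exponent",
    "volume_plated_ml", "suspension_volume_ml", "wet_mass_g",
    "dry_mass_fraction",
]


def read_dilution_counts(path) -> list[DilutionCount]:
    """Read dilution plating records; ``counts`` is a comma-separated list of
    replicate colony counts."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_DILUTION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        counts = tuple(int(c) for c in str(row["counts"]).split(",") if c.strip())
        records.append(DilutionCount(
            sample_id=row["sample_id"], medium=row["medium"],
            condition=row["condition"], counts=counts,
            dilution_exponent=int(row["dilution_exponent"]),
            volume_plated_ml=float(row["volume_plated_ml"]),
            suspension_volume_ml=float(row["suspension_volume_ml"]),
            wet_mass_g=float(row["wet_mass_g"]),
            dry_mass_fraction=float(row["dry_mass_fraction"]),
        ))
    return records


def write_dilution_counts(records: list[DilutionCount], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id, "medium": r.medium,
            "condition": r.condition,
            "counts": ",".join(str(c) for c in r.counts),
            "dilution_exponent": r.dilution_exponent,
            "volume_plated_ml": r.volume_plated_ml,
            "suspension_volume_ml": r.suspension_volume_ml,
            "wet_mass_g": r.wet_mass_g,
            "dry_mass_fraction": r.dry_mass_fraction,
        })
    pd.DataFrame(rows, columns=_DILUTION_COLUMNS).to_csv(path, sep="\t", index=False)
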