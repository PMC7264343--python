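"""Bottle-CSV schema, run configuration, and table round-tripping.

The bottle schema (exact headers, in order)::

    cruise, station, date_iso, lat_degn, lon_dege, sst_c, sss,
    ta_umol_kg, dic_umol_kg, do_percent, no3_umol_kg, po4_umol_kg,
    sio4_umol_kg, label

Dates are ISO-8601; coordinates decimal degrees, east-positive; all
concentrations umol kg-1.  Numeric CSV output is fixed to 6
significant digits so re-runs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BOTTLE_COLUMNS",
    "SchemaError",
    "RunConfig",
    "read_bottle_csv",
    "write_csv",
]

log = logging.getLogger(__name__)

BOTTLE_COLUMNS = (
    "cruise",
    "station",
    "date_iso",
    "lat_degn",
    "lon_dege",
    "sst_c",
    "sss",
    "ta_umol_kg",
    "dic_umol_kg",
    "do_percent",
    "no3_umol_kg",
    "po4_umol_kg",
    "sio4_umol_kg",
    "label",
)

_NUMERIC = (
    "lat_degn",
    "lon_dege",
    "sst_c",
    "sss",
    "ta_umol_kg",
    "dic_umol_kg",
    "do_percent",
    "no3_umol_kg",
    "po4_umol_kg",
    "sio4_umol_kg",
)

#: columns a row must carry to be speciated downstream
_MANDATORY_NUMERIC = ("sst_c", "sss", "ta_umol_kg", "dic_umol_kg")


class SchemaError(ValueError):
    """The file does not match the bottle-CSV schema."""


@dataclass
class RunConfig:
    """Flat, YAML-round-trippable run configuration.

    Every default is an assumption of this artifact unless noted:
    ``pco2_atm`` (395 uatm), the TA-S anchoring (S=35 -> 2280), winds
    (7 / 10.5 m s-1) and the winter-mixing rate follow the source
    analysis conventions; ``mld_m`` and the reference state span are
    engineering defaults.
    """

    borate: str = "uppstrom74"
    fugacity: bool = True
    ref_pco2: float = 395.0
    ref_ta: float = 2280.0
    ref_sal: float = 35.0
    ref_temp: float = 18.0
    pco2_atm: float = 395.0
    region: str = "nwa"
    mld_m: float = 20.0
    seed: int = 0
    out_dir: str = "."
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        return cls(**kwargs)


def read_bottle_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a bottle CSV into a typed transect table.

    Rows missing TA or DIC (or SST/SSS) are kept but flagged via a
    boolean ``speciable`` column and a logged count; non-numeric cells
    in numeric columns raise a row-level error report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in BOTTLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"bottle CSV {path} missing mandatory column(s): {', '.join(missing)}")

    bad_cells: list[str] = []
    for col in _NUMERIC:
        raw = df[col].replace("", np.nan)
        converted = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & converted.isna()
        for idx in df.index[bad]:
            bad_cells.append(f"row {idx + 1}, column {col!r}: {df.at[idx, col]!r}")
        df[col] = converted
    if bad_cells:
        raise SchemaError(
            f"bottle CSV {path} has non-numeric cells:\n  " + "\n  ".join(bad_cells)
        )

    df["station"] = pd.to_numeric(df["station"], errors="coerce").astype("Int64")
    df["speciable"] = df[list(_MANDATORY_NUMERIC)].notna().all(axis=1)
    n_excluded = int((~df["speciable"]).sum())
    if n_excluded:
        log.warning(
            "read_bottle_csv: %d of %d rows lack TA/DIC/SST/SSS and are excluded "
            "from speciation",
            n_excluded,
            len(df),
        )
    return df


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table with numeric cells fixed to 6 significant digits."""
    df.to_csv(path, index=False, float_format="%.6g")
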