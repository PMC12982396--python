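"""Reading and writing the pipeline's on-disk formats.

Event tables are CSV or Parquet (by file suffix) with the channel columns in
linear intensity; counts, profiles and expression tables are TSV. An
optional FCS ingestion adapter maps instrument channel names ($PnN) onto the
required columns via a user-supplied channel map; it needs the third-party
``fcsparser`` package and degrades with a clear error when that is absent.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .gating import PopulationCounts, REQUIRED_COLUMNS


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".parquet":
        events.to_parquet(path, index=False)
    else:
        events.to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        events = pd.read_parquet(path)
    else:
        events = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"{path}: missing required channels {missing}")
    return events


def standardize_channels(events: pd.DataFrame,
                         channel_map: Mapping[str, str]) -> pd.DataFrame:
    """Rename instrument channel names to the required column names.

    ``channel_map`` maps source names (e.g. FCS $PnN values) to the required
    columns (FSC_A, FSC_H, SSC_A, CD45, CD123, HLA_DR, CD63).
    """
    out = events.rename(columns=dict(channel_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"channel map leaves required columns missing: {missing}")
    return out


def read_fcs(path: str | Path, channel_map: Mapping[str, str]) -> pd.DataFrame:
    """Read an FCS 3.0/3.1 file into an event table (optional adapter)."""
    try:
        import fcsparser
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "FCS ingestion requires the optional 'fcsparser' package; "
            "install it or convert the file to CSV/Parquet with the channel "
            "columns " + ", ".join(REQUIRED_COLUMNS)
        ) from exc
    _, data = fcsparser.parse(str(path))
    return standardize_channels(pd.DataFrame(data), channel_map)


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def write_counts(counts: Sequence[PopulationCounts], path: str | Path) -> Path:
    from .gating import counts_table

    path = Path(path)
    counts_table(counts).to_csv(path, sep="\t", index=False)
    return path


def read_counts(path: str | Path) -> list[PopulationCounts]:
    df = pd.read_csv(path, sep="\t")
    fields = ["n_total", "n_singlets", "n_cd45", "n_basophil_intact",
              "n_basophil_altered", "n_cd63pos", "n_fsc_zero_dropped"]
    return [
        PopulationCounts(
            donor_id=str(row["donor_id"]), condition=str(row["condition"]),
            **{f: int(row[f]) for f in fields if f in df.columns},
        )
        for _, row in df.iterrows()
    ]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
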