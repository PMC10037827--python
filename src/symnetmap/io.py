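"""Plain-text readers for the pipeline's input layout.

All inputs are CSV/TSV: a phenotype table (one row per subject), a node
catalog, per-subject time-series TSVs (time x region with a header row
of region names), and per-seed structural map CSVs (columns
region,value). The synthetic generator's :func:`~symnetmap.synthetic.
write_cohort` emits exactly this layout.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from ._errors import SchemaError
from .structural import ConnectivityValueMap

__all__ = ["read_pheno", "read_nodes", "read_timeseries_dir", "read_structural_dir"]


def read_pheno(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise SchemaError(f"{path}: phenotype table needs a subject_id column")
    return df.set_index("subject_id")


def read_nodes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "region" not in df.columns:
        raise SchemaError(f"{path}: node catalog needs a region column")
    return df


def read_timeseries_dir(path) -> dict[str, pd.DataFrame]:
    path = Path(path)
    out = {}
    for f in sorted(path.glob("*.tsv")):
        out[f.stem] = pd.read_csv(f, sep="\t")
    if not out:
        raise SchemaError(f"{path}: no time-series TSV files found")
    return out


def read_structural_dir(path) -> dict[str, list[ConnectivityValueMap]]:
    """Read ``<path>/<seed>/<subject>.csv`` maps into per-seed lists."""
    path = Path(path)
    out: dict[str, list[ConnectivityValueMap]] = {}
    for seed_dir in sorted(p for p in path.iterdir() if p.is_dir()):
        maps = []
        for f in sorted(seed_dir.glob("*.csv")):
            df = pd.read_csv(f)
            if not {"region", "value"} <= set(df.columns):
                raise SchemaError(f"{f}: structural map needs region,value columns")
            maps.append(
                ConnectivityValueMap(
                    subject_id=f.stem,
                    seed_id=seed_dir.name,
                    values=df.set_index("region")["value"],
                )
            )
        if maps:
            out[seed_dir.name] = maps
    if not out:
        raise SchemaError(f"{path}: no structural maps found")
    return out
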