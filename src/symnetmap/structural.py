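"""Structural-constraint node screening.

Probabilistic tractography from a hippocampal seed yields, per subject,
a map of connectivity values over target units (cortical regions, or
voxels later reduced to regions). A target is structurally connected for
a subject when its value reaches a fraction of that subject's maximum
(the field-standard 15%-of-max rule); a region enters the candidate node
set when it is suprathreshold in at least a consensus fraction of
subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DegenerateInputError, SchemaError

__all__ = [
    "ConnectivityValueMap",
    "WMConnectionTable",
    "threshold_map",
    "consensus_nodes",
    "consensus_from_flags",
    "reduce_voxel_map",
]


@dataclass(frozen=True)
class ConnectivityValueMap:
    """One subject's connectivity value map for one seed.

    ``values`` is a nonnegative Series indexed by target unit (region
    name or voxel id).
    """

    subject_id: str
    seed_id: str
    values: pd.Series

    def __post_init__(self):
        vals = pd.Series(self.values, dtype=float)
        if (vals < 0).any():
            bad = vals.index[vals < 0][0]
            raise SchemaError(
                f"map {self.subject_id}/{self.seed_id}: negative value at {bad!r}"
            )
        object.__setattr__(self, "values", vals)


@dataclass
class WMConnectionTable:
    """Per-seed consensus of thresholded structural maps.

    ``flags`` is subjects x regions boolean (suprathreshold per subject);
    ``support`` the per-region fraction of flagged subjects; ``connected``
    the consensus decision.
    """

    seed_id: str
    flags: pd.DataFrame
    support: pd.Series
    connected: pd.Series
    threshold_fraction: float
    consensus_fraction: float

    @property
    def connected_regions(self) -> list:
        return list(self.connected.index[self.connected])

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-region summary for CSV output."""
        return pd.DataFrame(
            {
                "seed": self.seed_id,
                "n_suprathreshold": self.flags.sum(axis=0).astype(int),
                "n_subjects": len(self.flags),
                "support": self.support,
                "connected": self.connected,
                "threshold_fraction": self.threshold_fraction,
                "consensus_fraction": self.consensus_fraction,
            }
        ).rename_axis("region")


def _as_series(cvmap) -> pd.Series:
    if isinstance(cvmap, ConnectivityValueMap):
        return cvmap.values
    return pd.Series(cvmap, dtype=float)


def threshold_map(cvmap, fraction: float = 0.15) -> pd.Index:
    """Target units whose value reaches ``fraction`` of the map maximum.

    The comparison is inclusive (>=), so the unit attaining the maximum
    is always retained and an all-equal positive map keeps every unit.

    Raises
    ------
    ConfigurationError
        If ``fraction`` is outside (0, 1].
    DegenerateInputError
        If the map is all zero (no connection resolvable).
    """
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError(f"fraction must be in (0, 1], got {fraction}")
    values = _as_series(cvmap)
    if (values < 0).any():
        raise SchemaError("connectivity values must be nonnegative")
    vmax = float(values.max()) if len(values) else 0.0
    if vmax <= 0.0:
        raise DegenerateInputError("all-zero connectivity map: no connections resolvable")
    return values.index[values >= fraction * vmax]


def consensus_from_flags(flags: pd.DataFrame, consensus: float) -> pd.Series:
    """Consensus decision from per-subject boolean flags (subjects x regions)."""
    if not 0.0 < consensus <= 1.0:
        raise ConfigurationError(f"consensus must be in (0, 1], got {consensus}")
    return flags.mean(axis=0) >= consensus


def consensus_nodes(
    maps: Sequence[ConnectivityValueMap],
    fraction: float = 0.15,
    consensus: float = 0.5,
) -> WMConnectionTable:
    """Group-consensus structurally connected regions for one seed.

    A region is consensus-connected iff the fraction of subjects in which
    it is suprathreshold (per :func:`threshold_map`) is at least
    ``consensus``. Output ordering follows the shared target index.
    """
    if len(maps) < 2:
        raise ValueError("consensus needs at least 2 subjects")
    seed_ids = {m.seed_id for m in maps}
    if len(seed_ids) != 1:
        raise SchemaError(f"maps mix seeds: {sorted(seed_ids)}")
    ref = maps[0].values.index
    for m in maps[1:]:
        if not m.values.index.equals(ref):
            raise SchemaError(
                f"subject {m.subject_id!r}: target index differs from "
                f"subject {maps[0].subject_id!r}"
            )
    flags = pd.DataFrame(
        {
            m.subject_id: pd.Series(
                ref.isin(threshold_map(m, fraction)), index=ref
            )
            for m in maps
        }
    ).T
    support = flags.mean(axis=0)
    connected = consensus_from_flags(flags, consensus)
    return WMConnectionTable(
        seed_id=maps[0].seed_id,
        flags=flags,
        support=support,
        connected=connected,
        threshold_fraction=fraction,
        consensus_fraction=consensus,
    )


def reduce_voxel_map(
    cvmap,
    voxel_regions: pd.Series,
    fraction: float = 0.15,
    min_voxels: int = 1,
) -> pd.Series:
    """Reduce a voxel-level map to region-level suprathreshold flags.

    ``voxel_regions`` maps voxel id -> region name. A region is flagged
    when at least ``min_voxels`` of its voxels are suprathreshold under
    the per-map :func:`threshold_map` rule.
    """
    values = _as_series(cvmap)
    voxel_regions = pd.Series(voxel_regions)
    missing = values.index.difference(voxel_regions.index)
    if len(missing):
        raise SchemaError(f"voxels without region label: {list(missing)[:5]}")
    supra = threshold_map(values, fraction)
    counts = voxel_regions.loc[supra].value_counts()
    regions = pd.Index(pd.unique(voxel_regions.loc[values.index]))
    counts = counts.reindex(regions, fill_value=0)
    return counts >= int(min_voxels)
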