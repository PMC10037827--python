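"""Seed-based functional connectivity.

Functional connectivity (FC) between two brain regions is the Pearson
correlation of their mean BOLD time series, standardized through Fisher's
z transform, ``z = atanh(r)``, so that FC values are approximately normal
and comparable across subjects. The full node-by-node Fisher-z matrix
feeds the graph analysis; individual hippocampus-cortex pairs feed the
node-selection model.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import DegenerateInputError, SchemaError

__all__ = [
    "pearson_fc",
    "fisher_z",
    "inverse_fisher_z",
    "build_fc_matrices",
    "seed_target_z",
]

#: clip bound applied when ``clip=True`` and |r| reaches 1
_CLIP = 1.0 - 1e-7


def pearson_fc(x, y) -> float:
    """Pearson correlation between two equal-length series.

    Raises
    ------
    ValueError
        If the series differ in length, are shorter than 3 points, or
        contain non-finite values.
    DegenerateInputError
        If either series has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("series must be one-dimensional and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 time points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series contain non-finite values")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx <= 0.0 or vy <= 0.0:
        raise DegenerateInputError("zero-variance series has no defined correlation")
    r = float(xc @ yc) / np.sqrt(vx * vy)
    # guard against rounding just past the boundary
    return float(np.clip(r, -1.0, 1.0))


def fisher_z(r, clip: bool = False):
    """Fisher z transform, ``z = 0.5 * ln((1+r)/(1-r))``.

    Accepts scalars or arrays. With ``clip=True`` correlations at or past
    |r| = 1 are pulled back to 1 - 1e-7 instead of raising.
    """
    r = np.asarray(r, dtype=float)
    if clip:
        r = np.clip(r, -_CLIP, _CLIP)
    elif np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| >= 1 has no finite Fisher z; pass clip=True to clip")
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def inverse_fisher_z(z):
    """Inverse transform, ``r = tanh(z)``."""
    z = np.asarray(z, dtype=float)
    r = np.tanh(z)
    return float(r) if r.ndim == 0 else r


def build_fc_matrices(
    timeseries: Mapping[str, pd.DataFrame],
    nodes: Sequence[str],
    clip: bool = False,
) -> dict[str, pd.DataFrame]:
    """Per-subject symmetric Fisher-z FC matrices over the given nodes.

    Parameters
    ----------
    timeseries
        Mapping subject id -> (time x region) DataFrame with region-name
        columns.
    nodes
        Region names to include, in catalog order.
    clip
        Forwarded to :func:`fisher_z`; without it a perfectly correlated
        region pair raises :class:`DegenerateInputError`.

    Returns
    -------
    dict of subject id -> square DataFrame with NaN on the diagonal.
    """
    nodes = list(nodes)
    out: dict[str, pd.DataFrame] = {}
    for subject, ts in timeseries.items():
        missing = [n for n in nodes if n not in ts.columns]
        if missing:
            raise SchemaError(
                f"subject {subject!r}: time series missing nodes {missing}"
            )
        arr = ts[nodes].to_numpy(dtype=float)
        if arr.shape[0] < 3:
            raise ValueError(f"subject {subject!r}: need at least 3 time points")
        if not np.isfinite(arr).all():
            raise ValueError(f"subject {subject!r}: non-finite values in time series")
        sd = arr.std(axis=0)
        flat = [nodes[i] for i in np.flatnonzero(sd == 0.0)]
        if flat:
            raise DegenerateInputError(
                f"subject {subject!r}: zero-variance series for {flat}"
            )
        r = np.corrcoef(arr, rowvar=False)
        off = ~np.eye(len(nodes), dtype=bool)
        if not clip and np.any(np.abs(r[off]) >= 1.0):
            i, j = np.argwhere((np.abs(r) >= 1.0) & off)[0]
            raise DegenerateInputError(
                f"subject {subject!r}: |r| = 1 between {nodes[i]!r} and "
                f"{nodes[j]!r} (duplicated signal?); pass clip=True to force"
            )
        z = fisher_z(np.where(off, r, 0.0), clip=clip)
        z = (z + z.T) / 2.0  # exact symmetry
        np.fill_diagonal(z, np.nan)
        out[subject] = pd.DataFrame(z, index=nodes, columns=nodes)
    return out


def seed_target_z(
    fc: Mapping[str, pd.DataFrame],
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Extract seed-target Fisher-z values as a subjects x pairs table.

    Column names follow the ``FC_<seed>-<target>`` convention.
    """
    cols = {}
    for seed, target in pairs:
        name = f"FC_{seed}-{target}"
        vals = {}
        for subject, mat in fc.items():
            if seed not in mat.index or target not in mat.columns:
                raise SchemaError(f"pair ({seed!r}, {target!r}) absent from FC matrix")
            vals[subject] = mat.loc[seed, target]
        cols[name] = vals
    return pd.DataFrame(cols)
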