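"""HDF5 pipeline container and standard-format exports.

One self-describing HDF5 file carries the whole pipeline state under fixed
groups (``/sensor``, ``/leadfields``, ``/hmm``, ``/source``, ``/maps``,
``/meta``); state sequences and summaries have TSV sidecar writers, and
statistic maps export to NIfTI-1 volumes with an affine built from the
voxel grid.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

CONTAINER_VERSION = "1"

KNOWN_GROUPS = ("sensor", "leadfields", "hmm", "source", "maps", "meta")


def write_container(path, groups: dict, attrs: dict | None = None) -> Path:
    """Write nested ``{group: {name: array-or-scalar}}`` to HDF5."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["container_version"] = CONTAINER_VERSION
        for key, val in (attrs or {}).items():
            f.attrs[key] = val
        for gname, items in groups.items():
            g = f.create_group(gname)
            for name, value in items.items():
                arr = np.asarray(value)
                if arr.dtype.kind in "US":
                    g.attrs[name] = str(value)
                elif arr.ndim == 0:
                    g.attrs[name] = arr[()]
                else:
                    g.create_dataset(name, data=arr)
    return path


def read_container(path, require: tuple | list = ()) -> dict:
    """Read an HDF5 container back into nested dicts (arrays + attrs)."""
    import h5py

    path = Path(path)
    out: dict = {}
    with h5py.File(path, "r") as f:
        version = f.attrs.get("container_version")
        if version != CONTAINER_VERSION:
            raise ValueError(
                f"container version {version!r} does not match expected "
                f"{CONTAINER_VERSION!r}; regenerate the container"
            )
        for gname in require:
            if gname not in f:
                raise KeyError(f"required group '/{gname}' missing from {path}")
        for gname in f.keys():
            g = f[gname]
            items = {name: g[name][()] for name in g.keys()}
            items.update({k: g.attrs[k] for k in g.attrs.keys()})
            out[gname] = items
        out["_attrs"] = dict(f.attrs)
    return out


def write_state_tsv(path, labels: np.ndarray, fs: float) -> Path:
    """State sequence as TSV: sample_index, time_s, state."""
    import pandas as pd

    path = Path(path)
    idx = np.arange(labels.size)
    pd.DataFrame(
        {"sample_index": idx, "time_s": idx / fs, "state": labels}
    ).to_csv(path, sep="\t", index=False)
    return path


def write_summary_tsv(path, summary) -> Path:
    """State summary as TSV (state, fractional_occupancy, ...)."""
    import pandas as pd

    path = Path(path)
    K = summary.fractional_occupancy.size
    pd.DataFrame(
        {
            "state": np.arange(1, K + 1),
            "fractional_occupancy": summary.fractional_occupancy,
            "mean_lifetime_s": summary.mean_lifetime_s,
            "n_occurrences": summary.n_occurrences,
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def grid_to_affine(voxels: np.ndarray) -> tuple[np.ndarray, tuple, np.ndarray]:
    """Affine + shape + flat indices for a regular grid of MNI coordinates.

    Voxel ordering is x fastest.  Raises on an irregular grid.
    """
    voxels = np.atleast_2d(np.asarray(voxels, float))
    axes = []
    for dim in range(3):
        vals = np.unique(voxels[:, dim])
        if vals.size > 1:
            steps = np.diff(vals)
            if not np.allclose(steps, steps[0], atol=1e-6):
                raise ValueError(f"irregular grid spacing along axis {dim}")
            axes.append((vals, float(steps[0])))
        else:
            axes.append((vals, 1.0))
    shape = tuple(len(a[0]) for a in axes)
    affine = np.eye(4)
    for dim in range(3):
        affine[dim, dim] = axes[dim][1]
        affine[dim, 3] = axes[dim][0][0]
    ijk = np.empty((voxels.shape[0], 3), dtype=int)
    for dim in range(3):
        ijk[:, dim] = np.searchsorted(axes[dim][0], voxels[:, dim])
    return affine, shape, ijk


def export_nifti(stat_map, path) -> Path:
    """Write a StatMap as a NIfTI-1 volume (null marker stored as NaN)."""
    import nibabel as nib

    if stat_map.grid is None:
        raise ValueError("stat map has no voxel grid attached")
    affine, shape, ijk = grid_to_affine(stat_map.grid)
    vol = np.full(shape, np.nan)
    vals = stat_map.masked_values
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = vals
    img = nib.Nifti1Image(vol, affine)
    nib.save(img, str(path))
    return Path(path)
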