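"""Reading and writing the standard on-disk formats.

Volumes are NIfTI-1 (via nibabel), gradient tables FSL-style plain-text
bval/bvec files, cohort and region tables tab-separated values, and
configuration YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .scheme import GradientScheme, scheme_from_bvals_bvecs

__all__ = [
    "save_nifti", "load_nifti", "save_scheme", "load_scheme",
    "save_table", "load_table", "load_yaml", "save_yaml", "save_json",
]


def save_nifti(data: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_scheme(scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    """FSL convention: bvals on one row, bvecs as three rows (x, y, z)."""
    np.savetxt(str(bval_path), scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(str(bvec_path), scheme.bvecs.T, fmt="%.8f")


def load_scheme(bval_path: str | Path, bvec_path: str | Path) -> GradientScheme:
    bvals = np.loadtxt(str(bval_path))
    bvecs = np.loadtxt(str(bvec_path))
    return scheme_from_bvals_bvecs(bvals, bvecs)


def save_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(str(path), sep="\t", index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def save_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
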