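"""Readers/writers: cohort TSV, map matrices (TSV/NIfTI), model and report JSON.

Tabular payloads are tab-separated UTF-8 with a header row; floats are
serialized at 17 significant digits so write -> read round-trips are
lossless. Volumes use NIfTI-1 via nibabel; voxel vectors flatten x-fastest
(Fortran order), 0-based. Masks must share the map grid exactly — no
resampling is attempted; a mismatch is an error.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

FLOAT_FMT = "%.17g"
COHORT_COLUMNS = [
    "participant_id",
    "group",
    "age",
    "sex",
    "scanner",
    "mean_fd",
    "als",
    "madrs",
    "ymrs",
]
KNOWN_GROUPS = {"HC", "BD", "ADHD", "BPD"}
DEFAULT_GRID = (12, 12, 12)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_cohort(path, known_groups=KNOWN_GROUPS) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns: {missing}")
    unknown = set(df["group"].astype(str)) - set(known_groups)
    if known_groups and unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    return df


def write_matrix(X: np.ndarray, path, participant_ids=None) -> None:
    """Participant-by-voxel matrix as TSV (columns v0..v{V-1})."""
    X = np.asarray(X, float)
    df = pd.DataFrame(X, columns=[f"v{j}" for j in range(X.shape[1])])
    if participant_ids is not None:
        df.insert(0, "participant_id", list(participant_ids))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_matrix(path):
    """Returns ``(X, participant_ids)``; ids are None if absent."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    ids = None
    if "participant_id" in df.columns:
        ids = df.pop("participant_id").tolist()
    return df.to_numpy(float), ids


def vector_to_volume(values: np.ndarray, shape=DEFAULT_GRID) -> np.ndarray:
    values = np.asarray(values, float)
    if values.size != int(np.prod(shape)):
        raise ValueError(f"vector length {values.size} does not match grid {shape}")
    return values.reshape(shape, order="F")  # x-fastest


def volume_to_vector(vol: np.ndarray) -> np.ndarray:
    return np.asarray(vol, float).reshape(-1, order="F")


def write_nifti(values: np.ndarray, path, shape=DEFAULT_GRID, affine=None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(vector_to_volume(values, shape), affine), str(path))


def read_nifti_vector(path, expected_shape=None) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if expected_shape is not None and tuple(data.shape) != tuple(expected_shape):
        raise ValueError(f"grid mismatch: volume {data.shape} vs expected {tuple(expected_shape)}")
    return volume_to_vector(data)


def read_motion(path) -> np.ndarray:
    """Six-column whitespace-delimited realignment parameters
    (mm, mm, mm, rad, rad, rad)."""
    m = np.loadtxt(str(path))
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion file must have 6 columns")
    return m


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_model(model, path_json, path_brain_tsv=None) -> None:
    """Serialize a fitted PLSCorrelation: scalars and behavior-side vectors
    to JSON; brain-side saliences optionally to TSV (voxels x components)."""
    payload = {
        "n_components": model.n_components_,
        "n_samples": model.n_samples_,
        "singular_values": model.singular_values_,
        "explained_covariance": model.explained_covariance_,
        "y_saliences": model.y_saliences_,
        "y_mean": model.y_mean_,
        "y_sd": model.y_sd_,
    }
    write_json(payload, path_json)
    if path_brain_tsv is not None:
        pd.DataFrame(
            model.x_saliences_,
            columns=[f"lc{k + 1}" for k in range(model.n_components_)],
        ).to_csv(path_brain_tsv, sep="\t", index=False, float_format=FLOAT_FMT)


def component_table(model, perm_p=None) -> pd.DataFrame:
    """Per-component summary: `lc singular_value explained_cov perm_p r_scores`."""
    rows = []
    for k, comp in enumerate(model.components()):
        rows.append(
            {
                "lc": k + 1,
                "singular_value": comp.singular_value,
                "explained_cov": comp.explained_covariance,
                "perm_p": None if perm_p is None else float(perm_p[k]),
                "r_scores": comp.score_correlation,
            }
        )
    return pd.DataFrame(rows)
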