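"""Readers, writers, run configuration and report files.

Connectivity matrices travel as delimited text (square, node ids as
header row and column); lesion patterns as a wide patients x nodes
table with an optional reserved ``total_volume`` column, or as a long
(patient_id, node_id, lp) table.  Lesion masks and parcellations are
integer-labelled NIfTI volumes on a shared grid — a grid or affine
mismatch is an error, never silently resampled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError
from .lesion_model import LABEL_NAMES, LesionPattern
from .network_metrics import ConnectivityMatrix

_ASYM_TOL = 1e-8

__all__ = [
    "RunConfig",
    "read_connectivity",
    "write_connectivity",
    "read_lesion_patterns",
    "write_lesion_patterns",
    "read_nifti_pair",
    "write_report",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_connectivity(path) -> ConnectivityMatrix:
    """Read a square delimited connectivity matrix with id headers.

    Asymmetry up to 1e-8 is averaged away; anything larger, a NaN cell
    or a non-square table is a :class:`DataError` naming the offender.
    """
    path = Path(path)
    if path.suffix == ".npy":
        return _read_connectivity_npy(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[0] != df.shape[1]:
        raise DataError(f"{path}: matrix is not square ({df.shape[0]}x{df.shape[1]})")
    ids = tuple(str(i) for i in df.index)
    if ids != tuple(str(c) for c in df.columns):
        raise DataError(f"{path}: row and column ids differ")
    w = df.to_numpy(dtype=float)
    if np.isnan(w).any():
        i, j = np.argwhere(np.isnan(w))[0]
        raise DataError(f"{path}: NaN at row {ids[i]}, column {ids[j]}")
    asym = np.abs(w - w.T).max()
    if asym > _ASYM_TOL:
        raise DataError(f"{path}: asymmetry {asym:.3g} exceeds {_ASYM_TOL}")
    return ConnectivityMatrix(ids, (w + w.T) / 2.0)


def write_connectivity(cm: ConnectivityMatrix, path) -> Path:
    """Write a matrix as delimited text (or .npy with a sidecar id list)."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, cm.weights)
        path.with_suffix(".nodes.txt").write_text("\n".join(cm.node_ids) + "\n")
        return path
    pd.DataFrame(cm.weights, index=list(cm.node_ids), columns=list(cm.node_ids)).to_csv(
        path, sep=_sep_for(path)
    )
    return path


def _read_connectivity_npy(path: Path) -> ConnectivityMatrix:
    w = np.load(path)
    sidecar = path.with_suffix(".nodes.txt")
    if not sidecar.exists():
        raise DataError(f"missing node-id sidecar {sidecar}")
    ids = tuple(sidecar.read_text().split())
    return ConnectivityMatrix(ids, w)


def read_lesion_patterns(path, fmt: str = "wide") -> list:
    """Read lesion patterns from a wide or long delimited table.

    Wide: index patient_id, one column per node id, optional reserved
    ``total_volume`` column.  Long: columns patient_id, node_id, lp
    (missing pairs are zero).  If total volume is absent it defaults to
    the summed lesion fraction (parcel units).
    """
    path = Path(path)
    sep = _sep_for(path)
    if fmt == "wide":
        df = pd.read_csv(path, sep=sep, index_col=0)
        tv = df.pop("total_volume") if "total_volume" in df.columns else None
        node_ids = tuple(str(c) for c in df.columns)
        out = []
        for pid, row in df.iterrows():
            lp = row.to_numpy(dtype=float)
            vol = float(tv.loc[pid]) if tv is not None else float(lp.sum())
            out.append(LesionPattern(str(pid), node_ids, lp, vol))
        return out
    if fmt == "long":
        df = pd.read_csv(path, sep=sep, dtype={"patient_id": str, "node_id": str})
        required = {"patient_id", "node_id", "lp"}
        if not required.issubset(df.columns):
            raise DataError(f"{path}: long format needs columns {sorted(required)}")
        wide = df.pivot_table(
            index="patient_id", columns="node_id", values="lp", fill_value=0.0
        )
        out = []
        for pid, row in wide.iterrows():
            lp = row.to_numpy(dtype=float)
            out.append(LesionPattern(str(pid), tuple(wide.columns), lp, float(lp.sum())))
        return out
    raise ConfigError(f"unknown lesion-table format {fmt!r}")


def write_lesion_patterns(patterns, path) -> Path:
    """Write patterns as a wide table with a total_volume column."""
    path = Path(path)
    patterns = list(patterns)
    df = pd.DataFrame(
        [p.lp for p in patterns],
        index=pd.Index([p.patient_id for p in patterns], name="patient_id"),
        columns=list(patterns[0].node_ids),
    )
    df["total_volume"] = [p.total_volume for p in patterns]
    df.to_csv(path, sep=_sep_for(path))
    return path


def read_nifti_pair(mask_path, parcellation_path):
    """Load a lesion mask and a parcellation, enforcing a shared grid.

    Both must be 3-D integer-labelled volumes with equal shapes and
    affines; no resampling is ever performed.
    """
    import nibabel as nib

    mask = nib.load(str(mask_path))
    parc = nib.load(str(parcellation_path))
    for name, img in (("mask", mask), ("parcellation", parc)):
        if len(img.shape) != 3:
            raise DataError(f"{name} must be 3-D, got shape {img.shape}")
    if mask.shape != parc.shape:
        raise DataError(f"grid mismatch: mask {mask.shape} vs parcellation {parc.shape}")
    if not np.allclose(mask.affine, parc.affine, atol=1e-6):
        raise DataError("affine mismatch between mask and parcellation")
    return mask, parc


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration for an end-to-end run."""

    matrices: str = ""
    lesions: str = ""
    out_dir: str = "lesionhub_out"
    labels: tuple = LABEL_NAMES
    sparsity: float = 0.15
    auc_range: tuple | None = None
    auc_step: float = 0.01
    n_random: int = 100
    n_perm: int = 1000
    covariates: tuple = ("total_volume",)
    seed: int = 0

    def validate(self):
        bad = set(self.labels) - set(LABEL_NAMES)
        if bad:
            raise ConfigError(f"labels must be a subset of {LABEL_NAMES}, got {sorted(bad)}")
        if self.auc_range is not None:
            s1, s2 = self.auc_range
            if not (0 < s1 < s2 <= 1):
                raise ConfigError(f"AUC range must satisfy 0 < s1 < s2 <= 1, got {self.auc_range}")
        elif not 0 < self.sparsity <= 1:
            raise ConfigError(f"sparsity must lie in (0, 1], got {self.sparsity}")
        if self.n_perm < 1 or self.n_random < 1:
            raise ConfigError("n_perm and n_random must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("labels", "covariates", "auc_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["labels"] = list(d["labels"])
        d["covariates"] = list(d["covariates"])
        if d["auc_range"] is not None:
            d["auc_range"] = list(d["auc_range"])
        return d


# ---------------------------------------------------------------------------
# report


def write_report(results, hub_table, out_dir, config=None, seed=None) -> dict:
    """Write the standard report files for a completed run.

    Five files: per-patient predictions, per-model accuracy/P summary,
    the unthresholded feature-weight table, the significant-hub table
    with effect classes, and a JSON manifest echoing the configuration
    and seeds so the run is reproducible from the manifest alone.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_test"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise DataError(f"cannot write to output directory {out}: {exc}") from exc

    pred_rows = []
    summary_rows = []
    weight_frames = []
    for name, res in results.items():
        for pid, act, pred in zip(res.patient_ids, res.actual, res.predicted):
            pred_rows.append(
                {"patient_id": pid, "label": name, "actual": act, "predicted": pred}
            )
        summary_rows.append(
            {
                "label": name,
                "accuracy_r": res.accuracy_r,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            }
        )
        ft = res.feature_table()
        ft.insert(0, "label", name)
        weight_frames.append(ft.reset_index())

    paths = {
        "predictions": out / "predictions.tsv",
        "model_summary": out / "model_summary.tsv",
        "feature_weights": out / "feature_weights.tsv",
        "lesion_hubs": out / "lesion_hubs.tsv",
        "manifest": out / "manifest.json",
    }
    pd.DataFrame(pred_rows).to_csv(paths["predictions"], sep="\t", index=False)
    pd.DataFrame(summary_rows).to_csv(paths["model_summary"], sep="\t", index=False)
    pd.concat(weight_frames, ignore_index=True).to_csv(
        paths["feature_weights"], sep="\t", index=False
    )
    if hub_table is None:
        hub_table = pd.DataFrame(
            columns=[
                "locE_sig", "locE_sign", "gE_sig", "gE_sign",
                "sigma_sig", "sigma_sign", "effect_class",
            ],
            index=pd.Index([], name="feature_id"),
        )
    hub_table.to_csv(paths["lesion_hubs"], sep="\t")
    manifest = {
        "package": "lesionhub",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict() if isinstance(config, RunConfig) else config,
        "labels": sorted(results),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return paths
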