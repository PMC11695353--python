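"""Core containers: skeleton masks and multi-metric cohort datasets.

All analysis in this package happens on a *skeleton*: a thinned binary mask of
white-matter tract centres onto which per-subject scalar metric maps have been
projected.  The :class:`SkeletonMask` owns the bijection between 3-D voxel
coordinates and flat vector positions (row-major / C-order over the grid,
0-based), so that every downstream stage can work on ``(n_subjects, n_voxels)``
matrices and still write spatially meaningful NIfTI maps back out.

A :class:`CohortDataset` bundles one such matrix per metric together with the
group labels (``"A"`` = preterm-like, ``"B"`` = term-like control), the mask,
and — for synthetic cohorts — the planted ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_A = "A"
GROUP_B = "B"
VALID_GROUPS = (GROUP_A, GROUP_B)


@dataclasses.dataclass(frozen=True)
class SkeletonMask:
    """Binary 3-D analysis domain with a fixed voxel<->vector index map.

    Parameters
    ----------
    mask : boolean 3-D array
        True at the M skeleton voxels.
    affine : (4, 4) array, optional
        Voxel-to-world transform.  Carried through to every NIfTI written by
        this package but never interpreted; all computation is in voxel space.
    """

    mask: np.ndarray
    affine: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(4, dtype=float)
    )

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {mask.shape}")
        if not mask.any():
            raise ValueError("mask must contain at least one voxel")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "affine", affine)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        """M — number of skeleton voxels."""
        return int(self.mask.sum())

    @property
    def voxel_coords(self) -> np.ndarray:
        """(M, 3) integer coordinates in row-major (C) order.

        Row k is the grid coordinate mapped to vector position k; this is the
        package-wide voxel<->vector bijection.
        """
        return np.argwhere(self.mask)

    # -- volume <-> vector -------------------------------------------------

    def vectorize(self, volume: np.ndarray) -> np.ndarray:
        """Extract the length-M vector of ``volume`` values at mask voxels."""
        volume = np.asarray(volume)
        if volume.shape != self.grid_shape:
            raise ValueError(
                f"volume shape {volume.shape} does not match mask grid "
                f"{self.grid_shape}"
            )
        return volume[self.mask]

    def devectorize(self, vec: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a length-M vector back onto the grid; `fill` elsewhere."""
        vec = np.asarray(vec)
        if vec.shape != (self.n_voxels,):
            raise ValueError(
                f"vector length {vec.shape} does not match mask voxel count "
                f"({self.n_voxels},)"
            )
        out = np.full(self.grid_shape, fill, dtype=np.result_type(vec, float))
        out[self.mask] = vec
        return out

    # -- I/O ----------------------------------------------------------------

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.mask.astype(np.uint8), self.affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "SkeletonMask":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        return cls(mask=data > 0, affine=img.affine)

    def save_map(self, vec: np.ndarray, path: str | Path, fill: float = 0.0) -> None:
        """Write a skeleton vector as a NIfTI volume (fill off-skeleton)."""
        vol = self.devectorize(np.asarray(vec, dtype=float), fill=fill)
        nib.save(nib.Nifti1Image(vol.astype(np.float64), self.affine), str(path))


def vectorize(volume: np.ndarray, mask: SkeletonMask) -> np.ndarray:
    """Functional form of :meth:`SkeletonMask.vectorize`."""
    return mask.vectorize(volume)


def devectorize(vec: np.ndarray, mask: SkeletonMask, fill: float = 0.0) -> np.ndarray:
    """Functional form of :meth:`SkeletonMask.devectorize`."""
    return mask.devectorize(vec, fill=fill)


@dataclasses.dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort (see :mod:`skelfuse.simulate`).

    ``planted_voxels`` maps metric name -> sorted vector indices carrying a
    group effect; ``effect_size`` the corresponding Cohen's d.  ``latent_views``
    are the metrics loaded by the shared group-separating latent component,
    whose per-subject scores are ``latent_scores`` and whose spatial support
    (vector indices) is ``latent_support``.
    """

    planted_voxels: dict[str, np.ndarray]
    effect_size: dict[str, float]
    latent_views: tuple[str, ...]
    latent_scores: np.ndarray
    latent_support: np.ndarray
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_voxels": {
                k: np.asarray(v).astype(int).tolist()
                for k, v in self.planted_voxels.items()
            },
            "effect_size": {k: float(v) for k, v in self.effect_size.items()},
            "latent_views": list(self.latent_views),
            "latent_scores": np.asarray(self.latent_scores, dtype=float).tolist(),
            "latent_support": np.asarray(self.latent_support).astype(int).tolist(),
            "seed": int(self.seed),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_voxels={
                k: np.asarray(v, dtype=int) for k, v in d["planted_voxels"].items()
            },
            effect_size=dict(d["effect_size"]),
            latent_views=tuple(d["latent_views"]),
            latent_scores=np.asarray(d["latent_scores"], dtype=float),
            latent_support=np.asarray(d["latent_support"], dtype=int),
            seed=int(d["seed"]),
        )


@dataclasses.dataclass
class CohortDataset:
    """Two-group multi-metric skeleton dataset.

    ``metrics`` maps metric name -> (N, M) float matrix sharing the subject
    order of ``labels``/``subject_ids`` and the M columns of ``mask``.
    """

    metrics: dict[str, np.ndarray]
    labels: np.ndarray
    subject_ids: list[str]
    mask: SkeletonMask
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        n = len(self.labels)
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids and labels length mismatch")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids")
        bad = set(self.labels) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if not all(g in self.labels for g in VALID_GROUPS):
            raise ValueError("both groups A and B must be non-empty")
        m = self.mask.n_voxels
        for name, mat in self.metrics.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (n, m):
                raise ValueError(
                    f"metric {name!r} has shape {mat.shape}, expected ({n}, {m})"
                )
            if not np.isfinite(mat).all():
                raise ValueError(f"metric {name!r} contains non-finite values")
            self.metrics[name] = mat

    @property
    def n_subjects(self) -> int:
        return len(self.labels)

    @property
    def metric_names(self) -> list[str]:
        return list(self.metrics)

    def group_indices(self, group: str) -> np.ndarray:
        if group not in VALID_GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return np.flatnonzero(self.labels == group)

    def binary_labels(self, positive: str = GROUP_A) -> np.ndarray:
        """0/1 encoding with ``positive`` (default group A) as 1."""
        return (self.labels == positive).astype(int)

    # -- I/O ----------------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write mask, per-subject NIfTI volumes, TSV table, ground truth."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.mask.to_nifti(directory / "mask.nii.gz")
        pd.DataFrame(
            {"subject_id": self.subject_ids, "group": self.labels}
        ).to_csv(directory / "subjects.tsv", sep="\t", index=False)
        for name, mat in self.metrics.items():
            mdir = directory / name
            mdir.mkdir(exist_ok=True)
            for i, sid in enumerate(self.subject_ids):
                self.mask.save_map(mat[i], mdir / f"{sid}.nii.gz")
        if self.ground_truth is not None:
            self.ground_truth.to_json(directory / "ground_truth.json")

    @classmethod
    def load(cls, directory: str | Path) -> "CohortDataset":
        """Load a cohort written by :meth:`save` (metric dirs auto-discovered)."""
        directory = Path(directory)
        metric_names = sorted(
            p.name for p in directory.iterdir() if p.is_dir()
        )
        table = directory / "subjects.tsv"
        ids = pd.read_csv(table, sep="\t")["subject_id"].astype(str)
        volumes = {
            name: {
                sid: directory / name / f"{sid}.nii.gz" for sid in ids
            }
            for name in metric_names
        }
        ds = load_cohort(table, volumes, directory / "mask.nii.gz")
        gt = directory / "ground_truth.json"
        if gt.exists():
            ds.ground_truth = GroundTruth.from_json(gt)
        return ds


def load_cohort(
    subject_table: str | Path,
    metric_volumes: Mapping[str, Mapping[str, str | Path]],
    mask_path: str | Path,
) -> CohortDataset:
    """Assemble a :class:`CohortDataset` from files on disk.

    Parameters
    ----------
    subject_table : TSV with columns ``subject_id`` and ``group`` (A/B);
        extra covariate columns are carried along but ignored by computation.
    metric_volumes : metric name -> {subject_id -> NIfTI path}.
    mask_path : NIfTI skeleton mask.

    Missing values (NaN in any subject volume) are imputed with that voxel's
    across-subject mean for the metric; the imputation count is logged.
    """
    mask = SkeletonMask.from_nifti(mask_path)
    table = pd.read_csv(subject_table, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in table or "group" not in table:
        raise ValueError("subject table needs 'subject_id' and 'group' columns")
    ids = table["subject_id"].tolist()
    labels = table["group"].to_numpy(dtype=object)

    metrics: dict[str, np.ndarray] = {}
    total_imputed = 0
    for name, paths in metric_volumes.items():
        rows = []
        for sid in ids:
            img = nib.load(str(paths[sid]))
            vol = np.asanyarray(img.dataobj, dtype=float)
            if vol.shape != mask.grid_shape:
                raise ValueError(
                    f"volume for subject {sid}, metric {name} has grid "
                    f"{vol.shape}, mask grid is {mask.grid_shape}"
                )
            rows.append(mask.vectorize(vol))
        mat = np.vstack(rows)
        nan_mask = np.isnan(mat)
        n_nan = int(nan_mask.sum())
        if n_nan:
            col_mean = np.nanmean(mat, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            mat[nan_mask] = np.broadcast_to(col_mean, mat.shape)[nan_mask]
            total_imputed += n_nan
            logger.info("metric %s: imputed %d missing values", name, n_nan)
        metrics[name] = mat
    if total_imputed:
        logger.info("imputed %d missing values in total", total_imputed)
    return CohortDataset(
        metrics=metrics, labels=labels, subject_ids=ids, mask=mask
    )
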