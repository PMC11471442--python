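"""File formats: HDF5 cohort/stack interchange, TIFF ingestion, outcome CSVs.

The canonical on-disk layout for a synthetic cohort is an HDF5 hierarchy
``/patient_<id>/arm_<name>/well_<k>/burst_<j>`` holding the per-burst
``(n_pixels, n_samples)`` intensity arrays, with acquisition parameters and
burst times as root attributes and the truth grade / administered arm as
patient attributes. Hologram stacks travel as multi-page TIFF (ingestion)
or a flat HDF5 file. Outcome grades are a two-column CSV (``patient_id``,
``grade``) where grade tokens 2 and 3 pool into the single resistant class
on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .holography import HologramStack
from .synthetic import AcquisitionConfig, SyntheticCohort

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_hologram_stack",
    "read_hologram_stack",
    "write_outcomes",
    "read_outcomes",
]

_GRADE_POOL = {"0": "0", "1": "1", "2": "23", "3": "23", "23": "23"}


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, path: str | Path) -> None:
    """Write a synthetic cohort to the canonical HDF5 hierarchy."""
    with h5py.File(path, "w") as f:
        f.attrs["frame_rate_hz"] = cohort.acquisition.frame_rate_hz
        f.attrs["n_baseline_bursts"] = cohort.n_baseline_bursts
        f.attrs["seed"] = cohort.spec.seed if cohort.spec is not None else -1
        f.attrs["acquisition"] = json.dumps(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(cohort.acquisition).items()
            }
        )
        f.create_dataset("burst_times_hr", data=cohort.burst_times_hr)
        truth = {
            row["patient_id"]: (row["grade"], row["arm"])
            for _, row in cohort.grades.iterrows()
        }
        for (pid, arm), arr in cohort.series.items():
            grp = f.require_group(f"patient_{pid}")
            grade, administered = truth[pid]
            grp.attrs["grade"] = grade
            grp.attrs["administered_arm"] = administered
            agrp = grp.require_group(f"arm_{arm}")
            for wi in range(arr.shape[0]):
                wgrp = agrp.require_group(f"well_{wi}")
                for bi in range(arr.shape[1]):
                    wgrp.create_dataset(f"burst_{bi}", data=arr[wi, bi])


def read_cohort(path: str | Path) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort`."""
    series: dict[tuple[str, str], np.ndarray] = {}
    rows = []
    with h5py.File(path, "r") as f:
        acq = AcquisitionConfig(
            **{
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in json.loads(f.attrs["acquisition"]).items()
            }
        )
        times = np.asarray(f["burst_times_hr"])
        n_base = int(f.attrs["n_baseline_bursts"])
        for pkey in sorted(k for k in f.keys() if k.startswith("patient_")):
            pid = pkey.removeprefix("patient_")
            grp = f[pkey]
            rows.append(
                {
                    "patient_id": pid,
                    "grade": str(grp.attrs["grade"]),
                    "arm": str(grp.attrs["administered_arm"]),
                }
            )
            for akey in sorted(k for k in grp.keys() if k.startswith("arm_")):
                arm = akey.removeprefix("arm_")
                wells = sorted(
                    grp[akey].keys(), key=lambda s: int(s.removeprefix("well_"))
                )
                stack = []
                for wkey in wells:
                    bursts = sorted(
                        grp[akey][wkey].keys(),
                        key=lambda s: int(s.removeprefix("burst_")),
                    )
                    stack.append(
                        np.stack([np.asarray(grp[akey][wkey][b]) for b in bursts])
                    )
                series[(pid, arm)] = np.stack(stack)
    return SyntheticCohort(
        acquisition=acq,
        spec=None,
        phenotypes={},
        burst_times_hr=times,
        n_baseline_bursts=n_base,
        series=series,
        grades=pd.DataFrame(rows, columns=["patient_id", "grade", "arm"]),
    )


# ---------------------------------------------------------------------------
# hologram stacks
# ---------------------------------------------------------------------------


def write_hologram_stack(stack: HologramStack, path: str | Path, format: str = "hdf5") -> None:
    path = Path(path)
    if format == "tiff":
        tifffile.imwrite(path, stack.frames.astype(np.float32))
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=stack.frames)
            f.create_dataset("timestamps", data=stack.timestamps)
            f.attrs["pixel_pitch"] = stack.pixel_pitch
            if stack.carrier_hint is not None:
                f.attrs["carrier_hint"] = list(stack.carrier_hint)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_hologram_stack(path: str | Path, format: str | None = None) -> HologramStack:
    """Load a hologram stack from multi-page TIFF or the HDF5 layout."""
    path = Path(path)
    if format is None:
        format = "tiff" if path.suffix.lower() in (".tif", ".tiff") else "hdf5"
    if format == "tiff":
        try:
            frames = np.asarray(tifffile.imread(path), dtype=float)
        except Exception as exc:  # truncated / malformed container
            raise ValueError(f"cannot read TIFF stack {path}: {exc}") from exc
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3:
            raise ValueError(f"{path}: expected a stack of 2-D frames")
        return HologramStack(
            frames=frames, timestamps=np.arange(frames.shape[0], dtype=float)
        )
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            hint = f.attrs.get("carrier_hint")
            return HologramStack(
                frames=np.asarray(f["frames"]),
                timestamps=np.asarray(f["timestamps"]),
                pixel_pitch=float(f.attrs.get("pixel_pitch", 1.0)),
                carrier_hint=tuple(hint) if hint is not None else None,
            )
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------


def write_outcomes(grades: pd.DataFrame, path: str | Path) -> None:
    """Write the truth table (patient_id, grade[, arm]) as CSV."""
    grades.to_csv(path, index=False)


def read_outcomes(path: str | Path) -> pd.DataFrame:
    """Read and validate an outcome-grade CSV.

    Grade tokens 0/1/2/3/23 are accepted; 2 and 3 pool into '23'. Unknown
    tokens, duplicate patients, or an empty table are errors.
    """
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: outcome table is empty")
    required = {"patient_id", "grade"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate patient ids {sorted(set(dup))}")
    bad = [
        (i, g)
        for i, g in enumerate(df["grade"])
        if str(g).strip() not in _GRADE_POOL
    ]
    if bad:
        raise ValueError(f"{path}: unknown grade tokens at rows {bad}")
    df = df.copy()
    df["grade"] = [_GRADE_POOL[str(g).strip()] for g in df["grade"]]
    return df
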