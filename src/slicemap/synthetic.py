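"""Phantom cohorts: brain-like volumes plus an ADHD-200-dialect phenotype table.

The generator exists so every downstream stage — demographic filtering,
slab standardisation, feature extraction, activation maps, cross-validated
classification — is exercisable without downloading any real cohort. A
phantom is a single bright ellipsoidal "brain" over a dark background with
a smooth radial intensity gradient; diseased (class 1) subjects carry an
extra intensity perturbation in a fixed anterior subregion, echoing the
prefrontal involvement that motivates slice-based ADHD classification.
It makes no claim to anatomical realism: no tissue classes, no scanner or
site effects, no functional time series.

The phenotype CSV dialect is comma-separated with a header row and empty
fields for missing values, columns::

    Subject_ID, QC_Athena, QC_NIAK, DX, Age, Gender, Handedness,
    Full4_IQ, Secondary_DX

DX uses the 0-3 coding (0 typically developing; 1 combined, 2
hyperactive-impulsive, 3 inattentive). A configurable fraction of rows is
deliberately corrupted (both QC flags zero, out-of-range DX, or missing
IQ) so the demographic filters have something to reject.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["PhantomSpec", "make_phantom_volume", "make_cohort", "cohort_table",
           "perturbation_mask", "PHENOTYPE_COLUMNS"]

PHENOTYPE_COLUMNS = [
    "Subject_ID", "QC_Athena", "QC_NIAK", "DX", "Age", "Gender",
    "Handedness", "Full4_IQ", "Secondary_DX",
]

# affine that maps array axis 0 to the inferior-superior (S) direction so the
# slab standardiser slices axially, as an anatomical acquisition would
_AXIAL_AFFINE = np.array([
    [0.0, 1.0, 0.0, 0.0],
    [0.0, 0.0, 1.0, 0.0],
    [1.0, 0.0, 0.0, 0.0],
    [0.0, 0.0, 0.0, 1.0],
])

# normalised-coordinate geometry (volume spans [-1, 1] per axis)
_BRAIN_SEMI = (0.84, 0.80, 0.74)          # slice, anterior-posterior, left-right
_PERT_CENTER = (0.0, -0.45, 0.0)          # anterior = negative y
_PERT_SEMI = (0.28, 0.22, 0.28)
_EFFECT_GAIN = 0.05                       # intensity added per unit effect_size


@dataclass(frozen=True)
class PhantomSpec:
    """Cohort-level generation parameters.

    Defaults mirror an anatomical-T1 desk model of the study cohort: ~200
    axial slices at roughly 192-pixel in-plane matrices, paediatric age and
    IQ distributions, and a moderate class effect.
    """

    n_per_class: int = 30
    native_slices: int = 200
    in_plane: int = 192
    effect_size: float = 5.0
    noise_sd: float = 0.05
    covariate_effect: float = 1.0
    invalid_fraction: float = 0.0
    slice_jitter: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if self.native_slices < 1:
            raise ValueError(f"native_slices must be >= 1, got {self.native_slices}")
        if self.in_plane < 8:
            raise ValueError(f"in_plane must be >= 8, got {self.in_plane}")
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError(f"invalid_fraction must be in [0, 1], got {self.invalid_fraction}")


def _grid(n_slices: int, in_plane: int):
    z = np.linspace(-1.0, 1.0, n_slices)[:, None, None]
    y = np.linspace(-1.0, 1.0, in_plane)[None, :, None]
    x = np.linspace(-1.0, 1.0, in_plane)[None, None, :]
    return z, y, x


def perturbation_mask(spec: PhantomSpec, n_slices: int | None = None) -> np.ndarray:
    """Boolean mask of the anterior subregion carrying the class effect.

    Fixed in normalised coordinates, so it is identical for both classes
    and independent of the per-subject anatomy jitter.
    """
    n_slices = spec.native_slices if n_slices is None else n_slices
    z, y, x = _grid(n_slices, spec.in_plane)
    cz, cy, cx = _PERT_CENTER
    az, ay, ax = _PERT_SEMI
    return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0


def make_phantom_volume(class_label: int, spec: PhantomSpec, subject_seed: int,
                        n_slices: int | None = None,
                        out_path: str | Path | None = None) -> np.ndarray:
    """One phantom volume of shape ``(n_slices, in_plane, in_plane)``.

    Deterministic in ``(spec, subject_seed)``; the random stream never
    depends on ``class_label``, so zero ``effect_size`` makes the classes
    bit-identical. If ``out_path`` is given the volume is also written as
    a NIfTI-1 file whose affine marks axis 0 as inferior-superior.
    """
    if class_label not in (0, 1):
        raise ValueError(f"class_label must be 0 or 1, got {class_label!r}")
    n_slices = spec.native_slices if n_slices is None else int(n_slices)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_seed]))

    z, y, x = _grid(n_slices, spec.in_plane)
    jit = rng.uniform(0.97, 1.03, size=3)           # per-subject anatomy variation
    az, ay, ax = (s * j for s, j in zip(_BRAIN_SEMI, jit))
    r2 = (z / az) ** 2 + (y / ay) ** 2 + (x / ax) ** 2
    brain = r2 <= 1.0

    vol = np.zeros((n_slices, spec.in_plane, spec.in_plane))
    vol[brain] = 1.0 + 0.3 * (1.0 - r2[brain])      # brighter toward the core

    if class_label == 1 and spec.effect_size > 0:
        region = perturbation_mask(spec, n_slices) & brain
        vol[region] += _EFFECT_GAIN * spec.effect_size

    if spec.noise_sd > 0:
        vol[brain] += rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))
    np.clip(vol, 0.0, None, out=vol)
    vol = vol.astype(np.float32)

    if out_path is not None:
        nib.save(nib.Nifti1Image(vol, _AXIAL_AFFINE), str(out_path))
    return vol


_SECONDARY_DX_POOL = ["ODD", "LD", "Simple Phobia; ODD", "Learning Disorder", "Specific Phobia"]
_CORRUPTIONS = ("qc_both_zero", "dx_out_of_range", "iq_missing")


def cohort_table(spec: PhantomSpec) -> pd.DataFrame:
    """The cohort's phenotype table, before any file is written.

    Exactly ``n_per_class`` subjects per class before corruption. Native
    slice counts vary per subject over {native - jitter, native, native +
    jitter} so both the padding and the cropping branch of slab
    standardisation occur in one cohort. Class-1 covariates are shifted by
    ``covariate_effect`` (IQ down, age up). ``invalid_fraction`` of rows is
    corrupted in a round-robin over the three failure modes. Bookkeeping
    columns ``true_class``, ``subject_seed`` and ``native_slices`` ride
    along (they are not part of the CSV dialect).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 987654321]))

    n_total = 2 * spec.n_per_class
    rows = []
    for idx in range(n_total):
        cls = 0 if idx < spec.n_per_class else 1
        sid = f"S{idx + 1:04d}"
        native = int(max(4, spec.native_slices + int(rng.choice([-spec.slice_jitter, 0, spec.slice_jitter]))))
        subject_seed = int(rng.integers(2 ** 31))

        age = float(np.clip(rng.normal(12.0, 2.5), 7.0, 20.0))
        iq = float(np.clip(rng.normal(110.0, 12.0), 70.0, 160.0))
        if cls == 1:
            age += 1.0 * spec.covariate_effect
            iq -= 6.0 * spec.covariate_effect
        gender = int(rng.random() < 0.6)
        handedness = int(rng.choice([0, 1, 2], p=[0.10, 0.85, 0.05]))
        qc_a, qc_n = (1, 1) if rng.random() < 0.8 else ((0, 1) if rng.random() < 0.5 else (1, 0))
        dx = 0 if cls == 0 else int(rng.choice([1, 2, 3]))
        if cls == 1 and rng.random() < 0.35:
            secondary = str(rng.choice(_SECONDARY_DX_POOL))
        elif rng.random() < 0.05:
            secondary = "Specific Phobia"
        else:
            secondary = ""
        rows.append(dict(Subject_ID=sid, QC_Athena=qc_a, QC_NIAK=qc_n, DX=dx,
                         Age=round(age, 2), Gender=gender, Handedness=handedness,
                         Full4_IQ=round(iq, 1), Secondary_DX=secondary,
                         true_class=cls, subject_seed=subject_seed, native_slices=native))

    df = pd.DataFrame(rows)
    # shuffle row order so class blocks are not contiguous in the CSV
    df = df.iloc[rng.permutation(n_total)].reset_index(drop=True)

    n_bad = int(round(spec.invalid_fraction * n_total))
    bad_idx = rng.choice(n_total, size=n_bad, replace=False)
    for j, i in enumerate(sorted(bad_idx)):
        mode = _CORRUPTIONS[j % len(_CORRUPTIONS)]
        if mode == "qc_both_zero":
            df.loc[i, ["QC_Athena", "QC_NIAK"]] = 0
        elif mode == "dx_out_of_range":
            df.loc[i, "DX"] = 4
        else:
            df.loc[i, "Full4_IQ"] = np.nan
    return df


def make_cohort(spec: PhantomSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write one NIfTI per subject plus ``phenotype.csv``; return the table.

    The table is :func:`cohort_table`; the returned frame additionally
    carries ``nifti_path``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = cohort_table(spec)
    paths = []
    for _, row in df.iterrows():
        path = out_dir / f"{row.Subject_ID}.nii.gz"
        make_phantom_volume(int(row.true_class), spec, int(row.subject_seed),
                            n_slices=int(row.native_slices), out_path=path)
        paths.append(str(path))
    df["nifti_path"] = paths

    csv_cols = df[PHENOTYPE_COLUMNS].copy()
    csv_cols.to_csv(out_dir / "phenotype.csv", index=False, float_format="%g")
    return df
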