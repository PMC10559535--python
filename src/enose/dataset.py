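"""Cohort enumeration, instance building and patient-disjoint splitting.

The acquisition design multiplies each patient into many classifier
instances: 4 urine containers x 5 acquisitions per container x 32 sensor
channels = 640 instances per patient, and 800 acquisition files for the
full 40-patient cohort.  Splitting is done at the *patient* level so that
no patient's instances leak across the train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .calibration import DividerCircuit, SensorModel, load_sensor_models
from .curves import FEATURE_NAMES, FilterConfig, Provenance, featurize, read_acquisition

LABEL_HBP, LABEL_CAP = 0, 1

#: frozen feature-table schema: 32 features + label + provenance
TABLE_COLUMNS = list(FEATURE_NAMES) + ["label", "patient_id", "container", "acquisition", "socket"]


class DatasetError(ValueError):
    """Invalid dataset construction input."""


class ManifestEntry(NamedTuple):
    """One acquisition file slot in the cohort design."""

    path: Path
    patient_id: str
    label: int
    container: int
    acquisition: int


@dataclass(frozen=True)
class Instance:
    """One labeled feature vector with full provenance."""

    features: np.ndarray
    label: int
    patient_id: str
    container: int
    acquisition: int
    socket: int

    def __post_init__(self) -> None:
        if self.label not in (LABEL_HBP, LABEL_CAP):
            raise DatasetError(f"label must be 0 (HBP) or 1 (CaP), got {self.label}")


@dataclass(frozen=True)
class DatasetSplit:
    """Patient-disjoint train/test instance collections."""

    train: tuple[Instance, ...]
    test: tuple[Instance, ...]
    split_seed: int

    def __post_init__(self) -> None:
        train_pat = {i.patient_id for i in self.train}
        test_pat = {i.patient_id for i in self.test}
        if train_pat & test_pat:
            raise DatasetError(f"patient leakage across split: {train_pat & test_pat}")


def enumerate_cohort(
    root: str | Path,
    n_patients_per_class: int = 20,
    containers_per_patient: int = 4,
    acquisitions_per_container: int = 5,
) -> list[ManifestEntry]:
    """Enumerate the acquisition files of the redundancy design.

    Patient ids are ``H000..`` (benign hyperplasia, label 0) and ``C000..``
    (cancer, label 1); files live at
    ``root/<patient>/<patient>_c<container>_a<acquisition>.csv``.
    """
    if min(n_patients_per_class, containers_per_patient, acquisitions_per_container) < 1:
        raise DatasetError("all design counts must be >= 1")
    root = Path(root)
    manifest = []
    for label, prefix in ((LABEL_HBP, "H"), (LABEL_CAP, "C")):
        for p in range(n_patients_per_class):
            pid = f"{prefix}{p:03d}"
            for c in range(1, containers_per_patient + 1):
                for a in range(1, acquisitions_per_container + 1):
                    manifest.append(
                        ManifestEntry(
                            path=root / pid / f"{pid}_c{c}_a{a}.csv",
                            patient_id=pid,
                            label=label,
                            container=c,
                            acquisition=a,
                        )
                    )
    return manifest


def build_instances(
    manifest: Sequence[ManifestEntry],
    models: dict[str, SensorModel] | None = None,
    circuit: DividerCircuit = DividerCircuit(),
    filter_config: FilterConfig = FilterConfig(),
    on_error: str = "raise",
) -> list[Instance]:
    """Featurize every curve of every manifest file: one Instance per curve.

    ``on_error='skip'`` reports a malformed file (with its path) and keeps
    going; the default aborts on the first failure.
    """
    if on_error not in ("raise", "skip"):
        raise DatasetError("on_error must be 'raise' or 'skip'")
    models = models or load_sensor_models()
    instances: list[Instance] = []
    for entry in manifest:
        try:
            curves = read_acquisition(entry.path)
            for curve in curves:
                vec = featurize(curve, models[curve.model_id], circuit, filter_config)
                instances.append(
                    Instance(
                        features=vec,
                        label=entry.label,
                        patient_id=entry.patient_id,
                        container=entry.container,
                        acquisition=entry.acquisition,
                        socket=curve.socket_index,
                    )
                )
        except Exception as exc:
            if on_error == "raise":
                raise DatasetError(f"failed to process {entry.path}: {exc}") from exc
            import warnings

            warnings.warn(f"skipping {entry.path}: {exc}")
    return instances


def split_by_patient(
    instances: Sequence[Instance], n_per_class_per_side: int, seed: int
) -> DatasetSplit:
    """Seeded patient-level split, stratified by class.

    Draws ``n_per_class_per_side`` patients of each class into the training
    side and the same number (from the remaining patients) into the test
    side; every instance follows its patient.
    """
    by_class: dict[int, list[str]] = {LABEL_HBP: [], LABEL_CAP: []}
    seen = set()
    for inst in instances:
        if inst.patient_id not in seen:
            seen.add(inst.patient_id)
            by_class[inst.label].append(inst.patient_id)
    rng = np.random.default_rng(seed)
    train_pat: set[str] = set()
    test_pat: set[str] = set()
    for label, patients in by_class.items():
        if len(patients) < 2 * n_per_class_per_side:
            raise DatasetError(
                f"class {label}: need {2 * n_per_class_per_side} patients, have {len(patients)}"
            )
        order = rng.permutation(sorted(patients))
        train_pat.update(order[:n_per_class_per_side])
        test_pat.update(order[n_per_class_per_side : 2 * n_per_class_per_side])
    train = tuple(i for i in instances if i.patient_id in train_pat)
    test = tuple(i for i in instances if i.patient_id in test_pat)
    return DatasetSplit(train=train, test=test, split_seed=seed)


def instances_to_frame(instances: Sequence[Instance]) -> pd.DataFrame:
    """Feature table with the frozen column order."""
    rows = [
        list(i.features) + [i.label, i.patient_id, i.container, i.acquisition, i.socket]
        for i in instances
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def frame_to_instances(df: pd.DataFrame) -> list[Instance]:
    if list(df.columns) != TABLE_COLUMNS:
        raise DatasetError("feature table columns do not match the frozen schema")
    feats = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    return [
        Instance(
            features=feats[k],
            label=int(row.label),
            patient_id=str(row.patient_id),
            container=int(row.container),
            acquisition=int(row.acquisition),
            socket=int(row.socket),
        )
        for k, row in enumerate(df.itertuples(index=False))
    ]


def write_feature_table(instances: Sequence[Instance], path: str | Path) -> None:
    """Lossless CSV round trip of features, labels and provenance."""
    instances_to_frame(instances).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> list[Instance]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if df.empty and list(df.columns) == TABLE_COLUMNS:
        return []
    return frame_to_instances(df)


def features_labels(instances: Sequence[Instance]) -> tuple[np.ndarray, np.ndarray]:
    """Stack instances into (X, y) arrays for the classifier."""
    X = np.stack([i.features for i in instances])
    y = np.array([i.label for i in instances], dtype=int)
    return X, y
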