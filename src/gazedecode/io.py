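"""On-disk storage of :class:`~gazedecode.epochs.EpochSet` objects.

Layout: one HDF5 file per epoch set with datasets ``/data``, ``/times`` and
``/feature_labels``, plus a sidecar tab-delimited UTF-8 TSV (same path with a
``.tsv`` suffix) holding the trial table with a fixed column order and a
header row.  The round trip is bit-exact for the numeric arrays and exact for
all metadata.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .epochs import TRIAL_COLUMNS, EpochSet

__all__ = ["write_epochs", "read_epochs", "trials_tsv_path"]

_TRIAL_DTYPES = {
    "trial": np.int64,
    "stimulus_orientation_deg": float,
    "rotation_deg": float,
    "direction": str,
    "target_orientation_deg": float,
    "condition_label": str,
    "block": np.int64,
}


def trials_tsv_path(path) -> Path:
    """Sidecar TSV path for a given HDF5 path (``foo.h5`` -> ``foo.tsv``)."""
    p = Path(path)
    return p.with_suffix(".tsv") if p.suffix else p.parent / (p.name + ".tsv")


def write_epochs(epochs: EpochSet, path) -> None:
    """Write an epoch set to ``path`` (HDF5) and its sidecar TSV."""
    path = Path(path)
    try:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=epochs.data)
            f.create_dataset("times", data=epochs.times)
            f.create_dataset(
                "feature_labels",
                data=np.array(epochs.feature_labels, dtype=h5py.string_dtype("utf-8")),
            )
    except OSError as err:
        raise OSError(f"cannot write epoch container {path}: {err}") from err
    trials = epochs.trials.loc[:, TRIAL_COLUMNS].astype(
        {k: v for k, v in _TRIAL_DTYPES.items() if v is not str}
    )
    trials.to_csv(trials_tsv_path(path), sep="\t", index=False, encoding="utf-8")


def read_epochs(path) -> EpochSet:
    """Read an epoch set written by :func:`write_epochs`.

    Raises a ``ValueError`` naming the offending field when a file is missing
    or fails validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"epoch container not found: {path}")
    tsv = trials_tsv_path(path)
    if not tsv.exists():
        raise FileNotFoundError(f"trial-table sidecar not found: {tsv}")
    with h5py.File(path, "r") as f:
        for name in ("data", "times", "feature_labels"):
            if name not in f:
                raise ValueError(f"corrupt epoch container {path}: missing /{name}")
        data = f["data"][()]
        times = f["times"][()]
        labels = [s.decode("utf-8") if isinstance(s, bytes) else str(s)
                  for s in f["feature_labels"][()]]
    try:
        trials = pd.read_csv(tsv, sep="\t", dtype=_TRIAL_DTYPES)
    except (ValueError, pd.errors.ParserError) as err:
        raise ValueError(f"cannot parse trial table {tsv}: {err}") from err
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table {tsv} missing columns: {missing}")
    return EpochSet(data=data, times=times, feature_labels=labels, trials=trials)
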