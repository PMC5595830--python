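"""Array container with a JSON sidecar.

Every intermediate matrix of the pipeline (feature matrices, covariances,
transfer-entropy matrices, ...) is persisted as a plain ``.npy`` file next to
a ``.json`` sidecar that records column names, units and provenance metadata.
The pair round-trips bit-exactly, which the test-suite asserts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np

SIDE_CAR_SUFFIX = ".json"


def save_array(path: str | Path, array: np.ndarray, meta: dict[str, Any] | None = None) -> Path:
    """Write ``array`` to ``path`` (``.npy`` appended if absent) plus a JSON sidecar.

    ``meta`` must be JSON-serialisable; the array dtype and shape are recorded
    in the sidecar as well so the sidecar alone documents the artifact.
    """
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(path.suffix + ".npy")
    path.parent.mkdir(parents=True, exist_ok=True)
    array = np.asarray(array)
    np.save(path, array, allow_pickle=False)
    sidecar = {
        "dtype": str(array.dtype),
        "shape": list(array.shape),
        "meta": meta or {},
    }
    path.with_suffix(SIDE_CAR_SUFFIX).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def load_array(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    """Read an array written by :func:`save_array`; returns ``(array, meta)``."""
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(path.suffix + ".npy")
    array = np.load(path, allow_pickle=False)
    sidecar_path = path.with_suffix(SIDE_CAR_SUFFIX)
    meta: dict[str, Any] = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text()).get("meta", {})
    return array, meta
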