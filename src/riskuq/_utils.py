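"""Shared numeric and I/O helpers."""

from __future__ import annotations

import json
import os
import tempfile

import numpy as np
from scipy.special import expit as _expit
from scipy.special import logit as _logit

# expit(±ETA_MAX) is strictly inside (0, 1) in double precision.
ETA_MAX = 36.0


def safe_expit(eta):
    """Logistic function with the linear predictor clipped so the result is
    strictly inside (0, 1) in floating point."""
    return _expit(np.clip(eta, -ETA_MAX, ETA_MAX))


def logit(p):
    return _logit(p)


def spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return np.array([s.generate_state(1)[0] % (2**31 - 1) for s in ss.spawn(n)],
                    dtype=np.int64)


class NumpyJSONEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def atomic_write_text(path, text: str) -> None:
    """Write text to ``path`` via a temp file + rename so partial files never
    appear at the destination."""
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json_atomic(path, obj) -> None:
    atomic_write_text(path, json.dumps(obj, cls=NumpyJSONEncoder, indent=1))
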