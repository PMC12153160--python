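"""Deterministic file I/O helpers.

Checkpoints and embedding stores must be byte-identical across runs with the
same seed, so the ``.npz`` writer pins the zip timestamps that
``numpy.savez`` would otherwise take from the clock.  All outputs are
written atomically (temp file + rename).
"""

from __future__ import annotations

import hashlib
import io
import os
import tempfile
import zipfile
from pathlib import Path

import numpy as np

__all__ = ["savez_deterministic", "sha256_file", "atomic_write_text"]

_EPOCH = (1980, 1, 1, 0, 0, 0)


def savez_deterministic(path, arrays: dict[str, np.ndarray]) -> None:
    """Write an uncompressed ``.npz`` with fixed timestamps, atomically.

    The archive is loadable with ``numpy.load`` and its bytes depend only on
    the array names and contents.
    """
    path = Path(path)
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_STORED) as zf:
        for name in sorted(arrays):
            payload = io.BytesIO()
            np.lib.format.write_array(payload, np.asarray(arrays[name]),
                                      allow_pickle=False)
            info = zipfile.ZipInfo(name + ".npy", date_time=_EPOCH)
            zf.writestr(info, payload.getvalue())
    _atomic_write_bytes(path, buf.getvalue())


def _atomic_write_bytes(path: Path, data: bytes) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path, text: str) -> None:
    _atomic_write_bytes(Path(path), text.encode())


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
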