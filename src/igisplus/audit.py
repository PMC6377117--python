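"""Row-access instrumentation for leakage audits.

In a nested cross-validation the held-out outer fold must never influence
gene selection, discretization statistics or inner cross-validation.
:class:`RowAccessRecorder` is an ndarray proxy that records which sample
rows are explicitly indexed; running a selector on data backed by the
recorder and intersecting the touched rows with the held-out rows proves
(for that run) that selection never read a test row.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RowAccessRecorder", "record_row_access"]


class RowAccessRecorder(np.ndarray):
    """ndarray subclass that logs first-axis indices used in ``__getitem__``.

    The log is a shared set (``accessed_rows``) surviving views created by
    the indexing itself.
    """

    def __new__(cls, values: np.ndarray):
        obj = np.asarray(values).view(cls)
        obj.accessed_rows = set()
        return obj

    def __array_finalize__(self, obj):
        if obj is None:
            return
        self.accessed_rows = getattr(obj, "accessed_rows", set())

    def _log(self, key) -> None:
        row_key = key[0] if isinstance(key, tuple) else key
        if isinstance(row_key, (int, np.integer)):
            self.accessed_rows.add(int(row_key))
        elif isinstance(row_key, slice):
            self.accessed_rows.update(range(*row_key.indices(self.shape[0])))
        elif isinstance(row_key, (list, np.ndarray)):
            arr = np.asarray(row_key)
            if arr.dtype == bool:
                self.accessed_rows.update(np.flatnonzero(arr).tolist())
            else:
                self.accessed_rows.update(int(i) for i in arr.ravel())

    def __getitem__(self, key):
        self._log(key)
        return super().__getitem__(key)


def record_row_access(values: np.ndarray) -> RowAccessRecorder:
    """Wrap a matrix so every explicit row access is logged."""
    return RowAccessRecorder(values)
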