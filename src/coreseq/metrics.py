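"""Assembly contiguity metrics: N50 and expression-weighted ExN50."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import ParameterError


def n50(lengths) -> int:
    """Smallest length L such that transcripts of length >= L hold half the bases.

    Lengths are sorted descending and accumulated; the first transcript whose
    cumulative sum reaches at least half the total defines N50.
    """
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ParameterError("empty length list")
    if (arr <= 0).any():
        raise ParameterError("lengths must be positive")
    srt = np.sort(arr)[::-1]
    csum = np.cumsum(srt)
    idx = int(np.searchsorted(csum, csum[-1] / 2.0))
    return int(srt[idx])


def exn50(expression, lengths, ids=None) -> pd.DataFrame:
    """N50 restricted to the most-expressed transcripts at each expression share.

    Transcripts are ranked by normalized expression descending (ties broken
    by longer length, then id); for each Ex in 1..100 the minimal prefix
    whose expression reaches Ex% of the total defines the transcript set
    whose lengths are N50'd. Returns columns Ex, N50, n_transcripts.
    """
    expr = np.asarray(list(expression), dtype=float)
    lens = np.asarray(list(lengths), dtype=np.int64)
    if expr.shape != lens.shape:
        raise ParameterError("expression and length vectors differ in size")
    if (expr < 0).any():
        raise ParameterError("expression must be non-negative")
    total = expr.sum()
    if total <= 0:
        raise ParameterError("total expression is zero")
    if ids is None:
        ids = np.array([str(i) for i in range(len(expr))])
    else:
        ids = np.asarray([str(i) for i in ids])
    order = np.lexsort((ids, -lens, -expr))
    cum = np.cumsum(expr[order]) / total
    rows = []
    for ex in range(1, 101):
        k = int(np.searchsorted(cum, ex / 100.0 - 1e-12)) + 1
        k = min(k, len(expr))
        rows.append(dict(Ex=ex, N50=n50(lens[order][:k]), n_transcripts=k))
    return pd.DataFrame(rows)


__all__ = ["n50", "exn50"]
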