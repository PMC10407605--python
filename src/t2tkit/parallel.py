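"""Deterministic parallel map over independent work units.

Per-chromosome (or per-fragment) work may run concurrently, but results are
always collected in input order, so output is byte-identical to a serial run.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from typing import Callable, Sequence, TypeVar

T = TypeVar("T")
R = TypeVar("R")


def run_ordered(fn: Callable[[T], R], items: Sequence[T], threads: int = 1) -> list[R]:
    if threads <= 1 or len(items) <= 1:
        return [fn(x) for x in items]
    with ThreadPoolExecutor(max_workers=threads) as pool:
        return list(pool.map(fn, items))
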