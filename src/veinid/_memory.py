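"""Allocator hygiene for large-array training loops.

A training step allocates and frees hundreds of multi-megabyte arrays.
With glibc's default thresholds each of those is a fresh ``mmap`` that
must be page-faulted in and unmapped again, which can dominate the run
time.  ``tune_allocator`` raises the mmap threshold so large blocks are
served from (and returned to) the reusable heap, and ``trim`` gives
accumulated free pages back to the OS between epochs so fragmentation
cannot grow without bound.  Both are no-ops on non-glibc platforms.
"""

from __future__ import annotations

import ctypes

_M_MMAP_THRESHOLD = -3
_M_TRIM_THRESHOLD = -1

try:  # pragma: no cover - platform specific
    _libc = ctypes.CDLL("libc.so.6", use_errno=True)
except OSError:  # pragma: no cover
    _libc = None


def tune_allocator(mmap_threshold: int = 512 * 1024 * 1024,
                   trim_threshold: int = 64 * 1024 * 1024) -> bool:
    if _libc is None:
        return False
    try:
        _libc.mallopt(_M_MMAP_THRESHOLD, mmap_threshold)
        _libc.mallopt(_M_TRIM_THRESHOLD, trim_threshold)
        return True
    except Exception:  # pragma: no cover
        return False


def trim() -> None:
    if _libc is not None:
        try:
            _libc.malloc_trim(0)
        except Exception:  # pragma: no cover
            pass
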