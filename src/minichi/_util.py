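"""Small internal helpers."""

from __future__ import annotations

import sys
from contextlib import contextmanager


def _current_depth() -> int:
    depth = 0
    frame = sys._getframe()
    while frame is not None:
        depth += 1
        frame = frame.f_back
    return depth


@contextmanager
def recursion_headroom(frames: int):
    """Temporarily raise the recursion limit; graphs near the 1000-atom
    limit need deeper stacks than CPython's default."""
    old = sys.getrecursionlimit()
    needed = frames + _current_depth() + 50
    if needed > old:
        sys.setrecursionlimit(needed)
    try:
        yield
    finally:
        sys.setrecursionlimit(old)
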