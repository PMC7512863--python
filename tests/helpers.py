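"""Shared test utilities."""

import numpy as np


class ScriptedRng:
    """Deterministic stand-in for a Generator: replays scripted draws.

    ``uniforms`` feed ``random``; ``normals`` feed ``standard_normal``.
    Each sequence cycles if exhausted.
    """

    def __init__(self, uniforms=(0.5,), normals=(0.0,)):
        self._u = list(uniforms)
        self._n = list(normals)
        self._ui = 0
        self._ni = 0

    def _take(self, seq, idx_attr, size):
        out = []
        i = getattr(self, idx_attr)
        for _ in range(size if size is not None else 1):
            out.append(seq[i % len(seq)])
            i += 1
        setattr(self, idx_attr, i)
        if size is None:
            return out[0]
        return np.asarray(out)

    def random(self, size=None):
        return self._take(self._u, "_ui", size)

    def standard_normal(self, size=None):
        return self._take(self._n, "_ni", size)
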