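"""Small helpers shared between test modules (kept import-light)."""
import numpy as np

from cartimech.meshes import structured_hex_grid


class _Flat:
    def __init__(self, height, n_layers):
        self.height = height
        self.n_layers = n_layers

    def __call__(self, X, Y, k):
        return np.full_like(np.asarray(X, dtype=float), self.height * k / self.n_layers)


def flat_box_mesh(nx=4, ny=3, nz=2, lx=2.0, ly=1.5, lz=1.0):
    return structured_hex_grid(
        np.linspace(0.0, lx, nx + 1), np.linspace(0.0, ly, ny + 1), _Flat(lz, nz)
    )
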