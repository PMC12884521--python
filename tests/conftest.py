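import numpy as np
import pytest

from pocketconf.structure_io import Atom, MolecularStructure


def structure_from(symbols, coords, **kwargs):
    return MolecularStructure(
        atoms=[
            Atom(element=s, coords=np.asarray(c, dtype=float), **kwargs)
            for s, c in zip(symbols, coords)
        ]
    )


def snap_to_grid(angles, step=90.0):
    return tuple(round((a % 360.0) / step) % int(360 / step) * step for a in angles)


@pytest.fixture
def water_like():
    return structure_from(["O", "H"], [(0.0, 0.0, 0.0), (0.96, 0.0, 0.0)])
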