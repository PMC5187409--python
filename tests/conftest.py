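import numpy as np
import pandas as pd
import pytest

from mitodyn.screen import Library


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_library(rng):
    """Six genes x four shRNAs with unique random 21-mers."""
    rows = []
    seen = set()
    for g in range(6):
        for s in range(4):
            while True:
                seq = "".join(rng.choice(list("ACGT"), size=21))
                if seq not in seen:
                    seen.add(seq)
                    break
            rows.append((f"sh{g}_{s}", f"GENE{g}", seq))
    return Library(pd.DataFrame(rows, columns=["shrna_id", "gene", "sequence21"]))


def gaussian_blob(shape, x0, y0, sx, sy, peak):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return peak * np.exp(-0.5 * (((xx - x0) / sx) ** 2 + ((yy - y0) / sy) ** 2))
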