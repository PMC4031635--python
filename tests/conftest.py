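from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from locusscan.core import CohortSheet, GenotypeMatrix, VariantRecord


def make_matrix(calls, mafs=None, seed_pos=231_656_716, class_flags=None):
    """GenotypeMatrix from an integer calls array (-1 = missing); MAFs
    recomputed from the calls unless given explicitly."""
    calls = np.asarray(calls, dtype=np.int8)
    n, v = calls.shape
    variants = []
    for j in range(v):
        rec = VariantRecord("chr1", seed_pos + 1000 * j, "A", "G", site_quality=60.0)
        if class_flags is not None:
            rec.class_flags.update(class_flags[j])
        variants.append(rec)
    m = GenotypeMatrix([f"S{i}" for i in range(n)], variants, calls)
    if mafs is None:
        m.recompute_maf()
    else:
        for rec, maf in zip(m.variants, mafs):
            rec.maf, rec.minor_is_alt = maf, True
    return m


def make_sheet(groups, ages=None, sexes=None, traits=None):
    n = len(groups)
    frame = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "group": groups,
            "age": ages if ages is not None else np.full(n, 70.0),
            "sex": sexes if sexes is not None else ["M", "F"] * (n // 2) + ["M"] * (n % 2),
        }
    )
    if traits:
        for name, vals in traits.items():
            frame[name] = vals
    return CohortSheet(frame)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cc():
    """Tiny deterministic case-control dataset: 6 samples x 3 variants."""
    calls = np.array(
        [
            [0, 1, 2],
            [1, 0, 2],
            [2, 0, 2],
            [0, 0, 2],
            [0, 1, 2],
            [1, 0, 2],
        ]
    )
    m = make_matrix(calls)
    sheet = make_sheet(["SZ", "SZ", "SZ", "control", "control", "control"])
    return m, sheet
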