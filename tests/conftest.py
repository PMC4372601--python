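from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirsig import (
    ExpressionMatrix,
    build_expression_matrix,
    normalize_scan,
    simulate_cohort,
)
from mirsig.synthetic import SimulationConfig

# Published microarray group averages (normalized scale) for the eight
# qPCR-assayed miRNAs: (control mean, FM mean, printed control/FM ratio).
TABLE_ROWS: dict[str, tuple[float, float, float]] = {
    "hsa-miR-223-3p": (66736.98, 10577.74, 6.31),
    "hsa-miR-451a": (4830.07, 358.62, 13.47),
    "hsa-miR-338-3p": (374.20, 32.22, 11.62),
    "hsa-miR-143-3p": (506.26, 45.42, 11.15),
    "hsa-miR-145-5p": (546.05, 52.58, 10.39),
    "hsa-miR-21-5p": (5470.04, 1409.50, 3.88),
    "hsa-miR-1908-5p": (762.60, 660.45, 1.15),
    "hsa-miR-1260b": (23676.19, 17356.79, 1.36),
}

SIGNATURE_IDS = [
    "hsa-miR-451a",
    "hsa-miR-338-3p",
    "hsa-miR-143-3p",
    "hsa-miR-145-5p",
    "hsa-miR-223-3p",
]


@pytest.fixture(scope="session")
def table_matrix() -> ExpressionMatrix:
    """The published group means as a two-sample matrix (one per group)."""
    values = pd.DataFrame(
        {
            "C_mean": {m: c for m, (c, _f, _r) in TABLE_ROWS.items()},
            "FM_mean": {m: f for m, (_c, f, _r) in TABLE_ROWS.items()},
        }
    )
    return ExpressionMatrix(values, {"C_mean": "control", "FM_mean": "FM"})


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_matrix(default_cohort) -> ExpressionMatrix:
    profiles = [normalize_scan(s) for s in default_cohort.scans]
    return build_expression_matrix(profiles, default_cohort.sample_sheet.groups)


def random_scan_frame(rng: np.random.Generator, n_probes: int, n_blanks: int):
    """A small random scan as (blanks, probe_ids, intensities) arrays."""
    blanks = rng.lognormal(np.log(10.0), 0.3, n_blanks)
    ids = [f"m{i:03d}" for i in range(n_probes)]
    # span both sides of the detection threshold
    intensities = rng.lognormal(np.log(25.0), 1.0, n_probes)
    return blanks, ids, intensities
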