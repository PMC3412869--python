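"""Shared fixtures. Expensive whole-cell runs are session-scoped and reused
across the unit and acceptance tests; pre-pacing lengths are reduced from
the production 1000 beats (convergence flags are carried along)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mouseap import cell, metrics
from mouseap.drugs import DrugSpec

QUAL_BCLS = (80.0, 100.0, 200.0, 300.0, 500.0, 1000.0, 2000.0, 3000.0)


def beats_for(bcl: float) -> int:
    """Reduced pre-pacing: more beats at fast rates where memory is long."""
    return int(max(30, min(120, 60000 / bcl)))


@pytest.fixture(scope="session")
def endo_1hz():
    return cell.run_to_steady_pacing("endocardial", bcl=1000.0, n_beats=40)


@pytest.fixture(scope="session")
def epi_1hz():
    return cell.run_to_steady_pacing("epicardial", bcl=1000.0, n_beats=40)


@pytest.fixture(scope="session")
def endo_1hz_full_block():
    return cell.run_to_steady_pacing(
        "endocardial", bcl=1000.0, n_beats=40, conductance_overrides={"GKtof": 0.0}
    )


@pytest.fixture(scope="session")
def epi_1hz_full_block():
    return cell.run_to_steady_pacing(
        "epicardial", bcl=1000.0, n_beats=40, conductance_overrides={"GKtof": 0.0}
    )


def _scan(variant, drug):
    rows = []
    for bcl in QUAL_BCLS:
        res = cell.run_to_steady_pacing(
            variant, bcl=bcl, n_beats=beats_for(bcl), drug=drug
        )
        aset = metrics.apd_set(res.trace)
        rows.append({
            "BCL_ms": bcl, "apd30": aset.apd30, "apd50": aset.apd50,
            "apd75": aset.apd75, "apd90": aset.apd90,
        })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def bcl_scan_control():
    return _scan("endocardial", None)


@pytest.fixture(scope="session")
def bcl_scan_control_epi():
    return _scan("epicardial", None)


@pytest.fixture(scope="session")
def bcl_scan_drug_c_1mm():
    return _scan("endocardial", DrugSpec.drug_c(1.0))


@pytest.fixture(scope="session")
def bcl_scan_drug_o_01mm_epi():
    return _scan("epicardial", DrugSpec.drug_o(0.1))
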