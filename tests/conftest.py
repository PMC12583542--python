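import numpy as np
import pandas as pd
import pytest

import cellniche as cn
from cellniche.markers import MARKERS


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny deterministic cohort shared by read-only tests."""
    config = cn.SimulationConfig(n_patients_per_center_per_subtype=2, seed=11)
    return cn.generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_spot_cells(rng, n=300, extent=500.0, marker_p=0.3):
    """A random spot: uniform coordinates, iid marker calls."""
    cells = pd.DataFrame(rng.uniform(-extent, extent, (n, 2)), columns=["x_um", "y_um"])
    for m in MARKERS:
        cells[m] = (rng.uniform(size=n) < marker_p).astype(int)
    cells["compartment"] = "carcinoma"
    cells["spot_id"] = "S0"
    cells["patient_id"] = "P0"
    return cells


def make_survival_spot_rows(
    n_patients,
    betas,
    seed=0,
    n_niches=3,
    spots_per_patient=4,
    censoring_rate=0.3,
    spot_noise=0.03,
):
    """Spot-row table with proportional-hazards outcomes on niche proportions.

    ``betas`` has length n_niches + 1 (stage last). Patient-level niche
    proportions are Dirichlet(1,...,1); each spot jitters them slightly, so
    the multiple-instance structure (spots share their patient's outcome)
    is preserved.
    """
    betas = np.asarray(betas, dtype=float)
    assert betas.shape == (n_niches + 1,)
    config = cn.SimulationConfig(
        planted_prototypes=cn.default_prototypes()[:1] * n_niches,
        patient_archetypes=[np.full(n_niches, 1.0 / n_niches)],
        hazard_betas=betas,
        censoring_rate=censoring_rate,
        seed=seed,
    )
    master = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        pid = f"P{i:04d}"
        uicc8 = int(master.choice([1, 2, 3], p=[0.45, 0.35, 0.2]))
        props = master.dirichlet(np.ones(n_niches))
        z = np.append(props, float(uicc8))
        os_months, event = cn.generate_survival(z, config, int(master.integers(2**31)))
        for s in range(spots_per_patient):
            p = np.clip(props + master.normal(0, spot_noise, n_niches), 1e-6, None)
            p /= p.sum()
            rows.append(
                dict(
                    patient_id=pid,
                    spot_id=f"S{i:04d}_{s}",
                    os_months=os_months,
                    event=event,
                    uicc8=uicc8,
                    **{f"niche_{j + 1}": p[j] for j in range(n_niches)},
                )
            )
    return pd.DataFrame(rows)
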