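import numpy as np
import pytest

import d50tracts as d
import d50tracts.pipeline as pl
import d50tracts.progression as prog
import d50tracts.simulate as sim


@pytest.fixture(scope="session")
def benchmark():
    """Seeded benchmark study: 40 patients + 40 controls, 32x32x12 grid,
    planted group FA decrease (cst_like) and aggressiveness-linked AD
    elevation (frontal_assoc)."""
    spec = d.CohortSpec(n_patients=40, n_controls=40, seed=11)
    records, truth = sim.simulate_trajectories(spec)
    fits = prog.fit_cohort(records)
    covariates = pl.cohort_covariates(records, fits)
    geometry = sim.make_skeleton_mask((32, 32, 12))
    effects = sim.default_benchmark_effects()
    datasets = sim.simulate_metric_datasets(covariates, effects, geometry, seed=12)
    return {
        "records": records,
        "truth": truth,
        "fits": fits,
        "covariates": covariates,
        "geometry": geometry,
        "effects": effects,
        "datasets": datasets,
    }


@pytest.fixture()
def small_cohort():
    """Five noiseless patients on known curves plus degenerate cases."""
    records = []
    params = [(20.0, 8.0), (30.0, 12.0), (45.0, 18.0), (60.0, 25.0), (15.0, 6.0)]
    for i, (d50, dx) in enumerate(params):
        times = np.linspace(3, 1.4 * d50, 6)
        scores = np.clip(np.rint(d.cfs_curve(times, d50, dx)), 0, 48).astype(int)
        records.append(
            prog.PatientRecord(
                id=f"p{i}",
                age_at_mri=60.0 + i,
                sex="male" if i % 2 else "female",
                onset_type="limb" if i < 4 else "bulbar",
                mri_t_months=0.6 * d50,
                observations=[
                    prog.AlsfrsObservation(t_months=float(t), score=int(s))
                    for t, s in zip(times, scores)
                ],
            )
        )
    return records, params
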