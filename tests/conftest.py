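import numpy as np
import pytest

from radpk import (
    CONTROL_PARAMS,
    RADIATION_RATIOS,
    DoseEvent,
    ObservationRecord,
    dose_to_umol,
    solve,
)


@pytest.fixture(scope="session")
def control():
    return CONTROL_PARAMS


@pytest.fixture(scope="session")
def ratios():
    return RADIATION_RATIOS


@pytest.fixture(scope="session")
def gavage_300():
    return DoseEvent(amount=dose_to_umol(300.0), route="gavage")


@pytest.fixture(scope="session")
def iv_60():
    return DoseEvent(amount=dose_to_umol(60.0), route="iv")


@pytest.fixture(scope="session")
def two_animal_toy(control):
    """Two animals with near-noiseless observations at the model solution.

    Values are the exact model outputs scaled by small fixed factors, so the
    conditional eta posteriors are sharp and nearly Gaussian.
    """
    recs = []
    for aid, route, dose, times in [
        ("a1", "gavage", 300.0, [1.0, 2.0, 4.0, 8.0]),
        ("a2", "iv", 60.0, [5 / 60, 1.5, 24.0]),
    ]:
        d = DoseEvent(dose_to_umol(dose), route)
        traj = solve(control, d, times)
        for t, c in zip(times, traj.conc_plasma):
            recs.append(
                ObservationRecord(aid, "control", route, dose, t, "plasma", c * 1.02)
            )
        tr24 = solve(control, d, [24.0])
        recs.append(
            ObservationRecord(
                aid, "control", route, dose, 24.0, "urine", float(tr24.urine[0]) * 0.97
            )
        )
    return recs


def random_pk_parameters(rng: np.random.Generator):
    """A plausible random parameter set spanning a few orders of magnitude."""
    from radpk import PKParameters

    return PKParameters(
        ka=float(10 ** rng.uniform(-1.5, 0.7)),
        F=float(rng.uniform(0.05, 0.95)),
        Cl=float(10 ** rng.uniform(-3, -0.5)),
        Q=float(10 ** rng.uniform(-3, -0.5)),
        V2=float(10 ** rng.uniform(-2.5, -0.5)),
        V3=float(10 ** rng.uniform(-1.5, 0.5)),
    )
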