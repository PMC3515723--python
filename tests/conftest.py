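import numpy as np
import pandas as pd
import pytest

from petconn import roi_signals as roi
from petconn import synthetic as syn


def tiny_regions():
    return [
        syn.RegionSpec("A", (0.0, 16.0, 0.0), 8.0),
        syn.RegionSpec("B", (-16.0, -8.0, -4.0), 8.0),
        syn.RegionSpec("C", (16.0, -8.0, -4.0), 8.0),
    ]


def tiny_config(**overrides) -> syn.SyntheticConfig:
    """Desk-scale config: 16^3 grid at 4 mm, three spherical regions."""
    kwargs = dict(
        grid_shape=(16, 16, 16),
        voxel_size_mm=4.0,
        regions=tiny_regions(),
        brain_center_mm=(0.0, 2.0, -2.0),
        brain_semiaxes_mm=(30.0, 30.0, 28.0),
        session_edge_corr={
            "baseline": np.array([[1.0, 0.3, 0.4], [0.3, 1.0, 0.7], [0.4, 0.7, 1.0]]),
            "week1": np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.7], [0.3, 0.7, 1.0]]),
        },
        sessions=("baseline", "week1"),
        conditions=("rest", "task"),
        replicates_per_condition=2,
        n_participants=8,
        noise_sd=0.3,
        global_sd=1.0,
        response_edge=("A", "B"),
        response_session="baseline",
        seed=11,
    )
    kwargs.update(overrides)
    if "regions" in overrides and "session_edge_corr" not in overrides:
        k = len(kwargs["regions"])
        kwargs["session_edge_corr"] = {s: np.eye(k) for s in kwargs["sessions"]}
    if "regions" in overrides and "response_edge" not in overrides:
        names = [r.name for r in kwargs["regions"]]
        kwargs["response_edge"] = (names[0], names[-1])
    return syn.SyntheticConfig(**kwargs)


def single_session_config(n_participants=50, rho=0.6, **overrides) -> syn.SyntheticConfig:
    """One scan per participant, one session, for estimator-level checks."""
    kwargs = dict(
        sessions=("s",),
        conditions=("rest",),
        replicates_per_condition=1,
        session_edge_corr={
            "s": np.array([[1.0, rho, 0.0], [rho, 1.0, 0.0], [0.0, 0.0, 1.0]])
        },
        response_session="s",
        n_participants=n_participants,
    )
    kwargs.update(overrides)
    return tiny_config(**kwargs)


@pytest.fixture(scope="session")
def tiny_cohort():
    return syn.generate_cohort(tiny_config())


@pytest.fixture(scope="session")
def tiny_tables(tiny_cohort):
    """(combined table, per-condition table, masks) from the tiny cohort."""
    c = tiny_cohort
    roi_masks, brain = c.masks[:-1], c.masks[-1]
    comb = pd.concat(
        [
            roi.eigenvariate_table(s, roi_masks, brain)
            for s in roi.stack_scans(c.manifest, c.volumes, "session_combined").values()
        ],
        ignore_index=True,
    )
    cond = pd.concat(
        [
            roi.eigenvariate_table(s, roi_masks, brain)
            for s in roi.stack_scans(c.manifest, c.volumes, "session_condition").values()
        ],
        ignore_index=True,
    )
    return comb, cond, c.masks


def random_stack(rng, n_units=6, grid=(5, 5, 4), sessions=("s",)) -> roi.Stack:
    units = pd.DataFrame(
        dict(
            participant=[f"p{i}" for i in range(n_units)],
            session=[sessions[0]] * n_units,
            condition=["rest"] * n_units,
        )
    )
    return roi.Stack(
        data=rng.normal(size=(n_units, *grid)), units=units, affine=np.eye(4)
    )
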