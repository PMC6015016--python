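import pytest
from hypothesis import HealthCheck, settings

from glucocest.zspec import OffsetSchedule, Pool, PoolParams, ZSpectrum, zmodel

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule() -> OffsetSchedule:
    return OffsetSchedule.steady_state()


@pytest.fixture(scope="session")
def default_pools() -> PoolParams:
    """The phantom's baseline five-pool truth."""
    return PoolParams(
        water=Pool(0.85, 1.4, 0.0),
        noe=Pool(0.10, 3.5, -3.5),
        amine=Pool(0.03, 1.5, 2.0),
        amide=Pool(0.05, 1.5, 3.5),
        hydroxyl=Pool(0.02, 1.0, 1.2),
    )


def draw_admissible_pools(rng) -> tuple[PoolParams, float]:
    """A physically admissible random parameter set.

    Solute/rNOE centres ride on the water (B0) shift, as chemical shifts are
    relative to water; widths and amplitudes span literature-plausible
    ranges at 7 T.
    """
    b0 = rng.uniform(-0.3, 0.3)
    pools = PoolParams(
        water=Pool(rng.uniform(0.6, 0.9), rng.uniform(1.0, 2.0), b0),
        noe=Pool(rng.uniform(0.02, 0.15), rng.uniform(2.0, 5.0),
                 b0 - 3.5 + rng.uniform(-0.3, 0.3)),
        amine=Pool(rng.uniform(0.005, 0.06), rng.uniform(1.0, 2.5),
                   b0 + 2.0 + rng.uniform(-0.3, 0.3)),
        amide=Pool(rng.uniform(0.005, 0.08), rng.uniform(1.0, 2.5),
                   b0 + 3.5 + rng.uniform(-0.3, 0.3)),
        hydroxyl=Pool(rng.uniform(0.005, 0.05), rng.uniform(0.7, 1.5),
                      b0 + 1.2 + rng.uniform(-0.3, 0.3)),
    )
    return pools, rng.uniform(0.0, 0.15)


def simulate_zspectrum(schedule, pools, mt, noise_sd=0.0, rng=None,
                       timepoint_s=0.0) -> ZSpectrum:
    """Forward-simulate one Z-spectrum (normalisation frame pinned to 1)."""
    import warnings

    from glucocest.errors import NegativeSignalWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NegativeSignalWarning)
        z = zmodel(schedule.offsets, pools, mt)
    z[schedule.s0_index] = 1.0
    if noise_sd:
        z = z + rng.normal(0.0, noise_sd, z.shape)
        z /= z[schedule.s0_index]
    return ZSpectrum(schedule, z, timepoint_s=timepoint_s)
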